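"""Patient-cohort statistics: qPCR quantification, association tests, survival.

This layer mirrors a standard clinicopathological workup of a paired
tumor/normal cohort assayed by qRT-PCR:

* relative expression by the 2^-ddCt method;
* paired and independent t-tests on expression;
* median dichotomization into low/high expressors (ties go to low);
* Pearson chi-square contingency associations between the low/high
  label and categorical covariates (no continuity correction by
  default — the convention under which the standard clinical-table
  p-values are exactly reproducible);
* Kaplan-Meier curves with a two-group log-rank test;
* Pearson expression-expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "QPCRRecord",
    "ContingencyResult",
    "CLINICAL_COLUMNS",
    "read_clinical_table",
    "write_clinical_table",
    "ddct_fold_change",
    "paired_expression_test",
    "group_comparison_test",
    "dichotomize_by_median",
    "contingency_association",
    "association_table",
    "km_logrank",
    "pearson_correlation",
]

#: documented header of a clinical TSV
CLINICAL_COLUMNS = [
    "patient_id", "tumor_expr", "normal_expr", "T_stage", "N_stage",
    "clinical_stage", "sex", "age", "smoking", "alcohol", "location",
    "os_time", "os_event",
]


@dataclass(frozen=True)
class QPCRRecord:
    """One sample's raw Ct values for a target and a reference gene."""

    sample_id: str
    ct_target: float
    ct_reference: float
    reference_gene: str = "ACTB"

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be positive and finite, got {ct}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p_value: float


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    missing = set(CLINICAL_COLUMNS) - set(clin.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (clin["os_time"] < 0).any():
        raise ValueError("os_time must be non-negative")
    if ((clin["tumor_expr"] <= 0) | (clin["normal_expr"] <= 0)).any():
        raise ValueError("paired expression values must be positive")
    return clin


def write_clinical_table(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False, columns=CLINICAL_COLUMNS)


def ddct_fold_change(sample: QPCRRecord, calibrator: QPCRRecord) -> float:
    """Relative expression 2^-ddCt of ``sample`` versus ``calibrator``.

    ddCt = (Ct_target - Ct_reference)_sample
         - (Ct_target - Ct_reference)_calibrator.
    Equal delta-Cts give 1.0 by construction, and the result is
    invariant to any Ct shift applied to both samples' target Cts.
    """
    return float(2.0 ** -(sample.delta_ct - calibrator.delta_ct))


def paired_expression_test(
    tumor: Sequence[float], normal: Sequence[float]
) -> tuple[float, int, float]:
    """Classical paired t-test on per-patient differences.

    Returns (t, df, two-sided p) with df = n - 1. Zero-variance
    differences are handled explicitly: all-zero -> (0, df, 1);
    constant nonzero -> (signed inf, df, 0).
    """
    t_arr = np.asarray(tumor, dtype=float)
    n_arr = np.asarray(normal, dtype=float)
    if t_arr.shape != n_arr.shape or t_arr.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    diff = t_arr - n_arr
    df = diff.size - 1
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff[0]) * np.inf), df, 0.0
    t, p = stats.ttest_rel(t_arr, n_arr)
    return float(t), df, float(p)


def group_comparison_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def dichotomize_by_median(values: Sequence[float]) -> pd.Series:
    """Label each value 'low' (<= median) or 'high' (> median).

    Ties at the median go to the low group; with an even count of
    distinct values this yields an exact half/half split.
    """
    v = pd.Series(values, dtype=float)
    if v.empty:
        raise ValueError("cannot dichotomize an empty vector")
    median = v.median()
    return pd.Series(np.where(v <= median, "low", "high"), index=v.index, name="expr_group")


def contingency_association(
    labels: Sequence[str],
    covariate: Sequence[str],
    correction: str = "none",
) -> ContingencyResult:
    """Cross-tabulate covariate levels against low/high labels and test.

    ``correction`` selects the 2x2 treatment: "none" (Pearson
    chi-square, the default), "yates" (continuity-corrected), or
    "fisher" (exact test; chi2 reported as NaN).
    """
    table = pd.crosstab(pd.Series(covariate, name="covariate"),
                        pd.Series(labels, name="label"))
    counts = table.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 levels on each axis")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("structural zero margin in contingency table")
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if correction == "fisher":
        if counts.shape != (2, 2):
            raise ValueError("Fisher exact test implemented for 2x2 only")
        _, p = stats.fisher_exact(counts)
        return ContingencyResult(counts, np.nan, df, float(p))
    chi2, p, df_, _ = stats.chi2_contingency(counts, correction=(correction == "yates"))
    return ContingencyResult(counts, float(chi2), int(df_), float(p))


# covariate -> (column, level dichotomization) for a standard clinical report
_DEFAULT_COVARIATES: dict[str, tuple[str, callable]] = {
    "gender": ("sex", None),
    "age": ("age", lambda a: np.where(a <= np.median(a), "<=median", ">median")),
    "t_stage": ("T_stage", lambda s: np.where(np.isin(s, ["T1", "T2"]), "T1+T2", "T3+T4")),
    "clinical_stage": ("clinical_stage", lambda s: np.where(np.isin(s, ["I", "II"]), "I-II", "III-IV")),
    "lymph_node": ("N_stage", lambda s: np.where(s == "N0", "negative", "positive")),
    "alcohol": ("alcohol", None),
    "smoking": ("smoking", None),
    "location": ("location", None),
}


def association_table(
    clin: pd.DataFrame,
    expr_col: str = "tumor_expr",
    correction: str = "none",
) -> pd.DataFrame:
    """Full low/high association report over the standard covariates.

    Dichotomizes ``expr_col`` at its median, cross-tabulates every
    covariate, and returns one row per covariate level with counts,
    within-level percentages, and the covariate-wise chi-square
    statistic, df and p-value.
    """
    labels = dichotomize_by_median(clin[expr_col].to_numpy())
    rows = []
    for name, (col, leveller) in _DEFAULT_COVARIATES.items():
        values = clin[col].to_numpy()
        levels = pd.Series(values if leveller is None else leveller(values), name=name)
        result = contingency_association(labels, levels, correction=correction)
        tab = pd.crosstab(levels, labels)
        for level in tab.index:
            n_low = int(tab.loc[level].get("low", 0))
            n_high = int(tab.loc[level].get("high", 0))
            total = n_low + n_high
            rows.append(
                {
                    "covariate": name,
                    "level": level,
                    "n": total,
                    "pct_of_cohort": round(100.0 * total / len(clin), 1),
                    "n_low": n_low,
                    "pct_low": round(100.0 * n_low / total, 1) if total else np.nan,
                    "n_high": n_high,
                    "pct_high": round(100.0 * n_high / total, 1) if total else np.nan,
                    "chi2": result.chi2,
                    "df": result.df,
                    "p_value": result.p_value,
                }
            )
    return pd.DataFrame(rows)


def km_logrank(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[str],
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns ({group: survival step function as a DataFrame with columns
    time, survival}, log-rank chi-square, p). With zero events the
    log-rank statistic is undefined and an error is raised.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    names = sorted(set(g.tolist()))
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    if any((g == name).sum() == 0 for name in names):
        raise ValueError("each group needs at least one subject")
    if e.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    curves: dict[str, pd.DataFrame] = {}
    for name in names:
        mask = g == name
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask], label=name)
        sf = km.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[name].to_numpy()}
        )
    a, b = (g == names[0]), (g == names[1])
    res = logrank_test(t[a], t[b], event_observed_A=e[a], event_observed_B=e[b])
    return curves, float(res.test_statistic), float(res.p_value)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
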