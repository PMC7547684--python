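"""Differential promoter methylation screen for epigenetically regulated genes.

The screen compares promoter methylation (beta values in [0, 1]) between
tumor and normal samples per gene, tests the shift with a two-sided
Mann-Whitney U test, corrects per cancer type with Benjamini-Hochberg,
and classifies each gene by requiring a *concordant* expression change:

* silenced:  promoter hypermethylation (delta beta >= tau_beta) with
  significantly reduced expression (log2 fold change <= -tau_expr);
* activated: the mirrored condition (hypomethylation + up-expression);
* unaltered: everything else, including discordant genes.

A TSS-centered meta-profile of per-site differential methylation
(tumor mean minus normal mean, binned by TSS offset) summarizes where
in the +/-3 kb window the signal concentrates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import SiteMap

__all__ = [
    "DiffMethRecord",
    "EpiCall",
    "MetaProfile",
    "validate_beta",
    "promoter_beta",
    "differential_methylation",
    "differential_expression",
    "classify_epigenetic",
    "recurrence_summary",
    "rank_top_silenced",
    "tss_meta_profile",
]

#: pseudocount added to beta means in the methylation fold change
METH_EPSILON = 0.01


@dataclass(frozen=True)
class DiffMethRecord:
    gene_id: str
    mean_beta_tumor: float
    mean_beta_normal: float
    delta_beta: float
    log2fc_meth: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class EpiCall:
    gene_id: str
    cancer_type: str
    label: str  # silenced | activated | unaltered
    delta_beta: float
    expr_log2fc: float
    q_meth: float
    q_expr: float
    reason: str = ""


@dataclass(frozen=True)
class MetaProfile:
    """Binned mean differential methylation around the TSS."""

    bin_edges: np.ndarray  # length n_bins + 1, in bp offsets
    bin_values: np.ndarray  # mean delta beta per bin; NaN where empty
    bin_counts: np.ndarray  # sites per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def peak_offset(self) -> float:
        """Center of the bin with the largest mean differential methylation."""
        if not np.isfinite(self.bin_values).any():
            raise ValueError("meta-profile has no populated bins")
        idx = int(np.nanargmax(self.bin_values))
        return float(self.bin_centers[idx])


def validate_beta(beta: pd.DataFrame) -> None:
    """Check a sites x samples beta matrix: finite values within [0, 1].

    Missing values are allowed (NaN) and are ignored by downstream means.
    """
    values = beta.to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    if np.isinf(values).any():
        raise ValueError("beta values must be finite or NaN")


def _split_groups(
    samples: Iterable[str], groups: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    tumor = [s for s in samples if groups.get(s) == "tumor"]
    normal = [s for s in samples if groups.get(s) == "normal"]
    if not tumor or not normal:
        raise ValueError("need at least one tumor and one normal sample")
    return tumor, normal


def promoter_beta(beta: pd.DataFrame, sitemap: Sequence[SiteMap]) -> pd.DataFrame:
    """Collapse site-level betas to per-gene promoter means.

    Parameters
    ----------
    beta:
        sites x samples matrix indexed by site_id; NaN marks missing.
    sitemap:
        assignments from :func:`epilnc.annotation.map_sites`; unassigned
        records are skipped. A site mapped to two genes contributes to
        both.

    Returns
    -------
    genes x samples DataFrame of mean beta over assigned sites,
    missing values ignored pairwise. Genes with no assigned site are
    absent.
    """
    assignments: dict[str, list[str]] = {}
    for sm in sitemap:
        if sm.assigned_gene is None:
            continue
        if sm.site_id not in beta.index:
            raise KeyError(f"mapped site {sm.site_id} absent from beta matrix")
        assignments.setdefault(sm.assigned_gene, []).append(sm.site_id)
    if not assignments:
        return pd.DataFrame(columns=beta.columns)
    rows = {
        gene: beta.loc[site_ids].mean(axis=0, skipna=True)
        for gene, site_ids in assignments.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out.sort_index()


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    # identical constant samples make U degenerate; report p = 1
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    )


def differential_methylation(
    promoter_beta: pd.DataFrame,
    groups: Mapping[str, str],
    epsilon: float = METH_EPSILON,
) -> list[DiffMethRecord]:
    """Per-gene tumor-vs-normal differential promoter methylation.

    delta beta = tumor mean - normal mean; the fold change is
    log2((mean_t + eps) / (mean_n + eps)) with eps guarding near-zero
    means. P-values are two-sided Mann-Whitney U, q-values BH across
    genes. Groups with fewer than 2 samples yield p = q = NaN.
    """
    tumor, normal = _split_groups(promoter_beta.columns, groups)
    records: list[tuple[str, float, float, float]] = []
    pvals: list[float] = []
    for gene, row in promoter_beta.iterrows():
        t = row[tumor].to_numpy(dtype=float)
        n = row[normal].to_numpy(dtype=float)
        t, n = t[~np.isnan(t)], n[~np.isnan(n)]
        if t.size == 0 or n.size == 0:
            continue
        mt, mn = float(t.mean()), float(n.mean())
        p = _mannwhitney_p(t, n) if (t.size >= 2 and n.size >= 2) else np.nan
        records.append((gene, mt, mn, p))
        pvals.append(p)
    qvals = bh_adjust(np.asarray(pvals, dtype=float))
    out = []
    for (gene, mt, mn, p), q in zip(records, qvals):
        out.append(
            DiffMethRecord(
                gene_id=gene,
                mean_beta_tumor=mt,
                mean_beta_normal=mn,
                delta_beta=mt - mn,
                log2fc_meth=float(np.log2((mt + epsilon) / (mn + epsilon))),
                p_value=p,
                q_value=q,
            )
        )
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate."""
    q = np.full(pvals.shape, np.nan)
    mask = ~np.isnan(pvals)
    if mask.any():
        q[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return q


def differential_expression(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal expression change.

    log2fc = log2((mean_t + pc) / (mean_n + pc)); Mann-Whitney p, BH q.
    Returns a DataFrame indexed by gene_id with columns
    mean_tumor, mean_normal, log2fc, p_value, q_value.
    """
    tumor, normal = _split_groups(expr.columns, groups)
    rows = []
    for gene, row in expr.iterrows():
        t = row[tumor].to_numpy(dtype=float)
        n = row[normal].to_numpy(dtype=float)
        t, n = t[~np.isnan(t)], n[~np.isnan(n)]
        if t.size == 0 or n.size == 0:
            continue
        mt, mn = float(t.mean()), float(n.mean())
        p = _mannwhitney_p(t, n) if (t.size >= 2 and n.size >= 2) else np.nan
        rows.append(
            {
                "gene_id": gene,
                "mean_tumor": mt,
                "mean_normal": mn,
                "log2fc": float(np.log2((mt + pseudocount) / (mn + pseudocount))),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def classify_epigenetic(
    meth: Sequence[DiffMethRecord],
    expr: pd.DataFrame,
    cancer_type: str = "",
    tau_beta: float = 0.1,
    tau_expr: float = 0.585,
    alpha: float = 0.05,
) -> list[EpiCall]:
    """Label genes silenced / activated / unaltered by concordance.

    silenced:  delta_beta >= tau_beta, q_meth <= alpha,
               expr log2fc <= -tau_expr, q_expr <= alpha.
    activated: the exact mirror. Genes failing either arm — including
    discordant hypermethylated-but-upregulated genes — are unaltered.
    Genes present in only one input are unaltered with a reason flag.
    """
    calls: list[EpiCall] = []
    expr_genes = set(expr.index)
    for rec in meth:
        if rec.gene_id not in expr_genes:
            calls.append(
                EpiCall(rec.gene_id, cancer_type, "unaltered", rec.delta_beta,
                        np.nan, rec.q_value, np.nan, reason="no_expression_data")
            )
            continue
        lfc = float(expr.loc[rec.gene_id, "log2fc"])
        q_e = float(expr.loc[rec.gene_id, "q_value"])
        q_m = rec.q_value
        label, reason = "unaltered", ""
        if np.isnan(q_m) or np.isnan(q_e):
            reason = "missing_significance"
        elif (rec.delta_beta >= tau_beta and q_m <= alpha
              and lfc <= -tau_expr and q_e <= alpha):
            label = "silenced"
        elif (rec.delta_beta <= -tau_beta and q_m <= alpha
              and lfc >= tau_expr and q_e <= alpha):
            label = "activated"
        calls.append(
            EpiCall(rec.gene_id, cancer_type, label, rec.delta_beta,
                    lfc, q_m, q_e, reason=reason)
        )
    return calls


def recurrence_summary(calls: Iterable[EpiCall]) -> pd.DataFrame:
    """Count, per gene, the cancer types in which it is silenced/activated.

    Returns a DataFrame indexed by gene_id with columns
    n_types_silenced, n_types_activated, any_altered.
    """
    rows: dict[str, dict[str, int]] = {}
    for call in calls:
        entry = rows.setdefault(
            call.gene_id, {"n_types_silenced": 0, "n_types_activated": 0}
        )
        if call.label == "silenced":
            entry["n_types_silenced"] += 1
        elif call.label == "activated":
            entry["n_types_activated"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "gene_id"
    out["any_altered"] = (out["n_types_silenced"] + out["n_types_activated"]) > 0
    return out


def rank_top_silenced(
    calls: Iterable[EpiCall],
    meth_by_type: Mapping[str, Sequence[DiffMethRecord]],
    k: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Rank genes by how often and how strongly they are silenced.

    Order: number of cancer types silenced (descending), then mean
    methylation log2 fold change over those records (descending), then
    gene_id lexicographic. Returns the ordered gene list and the
    per-cancer log2fc matrix (genes x cancer types) restricted to it.
    """
    summary = recurrence_summary(calls)
    lfc = pd.DataFrame(
        {
            ct: {r.gene_id: r.log2fc_meth for r in recs}
            for ct, recs in meth_by_type.items()
        }
    )
    silenced = summary[summary["n_types_silenced"] > 0]
    mean_lfc = lfc.reindex(silenced.index).mean(axis=1, skipna=True)
    order = sorted(
        silenced.index,
        key=lambda g: (-silenced.loc[g, "n_types_silenced"], -mean_lfc[g], g),
    )
    if k is not None:
        order = order[:k]
    return order, lfc.reindex(order)


def tss_meta_profile(
    beta: pd.DataFrame,
    groups: Mapping[str, str],
    sitemap: Sequence[SiteMap],
    gene_subset: Iterable[str],
    window: int = 3000,
    bin_width: int = 100,
) -> MetaProfile:
    """Meta-profile of per-site differential methylation around the TSS.

    For each site assigned (profile mode) to a gene in ``gene_subset``,
    delta beta = tumor mean - normal mean of that site; sites are
    pooled into offset bins [edge, edge + bin_width) covering
    [-window, +window] and averaged per bin.
    """
    subset = set(gene_subset)
    if not subset:
        raise ValueError("gene_subset must be non-empty")
    tumor, normal = _split_groups(beta.columns, groups)
    t_mean = beta[tumor].mean(axis=1, skipna=True)
    n_mean = beta[normal].mean(axis=1, skipna=True)
    d_site = t_mean - n_mean

    edges = np.arange(-window, window + bin_width, bin_width)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for sm in sitemap:
        if sm.assigned_gene not in subset or sm.tss_offset is None:
            continue
        if not (-window <= sm.tss_offset <= window) or sm.site_id not in d_site.index:
            continue
        idx = min(int((sm.tss_offset + window) // bin_width), n_bins - 1)
        value = d_site[sm.site_id]
        if np.isnan(value):
            continue
        sums[idx] += value
        counts[idx] += 1
    values = np.full(n_bins, np.nan)
    populated = counts > 0
    values[populated] = sums[populated] / counts[populated]
    return MetaProfile(bin_edges=edges, bin_values=values, bin_counts=counts)
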