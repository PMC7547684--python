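"""Cell-line validation of tumor-derived epigenetic candidates.

Tumor screens can call a gene silenced for reasons other than promoter
methylation (cohort composition, purity). An independent check uses
cancer cell lines profiled for both promoter methylation and
expression: a genuinely methylation-driven gene shows a monotone
decreasing expression-versus-beta relation across lines. Spearman
correlation captures that without assuming linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import DiffMethRecord, EpiCall, rank_top_silenced

__all__ = ["ConcordanceRecord", "methylation_expression_correlation", "intersect_candidates"]


@dataclass(frozen=True)
class ConcordanceRecord:
    gene_id: str
    cancer_type: str
    spearman_rho: float  # NaN when undefined
    p_value: float
    n_lines: int
    confirmed: bool


def methylation_expression_correlation(
    promoter_beta: pd.DataFrame,
    expr: pd.DataFrame,
    cancer_type: str = "",
    rho_min: float = 0.3,
    alpha: float = 0.05,
    n_min: int = 5,
) -> list[ConcordanceRecord]:
    """Per-gene Spearman correlation of promoter beta vs expression.

    Both inputs are genes x cell-lines; only shared lines and shared
    genes are used, pairwise-complete per gene. A gene is confirmed
    when rho <= -rho_min, p <= alpha and at least n_min lines carry
    complete pairs. Degenerate inputs (constant vector, too few lines)
    yield rho = NaN and confirmed = False.
    """
    lines = [c for c in promoter_beta.columns if c in set(expr.columns)]
    records: list[ConcordanceRecord] = []
    for gene in promoter_beta.index:
        if gene not in expr.index:
            continue
        b = promoter_beta.loc[gene, lines].to_numpy(dtype=float)
        e = expr.loc[gene, lines].to_numpy(dtype=float)
        keep = ~(np.isnan(b) | np.isnan(e))
        b, e = b[keep], e[keep]
        n = int(keep.sum())
        if n < n_min or np.ptp(b) == 0 or np.ptp(e) == 0:
            records.append(
                ConcordanceRecord(gene, cancer_type, np.nan, np.nan, n, False)
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(b, e)
        confirmed = bool(rho <= -rho_min and p <= alpha)
        records.append(
            ConcordanceRecord(gene, cancer_type, float(rho), float(p), n, confirmed)
        )
    return records


def intersect_candidates(
    tumor_calls: Iterable[EpiCall],
    concordance: Sequence[ConcordanceRecord],
    meth_by_type: Mapping[str, Sequence[DiffMethRecord]],
    k: int | None = None,
) -> list[str]:
    """Genes silenced in tumors AND confirmed in cell lines, ranked.

    Ranking follows the tumor screen order (types silenced, then mean
    methylation fold change, then gene_id). An empty intersection is a
    valid outcome and returns an empty list with a warning.
    """
    confirmed = {rec.gene_id for rec in concordance if rec.confirmed}
    order, _ = rank_top_silenced(tumor_calls, meth_by_type, k=None)
    hits = [g for g in order if g in confirmed]
    if not hits:
        warnings.warn("no tumor-silenced gene confirmed in cell lines", stacklevel=2)
    return hits[:k] if k is not None else hits
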