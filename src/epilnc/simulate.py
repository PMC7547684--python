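"""Synthetic cohorts with planted ground truth for every analysis stage.

The generators emulate the statistical structure of the real inputs —
tumor/normal 450K-style promoter beta values, lncRNA expression,
cell-line methylation/expression pairs, a 44-patient clinical table
with paired qPCR expression, and bisulfite clone reads — while
planting known effects so recovery can be measured:

* beta values are Beta-distributed around a gene-level baseline
  (bounded, unimodal per gene, bimodal across genes), with planted
  hyper/hypomethylation that decays with distance from the TSS as a
  Gaussian bump (effect * exp(-offset^2 / 2 sigma^2));
* expression is log-normal, with planted-silenced genes shifted down
  in tumors by a configured log2 fold change (and the mirror for
  planted-activated genes);
* cell-line expression is a decreasing function of that line's
  promoter beta plus noise, for planted genes;
* the clinical cohort draws covariates with configured odds ratios
  against a latent low/high expression group and exponential survival
  with a configured hazard ratio;
* bisulfite clones draw per-CpG methylation as Bernoulli, convert
  unmethylated cytosines with the configured efficiency, and add
  uniform substitution errors.

Every generator is a pure function of its configuration (which
carries the seed): the same config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .bisulfite import AmpliconRef, find_cpg_sites

__all__ = [
    "SimulationConfig",
    "Truth",
    "simulate_methylation_cohort",
    "simulate_expression",
    "simulate_celllines",
    "simulate_clinical",
    "make_amplicon",
    "simulate_bisulfite_clones",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
]

# BSP primer pair targeting the converted top strand (no cytosines in
# the forward primer, no guanines in the reverse primer, as is
# characteristic of bisulfite primers).
DEFAULT_FWD_PRIMER = "GGTTTTTGTTAGTTATTTTGAAAAAGG"
DEFAULT_REV_PRIMER = "TCAATCCATAAAACCAAACCTAAA"


def _default_association_effects() -> dict[str, tuple[float, float]]:
    # covariate -> (P(adverse level | latent high expressor), odds ratio
    # of the adverse level in latent-low vs latent-high patients).
    return {
        "sex": (0.45, 1.0),  # adverse level: female (null association)
        "t_stage": (0.08, 12.0),  # T3+T4
        "clinical_stage": (0.15, 9.0),  # III-IV
        "lymph_node": (0.37, 1.2),  # node-positive
        "alcohol": (0.32, 1.8),
        "smoking": (0.18, 4.5),
    }


@dataclass
class SimulationConfig:
    """Knobs for every generator; defaults define the study conditions."""

    seed: int = 0
    # screen cohort
    n_genes: int = 200
    n_planted_silenced: int = 10
    n_planted_activated: int = 10
    n_tumor: int = 50
    n_normal: int = 50
    delta_beta_effect: float = 0.3
    expr_log2fc_effect: float = 2.0
    beta_noise_concentration: float = 50.0
    expr_dispersion: float = 0.5
    n_sites_per_promoter: int = 8
    tss_peak_width: float = 500.0
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    profile_window: int = 3000
    # cell lines
    n_celllines: int = 20
    cellline_slope: float = 4.0
    # clinical cohort
    n_patients: int = 44
    survival_hazard_ratio: float = 3.0
    association_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_association_effects
    )
    # bisulfite
    n_clones: int = 10
    conversion_rate: float = 0.99
    seq_error_rate: float = 0.001

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_tumor": self.n_tumor,
            "n_normal": self.n_normal, "n_celllines": self.n_celllines,
            "n_patients": self.n_patients, "n_clones": self.n_clones,
            "n_sites_per_promoter": self.n_sites_per_promoter,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_planted_silenced + self.n_planted_activated > self.n_genes:
            raise ValueError("more planted genes than genes")
        for name, value in (("conversion_rate", self.conversion_rate),
                            ("seq_error_rate", self.seq_error_rate)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not np.isfinite(self.delta_beta_effect) or not np.isfinite(self.expr_log2fc_effect):
            raise ValueError("effect sizes must be finite")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic per-stream generator derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class Truth:
    """Planted ground truth accompanying a simulated cohort."""

    labels: dict[str, str]  # gene -> silenced | activated | unaltered
    baseline_mu: dict[str, float]  # gene-level baseline beta
    site_effect: dict[str, float]  # site_id -> planted tumor delta beta
    expr_base_log2: dict[str, float]  # gene -> baseline log2 expression


_GENE_SPACING = 20_000


def _gene_layout(config: SimulationConfig) -> list[GeneModel]:
    genes = []
    for i in range(config.n_genes):
        start = 10_000 + i * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_id=f"LNC{i:04d}", chrom="chrS", start=start,
                end=start + 2_000, strand=strand, biotype="lncRNA",
            )
        )
    return genes


def simulate_methylation_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame, list[GeneModel], Truth]:
    """Simulate a tumor/normal promoter-methylation cohort.

    Returns (beta matrix sites x samples, sample->group mapping, site
    table with columns site_id/chrom/pos, gene models, truth).

    Each gene carries ``n_sites_per_promoter`` CpG sites uniform over
    the promoter window plus twice as many flanking sites filling the
    rest of the +/-``profile_window`` TSS neighborhood, so the same
    cohort feeds both the promoter screen and the TSS meta-profile.
    Normal-sample betas are Beta(mu*kappa, (1-mu)*kappa) around a
    gene baseline mu ~ U(0.05, 0.3); tumors of planted-silenced genes
    shift mu by ``delta_beta_effect * exp(-offset^2/2 sigma^2)``
    (planted-activated genes start high and shift down).
    """
    rng = config.rng(0)
    genes = _gene_layout(config)
    labels: dict[str, str] = {g.gene_id: "unaltered" for g in genes}
    planted = rng.permutation(config.n_genes)
    for i in planted[: config.n_planted_silenced]:
        labels[genes[i].gene_id] = "silenced"
    for i in planted[config.n_planted_silenced:
                     config.n_planted_silenced + config.n_planted_activated]:
        labels[genes[i].gene_id] = "activated"

    kappa = config.beta_noise_concentration
    sigma = config.tss_peak_width
    up, down, window = (config.promoter_upstream, config.promoter_downstream,
                        config.profile_window)
    samples = ([f"T{i:03d}" for i in range(config.n_tumor)]
               + [f"N{i:03d}" for i in range(config.n_normal)])
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    n_t = config.n_tumor

    site_rows = []
    beta_rows = []
    site_ids = []
    baseline_mu: dict[str, float] = {}
    site_effect: dict[str, float] = {}
    for g in genes:
        label = labels[g.gene_id]
        mu = (rng.uniform(0.5, 0.8) if label == "activated"
              else rng.uniform(0.05, 0.3))
        baseline_mu[g.gene_id] = mu
        n_prom = config.n_sites_per_promoter
        prom_offsets = rng.integers(-up, down, size=n_prom)
        flank_offsets = np.concatenate([
            rng.integers(-window, -up, size=n_prom),
            rng.integers(down, window + 1, size=n_prom),
        ])
        offsets = np.concatenate([prom_offsets, flank_offsets])
        tss_pos = g.start if g.strand == "+" else g.end - 1
        positions = tss_pos + offsets if g.strand == "+" else tss_pos - offsets

        if label == "silenced":
            shift = config.delta_beta_effect * np.exp(-(offsets**2) / (2 * sigma**2))
        elif label == "activated":
            shift = -config.delta_beta_effect * np.exp(-(offsets**2) / (2 * sigma**2))
        else:
            shift = np.zeros_like(offsets, dtype=float)

        for j, (off, pos, sh) in enumerate(zip(offsets, positions, shift)):
            sid = f"{g.gene_id}_s{j:02d}"
            mu_t = float(np.clip(mu + sh, 0.01, 0.99))
            values = np.empty(len(samples))
            values[:n_t] = rng.beta(mu_t * kappa, (1 - mu_t) * kappa, size=n_t)
            values[n_t:] = rng.beta(mu * kappa, (1 - mu) * kappa, size=config.n_normal)
            site_ids.append(sid)
            beta_rows.append(values)
            site_rows.append({"site_id": sid, "chrom": g.chrom, "pos": int(pos)})
            site_effect[sid] = float(sh)

    beta = pd.DataFrame(np.vstack(beta_rows), index=site_ids, columns=samples)
    beta.index.name = "site_id"
    sites = pd.DataFrame(site_rows)
    expr_base = {g.gene_id: float(r) for g, r in zip(genes, config.rng(1).uniform(3, 8, config.n_genes))}
    truth = Truth(labels=labels, baseline_mu=baseline_mu,
                  site_effect=site_effect, expr_base_log2=expr_base)
    return beta, groups, sites, genes, truth


def simulate_expression(truth: Truth, config: SimulationConfig) -> pd.DataFrame:
    """Log-normal tumor/normal expression matching the methylation truth.

    Planted-silenced genes are shifted by -``expr_log2fc_effect`` in
    tumors; planted-activated genes by the mirror. Columns follow the
    sample naming of :func:`simulate_methylation_cohort`.
    """
    rng = config.rng(2)
    samples = ([f"T{i:03d}" for i in range(config.n_tumor)]
               + [f"N{i:03d}" for i in range(config.n_normal)])
    n_t = config.n_tumor
    rows = []
    gene_ids = sorted(truth.labels)
    for gene in gene_ids:
        base = truth.expr_base_log2[gene]
        shift = {"silenced": -config.expr_log2fc_effect,
                 "activated": config.expr_log2fc_effect}.get(truth.labels[gene], 0.0)
        log2e = np.empty(len(samples))
        log2e[:n_t] = base + shift + rng.normal(0, config.expr_dispersion, n_t)
        log2e[n_t:] = base + rng.normal(0, config.expr_dispersion, config.n_normal)
        rows.append(2.0 ** log2e)
    expr = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=samples)
    expr.index.name = "gene_id"
    return expr


def simulate_celllines(
    truth: Truth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-line promoter beta and expression (genes x lines).

    For planted genes, lines span the full methylation range and
    expression decreases with beta (slope ``cellline_slope`` in log2
    units per unit beta) plus log-normal noise; unplanted genes sit at
    their baseline beta with no beta-expression coupling.
    """
    rng = config.rng(3)
    lines = [f"CL{i:02d}" for i in range(config.n_celllines)]
    gene_ids = sorted(truth.labels)
    beta_rows, expr_rows = [], []
    for gene in gene_ids:
        base = truth.expr_base_log2[gene]
        if truth.labels[gene] in ("silenced", "activated"):
            b = rng.uniform(0.1, 0.9, size=config.n_celllines)
            log2e = (base + config.cellline_slope * (0.5 - b)
                     + rng.normal(0, config.expr_dispersion, config.n_celllines))
        else:
            mu = truth.baseline_mu[gene]
            kappa = config.beta_noise_concentration
            b = rng.beta(mu * kappa, (1 - mu) * kappa, size=config.n_celllines)
            log2e = base + rng.normal(0, config.expr_dispersion, config.n_celllines)
        beta_rows.append(b)
        expr_rows.append(2.0 ** log2e)
    beta = pd.DataFrame(np.vstack(beta_rows), index=gene_ids, columns=lines)
    expr = pd.DataFrame(np.vstack(expr_rows), index=gene_ids, columns=lines)
    beta.index.name = expr.index.name = "gene_id"
    return beta, expr


_LOCATIONS = ("lips", "cheek", "buccal_mucosa", "tongue")


def simulate_clinical(config: SimulationConfig) -> pd.DataFrame:
    """A paired tumor/normal clinical cohort with planted associations.

    Half the patients belong to a latent low-expression group. Tumor
    expression separates the latent groups (log-normal, 2 log2 units
    apart), covariates are drawn with the configured odds ratios of
    the adverse level in latent-low vs latent-high patients, and
    overall survival is exponential with the configured hazard ratio
    for the latent-low group under independent uniform censoring.
    """
    rng = config.rng(4)
    n = config.n_patients
    n_low = n // 2
    latent_low = np.zeros(n, dtype=bool)
    latent_low[rng.permutation(n)[:n_low]] = True

    tumor_expr = 2.0 ** np.where(
        latent_low, rng.normal(1.0, 0.5, n), rng.normal(3.0, 0.5, n)
    )
    normal_expr = 2.0 ** rng.normal(3.0, 0.5, n)

    def draw(covariate: str) -> np.ndarray:
        p_high, odds_ratio = config.association_effects[covariate]
        odds_low = odds_ratio * p_high / (1 - p_high)
        p_low = odds_low / (1 + odds_low)
        p = np.where(latent_low, p_low, p_high)
        return rng.random(n) < p

    female = draw("sex")
    t34 = draw("t_stage")
    stage34 = draw("clinical_stage")
    node_pos = draw("lymph_node")
    alcohol = draw("alcohol")
    smoking = draw("smoking")

    hazard = np.where(latent_low, config.survival_hazard_ratio, 1.0) * (np.log(2) / 60.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(12.0, 84.0, n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "tumor_expr": tumor_expr,
            "normal_expr": normal_expr,
            "T_stage": np.where(t34, rng.choice(["T3", "T4"], n), rng.choice(["T1", "T2"], n)),
            "N_stage": np.where(node_pos, rng.choice(["N1", "N2"], n), "N0"),
            "clinical_stage": np.where(stage34, rng.choice(["III", "IV"], n),
                                       rng.choice(["I", "II"], n)),
            "sex": np.where(female, "female", "male"),
            "age": rng.integers(35, 81, n),
            "smoking": np.where(smoking, "present", "absent"),
            "alcohol": np.where(alcohol, "present", "absent"),
            "location": rng.choice(_LOCATIONS, n, p=(0.39, 0.18, 0.29, 0.14)),
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
        }
    )


def make_amplicon(
    n_cpgs: int = 10,
    name: str = "synthetic_promoter_amplicon",
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
) -> AmpliconRef:
    """Construct a synthetic BSP amplicon with planted primer sites.

    The sequence embeds the forward primer (cytosine-free, so it
    survives conversion unchanged), ``n_cpgs`` CpG dinucleotides each
    flanked by a non-CpG cytosine for conversion QC, and the
    reverse-primer binding site.
    """
    rev_site = rev_primer.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]
    unit = "ATTCACGTAA"  # one non-CpG C (pos 3) and one CpG (pos 5)
    seq = fwd_primer.upper() + unit * n_cpgs + rev_site
    ref = AmpliconRef(name=name, sequence=seq)
    if len(ref.cpg_positions) != n_cpgs:
        raise AssertionError("amplicon construction produced stray CpGs")
    return ref


def simulate_bisulfite_clones(
    amplicon: AmpliconRef,
    per_site_meth_prob: float | Sequence[float],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Simulate bisulfite clone reads from an amplicon.

    Per clone and CpG, the methylation state is Bernoulli with the
    given probability; unmethylated cytosines (CpG and non-CpG alike)
    convert to T with probability ``conversion_rate``; substitution
    errors hit every base with probability ``seq_error_rate``,
    uniformly over the three alternatives.

    Returns (clones as (id, sequence) pairs, planted clones x sites
    boolean methylation matrix).
    """
    rng = config.rng(5)
    probs = np.broadcast_to(
        np.asarray(per_site_meth_prob, dtype=float), (len(amplicon.cpg_positions),)
    )
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("methylation probabilities must be in [0, 1]")
    cpg_set = set(amplicon.cpg_positions)
    clones: list[tuple[str, str]] = []
    planted = np.zeros((config.n_clones, len(amplicon.cpg_positions)), dtype=bool)
    bases = np.array(list("ACGT"))
    for c in range(config.n_clones):
        meth = rng.random(len(probs)) < probs
        planted[c] = meth
        meth_pos = {pos for pos, m in zip(amplicon.cpg_positions, meth) if m}
        read = []
        for i, base in enumerate(amplicon.sequence):
            if base == "C" and i not in meth_pos:
                base = "T" if rng.random() < config.conversion_rate else "C"
            if config.seq_error_rate > 0 and rng.random() < config.seq_error_rate:
                base = rng.choice(bases[bases != base])
            read.append(base)
        clones.append((f"clone_{c:02d}", "".join(read)))
    return clones, planted
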