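# epilnc

A tested pipeline for finding **epigenetically regulated lncRNAs** from
paired tumor/normal DNA-methylation and expression data, together with
the downstream clinical and molecular statistics such a study needs:
qPCR relative quantification, clinicopathological association tables,
Kaplan–Meier survival, and bisulfite-sequencing-PCR methylation calling.
Every stage can run on synthetic cohorts with planted ground truth, so
the whole analysis is reproducible on a laptop with no downloads.

## Who it is for

Cancer epigenomics analysts who want to screen promoter methylation
(450K-style beta values) against expression for concordant silencing or
activation, validate candidates in cell lines, and work up a candidate
gene in a patient cohort — with every statistical step unit-tested
against independent oracles.

## The screen

For each gene *g*, promoter methylation is the mean beta value
β ∈ [0, 1] over CpG sites in a strand-aware promoter window (default
−1500 bp to +500 bp around the TSS). Comparing tumors with normals:

- Δβ(g) = mean β_tumor − mean β_normal, tested with a two-sided
  Mann–Whitney U, Benjamini–Hochberg-corrected across genes;
- expression log2 fold change log2((μ_T + 1)/(μ_N + 1)), same test;
- **silenced**: Δβ ≥ τ_β ∧ q_meth ≤ α ∧ log2FC ≤ −τ_e ∧ q_expr ≤ α
  (defaults τ_β = 0.1, τ_e = 0.585 ≈ 1.5-fold, α = 0.05);
- **activated**: the exact mirror; everything else (including
  discordant genes) is **unaltered**.

Candidates are ranked by how many cancer types silence them and by
methylation fold change, intersected with cell lines where promoter β
must anti-correlate with expression (Spearman ρ ≤ −0.3), and a
TSS-centered meta-profile of per-site Δβ (±3 kb, 100-bp bins) shows
where the differential methylation concentrates.

The clinical layer implements 2^−ΔΔCt relative expression, paired and
Welch t-tests, median dichotomization into low/high expressors (ties
to low), Pearson chi-square association tables (no continuity
correction — the convention that reproduces published 44-patient
association tables exactly), log-rank survival comparison, and Pearson
expression correlations. The bisulfite module converts reference
sequences in silico, locates amplicons from primer pairs, calls each
clone's CpGs as methylated (C) or unmethylated (T), and QCs clones by
non-CpG conversion efficiency (≥ 0.95).

## Worked example

```python
from epilnc.simulate import (SimulationConfig, simulate_methylation_cohort,
                             simulate_expression)
from epilnc.annotation import map_sites, promoter_interval
from epilnc.screen import (promoter_beta, differential_methylation,
                           differential_expression, classify_epigenetic,
                           tss_meta_profile)

cfg = SimulationConfig(seed=1)          # 200 genes, 50 tumor vs 50 normal,
beta, groups, sites, genes, truth = (   # 10 planted silenced + 10 activated
    simulate_methylation_cohort(cfg))
expr = simulate_expression(truth, cfg)

promoters = {g.gene_id: promoter_interval(g) for g in genes}
pb = promoter_beta(beta, map_sites(sites, genes, promoters=promoters))
meth = differential_methylation(pb, groups)
de = differential_expression(expr, groups)
calls = classify_epigenetic(meth, de, cancer_type="simulated")

silenced = [c for c in calls if c.label == "silenced"]
print(f"{len(silenced)} genes called silenced "
      f"(planted: {sum(l == 'silenced' for l in truth.labels.values())})")
top = max(silenced, key=lambda c: c.delta_beta)
print(f"top hit {top.gene_id}: delta_beta={top.delta_beta:.3f}, "
      f"expr_log2fc={top.expr_log2fc:.2f}, q_meth={top.q_meth:.2e}")
profile = tss_meta_profile(beta, groups,
                           map_sites(sites, genes, tss_window=3000),
                           [c.gene_id for c in silenced])
print(f"meta-profile peak at {profile.peak_offset():+.0f} bp from the TSS")
```

prints

```
10 genes called silenced (planted: 10)
top hit LNC0144: delta_beta=0.202, expr_log2fc=-1.92, q_meth=7.44e-17
meta-profile peak at +50 bp from the TSS
```

The screen recovers all 10 planted silenced genes; the top hit is
hypermethylated by Δβ ≈ 0.20 at the promoter (the planted 0.3 effect
averaged over the promoter window) with a near 4-fold expression drop,
and the differential methylation peaks essentially at the TSS.

The same analysis runs end to end from a shell:

```sh
epilnc all --outdir run --seed 1       # simulate → screen → … → bsp
epilnc table1 --clinical run/clinical.tsv
```

Every run writes a `manifest.json` with all parameters and output
checksums; the same config and seed reproduce identical files.

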