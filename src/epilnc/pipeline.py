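"""End-to-end orchestration with a config file and a run manifest.

The pipeline chains the stages over a fixed output layout::

    simulate    -> beta.tsv, expr.tsv, sites.tsv, genes.bed, truth.tsv,
                   cellline_beta.tsv, cellline_expr.tsv, clinical.tsv,
                   amplicon.fasta, clones.fasta
    annotate    -> promoters.bed, sitemap_promoter.tsv, sitemap_profile.tsv
    screen      -> diff_meth.tsv, diff_expr.tsv, calls.tsv, recurrence.tsv
    profile     -> meta_profile.tsv
    concordance -> concordance.tsv, candidates.tsv
    clin        -> table1.tsv, km_logrank.tsv
    bsp         -> bsp_pattern.tsv, bsp_summary.tsv

Every run writes ``manifest.json`` recording the stages run, the full
parameter set, and a sha256 checksum of every output file, so that a
rerun with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, bisulfite, clinical, concordance, screen, simulate

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "screen", "profile", "concordance", "clin", "bsp")


@dataclass
class RunConfig:
    """Validated pipeline parameters; loadable from YAML."""

    outdir: str = "epilnc_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # promoter / profile geometry
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    profile_window: int = 3000
    bin_width: int = 100
    # screen thresholds
    tau_beta: float = 0.1
    tau_expr: float = 0.585
    alpha: float = 0.05
    # concordance thresholds
    rho_min: float = 0.3
    n_min_lines: int = 5
    # bisulfite
    min_conversion: float = 0.95
    bsp_meth_prob: float = 0.73
    # simulation overrides (forwarded to SimulationConfig)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for name in ("tau_beta", "tau_expr", "alpha", "rho_min", "min_conversion"):
            value = getattr(self, name)
            if not (0 <= value) or not np.isfinite(value):
                raise ValueError(f"{name} must be non-negative and finite, got {value}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for name in ("promoter_upstream", "promoter_downstream", "profile_window", "bin_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> simulate.SimulationConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.seed)
        params.setdefault("promoter_upstream", self.promoter_upstream)
        params.setdefault("promoter_downstream", self.promoter_downstream)
        params.setdefault("profile_window", self.profile_window)
        return simulate.SimulationConfig(**params)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.outputs: list[Path] = []

    def emit(self, path: Path) -> None:
        self.outputs.append(path)

    # -- stages ---------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config.sim_config()
        beta, groups, sites, genes, truth = simulate.simulate_methylation_cohort(cfg)
        expr = simulate.simulate_expression(truth, cfg)
        cl_beta, cl_expr = simulate.simulate_celllines(truth, cfg)
        clin = simulate.simulate_clinical(cfg)
        amplicon = simulate.make_amplicon()
        clones, _ = simulate.simulate_bisulfite_clones(
            amplicon, self.config.bsp_meth_prob, cfg
        )
        out = self.outdir
        self.emit(_write_tsv(beta, out / "beta.tsv"))
        self.emit(_write_tsv(expr, out / "expr.tsv"))
        self.emit(_write_tsv(sites, out / "sites.tsv", index=False))
        annotation.write_bed(genes, out / "genes.bed")
        self.emit(out / "genes.bed")
        groups_df = pd.DataFrame(sorted(groups.items()), columns=["sample_id", "group"])
        self.emit(_write_tsv(groups_df, out / "groups.tsv", index=False))
        truth_df = pd.DataFrame(
            sorted(truth.labels.items()), columns=["gene_id", "planted_label"]
        )
        self.emit(_write_tsv(truth_df, out / "truth.tsv", index=False))
        self.emit(_write_tsv(cl_beta, out / "cellline_beta.tsv"))
        self.emit(_write_tsv(cl_expr, out / "cellline_expr.tsv"))
        clinical.write_clinical_table(clin, out / "clinical.tsv")
        self.emit(out / "clinical.tsv")
        with open(out / "amplicon.fasta", "w") as handle:
            handle.write(f">{amplicon.name}\n{amplicon.sequence}\n")
        self.emit(out / "amplicon.fasta")
        with open(out / "clones.fasta", "w") as handle:
            for clone_id, seq in clones:
                handle.write(f">{clone_id}\n{seq}\n")
        self.emit(out / "clones.fasta")

    def _load_screen_inputs(self):
        out = self.outdir
        beta = pd.read_csv(out / "beta.tsv", sep="\t", index_col=0)
        groups = dict(
            pd.read_csv(out / "groups.tsv", sep="\t").itertuples(index=False, name=None)
        )
        genes = annotation.parse_gene_models(out / "genes.bed")
        sites = annotation.read_site_table(out / "sites.tsv")
        return beta, groups, genes, sites

    def annotate(self) -> None:
        _, _, genes, sites = self._load_screen_inputs()
        cfg = self.config
        promoters = {
            g.gene_id: annotation.promoter_interval(
                g, cfg.promoter_upstream, cfg.promoter_downstream
            )
            for g in genes
        }
        annotation.write_bed(
            [
                annotation.GeneModel(g.gene_id, iv.chrom, iv.start, iv.end, g.strand)
                for g, iv in ((g, promoters[g.gene_id]) for g in genes)
            ],
            self.outdir / "promoters.bed",
        )
        self.emit(self.outdir / "promoters.bed")
        for mode, kwargs, name in (
            ("promoter", {"promoters": promoters}, "sitemap_promoter.tsv"),
            ("profile", {"tss_window": cfg.profile_window}, "sitemap_profile.tsv"),
        ):
            mapped = annotation.map_sites(sites, genes, **kwargs)
            df = pd.DataFrame(
                [
                    {
                        "site_id": m.site_id, "chrom": m.chrom, "pos": m.pos,
                        "assigned_gene": m.assigned_gene if m.assigned_gene else "",
                        "tss_offset": m.tss_offset if m.tss_offset is not None else "",
                    }
                    for m in mapped
                ]
            )
            self.emit(_write_tsv(df, self.outdir / name, index=False))

    def _load_sitemap(self, name: str) -> list[annotation.SiteMap]:
        df = pd.read_csv(self.outdir / name, sep="\t",
                         dtype={"site_id": str, "chrom": str})
        out = []
        for row in df.itertuples(index=False):
            gene = row.assigned_gene if isinstance(row.assigned_gene, str) and row.assigned_gene else None
            offset = int(row.tss_offset) if gene is not None and not pd.isna(row.tss_offset) else None
            out.append(annotation.SiteMap(str(row.site_id), str(row.chrom),
                                          int(row.pos), gene, offset))
        return out

    def screen(self) -> None:
        cfg = self.config
        beta, groups, _, _ = self._load_screen_inputs()
        expr = pd.read_csv(self.outdir / "expr.tsv", sep="\t", index_col=0)
        sitemap = self._load_sitemap("sitemap_promoter.tsv")
        prom_beta = screen.promoter_beta(beta, sitemap)
        meth = screen.differential_methylation(prom_beta, groups)
        de = screen.differential_expression(expr, groups)
        calls = screen.classify_epigenetic(
            meth, de, cancer_type="simulated",
            tau_beta=cfg.tau_beta, tau_expr=cfg.tau_expr, alpha=cfg.alpha,
        )
        meth_df = pd.DataFrame([vars(r) for r in meth]).set_index("gene_id")
        calls_df = pd.DataFrame([vars(c) for c in calls]).set_index("gene_id")
        self.emit(_write_tsv(meth_df, self.outdir / "diff_meth.tsv"))
        self.emit(_write_tsv(de, self.outdir / "diff_expr.tsv"))
        self.emit(_write_tsv(calls_df, self.outdir / "calls.tsv"))
        self.emit(_write_tsv(screen.recurrence_summary(calls),
                             self.outdir / "recurrence.tsv"))

    def profile(self) -> None:
        cfg = self.config
        beta, groups, _, _ = self._load_screen_inputs()
        calls = pd.read_csv(self.outdir / "calls.tsv", sep="\t", index_col=0)
        silenced = calls.index[calls["label"] == "silenced"].tolist()
        subset = silenced or calls.index.tolist()
        sitemap = self._load_sitemap("sitemap_profile.tsv")
        prof = screen.tss_meta_profile(
            beta, groups, sitemap, subset,
            window=cfg.profile_window, bin_width=cfg.bin_width,
        )
        df = pd.DataFrame(
            {
                "bin_start": prof.bin_edges[:-1],
                "bin_end": prof.bin_edges[1:],
                "mean_delta_beta": prof.bin_values,
                "n_sites": prof.bin_counts,
            }
        )
        self.emit(_write_tsv(df, self.outdir / "meta_profile.tsv", index=False))

    def concordance(self) -> None:
        cfg = self.config
        cl_beta = pd.read_csv(self.outdir / "cellline_beta.tsv", sep="\t", index_col=0)
        cl_expr = pd.read_csv(self.outdir / "cellline_expr.tsv", sep="\t", index_col=0)
        records = concordance.methylation_expression_correlation(
            cl_beta, cl_expr, cancer_type="simulated",
            rho_min=cfg.rho_min, alpha=cfg.alpha, n_min=cfg.n_min_lines,
        )
        df = pd.DataFrame([vars(r) for r in records]).set_index("gene_id")
        self.emit(_write_tsv(df, self.outdir / "concordance.tsv"))
        calls_df = pd.read_csv(self.outdir / "calls.tsv", sep="\t", index_col=0)
        meth_df = pd.read_csv(self.outdir / "diff_meth.tsv", sep="\t", index_col=0)
        calls = [
            screen.EpiCall(g, str(row["cancer_type"]), str(row["label"]),
                           float(row["delta_beta"]), float(row["expr_log2fc"]),
                           float(row["q_meth"]), float(row["q_expr"]))
            for g, row in calls_df.iterrows()
        ]
        meth = [
            screen.DiffMethRecord(g, float(r["mean_beta_tumor"]), float(r["mean_beta_normal"]),
                                  float(r["delta_beta"]), float(r["log2fc_meth"]),
                                  float(r["p_value"]), float(r["q_value"]))
            for g, r in meth_df.iterrows()
        ]
        hits = concordance.intersect_candidates(calls, records, {"simulated": meth})
        self.emit(_write_tsv(pd.DataFrame({"gene_id": hits}),
                             self.outdir / "candidates.tsv", index=False))

    def clin(self) -> None:
        clin = clinical.read_clinical_table(self.outdir / "clinical.tsv")
        table1 = clinical.association_table(clin)
        self.emit(_write_tsv(table1, self.outdir / "table1.tsv", index=False))
        labels = clinical.dichotomize_by_median(clin["tumor_expr"].to_numpy())
        _, chi2, p = clinical.km_logrank(
            clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), labels.to_numpy()
        )
        km_df = pd.DataFrame(
            [{"comparison": "low_vs_high_expression", "logrank_chi2": chi2, "p_value": p}]
        )
        self.emit(_write_tsv(km_df, self.outdir / "km_logrank.tsv", index=False))

    def bsp(self) -> None:
        ref_records = bisulfite.read_fasta(self.outdir / "amplicon.fasta")
        ref = bisulfite.AmpliconRef(name=ref_records[0][0], sequence=ref_records[0][1])
        clones = bisulfite.read_fasta(self.outdir / "clones.fasta")
        pattern = bisulfite.call_methylation(
            clones, ref, min_conversion=self.config.min_conversion
        )
        bisulfite.write_pattern_tsv(pattern, self.outdir / "bsp_pattern.tsv")
        self.emit(self.outdir / "bsp_pattern.tsv")
        per_site, overall = bisulfite.methylation_summary(pattern)
        summary = pd.DataFrame(
            {"cpg_position": pattern.cpg_positions, "fraction_methylated": per_site}
        )
        summary.loc[len(summary)] = ["overall", overall]
        self.emit(_write_tsv(summary, self.outdir / "bsp_summary.tsv", index=False))


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages in canonical order; return the manifest.

    Inputs required by a selected stage must exist (produced by an
    earlier stage in this run or a previous one); this is checked
    before any stage executes. On a stage failure the manifest still
    records the stages that completed.
    """
    run = _Run(config)
    selected = [s for s in STAGES if s in config.stages]
    _check_stage_inputs(run, selected)
    manifest: dict = {
        "parameters": asdict(config),
        "stages_run": [],
        "outputs": {},
    }
    try:
        for stage in selected:
            logger.info("running stage %s", stage)
            getattr(run, stage)()
            manifest["stages_run"].append(stage)
    finally:
        manifest["outputs"] = {
            str(p.relative_to(run.outdir)): _sha256(p) for p in run.outputs
        }
        with open(run.outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


_STAGE_INPUTS = {
    "annotate": ["genes.bed", "sites.tsv"],
    "screen": ["beta.tsv", "expr.tsv", "groups.tsv", "sitemap_promoter.tsv"],
    "profile": ["beta.tsv", "groups.tsv", "calls.tsv", "sitemap_profile.tsv"],
    "concordance": ["cellline_beta.tsv", "cellline_expr.tsv", "calls.tsv", "diff_meth.tsv"],
    "clin": ["clinical.tsv"],
    "bsp": ["amplicon.fasta", "clones.fasta"],
}


def _check_stage_inputs(run: _Run, selected: list[str]) -> None:
    produced: set[str] = set()
    if "simulate" in selected:
        produced.update(
            ["beta.tsv", "expr.tsv", "sites.tsv", "genes.bed", "groups.tsv",
             "truth.tsv", "cellline_beta.tsv", "cellline_expr.tsv",
             "clinical.tsv", "amplicon.fasta", "clones.fasta"]
        )
    if "annotate" in selected:
        produced.update(["promoters.bed", "sitemap_promoter.tsv", "sitemap_profile.tsv"])
    if "screen" in selected:
        produced.update(["diff_meth.tsv", "diff_expr.tsv", "calls.tsv", "recurrence.tsv"])
    missing = []
    for stage in selected:
        for name in _STAGE_INPUTS.get(stage, []):
            if name not in produced and not (run.outdir / name).exists():
                missing.append(f"{stage}: {name}")
    if missing:
        raise FileNotFoundError("missing stage inputs: " + "; ".join(missing))
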