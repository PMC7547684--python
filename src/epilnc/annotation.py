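"""Gene models, strand-aware promoters, and site-to-gene mapping.

All coordinates are 0-based half-open internally. GTF input (1-based,
inclusive) is converted on read; BED input is used as-is. The TSS of a
``+`` gene is its ``start``; of a ``-`` gene its ``end - 1``. Offsets
relative to the TSS are expressed in the transcription direction:
negative = upstream of the TSS, positive = downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "GenomicInterval",
    "SiteMap",
    "parse_gene_models",
    "write_bed",
    "tss",
    "promoter_interval",
    "map_sites",
    "read_site_table",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    biotype: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SiteMap:
    """Assignment of one methylation site to one gene.

    ``tss_offset`` is signed in the transcription direction: negative
    values lie upstream of the TSS.
    """

    site_id: str
    chrom: str
    pos: int
    assigned_gene: str | None
    tss_offset: int | None


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gene_models(
    path: str | Path, biotype_filter: Iterable[str] | None = None
) -> list[GeneModel]:
    """Parse gene records from a GTF (``gene`` feature rows) or BED6 file.

    Parameters
    ----------
    path:
        Annotation file. Format is sniffed: lines with 9 tab-separated
        fields and a feature column are treated as GTF, 6-column lines
        as BED.
    biotype_filter:
        If non-empty, keep only genes whose biotype is in the set.
        Genes with no biotype annotation are kept only when the filter
        is empty.

    Returns
    -------
    list of GeneModel with 0-based half-open coordinates.
    """
    wanted = set(biotype_filter or ())
    genes: list[GeneModel] = []
    seen: set[str] = set()
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 9:  # GTF
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gtf_attributes(fields[8])
                    gene_id = attrs.get("gene_id", "")
                    if not gene_id:
                        raise ValueError("missing gene_id attribute")
                    biotype = attrs.get("gene_type", attrs.get("gene_biotype", ""))
                    # GTF is 1-based inclusive on both ends
                    gene = GeneModel(
                        gene_id=gene_id,
                        chrom=fields[0],
                        start=int(fields[3]) - 1,
                        end=int(fields[4]),
                        strand=fields[6],
                        biotype=biotype,
                    )
                elif len(fields) >= 6:  # BED6
                    gene = GeneModel(
                        gene_id=fields[3],
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        strand=fields[5],
                        biotype="",
                    )
                else:
                    raise ValueError(f"expected 6 (BED) or 9 (GTF) fields, got {len(fields)}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if wanted:
                if gene.biotype not in wanted:
                    continue
            if gene.gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id}")
            seen.add(gene.gene_id)
            genes.append(gene)
    if not genes:
        warnings.warn(f"no gene records parsed from {path}", stacklevel=2)
    return genes


def write_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models (or promoters) as BED6."""
    with open(path, "w") as handle:
        for g in genes:
            handle.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def tss(gene: GeneModel) -> tuple[str, int]:
    """Transcription start site: ``start`` for '+', ``end - 1`` for '-'."""
    pos = gene.start if gene.strand == "+" else gene.end - 1
    return gene.chrom, pos


def promoter_interval(
    gene: GeneModel, upstream: int = 1500, downstream: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0.

    Covers ``upstream`` bp before the TSS and ``downstream`` bp after
    it in the transcription direction; the TSS base itself counts as
    the first downstream base.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if upstream + downstream == 0:
        raise ValueError("promoter window must have positive width")
    _, t = tss(gene)
    if gene.strand == "+":
        start, end = t - upstream, t + downstream
    else:
        start, end = t - downstream + 1, t + upstream + 1
    return GenomicInterval(gene.chrom, max(start, 0), end)


def tss_offset_of(pos: int, gene: GeneModel) -> int:
    """Signed TSS-relative offset of ``pos`` in the transcription sense."""
    _, t = tss(gene)
    return pos - t if gene.strand == "+" else t - pos


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV site table with columns site_id, chrom, pos."""
    sites = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str})
    missing = {"site_id", "chrom", "pos"} - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return sites


def map_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoters: Mapping[str, GenomicInterval] | None = None,
    tss_window: int | None = None,
) -> list[SiteMap]:
    """Assign methylation sites to genes.

    Two modes, selected by the arguments:

    * promoter mode (``promoters`` given): a site is assigned to every
      gene whose promoter interval contains it;
    * profile mode (``tss_window`` given): a site is assigned to every
      gene whose TSS lies within ``tss_window`` bp.

    One ``SiteMap`` record is emitted per (site, gene) assignment; a
    site overlapping two promoters contributes to both genes.
    """
    if (promoters is None) == (tss_window is None):
        raise ValueError("give exactly one of promoters= or tss_window=")
    gene_chroms = {g.chrom for g in genes}
    n_mismatch = int((~sites["chrom"].isin(gene_chroms)).sum())
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} site(s) on chromosomes absent from the annotation",
            stacklevel=2,
        )

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[SiteMap] = []
    for row in sites.itertuples(index=False):
        site_id, chrom, pos = str(row.site_id), str(row.chrom), int(row.pos)
        assigned = False
        for g in by_chrom.get(chrom, ()):
            if promoters is not None:
                interval = promoters.get(g.gene_id)
                hit = interval is not None and pos in interval
            else:
                hit = abs(tss_offset_of(pos, g)) <= tss_window
            if hit:
                out.append(
                    SiteMap(site_id, chrom, pos, g.gene_id, tss_offset_of(pos, g))
                )
                assigned = True
        if not assigned:
            out.append(SiteMap(site_id, chrom, pos, None, None))
    return out
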