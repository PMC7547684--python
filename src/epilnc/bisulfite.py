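"""Bisulfite-sequencing-PCR analysis of clone reads.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read
as T after PCR), while 5-methylcytosine — in practice confined to CpG
dinucleotides — is protected and stays C. Sequencing cloned amplicons
from the converted top strand therefore reads each CpG as C
(methylated) or T (unmethylated), while every non-CpG cytosine should
read T; the fraction of non-CpG cytosines actually converted is the
clone's conversion efficiency and flags incomplete treatment.

Clones are assumed pre-aligned to the amplicon (Sanger clone
sequencing of a fixed PCR product): every read has the amplicon's
length and no indels are modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import GenomicInterval

__all__ = [
    "AmpliconRef",
    "MethylPattern",
    "find_cpg_sites",
    "bisulfite_convert",
    "reverse_complement",
    "locate_amplicon",
    "read_fasta",
    "call_methylation",
    "methylation_summary",
    "write_pattern_tsv",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: integer codes in a MethylPattern call matrix
UNMETHYLATED, METHYLATED, AMBIGUOUS = 0, 1, -1


def find_cpg_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CpG dinucleotide."""
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


@dataclass(frozen=True)
class AmpliconRef:
    """A PCR amplicon reference with its CpG site index."""

    name: str
    sequence: str
    cpg_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError(f"amplicon {self.name}: sequence must be over ACGT")
        object.__setattr__(self, "sequence", seq)
        cpgs = tuple(find_cpg_sites(seq))
        if self.cpg_positions is None:
            object.__setattr__(self, "cpg_positions", cpgs)
        elif tuple(self.cpg_positions) != cpgs:
            raise ValueError(
                f"amplicon {self.name}: cpg_positions disagree with the sequence"
            )

    @property
    def non_cpg_c_positions(self) -> tuple[int, ...]:
        cpg = set(self.cpg_positions)
        return tuple(
            i for i, base in enumerate(self.sequence) if base == "C" and i not in cpg
        )


@dataclass
class MethylPattern:
    """Clones x CpG-sites methylation calls with per-clone QC."""

    clone_ids: list[str]
    cpg_positions: tuple[int, ...]
    calls: np.ndarray  # int matrix over {0 unmeth, 1 meth, -1 ambiguous}
    conversion_efficiency: np.ndarray  # per clone, NaN if no non-CpG C
    excluded: np.ndarray  # per clone boolean (failed conversion QC)

    def __post_init__(self) -> None:
        n, m = self.calls.shape
        if (len(self.clone_ids), len(self.cpg_positions)) != (n, m):
            raise ValueError("inconsistent MethylPattern dimensions")


def bisulfite_convert(seq: str, methylated: Iterable[int] = ()) -> str:
    """In-silico bisulfite conversion of the top strand.

    Every C becomes T except Cs at ``methylated`` positions, which must
    be CpG cytosines and stay C.
    """
    seq = seq.upper()
    meth = set(methylated)
    cpgs = set(find_cpg_sites(seq))
    bad = meth - cpgs
    if bad:
        raise ValueError(f"methylated positions not CpG cytosines: {sorted(bad)}")
    return "".join(
        "C" if (base == "C" and i in meth) else ("T" if base == "C" else base)
        for i, base in enumerate(seq)
    )


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1:
            return hits
        hits.append(idx)
        start = idx + 1


def locate_amplicon(
    reference: str,
    fwd_primer: str,
    rev_primer: str,
    chrom: str = "amplicon",
) -> GenomicInterval:
    """Locate the BSP product on the fully-converted plus strand.

    The reference is bisulfite-converted assuming no methylation; the
    forward primer must occur exactly once as a substring, and the
    reverse primer once as a match to the reverse complement of the
    converted strand. The product runs from the forward primer start
    to the end of the reverse-primer binding site, half-open.
    """
    converted = bisulfite_convert(reference.upper(), methylated=())
    fwd = fwd_primer.upper()
    rev_site = reverse_complement(rev_primer.upper())  # as seen on the plus strand
    fwd_hits = _find_all(converted, fwd)
    rev_hits = _find_all(converted, rev_site)
    for name, hits in (("forward", fwd_hits), ("reverse", rev_hits)):
        if len(hits) == 0:
            raise ValueError(f"{name} primer: no match in converted reference")
        if len(hits) > 1:
            raise ValueError(f"{name} primer: ambiguous, {len(hits)} matches")
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_site)
    if end <= start:
        raise ValueError("reverse primer binds upstream of the forward primer")
    return GenomicInterval(chrom, start, end)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file, uppercased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def call_methylation(
    clones: Sequence[tuple[str, str]],
    ref: AmpliconRef,
    min_conversion: float = 0.95,
) -> MethylPattern:
    """Call per-clone CpG methylation against an amplicon reference.

    At each CpG position a clone base C is methylated, T unmethylated,
    anything else ambiguous. Conversion efficiency is the fraction of
    the reference's non-CpG cytosines read as T in the clone; clones
    below ``min_conversion`` are flagged excluded but kept in the
    matrix. Clones whose length differs from the amplicon are skipped
    with a log entry.
    """
    non_cpg = ref.non_cpg_c_positions
    ids: list[str] = []
    rows: list[list[int]] = []
    effs: list[float] = []
    for clone_id, seq in clones:
        if len(seq) != len(ref.sequence):
            logger.warning(
                "clone %s skipped: length %d != amplicon length %d",
                clone_id, len(seq), len(ref.sequence),
            )
            continue
        calls = []
        for pos in ref.cpg_positions:
            base = seq[pos]
            calls.append(
                METHYLATED if base == "C" else UNMETHYLATED if base == "T" else AMBIGUOUS
            )
        if non_cpg:
            converted = sum(1 for pos in non_cpg if seq[pos] == "T")
            unconverted = sum(1 for pos in non_cpg if seq[pos] == "C")
            denom = converted + unconverted
            eff = converted / denom if denom else np.nan
        else:
            eff = np.nan
        ids.append(clone_id)
        rows.append(calls)
        effs.append(eff)
    eff_arr = np.asarray(effs, dtype=float)
    with np.errstate(invalid="ignore"):
        excluded = eff_arr < min_conversion
    return MethylPattern(
        clone_ids=ids,
        cpg_positions=tuple(ref.cpg_positions),
        calls=np.asarray(rows, dtype=int).reshape(len(ids), len(ref.cpg_positions)),
        conversion_efficiency=eff_arr,
        excluded=excluded,
    )


def methylation_summary(pattern: MethylPattern) -> tuple[np.ndarray, float]:
    """Per-site and overall methylated fraction over non-excluded clones.

    Ambiguous calls are dropped from numerator and denominator. Raises
    if every call is ambiguous or every clone excluded.
    """
    keep = ~pattern.excluded
    calls = pattern.calls[keep]
    if calls.size == 0:
        raise ValueError("no clones pass conversion QC")
    meth = (calls == METHYLATED).sum(axis=0).astype(float)
    unmeth = (calls == UNMETHYLATED).sum(axis=0).astype(float)
    denom = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom > 0, meth / denom, np.nan)
    total = denom.sum()
    if total == 0:
        raise ValueError("all methylation calls ambiguous")
    return per_site, float(meth.sum() / total)


def write_pattern_tsv(pattern: MethylPattern, path: str | Path) -> None:
    """Lollipop-style matrix: rows clones, columns CpG offsets, 0/1/NA."""
    df = pd.DataFrame(
        pattern.calls.astype(object),
        index=pattern.clone_ids,
        columns=[f"cpg_{pos}" for pos in pattern.cpg_positions],
    )
    df = df.where(df != AMBIGUOUS, other=pd.NA)
    df.insert(0, "conversion_efficiency", np.round(pattern.conversion_efficiency, 4))
    df.insert(1, "excluded", pattern.excluded.astype(int))
    df.index.name = "clone_id"
    df.to_csv(path, sep="\t", na_rep="NA")
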