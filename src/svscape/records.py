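"""Core domain types and genome model for somatic structural-variant cohorts.

A structural variant (SV) is represented by two breakpoints, each a
(chromosome, 1-based position, strand) triple, plus an SV type:

* ``DEL`` — deletion, ``DUP`` — tandem duplication, ``INV`` — inversion
  (all intra-chromosomal), ``TRA`` — inter-chromosomal translocation.

Cohorts are carried as :class:`pandas.DataFrame` objects with the columns in
:data:`SV_COLUMNS` (plus a stable ``sv_id``); :class:`SVRecord` is the
validated scalar view of one row.  All internal coordinates are 1-based
inclusive; BEDPE conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: hg19 (GRCh37) chromosome lengths in bp.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
STRANDS = ("+", "-", ".")

#: Canonical column order for an SV cohort table.
SV_COLUMNS = [
    "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2",
    "sv_type", "sample_id",
]

#: Canonical columns for a sample-metadata table.
META_COLUMNS = [
    "sample_id", "patient_id", "cancer_type", "category",
    "age_at_diagnosis", "tp53_status", "chromothripsis",
]

CATEGORIES = ("hematological", "brain", "solid")

#: The 16 pediatric cancer-type abbreviations and their broad category.
CANCER_TYPE_CATEGORY: dict[str, str] = {
    "B-ALL": "hematological", "T-ALL": "hematological", "AML": "hematological",
    "CPC": "brain", "EPD": "brain", "HGG": "brain", "LGG": "brain", "MB": "brain",
    "ACT": "solid", "EWS": "solid", "NBL": "solid", "OS": "solid",
    "RB": "solid", "RHB": "solid", "RT": "solid", "WT": "solid",
}

#: RIC-score retention thresholds per RSS spacer type (12 bp / 23 bp spacer).
RSS_THRESHOLDS: dict[int, float] = {12: -38.81, 23: -58.45}


class SVValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


@dataclass(frozen=True)
class SVRecord:
    """One somatic SV: two stranded breakpoints, a type, and a sample."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_type: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.pos1 < 1 or self.pos2 < 1:
            raise SVValidationError(f"positions must be >= 1: {self}")
        if self.sv_type not in SV_TYPES:
            raise SVValidationError(f"unknown sv_type {self.sv_type!r}")
        if (self.chrom1 != self.chrom2) != (self.sv_type == "TRA"):
            raise SVValidationError(
                f"sv_type {self.sv_type} inconsistent with chromosomes "
                f"{self.chrom1}/{self.chrom2}"
            )

    @property
    def span(self) -> int | None:
        """Breakpoint distance |pos2 - pos1|; undefined (None) for TRA."""
        if self.sv_type == "TRA":
            return None
        return abs(self.pos2 - self.pos1)

    def normalized(self) -> "SVRecord":
        """Return a copy with intra-chromosomal breakpoints ordered pos1 <= pos2."""
        if self.chrom1 == self.chrom2 and self.pos2 < self.pos1:
            return SVRecord(
                self.chrom1, self.pos2, self.strand2,
                self.chrom2, self.pos1, self.strand1,
                self.sv_type, self.sample_id,
            )
        return self


@dataclass(frozen=True)
class RSSSiteRecord:
    """A predicted recombination signal sequence (RSS) site.

    ``raw_ric`` is the recombination information content score on the
    native -1000..0 scale; ``adjusted_ric`` is raw minus the spacer-type
    threshold, so retained sites have ``adjusted_ric >= 0``.
    """

    chrom: str
    start: int
    end: int
    spacer_type: int
    raw_ric: float

    @property
    def adjusted_ric(self) -> float:
        return self.raw_ric - RSS_THRESHOLDS[self.spacer_type]

    @property
    def passes_threshold(self) -> bool:
        return self.raw_ric >= RSS_THRESHOLDS[self.spacer_type]


@dataclass
class GenomeModel:
    """Named chromosomes with lengths; defaults to hg19, scalable for tests."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(HG19_CHROM_LENGTHS)
    )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def scaled(self, factor: float) -> "GenomeModel":
        """A genome with every chromosome length multiplied by ``factor``."""
        return GenomeModel(
            {c: max(1, int(l * factor)) for c, l in self.chrom_lengths.items()}
        )


def assign_sv_ids(svs: pd.DataFrame) -> pd.DataFrame:
    """Attach a stable ``sv_id`` column (row order at assignment time)."""
    out = svs.reset_index(drop=True).copy()
    out["sv_id"] = [f"sv{i:06d}" for i in range(len(out))]
    return out


def validate_cohort(svs: pd.DataFrame) -> None:
    """Assert cohort-level invariants, raising :class:`SVValidationError`."""
    missing = [c for c in SV_COLUMNS if c not in svs.columns]
    if missing:
        raise SVValidationError(f"missing columns: {missing}")
    if len(svs) == 0:
        return
    if (svs["pos1"] < 1).any() or (svs["pos2"] < 1).any():
        raise SVValidationError("positions must be >= 1")
    intra = svs["chrom1"] == svs["chrom2"]
    if (intra & (svs["sv_type"] == "TRA")).any():
        raise SVValidationError("TRA records must have chrom1 != chrom2")
    if (~intra & (svs["sv_type"] != "TRA")).any():
        raise SVValidationError("inter-chromosomal records must be TRA")
    if (intra & (svs["pos1"] > svs["pos2"])).any():
        raise SVValidationError("intra-chromosomal records must have pos1 <= pos2")
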