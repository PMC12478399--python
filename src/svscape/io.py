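"""Readers, writers, and curation steps for SV cohorts and auxiliary tables.

Two SV dialects are supported:

* ``bedpe`` — standard BEDPE: ``chrom1 start1 end1 chrom2 start2 end2 name
  score strand1 strand2 sv_type sample_id`` with 0-based half-open starts.
  Internal positions use ``start + 1``.
* ``simple_tsv`` — the canonical internal layout (:data:`records.SV_COLUMNS`),
  1-based inclusive.

Malformed rows are never fatal: they are collected into a reject table with
a per-row reason so cohort curation is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    META_COLUMNS,
    RSS_THRESHOLDS,
    SV_COLUMNS,
    SV_TYPES,
    CANCER_TYPE_CATEGORY,
    GenomeModel,
    SVValidationError,
)

logger = logging.getLogger(__name__)

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sv_type", "sample_id",
]


@dataclass
class SVTable:
    """Result of reading an SV file: accepted rows plus a reject report."""

    svs: pd.DataFrame
    rejected: pd.DataFrame  # original row index, raw fields, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _normalize_rows(raw: pd.DataFrame, genome: GenomeModel | None) -> SVTable:
    """Validate and normalize parsed rows; route bad rows to the reject table."""
    reasons: list[tuple[int, str]] = []
    keep = np.ones(len(raw), dtype=bool)
    chroms = set(genome.chroms) if genome is not None else None

    for i, row in raw.iterrows():
        reason = None
        if chroms is not None and (
            row["chrom1"] not in chroms or row["chrom2"] not in chroms
        ):
            reason = "unknown chromosome"
        elif row["strand1"] not in ("+", "-", ".") or row["strand2"] not in ("+", "-", "."):
            reason = "invalid strand"
        elif row["sv_type"] not in SV_TYPES:
            reason = f"unknown sv_type {row['sv_type']!r}"
        elif row["pos1"] < 1 or row["pos2"] < 1:
            reason = "non-positive coordinate"
        elif (row["chrom1"] != row["chrom2"]) != (row["sv_type"] == "TRA"):
            reason = "sv_type inconsistent with chromosomes"
        if reason is not None:
            reasons.append((i, reason))
            keep[raw.index.get_loc(i)] = False

    accepted = raw[keep].copy()
    # Order intra-chromosomal breakpoints; swap silently but log.
    intra = accepted["chrom1"] == accepted["chrom2"]
    swap = intra & (accepted["pos2"] < accepted["pos1"])
    if swap.any():
        logger.info("swapped pos1/pos2 on %d rows with pos2 < pos1", int(swap.sum()))
        for a, b in (("pos1", "pos2"), ("strand1", "strand2")):
            tmp = accepted.loc[swap, a].copy()
            accepted.loc[swap, a] = accepted.loc[swap, b]
            accepted.loc[swap, b] = tmp

    rejected = raw.loc[[i for i, _ in reasons]].copy()
    rejected["reason"] = [r for _, r in reasons]
    out = accepted[SV_COLUMNS].reset_index(drop=True)
    out[["pos1", "pos2"]] = out[["pos1", "pos2"]].astype("int64")
    return SVTable(svs=out, rejected=rejected)


def read_sv_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    genome: GenomeModel | None = None,
) -> SVTable:
    """Read an SV cohort file into the canonical 1-based internal layout.

    Parameters
    ----------
    path : file path
    dialect : ``"bedpe"`` (0-based half-open starts) or ``"simple_tsv"``.
    genome : optional genome model used to validate chromosome names; when
        None, chromosome names are accepted as-is.
    """
    if genome is None:
        genome = GenomeModel()
    if dialect == "simple_tsv":
        raw = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
        missing = [c for c in SV_COLUMNS if c not in raw.columns]
        if missing:
            raise SVValidationError(f"{path}: missing columns {missing}")
    elif dialect == "bedpe":
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=BEDPE_COLUMNS,
            dtype={"chrom1": str, "chrom2": str},
        )
        raw["pos1"] = raw["start1"].astype("int64") + 1  # 0-based -> 1-based
        raw["pos2"] = raw["start2"].astype("int64") + 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _normalize_rows(raw, genome)


def write_sv_table(
    svs: pd.DataFrame, path: str | Path, dialect: str = "simple_tsv"
) -> None:
    """Write a cohort table in the requested dialect (UTF-8, tab-separated)."""
    if dialect == "simple_tsv":
        svs[SV_COLUMNS].to_csv(path, sep="\t", index=False)
    elif dialect == "bedpe":
        out = pd.DataFrame({
            "chrom1": svs["chrom1"],
            "start1": svs["pos1"].astype("int64") - 1,
            "end1": svs["pos1"].astype("int64"),
            "chrom2": svs["chrom2"],
            "start2": svs["pos2"].astype("int64") - 1,
            "end2": svs["pos2"].astype("int64"),
            "name": svs.get("sv_id", pd.Series(["."] * len(svs))),
            "score": ".",
            "strand1": svs["strand1"],
            "strand2": svs["strand2"],
            "sv_type": svs["sv_type"],
            "sample_id": svs["sample_id"],
        })
        out.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def deduplicate_svs(svs: pd.DataFrame, tolerance_bp: int = 10) -> pd.DataFrame:
    """Remove near-duplicate calls within each sample.

    Two records of the same sample and type are duplicates when both
    breakpoints lie within ``tolerance_bp``; the lexicographically smallest
    record (by chrom1, pos1, chrom2, pos2) of each duplicate group is kept.
    Deterministic and idempotent.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    if len(svs) == 0:
        return svs.copy()

    kept_parts = []
    sort_cols = ["chrom1", "pos1", "chrom2", "pos2"]
    for _, grp in svs.groupby(["sample_id", "sv_type", "chrom1", "chrom2"], sort=True):
        g = grp.sort_values(sort_cols, kind="mergesort")
        retained: list[int] = []  # positional indices into g
        p1 = g["pos1"].to_numpy()
        p2 = g["pos2"].to_numpy()
        for i in range(len(g)):
            dup = False
            for j in retained:
                if abs(p1[i] - p1[j]) <= tolerance_bp and abs(p2[i] - p2[j]) <= tolerance_bp:
                    dup = True
                    break
            if not dup:
                retained.append(i)
        kept_parts.append(g.iloc[retained])
    out = pd.concat(kept_parts).sort_values(
        ["sample_id", "chrom1", "pos1", "chrom2", "pos2", "sv_type"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def consolidate_patient_samples(
    svs: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep one sample per patient — the one with the most SVs.

    Ties break toward the lexicographically smallest sample id.  Returns the
    restricted cohort and metadata.  Samples absent from the metadata raise.
    """
    samples = set(svs["sample_id"].unique())
    known = set(metadata["sample_id"])
    orphans = sorted(samples - known)
    if orphans:
        raise SVValidationError(f"samples without metadata: {orphans}")

    counts = svs.groupby("sample_id").size()
    meta = metadata.copy()
    meta["n_svs"] = meta["sample_id"].map(counts).fillna(0).astype(int)
    meta = meta.sort_values(
        ["patient_id", "n_svs", "sample_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    # n_svs descending, sample_id ascending: the first row per patient wins,
    # but ties on n_svs must pick the smallest id — resort within ties.
    meta = meta.sort_values(
        ["patient_id", "n_svs"], ascending=[True, False], kind="mergesort"
    )
    chosen = []
    for _, grp in meta.groupby("patient_id", sort=True):
        top = grp[grp["n_svs"] == grp["n_svs"].max()]
        chosen.append(top.sort_values("sample_id").iloc[0]["sample_id"])
    keep_meta = metadata[metadata["sample_id"].isin(chosen)].reset_index(drop=True)
    keep_svs = svs[svs["sample_id"].isin(chosen)].reset_index(drop=True)
    return keep_svs, keep_meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV and check category consistency."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS[:4] if c not in meta.columns]
    if missing:
        raise SVValidationError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise SVValidationError(f"duplicate sample_id(s): {dups}")
    known = meta["cancer_type"].isin(CANCER_TYPE_CATEGORY)
    bad = meta[known & (
        meta["cancer_type"].map(CANCER_TYPE_CATEGORY) != meta["category"]
    )]
    if len(bad):
        raise SVValidationError(
            "category inconsistent with cancer_type for: "
            + ", ".join(bad["sample_id"].tolist())
        )
    return meta


def read_cn_segments(path: str | Path) -> pd.DataFrame:
    """Read copy-number segments (sample_id, chrom, start, end, copy_number)."""
    cn = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if (cn["start"] > cn["end"]).any():
        raise SVValidationError("CN segment with start > end")
    return cn


def merge_rss_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping retained RSS sites to union intervals.

    The merged interval keeps the best (maximum) adjusted RIC score of its
    members, per the convention that a locus is as recombinogenic as its
    strongest predicted site.
    """
    if len(sites) == 0:
        return sites.copy()
    merged_rows = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        g = grp.sort_values(["start", "end"], kind="mergesort")
        cur = None
        for row in g.itertuples(index=False):
            if cur is None:
                cur = dict(chrom=chrom, start=row.start, end=row.end,
                           adjusted_ric=row.adjusted_ric)
            elif row.start <= cur["end"]:  # 1-based inclusive overlap
                cur["end"] = max(cur["end"], row.end)
                cur["adjusted_ric"] = max(cur["adjusted_ric"], row.adjusted_ric)
            else:
                merged_rows.append(cur)
                cur = dict(chrom=chrom, start=row.start, end=row.end,
                           adjusted_ric=row.adjusted_ric)
        if cur is not None:
            merged_rows.append(cur)
    return pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "adjusted_ric"])


def read_rss_table(path: str | Path) -> pd.DataFrame:
    """Read an RSS-site table, apply spacer-type RIC thresholds, and merge.

    Input columns: ``chrom, start, end, spacer_type, raw_ric`` (RSSsite
    download layout).  Sites scoring below the spacer-type threshold
    (12-RSS: -38.81, 23-RSS: -58.45) are dropped; survivors get
    ``adjusted_ric = raw_ric - threshold`` and overlapping survivors are
    merged to union intervals keeping the best adjusted score.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ok_spacer = raw["spacer_type"].isin(RSS_THRESHOLDS)
    raw = raw[ok_spacer].copy()
    thr = raw["spacer_type"].map(RSS_THRESHOLDS)
    raw["adjusted_ric"] = raw["raw_ric"] - thr
    retained = raw[raw["adjusted_ric"] >= 0].copy()
    return merge_rss_sites(retained)


def read_bed(path: str | Path, name_col: bool = True) -> pd.DataFrame:
    """Read a BED (0-based half-open) into 1-based inclusive intervals."""
    names = ["chrom", "start", "end"] + (["name"] if name_col else [])
    bed = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=range(len(names)),
        names=names, dtype={"chrom": str},
    )
    bed["start"] = bed["start"].astype("int64") + 1
    bed["end"] = bed["end"].astype("int64")
    return bed
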