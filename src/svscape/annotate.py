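"""Hotspot classification: dominant type/category, immune, RSS, genic.

A hotspot's character is decided by 75% majority rules over its member SVs
or breakpoints:

* dominant SV type / contributing cancer category — the label carried by at
  least 75% of member SVs (an SV with both ends in the hotspot counts
  once), otherwise ``OTH`` / ``multiple``;
* immune — at least 75% of member breakpoints within 1 Mb of an antigen
  receptor locus (IGH, IGK, IGL, TRA, TRB, TRD, TRG, or an orphan
  receptor);
* RSS — at least 75% of member breakpoints within 20 bp of a retained
  recombination-signal-sequence site.

A heptamer scanner locates the RAG recognition motif CACAGTG on either
strand of a supplied sequence, padded 20 bp beyond the hotspot interval.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

RAG_HEPTAMER = "CACAGTG"
RAG_HEPTAMER_RC = "CACTGTG"  # reverse complement

IMMUNE_WINDOW_BP = 1_000_000
RSS_WINDOW_BP = 20
MAJORITY_THRESHOLD = 0.75


def load_asset_bed(name: str) -> pd.DataFrame:
    """Load a packaged BED asset into 1-based inclusive intervals."""
    from .io import read_bed

    with resources.as_file(resources.files("svscape.assets") / name) as p:
        return read_bed(p)


def _distance_to_intervals(
    positions: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Distance (bp) from each position to the nearest interval; 0 inside."""
    if len(starts) == 0:
        return np.full(len(positions), np.inf)
    order = np.argsort(starts)
    s, e = starts[order], ends[order]
    out = np.empty(len(positions))
    for i, p in enumerate(positions):
        left = np.maximum(s - p, 0)
        right = np.maximum(p - e, 0)
        out[i] = np.min(np.maximum(left, right))
    return out


def _fraction_within(
    chrom: str,
    positions: np.ndarray,
    intervals: pd.DataFrame,
    window: int,
) -> float:
    sub = intervals[intervals["chrom"] == chrom]
    d = _distance_to_intervals(
        positions,
        sub["start"].to_numpy(dtype=float),
        sub["end"].to_numpy(dtype=float),
    )
    return float((d <= window).mean()) if len(positions) else 0.0


def classify_dominant(
    labels: pd.Series, threshold: float = MAJORITY_THRESHOLD, other: str = "OTH"
) -> str:
    """Majority label at the >= threshold rule, else the 'other' label."""
    if len(labels) == 0:
        raise ValueError("no member labels")
    fractions = labels.value_counts(normalize=True)
    top = fractions.idxmax()
    return top if fractions.max() >= threshold else other


def annotate_immune(
    chrom: str,
    breakpoint_positions: np.ndarray,
    immune_loci: pd.DataFrame,
    window: int = IMMUNE_WINDOW_BP,
    threshold: float = MAJORITY_THRESHOLD,
) -> bool:
    """True when >= 75% of breakpoints fall within the window of an immune locus."""
    return _fraction_within(chrom, breakpoint_positions, immune_loci, window) >= threshold


def annotate_rss(
    chrom: str,
    breakpoint_positions: np.ndarray,
    rss_sites: pd.DataFrame,
    window: int = RSS_WINDOW_BP,
    threshold: float = MAJORITY_THRESHOLD,
) -> bool:
    """True when >= 75% of breakpoints lie within 20 bp of a retained RSS site."""
    if rss_sites is None or len(rss_sites) == 0:
        return False
    return _fraction_within(chrom, breakpoint_positions, rss_sites, window) >= threshold


def scan_heptamer(sequence: str) -> list[int]:
    """1-based start positions of the RAG heptamer on either strand.

    Matches CACAGTG and its reverse complement CACTGTG exactly; overlapping
    occurrences are all reported, sorted and deduplicated.
    """
    seq = sequence.upper()
    hits: set[int] = set()
    for motif in (RAG_HEPTAMER, RAG_HEPTAMER_RC):
        start = seq.find(motif)
        while start != -1:
            hits.add(start + 1)
            start = seq.find(motif, start + 1)
    return sorted(hits)


def scan_hotspot_heptamers(
    hotspots: pd.DataFrame, fasta_path, pad: int = 20
) -> pd.DataFrame:
    """Scan the padded interval of each hotspot for the RAG heptamer.

    Intervals are extended ``pad`` bp on each side before scanning.
    Requires a FASTA with an index (built on the fly if absent).  Returns
    one row per hit with genomic 1-based positions.
    """
    from pyfaidx import Fasta  # optional dependency, only for sequence scans

    fa = Fasta(str(fasta_path))
    rows = []
    for hsp in hotspots.itertuples(index=False):
        start = max(1, int(hsp.start) - pad)
        end = int(hsp.end) + pad
        seq = str(fa[hsp.chrom][start - 1:end])
        for offset in scan_heptamer(seq):
            rows.append({
                "segment_id": hsp.segment_id, "chrom": hsp.chrom,
                "position": start + offset - 1,
            })
    return pd.DataFrame(rows, columns=["segment_id", "chrom", "position"])


def assign_genic(
    chrom: str, start: int, end: int, gene_model: pd.DataFrame
) -> list[str]:
    """Gene symbols whose span overlaps [start, end] by >= 1 bp; [] if intergenic.

    Deterministic order: by gene start, then name.
    """
    sub = gene_model[gene_model["chrom"] == chrom]
    hit = sub[(sub["start"] <= end) & (sub["end"] >= start)]
    hit = hit.sort_values(["start", "name"], kind="mergesort")
    return list(dict.fromkeys(hit["name"]))


def annotate_hotspots(
    hotspots: pd.DataFrame,
    members: pd.DataFrame,
    svs: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    immune_loci: pd.DataFrame | None = None,
    rss_sites: pd.DataFrame | None = None,
    gene_model: pd.DataFrame | None = None,
    threshold: float = MAJORITY_THRESHOLD,
) -> pd.DataFrame:
    """Build the full annotation table for called hotspots.

    ``members`` is the breakpoint-membership table from hotspot detection
    (one row per member breakpoint with ``segment_id``); member SVs are
    looked up by ``sv_id``.  Assets that are not provided yield NA flags.
    """
    sv_by_id = svs.set_index("sv_id") if "sv_id" in svs.columns else None
    cat_of = (
        metadata.set_index("sample_id")["category"] if metadata is not None else None
    )
    rows = []
    for hs in hotspots.itertuples(index=False):
        mem = members[members["segment_id"] == hs.segment_id]
        positions = mem["pos"].to_numpy(dtype=float)
        member_sv_ids = list(dict.fromkeys(mem["sv_id"]))
        if sv_by_id is not None:
            member_svs = sv_by_id.loc[member_sv_ids]
            dominant_type = classify_dominant(member_svs["sv_type"], threshold)
            type_fracs = member_svs["sv_type"].value_counts(normalize=True).to_dict()
        else:
            dominant_type, type_fracs = None, {}
        if cat_of is not None and sv_by_id is not None:
            cats = member_svs["sample_id"].map(cat_of)
            dominant_category = classify_dominant(cats, threshold, other="multiple")
        else:
            dominant_category = None
        immune = (
            annotate_immune(hs.chrom, positions, immune_loci, threshold=threshold)
            if immune_loci is not None else None
        )
        rss = (
            annotate_rss(hs.chrom, positions, rss_sites, threshold=threshold)
            if rss_sites is not None else None
        )
        genes = (
            assign_genic(hs.chrom, hs.start, hs.end, gene_model)
            if gene_model is not None else None
        )
        rows.append({
            "segment_id": hs.segment_id, "chrom": hs.chrom,
            "start": hs.start, "end": hs.end,
            "n": hs.n, "n_samples": hs.n_samples,
            "dominant_type": dominant_type,
            "dominant_category": dominant_category,
            "immune": immune, "rss": rss,
            "genes": ";".join(genes) if genes else ("intergenic" if genes is not None else None),
            "type_fractions": ";".join(
                f"{k}={v:.3f}" for k, v in sorted(type_fracs.items())
            ),
        })
    return pd.DataFrame(rows)
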