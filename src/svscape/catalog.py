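"""32-channel SV classification and per-sample channel matrices.

Each SV maps to one of 32 channels: {del, dup, inv} x five size bins
(1-10 kb, 10-100 kb, 100 kb-1 Mb, 1-10 Mb, >10 Mb) x {clustered,
non-clustered}, plus {clustered, non-clustered} translocations.
Intra-chromosomal SVs under 1 kb are filtered out before classification.

"Clustered" is an intra-sample feature: per chromosome, the sorted
inter-breakpoint distances are segmented by a piecewise-constant fit
(binary segmentation on log distance with a BIC stopping rule), and a
breakpoint is clustered when its segment's mean inter-breakpoint distance
falls below one tenth of the sample's genome-wide mean.  An SV is clustered
if either of its breakpoints is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SIZE_BINS = ["1-10Kb", "10-100Kb", "100Kb-1Mb", "1Mb-10Mb", ">10Mb"]
_BIN_EDGES = [1_000, 10_000, 100_000, 1_000_000, 10_000_000]
MIN_SPAN_BP = 1_000

#: The 32 channel names: each clustered block ends with its trans channel.
CHANNELS: list[str] = (
    [f"clustered_{t}_{b}" for t in ("del", "dup", "inv") for b in SIZE_BINS]
    + ["clustered_trans"]
    + [f"non-clustered_{t}_{b}" for t in ("del", "dup", "inv") for b in SIZE_BINS]
    + ["non-clustered_trans"]
)

assert len(CHANNELS) == 32


def size_bin(span: int) -> str | None:
    """Half-open size bin for an intra-chromosomal span; None when < 1 kb."""
    if span < MIN_SPAN_BP:
        return None
    for edge, label in zip(_BIN_EDGES[1:], SIZE_BINS[:-1]):
        if span < edge:
            return label
    return SIZE_BINS[-1]


def classify_sv(sv_type: str, span: int | None, clustered: bool) -> str | None:
    """Map one SV to its 32-channel label, or None when filtered (< 1 kb)."""
    prefix = "clustered" if clustered else "non-clustered"
    if sv_type == "TRA":
        return f"{prefix}_trans"
    b = size_bin(int(span))
    if b is None:
        return None
    return f"{prefix}_{sv_type.lower()}_{b}"


def _binary_segmentation(x: np.ndarray, min_size: int = 2,
                         penalty_scale: float = 1.0) -> list[tuple[int, int]]:
    """Piecewise-constant segmentation of a 1-D signal.

    Recursive binary splitting on squared error; a split is accepted when it
    lowers BIC (Gaussian cost ``n * log(rss / n)`` plus ``2 log N`` per extra
    changepoint).  Returns half-open (start, end) index ranges.
    """
    n_total = len(x)

    def cost(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        rss = float(np.sum((seg - seg.mean()) ** 2))
        m = hi - lo
        return m * np.log(max(rss / m, 1e-12))

    def split(lo: int, hi: int, out: list) -> None:
        if hi - lo < 2 * min_size:
            out.append((lo, hi))
            return
        base = cost(lo, hi)
        best_gain, best_k = 0.0, None
        for k in range(lo + min_size, hi - min_size + 1):
            gain = base - cost(lo, k) - cost(k, hi)
            if gain > best_gain:
                best_gain, best_k = gain, k
        penalty = penalty_scale * 2.0 * np.log(n_total)
        if best_k is not None and best_gain > penalty:
            split(lo, best_k, out)
            split(best_k, hi, out)
        else:
            out.append((lo, hi))

    segments: list[tuple[int, int]] = []
    split(0, n_total, segments)
    return segments


def detect_clustered(sample_svs: pd.DataFrame,
                     ratio: float = 0.1) -> pd.Series:
    """Flag each SV of one sample as clustered / non-clustered.

    Returns a boolean Series aligned with ``sample_svs``.  Samples with
    fewer than two breakpoints on every chromosome are entirely
    non-clustered.  The criterion is scale-equivariant: it compares segment
    mean inter-breakpoint distance to ``ratio`` times the sample-wide mean.
    """
    svs = sample_svs.reset_index(drop=True)
    bp = pd.concat([
        pd.DataFrame({"chrom": svs["chrom1"], "pos": svs["pos1"], "row": svs.index}),
        pd.DataFrame({"chrom": svs["chrom2"], "pos": svs["pos2"], "row": svs.index}),
    ], ignore_index=True)

    gaps_all: list[np.ndarray] = []
    per_chrom: dict[str, pd.DataFrame] = {}
    for chrom, grp in bp.groupby("chrom", sort=True):
        g = grp.sort_values("pos", kind="mergesort").reset_index(drop=True)
        per_chrom[chrom] = g
        if len(g) >= 2:
            gaps_all.append(np.diff(g["pos"].to_numpy().astype(float)))
    clustered_rows: set[int] = set()
    if not gaps_all:
        return pd.Series(False, index=sample_svs.index)
    genome_mean = float(np.concatenate(gaps_all).mean())
    if genome_mean <= 0:
        genome_mean = 1.0

    for chrom, g in per_chrom.items():
        if len(g) < 3:
            continue
        gaps = np.diff(g["pos"].to_numpy().astype(float))
        logg = np.log10(gaps + 1.0)
        for lo, hi in _binary_segmentation(logg):
            if gaps[lo:hi].mean() < ratio * genome_mean:
                # breakpoints bounding these gaps are clustered
                for bi in range(lo, hi + 1):
                    clustered_rows.add(int(g.loc[bi, "row"]))

    flags = svs.index.isin(clustered_rows)
    return pd.Series(flags, index=sample_svs.index)


def classify_cohort(svs: pd.DataFrame, ratio: float = 0.1) -> pd.DataFrame:
    """Attach ``clustered`` and ``channel`` columns to a cohort table.

    Channel is NA for intra-chromosomal SVs under 1 kb (filtered).
    """
    out = svs.copy()
    out["clustered"] = False
    for sid, grp in svs.groupby("sample_id", sort=False):
        out.loc[grp.index, "clustered"] = detect_clustered(grp, ratio=ratio)
    spans = (out["pos2"] - out["pos1"]).abs()
    out["channel"] = [
        classify_sv(t, s, c)
        for t, s, c in zip(out["sv_type"], spans, out["clustered"])
    ]
    return out


def build_matrix(classified: pd.DataFrame, min_svs: int = 20) -> pd.DataFrame:
    """Build the 32 x samples channel-count matrix.

    Only samples with at least ``min_svs`` post-filter SVs are retained;
    column sums equal each retained sample's post-filter SV count.
    """
    kept = classified[classified["channel"].notna()]
    counts = kept.groupby("sample_id").size()
    samples = sorted(counts[counts >= min_svs].index)
    mat = pd.DataFrame(0, index=CHANNELS, columns=samples, dtype=int)
    sub = kept[kept["sample_id"].isin(samples)]
    tally = sub.groupby(["channel", "sample_id"]).size()
    for (ch, sid), v in tally.items():
        mat.loc[ch, sid] = int(v)
    return mat
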