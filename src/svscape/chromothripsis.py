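"""Simplified per-chromosome chromothripsis screen.

Chromothripsis — catastrophic shattering and random re-joining of a
chromosome region — leaves two hallmarks this screen checks: many mutually
interleaved intra-chromosomal SVs, and copy-number segments oscillating
between two states.  Two numeric criteria are evaluated per sample and
chromosome:

* criterion 1: >= 6 interleaved intra-chromosomal SVs and a run of >= 7
  contiguous CN segments oscillating between two states;
* criterion 2: >= 3 interleaved intra-chromosomal SVs, >= 4
  inter-chromosomal SVs with an end on the chromosome, and the same
  oscillation run.

The statistical refinements of dedicated callers (fragment-join tests,
chromosomal enrichment, exponential breakpoint spacing) are deliberately
not part of this screen: it is a sensitivity filter whose positives are
expected to be reviewed, not a high-confidence caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def count_interleaved(intra_svs: pd.DataFrame) -> int:
    """Count SVs whose interval partially overlaps at least one other.

    Partial overlap means the intervals intersect but neither contains the
    other; nested or disjoint intervals are not interleaved.  All records
    must already be normalized (pos1 <= pos2) and on one chromosome.
    """
    if len(intra_svs) < 2:
        return 0
    a = intra_svs["pos1"].to_numpy()
    b = intra_svs["pos2"].to_numpy()
    n = len(a)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            lo1, hi1, lo2, hi2 = a[i], b[i], a[j], b[j]
            overlap = max(lo1, lo2) <= min(hi1, hi2)
            contained = (lo1 <= lo2 and hi2 <= hi1) or (lo2 <= lo1 and hi1 <= hi2)
            if overlap and not contained:
                flags[i] = flags[j] = True
    return int(flags.sum())


def count_oscillations(cn_segments: pd.DataFrame) -> int:
    """Longest run of contiguous segments alternating between two CN states.

    Copy numbers are rounded to integer states; the run may use any state
    pair.  A single segment counts as a run of 1.
    """
    if len(cn_segments) == 0:
        return 0
    states = (
        cn_segments.sort_values("start")["copy_number"]
        .round().astype(int).to_numpy()
    )
    n = len(states)
    best = 1
    run = 1
    for i in range(1, n):
        if states[i] == states[i - 1]:
            run = 1
        elif i >= 2 and states[i] == states[i - 2]:
            run += 1
        else:
            run = 2  # new alternating pair starts at i-1
        best = max(best, run)
    return best


def screen(
    sample_svs: pd.DataFrame,
    cn_segments: pd.DataFrame | None,
    min_interleaved_1: int = 6,
    min_interleaved_2: int = 3,
    min_inter: int = 4,
    min_oscillation: int = 7,
) -> pd.DataFrame:
    """Screen one sample for chromothripsis, chromosome by chromosome.

    Returns one row per chromosome carrying any SV end, with counts and the
    criterion met (``criterion1`` / ``criterion2`` / ``none``).  Missing CN
    data makes the oscillation count unknown (flagged ``cn_missing``) and
    both criteria evaluate false.
    """
    intra = sample_svs[sample_svs["sv_type"] != "TRA"]
    inter = sample_svs[sample_svs["sv_type"] == "TRA"]
    chroms = sorted(
        set(sample_svs["chrom1"]) | set(sample_svs["chrom2"])
    )
    rows = []
    sid = sample_svs["sample_id"].iloc[0] if len(sample_svs) else None
    for chrom in chroms:
        chr_intra = intra[intra["chrom1"] == chrom]
        n_interleaved = count_interleaved(chr_intra)
        n_inter = int(((inter["chrom1"] == chrom) | (inter["chrom2"] == chrom)).sum())
        cn_missing = cn_segments is None or len(
            cn_segments[cn_segments["chrom"] == chrom]
        ) == 0
        osc = 0 if cn_missing else count_oscillations(
            cn_segments[cn_segments["chrom"] == chrom]
        )
        crit1 = (not cn_missing and n_interleaved >= min_interleaved_1
                 and osc >= min_oscillation)
        crit2 = (not cn_missing and n_interleaved >= min_interleaved_2
                 and n_inter >= min_inter and osc >= min_oscillation)
        rows.append({
            "sample_id": sid, "chrom": chrom,
            "n_interleaved_intra": n_interleaved, "n_inter": n_inter,
            "max_oscillation_run": osc, "cn_missing": cn_missing,
            "criteria_met": "criterion1" if crit1 else (
                "criterion2" if crit2 else "none"),
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "n_interleaved_intra", "n_inter",
        "max_oscillation_run", "cn_missing", "criteria_met",
    ])


def screen_cohort(svs: pd.DataFrame, cn_segments: pd.DataFrame) -> pd.DataFrame:
    """Run the screen over every sample in a cohort."""
    parts = []
    for sid, grp in svs.groupby("sample_id", sort=True):
        cn = cn_segments[cn_segments["sample_id"] == sid] if cn_segments is not None else None
        parts.append(screen(grp, cn))
    if not parts:
        return screen(svs.iloc[0:0], None)
    return pd.concat(parts, ignore_index=True)
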