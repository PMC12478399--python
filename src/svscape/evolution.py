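"""Truncal / shared / private grouping of SVs across a patient's samples.

Multiple spatiotemporally distinct samples from one patient (diagnosis vs
relapse, or several metastases) carry overlapping SV sets.  The same
physical rearrangement may be reported with coordinates offset by a few bp
between samples, so identity is established by coordinate-tolerance
matching (same type, same chromosomes, both breakpoints within a
tolerance, transitively closed).  Groups are then read off the
presence/absence pattern:

* truncal — present in every sample (early events);
* shared:<subset> — present in >= 2 but not all (intermediate);
* private:<sample> — present in exactly one (late).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import CHANNELS


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def match_svs_across_samples(
    patient_svs: pd.DataFrame, tolerance_bp: int = 10
) -> pd.DataFrame:
    """Build the SV-by-sample presence matrix for one patient.

    SVs match when their types and chromosome pairs agree and both
    breakpoints lie within ``tolerance_bp``; matching is transitively
    closed.  The canonical representative of each matched group is the
    record with the lexicographically smallest coordinates.

    Returns a boolean DataFrame indexed by representative SV key
    ``chrom1:pos1-chrom2:pos2:type`` with one column per sample, plus the
    representative fields as attached columns (``chrom1`` etc. are stored in
    ``DataFrame.attrs['representatives']``).
    """
    svs = patient_svs.reset_index(drop=True)
    samples = sorted(svs["sample_id"].unique())
    if len(samples) < 2:
        raise ValueError("presence matrix needs >= 2 samples")
    uf = _UnionFind(len(svs))
    for _, grp in svs.groupby(["sv_type", "chrom1", "chrom2"], sort=False):
        g = grp.sort_values(["pos1", "pos2"], kind="mergesort")
        order = g.index.to_numpy()
        p1 = g["pos1"].to_numpy()
        p2 = g["pos2"].to_numpy()
        for a in range(len(order)):
            b = a + 1
            while b < len(order) and p1[b] - p1[a] <= tolerance_bp:
                if abs(p2[b] - p2[a]) <= tolerance_bp:
                    uf.union(int(order[a]), int(order[b]))
                b += 1
    roots = np.array([uf.find(i) for i in range(len(svs))])

    rep_rows = []
    presence = {}
    for root in sorted(set(roots)):
        members = svs[roots == root]
        rep = members.sort_values(
            ["chrom1", "pos1", "chrom2", "pos2"], kind="mergesort"
        ).iloc[0]
        key = f"{rep['chrom1']}:{rep['pos1']}-{rep['chrom2']}:{rep['pos2']}:{rep['sv_type']}"
        presence[key] = {
            s: bool((members["sample_id"] == s).any()) for s in samples
        }
        rep_rows.append({
            "key": key, "chrom1": rep["chrom1"], "pos1": rep["pos1"],
            "chrom2": rep["chrom2"], "pos2": rep["pos2"],
            "sv_type": rep["sv_type"],
            "member_sv_ids": ",".join(members.get("sv_id", pd.Series(dtype=str)).astype(str)),
        })
    matrix = pd.DataFrame.from_dict(presence, orient="index", columns=samples)
    matrix = matrix.sort_index()
    matrix.attrs["representatives"] = pd.DataFrame(rep_rows).set_index("key").sort_index()
    return matrix


def group_svs(presence: pd.DataFrame) -> pd.Series:
    """Label each presence-matrix row truncal / shared:<subset> / private:<sample>.

    Subset keys are canonical: sorted sample ids joined by '-', using the
    suffix after the last '-' of each sample id when all ids share a common
    patient prefix (e.g. ``shared:M2-M3``).
    """
    samples = list(presence.columns)
    prefixes = {s.rsplit("-", 1)[0] for s in samples}
    short = (
        {s: s.rsplit("-", 1)[1] for s in samples}
        if len(prefixes) == 1 and all("-" in s for s in samples)
        else {s: s for s in samples}
    )
    labels = []
    for _, row in presence.iterrows():
        carriers = sorted(s for s in samples if row[s])
        if not carriers:
            raise ValueError("presence row with no carriers")
        if len(carriers) == len(samples):
            labels.append("truncal")
        elif len(carriers) == 1:
            labels.append(f"private:{short[carriers[0]]}")
        else:
            labels.append("shared:" + "-".join(short[c] for c in carriers))
    return pd.Series(labels, index=presence.index, name="group")


def group_channel_profiles(
    groups: pd.Series,
    channels: pd.Series,
    min_group_size: int = 20,
) -> pd.DataFrame:
    """Per-group normalized 32-channel proportion vectors.

    ``channels`` maps each presence-matrix key to its channel label (NA
    channels, i.e. size-filtered SVs, are dropped).  Groups smaller than
    ``min_group_size`` are flagged low-confidence rather than suppressed.
    """
    df = pd.DataFrame({"group": groups, "channel": channels}).dropna(subset=["channel"])
    rows = []
    for grp, sub in df.groupby("group", sort=True):
        counts = sub["channel"].value_counts()
        vec = np.array([counts.get(ch, 0) for ch in CHANNELS], dtype=float)
        total = vec.sum()
        props = vec / total if total else vec
        rows.append({
            "group": grp, "n_svs": int(total),
            "low_confidence": total < min_group_size,
            **{ch: p for ch, p in zip(CHANNELS, props)},
        })
    return pd.DataFrame(rows)
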