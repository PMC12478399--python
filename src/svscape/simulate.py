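"""Synthetic SV cohort generator with ground-truth labels.

The generator emulates the statistical structure a pediatric pan-cancer SV
analysis assumes, so every downstream stage can be exercised against known
truth without any external download:

* per-cancer-type SV burdens spanning roughly two orders of magnitude
  (default medians range from ~2 in low-burden embryonal tumors to 245 in
  osteosarcoma);
* a homogeneous background breakpoint process (uniform positions per
  chromosome, Poisson counts proportional to chromosome length);
* planted recurrent hotspots anchored at RSS coordinates, producing
  deletions of 10 kb–1 Mb with small breakpoint jitter (default SD 10 bp,
  consistent with recombinase cleavage landing within ~20 bp of its motif);
* chromothripsis-like bursts of interleaved intra-chromosomal SVs with
  copy-number segments oscillating between two states;
* per-sample SV draws from known 32-channel signature profiles;
* multi-sample patients with truncal / shared / private SV sets.

Every generated SV carries exactly one origin label in the truth table.
Randomness is driven by a single cohort seed; per-component streams are
derived with :func:`numpy.random.SeedSequence.spawn`-style child seeds so
adding one component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    CANCER_TYPE_CATEGORY,
    SV_COLUMNS,
    GenomeModel,
    assign_sv_ids,
)

#: Default median SV burden per cancer type (counts per genome); spans
#: ~100-fold as observed across pediatric cancer types.
DEFAULT_TYPE_BURDEN: dict[str, float] = {
    "B-ALL": 8, "T-ALL": 14, "AML": 3,
    "CPC": 8, "EPD": 10, "HGG": 37, "LGG": 2, "MB": 5,
    "ACT": 51, "EWS": 4, "NBL": 11, "OS": 245,
    "RB": 10, "RHB": 34, "RT": 3, "WT": 5,
}

DELETION_SIZE_RANGE = (10_000, 1_000_000)  # RSS-mediated deletion span (bp)


@dataclass
class PlantedHotspot:
    """A recurrent breakpoint locus hit by several samples."""

    chrom: str
    anchor: int            # recurrent breakpoint position (bp)
    partner: int           # partner breakpoint position (bp)
    n_samples_hit: int
    jitter_sd: float = 10.0
    sv_type: str = "DEL"
    hotspot_id: str = ""


@dataclass
class ChromothripsisBurst:
    """A clustered burst of interleaved SVs with oscillating copy number."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_svs: int = 12
    cn_states: tuple[int, int] = (2, 3)
    n_cn_segments: int = 9
    burst_id: str = ""


@dataclass
class MultiSamplePatient:
    """A patient with several samples sharing truncal/shared/private SVs."""

    patient_id: str
    n_samples: int
    n_truncal: int
    n_shared: int
    n_private: int
    shared_subset: tuple[int, ...] | None = None  # sample indices carrying shared SVs


@dataclass
class CohortSpec:
    """Everything the generator needs to materialize a cohort."""

    n_samples: dict[str, int] = field(default_factory=lambda: {"B-ALL": 20})
    genome: GenomeModel = field(default_factory=GenomeModel)
    background_rate_per_mb: float = 0.004   # background breakpoints per Mb per sample
    type_burden: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_BURDEN)
    )
    use_type_burden: bool = False           # draw per-sample counts from type medians
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    planted_rss: pd.DataFrame | None = None  # chrom/start/end/adjusted_ric
    bursts: list[ChromothripsisBurst] = field(default_factory=list)
    signature_profiles: np.ndarray | None = None   # k x 32, rows sum to 1
    signature_exposures: np.ndarray | None = None  # n_signature_samples x k
    signature_svs_per_sample: int = 500
    multi_sample_patients: list[MultiSamplePatient] = field(default_factory=list)
    seed: int = 0


@dataclass
class SyntheticCohort:
    """Generated cohort: SV calls, metadata, CN segments, and truth labels."""

    svs: pd.DataFrame
    metadata: pd.DataFrame
    cn_segments: pd.DataFrame
    truth: pd.DataFrame              # one row per SV: origin + label
    hotspot_truth: pd.DataFrame      # planted hotspot intervals + hit counts
    rss_sites: pd.DataFrame | None = None


def channel_matrix_from_signatures(
    profiles: np.ndarray,
    exposures: np.ndarray,
    n_svs_per_sample: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a 32 x samples channel-count matrix from signature mixtures.

    Each sample's channel counts are multinomial with probabilities
    ``exposure @ profiles`` (the generative model signature extraction
    assumes).  Used to test extraction without the SV-materialization and
    re-classification round trip.
    """
    from .catalog import CHANNELS

    rng = np.random.default_rng(seed)
    profiles = np.asarray(profiles, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    cols = {}
    for i, e in enumerate(exposures):
        w = e @ profiles
        w = w / w.sum()
        cols[f"SIG-{i:03d}"] = rng.multinomial(n_svs_per_sample, w)
    return pd.DataFrame(cols, index=CHANNELS)


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _background_sv_frame(rng: np.random.Generator, genome: GenomeModel,
                         sample_id: str, n: int) -> pd.DataFrame:
    """Vectorized draw of ``n`` background SVs for one sample."""
    if n == 0:
        return pd.DataFrame(columns=SV_COLUMNS)
    chroms = np.array(genome.chroms)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    # translocations need two chromosomes to exist at all
    is_tra = (rng.random(n) < 0.12) & (len(chroms) > 1)

    c1 = rng.choice(len(chroms), size=n, p=probs)
    c2 = rng.choice(len(chroms), size=n, p=probs)
    # translocations need two distinct chromosomes
    redo = is_tra & (c1 == c2)
    while redo.any():
        c2[redo] = rng.choice(len(chroms), size=int(redo.sum()), p=probs)
        redo = is_tra & (c1 == c2)

    max_span = np.minimum(10_000_000, lengths[c1] - 2)
    span = (10 ** rng.uniform(np.log10(1_000), np.log10(max_span))).astype(int)
    pos1 = np.empty(n, dtype=np.int64)
    pos2 = np.empty(n, dtype=np.int64)
    intra = ~is_tra
    hi1 = np.maximum(2, lengths[c1][intra] - span[intra]).astype(np.int64)
    pos1[intra] = (rng.random(int(intra.sum())) * (hi1 - 1)).astype(np.int64) + 1
    pos2[intra] = pos1[intra] + span[intra]
    n_tra = int(is_tra.sum())
    pos1[is_tra] = (rng.random(n_tra) * (lengths[c1][is_tra] - 1)).astype(np.int64) + 1
    pos2[is_tra] = (rng.random(n_tra) * (lengths[c2][is_tra] - 1)).astype(np.int64) + 1

    types = np.where(
        is_tra, "TRA", rng.choice(["DEL", "DUP", "INV"], size=n)
    )
    return pd.DataFrame({
        "chrom1": chroms[c1],
        "pos1": pos1, "strand1": "+",
        "chrom2": np.where(is_tra, chroms[c2], chroms[c1]),
        "pos2": pos2, "strand2": np.where(is_tra, "+", "-"),
        "sv_type": types, "sample_id": sample_id,
    })


def _random_background_sv(rng: np.random.Generator, genome: GenomeModel,
                          sample_id: str) -> dict:
    chroms = genome.chroms
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    if rng.random() < 0.12:  # translocation
        c1, c2 = rng.choice(len(chroms), size=2, replace=False, p=probs)
        return dict(
            chrom1=chroms[c1], pos1=int(rng.integers(1, lengths[c1])), strand1="+",
            chrom2=chroms[c2], pos2=int(rng.integers(1, lengths[c2])), strand2="+",
            sv_type="TRA", sample_id=sample_id,
        )
    ci = rng.choice(len(chroms), p=probs)
    chrom = chroms[ci]
    clen = int(lengths[ci])
    span = int(10 ** rng.uniform(np.log10(1_000), np.log10(min(10_000_000, clen - 2))))
    pos1 = int(rng.integers(1, max(2, clen - span)))
    sv_type = rng.choice(["DEL", "DUP", "INV"])
    return dict(
        chrom1=chrom, pos1=pos1, strand1="+",
        chrom2=chrom, pos2=pos1 + span, strand2="-",
        sv_type=str(sv_type), sample_id=sample_id,
    )


def _materialize_channel_sv(rng: np.random.Generator, genome: GenomeModel,
                            sample_id: str, channel: str,
                            cluster_centers: dict) -> dict:
    """Create one SV consistent with a 32-channel label.

    Clustered channels reuse a per-(sample, chrom) cluster center so that the
    intra-sample clustering detector sees a genuinely dense neighborhood.
    """
    clustered, rest = channel.split("_", 1)
    is_clustered = clustered == "clustered"
    chroms = genome.chroms
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    bin_bounds = {
        "1-10Kb": (1_000, 10_000), "10-100Kb": (10_000, 100_000),
        "100Kb-1Mb": (100_000, 1_000_000), "1Mb-10Mb": (1_000_000, 10_000_000),
        ">10Mb": (10_000_000, 50_000_000),
    }
    if rest == "trans":
        c1, c2 = rng.choice(len(chroms), size=2, replace=False, p=probs)
        chrom1, chrom2 = chroms[c1], chroms[c2]
        if is_clustered:
            key = (sample_id, chrom1)
            if key not in cluster_centers:
                cluster_centers[key] = int(rng.integers(1, lengths[c1] * 0.9))
            pos1 = cluster_centers[key] + int(rng.integers(0, 30_000))
        else:
            pos1 = int(rng.integers(1, lengths[c1]))
        return dict(
            chrom1=chrom1, pos1=max(1, pos1), strand1="+",
            chrom2=chrom2, pos2=int(rng.integers(1, lengths[c2])), strand2="+",
            sv_type="TRA", sample_id=sample_id,
        )
    svt, bin_label = rest.split("_", 1)
    lo, hi = bin_bounds[bin_label]
    # on scaled-down genomes, cap the bin at what the chromosomes can host
    hi = min(hi, int(lengths.max()) - 2)
    lo = min(lo, hi - 1)
    eligible = np.nonzero(lengths >= hi + 2)[0]
    ci = rng.choice(eligible, p=probs[eligible] / probs[eligible].sum())
    chrom = chroms[ci]
    clen = int(lengths[ci])
    span = int(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    span = min(span, clen - 2)
    if is_clustered:
        key = (sample_id, chrom)
        if key not in cluster_centers:
            cluster_centers[key] = int(rng.integers(1, max(2, clen - hi - 60_000)))
        pos1 = cluster_centers[key] + int(rng.integers(0, 30_000))
    else:
        pos1 = int(rng.integers(1, max(2, clen - span)))
    pos1 = min(max(1, pos1), max(1, clen - span - 1))
    return dict(
        chrom1=chrom, pos1=pos1, strand1="+",
        chrom2=chrom, pos2=pos1 + span, strand2="-",
        sv_type=svt.upper(), sample_id=sample_id,
    )


def plant_multisample_patient(
    patient: MultiSamplePatient, genome: GenomeModel, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-sample SV sets for one multi-sample patient.

    Truncal SVs appear in every sample, shared SVs in a strict subset of at
    least two samples, private SVs in exactly one.  Returns (svs, truth)
    where truth maps each physical SV row to its evolution group.
    """
    if patient.n_samples < 2:
        raise ValueError("multi-sample patient needs n_samples >= 2")
    if patient.n_shared > 0 and patient.n_samples < 3:
        raise ValueError(
            "shared SVs need a strict subset of >= 2 samples, so n_samples >= 3"
        )
    sample_ids = [f"{patient.patient_id}-M{i+1}" for i in range(patient.n_samples)]
    if patient.shared_subset is not None:
        subset = [sample_ids[i] for i in patient.shared_subset]
        if not (2 <= len(subset) < patient.n_samples):
            raise ValueError("shared_subset must be a strict subset of size >= 2")
    elif patient.n_shared > 0:
        size = int(rng.integers(2, patient.n_samples))
        subset = sorted(rng.choice(sample_ids, size=size, replace=False))
    else:
        subset = []

    rows, truth_rows = [], []

    def emit(base_sv: dict, carriers: list[str], group: str) -> None:
        for sid in carriers:
            sv = dict(base_sv)
            sv["sample_id"] = sid
            rows.append(sv)
            truth_rows.append({"sample_id": sid, "origin": "evolution",
                               "label": group, "patient_id": patient.patient_id})

    for i in range(patient.n_truncal):
        emit(_random_background_sv(rng, genome, ""), sample_ids, "truncal")
    for i in range(patient.n_shared):
        emit(_random_background_sv(rng, genome, ""), subset,
             "shared:" + "-".join(s.split("-")[-1] for s in subset))
    for i in range(patient.n_private):
        carrier = sample_ids[int(rng.integers(0, patient.n_samples))]
        emit(_random_background_sv(rng, genome, ""), [carrier],
             f"private:{carrier.split('-')[-1]}")

    svs = pd.DataFrame(rows, columns=SV_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return svs, truth


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Materialize a synthetic cohort from a :class:`CohortSpec`.

    Deterministic for a fixed ``spec.seed``.  Raises if a planted position
    falls outside its chromosome.
    """
    genome = spec.genome
    for hs in spec.planted_hotspots:
        clen = genome.chrom_lengths.get(hs.chrom)
        if clen is None or not (1 <= hs.anchor <= clen) or not (1 <= hs.partner <= clen):
            raise ValueError(f"planted hotspot outside chromosome: {hs}")
    for b in spec.bursts:
        clen = genome.chrom_lengths.get(b.chrom)
        if clen is None or not (1 <= b.start < b.end <= clen):
            raise ValueError(f"burst region outside chromosome: {b}")

    sample_rows = []
    for ctype, n in sorted(spec.n_samples.items()):
        for i in range(n):
            sid = f"{ctype}-{i:03d}"
            sample_rows.append({
                "sample_id": sid, "patient_id": f"P-{sid}",
                "cancer_type": ctype,
                "category": CANCER_TYPE_CATEGORY.get(ctype, "solid"),
                "age_at_diagnosis": float("nan"),
                "tp53_status": "unknown", "chromothripsis": "unknown",
            })
    metadata = pd.DataFrame(sample_rows, columns=[
        "sample_id", "patient_id", "cancer_type", "category",
        "age_at_diagnosis", "tp53_status", "chromothripsis",
    ])
    sample_ids = metadata["sample_id"].tolist()

    sv_rows: list[dict] = []
    truth_rows: list[dict] = []
    cn_rows: list[dict] = []

    def emit(sv: dict, origin: str, label: str) -> None:
        sv_rows.append(sv)
        truth_rows.append({"sample_id": sv["sample_id"], "origin": origin,
                           "label": label})

    # --- background / burden process (stream 0 + per-sample offsets)
    meta_rng = _child_rng(spec.seed, 0)
    ages = meta_rng.uniform(0.5, 17.5, size=len(metadata))
    metadata["age_at_diagnosis"] = np.round(ages, 1)
    bg_frames: list[pd.DataFrame] = []
    for si, row in metadata.iterrows():
        rng = _child_rng(spec.seed, 1000 + si)
        if spec.use_type_burden:
            mu = spec.type_burden.get(row["cancer_type"], 5.0)
            n_bg = int(rng.poisson(mu))
        else:
            # two breakpoints per SV, so halve the breakpoint rate
            n_bg = int(rng.poisson(
                spec.background_rate_per_mb * genome.total_bp / 1e6 / 2.0
            ))
        bg_frames.append(_background_sv_frame(rng, genome, row["sample_id"], n_bg))

    # --- planted hotspots (stream 1)
    hs_truth_rows = []
    hs_rng = _child_rng(spec.seed, 1)
    for hi, hs in enumerate(spec.planted_hotspots):
        hid = hs.hotspot_id or f"planted{hi:03d}"
        hit_samples = sorted(
            hs_rng.choice(sample_ids, size=min(hs.n_samples_hit, len(sample_ids)),
                          replace=False)
        )
        anchors = []
        for sid in hit_samples:
            a = int(round(hs.anchor + hs_rng.normal(0, hs.jitter_sd)))
            p = int(round(hs.partner + hs_rng.normal(0, hs.jitter_sd)))
            a = min(max(1, a), genome.chrom_lengths[hs.chrom])
            p = min(max(1, p), genome.chrom_lengths[hs.chrom])
            lo, hi_ = min(a, p), max(a, p)
            emit(dict(chrom1=hs.chrom, pos1=lo, strand1="+",
                      chrom2=hs.chrom, pos2=hi_, strand2="-",
                      sv_type=hs.sv_type, sample_id=sid),
                 "hotspot", hid)
            anchors.append(a)
        hs_truth_rows.append({
            "hotspot_id": hid, "chrom": hs.chrom,
            "anchor": hs.anchor, "partner": hs.partner,
            "start": min(anchors), "end": max(anchors),
            "n_samples_hit": len(hit_samples),
        })
    hotspot_truth = pd.DataFrame(hs_truth_rows, columns=[
        "hotspot_id", "chrom", "anchor", "partner", "start", "end", "n_samples_hit",
    ])

    # --- chromothripsis bursts (stream 2)
    ct_rng = _child_rng(spec.seed, 2)
    for bi, burst in enumerate(spec.bursts):
        bid = burst.burst_id or f"burst{bi:03d}"
        n = burst.n_svs
        pts = np.sort(ct_rng.integers(burst.start, burst.end, size=2 * n))
        # join point i to point i+n: every interval partially overlaps its
        # neighbors (interleaved chain), as expected for shattered fragments
        for i in range(n):
            emit(dict(chrom1=burst.chrom, pos1=int(pts[i]), strand1="+",
                      chrom2=burst.chrom, pos2=int(pts[i + n]), strand2="-",
                      sv_type=str(ct_rng.choice(["DEL", "INV", "DUP"])),
                      sample_id=burst.sample_id),
                 "chromothripsis", bid)
        # oscillating CN segments across the burst region
        bounds = np.linspace(burst.start, burst.end, burst.n_cn_segments + 1).astype(int)
        for k in range(burst.n_cn_segments):
            cn_rows.append({
                "sample_id": burst.sample_id, "chrom": burst.chrom,
                "start": int(bounds[k]) + (1 if k else 0),
                "end": int(bounds[k + 1]),
                "copy_number": burst.cn_states[k % 2],
            })

    # --- signature-mixture SVs (stream 3)
    if spec.signature_profiles is not None and spec.signature_exposures is not None:
        from .catalog import CHANNELS  # local import to avoid a cycle

        profiles = np.asarray(spec.signature_profiles, dtype=float)
        exposures = np.asarray(spec.signature_exposures, dtype=float)
        if profiles.shape[1] != len(CHANNELS):
            raise ValueError("signature profiles must have 32 channels")
        sig_rng = _child_rng(spec.seed, 3)
        cluster_centers: dict = {}
        for si in range(exposures.shape[0]):
            sid = f"SIG-{si:03d}"
            if sid not in set(metadata["sample_id"]):
                metadata = pd.concat([metadata, pd.DataFrame([{
                    "sample_id": sid, "patient_id": f"P-{sid}",
                    "cancer_type": "OS", "category": "solid",
                    "age_at_diagnosis": 10.0, "tp53_status": "unknown",
                    "chromothripsis": "unknown",
                }])], ignore_index=True)
            w = exposures[si] @ profiles
            w = w / w.sum()
            counts = sig_rng.multinomial(spec.signature_svs_per_sample, w)
            for ch_idx, cnt in enumerate(counts):
                for _ in range(cnt):
                    emit(_materialize_channel_sv(sig_rng, genome, sid,
                                                 CHANNELS[ch_idx], cluster_centers),
                         "signature", f"sig_channel:{CHANNELS[ch_idx]}")

    # --- multi-sample patients (stream 4)
    ev_rng = _child_rng(spec.seed, 4)
    for patient in spec.multi_sample_patients:
        p_svs, p_truth = plant_multisample_patient(patient, genome, ev_rng)
        for sid in sorted(p_svs["sample_id"].unique()):
            metadata = pd.concat([metadata, pd.DataFrame([{
                "sample_id": sid, "patient_id": patient.patient_id,
                "cancer_type": "OS", "category": "solid",
                "age_at_diagnosis": 10.0, "tp53_status": "unknown",
                "chromothripsis": "unknown",
            }])], ignore_index=True)
        for (_, sv), (_, tr) in zip(p_svs.iterrows(), p_truth.iterrows()):
            emit(sv.to_dict(), "evolution", tr["label"])

    background = pd.concat(bg_frames, ignore_index=True) if bg_frames else \
        pd.DataFrame(columns=SV_COLUMNS)
    bg_truth = pd.DataFrame({
        "sample_id": background["sample_id"],
        "origin": "background", "label": "background",
    })
    planted = pd.DataFrame(sv_rows, columns=SV_COLUMNS)
    svs = pd.concat([background, planted], ignore_index=True)
    svs = assign_sv_ids(svs)
    truth = pd.concat(
        [bg_truth, pd.DataFrame(truth_rows, columns=["sample_id", "origin", "label"])],
        ignore_index=True,
    )
    truth.insert(0, "sv_id", svs["sv_id"].to_numpy())
    cn = pd.DataFrame(cn_rows, columns=["sample_id", "chrom", "start", "end",
                                        "copy_number"])
    return SyntheticCohort(
        svs=svs, metadata=metadata.reset_index(drop=True), cn_segments=cn,
        truth=truth, hotspot_truth=hotspot_truth, rss_sites=spec.planted_rss,
    )
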