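"""Hotspot statistic: NN distances, cutoff mixture, segmentation, Poisson, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from svscape import hotspots as hs
from svscape.records import GenomeModel
from svscape.simulate import CohortSpec, PlantedHotspot, generate_cohort
from conftest import make_svs


def bp_frame(rows):
    """rows: (chrom, pos, sample_id)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "sample_id"])
    df["sv_id"] = [f"sv{i}" for i in range(len(df))]
    df["end_index"] = 1
    return df


class TestNNDistances:
    def test_symmetric_pair(self):
        d = hs.nn_distances(bp_frame([("chr1", 100, "A"), ("chr1", 150, "B")]))
        assert d.tolist() == [50, 50]

    def test_intra_sample_neighbors_ignored(self):
        d = hs.nn_distances(bp_frame([
            ("chr1", 100, "A"), ("chr1", 120, "A"), ("chr1", 500, "B"),
        ]))
        assert d.tolist() == [400, 380, 380]

    def test_no_cross_sample_neighbor_is_infinite(self):
        d = hs.nn_distances(bp_frame([
            ("chr1", 100, "A"), ("chr1", 200, "A"), ("chr2", 5, "B"),
        ]))
        assert np.isinf(d).all()

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"chr{rng.integers(1, 4)}", int(rng.integers(1, 5000)),
             f"S{rng.integers(0, 5)}")
            for _ in range(200)
        ]
        bps = bp_frame(rows)
        got = hs.nn_distances(bps)
        for i, (c, p, s) in enumerate(rows):
            ref = [
                abs(p - p2) for (c2, p2, s2) in rows if c2 == c and s2 != s
            ]
            expected = min(ref) if ref else np.inf
            assert got[i] == expected

    def test_planted_hotspots_create_short_distance_mode(self, small_genome):
        """Background alone is unimodal; planting recurrent loci adds a
        second mode below 100 bp (the pediatric-style dual-peak shape)."""
        base = CohortSpec(
            n_samples={"B-ALL": 40}, genome=small_genome,
            background_rate_per_mb=0.3, seed=5,
        )
        bg = generate_cohort(base)
        d_bg = hs.nn_distances(hs.breakpoints_from_svs(bg.svs))
        frac_bg = np.mean(d_bg[np.isfinite(d_bg)] < 100)

        planted = CohortSpec(
            n_samples={"B-ALL": 40}, genome=small_genome,
            background_rate_per_mb=0.3, seed=5,
            planted_hotspots=[
                PlantedHotspot(f"chr{1 + i % 5}", 2_000_000 * (1 + i),
                               2_000_000 * (1 + i) + 150_000, 10, jitter_sd=20)
                for i in range(8)
            ],
        )
        ch = generate_cohort(planted)
        d_hs = hs.nn_distances(hs.breakpoints_from_svs(ch.svs))
        frac_hs = np.mean(d_hs[np.isfinite(d_hs)] < 100)
        assert frac_bg < 0.02
        assert frac_hs > 3 * frac_bg


class TestEstimateCutoff:
    def test_point_masses_separate(self):
        d = np.array([10.0] * 200 + [10_000.0] * 200)
        est = hs.estimate_cutoff(d)
        assert 10 < est.cutoff_bp < 10_000
        assert not est.fallback

    def test_recovers_analytic_posterior_crossing(self):
        rng = np.random.default_rng(11)
        d = np.concatenate([
            10 ** rng.normal(1.2, 0.3, 5000), 10 ** rng.normal(4.0, 0.4, 5000)
        ])
        est = hs.estimate_cutoff(d, seed=11)
        crossing = brentq(
            lambda x: stats.norm.pdf(x, 1.2, 0.3) - stats.norm.pdf(x, 4.0, 0.4),
            1.2, 4.0,
        )
        assert abs(est.boundary_log10 - crossing) < 0.15

    def test_unseparated_distances_fall_back_to_default(self):
        rng = np.random.default_rng(1)
        d = 10 ** rng.normal(3.0, 0.2, 2000)  # one lognormal mode
        est = hs.estimate_cutoff(d)
        assert est.fallback
        assert est.cutoff_bp == hs.DEFAULT_CUTOFF_BP

    def test_too_few_distances_raise(self):
        with pytest.raises(ValueError, match="fixed cutoff"):
            hs.estimate_cutoff(np.array([50.0] * 30))


class TestSegmentBreakpoints:
    def test_chaining_and_singleton_discard(self):
        bps = bp_frame([
            ("chr1", 100, "A"), ("chr1", 150, "B"), ("chr1", 400, "A"),
        ])
        segments, members = hs.segment_breakpoints(bps, cutoff_bp=98)
        assert len(segments) == 1
        seg = segments.iloc[0]
        assert (seg["start"], seg["end"], seg["n"], seg["n_samples"]) == (100, 150, 2, 2)
        assert set(members["pos"]) == {100, 150}

    def test_single_sample_runs_never_segment(self):
        bps = bp_frame([("chr1", 100 + 10 * i, "A") for i in range(10)])
        segments, _ = hs.segment_breakpoints(bps, cutoff_bp=98)
        assert len(segments) == 0

    def test_matches_brute_force_chaining(self):
        rng = np.random.default_rng(9)
        rows = [
            ("chr1", int(p), f"S{rng.integers(0, 4)}")
            for p in np.sort(rng.integers(1, 20_000, 120))
        ]
        bps = bp_frame(rows)
        cutoff = 98
        segments, _ = hs.segment_breakpoints(bps, cutoff)

        # oracle: filter by cross-sample NN, then chain sorted gaps <= cutoff
        d = hs.nn_distances(bps)
        elig = sorted(
            (p for (c, p, s), di in zip(rows, d) if di <= cutoff)
        )
        runs, cur = [], [elig[0]]
        for p in elig[1:]:
            if p - cur[-1] <= cutoff:
                cur.append(p)
            else:
                runs.append(cur)
                cur = [p]
        runs.append(cur)
        expected = [(r[0], r[-1], len(r)) for r in runs if len(r) >= 2]
        got = [tuple(x) for x in segments[["start", "end", "n"]].to_numpy()]
        assert got == expected

    def test_planted_hotspot_yields_both_end_segments(self, small_genome):
        spec = CohortSpec(
            n_samples={"B-ALL": 12}, genome=small_genome,
            background_rate_per_mb=0.0, seed=2,
            planted_hotspots=[
                PlantedHotspot("chr1", 10_000_000, 10_200_000, 8, jitter_sd=20)
            ],
        )
        cohort = generate_cohort(spec)
        bps = hs.breakpoints_from_svs(cohort.svs)
        segments, _ = hs.segment_breakpoints(bps, 98)
        # both the anchor and the partner end cluster: 8 breakpoints each
        assert sorted(segments["n"].tolist()) == [8, 8]


class TestPoissonTest:
    def test_zero_count_gives_p_one(self):
        _, p = hs.poisson_test(0, 980, 98)
        assert p == 1.0

    def test_lambda_is_length_over_cutoff(self):
        lam, _ = hs.poisson_test(5, 980, 98)
        assert lam == pytest.approx(10.0)

    def test_unit_lambda_six_breakpoints(self):
        # oracle: 1 - sum_{k<6} e^-1 / k!
        expected = 1.0 - sum(math.exp(-1) / math.factorial(k) for k in range(6))
        lam, p = hs.poisson_test(6, 98, 98)
        assert lam == 1.0
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(5.94e-4, rel=2e-3)

    @pytest.mark.parametrize("lam_len", [10, 98, 980, 4900])
    def test_monotone_in_n_and_length(self, lam_len):
        ps = [hs.poisson_test(n, lam_len, 98)[1] for n in range(0, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        p_longer = [hs.poisson_test(10, L, 98)[1] for L in (10, 98, 980, 9800)]
        assert all(a <= b for a, b in zip(p_longer, p_longer[1:]))


class TestBH:
    def test_qvalues_monotone_and_above_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = hs.bh_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallHotspots:
    def test_row_order_and_sample_relabeling_invariance(self, small_genome):
        spec = CohortSpec(
            n_samples={"B-ALL": 15}, genome=small_genome,
            background_rate_per_mb=0.3, seed=4,
            planted_hotspots=[
                PlantedHotspot("chr2", 5_000_000, 5_150_000, 8, jitter_sd=15)
            ],
        )
        svs = generate_cohort(spec).svs
        base = hs.call_hotspots(svs, cutoff_bp=98)

        shuffled = svs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(
            sample_id=shuffled["sample_id"].map(lambda s: "X" + s)
        )
        for variant in (shuffled, relabeled):
            res = hs.call_hotspots(variant, cutoff_bp=98)
            got = res.hotspots[["chrom", "start", "end", "n", "n_samples"]]
            want = base.hotspots[["chrom", "start", "end", "n", "n_samples"]]
            pd.testing.assert_frame_equal(got, want)

    def test_null_cohort_rarely_calls_hotspots(self, small_genome):
        spec = CohortSpec(
            n_samples={"B-ALL": 50}, genome=small_genome,
            background_rate_per_mb=1.0, seed=8,
        )
        res = hs.call_hotspots(generate_cohort(spec).svs, cutoff_bp=98)
        assert len(res.tested) > 20
        assert len(res.hotspots) <= 0.05 * len(res.tested)

    def test_recovers_planted_hotspots(self, small_genome):
        hotspots = [
            PlantedHotspot(f"chr{1 + i % 5}", 3_000_000 + 4_000_000 * (i // 5),
                           3_200_000 + 4_000_000 * (i // 5), 8, jitter_sd=15,
                           hotspot_id=f"h{i}")
            for i in range(10)
        ]
        spec = CohortSpec(
            n_samples={"B-ALL": 30}, genome=small_genome,
            background_rate_per_mb=0.05, seed=6, planted_hotspots=hotspots,
        )
        cohort = generate_cohort(spec)
        res = hs.call_hotspots(cohort.svs, cutoff_bp=98)
        recovered = 0
        for t in cohort.hotspot_truth.itertuples(index=False):
            hit = res.hotspots[
                (res.hotspots["chrom"] == t.chrom)
                & (res.hotspots["start"] <= t.end)
                & (res.hotspots["end"] >= t.start)
            ]
            recovered += len(hit) > 0
        assert recovered >= 9
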