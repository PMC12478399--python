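"""Truncal/shared/private grouping and multi-sample SV matching."""

import numpy as np
import pandas as pd
import pytest

from svscape import evolution as evo
from svscape.records import GenomeModel
from svscape.simulate import (
    CohortSpec,
    MultiSamplePatient,
    generate_cohort,
    plant_multisample_patient,
)
from conftest import make_svs


class TestMatchAcrossSamples:
    def test_identical_sv_in_three_samples(self):
        svs = make_svs([
            ("chr1", 1000, "chr1", 50_000, "DEL", s) for s in ("M1", "M2", "M3")
        ])
        m = evo.match_svs_across_samples(svs)
        assert m.shape == (1, 3)
        assert m.iloc[0].all()

    def test_offset_within_tolerance_matches(self):
        svs = make_svs([
            ("chr1", 1000, "chr1", 50_000, "DEL", "M1"),
            ("chr1", 1005, "chr1", 50_003, "DEL", "M2"),
        ])
        m = evo.match_svs_across_samples(svs, tolerance_bp=10)
        assert m.shape == (1, 2)
        m2 = evo.match_svs_across_samples(svs, tolerance_bp=2)
        assert m2.shape == (2, 2)

    def test_type_mismatch_never_matches(self):
        svs = make_svs([
            ("chr1", 1000, "chr1", 50_000, "DEL", "M1"),
            ("chr1", 1000, "chr1", 50_000, "DUP", "M2"),
        ])
        assert evo.match_svs_across_samples(svs).shape[0] == 2

    def test_pairwise_oracle_on_random_patient(self):
        rng = np.random.default_rng(6)
        rows = []
        anchors = rng.integers(1, 1_000_000, size=20)
        for a in anchors:
            for s in ("M1", "M2"):
                if rng.random() < 0.7:
                    rows.append((
                        "chr1", int(a + rng.integers(-3, 4)),
                        "chr1", int(a + 60_000 + rng.integers(-3, 4)),
                        "DEL", s,
                    ))
        if not rows:
            pytest.skip("degenerate draw")
        svs = make_svs(rows)
        m = evo.match_svs_across_samples(svs, tolerance_bp=10)
        # anchors are far apart, so groups = number of distinct anchors used
        used = {
            min(r[1] // 1000 for r in rows if abs(r[1] - a) < 500)
            for a in anchors
            if any(abs(r[1] - a) < 500 for r in rows)
        }
        assert m.shape[0] == len(used)


class TestGroupSVs:
    def _presence(self, rows, samples):
        return pd.DataFrame(rows, columns=samples,
                            index=[f"sv{i}" for i in range(len(rows))])

    def test_truncal_shared_private_labels(self):
        samples = [f"P1-M{i}" for i in (1, 2, 3, 4, 5, 6)]
        presence = self._presence([
            [True] * 6,
            [False, True, True, False, False, False],   # shared:M2-M3
            [True, False, False, False, False, False],  # private:M1
        ], samples)
        groups = evo.group_svs(presence)
        assert groups.tolist() == ["truncal", "shared:M2-M3", "private:M1"]

    def test_invariant_under_sample_reordering(self):
        samples = [f"P1-M{i}" for i in (1, 2, 3, 4)]
        presence = self._presence(
            [[True, True, False, False], [True, True, True, True]], samples
        )
        g1 = evo.group_svs(presence)
        g2 = evo.group_svs(presence[list(reversed(samples))])
        assert g1.tolist() == g2.tolist()

    def test_groups_partition_the_sv_set(self):
        rng = np.random.default_rng(3)
        samples = [f"P-M{i}" for i in range(1, 5)]
        rows = []
        for _ in range(40):
            row = rng.random(4) < 0.5
            if row.any():
                rows.append(row.tolist())
        presence = self._presence(rows, samples)
        groups = evo.group_svs(presence)
        assert len(groups) == len(presence)
        assert groups.value_counts().sum() == len(rows)


class TestPlantAndRecover:
    def test_two_sample_patient_split(self, small_genome):
        rng = np.random.default_rng(0)
        patient = MultiSamplePatient("P1", n_samples=2, n_truncal=5,
                                     n_shared=0, n_private=3)
        svs, truth = plant_multisample_patient(patient, small_genome, rng)
        per_sample = svs.groupby("sample_id").size()
        assert (per_sample >= 5).all()
        assert (truth["label"] == "truncal").sum() == 10  # 5 SVs x 2 carriers
        assert truth["label"].str.startswith("private").sum() == 3

    def test_shared_requires_three_samples(self, small_genome):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="strict subset"):
            plant_multisample_patient(
                MultiSamplePatient("P1", 2, 1, n_shared=2, n_private=0),
                small_genome, rng,
            )

    def test_round_trip_recovers_truth_exactly(self, small_genome):
        """Grouping the generated per-sample SV sets reproduces the planted
        truncal/shared/private labels, including the M2-M3-style subset."""
        patients = [
            MultiSamplePatient("P1", 6, n_truncal=8, n_shared=4, n_private=5,
                               shared_subset=(1, 2)),
            MultiSamplePatient("P2", 2, n_truncal=6, n_shared=0, n_private=4),
            MultiSamplePatient("P3", 3, n_truncal=3, n_shared=2, n_private=2,
                               shared_subset=(0, 2)),
        ]
        spec = CohortSpec(
            n_samples={}, genome=small_genome, background_rate_per_mb=0.0,
            multi_sample_patients=patients, seed=7,
        )
        cohort = generate_cohort(spec)
        truth = cohort.truth.assign(
            patient_id=cohort.svs["sample_id"].str.rsplit("-", n=2).str[0]
        )
        for patient in patients:
            sids = cohort.metadata[
                cohort.metadata["patient_id"] == patient.patient_id
            ]["sample_id"]
            psvs = cohort.svs[cohort.svs["sample_id"].isin(sids)]
            presence = evo.match_svs_across_samples(psvs)
            groups = evo.group_svs(presence)
            expected = (
                truth[truth["sample_id"].isin(sids)]
                .drop_duplicates(subset=["label", "sample_id"])
                .groupby("label").size()
            )
            got_counts = groups.value_counts()
            want_counts = {
                "truncal": patient.n_truncal,
            }
            if patient.n_shared:
                subset_key = "shared:" + "-".join(
                    f"M{i+1}" for i in sorted(patient.shared_subset)
                )
                want_counts[subset_key] = patient.n_shared
            for label, count in want_counts.items():
                assert got_counts.get(label, 0) == count, (patient.patient_id, label)
            n_private = sum(
                v for k, v in got_counts.items() if k.startswith("private")
            )
            assert n_private == patient.n_private


class TestGroupChannelProfiles:
    def test_pure_group_has_unit_proportion(self):
        groups = pd.Series(["truncal"] * 10, index=[f"k{i}" for i in range(10)])
        channels = pd.Series(["non-clustered_del_10-100Kb"] * 10,
                             index=groups.index)
        prof = evo.group_channel_profiles(groups, channels)
        assert prof.loc[0, "non-clustered_del_10-100Kb"] == 1.0
        assert prof.loc[0, "low_confidence"]  # 10 < 20

    def test_min_size_flag_boundary(self):
        idx = [f"k{i}" for i in range(20)]
        groups = pd.Series(["truncal"] * 20, index=idx)
        channels = pd.Series(["non-clustered_trans"] * 20, index=idx)
        prof = evo.group_channel_profiles(groups, channels)
        assert not prof.loc[0, "low_confidence"]

    def test_similar_planted_proportions_agree(self):
        rng = np.random.default_rng(9)
        opts = ["non-clustered_del_10-100Kb", "non-clustered_del_100Kb-1Mb"]
        idx_t = [f"t{i}" for i in range(300)]
        idx_r = [f"r{i}" for i in range(300)]
        groups = pd.Series(["truncal"] * 300 + ["private:M2"] * 300,
                           index=idx_t + idx_r)
        channels = pd.Series(
            list(rng.choice(opts, size=300, p=[0.6, 0.4]))
            + list(rng.choice(opts, size=300, p=[0.6, 0.4])),
            index=idx_t + idx_r,
        )
        prof = evo.group_channel_profiles(groups, channels).set_index("group")
        diff = abs(prof.loc["truncal", opts[0]] - prof.loc["private:M2", opts[0]])
        assert diff < 0.12  # multinomial error at n=300
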