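"""Burden summaries, genic annotation, and regulatory locus rules."""

import numpy as np
import pandas as pd
import pytest

from svscape import burden as bd
from conftest import make_svs


def meta_frame(entries):
    """entries: (sample_id, cancer_type, category, tp53, chromothripsis, age)"""
    return pd.DataFrame(entries, columns=[
        "sample_id", "cancer_type", "category", "tp53_status",
        "chromothripsis", "age_at_diagnosis",
    ]).assign(patient_id=lambda d: "P-" + d["sample_id"])


class TestBurdenSummary:
    def test_medians_match_direct_tally(self):
        rng = np.random.default_rng(1)
        meta_rows, sv_rows = [], []
        counts = {}
        for i in range(12):
            sid = f"S{i:02d}"
            ctype = "OS" if i < 6 else "AML"
            n = int(rng.integers(0, 30))
            counts[sid] = n
            meta_rows.append((sid, ctype, "solid" if ctype == "OS" else "hematological",
                              "wildtype", "negative", 5.0 + i))
            for j in range(n):
                sv_rows.append(("chr1", 1_000_000 + j * 100_000, "chr1",
                                1_000_000 + j * 100_000 + 50_000, "DEL", sid))
        summary = bd.burden_summary(make_svs(sv_rows), meta_frame(meta_rows))
        per_type = summary["per_type"].set_index("cancer_type")
        os_counts = [counts[f"S{i:02d}"] for i in range(6)]
        assert per_type.loc["OS", "median_svs"] == float(np.median(os_counts))
        assert per_type.loc["OS", "n_samples"] == 6

    def test_zero_sv_samples_stay_in_median(self):
        meta = meta_frame([
            ("S1", "WT", "solid", "wildtype", "negative", 3.0),
            ("S2", "WT", "solid", "wildtype", "negative", 4.0),
        ])
        svs = make_svs([])
        summary = bd.burden_summary(svs, meta)
        assert summary["per_type"].iloc[0]["median_svs"] == 0.0

    def test_tp53_test_requires_three_altered(self):
        rows = []
        for i in range(10):
            status = "altered" if i < 2 else "wildtype"
            rows.append((f"S{i}", "HGG", "brain", status, "negative", 8.0))
        svs = make_svs([
            ("chr1", 1_000_000 * (i + 1), "chr1", 1_000_000 * (i + 1) + 50_000,
             "DEL", f"S{i}") for i in range(10)
        ])
        summary = bd.burden_summary(svs, meta_frame(rows))
        assert np.isnan(summary["tp53"].iloc[0]["p_value"])  # only 2 altered

    def test_age_correlation_detects_planted_trend(self):
        rows, sv_rows = [], []
        for i in range(12):
            sid = f"S{i}"
            rows.append((sid, "ACT", "solid", "wildtype", "negative", float(i)))
            for j in range(2 * i):  # burden grows with age
                sv_rows.append(("chr2", 1_000_000 + j * 200_000, "chr2",
                                1_000_000 + j * 200_000 + 20_000, "DEL", sid))
        summary = bd.burden_summary(make_svs(sv_rows), meta_frame(rows))
        r = summary["age_correlation"].iloc[0]["R"]
        assert r > 0.95


class TestAnnotateGenic:
    def test_breakpoint_in_gene(self, genes_bed):
        svs = make_svs([("chr13", 48_951_000, "chr13", 49_500_000, "DEL", "S1")])
        hits = bd.annotate_genic(svs, genes_bed, {"DMD"})
        assert set(hits["gene"]) == {"RB1", "RCBTB2"}
        assert not hits["fragile_site"].any()

    def test_intergenic_sv_has_no_hits(self, genes_bed):
        svs = make_svs([("chr13", 1_000, "chr13", 2_000_000, "DEL", "S1")])
        assert len(bd.annotate_genic(svs, genes_bed)) == 0

    def test_fragile_site_flag(self, genes_bed):
        genes = pd.concat([genes_bed, pd.DataFrame([{
            "chrom": "chrX", "start": 31_137_345, "end": 33_229_673,
            "name": "DMD",
        }])], ignore_index=True)
        svs = make_svs([("chrX", 31_500_000, "chrX", 31_800_000, "DEL", "S1")])
        hits = bd.annotate_genic(svs, genes, {"DMD"})
        assert hits.iloc[0]["gene"] == "DMD"
        assert hits.iloc[0]["fragile_site"]


@pytest.fixture(scope="module")
def rules():
    return bd.load_regulatory_rules()


class TestRegulatoryRules:
    def _one(self, chrom1, pos1, chrom2, pos2, sv_type):
        return make_svs([(chrom1, pos1, chrom2, pos2, sv_type, "S1")]).iloc[0]

    def test_nme_duplication(self, rules):
        sv = self._one("chr8", 130_165_000, "chr8", 130_200_000, "DUP")
        assert "NME" in bd.classify_regulatory(sv, rules)

    def test_nme_requires_duplication(self, rules):
        sv = self._one("chr8", 130_165_000, "chr8", 130_200_000, "DEL")
        assert "NME" not in bd.classify_regulatory(sv, rules)

    @pytest.mark.parametrize("span,expected", [(900_000, True), (1_200_000, False)])
    def test_flt3_span_bound_is_strict(self, rules, span, expected):
        sv = self._one("chr13", 28_600_000, "chr13", 28_600_000 + span, "DEL")
        assert ("FLT3" in bd.classify_regulatory(sv, rules)) == expected

    def test_unrelated_deletion_matches_nothing(self, rules):
        sv = self._one("chr2", 50_000_000, "chr2", 50_400_000, "DEL")
        assert bd.classify_regulatory(sv, rules) == []

    def test_tert_upstream_hit_but_not_gene_encompassing_del(self, rules):
        up = self._one("chr5", 1_400_000, "chr5", 1_500_000, "DEL")
        assert "TERT" in bd.classify_regulatory(up, rules)
        # deletion swallowing the whole TERT gene body is excluded
        across = self._one("chr5", 1_240_000, "chr5", 1_400_000, "DEL")
        assert "TERT" not in bd.classify_regulatory(across, rules)

    def test_sncaip_size_limit(self, rules):
        small = self._one("chr5", 121_600_000, "chr5", 121_700_000, "DUP")
        assert "SNCAIP" in bd.classify_regulatory(small, rules)
        large = self._one("chr5", 121_000_000, "chr5", 122_900_000, "DUP")
        assert "SNCAIP" not in bd.classify_regulatory(large, rules)

    def test_dux4_igh_translocation_needs_partner(self, rules):
        hit = self._one("chr4", 191_000_000, "chr14", 106_500_000, "TRA")
        assert "DUX4-IGH" in bd.classify_regulatory(hit, rules)
        miss = self._one("chr4", 191_000_000, "chr2", 50_000_000, "TRA")
        assert "DUX4-IGH" not in bd.classify_regulatory(miss, rules)

    def test_rule_independence(self, rules):
        """Disabling one rule never changes another rule's verdict."""
        sv = self._one("chr8", 130_165_000, "chr8", 130_200_000, "DUP")
        full = set(bd.classify_regulatory(sv, rules))
        without = [r for r in rules if r["name"] != "FLT3"]
        assert set(bd.classify_regulatory(sv, without)) == full - {"FLT3"}

    def test_malformed_interval_raises_with_rule_name(self, tmp_path):
        bad = tmp_path / "rules.yaml"
        bad.write_text(
            "rules:\n"
            "  - name: BROKEN\n"
            "    overlaps: {chrom: chr1, start: 500, end: 100}\n"
        )
        with pytest.raises(ValueError, match="BROKEN"):
            bd.load_regulatory_rules(bad)


class TestDisruptionPrevalence:
    def test_truth_tally(self):
        meta = meta_frame([
            (f"S{i}", "B-ALL", "hematological", "wildtype", "negative", 5.0)
            for i in range(100)
        ])
        ann = pd.DataFrame({
            "sv_id": [f"sv{i}" for i in range(10)],
            "sample_id": [f"S{i}" for i in range(10)],
            "gene": "RB1",
        })
        prev = bd.disruption_prevalence(ann, meta)
        assert prev.iloc[0]["percent"] == 10.0

    def test_idempotent_under_sv_duplication(self):
        meta = meta_frame([
            ("S1", "B-ALL", "hematological", "wildtype", "negative", 5.0),
            ("S2", "B-ALL", "hematological", "wildtype", "negative", 6.0),
        ])
        ann = pd.DataFrame({
            "sv_id": ["a", "b", "c"],
            "sample_id": ["S1", "S1", "S1"],
            "gene": "ETV6",
        })
        prev = bd.disruption_prevalence(ann, meta)
        assert prev.iloc[0]["n_samples_impacted"] == 1
        assert prev.iloc[0]["percent"] == 50.0

    def test_no_hits_gives_empty_table(self):
        meta = meta_frame([
            ("S1", "B-ALL", "hematological", "wildtype", "negative", 5.0),
        ])
        prev = bd.disruption_prevalence(
            pd.DataFrame(columns=["sv_id", "sample_id", "gene"]), meta
        )
        assert len(prev) == 0
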