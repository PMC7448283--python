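"""Feature matching, presence calls, and the three subtractive Venn stages."""

import numpy as np
import pandas as pd
import pytest

from nodmet.simulate import gen_feature_tables, study_venn_design
from nodmet.venn import (
    FeatureTable,
    TreatmentDesign,
    match_features,
    presence_calls,
    run_venn,
    stage1_microbe_features,
    stage2_unique,
    stage3_exclusion,
)


def table(treatment, replicate, rows):
    df = pd.DataFrame(rows, columns=["feature_id", "mz", "rt_min",
                                     "intensity"])
    return FeatureTable(treatment, replicate, df)


class TestMatchFeatures:
    def test_identical_tables_align_one_to_one(self):
        rows = [("f1", 400.0, 2.0, 1.0), ("f2", 800.0, 5.0, 1.0)]
        aligned = match_features([table("A", "r1", rows),
                                  table("B", "r1", rows)])
        assert len(aligned.clusters) == 2
        assert aligned.presence.all().all()

    def test_sub_tolerance_jitter_preserves_clustering(self):
        rng = np.random.default_rng(1)
        base = [(f"f{i}", mz, rt, 1.0)
                for i, (mz, rt) in enumerate(zip(rng.uniform(200, 2000, 40),
                                                 rng.uniform(0, 14, 40)))]
        jittered = [
            (fid, mz * (1 + rng.uniform(-3e-6, 3e-6)), rt, 1.0)
            for fid, mz, rt, _ in base
        ]
        clean = match_features([table("A", "r1", base),
                                table("B", "r1", base)], mz_tol_ppm=10)
        noisy = match_features([table("A", "r1", base),
                                table("B", "r1", jittered)], mz_tol_ppm=10)
        assert len(noisy.clusters) == len(clean.clusters)

    def test_well_separated_features_stay_apart(self):
        rows = [("f1", 1000.0, 2.0, 1.0), ("f2", 1000.05, 2.0, 1.0)]  # 50 ppm
        aligned = match_features([table("A", "r1", rows)], mz_tol_ppm=10)
        assert len(aligned.clusters) == 2

    def test_rt_separation_prevents_merging(self):
        rows = [("f1", 1000.0, 2.0, 1.0), ("f2", 1000.001, 8.0, 1.0)]
        aligned = match_features([table("A", "r1", rows)], rt_tol_min=0.2)
        assert len(aligned.clusters) == 2

    def test_chained_clusters_are_flagged(self):
        # features each within tolerance of the next, spanning > 2x tol
        rows = [("f1", 1000.000, 2.0, 1.0), ("f2", 1000.008, 2.0, 1.0),
                ("f3", 1000.016, 2.0, 1.0), ("f4", 1000.024, 2.0, 1.0)]
        aligned = match_features([table("A", "r1", rows)], mz_tol_ppm=10)
        assert len(aligned.clusters) == 1
        assert bool(aligned.clusters["chained"].iloc[0])

    def test_non_positive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_features([table("A", "r1", [("f", 100.0, 1.0, 1.0)])],
                           mz_tol_ppm=0)


class TestPresenceCalls:
    def make_aligned(self, detected_replicates):
        tables = []
        for rep in range(1, 5):
            rows = ([("f1", 500.0, 3.0, 1.0)]
                    if rep in detected_replicates else [])
            rows.append(("anchor", 900.0, 9.0, 1.0))
            tables.append(table("T", f"r{rep}", rows))
        return match_features(tables)

    @pytest.mark.parametrize(
        "detected,expected_present",
        [({1, 2, 3, 4}, True), ({1}, False), ({1, 2}, True)],
    )
    def test_half_replicate_rule_is_inclusive(self, detected,
                                              expected_present):
        aligned = self.make_aligned(detected)
        calls = presence_calls(aligned, min_replicate_fraction=0.5)
        feature = aligned.clusters.index[
            aligned.clusters["mz"].round() == 500
        ][0]
        assert (feature in calls["T"]) is expected_present

    def test_invalid_fraction_rejected(self):
        aligned = self.make_aligned({1})
        with pytest.raises(ValueError):
            presence_calls(aligned, min_replicate_fraction=0.0)


class TestStages:
    design = TreatmentDesign(
        microbes=["X", "Y"],
        triples={
            "X": {"in_vitro": "ivX", "single": "sX", "full": "full"},
            "Y": {"in_vitro": "ivY", "single": "sY", "full": "full"},
        },
        baseline="base",
        exclusion_communities={"noX": frozenset({"Y"})},
    )

    def test_stage1_intersection_minus_baseline(self):
        presence = {
            "ivX": {"a", "b", "c"}, "sX": {"a", "b"}, "full": {"a", "b", "d"},
            "base": {"b"}, "ivY": set(), "sY": set(),
        }
        assert stage1_microbe_features(self.design, presence, "X") == {"a"}

    def test_stage1_missing_treatment_named(self):
        with pytest.raises(KeyError, match="sX"):
            stage1_microbe_features(self.design, {"ivX": set()}, "X")

    def test_stage2_discards_shared_features(self):
        s2 = stage2_unique({"X": {"a", "s"}, "Y": {"b", "s"}})
        assert s2 == {"X": {"a"}, "Y": {"b"}}

    def test_stage3_drops_leaked_features(self):
        assert stage3_exclusion({"a", "b", "c"}, [{"b"}, {"c", "z"}]) == {"a"}


class TestPaperDesign:
    def test_planted_counts_recovered_exactly(self):
        spec = study_venn_design(seed=11)
        tables, design, manifest = gen_feature_tables(spec)
        _, s1, s2, s3, report = run_venn(tables, design)
        for m in design.microbes:
            assert len(s2[m]) == manifest["expected_counts"]["stage2"][m]
            assert len(s3[m]) == manifest["expected_counts"]["stage3"][m]
        counts = sorted(len(v) for v in s2.values())
        assert counts == [0, 4, 5, 16, 37]
        assert len(s3["B_brevis_Ag35"]) == 13

    def test_nesting_and_disjointness_invariants(self):
        tables, design, _ = gen_feature_tables(study_venn_design(seed=3))
        _, s1, s2, s3, _ = run_venn(tables, design)
        for m in design.microbes:
            assert s3[m] <= s2[m] <= s1[m]
        microbes = design.microbes
        for i, a in enumerate(microbes):
            for b in microbes[i + 1:]:
                assert not (s2[a] & s2[b])

    def test_permutation_invariance_of_table_order(self):
        tables, design, _ = gen_feature_tables(study_venn_design(seed=5))
        _, _, s2_fwd, s3_fwd, _ = run_venn(tables, design)
        rng = np.random.default_rng(0)
        shuffled = list(tables)
        rng.shuffle(shuffled)
        _, _, s2_shuf, s3_shuf, _ = run_venn(shuffled, design)
        assert s2_fwd == s2_shuf
        assert s3_fwd == s3_shuf

    def test_report_rows_match_stage_sets(self):
        tables, design, _ = gen_feature_tables(study_venn_design(seed=2))
        _, s1, s2, s3, report = run_venn(tables, design)
        row = report.loc["B_brevis_Ag35"]
        assert (row["stage1"], row["stage2_unique"], row["stage3_final"]) == (
            len(s1["B_brevis_Ag35"]), len(s2["B_brevis_Ag35"]),
            len(s3["B_brevis_Ag35"]),
        )
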