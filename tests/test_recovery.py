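"""Recovery rates, relative recovery, co-occurrence and interaction calls."""

import numpy as np
import pandas as pd
import pytest

from nodmet.recovery import (
    NoduleTable,
    classify_interactions,
    cooccurrence_counts,
    fold_change,
    recovery_rates,
    relative_recovery,
)
from nodmet.simulate import (
    ColonizationSpec,
    gen_nodule_table,
    study_colonization_spec,
)


def build_table(spec):
    """spec: {treatment: {strain: [cfu per nodule]}} with equal-length lists."""
    rows, inoc = [], {}
    for tr, strains in spec.items():
        inoc[tr] = frozenset(strains)
        n = len(next(iter(strains.values())))
        for i in range(n):
            for strain, cfus in strains.items():
                rows.append((tr, f"{tr}_n{i}", strain, cfus[i]))
    df = pd.DataFrame(rows, columns=["treatment", "nodule_id", "strain",
                                     "cfu"])
    return NoduleTable(df, inoc)


class TestRecoveryRates:
    def test_zero_of_fifteen(self):
        t = build_table({"solo": {"Ps": [0] * 15}})
        assert recovery_rates(t).loc[("solo", "Ps"), "rate_pct"] == 0.0

    def test_all_positive(self):
        t = build_table({"solo": {"A": [5] * 12}})
        assert recovery_rates(t).loc[("solo", "A"), "rate_pct"] == 100.0

    def test_ten_of_twelve(self):
        t = build_table({"solo": {"A": [3] * 10 + [0, 0]}})
        assert recovery_rates(t).loc[("solo", "A"),
                                     "rate_pct"] == pytest.approx(83.3, abs=0.1)

    def test_uninoculated_strain_not_reported(self):
        t = build_table({"solo": {"A": [1, 1]}})
        assert ("solo", "B") not in recovery_rates(t).index

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            recovery_rates(NoduleTable(
                pd.DataFrame(columns=["treatment", "nodule_id", "strain",
                                      "cfu"]),
                {},
            ))

    def test_strain_outside_inoculum_rejected(self):
        df = pd.DataFrame(
            [("t", "n1", "ghost", 5)],
            columns=["treatment", "nodule_id", "strain", "cfu"],
        )
        with pytest.raises(ValueError):
            NoduleTable(df, {"t": frozenset({"A"})})


class TestRelativeRecovery:
    def test_baseline_against_itself_is_zero(self):
        t = build_table({"sA": {"A": [1] * 5 + [0] * 5}})
        rel = relative_recovery(recovery_rates(t), {"A": "sA"})
        assert rel.loc[("sA", "A"), "delta_pct"] == 0.0
        assert rel.loc[("sA", "A"), "sign"] == "zero"

    def test_large_gain_is_positive(self):
        t = build_table({
            "sA": {"A": [0] * 12},
            "pair": {"A": [1] * 10 + [0, 0], "B": [1] * 10 + [0, 0]},
            "sB": {"B": [1] * 12},
        })
        rel = relative_recovery(recovery_rates(t), {"A": "sA", "B": "sB"})
        assert rel.loc[("pair", "A"), "delta_pct"] == pytest.approx(83.3,
                                                                    abs=0.1)
        assert rel.loc[("pair", "A"), "sign"] == "positive"

    def test_trio_drop_is_negative(self):
        t = build_table({
            "pair": {"A": [1] * 10 + [0, 0], "B": [1] * 12},
            "trio": {"A": [1, 1] + [0] * 10, "B": [1] * 12,
                     "C": [1] * 12},
            "sA": {"A": [1] * 5 + [0] * 7},
            "sB": {"B": [1] * 12},
            "sC": {"C": [1] * 12},
        })
        rel = relative_recovery(recovery_rates(t),
                                {"A": "sA", "B": "sB", "C": "sC"})
        assert rel.loc[("trio", "A"), "sign"] == "negative"

    def test_missing_baseline_rejected(self):
        t = build_table({"pair": {"A": [1] * 4, "B": [1] * 4}})
        with pytest.raises(KeyError):
            relative_recovery(recovery_rates(t), {"A": "pair"})


class TestCooccurrence:
    def test_all_empty_nodules_fall_in_none_class(self):
        t = build_table({"tr": {"A": [0] * 6, "B": [0] * 6}})
        counts = cooccurrence_counts(t, "tr")
        assert counts == {frozenset(): 6}

    def test_pair_subset_counting(self):
        t = build_table({
            "tr": {"A": [1] * 8 + [0] * 4, "B": [1] * 8 + [0, 0, 1, 1]},
        })
        counts = cooccurrence_counts(t, "tr")
        assert counts[frozenset({"A", "B"})] == 8
        assert counts[frozenset({"B"})] == 2
        assert counts[frozenset()] == 2

    def test_partition_property_on_random_tables(self):
        t = gen_nodule_table(study_colonization_spec(seed=9))
        for tr in t.treatments():
            counts = cooccurrence_counts(t, tr)
            assert sum(counts.values()) == len(t.nodules_of(tr))


class TestCfuSummary:
    def test_printed_means_give_four_fold_drop(self):
        # deterministic tables pinned to the printed means 280 and 69
        t = build_table({
            "alone": {"Pa": [280] * 10},
            "with_ps": {"Pa": [69] * 10, "Ps": [65] * 10},
        })
        summary = recovery_rates(t)
        fc = fold_change(summary, "Pa", "alone", "with_ps")
        assert fc["fold"] == pytest.approx(280 / 69, abs=1e-9)
        assert round(fc["fold"], 2) == 4.06

    def test_identical_treatments_fold_one(self):
        t = build_table({"a": {"X": [10, 20]}, "b": {"X": [10, 20]}})
        assert fold_change(recovery_rates(t), "X", "a", "b")["fold"] == 1.0

    def test_zero_denominator_is_undefined(self):
        t = build_table({"a": {"X": [10]}, "b": {"X": [0]}})
        assert fold_change(recovery_rates(t), "X", "a", "b")[
            "fold"] == "undefined"

    def test_mean_includes_zero_count_nodules(self):
        t = build_table({"a": {"X": [100, 0, 0, 0]}})
        assert recovery_rates(t).loc[("a", "X"), "mean_cfu"] == 25.0


class TestClassifyInteractions:
    def test_cooperation_when_both_members_gain(self):
        t = build_table({
            "sA": {"A": [0] * 10},
            "sB": {"B": [1] * 5 + [0] * 5},
            "pair": {"A": [50] * 8 + [0, 0], "B": [60] * 9 + [0]},
        })
        rel = relative_recovery(recovery_rates(t), {"A": "sA", "B": "sB"})
        calls = classify_interactions(t, rel)
        assert calls["pairs"][("A", "B")]["label"] == "cooperation"

    def test_mixed_when_recovery_and_cfu_disagree(self):
        t = build_table({
            "sA": {"A": [0] * 10},
            "sB": {"B": [280] * 5 + [0] * 5},
            "pair": {"A": [50] * 8 + [0, 0], "B": [69] * 9 + [0]},
        })
        rel = relative_recovery(recovery_rates(t), {"A": "sA", "B": "sB"})
        calls = classify_interactions(t, rel)
        assert calls["pairs"][("A", "B")]["label"] == "mixed"
        assert calls["pairs"][("A", "B")]["cfu_conflict"] == ["B"]

    def test_trio_competition_from_third_member(self):
        t = build_table({
            "sA": {"A": [0] * 10},
            "sB": {"B": [1] * 5 + [0] * 5},
            "sC": {"C": [1] * 4 + [0] * 6},
            "pair": {"A": [50] * 8 + [0, 0], "B": [60] * 9 + [0]},
            "trio": {"A": [1] + [0] * 9, "B": [1, 1] + [0] * 8,
                     "C": [1] * 5 + [0] * 5},
        })
        rel = relative_recovery(recovery_rates(t),
                                {"A": "sA", "B": "sB", "C": "sC"})
        calls = classify_interactions(t, rel)
        drops = {(e["strain"], e["third_member"]) for e in
                 calls["trio_effects"]}
        assert ("A", "C") in drops and ("B", "C") in drops


def test_estimated_rates_match_bernoulli_truth_within_three_se():
    """On large synthetic tables the empirical recovery rate sits within
    three binomial standard errors of the colonization probability."""
    probs = {"X": 0.83, "Y": 0.4, "Z": 0.0}
    n = 1000
    spec = ColonizationSpec(
        probabilities={"big": probs},
        cfu_lognormal={"big": {s: (4.0, 0.8) for s in probs}},
        nodules={"big": n},
        seed=123,
    )
    rates = recovery_rates(gen_nodule_table(spec))
    for strain, p in probs.items():
        est = rates.loc[("big", strain), "rate_pct"] / 100
        se = np.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= max(3 * se, 1e-12), strain
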