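"""Stratified audit: A2 accuracy, set sizes, confidences, regions, report."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dermconformal as dc
from dermconformal.audit import build_audit_report
from dermconformal.conformal import PredictionSet


def make_set(sid, labels, confs, truth):
    return PredictionSet(
        sample_id=sid, entries=tuple(zip(labels, confs)), truth=truth
    )


@pytest.fixture()
def rank_sets():
    """Three sets of class 0 with the truth at ranks 1, 2, 3."""
    return [
        make_set("a", [0, 1, 2], [0.7, 0.2, 0.1], truth=0),
        make_set("b", [1, 0, 2], [0.5, 0.3, 0.2], truth=0),
        make_set("c", [1, 2, 0], [0.5, 0.3, 0.2], truth=0),
    ]


class TestA2Accuracy:
    def test_counts_truth_in_top_two(self, rank_sets):
        out = dc.a2_accuracy(rank_sets, n_classes=3)
        assert out[0] == pytest.approx(100 * 2 / 3)

    def test_truth_always_top1_gives_100(self):
        sets = [make_set(str(i), [i % 2], [0.9], truth=i % 2) for i in range(6)]
        out = dc.a2_accuracy(sets, n_classes=2)
        assert out[0] == 100.0 and out[1] == 100.0

    def test_singleton_wrong_label_gives_0(self):
        sets = [make_set("x", [1], [0.9], truth=0)]
        assert dc.a2_accuracy(sets, n_classes=2)[0] == 0.0

    def test_absent_class_is_undefined(self, rank_sets):
        assert np.isnan(dc.a2_accuracy(rank_sets, n_classes=3)[1])

    def test_unordered_entries_rejected(self):
        bad = PredictionSet(sample_id="z", entries=((0, 0.1), (1, 0.9)), truth=0)
        with pytest.raises(ValueError, match="ordered"):
            dc.a2_accuracy([bad])

    def test_grouped_counts(self, rank_sets):
        groups = ["g1", "g1", "g2"]
        out = dc.a2_accuracy(rank_sets, groups=groups, n_classes=3)
        assert out["g1"][0] == 100.0
        assert out["g2"][0] == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_a2_dominates_top1(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for i in range(40):
            p = rng.dirichlet(np.ones(4))
            order = np.argsort(-p)
            k = int(rng.integers(1, 5))
            sets.append(
                make_set(str(i), order[:k].tolist(), np.sort(p)[::-1][:k].tolist(),
                         truth=int(rng.integers(4)))
            )
        a2 = dc.a2_accuracy(sets, n_classes=4)
        top1 = {
            c: 100 * np.mean([s.labels[0] == c for s in sets if s.truth == c])
            if any(s.truth == c for s in sets) else np.nan
            for c in range(4)
        }
        for c in range(4):
            if not np.isnan(a2[c]):
                assert a2[c] >= top1[c] - 1e-9


class TestSetSizeDistribution:
    def test_all_singletons_mass_at_one(self):
        sets = [make_set(str(i), [0], [0.9], truth=0) for i in range(5)]
        meta = {str(i): {"sex": "male"} for i in range(5)}
        hist = dc.set_size_distribution(sets, meta, "sex")
        assert hist == {"male": {1: 5}}

    def test_histogram_totals_equal_group_sizes(self, rank_sets):
        meta = {"a": {"sex": "male"}, "b": {"sex": "female"}, "c": {"sex": "female"}}
        hist = dc.set_size_distribution(rank_sets, meta, "sex")
        assert sum(hist["female"].values()) == 2
        assert sum(hist["male"].values()) == 1

    def test_missing_attribute_becomes_unknown(self, rank_sets):
        hist = dc.set_size_distribution(rank_sets, {}, "age_band")
        assert sum(hist["unknown"].values()) == 3


class TestGtConfidence:
    def test_uniform_rows_full_sets_give_eighth(self):
        calib = dc.CalibrationResult(alpha=0.2, n=1, scores=np.zeros(1), q_hat=1.0)
        sets = dc.build_sets(np.full((4, 8), 0.125), calib, truths=[0, 1, 2, 3])
        vals = dc.gt_confidence_values(sets, n_classes=8)
        assert all(v == pytest.approx(0.125) for c in range(4) for v in vals[c])

    def test_sets_missing_truth_are_excluded(self, rank_sets):
        missing = make_set("d", [1, 2], [0.6, 0.4], truth=0)
        vals = dc.gt_confidence_values(rank_sets + [missing], n_classes=3)
        assert len(vals[0]) == 3  # only the three truth-containing sets

    def test_lengths_match_truth_containing_counts(self, rank_sets):
        vals = dc.gt_confidence_values(rank_sets, n_classes=3)
        assert [len(vals[c]) for c in range(3)] == [3, 0, 0]


class TestTop2Guarantee:
    def test_identical_to_gt_values_when_truth_ranks_first(self):
        sets = [make_set(str(i), [0, 1], [0.8, 0.1], truth=0) for i in range(4)]
        assert dc.top2_guarantee(sets, n_classes=2) == dc.gt_confidence_values(
            sets, n_classes=2
        )

    def test_truth_at_rank_three_yields_empty(self):
        sets = [make_set("x", [1, 2, 0], [0.5, 0.3, 0.2], truth=0)]
        assert dc.top2_guarantee(sets, n_classes=3)[0] == []

    def test_hand_built_four_sets(self, rank_sets):
        extra = make_set("d", [0, 2], [0.55, 0.25], truth=0)
        out = dc.top2_guarantee(rank_sets + [extra], n_classes=3)
        assert sorted(out[0]) == pytest.approx([0.3, 0.55, 0.7])


class TestRegionTable:
    def test_single_site_cohort_gives_100_percent(self):
        sets = [make_set(str(i), [0], [0.9], truth=0) for i in range(5)]
        meta = {str(i): {"site": "anterior torso"} for i in range(5)}
        table = dc.region_table(sets, meta, n_classes=1)
        assert table[0] == [("anterior torso", 100.0)]

    def test_hand_built_site_counts(self):
        sites = ["head/neck"] * 3 + ["anterior torso"] * 6 + ["palms/soles"]
        sets, meta = [], {}
        for i, site in enumerate(sites):
            sets.append(make_set(str(i), [0], [0.9], truth=0))
            meta[str(i)] = {"site": site}
        table = dc.region_table(sets, meta, n_classes=1)
        assert table[0] == [
            ("anterior torso", 60.0),
            ("head/neck", 30.0),
            ("palms/soles", 10.0),
        ]

    def test_only_top2_correct_samples_counted(self):
        in_top2 = make_set("a", [0, 1], [0.6, 0.3], truth=0)
        rank3 = make_set("b", [1, 2, 0], [0.5, 0.3, 0.2], truth=0)
        meta = {"a": {"site": "s1"}, "b": {"site": "s2"}}
        table = dc.region_table([in_top2, rank3], meta, n_classes=3)
        assert table[0] == [("s1", 100.0)]

    def test_percentages_sum_to_100_when_sites_known(self, rng):
        sets, meta = [], {}
        for i in range(30):
            sets.append(make_set(str(i), [0, 1], [0.6, 0.3], truth=int(rng.integers(2))))
            meta[str(i)] = {"site": rng.choice(["s1", "s2", "s3"])}
        table = dc.region_table(sets, meta, n_classes=2)
        for c in range(2):
            if table[c]:
                assert sum(p for _, p in table[c]) == pytest.approx(100.0)


class TestPermutationTest:
    def test_obvious_group_difference_gets_small_p(self):
        sets = [make_set(str(i), list(range(4)), [0.4, 0.3, 0.2, 0.1], truth=0)
                for i in range(30)]
        sets += [make_set(str(30 + i), [0], [0.9], truth=0) for i in range(30)]
        groups = ["big"] * 30 + ["small"] * 30
        diff, p = dc.set_size_permutation_test(sets, groups, "big", seed=1)
        assert diff == pytest.approx(3.0)
        assert p < 0.01

    def test_degenerate_grouping_rejected(self):
        sets = [make_set("a", [0], [0.9], truth=0)]
        with pytest.raises(ValueError, match="nonempty"):
            dc.set_size_permutation_test(sets, ["g"], "g")


class TestAuditReport:
    def test_report_round_trips_to_json(self, rank_sets, tmp_path):
        meta = {
            "a": {"sex": "male", "age_band": "<30", "site": "s1"},
            "b": {"sex": "female", "age_band": "30-60", "site": "s2"},
            "c": {"sex": "female", "age_band": ">60", "site": "s1"},
        }
        report = build_audit_report(rank_sets, meta, n_classes=3,
                                    calibration=(0.01, 0.02))
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["n_samples"] == 3
        assert loaded["a2_overall"]["0"] == pytest.approx(100 * 2 / 3)
        assert loaded["calibration"] == {"ece": 0.01, "mce": 0.02}

    def test_csv_bundle_written(self, rank_sets, tmp_path):
        report = build_audit_report(rank_sets, {}, n_classes=3)
        report.write_csvs(tmp_path)
        for name in ("fig3_setsize.csv", "fig4_a2.csv", "fig5_violin.csv",
                     "fig6_top2.csv", "table10_regions.csv"):
            assert (tmp_path / name).exists()
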