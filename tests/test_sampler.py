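"""Dynamic F1-weight sampler: weight formulas, regulation, epoch sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dermconformal as dc
from dermconformal.sampler import kfold_mean_f1

positive_counts = st.lists(st.integers(min_value=1, max_value=10**6), min_size=2, max_size=12)
f1_lists = st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=12)


class TestFrequencyWeights:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10, 40], [0.8, 0.2]),
            ([7, 7, 7], [1 / 3, 1 / 3, 1 / 3]),
            ([11557, 239], [0.020262, 0.979738]),
        ],
    )
    def test_inverse_frequency_values(self, counts, expected):
        w = dc.frequency_weights(counts).weights
        assert w == pytest.approx(expected, abs=1e-6)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dc.frequency_weights([10, 0])

    @given(positive_counts, st.integers(min_value=2, max_value=100))
    def test_scale_invariance(self, counts, factor):
        base = dc.frequency_weights(counts).weights
        scaled = dc.frequency_weights([c * factor for c in counts]).weights
        assert np.allclose(base, scaled)

    @given(positive_counts)
    def test_normalised_to_one(self, counts):
        w = dc.frequency_weights(counts).weights
        assert abs(w.sum() - 1.0) < 1e-9
        assert (w >= 0).all()


class TestF1Weights:
    @pytest.mark.parametrize(
        "f1, floor, expected",
        [
            ([0.5, 1.0], 1e-3, [2 / 3, 1 / 3]),
            ([0.7, 0.7, 0.7], 1e-3, [1 / 3, 1 / 3, 1 / 3]),
            ([0.0, 0.5], 1e-3, [1000 / 1002, 2 / 1002]),
        ],
    )
    def test_inverse_f1_values(self, f1, floor, expected):
        w = dc.f1_weights(f1, floor).weights
        assert w == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dc.f1_weights([0.5, 1.2])

    def test_nan_treated_as_floor(self):
        w = dc.f1_weights([np.nan, 0.5], f1_floor=1e-3).weights
        assert w[0] > 0.99

    @given(f1_lists, st.integers(min_value=0, max_value=11), st.floats(0.01, 0.5))
    def test_lowering_one_f1_never_lowers_its_weight(self, f1, pos, shrink):
        pos = pos % len(f1)
        before = dc.f1_weights(f1).weights[pos]
        lowered = list(f1)
        lowered[pos] = lowered[pos] * shrink
        after = dc.f1_weights(lowered).weights[pos]
        assert after >= before - 1e-12

    @given(f1_lists)
    def test_normalised_to_one(self, f1):
        w = dc.f1_weights(f1).weights
        assert abs(w.sum() - 1.0) < 1e-9


class TestRegulateWeights:
    def test_equal_weights_pass_through_unchanged(self):
        raw = dc.ClassWeights(weights=np.full(4, 0.25), origin="f1")
        out = dc.regulate_weights(raw, dc.SamplerConfig())
        assert np.allclose(out.weights, raw.weights)

    def test_worked_example_majority_baseline_minority_kept(self):
        # mean 0.25, population SD 0.2598 -> lambda 0.5098, beta 0.7696:
        # class 0 is above threshold and under the cap, others go to baseline
        raw = dc.ClassWeights(weights=np.array([0.70, 0.10, 0.10, 0.10]), origin="f1")
        cfg = dc.SamplerConfig(lambda_multiplier=1.0, beta_multiplier=2.0)
        out = dc.regulate_weights(raw, cfg)
        expected = np.array([0.70, 0.25, 0.25, 0.25]) / 1.45
        assert out.weights == pytest.approx(expected, abs=1e-12)

    def test_beta_caps_runaway_minority_weight(self):
        raw = dc.ClassWeights(weights=np.array([0.97, 0.01, 0.01, 0.01]), origin="f1")
        cfg = dc.SamplerConfig(lambda_multiplier=1.0, beta_multiplier=1.5)
        out = dc.regulate_weights(raw, cfg)
        w = raw.weights
        beta = w.mean() + 1.5 * w.std()
        assert out.weights.max() <= beta / (beta + 3 * w.mean()) + 1e-12

    def test_floor_reading_keeps_majority_weights(self):
        raw = dc.ClassWeights(weights=np.array([0.70, 0.10, 0.10, 0.10]), origin="f1")
        out = dc.regulate_weights(raw, dc.SamplerConfig(beta_role="floor"))
        expected = np.array([0.70, 0.25, 0.25, 0.25]) / 1.45
        assert out.weights == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=10)
    )
    def test_output_is_a_distribution(self, raw_vals):
        raw = np.array(raw_vals)
        cw = dc.ClassWeights(weights=raw / raw.sum(), origin="f1")
        out = dc.regulate_weights(cw, dc.SamplerConfig())
        assert abs(out.weights.sum() - 1.0) < 1e-9
        assert (out.weights >= 0).all()


class TestSampleEpoch:
    def test_class_shares_follow_weights_within_3_sigma(self):
        weights = dc.ClassWeights(weights=np.array([0.9, 0.1]), origin="f1")
        labels = np.array([0] * 300 + [1] * 700)
        draws = dc.sample_epoch(weights, labels, n_draws=10000, seed=1)
        share0 = (labels[draws] == 0).mean()
        assert abs(share0 - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 10000)

    def test_uniform_weights_uniform_shares(self):
        weights = dc.ClassWeights(weights=np.full(4, 0.25), origin="frequency")
        labels = np.repeat(np.arange(4), 50)
        draws = dc.sample_epoch(weights, labels, n_draws=8000, seed=2)
        shares = np.bincount(labels[draws], minlength=4) / 8000
        assert np.all(np.abs(shares - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 8000))

    def test_zero_weight_class_never_drawn(self):
        weights = dc.ClassWeights(weights=np.array([1.0, 0.0]), origin="f1")
        labels = np.array([0] * 50 + [1] * 50)
        draws = dc.sample_epoch(weights, labels, n_draws=5000, seed=3)
        assert (labels[draws] == 0).all()

    def test_deterministic_given_seed(self):
        weights = dc.ClassWeights(weights=np.array([0.5, 0.5]), origin="f1")
        labels = np.array([0] * 30 + [1] * 30)
        a = dc.sample_epoch(weights, labels, 100, seed=4)
        b = dc.sample_epoch(weights, labels, 100, seed=4)
        assert np.array_equal(a, b)

    def test_positive_weight_class_without_records_rejected(self):
        weights = dc.ClassWeights(weights=np.array([0.5, 0.5]), origin="f1")
        with pytest.raises(ValueError, match=r"\[1\]"):
            dc.sample_epoch(weights, np.zeros(10, dtype=int), 10, seed=0)


class TestKFoldMeanF1:
    def test_perfect_predictions_give_unit_f1(self):
        labels = np.repeat([0, 1, 2], 20)
        probs = np.eye(3)[labels]
        assert np.allclose(dc.kfold_mean_f1(probs, labels, k=5, seed=0), 1.0)

    def test_k1_falls_back_to_whole_set_f1(self):
        # confusion: truth [0,0,0,0,1,1], preds [0,0,1,1,1,1]
        # class 0: precision 1, recall 1/2 -> F1 2/3; class 1: precision 1/2,
        # recall 1 -> F1 2/3
        labels = np.array([0, 0, 0, 0, 1, 1])
        preds = np.array([0, 0, 1, 1, 1, 1])
        probs = np.eye(2)[preds]
        out = dc.kfold_mean_f1(probs, labels, k=1, seed=0)
        assert out == pytest.approx([2 / 3, 2 / 3])

    def test_matches_per_fold_recount(self):
        """Aggregation agrees with an independent per-fold confusion recount."""
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, 90)
        probs = rng.dirichlet(np.ones(3), size=90)
        preds = probs.argmax(axis=1)
        k, seed = 3, 7
        out = dc.kfold_mean_f1(probs, labels, k=k, seed=seed)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        expected = np.zeros(3)
        counts = np.zeros(3)
        for _, idx in skf.split(probs, labels):
            for c in range(3):
                if not (labels[idx] == c).any():
                    continue
                tp = ((preds[idx] == c) & (labels[idx] == c)).sum()
                fp = ((preds[idx] == c) & (labels[idx] != c)).sum()
                fn = ((preds[idx] != c) & (labels[idx] == c)).sum()
                f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
                expected[c] += f1
                counts[c] += 1
        assert out == pytest.approx(expected / counts)

    def test_oversized_k_is_reduced(self):
        labels = np.array([0] * 20 + [1] * 3)
        probs = np.eye(2)[labels]
        out = kfold_mean_f1(probs, labels, k=10, seed=0)
        assert np.allclose(out, 1.0)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dc.kfold_mean_f1(np.zeros((0, 2)), np.array([], dtype=int), k=2, seed=0)
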