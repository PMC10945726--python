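import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from motifselect import (
    CVConfig,
    average_precision,
    calibrate_threshold,
    cohens_d,
    generate_nonpositive,
    label_preference,
    outer_cv,
    split_folds,
)

from conftest import coupled_sample, independent_sample


def oracle_average_precision(pos, neg):
    """Naive O(n^2) precision-recall integration over distinct thresholds."""
    scores = sorted(set(list(pos) + list(neg)), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in scores:
        tp = sum(1 for s in pos if s >= t)
        fp = sum(1 for s in neg if s >= t)
        precision = tp / (tp + fp)
        recall = tp / len(pos)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestSplitFolds:
    def test_even_split(self):
        folds = split_folds(range(14), 7, seed=11)
        assert sorted(len(f) for f in folds) == [2] * 7

    def test_uneven_split(self):
        folds = split_folds(range(15), 7, seed=11)
        assert sorted(len(f) for f in folds) == [2] * 6 + [3]

    def test_partition_and_determinism(self):
        a = split_folds(range(40), 7, seed=3)
        b = split_folds(range(40), 7, seed=3)
        assert a == b
        flat = [x for f in a for x in f]
        assert sorted(flat) == list(range(40))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_folds(range(5), 7, seed=0)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([3, 2], [1, 0]) == 1.0

    def test_single_positive_below_all_negatives(self):
        for n in (1, 5, 20):
            neg = list(range(1, n + 1))
            assert average_precision([0], neg) == pytest.approx(1 / (n + 1))

    def test_random_ranking_near_half(self):
        rng = np.random.default_rng(35)
        aps = [
            average_precision(rng.random(200), rng.random(200)) for _ in range(20)
        ]
        assert abs(np.mean(aps) - 0.5) < 0.05

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(36)
        for _ in range(30):
            # duplicate-prone integer scores exercise the tie handling
            pos = rng.integers(0, 10, size=rng.integers(1, 30)).astype(float)
            neg = rng.integers(0, 10, size=rng.integers(1, 30)).astype(float)
            assert average_precision(pos, neg) == pytest.approx(
                oracle_average_precision(pos, neg), abs=1e-12
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
            expected = average_precision_score(
                np.r_[np.ones(40), np.zeros(60)], np.r_[pos, neg]
            )
            assert average_precision(pos, neg) == pytest.approx(expected, abs=1e-12)

    def test_handles_minus_inf_scores(self):
        assert average_precision([1.0, -np.inf], [0.0]) == pytest.approx(
            oracle_average_precision([1.0, -np.inf], [0.0])
        )

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], [1.0])


class TestCalibrateThreshold:
    def test_midpoint_of_separating_gap(self):
        assert calibrate_threshold([3, 2], [1]) == pytest.approx(1.5)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(38)
        pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        t = calibrate_threshold(pos, neg)
        assert calibrate_threshold(pos + 5.0, neg + 5.0) == pytest.approx(t + 5.0)

    def test_identical_scores_warn(self):
        with pytest.warns(UserWarning):
            assert calibrate_threshold([1.0, 1.0], [1.0]) == 1.0

    def test_achieves_f1_one_when_separable(self):
        t = calibrate_threshold([5, 4, 3], [2, 1])
        assert 2 < t < 3


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([0.5, 0.6, 0.7], [0.7, 0.6, 0.5]) == pytest.approx(0.0)

    def test_worked_value(self):
        # means 0.90 vs 0.85, both variances 0.01 -> s = 0.1, D = 0.5
        rng = np.random.default_rng(39)
        a = rng.normal(size=7)
        a = (a - a.mean()) / a.std(ddof=1) * 0.1 + 0.90
        p = rng.normal(size=7)
        p = (p - p.mean()) / p.std(ddof=1) * 0.1 + 0.85
        assert cohens_d(a, p) == pytest.approx(0.5)

    def test_pooled_sd_of_equal_variances(self):
        rng = np.random.default_rng(40)
        a = rng.normal(0.8, 0.05, 7)
        shifted = a + 0.1  # identical variance, shifted mean
        expected = 0.1 / a.std(ddof=1)
        assert cohens_d(shifted, a) == pytest.approx(expected)

    def test_degenerate_variance(self):
        assert cohens_d([0.5] * 7, [0.5] * 7) == 0.0
        assert cohens_d([0.6] * 7, [0.5] * 7) == np.inf
        assert cohens_d([0.4] * 7, [0.5] * 7) == -np.inf

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([0.5] * 7, [0.5] * 6)


class TestLabelPreference:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.4, "APFA"), (0.39, "PWM"), (-2.0, "PWM"), (5.0, "APFA"), (np.inf, "APFA")],
    )
    def test_threshold_rule(self, d, expected):
        assert label_preference(d) == expected


@pytest.fixture(scope="module")
def tiny_cfg(small_grid):
    return CVConfig(seed=11, apfa_grid=small_grid)


# module-scoped copy of the session fixtures for the expensive runs
@pytest.fixture(scope="module")
def small_grid():
    from motifselect import LearnApfaHyperparams

    return (LearnApfaHyperparams(0.3, 2, 0.5), LearnApfaHyperparams(1.0, 10, 0.5))


class TestOuterCV:
    def test_reproducible_bit_identical(self, genome, null, tiny_cfg):
        sample = coupled_sample(l=6, n=70, seed=41)
        neg = generate_nonpositive(genome, 6, sample.n, n_fragments=500, seed=11)
        a = outer_cv(sample, neg, tiny_cfg, null)
        b = outer_cv(sample, neg, tiny_cfg, null)
        assert a == b

    def test_coupled_sample_favors_apfa(self, genome, null, tiny_cfg):
        sample = coupled_sample(l=6, n=100, seed=42)
        neg = generate_nonpositive(genome, 6, sample.n, n_fragments=500, seed=11)
        mc = outer_cv(sample, neg, tiny_cfg, null)
        assert mc.mean_ap_apfa >= mc.mean_ap_pwm
        assert mc.d >= 0.4 and mc.preferred == "APFA"

    def test_independent_sample_similar_models(self, genome, null, tiny_cfg):
        sample = independent_sample(l=6, n=100, seed=43)
        neg = generate_nonpositive(genome, 6, sample.n, n_fragments=500, seed=11)
        mc = outer_cv(sample, neg, tiny_cfg, null)
        assert abs(mc.d) < 0.4 and mc.preferred == "PWM"

    def test_ap_values_in_range_and_fields_consistent(self, genome, null, tiny_cfg):
        sample = independent_sample(l=6, n=70, seed=44)
        neg = generate_nonpositive(genome, 6, sample.n, n_fragments=500, seed=11)
        mc = outer_cv(sample, neg, tiny_cfg, null)
        assert len(mc.ap_pwm) == len(mc.ap_apfa) == 7
        assert all(0 <= x <= 1 for x in mc.ap_pwm + mc.ap_apfa)
        assert mc.mean_ap_pwm == pytest.approx(np.mean(mc.ap_pwm))
        assert mc.best_hp in tiny_cfg.apfa_grid

    def test_sample_too_small_rejected(self, genome, null, tiny_cfg):
        sample = independent_sample(l=6, n=10, seed=45)
        neg = generate_nonpositive(genome, 6, sample.n, n_fragments=500, seed=11)
        with pytest.raises(ValueError):
            outer_cv(sample, neg, tiny_cfg, null)

    def test_single_grid_point_selected(self, genome, null, small_grid):
        cfg = CVConfig(seed=11, apfa_grid=small_grid[:1])
        sample = independent_sample(l=6, n=70, seed=46)
        neg = generate_nonpositive(genome, 6, sample.n, n_fragments=500, seed=11)
        mc = outer_cv(sample, neg, cfg, null)
        assert mc.best_hp == small_grid[0]


def test_cvconfig_validation():
    with pytest.raises(ValueError):
        CVConfig(k_folds=1)
    with pytest.raises(ValueError):
        CVConfig(apfa_grid=())
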