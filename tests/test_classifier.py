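"""Pattern-score model fit, scaling, ROC and peak counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srmeth import (
    RegimeSpec,
    RegionFeatures,
    fit_pattern_model,
    kde_peaks,
    pattern_score,
    pattern_score_array,
    region_features,
    roc,
    score_elements,
    simulate_regime_vectors,
)
from srmeth.classifier import PatternModel
from srmeth.features import aggregate_elements


def feature(region_id, sd_read, meth=0.5, stoch=0.3, sd_site=0.1, element_id="e"):
    return RegionFeatures(
        region_id=region_id,
        element_id=element_id,
        n_reads=8,
        mean_read_meth=meth,
        sd_read_meth=sd_read,
        mean_stochasticity=stoch,
        sd_site_meth=sd_site,
        per_site_meth=(meth,) * 5,
    )


def simulate_labeled_features(class0, class1, n_per_class, n_reads, seed):
    rng = np.random.default_rng(seed)
    out = ([], [])
    for label, regime in ((0, class0), (1, class1)):
        for i in range(n_per_class):
            vectors = simulate_regime_vectors(regime, 5, n_reads, rng)
            out[label].append(
                region_features(
                    vectors, region_id=f"c{label}r{i}", element_id=f"e{label}_{i // 4}",
                    min_reads=1,
                )
            )
    return out


class TestFitPatternModel:
    def test_separable_single_feature_classes(self):
        f0 = [feature(f"a{i}", sd_read=0.1 + 0.01 * i) for i in range(10)]
        f1 = [feature(f"b{i}", sd_read=0.4 + 0.01 * i) for i in range(10)]
        model = fit_pattern_model(f0, f1, feature_names=("sd_read_meth",))
        scores = [pattern_score(model, f) for f in f0 + f1]
        labels = [0] * 10 + [1] * 10
        assert roc(scores, labels).auc == 1.0

    def test_constant_feature_dropped_with_warning(self):
        f0 = [feature(f"a{i}", sd_read=0.1 + 0.01 * i) for i in range(10)]
        f1 = [feature(f"b{i}", sd_read=0.4 + 0.01 * i) for i in range(10)]
        with pytest.warns(UserWarning, match="mean_read_meth"):
            model = fit_pattern_model(
                f0, f1, feature_names=("mean_read_meth", "sd_read_meth")
            )
        assert model.feature_names == ("sd_read_meth",)

    def test_methylation_filter_applied_before_fit(self):
        f0 = [feature(f"a{i}", 0.1, meth=0.05) for i in range(5)]
        f1 = [feature(f"b{i}", 0.4, meth=0.5) for i in range(5)]
        with pytest.raises(ValueError, match="non-empty"):
            fit_pattern_model(f0, f1, min_meth=0.10)

    def test_permuted_labels_give_near_zero_marginal_r2(self):
        rng = np.random.default_rng(0)
        regime = RegimeSpec("cmt2_like", p=0.4, cwa_boost=0.0)
        f0, f1 = simulate_labeled_features(regime, regime, 300, 8, seed=1)
        model = fit_pattern_model(f0, f1)
        assert max(model.per_feature_r2.values()) < 0.02

    def test_read_sd_dominates_for_bimodal_vs_bernoulli(self):
        """A read mixture (fully methylated vs background) against a
        mean-matched Bernoulli class is separated mainly by
        read-methylation SD, checked on the marginal r² of each feature."""
        bimodal = RegimeSpec("drm2_like", p=0.51, f_full=0.3, p_bg=0.3)
        bernoulli = RegimeSpec("cmt2_like", p=0.51, cwa_boost=0.0)
        f0, f1 = simulate_labeled_features(bernoulli, bimodal, 500, 12, seed=2)
        model = fit_pattern_model(f0, f1)
        r2 = model.per_feature_r2
        assert max(r2, key=r2.get) == "sd_read_meth"


class TestPatternScore:
    @pytest.fixture
    def model(self):
        f0 = [feature(f"a{i}", sd_read=0.1 + 0.05 * i) for i in range(5)]
        f1 = [feature(f"b{i}", sd_read=0.4 + 0.05 * i) for i in range(5)]
        return fit_pattern_model(f0, f1, feature_names=("sd_read_meth",))

    def test_training_extremes_map_to_zero_and_one(self, model):
        raws = model.raw_score(
            np.array([[0.1 + 0.05 * i] for i in range(5)] + [[0.4 + 0.05 * i] for i in range(5)])
        )
        scores = pattern_score_array(
            model,
            np.array([[0.1 + 0.05 * i] for i in range(5)] + [[0.4 + 0.05 * i] for i in range(5)]),
        )
        assert scores[np.argmin(raws)] == 0.0
        assert scores[np.argmax(raws)] == 1.0

    def test_out_of_range_clipped(self, model):
        assert pattern_score(model, feature("x", sd_read=50.0)) == 1.0
        assert pattern_score(model, feature("y", sd_read=-50.0)) == 0.0

    def test_missing_feature_is_error(self, model):
        class Incomplete:
            pass

        with pytest.raises(KeyError):
            pattern_score(model, Incomplete())

    def test_save_load_round_trip(self, model, tmp_path):
        path = tmp_path / "model.txt"
        model.save(path)
        loaded = PatternModel.load(path)
        assert loaded == model

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.5))
    def test_monotone_in_positive_coefficient_features(self, a, b, delta):
        model = PatternModel(
            feature_names=("f1", "f2"),
            coefficients=(0.8, -0.3),
            intercept=0.1,
            scale_low=0.0,
            scale_high=1.0,
        )
        base = model.raw_score(np.array([a, b]))
        bumped = model.raw_score(np.array([a + delta, b]))
        assert bumped >= base


class TestRoc:
    def test_perfect_ranking(self):
        assert roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_constant_scores_give_chance(self):
        assert roc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_hand_built_four_point_case(self):
        # pairs: (0.9,1) beats both negatives; (0.7,1) beats 0.1 only -> 3/4
        result = roc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert result.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], [1, 1])

    def test_curve_monotone(self):
        result = roc([0.3, 0.6, 0.2, 0.9, 0.5], [0, 1, 0, 1, 1])
        assert list(result.fpr) == sorted(result.fpr)
        assert list(result.tpr) == sorted(result.tpr)

    @settings(max_examples=80, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.integers(0, 1)), min_size=4, max_size=50
        )
    )
    def test_auc_equals_mann_whitney_pair_counting(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [l for _, l in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc(scores, labels).auc == pytest.approx(expected)


class TestKdePeaks:
    def test_jittered_point_mass_is_one_peak(self):
        rng = np.random.default_rng(0)
        values = 0.5 + rng.normal(0, 1e-3, size=200)
        assert kde_peaks(values).n_peaks == 1

    def test_balanced_separated_mixture_is_two_peaks(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [0.1 + rng.normal(0, 0.02, 100), 0.9 + rng.normal(0, 0.02, 100)]
        )
        result = kde_peaks(values)
        assert result.n_peaks == 2
        assert result.peak_positions[0] == pytest.approx(0.1, abs=0.05)
        assert result.peak_positions[1] == pytest.approx(0.9, abs=0.05)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0.2, 0.05, 60), rng.normal(0.8, 0.05, 60)])
        shuffled = values.copy()
        rng.shuffle(shuffled)
        assert kde_peaks(values).peak_positions == kde_peaks(shuffled).peak_positions

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kde_peaks([0.5] * 9)

    def test_zero_variance_degenerates_to_single_peak(self):
        result = kde_peaks([0.25] * 20)
        assert result.n_peaks == 1
        assert result.peak_positions[0] == pytest.approx(0.25, abs=0.01)


class TestRegimeRecovery:
    def test_region_auc_and_element_peaks_on_synthetic_regimes(self):
        """2000 regions per regime at default effect sizes: the fitted model
        separates them (AUC >= 0.9); element score distributions show two
        peaks for the mixture and one for a single regime."""
        from srmeth import CMT2_LIKE, DRM2_LIKE

        f0, f1 = simulate_labeled_features(DRM2_LIKE, CMT2_LIKE, 2000, 7, seed=3)
        model = fit_pattern_model(f0, f1)
        keep0 = [f for f in f0 if f.mean_read_meth >= 0.10]
        keep1 = [f for f in f1 if f.mean_read_meth >= 0.10]
        scores = [pattern_score(model, f) for f in keep0 + keep1]
        labels = [0] * len(keep0) + [1] * len(keep1)
        assert roc(scores, labels).auc >= 0.9

        elements0 = aggregate_elements(f0, min_regions=2)
        elements1 = aggregate_elements(f1, min_regions=2)
        mixed = [
            e.pattern_score for e in score_elements(model, elements0 + elements1)
        ]
        assert kde_peaks(mixed).n_peaks == 2
        single = [e.pattern_score for e in score_elements(model, elements1)]
        assert kde_peaks(single).n_peaks == 1
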