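"""Forest training, threshold optimization, importance, probability profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenlevels import (
    PREDICTOR_COLUMNS,
    ModelSpec,
    distance_to_perfect,
    fit_forest,
    optimize_threshold,
    permutation_importance,
    probability_profile,
    tune_mtry,
)
from pollenlevels.model import _metrics_at_cutoff


def make_feature_frame(X):
    return pd.DataFrame(X, columns=list(PREDICTOR_COLUMNS))


def separable_frame(n=120, seed=0):
    """Labels are a deterministic function of the GDD column."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 30))
    frame = make_feature_frame(X)
    y = frame["GDD_1DAYLAG"] > 0
    frame["GDD_1DAYLAG"] = frame["GDD_1DAYLAG"] + np.where(y, 3.0, -3.0)
    return frame, y.to_numpy()


# ---------------------------------------------------------------- distance


@pytest.mark.parametrize(
    "metrics, expected",
    [
        ((1, 1, 1, 1), 0.0),
        ((0.5, 0.5, 0.5, 0.5), 1.0),
        ((0.8, 0.9, 0.7, 0.95), 0.3774917),
    ],
)
def test_distance_examples(metrics, expected):
    assert distance_to_perfect(*metrics) == pytest.approx(expected)


def test_distance_rejects_out_of_range():
    with pytest.raises(ValueError):
        distance_to_perfect(1.2, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        distance_to_perfect(np.nan, 0.5, 0.5, 0.5)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(vals=st.lists(st.floats(0, 1), min_size=4, max_size=4))
def test_distance_zero_iff_perfect_and_symmetric(vals):
    d = distance_to_perfect(*vals)
    assert 0 <= d <= 2
    assert (d == 0) == all(v == 1 for v in vals)
    assert d == pytest.approx(distance_to_perfect(*reversed(vals)))


# ------------------------------------------------------- threshold optimizer


def test_separable_threshold_smallest_zero_distance_cutoff():
    probs = np.array([0.9] * 10 + [0.1] * 90)
    labels = np.array([True] * 10 + [False] * 90)
    res = optimize_threshold(probs, labels, ModelSpec())
    grid = ModelSpec().threshold_grid()
    zero_cutoffs = grid[(grid > 0.1) & (grid <= 0.9)]
    assert res.threshold_star == pytest.approx(zero_cutoffs[0])
    assert res.profile["distance"].min() == 0.0


def test_threshold_matches_brute_force_grid_argmin():
    """Exact agreement with an independent grid search on 50 random sets."""
    rng = np.random.default_rng(99)
    spec = ModelSpec()
    for _ in range(50):
        n = int(rng.integers(20, 200))
        probs = rng.random(n)
        labels = rng.random(n) < rng.uniform(0.1, 0.5)
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        res = optimize_threshold(probs, labels, spec)
        best_d, best_t = np.inf, None
        for t in spec.threshold_grid():
            pred = probs >= t
            tp = np.sum(pred & labels)
            fp = np.sum(pred & ~labels)
            tn = np.sum(~pred & ~labels)
            fn = np.sum(~pred & labels)
            four = [
                tp / (tp + fn) if tp + fn else 0,
                tn / (tn + fp) if tn + fp else 0,
                tp / (tp + fp) if tp + fp else 0,
                tn / (tn + fn) if tn + fn else 0,
            ]
            d = np.sqrt(sum((1 - m) ** 2 for m in four))
            if d < best_d:
                best_d, best_t = d, t
        assert res.threshold_star == pytest.approx(best_t)
        assert res.profile["distance"].min() == pytest.approx(best_d)


def test_degenerate_probabilities_flagged():
    with pytest.warns(UserWarning, match="not identifiable"):
        res = optimize_threshold(
            np.full(20, 0.3), np.array([True] * 5 + [False] * 15), ModelSpec()
        )
    assert res.degenerate
    assert len(res.profile) == 20


def test_threshold_rejects_single_class():
    with pytest.raises(ValueError):
        optimize_threshold(np.array([0.2, 0.4]), np.array([True, True]), ModelSpec())


def test_metrics_at_cutoff_resolves_undefined_to_zero():
    probs = np.array([0.1, 0.2])
    y = np.array([True, False])
    sens, spec, ppv, npv = _metrics_at_cutoff(probs, y, 0.9)  # nothing predicted high
    assert ppv == 0.0 and sens == 0.0 and spec == 1.0


# ------------------------------------------------------------------ tuning


def test_tune_single_candidate_is_identity():
    frame, y = separable_frame()
    spec = ModelSpec(ntree=30, mtry_grid=(3,), cv_folds=2, cv_repeats=1, seed=0)
    assert tune_mtry(frame, y, spec).mtry_star == 3


def test_tune_separable_prefers_smallest_mtry():
    frame, y = separable_frame(n=200)
    spec = ModelSpec(ntree=50, mtry_grid=(4, 12, 30), cv_folds=3, cv_repeats=1, seed=1)
    result = tune_mtry(frame, y, spec)
    assert (result.scores["score"] < 0.05).all()
    assert result.mtry_star == 4


def test_tune_deterministic_under_seed():
    frame, y = separable_frame(n=100, seed=5)
    spec = ModelSpec(ntree=30, mtry_grid=(5, 10), cv_folds=2, cv_repeats=1, seed=7)
    a = tune_mtry(frame, y, spec)
    b = tune_mtry(frame, y, spec)
    assert a.mtry_star == b.mtry_star
    np.testing.assert_array_equal(a.oof_probs, b.oof_probs)


def test_tune_rejects_single_class():
    frame, _ = separable_frame()
    spec = ModelSpec(ntree=10, mtry_grid=(3,), cv_folds=2, cv_repeats=1)
    with pytest.raises(ValueError, match="single class"):
        tune_mtry(frame, np.zeros(len(frame), dtype=bool), spec)


# ------------------------------------------------------------------ forest


def rank_auc(probs, y):
    """Rank-based AUC: probability a positive outranks a negative."""
    order = np.argsort(probs)
    ranks = np.empty(len(probs))
    ranks[order] = np.arange(1, len(probs) + 1)
    n_pos, n_neg = y.sum(), (~y).sum()
    return (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def test_forest_separates_training_data():
    frame, y = separable_frame(n=150, seed=2)
    spec = ModelSpec(ntree=50, seed=2)
    model = fit_forest(frame, y, mtry=5, spec=spec)
    probs = model.predict_proba_high(frame)
    assert rank_auc(probs, y) > 0.99


def test_forest_deterministic():
    frame, y = separable_frame(n=80, seed=3)
    spec = ModelSpec(ntree=40, seed=3)
    p1 = fit_forest(frame, y, 5, spec).predict_proba_high(frame)
    p2 = fit_forest(frame, y, 5, spec).predict_proba_high(frame)
    np.testing.assert_array_equal(p1, p2)


def test_permuted_labels_score_like_prevalence_guesser():
    """With labels shuffled, the optimized distance degrades to chance level."""
    rng = np.random.default_rng(4)
    frame, y = separable_frame(n=250, seed=4)
    y_shuffled = rng.permutation(y)
    spec = ModelSpec(ntree=60, mtry_grid=(10,), cv_folds=3, cv_repeats=1, seed=4)
    tuned = tune_mtry(frame, y_shuffled, spec)
    model_distance = float(tuned.scores["score"].iloc[0])
    prev = y_shuffled.mean()
    guess_distance = np.sqrt(2 * ((1 - prev) ** 2 + prev**2))
    assert model_distance > 0.5
    assert abs(model_distance - guess_distance) < 0.35


# ------------------------------------------------- importance and profiles


def test_importance_ranks_generative_drivers_high(small_model, betula_features):
    """Both generative drivers (cumulative GDD, 16-day evaporation) score
    among the leading predictors even on the small fixture world."""
    imp = small_model.importance
    assert set(imp.index) == set(PREDICTOR_COLUMNS)
    assert "EVAPORATION_16DAYS_AVG_1DAYLAG" in imp.index[:3]
    assert imp["GDD_1DAYLAG"] >= 0


def test_importance_of_unrelated_predictor_near_zero(small_model, betula_features):
    imp = permutation_importance(
        small_model, betula_features, betula_features["level"], n_repeats=3, seed=0
    )
    assert abs(imp["WINDSPEED_4DAYS_AVG_1DAYLAG"]) < 0.02
    assert imp["GDD_1DAYLAG"] > imp["WINDSPEED_4DAYS_AVG_1DAYLAG"]


def test_probability_profile_peaks_in_generative_bump(small_model, betula_features, small_world):
    prof = probability_profile(small_model, betula_features, "GDD_1DAYLAG")
    peak = prof.loc[prof["mean_probability"].idxmax(), "bin_center"]
    params = small_world.config.taxa["Betula"]
    assert params.gdd_mu - params.gdd_sigma <= peak <= params.gdd_mu + params.gdd_sigma
    assert prof["mean_probability"].between(0, 1).all()


def test_probability_profile_constant_predictor_single_bin(small_model, betula_features):
    frame = betula_features.copy()
    frame["ALTITUDE"] = 100.0
    with pytest.warns(UserWarning, match="constant"):
        prof = probability_profile(small_model, frame, "ALTITUDE")
    assert len(prof) == 1


def test_trained_classifier_round_trip(small_model, betula_features, tmp_path):
    from pollenlevels import TrainedClassifier

    path = tmp_path / "model.joblib"
    small_model.save(path)
    back = TrainedClassifier.load(path)
    np.testing.assert_array_equal(
        back.predict_proba_high(betula_features),
        small_model.predict_proba_high(betula_features),
    )
    assert back.threshold == small_model.threshold
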