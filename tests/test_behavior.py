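"""Behavioural statistics: clustering, lick DI, transitions, face features,
face-to-neural regression."""

import numpy as np
import pandas as pd
import pytest

from popdyn import behavior, synthetic as syn


# ---------------------------------------------------------------- clustering

def test_three_separated_blobs_select_k3(rng):
    centers = np.array([[20.0, 0.5], [50.0, 1.0], [85.0, 1.8]])
    pts = np.vstack([c + rng.normal(scale=[1.0, 0.02], size=(8, 2))
                     for c in centers])
    labels, k, sus = behavior.classify_cohort(pts[:, 0], pts[:, 1], seed=0)
    assert k == 3
    # lowest-preference blob is the susceptible cluster
    assert set(np.flatnonzero(labels == sus)) == set(range(8))


def test_duplicated_animals_get_identical_labels(rng):
    pref = np.concatenate([rng.normal(30, 2, 8), rng.normal(80, 2, 8)])
    si = np.concatenate([rng.normal(0.6, 0.05, 8), rng.normal(1.3, 0.05, 8)])
    labels, k, _ = behavior.classify_cohort(np.tile(pref, 2), np.tile(si, 2),
                                            seed=1)
    assert np.array_equal(labels[:16], labels[16:])
    assert k == 2


def test_identical_points_raise():
    with pytest.raises(ValueError):
        behavior.classify_cohort(np.full(12, 50.0), np.full(12, 1.0))


def test_default_cohort_classification_recovers_two_stress_subgroups():
    sessions = syn.simulate_cohort(n_control=0, n_susceptible=6, n_resilient=6,
                                   seed=42, n_trials=60, n_neurons=6,
                                   n_pretask_bins=30)
    pref = [s.sucrose_preference for s in sessions]
    si = [s.si_ratio for s in sessions]
    labels, k, sus = behavior.classify_cohort(pref, si, seed=2)
    assert k == 2
    truth = np.array([s.group == "susceptible" for s in sessions])
    assert np.array_equal(labels == sus, truth)


# ---------------------------------------------------------------- lick rates

def _toy_trials_licks(lick_map):
    """lick_map: trial -> {spout: times relative to reward}."""
    trials = pd.DataFrame({
        "trial_id": range(len(lick_map)),
        "reward_time_s": [100.0 * (i + 1) for i in range(len(lick_map))],
        "choice": [m["choice"] for m in lick_map],
    })
    rows = []
    for i, m in enumerate(lick_map):
        for spout in ("water", "sucrose"):
            for t in m.get(spout, []):
                rows.append((spout, trials.loc[i, "reward_time_s"] + t))
    return trials, pd.DataFrame(rows, columns=["spout", "time_s"])


def test_equal_rates_give_zero_di():
    licks = [
        {"choice": "sucrose", "water": [0.5, 1.5], "sucrose": [0.6, 1.6]},
        {"choice": "water", "water": [0.7, 2.0], "sucrose": [0.8, 2.1]},
    ]
    trials, lickdf = _toy_trials_licks(licks)
    res = behavior.lick_rates_and_di(trials, lickdf)
    assert res.di_post == pytest.approx(0.0)


def test_sucrose_only_licking_gives_positive_di():
    licks = [
        {"choice": "sucrose", "sucrose": [0.2, 0.4, 1.0]},
        {"choice": "water", "sucrose": [0.3, 0.9]},
    ]
    trials, lickdf = _toy_trials_licks(licks)
    assert behavior.lick_rates_and_di(trials, lickdf).di_post > 0


def test_di_matches_hand_computation():
    # sucrose trial: 3 sucrose-spout licks, 1 water-spout lick post-reward
    # water trial: 1 sucrose-spout lick, 2 water-spout licks
    licks = [
        {"choice": "sucrose", "sucrose": [0.1, 0.2, 0.3], "water": [0.5]},
        {"choice": "water", "sucrose": [1.0], "water": [1.5, 2.5]},
    ]
    trials, lickdf = _toy_trials_licks(licks)
    res = behavior.lick_rates_and_di(trials, lickdf)
    # rates over the 4-s window: sucrose trial (0.75 - 0.25), water (0.25 - 0.5)
    expected = ((0.75 - 0.25) + (0.25 - 0.5)) / 2
    assert res.di_post == pytest.approx(expected)
    assert res.di_pre == pytest.approx(0.0)


def test_di_antisymmetric_under_spout_swap():
    licks = [
        {"choice": "sucrose", "sucrose": [0.1, 0.2, 0.9], "water": [0.5]},
        {"choice": "water", "sucrose": [1.0], "water": [1.5, 2.5, 3.0]},
    ]
    trials, lickdf = _toy_trials_licks(licks)
    di = behavior.lick_rates_and_di(trials, lickdf).di_post
    swapped = lickdf.assign(
        spout=lickdf["spout"].map({"water": "sucrose", "sucrose": "water"}))
    trials_sw = trials.assign(
        choice=trials["choice"].map({"water": "sucrose", "sucrose": "water"}))
    di_sw = behavior.lick_rates_and_di(trials_sw, swapped).di_post
    assert di_sw == pytest.approx(-di)


def test_no_licks_warns_and_returns_zero():
    trials = pd.DataFrame({"trial_id": [0], "reward_time_s": [10.0],
                           "choice": ["water"]})
    empty = pd.DataFrame(columns=["spout", "time_s"])
    with pytest.warns(UserWarning):
        res = behavior.lick_rates_and_di(trials, empty)
    assert res.di_pre == res.di_post == 0.0


def test_time_translation_invariance():
    licks = [
        {"choice": "sucrose", "sucrose": [0.1, 0.2], "water": [0.5]},
        {"choice": "water", "sucrose": [1.0], "water": [1.5]},
    ]
    trials, lickdf = _toy_trials_licks(licks)
    base = behavior.lick_rates_and_di(trials, lickdf)
    shifted = behavior.lick_rates_and_di(
        trials.assign(reward_time_s=trials["reward_time_s"] + 1234.5),
        lickdf.assign(time_s=lickdf["time_s"] + 1234.5))
    assert shifted.di_post == pytest.approx(base.di_post)


# --------------------------------------------------------------- transitions

def test_alternating_sequence_transitions():
    stats = behavior.transition_analysis(["water", "sucrose"] * 10)
    assert stats.p_norm["WS"] == 1.0
    assert stats.p_norm["SW"] == 1.0
    assert stats.proportions["WW"] + stats.proportions["SS"] == 0.0
    assert stats.mean_run_length["W"] == 1.0


def test_enumerated_fixture_counts():
    # W,W,S,W,S,S -> ordered pairs WW, WS, SW, WS, SS
    stats = behavior.transition_analysis(
        ["water", "water", "sucrose", "water", "sucrose", "sucrose"])
    assert stats.pair_counts == {"WW": 1, "WS": 2, "SW": 1, "SS": 1}
    assert stats.p_norm["WW"] == pytest.approx(1 / 3)
    assert stats.p_norm["WS"] == pytest.approx(2 / 3)
    assert stats.p_norm["SW"] == pytest.approx(1 / 2)
    # chance-removed: P(WW) = 1/5 minus P(W)^2 = (3/6)^2
    assert stats.chance_removed["WW"] == pytest.approx(1 / 5 - 0.25)
    assert stats.mean_run_length["W"] == pytest.approx(1.5)
    assert stats.mean_run_length["S"] == pytest.approx(1.5)


def test_normalization_identity_on_any_sequence():
    seq = syn.simulate_choices(syn.RESILIENT, 500, seed=3)
    stats = behavior.transition_analysis(seq)
    assert stats.p_norm["WW"] + stats.p_norm["WS"] == pytest.approx(1.0, abs=1e-12)
    assert stats.p_norm["SS"] + stats.p_norm["SW"] == pytest.approx(1.0, abs=1e-12)


def test_absent_reward_type_yields_nan_not_zero():
    stats = behavior.transition_analysis(["water"] * 10)
    assert np.isnan(stats.p_norm["SS"]) and np.isnan(stats.p_norm["SW"])
    assert stats.p_norm["WW"] == 1.0


def test_transition_recovery_from_generator():
    profile = syn.CONTROL
    seq = syn.simulate_choices(profile, 10_000, seed=4)
    stats = behavior.transition_analysis(seq)
    A = profile.transition_matrix
    n_w = stats.pair_counts["WW"] + stats.pair_counts["WS"]
    n_s = stats.pair_counts["SS"] + stats.pair_counts["SW"]
    assert abs(stats.p_norm["WS"] - A[0, 1]) < 3 * np.sqrt(A[0, 1] * A[0, 0] / n_w)
    assert abs(stats.p_norm["SS"] - A[1, 1]) < 3 * np.sqrt(A[1, 1] * A[1, 0] / n_s)


# ------------------------------------------------------------- face features

def test_equal_eye_spans_give_ratio_one():
    kp = {name: np.zeros((1, 2)) for name in syn.KEYPOINT_NAMES}
    kp["eye_top"] = np.array([[0.0, 1.0]])
    kp["eye_bottom"] = np.array([[0.0, -1.0]])
    kp["eye_front"] = np.array([[1.0, 0.0]])
    kp["eye_back"] = np.array([[-1.0, 0.0]])
    kp["snout_tip"] = np.array([[5.0, 0.0]])
    kp["snout_top"] = np.array([[4.0, 1.0]])
    kp["snout_bottom"] = np.array([[4.0, -1.0]])
    feats = behavior.facial_features(kp)
    assert feats.loc[0, "eye_opening_ratio"] == pytest.approx(1.0)
    # snout top/bottom symmetric at +/-45 degrees about the tip -> right angle
    assert feats.loc[0, "snout_angle"] == pytest.approx(90.0)


def test_mouth_distance_is_euclidean():
    kp = {name: np.zeros((1, 2)) for name in syn.KEYPOINT_NAMES}
    kp["eye_top"] = np.array([[0.0, 1.0]])
    kp["eye_bottom"] = np.array([[0.0, -1.0]])
    kp["eye_front"] = np.array([[0.0, 0.0]])
    kp["eye_back"] = np.array([[-2.0, 0.0]])
    kp["snout_tip"] = np.array([[5.0, 0.0]])
    kp["snout_top"] = np.array([[4.0, 1.0]])
    kp["snout_bottom"] = np.array([[4.0, -1.0]])
    kp["mouth"] = np.array([[3.0, 4.0]])
    feats = behavior.facial_features(kp)
    assert feats.loc[0, "mouth_position"] == pytest.approx(5.0)


def test_coincident_keypoints_flag_frame_invalid():
    kp = {name: np.zeros((1, 2)) for name in syn.KEYPOINT_NAMES}
    feats = behavior.facial_features(kp)
    assert not feats.loc[0, "valid"]
    assert np.isnan(feats.loc[0, "eye_opening_ratio"])


# ----------------------------------------------------- face -> neural ridge

def test_exact_linear_relation_gives_r2_one(rng):
    X = rng.normal(size=(60, 6))
    A = rng.normal(size=(4, 6))
    Y = A @ X.T + rng.normal(size=(4, 1))
    fits = behavior.face_neural_regression(X, Y, ridge_grid=(0.0,))
    assert fits[0].r2_insample == pytest.approx(1.0, abs=1e-9)


def test_unrelated_rates_have_nonpositive_cv_r2(rng):
    X = rng.normal(size=(100, 6))
    Y = rng.normal(size=(5, 100))
    fits = behavior.face_neural_regression(X, Y, ridge_grid=(0.0, 10.0))
    assert all(f.r2_cv <= 0.05 for f in fits)


def test_ridge_coefficients_match_closed_form(rng):
    X = rng.normal(size=(30, 6))
    Y = rng.normal(size=(3, 30))
    lam = 10.0
    fits = behavior.face_neural_regression(X, Y, ridge_grid=(lam,))
    Xc = X - X.mean(axis=0)
    Yc = Y.T - Y.T.mean(axis=0)
    oracle = np.linalg.solve(Xc.T @ Xc + lam * np.eye(6), Xc.T @ Yc).T
    np.testing.assert_allclose(fits[0].coef, oracle, atol=1e-8)


def test_rank_deficient_ols_falls_back_to_pinv(rng):
    X = rng.normal(size=(25, 6))
    X[:, 5] = X[:, 0]  # exact collinearity
    Y = rng.normal(size=(2, 25))
    with pytest.warns(UserWarning):
        fits = behavior.face_neural_regression(X, Y, ridge_grid=(0.0,),
                                               n_folds=5)
    assert np.isfinite(fits[0].r2_insample)
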