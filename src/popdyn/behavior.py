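"""Behavioural classification and choice-sequence analysis.

Covers the behaviour-side statistics: K-means subtyping of stressed animals
on (sucrose preference, social-interaction ratio), lick-rate curves and the
lick discrimination index (DI), first-order Markov transition statistics on
reward-choice sequences, facial/limb feature derivation from 12 tracked
keypoints, and ridge regression of neural activity onto those features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import Ridge
from sklearn.metrics import silhouette_score
from sklearn.model_selection import KFold

from .synthetic import SUCROSE, WATER

PAIR_TYPES = ("WW", "WS", "SW", "SS")


# ---------------------------------------------------------------- clustering

def classify_cohort(preferences, si_ratios, k_range=range(2, 11), seed=0):
    """Unsupervised K-means subtyping on the two behavioural metrics.

    K is chosen by maximizing the mean silhouette score over ``k_range``
    (ties broken toward smaller K).  Returns ``(labels, k, susceptible)``
    where ``susceptible`` is the cluster index with the lowest mean sucrose
    preference.
    """
    X = np.column_stack([np.asarray(preferences, float), np.asarray(si_ratios, float)])
    if np.allclose(X, X[0]):
        raise ValueError("all animals identical: clustering is degenerate")
    if len(X) < max(k_range):
        raise ValueError("need at least max(k_range) animals")
    best_k, best_score, best_labels = None, -np.inf, None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        score = silhouette_score(X, km.labels_)
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, km.labels_
    pref = np.asarray(preferences, float)
    means = [pref[best_labels == c].mean() for c in range(best_k)]
    return best_labels, best_k, int(np.argmin(means))


# ---------------------------------------------------------------- lick rates

@dataclass
class LickResult:
    di_pre: float
    di_post: float
    rate_curves: dict        # (choice, spout) -> mean rate per 0.1-s bin
    bin_edges: np.ndarray
    raster_bin: float = 0.02


def _licks_by_trial(trials: pd.DataFrame, licks: pd.DataFrame, spout: str,
                    window=(-4.0, 4.0)):
    t = licks.loc[licks["spout"] == spout, "time_s"].to_numpy()
    out = []
    for rt in trials["reward_time_s"].to_numpy():
        rel = t - rt
        out.append(rel[(rel >= window[0]) & (rel < window[1])])
    return out


def lick_rates_and_di(trials: pd.DataFrame, licks: pd.DataFrame,
                      bin_width: float = 0.1, pre=(-4.0, 0.0),
                      post=(0.0, 4.0)) -> LickResult:
    """Lick-rate curves (0.1-s bins) and the discrimination index.

    For each window the DI is the average, over the two choice types, of
    (mean rate on the sucrose spout - mean rate on the water spout); DI > 0
    means licking favours the sucrose spout regardless of the chosen reward.
    """
    if len(licks) == 0:
        warnings.warn("no licks in session; DI set to 0")
        edges = np.arange(pre[0], post[1] + bin_width / 2, bin_width)
        return LickResult(0.0, 0.0, {}, edges)
    per_spout = {s: _licks_by_trial(trials, licks, s) for s in (WATER, SUCROSE)}
    edges = np.arange(pre[0], post[1] + bin_width / 2, bin_width)
    curves = {}
    for choice in (WATER, SUCROSE):
        mask = (trials["choice"] == choice).to_numpy()
        if not mask.any():
            raise ValueError(f"no {choice} trials; DI needs both choice types")
        for spout in (WATER, SUCROSE):
            trial_licks = [per_spout[spout][i] for i in np.flatnonzero(mask)]
            hists = [np.histogram(tl, bins=edges)[0] for tl in trial_licks]
            curves[(choice, spout)] = np.mean(hists, axis=0) / bin_width
    dis = []
    for window in (pre, post):
        w = (window[1] - window[0])
        diffs = []
        for choice in (WATER, SUCROSE):
            mask = np.flatnonzero((trials["choice"] == choice).to_numpy())
            rs = np.mean([_rate_in(per_spout[SUCROSE][i], window, w) for i in mask])
            rw = np.mean([_rate_in(per_spout[WATER][i], window, w) for i in mask])
            diffs.append(rs - rw)
        dis.append(float(np.mean(diffs)))
    return LickResult(dis[0], dis[1], curves, edges)


def _rate_in(times, window, width):
    return np.count_nonzero((times >= window[0]) & (times < window[1])) / width


def trial_lick_rates(trials: pd.DataFrame, licks: pd.DataFrame,
                     window=(0.0, 4.0)) -> np.ndarray:
    """Per-trial lick rate (Hz, all spouts pooled) in ``window``."""
    t = licks["time_s"].to_numpy()
    width = window[1] - window[0]
    out = np.empty(len(trials))
    for i, rt in enumerate(trials["reward_time_s"].to_numpy()):
        rel = t - rt
        out[i] = np.count_nonzero((rel >= window[0]) & (rel < window[1])) / width
    return out


# --------------------------------------------------------------- transitions

@dataclass
class TransitionStats:
    """Choice-history statistics over the (n-1) ordered pairs of a session.

    ``p_norm`` holds the normalized transition probabilities, conditioned
    on the previous reward so that P(WW) + P(WS) = 1 and P(SS) + P(SW) = 1.
    ``proportions`` are raw pair-type fractions of all pairs;
    ``chance_removed`` subtracts the joint-probability chance level
    P(prev) x P(curr).  Conditional probabilities are NaN (undefined, not 0)
    when the previous reward type never occurs.
    """

    pair_counts: dict
    p_norm: dict
    proportions: dict
    chance_removed: dict
    mean_run_length: dict
    stay_minus_switch: float


def transition_analysis(choices) -> TransitionStats:
    choices = [c[0].upper() for c in np.asarray(choices)]
    if len(choices) < 2:
        raise ValueError("need at least 2 trials")
    pairs = ["".join(p) for p in zip(choices[:-1], choices[1:])]
    counts = {pt: pairs.count(pt) for pt in PAIR_TYPES}
    n_pairs = len(pairs)
    p_norm = {}
    for prev in "WS":
        denom = counts[prev + "W"] + counts[prev + "S"]
        for cur in "WS":
            key = prev + cur
            p_norm[key] = counts[key] / denom if denom else np.nan
    props = {pt: counts[pt] / n_pairs for pt in PAIR_TYPES}
    marg = {c: choices.count(c) / len(choices) for c in "WS"}
    chance_removed = {pt: props[pt] - marg[pt[0]] * marg[pt[1]] for pt in PAIR_TYPES}
    runs = {"W": [], "S": []}
    i = 0
    while i < len(choices):
        j = i
        while j < len(choices) and choices[j] == choices[i]:
            j += 1
        runs[choices[i]].append(j - i)
        i = j
    mean_run = {c: (float(np.mean(r)) if r else np.nan) for c, r in runs.items()}
    stay = props["WW"] + props["SS"]
    switch = props["WS"] + props["SW"]
    return TransitionStats(counts, p_norm, props, chance_removed, mean_run,
                           stay - switch)


# ------------------------------------------------------------- face features

FACIAL_FEATURES = ("eye_opening_ratio", "snout_angle", "mouth_position",
                   "whisker_position", "left_limb_x", "left_limb_y")


def facial_features(keypoints: dict) -> pd.DataFrame:
    """Six per-frame facial/limb features from the 12 keypoints.

    eye_opening_ratio = |eye_top - eye_bottom| / |eye_front - eye_back|
    (ratio 1 = perfectly circular opened eye); snout_angle (degrees) is the
    angle at the snout tip between the vectors to snout top and bottom;
    mouth/whisker positions are distances to the eye front; the left-limb
    coordinates pass through.  Frames with a vanishing denominator are
    flagged invalid (features NaN, ``valid`` False).
    """
    kp = {k: np.atleast_2d(np.asarray(v, float)) for k, v in keypoints.items()}
    d_vert = np.linalg.norm(kp["eye_top"] - kp["eye_bottom"], axis=1)
    d_horz = np.linalg.norm(kp["eye_front"] - kp["eye_back"], axis=1)
    v1 = kp["snout_top"] - kp["snout_tip"]
    v2 = kp["snout_bottom"] - kp["snout_tip"]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    valid = (d_horz > 0) & (n1 > 0) & (n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, d_vert / d_horz, np.nan)
        cosang = np.clip((v1 * v2).sum(axis=1) / np.where(valid, n1 * n2, np.nan),
                         -1.0, 1.0)
        angle = np.degrees(np.arccos(cosang))
    df = pd.DataFrame({
        "eye_opening_ratio": ratio,
        "snout_angle": angle,
        "mouth_position": np.linalg.norm(kp["mouth"] - kp["eye_front"], axis=1),
        "whisker_position": np.linalg.norm(kp["whisker1"] - kp["eye_front"], axis=1),
        "left_limb_x": kp["left_hand"][:, 0],
        "left_limb_y": kp["left_hand"][:, 1],
    })
    df["valid"] = valid
    return df


# ------------------------------------------------------- face -> neural fit

@dataclass
class RegressionFit:
    alpha: float
    coef: np.ndarray       # (N, K) feature coefficients
    intercept: np.ndarray  # (N,) per-neuron offset
    r2_insample: float
    r2_cv: float


def face_neural_regression(features: np.ndarray, rates: np.ndarray,
                           ridge_grid=(0.0, 1.0, 10.0, 100.0, 1000.0),
                           n_folds: int = 5, seed=0) -> list[RegressionFit]:
    """Linear model Y = A X^T + beta of firing rates on face/limb features.

    Data are centred before fitting; the L2 penalty is swept over
    ``ridge_grid`` (0 = ordinary least squares, solved by pseudo-inverse if
    rank-deficient).  R-squared is reported both in-sample and by K-fold
    cross-validation; an everywhere-non-positive cross-validated R-squared
    indicates the features carry no predictive signal for the activity.
    """
    X = np.asarray(features, float)  # (T, K)
    Y = np.asarray(rates, float).T   # (T, N)
    if X.shape[0] < 20:
        raise ValueError("need at least 20 time bins")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and rates disagree on the number of bins")
    fits = []
    for alpha in ridge_grid:
        coef, intercept = _ridge_solve(X, Y, alpha)
        r2_in = _r2(Y, X @ coef.T + intercept)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        sse = sst = 0.0
        for tr, te in kf.split(X):
            c, b = _ridge_solve(X[tr], Y[tr], alpha)
            pred = X[te] @ c.T + b
            sse += ((Y[te] - pred) ** 2).sum()
            sst += ((Y[te] - Y[tr].mean(axis=0)) ** 2).sum()
        fits.append(RegressionFit(alpha, coef, intercept, r2_in, 1.0 - sse / sst))
    return fits


def _ridge_solve(X, Y, alpha):
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    if alpha == 0.0 and np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        warnings.warn("rank-deficient features at ridge 0; using pseudo-inverse")
        coef = (np.linalg.pinv(Xc) @ Yc).T
    else:
        model = Ridge(alpha=alpha, fit_intercept=False)
        model.fit(Xc, Yc)
        coef = model.coef_
    intercept = ym - xm @ coef.T
    return coef, intercept


def _r2(y, pred):
    sse = ((y - pred) ** 2).sum()
    sst = ((y - y.mean(axis=0)) ** 2).sum()
    return float(1.0 - sse / sst)


def behaviour_summary(session, lick_result: LickResult | None = None) -> dict:
    """One row of per-animal behavioural features (group-decoder inputs)."""
    if lick_result is None:
        lick_result = lick_rates_and_di(session.trials, session.licks)
    return {
        "animal_id": session.animal_id,
        "group": session.group,
        "condition": session.condition,
        "sucrose_preference": session.sucrose_preference,
        "si_ratio": session.si_ratio,
        "open_arm_pct": session.open_arm_pct,
        "lick_di_pre": lick_result.di_pre,
        "lick_di_post": lick_result.di_post,
    }
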