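"""Geometry and semantics of inferred hidden states.

Pearson-correlation distances between state activity vectors, complete-
linkage (farthest-point) agglomerative clustering curves, Shannon-entropy
identification of intention-selective states (states occurring exclusively
in switch or exclusively in stay trials), state-conditioned trial
filtering, and the across-time population correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

NEURAL_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)
FACE_THRESHOLDS = (0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass
class StateCorrelationMatrix:
    correlation: np.ndarray   # J: pairwise Pearson between state vectors
    distance: np.ndarray      # D = 1 - J
    kept_states: np.ndarray   # indices surviving the zero-variance screen


def state_correlations(emissions: np.ndarray) -> StateCorrelationMatrix:
    """Pairwise Pearson correlation between state activity vectors.

    ``emissions`` is (N, K): column j is state j's mean-activity vector over
    N neurons (or features).  Zero-variance columns have undefined
    correlations and are dropped with a warning.
    """
    E = np.asarray(emissions, float)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("emissions must be (N >= 2, K >= 2)")
    keep = np.flatnonzero(E.std(axis=0) > 0)
    if len(keep) < E.shape[1]:
        warnings.warn("dropping zero-variance state vectors")
    J = np.corrcoef(E[:, keep].T)
    D = 1.0 - J
    np.fill_diagonal(D, 0.0)
    return StateCorrelationMatrix(J, D, keep)


@dataclass
class ClusterCurve:
    thresholds: np.ndarray
    n_clusters: np.ndarray
    fraction: np.ndarray      # n_clusters / n_states


def agglomerate(distance: np.ndarray, thresholds=NEURAL_THRESHOLDS):
    """Complete-linkage agglomerative clustering on a distance matrix.

    Returns ``(Z, curve, assignments)``: the scipy linkage matrix, the
    cluster-count curve over ``thresholds``, and per-threshold cluster
    labels.  The number of clusters is non-increasing in the threshold.
    """
    D = np.asarray(distance, float)
    K = D.shape[0]
    thresholds = np.asarray(thresholds, float)
    if K == 1:
        ones = np.ones(len(thresholds), dtype=int)
        return None, ClusterCurve(thresholds, ones, ones.astype(float)), \
            [np.zeros(1, dtype=int) for _ in thresholds]
    Z = linkage(squareform(np.clip(D, 0.0, None), checks=False), method="complete")
    assignments, n_clusters = [], []
    for t in thresholds:
        lab = fcluster(Z, t, criterion="distance") - 1
        assignments.append(lab)
        n_clusters.append(lab.max() + 1)
    n_clusters = np.asarray(n_clusters)
    return Z, ClusterCurve(thresholds, n_clusters, n_clusters / K), assignments


def state_occurrences(paths: np.ndarray, labels, n_states: int | None = None):
    """Per-state bin-occurrence counts in switch and stay trials.

    ``paths`` is (n_trials, n_bins) of state ids over the pre-reward bins;
    ``labels`` the per-trial switch/stay labels.  Returns an (K, 2) array of
    counts (columns: switch, stay).
    """
    paths = np.asarray(paths)
    labels = np.asarray(labels)
    if n_states is None:
        n_states = int(paths.max()) + 1
    counts = np.zeros((n_states, 2), dtype=int)
    for col, lab in enumerate(("switch", "stay")):
        sel = paths[labels == lab]
        if sel.size:
            counts[:, col] = np.bincount(sel.ravel(), minlength=n_states)
    return counts


def intention_entropy(paths: np.ndarray, labels, n_states: int | None = None,
                      min_occurrence: int = 3) -> pd.DataFrame:
    """Shannon entropy of each state's switch/stay occurrence profile.

    Occurrence frequencies are normalized per trial type (so class imbalance
    does not masquerade as selectivity): P_switch is the state's rate in
    switch trials divided by the sum of its rates in the two types, and
    P_stay = 1 - P_switch.  H = -(P_switch ln P_switch + P_stay ln P_stay),
    with 0 ln 0 = 0.  A state is intention-selective iff H = 0, i.e. it
    occurs exclusively in one trial type; states occurring in fewer than
    ``min_occurrence`` bins overall are not flagged (a single stray bin
    trivially scores H = 0), and never-occurring states are excluded.
    """
    labels = np.asarray(labels)
    counts = state_occurrences(paths, labels, n_states)
    n_sw = max(int((labels == "switch").sum()), 1)
    n_st = max(int((labels == "stay").sum()), 1)
    rows = []
    for state, (c_sw, c_st) in enumerate(counts):
        total = c_sw + c_st
        if total == 0:
            continue
        f_sw, f_st = c_sw / n_sw, c_st / n_st
        p = f_sw / (f_sw + f_st)
        h = entropy_from_p(p)
        rows.append({
            "state": state, "n_switch": c_sw, "n_stay": c_st,
            "p_switch": p, "p_stay": 1.0 - p, "entropy": h,
            "intention_selective": bool(h == 0.0 and total >= min_occurrence),
        })
    return pd.DataFrame(rows)


def entropy_from_p(p_switch: float) -> float:
    """H = -(p ln p + (1-p) ln (1-p)), natural log, with 0 ln 0 = 0."""
    p, q = p_switch, 1.0 - p_switch
    h = 0.0
    if p > 0:
        h -= p * np.log(p)
    if q > 0:
        h -= q * np.log(q)
    return float(h)


def intention_fraction(emissions: np.ndarray, paths: np.ndarray, labels,
                       thresholds=(0.1, 0.2, 0.3, 0.4),
                       min_occurrence: int = 3) -> pd.DataFrame:
    """Fraction of intention-selective clusters per clustering threshold.

    States are first merged by complete-linkage clustering of the 1 - r
    distance matrix at each threshold; a merged cluster inherits the union
    of its member states' occurrences before the entropy test.  The
    fraction is (# entropy-0 clusters) / (# clusters).
    """
    corr = state_correlations(emissions)
    _, curve, assignments = agglomerate(corr.distance, thresholds)
    counts = state_occurrences(paths, labels, n_states=np.asarray(emissions).shape[1])
    counts = counts[corr.kept_states]
    labels = np.asarray(labels)
    n_sw = max(int((labels == "switch").sum()), 1)
    n_st = max(int((labels == "stay").sum()), 1)
    rows = []
    for t, lab, n_cl in zip(curve.thresholds, assignments, curve.n_clusters):
        n_sel = 0
        for c in range(n_cl):
            c_sw, c_st = counts[lab == c].sum(axis=0)
            total = c_sw + c_st
            if total == 0 or total < min_occurrence:
                continue
            p = (c_sw / n_sw) / (c_sw / n_sw + c_st / n_st)
            if entropy_from_p(p) == 0.0:
                n_sel += 1
        rows.append({"threshold": t, "n_clusters": int(n_cl),
                     "n_selective": n_sel,
                     "fraction_selective": n_sel / n_cl if n_cl else np.nan})
    return pd.DataFrame(rows)


def best_intention_threshold(fraction_table: pd.DataFrame) -> float:
    """Threshold yielding the most intention-selective clusters (smallest
    threshold on ties)."""
    t = fraction_table.sort_values(["n_selective", "threshold"],
                                   ascending=[False, True])
    return float(t.iloc[0]["threshold"])


def filter_trials_by_states(paths: np.ndarray, selective_states,
                            mode: str = "remove", min_bins: int = 3) -> np.ndarray:
    """Boolean keep-mask over trials by intention-state content.

    A trial "contains" the intention signature when flagged states occupy at
    least ``min_bins`` of its pre-reward bins.  ``mode='remove'`` drops such
    trials; ``mode='only'`` keeps only them.
    """
    paths = np.asarray(paths)
    selective = np.isin(paths, np.asarray(list(selective_states), dtype=int))
    hits = selective.sum(axis=1) >= min_bins
    if mode == "remove":
        keep = ~hits
    elif mode == "only":
        keep = hits
    else:
        raise ValueError("mode must be 'remove' or 'only'")
    if not keep.any():
        warnings.warn("trial filter removed every trial")
    return keep


def population_time_correlation(counts: np.ndarray) -> float:
    """Mean pairwise Pearson correlation between time-bin population vectors.

    Correlations are taken between all pairs of columns of the (N, T) count
    matrix (upper triangle); pairs involving a constant population vector
    are skipped.
    """
    X = np.asarray(counts, float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need N >= 2 neurons and T >= 2 bins")
    ok = np.flatnonzero(X.std(axis=0) > 0)
    if len(ok) < X.shape[1]:
        warnings.warn("skipping constant population vectors")
    if len(ok) < 2:
        return np.nan
    C = np.corrcoef(X[:, ok].T)
    return float(C[np.triu_indices_from(C, k=1)].mean())
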