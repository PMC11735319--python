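"""Trial-aligned single-unit metrics.

PSTHs z-scored to the pre-reward baseline, auROC reward-choice selectivity
against a trial-label shuffle, and Wilcoxon/FDR identification of
intention-modulated (switch vs stay) neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency, fisher_exact, rankdata, ranksums
from statsmodels.stats.multitest import multipletests

WINDOW = (-4.0, 4.0)


def bin_trials(spike_times_per_trial, bin_width: float,
               window=WINDOW) -> np.ndarray:
    """(n_trials, n_bins) spike counts on half-open bins over ``window``."""
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    return np.vstack([np.histogram(t, bins=edges)[0] for t in spike_times_per_trial])


@dataclass
class PSTHResult:
    z: np.ndarray              # (n_bins,) z-scored smoothed rate
    rate: np.ndarray           # (n_bins,) raw trial-mean rate, Hz
    valid: bool                # False when the baseline has zero variance
    bin_width: float = 0.01


def compute_psth(counts_10ms: np.ndarray, bin_width: float = 0.01,
                 window=WINDOW, baseline=(-1.0, 0.0),
                 smooth_bins: int = 5) -> PSTHResult:
    """Trial-averaged rate, z-scored to the pre-reward baseline and smoothed
    with a moving-average filter (5 x 10-ms bins = 50 ms)."""
    counts = np.atleast_2d(np.asarray(counts_10ms, float))
    if counts.shape[0] < 1:
        raise ValueError("need at least one trial")
    rate = counts.mean(axis=0) / bin_width
    t = window[0] + bin_width * np.arange(counts.shape[1])
    base = rate[(t >= baseline[0]) & (t < baseline[1])]
    mu, sd = base.mean(), base.std(ddof=0)
    if sd == 0:
        warnings.warn("zero baseline variance; z-scores undefined")
        return PSTHResult(np.full_like(rate, np.nan), rate, False, bin_width)
    z = (rate - mu) / sd
    kernel = np.ones(smooth_bins) / smooth_bins
    return PSTHResult(np.convolve(z, kernel, mode="same"), rate, True, bin_width)


def auroc(x, y) -> float:
    """Area under the ROC built by sweeping a threshold over firing rates:
    P(x > y) + 0.5 P(x = y) for random draws, via the rank formulation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ranks = rankdata(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    return float((rx - len(x) * (len(x) + 1) / 2) / (len(x) * len(y)))


@dataclass
class SelectivityResult:
    auroc: np.ndarray        # (n_bins,)
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    selective: np.ndarray    # (n_bins,) bool: outside shuffle mean +/- 2 s.d.
    is_selective: bool       # any bin selective


def auroc_selectivity(counts_500ms: np.ndarray, labels, n_shuffles: int = 10,
                      min_trials: int = 10, seed=None) -> SelectivityResult:
    """Per-bin auROC (sucrose vs water) with a whole-trial label shuffle.

    A bin is selective when its auROC lies outside the shuffle mean by more
    than 2 shuffle s.d.; a neuron is selective if any bin is.  Requires at
    least ``min_trials`` trials of each label.
    """
    counts = np.asarray(counts_500ms, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two trial labels required")
    a, b = (labels == classes[0]), (labels == classes[1])
    if a.sum() < min_trials or b.sum() < min_trials:
        raise ValueError(f"need >= {min_trials} trials per label")
    n_bins = counts.shape[1]
    obs = np.array([auroc(counts[a, i], counts[b, i]) for i in range(n_bins)])
    rng = np.random.default_rng(seed)
    shuf = np.empty((n_shuffles, n_bins))
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        pa, pb = perm == classes[0], perm == classes[1]
        shuf[s] = [auroc(counts[pa, i], counts[pb, i]) for i in range(n_bins)]
    mu, sd = shuf.mean(axis=0), shuf.std(axis=0, ddof=1)
    selective = np.abs(obs - mu) > 2 * sd
    return SelectivityResult(obs, mu, sd, selective, bool(selective.any()))


def intention_modulated(pre_rates: list, labels_per_neuron: list,
                        alpha: float = 0.05, min_trials: int = 10):
    """Flag neurons whose pre-reward firing differs between switch and stay.

    ``pre_rates[i]`` is the per-trial mean rate over [-4, 0) s of neuron i
    and ``labels_per_neuron[i]`` the matching switch/stay labels.  A
    Wilcoxon rank-sum test per neuron is followed by Benjamini-Hochberg FDR
    across all tested neurons; neurons with too few trials per label are
    excluded (flag NaN in the returned p-values, False flags).

    Returns ``(flags, p_adjusted, p_raw)`` arrays over neurons.
    """
    n = len(pre_rates)
    p_raw = np.full(n, np.nan)
    for i, (rates, labels) in enumerate(zip(pre_rates, labels_per_neuron)):
        rates, labels = np.asarray(rates, float), np.asarray(labels)
        sw, st = rates[labels == "switch"], rates[labels == "stay"]
        if len(sw) < min_trials or len(st) < min_trials:
            warnings.warn(f"neuron {i} excluded: <{min_trials} trials per label")
            continue
        if np.array_equal(np.sort(sw), np.sort(st)):
            p_raw[i] = 1.0
        else:
            p_raw[i] = ranksums(sw, st).pvalue
    tested = ~np.isnan(p_raw)
    p_adj = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    if tested.any():
        rej, adj, _, _ = multipletests(p_raw[tested], alpha=alpha, method="fdr_bh")
        p_adj[tested] = adj
        flags[tested] = rej
    return flags, p_adj, p_raw


def selective_fraction_test(table_2x2) -> tuple[float, str]:
    """Compare selective-neuron fractions between two groups.

    Uses Fisher's exact test when any cell count is below 5, otherwise a
    chi-squared test.  Returns (p-value, test name).
    """
    table = np.asarray(table_2x2)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if (table < 5).any():
        return float(fisher_exact(table)[1]), "fisher"
    return float(chi2_contingency(table, correction=False)[1]), "chi2"
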