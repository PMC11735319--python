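"""Hidden Markov models for binned neural and behavioural time series.

Two emission families are supported: independent Poisson counts per neuron
(spike-count data) and diagonal Gaussian (continuous facial/limb features).
A model is the parameter triple ``{A, T, E}``: initial state probabilities,
a row-stochastic transition matrix, and per-state emission parameters.

Fitting is Baum--Welch expectation-maximization with several random restarts;
model selection across state counts uses AIC.  Observation matrices follow
the neurons-by-time convention ``(N, T)``.  Multiple segments (e.g. trials
concatenated within a session) may be passed as a list; the forward
recursion restarts at every segment boundary, so no transition probability
is spent across a trial gap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

RATE_FLOOR = 1e-6  # keeps log(lambda) finite for silent neurons
VAR_FLOOR = 1e-6


@dataclass
class HiddenMarkovModel:
    """Parameter set {A, T, E} for a K-state HMM over N-dimensional data.

    Parameters
    ----------
    startprob : (K,) initial state distribution A.
    transmat : (K, K) row-stochastic transition matrix T.
    kind : "poisson" or "gaussian".
    rates : (N, K) Poisson rate matrix (column j = state j), Poisson only.
    means, variances : (N, K) per-state diagonal-Gaussian parameters.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    kind: str = "poisson"
    rates: np.ndarray | None = None
    means: np.ndarray | None = None
    variances: np.ndarray | None = None

    def __post_init__(self):
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("initial state probabilities must sum to 1")
        if np.any(self.startprob < -1e-12):
            raise ValueError("initial state probabilities must be non-negative")
        rows = self.transmat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("every transition-matrix row must sum to 1")
        if self.kind == "poisson":
            if self.rates is None:
                raise ValueError("Poisson model requires a rate matrix")
            self.rates = np.asarray(self.rates, dtype=float)
            if np.any(self.rates < 0):
                raise ValueError("Poisson rates must be non-negative")
        elif self.kind == "gaussian":
            if self.means is None or self.variances is None:
                raise ValueError("Gaussian model requires means and variances")
            self.means = np.asarray(self.means, dtype=float)
            self.variances = np.asarray(self.variances, dtype=float)
            if np.any(self.variances <= 0):
                raise ValueError("Gaussian variances must be positive")
        else:
            raise ValueError(f"unknown emission kind {self.kind!r}")

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_dims(self) -> int:
        e = self.rates if self.kind == "poisson" else self.means
        return e.shape[0]

    @property
    def state_means(self) -> np.ndarray:
        """(N, K) mean observation per state (rates for Poisson)."""
        return self.rates if self.kind == "poisson" else self.means

    def n_free_parameters(self) -> int:
        K, N = self.n_states, self.n_dims
        emission = N * K if self.kind == "poisson" else 2 * N * K
        return (K - 1) + K * (K - 1) + emission

    def to_json(self, path):
        obj = {
            "kind": self.kind,
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
        }
        if self.kind == "poisson":
            obj["rates"] = self.rates.tolist()
        else:
            obj["means"] = self.means.tolist()
            obj["variances"] = self.variances.tolist()
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "HiddenMarkovModel":
        with open(path) as fh:
            obj = json.load(fh)
        arrays = {
            k: np.asarray(v)
            for k, v in obj.items()
            if k in ("startprob", "transmat", "rates", "means", "variances")
        }
        return cls(kind=obj["kind"], **arrays)


@dataclass
class HMMFit:
    """Result of an EM fit: model, likelihood trace, AIC, posteriors, path."""

    model: HiddenMarkovModel
    loglik_trace: np.ndarray
    aic: float
    posteriors: list[np.ndarray] = field(default_factory=list)  # (T_s, K) per segment
    viterbi_paths: list[np.ndarray] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _as_segments(counts) -> list[np.ndarray]:
    if isinstance(counts, (list, tuple)):
        segs = [np.asarray(c, dtype=float) for c in counts]
    else:
        segs = [np.asarray(counts, dtype=float)]
    if not segs or any(s.size == 0 for s in segs):
        raise ValueError("empty observation data")
    n = segs[0].shape[0]
    if any(s.ndim != 2 or s.shape[0] != n for s in segs):
        raise ValueError("all segments must be 2-D with the same number of rows")
    return segs


def _log_emissions(model: HiddenMarkovModel, seg: np.ndarray) -> np.ndarray:
    """(T, K) log observation probability per bin and state."""
    x = seg.T  # (T, N)
    if model.kind == "poisson":
        lam = np.maximum(model.rates, RATE_FLOOR)  # (N, K)
        # sum_i [x log lam - lam - log x!]
        return x @ np.log(lam) - lam.sum(axis=0) - gammaln(x + 1).sum(axis=1)[:, None]
    mu, var = model.means, model.variances  # (N, K)
    quad = ((x[:, :, None] - mu[None]) ** 2 / var[None]).sum(axis=1)
    norm = (np.log(2 * np.pi * var)).sum(axis=0)
    return -0.5 * (quad + norm)


def _forward_backward(model, logb):
    """Scaled forward-backward; returns (loglik, gamma, xi_sum)."""
    T, K = logb.shape
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = model.startprob * b[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        return -np.inf, np.full((T, K), 1.0 / K), np.zeros((K, K))
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ model.transmat) * b[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            return -np.inf, np.full((T, K), 1.0 / K), np.zeros((K, K))
        alpha[t] = a / scale[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (model.transmat @ bb) / scale[t + 1]
        xi = model.transmat * np.outer(alpha[t], bb) / scale[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum() + logb.max(axis=1).sum())
    return loglik, gamma, xi_sum


def forward_loglik(model: HiddenMarkovModel, counts) -> float:
    """Log-likelihood of the data under the model (scaled forward algorithm).

    ``counts`` is an ``(N, T)`` matrix or a list of such segments; segment
    log-likelihoods add, with the chain re-initialized from ``A`` at each
    segment start.
    """
    total = 0.0
    for seg in _as_segments(counts):
        logb = _log_emissions(model, seg)
        ll, _, _ = _forward_backward(model, logb)
        if not np.isfinite(ll):
            warnings.warn("observation has zero probability under all states")
            return -np.inf
        total += ll
    return total


def posteriors(model: HiddenMarkovModel, counts) -> list[np.ndarray]:
    """Per-bin state posteriors gamma_t(j) = P(S_t = j | data), per segment."""
    out = []
    for seg in _as_segments(counts):
        _, gamma, _ = _forward_backward(model, _log_emissions(model, seg))
        out.append(gamma)
    return out


def viterbi(model: HiddenMarkovModel, counts) -> list[np.ndarray]:
    """Most likely state path per segment; ties break toward lower index."""
    paths = []
    with np.errstate(divide="ignore"):
        log_start = np.log(np.maximum(model.startprob, 1e-300))
        log_trans = np.log(np.maximum(model.transmat, 1e-300))
    for seg in _as_segments(counts):
        logb = _log_emissions(model, seg)
        T, K = logb.shape
        delta = log_start + logb[0]
        back = np.zeros((T, K), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + log_trans
            back[t] = cand.argmax(axis=0)
            delta = cand.max(axis=0) + logb[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(delta.argmax())
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        paths.append(path)
    return paths


def smooth_activity(model: HiddenMarkovModel, counts) -> list[np.ndarray]:
    """Posterior-mixed observations Y_t = sum_j gamma_t(j) mu_j, per segment.

    With posteriors (0.2, 0.8) over two states the smoothed bin is
    0.2*mu_1 + 0.8*mu_2; each Y_t lies in the convex hull of state means.
    Returned arrays are ``(N, T_seg)``.
    """
    mu = model.state_means  # (N, K)
    return [(gamma @ mu.T).T for gamma in posteriors(model, counts)]


def sample(model: HiddenMarkovModel, n_bins: int, seed=None):
    """Ancestral sampling: returns (observations (N, T), state path (T,))."""
    rng = np.random.default_rng(seed)
    K = model.n_states
    path = np.empty(n_bins, dtype=int)
    path[0] = rng.choice(K, p=model.startprob)
    for t in range(1, n_bins):
        path[t] = rng.choice(K, p=model.transmat[path[t - 1]])
    if model.kind == "poisson":
        obs = rng.poisson(model.rates[:, path]).astype(float)
    else:
        obs = rng.normal(model.means[:, path], np.sqrt(model.variances[:, path]))
    return obs, path


def _init_model(segs, K, kind, rng) -> HiddenMarkovModel:
    x = np.concatenate([s for s in segs], axis=1)  # (N, T_total)
    N = x.shape[0]
    start = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K) * 2.0, size=K)
    trans = 0.7 * np.eye(K) + 0.3 * trans  # sticky start helps segmentation
    trans /= trans.sum(axis=1, keepdims=True)
    mean = x.mean(axis=1)
    if kind == "poisson":
        rates = np.maximum(mean[:, None] * rng.uniform(0.5, 1.5, size=(N, K)), RATE_FLOOR)
        return HiddenMarkovModel(start, trans, "poisson", rates=rates)
    sd = x.std(axis=1) + VAR_FLOOR
    means = mean[:, None] + sd[:, None] * rng.normal(scale=0.5, size=(N, K))
    variances = np.tile((sd**2 + VAR_FLOOR)[:, None], (1, K))
    return HiddenMarkovModel(start, trans, "gaussian", means=means, variances=variances)


def _em_once(segs, K, kind, rng, max_iter, tol):
    model = _init_model(segs, K, kind, rng)
    trace = []
    for _ in range(max_iter):
        ll_total = 0.0
        start_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gam_acc = np.zeros(K)
        wx = 0.0
        wx2 = 0.0
        gammas = []
        for seg in segs:
            ll, gamma, xi = _forward_backward(model, _log_emissions(model, seg))
            ll_total += ll
            start_acc += gamma[0]
            xi_acc += xi
            gam_acc += gamma.sum(axis=0)
            wx = wx + seg @ gamma  # (N, K)
            if kind == "gaussian":
                wx2 = wx2 + (seg**2) @ gamma
            gammas.append(gamma)
        trace.append(ll_total)
        # M-step
        start = start_acc / start_acc.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        trans = np.where(rows > 0, xi_acc / np.maximum(rows, 1e-300), 1.0 / K)
        trans /= trans.sum(axis=1, keepdims=True)
        denom = np.maximum(gam_acc, 1e-300)
        if kind == "poisson":
            rates = np.maximum(wx / denom, RATE_FLOOR)
            model = HiddenMarkovModel(start, trans, "poisson", rates=rates)
        else:
            means = wx / denom
            variances = np.maximum(wx2 / denom - means**2, VAR_FLOOR)
            model = HiddenMarkovModel(start, trans, "gaussian", means=means, variances=variances)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            break
    final_ll = forward_loglik(model, segs)
    trace.append(final_ll)
    return model, np.asarray(trace)


def fit_em(counts, n_states: int, *, kind: str = "poisson", max_iter: int = 100,
           n_inits: int = 5, tol: float = 1e-6, seed=None,
           compute_posteriors: bool = True) -> HMMFit:
    """Baum--Welch fit; the best of ``n_inits`` random restarts is returned.

    The log-likelihood trace of the winning restart is non-decreasing up to
    the stated tolerance.  AIC = 2p - 2 logL with p counting (K-1) initial,
    K(K-1) transition, and all free emission parameters.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    segs = _as_segments(counts)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(n_inits, 1)):
        rng = np.random.default_rng(child)
        model, trace = _em_once(segs, n_states, kind, rng, max_iter, tol)
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    model, trace = best
    aic = 2 * model.n_free_parameters() - 2 * trace[-1]
    fit = HMMFit(model=model, loglik_trace=trace, aic=aic)
    if compute_posteriors:
        fit.posteriors = posteriors(model, segs)
        fit.viterbi_paths = viterbi(model, segs)
    return fit


def select_aic(counts, k_range, *, kind: str = "poisson", n_inits: int = 5,
               max_iter: int = 100, tol: float = 1e-6, seed=None) -> HMMFit:
    """Fit every K in ``k_range`` and keep the smallest-AIC model."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    best = None
    for K, child in zip(k_range, ss.spawn(len(k_range))):
        fit = fit_em(counts, K, kind=kind, n_inits=n_inits, max_iter=max_iter,
                     tol=tol, seed=child, compute_posteriors=False)
        if best is None or fit.aic < best.aic:
            best = fit
    segs = _as_segments(counts)
    best.posteriors = posteriors(best.model, segs)
    best.viterbi_paths = viterbi(best.model, segs)
    return best
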