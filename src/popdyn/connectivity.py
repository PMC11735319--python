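"""Inter-regional coupling between BLA and vCA1.

Pre-task coupling: per-region PCA followed by canonical-correlation
alignment of the two regions' dynamics, with the cross-correlogram of the
first canonical pair over +/-50 s lags and its power spectral density
(dominant-frequency estimate; Nyquist 0.5 Hz at 1-s bins).  Task epoch:
windowed Pearson correlation of regional mean rates per trial type, Fisher
z-transformed, and the sucrose-water contrast.  Intention epoch:
PCA-denoised correlations conditioned on intention-state bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import CCA

Z_CAP = 1.0 - 1e-6  # |r| cap before atanh


@dataclass
class CanonicalPair:
    weights_x: np.ndarray
    weights_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    correlation: float


@dataclass
class CouplingSpectrum:
    lags: np.ndarray
    crosscorr: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray
    dominant_freq: float
    stable: bool                # peak clearly above the spectral floor
    fs: float = 1.0             # sampling frequency of the binned signal, Hz

    @property
    def nyquist(self) -> float:
        """Highest accessible frequency, fs / 2 (0.5 Hz at 1-s bins)."""
        return self.fs / 2.0


def _pca_reduce(X, var_frac=0.9, max_pcs=5):
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_frac) + 1)
    k = max(1, min(k, max_pcs, len(s)))
    return U[:, :k].T @ Xc  # (k, T) PC time courses


def cca_coupling(X: np.ndarray, Y: np.ndarray, *, max_lag: int = 50,
                 var_frac: float = 0.9, max_pcs: int = 5,
                 min_neurons: int = 5):
    """Canonical-correlation alignment of two regions' pre-task dynamics.

    Each region's (neurons x time) count matrix is PCA-reduced (enough PCs
    for ``var_frac`` of variance, capped at ``max_pcs``), the first
    canonical pair is fitted, and the cross-correlogram of the canonical
    variates over lags of +/-``max_lag`` bins is Fourier-analysed.
    Returns ``(CanonicalPair, CouplingSpectrum)``.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] < min_neurons or Y.shape[0] < min_neurons:
        raise ValueError(f"need at least {min_neurons} neurons per region")
    T = X.shape[1]
    Px, Py = _pca_reduce(X, var_frac, max_pcs), _pca_reduce(Y, var_frac, max_pcs)
    cca = CCA(n_components=1, max_iter=1000)
    u, v = cca.fit_transform(Px.T, Py.T)
    u, v = u.ravel(), v.ravel()
    r = float(np.corrcoef(u, v)[0, 1])
    pair = CanonicalPair(cca.x_weights_.ravel(), cca.y_weights_.ravel(),
                         u, v, abs(r))
    if max_lag >= T:
        warnings.warn("lag range exceeds signal length; clipping")
        max_lag = T - 1
    lags = np.arange(-max_lag, max_lag + 1)
    uz = (u - u.mean()) / u.std()
    vz = (v - v.mean()) / v.std()
    cc = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = uz[: T - lag], vz[lag:]
        else:
            a, b = uz[-lag:], vz[: T + lag]
        cc[i] = float(np.mean(a * b))
    freqs = np.fft.rfftfreq(len(cc), d=1.0)
    psd = np.abs(np.fft.rfft(cc)) ** 2 / len(cc)
    nz = freqs > 0  # the DC term is the correlogram mean, not an oscillation
    peak = int(np.argmax(psd[nz]))
    dominant = float(freqs[nz][peak])
    stable = bool(psd[nz][peak] > 2.0 * np.median(psd[nz]))
    spectrum = CouplingSpectrum(lags, cc, freqs, psd, dominant, stable)
    return pair, spectrum


def fisher_z(r: float) -> float:
    """atanh(r) with |r| capped just below 1."""
    return float(np.arctanh(np.clip(r, -Z_CAP, Z_CAP)))


@dataclass
class RegionCorrelation:
    mean_z: dict                 # trial type -> mean Fisher z
    per_trial_z: dict            # trial type -> list of per-window z values
    delta_sucrose_water: float   # z_sucrose - z_water


def pre_reward_correlation(bla_traces: list, vca1_traces: list, trial_types,
                           bin_width: float = 0.01,
                           window_s: float = 1.0) -> RegionCorrelation:
    """Windowed inter-regional correlation of regional mean firing rates.

    ``bla_traces[k]`` / ``vca1_traces[k]`` are the trial-k mean-rate traces
    (10-ms bins over the pre-reward epoch).  A Pearson r is computed per
    1-s window, Fisher z-transformed, and averaged per trial type; windows
    with a constant trace are skipped.  The sucrose-water change is
    z_sucrose - z_water.
    """
    trial_types = np.asarray(trial_types)
    per_window = int(round(window_s / bin_width))
    zs: dict = {}
    for k, tt in enumerate(trial_types):
        x, y = np.asarray(bla_traces[k], float), np.asarray(vca1_traces[k], float)
        n_win = len(x) // per_window
        for w in range(n_win):
            a = x[w * per_window:(w + 1) * per_window]
            b = y[w * per_window:(w + 1) * per_window]
            if a.std() == 0 or b.std() == 0:
                warnings.warn("constant regional trace in window; skipped")
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if abs(r) >= Z_CAP:
                warnings.warn("near-perfect correlation capped before atanh")
            zs.setdefault(tt, []).append(fisher_z(r))
    mean_z = {tt: float(np.mean(v)) for tt, v in zs.items()}
    delta = mean_z.get("sucrose", np.nan) - mean_z.get("water", np.nan)
    return RegionCorrelation(mean_z, zs, float(delta))


def intention_state_connectivity(bla: np.ndarray, vca1: np.ndarray,
                                 intention_mask, *, n_samples: int = 1000,
                                 neurons_per_sample: int = 5, n_pcs: int = 5,
                                 min_bins: int = 5, seed=None):
    """PCA-denoised BLA-vCA1 correlation, intention vs non-intention bins.

    Per resample, ``neurons_per_sample`` neurons are drawn from each region;
    for each bin class the two (5 x bins) matrices are projected on their
    own leading PCs, and the absolute Pearson correlation between matched
    BLA/vCA1 PC time courses (PCs 1..5) is averaged.  Returns
    ``{"intention": mean_r, "non_intention": mean_r}`` (NaN for a class
    with fewer than ``min_bins`` bins, which is skipped with a warning).
    """
    bla, vca1 = np.asarray(bla, float), np.asarray(vca1, float)
    mask = np.asarray(intention_mask, bool)
    if bla.shape[0] < neurons_per_sample or vca1.shape[0] < neurons_per_sample:
        raise ValueError(f"need at least {neurons_per_sample} neurons per region")
    rng = np.random.default_rng(seed)
    out = {}
    for name, m in (("intention", mask), ("non_intention", ~mask)):
        if m.sum() < min_bins:
            warnings.warn(f"{name} class has fewer than {min_bins} bins; skipped")
            out[name] = np.nan
            continue
        vals = np.empty(n_samples)
        for s in range(n_samples):
            bi = rng.choice(bla.shape[0], neurons_per_sample, replace=False)
            vi = rng.choice(vca1.shape[0], neurons_per_sample, replace=False)
            Pb = _pca_reduce(bla[np.ix_(bi, np.flatnonzero(m))], 1.0, n_pcs)
            Pv = _pca_reduce(vca1[np.ix_(vi, np.flatnonzero(m))], 1.0, n_pcs)
            k = min(Pb.shape[0], Pv.shape[0])
            rs = []
            for i in range(k):
                if Pb[i].std() == 0 or Pv[i].std() == 0:
                    continue
                rs.append(abs(float(np.corrcoef(Pb[i], Pv[i])[0, 1])))
            vals[s] = np.mean(rs) if rs else np.nan
        out[name] = float(np.nanmean(vals))
    return out
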