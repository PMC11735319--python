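"""Supervised decoders.

Pseudo-population linear (SVM) decoding of current reward, previous reward,
or switch/stay intention with reward-history balancing; cross-time-bin
generalization; decoding from HMM posterior-smoothed activity; the
Mahalanobis-like single-animal group decoder with feature-importance by
leave-one-feature-out; the susceptible-vs-resilient decoder generalized to
a two-condition (e.g. saline/CNO) contrast; lick-rate trial equalization;
and group decoding from neural activity restricted to time bins where
face-feature decoding is at chance.

Trial-history balancing is central: pseudo-trials are always assembled with
equal numbers of the four previous-current pair types (WW, WS, SW, SS), so
that none of the binary targets is confounded by reward history.
Significance is assessed against 2 s.d. of a shuffled-label distribution
centred on the theoretical chance level of 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .single_neuron import bin_trials

PAIR_TYPES = ("WW", "WS", "SW", "SS")

# pair type -> binary label per decoding target; balanced by construction
TARGET_LABELS = {
    "current": {"WW": 0, "SW": 0, "WS": 1, "SS": 1},       # water vs sucrose now
    "previous": {"WW": 0, "WS": 0, "SW": 1, "SS": 1},      # water vs sucrose before
    "switch_stay": {"WW": 0, "SS": 0, "WS": 1, "SW": 1},   # stay vs switch
}


@dataclass
class PseudoPopulation:
    """Pooled neurons with per-pair-type trial pools.

    ``neurons[i][pt]`` is an (n_trials, n_bins) count matrix for neuron i
    and pair type pt.  Only neurons with at least ``min_trials`` trials of
    every pair type are admitted.
    """

    neurons: list
    bin_width: float = 0.5
    window: tuple = (-4.0, 4.0)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_bins(self) -> int:
        return next(iter(self.neurons[0].values())).shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window[0] + self.bin_width * (0.5 + np.arange(self.n_bins))

    def min_pool_size(self) -> int:
        return min(len(p[pt]) for p in self.neurons for pt in PAIR_TYPES)


def build_pseudopopulation(sessions, region: str, group: str | None = None,
                           bin_width: float = 0.5, window=(-4.0, 4.0),
                           min_trials: int = 8) -> PseudoPopulation:
    """Pool neurons across sessions of one region (and optionally group).

    Each neuron contributes its per-trial binned counts split by pair type;
    neurons lacking ``min_trials`` trials of any of the four pair types are
    excluded (history analyses discard the unlabelled first trial).
    """
    neurons = []
    for s in sessions:
        if group is not None and s.group != group:
            continue
        pair = s.trials["pair_type"].to_numpy()
        for trial_spikes in s.task[region].spike_times:
            counts = bin_trials(trial_spikes, bin_width, window)
            pools = {pt: counts[pair == pt] for pt in PAIR_TYPES}
            if all(len(v) >= min_trials for v in pools.values()):
                neurons.append(pools)
    if not neurons:
        raise ValueError(
            "no neuron satisfies the inclusion rule of at least "
            f"{min_trials} trials per each of the four trial types")
    return PseudoPopulation(neurons, bin_width, window)


def _assemble(neuron_pools, n_per_type, rng):
    """Pseudo-trials: per pair type, each neuron independently contributes
    ``n_per_type`` of its trials (without replacement within the draw)."""
    n_neurons = len(neuron_pools)
    n_bins = next(iter(neuron_pools[0].values())).shape[1]
    X = np.empty((4 * n_per_type, n_neurons, n_bins))
    pair_labels = np.repeat(PAIR_TYPES, n_per_type)
    for p, pt in enumerate(PAIR_TYPES):
        sl = slice(p * n_per_type, (p + 1) * n_per_type)
        for j, pools in enumerate(neuron_pools):
            pool = pools[pt]
            idx = rng.choice(len(pool), size=n_per_type,
                             replace=len(pool) < n_per_type)
            X[sl, j, :] = pool[idx]
    return X, pair_labels


def _split(y, test_frac, rng):
    """Stratified train/test split: an unbalanced training set would bias
    the classifier toward its majority class and pull the signal-free
    accuracy below the theoretical 0.5."""
    y = np.asarray(y)
    tr, te = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_test = max(int(round(test_frac * len(idx))), 1)
        te.append(idx[:n_test])
        tr.append(idx[n_test:])
    return np.concatenate(tr), np.concatenate(te)


def _svm_acc(Xtr, ytr, Xte, yte, C):
    if len(np.unique(ytr)) < 2:
        return 0.5
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, ytr)
    return float((clf.predict(Xte) == yte).mean())


@dataclass
class DecodeResult:
    accuracy: np.ndarray            # (n_bins,) mean accuracy per time bin
    samples: np.ndarray             # (n_subsamples, n_bins)
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    significant: np.ndarray         # |acc - 0.5| > 2 shuffle s.d.
    bin_centers: np.ndarray
    chance: float = 0.5
    shuffle_samples: np.ndarray | None = None  # (n_shuffles, n_bins)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_shuffle_sd(self) -> float:
        """s.d. of the bin-averaged accuracy across shuffles."""
        if self.shuffle_samples is None:
            return float(self.shuffle_sd.mean())
        return float(self.shuffle_samples.mean(axis=1).std(ddof=1))

    @property
    def mean_significant(self) -> bool:
        return bool(abs(self.mean_accuracy - self.chance) > 2 * self.mean_shuffle_sd)


def svm_decode(pseudo: PseudoPopulation, target: str = "current", *,
               n_neuron_subsamples: int = 10, subsample_size: int = 60,
               n_cv: int = 100, n_trials_per_type: int | None = None,
               test_frac: float = 0.2, n_shuffles: int = 100,
               C: float = 1.0, seed=None) -> DecodeResult:
    """Pseudo-population linear decoding of a binary trial variable.

    For each of ``n_neuron_subsamples`` random draws of ``subsample_size``
    neurons, pseudo-trials with equal pair-type counts are assembled and a
    linear-kernel SVM is trained per 0.5-s time bin with an 80:20
    cross-validated split, ``n_cv`` times; accuracies average over splits
    then subsamples.  Chance is the shuffled-label distribution; a bin is
    significant when its accuracy lies outside 2 shuffle s.d. around the
    theoretical level of 0.5.
    """
    if target not in TARGET_LABELS:
        raise ValueError(f"unknown target {target!r}")
    label_map = TARGET_LABELS[target]
    rng = np.random.default_rng(seed)
    size = subsample_size
    if size > pseudo.n_neurons:
        warnings.warn("subsample_size exceeds available neurons; using all")
        size = pseudo.n_neurons
    if n_trials_per_type is None:
        n_trials_per_type = pseudo.min_pool_size()
    n_bins = pseudo.n_bins

    def _one_pass(y_shuffler=None):
        acc = np.zeros(n_bins)
        idx = rng.choice(pseudo.n_neurons, size=size, replace=False)
        pools = [pseudo.neurons[i] for i in idx]
        for _ in range(n_cv):
            X, pair = _assemble(pools, n_trials_per_type, rng)
            y = np.array([label_map[pt] for pt in pair])
            if y_shuffler is not None:
                y = y_shuffler(y)
            tr, te = _split(y, test_frac, rng)
            for b in range(n_bins):
                acc[b] += _svm_acc(X[tr, :, b], y[tr], X[te, :, b], y[te], C)
        return acc / n_cv

    samples = np.vstack([_one_pass() for _ in range(n_neuron_subsamples)])
    accuracy = samples.mean(axis=0)
    shuf = np.vstack([
        _one_pass(y_shuffler=rng.permutation) for _ in range(n_shuffles)
    ]) if n_shuffles else np.full((1, n_bins), 0.5)
    sh_mean, sh_sd = shuf.mean(axis=0), shuf.std(axis=0, ddof=1)
    significant = np.abs(accuracy - 0.5) > 2 * sh_sd
    return DecodeResult(accuracy, samples, sh_mean, sh_sd, significant,
                        pseudo.bin_centers, shuffle_samples=shuf)


def cross_time_decode(pseudo: PseudoPopulation, target: str = "current", *,
                      n_neuron_subsamples: int = 5, subsample_size: int = 60,
                      n_cv: int = 20, n_trials_per_type: int | None = None,
                      test_frac: float = 0.2, C: float = 1.0,
                      seed=None) -> np.ndarray:
    """Train-bin x test-bin accuracy matrix; the diagonal is within-bin
    decoding (same splits), off-diagonal entries test temporal
    generalization of the code."""
    label_map = TARGET_LABELS[target]
    rng = np.random.default_rng(seed)
    size = min(subsample_size, pseudo.n_neurons)
    if n_trials_per_type is None:
        n_trials_per_type = pseudo.min_pool_size()
    n_bins = pseudo.n_bins
    M = np.zeros((n_bins, n_bins))
    for _ in range(n_neuron_subsamples):
        idx = rng.choice(pseudo.n_neurons, size=size, replace=False)
        pools = [pseudo.neurons[i] for i in idx]
        for _ in range(n_cv):
            X, pair = _assemble(pools, n_trials_per_type, rng)
            y = np.array([label_map[pt] for pt in pair])
            tr, te = _split(y, test_frac, rng)
            for btr in range(n_bins):
                clf = SVC(kernel="linear", C=C)
                clf.fit(X[tr, :, btr], y[tr])
                for bte in range(n_bins):
                    M[btr, bte] += (clf.predict(X[te, :, bte]) == y[te]).mean()
    return M / (n_neuron_subsamples * n_cv)


def decode_from_smoothed(session_pools: list, *, n_pseudo: int = 1000,
                         n_train: int = 100, n_test: int = 20,
                         n_cv: int = 100, n_shuffles: int = 100,
                         C: float = 1.0, seed=None) -> DecodeResult:
    """Switch-vs-stay decoding from HMM posterior-smoothed pre-reward
    activity.

    ``session_pools[s][pt]`` is an (n_trials, N_s, 4) array of smoothed
    activity (4 one-second pre-reward bins) for session s and pair type pt.
    Each session's trials of every pair type are first split in half, so
    the train and test pseudo-trial pools draw from disjoint underlying
    trials (resampling the same trial into both pools would let the
    classifier memorize trial identity).  ``n_pseudo`` pseudo-trials per
    pair type are assembled per pool by sampling one trial per session and
    concatenating the sessions' neurons; each cross-validation draws
    ``n_train`` training and ``n_test`` testing pseudo-trials, decodes each
    of the 4 bins with a linear SVM, and accuracies average over bins and
    CVs.
    """
    for pools in session_pools:
        missing = [pt for pt in PAIR_TYPES
                   if len(pools.get(pt, [])) < 2]
        if missing:
            raise ValueError(f"session lacks pair types {missing}")
    rng = np.random.default_rng(seed)

    halves = []  # per session: {pt: (train_trials, test_trials)}
    for pools in session_pools:
        h = {}
        for pt in PAIR_TYPES:
            arr = np.asarray(pools[pt])
            perm = rng.permutation(len(arr))
            cut = len(arr) // 2
            h[pt] = (arr[perm[cut:]], arr[perm[:cut]])
        halves.append(h)

    def make_pool(which):
        parts = {}
        for pt in PAIR_TYPES:
            per_sess = [h[pt][which][rng.integers(0, len(h[pt][which]),
                                                  size=n_pseudo)]
                        for h in halves]
            parts[pt] = np.concatenate(per_sess, axis=1)  # (n_pseudo, N_tot, 4)
        X = np.concatenate([parts[pt] for pt in PAIR_TYPES], axis=0)
        y = np.array([TARGET_LABELS["switch_stay"][pt]
                      for pt in PAIR_TYPES for _ in range(n_pseudo)])
        return X, y

    Xtr_pool, ytr_pool = make_pool(0)
    Xte_pool, yte_pool = make_pool(1)
    n_bins = Xtr_pool.shape[2]

    def run(y_tr, y_te):
        acc = np.zeros(n_bins)
        for _ in range(n_cv):
            tr = rng.choice(len(y_tr), size=n_train, replace=False)
            te = rng.choice(len(y_te), size=n_test, replace=False)
            for b in range(n_bins):
                acc[b] += _svm_acc(Xtr_pool[tr, :, b], y_tr[tr],
                                   Xte_pool[te, :, b], y_te[te], C)
        return acc / n_cv

    accuracy = run(ytr_pool, yte_pool)
    shuf = np.vstack([run(rng.permutation(ytr_pool), yte_pool)
                      for _ in range(n_shuffles)]) if n_shuffles else \
        np.full((1, n_bins), 0.5)
    sh_mean, sh_sd = shuf.mean(axis=0), shuf.std(axis=0, ddof=1)
    significant = np.abs(accuracy - 0.5) > 2 * sh_sd
    return DecodeResult(accuracy, accuracy[None, :], sh_mean, sh_sd,
                        significant, np.arange(-4.0, 0.0) + 0.5,
                        shuffle_samples=shuf)


# ---------------------------------------------------- group-identity decoder

def _mahalanobis_like(x, pts):
    """Euclidean distance from x to the centroid of pts, divided by the
    sample variance of pts projected on the centroid-to-x direction."""
    c = pts.mean(axis=0)
    diff = x - c
    dist = np.linalg.norm(diff)
    if dist == 0:
        return 0.0
    u = diff / dist
    var = (pts @ u).var(ddof=1)
    if var == 0:
        warnings.warn("zero variance along distance direction; "
                      "falling back to Euclidean distance")
        return dist
    return dist / var


def mahalanobis_group_decode(features: np.ndarray, labels, *,
                             n_cv: int = 1000, minmax_idx=(),
                             seed=None) -> float:
    """Single-animal group decoding with the Mahalanobis-like distance.

    Per cross-validation: the two groups are balanced by subsampling to the
    smaller group, one animal is held out, features listed in
    ``minmax_idx`` are min-max scaled on the training rows (test clipped to
    [0, 1]), and the held-out animal is assigned to the class with the
    smaller Mahalanobis-like distance.  Returns the correct fraction over
    ``n_cv`` runs.
    """
    X = np.asarray(features, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two groups required")
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    m = min(len(i) for i in idx_by_class)
    if m < 2:
        raise ValueError("need at least 2 animals per group")
    rng = np.random.default_rng(seed)
    minmax_idx = np.asarray(list(minmax_idx), dtype=int)
    correct = 0
    for _ in range(n_cv):
        sel = np.concatenate([rng.choice(i, size=m, replace=False)
                              for i in idx_by_class])
        t = rng.integers(len(sel))
        test_i, train_i = sel[t], np.delete(sel, t)
        Xtr, Xte = X[train_i].copy(), X[test_i].copy()
        if len(minmax_idx):
            lo = Xtr[:, minmax_idx].min(axis=0)
            hi = Xtr[:, minmax_idx].max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            Xtr[:, minmax_idx] = (Xtr[:, minmax_idx] - lo) / span
            Xte[minmax_idx] = np.clip((Xte[minmax_idx] - lo) / span, 0.0, 1.0)
        dists = [_mahalanobis_like(Xte, Xtr[labels[train_i] == c])
                 for c in classes]
        if classes[int(np.argmin(dists))] == labels[test_i]:
            correct += 1
    return correct / n_cv


def leave_one_feature_out(features: np.ndarray, labels, *, n_cv: int = 1000,
                          minmax_idx=(), seed=None):
    """Accuracy drop from removing each feature in turn.

    Returns ``(full_accuracy, drops)`` with ``drops[f]`` = full accuracy
    minus accuracy without feature f.
    """
    X = np.asarray(features, float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(X.shape[1] + 1)
    full = mahalanobis_group_decode(X, labels, n_cv=n_cv,
                                    minmax_idx=minmax_idx, seed=children[0])
    drops = np.empty(X.shape[1])
    for f in range(X.shape[1]):
        keep = [i for i in range(X.shape[1]) if i != f]
        mm = [keep.index(i) for i in minmax_idx if i != f]
        acc = mahalanobis_group_decode(X[:, keep], labels, n_cv=n_cv,
                                       minmax_idx=mm, seed=children[f + 1])
        drops[f] = full - acc
    return full, drops


@dataclass
class GeneralizationResult:
    internal_accuracy: float        # held-out-animal accuracy on train groups
    test_class_fraction: np.ndarray  # per test row: fraction of CVs -> class 1
    test_accuracy: float | None
    shuffle_mean: float
    shuffle_sd: float
    significant: bool
    classes: np.ndarray = field(default=None)


def generalize_decoder(train_X, train_y, test_X, test_y=None, *,
                       n_cv: int = 1000, n_shuffles: int = 100, C: float = 1.0,
                       seed=None) -> GeneralizationResult:
    """Train a linear SVM on one two-group contrast (e.g. susceptible vs
    resilient) and apply it, unretrained, to rows from another contrast
    (e.g. saline vs CNO).

    Per CV the training classes are balanced by subsampling and one animal
    is held out for the internal accuracy estimate; the fitted model also
    classifies every test row.  Significance of the internal accuracy is
    judged against 2 s.d. of ``n_shuffles`` label-shuffled runs centred on
    0.5.
    """
    Xtr = np.asarray(train_X, float)
    ytr = np.asarray(train_y)
    Xte = np.asarray(test_X, float)
    classes = np.unique(ytr)
    if len(classes) != 2:
        raise ValueError("training labels must have exactly two classes")
    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(ytr == c) for c in classes]
    m = min(len(i) for i in idx_by_class)

    def one_cv(y):
        sel = np.concatenate([rng.choice(i, size=m, replace=False)
                              for i in idx_by_class])
        t = rng.integers(len(sel))
        test_i, train_i = sel[t], np.delete(sel, t)
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr[train_i], y[train_i])
        internal = float(clf.predict(Xtr[test_i][None])[0] == y[test_i])
        return internal, clf.predict(Xte) == classes[1]

    internal = 0.0
    votes = np.zeros(len(Xte))
    for _ in range(n_cv):
        ok, pred1 = one_cv(ytr)
        internal += ok
        votes += pred1
    internal /= n_cv
    votes /= n_cv
    # each shuffle fixes one label permutation and averages the held-out
    # accuracy over several CVs, mirroring how the observed mean is formed
    n_cv_shuffle = max(min(n_cv, 20), 1)
    shuf = np.empty(n_shuffles)
    for s in range(n_shuffles):
        y_perm = rng.permutation(ytr)
        shuf[s] = np.mean([one_cv(y_perm)[0] for _ in range(n_cv_shuffle)])
    sh_mean, sh_sd = float(shuf.mean()), float(shuf.std(ddof=1))
    test_acc = None
    if test_y is not None:
        test_y = np.asarray(test_y)
        frac_correct = np.where(test_y == classes[1], votes, 1.0 - votes)
        test_acc = float(frac_correct.mean())
    return GeneralizationResult(internal, votes, test_acc, sh_mean, sh_sd,
                                bool(abs(internal - 0.5) > 2 * sh_sd), classes)


def equalize_lick_trials(trial_rates, rate_range=(3.0, 14.0)) -> np.ndarray:
    """Keep-mask for trials whose lick rate lies inside the closed range."""
    r = np.asarray(trial_rates, float)
    mask = (r >= rate_range[0]) & (r <= rate_range[1])
    if not mask.any():
        warnings.warn("no trial inside the lick-rate range")
    return mask


@dataclass
class FaceChanceResult:
    face_accuracy: np.ndarray     # per-bin face-feature decoding accuracy
    chance_bins: np.ndarray       # bool mask of bins at chance
    neural_accuracy: float | None  # group decoding on those bins
    shuffle_sd: np.ndarray


def face_chance_neural_decode(face_features: list, neural_counts: list,
                              groups, *, n_train_bins: int = 10,
                              n_shuffles: int = 20, sd_level: float = 2.0,
                              C: float = 1.0, seed=None) -> FaceChanceResult:
    """Group decoding from neural activity restricted to time bins where
    face/limb decoding is at chance.

    ``face_features[a]`` is (T, 6) per animal; ``neural_counts[a]`` is
    (N_a, T).  Leave-one-animal-out: a linear SVM on face features is
    trained on ``n_train_bins`` random bins of each training animal and
    tested on every bin of the held-out animal, giving a per-bin accuracy;
    bins within ``sd_level`` shuffle s.d. of 0.5 are "face-at-chance".  On
    those bins, group decoding is repeated with per-bin neural summary
    features (population mean and s.d. of the spike count).
    """
    groups = np.asarray(groups)
    T = face_features[0].shape[0]
    n_animals = len(face_features)
    rng = np.random.default_rng(seed)
    neural_feats = [np.column_stack([np.mean(c, axis=0), np.std(c, axis=0)])
                    for c in neural_counts]

    def per_bin_accuracy(feats, y):
        acc = np.zeros(T)
        for a in range(n_animals):
            # balance the training animals per class: an unbalanced
            # leave-one-out split biases the classifier against the
            # held-out animal's class
            rest = [b for b in range(n_animals) if b != a]
            by_class = {c: [b for b in rest if y[b] == c] for c in np.unique(y)}
            m = min(len(v) for v in by_class.values())
            if m == 0:
                continue
            train_animals = np.concatenate([
                rng.choice(v, size=m, replace=False) for v in by_class.values()])
            Xtr, ytr = [], []
            for b in train_animals:
                bins = rng.choice(T, size=min(n_train_bins, T), replace=False)
                Xtr.append(feats[b][bins])
                ytr.extend([y[b]] * len(bins))
            clf = SVC(kernel="linear", C=C)
            clf.fit(np.vstack(Xtr), np.asarray(ytr))
            acc += clf.predict(feats[a]) == y[a]
        return acc / n_animals

    face_acc = per_bin_accuracy(face_features, groups)
    shuf = np.vstack([per_bin_accuracy(face_features, rng.permutation(groups))
                      for _ in range(n_shuffles)])
    sd = shuf.std(axis=0, ddof=1)
    chance_bins = np.abs(face_acc - 0.5) <= sd_level * np.maximum(sd, 1e-12)
    if not chance_bins.any():
        warnings.warn("no face-at-chance bins; neural decoding skipped")
        return FaceChanceResult(face_acc, chance_bins, None, sd)
    neural_acc = per_bin_accuracy(neural_feats, groups)
    return FaceChanceResult(face_acc, chance_bins,
                            float(neural_acc[chance_bins].mean()), sd)
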