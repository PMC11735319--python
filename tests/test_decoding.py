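"""Decoders: pseudo-population SVM, smoothed-state decoding, group decoding."""

import numpy as np
import pytest

from popdyn import decoding, synthetic as syn
from popdyn.decoding import PAIR_TYPES


def make_pseudo(n_neurons=12, n_per_type=12, n_bins=16, signal=None, seed=0):
    """Synthetic pools; ``signal(pt)`` returns a per-bin rate offset."""
    rng = np.random.default_rng(seed)
    neurons = []
    for _ in range(n_neurons):
        base = rng.uniform(2.0, 6.0)
        pools = {}
        for pt in PAIR_TYPES:
            lam = np.full(n_bins, base)
            if signal is not None:
                lam = lam + signal(pt)
            pools[pt] = rng.poisson(lam, size=(n_per_type, n_bins)).astype(float)
        neurons.append(pools)
    return decoding.PseudoPopulation(neurons)


def test_pseudopopulation_inclusion_boundary():
    s = syn.simulate_session(syn.SUSCEPTIBLE, n_trials=120, n_neurons=6, seed=1)
    pseudo = decoding.build_pseudopopulation([s], "BLA")
    assert pseudo.n_neurons == 6
    assert pseudo.n_bins == 16
    # a neuron with fewer than 8 trials of some pair type is excluded
    counts = s.trials["pair_type"].value_counts()
    counts = counts[counts.index != ""]  # unlabelled first trial
    rare = counts.idxmin()
    trimmed = s.trials.copy()
    drop = trimmed.index[trimmed["pair_type"] == rare][: counts.min() - 7]
    keep = ~trimmed.index.isin(drop)
    s7 = syn.subset_trials(s, np.asarray(keep))
    with pytest.raises(ValueError, match="8 trials"):
        decoding.build_pseudopopulation([s7], "BLA")


def test_pseudo_trial_assembly_is_pair_type_balanced(rng):
    pseudo = make_pseudo()
    X, pair = decoding._assemble(pseudo.neurons, 10, rng)
    vals, counts = np.unique(pair, return_counts=True)
    assert sorted(vals) == sorted(PAIR_TYPES)
    assert np.all(counts == 10)
    # every binary target is balanced as a consequence
    for tgt, mapping in decoding.TARGET_LABELS.items():
        y = np.array([mapping[p] for p in pair])
        assert y.mean() == 0.5


def test_shuffled_labels_decode_at_chance():
    pseudo = make_pseudo(seed=2)
    res = decoding.svm_decode(pseudo, "current", n_neuron_subsamples=1,
                              subsample_size=12, n_cv=5, n_shuffles=20, seed=3)
    # no signal was injected: the bin-averaged accuracy sits within 2 s.d.
    # of the shuffled-label distribution around the theoretical 0.5
    assert abs(res.mean_accuracy - 0.5) <= 2 * res.mean_shuffle_sd
    assert not res.mean_significant


def test_injected_current_choice_signal_is_decoded():
    def signal(pt):
        s = np.zeros(16)
        if pt[1] == "S":          # current reward sucrose
            s[8:] = 4.0           # post-reward modulation only
        return s

    pseudo = make_pseudo(signal=signal, seed=4)
    res = decoding.svm_decode(pseudo, "current", n_neuron_subsamples=1,
                              subsample_size=12, n_cv=5, n_shuffles=10, seed=5)
    post = res.bin_centers > 0
    assert res.accuracy[post].mean() > 0.8
    assert res.accuracy[~post].mean() < 0.65
    assert res.significant[post].any()


def test_duplicating_neurons_leaves_accuracy_stable():
    def signal(pt):
        return np.full(16, 3.0) if pt[1] == "S" else np.zeros(16)

    pseudo = make_pseudo(n_neurons=8, signal=signal, seed=6)
    doubled = decoding.PseudoPopulation(pseudo.neurons * 2)
    a = decoding.svm_decode(pseudo, "current", n_neuron_subsamples=1,
                            subsample_size=8, n_cv=5, n_shuffles=0, seed=7)
    b = decoding.svm_decode(doubled, "current", n_neuron_subsamples=1,
                            subsample_size=16, n_cv=5, n_shuffles=0, seed=7)
    assert abs(a.mean_accuracy - b.mean_accuracy) < 0.1


def test_oversized_subsample_warns_and_uses_all():
    pseudo = make_pseudo(n_neurons=5)
    with pytest.warns(UserWarning):
        res = decoding.svm_decode(pseudo, "current", n_neuron_subsamples=1,
                                  subsample_size=60, n_cv=2, n_shuffles=0,
                                  seed=8)
    assert res.accuracy.shape == (16,)


def test_cross_time_matrix_shows_transient_code():
    def signal(pt):
        s = np.zeros(16)
        if pt[1] == "S":
            s[8:10] = 6.0         # code confined to two bins
        return s

    pseudo = make_pseudo(signal=signal, seed=9)
    M = decoding.cross_time_decode(pseudo, "current", n_neuron_subsamples=1,
                                   subsample_size=12, n_cv=4, seed=10)
    assert M.shape == (16, 16)
    assert M[8, 8] > 0.8
    assert M[8, 0] < 0.65         # training bin does not generalize backwards
    assert M[0, 0] < 0.65


def _smoothed_pools(separation, n_sessions=2, n_trials=12, n_neurons=5, seed=0):
    rng = np.random.default_rng(seed)
    pools = []
    for _ in range(n_sessions):
        base = rng.uniform(2, 5, size=n_neurons)
        d = {}
        for pt in PAIR_TYPES:
            shift = separation if pt in ("WS", "SW") else 0.0
            d[pt] = rng.normal(base[None, :, None] + shift,
                               0.5, size=(n_trials, n_neurons, 4))
        pools.append(d)
    return pools


def test_smoothed_decoding_above_chance_with_separated_states():
    pools = _smoothed_pools(3.0, seed=11)
    res = decoding.decode_from_smoothed(pools, n_pseudo=150, n_cv=10,
                                        n_shuffles=10, seed=12)
    assert res.mean_accuracy > 0.9


def test_smoothed_decoding_at_chance_without_signal():
    pools = _smoothed_pools(0.0, seed=13)
    res = decoding.decode_from_smoothed(pools, n_pseudo=150, n_cv=10,
                                        n_shuffles=20, seed=14)
    assert abs(res.mean_accuracy - 0.5) <= 2.5 * max(res.mean_shuffle_sd, 0.02)


def test_constant_smoothed_features_are_exactly_chance():
    # K = 1 smoothing: every pseudo-trial identical
    pools = [{pt: np.full((10, 4, 4), 3.0) for pt in PAIR_TYPES}]
    res = decoding.decode_from_smoothed(pools, n_pseudo=60, n_cv=5,
                                        n_shuffles=0, seed=15)
    assert res.mean_accuracy == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------- group-identity decoder

def test_point_mass_groups_decode_perfectly():
    X = np.vstack([np.tile([0.0, 0.0], (5, 1)), np.tile([10.0, -3.0], (5, 1))])
    y = np.array(["a"] * 5 + ["b"] * 5)
    with pytest.warns(UserWarning):  # zero variance -> Euclidean fallback
        acc = decoding.mahalanobis_group_decode(X, y, n_cv=200, seed=16)
    assert acc == 1.0


def test_single_distribution_groups_decode_at_chance(rng):
    X = rng.normal(size=(30, 4))
    y = np.array(["a", "b"] * 15)
    acc = decoding.mahalanobis_group_decode(X, y, n_cv=500, seed=17)
    assert abs(acc - 0.5) < 2 * np.sqrt(0.25 / 500) + 0.1


def test_mahalanobis_distance_matches_hand_fixture():
    """Five points: variance along the test direction penalizes the wide
    class, checked against an explicit projection computation."""
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0], [1.0, 1.0], [3.0, -1.0]])
    x = np.array([10.0, 0.0])
    c = pts.mean(axis=0)
    u = (x - c) / np.linalg.norm(x - c)
    expected = np.linalg.norm(x - c) / (pts @ u).var(ddof=1)
    assert decoding._mahalanobis_like(x, pts) == pytest.approx(expected)
    # tight class at the same distance wins despite equal centroid distance
    tight = np.array([[0.0, 1.0], [0.0, -1.0], [0.1, 0.0], [-0.1, 0.0], [0.0, 0.0]])
    wide = tight * np.array([50.0, 1.0])
    assert decoding._mahalanobis_like(x, tight + [2, 0]) > \
        decoding._mahalanobis_like(x, wide + [2, 0])


def test_minmax_scaling_applied_to_selected_features(rng):
    # feature 0 informative but huge scale; scaling must keep it within [0,1]
    X = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(4, 1, (8, 2))])
    X[:, 0] *= 1e4
    y = np.array(["a"] * 8 + ["b"] * 8)
    acc = decoding.mahalanobis_group_decode(X, y, n_cv=300, minmax_idx=(0,),
                                            seed=18)
    assert acc > 0.8


def test_leave_one_feature_out_ranks_informative_feature(rng):
    n = 10
    informative = np.concatenate([rng.normal(0, 0.5, n), rng.normal(5, 0.5, n)])
    constant = np.full(2 * n, 3.0)
    noise = rng.normal(size=2 * n)
    X = np.column_stack([informative, constant, noise])
    y = np.array(["a"] * n + ["b"] * n)
    full, drops = decoding.leave_one_feature_out(X, y, n_cv=300, seed=19)
    assert full > 0.9
    assert drops[0] > 0.3          # removing the signal feature is costly
    assert abs(drops[1]) < 0.1     # removing a constant is free
    assert np.argmax(drops) == 0


# ------------------------------------------------------------ generalization

def test_generalization_follows_training_distributions(rng):
    sus = rng.normal(0.0, 0.5, size=(10, 3))
    res = rng.normal(3.0, 0.5, size=(10, 3))
    Xtr = np.vstack([sus, res])
    ytr = np.array(["sus"] * 10 + ["res"] * 10)
    saline = rng.normal(0.0, 0.5, size=(5, 3))   # looks susceptible
    cno = rng.normal(3.0, 0.5, size=(5, 3))      # rescued toward resilient
    out = decoding.generalize_decoder(Xtr, ytr, np.vstack([saline, cno]),
                                      test_y=["sus"] * 5 + ["res"] * 5,
                                      n_cv=200, n_shuffles=30, seed=20)
    assert out.internal_accuracy > 0.9 and out.significant
    assert out.test_accuracy > 0.9
    # CNO rows classified opposite to saline rows: test_class_fraction is
    # the per-row fraction of CVs assigning the second class ("sus")
    assert out.classes[1] == "sus"
    assert out.test_class_fraction[:5].mean() > 0.8   # saline -> susceptible
    assert out.test_class_fraction[5:].mean() < 0.2   # CNO -> resilient


def test_shuffled_training_labels_are_chance(rng):
    Xtr = rng.normal(size=(20, 3))
    ytr = np.array(["sus", "res"] * 10)
    out = decoding.generalize_decoder(Xtr, rng.permutation(ytr),
                                      rng.normal(size=(4, 3)),
                                      n_cv=300, n_shuffles=50, seed=21)
    assert abs(out.internal_accuracy - 0.5) <= 2.5 * max(out.shuffle_sd, 0.02)


# ------------------------------------------------------------- lick matching

def test_equalize_lick_trials_boundaries():
    rates = np.array([2.9, 3.0, 8.0, 14.0, 14.1])
    mask = decoding.equalize_lick_trials(rates)
    np.testing.assert_array_equal(mask, [False, True, True, True, False])
    np.testing.assert_array_equal(
        decoding.equalize_lick_trials(rates, (3.0, 10.0)),
        [False, True, True, False, False])
    with pytest.warns(UserWarning):
        decoding.equalize_lick_trials(np.array([0.1, 20.0]))


# -------------------------------------------------- face-at-chance decoding

def _face_neural_animals(face_sep, neural_sep, n_per_group=4, T=40, seed=0):
    rng = np.random.default_rng(seed)
    faces, neurals, groups = [], [], []
    for g in (0, 1):
        for _ in range(n_per_group):
            faces.append(rng.normal(g * face_sep, 1.0, size=(T, 6)))
            neurals.append(rng.normal(5.0 + g * neural_sep, 1.0, size=(8, T)))
            groups.append(g)
    return faces, neurals, np.array(groups)


def test_identical_faces_leave_all_bins_at_chance_neural_decodes():
    faces, neurals, groups = _face_neural_animals(0.0, 3.0, seed=22)
    out = decoding.face_chance_neural_decode(faces, neurals, groups,
                                             n_shuffles=10, seed=23)
    assert out.chance_bins.mean() > 0.8
    assert out.neural_accuracy > 0.8


def test_face_only_signal_yields_chance_neural():
    faces, neurals, groups = _face_neural_animals(4.0, 0.0, seed=24)
    out = decoding.face_chance_neural_decode(faces, neurals, groups,
                                             n_shuffles=10, seed=25)
    # face decoding is high overall, so few bins qualify; neural is at chance
    if out.neural_accuracy is not None:
        assert abs(out.neural_accuracy - 0.5) < 0.3
    assert out.face_accuracy.mean() > 0.8
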