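"""Synthetic cohorts of head-fixed sucrose-preference sessions.

Generates, per simulated animal, everything the downstream analyses consume:
a first-order Markov reward-choice sequence, a trial table with
previous-choice and switch/stay labels, lick times on the two spouts,
pre-task spike counts drawn from a group-specific Poisson HMM, trial-aligned
task spikes with optional trial-type-exclusive ("intention") pre-reward
states, and 12-keypoint face/limb trajectories.  Ground truth (generating
parameters and state paths) rides along so recovery can be tested.

Group profiles encode the contrasts of interest: the susceptible profile
has water-biased choice transitions, a larger and less-correlated pre-task
state repertoire, blunted lick discrimination, and a nonzero probability of
entering switch- or stay-exclusive states before reward; control and
resilient profiles have none of the intention signal.  An optional rescue
modifier (emulating a chemogenetic manipulation) shifts choices toward
sucrose-stay and silences the intention states.

Every generator is a pure function of its parameters and seed; a session's
sub-streams are spawned deterministically from one root ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import hmm

WATER, SUCROSE = "water", "sucrose"
CHOICES = (WATER, SUCROSE)
REGIONS = ("BLA", "vCA1")

KEYPOINT_NAMES = (
    "eye_top", "eye_bottom", "eye_front", "eye_back",
    "snout_top", "snout_tip", "snout_bottom",
    "whisker1", "whisker2", "mouth", "left_hand", "right_hand",
)

# resting face/limb geometry (arbitrary camera units)
_KEYPOINT_BASE = {
    "eye_front": (0.0, 0.0), "eye_back": (-4.0, 0.0),
    "eye_top": (-2.0, 1.5), "eye_bottom": (-2.0, -1.5),
    "snout_tip": (6.0, 0.0), "snout_top": (4.0, 1.0), "snout_bottom": (4.0, -1.0),
    "whisker1": (2.0, -2.0), "whisker2": (2.5, -2.5),
    "mouth": (3.0, -3.0), "left_hand": (0.0, -8.0), "right_hand": (2.0, -8.0),
}

# ground-truth codes for pre-reward task states
BACKGROUND_STATE, SWITCH_STATE, STAY_STATE = 0, 1, 2


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one behavioural group.

    choice_transition rows/columns are ordered (water, sucrose); entry
    [i, j] is P(next = j | current = i).  ``state_similarity`` is the target
    mean Pearson correlation between pre-task state rate vectors;
    ``intention_state_strength`` is the probability that a 1-s pre-reward
    bin of a switch (stay) trial enters the switch- (stay-) exclusive state.
    """

    name: str
    choice_transition: tuple = ((0.3, 0.7), (0.15, 0.85))
    n_pretask_states: int = 4
    mean_rate: float = 5.0            # spikes / s
    state_rate_dispersion: float = 0.5  # multiplicative spread of state rates
    state_similarity: float = 0.5
    intention_state_strength: float = 0.0
    rescue_effect: bool = False
    # calibration of injected task signal and group-level behaviour metrics
    choice_mod_fraction: float = 0.5
    choice_mod_depth: float = 0.6
    lick_di_strength: float = 1.0     # Hz excess on the sucrose spout
    si_ratio_mean: float = 1.2
    si_ratio_sd: float = 0.15
    open_arm_mean: float = 30.0
    open_arm_sd: float = 6.0

    def __post_init__(self):
        A = np.asarray(self.choice_transition, dtype=float)
        if A.shape != (2, 2) or np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("choice_transition must be a 2x2 row-stochastic matrix")
        if not 0.0 <= self.intention_state_strength <= 1.0:
            raise ValueError("intention_state_strength must lie in [0, 1]")
        if self.n_pretask_states < 1:
            raise ValueError("n_pretask_states must be >= 1")
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be non-negative")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.choice_transition, dtype=float)


CONTROL = GroupProfile(
    name="control",
    choice_transition=((0.35, 0.65), (0.20, 0.80)),
    n_pretask_states=4, state_similarity=0.55,
    intention_state_strength=0.0, lick_di_strength=1.2,
    si_ratio_mean=1.3, si_ratio_sd=0.15, open_arm_mean=35.0, open_arm_sd=6.0,
)

RESILIENT = GroupProfile(
    name="resilient",
    choice_transition=((0.40, 0.60), (0.25, 0.75)),
    n_pretask_states=5, state_similarity=0.45,
    intention_state_strength=0.0, lick_di_strength=0.9,
    si_ratio_mean=1.1, si_ratio_sd=0.15, open_arm_mean=28.0, open_arm_sd=6.0,
)

SUSCEPTIBLE = GroupProfile(
    name="susceptible",
    choice_transition=((0.75, 0.25), (0.60, 0.40)),
    n_pretask_states=8, state_similarity=0.15,
    intention_state_strength=0.75, rescue_effect=True, lick_di_strength=0.2,
    si_ratio_mean=0.6, si_ratio_sd=0.15, open_arm_mean=15.0, open_arm_sd=5.0,
)

PROFILES = {p.name: p for p in (CONTROL, SUSCEPTIBLE, RESILIENT)}


def apply_rescue(profile: GroupProfile) -> GroupProfile:
    """Modifier emulating the chemogenetic rescue: choices shift toward
    sucrose-stay and the intention signal is silenced."""
    return replace(
        profile,
        choice_transition=((0.40, 0.60), (0.25, 0.75)),
        intention_state_strength=0.0,
        lick_di_strength=max(profile.lick_di_strength, 0.9),
    )


def simulate_choices(profile: GroupProfile, n_trials: int, seed=None,
                     first_choice: str | None = None) -> np.ndarray:
    """Sample a reward-choice sequence from the profile's Markov chain."""
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    A = profile.transition_matrix
    idx = np.empty(n_trials, dtype=int)
    if first_choice is None:
        idx[0] = rng.choice(2, p=_stationary(A))
    else:
        idx[0] = CHOICES.index(first_choice)
    u = rng.random(n_trials - 1)
    for t in range(1, n_trials):
        idx[t] = int(u[t - 1] > A[idx[t - 1], 0])
    return np.asarray(CHOICES)[idx]


def _stationary(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.abs(np.real(vecs[:, i]))
    if v.sum() == 0:  # defective (e.g. identity) chain: fall back to uniform
        return np.full(len(A), 1.0 / len(A))
    return v / v.sum()


def make_trial_table(choices, seed=None, first_reward_time: float = 30.0,
                     iti_range: tuple = (9.0, 12.0)) -> pd.DataFrame:
    """Trial table with reward times (>= 8-s ITI), previous-choice,
    previous-current pair type and switch/stay labels.

    The first trial has no preceding trial; its history labels are left
    missing and history analyses discard it.
    """
    choices = np.asarray(choices)
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(*iti_range, size=len(choices) - 1)
    times = first_reward_time + np.concatenate([[0.0], np.cumsum(gaps)])
    prev = np.concatenate([[""], choices[:-1]])
    pair = np.array([
        "" if p == "" else p[0].upper() + c[0].upper()
        for p, c in zip(prev, choices)
    ])
    sw = np.array([
        "" if p == "" else ("stay" if p == c else "switch")
        for p, c in zip(prev, choices)
    ])
    return pd.DataFrame({
        "trial_id": np.arange(len(choices)),
        "reward_time_s": times,
        "choice": choices,
        "prev_choice": prev,
        "pair_type": pair,
        "switch_stay": sw,
    })


@dataclass
class PretaskData:
    counts: np.ndarray          # (N, T) integer spike counts, 1-s bins
    state_path: np.ndarray      # (T,) ground-truth state per bin
    model: hmm.HiddenMarkovModel


def _state_rate_vectors(profile: GroupProfile, n_neurons: int, n_states: int,
                        rng) -> np.ndarray:
    """(N, K) per-state rates with mean pairwise column correlation close to
    ``state_similarity``: each state mixes a shared and a private factor."""
    s = float(np.clip(profile.state_similarity, 0.0, 1.0))
    d = profile.state_rate_dispersion
    shared = rng.standard_normal(n_neurons)
    private = rng.standard_normal((n_neurons, n_states))
    mix = np.sqrt(s) * shared[:, None] + np.sqrt(1.0 - s) * private
    rates = profile.mean_rate * (1.0 + d * mix)
    return np.maximum(rates, 0.05 * max(profile.mean_rate, 1e-3))


def pretask_model(profile: GroupProfile, n_neurons: int, seed=None,
                  stay_prob: float = 0.9) -> hmm.HiddenMarkovModel:
    """The generating Poisson HMM for a profile's pre-task activity: a
    sticky chain (uniform stationary distribution) over K state rate
    vectors."""
    rng = np.random.default_rng(seed)
    K = profile.n_pretask_states
    rates = _state_rate_vectors(profile, n_neurons, K, rng)
    if K == 1:
        trans = np.ones((1, 1))
    else:
        trans = np.full((K, K), (1.0 - stay_prob) / (K - 1))
        np.fill_diagonal(trans, stay_prob)
    return hmm.HiddenMarkovModel(np.full(K, 1.0 / K), trans, "poisson", rates=rates)


def simulate_pretask_counts(profile: GroupProfile, n_neurons: int,
                            n_bins: int = 360, seed=None) -> PretaskData:
    """Pre-task 1-s spike counts from the profile's hidden-state chain."""
    if n_neurons < 1 or n_bins < 1:
        raise ValueError("n_neurons and n_bins must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_model, s_sample = ss.spawn(2)
    model = pretask_model(profile, n_neurons, seed=s_model)
    counts, path = hmm.sample(model, n_bins, seed=s_sample)
    return PretaskData(counts=counts.astype(int), state_path=path, model=model)


@dataclass
class TaskData:
    """Trial-aligned spiking for one region.

    spike_times[i][k]: spike times of neuron i in trial k, seconds relative
    to reward at 0, within [-4, +4).  pre_state_path[k, b] is the
    ground-truth state of 1-s pre-reward bin b (b = 0 is [-4, -3) s).
    """

    spike_times: list
    pre_state_path: np.ndarray    # (n_trials, 4) ints
    baseline_rates: np.ndarray    # (N,)
    switch_rates: np.ndarray      # (N,)
    stay_rates: np.ndarray        # (N,)
    choice_pref: np.ndarray       # (N,) +1 sucrose-pref, -1 water-pref, 0 none


def simulate_task_spikes(profile: GroupProfile, trials: pd.DataFrame,
                         n_neurons: int, seed=None, condition: str = "saline",
                         window: tuple = (-4.0, 4.0)) -> TaskData:
    """Per-trial spike times around reward delivery.

    Post-reward, a ``choice_mod_fraction`` subset of neurons is
    reward-choice modulated (rate scaled by 1 +/- choice_mod_depth).
    Pre-reward, each switch (stay) trial enters the switch- (stay-)
    exclusive state for its whole 4-s window with probability
    ``intention_state_strength``; the rescue condition suppresses this.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    rng = np.random.default_rng(seed)
    strength = profile.intention_state_strength
    if condition == "CNO" and profile.rescue_effect:
        strength = 0.0

    base = profile.mean_rate * rng.uniform(0.5, 1.5, size=n_neurons)
    d = profile.state_rate_dispersion
    switch_rates = np.maximum(base * (1.0 + d * rng.standard_normal(n_neurons)), 0.05)
    stay_rates = np.maximum(base * (1.0 + d * rng.standard_normal(n_neurons)), 0.05)

    pref = np.zeros(n_neurons)
    n_mod = int(round(profile.choice_mod_fraction * n_neurons))
    mod_idx = rng.choice(n_neurons, size=n_mod, replace=False)
    pref[mod_idx[: n_mod // 2]] = 1.0
    pref[mod_idx[n_mod // 2:]] = -1.0

    # intention states are trial-granular: with probability ``strength`` a
    # switch (stay) trial spends its whole pre-reward window in the
    # switch- (stay-) exclusive state, mirroring the temporal persistence
    # of hidden states
    n_trials = len(trials)
    labels = trials["switch_stay"].to_numpy()
    pre_path = np.full((n_trials, 4), BACKGROUND_STATE, dtype=int)
    enter = rng.random(n_trials) < strength
    for k, lab in enumerate(labels):
        if enter[k] and lab == "switch":
            pre_path[k, :] = SWITCH_STATE
        elif enter[k] and lab == "stay":
            pre_path[k, :] = STAY_STATE

    choice_sign = np.where(trials["choice"].to_numpy() == SUCROSE, 1.0, -1.0)
    spike_times = [[] for _ in range(n_neurons)]
    state_rate = {BACKGROUND_STATE: base, SWITCH_STATE: switch_rates,
                  STAY_STATE: stay_rates}
    t0, t1 = window
    for k in range(n_trials):
        # pre-reward: 1-s bins with state-dependent rates
        for b in range(4):
            rates = state_rate[pre_path[k, b]]
            _add_poisson_spikes(spike_times, rates, t0 + b, t0 + b + 1, rng)
        # post-reward: choice-modulated constant rate
        post = base * (1.0 + profile.choice_mod_depth * pref * choice_sign[k])
        _add_poisson_spikes(spike_times, np.maximum(post, 0.0), 0.0, t1, rng)
    spike_times = [
        [np.sort(np.concatenate(trial_list[k * 5:(k + 1) * 5]))
         for k in range(n_trials)]
        for trial_list in spike_times
    ]
    return TaskData(spike_times=spike_times, pre_state_path=pre_path,
                    baseline_rates=base, switch_rates=switch_rates,
                    stay_rates=stay_rates, choice_pref=pref)


def _add_poisson_spikes(store, rates, a, b, rng):
    counts = rng.poisson(rates * (b - a))
    for i, c in enumerate(counts):
        store[i].append(np.sort(rng.uniform(a, b, size=c)))


def simulate_licks(trials: pd.DataFrame, profile: GroupProfile, seed=None,
                   consume_rate: float = 8.0, sample_rate: float = 2.0,
                   pre_rate: float = 3.0) -> pd.DataFrame:
    """Lick times per spout, absolute seconds.

    Post-reward the chosen spout is licked at ``consume_rate`` and the other
    at ``sample_rate``; pre-reward both spouts are sampled at ``pre_rate``.
    The sucrose spout carries an additive ``lick_di_strength`` excess
    (halved pre-reward), the generative counterpart of the lick-rate
    discrimination index.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, tr in trials.iterrows():
        for spout in CHOICES:
            bonus = profile.lick_di_strength if spout == SUCROSE else 0.0
            r_pre = pre_rate + 0.5 * bonus
            r_post = (consume_rate if spout == tr["choice"] else sample_rate) + bonus
            for rate, (a, b) in ((r_pre, (-4.0, 0.0)), (r_post, (0.0, 4.0))):
                n = rng.poisson(rate * (b - a))
                for t in np.sort(rng.uniform(a, b, size=n)):
                    rows.append((spout, tr["reward_time_s"] + t))
    df = pd.DataFrame(rows, columns=["spout", "time_s"])
    return df.sort_values("time_s", ignore_index=True)


def simulate_keypoints(n_frames: int, seed=None, fps: float = 30.0,
                       offsets: dict | None = None, jitter: float = 0.25,
                       smooth_frames: float = 5.0) -> dict:
    """Smooth 12-keypoint trajectories: resting geometry plus
    Gaussian-smoothed noise and optional per-keypoint (dx, dy) offsets.

    Returns ``{name: (n_frames, 2) array}``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = offsets or {}
    out = {}
    for name in KEYPOINT_NAMES:
        base = np.asarray(_KEYPOINT_BASE[name]) + np.asarray(offsets.get(name, (0.0, 0.0)))
        noise = rng.standard_normal((n_frames, 2))
        if n_frames > 1:
            noise = gaussian_filter1d(noise, sigma=smooth_frames, axis=0)
        out[name] = base + jitter * noise
    return out


@dataclass
class SyntheticSession:
    """One simulated animal: behaviour, spiking and ground truth."""

    animal_id: str
    group: str
    condition: str
    trials: pd.DataFrame
    licks: pd.DataFrame
    pretask: dict               # region -> PretaskData
    task: dict                  # region -> TaskData
    keypoints: dict
    si_ratio: float
    open_arm_pct: float
    profile: GroupProfile = field(repr=False, default=None)
    seed: int | None = None

    @property
    def sucrose_preference(self) -> float:
        """% of obtained rewards that were sucrose."""
        return 100.0 * float(np.mean(self.trials["choice"] == SUCROSE))


def simulate_session(profile: GroupProfile, *, n_trials: int = 200,
                     n_neurons: dict | int = 30, n_pretask_bins: int = 360,
                     n_keypoint_frames: int = 600, seed=None,
                     condition: str = "saline", same_reward: bool = False,
                     animal_id: str = "sim0") -> SyntheticSession:
    """Assemble a full session for one animal.

    ``n_neurons`` may be an int (both regions) or ``{region: count}``.
    With ``same_reward=True`` both spouts deliver the same reward (control
    experiment): choices become unbiased coin flips and no intention signal
    is injected.
    """
    if isinstance(n_neurons, int):
        n_neurons = {r: n_neurons for r in REGIONS}
    eff = profile
    if condition == "CNO" and profile.rescue_effect:
        eff = apply_rescue(profile)
    if same_reward:
        eff = replace(eff, choice_transition=((0.5, 0.5), (0.5, 0.5)),
                      intention_state_strength=0.0)
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(6 + 2 * len(n_neurons)))
    choices = simulate_choices(eff, n_trials, seed=next(streams))
    # the task starts after the 10-min pre-task recording period
    trials = make_trial_table(choices, seed=next(streams),
                              first_reward_time=630.0)
    licks = simulate_licks(trials, eff, seed=next(streams))
    keypoints = simulate_keypoints(n_keypoint_frames, seed=next(streams))
    pretask, task = {}, {}
    for region in n_neurons:
        pretask[region] = simulate_pretask_counts(
            eff, n_neurons[region], n_pretask_bins, seed=next(streams))
        task[region] = simulate_task_spikes(
            eff, trials, n_neurons[region], seed=next(streams), condition=condition)
    rng = np.random.default_rng(next(streams))
    si = float(rng.normal(profile.si_ratio_mean, profile.si_ratio_sd))
    oa = float(np.clip(rng.normal(profile.open_arm_mean, profile.open_arm_sd), 0, 100))
    return SyntheticSession(
        animal_id=animal_id, group=profile.name, condition=condition,
        trials=trials, licks=licks, pretask=pretask, task=task,
        keypoints=keypoints, si_ratio=si, open_arm_pct=oa,
        profile=eff, seed=seed)


def subset_trials(session: SyntheticSession, keep_mask) -> SyntheticSession:
    """A copy of the session restricted to the trials where ``keep_mask``
    is True (used by state-conditioned trial filtering)."""
    keep = np.asarray(keep_mask, bool)
    idx = np.flatnonzero(keep)
    task = {
        region: replace(
            td,
            spike_times=[[tr[i] for i in idx] for tr in td.spike_times],
            pre_state_path=td.pre_state_path[keep],
        )
        for region, td in session.task.items()
    }
    return replace(session, trials=session.trials.iloc[idx].reset_index(drop=True),
                   task=task)


def simulate_cohort(*, n_control: int = 15, n_susceptible: int = 12,
                    n_resilient: int = 33, seed=None, **session_kwargs) -> list:
    """A cohort mirroring the study design: 15 control + 45 stressed
    (~12 susceptible, ~33 resilient).  Pass smaller counts for quick runs."""
    ss = np.random.SeedSequence(seed)
    sessions = []
    spec_list = ([CONTROL] * n_control + [SUSCEPTIBLE] * n_susceptible
                 + [RESILIENT] * n_resilient)
    for i, (profile, child) in enumerate(zip(spec_list, ss.spawn(len(spec_list)))):
        sessions.append(simulate_session(
            profile, seed=child.generate_state(1)[0] % (2**31),
            animal_id=f"{profile.name[:3]}{i:03d}", **session_kwargs))
    return sessions
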