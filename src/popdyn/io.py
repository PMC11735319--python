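"""Session-bundle I/O, configuration, and pipeline orchestration.

A session bundle is a directory of plain-text files referenced from a YAML
manifest: spikes.csv (unit_id, region, spike_time_s), trials.csv,
licks.csv, keypoints.csv, and truth.json with the generating parameters
and ground-truth state paths.  Time is in seconds, session-relative,
0-based; bins are half-open [t, t + dt).  The pre-task analysis window is
minutes 2-8 (360 one-second bins).

``run_pipeline`` wires the modules into one seeded, reproducible run over a
simulated cohort; each stage is skippable and a stage failure is recorded
without aborting downstream-independent stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior, connectivity, decoding, geometry, hmm, state_analysis
from . import synthetic
from .single_neuron import bin_trials, intention_modulated
from .synthetic import REGIONS, SyntheticSession

PRETASK_WINDOW = (120.0, 480.0)  # minutes 2-8
PRETASK_BIN_S = 1.0


class SchemaError(ValueError):
    """A session-bundle file violates the expected schema."""


# ------------------------------------------------------------ session bundle

def write_session(session: SyntheticSession, out_dir) -> Path:
    """Write a session bundle; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for region in session.pretask:
        pre = session.pretask[region]
        rng = np.random.default_rng(abs(hash((session.animal_id, region))) % 2**31)
        for i in range(pre.counts.shape[0]):
            unit = f"{region}_{i}"
            for t, c in enumerate(pre.counts[i]):
                if c:
                    ts = PRETASK_WINDOW[0] + t + np.sort(rng.random(c))
                    rows.extend((unit, region, float(x)) for x in ts)
        task = session.task[region]
        reward_times = session.trials["reward_time_s"].to_numpy()
        for i, trials_spikes in enumerate(task.spike_times):
            unit = f"{region}_{i}"
            for k, st in enumerate(trials_spikes):
                rows.extend((unit, region, float(reward_times[k] + x)) for x in st)
    spikes = pd.DataFrame(rows, columns=["unit_id", "region", "spike_time_s"])
    spikes = spikes.sort_values(["unit_id", "spike_time_s"], ignore_index=True)
    spikes.to_csv(out / "spikes.csv", index=False)
    session.trials.to_csv(out / "trials.csv", index=False)
    session.licks.to_csv(out / "licks.csv", index=False)
    kp_rows = []
    for name, xy in session.keypoints.items():
        for f, (x, y) in enumerate(np.atleast_2d(xy)):
            kp_rows.append((f, name, float(x), float(y)))
    pd.DataFrame(kp_rows, columns=["frame", "name", "x", "y"]).to_csv(
        out / "keypoints.csv", index=False)
    truth = {
        "animal_id": session.animal_id,
        "group": session.group,
        "condition": session.condition,
        "si_ratio": session.si_ratio,
        "open_arm_pct": session.open_arm_pct,
        "seed": session.seed,
        "pretask_state_path": {r: p.state_path.tolist()
                               for r, p in session.pretask.items()},
        "pre_reward_state_path": {r: t.pre_state_path.tolist()
                                  for r, t in session.task.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)
    manifest = {
        "animal_id": session.animal_id,
        "group": session.group,
        "condition": session.condition,
        "files": {"spikes": "spikes.csv", "trials": "trials.csv",
                  "licks": "licks.csv", "keypoints": "keypoints.csv",
                  "truth": "truth.json"},
    }
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return mpath


@dataclass
class SessionBundle:
    animal_id: str
    group: str
    condition: str
    spikes: pd.DataFrame
    trials: pd.DataFrame
    licks: pd.DataFrame
    keypoints: dict
    truth: dict


_REQUIRED = {
    "spikes": ("unit_id", "region", "spike_time_s"),
    "trials": ("trial_id", "reward_time_s", "choice"),
    "licks": ("spout", "time_s"),
    "keypoints": ("frame", "name", "x", "y"),
}


def read_session(manifest_path) -> SessionBundle:
    """Read and validate a session bundle from its manifest."""
    mpath = Path(manifest_path)
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    base = mpath.parent
    tables = {}
    for key in ("spikes", "trials", "licks", "keypoints"):
        df = pd.read_csv(base / manifest["files"][key])
        missing = [c for c in _REQUIRED[key] if c not in df.columns]
        if missing:
            raise SchemaError(f"{key}.csv is missing column(s) {missing}")
        tables[key] = df
    bad = set(tables["spikes"]["region"]) - set(REGIONS)
    if bad:
        raise SchemaError(f"unknown region tag(s) {sorted(bad)}")
    g = tables["spikes"].groupby("unit_id")["spike_time_s"]
    if not g.apply(lambda s: s.is_monotonic_increasing).all():
        raise SchemaError("spike_time_s must be sorted within unit_id")
    kp = {name: grp.sort_values("frame")[["x", "y"]].to_numpy()
          for name, grp in tables["keypoints"].groupby("name")}
    with open(base / manifest["files"]["truth"]) as fh:
        truth = json.load(fh)
    return SessionBundle(manifest["animal_id"], manifest["group"],
                         manifest["condition"], tables["spikes"],
                         tables["trials"], tables["licks"], kp, truth)


def pretask_counts_from_spikes(spikes: pd.DataFrame, region: str,
                               window=PRETASK_WINDOW,
                               bin_s: float = PRETASK_BIN_S) -> np.ndarray:
    """(N, T) binned pre-task counts for one region (minutes 2-8 -> 360
    one-second bins by default)."""
    sel = spikes[spikes["region"] == region]
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    units = sorted(sel["unit_id"].unique(), key=lambda u: int(u.rsplit("_", 1)[1]))
    return np.vstack([
        np.histogram(sel.loc[sel["unit_id"] == u, "spike_time_s"], bins=edges)[0]
        for u in units
    ])


# ----------------------------------------------------------------- config

@dataclass
class Config:
    """Pipeline configuration; defaults are desk-scale (small cohort)."""

    seed: int = 0
    n_per_group: int = 3
    n_trials: int = 120
    n_neurons: int = 16
    pretask_bins: int = 360
    hmm_k_min: int = 2
    hmm_k_max: int = 6
    hmm_n_inits: int = 2
    decode_subsamples: int = 2
    decode_subsample_size: int = 60
    decode_cv: int = 10
    decode_shuffles: int = 10
    group_decode_cv: int = 200
    min_neurons_per_region: int = 5
    min_trials_per_label: int = 10
    min_trials_per_pair: int = 8
    stages: tuple = ("simulate", "behavior", "single_neuron", "hmm",
                     "states", "decoding", "geometry", "connectivity")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        if "stages" in obj:
            obj["stages"] = tuple(obj["stages"])
        return cls(**obj)

    @property
    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsStore:
    """Hierarchical results with provenance; serializable to JSON + HDF5."""

    provenance: dict
    results: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)   # name -> ndarray, to HDF5

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {"provenance": self.provenance, "errors": self.errors,
                   "results": _jsonable(self.results)}
        with open(out / "results.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        if self.arrays:
            with h5py.File(out / "arrays.h5", "w") as h5:
                for k, v in self.arrays.items():
                    h5.create_dataset(k, data=np.asarray(v))
        return out / "results.json"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


# ----------------------------------------------------------------- pipeline

def run_pipeline(config: Config | None = None) -> ResultsStore:
    """Execute the analysis stages in dependency order on a simulated
    cohort.  Identical (config, seed) runs produce identical stores."""
    cfg = config or Config()
    store = ResultsStore(provenance={"config_hash": cfg.hash, "seed": cfg.seed,
                                     "config": asdict(cfg)})
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: s.generate_state(1)[0] % 2**31
             for name, s in zip(cfg.stages, ss.spawn(len(cfg.stages)))}

    sessions = None
    if "simulate" in cfg.stages:
        sessions = synthetic.simulate_cohort(
            n_control=cfg.n_per_group, n_susceptible=cfg.n_per_group,
            n_resilient=cfg.n_per_group, seed=seeds["simulate"],
            n_trials=cfg.n_trials, n_neurons=cfg.n_neurons,
            n_pretask_bins=cfg.pretask_bins)
        store.results["simulate"] = {
            "n_sessions": len(sessions),
            "groups": [s.group for s in sessions],
        }
    if sessions is None:
        store.errors["simulate"] = "simulate stage skipped; nothing to analyse"
        return store

    def stage(name, fn):
        if name not in cfg.stages:
            return
        try:
            store.results[name] = fn()
        except Exception as exc:  # recorded, not fatal
            store.errors[name] = f"{type(exc).__name__}: {exc}"

    def _behavior():
        rows = [behavior.behaviour_summary(s) for s in sessions]
        summary = pd.DataFrame(rows)
        kmax = min(10, len(summary) - 1)
        labels, k, sus = behavior.classify_cohort(
            summary["sucrose_preference"], summary["si_ratio"],
            k_range=range(2, kmax + 1), seed=seeds["behavior"])
        trans = {s.animal_id: behavior.transition_analysis(s.trials["choice"]).p_norm
                 for s in sessions}
        return {"summary": summary, "kmeans_k": k, "labels": labels,
                "susceptible_cluster": sus, "transitions": trans}

    stage("behavior", _behavior)

    def _single_neuron():
        out = {}
        for group in ("control", "susceptible", "resilient"):
            rates, labels = [], []
            for s in sessions:
                if s.group != group:
                    continue
                lab = s.trials["switch_stay"].to_numpy()
                keep = lab != ""
                for spikes in s.task["BLA"].spike_times:
                    c = bin_trials(spikes, 4.0)[:, 0]  # [-4, 0) mean count
                    rates.append(c[keep] / 4.0)
                    labels.append(lab[keep])
            flags, _, _ = intention_modulated(
                rates, labels, min_trials=cfg.min_trials_per_label)
            out[group] = {"n_neurons": len(flags),
                          "frac_intention_modulated": float(np.mean(flags))}
        return out

    stage("single_neuron", _single_neuron)

    hmm_fits: dict = {}

    def _hmm():
        rng = np.random.SeedSequence(seeds["hmm"])
        out = {}
        for s, child in zip(sessions, rng.spawn(len(sessions))):
            keep = s.trials["switch_stay"].to_numpy() != ""
            # one (N, 4) segment of pre-reward counts per labelled trial
            segs = [bin_trials(ts, 1.0, (-4.0, 0.0))
                    for ts in zip(*s.task["BLA"].spike_times)]
            segs = [segs[i] for i in np.flatnonzero(keep)]
            fit = hmm.select_aic(segs, range(cfg.hmm_k_min, cfg.hmm_k_max + 1),
                                 n_inits=cfg.hmm_n_inits,
                                 seed=child.generate_state(1)[0] % 2**31)
            hmm_fits[s.animal_id] = (fit, segs, keep)
            out[s.animal_id] = {"k": fit.model.n_states, "aic": fit.aic,
                                "loglik": fit.loglik}
        return out

    stage("hmm", _hmm)

    def _states():
        out = {}
        for s in sessions:
            if s.animal_id not in hmm_fits:
                continue
            fit, segs, keep = hmm_fits[s.animal_id]
            paths = np.vstack(fit.viterbi_paths)
            labels = s.trials["switch_stay"].to_numpy()[keep]
            frac = state_analysis.intention_fraction(
                fit.model.rates, paths, labels)
            out[s.animal_id] = {
                "group": s.group,
                "fraction_selective": frac["fraction_selective"].tolist(),
                "n_clusters": frac["n_clusters"].tolist(),
            }
        return out

    if "hmm" in cfg.stages and "states" in cfg.stages and "hmm" not in store.errors:
        stage("states", _states)
    elif "states" in cfg.stages:
        store.errors["states"] = "skipped: hmm stage unavailable"

    def _decoding():
        out = {}
        for group in ("control", "susceptible", "resilient"):
            pseudo = decoding.build_pseudopopulation(
                sessions, "BLA", group, min_trials=cfg.min_trials_per_pair)
            res = decoding.svm_decode(
                pseudo, "switch_stay",
                n_neuron_subsamples=cfg.decode_subsamples,
                subsample_size=cfg.decode_subsample_size,
                n_cv=cfg.decode_cv, n_shuffles=cfg.decode_shuffles,
                seed=seeds["decoding"])
            pre = res.bin_centers < 0
            out[group] = {"pre_reward_accuracy": float(res.accuracy[pre].mean()),
                          "significant_bins": int(res.significant.sum())}
        summary = pd.DataFrame([behavior.behaviour_summary(s) for s in sessions])
        two = summary[summary["group"].isin(["control", "susceptible"])]
        feats = two[["sucrose_preference", "si_ratio", "open_arm_pct",
                     "lick_di_pre", "lick_di_post"]].to_numpy()
        out["group_decoder_control_vs_susceptible"] = \
            decoding.mahalanobis_group_decode(
                feats, two["group"].to_numpy(), n_cv=cfg.group_decode_cv,
                seed=seeds["decoding"])
        return out

    stage("decoding", _decoding)

    def _geometry():
        out = {}
        for s in sessions:
            spec = geometry.pca_cumvar(s.pretask["BLA"].counts,
                                       n_subsamples=200,
                                       seed=seeds["geometry"])
            out[s.animal_id] = {"group": s.group, "pr": spec.pr,
                                "cumvar3": spec.features.tolist()}
        return out

    stage("geometry", _geometry)

    def _connectivity():
        out = {}
        for s in sessions:
            pair, spectrum = connectivity.cca_coupling(
                s.pretask["BLA"].counts, s.pretask["vCA1"].counts)
            out[s.animal_id] = {"group": s.group,
                                "canonical_correlation": pair.correlation,
                                "dominant_freq": spectrum.dominant_freq,
                                "stable": spectrum.stable}
        return out

    stage("connectivity", _connectivity)
    return store
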