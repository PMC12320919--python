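"""Saccade-task emulation and decoder-dataset assembly.

Each trial presents a persistent target at +20 deg craniotopic; after a
uniformly distributed latency the model executes a 20 deg, 62 ms rightward
saccade.  Per trial, the proprioceptive synaptic delays are re-sampled and
fresh additive LIP noise is drawn, then the full network is simulated and
the recording exported aligned to saccade onset (t = 0) over the analysis
window.  Paired (population state, eye position) samples from many trials
form the decoder datasets, optionally with a temporal offset between input
time and target eye position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig, TrialProtocol
from .errors import EmptyDatasetError, InvalidParameterError
from .network import Recording, run_network
from .signals import SaccadeSpec

__all__ = [
    "TrialRecord",
    "DecoderDataset",
    "trial_rng",
    "sample_latency",
    "run_trial",
    "run_experiment",
    "build_dataset",
]

log = logging.getLogger(__name__)

MAP_POPULATIONS = ("lip_cd", "lip_pc")


@dataclass
class TrialRecord:
    """One trial aligned to saccade onset.

    ``time`` is in ms relative to saccade onset; ``lip_cd`` / ``lip_pc``
    are (time, n_eye, n_retinal) activity arrays; ``eye`` the true eye
    position at the recorded times; ``delays`` the PC synaptic delays (ms)
    sampled for this trial.
    """

    trial_id: int
    onset: float
    time: np.ndarray
    lip_cd: np.ndarray
    lip_pc: np.ndarray
    eye: np.ndarray
    delays: np.ndarray
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.lip_cd[0].size + self.lip_pc[0].size

    def features(self, populations: tuple[str, ...] = MAP_POPULATIONS) -> np.ndarray:
        """(time, neurons) input matrix, map(s) flattened in eye-major order."""
        t = self.time.size
        return np.concatenate(
            [getattr(self, p).reshape(t, -1) for p in populations], axis=1
        )


@dataclass
class DecoderDataset:
    """Samples x neurons matrix with offset targets and a trial-wise split.

    The input row at time t pairs with the eye position at t + offset; rows
    whose shifted target falls outside the trial are dropped.  ``split`` is
    "train"/"test" per sample, assigned by whole trials so no trial leaks
    across the split.  ``layout`` names the populations (and their map
    shape) the columns came from, so decoders can be re-applied to
    recordings.
    """

    X: np.ndarray
    y: np.ndarray
    time: np.ndarray
    trial_ids: np.ndarray
    split: np.ndarray
    offset: float
    layout: tuple[str, ...]
    map_shape: tuple[int, int]

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == "train"
        return self.X[m], self.y[m]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == "test"
        return self.X[m], self.y[m]

    @property
    def train_trials(self) -> np.ndarray:
        return np.unique(self.trial_ids[self.split == "train"])

    @property
    def test_trials(self) -> np.ndarray:
        return np.unique(self.trial_ids[self.split == "test"])


def trial_rng(master_seed: int, trial_index: int) -> np.random.Generator:
    """Independent per-trial generator; stable under changes of n_trials."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(trial_index,))
    )


def sample_latency(protocol: TrialProtocol, rng: np.random.Generator) -> float:
    """Uniform saccade latency (ms after stimulus onset), snapped to the
    recording grid so exported onset-aligned records share one time base."""
    lo, hi = protocol.latency_window
    lat = rng.uniform(lo, hi)
    snapped = round(lat / protocol.record_dt) * protocol.record_dt
    return float(min(max(snapped, lo), hi))


def run_trial(
    config: NetworkConfig, protocol: TrialProtocol, trial_index: int
) -> TrialRecord:
    """Simulate one trial and export it aligned to saccade onset."""
    rng = trial_rng(protocol.seed, trial_index)
    latency = sample_latency(protocol, rng)
    onset = protocol.stim_onset + latency
    spec = SaccadeSpec(
        start_position=protocol.start_position,
        amplitude=protocol.amplitude,
        duration=protocol.duration,
        onset_time=onset,
        latency_window=protocol.latency_window,
    )
    stride = int(round(protocol.record_dt / config.dt))
    if abs(stride * config.dt - protocol.record_dt) > 1e-9 or stride < 1:
        raise InvalidParameterError(
            f"record_dt {protocol.record_dt} must be a multiple of dt {config.dt}"
        )
    rec: Recording = run_network(
        config,
        spec,
        protocol.stim_position,
        protocol.stim_onset,
        seed=rng,
        record_stride=stride,
    )
    log.debug("trial %d: latency %.1f ms, delays [%.1f, %.1f] ms", trial_index,
              latency, rec.delays.min(), rec.delays.max())

    lo, hi = protocol.record_window
    rel = rec.time - onset
    keep = (rel >= lo - 1e-9) & (rel <= hi + 1e-9)
    time = rel[keep]
    eye = np.asarray(rec.trajectory.position_at(rec.time[keep]), dtype=float)
    extras = {
        k: v[keep] for k, v in rec.traces.items() if k not in MAP_POPULATIONS
    }
    return TrialRecord(
        trial_id=trial_index,
        onset=onset,
        time=time,
        lip_cd=rec.traces["lip_cd"][keep],
        lip_pc=rec.traces["lip_pc"][keep],
        eye=eye,
        delays=rec.delays,
        extras=extras,
    )


def run_experiment(config: NetworkConfig, protocol: TrialProtocol) -> list[TrialRecord]:
    """Run all trials of the protocol (deterministic given its master seed)."""
    records = []
    for i in range(protocol.n_trials):
        records.append(run_trial(config, protocol, i))
        if (i + 1) % 50 == 0:
            log.info("simulated %d/%d trials", i + 1, protocol.n_trials)
    return records


def build_dataset(
    records: list[TrialRecord],
    offset: float = 0.0,
    split_fraction: float = 0.8,
    seed: int = 0,
    populations: tuple[str, ...] = MAP_POPULATIONS,
) -> DecoderDataset:
    """Assemble the (input, offset eye-position target) regression dataset.

    ``offset`` is the temporal offset in ms added to the target: positive
    decodes the *future* eye position from the current population state,
    negative the *past*.  Samples whose shifted target index leaves the
    trial are dropped; the train/test split is by whole trials using a
    seeded permutation.
    """
    if not records:
        raise EmptyDatasetError("no trial records given")
    rec0 = records[0]
    record_dt = float(rec0.time[1] - rec0.time[0])
    k = offset / record_dt
    if abs(k - round(k)) > 1e-9:
        raise InvalidParameterError(
            f"offset {offset} ms is not a multiple of the recording step {record_dt} ms"
        )
    k = int(round(k))

    Xs, ys, ts, ids = [], [], [], []
    for rec in records:
        t = rec.time.size
        rows = np.arange(t)
        tgt = rows + k
        ok = (tgt >= 0) & (tgt < t)
        if not ok.any():
            continue
        Xs.append(rec.features(populations)[ok])
        ys.append(rec.eye[tgt[ok]])
        ts.append(rec.time[rows[ok]])
        ids.append(np.full(ok.sum(), rec.trial_id))
    if not Xs:
        raise EmptyDatasetError(
            f"offset {offset} ms leaves no valid samples in any trial"
        )
    X = np.concatenate(Xs).astype(np.float32)
    y = np.concatenate(ys).astype(np.float32)
    time = np.concatenate(ts)
    trial_ids = np.concatenate(ids)

    uniq = np.unique(trial_ids)
    perm = np.random.default_rng(seed).permutation(uniq)
    n_train = int(np.ceil(split_fraction * uniq.size))
    train_set = set(perm[:n_train].tolist())
    split = np.where(np.isin(trial_ids, list(train_set)), "train", "test")

    n = rec0.lip_cd.shape[1]
    return DecoderDataset(
        X=X,
        y=y,
        time=time,
        trial_ids=trial_ids,
        split=split,
        offset=float(offset),
        layout=tuple(populations),
        map_shape=(n, rec0.lip_cd.shape[2]),
    )
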