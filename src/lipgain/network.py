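"""Population dynamics of the two-map LIP gain-field model.

Two 40x40 gain-field maps integrate a retinotopic visual drive f(x) with an
eye-related gain signal g(y) along the orthogonal axis:

* ``lip_cd`` is gain-modulated by the craniotopic CD signal (``cd_head``,
  the retinotopic corollary discharge transformed through the current eye
  reference) and additionally receives a remapping feedback drive from the
  craniotopic stimulus population ``xh`` gated by ``cd_head`` — this places
  presaccadic activity at the stimulus's *future* retinal position.
* ``lip_pc`` is gain-modulated by the proprioceptive eye-position signal,
  where every map neuron receives its PC input through an individually
  delayed synapse (delays drawn per trial from the truncated normal phi).

Each map neuron's drive follows r = f(x) * (C + g(y) * gain) + noise, and
rates relax toward the drive with time constant tau using an exponential
integrator (exact for piecewise-constant drive), rectified at zero.

Craniotopic readouts run along the map anti-diagonals: a map neuron at
(eye-axis position yi, retinal-axis position xj) contributes to the
craniotopic bin h = yi + xj, normalised by diagonal length and clipped to
the modelled space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .config import NetworkConfig
from .errors import InstabilityError, InvalidParameterError, NumericalFaultError
from .signals import (
    CDParams,
    SaccadeSpec,
    SignalTrace,
    Trajectory,
    TuningCurve,
    cd_drive,
    default_centers,
    pc_drive,
    sample_projection_delays,
    saccade_trajectory,
    visual_drive,
)

__all__ = [
    "PopulationState",
    "NetworkState",
    "Recording",
    "Network",
    "diagonal_readout",
    "cd_to_head",
    "remap_feedback",
    "relax",
    "run_network",
]

POPULATIONS = ("cd_head", "xh", "lip_cd", "lip_pc")


@dataclass
class PopulationState:
    """Instantaneous rectified rates of one population."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rates)):
            raise NumericalFaultError("state", "non-finite rates in population state")


@dataclass
class NetworkState:
    """Rates of all dynamic populations plus the integration step index."""

    t_index: int
    rates: dict[str, np.ndarray]

    def copy(self) -> "NetworkState":
        return NetworkState(self.t_index, {k: v.copy() for k, v in self.rates.items()})


@dataclass
class Recording:
    """Full trial recording: traces per population + trajectory + metadata.

    ``traces`` maps population name to a (time, ...) array; the LIP maps are
    stored as (time, n_eye, n_retinal).  ``time`` is absolute trial time in
    ms at the recording resolution.
    """

    time: np.ndarray
    traces: dict[str, np.ndarray]
    trajectory: Trajectory
    spec: SaccadeSpec
    delays: np.ndarray
    seed: int | None = None

    def eye_at_recorded(self) -> np.ndarray:
        return np.asarray(self.trajectory.position_at(self.time), dtype=float)


# ---------------------------------------------------------------------------
# craniotopic (diagonal) readouts and gain-field transforms
# ---------------------------------------------------------------------------

def _diag_index(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map map-coordinates (i, j) to craniotopic output bins h = c_i + c_j.

    Returns (flat bin index, validity mask, per-bin diagonal counts); pairs
    whose sum falls outside the centers grid are clipped away.
    """
    spacing = centers[1] - centers[0]
    h = centers[:, None] + centers[None, :]
    idx = np.rint((h - centers[0]) / spacing).astype(int)
    valid = (idx >= 0) & (idx < centers.size)
    counts = np.bincount(idx[valid].ravel(), minlength=centers.size).astype(float)
    return idx, valid, counts


def diagonal_readout(map_rates: np.ndarray, centers: np.ndarray | None = None) -> np.ndarray:
    """Craniotopic population response read along the map diagonals.

    Output bin h averages (sum / diagonal length) all map neurons whose
    (eye, retinal) positions add up to h; bins outside the modelled space
    are dropped.  Total function of finite input.
    """
    map_rates = np.asarray(map_rates, dtype=float)
    n = map_rates.shape[0]
    if centers is None:
        centers = default_centers(n, 2.0, -float(n))
    idx, valid, counts = _diag_index(centers)
    sums = np.bincount(
        idx[valid].ravel(), weights=map_rates[valid].ravel(), minlength=centers.size
    )
    out = np.zeros(centers.size)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def cd_to_head(
    cd_retinotopic: np.ndarray,
    eye_estimate: np.ndarray,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Transform the retinotopic CD into a craniotopic signal.

    Gain-field combination of eye reference and displacement: the outer
    product (eye axis x retinal axis) is read out along its diagonals, so a
    +20 deg CD with the eye at 0 deg yields a craniotopic bump at +20 deg
    (the future eye position / saccade target in head coordinates).
    """
    cd_retinotopic = np.asarray(cd_retinotopic, dtype=float)
    eye_estimate = np.asarray(eye_estimate, dtype=float)
    return diagonal_readout(np.outer(eye_estimate, cd_retinotopic), centers)


def remap_feedback(
    xh_head: np.ndarray,
    cd_head: np.ndarray,
    centers: np.ndarray | None = None,
    gain: float = 1.0,
    enabled: bool = True,
) -> np.ndarray:
    """Predictive-remapping drive to the CD map.

    The craniotopic stimulus response ``xh_head`` is mapped back into map
    coordinates gated by the (future-eye) ``cd_head`` signal: map neuron
    (i, j) receives gain * cd_head[i] * xh_head[c_i + c_j].  With the CD
    active this places a drive at the retinal coordinate the stimulus will
    occupy after the saccade (craniotopic position minus future eye
    position); with the CD silent the drive is zero.  ``enabled=False`` is
    the ablation path and returns zeros.
    """
    xh_head = np.asarray(xh_head, dtype=float)
    cd_head = np.asarray(cd_head, dtype=float)
    n = cd_head.size
    if centers is None:
        centers = default_centers(n, 2.0, -float(n))
    if not enabled:
        return np.zeros((n, n))
    idx, valid, _ = _diag_index(centers)
    lookup = np.where(valid, xh_head[np.clip(idx, 0, n - 1)], 0.0)
    return gain * cd_head[:, None] * lookup


def relax(rates: np.ndarray, drive: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """One exponential-integrator step of tau * dr/dt = -r + drive, rectified.

    Exact for drive constant over the step: r <- drive + (r - drive) *
    exp(-dt/tau), then clipped at zero (rates are non-negative).
    """
    decay = np.exp(-dt / tau)
    return np.maximum(drive + (rates - drive) * decay, 0.0)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class Network:
    """Precomputed geometry plus the per-step update of all populations."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        n = config.n_neurons
        self.centers = default_centers(n, config.spacing, config.space_lo)
        self.vis_tuning = TuningCurve(self.centers, config.vis_width, config.signal_peak)
        self.eye_tuning = TuningCurve(self.centers, config.eye_width, config.signal_peak)
        self.cd_tuning = TuningCurve(self.centers, config.cd.width, config.signal_peak)
        self._idx, self._valid, self._counts = _diag_index(self.centers)
        self._row = np.broadcast_to(np.arange(n)[:, None], (n, n))

    # -- readouts using the cached index tables --------------------------------
    def _diag(self, mat: np.ndarray) -> np.ndarray:
        sums = np.bincount(
            self._idx[self._valid].ravel(),
            weights=mat[self._valid].ravel(),
            minlength=self.centers.size,
        )
        out = np.zeros(self.centers.size)
        nz = self._counts > 0
        out[nz] = sums[nz] / self._counts[nz]
        return out

    def _xh_lookup(self, xh: np.ndarray) -> np.ndarray:
        n = self.centers.size
        return np.where(self._valid, xh[np.clip(self._idx, 0, n - 1)], 0.0)

    def init_state(self) -> NetworkState:
        n = self.config.n_neurons
        return NetworkState(
            t_index=0,
            rates={
                "cd_head": np.zeros(n),
                "xh": np.zeros(n),
                "lip_cd": np.zeros((n, n)),
                "lip_pc": np.zeros((n, n)),
            },
        )

    def drives(
        self,
        state: NetworkState,
        vis_row: np.ndarray,
        cd_row: np.ndarray,
        pc_row: np.ndarray,
        pc_gain: np.ndarray,
        noise: Mapping[str, np.ndarray] | None = None,
    ) -> dict[str, np.ndarray]:
        """Compute the instantaneous drive of every dynamic population.

        ``pc_row`` is the undelayed proprioceptive drive (eye reference for
        the CD transform); ``pc_gain`` the (n, n) per-synapse delayed PC
        gain seen by the PC map.  ``noise`` maps map names to pre-drawn
        standard-normal arrays (scaled here by each map's noise sigma).
        """
        cfg = self.config
        if cfg.cd_gain_enabled:
            cdh = cfg.cd_head_weight * self._diag(np.outer(pc_row, cd_row))
        else:
            cdh = np.zeros_like(cd_row)
        xh = cfg.xh_weight * self._diag(state.rates["lip_pc"])

        cd_head_rates = state.rates["cd_head"]
        gain_cd = cd_head_rates[:, None]
        if cfg.mixed_population:
            # supplementary variant: every neuron mixes both gain signals
            gain_mix = 0.5 * (gain_cd + pc_gain)
            gain_cd = gain_mix
            gain_pc = gain_mix
        else:
            gain_pc = pc_gain

        lipcd = vis_row[None, :] * (
            cfg.lip_cd.baseline_gain + cfg.lip_cd.feedback_gain * gain_cd
        )
        if cfg.feedback_enabled:
            lipcd = lipcd + cfg.remap_gain * cd_head_rates[:, None] * self._xh_lookup(
                state.rates["xh"]
            )
        lippc = vis_row[None, :] * (
            cfg.lip_pc.baseline_gain + cfg.lip_pc.feedback_gain * gain_pc
        )
        if noise is not None:
            lipcd = lipcd + cfg.lip_cd.noise_sigma * noise["lip_cd"]
            lippc = lippc + cfg.lip_pc.noise_sigma * noise["lip_pc"]
        out = {"cd_head": cdh, "xh": xh, "lip_cd": lipcd, "lip_pc": lippc}
        for name, d in out.items():
            if not np.all(np.isfinite(d)):
                raise NumericalFaultError(name)
        return out

    def step(
        self,
        state: NetworkState,
        vis_row: np.ndarray,
        cd_row: np.ndarray,
        pc_row: np.ndarray,
        pc_gain: np.ndarray,
        noise: Mapping[str, np.ndarray] | None = None,
        dt: float | None = None,
    ) -> NetworkState:
        """Advance the network by one step (synchronous update of all maps)."""
        cfg = self.config
        dt = cfg.dt if dt is None else dt
        d = self.drives(state, vis_row, cd_row, pc_row, pc_gain, noise)
        new = {
            "cd_head": relax(state.rates["cd_head"], d["cd_head"], dt, cfg.readout_tau),
            "xh": relax(state.rates["xh"], d["xh"], dt, cfg.readout_tau),
            "lip_cd": relax(state.rates["lip_cd"], d["lip_cd"], dt, cfg.lip_cd.tau),
            "lip_pc": relax(state.rates["lip_pc"], d["lip_pc"], dt, cfg.lip_pc.tau),
        }
        ceiling = cfg.rate_ceiling
        for name, r in new.items():
            if r.max(initial=0.0) > ceiling:
                raise InstabilityError(state.t_index + 1, f"population '{name}' exceeded "
                                       f"the rate ceiling at step {state.t_index + 1}")
        return NetworkState(t_index=state.t_index + 1, rates=new)


def run_network(
    config: NetworkConfig,
    spec: SaccadeSpec,
    stim_position: float | None,
    stim_onset: float,
    seed: int | np.random.Generator = 0,
    delays: np.ndarray | None = None,
    record_stride: int = 1,
) -> Recording:
    """Simulate one full trial and record all population activities.

    Deterministic given (config, trial parameters, seed).  ``delays`` are
    the per-synapse PC delays (ms, shape (n, n)); when absent they are
    sampled from ``config.delays`` with the given seed — the same generator
    also produces the additive LIP noise.  ``record_stride`` keeps every
    k-th integration step in the returned traces.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = Network(config)
    n = config.n_neurons
    dt = config.dt

    traj = saccade_trajectory(spec, dt, config.trial_length)
    t_grid = traj.time
    n_steps = t_grid.size

    vis = visual_drive(stim_position, stim_onset, traj, config.visual_latency, net.vis_tuning)
    cd = cd_drive(spec, config.cd, t_grid, net.cd_tuning)
    pc = pc_drive(spec, net.eye_tuning, t_grid, config.pc_update_lag)

    if delays is None:
        delays = sample_projection_delays(n * n, config.delays, rng).reshape(n, n)
    dsteps = np.rint(np.asarray(delays) / dt).astype(int)
    if np.any(dsteps < 0):
        raise InvalidParameterError("PC synaptic delays must be non-negative")

    noisy = config.lip_cd.noise_sigma > 0 or config.lip_pc.noise_sigma > 0
    noise_block = (
        rng.standard_normal((n_steps, 2, n, n)).astype(np.float32) if noisy else None
    )

    kept = range(0, n_steps, record_stride)
    rec = {
        "lip_cd": np.empty((len(kept), n, n), dtype=np.float32),
        "lip_pc": np.empty((len(kept), n, n), dtype=np.float32),
        "cd_head": np.empty((len(kept), n), dtype=np.float32),
        "xh": np.empty((len(kept), n), dtype=np.float32),
    }

    state = net.init_state()
    pc_act = pc.activity
    row = net._row
    out_i = 0
    for k in range(n_steps):
        if k % record_stride == 0:
            rec["lip_cd"][out_i] = state.rates["lip_cd"]
            rec["lip_pc"][out_i] = state.rates["lip_pc"]
            rec["cd_head"][out_i] = state.rates["cd_head"]
            rec["xh"][out_i] = state.rates["xh"]
            out_i += 1
        pc_gain = pc_act[np.maximum(k - dsteps, 0), row]
        noise = (
            {"lip_cd": noise_block[k, 0], "lip_pc": noise_block[k, 1]}
            if noise_block is not None
            else None
        )
        state = net.step(state, vis.activity[k], cd.activity[k], pc_act[k], pc_gain, noise)

    rec_time = t_grid[:: record_stride][: out_i]
    return Recording(
        time=rec_time,
        traces=rec,
        trajectory=traj,
        spec=spec,
        delays=np.asarray(delays, dtype=float),
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
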