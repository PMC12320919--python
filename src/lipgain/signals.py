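"""Input signals of the LIP gain-field model.

Three external drives shape the model during a saccade trial:

* a **corollary discharge** (CD): a transient copy of the motor command,
  retinotopic, spatially centred on the saccade displacement.  It builds up
  during the 50 ms before saccade onset, peaks at onset and then decays.
* a **proprioceptive eye-position signal** (PC): a tonic craniotopic bump at
  the current eye-in-head position.  The drive itself updates step-wise at
  saccade offset; the *slow* arrival of that update in LIP is produced
  downstream by per-synapse delays drawn from a truncated normal
  distribution (:class:`DelayDistribution`).
* a **visual drive**: the retinal image of the (persistent) saccade target,
  lagged by a fixed visual latency, so the retinal bump sweeps across the
  population during the saccade with that lag.

Everything here is deterministic except :func:`sample_projection_delays`,
which takes an explicit seed / generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, InvalidSpecError, OutOfRangeError

__all__ = [
    "SaccadeSpec",
    "Trajectory",
    "DelayDistribution",
    "TuningCurve",
    "SignalTrace",
    "CDParams",
    "minimum_jerk_profile",
    "saccade_trajectory",
    "cd_drive",
    "sample_projection_delays",
    "pc_drive",
    "visual_drive",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaccadeSpec:
    """Kinematic description of one horizontal saccade.

    Parameters
    ----------
    start_position : float
        Craniotopic starting eye position in degrees.
    amplitude : float
        Signed displacement in degrees (positive = rightward).
    duration : float
        Saccade duration in ms (must be > 0).
    onset_time : float
        Saccade onset within the trial, in ms.
    latency_window : tuple of float, optional
        (min, max) ms between stimulus onset and saccade onset; carried as
        metadata for protocol-level validation.
    """

    start_position: float = 0.0
    amplitude: float = 20.0
    duration: float = 62.0
    onset_time: float = 300.0
    latency_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidSpecError(f"saccade duration must be > 0, got {self.duration}")
        if self.onset_time < 0:
            raise InvalidSpecError("saccade onset must lie within the trial (>= 0)")
        if self.latency_window is not None:
            lo, hi = self.latency_window
            if lo > hi or lo < 0:
                raise InvalidSpecError(f"invalid latency window {self.latency_window}")

    @property
    def end_position(self) -> float:
        return self.start_position + self.amplitude

    @property
    def offset_time(self) -> float:
        """Saccade offset (onset + duration) in ms."""
        return self.onset_time + self.duration


@dataclass(frozen=True)
class Trajectory:
    """Sampled eye-position trace on a uniform time grid (ms, degrees)."""

    time: np.ndarray
    eye: np.ndarray

    def __post_init__(self) -> None:
        if self.time.shape != self.eye.shape:
            raise InvalidSpecError("trajectory time and eye arrays must align")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def position_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Eye position at arbitrary times by linear interpolation.

        Times before / after the grid clamp to the first / last sample,
        which matches the fixate-saccade-fixate structure of a trial.
        """
        return np.interp(t, self.time, self.eye)


@dataclass(frozen=True)
class DelayDistribution:
    """Truncated normal distribution of synaptic delays (ms).

    Defaults are the proprioceptive-update distribution used throughout:
    mu = 200 ms, sigma = 100 ms, support [120, 250] ms.
    """

    mu: float = 200.0
    sigma: float = 100.0
    min_delay: float = 120.0
    max_delay: float = 250.0

    def __post_init__(self) -> None:
        if self.min_delay > self.max_delay:
            raise InvalidParameterError(
                f"empty delay support: [{self.min_delay}, {self.max_delay}]"
            )
        if self.sigma <= 0:
            raise InvalidParameterError("delay sigma must be > 0")
        if self.min_delay < 0:
            raise InvalidParameterError("delays must be non-negative")


@dataclass(frozen=True)
class TuningCurve:
    """Gaussian tuning over a shared population grid.

    ``centers`` are the preferred positions (strictly increasing, degrees),
    ``width`` the common Gaussian sigma and ``peak`` the response at the
    preferred position.  Used both for the retinal response f(x) and for the
    eye-signal gain g(y) of the gain-field drive.
    """

    centers: np.ndarray
    width: float
    peak: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("tuning width must be > 0")
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size < 2 or np.any(np.diff(c) <= 0):
            raise InvalidParameterError("tuning centers must be strictly increasing")
        object.__setattr__(self, "centers", c)

    @property
    def n(self) -> int:
        return self.centers.size

    @property
    def spacing(self) -> float:
        return float(self.centers[1] - self.centers[0])

    def response(self, position: float | np.ndarray) -> np.ndarray:
        """Population response to a stimulus at ``position``.

        For scalar input returns shape (n,); for an array of positions of
        shape (T,), returns (T, n).
        """
        p = np.asarray(position, dtype=float)
        d = p[..., None] - self.centers
        return self.peak * np.exp(-0.5 * (d / self.width) ** 2)

    def in_range(self, position: float) -> bool:
        half = 0.5 * self.spacing
        return self.centers[0] - half <= position <= self.centers[-1] + half


@dataclass(frozen=True)
class SignalTrace:
    """Time x neuron activity matrix for any drive or recording.

    ``frame`` names the reference frame of the neuron axis, either
    ``"retinotopic"`` or ``"craniotopic"``.
    """

    time: np.ndarray
    activity: np.ndarray
    frame: str

    def __post_init__(self) -> None:
        if self.frame not in ("retinotopic", "craniotopic"):
            raise InvalidParameterError(f"unknown frame {self.frame!r}")
        if self.activity.ndim != 2 or self.activity.shape[0] != self.time.size:
            raise InvalidParameterError("activity must be (time, neurons)")
        if np.any(self.activity < 0):
            raise InvalidParameterError("signal activity must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]


@dataclass(frozen=True)
class CDParams:
    """Temporal and spatial shape of the corollary discharge.

    The envelope ramps linearly over ``rise_window`` ms before saccade
    onset, peaks exactly at onset, decays exponentially with ``decay_tau``
    and is clamped to exactly zero after ``cutoff_taus`` decay constants
    (so the drive has compact support).
    """

    rise_window: float = 50.0
    decay_tau: float = 25.0
    peak: float = 1.0
    width: float = 6.0
    cutoff_taus: float = 5.0

    def __post_init__(self) -> None:
        if self.rise_window <= 0:
            raise InvalidParameterError("CD rise window must be > 0")
        if self.decay_tau <= 0:
            raise InvalidParameterError("CD decay tau must be > 0")


# ---------------------------------------------------------------------------
# saccade trajectory
# ---------------------------------------------------------------------------

def minimum_jerk_profile(s: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on s in [0, 1].

    x(s) = 10 s^3 - 15 s^4 + 6 s^5; monotone, with a single-peaked,
    bell-shaped velocity profile peaking at s = 1/2.  This reproduces the
    stereotyped accelerate-then-decelerate velocity shape of saccades for a
    fixed (amplitude, duration) pair; alternative parametric profiles can be
    passed to :func:`saccade_trajectory` via ``profile``.
    """
    s = np.clip(s, 0.0, 1.0)
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


def saccade_trajectory(
    spec: SaccadeSpec,
    dt: float,
    t_total: float = 1000.0,
    profile: Callable[[np.ndarray], np.ndarray] = minimum_jerk_profile,
) -> Trajectory:
    """Sample the eye-position trace of one saccade on a uniform grid.

    The eye fixates at ``spec.start_position`` before onset, follows the
    rescaled ``profile`` during the saccade and fixates at
    ``start_position + amplitude`` afterwards.

    Parameters
    ----------
    spec : SaccadeSpec
    dt : float
        Grid step in ms; must be positive and divide ``t_total``.
    t_total : float
        Trial length in ms (grid covers [0, t_total]).
    profile : callable
        Monotone map [0,1] -> [0,1] with profile(0)=0, profile(1)=1.
    """
    if dt <= 0:
        raise InvalidSpecError(f"dt must be > 0, got {dt}")
    n_steps = t_total / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidSpecError(f"dt={dt} does not divide the trial length {t_total}")
    time = np.arange(round(n_steps) + 1) * dt
    s = (time - spec.onset_time) / spec.duration
    eye = spec.start_position + spec.amplitude * profile(s)
    return Trajectory(time=time, eye=eye)


# ---------------------------------------------------------------------------
# drives
# ---------------------------------------------------------------------------

def cd_drive(
    spec: SaccadeSpec,
    params: CDParams,
    t_grid: np.ndarray,
    tuning: TuningCurve | None = None,
) -> SignalTrace:
    """Corollary-discharge drive: transient, retinotopic, displacement-tuned.

    The spatial profile is a Gaussian bump centred on the saccade
    displacement (``spec.amplitude``, retinotopic); the temporal envelope is
    zero before ``onset - rise_window``, ramps linearly to ``peak`` at
    saccade onset and decays exponentially afterwards, clamped to zero
    beyond ``cutoff_taus * decay_tau``.
    """
    if tuning is None:
        tuning = TuningCurve(centers=default_centers(), width=params.width)
    t = np.asarray(t_grid, dtype=float)
    if spec.amplitude == 0.0:
        # no planned displacement, no motor burst: the CD is silent
        return SignalTrace(
            time=t, activity=np.zeros((t.size, tuning.n)), frame="retinotopic"
        )
    rel = t - spec.onset_time
    env = np.zeros_like(t)
    rising = (rel >= -params.rise_window) & (rel <= 0)
    env[rising] = 1.0 + rel[rising] / params.rise_window
    falling = (rel > 0) & (rel <= params.cutoff_taus * params.decay_tau)
    env[falling] = np.exp(-rel[falling] / params.decay_tau)
    spatial = tuning.response(spec.amplitude)  # displacement in retinotopic space
    activity = params.peak * env[:, None] * spatial[None, :]
    return SignalTrace(time=t, activity=activity, frame="retinotopic")


def sample_projection_delays(
    n: int,
    dist: DelayDistribution = DelayDistribution(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` synaptic delays (ms) from the truncated normal ``dist``.

    Samples follow the normal(mu, sigma) law conditioned on the interval
    [min_delay, max_delay] (no probability mass piles up at the bounds, as
    clipping would produce).  Identical seeds give identical draws; callers
    re-draw independently per trial and per synapse.
    """
    if n < 1:
        raise InvalidParameterError(f"need n >= 1 delays, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = (dist.min_delay - dist.mu) / dist.sigma
    b = (dist.max_delay - dist.mu) / dist.sigma
    return stats.truncnorm.rvs(a, b, loc=dist.mu, scale=dist.sigma, size=n, random_state=rng)


def pc_drive(
    spec: SaccadeSpec,
    pc_tuning: TuningCurve,
    t_grid: np.ndarray,
    update_lag: float = 0.0,
) -> SignalTrace:
    """Proprioceptive eye-position drive: tonic, craniotopic, step update.

    Encodes ``start_position`` as a Gaussian population bump until the
    update time (saccade offset plus ``update_lag``), then switches
    step-wise to encode the postsaccadic position.  The slow arrival of this
    update in LIP comes from per-synapse delays applied downstream by the
    network, not here.
    """
    update_time = spec.offset_time + update_lag
    if update_time < spec.onset_time:
        raise InvalidSpecError(
            f"PC update time {update_time} ms precedes saccade onset {spec.onset_time} ms"
        )
    t = np.asarray(t_grid, dtype=float)
    pre = pc_tuning.response(spec.start_position)
    post = pc_tuning.response(spec.end_position)
    updated = (t >= update_time)[:, None]
    activity = np.where(updated, post[None, :], pre[None, :])
    return SignalTrace(time=t, activity=activity, frame="craniotopic")


def visual_drive(
    stim_craniotopic: float | None,
    stim_onset: float,
    traj: Trajectory,
    latency: float,
    vis_tuning: TuningCurve,
) -> SignalTrace:
    """Latency-delayed retinal response to a persistent stimulus.

    At time t the population encodes the retinal position
    ``stim_craniotopic - eye(t - latency)``; rows before
    ``stim_onset + latency`` are zero.  The stimulus stays visible until the
    end of the trial, so the retinal bump sweeps during the saccade with a
    ``latency`` ms lag.  ``stim_craniotopic=None`` means no stimulus.
    """
    if latency < 0:
        raise InvalidParameterError("visual latency must be >= 0")
    t = traj.time
    if stim_craniotopic is None:
        return SignalTrace(
            time=t, activity=np.zeros((t.size, vis_tuning.n)), frame="retinotopic"
        )
    if not vis_tuning.in_range(stim_craniotopic):
        raise OutOfRangeError(
            f"stimulus at {stim_craniotopic} deg is outside the modelled space"
        )
    retinal = stim_craniotopic - traj.position_at(t - latency)
    activity = vis_tuning.response(retinal)
    activity[t < stim_onset + latency] = 0.0
    return SignalTrace(time=t, activity=activity, frame="retinotopic")


def default_centers(n: int = 40, spacing: float = 2.0, lo: float = -40.0) -> np.ndarray:
    """Standard population grid: ``n`` centers from ``lo`` with ``spacing`` deg.

    Defaults give centers -40, -38, ..., +38: 40 neurons, 2 deg apart,
    covering the modelled -40..+40 deg space.  Sums of two centers land on
    the same parity grid, which keeps the diagonal (craniotopic) readout of
    the 2-D maps exactly aligned with neuron centers.
    """
    return lo + spacing * np.arange(n)
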