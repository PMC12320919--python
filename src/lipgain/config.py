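"""Configuration objects, YAML round-tripping and run manifests.

A run is fully described by a :class:`NetworkConfig` (model geometry,
tuning, gains, noise, integration) plus a :class:`TrialProtocol` (task
timing, trial count, seeds).  ``load_config`` fills defaults for absent
keys and rejects unknown ones, so an empty file yields the published
default model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .signals import CDParams, DelayDistribution

__all__ = [
    "GainFieldParams",
    "NetworkConfig",
    "TrialProtocol",
    "GFIParams",
    "DecoderHyperparams",
    "RunManifest",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass(frozen=True)
class GainFieldParams:
    """Parameters of one LIP gain-field map (drive f(x)*(C + g(y)*gain) + noise).

    ``baseline_gain`` is the constant C that lets neurons respond to a
    stimulus in their RF even when the eye-signal gain g(y) is silent
    (essential for the transient CD signal); ``feedback_gain`` scales the
    multiplicative eye-signal input; ``noise_sigma`` is the std of the
    additive Gaussian drive noise per step (rate units); ``tau`` the rate
    relaxation constant (ms).
    """

    baseline_gain: float = 0.5
    feedback_gain: float = 1.0
    noise_sigma: float = 0.02
    tau: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline_gain <= 0:
            raise ConfigError("baseline gain C must be > 0")
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be >= 0")


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry, tuning, gains and integration of the two-map LIP model."""

    n_neurons: int = 40
    spacing: float = 2.0
    space_lo: float = -40.0
    space_hi: float = 40.0
    vis_width: float = 4.0
    eye_width: float = 6.0
    signal_peak: float = 1.0
    visual_latency: float = 30.0
    pc_update_lag: float = 0.0
    cd: CDParams = field(default_factory=CDParams)
    delays: DelayDistribution = field(default_factory=DelayDistribution)
    lip_cd: GainFieldParams = field(default_factory=GainFieldParams)
    lip_pc: GainFieldParams = field(default_factory=GainFieldParams)
    # projection weights undoing the diagonal-mean attenuation of the readouts,
    # calibrated once so the gain signals reaching the maps have O(1) peaks
    cd_head_weight: float = 6.5
    xh_weight: float = 4.0
    remap_gain: float = 1.0
    readout_tau: float = 10.0
    feedback_enabled: bool = True
    cd_gain_enabled: bool = True
    mixed_population: bool = False
    dt: float = 1.0
    trial_length: float = 1000.0
    rate_ceiling: float = 50.0

    def __post_init__(self) -> None:
        span = self.space_hi - self.space_lo
        if abs(self.n_neurons * self.spacing - span) > 1e-9:
            raise ConfigError(
                f"{self.n_neurons} neurons x {self.spacing} deg spacing does not "
                f"span the space [{self.space_lo}, {self.space_hi}]"
            )
        if self.dt <= 0 or self.trial_length <= 0:
            raise ConfigError("dt and trial length must be > 0")


@dataclass(frozen=True)
class TrialProtocol:
    """Saccade-to-target task: timing, trial count and master seed.

    The stimulus appears at ``stim_position`` (craniotopic, equal to the
    saccade target) at ``stim_onset`` and stays visible; the saccade starts
    after a per-trial latency drawn uniformly from ``latency_window``.
    Recordings are exported aligned to saccade onset over ``record_window``
    at ``record_dt`` resolution.  Per-trial seeds are spawned from ``seed``
    so adding trials never perturbs earlier trials' randomness.
    """

    n_trials: int = 200
    stim_position: float = 20.0
    stim_onset: float = 200.0
    latency_window: tuple[float, float] = (100.0, 300.0)
    start_position: float = 0.0
    amplitude: float = 20.0
    duration: float = 62.0
    seed: int = 0
    record_window: tuple[float, float] = (-300.0, 500.0)
    record_dt: float = 5.0
    train_fraction: float = 0.8
    decode_offsets: tuple[float, ...] = (100.0, 0.0, -200.0)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("need at least one trial")
        lo, hi = self.latency_window
        if lo > hi or lo < 0:
            raise ConfigError(f"invalid latency window {self.latency_window}")
        if self.record_dt <= 0:
            raise ConfigError("record_dt must be > 0")
        object.__setattr__(self, "latency_window", (float(lo), float(hi)))
        object.__setattr__(self, "record_window", tuple(map(float, self.record_window)))
        object.__setattr__(self, "decode_offsets", tuple(map(float, self.decode_offsets)))


@dataclass(frozen=True)
class GFIParams:
    """Steady windows (ms re saccade onset) and selection criteria for the GFI.

    Both windows sit after the saccade: the pre window after the CD
    transient and visual settling but before the earliest possible PC
    update, the post window after the latest one, so the steady-rate
    difference is purely PC-driven.  ``threshold`` is the minimum rate
    change as a fraction of the pre-steady rate; ``consistency`` the
    fraction of trials that must agree on the sign of the change.
    """

    pre_window: tuple[float, float] = (110.0, 175.0)
    post_window: tuple[float, float] = (350.0, 500.0)
    threshold: float = 0.2
    min_abs_change: float = 0.05
    consistency: float = 0.9


@dataclass(frozen=True)
class DecoderHyperparams:
    """Training regime of the linear temporal-offset decoder."""

    ridge_alpha: float = 1e-2
    epochs: int = 100
    learning_rate: float | None = None  # None -> 1/L from a power-iteration bound
    standardize: bool = True
    use_relu: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.ridge_alpha < 0:
            raise ConfigError("ridge alpha must be >= 0")


# ---------------------------------------------------------------------------
# (de)serialisation
# ---------------------------------------------------------------------------

_SECTIONS: dict[str, type] = {
    "network": NetworkConfig,
    "protocol": TrialProtocol,
    "gfi": GFIParams,
    "decoder": DecoderHyperparams,
}

_NESTED: dict[str, type] = {
    "cd": CDParams,
    "delays": DelayDistribution,
    "lip_cd": GainFieldParams,
    "lip_pc": GainFieldParams,
}


def _build(cls: type, data: dict[str, Any], where: str):
    known = {f.name: f for f in fields(cls)}
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ConfigError(f"unknown key(s) under '{where}': {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{where}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config; absent keys get defaults, unknown keys raise.

    Returns a dict with keys ``network``, ``protocol``, ``gfi``, ``decoder``
    holding the corresponding parameter objects.  ``path=None`` or an empty
    file yields the full default configuration.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config root must be a mapping")
            raw = loaded
    unknown = sorted(set(raw) - set(_SECTIONS))
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(unknown)}")
    return {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    return obj


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    """Write the configuration dict back to YAML (round-trips losslessly)."""
    plain = {name: _to_plain(cfg[name]) for name in _SECTIONS}
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=True))


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of the full configuration (provenance key)."""
    plain = {name: _to_plain(cfg[name]) for name in _SECTIONS}
    blob = json.dumps(plain, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of a run: config hash, seeds, version, per-stage artifacts."""

    config_hash: str
    seed: int
    version: str
    stages: list[dict[str, str]] = field(default_factory=list)

    def add(self, stage: str, artifact: str) -> None:
        self.stages.append({"stage": stage, "artifact": artifact})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))
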