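"""Gain-field-index (GFI) analysis and eye/stimulus information maps.

The GFI locates a neuron's current response between its two steady states
around the proprioceptive (PC) eye-position update:

    GFI(t) = (V_probe(t) - V_poststeady) / (V_presteady - V_poststeady)

so GFI = 1 while the response still reflects the presaccadic eye position,
GFI = 0 once it reflects the postsaccadic one, and intermediate values mark
partially completed PC updates.  For the index to be meaningful the steady
rate difference must be *purely* PC-driven, so both steady windows sit
after the saccade: the pre window after the corollary-discharge transient
and visual settling but before the earliest synaptic PC delay, the post
window after the latest one.  Analysed neurons come from the PC-modulated
map only; CD-map neurons change their activity through the CD/remapping
pathway and are never selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GFIParams
from .errors import DegenerateSteadyStateError, InvalidWindowError
from .experiment import TrialRecord

__all__ = [
    "GFITrace",
    "select_gfi_neurons",
    "compute_gfi",
    "median_gfi_curves",
    "info_map",
]

EPS = 1e-9


@dataclass
class GFITrace:
    """Per-neuron GFI time course with its steady responses and class."""

    neuron: tuple[int, int]
    v_presteady: float
    v_poststeady: float
    v_probe: np.ndarray
    gfi: np.ndarray
    time: np.ndarray
    klass: str  # "low_to_high" | "high_to_low"


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    m = (time >= window[0]) & (time <= window[1])
    if not m.any():
        raise InvalidWindowError(f"window {window} contains no recorded samples")
    return m


def _validate_windows(
    records: list[TrialRecord], params: GFIParams
) -> None:
    """Steady windows must avoid the saccade and the PC-delay span."""
    spans = []
    duration = None
    for rec in records:
        lo = rec.delays.min() + _duration(rec)
        hi = rec.delays.max() + _duration(rec)
        spans.append((lo, hi))
        duration = _duration(rec)
    delay_lo = min(s[0] for s in spans)
    delay_hi = max(s[1] for s in spans)
    forbidden = [(0.0, duration), (delay_lo, delay_hi)]
    for window in (params.pre_window, params.post_window):
        for flo, fhi in forbidden:
            if window[0] < fhi and window[1] > flo:
                raise InvalidWindowError(
                    f"steady window {window} overlaps the saccade or PC-delay "
                    f"span [{flo:.0f}, {fhi:.0f}] ms"
                )


def _duration(rec: TrialRecord) -> float:
    # saccade duration recovered from the aligned trajectory samples
    moving = np.flatnonzero(np.abs(np.diff(rec.eye)) > 1e-9)
    if moving.size == 0:
        return 0.0
    return float(rec.time[moving[-1] + 1])


def trial_average(records: list[TrialRecord], population: str = "lip_pc") -> np.ndarray:
    """Trial-averaged (time, n, n) activity of one LIP map (onset aligned)."""
    return np.mean([getattr(rec, population) for rec in records], axis=0)


def select_gfi_neurons(
    records: list[TrialRecord], params: GFIParams | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Select PC-map neurons whose steady rate change is purely PC-driven.

    A neuron qualifies when its trial-averaged steady rate changes by more
    than ``threshold`` x its pre-steady rate (and an absolute floor)
    between the two windows, with the sign of the per-trial change
    consistent across at least ``consistency`` of trials.  Increases are
    classified ``low_to_high``, decreases ``high_to_low``.
    """
    params = params or GFIParams()
    _validate_windows(records, params)
    time = records[0].time
    pre_m = _window_mask(time, params.pre_window)
    post_m = _window_mask(time, params.post_window)

    stack = np.stack([rec.lip_pc for rec in records])  # (trials, T, n, n)
    pre_rates = stack[:, pre_m].mean(axis=1)  # (trials, n, n)
    post_rates = stack[:, post_m].mean(axis=1)
    pre_avg = pre_rates.mean(axis=0)
    post_avg = post_rates.mean(axis=0)

    diff = post_avg - pre_avg
    thresh = np.maximum(params.threshold * pre_avg, params.min_abs_change)
    candidate = np.abs(diff) > thresh

    sign = np.sign(diff)
    agree = (np.sign(post_rates - pre_rates) == sign).mean(axis=0)
    consistent = agree >= params.consistency

    selected = candidate & consistent
    out: dict[str, list[tuple[int, int]]] = {"low_to_high": [], "high_to_low": []}
    for i, j in zip(*np.nonzero(selected)):
        klass = "low_to_high" if diff[i, j] > 0 else "high_to_low"
        out[klass].append((int(i), int(j)))
    return out


def compute_gfi(
    trace: np.ndarray,
    time: np.ndarray,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    probe_from: float | None = None,
    neuron: tuple[int, int] = (-1, -1),
) -> GFITrace:
    """GFI time course of one rate trace.

    ``probe_from`` restricts the probe domain (default: start of the pre
    window, where the neuron's visual drive is established and constant —
    the model analogue of probing with a stimulus in the RF).  Raises
    :class:`DegenerateSteadyStateError` when the steady responses coincide;
    callers treat that as "exclude the neuron".
    """
    trace = np.asarray(trace, dtype=float)
    v_pre = float(trace[_window_mask(time, pre_window)].mean())
    v_post = float(trace[_window_mask(time, post_window)].mean())
    denom = v_pre - v_post
    if abs(denom) < EPS:
        raise DegenerateSteadyStateError(
            f"steady responses coincide (pre={v_pre:.4g}, post={v_post:.4g})"
        )
    start = pre_window[0] if probe_from is None else probe_from
    m = time >= start
    probe = trace[m]
    gfi = (probe - v_post) / denom
    klass = "low_to_high" if v_post > v_pre else "high_to_low"
    return GFITrace(
        neuron=neuron,
        v_presteady=v_pre,
        v_poststeady=v_post,
        v_probe=probe,
        gfi=gfi,
        time=time[m],
        klass=klass,
    )


def gfi_traces(
    records: list[TrialRecord], params: GFIParams | None = None
) -> list[GFITrace]:
    """GFI time courses for all selected PC-map neurons (trial-averaged)."""
    params = params or GFIParams()
    selected = select_gfi_neurons(records, params)
    avg = trial_average(records, "lip_pc")
    time = records[0].time
    out = []
    for klass, neurons in selected.items():
        for (i, j) in neurons:
            try:
                tr = compute_gfi(
                    avg[:, i, j], time, params.pre_window, params.post_window,
                    neuron=(i, j),
                )
            except DegenerateSteadyStateError:
                continue
            out.append(tr)
    return out


def median_gfi_curves(
    traces: list[GFITrace],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class median GFI curves plus the class-pooled mean curve.

    Returns a mapping of ``"low_to_high"`` / ``"high_to_low"`` /
    ``"pooled_mean"`` to (time, curve) pairs; classes without neurons are
    omitted.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if not traces:
        return out
    time = traces[0].time
    for klass in ("low_to_high", "high_to_low"):
        sel = [t.gfi for t in traces if t.klass == klass]
        if sel:
            out[klass] = (time, np.median(np.stack(sel), axis=0))
    out["pooled_mean"] = (time, np.mean(np.stack([t.gfi for t in traces]), axis=0))
    return out


def info_map(
    records: list[TrialRecord], mode: str = "eye_position"
) -> tuple[np.ndarray, np.ndarray]:
    """Time x position matrix of eye or retinal-stimulus information.

    Both LIP maps are normalised to their own maximum over the window and
    summed; for each timestep only the map slice (a retinal column for
    ``eye_position``, an eye row for ``retinal_stimulus``) with the highest
    summed activity is emitted, yielding the position profile that
    dominates the combined maps at that moment.

    Returns (time, matrix) with matrix of shape (time, n).
    """
    if mode not in ("eye_position", "retinal_stimulus"):
        raise InvalidWindowError(f"unknown info-map mode {mode!r}")
    avg_cd = trial_average(records, "lip_cd")
    avg_pc = trial_average(records, "lip_pc")
    total = np.zeros_like(avg_cd)
    for avg in (avg_cd, avg_pc):
        peak = avg.max()
        if peak > 0:
            total = total + avg / peak
    time = records[0].time
    if mode == "eye_position":
        # slices along the retinal axis; emit the eye-axis profile
        scores = total.sum(axis=1)  # (T, n_retinal)
        best = scores.argmax(axis=1)
        out = total[np.arange(time.size), :, best]
    else:
        scores = total.sum(axis=2)  # (T, n_eye)
        best = scores.argmax(axis=1)
        out = total[np.arange(time.size), best, :]
    return time, out
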