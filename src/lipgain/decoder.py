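"""Static linear temporal-offset decoder of eye position.

A single dense readout with a rectified-linear output maps the
instantaneous activity of all LIP neurons to the eye position at a chosen
temporal offset (past / current / future).  Training minimises the mean
squared error of ``relu(w . x + b)`` against the target eye position:
the weights are initialised at the closed-form ridge solution of the
linear part and then refined by full-batch gradient descent through the
rectifier with a backtracking step size, so the training loss is
non-increasing and the procedure is deterministic.

The decoder is a probe, not a mechanism: succeeding proves the eye
position is linearly accessible in the population activity; its weight
maps (reshaped per map) show *where* that information lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DecoderHyperparams, NetworkConfig
from .errors import EmptyDatasetError, InvalidParameterError, LayoutError
from .experiment import DecoderDataset, TrialRecord

__all__ = [
    "DecoderWeights",
    "DecodeResult",
    "train_decoder",
    "decode",
    "restrict_inputs",
    "weight_map",
    "rmse",
    "window_rmse",
    "sluggish_baseline_rmse",
    "transition_span",
    "transition_midpoint",
    "mean_decoded_trace",
]


@dataclass
class DecoderWeights:
    """Trained readout: one weight per LIP input neuron plus a bias.

    ``mu``/``sigma`` are the per-neuron training-split standardisation
    statistics (applied again at decode time); ``layout``/``map_shape``
    record which populations the columns came from.
    """

    w: np.ndarray
    b: float
    mu: np.ndarray
    sigma: np.ndarray
    offset: float
    layout: tuple[str, ...]
    map_shape: tuple[int, int]
    use_relu: bool = True
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = (X - self.mu) / self.sigma @ self.w + self.b
        return np.maximum(z, 0.0) if self.use_relu else z


@dataclass
class DecodeResult:
    """Decoded vs target eye position for one trial, with error summaries."""

    time: np.ndarray
    decoded: np.ndarray
    target: np.ndarray
    rmse: float
    window_rmse: dict[str, float]


def _loss(pred: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float) -> float:
    r = pred - y
    return float(np.mean(r * r) + alpha * np.dot(w, w))


def train_decoder(
    dataset: DecoderDataset,
    hyper: DecoderHyperparams | None = None,
    seed: int = 0,
) -> DecoderWeights:
    """Fit the static readout on the training split of ``dataset``.

    Deterministic given (dataset, hyperparameters, seed).  The learning
    rate defaults to 1/L with L an upper bound on the loss curvature from
    power iteration on the Gram matrix; each epoch halves the step until
    the loss does not increase, so the recorded loss curve is monotone.
    """
    hyper = hyper or DecoderHyperparams()
    X, y = dataset.train
    if X.shape[0] == 0:
        raise EmptyDatasetError("training split is empty")
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    n, d = X.shape

    if hyper.standardize:
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        sigma = np.where(sigma < 1e-8, 1.0, sigma)
    else:
        mu = np.zeros(d, dtype=np.float32)
        sigma = np.ones(d, dtype=np.float32)
    Xs = (X - mu) / sigma

    alpha = hyper.ridge_alpha
    G = (Xs.T @ Xs).astype(np.float64)

    # ridge initialisation of the linear part (bias unpenalised)
    b = float(y.mean())
    A = G + n * alpha * np.eye(d)
    w = np.linalg.solve(A, Xs.T @ (y - b)).astype(np.float64)
    b = float(np.mean(y - Xs @ w.astype(np.float32)))

    # curvature bound for the gradient step
    if hyper.learning_rate is None:
        v = np.random.default_rng(seed).standard_normal(d)
        v /= np.linalg.norm(v)
        for _ in range(30):
            v = G @ v
            v /= np.linalg.norm(v)
        lam_max = float(v @ (G @ v))
        lr = 1.0 / (2.0 * lam_max / n + 2.0 * alpha + 1e-12)
    else:
        lr = hyper.learning_rate

    w32 = w.astype(np.float32)
    z = Xs @ w32 + b
    pred = np.maximum(z, 0.0) if hyper.use_relu else z
    loss = _loss(pred, y, w, alpha)
    losses = [loss]
    for _ in range(hyper.epochs):
        grad_z = pred - y
        if hyper.use_relu:
            grad_z = grad_z * (z > 0)
        gw = (2.0 / n) * (Xs.T @ grad_z).astype(np.float64) + 2.0 * alpha * w
        gb = float((2.0 / n) * grad_z.sum())
        step = lr
        for _try in range(30):
            w_new = w - step * gw
            b_new = b - step * gb
            z_new = Xs @ w_new.astype(np.float32) + b_new
            pred_new = np.maximum(z_new, 0.0) if hyper.use_relu else z_new
            loss_new = _loss(pred_new, y, w_new, alpha)
            if loss_new <= loss + 1e-12:
                break
            step *= 0.5
        else:  # no productive step found; keep current weights
            w_new, b_new, z_new, pred_new, loss_new = w, b, z, pred, loss
        w, b, z, pred, loss = w_new, b_new, z_new, pred_new, loss_new
        losses.append(loss)

    return DecoderWeights(
        w=np.asarray(w, dtype=np.float64),
        b=float(b),
        mu=np.asarray(mu, dtype=np.float64),
        sigma=np.asarray(sigma, dtype=np.float64),
        offset=dataset.offset,
        layout=dataset.layout,
        map_shape=dataset.map_shape,
        use_relu=hyper.use_relu,
        meta={
            "epochs": hyper.epochs,
            "learning_rate": lr,
            "seed": seed,
            "final_loss": loss,
            "loss_curve": losses,
            "n_train": int(n),
        },
    )


def decode(weights: DecoderWeights, record: TrialRecord) -> DecodeResult:
    """Apply a trained decoder to one trial.

    Predictions are produced at every recorded timestep; the RMSE is
    computed only on the range where the offset-shifted target exists.
    Window RMSEs cover pre ([-300, -50)), peri ([-50, +62]) and post
    ((+62, +500]) saccadic epochs, in ms re saccade onset.
    """
    X = record.features(weights.layout)
    if X.shape[1] != weights.w.size:
        raise LayoutError(
            f"record provides {X.shape[1]} inputs for populations {weights.layout}, "
            f"decoder expects {weights.w.size}"
        )
    pred = weights.predict(X)

    record_dt = float(record.time[1] - record.time[0])
    k = int(round(weights.offset / record_dt))
    t = record.time.size
    rows = np.arange(t)
    ok = (rows + k >= 0) & (rows + k < t)
    time = record.time[ok]
    decoded = pred[ok]
    target = record.eye[rows[ok] + k]

    err = decoded - target
    windows = {"pre": (-300.0, -50.0), "peri": (-50.0, 62.0), "post": (62.0, 500.0)}
    wr = {}
    for name, (lo, hi) in windows.items():
        m = (time >= lo) & (time <= hi)
        wr[name] = float(np.sqrt(np.mean(err[m] ** 2))) if m.any() else float("nan")
    return DecodeResult(
        time=time,
        decoded=decoded,
        target=target,
        rmse=float(np.sqrt(np.mean(err**2))),
        window_rmse=wr,
    )


def restrict_inputs(dataset: DecoderDataset, selector: str) -> DecoderDataset:
    """Restrict the input columns to one LIP map (or keep both).

    ``selector`` is one of ``"both"``, ``"lip_cd"``, ``"lip_pc"``; all other
    dataset content (targets, split, offset) is unchanged.
    """
    if selector == "both":
        return dataset
    if selector not in dataset.layout:
        raise InvalidParameterError(
            f"selector {selector!r} not in dataset layout {dataset.layout}"
        )
    block = dataset.map_shape[0] * dataset.map_shape[1]
    start = dataset.layout.index(selector) * block
    return DecoderDataset(
        X=dataset.X[:, start : start + block],
        y=dataset.y,
        time=dataset.time,
        trial_ids=dataset.trial_ids,
        split=dataset.split,
        offset=dataset.offset,
        layout=(selector,),
        map_shape=dataset.map_shape,
    )


def weight_map(
    weights: DecoderWeights, config: NetworkConfig | None = None
) -> dict[str, np.ndarray]:
    """Reshape the flat weight vector into per-map (eye x retinal) grids.

    Lossless: concatenating the flattened maps in layout order recovers the
    weight vector exactly.
    """
    shape = weights.map_shape
    if config is not None and shape[0] != config.n_neurons:
        raise LayoutError("weight layout does not match the network geometry")
    block = shape[0] * shape[1]
    if weights.w.size != block * len(weights.layout):
        raise LayoutError("weight vector length does not match layout")
    return {
        pop: weights.w[i * block : (i + 1) * block].reshape(shape)
        for i, pop in enumerate(weights.layout)
    }


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def window_rmse(
    time: np.ndarray, decoded: np.ndarray, target: np.ndarray,
    window: tuple[float, float],
) -> float:
    m = (time >= window[0]) & (time <= window[1])
    return rmse(decoded[m], target[m])


def pooled_rmse(results: list[DecodeResult], window: tuple[float, float] | None = None) -> float:
    """RMS error pooled over all samples of several decode results."""
    sq, cnt = 0.0, 0
    for r in results:
        err = r.decoded - r.target
        if window is not None:
            m = (r.time >= window[0]) & (r.time <= window[1])
            err = err[m]
        sq += float(np.sum(err**2))
        cnt += err.size
    return float(np.sqrt(sq / max(cnt, 1)))


def sluggish_baseline_rmse(
    records: list[TrialRecord], ramp_duration: float = 250.0
) -> float:
    """RMSE of the classical sluggish eye-position signal against the truth.

    Replaces each trial's 62 ms saccade with a linear ramp of
    ``ramp_duration`` ms starting at saccade onset — the canonical slow
    signal — and pools the error over the analysis window.  Decoders that
    "largely accurately" track the eye must beat this number.
    """
    sq, cnt = 0.0, 0
    for rec in records:
        start = rec.eye[0]
        amp = rec.eye[-1] - rec.eye[0]
        frac = np.clip(rec.time / ramp_duration, 0.0, 1.0)
        sluggish = start + amp * frac
        err = sluggish - rec.eye
        sq += float(np.sum(err**2))
        cnt += err.size
    return float(np.sqrt(sq / max(cnt, 1)))


def _smooth(trace: np.ndarray, k: int = 3) -> np.ndarray:
    if k <= 1:
        return trace
    kernel = np.ones(k) / k
    return np.convolve(trace, kernel, mode="same")


def _crossing_time(time: np.ndarray, trace: np.ndarray, level: float) -> float:
    """First upward crossing of ``level``, linearly interpolated (nan if none)."""
    above = trace >= level
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(time[0])
    t0, t1 = time[i - 1], time[i]
    v0, v1 = trace[i - 1], trace[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def transition_levels(time: np.ndarray, trace: np.ndarray) -> tuple[float, float]:
    """Early / late plateau levels of a decoded trace.

    Uses the pre (-150 ms) and late (+400 ms) epochs when the trace covers
    them, otherwise falls back to its first / last 15% of samples (offset
    decoders lose part of the window to target shifting).
    """
    early = time <= -150.0
    late = time >= 400.0
    k = max(3, time.size // 7)
    v0 = float(np.mean(trace[early])) if early.any() else float(np.mean(trace[:k]))
    v1 = float(np.mean(trace[late])) if late.any() else float(np.mean(trace[-k:]))
    return v0, v1


def transition_span(
    time: np.ndarray, trace: np.ndarray,
    fracs: tuple[float, float] = (0.1, 0.9),
) -> float:
    """Duration (ms) between the 10% and 90% crossings of a decoded trace.

    Plateau levels are estimated from the early (< -150 ms) and late
    (> +400 ms) portions of the smoothed trace.
    """
    s = _smooth(np.asarray(trace, dtype=float))
    v0, v1 = transition_levels(time, s)
    lo = v0 + fracs[0] * (v1 - v0)
    hi = v0 + fracs[1] * (v1 - v0)
    return _crossing_time(time, s, hi) - _crossing_time(time, s, lo)


def transition_midpoint(time: np.ndarray, trace: np.ndarray) -> float:
    """Time (ms) of the 50% crossing of a decoded transition."""
    s = _smooth(np.asarray(trace, dtype=float))
    v0, v1 = transition_levels(time, s)
    return _crossing_time(time, s, v0 + 0.5 * (v1 - v0))


def mean_decoded_trace(
    weights: DecoderWeights, records: list[TrialRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Average decoded trace across trials (records share one time base)."""
    results = [decode(weights, rec) for rec in records]
    time = results[0].time
    mean = np.mean([r.decoded for r in results], axis=0)
    return time, mean
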