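"""HDF5 persistence for runs, decoder weights and analysis tables.

One container file per run: ``/trials/<id>`` groups hold the onset-aligned
LIP map traces, eye trace and sampled PC delays of each trial; decoder
weights live under ``/decoders/<name>`` as flat arrays with layout
metadata.  All datasets are written with ``track_times=False`` so the same
seed yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import h5py
import numpy as np

from . import __version__
from .config import RunManifest, config_hash
from .decoder import DecoderWeights
from .experiment import TrialRecord

__all__ = ["save_run", "load_run", "save_weights", "load_weights", "load_manifest"]

_DSET_OPTS = dict(track_times=False, compression="gzip", compression_opts=4, shuffle=True)


def _write(group: h5py.Group, name: str, data: np.ndarray) -> None:
    group.create_dataset(name, data=data, **_DSET_OPTS)


def save_run(
    path: str | Path,
    records: list[TrialRecord],
    cfg: dict[str, Any],
    manifest: RunManifest | None = None,
) -> RunManifest:
    """Persist all trial records plus configuration/provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = RunManifest(
            config_hash=config_hash(cfg),
            seed=cfg["protocol"].seed,
            version=__version__,
        )
    manifest.add("simulate", path.name)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["config_hash"] = manifest.config_hash
        f.attrs["seed"] = manifest.seed
        f.attrs["version"] = manifest.version
        f.attrs["manifest"] = manifest.to_json()
        trials = f.create_group("trials", track_order=True)
        for rec in records:
            g = trials.create_group(f"{rec.trial_id:05d}")
            g.attrs["trial_id"] = rec.trial_id
            g.attrs["onset"] = rec.onset
            _write(g, "time", rec.time)
            _write(g, "lip_cd", rec.lip_cd)
            _write(g, "lip_pc", rec.lip_pc)
            _write(g, "eye", rec.eye)
            _write(g, "delays", rec.delays)
            for name, arr in rec.extras.items():
                _write(g, f"extra_{name}", arr)
    return manifest


def load_run(path: str | Path) -> tuple[list[TrialRecord], dict[str, Any]]:
    """Load trial records and file-level metadata from a run container."""
    records: list[TrialRecord] = []
    with h5py.File(path, "r") as f:
        meta = dict(f.attrs)
        for key in sorted(f["trials"]):
            g = f["trials"][key]
            extras = {
                name[len("extra_"):]: g[name][...]
                for name in g
                if name.startswith("extra_")
            }
            records.append(
                TrialRecord(
                    trial_id=int(g.attrs["trial_id"]),
                    onset=float(g.attrs["onset"]),
                    time=g["time"][...],
                    lip_cd=g["lip_cd"][...],
                    lip_pc=g["lip_pc"][...],
                    eye=g["eye"][...],
                    delays=g["delays"][...],
                    extras=extras,
                )
            )
    return records, meta


def save_weights(path: str | Path, weights: DecoderWeights, name: str) -> None:
    """Append one decoder's weights (flat array + layout metadata)."""
    with h5py.File(path, "a", track_order=True) as f:
        dec = f.require_group("decoders")
        if name in dec:
            del dec[name]
        g = dec.create_group(name)
        _write(g, "w", weights.w)
        _write(g, "mu", weights.mu)
        _write(g, "sigma", weights.sigma)
        g.attrs["b"] = weights.b
        g.attrs["offset"] = weights.offset
        g.attrs["layout"] = ",".join(weights.layout)
        g.attrs["map_shape"] = list(weights.map_shape)
        g.attrs["use_relu"] = weights.use_relu
        g.attrs["final_loss"] = weights.meta.get("final_loss", float("nan"))


def load_weights(path: str | Path, name: str) -> DecoderWeights:
    with h5py.File(path, "r") as f:
        g = f["decoders"][name]
        return DecoderWeights(
            w=g["w"][...],
            b=float(g.attrs["b"]),
            mu=g["mu"][...],
            sigma=g["sigma"][...],
            offset=float(g.attrs["offset"]),
            layout=tuple(g.attrs["layout"].split(",")),
            map_shape=tuple(int(x) for x in g.attrs["map_shape"]),
            use_relu=bool(g.attrs["use_relu"]),
            meta={"final_loss": float(g.attrs["final_loss"])},
        )


def load_manifest(path: str | Path) -> RunManifest:
    with h5py.File(path, "r") as f:
        return RunManifest.from_json(f.attrs["manifest"])
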