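"""Raster and model serialization.

Rasters travel as CSV (a comment header carrying the bin width, one
column per neuron, an optional trailing "repeat" column) or as
compressed npz.  Fitted models are stored as a versioned JSON archive
holding every parameter array, grid metadata, and the training
provenance; floats are serialized with full round-trip precision and a
payload checksum guards against truncation or corruption.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    IndependentEnergy,
    Nonlinearity,
    PairwiseEnergy,
    PopulationModel,
)
from .raster import SpikeRaster

__all__ = ["read_raster", "write_raster", "save_model", "load_model",
           "ARCHIVE_VERSION"]

ARCHIVE_VERSION = 1
_MAGIC = "# semipop-raster v1"


def write_raster(raster: SpikeRaster, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "binary":
        payload = {"activity": raster.activity, "bin_width": raster.bin_width}
        if raster.repeat_labels is not None:
            payload["repeat_labels"] = raster.repeat_labels
        with open(path, "wb") as fh:  # keep the exact path (savez appends .npz)
            np.savez_compressed(fh, **payload)
        return
    if format != "csv":
        raise ValueError(f"unknown raster format {format!r}")
    cols = [f"n{i}" for i in range(raster.n_neurons)]
    df = pd.DataFrame(raster.activity, columns=cols)
    if raster.repeat_labels is not None:
        df["repeat"] = raster.repeat_labels
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC} bin_width={raster.bin_width!r}\n")
        df.to_csv(fh, index=False)


def read_raster(path, format: str = "csv") -> SpikeRaster:
    path = Path(path)
    if format == "binary":
        with np.load(path) as z:
            return SpikeRaster(
                z["activity"], float(z["bin_width"]),
                z["repeat_labels"] if "repeat_labels" in z else None,
            )
    if format != "csv":
        raise ValueError(f"unknown raster format {format!r}")
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_MAGIC):
            raise ValueError(f"{path} is not a semipop raster CSV (bad header)")
        bin_width = float(header.split("bin_width=")[1])
        df = pd.read_csv(fh)
    if df.empty:
        raise ValueError(f"{path} contains no time bins")
    labels = None
    if "repeat" in df.columns:
        labels = df.pop("repeat").to_numpy(dtype=np.int64)
    activity = df.to_numpy()
    bad = np.argwhere(~np.isin(activity, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-binary cell value {activity[r, c]!r} at row {r}, "
            f"column {df.columns[c]!r} of {path}"
        )
    return SpikeRaster(activity, bin_width, labels)


# ---------------------------------------------------------------------------
# model archives

def _arr(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": np.asarray(a, dtype=float).ravel().tolist()}


def _unarr(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


def _model_payload(model: PopulationModel) -> dict:
    if isinstance(model.energy, IndependentEnergy):
        energy = {"kind": "independent", "alpha": _arr(model.energy.alpha)}
    elif isinstance(model.energy, PairwiseEnergy):
        energy = {"kind": "pairwise", "J": _arr(model.energy.J)}
    else:
        raise TypeError(f"unsupported energy type {type(model.energy).__name__}")
    nl = None
    if model.nonlinearity is not None:
        v = model.nonlinearity
        nl = {"gamma1": v.gamma1, "gamma2": v.gamma2, "beta": _arr(v.beta),
              "e0": v.e0, "e1": v.e1}
    return {
        "energy": energy,
        "nonlinearity": nl,
        "k_potential": None if model.k_potential is None else _arr(model.k_potential),
        "log_z": model.log_z,
        "log_z_method": model.log_z_method,
        "provenance": model.provenance,
    }


def save_model(model: PopulationModel, path) -> None:
    payload = _model_payload(model)
    blob = json.dumps(payload, sort_keys=True)
    archive = {
        "format": "semipop-model",
        "version": ARCHIVE_VERSION,
        "sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "model": payload,
    }
    Path(path).write_text(json.dumps(archive, indent=1, sort_keys=True))


def load_model(path) -> PopulationModel:
    try:
        archive = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"model archive {path} is truncated or corrupt: {err}")
    if archive.get("format") != "semipop-model":
        raise ValueError(f"{path} is not a semipop model archive")
    if archive.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"archive version {archive.get('version')} not supported "
            f"(expected {ARCHIVE_VERSION})"
        )
    payload = archive["model"]
    blob = json.dumps(payload, sort_keys=True)
    if hashlib.sha256(blob.encode()).hexdigest() != archive.get("sha256"):
        raise ValueError(f"model archive {path} failed its integrity check")
    en = payload["energy"]
    energy = (IndependentEnergy(_unarr(en["alpha"])) if en["kind"] == "independent"
              else PairwiseEnergy(_unarr(en["J"])))
    nl = None
    if payload["nonlinearity"] is not None:
        d = payload["nonlinearity"]
        nl = Nonlinearity(d["gamma1"], d["gamma2"], _unarr(d["beta"]),
                          d["e0"], d["e1"])
    kp = None if payload["k_potential"] is None else _unarr(payload["k_potential"])
    return PopulationModel(
        energy, nl, kp,
        log_z=payload["log_z"], log_z_method=payload["log_z_method"],
        provenance=payload.get("provenance", {}),
    )
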