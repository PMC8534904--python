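"""Dataset and model readers/writers.

Datasets travel either as an HDF5 file (dataset ``X`` of shape n x p x q,
optional integer dataset ``labels`` of length n) or as a directory of
equally shaped per-matrix CSV files plus an optional ``labels.csv``
(one 0-based integer per line).  Models round-trip through a versioned
JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .em import EMTrace, MixtureModel, PenaltyConfig
from .exceptions import ModelFormatError, ShapeError
from .matnorm import MatrixNormalParams, MatrixSampleSet

MODEL_FORMAT_VERSION = 1

__all__ = [
    "load_dataset",
    "save_dataset",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
]


def load_dataset(path) -> tuple[MatrixSampleSet, np.ndarray | None]:
    """Read a sample stack (and labels, if present) from HDF5 or a CSV directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path {path} does not exist")
    if path.is_dir():
        return _load_csv_dir(path)
    with h5py.File(path, "r") as f:
        if "X" not in f:
            raise ShapeError(f"{path} has no dataset 'X'")
        X = np.asarray(f["X"], dtype=float)
        if X.ndim != 3:
            raise ShapeError(f"dataset 'X' in {path} must be 3-D, got {X.shape}")
        labels = np.asarray(f["labels"], dtype=int) if "labels" in f else None
    if labels is not None and labels.shape != (X.shape[0],):
        raise ShapeError(
            f"labels in {path} have shape {labels.shape}, expected ({X.shape[0]},)"
        )
    return MatrixSampleSet(X), labels


def _load_csv_dir(path: Path) -> tuple[MatrixSampleSet, np.ndarray | None]:
    files = sorted(
        f for f in path.iterdir()
        if f.suffix == ".csv" and f.name != "labels.csv"
    )
    if not files:
        raise FileNotFoundError(f"no matrix CSV files found in {path}")
    mats = []
    shape = None
    for f in files:
        try:
            A = np.loadtxt(f, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ShapeError(f"non-numeric content in {f}") from exc
        if shape is None:
            shape = A.shape
        elif A.shape != shape:
            raise ShapeError(
                f"matrix {f.name} has shape {A.shape}, expected {shape} "
                f"(set by {files[0].name})"
            )
        mats.append(A)
    labels = None
    labels_file = path / "labels.csv"
    if labels_file.exists():
        labels = np.loadtxt(labels_file, dtype=int, ndmin=1)
        if labels.shape != (len(mats),):
            raise ShapeError(
                f"labels.csv has {labels.size} entries for {len(mats)} matrices"
            )
    return MatrixSampleSet(np.stack(mats)), labels


def save_dataset(path, samples: MatrixSampleSet, labels=None) -> None:
    """Write a sample stack (+ optional labels) to an HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=samples.data)
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels, dtype=int))


def model_to_dict(model: MixtureModel) -> dict:
    """JSON-serializable document for a fitted mixture (format-versioned)."""
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "G": model.G,
        "weights": model.weights.tolist(),
        "penalties": {
            "lambda1": model.penalties.lambda1,
            "lambda2": model.penalties.lambda2,
            "lambda3": model.penalties.lambda3,
        },
        "components": [
            {
                "M": c.M.tolist(),
                "U": c.U.tolist(),
                "V": c.V.tolist(),
                "U_inv": None if c.U_inv is None else c.U_inv.tolist(),
                "V_inv": None if c.V_inv is None else c.V_inv.tolist(),
            }
            for c in model.components
        ],
        "trace": {
            "loglik_history": [float(v) for v in model.trace.loglik_history],
            "n_iter": model.trace.n_iter,
            "converged": model.trace.converged,
            "restart_index": model.trace.restart_index,
        },
    }


def model_from_dict(doc: dict) -> MixtureModel:
    if "format_version" not in doc:
        raise ModelFormatError("model document has no format_version field")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {doc['format_version']} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    try:
        pen = PenaltyConfig(**doc["penalties"])
        components = [
            MatrixNormalParams(
                M=np.asarray(c["M"], dtype=float),
                U=np.asarray(c["U"], dtype=float),
                V=np.asarray(c["V"], dtype=float),
                U_inv=None if c.get("U_inv") is None else np.asarray(c["U_inv"]),
                V_inv=None if c.get("V_inv") is None else np.asarray(c["V_inv"]),
            )
            for c in doc["components"]
        ]
        trace = EMTrace(
            loglik_history=list(doc.get("trace", {}).get("loglik_history", [])),
            n_iter=doc.get("trace", {}).get("n_iter", 0),
            converged=doc.get("trace", {}).get("converged", False),
            restart_index=doc.get("trace", {}).get("restart_index", 0),
        )
        return MixtureModel(
            weights=np.asarray(doc["weights"], dtype=float),
            components=components,
            penalties=pen,
            trace=trace,
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed model document: {exc}") from exc


def save_model(model: MixtureModel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model_to_dict(model)))


def load_model(path) -> MixtureModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    return model_from_dict(doc)
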