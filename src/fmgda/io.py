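"""Plain-text (JSON/CSV) serialization of feature sets, models, and tables.

Matrices are stored as shape metadata plus row-major value lists, so the
containers are portable and diff-able; pairwise-distance matrices and fit
diagnostics export to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discriminant import FMGDAConfig, FMGDAModel
from .grassmann import GrassmannPoint, LabeledGrassmannSet, pairwise_projection_distances

FORMAT_VERSION = 1


def _matrix_to_obj(M: np.ndarray) -> dict:
    return {"shape": list(M.shape), "values": np.asarray(M).ravel(order="C").tolist()}


def _matrix_from_obj(obj: dict) -> np.ndarray:
    return np.asarray(obj["values"], dtype=float).reshape(obj["shape"], order="C")


def save_grassmann_set(
    data: LabeledGrassmannSet, path: str | Path, meta: dict | None = None
) -> None:
    """Write a labeled Grassmann set as one JSON document."""
    doc = {
        "format": "fmgda.grassmann_set",
        "version": FORMAT_VERSION,
        "ambient_dim": data.ambient_dim,
        "subspace_dim": data.subspace_dim,
        "labels": data.labels.tolist(),
        "label_names": list(data.label_names) if data.label_names else None,
        "bases": _matrix_to_obj(data.bases),
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_grassmann_set(path: str | Path) -> LabeledGrassmannSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fmgda.grassmann_set":
        raise ValueError(f"{path}: not a Grassmann set container")
    names = doc.get("label_names")
    return LabeledGrassmannSet(
        _matrix_from_obj(doc["bases"]),
        np.asarray(doc["labels"], dtype=int),
        tuple(names) if names else None,
    )


def save_model(model: FMGDAModel, path: str | Path) -> None:
    """Write a fitted FMGDA model (mapping, means, config, traces) as JSON."""
    doc = {
        "format": "fmgda.model",
        "version": FORMAT_VERSION,
        "A": _matrix_to_obj(model.A),
        "class_means": [_matrix_to_obj(m.basis) for m in model.class_means],
        "global_mean": _matrix_to_obj(model.global_mean.basis),
        "objective_trace": model.objective_trace.tolist(),
        "lambda_traces": [t.tolist() for t in model.lambda_traces],
        "label_names": list(model.label_names) if model.label_names else None,
        "config": {
            "target_dim": model.config.target_dim,
            "outer_iters": model.config.outer_iters,
            "trace_ratio_iters": model.config.trace_ratio_iters,
            "tol": model.config.tol,
            "inner_tol": model.config.inner_tol,
            "within_weighting": model.config.within_weighting,
            "init": model.config.init,
            "seed": model.config.seed,
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> FMGDAModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fmgda.model":
        raise ValueError(f"{path}: not an FMGDA model container")
    names = doc.get("label_names")
    return FMGDAModel(
        A=_matrix_from_obj(doc["A"]),
        class_means=tuple(
            GrassmannPoint(_matrix_from_obj(m)) for m in doc["class_means"]
        ),
        global_mean=GrassmannPoint(_matrix_from_obj(doc["global_mean"])),
        objective_trace=np.asarray(doc["objective_trace"], dtype=float),
        lambda_traces=tuple(np.asarray(t, dtype=float) for t in doc["lambda_traces"]),
        config=FMGDAConfig(**doc["config"]),
        label_names=tuple(names) if names else None,
    )


def distance_matrix_to_csv(
    data: LabeledGrassmannSet, path: str | Path
) -> pd.DataFrame:
    """Export the pairwise projection-distance matrix of a set as CSV."""
    D = pairwise_projection_distances(data, data)
    ids = [f"pt{i}_c{l}" for i, l in enumerate(data.labels)]
    df = pd.DataFrame(D, index=ids, columns=ids)
    df.to_csv(path)
    return df


def diagnostics_to_csv(model: FMGDAModel, path: str | Path) -> pd.DataFrame:
    """Export fit diagnostics: outer iteration, objective, final lambda."""
    rows = []
    for t, obj in enumerate(model.objective_trace):
        lam = (
            float(model.lambda_traces[t - 1][-1])
            if 1 <= t <= len(model.lambda_traces)
            else np.nan
        )
        rows.append({"outer_iter": t, "objective": float(obj), "lambda": lam})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
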