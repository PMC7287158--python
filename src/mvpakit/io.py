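"""File I/O: data loading and result export.

Data comes in as CSV (2-D, optional header row used as feature names)
or NPY (N-dimensional); labels/responses as single-column CSV.  Result
grids are written as NPY arrays with a JSON sidecar carrying dimension
names/coordinates, plus a CSV summary for scalar-per-point metrics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .base import DataError, StructuralError
from .data import DataSet


def load_array(path, dim_roles=None) -> DataSet:
    """Load a data array from .npy (N-D) or .csv (2-D)."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
        coords = {}
    elif path.suffix == ".csv":
        df = pd.read_csv(path, header="infer" if _has_header(path) else None)
        values = df.to_numpy(dtype=float)
        coords = {1: [str(c) for c in df.columns]} if _has_header(path) else {}
    else:
        raise DataError(f"unsupported data format {path.suffix!r} (use .npy or .csv)")
    ds = DataSet(values, tuple(dim_roles or ()), coords)
    return ds


def _has_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline().split(",")
    for tok in first:
        try:
            float(tok)
            return False
        except ValueError:
            continue
    return True


def load_targets(path, kind="classification") -> np.ndarray:
    """Load labels/responses from a single-column CSV (or .npy vector)."""
    path = Path(path)
    if path.suffix == ".npy":
        t = np.load(path)
    else:
        t = pd.read_csv(path, header=None).to_numpy().ravel()
    t = np.asarray(t)
    if t.ndim != 1:
        raise StructuralError("targets must be a single column")
    return t.astype(int) if kind == "classification" else t.astype(float)


def save_result_grid(grid, out_prefix) -> list[str]:
    """Write a ResultGrid: one .npy per metric + a .json sidecar
    (+ .csv summary for scalar grids).  Returns written paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    sidecar = {
        "metrics": {},
        "dim_names": list(grid.dim_names),
        "dim_coords": {
            str(k): (list(v) if v is not None else None)
            for k, v in grid.dim_coords.items()
        },
        "cfg": _jsonable(grid.cfg),
    }
    for name, value in grid.metrics.items():
        if name == "none":
            continue
        arr = np.asarray(value, dtype=float)
        npy = out_prefix.parent / f"{out_prefix.name}_{name}.npy"
        np.save(npy, arr)
        written.append(str(npy))
        sidecar["metrics"][name] = {
            "file": npy.name,
            "shape": list(arr.shape),
            "value": arr.tolist() if arr.size <= 1000 else None,
        }
        if arr.ndim <= 2:
            csv = out_prefix.parent / f"{out_prefix.name}_{name}.csv"
            np.savetxt(csv, np.atleast_2d(arr), delimiter=",", fmt="%.10g")
            written.append(str(csv))
    sidecar_path = out_prefix.parent / f"{out_prefix.name}_result.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    written.append(str(sidecar_path))
    return written


def save_stat_result(result, out_prefix) -> list[str]:
    """Write a StatTestResult as JSON (+ NPY mask/p maps if array-valued)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    report = {
        "alpha": result.alpha,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "info": _jsonable(result.info),
        "statistic": _jsonable(result.statistic),
        "p": _jsonable(result.p),
        "clusters": [
            {
                "members": [list(map(int, m)) for m in zip(*cl.members)],
                "mass": cl.mass,
                "size": cl.size,
                "p": cl.p,
            }
            for cl in result.clusters
        ],
    }
    for attr in ("mask", "p"):
        val = getattr(result, attr)
        if isinstance(val, np.ndarray) and val.ndim >= 1:
            npy = out_prefix.parent / f"{out_prefix.name}_{attr}.npy"
            np.save(npy, val)
            written.append(str(npy))
    path = out_prefix.parent / f"{out_prefix.name}_stats.json"
    path.write_text(json.dumps(report, indent=2))
    written.append(str(path))
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)
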