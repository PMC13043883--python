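"""Readers and writers for the pipeline's tabular artefacts.

One fixed CSV dialect throughout: comma-separated, UTF-8, "." decimal,
mandatory header row, subject_id as the index column for matrices.  Every
file written here starts with a ``#`` comment line carrying the package
version and the run-config hash, which the readers skip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ConnectivityStack

__all__ = [
    "write_csv", "read_csv",
    "write_subjects", "read_subjects",
    "write_matrix", "read_matrix",
    "write_connectivity", "read_connectivity",
    "write_yaml", "read_yaml",
]


def _header(meta: dict | None) -> str:
    from . import __version__

    parts = [f"substage v{__version__}"]
    for k, v in (meta or {}).items():
        parts.append(f"{k}={v}")
    return "# " + " ".join(parts) + "\n"


def write_csv(df: pd.DataFrame, path, meta: dict | None = None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=index)


def read_csv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_subjects(subjects: pd.DataFrame, path, meta=None) -> None:
    write_csv(subjects, path, meta, index=False)


def read_subjects(path) -> pd.DataFrame:
    df = read_csv(path)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r} in {path}")
    return df


def write_matrix(matrix: pd.DataFrame, path, meta=None) -> None:
    """Subjects x columns matrix with subject_id index."""
    write_csv(matrix, path, meta, index=True)


def read_matrix(path) -> pd.DataFrame:
    df = read_csv(path, index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric matrix column(s) {list(bad)} in {path}")
    return df


def write_connectivity(stack: ConnectivityStack, path, meta=None) -> None:
    """Long format: one row per (subject, region_i, region_j) upper-triangle edge."""
    iu = np.triu_indices(stack.n_regions, k=1)
    rows = []
    for s, sid in enumerate(stack.subject_ids):
        rows.append(pd.DataFrame({
            "subject_id": sid,
            "region_i": [stack.regions[a] for a in iu[0]],
            "region_j": [stack.regions[b] for b in iu[1]],
            "value": stack.data[s, iu[0], iu[1]],
        }))
    write_csv(pd.concat(rows, ignore_index=True), path, meta, index=False)


def read_connectivity(path, tol: float = 1e-8) -> ConnectivityStack:
    df = read_csv(path)
    subjects = df["subject_id"].drop_duplicates().tolist()
    regions = sorted(set(df["region_i"]) | set(df["region_j"]))
    r_idx = {r: k for k, r in enumerate(regions)}
    s_idx = {s: k for k, s in enumerate(subjects)}
    data = np.zeros((len(subjects), len(regions), len(regions)))
    si = df["subject_id"].map(s_idx).to_numpy()
    ri = df["region_i"].map(r_idx).to_numpy()
    rj = df["region_j"].map(r_idx).to_numpy()
    vals = df["value"].to_numpy(dtype=float)
    data[si, ri, rj] = vals
    data[si, rj, ri] = vals
    return ConnectivityStack(data, regions, subjects)


def _pythonize(obj):
    """Recursively strip numpy scalar/array types for YAML emission."""
    if isinstance(obj, dict):
        return {k: _pythonize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pythonize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _pythonize(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_yaml(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_pythonize(obj), fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
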