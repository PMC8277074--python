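"""Matrix readers/writers and the [0,1] feature scaling utilities.

Internal convention throughout the package: samples in rows, features
in columns, 0-based indices. Gene x cell matrices arriving transposed
are flipped with ``transpose=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["MatrixData", "read_matrix", "write_matrix",
           "ScalingMeta", "scale_minmax", "inverse_scale"]


@dataclass
class MatrixData:
    values: np.ndarray
    row_names: list[str]
    col_names: list[str]


def _default_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def read_matrix(path: str | Path, fmt: str = "auto",
                transpose: bool = False) -> MatrixData:
    """Read a dense sample x feature matrix from CSV/TSV/MatrixMarket.

    CSV/TSV files are expected to carry a header row of feature names
    and a first column of sample identifiers. MTX files may have
    companion ``<stem>.rows``/``<stem>.cols`` name files (one name per
    line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")

    if fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat,
                            dtype=np.float64)
        rows_file = path.with_suffix(".rows")
        cols_file = path.with_suffix(".cols")
        row_names = (rows_file.read_text().split() if rows_file.exists()
                     else _default_names("sample", values.shape[0]))
        col_names = (cols_file.read_text().split() if cols_file.exists()
                     else _default_names("feature", values.shape[1]))
    else:
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            values = df.to_numpy(dtype=np.float64)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric or ragged content ({exc})") from exc
        row_names = [str(r) for r in df.index]
        col_names = [str(c) for c in df.columns]

    data = MatrixData(values=values, row_names=row_names, col_names=col_names)
    if transpose:
        data = MatrixData(values=data.values.T, row_names=data.col_names,
                          col_names=data.row_names)
    if data.values.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D matrix")
    return data


def write_matrix(data: MatrixData, path: str | Path, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(path.suffix.lower(), "csv")
    if fmt == "mtx":
        spio.mmwrite(str(path.with_suffix("")), sparse.coo_matrix(data.values))
        path.with_suffix(".rows").write_text("\n".join(data.row_names) + "\n")
        path.with_suffix(".cols").write_text("\n".join(data.col_names) + "\n")
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(data.values, index=data.row_names, columns=data.col_names)
        df.to_csv(path, sep=sep)


@dataclass
class ScalingMeta:
    """Per-feature min-max parameters; enables exact inversion for
    generated samples."""

    mins: np.ndarray
    ranges: np.ndarray  # 0 for constant features

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "ranges": self.ranges.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingMeta":
        return cls(mins=np.asarray(d["mins"]), ranges=np.asarray(d["ranges"]))


def scale_minmax(x: np.ndarray) -> tuple[np.ndarray, ScalingMeta]:
    """Per-feature min-max scaling into [0, 1].

    Constant features map to 0 (with a warning); non-finite input is
    rejected with the offending cells listed.
    """
    x = np.asarray(x, dtype=np.float64)
    bad = ~np.isfinite(x)
    if bad.any():
        cells = list(zip(*np.nonzero(bad)))[:10]
        raise ValueError(f"non-finite values at cells {cells}")
    mins = x.min(axis=0)
    ranges = x.max(axis=0) - mins
    constant = ranges == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) mapped to 0"
        )
    safe = np.where(constant, 1.0, ranges)
    scaled = (x - mins) / safe
    scaled[:, constant] = 0.0
    return scaled, ScalingMeta(mins=mins, ranges=ranges)


def inverse_scale(x_scaled: np.ndarray, meta: ScalingMeta) -> np.ndarray:
    """Exact inverse of :func:`scale_minmax` (constant features recover
    their original value)."""
    return np.asarray(x_scaled) * np.where(meta.ranges == 0, 0.0, meta.ranges) + meta.mins
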