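"""Core data containers and on-disk formats.

The canonical in-memory orientation for expression data is features x spots
(an ``N x M`` sparse matrix); every reader normalizes to it.  Coordinates are
a dense ``M x D`` array with ``D`` of 2 or 3.  Matrix Market files are
1-based on disk (the MTX standard) and 0-based once loaded.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialCoordinates",
    "ExpressionMatrix",
    "SVFResult",
    "ValidationError",
    "load_expression",
    "load_coordinates",
    "write_results",
    "read_results",
]


class ValidationError(ValueError):
    """An input violates a structural contract (shape, sign, uniqueness)."""


@dataclasses.dataclass
class SpatialCoordinates:
    """Spot positions for one sample.

    Parameters
    ----------
    positions
        ``M x D`` array of spot coordinates, ``D`` in {2, 3}.  Units are
        arbitrary until density rescaling marks ``is_rescaled``.
    spot_ids
        ``M`` unique identifiers, kept in file order.
    is_rescaled
        True once the coordinates have been normalized to unit spot density.
    """

    positions: np.ndarray
    spot_ids: np.ndarray
    is_rescaled: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2:
            raise ValidationError("positions must be a 2-D array of shape (M, D)")
        m, d = self.positions.shape
        if d not in (2, 3):
            raise ValidationError(f"coordinate dimension must be 2 or 3, got {d}")
        if m < 2:
            raise ValidationError(
                "at least 2 spots are required (a single spot has no neighbors)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("coordinates contain non-finite values")
        self.spot_ids = np.asarray(self.spot_ids)
        if self.spot_ids.shape != (m,):
            raise ValidationError("spot_ids length must match the number of rows")
        if len(np.unique(self.spot_ids)) != m:
            raise ValidationError("spot_ids must be unique")

    @property
    def n_spots(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]


@dataclasses.dataclass
class ExpressionMatrix:
    """A non-negative sparse ``N features x M spots`` matrix."""

    values: sp.csr_matrix
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.values.eliminate_zeros()  # canonical form: stored entries are non-zero
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("expression values must be non-negative")
        self.feature_ids = np.asarray(self.feature_ids)
        n = self.values.shape[0]
        if self.feature_ids.shape != (n,):
            raise ValidationError("feature_ids length must match the number of rows")
        if len(np.unique(self.feature_ids)) != n:
            raise ValidationError("feature_ids must be unique")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    @property
    def density(self) -> float:
        """Fraction of stored non-zero entries."""
        n, m = self.values.shape
        return self.values.nnz / (n * m)


@dataclasses.dataclass
class SVFResult:
    """Per-feature output of a run: variance, weight, ratio, p-value.

    Excluded (degenerate) features carry ``ratio = 0`` and ``p_value = 1`` so
    every input feature has a defined row, in input order.
    """

    feature_ids: np.ndarray
    raw_variance: np.ndarray
    weight: np.ndarray
    ratio: np.ndarray
    p_value: np.ndarray
    excluded: np.ndarray
    alpha: float = 0.05
    q_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        for name in ("raw_variance", "weight", "ratio", "p_value", "excluded"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one entry per feature")
            setattr(self, name, arr)

    @property
    def significant(self) -> np.ndarray:
        return (self.p_value < self.alpha) & ~self.excluded

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "raw_variance": self.raw_variance,
                "weight": self.weight,
                "ratio": self.ratio,
                "p_value": self.p_value,
                "excluded": self.excluded.astype(bool),
            }
        )
        if self.q_value is not None:
            df["q_value"] = self.q_value
        return df


def _read_sidecar(path: Path) -> np.ndarray:
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return np.asarray(names, dtype=object)


def load_expression(
    path: str | Path,
    fmt: str | None = None,
    orientation: str = "features_by_spots",
    feature_file: str | Path | None = None,
    spot_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX or dense CSV/TSV.

    Parameters
    ----------
    path
        The matrix file.  For ``mtx``, feature/spot names come from sidecar
        files (defaults: ``<stem>.features.txt`` / ``<stem>.spots.txt`` next
        to the matrix).  For ``csv``/``tsv`` the first column holds row names
        and the header holds column names.
    fmt
        ``mtx``, ``csv`` or ``tsv``; inferred from the suffix when omitted.
    orientation
        How the file is laid out on disk.  The returned matrix is always
        features x spots.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("mtx", "csv", "tsv"):
        raise ValidationError(f"unknown expression format {fmt!r}")
    if orientation not in ("features_by_spots", "spots_by_features"):
        raise ValidationError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        try:
            mat = sp.csr_matrix(scipy.io.mmread(path))
        except Exception as exc:  # scipy raises bare ValueError on bad lines
            raise ValidationError(f"failed to parse Matrix Market file {path}: {exc}")
        feature_file = Path(feature_file) if feature_file else path.with_suffix(".features.txt")
        spot_file = Path(spot_file) if spot_file else path.with_suffix(".spots.txt")
        row_names = _read_sidecar(feature_file)
        col_names = _read_sidecar(spot_file)
        if orientation == "spots_by_features":
            row_names, col_names = col_names, row_names
            mat = sp.csr_matrix(mat.T)
        if len(row_names) != mat.shape[0]:
            raise ValidationError(
                f"sidecar lists {len(row_names)} feature names but the matrix "
                f"has {mat.shape[0]} feature rows"
            )
        if len(col_names) != mat.shape[1]:
            raise ValidationError(
                f"sidecar lists {len(col_names)} spot names but the matrix "
                f"has {mat.shape[1]} spot columns"
            )
        return ExpressionMatrix(values=mat, feature_ids=row_names)

    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValidationError(f"failed to parse {fmt.upper()} file {path}: {exc}")
    if orientation == "spots_by_features":
        df = df.T
    mat = sp.csr_matrix(df.to_numpy(dtype=float))
    return ExpressionMatrix(values=mat, feature_ids=df.index.to_numpy(dtype=object))


def load_coordinates(
    path: str | Path,
    columns: Sequence[str] | None = None,
    spot_column: str | None = None,
) -> SpatialCoordinates:
    """Read a spot coordinate table (CSV or TSV by suffix).

    ``columns`` names the x, y (and optionally z) columns; by default
    ``("x", "y", "z")`` are used with ``z`` optional.  Spot order follows
    file order.  Spot ids come from ``spot_column`` when given, else from
    row position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if columns is None:
        columns = ["x", "y", "z"] if "z" in df.columns else ["x", "y"]
    for col in columns:
        if col not in df.columns:
            raise ValidationError(f"coordinate column {col!r} not found in {path}")
    sub = df[list(columns)]
    bad = sub.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        row = int(bad.isna().any(axis=1).idxmax())
        raise ValidationError(f"non-numeric coordinate value at row {row} of {path}")
    if spot_column is not None:
        if spot_column not in df.columns:
            raise ValidationError(f"spot id column {spot_column!r} not found in {path}")
        ids = df[spot_column].to_numpy(dtype=object)
    else:
        ids = np.asarray([f"spot_{i}" for i in range(len(df))], dtype=object)
    return SpatialCoordinates(positions=bad.to_numpy(dtype=float), spot_ids=ids)


def write_results(result: SVFResult, path: str | Path) -> None:
    """Write a result table as CSV, one row per input feature in input order."""
    result.to_frame().to_csv(path, index=False)


def write_expression_mtx(expr: ExpressionMatrix, path: str | Path, spot_ids=None) -> None:
    """Write an expression matrix as Matrix Market plus name sidecars
    (``<stem>.features.txt`` and ``<stem>.spots.txt``)."""
    path = Path(path)
    scipy.io.mmwrite(path, expr.values)
    path.with_suffix(".features.txt").write_text(
        "\n".join(str(f) for f in expr.feature_ids) + "\n"
    )
    if spot_ids is None:
        spot_ids = [f"spot_{i}" for i in range(expr.n_spots)]
    path.with_suffix(".spots.txt").write_text(
        "\n".join(str(s) for s in spot_ids) + "\n"
    )


def write_coordinates(coords: SpatialCoordinates, path: str | Path) -> None:
    """Write a coordinate table as CSV with columns spot, x, y (, z)."""
    cols = ["x", "y", "z"][: coords.n_dims]
    df = pd.DataFrame(coords.positions, columns=cols)
    df.insert(0, "spot", coords.spot_ids)
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path)
    required = {"feature_id", "raw_variance", "weight", "ratio", "p_value", "excluded"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"results file {path} lacks columns {sorted(missing)}")
    return df
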