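"""Coordinate density rescaling and per-feature max-absolute expression scaling.

Coordinates are multiplied by the single isotropic factor
``(M / prod_d range_d) ** (1/D)`` so that the product of the per-dimension
ranges equals the number of spots — i.e. unit average spot density.  One
scalar is applied to every axis, so anisotropic spacing (e.g. a stretched
z-axis between serial sections) is preserved, and all distance ratios are
unchanged (a similarity transform).

Expression rows are divided by their maximum, mapping each non-empty feature
into [0, 1] without disturbing the sparsity pattern.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, SpatialCoordinates, ValidationError

__all__ = [
    "RescaleRecord",
    "rescale_coordinates",
    "scale_expression_maxabs",
    "drop_degenerate_features",
]


@dataclasses.dataclass(frozen=True)
class RescaleRecord:
    """Per-dimension coordinate ranges and the global scale factor applied."""

    ranges: np.ndarray  # range of each raw coordinate dimension
    factor: float  # (M / prod(ranges)) ** (1/D)


def rescale_coordinates(
    coords: SpatialCoordinates,
) -> tuple[SpatialCoordinates, RescaleRecord]:
    """Normalize spot coordinates to unit density.

    Returns the rescaled coordinates (``is_rescaled=True``) and a record of
    the ranges and factor.  After rescaling the product of per-dimension
    ranges equals M (to floating tolerance).

    Raises
    ------
    ValidationError
        If the coordinates are already rescaled, or any dimension has zero
        range (drop the degenerate dimension or jitter it before calling).
    """
    if coords.is_rescaled:
        raise ValidationError("coordinates are already rescaled")
    pos = coords.positions
    m, d = pos.shape
    ranges = pos.max(axis=0) - pos.min(axis=0)
    if np.any(ranges <= 0):
        dim = int(np.argmax(ranges <= 0))
        raise ValidationError(
            f"coordinate dimension {dim} has zero range; drop it or jitter "
            "the coordinates before rescaling"
        )
    factor = float((m / np.prod(ranges)) ** (1.0 / d))
    rescaled = SpatialCoordinates(
        positions=pos * factor, spot_ids=coords.spot_ids, is_rescaled=True
    )
    return rescaled, RescaleRecord(ranges=ranges, factor=factor)


def scale_expression_maxabs(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list]:
    """Divide each feature row by its maximum value (max-absolute scaling).

    Every non-empty row attains 1 at its argmax; the sparsity pattern is
    unchanged; all-zero rows are left as-is and reported in the returned
    list of feature ids.  Idempotent on already-scaled input.
    """
    mat = expr.values.tocsr(copy=True)
    n = mat.shape[0]
    row_max = np.zeros(n)
    if mat.nnz:
        # non-negative matrix: the row max is the max of stored values
        maxes = mat.max(axis=1).toarray().ravel()
        row_max = maxes
    all_zero = row_max == 0
    scale = np.ones(n)
    scale[~all_zero] = 1.0 / row_max[~all_zero]
    mat = sp.diags(scale) @ mat
    scaled = ExpressionMatrix(values=sp.csr_matrix(mat), feature_ids=expr.feature_ids)
    return scaled, list(expr.feature_ids[all_zero])


def degenerate_feature_mask(expr: ExpressionMatrix) -> np.ndarray:
    """Boolean mask of features with zero variance across spots.

    A feature is degenerate iff it is all-zero, or fully dense with a single
    repeated value — the only ways a row with implicit zeros can be constant.
    The test is exact (no floating tolerance).
    """
    mat = expr.values.tocsr()
    n, m = mat.shape
    nnz_per_row = np.diff(mat.indptr)
    mask = nnz_per_row == 0
    full = nnz_per_row == m
    if np.any(full):
        for j in np.flatnonzero(full):
            row = mat.data[mat.indptr[j] : mat.indptr[j + 1]]
            if row.max() == row.min():
                mask[j] = True
    return mask


def drop_degenerate_features(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list]:
    """Remove zero-variance features, returning the retained matrix and the
    excluded feature ids (these receive p = 1 downstream).

    Raises
    ------
    ValidationError
        If every feature is degenerate.
    """
    mask = degenerate_feature_mask(expr)
    if mask.all():
        raise ValidationError("all features have zero variance; nothing to test")
    if not mask.any():
        return expr, []
    keep = ~mask
    retained = ExpressionMatrix(
        values=sp.csr_matrix(expr.values[keep]),
        feature_ids=expr.feature_ids[keep],
    )
    return retained, list(expr.feature_ids[mask])
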