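"""Benchmark simulators with ground-truth spatially-variable labels.

Four families:

* ``simulate_2d`` — a jittered 2D lattice (default 260 spots, the size of a
  mouse-olfactory-bulb array) with three parameterized pattern masks
  (hotspot disk, diagonal streak, annulus).  Patterned counts follow a
  log-normal-Poisson model: ``y ~ Poisson(lambda)`` with
  ``ln lambda = beta_base + ln(FC) * marked + eps``, ``eps ~ N(0, tau2)``.
* ``simulate_3d_continuous`` — 10 serial sections of a 15 x 15 grid (2,250
  spots); the pattern is a chain of spheres whose centers follow a
  fixed-step random walk, with monotonicity constraints selecting a curved
  strand, a tissue layer, or an irregular aggregate.
* ``simulate_3d_discrete`` — 10 sections of a 30 x 30 grid (9,000 spots);
  16 isolated spherical nodules on a regular 8-unit grid at mid-depth,
  jittered by U(-2, 2) per coordinate.
* ``simulate_sparse_random`` — unstructured sparse counts
  ``floor(1 + 10 * Beta(1, 5))`` at a chosen density, for scale testing.

In the 3D families, marked spots sample from the upper quartile of a
right-skewed reference count distribution (negative binomial, mean 2,
dispersion 0.5 — a synthetic stand-in for a single-molecule imaging count
distribution) and unmarked spots sample from the full distribution, with
marked values scaled so the marked/unmarked mean ratio approximates the
requested fold change.  Null features are spot-permutations of generated
features, so each null's value multiset equals its source's.  Optional
Gaussian noise (sd proportional to the cohort's average per-feature sd,
truncated at zero) is applied before the permutation step.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, SpatialCoordinates, ValidationError

__all__ = [
    "SimulatedDataset",
    "simulate_2d",
    "simulate_3d_continuous",
    "simulate_3d_discrete",
    "apply_dropout",
    "stretch_interplane",
    "simulate_sparse_random",
]

# reference count distribution for the 3D generators
_NB_MEAN = 2.0
_NB_DISPERSION = 0.5
_UPPER_QUANTILE = 0.75
_REFERENCE_POOL = 100_000

PATTERNS_2D = ("hotspot", "streak", "gradient-annulus")
PATTERNS_3D_CONTINUOUS = ("curved_strand", "tissue_layer", "irregular_aggregate")


@dataclasses.dataclass
class SimulatedDataset:
    """Expression + coordinates + ground truth emitted by a simulator."""

    expression: ExpressionMatrix
    coords: SpatialCoordinates
    is_svf: np.ndarray  # per-feature ground-truth label
    pattern_mask: np.ndarray  # per-spot: inside the spatial pattern
    spec: dict  # full parameter record, sufficient to regenerate

    def __post_init__(self) -> None:
        if self.is_svf.shape != (self.expression.n_features,):
            raise ValidationError("is_svf must have one entry per feature")
        if self.pattern_mask.shape != (self.coords.n_spots,):
            raise ValidationError("pattern_mask must have one entry per spot")


def _feature_ids(n_svf: int, n_null: int) -> np.ndarray:
    ids = [f"svf_{i:05d}" for i in range(n_svf)]
    ids += [f"null_{i:05d}" for i in range(n_null)]
    return np.asarray(ids, dtype=object)


def _permuted_nulls(
    svf_matrix: np.ndarray, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """Null features: spot-permutations of generated features (sources drawn
    with replacement when n_null exceeds the SVF count)."""
    n_svf, m = svf_matrix.shape
    sources = rng.integers(0, n_svf, size=n_null)
    nulls = np.empty((n_null, m), dtype=svf_matrix.dtype)
    for i, src in enumerate(sources):
        nulls[i] = svf_matrix[src, rng.permutation(m)]
    return nulls


def _assemble(
    svf_expr: np.ndarray,
    n_null: int,
    positions: np.ndarray,
    mask: np.ndarray,
    spec: dict,
    rng: np.random.Generator,
    noise_sigma: float = 0.0,
) -> SimulatedDataset:
    if noise_sigma > 0:
        sd = float(svf_expr.std(axis=1).mean())
        svf_expr = np.clip(
            svf_expr + rng.normal(0.0, noise_sigma * sd, size=svf_expr.shape), 0.0, None
        )
    nulls = _permuted_nulls(svf_expr, n_null, rng)
    full = np.vstack([svf_expr, nulls])
    n_svf = svf_expr.shape[0]
    expr = ExpressionMatrix(
        values=sp.csr_matrix(full), feature_ids=_feature_ids(n_svf, n_null)
    )
    coords = SpatialCoordinates(
        positions=positions,
        spot_ids=np.asarray([f"spot_{i}" for i in range(len(positions))], dtype=object),
    )
    labels = np.zeros(n_svf + n_null, dtype=bool)
    labels[:n_svf] = True
    return SimulatedDataset(
        expression=expr, coords=coords, is_svf=labels, pattern_mask=mask, spec=spec
    )


# ---------------------------------------------------------------------------
# 2D lattice with log-normal-Poisson counts


def _lattice_2d(n_spots: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_spots)))
    xx, yy = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    pos = np.column_stack([xx.ravel(), yy.ravel()])[:n_spots]
    return pos + rng.uniform(-jitter, jitter, size=pos.shape)


def _mask_2d(pattern: str, positions: np.ndarray) -> np.ndarray:
    lo, hi = positions.min(axis=0), positions.max(axis=0)
    side = float(np.mean(hi - lo))
    center = (lo + hi) / 2.0
    if pattern == "hotspot":
        # off-center disk, ~20% of spots
        c = lo + 0.35 * (hi - lo)
        return np.linalg.norm(positions - c, axis=1) < 0.25 * side
    if pattern == "streak":
        # diagonal band, ~17% of spots
        rel = positions - lo
        return np.abs(rel[:, 0] - rel[:, 1]) < 0.09 * side
    if pattern == "gradient-annulus":
        r = np.linalg.norm(positions - center, axis=1)
        return (r > 0.20 * side) & (r < 0.33 * side)
    raise ValidationError(f"unknown 2D pattern {pattern!r}; choose from {PATTERNS_2D}")


def simulate_2d(
    pattern: str = "hotspot",
    n_spots: int = 260,
    n_svf: int = 1000,
    n_null: int = 9000,
    fc: float = 5.0,
    tau2: float = 0.2,
    beta_base: float = float(np.log(2.0)),
    jitter: float = 0.25,
    seed: int | None = None,
) -> SimulatedDataset:
    """Patterned 2D counts on a jittered lattice.

    ``fc`` is the fold change of mean expression inside vs. outside the
    pattern; ``tau2`` the log-scale dispersion of the spot-level rate.
    """
    if n_spots < 50:
        raise ValidationError("n_spots must be at least 50")
    if fc <= 1:
        raise ValidationError("fold change must exceed 1")
    rng = np.random.default_rng(seed)
    positions = _lattice_2d(n_spots, jitter, rng)
    mask = _mask_2d(pattern, positions)
    if not 0 < mask.sum() < n_spots:
        raise ValidationError(f"pattern {pattern!r} marks no (or all) spots")
    log_lam = beta_base + np.log(fc) * mask[None, :] + rng.normal(
        0.0, np.sqrt(tau2), size=(n_svf, n_spots)
    )
    svf_expr = rng.poisson(np.exp(log_lam)).astype(float)
    spec = dict(
        family="2d", pattern=pattern, n_spots=n_spots, n_svf=n_svf, n_null=n_null,
        fc=fc, tau2=tau2, beta_base=beta_base, jitter=jitter, seed=seed,
    )
    return _assemble(svf_expr, n_null, positions, mask, spec, rng)


# ---------------------------------------------------------------------------
# 3D generators


def _grid_3d(nx: int, ny: int, nz: int) -> np.ndarray:
    """Unit-spaced grid: x, y at half-integer positions, z at 1..nz (one
    serial section per integer depth)."""
    xs = np.arange(nx, dtype=float) + 0.5
    ys = np.arange(ny, dtype=float) + 0.5
    zs = np.arange(1, nz + 1, dtype=float)
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def _reference_pool(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Full and upper-quartile pools of the right-skewed reference counts.

    Dispersion follows the usual genomics convention, alpha in
    var = mu + alpha * mu^2, so the negative-binomial size is 1/alpha.
    """
    r = 1.0 / _NB_DISPERSION
    p = r / (r + _NB_MEAN)
    pool = rng.negative_binomial(r, p, size=_REFERENCE_POOL).astype(float)
    cut = np.quantile(pool, _UPPER_QUANTILE)
    upper = pool[pool >= cut]
    return pool, upper


def _pattern_expression(
    mask: np.ndarray,
    n_svf: int,
    fc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Marked spots sample from the upper quartile of the reference pool,
    unmarked from the full pool; marked values are scaled so the
    marked/unmarked mean ratio approximates ``fc``."""
    pool, upper = _reference_pool(rng)
    m = len(mask)
    expr = pool[rng.integers(0, len(pool), size=(n_svf, m))]
    n_marked = int(mask.sum())
    marked_vals = upper[rng.integers(0, len(upper), size=(n_svf, n_marked))]
    scale = fc * pool.mean() / upper.mean()
    expr[:, mask] = marked_vals * scale
    return expr


def _random_walk_centers(
    pattern: str,
    n_centers: int,
    step: float,
    rng: np.random.Generator,
    box: np.ndarray,
) -> np.ndarray:
    """Sphere centers from a fixed-step random walk.

    Monotonicity selects the pattern class: a curved strand moves
    monotonically along two axes, a tissue layer along one, an irregular
    aggregate along none.
    """
    n_monotone = {"curved_strand": 2, "tissue_layer": 1, "irregular_aggregate": 0}[pattern]
    lo, hi = box[0], box[1]
    start = lo + rng.uniform(0.15, 0.45, size=3) * (hi - lo)
    if n_monotone == 0:
        start = (lo + hi) / 2.0 + rng.uniform(-1, 1, size=3)
    centers = [start]
    for _ in range(n_centers - 1):
        direction = rng.normal(size=3)
        direction[:n_monotone] = np.abs(direction[:n_monotone])  # enforce monotone axes
        direction /= np.linalg.norm(direction)
        centers.append(centers[-1] + step * direction)
    return np.asarray(centers)


def _mark_spheres(
    positions: np.ndarray, centers: np.ndarray, radius: float
) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for c in centers:
        mask |= np.linalg.norm(positions - c, axis=1) < radius
    return mask


def simulate_3d_continuous(
    pattern: str = "curved_strand",
    radius: float = 2.0,
    fc: float = 3.0,
    noise_sigma: float = 0.0,
    n_svf: int = 1000,
    n_null: int = 9000,
    n_centers: int = 8,
    step: float = 2.0,
    seed: int | None = None,
) -> SimulatedDataset:
    """Continuous 3D pattern: spheres along a constrained random walk,
    on 10 serial sections of a 15 x 15 grid (2,250 spots)."""
    if pattern not in PATTERNS_3D_CONTINUOUS:
        raise ValidationError(
            f"unknown 3D pattern {pattern!r}; choose from {PATTERNS_3D_CONTINUOUS}"
        )
    rng = np.random.default_rng(seed)
    positions = _grid_3d(15, 15, 10)
    box = np.array([positions.min(axis=0), positions.max(axis=0)])
    centers = _random_walk_centers(pattern, n_centers, step, rng, box)
    mask = _mark_spheres(positions, centers, radius)
    if mask.sum() == 0:
        raise ValidationError("pattern radius too small: no spot is marked")
    svf_expr = _pattern_expression(mask, n_svf, fc, rng)
    spec = dict(
        family="3d_continuous", pattern=pattern, radius=radius, fc=fc,
        noise_sigma=noise_sigma, n_svf=n_svf, n_null=n_null,
        n_centers=n_centers, step=step, seed=seed,
        centers=centers.tolist(),
    )
    return _assemble(svf_expr, n_null, positions, mask, spec, rng, noise_sigma)


def simulate_3d_discrete(
    radius: float = 2.0,
    fc: float = 3.0,
    noise_sigma: float = 0.0,
    n_svf: int = 1000,
    n_null: int = 9000,
    center_jitter: float = 2.0,
    seed: int | None = None,
) -> SimulatedDataset:
    """Isolated-nodule pattern: 16 spheres spaced 8 units apart at mid-depth,
    on 10 serial sections of a 30 x 30 grid (9,000 spots).

    Center x, y run over {3, 11, 19, 27}, z is fixed at 5.5, and every
    center coordinate is jittered by U(-jitter, jitter).
    """
    rng = np.random.default_rng(seed)
    positions = _grid_3d(30, 30, 10)
    grid = np.arange(3.0, 28.0, 8.0)  # 3, 11, 19, 27
    cx, cy = np.meshgrid(grid, grid)
    centers = np.column_stack([cx.ravel(), cy.ravel(), np.full(16, 5.5)])
    centers = centers + rng.uniform(-center_jitter, center_jitter, size=centers.shape)
    mask = _mark_spheres(positions, centers, radius)
    if mask.sum() == 0:
        raise ValidationError("pattern radius too small: no spot is marked")
    svf_expr = _pattern_expression(mask, n_svf, fc, rng)
    spec = dict(
        family="3d_discrete", radius=radius, fc=fc, noise_sigma=noise_sigma,
        n_svf=n_svf, n_null=n_null, center_jitter=center_jitter, seed=seed,
        centers=centers.tolist(),
    )
    return _assemble(svf_expr, n_null, positions, mask, spec, rng, noise_sigma)


# ---------------------------------------------------------------------------
# perturbations


def apply_dropout(
    data: SimulatedDataset, rate: float, seed: int | None = None
) -> SimulatedDataset:
    """Zero out a random subset of exactly ``floor(rate * M)`` spots across
    all features, emulating capture dropout."""
    if not 0 < rate < 1:
        raise ValidationError(f"dropout rate must be in (0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    m = data.expression.n_spots
    n_drop = int(np.floor(rate * m))
    dropped = rng.choice(m, size=n_drop, replace=False)
    mat = data.expression.values.tolil(copy=True)
    mat[:, dropped] = 0.0
    expr = ExpressionMatrix(
        values=mat.tocsr(), feature_ids=data.expression.feature_ids
    )
    spec = dict(data.spec, dropout_rate=rate, dropout_seed=seed,
                dropped_spots=sorted(int(i) for i in dropped))
    return SimulatedDataset(
        expression=expr, coords=data.coords, is_svf=data.is_svf,
        pattern_mask=data.pattern_mask, spec=spec,
    )


def stretch_interplane(
    coords: SpatialCoordinates, factor: float = 10.0
) -> SpatialCoordinates:
    """Multiply the z coordinate by ``factor``, emulating the reduced
    inter-plane resolution of serially sectioned samples."""
    if coords.n_dims != 3:
        raise ValidationError("inter-plane stretch requires 3-D coordinates")
    pos = coords.positions.copy()
    pos[:, 2] *= factor
    return SpatialCoordinates(
        positions=pos, spot_ids=coords.spot_ids, is_rescaled=coords.is_rescaled
    )


# ---------------------------------------------------------------------------
# unstructured sparse counts for scale testing


def simulate_sparse_random(
    n_features: int,
    n_spots: int,
    density: float,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SpatialCoordinates]:
    """Sparse random counts: each entry non-zero independently with
    probability ``density``; non-zero values are ``floor(1 + 10*Beta(1,5))``
    (integers 1..10).  Coordinates are uniform on a square of unit average
    density, returned unrescaled."""
    if not 0 < density <= 1:
        raise ValidationError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    indptr = np.zeros(n_features + 1, dtype=np.int64)
    cols_all = []
    counts = rng.binomial(n_spots, density, size=n_features)
    for j in range(n_features):
        k = counts[j]
        cols = rng.choice(n_spots, size=k, replace=False) if k else np.empty(0, int)
        cols.sort()
        cols_all.append(cols)
        indptr[j + 1] = indptr[j] + k
    indices = np.concatenate(cols_all) if cols_all else np.empty(0, int)
    values = np.floor(1.0 + 10.0 * rng.beta(1.0, 5.0, size=len(indices)))
    mat = sp.csr_matrix(
        (values, indices, indptr), shape=(n_features, n_spots)
    )
    expr = ExpressionMatrix(
        values=mat,
        feature_ids=np.asarray([f"feat_{j:06d}" for j in range(n_features)], dtype=object),
    )
    side = float(np.sqrt(n_spots))
    positions = rng.uniform(0.0, side, size=(n_spots, 2))
    coords = SpatialCoordinates(
        positions=positions,
        spot_ids=np.asarray([f"spot_{i}" for i in range(n_spots)], dtype=object),
    )
    return expr, coords
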