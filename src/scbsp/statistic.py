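"""The big-small-patch variance-ratio statistic and its null models.

For each feature j the local means of max-abs-scaled expression are taken
over every spot's small patch (radius R1) and big patch (radius R2 > R1).
Writing sigma2[j, k] for the variance across spots of those local means, the
statistic is

    r_j = w_j * sigma2[j, 2] / sigma2[j, 1],

where w_j = var(raw expression of j) / max_n var(raw expression of n)
normalizes by the most variable feature.  A feature whose expression tracks
spatial structure keeps most of its local-mean variance when the patch grows,
so r_j lands in the upper tail; a spatially random feature is averaged away.
The bulk of r over all features is approximated by a lognormal distribution
and each feature receives the one-sided upper-tail p-value.  For panels with
too few features to fit that bulk, an explicit permutation null (features
shuffled across spots) replaces the lognormal fit.

Variances use the population (divide-by-M) convention throughout, including
the log-space standard deviation of the lognormal fit; a single switch flips
every denominator to the sample convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .io import ExpressionMatrix, SpatialCoordinates, SVFResult, ValidationError
from .neighborhoods import (
    PatchAssignment,
    build_spatial_index,
    compute_local_means,
    compute_patch_matrix,
)
from .preprocessing import (
    drop_degenerate_features,
    rescale_coordinates,
    scale_expression_maxabs,
)

__all__ = [
    "NullModel",
    "DegenerateFitError",
    "row_variances",
    "compute_variance_ratio",
    "fit_lognormal_null",
    "compute_pvalues",
    "permutation_null",
    "run_scbsp",
]

MIN_LOGNORMAL_FEATURES = 10
MIN_PERMUTATIONS = 100


class DegenerateFitError(ValueError):
    """The null model cannot be fit (zero spread or too few usable ratios)."""


@dataclasses.dataclass
class NullModel:
    """Fitted null distribution of the variance ratio.

    ``lognormal`` holds the Gaussian parameters of log r; ``permutation``
    holds the sorted empirical null ratios.
    """

    kind: str  # "lognormal" | "permutation"
    mu: float | None = None
    sigma: float | None = None
    null_ratios: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "permutation"):
            raise ValidationError(f"unknown null model kind {self.kind!r}")


def row_variances(mat: sp.spmatrix, denominator: str = "population") -> np.ndarray:
    """Variance of each row of a sparse matrix, zeros included.

    Never densifies: uses E[x^2] - E[x]^2 on the stored values, with the
    divide-by-M (population) or divide-by-(M-1) (sample) convention.
    """
    mat = sp.csr_matrix(mat)
    n, m = mat.shape
    s1 = np.asarray(mat.sum(axis=1)).ravel()
    s2 = np.asarray(mat.multiply(mat).sum(axis=1)).ravel()
    var = s2 / m - (s1 / m) ** 2
    if denominator == "sample":
        if m < 2:
            raise ValidationError("sample variance needs at least 2 spots")
        var *= m / (m - 1)
    elif denominator != "population":
        raise ValidationError(f"unknown variance denominator {denominator!r}")
    return np.maximum(var, 0.0)  # clamp float cancellation noise


def compute_variance_ratio(
    expr_raw: ExpressionMatrix,
    expr_scaled: ExpressionMatrix,
    patches_small: PatchAssignment,
    patches_big: PatchAssignment,
    variance_denominator: str = "population",
    weight_on_scaled: bool = False,
    max_raw_variance: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature (raw variance, weight, ratio, small-patch-degenerate mask).

    The weight defaults to raw-expression variance over the cohort maximum;
    ``weight_on_scaled`` computes it on the scaled matrix instead.
    ``max_raw_variance`` fixes the weight denominator externally (used when
    scoring permuted null draws against the observed cohort).  Features whose
    small-patch local means have zero variance get a True mask entry and a
    ratio of 0 (callers route them to the exclusion list).
    """
    if not np.array_equal(expr_raw.feature_ids, expr_scaled.feature_ids):
        raise ValidationError("raw and scaled matrices carry different features")
    local_small = compute_local_means(expr_scaled, patches_small)
    local_big = compute_local_means(expr_scaled, patches_big)
    var_small = row_variances(local_small, variance_denominator)
    var_big = row_variances(local_big, variance_denominator)
    weight_source = expr_scaled if weight_on_scaled else expr_raw
    sigma2 = row_variances(weight_source.values, variance_denominator)
    denom = max_raw_variance if max_raw_variance is not None else sigma2.max()
    if denom <= 0:
        raise ValidationError("all features have zero variance")
    weight = sigma2 / denom
    degenerate = var_small == 0
    ratio = np.zeros(len(sigma2))
    ok = ~degenerate
    ratio[ok] = weight[ok] * var_big[ok] / var_small[ok]
    raw_var = sigma2 if not weight_on_scaled else row_variances(
        expr_raw.values, variance_denominator
    )
    return raw_var, weight, ratio, degenerate


def fit_lognormal_null(
    ratios: np.ndarray,
    variance_denominator: str = "population",
    trim_top: float = 0.0,
) -> NullModel:
    """Gaussian fit on log ratios: mu = mean(ln r), sigma = sd(ln r).

    Non-positive ratios are dropped before fitting.  ``trim_top`` optionally
    removes the given top fraction of ratios before fitting, a robustness
    guard when strong signal features would otherwise inflate the tail.
    """
    ratios = np.asarray(ratios, dtype=float)
    usable = ratios[ratios > 0]
    if trim_top > 0 and len(usable):
        cut = np.quantile(usable, 1.0 - trim_top)
        usable = usable[usable <= cut]
    if len(usable) < MIN_LOGNORMAL_FEATURES:
        raise DegenerateFitError(
            f"only {len(usable)} positive ratios; need at least "
            f"{MIN_LOGNORMAL_FEATURES} — use the permutation null instead"
        )
    logs = np.log(usable)
    mu = float(logs.mean())
    ddof = 0 if variance_denominator == "population" else 1
    sigma = float(logs.std(ddof=ddof))
    if sigma == 0:
        raise DegenerateFitError(
            "all ratios are identical (zero log spread) — use the "
            "permutation null instead"
        )
    return NullModel(kind="lognormal", mu=mu, sigma=sigma)


def compute_pvalues(ratios: np.ndarray, null: NullModel) -> np.ndarray:
    """One-sided upper-tail p-values for each ratio under the fitted null.

    Lognormal: ``p = 1 - Phi((ln r - mu) / sigma)``.  Permutation:
    add-one empirical tail ``(1 + #{null >= r}) / (1 + n_null)``.
    Non-positive ratios get p = 1.
    """
    ratios = np.asarray(ratios, dtype=float)
    p = np.ones(len(ratios))
    ok = ratios > 0
    if null.kind == "lognormal":
        z = (np.log(ratios[ok]) - null.mu) / null.sigma
        p[ok] = stats.norm.sf(z)
    else:
        null_sorted = np.sort(null.null_ratios)
        n_null = len(null_sorted)
        # count of null ratios >= r via searchsorted on the sorted nulls
        geq = n_null - np.searchsorted(null_sorted, ratios[ok], side="left")
        p[ok] = (1.0 + geq) / (1.0 + n_null)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def permutation_null(
    expr_raw: ExpressionMatrix,
    expr_scaled: ExpressionMatrix,
    patches_small: PatchAssignment,
    patches_big: PatchAssignment,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    variance_denominator: str = "population",
    weight_on_scaled: bool = False,
) -> NullModel:
    """Empirical null from features permuted across spatial locations.

    Draws ``n_perm`` features with replacement, independently shuffles each
    across spots, and records the resulting variance ratios.  Permutation
    preserves each feature's value multiset, hence its raw variance and
    weight; only the spatial arrangement is destroyed.  Degenerate draws
    (zero small-patch variance) are dropped from the null.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValidationError(
            f"n_perm must be at least {MIN_PERMUTATIONS}, got {n_perm}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = expr_scaled.values.shape
    picks = rng.integers(0, n, size=n_perm)
    scaled = expr_scaled.values.tocsr()
    raw = expr_raw.values.tocsr()
    rows_scaled, rows_raw = [], []
    for j in picks:
        perm = rng.permutation(m)
        rows_scaled.append(scaled[[j]][:, perm])
        rows_raw.append(raw[[j]][:, perm])
    ids = np.asarray([f"perm_{i}" for i in range(n_perm)], dtype=object)
    perm_scaled = ExpressionMatrix(values=sp.vstack(rows_scaled).tocsr(), feature_ids=ids)
    perm_raw = ExpressionMatrix(values=sp.vstack(rows_raw).tocsr(), feature_ids=ids)
    weight_source = expr_scaled if weight_on_scaled else expr_raw
    max_var = row_variances(weight_source.values, variance_denominator).max()
    _, _, ratio, degenerate = compute_variance_ratio(
        perm_raw, perm_scaled, patches_small, patches_big,
        variance_denominator=variance_denominator,
        weight_on_scaled=weight_on_scaled,
        max_raw_variance=max_var,
    )
    return NullModel(kind="permutation", null_ratios=np.sort(ratio[~degenerate]))


def run_scbsp(
    expr: ExpressionMatrix,
    coords: SpatialCoordinates,
    r1: float = 1.0,
    r2: float = 3.0,
    null_kind: str = "lognormal",
    n_perm: int = 1000,
    mode: str = "exact",
    recall_target: float = 0.99,
    seed: int | None = None,
    alpha: float = 0.05,
    variance_denominator: str = "population",
    weight_on_scaled: bool = False,
    trim_top: float = 0.0,
    adjust: str = "none",
) -> SVFResult:
    """Run the full pipeline: rescale, scale, patch, ratio, null, p-values.

    Deterministic under the lognormal null; the permutation null is
    reproducible given ``seed``.  Output rows follow input feature order;
    excluded (degenerate) features carry ratio 0 and p-value 1.
    """
    if r1 >= r2:
        raise ValidationError(f"small radius must be below big radius (got {r1} >= {r2})")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if expr.n_spots != coords.n_spots:
        raise ValidationError(
            f"expression has {expr.n_spots} spots but coordinates have {coords.n_spots}"
        )
    if adjust not in ("none", "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")

    rescaled = coords
    if not coords.is_rescaled:
        rescaled, _ = rescale_coordinates(coords)
    retained, excluded_ids = drop_degenerate_features(expr)
    scaled, _ = scale_expression_maxabs(retained)

    index = build_spatial_index(rescaled, mode=mode, recall_target=recall_target)
    patches_small = compute_patch_matrix(index, r1)
    patches_big = compute_patch_matrix(index, r2)

    raw_var, weight, ratio, degen = compute_variance_ratio(
        retained, scaled, patches_small, patches_big,
        variance_denominator=variance_denominator,
        weight_on_scaled=weight_on_scaled,
    )
    usable = ~degen
    if null_kind == "lognormal":
        null = fit_lognormal_null(
            ratio[usable], variance_denominator=variance_denominator,
            trim_top=trim_top,
        )
    elif null_kind == "permutation":
        null = permutation_null(
            retained, scaled, patches_small, patches_big,
            n_perm=n_perm, seed=seed,
            variance_denominator=variance_denominator,
            weight_on_scaled=weight_on_scaled,
        )
    else:
        raise ValidationError(f"unknown null kind {null_kind!r}")

    p_retained = np.ones(retained.n_features)
    p_retained[usable] = compute_pvalues(ratio[usable], null)
    ratio = np.where(degen, 0.0, ratio)

    # reassemble in input feature order, folding the excluded features back in
    n = expr.n_features
    order = {fid: i for i, fid in enumerate(expr.feature_ids)}
    out_raw = np.zeros(n)
    out_weight = np.zeros(n)
    out_ratio = np.zeros(n)
    out_p = np.ones(n)
    out_excl = np.ones(n, dtype=bool)
    idx = np.asarray([order[fid] for fid in retained.feature_ids])
    out_raw[idx] = raw_var
    out_weight[idx] = weight
    out_ratio[idx] = ratio
    out_p[idx] = p_retained
    out_excl[idx] = degen

    q = None
    if adjust == "bh":
        q = _benjamini_hochberg(out_p)
    return SVFResult(
        feature_ids=np.asarray(expr.feature_ids),
        raw_variance=out_raw,
        weight=out_weight,
        ratio=out_ratio,
        p_value=out_p,
        excluded=out_excl,
        alpha=alpha,
        q_value=q,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
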