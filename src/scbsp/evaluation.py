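"""Scoring detector output: power-vs-FDR curves, Jaccard overlap, and
Stouffer meta-combination of p-values across samples.

Power curves use the *realized* false-discovery proportion computed from
known simulation labels, not an estimated FDR: features are ranked by
p-value and, for each target FDR, the reported power is the best
true-positive rate achievable by any p-value cutoff whose realized FDR stays
at or below the target.  Ranking-based evaluation makes detectors with
differently calibrated p-value scales comparable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = ["PowerCurve", "MetaResult", "power_at_fdr", "jaccard_index", "stouffer_combine"]

DEFAULT_FDR_GRID = (0.01, 0.02, 0.05, 0.1, 0.15, 0.2)


@dataclasses.dataclass
class PowerCurve:
    """Power (TPR among true SVFs) achievable at each realized-FDR level."""

    fdr_grid: np.ndarray
    power: np.ndarray
    threshold: np.ndarray  # p-value cutoff achieving each point (NaN if none)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fdr": self.fdr_grid, "power": self.power, "p_threshold": self.threshold}
        )


@dataclasses.dataclass
class MetaResult:
    """Combined one-sided p-values across samples (unweighted Stouffer)."""

    combined_z: np.ndarray
    combined_p: np.ndarray
    per_sample_p: np.ndarray  # k x n matrix of the inputs

    def to_frame(self, feature_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"combined_z": self.combined_z, "combined_p": self.combined_p})
        if feature_ids is not None:
            df.insert(0, "feature_id", np.asarray(feature_ids))
        return df


def power_at_fdr(
    p_values: np.ndarray,
    labels: np.ndarray,
    fdr_grid=DEFAULT_FDR_GRID,
) -> PowerCurve:
    """Best power at each realized-FDR level.

    Features are sorted by p ascending; tied p-values enter or leave the
    discovery set as a block.  At each prefix ending on a tie-group
    boundary, realized FDR = FP / (FP + TP) and power = TP / n_svf; for
    each grid value the maximum power over prefixes with FDR at or below
    it is reported, together with the p cutoff achieving it.
    """
    p_values = np.asarray(p_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if p_values.shape != labels.shape:
        raise ValidationError("p_values and labels must align")
    n_svf = int(labels.sum())
    if n_svf == 0 or n_svf == len(labels):
        raise ValidationError("labels must contain both true SVFs and nulls")

    order = np.argsort(p_values, kind="stable")
    p_sorted = p_values[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    # prefixes must end where the p-value changes (whole tie groups)
    boundary = np.ones(len(p_sorted), dtype=bool)
    boundary[:-1] = p_sorted[:-1] != p_sorted[1:]
    tp, fp, p_cut = tp[boundary], fp[boundary], p_sorted[boundary]
    realized_fdr = fp / (fp + tp)
    power = tp / n_svf

    fdr_grid = np.asarray(fdr_grid, dtype=float)
    out_power = np.zeros(len(fdr_grid))
    out_thr = np.full(len(fdr_grid), np.nan)
    for i, f in enumerate(fdr_grid):
        ok = realized_fdr <= f
        if ok.any():
            best = np.flatnonzero(ok)[np.argmax(power[ok])]
            out_power[i] = power[best]
            out_thr[i] = p_cut[best]
    return PowerCurve(fdr_grid=fdr_grid, power=out_power, threshold=out_thr)


def jaccard_index(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def stouffer_combine(p_values: np.ndarray) -> MetaResult:
    """Unweighted Stouffer combination of one-sided p-values.

    ``p_values`` is a k x n array (k samples, n features).  Each p is
    mapped to z = Phi^{-1}(1 - p); Z = sum(z) / sqrt(k); combined
    p = 1 - Phi(Z).  Exact 0/1 inputs are clipped to the open interval
    with a warning (a reporting floor, not a model statement).
    """
    p = np.atleast_2d(np.asarray(p_values, dtype=float))
    k = p.shape[0]
    if k < 2:
        raise ValidationError("Stouffer combination needs at least 2 samples")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    tiny = np.nextafter(0, 1)
    if np.any((p == 0) | (p == 1)):
        warnings.warn("p-values of exactly 0 or 1 clipped to the open interval",
                      stacklevel=2)
        p = np.clip(p, tiny, 1 - np.finfo(float).eps)
    z = stats.norm.isf(p)  # Phi^{-1}(1 - p)
    combined_z = z.sum(axis=0) / np.sqrt(k)
    combined_p = np.clip(stats.norm.sf(combined_z), tiny, 1.0)
    return MetaResult(combined_z=combined_z, combined_p=combined_p, per_sample_p=p)
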