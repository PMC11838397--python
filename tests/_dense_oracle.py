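"""Independent dense reference implementation of the full detector.

Written deliberately without sparse matrices, KD-trees or any code shared
with the package: plain Python loops over an O(M^2) distance matrix, numpy
means/variances, and an erfc-based normal tail.  Used as the ground truth
the optimized pipeline must reproduce.
"""

import math

import numpy as np


def dense_pipeline(X, coords, r1=1.0, r2=3.0, rescale=True):
    """Run the whole method densely; returns a dict of per-feature arrays
    (raw_variance, weight, ratio, p_value, excluded) in input order."""
    X = np.asarray(X, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, m = X.shape
    d = coords.shape[1]

    if rescale:
        ranges = coords.max(axis=0) - coords.min(axis=0)
        factor = (m / np.prod(ranges)) ** (1.0 / d)
        coords = coords * factor

    constant = np.array([np.all(row == row[0]) for row in X])

    # per-feature max scaling
    Xs = np.array([row / row.max() if row.max() > 0 else row for row in X])

    def patches(radius):
        out = []
        for c in range(m):
            members = [
                i for i in range(m)
                if i != c and math.dist(coords[c], coords[i]) < radius
            ]
            out.append(members if members else [c])
        return out

    small, big = patches(r1), patches(r2)

    def local_variance(feature_scaled, patch_sets):
        means = np.array([feature_scaled[p].mean() for p in patch_sets])
        return means.var()  # population

    raw_var = np.array([X[j].var() for j in range(n)])
    retained = ~constant
    max_var = raw_var[retained].max()

    weight = np.zeros(n)
    ratio = np.zeros(n)
    p_value = np.ones(n)
    excluded = constant.copy()
    for j in range(n):
        if constant[j]:
            raw_var[j] = 0.0
            continue
        weight[j] = raw_var[j] / max_var
        v1 = local_variance(Xs[j], small)
        v2 = local_variance(Xs[j], big)
        if v1 == 0:
            excluded[j] = True
            continue
        ratio[j] = weight[j] * v2 / v1

    usable = retained & ~excluded
    logs = np.log(ratio[usable & (ratio > 0)])
    mu, sigma = logs.mean(), logs.std()
    for j in range(n):
        if usable[j] and ratio[j] > 0:
            z = (math.log(ratio[j]) - mu) / sigma
            p_value[j] = 0.5 * math.erfc(z / math.sqrt(2.0))

    return dict(
        raw_variance=raw_var, weight=weight, ratio=ratio,
        p_value=p_value, excluded=excluded,
    )
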