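# Methods

## Model and assumptions

The detector asks, for every feature, whether its expression field retains
variance when viewed at a coarse spatial granularity. Expression is averaged
over a *small* patch (radius `R1`, default 1 rescaled unit) and a *big*
patch (`R2`, default 3) around every spot; the statistic is the ratio of
the across-spot variances of those local means, weighted by the feature's
relative overall variance:

    r_j = w_j · σ²_{j,big} / σ²_{j,small},   w_j = σ²_j / max_n σ²_n.

No distribution is assumed for the expression values themselves — counts,
normalized intensities and binary accessibility all work — which is why the
method tolerates the extreme sparsity and dropout of high-resolution
platforms. The only distributional step is the null: across a large feature
panel the bulk of `r` is taken to be lognormal, with true SVFs a minority
in the upper tail. When that assumption is untenable (panels of a few
hundred features, heavily curated gene sets), the permutation null replaces
it: features are shuffled across spots, destroying spatial arrangement
while preserving each feature's value multiset, and the empirical upper
tail supplies p-values.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r1`, `r2` | 1.0, 3.0 | patch radii in rescaled units (unit spot density); `r1 < r2` |
| `null_kind` | lognormal | `permutation` recommended below ~1,000 features |
| `n_perm` | 1000 | permutation draws (minimum 100) |
| `mode` | exact | `approximate` enables eps-pruned KD-tree queries with a measured recall ≥ `recall_target` (default 0.99) |
| `alpha` | 0.05 | significance call only; p-values are always reported |
| `variance_denominator` | population | divide-by-M everywhere, including the log-sd of the null fit; one switch flips all denominators to sample form. Ratios σ²_big/σ²_small are invariant; `w_j` and the fitted ŝ are not, so consistency matters more than the choice |
| `weight_on_scaled` | false | compute `w_j` on the max-abs-scaled matrix instead of raw counts |
| `trim_top` | 0.0 | optionally drop the top fraction of ratios before the lognormal fit, a robustness guard when strong signal would inflate the fitted tail |

Coordinate rescaling multiplies all axes by the single scalar
`(M / ∏ Δs(d))^{1/D}`; it is a similarity transform, so distance ratios and
any anisotropy in the raw geometry (e.g. coarse inter-section spacing in
serial-section 3D data) are preserved deliberately.

## Numerical choices and degenerate inputs

* Patch membership uses strict inequality `dist < R`. On exact lattices the
  rescaling formula leaves nearest-neighbor spacing marginally above one
  unit (`w/(w-1)` per axis for a `w`-wide grid), so small patches on grid
  data collapse to the self-fallback and `σ²_{j,small}` equals the
  feature's scaled variance. The pipeline is well-defined and calibrated in
  this regime; irregular (jittered or dissociated-cell) geometries populate
  small patches normally.
* The patch matrix is stored column-wise (`B[i, c] = 1` when spot `i` lies
  in the patch of center `c`), so the local-mean computation is literally
  the sparse product `X̃ · B · diag(1/|patch|)`; nothing is densified, and
  peak memory follows the non-zeros of the operands.
* Features with zero variance across spots (all-zero or constant rows,
  detected exactly, no tolerance) are excluded up front; features whose
  small-patch local means are constant (possible only through discreteness
  artifacts) are excluded at scoring time. Excluded features always appear
  in the output with `ratio = 0`, `p = 1`.
* Row variances use `E[x²] − E[x]²` on sparse data with negative
  cancellation clamped to zero. The lognormal fit is the Gaussian MLE on
  `ln r` over all positive ratios of non-excluded features; a fit with
  fewer than 10 usable ratios or zero spread raises a degenerate-fit error
  that points to the permutation null.
* p-values are clipped into `(0, 1]`; the permutation tail uses the
  add-one estimator `(1 + #{null ≥ r}) / (1 + n_null)`, so no permutation
  p-value is ever 0.
* One seeded generator drives each run; the permutation null consumes it in
  a fixed documented order (feature pick, then permutation, per draw), so
  runs are bit-reproducible.
* No multiple-testing correction is applied by default; `adjust="bh"` adds
  a Benjamini–Hochberg q-value column without changing the p-values.

## Simulators

The generators produce the benchmark families used by the tests and the
acceptance script, each with ground-truth labels and a parameter record
sufficient to regenerate the dataset bit-for-bit.

* **2D lattice** (default 260 spots, the size of a mouse-olfactory-bulb
  array): a jittered square lattice (jitter U(−0.25, 0.25) per axis) with
  three mask shapes — an off-center disk, a diagonal streak, an annulus —
  each marking roughly 15–20% of spots. Counts follow a
  log-normal-Poisson model, `y ~ Poisson(exp(β₀ + ln(FC)·marked + ε))`,
  `ε ~ N(0, τ²)`, `β₀ = ln 2`, so the marked/unmarked mean ratio is exactly
  the fold change FC.
* **3D continuous patterns** (2,250 spots: 10 serial sections of a 15×15
  grid at unit spacing, sections at z = 1…10): the pattern is the union of
  spheres whose centers perform a fixed-step (length 2) random walk; the
  number of monotone axes selects a curved strand (2), a tissue layer (1),
  or an irregular aggregate (0).
* **3D discrete nodules** (9,000 spots: 10 sections of a 30×30 grid):
  16 spheres with centers on the {3, 11, 19, 27}² grid at z = 5.5, each
  coordinate jittered by U(−2, 2).
* In both 3D families, marked spots sample from the upper quartile of a
  right-skewed reference count distribution and unmarked spots from the
  full distribution, with marked values rescaled so the marked/unmarked
  mean ratio approximates FC. The reference is negative binomial with
  mean 2 and dispersion 0.5 (dispersion in the `var = μ + αμ²` sense, so
  variance 4) — a synthetic stand-in for a single-molecule imaging count
  distribution; both parameters are module constants. Optional Gaussian
  noise with sd = σ × (average per-feature sd), truncated at zero, is
  added before null construction.
* **Null features** are spot-permutations of generated features (sources
  drawn with replacement), so every null feature's value multiset equals a
  real feature's and only spatial arrangement distinguishes the classes.
* **Perturbations**: dropout zeroes exactly ⌊rate·M⌋ spots across all
  features; the inter-plane stretch multiplies z by a factor (default 10).
* **Sparse scale generator**: entries are non-zero independently with the
  requested density, values `⌊1 + 10·Beta(1, 5)⌋ ∈ {1,…,10}` — matching the
  sparsity profile of high-definition platforms (~0.04% density) without
  any spatial structure, which also makes it the global-null dataset for
  calibration checks.

What the simulators do *not* emulate: real segmentation noise, spatially
varying capture efficiency, cell-type mixtures, or platform-specific count
distributions. Passing benchmarks here shows the statistic separates
arranged from permuted signal under controlled geometry; it does not certify
performance on any particular real tissue.

## Evaluation

Power curves use the **realized** false-discovery proportion from known
labels: features are ranked by p-value, tie groups enter whole, and the
power reported at an FDR level is the best TPR over all cutoffs whose
realized FDR stays at or below it. This makes methods with differently
calibrated p-value scales comparable, at the cost of requiring ground
truth — it is an evaluation device for simulations, not an error-control
procedure for real data. Cross-sample agreement uses the Jaccard index;
multi-sample evidence is combined with unweighted Stouffer
(`Z = Σ Φ⁻¹(1−p_i)/√k`), with exact-0/1 inputs clipped to the open
interval as a reporting floor.

## Problem sizes

The test suite and acceptance script run the full pipeline at 200
SVF + 1,800 null features on the 9,000-spot 3D geometry, 5,000 features ×
2,000 spots for calibration (10 seeds), and one 20,000 × 50,000 scale run
at density 5·10⁻⁴; the oracle-equivalence check covers 100 random
instances up to 200 spots × 50 features against a dense brute-force
reference written independently of the package.

## Known limitations

* Empty small patches on perfect lattices (see above) mean `R1` carries no
  smoothing there; the statistic then compares big-patch smoothing against
  raw variance, which remains calibrated but is a different contrast than
  on irregular geometries.
* The lognormal null is fitted to all positive ratios, signal included;
  with a large fraction of strong SVFs the fit inflates and p-values become
  conservative (`trim_top` mitigates this).
* Approximate neighbor mode trades boundary-distance neighbors for speed;
  its recall is measured per run against a brute-force sample rather than
  guaranteed analytically.
* Weights `w_j` are computed on raw variance, so features on very different
  scales compete through `w_j`; `weight_on_scaled` removes the scale effect
  at the cost of deviating from the default formulation.
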