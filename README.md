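# scbsp

Detection of **spatially variable features** (SVFs — genes, chromatin peaks,
or any measured feature) in high-resolution 2D and 3D spatial omics data,
using a big–small-patch variance-ratio statistic, together with the
simulators and evaluation tools needed to benchmark it.

It is aimed at people analyzing spatially resolved transcriptomics (Visium,
Stereo-seq, HDST, Xenium, CosMx, serial-section 3D data) or spatial
ATAC-seq, where the expression matrix is large (10⁴–10⁵ features ×
10⁴–10⁵ spots) and extremely sparse, and where a detector must be
distribution-free, fast, and dimension-agnostic.

## The statistic

For a sample with `M` spots and `N` features, coordinates are first
rescaled by the single isotropic factor

```
s̃ = (M / ∏_d Δs(d))^(1/D) · s
```

so the spot density is one spot per unit volume. For each spot a *small*
and a *big* patch are formed — the sets of other spots within radii
`R1 = 1` and `R2 = 3` rescaled units (a spot with an empty patch gets
itself). Expression is max-abs scaled to `[0, 1]` per feature, and the
local mean of each feature over every spot's patch is computed by one
sparse matrix product `X̃ · B(k) · diag(1/|patch|)`. With
`σ²_{j,k} = var_i( x̄_{j,i}(k) )` the variance across spots of those local
means, the score of feature `j` is

```
r_j = w_j · σ²_{j,2} / σ²_{j,1},     w_j = σ²_j / max_n σ²_n
```

where `σ²_j` is the raw-expression variance of feature `j`. Spatially
random features are averaged away as the patch grows, so their `r_j` is
small; features with spatial structure retain local-mean variance at coarse
granularity and land in the upper tail. The bulk of `r` across features is
approximated by a lognormal distribution and each feature gets the
one-sided upper-tail p-value `1 − Φ((ln r_j − μ̂)/ŝ)`. For small feature
panels (where no bulk of null features exists) an explicit permutation null
is provided instead.

Everything runs on sparse matrices and a KD-tree, so a
20,000 × 50,000 matrix at density 5·10⁻⁴ completes in seconds within ~1.5 GB.

## Worked example

```python
import scbsp

# 9,000 spots on 10 serial sections; 16 spherical nodules of radius 2;
# 50 patterned features + 450 spot-permuted null features
data = scbsp.simulate_3d_discrete(radius=2.0, fc=3.0, n_svf=50, n_null=450, seed=7)
result = scbsp.run_scbsp(data.expression, data.coords)

df = result.to_frame().sort_values("p_value")
print(df.head(5).to_string(index=False))
curve = scbsp.power_at_fdr(result.p_value, data.is_svf, [0.05])
print(f"power at realized FDR 0.05: {curve.power[0]:.3f}")
```

prints

```
feature_id  raw_variance  weight   ratio   p_value  excluded
 svf_00019         5.085   0.988 0.04313 0.0004231     False
 svf_00006         4.996  0.9707 0.04264   0.00048     False
 svf_00016         5.031  0.9776 0.04146 0.0006504     False
 svf_00036         5.147       1 0.04142 0.0006575     False
 svf_00009         5.047  0.9806  0.0412 0.0006972     False
power at realized FDR 0.05: 1.000
```

All 50 planted features rank above every null feature: `ratio` is the
variance ratio `r_j`, and `p_value` its upper-tail probability under the
lognormal null fitted to the whole cohort. Exactly the 50 planted features
are significant at α = 0.05.

The same pipeline is available from the shell:

```
scbsp simulate 3d-discrete --radius 2 --fc 3 --seed 7 --outdir sim/
scbsp run sim/expression.mtx sim/coordinates.csv --out results.csv
scbsp evaluate results.csv sim/labels.csv --out power.csv
scbsp meta resultsA.csv resultsB.csv --out combined.csv   # Stouffer across samples
```

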