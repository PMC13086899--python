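# Methods

This note documents the statistical model, the defaults, the synthetic
data generator, and the numerical and design choices behind
`neuroallometry`.

## Phylogenetic covariance

A rooted tree with branch lengths induces, under Brownian motion (BM),
a trait covariance between species i and j equal to the path length
from the root to their most recent common ancestor, and a variance for
species i equal to its root-to-tip depth. `PhyloTree.vcv()` builds this
matrix **C** in one postorder sweep; polytomies need no special
handling and the stem edge of the root, if present, is ignored
(standard comparative-methods convention). Trees are not required to be
ultrametric and are never rescaled. Pruning preserves pairwise path
lengths between retained tips and collapses unifurcations; the
covariance of a pruned tree equals the corresponding submatrix of the
full tree's covariance (tested to 1e-10).

Tip labels are matched across inputs exactly after trimming and
space/underscore unification; mismatches are hard errors naming every
offender. Zero-length terminal branches are allowed with a warning —
they can make **C** singular, which the GLS layer reports as an error
unless a ridge ε > 0 is supplied.

## Volumetric aggregation

Paired neuropils are summed across hemispheres per specimen; species
values are the mean ± SD (n−1 denominator) of the specimens'
raw volumes, logged later for regression (mean-then-log). A
geometric-mean alternative (mean of logs) is available via
`species_aggregate(method="geometric")` for sensitivity analysis. The
reference volume is the per-specimen sum of the six undefined
central-brain regions, averaged per species; relative volumes are
species means divided by the species reference. Species missing a
neuropil are dropped pairwise per analysis, never globally.

## Blomberg's K

With phylogenetic mean â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x,

    MSE0 = (x−â)ᵀ(x−â)/(n−1)
    MSE  = (x−â)ᵀC⁻¹(x−â)/(n−1)
    K    = (MSE0/MSE) / [(tr C − n/(1ᵀC⁻¹1))/(n−1)]

K is invariant to affine trait transforms and equals 1 identically on a
star phylogeny with equal depths (both checked to 1e-10). The
implementation is verified against an independent reference
implementation to 1e-9 and against a direct matrix-inverse evaluation
of the formula to 1e-10.

Two tests accompany K:

* **K = 0** (no signal): one-sided permutation test, shuffling tip
  values across the phylogeny; significance means relatives are more
  similar than random relabelling allows.
* **K = 1** (exactly BM): two-sided test against K computed on traits
  simulated under BM on the same tree (unit rate — K is
  scale-invariant).

Both use the add-one convention p = (1 + #exceedances)/(n_draws + 1) so
p is never exactly 0; defaults are 10,000 draws each. By default the
signal analysis runs on log10 relative volumes; raw or absolute traits
can be passed instead, since the right transform is a genuinely open
choice.

## PGLS, slope index, grade-shift index

The allometric model y = a·x^b is fitted as log y = log a + b·log x by
exact GLS under BM: Cholesky-whiten by **C**, then least squares.
σ̂² uses the n−p denominator (unbiased; an ML n-denominator switch
exists for cross-checks), and R² compares the C-weighted residual sum
of squares against the intercept-only GLS model. No Pagel's λ or other
branch-length transform is estimated: the framework is deliberately
pure-BM. Natural logs are used internally; si and gsi are base-free.

Hypotheses are Wald χ² tests of linear constraints Rβ = r. With a
single constraint this is the squared z statistic; the asymptotic χ²
reference is mildly anticonservative at n = 15 (measured type-I error
≈ 0.06–0.08 at nominal 0.05 in the calibration suite), which is
accepted rather than patched because it matches the standard practice
this pipeline mirrors.

The grade-shift analysis is two-step: fit group-specific intercepts
*and* slopes, test slope equality; only if slopes are indistinguishable
(α = 0.05) refit with a common slope and report gsi = exp(Δ log â) − 1
with its intercept test. Otherwise only the slope difference is
reported and gsi is marked invalid. Analyses are gated on adjusted
R² > 0.6 (the `include` flag); each group must retain ≥ 3 species.
No multiple-testing correction is applied across neuropils, matching
per-neuropil reporting conventions; users can correct downstream.

The leverage screen normalizes absolute whitened residuals to their
sum and flags species above mean + 2 SD (sample SD). The two-factor
robustness model puts both binary factors on intercept and slope
simultaneously; a rank-deficient design (perfectly confounded factors)
is reported as an error, never silently reduced.

## Pairwise slopes and clustering

Every neuropil's log relative volume is PGLS-regressed on every
other's, giving an asymmetric slope matrix with unit diagonal
(noiseless proportional traits give exactly reciprocal slopes, e.g. 2
and 0.5). The symmetrization and distance transform are not uniquely
determined by the analysis this mirrors, so the package defaults are
deliberately simple and exposed as config: association = mean of the
two directed slopes, normalized by the maximum absolute off-diagonal
association into [−1, 1]; distance = 1 − association (0 for perfectly
synchronous pairs, 2 for maximal negative coupling). Cells with fewer
than 4 shared species are imputed by row/column medians with a warning
(or rejected in strict mode). Clustering is agglomerative
(average linkage by default; complete and Ward available), with the
dendrogram exportable as an ultrametric Newick string. The raw
asymmetric slope matrix is always emitted so alternative transforms can
be applied.

## Synthetic-data generator

The generator reproduces the statistical structure the pipeline
assumes, at the study's scale:

* **Tree**: pure-birth, n = 15 species by default, depth normalized to
  1 so BM rates are comparable across sizes.
* **Body size and reference volume**: log wingspan deviation evolves by
  BM and drives the log reference volume with the isometric
  volume-length exponent 3, plus a small BM deviation
  (`ref_resid_sigma2 = 0.02`) off that line; the total BM rate of the
  log reference is `sigma2_bm = 0.5` (tip SD ≈ 0.71 natural-log units,
  a ~16-fold 95% range, consistent with a clade whose brain sizes span
  almost two orders of magnitude). The direction matters: body size
  must drive brain size, not the reverse, otherwise independent noise
  on the predictor attenuates the PGLS slope and no calibration study
  can recover the planted exponent.
* **Neuropils**: ~24 regions mirroring a lepidopteran inventory, each
  with log a and b per ecology group and a BM residual
  (rate 0.03 by default). Defaults plant the effects the analysis is
  meant to detect: visual regions ~1.8× larger in diurnal species, the
  antennal lobe larger in nocturnal ones; fan-shaped body, accessory
  medulla and mushroom-body spur larger in migrants; central-complex
  regions with shallow slopes (0.7–0.8); the gall with genuinely
  different slopes per activity group; one deliberately noisy region
  (the bulb) that fails the R² filter.
* **Individuals**: 2–6 per species (default 3), multiplicative Gaussian
  noise on the raw scale with CV = 0.05, resampled if a draw falls
  at or below zero. Paired neuropils are emitted as left/right halves
  (fraction ≈ N(0.5, 0.02), clipped to [0.3, 0.7]) summing to the
  individual total. The six undefined regions split the reference
  volume by a species-level Dirichlet(10) draw.
* **Ecology**: half the species diurnal, one third (≥ 3) migratory,
  assigned by seeded shuffles independently of the tree.

With these defaults the between-species log-volume spread exceeds the
within-species spread by well over an order of magnitude — the
dataset-level summary is the mean across neuropils of the
between-species log-SD divided by the mean within-species log-SD —
which is the regime in which species means are trustworthy from 2–6
brains. All outputs are bit-reproducible: one master seed spawns
independent streams (tree, ecology, reference, neuropils, noise,
body size) via `numpy.random.SeedSequence`.

What the generator does **not** emulate: reconstruction error that
scales inversely with neuropil size, asymmetric left/right biases,
missing neuropils (absent regions must be injected by the caller),
non-BM trait evolution (e.g. OU attraction), and ecological factors
correlated with phylogeny. Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness
to violations of it.

## Validation studies and problem sizes

The test and acceptance suites run Monte-Carlo studies sized for quick,
stable verdicts: 1,500 BM replicates for the K calibration
(mean K ∈ 1 ± 0.1), 500 datasets for slope unbiasedness (mean ∈ 1 ±
0.05), 200 replicates for grade-shift recovery (planted gsi = 1 within
2 Monte-Carlo SEs) and slope-difference power (1.4 vs 0.8 detected in
≥ 80%), 1,000 replicates for Wald type-I calibration, 500 × 199
permutations for the uniformity of permutation p-values, and 100
replicates for exact two-block clustering recovery at low noise.

## Known limitations

* Pure-BM residuals only; no λ/OU refinements, by design.
* Wald χ² small-sample anticonservatism (above).
* The slope→distance transform is one reasonable choice among several;
  conclusions about cluster boundaries should be checked against the
  emitted raw slope matrix.
* Mean-then-log aggregation introduces a small convexity offset
  (≈ CV²/2) that is uniform across species at the generator's noise
  level and therefore does not bias slopes; the geometric-mean switch
  exists to verify this on real data.
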