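# neuroallometry

Phylogenetically corrected volumetric allometry of insect brain
neuropils.

Comparative neuroanatomy asks how the sizes of individual brain regions
(neuropils) change across species, and whether those changes track
ecology — activity period, migratory behaviour — rather than merely
shared ancestry. Closely related species have similar brains because
they diverged recently, so any cross-species regression must model that
non-independence. This package implements the full statistical pipeline
for such a study on a clade of ~15 species with a handful of measured
brains each: it is aimed at comparative neurobiologists who have a
dated phylogeny, per-specimen neuropil volumes, and a species ecology
table.

## What it computes

Given a rooted tree with branch lengths, trait covariance under
Brownian motion (BM) is proportional to the matrix **C** with
C<sub>ij</sub> = shared root-to-ancestor path length. On top of **C**
the package provides:

* **Phylogenetic signal** — Blomberg's *K* per neuropil, with a
  permutation test of *K* = 0 (no signal) and a BM-simulation test of
  *K* = 1 (exactly Brownian).
* **Allometric scaling** — phylogenetic generalized least squares
  (PGLS) fits of the power law *y = a·x<sup>b</sup>* on the log scale,
  where *x* is a per-species reference volume (the summed "undefined"
  central-brain regions, chosen so no dependent variable contaminates
  the control). The slope index **si = b − 1** measures departure from
  isometry; the grade-shift index **gsi = a₁/a₂ − 1** measures a
  systematic intercept offset between two ecological groups at a
  common slope (and is only reported when the group slopes are
  statistically indistinguishable). Hypotheses on coefficients are
  Wald χ² tests.
* **Scaling clusters** — PGLS slopes for every neuropil pair, turned
  into a signed association and then a distance matrix, clustered
  hierarchically into putative functional units (dendrogram exported
  as Newick).
* **Robustness checks** — intra- vs inter-species variability, a
  leverage screen on normalized residuals (mean + 2 SD cut-off), and a
  two-factor PGLS with both ecological factors on intercept and slope.
* **A synthetic-data generator** that emulates the study's structure
  (ultrametric pure-birth tree, BM reference volume driven by body
  size, group-specific intercepts/slopes, BM residuals, paired
  left/right volumes, within-species noise an order of magnitude below
  between-species spread), so every estimator is testable against
  known ground truth.

## Worked example

```python
import neuroallometry as na

cfg = na.SimulationConfig(seed=11)           # 15 species, 3 brains each
tree, volumes, ecology = na.simulate_dataset(cfg)
rc = na.RunConfig(seed=11, n_perm=999, n_sim=999)
bundle = na.run_pipeline(tree, volumes, ecology, rc)

print(bundle["isometry"][["b", "si", "p_b", "r2_adj", "include"]]
      .loc[["ME", "EB", "PB", "CA"]].round(3))
```

```
              b     si    p_b  r2_adj  include
neuropil
ME        0.659 -0.341  0.466   0.065    False
EB        0.567 -0.433  0.000   0.786     True
PB        0.817 -0.183  0.099   0.793     True
CA        1.026  0.026  0.862   0.761     True
```

The ellipsoid body (EB) was simulated with a genuinely shallow exponent
(*b* = 0.7): the fitted slope is 0.567 with *p* < 0.001 against
isometry, and the fit clears the adjusted-R² > 0.6 inclusion filter.
The calyx (CA) was simulated isometrically and shows si ≈ 0. The
medulla (ME) carries a large activity-period grade shift, which ruins a
single-line fit (R² = 0.065) but is exactly what the grouped analysis
recovers:

```python
print(bundle["gradeshift_activity"][["gsi", "gsi_p", "slopes_differ", "gsi_valid"]]
      .loc[["ME", "AL", "GA"]].round(4))
```

```
             gsi  gsi_p  slopes_differ  gsi_valid
neuropil
ME        0.7630    0.0          False       True
AL       -0.4575    0.0          False       True
GA           NaN    NaN           True      False
```

The medulla is ~76% larger in diurnal species (planted ratio 1.8, i.e.
gsi = 0.8), the antennal lobe is larger in nocturnal species, and the
gall (GA), simulated with genuinely different slopes per group, is
correctly flagged: its slopes differ, so no grade-shift index is
reported. A brain-vs-wingspan regression on the same dataset gives
*b* = 3.27 ± 0.22 (χ² = 1.52, *p* = 0.22 against the volume-vs-length
isometric null *b*₀ = 3), i.e. no detectable departure from isometry —
as simulated.

The same pipeline runs from the shell on delimited text files:

```sh
neuroallometry simulate --n-species 15 --seed 4 --out data/
neuroallometry run-all --tree data/tree.nwk --volumes data/volumes.csv \
    --ecology data/ecology.csv
```

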