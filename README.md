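# copulafc

**Multivariate Gaussian-copula mutual information for functional
connectivity**, with the evaluation machinery to compare it against the
standard estimators: a two-region interaction simulator, permutation-null
significance testing, and graph-level network analyses.

## The problem

Functional connectivity (FC) is the statistical dependence between the
temporal activity of two brain regions, each observed as a voxels ×
timepoints matrix. The workhorse estimator — the absolute Pearson
correlation between the regions' voxel-average series (PCor) — misses two
things: nonlinear dependence, and everything the multivoxel *pattern*
carries that the average does not (anticorrelated voxel populations cancel
in the mean).

`copulafc` implements the rank-based alternative: transform each series to
a standard-normal marginal through its empirical CDF
(z = Φ⁻¹(rank/(n+1))), fit a Gaussian to the resulting copula, and read MI
off the closed form

&nbsp;&nbsp;&nbsp;&nbsp;MI(X, Y) = ½ log₂( |Σ_X| |Σ_Y| / |Σ_XY| ) &nbsp; [bits],

a lower bound on the true MI that is exactly invariant under monotone
distortions of each input dimension. Because the copula form accepts
multidimensional blocks, each region can contribute its top-5 PCA score
series instead of a single average — the **mvMI** measure. Four measures
are provided on a common [0, 1] scale (MI values mapped through
r = √(1 − 2^(−2·MI))):

- `pcor` — |Pearson r| between voxel averages;
- `svd_fc` — |Pearson r| between first temporal singular vectors;
- `uv_mi` — rescaled copula MI between voxel averages;
- `mv_mi` — rescaled copula MI between the two regions' 5-component PCA
  score blocks.

Around the estimators: a simulator of two-region interactions (linear,
squared, dense multivariate, shared structural noise — each under three
within-region homogeneity regimes), permutation nulls with a
95th-percentile significance rule, and whole-matrix analyses
(within/between-network partitioning, rank-correlation similarity of
measures, fraction-of-maximum thresholding, spectral edge-nonrandomness,
between-subject similarity) plus a synthetic multi-subject cohort
generator so every stage runs with no external data.

## Worked example

```python
import numpy as np
from copulafc import ScenarioSpec, simulate_pair, pcor, svd_fc, uv_mi, mv_mi

# two regions (100 and 150 voxels, 500 timepoints) with a linear one-to-one
# voxel interaction; half of region X's voxels anticorrelated with the other half
pair = simulate_pair(ScenarioSpec(scenario="linear", regime="mixed", seed=7))
x, y = pair.region_x, pair.region_y
print(f"pcor  {pcor(x, y):.3f}   uv_mi {uv_mi(x, y):.3f}")
print(f"svd   {svd_fc(x, y):.3f}   mv_mi {mv_mi(x, y):.3f}")
```

prints

```
pcor  0.234   uv_mi 0.237
svd   0.997   mv_mi 0.997
```

The interaction is strong, but averaging cancels the anticorrelated voxel
blocks, so the average-based measures (left column) collapse toward their
noise floor while the pattern-based measures (right column) stay near 1.
Significance of a single connection against its voxel-shuffled permutation
null:

```python
from copulafc import build_null, performance
null = build_null(x, y, "mvmi", n_perm=100, seed=0)
verdict = performance(mv_mi(x, y), null)
print(verdict.performance, verdict.significant)   # 0.73…, True
```

The `examples/` directory walks through each capability (copula MI basics,
the four measures, permutation significance, the scenario benchmark, and
the cohort-level graph analyses); each script prints its numbers with a
line on what they mean. A thin CLI mirrors the pipeline stages:

```bash
copulafc simulate --scenario linear --regime mixed --reps 3 --seed 1 --out sim/
copulafc cohort --subjects 8 --nonlinear --seed 1 --out cohort/
copulafc fc --manifest cohort/manifest.tsv --measure mvmi --out fc/
copulafc bench --scenario structural_noise --reps 10 --seed 1 --out bench.tsv
copulafc analyze --cohort-dir cohort/ --out results/
```

All inputs and outputs are delimited text (one region = one TSV matrix,
plus a manifest); every stage writes a provenance file carrying the full
parameter echo and a config hash, and all randomness is seed-derived, so
reruns are byte-identical.

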