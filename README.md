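# bach3d

Bayesian reconstruction of 3D chromatin structure — and of structural
variation — from Hi-C contact matrices, for computational biologists
studying genome organization at the topological-domain scale.

## What it does

A genomic region is modelled as beads on a string: locus *i* sits at
coordinates *p<sub>i</sub>*, and the Hi-C read count between loci *i*
and *j* is Poisson with

```
ln λ_ij = β0 + β_d ln d_ij + β_e ln(x_i x_j) + β_g ln(g_i g_j) + β_m ln(m_i m_j)
```

where *d<sub>ij</sub>* is the Euclidean distance between the beads and
*x*, *g*, *m* are each locus's restriction fragment-end count, GC
content and mappability — the known systematic biases of Hi-C.  On top
of this likelihood the package provides:

- **Consensus-structure inference** (`run_bach`): Poisson-regression
  initialization, sequential importance sampling of an initial
  structure, and Gibbs refinement with hybrid Monte Carlo for the
  coordinates and slice sampling for the nuisance parameters; posterior
  mode, per-pair distance posteriors with credible intervals,
  Gelman–Rubin diagnostics, AIC.
- **Structural-variation inference** (`run_bach_mix`): the spatial
  arrangement of two adjacent sub-regions is a mixture over discretized
  Euler rotations and mirror reflections; multinomial proportions are
  inferred jointly with the nuisance parameters, insignificant
  arrangements (< 1%) are pruned and the model refitted, and the result
  is compared with the single-consensus model by AIC.
- **Geometry statistics**: cylinder height-to-diameter (HD) ratio from
  a PCA fit, scale- and rigid-motion-invariant normalized RMSD
  superposition (SVD), sliding-window local alignment, and a Fisher
  exact test of spatial separation across a fitted plane.
- **Two-step dominance test** (`two_step_procedure`): fit, subtract half
  of the expected contact matrix, refit; if the two modes superpose
  within the lower 5% tail of a random-walk RMSD reference, the region
  has a dominant population structure.
- **Synthetic data** (`bach3d.simulate`): bias-covariate-modulated,
  distance-decaying Poisson contact matrices over random-walk, helix or
  line backbones, including arrangement mixtures — the test bed for
  every inference module.

See `docs/methods.md` for the model, algorithmic choices, and known
limitations.

## Worked example

```python
import numpy as np
from bach3d import (SamplerConfig, SimScenario, pairwise_distances,
                    run_bach, simulate_single_population)

# a 1 Mb domain at 40 kb resolution: 25 loci, mean pair count 50
scenario = SimScenario(n_loci=25, seed=3, mean_count=50.0)
cm, truth = simulate_single_population(scenario)

cfg = SamplerConfig(n_chains=3, n_iter=3000, burn_in=1000, thin=20, seed=11)
fit = run_bach(cm, truth.features, cfg)

iu = np.triu_indices(25, k=1)
r = np.corrcoef(pairwise_distances(truth.structure)[iu],
                fit.distance_mean[iu])[0, 1]
print(f"converged={fit.converged}  gelman_rubin={fit.gelman_rubin:.3f}")
print(f"pearson r (true vs posterior-mean distances) = {r:.3f}")
print(f"decay exponent beta_d = {fit.mode_params.beta_d:.2f}")
```

Output:

```
converged=True  gelman_rubin=1.011
pearson r (true vs posterior-mean distances) = 0.994
decay exponent beta_d = -1.00
```

The Gelman–Rubin factor below 1.1 says the three chains mixed; the
correlation of 0.99 says the relative geometry of the domain was
recovered (the absolute scale is not identifiable and is compared after
one global rescaling); the fitted decay exponent matches the generating
value of −1.

The same models drive the `bach3d` command line:
`bach3d simulate`, `bach3d fit`, `bach3d mix`, `bach3d geom`,
`bach3d twostep`, `bach3d pipeline`.

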