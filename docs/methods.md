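# Methods

## The model

A genomic region is divided into N consecutive, equally sized loci; locus
i is a bead at Cartesian position p_i.  The Hi-C contact count n_ij
between loci i and j (off-diagonal, each unordered pair counted once) is
modelled as Poisson with log-rate

    ln λ_ij = β0 + β_d ln d_ij + β_e ln(x_i x_j) + β_g ln(g_i g_j) + β_m ln(m_i m_j)

where d_ij = ‖p_i − p_j‖ and x, g, m are the per-locus restriction
fragment-end count, GC content, and mappability.  β_d < 0 encodes the
decay of contact frequency with spatial distance; the three bias
coefficients implement the standard multiplicative Hi-C bias model
(enzyme, GC, mappability effects).  Setting `bias_terms=False` gives the
uncorrected variant.  Priors are non-informative (flat); β_d is softly
constrained negative by rejecting non-negative values in its conditional
update (`enforce_negative_decay`, default on).

### Gauge freedom

The likelihood is invariant under translation, rotation and reflection of
the structure, and a global rescaling of coordinates trades off exactly
against β0.  None of these gauges is fixed in the sampler.  Consequences
handled downstream:

- Distance posterior summaries rescale every retained sample to the
  posterior-mean overall scale before averaging, so credible intervals
  describe shape, not the unidentifiable scale.  Comparisons against an
  external standard (a known truth, FISH-style distances) require one
  global scale adjustment, done by regression.
- Structure comparisons go through the scale- and rigid-motion-invariant
  normalized RMSD (below).  Reflection is *not* absorbed by the
  alignment; chirality is a modelling statement carried by the mirror
  index of the arrangement mixture.
- When two separately fitted sub-structures are composed (arrangement
  mixture), each is first normalized to unit mean bond length, because
  their *relative* scale is not absorbable by the rate parameters.

## Three-stage inference (consensus fit)

1. **Poisson regression start.**  A GLM of n_ij on ln|i−j| (genomic
   distance as a proxy for log spatial distance) and the pairwise log
   bias covariates initializes the five nuisance parameters.  A
   non-convergent GLM falls back to (ln mean count, −1, 0, 0, 0).
2. **Sequential importance sampling.**  Structures grow bead by bead.
   Each of `sis_particles` (default 100) partial structures proposes
   `sis_enrich` (default 10) isotropic candidate positions around the
   chain end at the scale implied by the decay fit; one candidate is kept
   with probability proportional to the partial likelihood of the new
   bead's contacts, the particle weight absorbs the candidate-averaged
   likelihood, and particles are resampled when the effective sample size
   halves (rejection control).  The highest-weight completed structure
   initializes each chain.
3. **Gibbs refinement.**  Per sweep: one hybrid Monte Carlo trajectory
   updates all coordinates jointly (leapfrog, default 10 steps, step size
   auto-tuned during burn-in toward 60–90% acceptance), then each
   nuisance parameter is redrawn from its univariate log-concave
   conditional by slice sampling — the stationary law an adaptive
   rejection sampler would target, chosen for robustness over sampler
   mechanics.

Defaults mirror the reference setting: 3 chains × 5000 sweeps, 1000
burn-in, every 50th retained.  Convergence is monitored with the
Gelman–Rubin factor on the log-likelihood traces (< 1.1 declared
converged; the factor is clamped at 1 from below).

**Posterior mode.**  The reported structure is the retained sample of
highest log-likelihood, sharpened by a local L-BFGS maximization of the
coordinate likelihood at that sample's parameters (`polish_mode`).  Each
chain's best sample is polished and the global winner kept, because
chains may land in different folding basins whose unpolished
log-likelihoods overlap.  Reflected (mirror-image) modes are equally
likely by symmetry.

## Arrangement mixture of two adjacent regions

Both sub-regions keep fixed consensus structures (their BACH modes); the
population varies in how region B sits relative to region A.  An
arrangement is M(s)·R(α, β, γ) with R the Z-Y-Z Euler rotation,
M = diag(1, 1, s), s ∈ {+1, −1} the mirror index.  Region B is anchored
with its first bead one mean bond length beyond region A's last bead
along the chain-end tangent, and transformed about that anchor — the
anchoring convention preserves chain adjacency and is this package's
choice.  The inter-region count n_ij is Poisson with rate
Σ_k π_k exp(β0 + β_d ln d_ijk + bias terms), d_ijk the cross distance
under arrangement k.

Inference details that matter:

- **Proportions** live on the softmax scale (last logit pinned).  The
  prior on π is uniform on the simplex; in logit space this contributes
  the log-Jacobian Σ_k ln π_k, without which the posterior over a null
  component's logit is improper.
- **Initialization** is a multi-start alternating MAP: for fixed
  nuisance parameters the cross log-likelihood is concave in π, so the
  proportion step solves a well-posed problem; alternating with a
  nuisance step (nuisance first when a restart favors one component) and
  a joint polish, over restarts that favor each candidate in turn,
  reliably finds the sparse optimum that flat starts miss.
- **Sampling** uses HMC with a diagonal mass matrix from the
  finite-difference Hessian at the MAP; without preconditioning the step
  size collapses to the intercept's curvature scale and the logits never
  mix.
- **Sparsification** follows the two-step rule: components below the 1%
  threshold are removed and the reduced model refitted, iterated to a
  fixed point.  The prune decision uses the maximum-likelihood
  proportions (the posterior mean of a boundary component has a
  positivity floor of a few percent that never clears a 1% rule at
  moderate depth).  A subsequent backward elimination removes any
  component whose deletion costs less than the BIC penalty
  0.5·ln(number of pairs) in log-likelihood — such a component absorbs
  Poisson noise, not population structure.
- **Candidates.**  The default grid discretizes each Euler angle into
  four bins crossed with both mirrors (≤128 after merging coinciding
  matrices).  Because separately fitted sub-structures carry arbitrary
  rotation/mirror gauges, the arrangement relating them is generally off
  any fixed grid; when no candidate list is supplied, the package first
  fits the best one and two *continuous* arrangements by direct
  likelihood maximization over the Euler angles (matching pursuit, both
  mirrors, multi-start) and adds a well-separated subset of the grid.
  `select_separated_arrangements` picks grid candidates by greedy
  farthest-point selection on their cross-distance patterns, since
  matrix-distinct arrangements can be near-aliased in distance space
  (for an elongated region B the cross distances depend mostly on the
  image of its long axis).

Effective structures are components with proportion above 5% (strictly);
the count is non-increasing in the threshold by construction.

**Model comparison.**  AIC = 2k − 2·loglik with k = 3N + 5 for the
consensus model and k = 3N_A + 3N_B + 5 + (K−1) for the mixture (gauge
degrees of freedom appear in both counts and cancel in the comparison).
The mixture's log-likelihood totals the two intra-region fits plus the
cross-block mixture fit.

## Geometry statistics

- **HD ratio.**  Center, rotate to principal axes; height = 10–90%
  inter-quantile range of the first-axis coordinates; radius = 2 × median
  radial distance in the PC2–PC3 plane; raw ratio = height / diameter;
  normalized by N / n_ref (default n_ref = 25 loci ≈ 1 Mb at 40 kb).
  The size normalization by N/n_ref is this package's reading of
  "normalized by region size"; it is configurable.
- **Normalized RMSD.**  The scale between two structures is reported as
  the slope of a through-origin regression of pairwise distances.  For
  the RMSD itself both centered structures are normalized to unit radius
  of gyration — a symmetric normalization, so rmsd(a,b) = rmsd(b,a)
  exactly — and the optimal proper rotation comes from the SVD of the
  cross-covariance (negative-determinant solutions corrected).
  Interpretation thresholds: < 0.1 high similarity, 0.1–0.2 moderate,
  > 0.2 low.
- **Sliding window.**  K-bead structures scanned with a 10-unit window
  give exactly K − 9 local RMSDs.
- **Plane separation.**  A total-least-squares plane through the
  mid-group points (normal = smallest principal component); low/high
  points classified by side; two-sided Fisher exact test on the 2×2
  table; Haldane-corrected odds ratio when a cell is zero.

## Two-step dominant-structure test

Fit the region (s1 = posterior mode), subtract **half** of the expected
matrix implied by s1 from the counts (clamped at zero and rounded so the
residual is again a valid count matrix), refit (s2), and compare
RMSD(s1, s2) with the empirical RMSD distribution of independent
random-walk pairs of the same length (default 1000 draws; the reference
is essentially independent of chain length).  A dominant structure is
declared when the observed RMSD falls in the lower 5% tail.  Both fits
launch chains from diverse random-walk starts (default 10 chains here)
so that a mixed population can express distinct posterior modes.

## Synthetic data

The generator draws unit-bond backbones (free ideal chain; helix, which
has analytic cylinder geometry; straight line, for which the
genomic-distance GLM proxy is exact), covariates resembling 40 kb bins
(fragment ends log-normal ≥ 6, GC uniform on 0.35–0.65, mappability
uniform on 0.85–1.0 — all above the default quality filters by
construction), and Poisson counts from the model above.  Depth is set
through the intercept via a target mean off-diagonal count
(`beta0_for_depth`), the single difficulty knob.  Default parameters:
β_d = −1 (the shallow end of the physically plausible range; steeper
values starve distal pairs of counts at moderate depth), bias
coefficients (0.3, 0.5, 0.8), mean count 50.  Mixtures are generated
either as arrangement mixtures of two sub-regions (cross block) or as
whole-region rate mixtures of several backbones.

What the generator does **not** emulate: ligation artifacts, copy-number
variation, unmappable gaps, domain-boundary insulation beyond distance
decay, and read-level noise.  Passing recovery tests therefore show the
inference is correct *under its own model*, not that the model captures
every feature of real Hi-C libraries.

## Problem sizes and test-bed choices

Recovery tests run at the reference scale for a topological domain
(~25 loci ≈ 1 Mb at 40 kb) with mean off-diagonal counts of a few tens
to a few hundreds, and sampler settings scaled to a few thousand sweeps
over 2–3 chains — enough for the Gelman–Rubin factor to clear 1.1 on
these sizes.  The arrangement-recovery design uses two 13-locus regions
(the reference benchmark size for the mixture algorithm) with 12
well-separated candidates and deep cross counts.  The GLM-recovery test
uses a straight-line backbone, where the genomic-distance proxy is
exact, at depth high enough that regression error is dominated by
identifiability, not noise.

## Known limitations

- At desk scale (N ≈ 20–40 loci) a single consensus structure often
  approximates a 50/50 two-structure mixture surprisingly well: the
  best-fit "compromise" embedding can beat both pure components in
  likelihood.  The AIC comparison and the two-step test therefore
  discriminate mixtures from consensus populations only weakly at these
  sizes; discrimination strengthens with region length, where the
  compromise embedding runs out of geometric freedom.
- The mixture model fixes the sub-region structures at their consensus
  modes; their residual estimation error enters the cross-block
  likelihood multiplied by the cross depth, which can dominate the
  comparison against a free-form consensus fit.
- Reflected modes are unavoidable (the likelihood cannot distinguish a
  structure from its mirror image); comparisons against a reference
  structure should consider both chiralities unless external information
  fixes one.
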