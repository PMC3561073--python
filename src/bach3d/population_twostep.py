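"""Two-step test for a dominant population structure.

A consensus fit to a mixed cell population tends to track the most
abundant conformation.  The test exploits this: fit once, subtract half
of the expected contact matrix implied by the fitted structure, and fit
again on the residual counts.  If one conformation dominates, both fits
see essentially the same signal and the two mode structures superpose
closely; if the population is an even mixture, the residual is dominated
by a different conformation and the two fits diverge.  "Closely" is
calibrated against the RMSD distribution of independent random-walk
structure pairs of the same length: the structure is called dominant when
the observed RMSD falls within the lower 5% tail of that reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bach_sampler import BachFit, SamplerConfig, run_bach
from .contact_data import ContactMatrix, LocusFeatures
from .geometry import optimal_superposition
from .poisson_model import ModelParams, Structure3D, poisson_rates

__all__ = [
    "TwoStepResult",
    "ReferenceDistribution",
    "expected_matrix",
    "residual_matrix",
    "random_walk",
    "rmsd_reference",
    "two_step_procedure",
]


@dataclass
class TwoStepResult:
    s1: Structure3D
    s2: Structure3D
    rmsd: float
    tail_probability: float
    dominant: bool
    converged: bool
    fit1: BachFit
    fit2: BachFit


@dataclass
class ReferenceDistribution:
    """Empirical RMSD distribution between independent random-walk pairs."""

    draws: np.ndarray
    n_loci: int

    def __post_init__(self) -> None:
        self.draws = np.sort(np.asarray(self.draws, dtype=float))
        if np.any(self.draws < 0):
            raise ValueError("negative RMSD draw")

    def tail_probability(self, observed: float) -> float:
        """Fraction of reference draws at or below the observed RMSD."""
        return float(np.searchsorted(self.draws, observed, side="right")
                     / len(self.draws))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.draws, q))


def expected_matrix(s: Structure3D, lf: LocusFeatures,
                    p: ModelParams, bias_terms: bool = True) -> np.ndarray:
    """Expected Hi-C contact matrix implied by a fitted structure."""
    return poisson_rates(s, lf, p, bias_terms=bias_terms)


def residual_matrix(cm: ContactMatrix, expected: np.ndarray) -> ContactMatrix:
    """Counts minus half of the expected matrix, clamped at zero and
    rounded so the result is again a valid count matrix."""
    if expected.shape != cm.counts.shape:
        raise ValueError("expected matrix shape mismatch")
    resid = np.rint(np.maximum(0.0, cm.counts - expected / 2.0)).astype(np.int64)
    np.fill_diagonal(resid, cm.counts.diagonal())
    return ContactMatrix(cm.bins, resid)


def random_walk(n_steps: int, step_len: float = 1.0,
                seed: int | np.random.Generator = 0) -> Structure3D:
    """Free ideal chain: isotropic uniform step directions, fixed length."""
    if n_steps < 2:
        raise ValueError("need at least 2 beads")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    steps = rng.normal(size=(n_steps - 1, 3))
    steps *= step_len / np.linalg.norm(steps, axis=1)[:, None]
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Structure3D(coords)


def rmsd_reference(n_loci: int, n_reps: int = 1000,
                   seed: int = 0) -> ReferenceDistribution:
    """Normalized RMSDs between ``n_reps`` independent random-walk pairs."""
    if n_reps < 100:
        raise ValueError("need at least 100 reference draws")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_reps)
    for r in range(n_reps):
        a = random_walk(n_loci, seed=rng)
        b = random_walk(n_loci, seed=rng)
        draws[r] = optimal_superposition(a, b).rmsd
    return ReferenceDistribution(draws=draws, n_loci=n_loci)


def two_step_procedure(cm: ContactMatrix, lf: LocusFeatures,
                       cfg: SamplerConfig = SamplerConfig(),
                       n_reps: int = 1000,
                       reference: ReferenceDistribution | None = None,
                       alpha: float = 0.05) -> TwoStepResult:
    """Fit, subtract half the expected matrix, refit, and test dominance.

    ``reference`` may be supplied to reuse a precomputed random-walk RMSD
    distribution (it must match the filtered locus count).  The dominance
    call uses the lower-``alpha`` rule on the tail probability.
    """
    # both fits launch chains from a variety of random-walk structures so
    # that, when the population is mixed, independent chains can land in
    # distinct posterior modes and the best mode wins
    cfg1 = SamplerConfig(**{**cfg.__dict__, "init_strategy": "random"})
    fit1 = run_bach(cm, lf, cfg1)
    exp1 = expected_matrix(fit1.mode_structure, lf, fit1.mode_params,
                           bias_terms=cfg.bias_terms)
    resid = residual_matrix(cm, exp1)
    cfg2 = SamplerConfig(**{**cfg1.__dict__, "seed": cfg.seed + 104729})
    fit2 = run_bach(resid, lf, cfg2)
    rmsd = optimal_superposition(fit1.mode_structure,
                                 fit2.mode_structure).rmsd
    if reference is None:
        reference = rmsd_reference(cm.n_loci, n_reps=n_reps,
                                   seed=cfg.seed + 65537)
    elif reference.n_loci != cm.n_loci:
        raise ValueError("reference distribution length mismatch")
    tail = reference.tail_probability(rmsd)
    return TwoStepResult(s1=fit1.mode_structure, s2=fit2.mode_structure,
                         rmsd=rmsd, tail_probability=tail,
                         dominant=bool(tail < alpha),
                         converged=fit1.converged and fit2.converged,
                         fit1=fit1, fit2=fit2)
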