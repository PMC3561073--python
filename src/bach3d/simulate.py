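"""Synthetic Hi-C data under the model's own generative assumptions.

The factory draws a polymer backbone (random walk, helix, or straight
line), per-locus bias covariates whose marginals resemble real 40 kb bins
(and which always clear the default quality filters), and Poisson contact
counts from the bias-modulated, distance-decaying rate model — for a
single consensus structure, for a whole-population mixture of backbones,
or for a mixture of arrangements of two sub-regions.  Every generator is
a pure function of its seed.

Sequencing depth is controlled through the intercept: ``beta0_for_depth``
solves for the intercept giving a target mean off-diagonal count, so
difficulty is a single knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bach_mix import Arrangement, place_region_b
from .contact_data import ContactMatrix, GenomicBin, LocusFeatures
from .poisson_model import ModelParams, Structure3D, covariate_terms, poisson_rates
from .population_twostep import random_walk

__all__ = [
    "SimScenario",
    "simulate_features",
    "make_backbone",
    "make_bins",
    "beta0_for_depth",
    "simulate_single_population",
    "simulate_two_region",
    "simulate_population_mixture",
    "simulate_mixture_population",
]

DEFAULT_PARAMS = ModelParams(beta0=3.0, beta_d=-1.0, beta_e=0.3,
                             beta_g=0.5, beta_m=0.8)


@dataclass
class SimScenario:
    """One simulation design: backbone, model parameters, optional mixture."""

    n_loci: int
    backbone: str = "random_walk"        # random_walk | helix | line
    params: ModelParams = field(default_factory=lambda: DEFAULT_PARAMS)
    mean_count: float | None = 50.0      # overrides params.beta0 when set
    mixture_arrangements: list[Arrangement] | None = None
    mixture_proportions: np.ndarray | None = None
    split_at: int | None = None          # region A size for cross simulations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 3:
            raise ValueError("need at least 3 loci")
        if self.mixture_proportions is not None:
            p = np.asarray(self.mixture_proportions, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("mixture proportions must sum to 1")
            self.mixture_proportions = p


@dataclass
class SimTruth:
    """Everything the generator knew: for oracle comparisons in tests."""

    structure: Structure3D
    params: ModelParams
    rates: np.ndarray
    features: LocusFeatures
    bins: list[GenomicBin]
    extra: dict = field(default_factory=dict)


def simulate_features(n_loci: int, seed: int | np.random.Generator = 0,
                      ) -> LocusFeatures:
    """Per-locus covariates that always pass the default quality filters:
    fragment ends > 5 (log-normal, rounded), GC in (0.35, 0.65),
    mappability in (0.85, 1.0]."""
    if n_loci < 3:
        raise ValueError("need at least 3 loci")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    frag = 6 + np.rint(np.exp(rng.normal(np.log(40.0), 0.35, n_loci)))
    gc = rng.uniform(0.35, 0.65, n_loci)
    mapp = rng.uniform(0.85, 1.0, n_loci)
    return LocusFeatures(frag, gc, mapp)


def make_backbone(kind: str, n_loci: int,
                  rng: np.random.Generator) -> Structure3D:
    """Polymer backbone with unit bond length."""
    if kind == "random_walk":
        return random_walk(n_loci, step_len=1.0, seed=rng)
    if kind == "line":
        coords = np.zeros((n_loci, 3))
        coords[:, 0] = np.arange(n_loci)
        return Structure3D(coords)
    if kind == "helix":
        # unit-pitch-adjusted helix with unit bond length, radius 1
        turns = n_loci / 10.0
        t = np.linspace(0, 2 * np.pi * turns, n_loci)
        xy = np.column_stack([np.cos(t), np.sin(t)])
        dz = np.sqrt(max(1e-6, 1.0 - (2 * np.sin((t[1] - t[0]) / 2)) ** 2))
        coords = np.column_stack([xy, dz * np.arange(n_loci)])
        return Structure3D(coords)
    raise ValueError(f"unknown backbone kind {kind!r}")


def make_bins(n_loci: int, chrom: str = "chrSim",
              bin_size: int = 40_000) -> list[GenomicBin]:
    return [GenomicBin(chrom, i * bin_size, (i + 1) * bin_size)
            for i in range(n_loci)]


def beta0_for_depth(mean_count: float, structure: Structure3D,
                    lf: LocusFeatures, p: ModelParams) -> float:
    """Intercept giving the requested mean off-diagonal count."""
    trial = ModelParams(0.0, p.beta_d, p.beta_e, p.beta_g, p.beta_m)
    lam = poisson_rates(structure, lf, trial)
    iu = np.triu_indices(structure.n_loci, k=1)
    return float(np.log(mean_count) - np.log(lam[iu].mean()))


def _draw_counts(rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson per unordered pair, mirrored; zero diagonal."""
    n = rates.shape[0]
    iu = np.triu_indices(n, k=1)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu] = rng.poisson(rates[iu])
    return counts + counts.T


def _resolve_params(scenario: SimScenario, structure: Structure3D,
                    lf: LocusFeatures) -> ModelParams:
    p = scenario.params
    if scenario.mean_count is not None:
        b0 = beta0_for_depth(scenario.mean_count, structure, lf, p)
        p = ModelParams(b0, p.beta_d, p.beta_e, p.beta_g, p.beta_m)
    return p


def simulate_single_population(scenario: SimScenario,
                               ) -> tuple[ContactMatrix, SimTruth]:
    """Counts from one consensus structure under the Poisson rate model."""
    if scenario.mixture_arrangements is not None:
        raise ValueError("scenario carries a mixture; use the mixture generator")
    rng = np.random.default_rng(scenario.seed)
    structure = make_backbone(scenario.backbone, scenario.n_loci, rng)
    lf = simulate_features(scenario.n_loci, rng)
    p = _resolve_params(scenario, structure, lf)
    rates = poisson_rates(structure, lf, p)
    counts = _draw_counts(rates, rng)
    bins = make_bins(scenario.n_loci)
    cm = ContactMatrix(bins, counts)
    return cm, SimTruth(structure=structure, params=p, rates=rates,
                        features=lf, bins=bins)


def simulate_population_mixture(structures: list[Structure3D],
                                weights: np.ndarray, lf: LocusFeatures,
                                p: ModelParams, seed: int = 0,
                                mean_count: float | None = None,
                                ) -> tuple[ContactMatrix, SimTruth]:
    """Counts from a cell population split across whole-region backbones:
    the Poisson rate is the weight-averaged per-structure rate."""
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if mean_count is not None:
        b0 = np.mean([beta0_for_depth(mean_count, s, lf, p)
                      for s in structures])
        p = ModelParams(float(b0), p.beta_d, p.beta_e, p.beta_g, p.beta_m)
    rates = sum(w * poisson_rates(s, lf, p)
                for w, s in zip(weights, structures))
    rng = np.random.default_rng(seed)
    counts = _draw_counts(rates, rng)
    bins = make_bins(structures[0].n_loci)
    cm = ContactMatrix(bins, counts)
    return cm, SimTruth(structure=structures[0], params=p, rates=rates,
                        features=lf, bins=bins,
                        extra={"structures": structures, "weights": weights})


def simulate_two_region(scenario: SimScenario,
                        ) -> tuple[ContactMatrix, SimTruth]:
    """Full contact matrix for two adjacent regions whose relative
    arrangement varies across the population.

    Intra-region counts are identical in every sub-population (an
    arrangement moves region B rigidly), so they come from the two
    sub-structures directly; the cross block uses the arrangement
    mixture.  With a single identity-like arrangement this reduces to a
    consensus two-region structure.
    """
    cross, truth = simulate_mixture_population(scenario)
    rng = np.random.default_rng(scenario.seed + 777)
    na = scenario.split_at
    struct_a = truth.extra["struct_a"]
    struct_b = truth.extra["struct_b"]
    lf = truth.features
    p = truth.params
    lam_a = poisson_rates(struct_a, truth.extra["lf_a"], p)
    lam_b = poisson_rates(struct_b, truth.extra["lf_b"], p)
    n = scenario.n_loci
    counts = np.zeros((n, n), dtype=np.int64)
    counts[:na, :na] = _draw_counts(lam_a, rng)
    counts[na:, na:] = _draw_counts(lam_b, rng)
    counts[:na, na:] = cross
    counts[na:, :na] = cross.T
    cm = ContactMatrix(truth.bins, counts)
    return cm, truth


def simulate_mixture_population(scenario: SimScenario,
                                ) -> tuple[np.ndarray, SimTruth]:
    """Inter-region counts from a mixture of arrangements of two adjacent
    sub-regions.  Returns the N_A x N_B cross count matrix plus truth."""
    if scenario.mixture_arrangements is None:
        raise ValueError("scenario has no arrangement mixture")
    if len(scenario.mixture_arrangements) == 0:
        raise ValueError("empty arrangement list")
    if scenario.split_at is None or not (2 <= scenario.split_at
                                         <= scenario.n_loci - 2):
        raise ValueError("split_at must leave >= 2 loci in each region")
    rng = np.random.default_rng(scenario.seed)
    na = scenario.split_at
    nb = scenario.n_loci - na
    struct_a = make_backbone(scenario.backbone, na, rng)
    struct_b = make_backbone(scenario.backbone, nb, rng)
    lf = simulate_features(scenario.n_loci, rng)
    lf_a, lf_b = lf.subset(np.arange(na)), lf.subset(np.arange(na, na + nb))
    p = scenario.params

    cov = covariate_terms(lf)[:, :na, na:]
    base = (p.beta0 + p.beta_e * cov[0] + p.beta_g * cov[1]
            + p.beta_m * cov[2])
    per_arr = []
    for arr in scenario.mixture_arrangements:
        placed = place_region_b(struct_a, struct_b, arr).coords
        diff = struct_a.coords[:, None, :] - placed[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=2))
        per_arr.append(np.exp(base + p.beta_d * np.log(d)))
    per_arr = np.stack(per_arr)
    props = scenario.mixture_proportions
    rates = np.einsum("k,kij->ij", props, per_arr)
    if scenario.mean_count is not None:
        factor = scenario.mean_count / rates.mean()
        rates = rates * factor
        p = ModelParams(p.beta0 + float(np.log(factor)), p.beta_d,
                        p.beta_e, p.beta_g, p.beta_m)
    counts = rng.poisson(rates)
    truth = SimTruth(structure=struct_a, params=p, rates=rates, features=lf,
                     bins=make_bins(scenario.n_loci),
                     extra={"struct_a": struct_a, "struct_b": struct_b,
                            "lf_a": lf_a, "lf_b": lf_b,
                            "arrangements": scenario.mixture_arrangements,
                            "proportions": props})
    return counts, truth
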