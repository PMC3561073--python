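"""Self-contained evaluation scenarios for the inference stack.

Each function builds its own synthetic data at a fixed design, runs the
relevant part of the package, and returns plain numbers.  The same
scenarios back the acceptance test suite and the acceptance script, so
the designs live in exactly one place.

Design notes: structure-recovery runs use the reference domain scale
(25 loci); arrangement-mixture runs use two 13-locus regions with twelve
well-separated candidates and deep cross counts; the model-selection and
dominance studies run twenty replicates each at sizes a single CPU
handles in minutes.  Problem sizes and sampler lengths are stated in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .bach_mix import (compare_models_aic, run_bach_mix,
                       select_separated_arrangements)
from .bach_sampler import SamplerConfig, init_params_glm, run_bach
from .contact_data import ContactMatrix
from .geometry import hd_ratio, optimal_superposition
from .poisson_model import (ModelParams, Structure3D, grad_log_posterior,
                            log_likelihood, pairwise_distances, poisson_rates)
from .population_twostep import (random_walk, rmsd_reference,
                                 two_step_procedure)
from .simulate import (SimScenario, make_backbone, simulate_features,
                       simulate_mixture_population,
                       simulate_population_mixture,
                       simulate_single_population, simulate_two_region)

__all__ = [
    "gradient_check",
    "superposition_check",
    "bach_recovery",
    "glm_recovery",
    "mix_recovery",
    "aic_selection_study",
    "twostep_dominance_study",
    "helix_hd_check",
]


def gradient_check(seed: int = 0, n_loci: int = 7) -> float:
    """Max |analytic − central-difference| over all coordinate and
    parameter partials on a random instance."""
    sc = SimScenario(n_loci=n_loci, seed=seed, mean_count=25)
    cm, truth = simulate_single_population(sc)
    s, lf, p = truth.structure, truth.features, truth.params
    gc, gp = grad_log_posterior(cm, s, lf, p)

    def ll(coords, params):
        return log_likelihood(cm, poisson_rates(Structure3D(coords), lf,
                                                params))

    eps, err = 1e-6, 0.0
    for i in range(n_loci):
        for k in range(3):
            up, dn = s.coords.copy(), s.coords.copy()
            up[i, k] += eps
            dn[i, k] -= eps
            num = (ll(up, p) - ll(dn, p)) / (2 * eps)
            err = max(err, abs(num - gc[i, k]))
    base = p.as_array()
    for k in range(5):
        up, dn = base.copy(), base.copy()
        up[k] += eps
        dn[k] -= eps
        num = (ll(s.coords, ModelParams.from_array(up))
               - ll(s.coords, ModelParams.from_array(dn))) / (2 * eps)
        err = max(err, abs(num - gp[k]))
    return float(err)


def _rotation_grid_min(ua: np.ndarray, ub: np.ndarray) -> float:
    """Brute-force minimum RMSD over a refined Euler grid (the oracle the
    SVD superposition is checked against)."""
    from itertools import product

    def euler_rot(al, be, ga):
        ca, sa = np.cos(al), np.sin(al)
        cb, sb = np.cos(be), np.sin(be)
        cg, sg = np.cos(ga), np.sin(ga)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
        return rz1 @ ry @ rz2

    def rmsd_for(rot):
        resid = ua - ub @ rot.T
        return np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))

    best, best_ang = np.inf, (0.0, 0.0, 0.0)
    grid = np.linspace(0, 2 * np.pi, 21, endpoint=False)
    for al, be, ga in product(grid, np.linspace(0, np.pi, 11), grid):
        v = rmsd_for(euler_rot(al, be, ga))
        if v < best:
            best, best_ang = v, (al, be, ga)
    width = 2 * np.pi / 21
    for _ in range(6):
        al0, be0, ga0 = best_ang
        offs = np.linspace(-width, width, 9)
        for da, db, dg in product(offs, offs, offs):
            v = rmsd_for(euler_rot(al0 + da, be0 + db, ga0 + dg))
            if v < best:
                best, best_ang = v, (al0 + da, be0 + db, ga0 + dg)
        width /= 4.0
    return float(best)


def superposition_check(seed: int = 0) -> tuple[float, float]:
    """(|rmsd − grid-oracle minimum| on a random 5-bead pair,
    rmsd of a scaled+rotated+translated copy)."""
    from scipy.stats import special_ortho_group

    rng = np.random.default_rng(seed)
    a = Structure3D(rng.normal(size=(5, 3)))
    b = Structure3D(rng.normal(size=(5, 3)))
    res = optimal_superposition(a, b)
    ca = a.coords - a.coords.mean(axis=0)
    cb = b.coords - b.coords.mean(axis=0)
    ua = ca / np.sqrt(np.mean(np.sum(ca ** 2, axis=1)))
    ub = cb / np.sqrt(np.mean(np.sum(cb ** 2, axis=1)))
    gap = abs(res.rmsd - _rotation_grid_min(ua, ub))

    rot = special_ortho_group.rvs(3, random_state=seed + 1)
    copy = Structure3D(2.0 * a.coords @ rot.T + [1.0, -2.0, 0.5])
    copy_rmsd = optimal_superposition(a, copy).rmsd
    return float(gap), float(copy_rmsd)


def bach_recovery(seed: int = 3, n_loci: int = 25, mean_count: float = 50.0,
                  ) -> tuple[float, float]:
    """(Pearson r between true and posterior-mean pairwise distances,
    fraction of 95% credible intervals covering the truth).

    Scale gauge: truth and posterior are both normalized to unit mean
    pairwise distance before comparison (one global scale adjustment).
    """
    sc = SimScenario(n_loci=n_loci, seed=seed, mean_count=mean_count)
    cm, truth = simulate_single_population(sc)
    cfg = SamplerConfig(n_chains=6, n_iter=3000, burn_in=800, thin=15,
                        sis_particles=50, sis_enrich=5, seed=seed + 7)
    fit = run_bach(cm, truth.features, cfg)
    iu = np.triu_indices(n_loci, 1)
    td = pairwise_distances(truth.structure)[iu]
    md = fit.distance_mean[iu]
    r = float(np.corrcoef(td, md)[0, 1])
    scale = td.mean() / md.mean()
    cover = float(np.mean((fit.distance_lower[iu] * scale <= td)
                          & (td <= fit.distance_upper[iu] * scale)))
    return r, cover


def glm_recovery(seed: int = 2) -> float:
    """Max absolute coefficient error of the Poisson-regression start on
    deep straight-line data (where the genomic-distance proxy is exact)."""
    sc = SimScenario(n_loci=25, backbone="line", seed=seed, mean_count=None,
                     params=ModelParams(7.0, -1.2, 0.3, 0.6, 0.9))
    cm, truth = simulate_single_population(sc)
    est = init_params_glm(cm, truth.features)
    return float(np.max(np.abs(est.as_array() - truth.params.as_array())))


def mix_recovery(seed: int = 5) -> dict:
    """Arrangement-mixture recovery at the reference two-region size.

    Two 13-locus random-walk regions, twelve well-separated candidates,
    truth proportions (0.7, 0.3) at deep cross counts; plus a
    single-arrangement dataset that must collapse to one component.
    """
    rng = np.random.default_rng(seed)
    a = make_backbone("random_walk", 13, rng)
    b = make_backbone("random_walk", 13, rng)
    cands = select_separated_arrangements(a, b, k=12)
    cfg = SamplerConfig(n_chains=2, n_iter=1500, burn_in=500, thin=10,
                        seed=seed + 2)

    props = np.zeros(12)
    props[2], props[7] = 0.7, 0.3
    sc = SimScenario(n_loci=26, split_at=13, seed=seed, mean_count=300,
                     mixture_arrangements=cands, mixture_proportions=props)
    cross, truth = simulate_mixture_population(sc)
    fit = run_bach_mix(cross, truth.extra["struct_a"],
                       truth.extra["struct_b"], truth.extra["lf_a"],
                       truth.extra["lf_b"], cfg, arrangements=cands)
    by_id = {id(c): p for c, p in zip(fit.mixture.arrangements,
                                      fit.mixture.proportions)}
    err_dom = abs(by_id.get(id(cands[2]), 0.0) - 0.7)
    err_min = abs(by_id.get(id(cands[7]), 0.0) - 0.3)

    props1 = np.zeros(12)
    props1[4] = 1.0
    sc1 = SimScenario(n_loci=26, split_at=13, seed=seed + 1, mean_count=300,
                      mixture_arrangements=cands,
                      mixture_proportions=props1)
    cross1, truth1 = simulate_mixture_population(sc1)
    fit1 = run_bach_mix(cross1, truth1.extra["struct_a"],
                        truth1.extra["struct_b"], truth1.extra["lf_a"],
                        truth1.extra["lf_b"], cfg, arrangements=cands)
    return {"err_dominant": float(err_dom), "err_minor": float(err_min),
            "k_two": fit.mixture.k, "k_single": fit1.mixture.k}


def _aic_one(seed: int, mixture: bool, cfg: SamplerConfig) -> str:
    rng = np.random.default_rng(seed)
    a = make_backbone("random_walk", 13, rng)
    b = make_backbone("random_walk", 13, rng)
    cands = select_separated_arrangements(a, b, k=8)
    props = np.zeros(8)
    if mixture:
        props[1], props[5] = 0.5, 0.5
    else:
        props[2] = 1.0
    sc = SimScenario(n_loci=26, split_at=13, seed=seed, mean_count=100,
                     mixture_arrangements=cands, mixture_proportions=props)
    cm, truth = simulate_two_region(sc)
    lf = truth.features
    fit_full = run_bach(cm, lf, cfg)
    ia, ib = np.arange(13), np.arange(13, 26)
    cm_a = ContactMatrix([cm.bins[i] for i in ia],
                         cm.counts[np.ix_(ia, ia)])
    cm_b = ContactMatrix([cm.bins[i] for i in ib],
                         cm.counts[np.ix_(ib, ib)])
    fit_a = run_bach(cm_a, lf.subset(ia), cfg)
    fit_b = run_bach(cm_b, lf.subset(ib), cfg)
    mix = run_bach_mix(cm.counts[np.ix_(ia, ib)], fit_a, fit_b,
                       lf.subset(ia), lf.subset(ib), cfg,
                       bins_per_angle=3)
    return compare_models_aic(fit_full, mix).selected


def aic_selection_study(seed: int = 0, n_reps: int = 20,
                        ) -> tuple[float, float]:
    """(fraction of single-population replicates where the consensus
    model wins the AIC comparison, fraction of 50/50 two-arrangement
    replicates where the mixture model wins)."""
    cfg_base = dict(n_chains=2, n_iter=600, burn_in=200, thin=10,
                    sis_particles=30, sis_enrich=5)
    single_wins = mixture_wins = 0
    for rep in range(n_reps):
        cfg = SamplerConfig(**cfg_base, seed=seed + 100 + rep)
        if _aic_one(seed + rep, False, cfg) == "single":
            single_wins += 1
        cfg = SamplerConfig(**cfg_base, seed=seed + 200 + rep)
        if _aic_one(seed + rep, True, cfg) == "mixture":
            mixture_wins += 1
    return single_wins / n_reps, mixture_wins / n_reps


def twostep_dominance_study(seed: int = 0, n_reps: int = 20,
                            n_loci: int = 20, n_ref_reps: int = 500,
                            ) -> tuple[float, float]:
    """(fraction of single-structure replicates called dominant,
    fraction of 50/50 backbone-mixture replicates called non-dominant)."""
    ref = rmsd_reference(n_loci, n_reps=n_ref_reps, seed=seed + 999)
    p = ModelParams(3.0, -1.0, 0.3, 0.5, 0.8)
    dominant = nondominant = 0
    for rep in range(n_reps):
        cfg = SamplerConfig(n_chains=6, n_iter=700, burn_in=250, thin=10,
                            sis_particles=30, sis_enrich=5,
                            seed=seed + 300 + rep)
        sc = SimScenario(n_loci=n_loci, seed=seed + rep, mean_count=200,
                         params=p)
        cm, truth = simulate_single_population(sc)
        res = two_step_procedure(cm, truth.features, cfg, reference=ref)
        dominant += res.dominant

        rng = np.random.default_rng(seed + 400 + rep)
        lf = simulate_features(n_loci, rng)
        s1 = random_walk(n_loci, seed=rng)
        s2 = random_walk(n_loci, seed=rng)
        cm2, _ = simulate_population_mixture([s1, s2], [0.5, 0.5], lf, p,
                                             seed=seed + 500 + rep,
                                             mean_count=200)
        cfg2 = SamplerConfig(n_chains=6, n_iter=700, burn_in=250, thin=10,
                             sis_particles=30, sis_enrich=5,
                             seed=seed + 600 + rep)
        res2 = two_step_procedure(cm2, lf, cfg2, reference=ref)
        nondominant += not res2.dominant
    return dominant / n_reps, nondominant / n_reps


def helix_hd_check(n_points: int = 2000) -> float:
    """Raw height/diameter of a dense uniform helix (height 10, radius 1):
    the quantile construction gives 0.8·10 / 4 = 2.0 analytically."""
    t = np.linspace(0, 2 * np.pi * 12, n_points)
    z = np.linspace(0, 10.0, n_points)
    s = Structure3D(np.column_stack([np.cos(t), np.sin(t), z]))
    return float(hd_ratio(s).hd_raw)
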