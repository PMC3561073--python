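"""Three-stage Bayesian inference of a consensus 3D structure.

Stage 1 initializes the nuisance parameters by Poisson regression with
genomic distance standing in for spatial distance.  Stage 2 grows an
initial structure bead by bead with sequential importance sampling (SIS)
and rejection-control enrichment.  Stage 3 refines structure and
parameters with a Gibbs sampler: one hybrid (Hamiltonian) Monte Carlo
trajectory for the coordinates per sweep, then each nuisance parameter
from its univariate log-concave conditional (slice sampling, which targets
the same conditional law as adaptive rejection sampling).

Priors are non-informative (improper flat); the distance exponent can be
constrained negative.  Convergence across chains is monitored with the
Gelman-Rubin potential scale reduction factor on the log-likelihood trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from .contact_data import ContactMatrix, LocusFeatures
from .poisson_model import (ModelParams, Structure3D, aic,
                            covariate_terms)

__all__ = [
    "SamplerConfig",
    "PosteriorSample",
    "BachFit",
    "init_params_glm",
    "sis_initial_structure",
    "run_bach",
    "gelman_rubin",
]


@dataclass
class SamplerConfig:
    """Knobs of the three-stage sampler.

    Defaults: three parallel chains of 5000 sweeps, 1000 dropped as
    burn-in, every 50th retained; SIS with 100 particles enriched tenfold.
    The HMC step size is auto-tuned during burn-in toward 60-90%
    acceptance unless given explicitly with tuning disabled.
    """

    n_chains: int = 3
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 50
    sis_particles: int = 100
    sis_enrich: int = 10
    hmc_step_size: float | None = None
    hmc_leapfrog_steps: int = 10
    hmc_tune: bool = True
    bias_terms: bool = True
    enforce_negative_decay: bool = True
    init_strategy: str = "sis"   # "sis" | "random": random-walk starts
    polish_mode: bool = True     # sharpen the mode by local optimization
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.sis_particles < 1 or self.sis_enrich < 1:
            raise ValueError("thin, sis_particles, sis_enrich must be >= 1")


@dataclass
class PosteriorSample:
    structure: Structure3D
    params: ModelParams
    loglik: float
    chain: int
    iteration: int


@dataclass
class BachFit:
    """Posterior summary of one BACH run."""

    samples: list[PosteriorSample]
    mode_structure: Structure3D
    mode_params: ModelParams
    mode_loglik: float
    distance_mean: np.ndarray     # N x N posterior mean pairwise distance
    distance_lower: np.ndarray    # 2.5% quantile
    distance_upper: np.ndarray    # 97.5% quantile
    gelman_rubin: float
    converged: bool
    aic: float
    accept_rates: list[float] = field(default_factory=list)
    sis_logliks: list[float] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return self.mode_structure.n_loci


# ---------------------------------------------------------------------------
# Internal flattened likelihood machinery (upper-triangle pair vectors)


class _PairData:
    """Per-pair count and covariate vectors for fast repeated evaluation."""

    def __init__(self, cm: ContactMatrix, lf: LocusFeatures, bias: bool):
        n = cm.n_loci
        self.n_loci = n
        self.i, self.j = np.triu_indices(n, k=1)
        self.counts = cm.counts[self.i, self.j].astype(float)
        cov = covariate_terms(lf) if bias else np.zeros((3, n, n))
        self.cov = cov[:, self.i, self.j]            # (3, M)
        self.const = float(gammaln(self.counts + 1).sum())

    def dist(self, coords: np.ndarray) -> np.ndarray:
        d = coords[self.i] - coords[self.j]
        # floor avoids NaN from 0 * log(0) for a transient coincident pair
        return np.maximum(np.sqrt(np.sum(d * d, axis=1)), 1e-12)

    def eta(self, log_d: np.ndarray, beta: np.ndarray) -> np.ndarray:
        return (beta[0] + beta[1] * log_d + beta[2] * self.cov[0]
                + beta[3] * self.cov[1] + beta[4] * self.cov[2])

    def loglik(self, coords: np.ndarray, beta: np.ndarray) -> float:
        eta = self.eta(np.log(self.dist(coords)), beta)
        return float(np.sum(self.counts * eta - np.exp(eta)) - self.const)

    def loglik_and_coord_grad(self, coords: np.ndarray, beta: np.ndarray,
                              ) -> tuple[float, np.ndarray]:
        diff = coords[self.i] - coords[self.j]
        d = np.maximum(np.sqrt(np.sum(diff * diff, axis=1)), 1e-12)
        eta = self.eta(np.log(d), beta)
        lam = np.exp(eta)
        ll = float(np.sum(self.counts * eta - lam) - self.const)
        w = (self.counts - lam) * beta[1] / (d * d)
        contrib = w[:, None] * diff
        grad = np.zeros_like(coords)
        np.add.at(grad, self.i, contrib)
        np.add.at(grad, self.j, -contrib)
        return ll, grad


# ---------------------------------------------------------------------------
# Stage 1: GLM initialization


def init_params_glm(cm: ContactMatrix, lf: LocusFeatures,
                    bias_terms: bool = True) -> ModelParams:
    """Initial nuisance parameters from a Poisson regression of counts on
    log genomic distance (proxy for log spatial distance) and the pairwise
    log bias covariates.

    Falls back to (ln(mean count), -1, 0, 0, 0) with a warning when the
    GLM does not converge.
    """
    n = cm.n_loci
    i, j = np.triu_indices(n, k=1)
    if len(i) < 6:
        raise ValueError("need at least 6 informative pairs")
    y = cm.counts[i, j].astype(float)
    ld = np.log((j - i).astype(float))
    cols = [np.ones_like(ld), ld]
    if bias_terms:
        cov = covariate_terms(lf)
        cols += [cov[0][i, j], cov[1][i, j], cov[2][i, j]]
    x = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, x, family=sm.families.Poisson()).fit()
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite GLM coefficients")
        coef = np.zeros(5)
        coef[: x.shape[1]] = res.params
        return ModelParams.from_array(coef)
    except Exception:  # noqa: BLE001 - any GLM failure triggers the fallback
        warnings.warn("Poisson GLM initialization failed; using fallback "
                      "(ln mean count, -1, 0, 0, 0)", stacklevel=2)
        mean_count = max(y.mean(), 1e-8)
        return ModelParams(float(np.log(mean_count)), -1.0)


# ---------------------------------------------------------------------------
# Stage 2: sequential importance sampling


def _proposal_scale(pd_: _PairData, beta: np.ndarray) -> float:
    """Typical adjacent-bead distance implied by the decay fit: solves the
    rate equation for the mean count of |i-j| = 1 pairs."""
    adj = pd_.j - pd_.i == 1
    mean_adj = max(pd_.counts[adj].mean(), 0.5)
    base = beta[0] + (beta[2] * pd_.cov[0][adj] + beta[3] * pd_.cov[1][adj]
                      + beta[4] * pd_.cov[2][adj]).mean()
    bd = min(beta[1], -0.1)  # guard against a flat decay estimate
    return float(np.exp((np.log(mean_adj) - base) / bd))


def sis_initial_structure(cm: ContactMatrix, lf: LocusFeatures,
                          p: ModelParams, cfg: SamplerConfig,
                          rng: np.random.Generator | None = None,
                          ) -> Structure3D:
    """Grow an initial structure bead by bead.

    Each of ``sis_particles`` partial structures extends by one bead per
    step: ``sis_enrich`` candidate positions are drawn isotropically around
    the current chain end at the scale implied by the decay fit, one is
    kept with probability proportional to the partial likelihood of all
    contacts involving the new bead, and the particle weight absorbs the
    candidate-averaged likelihood.  Low-weight particles are resampled
    (rejection control) whenever the effective sample size halves.  The
    highest-weight completed structure is returned.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pd_ = _PairData(cm, lf, cfg.bias_terms)
    beta = p.as_array()
    if not cfg.bias_terms:
        beta = np.array([beta[0], beta[1], 0.0, 0.0, 0.0])
    n, np_, ne = pd_.n_loci, cfg.sis_particles, cfg.sis_enrich
    scale = _proposal_scale(pd_, beta)
    sigma = scale / np.sqrt(3.0)

    cov_full = (covariate_terms(lf) if cfg.bias_terms
                else np.zeros((3, n, n)))

    for attempt in range(4):
        coords = np.zeros((np_, n, 3))
        logw = np.zeros(np_)
        ok = True
        for t in range(1, n):
            # candidate positions: (P, E, 3), isotropic around the chain end
            step = rng.normal(scale=sigma, size=(np_, ne, 3))
            cand = coords[:, t - 1, None, :] + step
            # partial log-likelihood of contacts between bead t and 0..t-1
            diff = cand[:, :, None, :] - coords[:, None, :t, :]  # (P,E,t,3)
            d = np.sqrt(np.sum(diff * diff, axis=3))
            d = np.maximum(d, 1e-12)
            base = (beta[0] + beta[2] * cov_full[0, t, :t]
                    + beta[3] * cov_full[1, t, :t]
                    + beta[4] * cov_full[2, t, :t])       # (t,)
            eta = base + beta[1] * np.log(d)              # (P,E,t)
            nt = cm.counts[t, :t].astype(float)
            pll = np.sum(nt * eta - np.exp(eta), axis=2)  # (P,E)
            pll_max = pll.max()
            if not np.isfinite(pll_max):
                ok = False
                break
            # select one candidate per particle proportional to likelihood
            w = np.exp(pll - pll.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            u = rng.uniform(size=np_)
            pick = np.minimum((w.cumsum(axis=1) < u[:, None]).sum(axis=1),
                              ne - 1)
            coords[:, t, :] = cand[np.arange(np_), pick, :]
            logw += logsumexp(pll, axis=1) - np.log(ne)
            # rejection control / resampling
            lw = logw - logsumexp(logw)
            ess = 1.0 / np.sum(np.exp(2 * lw))
            if ess < np_ / 2:
                probs = np.exp(lw)
                idx = rng.choice(np_, size=np_, p=probs)
                coords = coords[idx]
                logw = np.zeros(np_)
        if ok:
            final_ll = np.array([pd_.loglik(coords[k], beta)
                                 for k in range(np_)])
            best = int(np.argmax(final_ll + logw))
            return Structure3D(coords[best])
        sigma *= 2.0  # all weights underflowed; retry with a wider proposal
    raise RuntimeError("SIS failed: weights underflowed at every retry")


# ---------------------------------------------------------------------------
# Stage 3: Gibbs refinement (HMC for coordinates, slice for each beta)


def _hmc_update(coords: np.ndarray, beta: np.ndarray, pd_: _PairData,
                step: float, n_leap: int, rng: np.random.Generator,
                ) -> tuple[np.ndarray, bool, float]:
    mom = rng.normal(size=coords.shape)
    ll0, grad = pd_.loglik_and_coord_grad(coords, beta)
    h0 = ll0 - 0.5 * np.sum(mom * mom)
    q, g = coords, grad
    m = mom + 0.5 * step * g
    for leap in range(n_leap):
        q = q + step * m
        ll, g = pd_.loglik_and_coord_grad(q, beta)
        if not np.isfinite(ll):
            return coords, False, ll0
        m = m + (step if leap < n_leap - 1 else 0.5 * step) * g
    h1 = ll - 0.5 * np.sum(m * m)
    if np.log(rng.uniform()) < h1 - h0:
        return q, True, ll
    return coords, False, ll0


def _slice_sample(logp, x0: float, rng: np.random.Generator,
                  width: float = 0.25, max_steps: int = 50,
                  upper: float | None = None) -> float:
    """Univariate slice sampler (stepping out + shrinkage)."""
    f0 = logp(x0)
    y = f0 + np.log(rng.uniform() + 1e-300)
    lo = x0 - width * rng.uniform()
    hi = lo + width
    steps = max_steps
    while steps > 0 and logp(lo) > y:
        lo -= width
        steps -= 1
    steps = max_steps
    while steps > 0 and (upper is None or hi < upper) and logp(hi) > y:
        hi += width
        steps -= 1
    if upper is not None:
        hi = min(hi, upper)
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _update_betas(coords: np.ndarray, beta: np.ndarray, pd_: _PairData,
                  rng: np.random.Generator, bias: bool,
                  neg_decay: bool) -> np.ndarray:
    log_d = np.log(pd_.dist(coords))
    design = np.vstack([np.ones_like(log_d), log_d, pd_.cov])  # (5, M)
    beta = beta.copy()
    idx = range(5) if bias else range(2)
    for k in idx:
        others = pd_.eta(log_d, beta) - beta[k] * design[k]

        def logp(b: float, _k=k, _o=others) -> float:
            if neg_decay and _k == 1 and b >= 0:
                return -np.inf
            eta = _o + b * design[_k]
            return float(np.sum(pd_.counts * eta - np.exp(eta)))

        upper = 0.0 if (neg_decay and k == 1) else None
        beta[k] = _slice_sample(logp, beta[k], rng, upper=upper)
    return beta


def run_bach(cm: ContactMatrix, lf: LocusFeatures,
             cfg: SamplerConfig = SamplerConfig()) -> BachFit:
    """Full three-stage fit; returns posterior samples and summaries.

    Chains start from independent SIS structures.  The posterior mode is
    the retained sample of highest log-likelihood (flat priors).  The AIC
    uses k = 3N + 5 parameters.  ``converged`` is False when the
    Gelman-Rubin factor on the log-likelihood traces exceeds 1.1 (only
    meaningful with >= 2 chains).
    """
    pd_ = _PairData(cm, lf, cfg.bias_terms)
    n = pd_.n_loci
    p0 = init_params_glm(cm, lf, bias_terms=cfg.bias_terms)
    beta0 = p0.as_array()
    if cfg.enforce_negative_decay and beta0[1] >= 0:
        beta0[1] = -1.0

    samples: list[PosteriorSample] = []
    traces: list[np.ndarray] = []
    accept_rates: list[float] = []
    sis_logliks: list[float] = []
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([cfg.seed, chain])
        if cfg.init_strategy == "random":
            # diverse random-walk starts let independent chains discover
            # distinct posterior modes when the population is mixed
            scale0 = _proposal_scale(pd_, beta0)
            steps = rng.normal(size=(n - 1, 3))
            steps *= scale0 / np.linalg.norm(steps, axis=1)[:, None]
            coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        else:
            init = sis_initial_structure(cm, lf,
                                         ModelParams.from_array(beta0),
                                         cfg, rng)
            coords = init.coords
        coords = coords - coords.mean(axis=0)
        beta = beta0.copy()
        sis_logliks.append(pd_.loglik(coords, beta))
        scale = _proposal_scale(pd_, beta)
        step = cfg.hmc_step_size if cfg.hmc_step_size is not None \
            else 0.02 * scale
        trace = np.empty(cfg.n_iter)
        n_acc = 0
        for it in range(cfg.n_iter):
            coords, accepted, ll = _hmc_update(
                coords, beta, pd_, step, cfg.hmc_leapfrog_steps, rng)
            n_acc += accepted
            if cfg.hmc_tune and it < cfg.burn_in:
                step *= 1.02 if accepted else 0.96
            beta = _update_betas(coords, beta, pd_, rng, cfg.bias_terms,
                                 cfg.enforce_negative_decay)
            ll = pd_.loglik(coords, beta)
            trace[it] = ll
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                samples.append(PosteriorSample(
                    Structure3D(coords.copy()),
                    ModelParams.from_array(beta), ll, chain, it))
        traces.append(trace[cfg.burn_in:])
        accept_rates.append(n_acc / cfg.n_iter)

    mode = max(samples, key=lambda s: s.loglik)
    mode_structure, mode_loglik = mode.structure, mode.loglik
    if cfg.polish_mode:
        # polish each chain's best sample: chains can land in different
        # folding basins, and the pre-polish log-likelihoods of a shallow
        # and a deep basin overlap
        for chain in range(cfg.n_chains):
            chain_best = max((s for s in samples if s.chain == chain),
                             key=lambda s: s.loglik)
            cand_s, cand_ll = _polish_structure(
                chain_best.structure, chain_best.params.as_array(), pd_)
            if cand_ll > mode_loglik:
                mode_structure, mode_loglik = cand_s, cand_ll
    dists = np.stack([_dist_matrix(s.structure.coords) for s in samples])
    # Remove the scale gauge (a global rescaling trades off exactly against
    # beta0) before summarizing: normalize each sample to the posterior-mean
    # overall scale, so credible intervals reflect shape uncertainty only.
    iu = np.triu_indices(n, k=1)
    scales = dists[:, iu[0], iu[1]].mean(axis=1)
    dists *= (scales.mean() / scales)[:, None, None]
    dmean = dists.mean(axis=0)
    dlo, dhi = np.quantile(dists, [0.025, 0.975], axis=0)
    gr = gelman_rubin(traces) if cfg.n_chains >= 2 else 1.0
    fit_aic = aic(mode_loglik, 3 * n + 5)
    return BachFit(samples=samples, mode_structure=mode_structure,
                   mode_params=mode.params, mode_loglik=mode_loglik,
                   distance_mean=dmean, distance_lower=dlo,
                   distance_upper=dhi, gelman_rubin=float(gr),
                   converged=bool(gr <= 1.1), aic=fit_aic,
                   accept_rates=accept_rates, sis_logliks=sis_logliks)


def _polish_structure(s: Structure3D, beta: np.ndarray, pd_: _PairData,
                      ) -> tuple[Structure3D, float]:
    """Local maximization of the coordinate log-likelihood at fixed
    nuisance parameters: turns the best retained sample into the actual
    posterior mode of its basin."""
    from scipy.optimize import minimize

    def neg(x):
        return -pd_.loglik(x.reshape(-1, 3), beta)

    def neg_grad(x):
        return -pd_.loglik_and_coord_grad(x.reshape(-1, 3), beta)[1].ravel()

    res = minimize(neg, s.coords.ravel(), jac=neg_grad, method="L-BFGS-B")
    return Structure3D(res.x.reshape(-1, 3)), float(-res.fun)


def _dist_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def gelman_rubin(chains: list[np.ndarray] | np.ndarray) -> float:
    """Potential scale reduction factor from >= 2 equal-length traces.

    Zero within-chain variance returns 1.0 for identical chains and +inf
    for chains stuck at different values.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    # the factor is clamped at 1: values below 1 (zero between-chain
    # variance) carry no extra information about convergence
    return float(max(1.0, np.sqrt(var_plus / w)))
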