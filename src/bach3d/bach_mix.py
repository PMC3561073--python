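"""Mixture modelling of the spatial arrangement of two adjacent regions.

Each region keeps a fixed consensus structure (a prior BACH fit); what
varies across the cell population is how region B sits relative to region
A.  An arrangement is a Z-Y-Z Euler rotation optionally composed with a
mirror reflection, applied to region B about its anchor point at the end
of region A.  The candidate arrangements come from a discrete grid over
the Euler angles crossed with both mirror states; a multinomial proportion
vector over the candidates is inferred from the inter-region contact
matrix under a mixture Poisson model whose rate for a locus pair (i in A,
j in B) is the proportion-weighted sum of the single-arrangement rates.

Proportions are parameterized on the softmax scale (last logit pinned at
zero) so hybrid Monte Carlo can update them jointly with the nuisance
parameters without constraints.  After sampling, arrangements whose
posterior-mean proportion falls below the pruning threshold (1% by
default) are removed and the reduced model refitted.  Effective structures
are the components whose proportion exceeds a reporting threshold (5% by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, softmax

from .bach_sampler import BachFit, SamplerConfig, gelman_rubin
from .contact_data import LocusFeatures
from .poisson_model import ModelParams, Structure3D, aic

__all__ = [
    "Arrangement",
    "ArrangementMixture",
    "MixFit",
    "arrangement_transform",
    "enumerate_arrangements",
    "place_region_b",
    "mixture_rates",
    "run_bach_mix",
    "prune_mixture",
    "effective_structures",
    "compare_models_aic",
    "ModelSelection",
]


@dataclass
class Arrangement:
    """One candidate placement: Euler rotation composed with optional mirror."""

    euler: tuple[float, float, float]
    mirror: int
    transform: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.transform, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("transform must be 3x3")
        if not np.allclose(t @ t.T, np.eye(3), atol=1e-10):
            raise ValueError("transform is not orthogonal")
        self.transform = t


@dataclass
class ArrangementMixture:
    arrangements: list[Arrangement]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.arrangements) != len(self.proportions):
            raise ValueError("arrangement/proportion length mismatch")
        if len(self.arrangements) < 1:
            raise ValueError("need at least one arrangement")
        if np.any(self.proportions < 0) or \
                abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")

    @property
    def k(self) -> int:
        return len(self.arrangements)


@dataclass
class MixFit:
    """Posterior summary of an arrangement-mixture fit."""

    mixture: ArrangementMixture
    params: ModelParams
    loglik: float            # cross-block log-likelihood at the mode
    total_loglik: float      # + intra-region log-likelihoods when available
    aic: float
    converged: bool
    gelman_rubin: float
    proportion_samples: np.ndarray = field(default=None, repr=False)

    def effective_count(self, threshold: float = 0.05) -> int:
        return effective_structures(self.mixture, threshold)


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def arrangement_transform(euler: tuple[float, float, float],
                          mirror: int) -> Arrangement:
    """Build the arrangement matrix M(mirror) @ R(alpha, beta, gamma) with
    R the Z-Y-Z Euler rotation and M = diag(1, 1, mirror)."""
    if mirror not in (-1, 1):
        raise ValueError("mirror must be +1 or -1")
    alpha, beta, gamma = euler
    r = _rot_z(alpha) @ _rot_y(beta) @ _rot_z(gamma)
    m = np.diag([1.0, 1.0, float(mirror)])
    return Arrangement(euler=tuple(map(float, euler)), mirror=mirror,
                       transform=m @ r)


def enumerate_arrangements(bins_per_angle: int = 4,
                           dedup_tol: float = 1e-6) -> list[Arrangement]:
    """Grid of bin-center Euler angles crossed with both mirror states.

    alpha and gamma range over [0, 2pi), beta over [0, pi]; with the
    default four bins per angle this gives 4 x 4 x 4 x 2 = 128 candidates
    before merging transforms that coincide within ``dedup_tol``.
    """
    if bins_per_angle < 1:
        raise ValueError("bins_per_angle must be >= 1")
    b = bins_per_angle
    alphas = (np.arange(b) + 0.5) * 2 * np.pi / b
    betas = (np.arange(b) + 0.5) * np.pi / b
    gammas = alphas
    out: list[Arrangement] = []
    for mirror in (1, -1):
        for al in alphas:
            for be in betas:
                for ga in gammas:
                    cand = arrangement_transform((al, be, ga), mirror)
                    if not any(np.max(np.abs(cand.transform - a.transform))
                               <= dedup_tol for a in out):
                        out.append(cand)
    return out


def select_separated_arrangements(struct_a: Structure3D,
                                  struct_b: Structure3D,
                                  k: int = 12,
                                  pool: list[Arrangement] | None = None,
                                  ) -> list[Arrangement]:
    """Pick ``k`` arrangements whose cross-distance patterns are mutually
    well separated for the given structures.

    Arrangements that are distinct as matrices can still induce nearly
    identical inter-region distances (for an elongated region B the
    distances depend mostly on the image of its long axis), which makes
    mixture proportions over the raw grid weakly identified.  Greedy
    farthest-point selection on the RMS difference of log cross-distance
    matrices yields a candidate set without such near-aliases.
    """
    if pool is None:
        pool = enumerate_arrangements(4)
    if k > len(pool):
        raise ValueError("k exceeds the pool size")
    ld = _cross_log_dists(struct_a, struct_b, pool).reshape(len(pool), -1)
    chosen = [0]
    d2 = np.mean((ld - ld[0]) ** 2, axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.mean((ld - ld[nxt]) ** 2, axis=1))
    return [pool[i] for i in sorted(chosen)]


def place_region_b(struct_a: Structure3D, struct_b: Structure3D,
                   arr: Arrangement) -> Structure3D:
    """Place region B relative to region A under one arrangement.

    B is translated so its first bead sits at the anchor — region A's last
    bead extended by one mean bond length along the A-end tangent — then
    rotated/mirrored about that anchor.  This preserves chain adjacency
    across the junction for every arrangement.
    """
    a = struct_a.coords
    tangent = a[-1] - a[-2]
    tnorm = np.linalg.norm(tangent)
    if tnorm < 1e-12:
        raise ValueError("degenerate region A: last two beads coincide")
    bond = float(np.mean(np.linalg.norm(np.diff(a, axis=0), axis=1)))
    anchor = a[-1] + bond * tangent / tnorm
    b = struct_b.coords - struct_b.coords[0] + anchor
    placed = (b - anchor) @ arr.transform.T + anchor
    return Structure3D(placed)


def _cross_cov(lf_a: LocusFeatures, lf_b: LocusFeatures) -> np.ndarray:
    """(3, N_A, N_B) pairwise log bias covariates across the two regions."""
    out = []
    for fa, fb in ((lf_a.frag_ends, lf_b.frag_ends), (lf_a.gc, lf_b.gc),
                   (lf_a.mappability, lf_b.mappability)):
        out.append(np.log(fa)[:, None] + np.log(fb)[None, :])
    return np.stack(out)


def _cross_log_dists(struct_a: Structure3D, struct_b: Structure3D,
                     arrangements: list[Arrangement]) -> np.ndarray:
    """(K, N_A, N_B) log distances between A beads and placed B beads."""
    lds = []
    for arr in arrangements:
        placed = place_region_b(struct_a, struct_b, arr).coords
        diff = struct_a.coords[:, None, :] - placed[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=2))
        if np.any(d <= 0):
            raise ValueError("zero cross-region distance under an arrangement")
        lds.append(np.log(d))
    return np.stack(lds)


def mixture_rates(struct_a: Structure3D, struct_b: Structure3D,
                  mixture: ArrangementMixture, lf_a: LocusFeatures,
                  lf_b: LocusFeatures, p: ModelParams) -> np.ndarray:
    """Inter-region expected counts: the proportion-weighted sum of the
    single-arrangement Poisson rates (N_A x N_B)."""
    ld = _cross_log_dists(struct_a, struct_b, mixture.arrangements)
    cov = _cross_cov(lf_a, lf_b)
    base = (p.beta0 + p.beta_e * cov[0] + p.beta_g * cov[1]
            + p.beta_m * cov[2])
    per_arr = np.exp(base[None] + p.beta_d * ld)   # (K, N_A, N_B)
    return np.einsum("k,kij->ij", mixture.proportions, per_arr)


# ---------------------------------------------------------------------------
# Joint HMC over softmax logits and nuisance parameters


class _MixTarget:
    """Flattened mixture posterior over theta = (logits[:-1], betas).

    The prior on the proportions is uniform on the simplex, which in the
    softmax parameterization contributes the log-Jacobian sum(ln pi_k);
    without it the posterior over a null component's logit is improper
    and its proportion never concentrates at zero.  ``with_prior=False``
    gives the bare likelihood (used by the MAP initializer).
    """

    def __init__(self, counts: np.ndarray, ld: np.ndarray, cov: np.ndarray,
                 neg_decay: bool, with_prior: bool = True):
        self.with_prior = with_prior
        self.k = ld.shape[0]
        self.counts = counts.ravel().astype(float)
        self.ld = ld.reshape(self.k, -1)             # (K, M)
        self.cov = cov.reshape(3, -1)                # (3, M)
        self.const = float(gammaln(self.counts + 1).sum())
        self.neg_decay = neg_decay
        self.dim = (self.k - 1) + 5

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits = np.concatenate([theta[: self.k - 1], [0.0]])
        return softmax(logits), theta[self.k - 1:]

    def loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pi, beta = self.unpack(theta)
        if self.neg_decay and beta[1] >= 0:
            return -np.inf, np.zeros_like(theta)
        base = (beta[0] + beta[2] * self.cov[0] + beta[3] * self.cov[1]
                + beta[4] * self.cov[2])             # (M,)
        a = np.exp(base[None] + beta[1] * self.ld)   # (K, M)
        lam = pi @ a                                 # (M,)
        lam = np.maximum(lam, 1e-300)
        ll = float(np.sum(self.counts * np.log(lam) - lam) - self.const)
        r = self.counts / lam - 1.0                  # dll/dlam
        g_pi = a @ r                                 # (K,)
        g_logits = pi * (g_pi - pi @ g_pi)
        if self.with_prior:
            ll += float(np.sum(np.log(np.maximum(pi, 1e-300))))
            g_logits = g_logits + (1.0 - self.k * pi)
        resid = self.counts - lam
        g_beta = np.array([
            resid.sum(),
            float(r @ (pi @ (a * self.ld))),
            resid @ self.cov[0],
            resid @ self.cov[1],
            resid @ self.cov[2],
        ])
        return ll, np.concatenate([g_logits[: self.k - 1], g_beta])


def _hmc_theta(theta: np.ndarray, target: _MixTarget, step: float,
               n_leap: int, rng: np.random.Generator,
               scale: np.ndarray | None = None,
               ) -> tuple[np.ndarray, bool, float]:
    """One preconditioned HMC trajectory.

    ``scale`` rescales each coordinate (a diagonal mass matrix): logits
    and intercept live on wildly different curvature scales, and a common
    step size would crawl along the flatter directions.
    """
    if scale is None:
        scale = np.ones_like(theta)
    eps = step * scale
    mom = rng.normal(size=theta.shape)
    ll0, g = target.loglik_grad(theta)
    h0 = ll0 - 0.5 * np.sum(mom * mom)
    q = theta
    m = mom + 0.5 * eps * g
    for leap in range(n_leap):
        q = q + eps * m
        ll, g = target.loglik_grad(q)
        if not np.isfinite(ll):
            return theta, False, ll0
        m = m + (eps if leap < n_leap - 1 else 0.5 * eps) * g
    h1 = ll - 0.5 * np.sum(m * m)
    if np.log(rng.uniform()) < h1 - h0:
        return q, True, ll
    return theta, False, ll0


def _hessian_scale(target: _MixTarget, theta: np.ndarray,
                   h: float = 1e-4) -> np.ndarray:
    """Per-coordinate scale 1/sqrt(curvature) from a finite-difference
    diagonal Hessian of the log posterior at the mode."""
    diag = np.empty(theta.size)
    for k in range(theta.size):
        e = np.zeros_like(theta)
        e[k] = h
        _, gp = target.loglik_grad(theta + e)
        _, gm = target.loglik_grad(theta - e)
        diag[k] = -(gp[k] - gm[k]) / (2 * h)
    diag = np.clip(diag, 1e-2, None)
    s = 1.0 / np.sqrt(diag)
    return s / s.max()


def _init_betas(counts: np.ndarray, ld: np.ndarray,
                cov: np.ndarray) -> np.ndarray:
    """Starting betas from a Poisson GLM of the cross counts on the
    arrangement-averaged log distance and the pairwise bias covariates.

    Getting the bias coefficients roughly right up front matters: the
    proportion step of the MAP initialization is only as good as the
    rate model it is handed.
    """
    import statsmodels.api as sm

    y = counts.ravel().astype(float)
    ld_avg = np.log(np.exp(ld.reshape(ld.shape[0], -1)).mean(axis=0))
    x = np.column_stack([np.ones_like(y), ld_avg] + list(cov.reshape(3, -1)))
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, x, family=sm.families.Poisson()).fit()
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            if beta[1] >= 0:
                beta[1] = -1.0
            return beta
    except Exception:  # noqa: BLE001
        pass
    b0 = float(np.log(max(y.mean(), 1e-8)) + ld.mean())
    return np.array([b0, -1.0, 0.0, 0.0, 0.0])


def _map_theta(target: _MixTarget, counts: np.ndarray, ld: np.ndarray,
               cov: np.ndarray) -> np.ndarray:
    """Posterior-mode starting point by alternating maximization.

    For fixed betas the log-likelihood is concave in the proportions (the
    rate is linear in them), so the proportion step reaches its global
    optimum; alternating with a beta step and a joint polish avoids the
    flat-start basin the joint surface has in logit space.
    """
    from scipy.optimize import minimize

    k = target.k

    def neg(t):
        ll, _ = target.loglik_grad(t)
        return -ll

    def neg_grad(t):
        _, g = target.loglik_grad(t)
        return -g

    beta_init = _init_betas(counts, ld, cov)

    # restart list: flat proportions plus starts favoring one component
    # each; for large candidate sets only the best-scoring single
    # components (by their pure-component likelihood) are favored
    starts = [np.zeros(k - 1)]
    fav = list(range(k))
    if k > 16:
        scores = [target.loglik_grad(np.concatenate(
            [_favor(j, k), beta_init]))[0] for j in range(k)]
        fav = list(np.argsort(scores)[::-1][:12])
    starts += [_favor(j, k) for j in fav]

    best, best_ll = None, -np.inf
    for logits0 in starts:
        theta = np.concatenate([logits0, beta_init])
        # beta step first so a favored component shapes the rate model
        # before the (concave, globally solvable) proportion step runs
        for _ in range(3):
            res = minimize(lambda b: neg(np.concatenate([theta[: k - 1], b])),
                           theta[k - 1:],
                           jac=lambda b: neg_grad(
                               np.concatenate([theta[: k - 1], b]))[k - 1:],
                           method="L-BFGS-B")
            theta[k - 1:] = res.x
            res = minimize(lambda l: neg(np.concatenate([l, theta[k - 1:]])),
                           theta[: k - 1],
                           jac=lambda l: neg_grad(
                               np.concatenate([l, theta[k - 1:]]))[: k - 1],
                           method="L-BFGS-B")
            theta[: k - 1] = res.x
        res = minimize(neg, theta, jac=neg_grad, method="L-BFGS-B")
        if -res.fun > best_ll:
            best_ll, best = -res.fun, res.x
    return best


def _favor(j: int, k: int) -> np.ndarray:
    """Logits concentrating initial mass on component j (last logit pinned)."""
    full = np.zeros(k)
    full[j] = 6.0
    return full[: k - 1] - full[k - 1]


def _sample_mixture(counts: np.ndarray, ld: np.ndarray, cov: np.ndarray,
                    cfg: SamplerConfig) -> tuple[np.ndarray, np.ndarray,
                                                 float, float, np.ndarray]:
    """Run the joint HMC chains; return (pi posterior mean, samples,
    mode cross loglik, Gelman-Rubin, mode betas)."""
    target = _MixTarget(counts, ld, cov, cfg.enforce_negative_decay)
    target_lik = _MixTarget(counts, ld, cov, cfg.enforce_negative_decay,
                            with_prior=False)
    theta_map = _map_theta(target_lik, counts, ld, cov)
    map_pi, _ = target_lik.unpack(theta_map)
    # extreme logits (pruned-to-zero components) destabilize the leapfrog
    theta_map[: target.k - 1] = np.clip(theta_map[: target.k - 1], -12, 12)
    mass_scale = _hessian_scale(target, theta_map)
    pi_samples: list[np.ndarray] = []
    mode_ll = -np.inf
    mode_theta = None
    traces = []
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([cfg.seed, 7919, chain])
        theta = theta_map + 0.05 * rng.normal(size=target.dim)
        step = cfg.hmc_step_size if cfg.hmc_step_size is not None else 0.2
        trace = np.empty(cfg.n_iter)
        for it in range(cfg.n_iter):
            theta, accepted, ll = _hmc_theta(
                theta, target, step, cfg.hmc_leapfrog_steps, rng,
                scale=mass_scale)
            if cfg.hmc_tune and it < cfg.burn_in:
                step *= 1.02 if accepted else 0.96
            trace[it] = ll
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                pi, _ = target.unpack(theta)
                pi_samples.append(np.concatenate([pi, theta[target.k - 1:]]))
                if ll > mode_ll:
                    mode_ll, mode_theta = ll, theta.copy()
        traces.append(trace[cfg.burn_in:])
    arr = np.asarray(pi_samples)
    pi_mean = arr[:, : target.k].mean(axis=0)
    pi_mean /= pi_mean.sum()
    gr = gelman_rubin(traces) if cfg.n_chains >= 2 else 1.0
    _, mode_beta = target.unpack(mode_theta)
    return pi_mean, arr, map_pi, mode_ll, float(gr), mode_beta


def _backward_eliminate(counts: np.ndarray, cov: np.ndarray,
                        struct_a: Structure3D, struct_b: Structure3D,
                        arrangements: list[Arrangement],
                        neg_decay: bool) -> list[Arrangement]:
    """Remove components one at a time (smallest ML proportion first)
    while the log-likelihood cost of removal stays below the BIC penalty
    0.5 ln(number of pairs); each component is one degree of freedom."""
    from scipy.optimize import minimize

    penalty = 0.5 * np.log(counts.size)

    def _mle(arrs, theta0):
        tgt = _MixTarget(counts, _cross_log_dists(struct_a, struct_b, arrs),
                         cov, neg_decay, with_prior=False)
        res = minimize(lambda t: -tgt.loglik_grad(t)[0], theta0,
                       jac=lambda t: -tgt.loglik_grad(t)[1],
                       method="L-BFGS-B")
        pi, _ = tgt.unpack(res.x)
        return -res.fun, res.x, pi

    active = list(arrangements)
    ld = _cross_log_dists(struct_a, struct_b, active)
    tgt = _MixTarget(counts, ld, cov, neg_decay, with_prior=False)
    theta = _map_theta(tgt, counts, ld, cov)
    ll, _, pi = _mle(active, theta)
    while len(active) > 1:
        j = int(np.argmin(pi))
        sub = [a for i, a in enumerate(active) if i != j]
        pi_sub = np.maximum(np.delete(pi, j), 1e-9)
        logits = np.log(pi_sub / pi_sub.sum())
        logits -= logits[-1]
        theta0 = np.concatenate([logits[:-1], theta[len(active) - 1:]])
        ll_sub, theta_sub, pi_new = _mle(sub, theta0)
        if ll - ll_sub >= penalty:
            break
        active, ll, theta, pi = sub, ll_sub, theta_sub, pi_new
    return active


def fit_continuous_arrangements(counts: np.ndarray, struct_a: Structure3D,
                                struct_b: Structure3D, lf_a: LocusFeatures,
                                lf_b: LocusFeatures,
                                neg_decay: bool = True,
                                ) -> list[Arrangement]:
    """Best one and two continuous arrangements of B by matching pursuit.

    The sub-structures come out of their fits in arbitrary rotation/mirror
    gauges, so the arrangement relating them is generally off any fixed
    Euler grid; a grid-only candidate set then pays a quantization penalty
    that a continuous single-structure fit does not.  This routine
    maximizes the cross-block likelihood over the Euler angles directly
    (both mirror states, multi-start), first for one arrangement, then for
    a second one added with a free weight.  The two fitted arrangements
    anchor the candidate set that the discrete mixture machinery refines.
    """
    from scipy.optimize import minimize

    cov = _cross_cov(lf_a, lf_b)

    def _target(arrs):
        return _MixTarget(counts, _cross_log_dists(struct_a, struct_b, arrs),
                          cov, neg_decay, with_prior=False)

    beta0 = _init_betas(counts,
                        _cross_log_dists(struct_a, struct_b,
                                         [arrangement_transform((0, 0, 0),
                                                                1)]),
                        cov)
    starts = [(a, b, g) for a in (0.8, 2.4, 4.0, 5.6)
              for b in (0.8, 2.4) for g in (1.6,)]

    def _fit_k1():
        best = (-np.inf, None, None)
        for mirror in (1, -1):
            for e0 in starts:
                def neg(x):
                    arr = arrangement_transform(tuple(x[:3]), mirror)
                    tgt = _target([arr])
                    return -tgt.loglik_grad(np.asarray(x[3:]))[0]

                res = minimize(neg, np.concatenate([e0, beta0]),
                               method="Nelder-Mead",
                               options={"maxiter": 400, "xatol": 1e-3,
                                        "fatol": 1e-3})
                if -res.fun > best[0]:
                    best = (-res.fun,
                            arrangement_transform(tuple(res.x[:3]), mirror),
                            res.x[3:])
        return best

    ll1, arr1, beta1 = _fit_k1()

    def _fit_k2(first):
        best = (-np.inf, None)
        for mirror in (1, -1):
            for e0 in starts:
                def neg(x):
                    arr2 = arrangement_transform(tuple(x[:3]), mirror)
                    tgt = _target([first, arr2])
                    theta = np.concatenate([[x[3]], x[4:]])
                    return -tgt.loglik_grad(theta)[0]

                x0 = np.concatenate([e0, [0.0], beta1])
                res = minimize(neg, x0, method="Nelder-Mead",
                               options={"maxiter": 400, "xatol": 1e-3,
                                        "fatol": 1e-3})
                if -res.fun > best[0]:
                    best = (-res.fun,
                            arrangement_transform(tuple(res.x[:3]), mirror))
        return best

    ll2, arr2 = _fit_k2(arr1)
    return [arr1, arr2]


def _unit_bonds(s: Structure3D) -> Structure3D:
    bonds = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
    mean_bond = float(bonds.mean())
    if mean_bond <= 0:
        raise ValueError("degenerate structure: zero mean bond length")
    return Structure3D(s.coords / mean_bond)


def prune_mixture(mixture: ArrangementMixture,
                  threshold: float = 0.01) -> ArrangementMixture:
    """Drop components with proportion below ``threshold`` and renormalize;
    the largest component is always kept."""
    keep = mixture.proportions >= threshold
    if not keep.any():
        keep[np.argmax(mixture.proportions)] = True
    arrs = [a for a, k in zip(mixture.arrangements, keep) if k]
    props = mixture.proportions[keep]
    return ArrangementMixture(arrs, props / props.sum())


def effective_structures(mixture: ArrangementMixture,
                         threshold: float = 0.05) -> int:
    """Number of components with proportion strictly above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return int(np.sum(mixture.proportions > threshold))


def run_bach_mix(cm_cross: np.ndarray,
                 fit_a: BachFit | Structure3D, fit_b: BachFit | Structure3D,
                 lf_a: LocusFeatures, lf_b: LocusFeatures,
                 cfg: SamplerConfig = SamplerConfig(),
                 arrangements: list[Arrangement] | None = None,
                 prune_threshold: float = 0.01,
                 bins_per_angle: int = 4) -> MixFit:
    """Infer the arrangement mixture from the inter-region contact matrix.

    ``fit_a``/``fit_b`` are the BACH fits (or bare structures) of the two
    sub-regions; their mode structures are held fixed.  Proportions and
    nuisance parameters are updated jointly by HMC; components below
    ``prune_threshold`` posterior-mean proportion are removed and the
    reduced model refitted.  When BACH fits are supplied their intra-region
    log-likelihoods enter ``total_loglik`` and the AIC, with
    k = 3 N_A + 3 N_B + 5 + (K - 1) parameters.
    """
    struct_a = fit_a.mode_structure if isinstance(fit_a, BachFit) else fit_a
    struct_b = fit_b.mode_structure if isinstance(fit_b, BachFit) else fit_b
    # Each sub-fit carries an arbitrary scale gauge (coordinate scale
    # trades off against the intercept), and the RELATIVE scale of B to A
    # is not absorbable by the rate parameters: bring both structures to
    # unit mean bond length before composing them.
    struct_a = _unit_bonds(struct_a)
    struct_b = _unit_bonds(struct_b)
    counts = np.asarray(cm_cross, dtype=float)
    if counts.shape != (struct_a.n_loci, struct_b.n_loci):
        raise ValueError("cross matrix shape does not match the structures")
    if arrangements is None:
        # data-adapted candidates: the two best continuous arrangements
        # plus a well-separated subset of the Euler grid
        adapted = fit_continuous_arrangements(
            counts, struct_a, struct_b, lf_a, lf_b,
            neg_decay=cfg.enforce_negative_decay)
        grid = select_separated_arrangements(
            struct_a, struct_b, k=10,
            pool=enumerate_arrangements(bins_per_angle))
        arrangements = adapted + grid
    cov = _cross_cov(lf_a, lf_b)

    def _one_round(arrs):
        ld = _cross_log_dists(struct_a, struct_b, arrs)
        pi, samples, map_pi, ll, gr, beta = _sample_mixture(
            counts, ld, cov, cfg)
        return ArrangementMixture(arrs, pi), samples, map_pi, ll, gr, beta

    mixture, samples, map_pi, ll, gr, beta = _one_round(arrangements)
    # Prune-and-refit until every component clears the rule.  The pruning
    # decision uses the maximum-likelihood proportions of the round: the
    # posterior mean of a boundary (zero) component is biased upward by
    # simplex positivity and would never fall below the rule, while the
    # likelihood optimum is exactly sparse.
    for _ in range(len(arrangements)):
        map_mixture = ArrangementMixture(mixture.arrangements,
                                         map_pi / map_pi.sum())
        pruned = prune_mixture(map_mixture, prune_threshold)
        if pruned.k == mixture.k:
            break
        mixture, samples, map_pi, ll, gr, beta = _one_round(
            pruned.arrangements)
    # Backward elimination: a component whose removal costs less than the
    # BIC penalty (half the log of the number of informative pairs) in
    # log-likelihood is absorbing Poisson noise, not population structure.
    survivors = _backward_eliminate(counts, cov, struct_a, struct_b,
                                    list(mixture.arrangements),
                                    cfg.enforce_negative_decay)
    if len(survivors) < mixture.k:
        mixture, samples, map_pi, ll, gr, beta = _one_round(survivors)

    intra = 0.0
    have_intra = isinstance(fit_a, BachFit) and isinstance(fit_b, BachFit)
    if have_intra:
        intra = fit_a.mode_loglik + fit_b.mode_loglik
    total = ll + intra
    k_params = (3 * struct_a.n_loci + 3 * struct_b.n_loci + 5
                + (mixture.k - 1)) if have_intra else 5 + (mixture.k - 1)
    return MixFit(mixture=mixture, params=ModelParams.from_array(beta),
                  loglik=ll, total_loglik=total,
                  aic=aic(total, k_params), converged=bool(gr <= 1.1),
                  gelman_rubin=gr, proportion_samples=samples)


@dataclass
class ModelSelection:
    selected: str            # "single" or "mixture"
    aic_single: float
    aic_mixture: float


def compare_models_aic(bach_fit: BachFit, mix_fit: MixFit) -> ModelSelection:
    """Pick the model with smaller AIC: one consensus structure for the
    whole region versus a mixture of arrangements of its two halves."""
    selected = "single" if bach_fit.aic <= mix_fit.aic else "mixture"
    return ModelSelection(selected=selected, aic_single=bach_fit.aic,
                          aic_mixture=mix_fit.aic)
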