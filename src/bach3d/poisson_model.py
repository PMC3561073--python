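"""Bias-corrected Poisson likelihood linking 3D structure to Hi-C counts.

Off-diagonal counts n_ij are modelled as Poisson with log-rate

    ln lambda_ij = beta0 + beta_d ln d_ij
                 + beta_e ln(x_i x_j) + beta_g ln(g_i g_j) + beta_m ln(m_i m_j)

where d_ij is the Euclidean distance between beads i and j, and x, g, m are
the restriction fragment-end count, GC content and mappability of each
locus.  beta_d < 0 encodes contact-frequency decay with spatial distance;
the bias terms follow the log-linear normalization framework standard for
Hi-C (enzyme, GC and mappability effects multiply the rate).

The likelihood is invariant to rigid motions of the structure, and a global
rescaling of coordinates trades off exactly against beta0; this gauge
freedom is deliberately not fixed here — posterior structures are compared
after superposition (see :mod:`bach3d.geometry`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .contact_data import ContactMatrix, GenomicBin, LocusFeatures

__all__ = [
    "Structure3D",
    "ModelParams",
    "pairwise_distances",
    "covariate_terms",
    "poisson_rates",
    "log_likelihood",
    "grad_log_posterior",
    "aic",
    "write_structure",
    "read_structure",
]


@dataclass
class Structure3D:
    """Ordered bead coordinates (N x 3, arbitrary units), one row per locus."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N x 3, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_loci(self) -> int:
        return self.coords.shape[0]

    def centered(self) -> "Structure3D":
        return Structure3D(self.coords - self.coords.mean(axis=0))


@dataclass
class ModelParams:
    """Nuisance parameters of the Poisson rate.

    beta_d is the distance-decay exponent (expected negative); beta_e,
    beta_g, beta_m scale the enzyme, GC and mappability bias effects.
    """

    beta0: float
    beta_d: float
    beta_e: float = 0.0
    beta_g: float = 0.0
    beta_m: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_d, self.beta_e,
                         self.beta_g, self.beta_m])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "ModelParams":
        return cls(*map(float, a))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls(**json.loads(Path(path).read_text()))


def pairwise_distances(s: Structure3D) -> np.ndarray:
    """Symmetric Euclidean distance matrix; zero diagonal.

    Coincident distinct beads are flagged because ln d would be -inf
    downstream.
    """
    d = squareform(pdist(s.coords))
    off = d + np.eye(s.n_loci)
    if np.any(off <= 0):
        i, j = np.argwhere((d == 0) & ~np.eye(s.n_loci, dtype=bool))[0]
        raise ValueError(f"coincident loci {i} and {j}: zero distance")
    return d


def covariate_terms(lf: LocusFeatures) -> np.ndarray:
    """Stack of the three pairwise log-covariate matrices.

    Returns shape (3, N, N): ln(x_i x_j), ln(g_i g_j), ln(m_i m_j).
    """
    lx, lg, lm = np.log(lf.frag_ends), np.log(lf.gc), np.log(lf.mappability)
    return np.stack([lx[:, None] + lx[None, :],
                     lg[:, None] + lg[None, :],
                     lm[:, None] + lm[None, :]])


def _log_rates(dist: np.ndarray, cov: np.ndarray, p: ModelParams) -> np.ndarray:
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        ld = np.log(dist + np.eye(n))  # diagonal unused; avoid log 0
    return (p.beta0 + p.beta_d * ld
            + p.beta_e * cov[0] + p.beta_g * cov[1] + p.beta_m * cov[2])


def poisson_rates(s: Structure3D, lf: LocusFeatures, p: ModelParams,
                  bias_terms: bool = True) -> np.ndarray:
    """Expected-count matrix lambda_ij (diagonal meaningless, set to 0).

    ``bias_terms=False`` drops the enzyme/GC/mappability effects (the
    uncorrected model variant).
    """
    if s.n_loci != len(lf):
        raise ValueError("structure and features disagree on locus count")
    dist = pairwise_distances(s)
    cov = covariate_terms(lf) if bias_terms else np.zeros((3, s.n_loci, s.n_loci))
    p_eff = p if bias_terms else ModelParams(p.beta0, p.beta_d, 0.0, 0.0, 0.0)
    lam = np.exp(_log_rates(dist, cov, p_eff))
    np.fill_diagonal(lam, 0.0)
    return lam


def log_likelihood(cm: ContactMatrix | np.ndarray, rates: np.ndarray) -> float:
    """Poisson log-likelihood over unordered off-diagonal pairs.

    sum_{i<j} [ n_ij ln lambda_ij - lambda_ij - ln(n_ij!) ]
    """
    counts = cm.counts if isinstance(cm, ContactMatrix) else np.asarray(cm)
    if counts.shape != rates.shape:
        raise ValueError("count and rate matrices differ in shape")
    iu = np.triu_indices(counts.shape[0], k=1)
    n, lam = counts[iu].astype(float), rates[iu]
    if np.any(lam <= 0):
        raise ValueError("nonpositive rate on an off-diagonal pair")
    return float(np.sum(n * np.log(lam) - lam - gammaln(n + 1)))


def grad_log_posterior(cm: ContactMatrix, s: Structure3D, lf: LocusFeatures,
                       p: ModelParams, bias_terms: bool = True,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the log-likelihood (flat priors, so this is the
    log-posterior gradient).

    Returns (coordinate gradient N x 3, parameter gradient length 5).
    Coordinate chain rule: d ln lambda_ij / d p_i = beta_d (p_i - p_j) / d_ij^2.
    """
    dist = pairwise_distances(s)
    cov = (covariate_terms(lf) if bias_terms
           else np.zeros((3, s.n_loci, s.n_loci)))
    p_eff = p if bias_terms else ModelParams(p.beta0, p.beta_d, 0.0, 0.0, 0.0)
    lam = np.exp(_log_rates(dist, cov, p_eff))
    np.fill_diagonal(lam, 0.0)
    resid = cm.counts - lam          # n_ij - lambda_ij, zero diagonal
    np.fill_diagonal(resid, 0.0)

    n = s.n_loci
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(np.eye(n, dtype=bool), 0.0, resid * p.beta_d / dist ** 2)
    diff = s.coords[:, None, :] - s.coords[None, :, :]   # p_i - p_j
    grad_coords = np.einsum("ij,ijk->ik", w, diff)

    iu = np.triu_indices(n, k=1)
    r = resid[iu]
    ld = np.log(dist[iu])
    grad_params = np.array([
        r.sum(),
        (r * ld).sum(),
        (r * cov[0][iu]).sum(),
        (r * cov[1][iu]).sum(),
        (r * cov[2][iu]).sum(),
    ])
    return grad_coords, grad_params


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 loglik (smaller is better)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * loglik


# ---------------------------------------------------------------------------
# Structure serialization: TSV of (index, chrom, start, end, x, y, z)


def write_structure(s: Structure3D, bins: list[GenomicBin],
                    path: str | Path) -> None:
    df = pd.DataFrame({
        "index": np.arange(s.n_loci),
        "chrom": [b.chrom for b in bins],
        "start": [b.start for b in bins],
        "end": [b.end for b in bins],
        "x": s.coords[:, 0], "y": s.coords[:, 1], "z": s.coords[:, 2],
    })
    df.to_csv(path, sep="\t", index=False)


def read_structure(path: str | Path) -> tuple[Structure3D, list[GenomicBin]]:
    df = pd.read_csv(path, sep="\t")
    bins = [GenomicBin(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)]
    return Structure3D(df[["x", "y", "z"]].values), bins
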