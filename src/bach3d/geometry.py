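"""Structure analytics: cylinder height/diameter ratio, scale-invariant
RMSD superposition, sliding-window local alignment, and the plane-separation
Fisher test.

Interpretive thresholds for the normalized RMSD: below
``RMSD_HIGH_SIMILARITY`` (0.1) two structures are highly similar, between
0.1 and ``RMSD_MODERATE_SIMILARITY`` (0.2) moderately similar, above 0.2
dissimilar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .poisson_model import Structure3D

__all__ = [
    "CylinderFit",
    "AlignmentResult",
    "RMSD_HIGH_SIMILARITY",
    "RMSD_MODERATE_SIMILARITY",
    "hd_ratio",
    "optimal_superposition",
    "sliding_window_rmsd",
    "plane_separation_test",
]

RMSD_HIGH_SIMILARITY = 0.1
RMSD_MODERATE_SIMILARITY = 0.2


@dataclass
class CylinderFit:
    """Cylinder approximation of a structure in its principal-axis frame."""

    height: float
    diameter: float
    hd_raw: float        # height / diameter, before size normalization
    hd_ratio: float      # normalized by N / n_ref
    pc_axes: np.ndarray  # rows are principal directions


@dataclass
class AlignmentResult:
    scale: float          # slope of distance regression through the origin
    rotation: np.ndarray  # proper rotation applied to the second structure
    rmsd: float           # normalized RMSD


def hd_ratio(s: Structure3D, n_ref: int = 25) -> CylinderFit:
    """Height-to-diameter ratio of a PCA-fitted cylinder.

    The structure is centered and rotated so the x-axis is the first
    principal component.  Height is the 10-90% inter-quantile range of the
    first-axis coordinates; the radius is twice the median radial distance
    in the plane of the second and third components.  The raw ratio
    height / diameter is then divided by N / n_ref so regions of different
    genomic size are comparable (n_ref = 25 loci, about 1 Mb at 40 kb bins).
    Larger values mean a more elongated structure.
    """
    x = s.coords - s.coords.mean(axis=0)
    if s.n_loci < 4:
        raise ValueError("need at least 4 loci for a cylinder fit")
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    rotated = x @ vt.T
    q10, q90 = np.quantile(rotated[:, 0], [0.1, 0.9])
    height = q90 - q10
    radial = np.hypot(rotated[:, 1], rotated[:, 2])
    med = float(np.median(radial))
    if med <= 0:
        raise ValueError("collinear structure: radial median is zero")
    radius = 2.0 * med
    diameter = 2.0 * radius
    hd_raw = height / diameter
    return CylinderFit(height=float(height), diameter=float(diameter),
                       hd_raw=float(hd_raw),
                       hd_ratio=float(hd_raw / (s.n_loci / n_ref)),
                       pc_axes=vt)


def _kabsch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||a - b R^T|| for centered point sets."""
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def optimal_superposition(a: Structure3D, b: Structure3D) -> AlignmentResult:
    """Scale- and rigid-motion-invariant superposition of two structures.

    The scale relating the two is estimated by regressing the pairwise
    distances of ``b`` on those of ``a`` through the origin.  For the RMSD
    itself each centered structure is normalized to unit radius of gyration
    — a symmetric normalization, so rmsd(a, b) == rmsd(b, a) exactly — and
    the optimal proper rotation comes from the SVD of the cross-covariance.
    Reflections are never absorbed by the alignment: mirror images are a
    modelling statement (see the arrangement mixture), not an alignment fix.
    """
    if a.n_loci != b.n_loci:
        raise ValueError("structures differ in length")
    if a.n_loci < 3:
        raise ValueError("need at least 3 beads")
    da, db = pdist(a.coords), pdist(b.coords)
    if np.allclose(da, 0) or np.allclose(db, 0):
        raise ValueError("degenerate structure: all points coincident")
    scale = float(np.dot(da, db) / np.dot(da, da))

    ca = a.coords - a.coords.mean(axis=0)
    cb = b.coords - b.coords.mean(axis=0)
    ra = np.sqrt(np.mean(np.sum(ca ** 2, axis=1)))
    rb = np.sqrt(np.mean(np.sum(cb ** 2, axis=1)))
    ua, ub = ca / ra, cb / rb
    rot = _kabsch(ua, ub)
    resid = ua - ub @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return AlignmentResult(scale=scale, rotation=rot, rmsd=rmsd)


def sliding_window_rmsd(a: Structure3D, b: Structure3D,
                        window: int = 10) -> np.ndarray:
    """Normalized RMSD over each length-``window`` stretch of two equal-length
    structures; K beads give exactly K - window + 1 values."""
    if a.n_loci != b.n_loci:
        raise ValueError("structures differ in length")
    k = a.n_loci
    if k < window:
        raise ValueError(f"structure length {k} shorter than window {window}")
    out = np.empty(k - window + 1)
    for i in range(k - window + 1):
        wa = Structure3D(a.coords[i:i + window])
        wb = Structure3D(b.coords[i:i + window])
        out[i] = optimal_superposition(wa, wb).rmsd
    return out


def plane_separation_test(coords: np.ndarray, labels: np.ndarray,
                          ) -> tuple[float, float, np.ndarray]:
    """Test spatial separation of two point groups across a fitted plane.

    A least-squares plane is fitted through the points labelled ``"mid"``
    (total least squares: the plane through their centroid normal to their
    smallest principal component).  Points labelled ``"low"`` and ``"high"``
    are classified by plane side, and a two-sided Fisher exact test on the
    2x2 group-by-side table measures separation.

    Returns (odds ratio, p-value, table).  If the table has a zero cell the
    odds ratio uses the Haldane correction (+0.5 per cell); the p-value is
    the uncorrected Fisher exact value.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    mid = coords[labels == "mid"]
    lo = coords[labels == "low"]
    hi = coords[labels == "high"]
    if len(mid) < 3:
        raise ValueError("need at least 3 mid-group points to fit a plane")
    if len(lo) < 1 or len(hi) < 1:
        raise ValueError("need at least one point in each of low and high")
    centered = mid - mid.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300):
        raise ValueError("mid points are collinear: plane under-determined")
    normal = vt[2]
    side_lo = (lo - mid.mean(axis=0)) @ normal > 0
    side_hi = (hi - mid.mean(axis=0)) @ normal > 0
    table = np.array([[int(side_lo.sum()), int((~side_lo).sum())],
                      [int(side_hi.sum()), int((~side_hi).sum())]])
    _, pvalue = stats.fisher_exact(table, alternative="two-sided")
    if np.any(table == 0):
        t = table + 0.5
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return odds, float(pvalue), table
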