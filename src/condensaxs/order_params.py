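"""Structural order parameters of RNA conformers and ensembles.

The orientation correlation function (OCF) is the mean cosine between
normalized bond vectors of consecutive backbone phosphorus atoms, as a
function of the separation |i - j| between linkages; oscillation signals
helicity, exponential decay a featureless random chain.  Summing the OCF and
multiplying by the mean bond length gives a correlation length l_OCF, a
stiffness/order proxy.  Base stacking is detected from total-least-squares
planes fitted to each nucleotide's aromatic ring: two bases are stacked when
their plane centroids are within a distance cutoff (default 5 A) and their
normals within an angular cutoff (default 45 deg, acute angle).

Convention for l_OCF: the sum runs over separations s = 0 .. n_bonds-1 of the
mean OCF value per separation (s = 0 contributes 1), multiplied by the mean
bond length b, so a rigid rod of n bonds gives n*b and a delta-correlated
chain gives b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import angle_between
from .chains import BASE_RING_ATOMS, Conformer

__all__ = [
    "OCFResult",
    "StackingResult",
    "ocf",
    "locf",
    "stacking_fraction",
    "ensemble_weighted_metric",
    "base_planes",
]


@dataclass
class OCFResult:
    separations: np.ndarray   # 0 .. n_bonds-1
    ocf: np.ndarray           # mean cos(theta) per separation
    b: float                  # mean bond length, A

    def __post_init__(self):
        self.separations = np.asarray(self.separations)
        self.ocf = np.asarray(self.ocf, dtype=float)


def ocf(conformer: Conformer, backbone_atom: str = "P") -> OCFResult:
    """Orientation correlation function of the backbone bond vectors."""
    pts = conformer.backbone_points(backbone_atom)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 backbone points")
    bonds = np.diff(pts, axis=0)
    norms = np.linalg.norm(bonds, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("coincident consecutive backbone points")
    unit = bonds / norms[:, None]
    n = unit.shape[0]
    dots = unit @ unit.T
    vals = np.empty(n)
    for s in range(n):
        vals[s] = np.mean(np.diagonal(dots, offset=s))
    return OCFResult(separations=np.arange(n), ocf=vals, b=float(norms.mean()))


def locf(ocf_result: OCFResult) -> float:
    """Correlation length l_OCF = b * sum_s OCF(s), s = 0 .. n_bonds-1 (A)."""
    return float(ocf_result.b * np.sum(ocf_result.ocf))


@dataclass
class StackingResult:
    percent_stacked: float               # % of bases with >= 1 stacking partner
    pairs: list[tuple[int, int]]
    dist_cutoff: float
    angle_cutoff: float
    normals: np.ndarray                  # (n_res, 3) fitted plane normals
    centroids: np.ndarray                # (n_res, 3)


def base_planes(conformer: Conformer):
    """Total-least-squares plane per base ring: (centroids, unit normals).

    The normal is the smallest-variance eigenvector of the ring-atom scatter,
    which makes the fit rotation invariant; rings need >= 3 non-collinear
    heavy atoms.
    """
    n_res = conformer.n_residues
    centroids = np.empty((n_res, 3))
    normals = np.empty((n_res, 3))
    for r in range(n_res):
        base = conformer.sequence[r]
        names = BASE_RING_ATOMS[base]
        pts = np.array([conformer.atom(r, nm) for nm in names])
        c = pts.mean(axis=0)
        u, s, vt = np.linalg.svd(pts - c)
        if s[1] < 1e-9:
            raise ValueError(f"collinear ring coordinates in residue {r}")
        centroids[r] = c
        normals[r] = vt[2]
    return centroids, normals


def stacking_fraction(conformer: Conformer, dist_cutoff: float = 5.0,
                      angle_cutoff: float = 45.0,
                      adjacent_only: bool = False) -> StackingResult:
    """Fraction of bases with at least one stacking partner.

    A pair is stacked when the fitted-plane centroids are <= dist_cutoff apart
    and the acute angle between the plane normals is <= angle_cutoff.
    adjacent_only restricts partners to sequence neighbours.
    """
    centroids, normals = base_planes(conformer)
    n = centroids.shape[0]
    pairs = []
    stacked = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if adjacent_only and j != i + 1:
                continue
            if np.linalg.norm(centroids[i] - centroids[j]) > dist_cutoff:
                continue
            ang = angle_between(normals[i], normals[j])
            if min(ang, 180.0 - ang) > angle_cutoff:
                continue
            pairs.append((i, j))
            stacked[i] = stacked[j] = True
    return StackingResult(percent_stacked=100.0 * stacked.mean(), pairs=pairs,
                          dist_cutoff=dist_cutoff, angle_cutoff=angle_cutoff,
                          normals=normals, centroids=centroids)


def ensemble_weighted_metric(values, weights):
    """Selection-weighted mean and standard deviation of a per-conformer metric."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must be parallel")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    mean = float(w @ v)
    var = float(w @ (v - mean) ** 2)
    return mean, float(np.sqrt(var))
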