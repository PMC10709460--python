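"""Gyration-tensor shape descriptors and their probability densities.

The (weighted) gyration tensor of a point set is

    S_ab = sum_i w_i (r_i - rbar)_a (r_i - rbar)_b / sum_i w_i

with rbar the weighted centroid.  Its eigenvalues lambda1 >= lambda2 >=
lambda3 (nm^2) give

* the squared radius of gyration  Rg^2 = lambda1 + lambda2 + lambda3,
* the relative shape anisotropy
      kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l1 l3) / (l1 + l2 + l3)^2,
  which is 0 for highly symmetric (spherical) distributions and 1 for an
  ideal linear chain,
* the asphericity  b = lambda1 - (lambda2 + lambda3) / 2  (nm^2), zero for
  spherical symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cdtraj.model_io import Topology, Trajectory, TailWindow

__all__ = [
    "ShapeRecord", "DensityEstimate",
    "gyration_tensor", "shape_descriptors", "shape_series", "descriptor_density",
]


@dataclass(frozen=True)
class ShapeRecord:
    """Eigenvalues (nm^2), Rg (nm), kappa^2 and asphericity b (nm^2)."""

    lambda1: float
    lambda2: float
    lambda3: float
    rg: float
    kappa2: float
    b: float


def gyration_tensor(points: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted second-moment tensor about the weighted centroid (3x3, nm^2)."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise ValueError("points must be (n, 3) with n >= 1")
    if weights is None:
        w = np.ones(p.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (p.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per point")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    centroid = (w[:, None] * p).sum(axis=0) / total
    c = p - centroid
    return (w[:, None, None] * c[:, :, None] * c[:, None, :]).sum(axis=0) / total


def shape_descriptors(tensor: np.ndarray) -> ShapeRecord:
    """Eigen-decompose a gyration tensor into the shape descriptors.

    kappa^2 is clamped to [0, 1] only against round-off (excursions below
    1e-10); the zero tensor maps to kappa^2 = 0 by the continuity
    convention that a point is perfectly symmetric.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("tensor must be symmetric")
    eig = np.linalg.eigvalsh(t)[::-1]            # descending
    eig = np.where(np.abs(eig) < 1e-14, np.abs(eig), eig)
    if np.any(eig < -1e-10):
        raise ValueError("tensor must be positive semi-definite")
    eig = np.clip(eig, 0.0, None)
    l1, l2, l3 = eig
    trace = l1 + l2 + l3
    if trace <= 0:
        return ShapeRecord(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    kappa2 = 1.0 - 3.0 * (l1 * l2 + l2 * l3 + l1 * l3) / trace ** 2
    if kappa2 < -1e-10 or kappa2 > 1 + 1e-10:
        raise ValueError(f"kappa^2 = {kappa2} outside [0, 1] beyond round-off")
    kappa2 = float(np.clip(kappa2, 0.0, 1.0))
    b = l1 - 0.5 * (l2 + l3)
    return ShapeRecord(float(l1), float(l2), float(l3),
                       float(np.sqrt(trace)), kappa2, float(b))


def shape_series(trajectory: Trajectory, indices, topology: Topology | None = None,
                 weighting: str = "mass",
                 window: TailWindow | None = None) -> pd.DataFrame:
    """Per-frame shape descriptors of an atom group.

    ``weighting`` is 'mass' (uses topology masses when present, else
    uniform) or 'uniform'.
    """
    idx = np.asarray(indices, dtype=int)
    if weighting == "mass" and topology is not None:
        w = topology.mass_weights(idx)
    elif weighting in ("mass", "uniform"):
        w = None
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    frames = window.indices if window is not None else range(trajectory.n_frames)
    rows = []
    for i in frames:
        rec = shape_descriptors(gyration_tensor(trajectory.frames[i].coordinates[idx], w))
        rows.append({
            "frame": i,
            "time_ps": trajectory.t0 + i * trajectory.dt,
            "lambda1": rec.lambda1, "lambda2": rec.lambda2, "lambda3": rec.lambda3,
            "Rg": rec.rg, "kappa2": rec.kappa2, "b": rec.b,
        })
    return pd.DataFrame(rows)


@dataclass
class DensityEstimate:
    """A normalized probability density on a 1D grid."""

    grid: np.ndarray        # bin centers (histogram) or evaluation points (kde)
    density: np.ndarray
    bin_width: float
    mode: float             # grid location of the density maximum

    def integral(self) -> float:
        return float(self.density.sum() * self.bin_width)


def descriptor_density(series: np.ndarray, support: tuple[float, float] | None = None,
                       bins: int = 50, bandwidth: float | None = None,
                       method: str = "histogram") -> DensityEstimate:
    """Probability density of a descriptor series.

    Default: a normalized histogram with ``bins`` bins on ``support`` (the
    data range when omitted).  ``method='kde'`` evaluates a Gaussian kernel
    density (scipy, Scott bandwidth unless given) on the same grid.
    """
    s = np.asarray(series, dtype=float).ravel()
    if len(s) < 2:
        raise ValueError("need at least 2 samples")
    if support is None:
        lo, hi = float(s.min()), float(s.max())
        if hi == lo:
            hi = lo + max(abs(lo), 1.0) * 1e-6
    else:
        lo, hi = support
        if not hi > lo:
            raise ValueError("support must be an increasing interval")
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    if method == "histogram":
        dens, _ = np.histogram(s, bins=edges, density=True)
    elif method == "kde":
        from scipy.stats import gaussian_kde
        if s.std() == 0:
            if not bandwidth:
                raise ValueError("constant series with zero bandwidth")
            dens = np.exp(-0.5 * ((centers - s[0]) / bandwidth) ** 2)
            dens /= dens.sum() * width
        else:
            kde = gaussian_kde(s, bw_method=bandwidth)
            dens = kde(centers)
            dens = dens / (dens.sum() * width)
    else:
        raise ValueError(f"unknown density method: {method!r}")
    mode = float(centers[int(np.argmax(dens))])
    return DensityEstimate(grid=centers, density=dens, bin_width=float(width), mode=mode)
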