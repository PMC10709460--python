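"""Kabsch-superposition RMSD and 2D free-energy landscapes over (RMSD, Rg).

The landscape is Boltzmann inversion of the sampled 2D histogram of the
two collective variables:

    F(x, y) = -kT ln( P(x, y) / P_max ),

so the global minimum is exactly 0 on the most occupied bin; empty bins
are masked, never assigned a finite free energy.  Basin minima and the
barrier between them (lowest saddle along any occupied-bin path,
4-connectivity) are located on the discrete grid with no smoothing.

Note RMSD after optimal superposition is not a metric (the triangle
inequality can fail); only symmetry is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cdtraj.model_io import Topology, Trajectory, TailWindow

__all__ = ["Landscape2D", "kabsch_rmsd", "cv_series", "fel_2d", "find_minima"]


def kabsch_rmsd(coords: np.ndarray, reference: np.ndarray,
                weights: np.ndarray | None = None) -> float:
    """Weighted RMSD (nm) after optimal rigid superposition.

    Both centroids are removed and the optimal rotation found from the SVD
    of the weighted covariance, with det = +1 enforced (no reflections).
    """
    a = np.asarray(coords, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3) with equal n")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms")
    if weights is None:
        w = np.ones(a.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (a.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    ac = a - (wn[:, None] * a).sum(axis=0)
    bc = b - (wn[:, None] * b).sum(axis=0)
    cov = (wn[:, None] * bc).T @ ac
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = ac @ rot.T - bc
    return float(np.sqrt((wn * (diff ** 2).sum(axis=1)).sum()))


def cv_series(trajectory: Trajectory, indices, reference: np.ndarray,
              topology: Topology | None = None, weighting: str = "mass",
              window: TailWindow | None = None) -> pd.DataFrame:
    """Per-frame collective variables: Kabsch RMSD vs a fixed reference, and Rg."""
    from cdtraj.shape import gyration_tensor, shape_descriptors

    idx = np.asarray(indices, dtype=int)
    ref = np.asarray(reference, dtype=float)[idx] if len(reference) > len(idx) \
        else np.asarray(reference, dtype=float)
    if weighting == "mass" and topology is not None:
        w = topology.mass_weights(idx)
    else:
        w = None
    frames = window.indices if window is not None else range(trajectory.n_frames)
    rows = []
    for i in frames:
        pts = trajectory.frames[i].coordinates[idx]
        rec = shape_descriptors(gyration_tensor(pts, w))
        rows.append({
            "frame": i,
            "time_ps": trajectory.t0 + i * trajectory.dt,
            "rmsd": kabsch_rmsd(pts, ref, w),
            "Rg": rec.rg,
        })
    return pd.DataFrame(rows)


@dataclass
class Landscape2D:
    """Free energies (kJ/mol) on a 2D collective-variable grid.

    ``free_energy`` is a masked array: masked entries are never-visited
    bins.  The minimum over occupied bins is exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray
    kT: float
    counts: np.ndarray

    def bin_center(self, ij: tuple[int, int]) -> tuple[float, float]:
        i, j = ij
        return (0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
                0.5 * (self.y_edges[j] + self.y_edges[j + 1]))


def fel_2d(x: np.ndarray, y: np.ndarray, kT: float,
           bins: int | tuple[int, int] = 60,
           ranges=None, pad: float = 0.05) -> Landscape2D:
    """Free-energy landscape F = -kT ln(P / P_max) over two CV series.

    The grid spans the observed range of each variable padded by ``pad``
    (fraction of the span) unless explicit ``ranges`` are given.
    Reordering samples or scaling all counts leaves F unchanged.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be equal-length, non-empty series")
    if kT <= 0:
        raise ValueError("kT must be positive")
    if ranges is None:
        ranges = []
        for s in (x, y):
            lo, hi = float(s.min()), float(s.max())
            span = hi - lo if hi > lo else max(abs(hi), 1.0) * 1e-6
            ranges.append((lo - pad * span, hi + pad * span))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=ranges)
    if counts.sum() == 0:
        raise ValueError("no samples fall inside the landscape ranges")
    p = counts / counts.sum()
    occupied = counts > 0
    f = np.ma.masked_array(np.zeros_like(p), mask=~occupied)
    pmax = p.max()
    f[occupied] = -kT * np.log(p[occupied] / pmax)
    return Landscape2D(x_edges=x_edges, y_edges=y_edges, free_energy=f,
                       kT=kT, counts=counts.astype(int))


def find_minima(landscape: Landscape2D,
                depth_threshold: float | None = None) -> list[dict]:
    """Local minima of the landscape with pairwise minimax barriers.

    A bin is a local minimum if no occupied 4-neighbour lies strictly
    below it (plateaus keep their first bin in scan order).  The barrier
    between two minima is the lowest ridge F crossed on any occupied-bin
    path between them (computed by a union-find sweep in order of
    increasing F).  Each entry: ``{"bin", "cv", "F", "barriers": {other_rank:
    saddle_F}}``; minima are ranked by F.
    """
    f = landscape.free_energy
    occ = ~f.mask
    nx, ny = f.shape
    neigh = ((1, 0), (-1, 0), (0, 1), (0, -1))

    minima = []
    claimed = np.zeros_like(occ, dtype=bool)
    for i in range(nx):
        for j in range(ny):
            if not occ[i, j] or claimed[i, j]:
                continue
            val = f[i, j]
            is_min = True
            plateau_tied = False
            for di, dj in neigh:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and occ[a, b]:
                    if f[a, b] < val:
                        is_min = False
                        break
                    if f[a, b] == val and claimed[a, b]:
                        plateau_tied = True
            if is_min and not plateau_tied:
                if depth_threshold is None or val <= depth_threshold:
                    minima.append({"bin": (i, j), "F": float(val)})
                    claimed[i, j] = True
    minima.sort(key=lambda m: m["F"])

    # minimax saddles by Kruskal-style sweep over occupied bins
    order = sorted(((float(f[i, j]), i, j) for i in range(nx) for j in range(ny)
                    if occ[i, j]))
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    min_of: dict[tuple[int, int], set[int]] = {}
    bin_to_rank = {tuple(m["bin"]): r for r, m in enumerate(minima)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    barriers: dict[tuple[int, int], float] = {}
    active = np.zeros_like(occ, dtype=bool)
    for val, i, j in order:
        key = (i, j)
        parent[key] = key
        min_of[key] = {bin_to_rank[key]} if key in bin_to_rank else set()
        active[i, j] = True
        for di, dj in neigh:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and active[a, b]:
                ra, rb = find(key), find((a, b))
                if ra == rb:
                    continue
                for m1 in min_of[ra]:
                    for m2 in min_of[rb]:
                        pair = (min(m1, m2), max(m1, m2))
                        barriers.setdefault(pair, val)
                parent[ra] = rb
                min_of[rb] = min_of[rb] | min_of[ra]

    for r, m in enumerate(minima):
        m["cv"] = landscape.bin_center(m["bin"])
        m["barriers"] = {other: barriers[(min(r, other), max(r, other))]
                         for other in range(len(minima))
                         if other != r and (min(r, other), max(r, other)) in barriers}
    return minima
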