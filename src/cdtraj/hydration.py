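"""Cavity hydration: shell-wise water occupancy and radial distribution.

A water molecule is located by its oxygen (standard convention).  The
cavity center is the midpoint between the PHR and SHR rim centroids,
recomputed every frame.  Shell occupancy counts water oxygens whose
minimum-image distance to that center falls in half-open, lower-inclusive
radial bins (defaults [0, 0.5, 0.8, 0.9, 1.0] nm).  The radial
distribution function normalizes the per-shell counts by an ideal-gas
expectation at the bulk density, g(r) = <n(r)> / (rho * 4 pi r^2 dr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cdtraj.model_io import Topology, Trajectory, TailWindow
from cdtraj.geometry import cavity_axis, minimum_image

__all__ = ["ShellOccupancy", "DEFAULT_SHELL_EDGES", "shell_counts", "rdf"]

DEFAULT_SHELL_EDGES = (0.0, 0.5, 0.8, 0.9, 1.0)


@dataclass
class ShellOccupancy:
    """Per-frame integer shell counts and their windowed mean +/- SE."""

    edges: np.ndarray
    per_frame: pd.DataFrame    # one row per frame, one column per shell + total
    summary: pd.DataFrame      # shell, mean, se

    @property
    def totals(self) -> np.ndarray:
        return self.per_frame["total"].to_numpy()


def _cavity_centers(trajectory: Trajectory, topology: Topology, center_def: str,
                    frames) -> np.ndarray:
    centers = np.empty((len(frames), 3))
    for k, i in enumerate(frames):
        f = trajectory.frames[i]
        if center_def == "cavity":
            _, centers[k] = cavity_axis(f, topology)
        elif center_def == "box":
            centers[k] = 0.5 * f.box
        else:
            raise ValueError(f"unknown center definition: {center_def!r}")
    return centers


def shell_counts(trajectory: Trajectory, topology: Topology,
                 center_def: str = "cavity",
                 edges=DEFAULT_SHELL_EDGES,
                 window: TailWindow | None = None,
                 n_blocks: int = 5) -> ShellOccupancy:
    """Count water oxygens in concentric spherical shells around the cavity center.

    Bins are half-open ``[edge_k, edge_{k+1})``; a water exactly on an edge
    belongs to the outer shell.  The summary is a block-averaged mean +/- SE
    per shell over the analysis window, plus the total over the full range.
    """
    from cdtraj.energetics import block_average

    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0) or edges[0] < 0:
        raise ValueError("edges must be non-negative and strictly increasing")
    waters = np.asarray(topology.water_oxygens, dtype=int)
    if len(waters) == 0:
        raise ValueError("topology has no water oxygens")
    frames = list(window.indices) if window is not None else list(range(trajectory.n_frames))
    centers = _cavity_centers(trajectory, topology, center_def, frames)
    n_shell = len(edges) - 1
    counts = np.zeros((len(frames), n_shell), dtype=int)
    for k, i in enumerate(frames):
        f = trajectory.frames[i]
        d = np.linalg.norm(
            minimum_image(f.coordinates[waters] - centers[k], f.box), axis=1)
        for s in range(n_shell):
            counts[k, s] = int(np.sum((d >= edges[s]) & (d < edges[s + 1])))
    labels = [f"{edges[s]:g}-{edges[s+1]:g}nm" for s in range(n_shell)]
    per_frame = pd.DataFrame(counts, columns=labels)
    per_frame.insert(0, "frame", frames)
    per_frame["total"] = counts.sum(axis=1)

    rows = []
    for s, lab in enumerate(labels + ["total"]):
        series = (counts[:, s] if s < n_shell else counts.sum(axis=1)).astype(float)
        if len(series) >= n_blocks:
            mean, se = block_average(series, n_blocks)
        else:
            mean, se = float(series.mean()), 0.0
        rows.append({"shell": lab, "mean": mean, "se": se})
    return ShellOccupancy(edges=edges, per_frame=per_frame, summary=pd.DataFrame(rows))


def rdf(trajectory: Trajectory, topology: Topology,
        center_def: str = "cavity", water_group=None,
        bin_width: float = 0.02, r_max: float | None = None,
        window: TailWindow | None = None) -> pd.DataFrame:
    """Radial distribution g(r) of water oxygens around a single reference point.

    rho_bulk = N_water / V_box per frame;
    g(r) = <n(r)> / (rho_bulk * 4 pi r^2 dr).  ``r_max`` defaults to (and
    must not exceed) half the smallest box edge.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    waters = np.asarray(
        topology.water_oxygens if water_group is None else water_group, dtype=int)
    if len(waters) == 0:
        raise ValueError("empty water group")
    frames = list(window.indices) if window is not None else list(range(trajectory.n_frames))
    half_min_edge = min(float(trajectory.frames[i].box.min()) for i in frames) / 2.0
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-9:
        raise ValueError(
            f"r_max = {r_max} nm exceeds half the smallest box edge ({half_min_edge} nm)")
    centers = _cavity_centers(trajectory, topology, center_def, frames)
    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    norm = np.zeros(n_bins)
    for k, i in enumerate(frames):
        f = trajectory.frames[i]
        d = np.linalg.norm(
            minimum_image(f.coordinates[waters] - centers[k], f.box), axis=1)
        h, _ = np.histogram(d, bins=edges)
        hist += h
        rho = len(waters) / float(np.prod(f.box))
        shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        norm += rho * shell_vol
    g = np.where(norm > 0, hist / np.maximum(norm, 1e-300), 0.0)
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": centers_r, "g": g,
                         "mean_count": hist / len(frames)})
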