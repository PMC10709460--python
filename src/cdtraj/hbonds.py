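"""Geometric hydrogen-bond detection, per-pair counts and lifetimes.

A donor-hydrogen-acceptor triple forms a bond when the minimum-image
donor-acceptor distance is at most ``r_da`` (default 0.35 nm) and the
H-D-A angle is at most ``angle`` (default 30 degrees) - the GROMACS
geometric convention.  Detected bonds are labelled by the group pair of
their donor and acceptor molecules (water-CD, water-guest, guest-CD,
CD-CD); CD-CD bonds are the macrocycle's internal hydrogen bonds.

Lifetimes come in two definitions:

* ``continuous`` (default): mean length of uninterrupted presence
  episodes times the frame spacing - appropriate for episode-scale
  (tens of ps) lifetimes;
* ``intermittent``: integral of the normalized existence autocorrelation
  C(t) up to its first decay below 1/e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cdtraj.model_io import Frame, Topology, Trajectory, TailWindow
from cdtraj.geometry import minimum_image

__all__ = [
    "HBondCriterion", "HBond", "HBondSeries",
    "find_hbonds", "pair_counts", "lifetimes", "atom_group_label",
]

GROUP_PAIRS = ("water-CD", "water-guest", "guest-CD", "CD-CD")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: r(D,A) <= r_da nm and angle(H-D-A) <= angle deg."""

    r_da: float = 0.35
    angle: float = 30.0

    def __post_init__(self) -> None:
        if self.r_da <= 0 or self.angle <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    label: str


def atom_group_label(index: int, topology: Topology) -> str:
    """'water' / 'guest' / 'CD' membership of an atom for pair labelling."""
    if index in topology.guest_atoms:
        return "guest"
    resname = topology.resnames[index].upper()
    if resname in ("SOL", "WAT", "HOH", "TIP3", "SPC") or index in topology.water_oxygens:
        return "water"
    return "CD"


def _pair_label(donor_group: str, acceptor_group: str) -> str:
    pair = tuple(sorted((donor_group, acceptor_group)))
    mapping = {
        ("CD", "water"): "water-CD",
        ("guest", "water"): "water-guest",
        ("CD", "guest"): "guest-CD",
        ("CD", "CD"): "CD-CD",
        ("water", "water"): "water-water",
        ("guest", "guest"): "guest-guest",
    }
    return mapping[pair]


def find_hbonds(frame: Frame, topology: Topology,
                criterion: HBondCriterion = HBondCriterion()) -> list[HBond]:
    """All donor-H-acceptor triples satisfying the geometric criterion.

    Every annotated hydrogen must carry its covalent donor assignment;
    the trivial pair D == A is excluded.
    """
    if not topology.hydrogens:
        raise ValueError("topology has no hydrogen->donor assignments")
    acceptors = np.asarray(topology.acceptors, dtype=int)
    if len(acceptors) == 0:
        return []
    coords = frame.coordinates
    box = frame.box
    cos_cut = np.cos(np.deg2rad(criterion.angle))
    bonds: list[HBond] = []
    acc_pos = coords[acceptors]
    for h, d in sorted(topology.hydrogens.items()):
        if d not in topology.donors:
            raise ValueError(f"hydrogen {h} assigned to unannotated donor {d}")
        da = minimum_image(acc_pos - coords[d], box)
        dist = np.linalg.norm(da, axis=1)
        dh = minimum_image(coords[h] - coords[d], box)
        dh_norm = np.linalg.norm(dh)
        within = (dist <= criterion.r_da) & (acceptors != d)
        if dh_norm < 1e-12:
            continue
        for j in np.nonzero(within)[0]:
            cos_a = float(np.dot(dh, da[j]) / (dh_norm * dist[j]))
            if cos_a >= cos_cut:   # angle H-D-A <= cutoff
                a = int(acceptors[j])
                bonds.append(HBond(
                    donor=int(d), hydrogen=int(h), acceptor=a,
                    label=_pair_label(atom_group_label(d, topology),
                                      atom_group_label(a, topology))))
    return bonds


@dataclass
class HBondSeries:
    """Per-frame bond lists with group-pair counts, summaries and lifetimes."""

    per_frame_counts: pd.DataFrame              # frame x group-pair counts
    summary: pd.DataFrame                       # pair, mean, se, lifetime_ps
    bonds: list = field(default_factory=list)   # per-frame list[HBond]


def pair_counts(trajectory: Trajectory, topology: Topology,
                criterion: HBondCriterion = HBondCriterion(),
                window: TailWindow | None = None,
                dt: float | None = None,
                lifetime_definition: str = "continuous",
                n_blocks: int = 5) -> HBondSeries:
    """Hydrogen-bond counts per group pair with block-averaged means and lifetimes.

    Lifetimes are estimated from the existence matrix of every distinct
    (donor, hydrogen, acceptor) triple observed within the window.
    """
    from cdtraj.energetics import block_average

    frames = list(window.indices) if window is not None else list(range(trajectory.n_frames))
    dt = trajectory.dt if dt is None else dt
    all_bonds = []
    counts = {p: np.zeros(len(frames)) for p in GROUP_PAIRS}
    triple_presence: dict[tuple, np.ndarray] = {}
    triple_label: dict[tuple, str] = {}
    for k, i in enumerate(frames):
        bonds = find_hbonds(trajectory.frames[i], topology, criterion)
        all_bonds.append(bonds)
        for b in bonds:
            if b.label in counts:
                counts[b.label][k] += 1
            key = (b.donor, b.hydrogen, b.acceptor)
            if key not in triple_presence:
                triple_presence[key] = np.zeros(len(frames), dtype=bool)
                triple_label[key] = b.label
            triple_presence[key][k] = True

    life: dict[str, float | None] = {}
    for pair in GROUP_PAIRS:
        keys = [k for k, lab in triple_label.items() if lab == pair]
        if not keys:
            life[pair] = None
            continue
        mat = np.stack([triple_presence[k] for k in keys])
        lt = lifetimes(mat, dt, definition=lifetime_definition)
        life[pair] = lt["overall"]

    rows = []
    for pair in GROUP_PAIRS:
        series = counts[pair]
        if len(series) >= n_blocks:
            mean, se = block_average(series, n_blocks)
        else:
            mean, se = float(series.mean()), 0.0
        rows.append({"pair": pair, "mean": mean, "se": se,
                     "lifetime_ps": life[pair]})
    per_frame = pd.DataFrame({p: counts[p] for p in GROUP_PAIRS})
    per_frame.insert(0, "frame", frames)
    return HBondSeries(per_frame_counts=per_frame, summary=pd.DataFrame(rows),
                       bonds=all_bonds)


def lifetimes(existence_matrix: np.ndarray, dt: float,
              definition: str = "continuous") -> dict:
    """Hydrogen-bond lifetime (ps) from a boolean pairs x frames matrix.

    Returns ``{"overall": ps or None, "per_pair": list, "censored": bool}``.
    A bond never present has an undefined (None) lifetime, not 0; a bond
    present through the whole window is censored and flagged.
    """
    m = np.atleast_2d(np.asarray(existence_matrix, dtype=bool))
    if dt <= 0:
        raise ValueError("dt must be positive")
    if definition == "continuous":
        per_pair = []
        censored = False
        all_lengths = []
        for row in m:
            lengths = _episode_lengths(row)
            if len(lengths) == 1 and lengths[0] == m.shape[1]:
                censored = True
            per_pair.append(float(np.mean(lengths)) * dt if lengths else None)
            all_lengths.extend(lengths)
        overall = float(np.mean(all_lengths)) * dt if all_lengths else None
        return {"overall": overall, "per_pair": per_pair, "censored": censored}
    if definition == "intermittent":
        present = m.any(axis=1)
        if not present.any():
            return {"overall": None, "per_pair": [None] * m.shape[0], "censored": False}
        per_pair = [
            _intermittent_lifetime(row, dt) if row.any() else None for row in m]
        vals = [v for v in per_pair if v is not None]
        return {"overall": float(np.mean(vals)), "per_pair": per_pair,
                "censored": bool(m.all(axis=1).any())}
    raise ValueError(f"unknown lifetime definition: {definition!r}")


def _episode_lengths(row: np.ndarray) -> list[int]:
    """Lengths (frames) of maximal runs of True."""
    padded = np.concatenate([[0], row.astype(int), [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list((ends - starts).astype(int))


def _intermittent_lifetime(row: np.ndarray, dt: float) -> float:
    """Integral of the normalized existence autocorrelation up to 1/e decay."""
    h = row.astype(float)
    n = len(h)
    c = np.array([
        np.mean(h[: n - t] * h[t:]) for t in range(n)
    ])
    if c[0] <= 0:
        return 0.0
    c = c / c[0]
    below = np.nonzero(c < 1.0 / np.e)[0]
    t_end = int(below[0]) if len(below) else n - 1
    return float(np.trapezoid(c[: t_end + 1], dx=1.0) * dt)
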