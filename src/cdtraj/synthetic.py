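"""Synthetic fixtures with known ground truth for every analysis stage.

Nothing here integrates equations of motion.  The generators build the
*stated world* the analyses are tested against:

* a 7-unit macrocycle as three stacked oxygen rims (PHR/MID/SHR) whose
  radii and offsets default to the beta-cyclodextrin scale (rim areas
  ~1.10 / 0.83 / 1.32 nm^2, heights h16 = 0.33 and h12 = 0.22 nm);
* a rigid 8-bead elongated guest (~1.7 nm, one end tagged as the guest
  hydroxyl oxygen) moved along a scripted approach/insertion path with a
  controllable mechanism and orientation, with the per-frame true state
  recorded as a side channel;
* water baths with exact prescribed shell occupancies (inverse-CDF radial
  sampling, so uniform density within each shell is exact);
* hydrogen-bond existence matrices with planted episode structure;
* Crooks-consistent Gaussian work samples for validating the free-energy
  estimators: forward work ~ N(dG + sigma^2/(2kT), sigma^2) and reverse
  work ~ N(-dG + sigma^2/(2kT), sigma^2).

Every generator is reproducible bitwise from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cdtraj.model_io import Frame, Topology, Trajectory
from cdtraj.energetics import KB_KJ_PER_MOL_K, LambdaWindowSamples

__all__ = [
    "RingSpec", "BindingScript", "WorkSampleSpec",
    "make_cd_ring", "make_binding_trajectory", "make_water_bath",
    "carve_guest_exclusion", "make_hydrated_complex",
    "make_bar_samples", "make_hbond_episodes",
    "BETA_CD_RING", "METHYLATED_CD_RING",
]

O_MASS = 15.999
C_MASS = 12.011
GUEST_LENGTH_NM = 1.7
GUEST_BEADS = 8


def _radius_for_area(area: float, n: int) -> float:
    """Circumradius giving a regular n-gon the requested area."""
    return float(np.sqrt(2.0 * area / (n * np.sin(2.0 * np.pi / n))))


@dataclass(frozen=True)
class RingSpec:
    """Geometry of the three stacked rim-oxygen rings.

    Defaults reproduce the beta-cyclodextrin scale; with zero jitter and
    unit ellipticity every rim is a regular n-gon.  ``ellipticity`` > 1
    stretches a rim along x, lowering its circularity.
    """

    n_units: int = 7
    radius_phr: float = _radius_for_area(1.10, 7)
    radius_mid: float = _radius_for_area(0.83, 7)
    radius_shr: float = _radius_for_area(1.32, 7)
    z_phr: float = 0.33      # h16: MID (z=0) to PHR
    z_shr: float = -0.22     # h12: MID to SHR
    ellipticity_phr: float = 1.0
    ellipticity_mid: float = 1.0
    ellipticity_shr: float = 1.0
    jitter: float = 0.0      # per-atom Gaussian sigma, nm
    box: float = 4.0         # cubic box edge, nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("n_units must be >= 3")
        for r in (self.radius_phr, self.radius_mid, self.radius_shr):
            if r <= 0:
                raise ValueError("rim radii must be positive")
        if min(self.ellipticity_phr, self.ellipticity_mid, self.ellipticity_shr) < 1:
            raise ValueError("ellipticity factors must be >= 1")


BETA_CD_RING = RingSpec()
# functionalized (methylated) variant: smaller rims and heights
METHYLATED_CD_RING = RingSpec(
    radius_phr=_radius_for_area(1.05, 7),
    radius_mid=_radius_for_area(0.70, 7),
    radius_shr=_radius_for_area(1.08, 7),
    z_phr=0.22, z_shr=-0.12,
)


def make_cd_ring(spec: RingSpec = BETA_CD_RING) -> tuple[Topology, Frame]:
    """Three stacked rim-oxygen rings centred in a cubic box.

    Atom order: PHR oxygens (O6), MID oxygens (O1), SHR oxygens (O3), each
    ring in cyclic order.  The cavity axis points along +z toward the PHR.
    """
    n = spec.n_units
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.box / 2.0)
    angles = 2.0 * np.pi * np.arange(n) / n
    rims = [
        (spec.radius_phr, spec.z_phr, spec.ellipticity_phr),
        (spec.radius_mid, 0.0, spec.ellipticity_mid),
        (spec.radius_shr, spec.z_shr, spec.ellipticity_shr),
    ]
    coords = []
    for radius, z, ell in rims:
        ring = np.stack([
            radius * ell * np.cos(angles),
            radius * np.sin(angles),
            np.full(n, z),
        ], axis=1)
        if spec.jitter > 0:
            ring = ring + rng.normal(0.0, spec.jitter, size=ring.shape)
        coords.append(ring + center)
    coords = np.vstack(coords)
    names = [f"O6{i+1}" for i in range(n)] + [f"O1{i+1}" for i in range(n)] \
        + [f"O3{i+1}" for i in range(n)]
    topo = Topology(
        names=names,
        resnames=["BCD"] * (3 * n),
        resids=[1] * (3 * n),
        elements=["O"] * (3 * n),
        masses=np.full(3 * n, O_MASS),
        phr_oxygens=list(range(n)),
        mid_oxygens=list(range(n, 2 * n)),
        shr_oxygens=list(range(2 * n, 3 * n)),
    )
    return topo, Frame(coordinates=coords, box=np.full(3, spec.box))


@dataclass(frozen=True)
class BindingScript:
    """A scripted guest path: mechanism, orientation and event timing.

    ``direct_insert``: hold beyond the surface threshold, then transit to
    the cavity center, fully inserted from ``insertion_frame`` on.
    ``surface_then_insert``: dwell lying across the SHR face, then rotate
    upright (cubic ease-in over ``rotation_frames``) into the cavity -
    the pathway seen for the methylated host, scaled down.
    ``never_bind``: remain > 1 nm from the cavity at every frame.
    """

    mechanism: str = "direct_insert"            # | surface_then_insert | never_bind
    orientation: str = "O_toward_PHR"           # | O_toward_SHR
    insertion_frame: int = 100
    start_distance: float = 1.5                 # nm from the SHR rim
    noise: float = 0.02                         # guest-COG jitter sigma, nm
    rotation_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("direct_insert", "surface_then_insert", "never_bind"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.orientation not in ("O_toward_PHR", "O_toward_SHR"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def _guest_beads(cog: np.ndarray, axis: np.ndarray, orientation: str) -> np.ndarray:
    """Rigid rod of 8 beads; bead 0 is the hydroxyl-oxygen end."""
    axis = axis / np.linalg.norm(axis)
    offsets = np.linspace(GUEST_LENGTH_NM / 2.0, -GUEST_LENGTH_NM / 2.0, GUEST_BEADS)
    if orientation == "O_toward_SHR":
        offsets = -offsets
    return cog[None, :] + offsets[:, None] * axis[None, :]


def make_binding_trajectory(ring_spec: RingSpec = BETA_CD_RING,
                            script: BindingScript = BindingScript(),
                            n_frames: int = 200, dt: float = 10.0
                            ) -> tuple[Topology, Trajectory, pd.DataFrame]:
    """Host + scripted guest trajectory with a per-frame truth ledger.

    The returned ground truth records the scripted state
    ('unbound'/'surface'/'inserted'), the scripted orientation and the
    noise-free guest-COG distance from the cavity center per frame.
    """
    if script.mechanism != "never_bind" and not 0 < script.insertion_frame < n_frames:
        raise ValueError("insertion_frame must fall inside the trajectory")
    host_topo, host_frame = make_cd_ring(ring_spec)
    nh = host_topo.n_atoms
    center = np.full(3, ring_spec.box / 2.0)   # cavity center (z mid-plane)
    zc = center + np.array([0.0, 0.0, (ring_spec.z_phr + ring_spec.z_shr) / 2.0])
    axis = np.array([0.0, 0.0, 1.0])           # toward PHR
    shr_z = ring_spec.z_shr
    rng = np.random.default_rng(script.seed)

    hold_d = 1.0          # beyond d_surface while approaching
    surface_d = abs((ring_spec.z_phr + ring_spec.z_shr) / 2.0 - shr_z) + 0.15

    frames = []
    truth_rows = []
    for t in range(n_frames):
        state = "unbound"
        horizontal = False
        if script.mechanism == "never_bind":
            d = script.start_distance + 0.1 * np.sin(2 * np.pi * t / max(n_frames, 1))
            cog = zc - axis * d
        elif script.mechanism == "direct_insert":
            f_ins = script.insertion_frame
            if t >= f_ins:
                cog = zc.copy()
                state = "inserted"
            elif t >= f_ins - 2:
                # 2-frame transit from the hold distance to the center
                frac = (f_ins - t) / 2.0
                cog = zc - axis * (hold_d * frac)
                state = "surface" if hold_d * frac <= 0.80 else "unbound"
            else:
                span = max(f_ins - 2, 1)
                d = script.start_distance + (hold_d - script.start_distance) * t / span
                cog = zc - axis * d
        else:  # surface_then_insert
            f_ins = script.insertion_frame
            rot = script.rotation_frames
            approach_end = max(f_ins - rot - 20, 1)
            if t < approach_end:
                d = script.start_distance + (surface_d - script.start_distance) \
                    * t / approach_end
                cog = zc - axis * d
                state = "surface" if d <= 0.80 else "unbound"
                horizontal = True
            elif t < f_ins - rot:
                cog = zc - axis * surface_d
                state = "surface"
                horizontal = True
            elif t < f_ins:
                # cubic ease-in: most of the motion happens in the last frames
                p = (1.0 - (f_ins - t) / rot) ** 3
                cog = zc - axis * surface_d * (1.0 - p)
                state = "surface"
                tilt = np.deg2rad(90.0 * (1.0 - p))
                guest_axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
            else:
                cog = zc.copy()
                state = "inserted"
        if horizontal:
            guest_axis = np.array([1.0, 0.0, 0.0])
        elif script.mechanism != "surface_then_insert" or state != "surface":
            guest_axis = axis
        true_d = float(np.linalg.norm(cog - zc))
        noisy_cog = cog + rng.normal(0.0, script.noise, size=3)
        guest = _guest_beads(noisy_cog, guest_axis, script.orientation)
        coords = np.vstack([host_frame.coordinates, guest])
        frames.append(Frame(coordinates=coords, box=host_frame.box.copy()))
        truth_rows.append({
            "frame": t, "state": state,
            "orientation": "undefined" if state == "unbound" else script.orientation,
            "cog_distance": true_d,
        })

    topo = Topology(
        names=host_topo.names + [f"G{i+1}" if i else "OG" for i in range(GUEST_BEADS)],
        resnames=host_topo.resnames + ["CHO"] * GUEST_BEADS,
        resids=host_topo.resids + [2] * GUEST_BEADS,
        elements=(host_topo.elements or []) + ["O"] + ["C"] * (GUEST_BEADS - 1),
        masses=np.concatenate([host_topo.masses,
                               [O_MASS] + [C_MASS] * (GUEST_BEADS - 1)]),
        phr_oxygens=host_topo.phr_oxygens,
        mid_oxygens=host_topo.mid_oxygens,
        shr_oxygens=host_topo.shr_oxygens,
        guest_atoms=list(range(nh, nh + GUEST_BEADS)),
        guest_oxygen=nh,
    )
    truth = pd.DataFrame(truth_rows)
    return topo, Trajectory(frames=frames, dt=dt), truth


def make_water_bath(center: np.ndarray, shell_counts, edges, box,
                    n_bulk: int = 0, seed: int = 0) -> np.ndarray:
    """Exact shell occupancies by inverse-CDF radial sampling.

    Places exactly ``shell_counts[k]`` points uniformly within each
    spherical shell ``[edges[k], edges[k+1])`` around ``center`` (radius
    sampled with r^3 uniform, so density is exactly uniform), plus
    ``n_bulk`` points uniformly in the box but outside ``edges[-1]``.
    """
    edges = np.asarray(edges, dtype=float)
    counts = np.asarray(shell_counts, dtype=int)
    if len(counts) != len(edges) - 1:
        raise ValueError("need one count per shell (len(edges) - 1)")
    if np.any(np.diff(edges) <= 0):
        zero = np.nonzero(np.diff(edges) <= 0)[0]
        if np.any(counts[zero] > 0):
            raise ValueError("cannot place points in a zero-width shell")
        raise ValueError("edges must be strictly increasing")
    center = np.asarray(center, dtype=float)
    box = np.asarray(box, dtype=float) * np.ones(3)
    rng = np.random.default_rng(seed)
    points = []
    for k, c in enumerate(counts):
        if c == 0:
            continue
        r3 = rng.uniform(edges[k] ** 3, edges[k + 1] ** 3, size=c)
        r = np.cbrt(r3)
        v = rng.normal(size=(c, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        points.append(center + r[:, None] * v)
    placed = 0
    while placed < n_bulk:
        cand = rng.uniform(0.0, 1.0, size=(max(n_bulk - placed, 16), 3)) * box
        d = np.linalg.norm(cand - center, axis=1)
        keep = cand[d >= edges[-1]]
        if len(keep):
            take = keep[: n_bulk - placed]
            points.append(take)
            placed += len(take)
    if not points:
        return np.empty((0, 3))
    return np.vstack(points)


def carve_guest_exclusion(water_positions: np.ndarray, guest_positions: np.ndarray,
                          r_excl: float = 0.4) -> np.ndarray:
    """Delete waters overlapping the guest (within ``r_excl`` of any bead)."""
    w = np.asarray(water_positions, dtype=float)
    g = np.asarray(guest_positions, dtype=float)
    if len(w) == 0 or len(g) == 0:
        return w
    d = np.linalg.norm(w[:, None, :] - g[None, :, :], axis=-1).min(axis=1)
    return w[d >= r_excl]


def make_hydrated_complex(n_frames: int = 100, insertion_frame: int = 50,
                          seed: int = 1, n_bulk: int = 50,
                          shell_counts=(5, 10, 10, 20),
                          ring_spec: RingSpec | None = None):
    """Host + guest binding trajectory with a static water bath and H-bond roles.

    Each water is an oxygen plus one hydrogen 0.1 nm along +x, annotated as
    a donor; the PHR oxygens are acceptors, so water-host hydrogen bonds can
    form.  Returns ``(topology, trajectory, truth)`` with the binding truth
    ledger of :func:`make_binding_trajectory`.
    """
    ring = ring_spec or RingSpec(seed=seed)
    script = BindingScript(insertion_frame=insertion_frame, seed=seed)
    topo, traj, truth = make_binding_trajectory(ring, script, n_frames)
    center = np.full(3, ring.box / 2) \
        + [0, 0, (ring.z_phr + ring.z_shr) / 2]
    wpos = make_water_bath(center, list(shell_counts), [0, 0.5, 0.8, 0.9, 1.0],
                           ring.box, n_bulk=n_bulk, seed=seed + 1)
    nw = len(wpos)
    n0 = topo.n_atoms
    water_ox = [n0 + 2 * i for i in range(nw)]
    topo2 = Topology(
        names=topo.names + [x for i in range(nw) for x in (f"OW{i}", f"HW{i}")],
        resnames=topo.resnames + ["SOL"] * 2 * nw,
        resids=topo.resids + [3 + i for i in range(nw) for _ in range(2)],
        masses=np.concatenate([topo.masses, np.tile([O_MASS, 1.008], nw)]),
        phr_oxygens=topo.phr_oxygens, mid_oxygens=topo.mid_oxygens,
        shr_oxygens=topo.shr_oxygens, guest_atoms=topo.guest_atoms,
        guest_oxygen=topo.guest_oxygen, water_oxygens=water_ox,
        donors=water_ox, hydrogens={n0 + 2 * i + 1: n0 + 2 * i for i in range(nw)},
        acceptors=water_ox + topo.phr_oxygens)
    wat = np.empty((2 * nw, 3))
    wat[0::2] = wpos
    wat[1::2] = wpos + [0.1, 0.0, 0.0]
    frames = [Frame(coordinates=np.vstack([f.coordinates, wat]), box=f.box)
              for f in traj.frames]
    return topo2, Trajectory(frames=frames, dt=traj.dt), truth


@dataclass(frozen=True)
class WorkSampleSpec:
    """Crooks-consistent Gaussian work distributions for estimator validation."""

    delta_g_true: float = -70.0   # kJ/mol
    sigma_w: float = 5.0          # kJ/mol
    kT: float = 2.577             # kJ/mol (310 K)
    n_forward: int = 10_000
    n_reverse: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive")
        if self.n_forward < 1 or self.n_reverse < 1:
            raise ValueError("need at least one sample per direction")


def make_bar_samples(spec: WorkSampleSpec = WorkSampleSpec()) -> LambdaWindowSamples:
    """Two-window lambda samples whose work distributions satisfy Crooks.

    Forward work ~ N(dG + sigma^2/(2kT), sigma^2) and reverse work
    ~ N(-dG + sigma^2/(2kT), sigma^2), which obey
    P_F(W) / P_R(-W) = exp((W - dG)/kT) exactly in distribution.  dH/dlambda
    samples ~ N(dG, sigma^2) are included so TI sees the same ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    shift = spec.sigma_w ** 2 / (2.0 * spec.kT)
    fwd = rng.normal(spec.delta_g_true + shift, spec.sigma_w, size=spec.n_forward)
    rev = rng.normal(-spec.delta_g_true + shift, spec.sigma_w, size=spec.n_reverse)
    dhdl0 = rng.normal(spec.delta_g_true, spec.sigma_w, size=spec.n_forward)
    dhdl1 = rng.normal(spec.delta_g_true, spec.sigma_w, size=spec.n_reverse)
    return LambdaWindowSamples(
        lambdas=np.array([0.0, 1.0]),
        dhdl=[dhdl0, dhdl1],
        forward=[fwd],
        reverse=[rev],
        temperature_K=spec.kT / KB_KJ_PER_MOL_K,
        metadata={"delta_g_true": str(spec.delta_g_true),
                  "sigma_w": str(spec.sigma_w)},
    )


def make_hbond_episodes(n_pairs: int, n_frames: int, episode_lengths,
                        seed: int = 0) -> tuple[np.ndarray, dict]:
    """Boolean pairs x frames matrix with planted, non-overlapping episodes.

    ``episode_lengths[p]`` lists the episode lengths (frames, >= 1) for
    pair p.  Episodes are placed at seeded random positions separated by
    at least one absent frame; if they cannot fit without overlap, an
    error is raised.  The returned ledger records the planted lengths and
    their mean for validating lifetime estimators.
    """
    if len(episode_lengths) != n_pairs:
        raise ValueError("need one episode-length list per pair")
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_pairs, n_frames), dtype=bool)
    all_lengths = []
    for p, lengths in enumerate(episode_lengths):
        lengths = [int(x) for x in lengths]
        if any(x < 1 for x in lengths):
            raise ValueError("episode lengths must be >= 1 frame")
        k = len(lengths)
        if k == 0:
            continue
        need = sum(lengths) + (k - 1)
        slack = n_frames - need
        if slack < 0:
            raise ValueError(
                f"pair {p}: episodes of total length {sum(lengths)} cannot fit "
                f"in {n_frames} frames without overlap")
        # distribute the slack over k+1 gaps (stars and bars)
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = gaps[0]
        for e, length in enumerate(lengths):
            mat[p, pos: pos + length] = True
            pos += length + 1 + gaps[e + 1]
        all_lengths.extend(lengths)
    ledger = {
        "per_pair_lengths": [list(map(int, l)) for l in episode_lengths],
        "mean_length_frames": float(np.mean(all_lengths)) if all_lengths else 0.0,
        "n_episodes": len(all_lengths),
    }
    return mat, ledger
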