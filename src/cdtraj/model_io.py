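"""Data model and I/O for topologies, trajectories and lambda-window samples.

Canonical units everywhere in the package: coordinates in nm, times in ps,
energies in kJ/mol.  PDB files (Angstrom convention) are converted on read
and write; GRO files are already in nm.

The topology is not inferred from chemistry.  It is an annotation file
(YAML) naming the atom records and the index groups the analyses need:
the three ordered rim-oxygen rings of the macrocycle (primary-hydroxyl
rim PHR = O6 atoms, middle rim MID = O1 glycosidic oxygens,
secondary-hydroxyl rim SHR = O3 atoms), the guest atoms and the guest
hydroxyl oxygen, water oxygens, and donor/hydrogen/acceptor lists for
hydrogen-bond analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Topology", "Frame", "Trajectory", "TailWindow",
    "read_trajectory", "write_trajectory", "write_gro",
    "read_topology", "write_topology",
    "tail_window", "read_lambda_samples", "write_lambda_samples",
]

PDB_TO_NM = 0.1
NM_TO_PDB = 10.0


class TrajectoryFormatError(ValueError):
    """A structural problem in a trajectory file (frame/atom mismatch, bad record)."""


@dataclass
class Topology:
    """Atom records plus the named index groups used by the analyses.

    The three rim rings must be supplied in cyclic order around the
    macrocycle; ring order is needed for polygon areas and is not
    inferred from coordinates.
    """

    names: list[str]
    resnames: list[str]
    resids: list[int]
    elements: list[str] | None = None
    masses: np.ndarray | None = None      # u
    charges: np.ndarray | None = None     # e
    phr_oxygens: list[int] = field(default_factory=list)
    mid_oxygens: list[int] = field(default_factory=list)
    shr_oxygens: list[int] = field(default_factory=list)
    guest_atoms: list[int] = field(default_factory=list)
    guest_oxygen: int | None = None
    water_oxygens: list[int] = field(default_factory=list)
    donors: list[int] = field(default_factory=list)
    # hydrogen index -> covalently bound donor index (exactly one donor each)
    hydrogens: dict[int, int] = field(default_factory=dict)
    acceptors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(self.resnames) != n or len(self.resids) != n:
            raise ValueError("names, resnames and resids must have equal length")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses must have one entry per atom")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise ValueError("charges must have one entry per atom")
        rims = [self.phr_oxygens, self.mid_oxygens, self.shr_oxygens]
        if any(rims):
            sizes = {len(r) for r in rims}
            if len(sizes) != 1 or sizes.pop() < 3:
                raise ValueError("the three rim rings must have equal length n >= 3")
            flat = self.phr_oxygens + self.mid_oxygens + self.shr_oxygens
            if len(set(flat)) != len(flat):
                raise ValueError("rim rings must be disjoint")
        if self.guest_oxygen is not None and self.guest_oxygen not in self.guest_atoms:
            raise ValueError("guest_oxygen must be a member of guest_atoms")
        for h, d in self.hydrogens.items():
            if not (0 <= h < n and 0 <= d < n):
                raise ValueError(f"hydrogen/donor index out of range: {h}->{d}")
        for g in rims + [self.guest_atoms, self.water_oxygens, self.donors, self.acceptors]:
            for i in g:
                if not 0 <= i < n:
                    raise ValueError(f"atom index {i} out of range (n={n})")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def mass_weights(self, indices) -> np.ndarray:
        """Masses for a group, or uniform weights if masses are absent."""
        if self.masses is None:
            return np.ones(len(indices))
        return self.masses[np.asarray(indices, dtype=int)]


@dataclass
class Frame:
    """One trajectory frame: coordinates (nm) and an orthorhombic box (nm)."""

    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray          # (3,) nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (nm)")


@dataclass
class Trajectory:
    """Ordered frames with a constant frame spacing dt (ps)."""

    frames: list[Frame]
    dt: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        n = self.frames[0].coordinates.shape[0]
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise TrajectoryFormatError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, expected {n}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].coordinates.shape[0]

    def coords(self) -> np.ndarray:
        """All coordinates stacked, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)


@dataclass(frozen=True)
class TailWindow:
    """The contiguous final ceil(fraction * n_frames) frames of a trajectory."""

    fraction: float
    start: int
    stop: int  # exclusive

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def indices(self) -> range:
        return range(self.start, self.stop)


def tail_window(trajectory: Trajectory | int, fraction: float = 0.10) -> TailWindow:
    """Resolve the analysis window: the last ``ceil(fraction * N)`` frames.

    Frame counts, not time stamps, define the window, which makes it
    deterministic and robust to a missing time origin.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = trajectory if isinstance(trajectory, int) else trajectory.n_frames
    if n < 1:
        raise ValueError("empty trajectory")
    k = math.ceil(fraction * n)
    return TailWindow(fraction=fraction, start=n - k, stop=n)


# ---------------------------------------------------------------------------
# trajectory readers / writers
# ---------------------------------------------------------------------------

_FALLBACK_PAD_NM = 3.0


def _fallback_box(coords_nm: np.ndarray) -> np.ndarray:
    span = coords_nm.max(axis=0) - coords_nm.min(axis=0)
    return span + _FALLBACK_PAD_NM


def read_trajectory(path, format: str, topology: Topology | None = None) -> Trajectory:
    """Read a multi-frame trajectory from a multi-model PDB or concatenated GRO.

    Coordinates are converted to nm regardless of the source convention
    (PDB Angstrom -> nm).  If ``topology`` is given, the per-frame atom
    count must match it.
    """
    fmt = format.lower()
    if fmt == "pdb":
        traj = _read_pdb(path)
    elif fmt == "gro":
        traj = _read_gro(path)
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")
    if topology is not None:
        for i, f in enumerate(traj.frames):
            if f.coordinates.shape[0] != topology.n_atoms:
                raise TrajectoryFormatError(
                    f"frame {i}: {f.coordinates.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}")
    return traj


def _read_pdb(path) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = []
        for ts in u.trajectory:
            coords = ts.positions.astype(float) * PDB_TO_NM
            dims = ts.dimensions
            if dims is not None and np.all(dims[:3] > 0):
                box = dims[:3].astype(float) * PDB_TO_NM
            else:
                box = _fallback_box(coords)
            frames.append(Frame(coordinates=coords, box=box))
    if not frames:
        raise TrajectoryFormatError(f"no frames found in {path}")
    return Trajectory(frames=frames)


def _read_gro(path) -> Trajectory:
    """Concatenated GRO frames: title / natoms / atom lines / box line, repeated."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nline = len(lines)
    frame_idx = 0
    while i < nline:
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= nline:
            raise TrajectoryFormatError(
                f"truncated GRO frame {frame_idx} at line {i + 1}")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"bad atom-count record at line {i + 2}: {lines[i + 1]!r}") from exc
        atom_lines = lines[i + 2: i + 2 + natoms]
        if len(atom_lines) < natoms or i + 2 + natoms >= nline:
            raise TrajectoryFormatError(
                f"truncated GRO frame {frame_idx}: expected {natoms} atoms")
        coords = np.empty((natoms, 3))
        for j, ln in enumerate(atom_lines):
            try:
                coords[j] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"unparseable GRO atom record at line {i + 3 + j}") from exc
        box_fields = lines[i + 2 + natoms].split()
        try:
            box = np.array([float(x) for x in box_fields[:3]])
        except (ValueError, IndexError) as exc:
            raise TrajectoryFormatError(
                f"unparseable GRO box record at line {i + 3 + natoms}") from exc
        frames.append(Frame(coordinates=coords, box=box))
        i += natoms + 3
        frame_idx += 1
    if not frames:
        raise TrajectoryFormatError(f"no frames found in {path}")
    return Trajectory(frames=frames)


def write_trajectory(trajectory: Trajectory, topology: Topology, path,
                     format: str = "pdb") -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    if format.lower() != "pdb":
        raise ValueError("write_trajectory supports multi-model PDB only")
    if trajectory.n_frames < 1:
        raise ValueError("refusing to write an empty trajectory")
    if trajectory.n_atoms != topology.n_atoms:
        raise TrajectoryFormatError(
            f"trajectory has {trajectory.n_atoms} atoms, topology {topology.n_atoms}")
    coords = trajectory.coords() * NM_TO_PDB
    # PDB coordinate field is %8.3f: magnitudes >= 10000 A would be truncated
    if np.any(np.abs(coords) >= 10000) or np.any(~np.isfinite(coords)):
        raise ValueError("coordinates exceed the PDB field width (|x| >= 1000 nm)")

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_names, resindex = _unique_ordered(topology.resnames, topology.resids)
        u = mda.Universe.empty(
            topology.n_atoms,
            n_residues=len(res_names),
            atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", topology.names)
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", list(dict.fromkeys(topology.resids)))
        u.load_new(coords.astype(np.float32), format=MemoryReader)
        boxes = np.stack([f.box for f in trajectory.frames]) * NM_TO_PDB
        with mda.Writer(str(path), multiframe=True, n_atoms=topology.n_atoms) as w:
            for k, ts in enumerate(u.trajectory):
                ts.dimensions = [*boxes[k], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def _unique_ordered(resnames: list[str], resids: list[int]):
    """Per-residue resnames and the atom->residue index map, preserving order."""
    order: dict[int, int] = {}
    names: list[str] = []
    for rn, ri in zip(resnames, resids):
        if ri not in order:
            order[ri] = len(order)
            names.append(rn)
    idx = np.array([order[ri] for ri in resids], dtype=int)
    return names, idx


def write_gro(trajectory: Trajectory, topology: Topology, path,
              title: str = "cdtraj frame") -> None:
    """Write concatenated GRO frames (coordinates already in nm)."""
    if trajectory.n_atoms != topology.n_atoms:
        raise TrajectoryFormatError("atom count mismatch between trajectory and topology")
    with open(path, "w") as fh:
        for k, frame in enumerate(trajectory.frames):
            fh.write(f"{title} t= {trajectory.t0 + k * trajectory.dt:.3f}\n")
            fh.write(f"{topology.n_atoms:5d}\n")
            for i in range(topology.n_atoms):
                x, y, z = frame.coordinates[i]
                fh.write(
                    f"{topology.resids[i] % 100000:>5d}{topology.resnames[i]:<5.5s}"
                    f"{topology.names[i]:>5.5s}{(i + 1) % 100000:>5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# topology annotation (YAML)
# ---------------------------------------------------------------------------

def write_topology(topology: Topology, path) -> None:
    doc = {
        "atoms": {
            "names": list(topology.names),
            "resnames": list(topology.resnames),
            "resids": [int(r) for r in topology.resids],
        },
        "groups": {
            "phr_oxygens": [int(i) for i in topology.phr_oxygens],
            "mid_oxygens": [int(i) for i in topology.mid_oxygens],
            "shr_oxygens": [int(i) for i in topology.shr_oxygens],
            "guest_atoms": [int(i) for i in topology.guest_atoms],
            "water_oxygens": [int(i) for i in topology.water_oxygens],
            "donors": [int(i) for i in topology.donors],
            "hydrogens": {int(h): int(d) for h, d in topology.hydrogens.items()},
            "acceptors": [int(i) for i in topology.acceptors],
        },
    }
    if topology.elements is not None:
        doc["atoms"]["elements"] = list(topology.elements)
    if topology.masses is not None:
        doc["atoms"]["masses"] = [float(m) for m in topology.masses]
    if topology.charges is not None:
        doc["atoms"]["charges"] = [float(q) for q in topology.charges]
    if topology.guest_oxygen is not None:
        doc["groups"]["guest_oxygen"] = int(topology.guest_oxygen)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology(path) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    atoms = doc.get("atoms", {})
    groups = doc.get("groups", {})
    return Topology(
        names=atoms["names"],
        resnames=atoms["resnames"],
        resids=atoms["resids"],
        elements=atoms.get("elements"),
        masses=np.asarray(atoms["masses"], float) if "masses" in atoms else None,
        charges=np.asarray(atoms["charges"], float) if "charges" in atoms else None,
        phr_oxygens=groups.get("phr_oxygens", []),
        mid_oxygens=groups.get("mid_oxygens", []),
        shr_oxygens=groups.get("shr_oxygens", []),
        guest_atoms=groups.get("guest_atoms", []),
        guest_oxygen=groups.get("guest_oxygen"),
        water_oxygens=groups.get("water_oxygens", []),
        donors=groups.get("donors", []),
        hydrogens={int(h): int(d) for h, d in groups.get("hydrogens", {}).items()},
        acceptors=groups.get("acceptors", []),
    )


# ---------------------------------------------------------------------------
# lambda-window samples (TSV)
# ---------------------------------------------------------------------------

def write_lambda_samples(samples, path) -> None:
    """Write per-lambda samples as TSV with '#'-comment metadata lines.

    Columns: lambda, index, dhdl, du_forward, du_reverse.  The forward and
    reverse columns hold cross-evaluated energy differences toward the
    next/previous window; they are empty where not applicable.
    """
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {samples.temperature_K}\n")
        for k, v in sorted(samples.metadata.items()):
            fh.write(f"# {k} = {v}\n")
        fh.write("lambda\tindex\tdhdl\tdu_forward\tdu_reverse\n")
        for i, lam in enumerate(samples.lambdas):
            dhdl = samples.dhdl[i]
            fwd = samples.forward[i] \
                if samples.forward and i < len(samples.lambdas) - 1 else None
            rev = samples.reverse[i - 1] if samples.reverse and i > 0 else None
            n = len(dhdl)
            for j in range(n):
                f = "" if fwd is None or j >= len(fwd) else f"{fwd[j]:.10g}"
                r = "" if rev is None or j >= len(rev) else f"{rev[j]:.10g}"
                fh.write(f"{lam:.10g}\t{j}\t{dhdl[j]:.10g}\t{f}\t{r}\n")


def read_lambda_samples(path):
    """Parse a lambda-sample TSV into :class:`~cdtraj.energetics.LambdaWindowSamples`.

    Rows are grouped by lambda; lambda values must lie in [0, 1] and each
    lambda must form one contiguous block.
    """
    from cdtraj.energetics import LambdaWindowSamples

    metadata: dict[str, str] = {}
    temperature = 310.0
    rows: list[tuple[float, float, float | None, float | None]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    k, v = k.strip(), v.strip()
                    if k == "temperature_K":
                        temperature = float(v)
                    else:
                        metadata[k] = v
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: unparseable record at line {lineno}")
            try:
                lam = float(parts[0])
                dhdl = float(parts[2])
                fwd = float(parts[3]) if len(parts) > 3 and parts[3] != "" else None
                rev = float(parts[4]) if len(parts) > 4 and parts[4] != "" else None
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable record at line {lineno}") from exc
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"{path}: lambda {lam} outside [0, 1] at line {lineno}")
            rows.append((lam, dhdl, fwd, rev))

    if not rows:
        raise ValueError(f"{path}: no samples")
    # lambda values must appear in contiguous blocks
    seen: list[float] = []
    for lam, *_ in rows:
        if not seen or seen[-1] != lam:
            if lam in seen:
                raise ValueError(f"{path}: duplicate non-contiguous block for lambda={lam}")
            seen.append(lam)

    lambdas = sorted(seen)
    by_lam: dict[float, list[tuple[float, float | None, float | None]]] = {
        lam: [] for lam in lambdas}
    for lam, dhdl, fwd, rev in rows:
        by_lam[lam].append((dhdl, fwd, rev))

    dhdl_groups = [np.array([r[0] for r in by_lam[lam]]) for lam in lambdas]
    forward = []
    reverse = []
    for i, lam in enumerate(lambdas[:-1]):
        f = [r[1] for r in by_lam[lam] if r[1] is not None]
        forward.append(np.array(f) if f else np.array([]))
    for i, lam in enumerate(lambdas[1:]):
        r = [x[2] for x in by_lam[lam] if x[2] is not None]
        reverse.append(np.array(r) if r else np.array([]))

    return LambdaWindowSamples(
        lambdas=np.array(lambdas),
        dhdl=dhdl_groups,
        forward=forward,
        reverse=reverse,
        temperature_K=temperature,
        metadata=metadata,
    )
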