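"""Core data model and I/O for labeled particle trajectories and shell geometry.

The in-memory containers are thin dataclasses over NumPy arrays: a
:class:`ParticleSet` holds per-particle labels (species, role, complex id),
a :class:`Trajectory` holds time-ordered coordinates with box metadata, and
a :class:`ShellGeometry` records the fitted spherical shell (center,
mid-surface radius, hysteresis radii, pores, surface area).

Supported on-disk formats: PDB (via MDAnalysis), DCD (via MDAnalysis), and
a columnar text dialect designed as a language-agnostic fixture format::

    # unwrapped true
    # box 500.0 500.0 500.0
    frame,time_ns,particle_id,x,y,z
    0,0.0,0,1.0,2.0,3.0
    ...

Operations that consume mean-squared displacements require unwrapped
coordinates and refuse wrapped input rather than guessing an unwrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParticleSet",
    "Trajectory",
    "ShellGeometry",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "fit_shell_geometry",
]

VALID_SPECIES = {"water", "G3P", "DHAP", "ion", "pseudo"}
VALID_ROLES = {"shell", "cargo", "solvent", "metabolite"}


@dataclass
class ParticleSet:
    """Labeled particles: identities, species/role tags and reference coordinates.

    ``complex_id`` groups the members of one multimeric complex; it is -1 for
    particles that belong to none. ``is_calpha`` flags alpha-carbon sites used
    by the contact-network analyses. ``is_heavy`` flags non-hydrogen atoms.
    """

    particle_id: np.ndarray            # (n,) int
    species: np.ndarray                # (n,) str
    role: np.ndarray                   # (n,) str
    complex_id: np.ndarray             # (n,) int, -1 = no complex
    is_calpha: np.ndarray              # (n,) bool
    coordinates: np.ndarray            # (n, 3) float, Å
    is_heavy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.particle_id = np.asarray(self.particle_id, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        self.complex_id = np.asarray(self.complex_id, dtype=np.int64)
        self.is_calpha = np.asarray(self.is_calpha, dtype=bool)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.is_heavy is None:
            self.is_heavy = np.ones(self.n_particles, dtype=bool)
        else:
            self.is_heavy = np.asarray(self.is_heavy, dtype=bool)
        if len(np.unique(self.particle_id)) != self.n_particles:
            raise ValueError("particle_id values must be unique")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        cargo = self.role == "cargo"
        if np.any(cargo & (self.complex_id < 0)):
            raise ValueError("every cargo particle needs a complex_id")

    @property
    def n_particles(self) -> int:
        return len(self.particle_id)

    def select(self, **criteria) -> np.ndarray:
        """Boolean mask of particles matching all keyword criteria.

        Values may be a single label or a sequence of acceptable labels,
        e.g. ``select(role="cargo", species=("G3P", "DHAP"))``.
        """
        mask = np.ones(self.n_particles, dtype=bool)
        for key, value in criteria.items():
            arr = getattr(self, key)
            if isinstance(value, (str, int, bool, np.integer)):
                mask &= arr == value
            else:
                mask &= np.isin(arr, list(value))
        return mask


@dataclass
class Trajectory:
    """Time-ordered particle positions with box metadata.

    ``positions`` has shape (n_frames, n_particles, 3) in Å; ``times`` is in
    ns and strictly increasing. ``unwrapped`` declares whether coordinates
    are continuous across the periodic box.
    """

    times: np.ndarray                  # (n_frames,) ns
    positions: np.ndarray              # (n_frames, n, 3) Å
    box_edges: np.ndarray              # (3,) Å, zeros = non-periodic
    unwrapped: bool
    particles: ParticleSet

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box_edges = np.asarray(self.box_edges, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n, 3)")
        if len(self.times) != self.positions.shape[0]:
            raise ValueError("times and positions frame counts differ")
        if self.positions.shape[1] != self.particles.n_particles:
            raise ValueError(
                f"per-frame position count {self.positions.shape[1]} does not "
                f"match particle count {self.particles.n_particles}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def subset(self, mask: np.ndarray) -> "Trajectory":
        """Restrict to the particles selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        ps = ParticleSet(
            particle_id=self.particles.particle_id[mask],
            species=self.particles.species[mask],
            role=self.particles.role[mask],
            complex_id=self.particles.complex_id[mask],
            is_calpha=self.particles.is_calpha[mask],
            coordinates=self.particles.coordinates[mask],
            is_heavy=self.particles.is_heavy[mask],
        )
        return Trajectory(self.times, self.positions[:, mask], self.box_edges,
                          self.unwrapped, ps)


@dataclass
class ShellGeometry:
    """Spherical shell descriptor: center, radii, pores and surface area.

    ``R_in < R_mid < R_out`` define the hysteresis band used by transition
    counting. ``pores`` is a list of ``(axis unit vector, radius Å)`` pairs.
    ``A`` is the surface area in Å² used to normalise crossing counts.
    """

    center: np.ndarray
    R_mid: float
    R_in: float
    R_out: float
    A: float
    pores: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (self.R_in < self.R_mid < self.R_out):
            raise ValueError("require R_in < R_mid < R_out")
        if self.A <= 0:
            raise ValueError("surface area must be positive")
        self.pores = [(np.asarray(a, float) / np.linalg.norm(a), float(r))
                      for a, r in self.pores]

    @property
    def pore_area(self) -> float:
        """Total open pore area, Å²."""
        return float(sum(np.pi * r * r for _, r in self.pores))

    @property
    def pore_area_fraction(self) -> float:
        return self.pore_area / self.A


# ---------------------------------------------------------------------------
# PDB I/O

def read_structure(path, role_map: Mapping[str, str] | None = None,
                   species_map: Mapping[str, str] | None = None) -> ParticleSet:
    """Read a PDB file into a labeled :class:`ParticleSet`.

    Roles are assigned from ``role_map``, keyed by chain ID (falling back to
    segment ID); unmapped chains default to role ``shell`` with a warning.
    ``species_map`` maps residue names to species labels; unmapped residues
    become ``pseudo`` (or ``water`` for common water residue names).
    Multimer grouping uses the residue sequence number as ``complex_id`` for
    cargo particles.
    """
    import MDAnalysis as mda

    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty structure file: {path}")
    role_map = dict(role_map or {})
    species_map = dict(species_map or {})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="PDB")
        except Exception as exc:  # noqa: BLE001 - surface parser context
            raise ValueError(f"failed to parse PDB {path}: {exc}") from exc

    n = len(u.atoms)
    if n == 0:
        raise ValueError(f"no atoms in structure file: {path}")

    chains = _atom_attr(u, "chainIDs", n)
    segids = _atom_attr(u, "segids", n)
    resnames = _atom_attr(u, "resnames", n, default="UNK")
    names = _atom_attr(u, "names", n, default="X")
    resids = (u.atoms.resids if hasattr(u.atoms, "resids")
              else np.zeros(n, dtype=int))

    water_resnames = {"HOH", "TIP3", "WAT", "SOL", "TIP"}
    roles, species = [], []
    unmapped: set[str] = set()
    for i in range(n):
        key = chains[i] or segids[i]
        if key in role_map:
            roles.append(role_map[key])
        else:
            unmapped.add(str(key))
            roles.append("shell")
        rn = resnames[i]
        if rn in species_map:
            species.append(species_map[rn])
        elif rn in water_resnames:
            species.append("water")
        elif rn in VALID_SPECIES:
            species.append(rn)
        else:
            species.append("pseudo")
    if unmapped and role_map:
        warnings.warn(
            f"chains {sorted(unmapped)} missing from role map; "
            "defaulting to role=shell", stacklevel=2)

    roles = np.asarray(roles, dtype=object)
    complex_id = np.where(roles == "cargo", resids, -1)
    is_calpha = np.asarray([nm.strip() == "CA" for nm in names])
    is_heavy = np.asarray([not nm.strip().startswith("H") for nm in names])

    return ParticleSet(
        particle_id=np.arange(n),
        species=np.asarray(species, dtype=object),
        role=roles,
        complex_id=complex_id,
        is_calpha=is_calpha,
        coordinates=u.atoms.positions.astype(float),
        is_heavy=is_heavy,
    )


def _atom_attr(u, attr: str, n: int, default: str = "") -> list[str]:
    try:
        return [str(x).strip() for x in getattr(u.atoms, attr)]
    except Exception:   # attribute absent from this PDB
        return [default] * n


def write_structure(particles: ParticleSet, path) -> None:
    """Write a ParticleSet as a minimal PDB (one HETATM-free ATOM per particle)."""
    import MDAnalysis as mda

    n = particles.n_particles
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", ["CA" if c else "X"
                                 for c in particles.is_calpha])
    u.add_TopologyAttr("resnames", [_resname_for(s) for s in particles.species])
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.add_TopologyAttr("chainIDs", [_chain_for(r) for r in particles.role])
    u.atoms.positions = particles.coordinates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _resname_for(species: str) -> str:
    return {"water": "HOH", "G3P": "G3P", "DHAP": "DHA",
            "ion": "ION"}.get(species, "PSU")


def _chain_for(role: str) -> str:
    return {"shell": "A", "cargo": "B", "solvent": "C", "metabolite": "D"}.get(role, "A")


# ---------------------------------------------------------------------------
# Trajectory I/O

def write_trajectory(traj: Trajectory, path) -> None:
    """Write the columnar text trajectory dialect (see module docstring)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unwrapped {'true' if traj.unwrapped else 'false'}\n")
        bx, by, bz = traj.box_edges
        fh.write(f"# box {bx:.6g} {by:.6g} {bz:.6g}\n")
        fh.write("frame,time_ns,particle_id,x,y,z\n")
        ids = traj.particles.particle_id
        for f in range(traj.n_frames):
            t = traj.times[f]
            pos = traj.positions[f]
            for j in range(traj.n_particles):
                fh.write(f"{f},{t:.9g},{ids[j]},"
                         f"{pos[j, 0]:.6f},{pos[j, 1]:.6f},{pos[j, 2]:.6f}\n")


def read_trajectory(path, particles: ParticleSet, *,
                    unwrapped: bool | None = None,
                    dt_ns: float | None = None) -> Trajectory:
    """Read a trajectory (columnar text or DCD) against a known ParticleSet.

    For text files the ``unwrapped`` flag and box come from the header; for
    DCD the caller must declare ``unwrapped`` (there is no metadata slot) and
    may override the frame interval with ``dt_ns``.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        if unwrapped is None:
            raise ValueError("DCD carries no unwrap metadata; pass unwrapped=")
        return _read_dcd(path, particles, unwrapped, dt_ns)
    return _read_text(path, particles, unwrapped_override=unwrapped)


def _read_text(path: Path, particles: ParticleSet,
               unwrapped_override: bool | None = None) -> Trajectory:
    import pandas as pd

    unwrapped = False
    box = np.zeros(3)
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            parts = line[1:].split()
            if parts and parts[0] == "unwrapped":
                unwrapped = parts[1].lower() == "true"
            elif parts and parts[0] == "box":
                box = np.array([float(x) for x in parts[1:4]])

    df = pd.read_csv(path, skiprows=header_lines)
    required = {"frame", "time_ns", "particle_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file missing columns "
                         f"{sorted(required - set(df.columns))}")
    if df[["x", "y", "z"]].isna().any().any() or \
            not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy())):
        raise ValueError("trajectory contains NaN/non-finite coordinates")

    n = particles.n_particles
    frames = np.sort(df["frame"].unique())
    times = np.empty(len(frames))
    positions = np.empty((len(frames), n, 3))
    id_to_col = {pid: j for j, pid in enumerate(particles.particle_id)}
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != n:
            raise ValueError(
                f"frame {f}: expected {n} particles, found {len(sub)}")
        times[k] = sub["time_ns"].iloc[0]
        cols = np.fromiter((id_to_col[pid] for pid in sub["particle_id"]),
                           dtype=int, count=n)
        positions[k, cols] = sub[["x", "y", "z"]].to_numpy()

    if unwrapped_override is not None:
        unwrapped = unwrapped_override
    return Trajectory(times, positions, box, unwrapped, particles)


def _read_dcd(path: Path, particles: ParticleSet, unwrapped: bool,
              dt_ns: float | None) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe.empty(particles.n_particles, trajectory=True)
    u.load_new(str(path), format="DCD")
    positions, times, boxes = [], [], []
    for ts in u.trajectory:
        positions.append(ts.positions.copy().astype(float))
        times.append(ts.time)  # MDAnalysis time is ps
        boxes.append(ts.dimensions[:3] if ts.dimensions is not None
                     else np.zeros(3))
    times = np.asarray(times) * 1e-3  # ps -> ns
    if dt_ns is not None:
        times = dt_ns * np.arange(len(positions))
    elif len(times) > 1 and np.allclose(np.diff(times), 0):
        times = np.arange(len(positions), dtype=float)
    box = np.asarray(boxes[0], dtype=float)
    return Trajectory(times, np.asarray(positions), box, unwrapped, particles)


def write_dcd(traj: Trajectory, path) -> None:
    """Write trajectory coordinates to DCD (positions only; times implicit)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_particles, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.n_particles) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[f]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# Shell geometry

def fit_shell_geometry(traj: Trajectory,
                       shell_selection: np.ndarray | None = None,
                       delta: float = 10.0,
                       pores: Sequence[tuple[np.ndarray, float]] = ()) -> ShellGeometry:
    """Fit a spherical shell to the shell particles of the first frame.

    center = centroid of shell particles; R_mid = mean radial distance;
    R_in/R_out = R_mid ∓ delta; A = 4π R_mid². ``delta`` is the hysteresis
    half-width in Å and must be positive.
    """
    if delta <= 0:
        raise ValueError("hysteresis half-width delta must be positive")
    if shell_selection is None:
        shell_selection = traj.particles.select(role="shell")
    shell_selection = np.asarray(shell_selection, dtype=bool)
    if shell_selection.sum() < 10:
        raise ValueError("need at least 10 shell particles to fit geometry")
    pts = traj.positions[0][shell_selection]
    center = pts.mean(axis=0)
    r_mid = float(np.linalg.norm(pts - center, axis=1).mean())
    return ShellGeometry(center=center, R_mid=r_mid, R_in=r_mid - delta,
                         R_out=r_mid + delta, A=4 * np.pi * r_mid**2,
                         pores=list(pores))
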