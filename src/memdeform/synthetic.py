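"""Synthetic deformed-bilayer trajectories and ideal helix bundles.

Every downstream stage of the pipeline (leaflet surfaces, thickness maps,
occupancy volumes, helix geometry) is validated against data with a known
analytic ground truth generated here, without any download.

The bilayer is reduced to its phosphorus "head" particles: two leaflets of
point particles riding on analytic surfaces separated by a nominal
thickness ``T0``, with a radial Gaussian thinning well of depth ``D`` and
lateral width ``sigma_w`` near the (protein) center, mimicking the local
bilayer thinning an embedded insertase induces. The ``asym`` parameter
sets which fraction of the thinning is carried by the upper (cytosolic)
leaflet — the leaflet reported to be more distorted. The Gaussian well
shape is a modelling choice of this package: it is the simplest radial
deformation with independent depth and width, not a literature form.

Particles diffuse laterally as a periodic random walk and their z is
resampled from the surface each frame plus Gaussian noise (no z-memory),
the simplest process with the right stationary distribution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np

from .trajectory import AtomRecord, Trajectory, write_structure, write_trajectory

__all__ = [
    "SyntheticBilayerSpec",
    "SyntheticProteinSpec",
    "HelixSpec",
    "analytic_thickness",
    "leaflet_surface_z",
    "generate_bilayer_trajectory",
    "make_helix_bundle",
    "make_c2_dimer",
    "write_synthetic_system",
]

_BOX_HEIGHT_PAD = 40.0  # Å of z-clearance above/below the leaflets


@dataclass(frozen=True)
class SyntheticBilayerSpec:
    """Full parameterization of a synthetic deformed bilayer trajectory.

    Parameters
    ----------
    T0 : nominal bilayer thickness, Å.
    D : thinning-well depth, Å (0 = flat bilayer).
    sigma_w : lateral 1/e²-related width of the Gaussian well, Å.
    asym : fraction of the thinning carried by the upper leaflet, in [0, 1].
    Lx, Ly : lateral box dimensions, Å (Lx, Ly > 4·sigma_w recommended).
    n_per_leaflet : phosphorus particles per leaflet.
    noise_z : per-frame Gaussian z-displacement s.d., Å.
    step_xy : per-frame lateral random-walk step s.d., Å.
    n_frames : frame count; frame times are k·dt for k = 1…n_frames.
    dt : frame spacing, ns.
    n_replicates : number of independent replicate trajectories.
    seed : root RNG seed; replicate r uses stream seed + r.
    center : well center (x, y); defaults to the box center.
    """

    T0: float = 40.0
    D: float = 0.0
    sigma_w: float = 15.0
    asym: float = 0.5
    Lx: float = 120.0
    Ly: float = 120.0
    n_per_leaflet: int = 256
    noise_z: float = 0.0
    step_xy: float = 1.0
    n_frames: int = 50
    dt: float = 1.0
    n_replicates: int = 1
    seed: int = 0
    center: tuple[float, float] | None = None

    def validate(self) -> None:
        if not self.T0 > self.D >= 0:
            raise ValueError(f"requires T0 > D >= 0, got T0={self.T0}, D={self.D}")
        if not self.sigma_w > 0:
            raise ValueError(f"requires sigma_w > 0, got {self.sigma_w}")
        if not 0.0 <= self.asym <= 1.0:
            raise ValueError(f"requires 0 <= asym <= 1, got {self.asym}")
        if self.n_per_leaflet < 16:
            raise ValueError(f"requires n_per_leaflet >= 16, got {self.n_per_leaflet}")
        if self.n_frames < 1:
            raise ValueError(f"requires n_frames >= 1, got {self.n_frames}")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("box dimensions must be positive")
        if self.noise_z < 0 or self.step_xy < 0:
            raise ValueError("noise_z and step_xy must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def well_center(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        return np.array([self.Lx / 2.0, self.Ly / 2.0])

    @property
    def box(self) -> np.ndarray:
        return np.diag([self.Lx, self.Ly, self.T0 + _BOX_HEIGHT_PAD])


def _well(spec: SyntheticBilayerSpec, x, y, depth: float | None = None):
    depth = spec.D if depth is None else depth
    dx = np.asarray(x, dtype=float) - spec.well_center[0]
    dy = np.asarray(y, dtype=float) - spec.well_center[1]
    r2 = dx * dx + dy * dy
    return depth * np.exp(-r2 / (2.0 * spec.sigma_w ** 2))


def analytic_thickness(spec: SyntheticBilayerSpec, x, y):
    """Ground-truth thickness T(r) = T0 − D·exp(−r²/(2σ_w²)), Å."""
    spec.validate()
    return spec.T0 - _well(spec, x, y)


def leaflet_surface_z(spec: SyntheticBilayerSpec, leaflet: str, x, y,
                      depth: float | None = None):
    """Analytic leaflet surface height, Å.

    upper: +T0/2 − asym·well(r); lower: −T0/2 + (1−asym)·well(r). Their
    difference is the analytic thickness.
    """
    w = _well(spec, x, y, depth)
    if leaflet == "upper":
        return spec.T0 / 2.0 - spec.asym * w
    if leaflet == "lower":
        return -spec.T0 / 2.0 + (1.0 - spec.asym) * w
    raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")


def _bilayer_topology(n_per_leaflet: int) -> list[AtomRecord]:
    top = []
    for i in range(2 * n_per_leaflet):
        top.append(AtomRecord(atom_name="P", element="P", residue_name="LIP",
                              residue_id=i + 1, chain_id="L"))
    return top


def generate_bilayer_trajectory(
    spec: SyntheticBilayerSpec,
    replicate: int = 0,
    depth_at: Callable[[float], float] | None = None,
) -> Trajectory:
    """Generate one replicate of the synthetic phosphorus trajectory.

    Atom order: the first ``n_per_leaflet`` particles are the upper
    leaflet, the rest the lower leaflet; particles never change leaflet.
    ``depth_at(t_ns)`` optionally overrides the well depth per frame (used
    to construct non-stationary test trajectories); the default is the
    constant ``spec.D``.

    Deterministic for a fixed (seed, replicate): the replicate's RNG
    stream is seeded with ``spec.seed + replicate``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + replicate)
    n = spec.n_per_leaflet
    xy = np.empty((2 * n, 2))
    xy[:, 0] = rng.uniform(0.0, spec.Lx, size=2 * n)
    xy[:, 1] = rng.uniform(0.0, spec.Ly, size=2 * n)

    coords = np.empty((spec.n_frames, 2 * n, 3))
    times = (np.arange(spec.n_frames) + 1) * spec.dt
    for k in range(spec.n_frames):
        if spec.step_xy > 0:
            xy = xy + rng.normal(0.0, spec.step_xy, size=xy.shape)
            xy[:, 0] %= spec.Lx
            xy[:, 1] %= spec.Ly
        depth = None if depth_at is None else float(depth_at(times[k]))
        z_up = leaflet_surface_z(spec, "upper", xy[:n, 0], xy[:n, 1], depth)
        z_lo = leaflet_surface_z(spec, "lower", xy[n:, 0], xy[n:, 1], depth)
        z = np.concatenate([z_up, z_lo])
        if spec.noise_z > 0:
            z = z + rng.normal(0.0, spec.noise_z, size=z.shape)
        coords[k, :, :2] = xy
        coords[k, :, 2] = z
    boxes = np.repeat(spec.box[None, :, :], spec.n_frames, axis=0)
    return Trajectory(topology=_bilayer_topology(n), coordinates=coords,
                      times=times, boxes=boxes, replicate_id=replicate)


def generate_replicates(spec: SyntheticBilayerSpec) -> list[Trajectory]:
    """All ``spec.n_replicates`` replicate trajectories."""
    return [generate_bilayer_trajectory(spec, r) for r in range(spec.n_replicates)]


# ---------------------------------------------------------------------------
# ideal helices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """One ideal α-helix: anchor (N-terminus), unit direction, residue count."""

    anchor: tuple[float, float, float]
    direction: tuple[float, float, float]
    n_residues: int

    def validate(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError(f"helix direction must be a unit vector, |d|="
                             f"{np.linalg.norm(d):.6f}")
        if self.n_residues < 6:
            raise ValueError(f"helix needs >= 6 residues, got {self.n_residues}")


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """An ideal-helix bundle with known axes, for geometry ground truth."""

    helices: tuple[HelixSpec, ...]
    rise_per_residue: float = 1.5  # Å, canonical α-helix rise
    helix_radius: float = 2.3  # Å, Cα distance from the helix axis
    twist_per_residue: float = 100.0  # degrees

    def validate(self) -> None:
        if not self.helices:
            raise ValueError("at least one helix required")
        for h in self.helices:
            h.validate()


def _frame_for_direction(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d (right-handed with d)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def make_helix_bundle(spec: SyntheticProteinSpec) -> tuple[list[AtomRecord], np.ndarray]:
    """Cα coordinates of the ideal bundle; chains A, B, … per helix."""
    spec.validate()
    topology: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for h_idx, h in enumerate(spec.helices):
        d = np.asarray(h.direction, dtype=float)
        anchor = np.asarray(h.anchor, dtype=float)
        u, v = _frame_for_direction(d)
        chain = chr(ord("A") + h_idx % 26)
        for i in range(h.n_residues):
            phi = np.deg2rad(spec.twist_per_residue * i)
            pos = (anchor + d * (spec.rise_per_residue * i)
                   + spec.helix_radius * (np.cos(phi) * u + np.sin(phi) * v))
            topology.append(AtomRecord(atom_name="CA", element="C",
                                       residue_name="ALA", residue_id=i + 1,
                                       chain_id=chain))
            coords.append(pos)
    return topology, np.asarray(coords)


def make_c2_dimer(n_residues: int = 40, axis: Sequence[float] = (0.0, 0.0, 1.0),
                  anchor: Sequence[float] = (0.0, 0.0, 0.0),
                  noise: float = 0.0, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two chains related by an exact 180° rotation about ``axis`` through
    ``anchor``; optional iid Gaussian coordinate noise on both chains.

    Returns (chainA, chainB) matched Cα coordinate arrays.
    """
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    anchor = np.asarray(anchor, dtype=float)
    helix = HelixSpec(anchor=(8.0, 3.0, -20.0), direction=(0.12, -0.08, 0.98986868),
                      n_residues=n_residues)
    d = np.asarray(helix.direction)
    helix = HelixSpec(anchor=helix.anchor,
                      direction=tuple(d / np.linalg.norm(d)),
                      n_residues=n_residues)
    _, chainA = make_helix_bundle(SyntheticProteinSpec(helices=(helix,)))
    R = Rotation.from_rotvec(np.pi * axis).as_matrix()
    chainB = (chainA - anchor) @ R.T + anchor
    if noise > 0:
        rng = np.random.default_rng(seed)
        chainA = chainA + rng.normal(0.0, noise, chainA.shape)
        chainB = chainB + rng.normal(0.0, noise, chainB.shape)
    return chainA, chainB


def write_synthetic_system(outdir: str | os.PathLike, spec: SyntheticBilayerSpec,
                           protein: SyntheticProteinSpec | None = None,
                           traj_format: str = "xtc") -> dict:
    """Write topology (PDB) and per-replicate trajectories; returns a manifest.

    Lipid phosphorus particles are single-atom residues named LIP (atom P);
    protein helices are ALA Cα traces appended after the lipids.
    """
    spec.validate()
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    prot_top: list[AtomRecord] = []
    prot_xyz = np.empty((0, 3))
    if protein is not None:
        prot_top, prot_xyz = make_helix_bundle(protein)

    manifest: dict = {"topology": os.path.join(outdir, "system.pdb"),
                      "trajectories": [], "spec": asdict(spec)}
    first = generate_bilayer_trajectory(spec, 0)
    top = first.topology + prot_top
    coords0 = np.vstack([first.coordinates[0], prot_xyz])
    write_structure(manifest["topology"], top, coords0)
    for r in range(spec.n_replicates):
        traj = generate_bilayer_trajectory(spec, r) if r else first
        n_f = traj.n_frames
        full = np.concatenate(
            [traj.coordinates, np.repeat(prot_xyz[None], n_f, axis=0)], axis=1)
        full_traj = Trajectory(topology=top, coordinates=full, times=traj.times,
                               boxes=traj.boxes, replicate_id=r)
        path = os.path.join(outdir, f"replicate_{r}.{traj_format}")
        write_trajectory(path, full_traj)
        manifest["trajectories"].append(path)
    return manifest
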