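"""Trajectory containers, structure/trajectory I/O, and superposition.

The analysis pipeline works on a lightweight in-memory :class:`Trajectory`
(topology + coordinate stack) rather than on a live MDAnalysis Universe, so
that synthetic trajectories, file-backed trajectories and unit-test fixtures
all flow through identical code. Structures are parsed with gemmi (PDB and
mmCIF); trajectory frames are read and written with MDAnalysis (DCD, XTC,
TRR).

The superposition used throughout is deliberately *in-plane*: the membrane
normal is the z axis, so frames are aligned to the reference with a rotation
about z plus a free translation. A full 3D Kabsch superposition is also
provided (and used for the C2 symmetry-axis derivation), but applying it to
membrane frames would tilt the bilayer and is therefore not the default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SelectionMask",
    "SuperpositionResult",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "discard_equilibration",
    "kabsch_superpose",
    "align_frames_in_plane",
    "select_atoms",
    "select_phosphorus",
    "infer_tm_calpha_mask",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology: identity, not coordinates."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str


@dataclass
class Frame:
    """A single coordinate frame.

    ``box`` holds the three triclinic cell vectors as rows (Å); a zero
    matrix means "no periodic box".
    """

    time: float  # ns
    box: np.ndarray  # (3, 3) Å
    coordinates: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("frame coordinates must be finite")


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    Coordinates are stored as one (n_frames, n_atoms, 3) array; ``frame(i)``
    returns a :class:`Frame` view for APIs that want a single frame.
    """

    topology: list[AtomRecord]
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray  # (n_frames,) ns
    boxes: np.ndarray  # (n_frames, 3, 3) Å
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology atom count {len(self.topology)}"
            )
        if len(self.times) != self.n_frames:
            raise ValueError("one time per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i],
                     coordinates=self.coordinates[i])

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class SelectionMask:
    """Indices of selected topology atoms plus a role label."""

    indices: np.ndarray
    role: str = "custom"  # phosphorus | tm_calpha | custom

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.indices)

    def require_nonempty(self) -> None:
        if self.n_atoms == 0:
            raise ValueError(f"selection mask (role={self.role!r}) is empty")


@dataclass
class SuperpositionResult:
    """Rigid-body transform mapping a mobile set onto a reference."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, after transformation
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# structure and trajectory I/O
# ---------------------------------------------------------------------------

def read_structure(path: str | os.PathLike) -> tuple[list[AtomRecord], np.ndarray]:
    """Read a PDB or mmCIF file into (topology, coordinates).

    Only the first model is used; for atoms with alternate locations the
    first altloc is kept. Hydrogens are retained (callers filter by
    element where needed).
    """
    import gemmi

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path!r}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"structure file {path!r} contains no model")
    structure.setup_entities()
    model = structure[0]
    topology: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for residue in chain:
            seen: set[str] = set()
            for atom in residue:
                if atom.name in seen:  # keep first altloc only
                    continue
                seen.add(atom.name)
                topology.append(AtomRecord(
                    atom_name=atom.name,
                    element=atom.element.name,
                    residue_name=residue.name,
                    residue_id=residue.seqid.num,
                    chain_id=chain.name,
                ))
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not topology:
        raise ValueError(f"structure file {path!r} contains no atoms")
    return topology, np.asarray(coords, dtype=float)


def write_structure(path: str | os.PathLike, topology: Sequence[AtomRecord],
                    coordinates: np.ndarray) -> None:
    """Write topology + one coordinate set as a PDB file (gemmi)."""
    import gemmi

    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (len(topology), 3):
        raise ValueError("coordinates must be (n_atoms, 3) matching the topology")
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec, xyz in zip(topology, coordinates):
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
        if (len(chain) == 0 or chain[-1].seqid.num != rec.residue_id
                or chain[-1].name != rec.residue_name):
            residue = gemmi.Residue()
            residue.name = rec.residue_name
            residue.seqid = gemmi.SeqId(rec.residue_id, " ")
            chain.add_residue(residue)
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*xyz)
        chain[-1].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(os.fspath(path))


def _box_to_mda_dimensions(box: np.ndarray) -> np.ndarray:
    """Triclinic cell vectors (rows) -> MDAnalysis [lx, ly, lz, α, β, γ]."""
    from MDAnalysis.lib.mdamath import triclinic_box

    box = np.asarray(box, dtype=float)
    if np.allclose(box, 0.0):
        return np.zeros(6)
    return triclinic_box(box[0], box[1], box[2])


def _mda_dimensions_to_box(dim) -> np.ndarray:
    from MDAnalysis.lib.mdamath import triclinic_vectors

    if dim is None or np.allclose(dim[:3], 0.0):
        return np.zeros((3, 3))
    return np.asarray(triclinic_vectors(dim), dtype=float)


def write_trajectory(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write frames to a standard trajectory format (by extension: .dcd/.xtc/.trr)."""
    import MDAnalysis as mda

    path = os.fspath(path)
    n_atoms = traj.n_atoms
    with mda.Writer(path, n_atoms=n_atoms) as writer:
        universe = mda.Universe.empty(n_atoms, trajectory=True)
        for i in range(traj.n_frames):
            universe.atoms.positions = traj.coordinates[i].astype(np.float32)
            universe.trajectory.ts.time = traj.times[i] * 1000.0  # ns -> ps
            universe.trajectory.ts.frame = i
            dim = _box_to_mda_dimensions(traj.boxes[i])
            universe.trajectory.ts.dimensions = dim if dim[:3].any() else None
            writer.write(universe.atoms)


def read_trajectory(topology: Sequence[AtomRecord], path: str | os.PathLike,
                    replicate_id: int = 0) -> Trajectory:
    """Read a DCD/XTC/TRR trajectory against an in-memory topology.

    The frame atom count must match the topology; a mismatch is an error
    stating both counts.
    """
    from MDAnalysis.coordinates.core import get_reader_for

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    reader_cls = get_reader_for(path)
    coords, times, boxes = [], [], []
    with reader_cls(path) as reader:
        if reader.n_atoms != len(topology):
            raise ValueError(
                f"trajectory {path!r} has {reader.n_atoms} atoms but the "
                f"topology has {len(topology)}"
            )
        for ts in reader:
            coords.append(np.array(ts.positions, dtype=float))
            times.append(ts.time / 1000.0)  # ps -> ns
            boxes.append(_mda_dimensions_to_box(ts.dimensions))
    return Trajectory(topology=list(topology), coordinates=np.array(coords),
                      times=np.array(times), boxes=np.array(boxes),
                      replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select_atoms(topology: Sequence[AtomRecord], *,
                 chain_ids: Sequence[str] | None = None,
                 residue_ranges: Sequence[tuple[int, int]] | None = None,
                 atom_names: Sequence[str] | None = None,
                 elements: Sequence[str] | None = None,
                 role: str = "custom") -> SelectionMask:
    """Select atoms by chain, inclusive residue-id range, atom name, element."""
    chain_set = set(chain_ids) if chain_ids is not None else None
    name_set = set(atom_names) if atom_names is not None else None
    elem_set = {e.upper() for e in elements} if elements is not None else None
    indices = []
    for i, rec in enumerate(topology):
        if chain_set is not None and rec.chain_id not in chain_set:
            continue
        if name_set is not None and rec.atom_name not in name_set:
            continue
        if elem_set is not None and rec.element.upper() not in elem_set:
            continue
        if residue_ranges is not None and not any(
                lo <= rec.residue_id <= hi for lo, hi in residue_ranges):
            continue
        indices.append(i)
    return SelectionMask(indices=np.array(indices, dtype=int), role=role)


def select_phosphorus(topology: Sequence[AtomRecord]) -> SelectionMask:
    """All phosphorus atoms (lipid headgroup markers)."""
    mask = select_atoms(topology, elements=["P"], role="phosphorus")
    if mask.n_atoms == 0:
        mask = select_atoms(topology, atom_names=["P"], role="phosphorus")
    return mask


def infer_tm_calpha_mask(topology: Sequence[AtomRecord], coordinates: np.ndarray,
                         half_width: float = 15.0) -> SelectionMask:
    """Default transmembrane mask: Cα atoms within a z-slab about the
    phosphorus midplane of the given (first-frame) coordinates.

    Explicit residue ranges in config are preferred; this keeps the CLI
    runnable when none are given.
    """
    p_mask = select_phosphorus(topology)
    p_mask.require_nonempty()
    midplane = float(np.median(coordinates[p_mask.indices, 2]))
    indices = [i for i, rec in enumerate(topology)
               if rec.atom_name == "CA"
               and abs(coordinates[i, 2] - midplane) <= half_width]
    return SelectionMask(indices=np.array(indices, dtype=int), role="tm_calpha")


# ---------------------------------------------------------------------------
# equilibration and superposition
# ---------------------------------------------------------------------------

def discard_equilibration(traj: Trajectory, t_cut: float) -> Trajectory:
    """Drop frames with time <= t_cut (ns); the boundary frame is discarded."""
    if t_cut < 0:
        raise ValueError("t_cut must be >= 0")
    keep = traj.times > t_cut
    if not np.any(keep):
        raise ValueError(
            f"no frames survive t_cut={t_cut} ns (last frame at "
            f"{traj.times[-1]:.6g} ns)"
        )
    return Trajectory(topology=traj.topology, coordinates=traj.coordinates[keep],
                      times=traj.times[keep], boxes=traj.boxes[keep],
                      replicate_id=traj.replicate_id)


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (Kabsch).

    Returns the proper rotation (det = +1) and translation minimizing
    ||R·B + t − A||, with the RMSD evaluated after the transform.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must be equal-shape (n, 3) coordinate sets")
    n = A.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired atoms are required")
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    H = (B - cB).T @ (A - cA)
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (rank-deficient) coordinate sets")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cA - R @ cB
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _inplane_transform(ref_xy: np.ndarray, mob_xy: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal rotation angle about z + xy translation mapping mob onto ref."""
    cR, cM = ref_xy.mean(axis=0), mob_xy.mean(axis=0)
    r = ref_xy - cR
    m = mob_xy - cM
    # 2D Kabsch: theta = atan2(sum(m x r), sum(m . r))
    num = float(np.sum(m[:, 0] * r[:, 1] - m[:, 1] * r[:, 0]))
    den = float(np.sum(m[:, 0] * r[:, 0] + m[:, 1] * r[:, 1]))
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    rot2 = np.array([[c, -s], [s, c]])
    t_xy = cR - rot2 @ cM
    return theta, t_xy


def _wrap_around_centroid(coords: np.ndarray, box: np.ndarray,
                          center_idx: np.ndarray) -> np.ndarray:
    """Translate the frame so the selected-atom centroid lies in the primary
    cell; triclinic boxes are handled via fractional coordinates."""
    if np.allclose(box, 0.0) or np.linalg.det(box) <= 0:
        return coords
    centroid = coords[center_idx].mean(axis=0)
    frac = np.linalg.solve(box.T, centroid)
    shift = (frac - np.floor(frac)) - frac
    if np.allclose(shift, 0.0):
        return coords
    return coords + box.T @ shift


def align_frames_in_plane(traj: Trajectory, reference: np.ndarray,
                          mask: SelectionMask, *,
                          full_3d: bool = False,
                          wrap: bool = True) -> Trajectory:
    """Superpose every frame to the reference on the membrane (xy) plane.

    The rigid motion is restricted to a rotation about the z axis plus a
    free translation: the in-plane part minimizes the squared xy-deviation
    of the masked atoms from the reference, and z is shifted by the
    masked-atom centroid offset only — out-of-plane tilt is deliberately
    left untouched so the bilayer is not rotated out of its plane. With
    ``full_3d=True`` an unrestricted Kabsch superposition is applied
    instead (for comparison).
    """
    reference = np.asarray(reference, dtype=float)
    idx = mask.indices
    if len(idx) < 3:
        raise ValueError("in-plane alignment needs at least 3 masked atoms")
    if reference.shape[0] == traj.n_atoms:
        ref_sel = reference[idx]
    elif reference.shape[0] == len(idx):
        ref_sel = reference
    else:
        raise ValueError(
            "reference must cover either all atoms or exactly the masked atoms")
    # collinearity in xy makes the rotation angle ill-determined
    xy = ref_sel[:, :2] - ref_sel[:, :2].mean(axis=0)
    if np.linalg.svd(xy, compute_uv=False)[1] < 1e-8:
        raise ValueError("masked atoms are collinear in xy; rotation is degenerate")

    out = np.empty_like(traj.coordinates)
    for i in range(traj.n_frames):
        coords = traj.coordinates[i]
        if wrap:
            coords = _wrap_around_centroid(coords, traj.boxes[i], idx)
        if full_3d:
            sup = kabsch_superpose(ref_sel, coords[idx])
            out[i] = sup.apply(coords)
            continue
        theta, t_xy = _inplane_transform(ref_sel[:, :2], coords[idx, :2])
        c, s = np.cos(theta), np.sin(theta)
        moved = coords.copy()
        x, y = coords[:, 0], coords[:, 1]
        moved[:, 0] = c * x - s * y + t_xy[0]
        moved[:, 1] = s * x + c * y + t_xy[1]
        dz = ref_sel[:, 2].mean() - coords[idx, 2].mean()
        moved[:, 2] = coords[:, 2] + dz
        out[i] = moved
    return Trajectory(topology=traj.topology, coordinates=out, times=traj.times,
                      boxes=traj.boxes, replicate_id=traj.replicate_id)
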