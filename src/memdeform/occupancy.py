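"""3D iso-occupancy volumes of selected atoms over a trajectory.

Occupancy of a voxel is the fraction of frames (pooled over replicates) in
which at least one selected atom falls inside it — a binary per-frame
indicator, which makes an iso-level like 0.6 directly interpretable as
"occupied in 60% of frames". An atom-count-density mode is available for
comparison. Iso-surfaces are extracted with marching cubes and exported as
Wavefront OBJ; volumes are written as OpenDX scalar fields readable by VMD,
PyMOL and ChimeraX.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import SelectionMask, Trajectory

__all__ = [
    "GridSpec3D",
    "OccupancyGrid",
    "TriangleMesh",
    "occupancy_grid",
    "extract_isosurface",
    "write_volume",
    "read_volume",
    "write_obj",
]


@dataclass(frozen=True)
class GridSpec3D:
    """Cubic-voxel 3D grid: origin (Å), voxel edge (Å), dimensions."""

    origin: tuple[float, float, float]
    voxel: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.voxel <= 0:
            raise ValueError("voxel edge must be > 0")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid needs at least 2 voxels per axis")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.origin) + self.voxel * np.asarray(self.shape)

    @classmethod
    def from_points(cls, points: np.ndarray, voxel: float = 1.0,
                    margin: float = 5.0) -> "GridSpec3D":
        """Auto-size to the bounding box of ``points`` plus a margin."""
        points = np.asarray(points, dtype=float)
        lo = points.min(axis=0) - margin
        hi = points.max(axis=0) + margin
        shape = tuple(int(np.ceil((h - l) / voxel)) for l, h in zip(lo, hi))
        shape = tuple(max(n, 2) for n in shape)
        return cls(origin=tuple(lo), voxel=voxel, shape=shape)


@dataclass
class OccupancyGrid:
    """Per-voxel occupied-frame fraction in [0, 1]."""

    grid: GridSpec3D
    values: np.ndarray  # (nx, ny, nz) float
    n_frames: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match the grid")


@dataclass
class TriangleMesh:
    vertices: np.ndarray  # (n_v, 3) Å
    triangles: np.ndarray  # (n_t, 3) int

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0


def _voxel_indices(coords: np.ndarray, grid: GridSpec3D
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Voxel index of each coordinate; half-open intervals [low, high).

    Returns (indices inside the grid, boolean inside-mask over coords).
    """
    rel = (coords - np.asarray(grid.origin)) / grid.voxel
    idx = np.floor(rel).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    return idx[inside], inside


def occupancy_grid(trajs: Trajectory | Sequence[Trajectory],
                   mask: SelectionMask, grid: GridSpec3D,
                   mode: str = "binary") -> OccupancyGrid:
    """Occupancy over all frames of all trajectories.

    mode="binary" (default): fraction of frames with ≥ 1 masked atom in the
    voxel. mode="density": mean masked-atom count per voxel per frame.
    Atoms outside the grid are ignored but tallied; if more than half of
    all masked atom-frames fall outside, the grid is considered misplaced
    and an error is raised.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if mode not in ("binary", "density"):
        raise ValueError(f"unknown occupancy mode {mode!r}")
    mask.require_nonempty()
    shape = grid.shape
    acc = np.zeros(shape)
    n_frames = 0
    n_total = 0
    n_outside = 0
    for traj in trajs:
        for k in range(traj.n_frames):
            coords = traj.coordinates[k][mask.indices]
            idx, inside = _voxel_indices(coords, grid)
            n_total += len(coords)
            n_outside += int(np.sum(~inside))
            if len(idx):
                if mode == "binary":
                    uniq = np.unique(idx, axis=0)
                    acc[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1.0
                else:
                    np.add.at(acc, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
            n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames provided")
    if n_total and n_outside > 0.5 * n_total:
        raise ValueError(
            f"{n_outside}/{n_total} masked atom-frames fall outside the "
            "grid; the grid does not cover the selection")
    return OccupancyGrid(grid=grid, values=acc / n_frames, n_frames=n_frames)


def extract_isosurface(occ: OccupancyGrid, level: float = 0.6) -> TriangleMesh:
    """Marching-cubes iso-surface of the occupancy field.

    Vertices are in Å, located at voxel centers ± linear interpolation
    along voxel edges. Default level 0.6: the voxel set visited by lipid
    headgroups in ≥ 60% of frames.
    """
    from skimage import measure

    if not 0.0 < level < 1.0:
        raise ValueError(f"iso level must be in (0, 1), got {level}")
    values = occ.values
    if values.max() <= level:
        return TriangleMesh(vertices=np.empty((0, 3)),
                            triangles=np.empty((0, 3), dtype=int))
    verts, faces, _, _ = measure.marching_cubes(
        values, level=level, spacing=(occ.grid.voxel,) * 3)
    # marching_cubes indexes voxel centers at i·voxel; shift to Å
    verts = verts + np.asarray(occ.grid.origin) + occ.grid.voxel / 2.0
    return TriangleMesh(vertices=verts, triangles=faces.astype(int))


# ---------------------------------------------------------------------------
# OpenDX and OBJ output
# ---------------------------------------------------------------------------

def write_volume(occ: OccupancyGrid, path: str | os.PathLike) -> None:
    """Write the occupancy volume as an OpenDX scalar field.

    Grid positions are the voxel centers; data ordering is row-major with
    z varying fastest (the OpenDX convention).
    """
    grid = occ.grid
    nx, ny, nz = grid.shape
    origin = np.asarray(grid.origin) + grid.voxel / 2.0  # voxel centers
    lines = [
        "# OpenDX scalar volume (occupancy fractions)",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}",
        f"delta {grid.voxel:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.voxel:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.voxel:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = occ.values.ravel(order="C")  # (x, y, z) with z fastest
    for i in range(0, len(flat), 3):
        chunk = flat[i:i + 3]
        lines.append(" ".join(f"{v:.10g}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "occupancy" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_volume(path: str | os.PathLike) -> OccupancyGrid:
    """Read an OpenDX scalar volume written by :func:`write_volume`."""
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    in_data = False
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_data and n_items is not None and len(data) < n_items:
                if line.startswith(("attribute", "object", "component")):
                    in_data = False
                else:
                    data.extend(float(tok) for tok in line.split())
                    continue
            if line.startswith("object 1"):
                counts = tuple(int(tok) for tok in line.split()[-3:])
            elif line.startswith("origin"):
                origin = tuple(float(tok) for tok in line.split()[1:4])
            elif line.startswith("delta"):
                deltas.append([float(tok) for tok in line.split()[1:4]])
            elif "data follows" in line:
                n_items = int(line.split("items")[1].split()[0])
                in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path!r} is not a recognised OpenDX scalar volume")
    voxel = deltas[0][0]
    values = np.asarray(data, dtype=float).reshape(counts, order="C")
    grid = GridSpec3D(origin=tuple(np.asarray(origin) - voxel / 2.0),
                      voxel=voxel, shape=counts)
    return OccupancyGrid(grid=grid, values=values, n_frames=0)


def write_obj(mesh: TriangleMesh, path: str | os.PathLike) -> None:
    """Export a triangle mesh as Wavefront OBJ (1-based vertex indices)."""
    with open(os.fspath(path), "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
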