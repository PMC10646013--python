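"""Geometry of membrane-embedded helices and protein interfaces.

Quantities that characterise how an insertase sits in the bilayer: the
dimer C2 symmetry axis (which defines the membrane normal), per-helix axes
from a principal-component fit of the Cα trace, tilt angles against the
normal, inter-helix angles, helix lengths, lipid-tail tilt, and buried
interface areas from Shrake–Rupley solvent-accessible surface areas.

Conventions: helix axes are oriented N→C; tilt and inter-helix angles are
line angles in [0°, 90°] (insensitive to axis sign); the lipid-tail tilt
is directional in [0°, 180°]. Buried area is the half-sum convention,
0.5·(SASA(A) + SASA(B) − SASA(A∪B)), equal to the mean of the two
per-side ΔSASA values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import AtomRecord, kabsch_superpose

__all__ = [
    "SymmetryAxis",
    "HelixAxis",
    "InterfaceArea",
    "c2_symmetry_axis",
    "helix_axis",
    "tilt_angle",
    "interhelix_angle",
    "lipid_tail_tilt",
    "shrake_rupley_sasa",
    "buried_interface_area",
    "VDW_RADII",
]

# van der Waals radii (Å) for SASA; hydrogens are ignored
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "ZN": 1.39}


@dataclass
class SymmetryAxis:
    """Unit direction + anchor point of a (C2) symmetry axis."""

    direction: np.ndarray
    anchor: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.anchor = np.asarray(self.anchor, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-6:
            self.direction = self.direction / n


@dataclass
class HelixAxis:
    """Principal axis of a helix Cα trace, oriented N→C."""

    direction: np.ndarray  # unit
    centroid: np.ndarray  # Å
    length: float  # Å, extent of Cα projections onto the axis

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class InterfaceArea:
    buried_area: float  # Å², half-sum convention
    dsasa_a: float  # Å², SASA lost by side A on complexation
    dsasa_b: float  # Å²
    probe_radius: float  # Å


def c2_symmetry_axis(chainA: np.ndarray, chainB: np.ndarray,
                     angle_tol: float = 15.0) -> SymmetryAxis:
    """C2 symmetry axis of a homodimer from matched Cα sets.

    The rotation superposing chainB onto chainA must be within
    ``angle_tol`` degrees of a half-turn; its rotation axis (the
    +1-eigenvector) is the symmetry axis, anchored at the midpoint of the
    chain centroids. The returned direction is sign-fixed so its largest
    component is positive.
    """
    chainA = np.asarray(chainA, dtype=float)
    chainB = np.asarray(chainB, dtype=float)
    if chainA.shape != chainB.shape:
        raise ValueError("chains must be residue-matched (equal shapes)")
    if chainA.shape[0] < 20:
        raise ValueError("need at least 20 matched residues")
    sup = kabsch_superpose(chainA, chainB)
    R = sup.rotation
    cos_angle = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_angle))
    if abs(angle - 180.0) > angle_tol:
        raise ValueError(
            f"not a C2 pair: rotation angle {angle:.2f}° deviates from 180° "
            f"by more than {angle_tol}°")
    # +1-eigenvector of R (rotation axis); symmetric part is robust near 180°
    w, v = np.linalg.eigh((R + R.T) / 2.0)
    axis = v[:, np.argmax(w)]
    axis = axis / np.linalg.norm(axis)
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    anchor = 0.5 * (chainA.mean(axis=0) + chainB.mean(axis=0))
    return SymmetryAxis(direction=axis, anchor=anchor)


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Helix axis from the first principal component of the ordered Cα trace.

    The direction is sign-fixed toward the C-terminus (positive projection
    of the first→last Cα vector); length is the max−min extent of Cα
    projections onto the axis.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca_coords must be (n, 3)")
    if ca.shape[0] < 6:
        raise ValueError(f"helix axis needs >= 6 residues, got {ca.shape[0]}")
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    direction = Vt[0]
    if direction @ (ca[-1] - ca[0]) < 0:
        direction = -direction
    proj = centered @ direction
    return HelixAxis(direction=direction, centroid=centroid,
                     length=float(proj.max() - proj.min()))


def tilt_angle(helix: HelixAxis, normal: SymmetryAxis) -> float:
    """Line angle (degrees, 0–90) between a helix axis and the membrane normal."""
    c = abs(float(helix.direction @ normal.direction))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def interhelix_angle(h1: HelixAxis, h2: HelixAxis) -> float:
    """Line angle (degrees, 0–90) between two helix axes."""
    c = abs(float(h1.direction @ h2.direction))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def lipid_tail_tilt(head: np.ndarray, tail_end: np.ndarray,
                    normal: SymmetryAxis) -> float:
    """Directional angle (degrees, 0–180) of the head→tail vector vs. normal."""
    v = np.asarray(tail_end, dtype=float) - np.asarray(head, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("head and tail_end coincide")
    c = float(v @ normal.direction) / n
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA and buried interface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _radii_for(topology: Sequence[AtomRecord] | Sequence[str]) -> np.ndarray:
    radii = []
    for rec in topology:
        elem = (rec.element if isinstance(rec, AtomRecord) else rec).upper()
        if elem == "H":
            radii.append(-1.0)  # excluded
            continue
        if elem not in VDW_RADII:
            name = rec.atom_name if isinstance(rec, AtomRecord) else elem
            raise ValueError(f"no van der Waals radius for element {elem!r} "
                             f"(atom {name!r})")
        radii.append(VDW_RADII[elem])
    return np.asarray(radii)


def shrake_rupley_sasa(coords: np.ndarray, elements: Sequence[str] | Sequence[AtomRecord],
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    Each atom's solvent sphere (vdW radius + probe) is sampled with
    ``n_points`` golden-spiral points; a point is accessible when it lies
    outside every neighbor's solvent sphere. Hydrogens are ignored (zero
    area, and they do not occlude).
    """
    coords = np.asarray(coords, dtype=float)
    radii = _radii_for(elements)
    keep = radii > 0
    sasa = np.zeros(len(coords))
    if not np.any(keep):
        return sasa
    xyz = coords[keep]
    r_s = radii[keep] + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    for i in range(len(xyz)):
        pts = xyz[i] + r_s[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], r_s[i] + r_s.max())
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > r_s[j] ** 2
        area_idx = np.flatnonzero(keep)[i]
        sasa[area_idx] = 4.0 * np.pi * r_s[i] ** 2 * accessible.mean()
    return sasa


def buried_interface_area(coordsA: np.ndarray, elementsA,
                          coordsB: np.ndarray, elementsB,
                          probe: float = 1.4, n_points: int = 960
                          ) -> InterfaceArea:
    """Buried SASA between two atom sets (half-sum convention).

    buried = 0.5·(SASA(A) + SASA(B) − SASA(A∪B)); the per-side ΔSASA
    values are also reported. Symmetric in (A, B) by construction.
    """
    coordsA = np.asarray(coordsA, dtype=float)
    coordsB = np.asarray(coordsB, dtype=float)
    if len(coordsA) == 0 or len(coordsB) == 0:
        raise ValueError("both atom sets must be non-empty")
    sasaA = shrake_rupley_sasa(coordsA, elementsA, probe, n_points)
    sasaB = shrake_rupley_sasa(coordsB, elementsB, probe, n_points)
    coordsAB = np.vstack([coordsA, coordsB])
    elementsAB = list(elementsA) + list(elementsB)
    sasaAB = shrake_rupley_sasa(coordsAB, elementsAB, probe, n_points)
    nA = len(coordsA)
    dsasa_a = float(sasaA.sum() - sasaAB[:nA].sum())
    dsasa_b = float(sasaB.sum() - sasaAB[nA:].sum())
    buried = 0.5 * (dsasa_a + dsasa_b)
    return InterfaceArea(buried_area=buried, dsasa_a=dsasa_a, dsasa_b=dsasa_b,
                         probe_radius=probe)
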