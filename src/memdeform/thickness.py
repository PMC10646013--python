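"""Leaflet-resolved bilayer thickness maps from phosphorus coordinates.

The central computation of the package: per frame, phosphorus atoms are
partitioned into upper and lower leaflets about the median midplane; each
leaflet's z-coordinates are interpolated onto a common xy grid with a C1
piecewise-cubic Clough–Tocher interpolant on the Delaunay triangulation of
the (x, y) positions; the two surfaces are subtracted; and the per-cell
difference is averaged over frames within each replicate and then across
replicates with frame-count weights (equivalent to pooling all frames).

Points are replicated into a periodic margin across the box edges before
triangulation so the convex hull covers the grid interior; cells that fall
outside the hull in a frame simply do not contribute to that frame's
average (coverage is tracked per cell in ``n_samples``).

A 2D lateral density of selected (protein) atoms and a windowed thickness
time series complete the map products, and a radial-Gaussian thinning-well
model can be fitted to a map to quantify protein-induced thinning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .trajectory import SelectionMask, Trajectory

__all__ = [
    "GridSpec2D",
    "LeafletAssignment",
    "ThicknessMap",
    "LateralDensityMap",
    "ThicknessTimeseries",
    "assign_leaflets",
    "leaflet_surface",
    "thickness_map",
    "thickness_timeseries",
    "lateral_density",
    "fit_thinning_well",
    "ThinningWellModel",
    "ThinningWellResults",
    "write_map_tsv",
]


@dataclass(frozen=True)
class GridSpec2D:
    """Regular xy grid: extents in Å, one value per cell center.

    Default spacing is 2 Å — about one cell per lipid headgroup diameter
    at typical box sizes; configurable.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    spacing: float = 2.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grid needs at least 4 cells per axis")

    @property
    def nx(self) -> int:
        return int(np.floor((self.x_max - self.x_min) / self.spacing))

    @property
    def ny(self) -> int:
        return int(np.floor((self.y_max - self.y_min) / self.spacing))

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.spacing

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers, indexing="ij")

    @classmethod
    def from_box(cls, box: np.ndarray, spacing: float = 2.0) -> "GridSpec2D":
        box = np.asarray(box, dtype=float)
        return cls(0.0, float(box[0, 0]), 0.0, float(box[1, 1]), spacing)


@dataclass
class LeafletAssignment:
    """Boolean upper-leaflet flag per selected phosphorus atom (one frame)."""

    upper: np.ndarray  # bool, True = upper leaflet
    midplane_z: float

    @property
    def n_upper(self) -> int:
        return int(np.sum(self.upper))

    @property
    def n_lower(self) -> int:
        return int(np.sum(~self.upper))


def assign_leaflets(coordinates: np.ndarray, p_mask: SelectionMask,
                    frame_index: int | None = None) -> LeafletAssignment:
    """Partition phosphorus atoms into leaflets about the median z.

    Atoms with z strictly above the midplane (median z of the selection)
    are upper; below, lower; atoms exactly at the midplane are assigned to
    the upper leaflet (fixed tie rule). Re-evaluated per frame by callers.
    """
    p_mask.require_nonempty()
    idx = p_mask.indices
    if len(idx) < 8:
        raise ValueError("leaflet assignment needs at least 8 phosphorus atoms")
    z = np.asarray(coordinates, dtype=float)[idx, 2]
    midplane = float(np.median(z))
    upper = z >= midplane
    where = "" if frame_index is None else f" in frame {frame_index}"
    if upper.sum() < 4 or (~upper).sum() < 4:
        raise ValueError(f"fewer than 4 atoms in one leaflet{where}")
    return LeafletAssignment(upper=upper, midplane_z=midplane)


def _periodic_margin(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Replicate points into a margin across periodic box edges.

    Margin width is twice the mean nearest-neighbor spacing of the (x, y)
    positions, so the Delaunay hull covers the full primary cell.
    """
    if np.allclose(box, 0.0):
        return points
    Lx, Ly = float(box[0, 0]), float(box[1, 1])
    if Lx <= 0 or Ly <= 0:
        return points
    xy = points[:, :2]
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    margin = 2.0 * float(np.mean(d[:, 1]))
    out = [points]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shifted = points + np.array([sx * Lx, sy * Ly, 0.0])
            keep = ((shifted[:, 0] > -margin) & (shifted[:, 0] < Lx + margin)
                    & (shifted[:, 1] > -margin) & (shifted[:, 1] < Ly + margin))
            if np.any(keep):
                out.append(shifted[keep])
    return np.vstack(out)


def leaflet_surface(points: np.ndarray, grid: GridSpec2D,
                    box: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Clough–Tocher interpolation of leaflet z onto the grid cell centers.

    Returns (surface, defined) with shape (nx, ny); cells outside the
    triangulation hull are NaN with defined=False. The C1 interpolant
    reproduces planar fields exactly, so a flat leaflet maps to a constant
    surface regardless of the scatter of points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3) = (x, y, z)")
    if points.shape[0] < 4:
        raise ValueError("at least 4 points required for surface interpolation")
    if box is not None:
        points = _periodic_margin(points, np.asarray(box, dtype=float))
    try:
        # tight gradient-estimation tolerance so planar fields are
        # reproduced to well below 1e-6
        interp = CloughTocher2DInterpolator(points[:, :2], points[:, 2],
                                            tol=1e-10)
    except Exception as exc:  # scipy QhullError on degenerate input
        raise ValueError(f"degenerate triangulation: {exc}") from exc
    gx, gy = grid.meshgrid()
    surface = interp(gx, gy)
    defined = np.isfinite(surface)
    if not np.any(defined):
        raise ValueError("interpolated surface is undefined on the whole grid")
    return surface, defined


@dataclass
class ThicknessMap:
    """Time/replicate-averaged upper−lower leaflet distance on a 2D grid.

    ``mean_thickness`` is the frame-count-weighted mean of the
    ``per_replicate`` layers (identical to pooling all frames);
    ``n_samples`` counts contributing frames per cell over all replicates.
    """

    grid: GridSpec2D
    mean_thickness: np.ndarray  # (nx, ny), Å; NaN where undefined
    per_replicate: np.ndarray  # (n_rep, nx, ny), Å
    n_samples: np.ndarray  # (nx, ny) int
    defined_mask: np.ndarray  # (nx, ny) bool
    replicate_n_samples: np.ndarray = field(default=None)  # (n_rep, nx, ny)

    def spatial_mean(self) -> float:
        return float(np.nanmean(self.mean_thickness[self.defined_mask]))


def _accumulate_thickness(traj: Trajectory, p_mask: SelectionMask,
                          grid: GridSpec2D) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (sum of thickness, count of defined frames) for one trajectory."""
    total = np.zeros((grid.nx, grid.ny))
    count = np.zeros((grid.nx, grid.ny), dtype=int)
    idx = p_mask.indices
    for k in range(traj.n_frames):
        coords = traj.coordinates[k]
        box = traj.boxes[k]
        assign = assign_leaflets(coords, p_mask, frame_index=k)
        pts = coords[idx]
        up, defined_up = leaflet_surface(pts[assign.upper], grid, box)
        lo, defined_lo = leaflet_surface(pts[~assign.upper], grid, box)
        both = defined_up & defined_lo
        thickness = up - lo
        total[both] += thickness[both]
        count[both] += 1
    return total, count


def thickness_map(trajs: Trajectory | Sequence[Trajectory],
                  p_mask: SelectionMask, grid: GridSpec2D) -> ThicknessMap:
    """Average thickness map over frames and replicates.

    Input trajectories must already be aligned to a common reference and
    have equilibration discarded. Cells undefined in some frames are
    averaged over their defined frames only.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("at least one trajectory required")
    sums, counts = [], []
    for traj in trajs:
        s, c = _accumulate_thickness(traj, p_mask, grid)
        sums.append(s)
        counts.append(c)
    sums_arr = np.array(sums)
    counts_arr = np.array(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_rep = np.where(counts_arr > 0, sums_arr / counts_arr, np.nan)
        total_count = counts_arr.sum(axis=0)
        mean = np.where(total_count > 0, sums_arr.sum(axis=0) / total_count, np.nan)
    defined = total_count > 0
    if not np.any(defined):
        raise ValueError("thickness map has zero defined cells")
    # a leaflet-label swap negates per-frame thickness everywhere; the
    # averaged map must be positive in every defined cell
    if np.any(mean[defined] <= 0):
        raise ValueError(
            "non-positive mean thickness in defined cells: upper/lower "
            "leaflet labels appear to be swapped")
    return ThicknessMap(grid=grid, mean_thickness=mean, per_replicate=per_rep,
                        n_samples=total_count, defined_mask=defined,
                        replicate_n_samples=counts_arr)


@dataclass
class ThicknessTimeseries:
    """Windowed spatial-mean bilayer thickness (equilibration diagnostic)."""

    times: np.ndarray  # ns, window end times
    thickness: np.ndarray  # Å, per complete window
    window: float  # ns


def thickness_timeseries(traj: Trajectory, p_mask: SelectionMask,
                         window: float, grid: GridSpec2D | None = None
                         ) -> ThicknessTimeseries:
    """Spatial-mean thickness per complete time window of length ``window`` ns."""
    if window <= 0:
        raise ValueError("window must be > 0")
    t0 = float(traj.times[0])
    span = float(traj.times[-1]) - t0
    if window > span + 1e-9:
        raise ValueError(
            f"window {window} ns exceeds trajectory span {span:.6g} ns")
    if grid is None:
        grid = GridSpec2D.from_box(traj.boxes[0])
    # windows w = 1…n_win cover rel time ((w−1)·W, w·W], with the first
    # frame in window 1; frames in an incomplete trailing window are dropped
    n_win = int(np.floor(span / window + 1e-9))
    rel = traj.times - t0
    win_idx = np.minimum(np.floor(rel / window - 1e-12).astype(int) + 1, n_win)
    win_idx[rel <= 0] = 1
    in_complete = rel <= n_win * window + 1e-9
    times, values = [], []
    for w in range(1, n_win + 1):
        sel = (win_idx == w) & in_complete
        if not np.any(sel):
            continue
        sub = Trajectory(topology=traj.topology,
                         coordinates=traj.coordinates[sel],
                         times=traj.times[sel], boxes=traj.boxes[sel],
                         replicate_id=traj.replicate_id)
        tmap = thickness_map(sub, p_mask, grid)
        times.append(t0 + w * window)
        values.append(tmap.spatial_mean())
    return ThicknessTimeseries(times=np.asarray(times),
                               thickness=np.asarray(values), window=window)


@dataclass
class LateralDensityMap:
    """Normalized 2D histogram of selected-atom (x, y) over frames/replicates."""

    grid: GridSpec2D
    density: np.ndarray  # (nx, ny), sums to 1


def lateral_density(trajs: Trajectory | Sequence[Trajectory],
                    mask: SelectionMask, grid: GridSpec2D) -> LateralDensityMap:
    """2D lateral density of masked atoms, normalized to unit total.

    Used to overlay the transmembrane-helix footprint onto thickness maps.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    mask.require_nonempty()
    x_edges = np.concatenate([[grid.x_min], grid.x_centers + grid.spacing / 2])
    y_edges = np.concatenate([[grid.y_min], grid.y_centers + grid.spacing / 2])
    hist = np.zeros((grid.nx, grid.ny))
    for traj in trajs:
        xy = traj.coordinates[:, mask.indices, :2].reshape(-1, 2)
        h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[x_edges, y_edges])
        hist += h
    total = hist.sum()
    if total == 0:
        raise ValueError("no masked atoms fall inside the grid")
    return LateralDensityMap(grid=grid, density=hist / total)


# ---------------------------------------------------------------------------
# thinning-well model
# ---------------------------------------------------------------------------

class ThinningWellResults:
    """Estimates for the radial-Gaussian thinning well fitted to a map.

    Attributes
    ----------
    T0, D, sigma : far-field thickness (Å), well depth (Å), well width (Å).
    bse : approximate standard errors from the Jacobian at the optimum.
    resid_rms : RMS of per-cell residuals, Å.
    """

    def __init__(self, params: np.ndarray, bse: np.ndarray, resid_rms: float,
                 n_cells: int, center: tuple[float, float]):
        self.params = params
        self.T0, self.D, self.sigma = (float(p) for p in params)
        self.bse = bse
        self.resid_rms = float(resid_rms)
        self.n_cells = int(n_cells)
        self.center = center

    def summary(self) -> str:
        names = ["T0 (far-field thickness, A)", "D (well depth, A)",
                 "sigma (well width, A)"]
        lines = ["Radial Gaussian thinning-well fit",
                 f"  cells used: {self.n_cells}   "
                 f"center: ({self.center[0]:.2f}, {self.center[1]:.2f})",
                 f"  residual RMS: {self.resid_rms:.4f} A",
                 f"  {'parameter':<30}{'estimate':>12}{'std err':>12}"]
        for name, p, se in zip(names, self.params, self.bse):
            lines.append(f"  {name:<30}{p:>12.4f}{se:>12.4f}")
        return "\n".join(lines)


class ThinningWellModel:
    """Least-squares fit of T(r) = T0 − D·exp(−r²/(2σ²)) to a thickness map.

    ``center`` is the well center in grid coordinates (the protein
    position); r is measured from it.
    """

    def __init__(self, tmap: ThicknessMap, center: tuple[float, float]):
        defined = tmap.defined_mask
        if int(defined.sum()) < 20:
            raise ValueError("thinning-well fit needs at least 20 defined cells")
        gx, gy = tmap.grid.meshgrid()
        self.r = np.sqrt((gx[defined] - center[0]) ** 2
                         + (gy[defined] - center[1]) ** 2)
        self.t = tmap.mean_thickness[defined]
        self.center = (float(center[0]), float(center[1]))

    def fit(self) -> ThinningWellResults:
        r, t = self.r, self.t
        far = r > np.percentile(r, 75)
        T0_init = float(np.mean(t[far])) if np.any(far) else float(np.mean(t))
        D_init = max(T0_init - float(np.min(t)), 1e-3)
        sigma_init = max(float(np.percentile(r, 30)), 1.0)

        def resid(p):
            T0, D, sigma = p
            return T0 - D * np.exp(-r ** 2 / (2.0 * sigma ** 2)) - t

        sol = least_squares(resid, x0=[T0_init, D_init, sigma_init],
                            bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]))
        if not sol.success:
            raise RuntimeError(
                f"thinning-well fit did not converge (last iterate {sol.x})")
        resid_rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        # covariance from the Jacobian; guard the rank-deficient D≈0 case
        dof = max(len(t) - 3, 1)
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (resid_rms ** 2
                                                        * len(t) / dof)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(3, np.nan)
        return ThinningWellResults(sol.x, bse, resid_rms, len(t), self.center)


def fit_thinning_well(tmap: ThicknessMap, center: tuple[float, float]
                      ) -> tuple[float, float, float]:
    """Convenience wrapper: (T0_hat, D_hat, sigma_hat)."""
    res = ThinningWellModel(tmap, center).fit()
    return res.T0, res.D, res.sigma


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_map_tsv(path: str, tmap: ThicknessMap | LateralDensityMap,
                  sidecar: dict | None = None) -> None:
    """Write a 2D map as TSV (x_center, y_center, value, n_samples) with a
    JSON sidecar carrying grid spec and provenance."""
    import pandas as pd

    grid = tmap.grid
    gx, gy = grid.meshgrid()
    if isinstance(tmap, ThicknessMap):
        value = tmap.mean_thickness
        n = tmap.n_samples
    else:
        value = tmap.density
        n = np.zeros_like(value, dtype=int)
    df = pd.DataFrame({
        "x_center": gx.ravel(), "y_center": gy.ravel(),
        "value": value.ravel(), "n_samples": n.ravel().astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {"grid": {"x_min": grid.x_min, "x_max": grid.x_max,
                     "y_min": grid.y_min, "y_max": grid.y_max,
                     "spacing": grid.spacing, "nx": grid.nx, "ny": grid.ny}}
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
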