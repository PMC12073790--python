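"""Dual-probe SASA and monolayer surface morphology.

SASA follows Shrake-Rupley: each atom's sphere of radius (vdw + probe) is
sampled at quasi-uniform points (a deterministic Fibonacci lattice, for
exact reproducibility) and the exposed fraction scales the sphere area.
A small probe (0.15 nm) mimics water accessibility; a large one (1.5 nm)
mimics accessibility to the IgV-like domain of PD-L1.

The height map renders the monolayer's top surface on an XY grid and
extracts pockets - connected depressions deep enough below the surrounding
surface level - whose depth/width are compared against the IgV-proxy
dimensions (4 nm deep, 3 nm wide).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import AnalysisError, ChemistryError
from .io import Frame, Topology, Trajectory

__all__ = [
    "SasaResult",
    "HeightMap",
    "Pocket",
    "fibonacci_sphere",
    "sasa",
    "sasa_timeseries",
    "scale_patch_to_sphere",
    "height_map",
    "accommodates_probe",
]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    probe_radius: float
    per_atom: np.ndarray          # nm^2, aligned with the selection
    per_peptide: dict[int, float]  # nm^2 summed over peptide_index >= 0
    total: float
    n_sphere_points: int


def sasa(
    frame: Frame,
    topology: Topology,
    selection: np.ndarray,
    probe_radius: float,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley SASA of a selection (selection atoms are the occluders).

    Periodic images are not considered; callers analysing a periodic slab
    should pass a patch comfortably smaller than the box.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    radii = topology.vdw_radii[selection]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ChemistryError("missing or non-positive vdW radius in selection")
    centers = frame.positions[selection]
    R = radii + probe_radius
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(centers)
    rmax = float(R.max())
    per_atom = np.empty(len(selection))
    for k in range(len(selection)):
        neigh = tree.query_ball_point(centers[k], R[k] + rmax)
        neigh = [j for j in neigh if j != k]
        pts = centers[k] + R[k] * unit
        if neigh:
            nc = centers[neigh]
            nr = R[np.asarray(neigh)]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[k] = frac * 4.0 * math.pi * R[k] ** 2
    per_pep: dict[int, float] = {}
    for k, a in enumerate(selection):
        c = int(topology.peptide_indices[a])
        if c >= 0:
            per_pep[c] = per_pep.get(c, 0.0) + per_atom[k]
    return SasaResult(probe_radius, per_atom, per_pep, float(per_atom.sum()), n_points)


def sasa_timeseries(
    traj: Trajectory,
    selection: np.ndarray,
    probe_radius: float,
    window: tuple[float, float] | None = None,
    stride: int = 1,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-frame per-peptide SASA over a window (columns = peptide index)."""
    idx = traj.window(*window) if window else list(range(len(traj.frames)))
    if not idx:
        raise AnalysisError("analysis window contains no frames")
    idx = idx[::stride]
    rows = []
    for i in idx:
        res = sasa(traj.frames[i], traj.topology, selection, probe_radius, n_points)
        rows.append(res.per_peptide)
    df = pd.DataFrame(rows, index=traj.times[idx]).sort_index(axis=1)
    df.index.name = "time_ps"
    return df


def scale_patch_to_sphere(delta_per_patch: float, patch_area: float, sphere_radius: float) -> float:
    """Scale a per-patch SASA difference to a whole spherical nanoparticle.

    Returns delta_per_patch * 4 pi R^2 / patch_area (nm^2).
    """
    if delta_per_patch < 0 or patch_area <= 0 or sphere_radius <= 0:
        raise ValueError("inputs must be positive (delta may be zero)")
    return delta_per_patch * 4.0 * math.pi * sphere_radius**2 / patch_area


@dataclass
class Pocket:
    depth: float      # nm below the reference surface level
    width: float      # nm, diameter of the largest inscribed disc
    area: float       # nm^2
    centroid: tuple[float, float]


@dataclass
class HeightMap:
    grid_resolution: float
    top_surface: np.ndarray      # Z (nm) on the XY grid, indexed [ix, iy]
    pockets: list[Pocket]
    surface_level: float         # reference (90th percentile) level

    def max_pocket_depth(self) -> float:
        return max((p.depth for p in self.pockets), default=0.0)


def height_map(
    frame: Frame,
    topology: Topology,
    selection: np.ndarray,
    grid_resolution: float = 0.2,
    depth_threshold: float = 1.5,
    surface_percentile: float = 90.0,
) -> HeightMap:
    """Top-surface height map and pocket morphology of a monolayer.

    Each grid cell records max(z + vdw) over atoms projecting into it
    (nearest-neighbour filled where empty).  Pockets are connected
    components of cells lying more than ``depth_threshold`` below the
    ``surface_percentile`` surface level; their width is the diameter of
    the largest inscribed disc.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    box = frame.box
    if grid_resolution > min(box[0], box[1]):
        raise ValueError("grid resolution exceeds the box")
    nx = max(1, int(round(box[0] / grid_resolution)))
    ny = max(1, int(round(box[1] / grid_resolution)))
    pos = frame.positions[selection]
    tops = pos[:, 2] + topology.vdw_radii[selection]
    ix = np.clip((pos[:, 0] % box[0]) / box[0] * nx, 0, nx - 1).astype(int)
    iy = np.clip((pos[:, 1] % box[1]) / box[1] * ny, 0, ny - 1).astype(int)
    grid = np.full((nx, ny), -np.inf)
    np.maximum.at(grid, (ix, iy), tops)
    empty = ~np.isfinite(grid)
    if empty.any():
        if empty.all():
            raise AnalysisError("no atoms project onto the grid")
        _, (fx, fy) = ndimage.distance_transform_edt(empty, return_indices=True)
        grid = grid[fx, fy]
    level = float(np.percentile(grid, surface_percentile))
    mask = grid < level - depth_threshold
    pockets: list[Pocket] = []
    if mask.any():
        lab, nlab = ndimage.label(mask)
        edt = ndimage.distance_transform_edt(mask)
        res = grid_resolution
        for li in range(1, nlab + 1):
            m = lab == li
            depth = level - float(grid[m].min())
            # +0.5 cell: distance from the deepest cell centre to the pocket edge
            width = 2.0 * (float(edt[m].max()) + 0.5) * res
            area = float(m.sum()) * res * res
            cx, cy = ndimage.center_of_mass(m)
            pockets.append(Pocket(depth, width, area, (cx * res, cy * res)))
    pockets.sort(key=lambda p: -p.depth)
    return HeightMap(grid_resolution, grid, pockets, level)


def mean_height_map(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[float, float] | None = None,
    stride: int = 1,
    grid_resolution: float = 0.2,
    depth_threshold: float = 1.5,
    surface_percentile: float = 90.0,
) -> HeightMap:
    """Height map of the time-averaged top surface over a window.

    Averaging the per-frame top surface per cell suppresses transient
    thermal gaps, so the pockets that remain are the persistent
    morphological features of the monolayer.
    """
    idx = traj.window(*window) if window else list(range(len(traj.frames)))
    if not idx:
        raise AnalysisError("analysis window contains no frames")
    idx = idx[::stride]
    acc = None
    for i in idx:
        hm = height_map(
            traj.frames[i], traj.topology, selection, grid_resolution,
            depth_threshold, surface_percentile,
        )
        acc = hm.top_surface if acc is None else acc + hm.top_surface
    mean_grid = acc / len(idx)
    level = float(np.percentile(mean_grid, surface_percentile))
    mask = mean_grid < level - depth_threshold
    pockets: list[Pocket] = []
    if mask.any():
        lab, nlab = ndimage.label(mask)
        edt = ndimage.distance_transform_edt(mask)
        for li in range(1, nlab + 1):
            m = lab == li
            depth = level - float(mean_grid[m].min())
            width = 2.0 * (float(edt[m].max()) + 0.5) * grid_resolution
            area = float(m.sum()) * grid_resolution**2
            cx, cy = ndimage.center_of_mass(m)
            pockets.append(Pocket(depth, width, area, (cx * grid_resolution, cy * grid_resolution)))
    pockets.sort(key=lambda p: -p.depth)
    return HeightMap(grid_resolution, mean_grid, pockets, level)


def accommodates_probe(
    hmap: HeightMap, probe_depth: float = 4.0, probe_width: float = 3.0
) -> tuple[bool, list[Pocket]]:
    """Whether any pocket can host the IgV-proxy probe (depth x width).

    Pocket depth and width carry a discretization error of about one grid
    cell, so the comparison allows one grid resolution of slack.
    """
    tol = hmap.grid_resolution
    qualifying = [
        p for p in hmap.pockets
        if p.depth >= probe_depth - tol and p.width >= probe_width - tol
    ]
    return bool(qualifying), qualifying
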