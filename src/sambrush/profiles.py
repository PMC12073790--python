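"""Slab density profiles, threshold distances and tensile displacement.

Densities are mass-weighted (kg/m^3) in fixed-width slices along Z measured
from the gold plane, averaged over the frames of an analysis window.  Atoms
are binned by point position; partial-volume smearing is ignored at the
default 0.15 nm slice width.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .geometry import pair_distance_matrix
from .io import Moiety, Trajectory

__all__ = [
    "DensityProfile",
    "density_profile",
    "moiety_density_profiles",
    "threshold_distance",
    "density_centroid",
    "density_centroid_shift",
    "convergence_min_distance",
    "U_TO_KG",
]

#: 1 atomic mass unit in kg; with nm^3 volumes (1 nm^3 = 1e-27 m^3) the
#: density in kg/m^3 is mass_u * U_TO_KG / (V_nm3 * 1e-27) = mass_u * 1.66054 / V_nm3.
U_TO_KG = 1.66053906892e-27
_U_PER_NM3_TO_KG_M3 = 1.66053906892


@dataclass
class DensityProfile:
    """Per-label mass density (kg/m^3) versus distance Z from the gold plane."""

    slice_width: float
    z_centers: np.ndarray
    density: dict[str, np.ndarray]
    window: tuple[float, float]
    box_xy_area: float

    def total_mass(self, key: str) -> float:
        """Selected mass in u implied by the profile (conservation check)."""
        vol_nm3 = self.slice_width * self.box_xy_area
        return float(np.sum(self.density[key]) * vol_nm3 / _U_PER_NM3_TO_KG_M3)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_center": self.z_centers})
        for k, v in self.density.items():
            df[k] = v
        return df


def _window_frames(traj: Trajectory, window) -> list[int]:
    if window is None:
        idx = list(range(len(traj.frames)))
    else:
        idx = traj.window(*window)
    if not idx:
        raise AnalysisError("analysis window contains no frames")
    return idx


def density_profile(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[float, float] | None = None,
    slice_width: float = 0.15,
    label: str = "selection",
) -> DensityProfile:
    """Mass-weighted Z histogram of a selection, averaged over a window."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise AnalysisError("empty selection")
    idx = _window_frames(traj, window)
    masses = traj.topology.masses[selection]
    box = traj.frames[idx[0]].box
    area = box[0] * box[1]
    zmax = max(float(traj.frames[i].positions[selection, 2].max()) for i in idx)
    n_slices = max(1, int(np.floor(zmax / slice_width)) + 1)
    hist = np.zeros(n_slices)
    for i in idx:
        z = traj.frames[i].positions[selection, 2]
        bins = np.clip(np.floor(z / slice_width).astype(int), 0, n_slices - 1)
        hist += np.bincount(bins, weights=masses, minlength=n_slices)
    hist /= len(idx)
    dens = hist * _U_PER_NM3_TO_KG_M3 / (area * slice_width)
    centers = (np.arange(n_slices) + 0.5) * slice_width
    t0, t1 = traj.frames[idx[0]].time, traj.frames[idx[-1]].time
    return DensityProfile(slice_width, centers, {label: dens}, (t0, t1), area)


def moiety_density_profiles(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    slice_width: float = 0.15,
    moieties: tuple[str, ...] = ("linker", "peptide"),
) -> DensityProfile:
    """One profile per moiety on a shared grid (linker and peptide by default)."""
    profiles = {}
    zmax = 0.0
    for m in moieties:
        sel = np.nonzero(traj.topology.moieties == Moiety(m).value)[0]
        if sel.size == 0:
            continue
        profiles[m] = density_profile(traj, sel, window, slice_width, label=m)
        zmax = max(zmax, profiles[m].z_centers[-1])
    if not profiles:
        raise AnalysisError(f"no atoms in moieties {moieties}")
    n = int(round(zmax / slice_width + 0.5))
    centers = (np.arange(n) + 0.5) * slice_width
    dens = {}
    for m, p in profiles.items():
        v = np.zeros(n)
        v[: len(p.density[m])] = p.density[m]
        dens[m] = v
    any_p = next(iter(profiles.values()))
    return DensityProfile(slice_width, centers, dens, any_p.window, any_p.box_xy_area)


def threshold_distance(
    profile: DensityProfile, threshold: float = 200.0, key: str | None = None
) -> float | None:
    """Outermost distance at which the density falls through ``threshold``.

    Scanning from the top of the profile, the first slice (largest Z) with
    density >= threshold defines the crossing; the result interpolates
    linearly toward the next (sub-threshold) slice.  Returns None when the
    profile never reaches the threshold.
    """
    if key is None:
        key = next(iter(profile.density))
    d = profile.density[key]
    z = profile.z_centers
    above = np.nonzero(d >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[-1])
    d_hi = d[i]
    if i + 1 < len(d):
        d_lo, z_lo = d[i + 1], z[i + 1]
    else:
        d_lo, z_lo = 0.0, z[i] + profile.slice_width
    if d_hi == d_lo:
        return float(z[i])
    return float(z[i] + (d_hi - threshold) / (d_hi - d_lo) * (z_lo - z[i]))


def density_centroid(profile: DensityProfile, key: str | None = None) -> float:
    """Density-weighted mean Z of a profile (nm)."""
    if key is None:
        key = next(iter(profile.density))
    d = profile.density[key]
    total = d.sum()
    if total <= 0:
        raise AnalysisError("profile carries no mass")
    return float(np.sum(profile.z_centers * d) / total)


def density_centroid_shift(
    before: DensityProfile, after: DensityProfile, key: str | None = None
) -> float:
    """Shift of the density-weighted mean Z (after - before), nm.

    Negative values mean displacement toward the gold surface.  Profiles
    must share the slice grid (width; centers may differ in extent).
    """
    if abs(before.slice_width - after.slice_width) > 1e-12:
        raise AnalysisError("profiles use different slice widths")
    return density_centroid(after, key) - density_centroid(before, key)


def convergence_min_distance(
    traj: Trajectory,
    protein_sel: np.ndarray,
    window: tuple[float, float] | None = None,
    qualify_cutoff: float = 0.7,
) -> pd.Series:
    """Per-frame mean of minimum side-chain-to-protein heavy-atom distances.

    A grafted peptide qualifies when any of its side-chain heavy atoms comes
    within ``qualify_cutoff`` of the protein selection during the window;
    the series then averages, per frame, the minimum distance of each
    qualifying peptide.  Empty result (with a warning) when nothing
    qualifies.
    """
    topo = traj.topology
    protein_sel = np.asarray(protein_sel, dtype=int)
    if protein_sel.size == 0:
        raise AnalysisError("protein selection is empty")
    prot_heavy = protein_sel[topo.is_heavy[protein_sel]]
    idx = _window_frames(traj, window)
    chains = sorted(c for c in set(topo.peptide_indices) if c >= 0)
    sc_sets = {}
    for c in chains:
        m = (topo.peptide_indices == c) & topo.is_sidechain & topo.is_heavy \
            & (topo.moieties == Moiety.PEPTIDE.value)
        if m.any():
            sc_sets[c] = np.nonzero(m)[0]
    box = traj.frames[idx[0]].box
    # per-frame minimum distance per peptide
    mins = np.full((len(idx), len(sc_sets)), np.inf)
    keys = list(sc_sets)
    for fi, i in enumerate(idx):
        pos = traj.frames[i].positions
        ppos = pos[prot_heavy]
        for ci, c in enumerate(keys):
            dm = pair_distance_matrix(pos[sc_sets[c]], ppos, box)
            mins[fi, ci] = dm.min()
    qualifying = [ci for ci in range(len(keys)) if (mins[:, ci] < qualify_cutoff).any()]
    times = traj.times[idx]
    if not qualifying:
        warnings.warn("no peptide qualifies within the cutoff; empty series")
        return pd.Series(dtype=float, name="mean_min_distance")
    series = mins[:, qualifying].mean(axis=1)
    return pd.Series(series, index=times, name="mean_min_distance")
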