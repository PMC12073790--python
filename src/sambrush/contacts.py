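"""Contact scoring: rational switching function, close contacts,
active-spot persistence maps, and a contact-potential energy score.

The switching (S) function counts inter-peptide atomic contacts smoothly:

    s(r) = [1 - (r/r0)^a] / [1 - (r/r0)^b],   r0 = 0.6 nm, a = 6, b = 14,

summed over heavy-atom pairs belonging to different peptides, optionally
normalized by n(n-1)/2 with n the number of peptides.  At r = r0 the
analytic limit a/b applies; the term is continuous and strictly decreasing.

All contact definitions default to heavy atoms (united-atom topologies may
carry no hydrogens) and use strict inequality at the cutoffs.  Periodicity
is XY-only (slab geometry).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, MatrixError, SelectionError
from .geometry import min_image_displacements, xy_periodic_tree
from .io import Frame, Moiety, Topology, Trajectory

__all__ = [
    "SwitchParams",
    "ActiveSpotSet",
    "PersistenceMap",
    "ContactSeries",
    "switch_term",
    "s_function",
    "s_function_series",
    "close_contacts",
    "persistence_map",
    "residue_pair_contacts",
    "contact_energy",
]


@dataclass(frozen=True)
class SwitchParams:
    r0: float = 0.6
    num_exp: int = 6
    den_exp: int = 14

    def __post_init__(self):
        if not (self.den_exp > self.num_exp > 0) or self.r0 <= 0:
            raise ValueError("require den_exp > num_exp > 0 and r0 > 0")


@dataclass(frozen=True)
class ActiveSpotSet:
    """The PD-L1 residues forming the PD-1 contact surface (active spots)."""

    residues: tuple[tuple[str, int], ...] = (
        ("PHE", 19), ("ASP", 26), ("ILE", 54), ("TYR", 56), ("GLN", 66),
        ("ARG", 113), ("MET", 115), ("ALA", 121), ("ASP", 122), ("TYR", 123),
        ("LYS", 124), ("ARG", 125),
    )

    def __post_init__(self):
        idx = [i for _, i in self.residues]
        if len(idx) != len(set(idx)):
            raise ValueError("active-spot residue indices must be unique")

    @property
    def labels(self) -> list[str]:
        return [f"{n.capitalize()}{i}" for n, i in self.residues]


def switch_term(r, p: SwitchParams = SwitchParams()):
    """Smooth contact weight in (0, 1] for distances r >= 0 (vectorized).

    Returns the analytic limit num_exp/den_exp at r = r0.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    x = np.atleast_1d(r) / p.r0
    out = np.empty_like(x)
    at_limit = np.abs(x - 1.0) < 1e-9
    safe = ~at_limit
    xs = x[safe]
    out[safe] = (1.0 - xs**p.num_exp) / (1.0 - xs**p.den_exp)
    out[at_limit] = p.num_exp / p.den_exp
    return float(out[0]) if scalar else out


def _peptide_heavy(topology: Topology) -> np.ndarray:
    return np.nonzero((topology.moieties == Moiety.PEPTIDE.value) & topology.is_heavy)[0]


def s_function(
    frame: Frame,
    topology: Topology,
    p: SwitchParams = SwitchParams(),
    normalize: bool = False,
    cutoff: float | None = None,
    selection: np.ndarray | None = None,
) -> float:
    """Sum of switch terms over heavy-atom pairs of different peptides.

    ``cutoff`` truncates the pair sum (default 5 * r0, where the term is
    below ~1e-5); the same strict r < cutoff rule is applied to distances
    computed under the XY minimum image.  With ``normalize`` the sum is
    divided by n(n-1)/2, n being the number of peptides present.
    """
    sel = _peptide_heavy(topology) if selection is None else np.asarray(selection, int)
    chains = topology.peptide_indices[sel]
    uniq = np.unique(chains[chains >= 0])
    n_pep = len(uniq)
    if n_pep < 2:
        raise AnalysisError("S function requires at least two peptides")
    if cutoff is None:
        cutoff = 5.0 * p.r0
    box = frame.box
    pos = frame.positions[sel]
    tree, wrapped, _ = xy_periodic_tree(pos, box)
    pairs = tree.query_pairs(cutoff * (1 + 1e-9), output_type="ndarray")
    if len(pairs) == 0:
        total = 0.0
    else:
        i, j = pairs[:, 0], pairs[:, 1]
        keep = chains[i] != chains[j]
        i, j = i[keep], j[keep]
        dv = min_image_displacements(pos[i] - pos[j], box)
        r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
        m = r < cutoff
        total = float(np.sum(switch_term(r[m], p)))
    if normalize:
        total /= n_pep * (n_pep - 1) / 2
    return total


def s_function_series(
    traj: Trajectory,
    p: SwitchParams = SwitchParams(),
    normalize: bool = True,
    window: tuple[float, float] | None = None,
    stride: int = 1,
) -> pd.Series:
    """S function per frame over a window (strided)."""
    idx = traj.window(*window) if window else list(range(len(traj.frames)))
    if not idx:
        raise AnalysisError("analysis window contains no frames")
    idx = idx[::stride]
    vals = [s_function(traj.frames[i], traj.topology, p, normalize) for i in idx]
    return pd.Series(vals, index=traj.times[idx], name="S")


@dataclass
class ContactSeries:
    times: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float


def close_contacts(
    traj: Trajectory,
    set_a: np.ndarray,
    set_b: np.ndarray,
    cutoff: float = 0.5,
    window: tuple[float, float] | None = None,
    include_hydrogens: bool = False,
) -> ContactSeries:
    """Per-frame count of A-B atom pairs at distance strictly < cutoff."""
    set_a = np.asarray(set_a, int)
    set_b = np.asarray(set_b, int)
    if np.intersect1d(set_a, set_b).size:
        raise SelectionError("close-contact selections must be disjoint")
    topo = traj.topology
    if not include_hydrogens:
        set_a = set_a[topo.is_heavy[set_a]]
        set_b = set_b[topo.is_heavy[set_b]]
    idx = traj.window(*window) if window else list(range(len(traj.frames)))
    if not idx:
        raise AnalysisError("analysis window contains no frames")
    counts = np.zeros(len(idx), dtype=int)
    for k, i in enumerate(idx):
        frame = traj.frames[i]
        box = frame.box
        pos = np.concatenate([frame.positions[set_a], frame.positions[set_b]])
        tree, wrapped, _ = xy_periodic_tree(pos, box)
        na = len(set_a)
        pairs = tree.query_pairs(cutoff * (1 + 1e-9), output_type="ndarray")
        if len(pairs):
            i0, j0 = pairs[:, 0], pairs[:, 1]
            cross = (i0 < na) != (j0 < na)
            i0, j0 = i0[cross], j0[cross]
            dv = min_image_displacements(pos[i0] - pos[j0], box)
            r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
            counts[k] = int(np.sum(r < cutoff))
    times = traj.times[idx]
    return ContactSeries(times, counts, float(counts.mean()), float(counts.std(ddof=0)))


@dataclass
class PersistenceMap:
    """Peptide-residue x active-spot matrix of contact persistence (ns)."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray
    window_length: float

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.values > self.window_length + 1e-9):
            raise AnalysisError("persistence values must lie in [0, window_length]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)


def _peptide_residue_positions(topo: Topology) -> tuple[list[str], dict[int, np.ndarray]]:
    """Label peptide residues by their ordinal position within each chain.

    All grafted chains are assumed to share one sequence; atoms of position
    k across chains are pooled, matching a per-residue (not per-chain)
    persistence histogram.
    """
    labels: list[str] = []
    groups: dict[int, list[int]] = {}
    chains = sorted(c for c in set(topo.peptide_indices) if c >= 0)
    for c in chains:
        atom_idx = np.nonzero(
            (topo.peptide_indices == c) & (topo.moieties == Moiety.PEPTIDE.value)
        )[0]
        # residues in atom order within the chain
        seen: dict[int, int] = {}
        for ai in atom_idx:
            rid = topo.residue_indices[ai]
            if rid not in seen:
                seen[rid] = len(seen)
            k = seen[rid]
            groups.setdefault(k, []).append(ai)
            if len(labels) <= k:
                labels.append(f"{topo.residue_names[ai].capitalize()}{k + 1}")
    return labels, {k: np.asarray(v) for k, v in groups.items()}


def persistence_map(
    traj: Trajectory,
    spots: ActiveSpotSet = ActiveSpotSet(),
    cutoff: float = 0.5,
    window: tuple[float, float] | None = None,
) -> PersistenceMap:
    """Persistence time (ns) of residue-to-active-spot contacts.

    Cell (i, j) counts frames in which any heavy-atom pair between peptide
    residue position i (pooled over chains) and spot j is strictly closer
    than ``cutoff``, times the frame interval.
    """
    topo = traj.topology
    labels, groups = _peptide_residue_positions(topo)
    if not groups:
        raise AnalysisError("no grafted peptide residues in topology")
    spot_sets = []
    missing = []
    for name, rid in spots.residues:
        m = (topo.moieties == Moiety.PROTEIN.value) & (topo.residue_names == name.upper()) \
            & (topo.residue_indices == rid) & topo.is_heavy
        if not m.any():
            missing.append(f"{name}{rid}")
        spot_sets.append(np.nonzero(m)[0])
    if missing:
        raise AnalysisError(f"active spots absent from topology: {missing}")
    idx = traj.window(*window) if window else list(range(len(traj.frames)))
    if not idx:
        raise AnalysisError("analysis window contains no frames")
    pep_heavy = {k: g[topo.is_heavy[g]] for k, g in groups.items()}
    counts = np.zeros((len(labels), len(spot_sets)), dtype=int)
    for i in idx:
        frame = traj.frames[i]
        box = frame.box
        pos = frame.positions
        for ci, g in pep_heavy.items():
            gp = pos[g]
            for sj, s in enumerate(spot_sets):
                dv = min_image_displacements(gp[:, None, :] - pos[s][None, :, :], box)
                r2 = np.einsum("ijk,ijk->ij", dv, dv)
                if (r2 < cutoff**2).any():
                    counts[ci, sj] += 1
    dt_ns = traj.frame_interval / 1000.0
    window_len = len(idx) * dt_ns
    return PersistenceMap(labels, spots.labels, counts * dt_ns, window_len)


def residue_pair_contacts(
    frame: Frame,
    topology: Topology,
    set_a: np.ndarray,
    set_b: np.ndarray,
    cutoff: float = 0.5,
) -> dict[tuple[str, str], int]:
    """Residue-pair contact counts (one count per residue pair in contact)."""
    set_a = np.asarray(set_a, int)
    set_b = np.asarray(set_b, int)
    box = frame.box
    topo = topology
    dv = min_image_displacements(
        frame.positions[set_a][:, None, :] - frame.positions[set_b][None, :, :], box
    )
    r2 = np.einsum("ijk,ijk->ij", dv, dv)
    contact = r2 < cutoff**2
    pairs: dict[tuple[str, str], set[tuple[int, int]]] = {}
    ai, bj = np.nonzero(contact)
    for i, j in zip(ai, bj):
        a, b = set_a[i], set_b[j]
        key = (topo.residue_names[a], topo.residue_names[b])
        pairs.setdefault(key, set()).add((topo.residue_indices[a], topo.residue_indices[b]))
    return {k: len(v) for k, v in pairs.items()}


def contact_energy(contact_counts: dict, matrix: dict) -> float:
    """Contact-potential energy: sum of matrix(type_a, type_b) over contacts.

    ``matrix`` maps unordered residue-type pairs to energies; it must cover
    every pair present.  Linear in the counts (additive over disjoint sets).
    """
    total = 0.0
    for (a, b), n in contact_counts.items():
        key = (a, b) if (a, b) in matrix else (b, a)
        if key not in matrix:
            raise MatrixError(f"no energy for residue pair {(a, b)}")
        total += matrix[key] * n
    return total
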