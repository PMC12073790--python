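"""Synthetic Brownian (overdamped) bead-chain dynamics.

Generates desk-scale trajectories with the statistical structure the
analysis stages assume: chains of beads (one bead per residue) grafted to a
reflecting wall at Z = 0 standing in for the gold surface, a tunable
short-range attraction between peptide beads of *different* chains that
switches the layer between clustered and grid-like morphologies, an
optional rigid cylindrical probe body standing in for the IgV-like domain
of PD-L1, and a constant-force tensile mode pulling every C-alpha bead
toward the surface.

Units are self-consistent simulation units: length nm, time ps, mass u,
energy u nm^2 ps^-2.  The position update is Euler-Maruyama,

    x(t+dt) = x(t) + mobility * F(x) * dt + sqrt(2 * mobility * T * dt) * xi,

with T = temperature_factor (in energy units) and xi standard normal, so a
free bead under constant force f drifts by mobility * f * t on average.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import StabilityError
from .io import AtomRecord, Frame, Moiety, Topology, Trajectory
from .builder import CLP002, RESIDUE_MASS_U

__all__ = [
    "ProbeSpec",
    "SyntheticParams",
    "DEFAULT_ACTIVE_SPOTS",
    "build_topology",
    "simulate",
    "make_morphology_pair",
    "potential_energy",
]

#: The 12 PD-L1 active-spot residues at the PD-1 contact surface.
DEFAULT_ACTIVE_SPOTS: tuple[tuple[str, int], ...] = (
    ("PHE", 19), ("ASP", 26), ("ILE", 54), ("TYR", 56), ("GLN", 66),
    ("ARG", 113), ("MET", 115), ("ALA", 121), ("ASP", 122), ("TYR", 123),
    ("LYS", 124), ("ARG", 125),
)


@dataclass(frozen=True)
class ProbeSpec:
    """Rigid cylindrical proxy for the IgV-like domain (4 nm deep, 3 nm wide).

    Beads are arranged in rings on the cylinder surface; the lowest ring
    (the binding face) carries the 12 active-spot residue labels so
    persistence maps can be exercised synthetically.
    """

    radius: float = 1.5
    depth: float = 4.0
    n_per_ring: int = 12
    n_rings: int = 8
    center_xy: tuple[float, float] | None = None
    z_bottom: float | None = None
    mobile: bool = False
    bead_mass: float = 110.0
    bead_radius: float = 0.25
    active_spots: tuple[tuple[str, int], ...] = DEFAULT_ACTIVE_SPOTS


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one synthetic run (defaults = desk-scale study conditions)."""

    n_chains: int = 9
    beads_per_chain: int = 12
    linker_beads: int = 4
    graft_spacing: float = 1.2
    bond_length: float = 0.35
    bond_stiffness: float = 800.0
    interchain_attraction: float = 0.0
    attraction_range: float = 0.5
    peptide_stiffness: float = 10.0  # bending stiffness of the peptide block
    excluded_volume_radius: float = 0.35
    ev_strength: float = 100.0
    temperature_factor: float = 1.0
    mobility: float = 0.01
    timestep: float = 0.01
    n_steps: int = 16000
    save_stride: int = 100
    seed: int = 0
    pull_acceleration: float = 0.0
    probe: ProbeSpec | None = None
    box_height: float = 10.0
    graft_chains: bool = True
    reflecting_wall: bool = True
    graft_height: float = 0.15
    peptide_sequence: tuple[str, ...] = CLP002
    bead_mass_linker: float = 44.0
    bead_vdw: float = 0.25
    initial_conformation: str = "extended"  # construction geometry | "coil"

    def __post_init__(self):
        if self.timestep <= 0 or self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("timestep > 0, n_steps >= 1, save_stride >= 1 required")
        if self.pull_acceleration < 0 or self.interchain_attraction < 0:
            raise ValueError("pull_acceleration and interchain_attraction must be >= 0")
        if self.temperature_factor < 0:
            raise ValueError("temperature_factor must be >= 0")

    @property
    def beads_total_per_chain(self) -> int:
        # linker beads (bead 0 doubles as the graft anchor) then peptide beads
        return self.linker_beads + self.beads_per_chain

    @property
    def box(self) -> tuple[float, float, float]:
        side = math.ceil(math.sqrt(self.n_chains))
        L = side * self.graft_spacing
        return (L, L, self.box_height)


def _probe_layout(probe: ProbeSpec, box, z_bottom: float) -> tuple[list[AtomRecord], np.ndarray, int]:
    cx, cy = probe.center_xy if probe.center_xy else (box[0] / 2, box[1] / 2)
    pos, atoms = [], []
    dz = probe.depth / max(probe.n_rings - 1, 1)
    spots = list(probe.active_spots)
    k = 0
    for ring in range(probe.n_rings):
        z = z_bottom + ring * dz
        for j in range(probe.n_per_ring):
            th = 2 * math.pi * j / probe.n_per_ring + (ring % 2) * math.pi / probe.n_per_ring
            pos.append((cx + probe.radius * math.cos(th), cy + probe.radius * math.sin(th), z))
            if ring == 0 and k < len(spots):
                resname, resid = spots[k]
            else:
                resname, resid = "PRB", 1000 + k
            atoms.append(
                AtomRecord(
                    atom_index=-1, atom_name="BB", element="C", residue_name=resname,
                    residue_index=resid, peptide_index=-1, moiety=Moiety.PROTEIN,
                    mass=probe.bead_mass, vdw_radius=probe.bead_radius,
                    is_heavy=True, is_sidechain=False, is_calpha=False,
                )
            )
            k += 1
    return atoms, np.asarray(pos, dtype=float), len(pos)


def build_topology(params: SyntheticParams) -> tuple[Topology, np.ndarray]:
    """Topology and initial grafted positions for a run.

    The default "coil" start grows each chain as a seeded self-avoiding-ish
    random walk above the wall (near its entropic equilibrium), so short
    runs sample relaxed configurations; "extended" reproduces the upright
    all-trans construction geometry instead.
    """
    box = params.box
    side = math.ceil(math.sqrt(params.n_chains))
    atoms: list[AtomRecord] = []
    pos: list[tuple[float, float, float]] = []
    seq = params.peptide_sequence
    rng = np.random.default_rng(params.seed ^ 0x5EED)
    idx = 0
    resid = 1
    for c in range(params.n_chains):
        gx = (c % side + 0.5) * params.graft_spacing
        gy = (c // side + 0.5) * params.graft_spacing
        placed = np.asarray(pos, dtype=float) if pos else np.empty((0, 3))

        def clearance(p):
            if placed.size == 0:
                return np.inf
            return float(np.min(np.linalg.norm(placed - p, axis=1)))

        prev = np.array([gx, gy, params.graft_height])
        rod_dir = None
        for b in range(params.beads_total_per_chain):
            if params.initial_conformation == "extended" or b == 0:
                p = np.array([gx, gy, params.graft_height + b * params.bond_length])
            elif b < params.linker_beads:
                # flexible linker: random-walk step, mildly upward, wall-reflected;
                # among a few candidates take the first clear of other chains
                best, best_c = None, -1.0
                for _ in range(12):
                    step = rng.standard_normal(3)
                    step[2] += 0.3
                    step *= params.bond_length / np.linalg.norm(step)
                    q = prev + step
                    if q[2] < params.graft_height:
                        q[2] = 2 * params.graft_height - q[2]
                    cl = clearance(q)
                    if cl >= 2.0 * params.excluded_volume_radius:
                        best = q
                        break
                    if cl > best_c:
                        best, best_c = q, cl
                p = best
            else:
                # semi-rigid peptide: persistent upward-tilted direction chosen
                # to keep the whole rod clear of previously placed chains
                if rod_dir is None:
                    n_rod = params.beads_per_chain
                    best, best_c = None, -1.0
                    for _ in range(16):
                        d = rng.standard_normal(3)
                        d[2] = abs(d[2]) + 1.0
                        d /= np.linalg.norm(d)
                        rod = prev + np.outer(np.arange(1, n_rod + 1),
                                              d * params.bond_length)
                        cl = min(clearance(q) for q in rod)
                        if cl >= 2.0 * params.excluded_volume_radius:
                            best = d
                            break
                        if cl > best_c:
                            best, best_c = d, cl
                    rod_dir = best
                p = prev + rod_dir * params.bond_length
            prev = p
            pos.append(tuple(p))
            if b < params.linker_beads:
                resname, moiety = "PEG", Moiety.LINKER
                mass, is_pep = params.bead_mass_linker, False
            else:
                k = b - params.linker_beads
                resname = seq[k % len(seq)]
                moiety = Moiety.PEPTIDE
                mass, is_pep = RESIDUE_MASS_U.get(resname, 110.0), True
            atoms.append(
                AtomRecord(
                    atom_index=idx, atom_name="CA" if is_pep else "C1", element="C",
                    residue_name=resname, residue_index=resid, peptide_index=c,
                    moiety=moiety, mass=mass, vdw_radius=params.bead_vdw,
                    is_heavy=True, is_sidechain=is_pep, is_calpha=is_pep,
                )
            )
            idx += 1
            resid += 1
    n_chain_beads = idx
    if params.probe is not None:
        zb = params.probe.z_bottom
        if zb is None:
            # default pose: lowered onto the nominal monolayer top surface
            zb = params.graft_height + 0.5 * params.beads_total_per_chain * params.bond_length
        p_atoms, p_pos, _ = _probe_layout(params.probe, box, zb)
        for a in p_atoms:
            atoms.append(replace(a, atom_index=idx))
            idx += 1
        pos.extend(map(tuple, p_pos))
    return Topology(atoms), np.asarray(pos, dtype=float)


def _pair_lists(params: SyntheticParams, topo: Topology):
    chain = topo.peptide_indices
    is_pep = topo.moieties == Moiety.PEPTIDE.value
    is_protein = topo.moieties == Moiety.PROTEIN.value
    n = len(topo)
    idx = np.arange(n)
    # attraction: peptide beads of different chains
    pep = idx[is_pep]
    ai, aj = np.meshgrid(pep, pep, indexing="ij")
    m = (ai < aj) & (chain[ai] != chain[aj])
    att_i, att_j = ai[m], aj[m]
    # excluded volume: any beads of different chains, plus chain-probe pairs
    nonprobe = idx[~is_protein]
    ei, ej = np.meshgrid(nonprobe, nonprobe, indexing="ij")
    m = (ei < ej) & (chain[ei] != chain[ej])
    ev_i, ev_j = ei[m], ej[m]
    if is_protein.any():
        probe_idx = idx[is_protein]
        pi, pj = np.meshgrid(nonprobe, probe_idx, indexing="ij")
        ev_i = np.concatenate([ev_i, pi.ravel()])
        ev_j = np.concatenate([ev_j, pj.ravel()])
    return (att_i, att_j), (ev_i, ev_j)


def _bond_lists(params: SyntheticParams, topo: Topology):
    b0, b1 = [], []
    per = params.beads_total_per_chain
    for c in range(params.n_chains):
        base = c * per
        for b in range(per - 1):
            b0.append(base + b)
            b1.append(base + b + 1)
    return np.asarray(b0), np.asarray(b1)


def _angle_lists(params: SyntheticParams):
    """Bead triplets of the peptide block carrying the bending potential.

    The peptide is modelled as semi-rigid (stable elongated conformation);
    the linker stays fully flexible.
    """
    t0, t1, t2 = [], [], []
    per = params.beads_total_per_chain
    lo = params.linker_beads
    for c in range(params.n_chains):
        base = c * per
        for b in range(max(lo, 1), per - 1):
            t0.append(base + b - 1)
            t1.append(base + b)
            t2.append(base + b + 1)
    return np.asarray(t0), np.asarray(t1), np.asarray(t2)


def _angle_forces(x, k, triplets, out):
    """U = k (1 - cos phi) per triplet, phi the bond-bond angle (0 = straight)."""
    i0, i1, i2 = triplets
    if not len(i0) or k <= 0:
        return 0.0
    b1 = x[i1] - x[i0]
    b2 = x[i2] - x[i1]
    n1 = np.sqrt(np.einsum("ij,ij->i", b1, b1))
    n2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    # floor at a fraction of the bond scale: the 1/(|b1||b2|) gradient would
    # otherwise diverge when crowding momentarily compresses a bond
    floor = 0.15
    n1 = np.where(n1 < floor, floor, n1)
    n2 = np.where(n2 < floor, floor, n2)
    c = np.einsum("ij,ij->i", b1, b2) / (n1 * n2)
    c = np.clip(c, -1.0, 1.0)
    dcdb1 = b2 / (n1 * n2)[:, None] - (c / n1**2)[:, None] * b1
    dcdb2 = b1 / (n1 * n2)[:, None] - (c / n2**2)[:, None] * b2
    f0 = -k * dcdb1
    f2 = k * dcdb2
    f1 = -(f0 + f2)
    for ax in range(3):
        out[:, ax] += np.bincount(i0, f0[:, ax], minlength=len(x))
        out[:, ax] += np.bincount(i1, f1[:, ax], minlength=len(x))
        out[:, ax] += np.bincount(i2, f2[:, ax], minlength=len(x))
    return float(k * np.sum(1.0 - c))


def _xy_min_image(dv: np.ndarray, box) -> np.ndarray:
    dv[:, 0] -= box[0] * np.round(dv[:, 0] / box[0])
    dv[:, 1] -= box[1] * np.round(dv[:, 1] / box[1])
    return dv


def _forces(x, params, box, bonds, triplets, att_pairs, ev_pairs, pull_mask, masses, out):
    out[:] = 0.0
    b0, b1 = bonds
    _angle_forces(x, params.peptide_stiffness, triplets, out)
    if len(b0):
        dv = _xy_min_image(x[b1] - x[b0], box)
        r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
        r = np.where(r < 1e-12, 1e-12, r)
        fmag = params.bond_stiffness * (r - params.bond_length) / r
        f = fmag[:, None] * dv
        for ax in range(3):
            out[:, ax] += np.bincount(b0, f[:, ax], minlength=len(x))
            out[:, ax] -= np.bincount(b1, f[:, ax], minlength=len(x))
    eps, w = params.interchain_attraction, params.attraction_range
    if eps > 0 and len(att_pairs[0]):
        i, j = att_pairs
        rc = 2.0 * params.excluded_volume_radius  # contact distance
        dv = _xy_min_image(x[j] - x[i], box)
        r2 = np.einsum("ij,ij->i", dv, dv)
        cut = rc + 3.0 * w
        m = r2 < cut * cut
        if m.any():
            i, j, dv = i[m], j[m], dv[m]
            r = np.sqrt(r2[m])
            r = np.where(r < 1e-12, 1e-12, r)
            # contact well U = -eps * exp(-((r-rc)/w)^2): attraction toward
            # bead-bead contact, repulsive inside (adds to excluded volume)
            pref = eps * (2.0 * (r - rc) / w**2) * np.exp(-(((r - rc) / w) ** 2)) / r
            f = pref[:, None] * dv
            for ax in range(3):
                out[:, ax] += np.bincount(i, f[:, ax], minlength=len(x))
                out[:, ax] -= np.bincount(j, f[:, ax], minlength=len(x))
    d_ev = 2.0 * params.excluded_volume_radius
    if params.ev_strength > 0 and len(ev_pairs[0]):
        i, j = ev_pairs
        dv = _xy_min_image(x[j] - x[i], box)
        r2 = np.einsum("ij,ij->i", dv, dv)
        m = r2 < d_ev**2
        if m.any():
            i, j, dv = i[m], j[m], dv[m]
            r = np.sqrt(r2[m])
            r = np.where(r < 1e-12, 1e-12, r)
            # U = A (1 - r/d)^2 for r < d; repulsive
            pref = -2.0 * params.ev_strength / d_ev * (1.0 - r / d_ev) / r
            f = pref[:, None] * dv
            for ax in range(3):
                out[:, ax] += np.bincount(i, f[:, ax], minlength=len(x))
                out[:, ax] -= np.bincount(j, f[:, ax], minlength=len(x))
    if params.pull_acceleration > 0:
        out[pull_mask, 2] -= masses[pull_mask] * params.pull_acceleration
    return out


def potential_energy(params: SyntheticParams, topo: Topology, x: np.ndarray) -> float:
    """Total potential (bonds + attraction + excluded volume + pull)."""
    box = params.box
    b0, b1 = _bond_lists(params, topo)
    (ai, aj), (ei, ej) = _pair_lists(params, topo)
    E = 0.0
    if params.peptide_stiffness > 0:
        scratch = np.zeros_like(x)
        E += _angle_forces(x, params.peptide_stiffness, _angle_lists(params), scratch)
    dv = _xy_min_image(x[b1] - x[b0], box)
    r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
    E += 0.5 * params.bond_stiffness * np.sum((r - params.bond_length) ** 2)
    if params.interchain_attraction > 0 and len(ai):
        dv = _xy_min_image(x[aj] - x[ai], box)
        r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
        w = params.attraction_range
        rc = 2.0 * params.excluded_volume_radius
        m = r < rc + 3.0 * w
        E += -params.interchain_attraction * np.sum(
            np.exp(-(((r[m] - rc) / w) ** 2))
        )
    d = 2.0 * params.excluded_volume_radius
    if params.ev_strength > 0 and len(ei):
        dv = _xy_min_image(x[ej] - x[ei], box)
        r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
        m = r < d
        E += params.ev_strength * np.sum((1.0 - r[m] / d) ** 2)
    if params.pull_acceleration > 0:
        pull = topo.is_calpha & (topo.moieties == Moiety.PEPTIDE.value)
        E += np.sum(topo.masses[pull] * params.pull_acceleration * x[pull, 2])
    return float(E)


def simulate(params: SyntheticParams) -> Trajectory:
    """Run overdamped dynamics; fully reproducible per seed.

    Raises StabilityError when a deterministic (force-driven) displacement
    exceeds the bond length in one step.
    """
    topo, x = build_topology(params)
    x = x.copy()
    box = params.box
    bonds = _bond_lists(params, topo)
    triplets = _angle_lists(params)
    att_pairs, ev_pairs = _pair_lists(params, topo)
    chain_mask = topo.peptide_indices >= 0
    fixed = np.zeros(len(topo), dtype=bool)
    if params.graft_chains:
        per = params.beads_total_per_chain
        fixed[np.arange(params.n_chains) * per] = True
    probe_mask = topo.moieties == Moiety.PROTEIN.value
    probe_free = params.probe is not None and params.probe.mobile
    if params.probe is not None and not probe_free:
        fixed |= probe_mask
    pull_mask = topo.is_calpha & (topo.moieties == Moiety.PEPTIDE.value)
    masses = topo.masses
    rng = np.random.default_rng(params.seed)
    mu, dt = params.mobility, params.timestep
    sigma = math.sqrt(2.0 * mu * params.temperature_factor * dt)
    F = np.zeros_like(x)
    frames = [Frame(x.copy(), box, 0.0)]
    x0 = x.copy()
    for step in range(1, params.n_steps + 1):
        _forces(x, params, box, bonds, triplets, att_pairs, ev_pairs, pull_mask, masses, F)
        drift = mu * dt * F
        max_disp = float(np.abs(drift[~fixed]).max()) if (~fixed).any() else 0.0
        if max_disp > params.bond_length:
            raise StabilityError(
                f"step {step}: deterministic displacement {max_disp:.3f} nm exceeds "
                f"the bond length {params.bond_length} nm; reduce timestep"
            )
        dx = drift
        if sigma > 0:
            dx = dx + sigma * rng.standard_normal(x.shape)
        if probe_free and probe_mask.any():
            # rigid probe: average Z force, vertical diffusion only
            fz = drift[probe_mask, 2].mean()
            nz = sigma * rng.standard_normal() / math.sqrt(probe_mask.sum()) if sigma > 0 else 0.0
            dx[probe_mask] = 0.0
            dx[probe_mask, 2] = fz + nz
        x = x + dx
        x[fixed] = x0[fixed]
        if params.reflecting_wall:
            np.abs(x[:, 2], out=x[:, 2])
        if step % params.save_stride == 0:
            frames.append(Frame(x.copy(), box, step * dt))
    return Trajectory(topo, frames, frame_interval=params.save_stride * dt)


def make_morphology_pair(
    base: SyntheticParams,
    eps_clustered: float = 1.5,
    eps_grid: float = 0.0,
) -> tuple[Trajectory, Trajectory]:
    """Clustered vs grid morphologies differing only in interchain attraction.

    High attraction draws the peptide blocks of neighbouring chains into
    persistent bundles; zero attraction leaves an unassociated brush.  The
    same seed discipline applies to both members.
    """
    clustered = simulate(replace(base, interchain_attraction=eps_clustered))
    grid = simulate(replace(base, interchain_attraction=eps_grid))
    return clustered, grid
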