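"""Initial monolayer construction: gold lattice, grafted conjugates, ions.

The model gold surface is a single hexagonally close-packed (triangular)
layer of Au atoms.  Conjugates (linker + 12-mer peptide) are inserted with
their long axis along +Z, anchor sulfur 0.294 nm above the gold plane, on a
uniform grid of anchor sites with a seeded jitter.  Chloride counterions
enforce electroneutrality; their count follows from fixed neutral-pH
side-chain charge rules.

Water is implicit throughout: the water counts of the reference systems are
carried as metadata only and no solvent atoms are ever placed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ChemistryError, PackingError
from .io import AtomRecord, Frame, Moiety, Topology, Trajectory

__all__ = [
    "ConjugateSequence",
    "MonolayerSpec",
    "CLP002",
    "SCLP002",
    "conjugate_preset",
    "monolayer_preset",
    "formal_charge",
    "counterion_count",
    "build_gold_layer",
    "graft_conjugates",
    "build_system",
    "PRESET_NAMES",
]

#: CLP002 12-mer (PD-L1-binding peptide) and its scrambled control.
CLP002 = ("TRP", "HIS", "ARG", "SER", "TYR", "TYR", "THR", "TRP", "ASN", "LEU", "ASN", "THR")
SCLP002 = ("THR", "ARG", "TRP", "SER", "HIS", "TYR", "ASN", "THR", "LEU", "TRP", "TYR", "ASN")

#: PEG 3000 Da at 44 Da per ethylene-oxide monomer.
PEG3000_MONOMERS = 68

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: Average residue (monomer) masses in u, used for coarse single-bead residues.
RESIDUE_MASS_U = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
    # linker units
    "PEG": 44.05, "O2OC": 145.16, "ACE": 42.04,
}

#: Side-chain formal charges at neutral pH.  His neutral; thiol / S-Au
#: cysteine neutral; PEG, O2oc, acetyl and blocked termini carry no charge.
SIDECHAIN_CHARGE = {
    "ARG": +1, "LYS": +1, "HIS": 0, "ASP": -1, "GLU": -1, "CYS": 0,
    "ALA": 0, "ASN": 0, "GLN": 0, "GLY": 0, "ILE": 0, "LEU": 0, "MET": 0,
    "PHE": 0, "PRO": 0, "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
}

LINKER_UNIT_CHARGE = {"HS-PEG": 0, "PEG": 0, "ACE": 0, "O2OC": 0, "CYS": 0,
                      "LYS": +1, "GLY": 0}

#: Extended-chain rise per unit along Z (nm): 0.35 per amino-acid residue
#: (a 12-mer peptide then spans ~4.2 nm, matching the elongated-state
#: estimate of ~4 nm), 0.28 per PEG monomer, O2oc counts as two monomers.
UNIT_RISE_NM = {"PEG": 0.28, "O2OC": 0.56, "ACE": 0.20, "RESIDUE": 0.35}


@dataclass(frozen=True)
class ConjugateSequence:
    """A linker + peptide conjugate as grafted on the gold surface."""

    name: str
    linker_units: tuple[str, ...]
    peptide_residues: tuple[str, ...]
    cterm: str = "amide"
    nterm_blocked: bool = True

    def __post_init__(self):
        object.__setattr__(self, "linker_units", tuple(u.upper() for u in self.linker_units))
        res = tuple(
            _AA1TO3[r.upper()] if len(r) == 1 else r.upper() for r in self.peptide_residues
        )
        object.__setattr__(self, "peptide_residues", res)


def _p_linker() -> tuple[str, ...]:
    # HS-PEG(3000)-Lys3-Gly2: thiol-terminated PEG then the charged spacer.
    return ("HS-PEG",) + ("PEG",) * (PEG3000_MONOMERS - 1) + ("LYS",) * 3 + ("GLY",) * 2


def _c_linker() -> tuple[str, ...]:
    return ("ACE", "CYS", "O2OC", "O2OC")


def conjugate_preset(name: str) -> ConjugateSequence:
    """Table-defined conjugates: P-CLP, P-SCLP, C-CLP."""
    key = name.upper().replace("_", "-")
    if key == "P-CLP":
        return ConjugateSequence("P-CLP", _p_linker(), CLP002)
    if key == "P-SCLP":
        return ConjugateSequence("P-SCLP", _p_linker(), SCLP002)
    if key == "C-CLP":
        return ConjugateSequence("C-CLP", _c_linker(), CLP002)
    raise ChemistryError(f"unknown conjugate preset {name!r}")


@dataclass(frozen=True)
class MonolayerSpec:
    """Build recipe for one gold-slab + grafted-conjugate system."""

    conjugate: ConjugateSequence
    n_peptides: int
    box: tuple[float, float, float]
    lattice_spacing: float = 0.288
    s_au_distance: float = 0.294
    n_counterions: int | None = None
    restraint_k: float = 10000.0
    min_anchor_distance: float = 0.5
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.n_peptides <= 0:
            raise ValueError("n_peptides must be > 0")
        if self.n_counterions is None:
            object.__setattr__(
                self, "n_counterions", counterion_count(self.conjugate, self.n_peptides)
            )


PRESET_NAMES = ("NS@P-CLP", "NS@P-SCLP", "NS@C-CLP")


def monolayer_preset(name: str) -> MonolayerSpec:
    """Reference monolayer systems (peptide counts, boxes, ion counts)."""
    key = name.upper()
    if key == "NS@P-CLP":
        return MonolayerSpec(conjugate_preset("P-CLP"), 45, (10.32, 9.99, 27.55),
                             metadata={"n_water": 79050})
    if key == "NS@P-SCLP":
        return MonolayerSpec(conjugate_preset("P-SCLP"), 45, (10.30, 9.97, 27.50),
                             metadata={"n_water": 78349})
    if key == "NS@C-CLP":
        return MonolayerSpec(conjugate_preset("C-CLP"), 90, (10.31, 9.98, 18.17),
                             metadata={"n_water": 50807})
    raise ChemistryError(f"unknown monolayer preset {name!r}")


def formal_charge(conjugate: ConjugateSequence) -> int:
    """Net formal charge of a conjugate at neutral pH.

    Side chains: Arg/Lys +1, His 0, Asp/Glu -1, Cys (thiol or S-Au) 0.
    Amidated C-terminus and blocked N-terminus contribute nothing; a free
    C-terminus counts -1 and an unblocked N-terminus +1.
    """
    q = 0
    for unit in conjugate.linker_units:
        if unit not in LINKER_UNIT_CHARGE:
            raise ChemistryError(f"unknown linker unit {unit!r}")
        q += LINKER_UNIT_CHARGE[unit]
    for res in conjugate.peptide_residues:
        if res not in SIDECHAIN_CHARGE:
            raise ChemistryError(f"unknown residue {res!r}")
        q += SIDECHAIN_CHARGE[res]
    if conjugate.cterm != "amide":
        q -= 1
    if not conjugate.nterm_blocked:
        q += 1
    return q


def counterion_count(conjugate: ConjugateSequence, n_peptides: int) -> int:
    """Chloride ions needed for electroneutrality of n_peptides conjugates."""
    q = formal_charge(conjugate)
    if q < 0:
        raise ChemistryError(
            "anionic conjugates are unsupported (would need cation counterions)"
        )
    return n_peptides * q


# ---------------------------------------------------------------------------
# geometry


def build_gold_layer(spacing: float, nx: int, ny: int) -> Trajectory:
    """Single planar triangular (HCP in-plane) gold layer at Z = 0.

    Rows are offset by spacing/2 and separated by spacing*sqrt(3)/2, so the
    nearest-neighbour distance equals ``spacing`` everywhere.
    """
    if spacing <= 0 or nx < 1 or ny < 1:
        raise ValueError("spacing must be > 0 and nx, ny >= 1")
    xs, ys = [], []
    dy = spacing * math.sqrt(3) / 2
    for j in range(ny):
        off = (j % 2) * spacing / 2
        for i in range(nx):
            xs.append(i * spacing + off)
            ys.append(j * dy)
    n = nx * ny
    pos = np.column_stack([xs, ys, np.zeros(n)])
    atoms = [
        AtomRecord(
            atom_index=k, atom_name="AU", element="AU", residue_name="AU",
            residue_index=k + 1, peptide_index=-1, moiety=Moiety.GOLD,
            mass=196.967, vdw_radius=0.166,
        )
        for k in range(n)
    ]
    box = (nx * spacing, ny * dy, 10.0)
    return Trajectory(Topology(atoms), [Frame(pos, box, 0.0)])


def _chain_units(conjugate: ConjugateSequence):
    """(resname, moiety, mass, rise, is_peptide_residue) per bead, anchor first."""
    units = []
    # anchor sulfur of the thiol / cysteine
    units.append(("THL", Moiety.LINKER, 32.06, 0.0, False))
    for u in conjugate.linker_units:
        if u == "HS-PEG":
            units.append(("PEG", Moiety.LINKER, RESIDUE_MASS_U["PEG"], UNIT_RISE_NM["PEG"], False))
        elif u == "PEG":
            units.append(("PEG", Moiety.LINKER, RESIDUE_MASS_U["PEG"], UNIT_RISE_NM["PEG"], False))
        elif u == "O2OC":
            units.append(("O2OC", Moiety.LINKER, RESIDUE_MASS_U["O2OC"], UNIT_RISE_NM["O2OC"], False))
        elif u == "ACE":
            units.append(("ACE", Moiety.LINKER, RESIDUE_MASS_U["ACE"], UNIT_RISE_NM["ACE"], False))
        else:  # amino-acid linker unit (Lys, Gly, Cys)
            units.append((u, Moiety.LINKER, RESIDUE_MASS_U[u], UNIT_RISE_NM["RESIDUE"], False))
    for res in conjugate.peptide_residues:
        units.append((res, Moiety.PEPTIDE, RESIDUE_MASS_U[res], UNIT_RISE_NM["RESIDUE"], True))
    return units


def anchor_grid(
    n: int, box_xy: tuple[float, float], seed: int, min_distance: float,
    jitter_frac: float = 0.1,
) -> np.ndarray:
    """Uniform grid of n anchor XY sites with seeded jitter.

    Raises PackingError (reporting the maximum feasible count) when the grid
    pitch cannot respect ``min_distance``.
    """
    Lx, Ly = box_xy
    nxg = max(1, round(math.sqrt(n * Lx / Ly)))
    nyg = math.ceil(n / nxg)
    while nxg * nyg < n:
        nxg += 1
    px, py = Lx / nxg, Ly / nyg
    jitter = jitter_frac * min(px, py)
    if min(px, py) - 2 * jitter < min_distance:
        feas_x = int(Lx // (min_distance / (1 - 2 * jitter_frac)))
        feas_y = int(Ly // (min_distance / (1 - 2 * jitter_frac)))
        raise PackingError(
            f"cannot place {n} anchors at >= {min_distance} nm separation; "
            f"maximum feasible count is about {feas_x * feas_y}"
        )
    rng = np.random.default_rng(seed)
    sites = []
    for j in range(nyg):
        for i in range(nxg):
            sites.append(((i + 0.5) * px, (j + 0.5) * py))
    sites = np.asarray(sites[:n])
    sites += rng.uniform(-jitter, jitter, size=sites.shape)
    return sites


def graft_conjugates(
    gold: Trajectory | Frame,
    spec: MonolayerSpec,
    seed: int = 0,
    head_conformation: np.ndarray | None = None,
) -> Trajectory:
    """Gold layer + grafted conjugates + counterions as one starting frame.

    Every anchor sulfur sits exactly ``spec.s_au_distance`` above the gold
    plane; chains extend along +Z with per-unit rises (all-trans proxy).
    ``head_conformation`` optionally supplies per-bead offsets (relative to
    the first peptide bead) replacing the extended peptide head.
    """
    if isinstance(gold, Trajectory):
        gold_topo, gold_frame = gold.topology, gold.frames[0]
    else:
        raise TypeError("gold must be a Trajectory from build_gold_layer")
    gpos = gold_frame.positions
    if gpos[:, 0].max() - gpos[:, 0].min() + spec.lattice_spacing < spec.box[0] - 1e-9 or \
       gpos[:, 1].max() - gpos[:, 1].min() + spec.lattice_spacing < spec.box[1] - 1e-9:
        raise PackingError("gold layer XY extent smaller than the requested box")
    z_plane = float(gpos[:, 2].mean())
    anchors = anchor_grid(
        spec.n_peptides, (spec.box[0], spec.box[1]), seed, spec.min_anchor_distance
    )
    units = _chain_units(spec.conjugate)
    atoms: list[AtomRecord] = list(gold_topo.atoms)
    positions: list[np.ndarray] = [gpos]
    idx = len(atoms)
    resid = int(gold_topo.residue_indices.max()) + 1
    n_pep_units = len(spec.conjugate.peptide_residues)
    for c, (ax, ay) in enumerate(anchors):
        z = z_plane + spec.s_au_distance
        chain_pos = []
        pep_start_z = None
        k_pep = 0
        for (resname, moiety, mass, rise, is_pep) in units:
            z += rise
            if is_pep and head_conformation is not None:
                if pep_start_z is None:
                    pep_start_z = z
                    base = np.array([ax, ay, pep_start_z])
                p = base + head_conformation[k_pep]
                k_pep += 1
            else:
                p = np.array([ax, ay, z if rise > 0 or resname == "THL" else z])
                if resname == "THL":
                    p = np.array([ax, ay, z_plane + spec.s_au_distance])
            chain_pos.append(p)
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name="CA" if is_pep else ("S" if resname == "THL" else "C1"),
                    element="S" if resname == "THL" else "C",
                    residue_name=resname,
                    residue_index=resid,
                    peptide_index=c,
                    moiety=moiety,
                    mass=mass,
                    vdw_radius=0.25 if is_pep else (0.18 if resname == "THL" else 0.21),
                    is_heavy=True,
                    is_sidechain=is_pep,
                    is_calpha=is_pep,
                )
            )
            idx += 1
            resid += 1
        positions.append(np.asarray(chain_pos))
    # counterions scattered in the solvent region above the monolayer
    rng = np.random.default_rng(seed + 7919)
    chain_top = max(p[:, 2].max() for p in positions[1:])
    n_ions = spec.n_counterions
    if n_ions:
        zlo = min(chain_top + 0.5, spec.box[2] - 1.0)
        ion_pos = rng.uniform(
            [0.0, 0.0, zlo], [spec.box[0], spec.box[1], spec.box[2]], size=(n_ions, 3)
        )
        positions.append(ion_pos)
        for k in range(n_ions):
            atoms.append(
                AtomRecord(
                    atom_index=idx, atom_name="CL", element="CL", residue_name="CL",
                    residue_index=resid, peptide_index=-1, moiety=Moiety.ION,
                    mass=35.45, vdw_radius=0.175,
                )
            )
            idx += 1
            resid += 1
    allpos = np.concatenate(positions)
    allpos = allpos.copy()
    allpos[:, 2] -= z_plane  # gold plane defines Z = 0
    return Trajectory(Topology(atoms), [Frame(allpos, spec.box, 0.0)])


def build_system(spec: MonolayerSpec | str, seed: int = 0) -> Trajectory:
    """Convenience: size a gold layer to the recipe's box and graft onto it."""
    if isinstance(spec, str):
        spec = monolayer_preset(spec)
    nx = math.ceil(spec.box[0] / spec.lattice_spacing) + 1
    ny = math.ceil(spec.box[1] / (spec.lattice_spacing * math.sqrt(3) / 2)) + 1
    gold = build_gold_layer(spec.lattice_spacing, nx, ny)
    return graft_conjugates(gold, spec, seed=seed)
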