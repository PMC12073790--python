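"""Domain types and coordinate I/O for slab trajectories.

Internal unit discipline: lengths in nm, times in ps, masses in atomic mass
units, densities in kg/m^3.  Unit conversion happens only at format
boundaries (PDB stores Angstrom; GRO stores nm natively).

The coordinate convention throughout the package puts Z = 0 at the mean
plane of the gold atoms with Z increasing toward the solvent, so every
profile analysis reports distance from the gold surface directly.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ParseError, SelectionError, StructureError

__all__ = [
    "Moiety",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "read_coordinates",
    "write_coordinates",
    "select",
    "ELEMENT_MASS_U",
    "ELEMENT_VDW_NM",
    "DEFAULT_MOIETY_MAP",
]


class Moiety(str, Enum):
    GOLD = "gold"
    LINKER = "linker"
    PEPTIDE = "peptide"
    PROTEIN = "protein"
    ION = "ion"


#: Atomic masses in u (only elements the pipeline touches).
ELEMENT_MASS_U = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "AU": 196.967, "CL": 35.45, "NA": 22.990, "X": 100.0,
}

#: van der Waals radii in nm, united-atom-compatible; overridable per call.
ELEMENT_VDW_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "AU": 0.166, "CL": 0.175, "NA": 0.227, "X": 0.170,
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Residue-name -> moiety mapping.  Standard amino acids default to the
#: grafted-peptide moiety; protein atoms must be labelled via an override
#: map (or are built in memory with explicit moieties).
DEFAULT_MOIETY_MAP: dict[str, Moiety] = {
    **{aa: Moiety.PEPTIDE for aa in _STANDARD_AA},
    "AU": Moiety.GOLD,
    "AUS": Moiety.GOLD,
    "PEG": Moiety.LINKER,
    "O2O": Moiety.LINKER,
    "O2OC": Moiety.LINKER,
    "ACE": Moiety.LINKER,
    "THL": Moiety.LINKER,
    "LNK": Moiety.LINKER,
    "CL": Moiety.ION,
    "CL-": Moiety.ION,
    "NA": Moiety.ION,
    "NA+": Moiety.ION,
    "ION": Moiety.ION,
    "PRB": Moiety.PROTEIN,
    "PRO": Moiety.PEPTIDE,
}


@dataclass(frozen=True, slots=True)
class AtomRecord:
    """One atom (or coarse bead) of the topology."""

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    peptide_index: int = -1
    moiety: Moiety = Moiety.PEPTIDE
    mass: float = 100.0
    vdw_radius: float = 0.17
    is_heavy: bool = True
    is_sidechain: bool = False
    is_calpha: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.vdw_radius <= 0:
            raise StructureError(
                f"atom {self.atom_index}: mass and vdw_radius must be positive"
            )
        if self.moiety in (Moiety.LINKER, Moiety.PEPTIDE) and self.peptide_index < 0:
            raise StructureError(
                f"atom {self.atom_index}: linker/peptide atoms need peptide_index >= 0"
            )
        if self.is_calpha and self.moiety not in (Moiety.PEPTIDE, Moiety.PROTEIN):
            raise StructureError(
                f"atom {self.atom_index}: C-alpha flag requires peptide/protein moiety"
            )


class Topology:
    """Immutable atom list with cached numpy views for analysis code."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self._atoms = tuple(atoms)

    def __len__(self) -> int:
        return len(self._atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self._atoms)

    def __getitem__(self, i):
        return self._atoms[i]

    @property
    def atoms(self) -> tuple[AtomRecord, ...]:
        return self._atoms

    @functools.cached_property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self._atoms])

    @functools.cached_property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self._atoms])

    @functools.cached_property
    def moieties(self) -> np.ndarray:
        return np.array([a.moiety.value for a in self._atoms])

    @functools.cached_property
    def peptide_indices(self) -> np.ndarray:
        return np.array([a.peptide_index for a in self._atoms])

    @functools.cached_property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self._atoms])

    @functools.cached_property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self._atoms])

    @functools.cached_property
    def is_heavy(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self._atoms])

    @functools.cached_property
    def is_sidechain(self) -> np.ndarray:
        return np.array([a.is_sidechain for a in self._atoms])

    @functools.cached_property
    def is_calpha(self) -> np.ndarray:
        return np.array([a.is_calpha for a in self._atoms])


@dataclass
class Frame:
    """Positions (nm) in an orthorhombic box at one time stamp (ps)."""

    positions: np.ndarray
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = tuple(float(b) for b in self.box)
        if any(b <= 0 for b in self.box):
            raise StructureError("box lengths must be strictly positive")
        if self.time < 0:
            raise StructureError("frame time must be >= 0")


@dataclass
class Trajectory:
    """Constant-topology, time-ordered frame sequence."""

    topology: Topology
    frames: list[Frame]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.topology, (list, tuple)):
            self.topology = Topology(self.topology)
        if self.frame_interval <= 0:
            raise StructureError("frame_interval must be > 0")
        n = len(self.topology)
        for k, f in enumerate(self.frames):
            if len(f.positions) != n:
                raise StructureError(
                    f"frame {k} has {len(f.positions)} positions for {n} atoms"
                )
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def window(self, t_start: float | None = None, t_end: float | None = None) -> list[int]:
        """Indices of frames with t_start <= time <= t_end."""
        t = self.times
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        return list(np.nonzero((t >= lo) & (t <= hi))[0])


# ---------------------------------------------------------------------------
# element / moiety inference


def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip().upper()
    res = residue_name.strip().upper()
    if res in ("AU", "AUS") or name.startswith("AU"):
        return "AU"
    if res.startswith("CL") or name.startswith("CL"):
        return "CL"
    if res.startswith("NA") and len(res) <= 3 and res in ("NA", "NA+"):
        return "NA"
    stripped = name.lstrip("0123456789")
    return stripped[:1] if stripped else "X"


def _records_from_fields(
    fields: list[tuple[int, str, str, int]],
    moiety_map: dict[str, Moiety] | None,
) -> Topology:
    """Build AtomRecords from (atom_index, atom_name, resname, resid) tuples.

    Moieties come from the residue-name map; grafted-chain indices are
    inferred as maximal contiguous runs of linker/peptide atoms.
    """
    mmap = dict(DEFAULT_MOIETY_MAP)
    if moiety_map:
        mmap.update({k.upper(): Moiety(v) for k, v in moiety_map.items()})
    records: list[AtomRecord] = []
    chain = -1
    prev_chain_atom = False
    prev_resid: int | None = None
    for idx, name, resname, resid in fields:
        res = resname.strip().upper()
        moiety = mmap.get(res, Moiety.PEPTIDE if res in _STANDARD_AA else Moiety.PROTEIN)
        in_chain = moiety in (Moiety.LINKER, Moiety.PEPTIDE)
        if in_chain:
            # new grafted chain when the run restarts or residue numbering resets
            if not prev_chain_atom or (prev_resid is not None and resid < prev_resid):
                chain += 1
            pep_idx = chain
        else:
            pep_idx = -1
        elem = _infer_element(name, resname)
        records.append(
            AtomRecord(
                atom_index=idx,
                atom_name=name.strip(),
                element=elem,
                residue_name=res[:5],
                residue_index=resid,
                peptide_index=pep_idx,
                moiety=moiety,
                mass=ELEMENT_MASS_U.get(elem, ELEMENT_MASS_U["X"]),
                vdw_radius=ELEMENT_VDW_NM.get(elem, ELEMENT_VDW_NM["X"]),
                is_heavy=elem != "H",
                is_sidechain=False,
                is_calpha=(name.strip().upper() == "CA" and moiety in (Moiety.PEPTIDE, Moiety.PROTEIN)),
            )
        )
        prev_chain_atom = in_chain
        prev_resid = resid
    return Topology(records)


# ---------------------------------------------------------------------------
# GRO


def _read_gro(path: Path, moiety_map=None, frame_interval=None) -> Trajectory:
    lines = path.read_text().splitlines()
    pos_frames: list[np.ndarray] = []
    boxes: list[tuple[float, float, float]] = []
    times: list[float] = []
    fields: list[tuple[int, str, str, int]] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        t = None
        if "t=" in title:
            try:
                t = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                t = None
        try:
            natoms = int(lines[i + 1].strip())
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{i + 2}: expected atom count") from exc
        body = lines[i + 2: i + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(f"{path}:{i + 2}: truncated frame ({len(body)}/{natoms} atoms)")
        frame_fields: list[tuple[int, str, str, int]] = []
        pos = np.empty((natoms, 3))
        for k, line in enumerate(body):
            lineno = i + 3 + k
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                atomname = line[10:15].strip()
                atomnum = int(line[15:20])
                floats = [float(x) for x in line[20:].split()]
                pos[k] = floats[:3]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed GRO atom line") from exc
            frame_fields.append((k, atomname, resname, resid))
        try:
            box_vals = [float(x) for x in lines[i + 2 + natoms].split()]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{i + 3 + natoms}: malformed box line") from exc
        boxes.append((box_vals[0], box_vals[1], box_vals[2]))
        if fields is None:
            fields = frame_fields
        elif len(frame_fields) != len(fields):
            raise StructureError(
                f"{path}: frame {len(pos_frames)} has {len(frame_fields)} atoms, "
                f"expected {len(fields)}"
            )
        pos_frames.append(pos)
        times.append(t)
        i = i + 3 + natoms
    if fields is None:
        raise ParseError(f"{path}: no frames found")
    if any(t is None for t in times):
        dt = frame_interval or 1.0
        times = [k * dt for k in range(len(pos_frames))]
    topo = _records_from_fields(fields, moiety_map)
    if frame_interval is None:
        frame_interval = times[1] - times[0] if len(times) > 1 else 1.0
    frames = [Frame(p, b, t) for p, b, t in zip(pos_frames, boxes, times)]
    return Trajectory(topo, frames, frame_interval=frame_interval)


def _write_gro(traj: Trajectory, path: Path) -> None:
    # Atom and residue numbers wrap modulo 100000/100000 as in GROMACS, so
    # fixed five-character fields never overflow on large systems.
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"sambrush t= {frame.time:.4f}\n")
            fh.write(f"{len(traj.topology):d}\n")
            for a, p in zip(traj.topology, frame.positions):
                fh.write(
                    f"{(a.residue_index % 100000):5d}{a.residue_name:<5.5s}"
                    f"{a.atom_name:>5.5s}{((a.atom_index + 1) % 100000):5d}"
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n"
                )
            fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (multi-model; Angstrom on disk, nm in memory)


def _read_pdb(path: Path, moiety_map=None, frame_interval=None) -> Trajectory:
    lines = path.read_text().splitlines()
    box = None
    pos_frames: list[list[tuple[float, float, float]]] = []
    fields_frames: list[list[tuple[int, str, str, int]]] = []
    cur_pos: list[tuple[float, float, float]] = []
    cur_fields: list[tuple[int, str, str, int]] = []
    in_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = (float(line[6:15]) / 10, float(line[15:24]) / 10, float(line[24:33]) / 10)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed CRYST1") from exc
        elif rec == "MODEL":
            in_model = True
            cur_pos, cur_fields = [], []
        elif rec == "ENDMDL":
            in_model = False
            pos_frames.append(cur_pos)
            fields_frames.append(cur_fields)
            cur_pos, cur_fields = [], []
        elif rec in ("ATOM", "HETATM"):
            try:
                name = line[12:16].strip()
                resname = line[17:21].strip()
                resid = int(line[22:26])
                x = float(line[30:38]) / 10
                y = float(line[38:46]) / 10
                z = float(line[46:54]) / 10
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed ATOM record") from exc
            cur_fields.append((len(cur_fields), name, resname, resid))
            cur_pos.append((x, y, z))
    if cur_pos and not in_model:
        pos_frames.append(cur_pos)
        fields_frames.append(cur_fields)
    if not pos_frames:
        raise ParseError(f"{path}: no ATOM records found")
    n0 = len(fields_frames[0])
    for k, f in enumerate(fields_frames):
        if len(f) != n0:
            raise StructureError(f"{path}: model {k + 1} has {len(f)} atoms, expected {n0}")
    if box is None:
        flat = np.concatenate([np.asarray(p) for p in pos_frames])
        box = tuple(float(x) for x in (flat.max(axis=0) - np.minimum(flat.min(axis=0), 0) + 1.0))
    topo = _records_from_fields(fields_frames[0], moiety_map)
    dt = frame_interval or 1.0
    frames = [Frame(np.asarray(p), box, k * dt) for k, p in enumerate(pos_frames)]
    return Trajectory(topo, frames, frame_interval=dt)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        b = traj.frames[0].box
        fh.write(
            f"CRYST1{b[0] * 10:9.3f}{b[1] * 10:9.3f}{b[2] * 10:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for a, p in zip(traj.topology, frame.positions):
                serial = (a.atom_index + 1) % 100000
                name = a.atom_name[:4]
                fh.write(
                    f"ATOM  {serial:5d} {name:<4.4s}{a.residue_name:<4.4s} "
                    f"{(a.residue_index % 10000):4d}    "
                    f"{p[0] * 10:8.3f}{p[1] * 10:8.3f}{p[2] * 10:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gro", "pdb"):
        return suffix
    raise ValueError(f"cannot infer coordinate format from {path!r}; pass format=")


def read_coordinates(
    path,
    format: str | None = None,
    moiety_map: dict[str, Moiety] | None = None,
    frame_interval: float | None = None,
) -> Trajectory:
    """Read a (possibly multi-frame) GRO or PDB file into a Trajectory.

    PDB coordinates are converted from Angstrom to nm.  Moieties are
    inferred from residue names via :data:`DEFAULT_MOIETY_MAP`, overridable
    through ``moiety_map``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gro":
        return _read_gro(path, moiety_map, frame_interval)
    if fmt == "pdb":
        return _read_pdb(path, moiety_map, frame_interval)
    raise ValueError(f"unsupported format {fmt!r}")


def write_coordinates(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a Trajectory as multi-frame GRO or multi-model PDB."""
    if not traj.frames:
        raise StructureError("cannot write an empty trajectory")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gro":
        _write_gro(traj, path)
    elif fmt == "pdb":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# selection


def select(
    topology: Topology,
    moiety: Moiety | str | Iterable[Moiety | str] | None = None,
    peptide_index: int | Iterable[int] | None = None,
    heavy_only: bool = False,
    sidechain_only: bool = False,
    calpha_only: bool = False,
    residue_list: Iterable[str] | None = None,
) -> np.ndarray:
    """Atom indices satisfying the conjunction of the named criteria.

    Returns indices sorted by atom_index (deterministic).  Raises
    SelectionError when ``residue_list`` names a residue absent from the
    topology.
    """
    mask = np.ones(len(topology), dtype=bool)
    if moiety is not None:
        if isinstance(moiety, (str, Moiety)):
            moiety = [moiety]
        wanted = {Moiety(m).value for m in moiety}
        mask &= np.isin(topology.moieties, sorted(wanted))
    if peptide_index is not None:
        if isinstance(peptide_index, (int, np.integer)):
            peptide_index = [int(peptide_index)]
        mask &= np.isin(topology.peptide_indices, list(peptide_index))
    if heavy_only:
        mask &= topology.is_heavy
    if sidechain_only:
        mask &= topology.is_sidechain
    if calpha_only:
        mask &= topology.is_calpha
    if residue_list is not None:
        wanted_res = {r.upper() for r in residue_list}
        present = set(topology.residue_names)
        missing = wanted_res - present
        if missing:
            raise SelectionError(f"residues not in topology: {sorted(missing)}")
        mask &= np.isin(topology.residue_names, sorted(wanted_res))
    return np.nonzero(mask)[0]
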