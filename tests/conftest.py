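import numpy as np
import pytest

from sambrush.io import AtomRecord, Frame, Moiety, Topology, Trajectory


def make_bead_topology(n_chains: int, beads: int, box=(5.0, 5.0, 10.0)) -> Topology:
    """Minimal bead topology: n_chains grafted chains of `beads` peptide beads."""
    atoms = []
    idx = 0
    for c in range(n_chains):
        for b in range(beads):
            atoms.append(
                AtomRecord(
                    atom_index=idx, atom_name="CA", element="C", residue_name="ALA",
                    residue_index=idx + 1, peptide_index=c, moiety=Moiety.PEPTIDE,
                    mass=100.0, vdw_radius=0.2, is_heavy=True,
                    is_sidechain=True, is_calpha=True,
                )
            )
            idx += 1
    return Topology(atoms)


def random_bead_trajectory(rng, n_chains=4, beads=10, n_frames=3, box=(5.0, 5.0, 10.0)):
    topo = make_bead_topology(n_chains, beads, box)
    frames = [
        Frame(
            rng.uniform([0, 0, 0], [box[0], box[1], box[2] * 0.6], size=(n_chains * beads, 3)),
            box,
            float(t),
        )
        for t in range(n_frames)
    ]
    return Trajectory(topo, frames, frame_interval=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
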