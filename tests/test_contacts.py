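"""Contact scoring against direct arithmetic and brute-force oracles."""
import numpy as np
import pytest

from sambrush.contacts import (
    ActiveSpotSet, SwitchParams, close_contacts, contact_energy,
    persistence_map, residue_pair_contacts, s_function, switch_term,
)
from sambrush.errors import AnalysisError, MatrixError, SelectionError
from sambrush.geometry import min_image_displacements
from sambrush.io import AtomRecord, Frame, Moiety, Topology, Trajectory
from tests.conftest import make_bead_topology, random_bead_trajectory


def brute_force_s(frame, topology, p, cutoff, normalize=False):
    """O(N^2) reference: loop over all heavy-atom pairs of different peptides."""
    sel = np.nonzero((topology.moieties == Moiety.PEPTIDE.value) & topology.is_heavy)[0]
    chains = topology.peptide_indices[sel]
    pos = frame.positions[sel]
    total = 0.0
    for i in range(len(sel)):
        for j in range(i + 1, len(sel)):
            if chains[i] == chains[j]:
                continue
            dv = min_image_displacements(pos[i] - pos[j], frame.box)
            r = float(np.linalg.norm(dv))
            if r < cutoff:
                total += switch_term(r, p)
    if normalize:
        n = len(np.unique(chains))
        total /= n * (n - 1) / 2
    return total


def brute_force_contacts(frame, topology, set_a, set_b, cutoff):
    pos = frame.positions
    count = 0
    for a in set_a:
        for b in set_b:
            dv = min_image_displacements(pos[a] - pos[b], frame.box)
            if float(np.linalg.norm(dv)) < cutoff:
                count += 1
    return count


class TestSwitchTerm:
    def test_reference_values(self):
        p = SwitchParams()
        assert switch_term(0.0, p) == pytest.approx(1.0, abs=1e-12)
        assert switch_term(0.6, p) == pytest.approx(6 / 14, abs=1e-9)
        expected_03 = (1 - 0.5**6) / (1 - 0.5**14)
        assert switch_term(0.3, p) == pytest.approx(expected_03, abs=1e-12)
        assert expected_03 == pytest.approx(0.984435, abs=5e-7)

    def test_continuity_at_r0(self):
        p = SwitchParams()
        for eps in (1e-8, -1e-8):
            assert switch_term(0.6 + eps, p) == pytest.approx(6 / 14, abs=1e-6)

    def test_strictly_decreasing(self):
        r = np.linspace(0.0, 3.0, 1000)
        v = switch_term(r)
        assert np.all(np.diff(v) < 0)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            SwitchParams(r0=0.6, num_exp=14, den_exp=6)


class TestSFunction:
    def test_single_pair_at_r0(self):
        topo = make_bead_topology(2, 1)
        frame = Frame(np.array([[1.0, 1.0, 1.0], [1.6, 1.0, 1.0]]), (5, 5, 10))
        s_raw = s_function(frame, topo, normalize=False)
        assert s_raw == pytest.approx(6 / 14, abs=1e-9)
        # n=2 -> n(n-1)/2 = 1: normalization leaves the value unchanged
        assert s_function(frame, topo, normalize=True) == pytest.approx(s_raw)

    def test_distant_peptides_negligible(self):
        topo = make_bead_topology(2, 1, box=(20.0, 20.0, 20.0))
        frame = Frame(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 5.0]]), (20, 20, 20))
        assert s_function(frame, topo, cutoff=None) < 1e-3

    def test_requires_two_peptides(self):
        topo = make_bead_topology(1, 3)
        frame = Frame(np.zeros((3, 3)) + 1.0, (5, 5, 10))
        with pytest.raises(AnalysisError):
            s_function(frame, topo)

    def test_matches_brute_force_small(self, rng):
        """Cell-list (KD-tree) path equals the O(N^2) oracle, XY images included."""
        p = SwitchParams()
        for _ in range(20):
            traj = random_bead_trajectory(rng, n_chains=5, beads=8, n_frames=1,
                                          box=(4.0, 4.0, 8.0))
            frame = traj.frames[0]
            got = s_function(frame, traj.topology, p, normalize=True)
            want = brute_force_s(frame, traj.topology, p, cutoff=3.0, normalize=True)
            assert got == pytest.approx(want, abs=1e-10)

    def test_truncation_error_bounded(self, rng):
        traj = random_bead_trajectory(rng, n_chains=4, beads=10, n_frames=1,
                                      box=(6.0, 6.0, 8.0))
        frame = traj.frames[0]
        full = brute_force_s(frame, traj.topology, SwitchParams(), cutoff=np.inf)
        truncated = s_function(frame, traj.topology)
        assert abs(full - truncated) < 1e-2


class TestCloseContacts:
    def _two_bead_traj(self, distance):
        topo = make_bead_topology(2, 1)
        frame = Frame(np.array([[1.0, 1.0, 1.0], [1.0 + distance, 1.0, 1.0]]), (5, 5, 10))
        return Trajectory(topo, [frame])

    def test_strict_cutoff_boundary(self):
        for d, expected in ((0.49, 1), (0.51, 0), (0.5, 0)):
            traj = self._two_bead_traj(d)
            res = close_contacts(traj, np.array([0]), np.array([1]), cutoff=0.5)
            assert res.counts[0] == expected

    def test_coincident_atoms_counted_once(self):
        traj = self._two_bead_traj(0.0)
        res = close_contacts(traj, np.array([0]), np.array([1]))
        assert res.counts[0] == 1

    def test_overlapping_selections_rejected(self):
        traj = self._two_bead_traj(0.3)
        with pytest.raises(SelectionError):
            close_contacts(traj, np.array([0, 1]), np.array([1]))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            traj = random_bead_trajectory(rng, n_chains=4, beads=10, n_frames=2,
                                          box=(3.0, 3.0, 6.0))
            n = len(traj.topology)
            set_a = np.arange(0, n // 2)
            set_b = np.arange(n // 2, n)
            res = close_contacts(traj, set_a, set_b, cutoff=0.5)
            for k, fi in enumerate(range(len(traj.frames))):
                want = brute_force_contacts(traj.frames[fi], traj.topology,
                                            set_a, set_b, 0.5)
                assert res.counts[k] == want


def _probe_traj(contact_pattern, n_frames=10, interval=2000.0):
    """2 chains x 2 peptide residues + one PHE19 protein bead.

    ``contact_pattern(frame_index)`` says whether residue 0 of chain 0
    touches the spot in that frame.
    """
    atoms = []
    idx = 0
    for c in range(2):
        for b in range(2):
            atoms.append(AtomRecord(idx, "CA", "C", "ALA", idx + 1, c,
                                    Moiety.PEPTIDE, 100.0, 0.2, is_sidechain=True,
                                    is_calpha=True))
            idx += 1
    atoms.append(AtomRecord(idx, "BB", "C", "PHE", 19, -1, Moiety.PROTEIN, 100.0, 0.2))
    topo = Topology(atoms)
    frames = []
    for t in range(n_frames):
        pos = np.array([
            [1.0, 1.0, 1.0], [1.0, 1.0, 1.4],
            [3.0, 3.0, 1.0], [3.0, 3.0, 1.4],
            [1.0, 1.0, 1.3],
        ])
        if not contact_pattern(t):
            pos[4] = [4.0, 4.0, 5.0]
        frames.append(Frame(pos, (6.0, 6.0, 8.0), t * interval))
    return Trajectory(topo, frames, frame_interval=interval)


class TestPersistence:
    SPOTS = ActiveSpotSet(residues=(("PHE", 19),))

    def test_permanent_contact_attains_window_length(self):
        traj = _probe_traj(lambda t: True)
        pm = persistence_map(traj, self.SPOTS)
        assert pm.values.max() == pytest.approx(pm.window_length)
        assert pm.window_length == pytest.approx(10 * 2000.0 / 1000.0)  # 20 ns

    def test_no_contact_is_zero(self):
        traj = _probe_traj(lambda t: False)
        pm = persistence_map(traj, self.SPOTS)
        assert np.all(pm.values == 0.0)

    def test_alternating_contact_half_window(self):
        traj = _probe_traj(lambda t: t % 2 == 0)
        pm = persistence_map(traj, self.SPOTS)
        assert pm.values[0, 0] == pytest.approx(pm.window_length / 2)

    def test_values_bounded_by_window(self, rng):
        traj = _probe_traj(lambda t: rng.random() < 0.5)
        pm = persistence_map(traj, self.SPOTS)
        assert np.all(pm.values <= pm.window_length + 1e-12)

    def test_missing_spot_listed(self):
        traj = _probe_traj(lambda t: True)
        with pytest.raises(AnalysisError, match="ARG113"):
            persistence_map(traj, ActiveSpotSet(residues=(("ARG", 113),)))

    def test_duplicate_spot_indices_rejected(self):
        with pytest.raises(ValueError):
            ActiveSpotSet(residues=(("PHE", 19), ("TYR", 19)))


class TestContactEnergy:
    def test_no_contacts_zero(self):
        assert contact_energy({}, {("TRP", "PHE"): -1.0}) == 0.0

    def test_single_pair_value(self):
        assert contact_energy({("TRP", "PHE"): 1}, {("PHE", "TRP"): -2.5}) == -2.5

    def test_additivity(self):
        m = {("TRP", "PHE"): -2.5, ("ALA", "GLY"): -0.5}
        e1 = contact_energy({("TRP", "PHE"): 2}, m)
        e2 = contact_energy({("ALA", "GLY"): 3}, m)
        both = contact_energy({("TRP", "PHE"): 2, ("ALA", "GLY"): 3}, m)
        assert both == pytest.approx(e1 + e2)

    def test_missing_pair_raises(self):
        with pytest.raises(MatrixError):
            contact_energy({("TRP", "TRP"): 1}, {("TRP", "PHE"): -1.0})

    def test_residue_pair_counting(self):
        traj = _probe_traj(lambda t: True)
        counts = residue_pair_contacts(
            traj.frames[0], traj.topology, np.array([0, 1, 2, 3]), np.array([4]),
            cutoff=0.5,
        )
        assert counts == {("ALA", "PHE"): 2}
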