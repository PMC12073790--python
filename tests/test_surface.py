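"""SASA against closed-form sphere oracles; height-map pocket detection."""
import math

import numpy as np
import pytest

from sambrush.errors import AnalysisError
from sambrush.io import AtomRecord, Frame, Moiety, Topology
from sambrush.surface import (
    accommodates_probe, fibonacci_sphere, height_map, sasa,
    sasa_timeseries, scale_patch_to_sphere,
)
from tests.conftest import make_bead_topology


def _atoms(n, vdw=0.15):
    return Topology([
        AtomRecord(i, "CA", "C", "ALA", i + 1, 0, Moiety.PEPTIDE, 100.0, vdw,
                   is_calpha=True)
        for i in range(n)
    ])


def two_sphere_sasa_closed_form(r1, r2, probe, d):
    """Analytic SASA of two overlapping expanded spheres (cap formula)."""
    R1, R2 = r1 + probe, r2 + probe
    total = 4 * math.pi * (R1**2 + R2**2)
    if d >= R1 + R2:
        return total
    # cap height of sphere i hidden inside sphere j
    h1 = (R2**2 - (d - R1) ** 2) / (2 * d)
    h2 = (R1**2 - (d - R2) ** 2) / (2 * d)
    return total - 2 * math.pi * (R1 * h1 + R2 * h2)


class TestFibonacciSphere:
    def test_unit_vectors_deterministic(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(960))

    def test_quasi_uniform_centroid(self):
        pts = fibonacci_sphere(960)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-2


class TestSasa:
    def test_lone_sphere_closed_form(self):
        topo = _atoms(1)
        frame = Frame(np.array([[5.0, 5.0, 5.0]]), (10, 10, 10))
        res = sasa(frame, topo, np.array([0]), probe_radius=0.15)
        assert res.total == pytest.approx(4 * math.pi * 0.3**2, rel=1e-12)
        assert res.total == pytest.approx(1.13097, abs=1e-4)

    def test_distant_atoms_additive(self):
        topo = _atoms(2)
        frame = Frame(np.array([[1.0, 1.0, 1.0], [90.0, 1.0, 1.0]]), (100, 100, 100))
        res = sasa(frame, topo, np.array([0, 1]), probe_radius=0.15)
        assert res.total == pytest.approx(2 * 4 * math.pi * 0.3**2, rel=1e-9)

    @pytest.mark.parametrize("d_frac", [0.3, 0.5, 0.7, 0.9])
    def test_two_sphere_cap_oracle(self, d_frac):
        r, probe = 0.15, 0.15
        d = d_frac * 2 * (r + probe)
        topo = _atoms(2)
        frame = Frame(np.array([[2.0, 2.0, 2.0], [2.0 + d, 2.0, 2.0]]), (10, 10, 10))
        res = sasa(frame, topo, np.array([0, 1]), probe_radius=probe, n_points=960)
        want = two_sphere_sasa_closed_form(r, r, probe, d)
        assert res.total == pytest.approx(want, rel=2 / math.sqrt(960))

    def test_two_sphere_random_geometries(self, rng):
        for _ in range(50):
            r1, r2 = rng.uniform(0.1, 0.3, 2)
            probe = rng.uniform(0.1, 1.0)
            dmax = r1 + r2 + 2 * probe
            dmin = abs((r1 + probe) - (r2 + probe)) + 0.05
            d = rng.uniform(max(dmin, 0.3 * dmax), 0.99 * dmax)
            topo = Topology([
                AtomRecord(0, "CA", "C", "ALA", 1, 0, Moiety.PEPTIDE, 1.0, r1, is_calpha=True),
                AtomRecord(1, "CA", "C", "ALA", 2, 0, Moiety.PEPTIDE, 1.0, r2, is_calpha=True),
            ])
            frame = Frame(np.array([[5.0, 5.0, 5.0], [5.0 + d, 5.0, 5.0]]), (20, 20, 20))
            res = sasa(frame, topo, np.array([0, 1]), probe_radius=probe, n_points=960)
            want = two_sphere_sasa_closed_form(r1, r2, probe, d)
            assert res.total == pytest.approx(want, rel=2 / math.sqrt(960))

    def test_fully_buried_atom(self):
        # central atom caged by 12 touching neighbors (fcc shell) is buried
        r = 0.3
        phi = (1 + math.sqrt(5)) / 2
        verts = []
        for a in (1, -1):
            for b in (phi, -phi):
                verts += [(0, a, b), (a, b, 0), (b, 0, a)]
        verts = np.array(verts) / np.linalg.norm([1, phi]) * (2 * r * 0.8)
        pos = np.vstack([[0.0, 0.0, 0.0], verts]) + 5.0
        topo = _atoms(13, vdw=r)
        frame = Frame(pos, (10, 10, 10))
        res = sasa(frame, topo, np.arange(13), probe_radius=0.05, n_points=960)
        assert res.per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_convergence_960_vs_3840(self, rng):
        topo = make_bead_topology(5, 10)
        pos = rng.uniform(1, 3, (50, 3))
        frame = Frame(pos, (5, 5, 10))
        sel = np.arange(50)
        a = sasa(frame, topo, sel, 0.15, n_points=960).total
        b = sasa(frame, topo, sel, 0.15, n_points=3840).total
        assert abs(a - b) / b < 0.01

    def test_occluder_monotonicity(self, rng):
        """Adding an occluder atom never increases the selection's SASA."""
        topo = make_bead_topology(2, 5)
        pos = np.vstack([rng.uniform(2, 3, (5, 3)), rng.uniform(2, 3, (5, 3))])
        frame = Frame(pos, (6, 6, 10))
        base_sel = np.arange(5)
        a = sasa(frame, topo, base_sel, 0.15).total
        widened = sasa(frame, topo, np.arange(6), 0.15)
        assert widened.per_atom[:5].sum() <= a + 1e-9

    def test_per_peptide_sums_to_total(self, rng):
        topo = make_bead_topology(3, 4)
        frame = Frame(rng.uniform(1, 4, (12, 3)), (5, 5, 10))
        res = sasa(frame, topo, np.arange(12), 0.15)
        assert sum(res.per_peptide.values()) == pytest.approx(res.total, abs=1e-9)


class TestScaleUp:
    def test_reference_scale_up(self):
        # 63 nm^2 per ~10x10 nm patch on a 10 nm-radius sphere
        val = scale_patch_to_sphere(63.0, 10.32 * 9.99, 10.0)
        assert val == pytest.approx(768.0, abs=1.0)
        assert val / 75.0 > 10.0

    def test_zero_delta(self):
        assert scale_patch_to_sphere(0.0, 100.0, 10.0) == 0.0

    def test_linearity(self):
        one = scale_patch_to_sphere(10.0, 100.0, 10.0)
        assert scale_patch_to_sphere(20.0, 100.0, 10.0) == pytest.approx(2 * one)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            scale_patch_to_sphere(10.0, -1.0, 10.0)


def _flat_layer_frame(box=(10.0, 10.0, 12.0), z=5.0, spacing=0.15, vdw=0.1):
    xs = np.arange(spacing / 2, box[0], spacing)
    ys = np.arange(spacing / 2, box[1], spacing)
    gx, gy = np.meshgrid(xs, ys)
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    topo = Topology([
        AtomRecord(i, "CA", "C", "ALA", i + 1, 0, Moiety.PEPTIDE, 100.0, vdw,
                   is_calpha=True)
        for i in range(len(pos))
    ])
    return topo, pos


class TestHeightMap:
    def test_flat_layer_has_no_pockets(self):
        topo, pos = _flat_layer_frame()
        frame = Frame(pos, (10, 10, 12))
        hm = height_map(frame, topo, np.arange(len(pos)))
        assert hm.pockets == []
        assert np.ptp(hm.top_surface) <= 0.1  # within one vdw radius

    def test_carved_well_detected(self):
        topo, pos = _flat_layer_frame(z=5.0)
        # carve a cylindrical well: depth 4 nm, diameter 3 nm
        center = np.array([5.0, 5.0])
        rad = np.linalg.norm(pos[:, :2] - center, axis=1)
        pos = pos.copy()
        pos[rad < 1.5, 2] = 1.0
        frame = Frame(pos, (10, 10, 12))
        hm = height_map(frame, topo, np.arange(len(pos)), grid_resolution=0.2)
        assert len(hm.pockets) == 1
        p = hm.pockets[0]
        assert p.depth == pytest.approx(4.0, abs=0.2)
        assert p.width == pytest.approx(3.0, abs=0.2)
        ok, hits = accommodates_probe(hm, probe_depth=4.0, probe_width=3.0)
        assert ok and len(hits) == 1

    def test_shallow_well_not_accommodating(self):
        topo, pos = _flat_layer_frame(z=5.0)
        center = np.array([5.0, 5.0])
        rad = np.linalg.norm(pos[:, :2] - center, axis=1)
        pos = pos.copy()
        pos[rad < 1.5, 2] = 3.0  # only 2 nm deep
        frame = Frame(pos, (10, 10, 12))
        hm = height_map(frame, topo, np.arange(len(pos)), grid_resolution=0.2)
        ok, _ = accommodates_probe(hm, probe_depth=4.0, probe_width=3.0)
        assert not ok

    def test_flat_surface_not_accommodating(self):
        topo, pos = _flat_layer_frame()
        hm = height_map(Frame(pos, (10, 10, 12)), topo, np.arange(len(pos)))
        ok, hits = accommodates_probe(hm)
        assert not ok and hits == []

    def test_pocket_depth_bounded_by_z_range(self, rng):
        topo = make_bead_topology(5, 20)
        pos = rng.uniform([0, 0, 0.5], [5, 5, 4.0], (100, 3))
        frame = Frame(pos, (5, 5, 10))
        hm = height_map(frame, topo, np.arange(100), grid_resolution=0.25)
        zspan = pos[:, 2].max() - pos[:, 2].min() + 0.4  # + two vdw radii
        for p in hm.pockets:
            assert p.depth <= zspan + 1e-9

    def test_translation_invariance_modulo_grid(self):
        topo, pos = _flat_layer_frame(z=5.0)
        center = np.array([5.0, 5.0])
        rad = np.linalg.norm(pos[:, :2] - center, axis=1)
        pos = pos.copy()
        pos[rad < 1.5, 2] = 1.0
        hm0 = height_map(Frame(pos, (10, 10, 12)), topo, np.arange(len(pos)),
                         grid_resolution=0.2)
        shifted = pos.copy()
        shifted[:, 0] = (shifted[:, 0] + 1.0) % 10.0  # whole grid cells
        hm1 = height_map(Frame(shifted, (10, 10, 12)), topo, np.arange(len(pos)),
                         grid_resolution=0.2)
        assert hm1.pockets[0].depth == pytest.approx(hm0.pockets[0].depth, abs=1e-9)
        assert hm1.pockets[0].width == pytest.approx(hm0.pockets[0].width, abs=1e-9)

    def test_resolution_larger_than_box_rejected(self):
        topo, pos = _flat_layer_frame()
        with pytest.raises(ValueError):
            height_map(Frame(pos, (10, 10, 12)), topo, np.arange(len(pos)),
                       grid_resolution=11.0)

    def test_empty_selection_rejected(self):
        topo, pos = _flat_layer_frame()
        with pytest.raises(AnalysisError):
            height_map(Frame(pos, (10, 10, 12)), topo, np.array([], dtype=int))
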