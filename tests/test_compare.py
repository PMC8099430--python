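"""Superposition, screw geometry, SASA and interface analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from xlwalk.compare import (
    DegenerateInputError,
    DegenerateScrewError,
    Transform,
    buried_area,
    com_displacement,
    helical_pitch,
    mt_register_displacement,
    sasa,
    screw_parameters,
    select_ca,
    site_context,
    superpose,
    parse_selection,
)
from tests.conftest import structure_from_chains


def random_transform(rng) -> Transform:
    R = Rotation.random(random_state=int(rng.integers(2**16))).as_matrix()
    return Transform(R, rng.normal(scale=20, size=3))


class TestSuperpose:
    def test_self_superposition_is_identity(self, rng):
        a = rng.normal(scale=10, size=(8, 3))
        tr, rmsd = superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0, atol=1e-9)

    def test_recovers_random_rigid_motion(self, rng):
        a = rng.normal(scale=10, size=(10, 3))
        applied = random_transform(rng)
        b = applied.apply(a)
        tr, rmsd = superpose(a, b)
        assert rmsd < 1e-6
        assert np.max(np.abs(tr.apply(b) - a)) < 1e-6
        # recovered transform is the inverse of the applied one
        assert np.allclose(tr.rotation, applied.rotation.T, atol=1e-9)

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5), [1.0, 0, 0])
        with pytest.raises(DegenerateInputError):
            superpose(line, line + 1.0)


class TestComDisplacement:
    def test_identical_states_zero(self, rng):
        a = rng.normal(scale=10, size=(12, 3))
        d = com_displacement(a, a, np.arange(6), np.arange(6, 12))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_translated_component_with_fixed_frame(self, rng):
        a = rng.normal(scale=10, size=(12, 3))
        b = a.copy()
        b[6:] += (3.0, 4.0, 0.0)
        d = com_displacement(a, b, np.arange(6), np.arange(6, 12))
        assert d == pytest.approx(5.0, abs=1e-9)

    def test_matches_explicit_transform_oracle(self, rng):
        a = rng.normal(scale=10, size=(15, 3))
        tr = random_transform(rng)
        b = tr.apply(a)
        b[10:] = tr.apply(a[10:] + rng.normal(scale=4, size=(5, 3)))
        align, comp = np.arange(10), np.arange(10, 15)
        d = com_displacement(a, b, align, comp)
        # oracle: bring B back with the inverse of the applied transform
        b_back = tr.inverse().apply(b)
        expected = np.linalg.norm(b_back[comp].mean(0) - a[comp].mean(0))
        assert d == pytest.approx(expected, abs=1e-6)

    def test_empty_component_rejected(self, rng):
        a = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            com_displacement(a, a, np.arange(6), np.array([], dtype=int))


class TestScrew:
    def test_axis_aligned_screw(self):
        R = Rotation.from_euler("z", 60, degrees=True).as_matrix()
        sp = screw_parameters(Transform(R, np.array([0.0, 0.0, 21.0])))
        assert sp.twist == pytest.approx(60.0)
        assert sp.rise == pytest.approx(21.0)
        assert abs(sp.axis[2]) == pytest.approx(1.0)

    def test_pure_translation_degenerate(self):
        with pytest.raises(DegenerateScrewError):
            screw_parameters(Transform(np.eye(3), np.array([1.0, 2.0, 3.0])))

    def test_random_screw_round_trip(self, rng):
        for _ in range(20):
            tr = random_transform(rng)
            sp = screw_parameters(tr)
            assert 0 < sp.twist <= 180.0
            rebuilt = sp.to_transform()
            pts = rng.normal(scale=30, size=(12, 3))
            assert np.max(np.abs(rebuilt.apply(pts) - tr.apply(pts))) < 1e-6

    def test_pitch_invariant_under_conjugation(self, rng):
        tr = random_transform(rng)
        sp = screw_parameters(tr)
        g = random_transform(rng)
        conj = g.compose(tr).compose(g.inverse())
        sp2 = screw_parameters(conj)
        p1 = helical_pitch(sp.twist, abs(sp.rise))
        p2 = helical_pitch(sp2.twist, abs(sp2.rise))
        assert p1[0] == pytest.approx(p2[0], abs=1e-6)
        assert p1[1] == pytest.approx(p2[1], abs=1e-9)


class TestHelicalPitch:
    def test_open_state_values(self):
        pitch, per_turn = helical_pitch(54.5, 21.2)
        assert pitch == pytest.approx(140.0, abs=0.1)
        assert per_turn == pytest.approx(6.61, abs=0.01)

    def test_closed_state_values(self):
        pitch, _ = helical_pitch(55.1, 20.2)
        assert pitch == pytest.approx(132.0, abs=0.1)

    def test_full_turn_pitch_equals_rise(self):
        assert helical_pitch(360.0, 10.0)[0] == pytest.approx(10.0)

    def test_nonpositive_twist_rejected(self):
        with pytest.raises(ValueError):
            helical_pitch(0.0, 5.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        twist=st.floats(0.1, 180.0, allow_nan=False),
        rise=st.floats(0.0, 100.0, allow_nan=False),
    )
    def test_pitch_identity_property(self, twist, rise):
        pitch, per_turn = helical_pitch(twist, rise)
        assert pitch == pytest.approx(rise * per_turn, rel=1e-12, abs=1e-12)
        assert per_turn * twist == pytest.approx(360.0, rel=1e-12)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        area = sasa(np.zeros((1, 3)), np.array([2.0]), probe=1.4)
        assert area[0] == pytest.approx(4 * math.pi * 3.4**2, rel=0.01)

    def test_distant_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = sasa(coords, np.array([2.0, 1.5]))
        singles = [
            sasa(np.zeros((1, 3)), np.array([r]))[0] for r in (2.0, 1.5)
        ]
        assert areas == pytest.approx(singles, rel=1e-12)

    def test_caged_atom_fully_buried(self):
        # octahedral + cubic cage of large spheres around a small one
        dirs = np.array(
            [
                [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
                [0, 0, -1], [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
                [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1],
            ],
            dtype=float,
        )
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0, 0], 3.0 * dirs])
        radii = np.array([1.0] + [3.0] * len(dirs))
        areas = sasa(coords, radii)
        assert areas[0] == 0.0

    def test_rotation_invariance_within_sampling_tolerance(self, rng):
        coords = rng.normal(scale=4, size=(20, 3))
        radii = rng.uniform(1.2, 2.0, size=20)
        total = sasa(coords, radii).sum()
        R = Rotation.random(random_state=7).as_matrix()
        total_rot = sasa(coords @ R.T, radii).sum()
        assert total_rot == pytest.approx(total, rel=0.01)


def two_sphere_structure(d: float):
    return structure_from_chains(
        {"A": np.array([[0.0, 0.0, 0.0]]), "B": np.array([[d, 0.0, 0.0]])}
    )


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self):
        rep = buried_area(two_sphere_structure(100.0), ["A"], ["B"])
        assert rep.buried_area == pytest.approx(0.0, abs=1e-9)
        assert rep.interface_residues_a == ()

    def test_touching_spheres_match_cap_area_oracle(self):
        # carbon radii 1.70 + probe 1.4 -> expanded R = 3.10 each
        d = 4.0
        rep = buried_area(two_sphere_structure(d), ["A"], ["B"], n_points=4000)
        R = 1.70 + 1.4
        # spherical cap blocked on each sphere: h = R - d/2
        h = R - d / 2
        buried_each = 2 * math.pi * R * h
        assert rep.buried_area == pytest.approx(2 * buried_each, rel=0.02)

    def test_symmetric_under_chain_swap(self):
        st = two_sphere_structure(4.0)
        r1 = buried_area(st, ["A"], ["B"])
        r2 = buried_area(st, ["B"], ["A"])
        assert r1.buried_area == r2.buried_area
        assert r1.sasa_a_free == r2.sasa_b_free

    def test_overlapping_chain_sets_rejected(self):
        with pytest.raises(ValueError):
            buried_area(two_sphere_structure(4.0), ["A"], ["A"])


class TestMtRegister:
    def ring(self, rng, n=13):
        ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return np.stack(
            [50 * np.cos(ang), 50 * np.sin(ang), np.linspace(0, 12, n)], axis=1
        )

    def test_identical_ring_zero_displacement(self, rng):
        ring = self.ring(rng)
        disp, dmax = mt_register_displacement(ring, ring, [0, 1, 2])
        assert dmax == pytest.approx(0.0, abs=1e-9)

    def test_single_moved_subunit_detected(self, rng):
        ring = self.ring(rng)
        ref = ring.copy()
        ref[7] += (7.0, 0.0, 0.0)
        disp, dmax = mt_register_displacement(ring, ref, [0, 1, 2])
        assert dmax == pytest.approx(7.0, abs=1e-9)
        assert np.argmax(disp) == 7

    def test_matches_explicit_superpose_oracle(self, rng):
        ring = self.ring(rng) + rng.normal(scale=3, size=(13, 3))
        ref = self.ring(rng)
        pairs = [0, 1, 2, 3]
        disp, dmax = mt_register_displacement(ring, ref, pairs)
        tr, _ = superpose(ref[pairs], ring[pairs])
        expected = np.linalg.norm(tr.apply(ring) - ref, axis=1)
        assert disp == pytest.approx(expected, abs=1e-9)
        assert dmax == pytest.approx(expected.max())

    def test_too_few_pairs_rejected(self, rng):
        ring = self.ring(rng)
        with pytest.raises(ValueError):
            mt_register_displacement(ring, ring, [0])


class TestSiteContext:
    def structure(self, rng):
        return structure_from_chains(
            {
                "A": np.array([[0.0, 0, 0], [50.0, 0, 0]]),
                "B": np.array([[3.0, 0, 0]]),
                "C": np.array([[100.0, 0, 0]]),
            }
        )

    def test_contact_within_cutoff(self, rng):
        ctx = site_context(self.structure(rng), "A", 1, ["B", "C"], cutoff=4.5)
        assert ctx.mapped and ctx.within_interface
        assert ctx.distances["B"] == pytest.approx(3.0)

    def test_isolated_residue_not_interface(self, rng):
        ctx = site_context(self.structure(rng), "A", 2, ["C"], cutoff=4.5)
        assert ctx.mapped and not ctx.within_interface
        assert ctx.distances["C"] == pytest.approx(50.0)

    def test_unresolved_residue_reported_unmapped(self, rng):
        ctx = site_context(self.structure(rng), "A", 99, ["B"])
        assert not ctx.mapped and not ctx.within_interface

    def test_matches_all_pairs_brute_force(self, rng):
        chains = {
            "A": rng.normal(scale=10, size=(30, 3)),
            "B": rng.normal(scale=10, size=(40, 3)),
        }
        st = structure_from_chains(chains)
        for res in (1, 7, 30):
            ctx = site_context(st, "A", res, ["B"], cutoff=6.0)
            expected = min(
                np.linalg.norm(chains["A"][res - 1] - b) for b in chains["B"]
            )
            assert ctx.distances["B"] == pytest.approx(expected, rel=1e-12)
            assert ctx.within_interface == (expected <= 6.0)


class TestSelections:
    def test_parse_ranges_and_singles(self):
        sel = parse_selection("A:52-276+B:178-342+C+D:7")
        assert sel == [("A", 52, 276), ("B", 178, 342), ("C", None, None),
                       ("D", 7, 7)]

    def test_select_ca_orders_and_filters(self, rng):
        st = structure_from_chains(
            {"A": rng.normal(size=(10, 3)), "B": rng.normal(size=(4, 3))}
        )
        coords, labels = select_ca(st, "A:3-5+B")
        assert labels == [("A", 3), ("A", 4), ("A", 5)] + [("B", i) for i in
                                                           range(1, 5)]
        assert coords.shape == (7, 3)
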