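"""Restraint scoring: flat-bottom crosslinks, excluded volume, connectivity."""

import numpy as np
import pytest

from xlwalk.representation import bead_radius
from xlwalk.restraints import RestraintSet, Scorer
from xlwalk.xlinks import Crosslink
from tests.conftest import bead_system


def link(r1=1, r2=1, L=None, linker="DSS"):
    return Crosslink("R", r1, "L", r2, linker, threshold_override=L)


@pytest.fixture
def pair_system():
    """R: 1 bead (copy 1), L: 1 bead in two copies."""
    return bead_system([("R", 1, 1), ("L", 1, 2)])


class TestCrosslinkScore:
    def set_positions(self, sys_, d0, d1):
        coords = np.zeros((sys_.n_particles, 3))
        coords[sys_.residue_map[("L", 0, 1)]] = (d0, 0, 0)
        coords[sys_.residue_map[("L", 1, 1)]] = (d1, 0, 0)
        return coords

    def test_inside_flat_bottom_is_zero(self, pair_system):
        sc = Scorer(pair_system, RestraintSet(crosslinks=(link(L=35.0),)))
        assert sc.crosslink_scores(self.set_positions(pair_system, 10, 200))[0] == 0

    def test_quadratic_beyond_threshold(self, pair_system):
        sc = Scorer(pair_system, RestraintSet(crosslinks=(link(L=35.0),), k_xl=1.0))
        score = sc.crosslink_scores(self.set_positions(pair_system, 45, 200))[0]
        assert score == pytest.approx(100.0)

    def test_ambiguity_minimum_over_copies(self, pair_system):
        sc = Scorer(pair_system, RestraintSet(crosslinks=(link(L=35.0),)))
        assert sc.crosslink_scores(self.set_positions(pair_system, 50, 20))[0] == 0

    def test_infinite_threshold_zeroes_term(self, pair_system, rng):
        sc = Scorer(
            pair_system, RestraintSet(crosslinks=(link(L=np.inf),))
        )
        coords = rng.normal(scale=500, size=(pair_system.n_particles, 3))
        assert sc.crosslink_scores(coords)[0] == 0


class TestExcludedVolume:
    def test_separated_particles_score_zero(self):
        sys_ = bead_system([("A", 3, 1)])
        coords = np.array([[0, 0, 0], [20, 0, 0], [40, 0, 0]], dtype=float)
        sc = Scorer(sys_, RestraintSet())
        assert sc.excluded_volume_score(coords) == 0

    def test_overlap_penalty_quadratic(self):
        # two beads three residues apart in sequence (not adjacent)
        sys_ = bead_system([("A", 4, 1)])
        sys_.radii[:] = 3.0
        sc = Scorer(sys_, RestraintSet(k_ev=1.0))
        coords = np.array(
            [[0, 0, 0], [100, 0, 0], [200, 0, 0], [4.0, 0, 0]], dtype=float
        )
        # only pair (1st, 4th) overlaps: (3+3-4)^2 = 4
        assert sc.excluded_volume_score(coords) == pytest.approx(4.0)

    def test_sequence_adjacent_pairs_exempt(self):
        sys_ = bead_system([("A", 2, 1)])
        sc = Scorer(sys_, RestraintSet())
        coords = np.array([[0, 0, 0], [0.1, 0, 0]])
        assert sc.excluded_volume_score(coords) == 0

    def test_same_rigid_body_exempt(self, rng):
        from xlwalk.representation import Molecule, Segment, Topology, build_system
        from tests.conftest import structure_from_chains

        st = structure_from_chains({"A": rng.normal(scale=1.0, size=(5, 3))})
        topo = Topology(
            (Molecule("M", 5, (Segment(1, 5, "rigid", structure="s", chain="A"),)),)
        )
        sys_ = build_system(topo, {"s": st})
        sc = Scorer(sys_, RestraintSet())
        assert sc.excluded_volume_score(sys_.coords) == 0


class TestConnectivity:
    def test_within_allowance_scores_zero(self):
        sys_ = bead_system([("A", 2, 1)])
        sc = Scorer(sys_, RestraintSet())
        coords = np.array([[0, 0, 0], [5.0, 0, 0]])
        # U = 2 * 3.166 + 3.8 = 10.13: comfortably slack
        assert sc.connectivity_score(coords) == 0

    def test_stretch_penalty_closed_form(self):
        sys_ = bead_system([("A", 2, 1)])
        sc = Scorer(sys_, RestraintSet(k_conn=4.0))
        u = 2 * bead_radius(1) + 3.8
        d = u + 2.0
        coords = np.array([[0, 0, 0], [d, 0, 0]])
        assert sc.connectivity_score(coords) == pytest.approx(4.0 * 4.0)

    def test_single_particle_chain_scores_zero(self):
        sys_ = bead_system([("A", 1, 1)])
        sc = Scorer(sys_, RestraintSet())
        assert sc.connectivity_score(sys_.coords) == 0

    def test_gap_scales_allowance(self):
        from xlwalk.representation import Molecule, Segment, Topology, build_system

        # 2 beads of 5 residues each: centers span g=5 residues
        topo = Topology(
            (Molecule("A", 10, (Segment(1, 10, "beads", residues_per_bead=5),)),)
        )
        sys_ = build_system(topo)
        sc = Scorer(sys_, RestraintSet(k_conn=1.0))
        u = 2 * bead_radius(5) + 3.8 * 5
        coords = np.array([[0, 0, 0], [u + 3.0, 0, 0]])
        assert sc.connectivity_score(coords) == pytest.approx(9.0)


class TestTotalScore:
    def brute_force(self, sys_, rs, coords):
        """Independent loop-based re-implementation of the total score."""
        n = sys_.n_particles
        ev = 0.0
        adjacent = set()
        for key in sorted(sys_.chains):
            order = sys_.chains[key]
            for a, b in zip(order[:-1], order[1:]):
                adjacent.add(frozenset((int(a), int(b))))
        for i in range(n):
            for j in range(i + 1, n):
                if sys_.body_id[i] == sys_.body_id[j] and sys_.body_id[i] >= 0:
                    continue
                if sys_.fixed[i] and sys_.fixed[j]:
                    continue
                if frozenset((i, j)) in adjacent:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                ov = sys_.radii[i] + sys_.radii[j] - rs.ev_slack - d
                if ov > 0:
                    ev += rs.k_ev * ov**2
        conn = 0.0
        for key in sorted(sys_.chains):
            order = sys_.chains[key]
            for a, b in zip(order[:-1], order[1:]):
                if sys_.fixed[a] and sys_.fixed[b]:
                    continue
                pa, pb = sys_.particles[a], sys_.particles[b]
                g = max(
                    1.0,
                    (pb.res_first + pb.res_last) / 2
                    - (pa.res_first + pa.res_last) / 2,
                )
                u = sys_.radii[a] + sys_.radii[b] + rs.c * g
                st = np.linalg.norm(coords[a] - coords[b]) - u
                if st > 0:
                    conn += rs.k_conn * st**2
        xls = 0.0
        for li, li_link in enumerate(rs.crosslinks):
            best = np.inf
            for c1 in range(sys_.copy_count(li_link.protein1)):
                k1 = (li_link.protein1, c1, li_link.residue1)
                if k1 not in sys_.residue_map:
                    continue
                for c2 in range(sys_.copy_count(li_link.protein2)):
                    k2 = (li_link.protein2, c2, li_link.residue2)
                    if k2 not in sys_.residue_map:
                        continue
                    p1, p2 = sys_.residue_map[k1], sys_.residue_map[k2]
                    if p1 == p2:
                        continue
                    best = min(best, np.linalg.norm(coords[p1] - coords[p2]))
            ex = max(0.0, best - li_link.threshold(rs.thresholds))
            xls += rs.k_xl * ex**2
        return rs.w_xl * xls + rs.w_ev * ev + rs.w_conn * conn

    def test_all_zero_terms_give_zero_total(self):
        sys_ = bead_system([("A", 3, 1)])
        coords = np.array([[0, 0, 0], [8, 0, 0], [16, 0, 0]], dtype=float)
        sb = Scorer(sys_, RestraintSet()).total(coords)
        assert sb.total == 0

    def test_weight_linearity(self, pair_system):
        coords = np.zeros((pair_system.n_particles, 3))
        coords[pair_system.residue_map[("L", 0, 1)]] = (45, 0, 0)
        coords[pair_system.residue_map[("L", 1, 1)]] = (45, 100, 0)
        rs1 = RestraintSet(crosslinks=(link(L=35.0),), w_xl=1.0)
        rs2 = RestraintSet(crosslinks=(link(L=35.0),), w_xl=2.0)
        t1 = Scorer(pair_system, rs1).total(coords)
        t2 = Scorer(pair_system, rs2).total(coords)
        assert t2.total == pytest.approx(2 * t1.total)
        assert t2.crosslink == pytest.approx(t1.crosslink)  # raw term unweighted

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(100):
            sys_ = bead_system([("R", 3, 1), ("L", 4, 2)], seed=trial)
            rs = RestraintSet(
                crosslinks=(link(1, 2, L=8.0), link(3, 4, L=5.0)),
                k_ev=0.7, k_conn=1.3, w_xl=1.5, w_ev=0.8, w_conn=2.0,
            )
            coords = rng.normal(scale=8, size=(sys_.n_particles, 3))
            sb = Scorer(sys_, rs).total(coords)
            assert sb.total == pytest.approx(
                self.brute_force(sys_, rs, coords), rel=1e-9, abs=1e-9
            )

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        sys_ = bead_system([("R", 2, 1), ("L", 5, 2)], seed=7)
        rs = RestraintSet(crosslinks=(link(1, 3, L=6.0),))
        coords = rng.normal(scale=6, size=(sys_.n_particles, 3))
        sb = Scorer(sys_, rs).total(coords)
        R = Rotation.random(random_state=3).as_matrix()
        moved = coords @ R.T + np.array([11.0, -4.0, 2.5])
        sb2 = Scorer(sys_, rs).total(moved)
        for a, b in zip(sb.as_dict().values(), sb2.as_dict().values()):
            assert a == pytest.approx(b, abs=1e-6)

    def test_score_continuous_at_flat_bottom_boundary(self, pair_system):
        sc = Scorer(pair_system, RestraintSet(crosslinks=(link(L=35.0),)))
        eps = 1e-7
        coords = np.zeros((pair_system.n_particles, 3))
        coords[pair_system.residue_map[("L", 1, 1)]] = (500, 0, 0)
        vals = []
        for d in (35.0 - eps, 35.0, 35.0 + eps):
            coords[pair_system.residue_map[("L", 0, 1)]] = (d, 0, 0)
            vals.append(sc.crosslink_scores(coords)[0])
        assert vals[0] == 0 and vals[1] == 0
        assert vals[2] == pytest.approx(0.0, abs=1e-10)

    def test_local_energy_delta_matches_full_delta(self, rng):
        sys_ = bead_system([("R", 2, 1), ("L", 6, 2)], seed=9)
        rs = RestraintSet(crosslinks=(link(1, 2, L=6.0), link(2, 5, L=7.0)))
        sc = Scorer(sys_, rs)
        coords = rng.normal(scale=5, size=(sys_.n_particles, 3))
        for _ in range(50):
            i = int(rng.integers(sys_.n_particles))
            moved = np.array([i])
            before_local = sc.local_energy(coords, moved)
            before_full = sc.total(coords).total
            new = coords.copy()
            new[i] += rng.normal(scale=3, size=3)
            after_local = sc.local_energy(new, moved)
            after_full = sc.total(new).total
            assert after_local - before_local == pytest.approx(
                after_full - before_full, rel=1e-9, abs=1e-9
            )
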