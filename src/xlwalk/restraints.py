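"""Scoring: crosslink, excluded-volume, and sequence-connectivity restraints.

All three terms are flat-bottom harmonic penalties (score units per A^2):

* crosslink -- ``k_xl * max(0, d_min - L)^2`` on the *ambiguous minimum*
  endpoint distance ``d_min`` (minimum over all chain-copy combinations),
  with per-linker cap ``L``;
* excluded volume -- ``k_ev * max(0, r_i + r_j - slack - d_ij)^2`` summed over
  unordered particle pairs that are neither in the same rigid body nor
  sequence-adjacent;
* connectivity -- for consecutive chain particles spanning ``g`` residues,
  ``k_conn * max(0, d - (r_i + r_j + c*g))^2`` with ``c`` the Calpha virtual
  bond length, including bead-to-rigid anchor bonds.

The :class:`Scorer` precomputes pair bookkeeping once per system and offers
both a full score breakdown and the local energy of a particle subset, which
is what makes incremental Monte Carlo updates cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from xlwalk.representation import CA_STEP_A, SystemModel
from xlwalk.xlinks import DEFAULT_THRESHOLDS, Crosslink, MappingError


@dataclass
class RestraintSet:
    """Restraint parameters for one sampling run."""

    crosslinks: tuple[Crosslink, ...] = ()
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    k_xl: float = 1.0
    k_ev: float = 1.0
    ev_slack: float = 0.0
    c: float = CA_STEP_A
    k_conn: float = 1.0
    w_xl: float = 1.0
    w_ev: float = 1.0
    w_conn: float = 1.0

    def __post_init__(self) -> None:
        self.crosslinks = tuple(self.crosslinks)
        if min(self.k_xl, self.k_ev, self.k_conn) < 0:
            raise ValueError("force constants must be >= 0")
        if self.c <= 0:
            raise ValueError("per-residue connectivity length must be > 0")
        for xl in self.crosslinks:
            if xl.threshold_override is None and xl.linker not in self.thresholds:
                raise ValueError(f"no threshold for linker {xl.linker}")
            if xl.threshold(self.thresholds) <= 0:
                raise ValueError("crosslink thresholds must be > 0")


@dataclass(frozen=True)
class ScoreBreakdown:
    total: float
    crosslink: float
    excluded_volume: float
    connectivity: float
    per_crosslink: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total,
            "crosslink": self.crosslink,
            "excluded_volume": self.excluded_volume,
            "connectivity": self.connectivity,
        }


class Scorer:
    """Precomputed scoring engine for one (system, restraint set) pair."""

    def __init__(self, system: SystemModel, restraints: RestraintSet):
        self.system = system
        self.restraints = restraints
        n = system.n_particles
        self.radii = system.radii
        self.body = system.body_id

        # connectivity bonds: consecutive particles along every chain copy;
        # bonds internal to the fixed scaffold carry no sampled degree of
        # freedom and are excluded from the score
        bi, bj, gaps = [], [], []
        for key in sorted(system.chains):
            order = system.chains[key]
            for a, b in zip(order[:-1], order[1:]):
                if system.fixed[a] and system.fixed[b]:
                    continue
                pa, pb = system.particles[a], system.particles[b]
                bi.append(a)
                bj.append(b)
                # residues spanned center-to-center between the two particles
                g = (pb.res_first + pb.res_last) / 2 - (pa.res_first + pa.res_last) / 2
                gaps.append(max(1.0, g))
        self.bond_i = np.array(bi, dtype=int)
        self.bond_j = np.array(bj, dtype=int)
        gaps_arr = np.array(gaps, dtype=float) if gaps else np.empty(0)
        self.bond_U = (
            self.radii[self.bond_i] + self.radii[self.bond_j]
            + restraints.c * gaps_arr
        ) if len(bi) else np.empty(0)
        self._bonds_of: list[list[int]] = [[] for _ in range(n)]
        for k, (a, b) in enumerate(zip(self.bond_i, self.bond_j)):
            self._bonds_of[a].append(k)
            self._bonds_of[b].append(k)

        # sequence-adjacency matrix entries exempt from excluded volume
        self._adjacent: list[set[int]] = [set() for _ in range(n)]
        for a, b in zip(self.bond_i, self.bond_j):
            self._adjacent[a].add(b)
            self._adjacent[b].add(a)

        # crosslink endpoint candidates (per copy), resolved once
        self._xl_p1: list[np.ndarray] = []
        self._xl_p2: list[np.ndarray] = []
        self._xl_L = np.empty(len(restraints.crosslinks))
        self._links_of: list[set[int]] = [set() for _ in range(n)]
        for li, xl in enumerate(restraints.crosslinks):
            p1 = self._endpoint(xl.protein1, xl.residue1)
            p2 = self._endpoint(xl.protein2, xl.residue2)
            self._xl_p1.append(p1)
            self._xl_p2.append(p2)
            self._xl_L[li] = xl.threshold(restraints.thresholds)
            for p in np.concatenate([p1, p2]):
                self._links_of[int(p)].add(li)

    def _endpoint(self, protein: str, residue: int) -> np.ndarray:
        sm = self.system
        idxs = [
            sm.residue_map[(protein, c, residue)]
            for c in range(sm.copy_count(protein))
            if (protein, c, residue) in sm.residue_map
        ]
        if not idxs:
            raise MappingError(f"endpoint {protein}:{residue} is not mapped")
        return np.array(idxs, dtype=int)

    # -- per-term scores ---------------------------------------------------

    def crosslink_distances(self, coords: np.ndarray) -> np.ndarray:
        """Ambiguous minimum distance per crosslink for one configuration."""
        out = np.empty(len(self._xl_p1))
        for li, (p1, p2) in enumerate(zip(self._xl_p1, self._xl_p2)):
            d = cdist(coords[p1], coords[p2])
            if p1.size and p2.size:
                same = p1[:, None] == p2[None, :]
                d = np.where(same, np.inf, d)
            out[li] = d.min()
        return out

    def crosslink_scores(self, coords: np.ndarray) -> np.ndarray:
        d = self.crosslink_distances(coords)
        excess = np.maximum(0.0, d - self._xl_L)
        return self.restraints.k_xl * excess**2

    def excluded_volume_score(self, coords: np.ndarray) -> float:
        n = len(coords)
        if n < 2:
            return 0.0
        d = cdist(coords, coords)
        overlap = self.radii[:, None] + self.radii[None, :] \
            - self.restraints.ev_slack - d
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        same_body = (self.body[:, None] == self.body[None, :]) \
            & (self.body[:, None] >= 0)
        mask &= ~same_body
        fixed = self.system.fixed
        mask &= ~(fixed[:, None] & fixed[None, :])  # static scaffold pairs
        for a in range(n):
            for b in self._adjacent[a]:
                mask[a, b] = mask[b, a] = False
        viol = np.maximum(0.0, overlap[mask])
        return float(self.restraints.k_ev * np.sum(viol**2))

    def connectivity_score(self, coords: np.ndarray) -> float:
        if not len(self.bond_i):
            return 0.0
        d = np.linalg.norm(coords[self.bond_i] - coords[self.bond_j], axis=1)
        stretch = np.maximum(0.0, d - self.bond_U)
        return float(self.restraints.k_conn * np.sum(stretch**2))

    def total(self, coords: np.ndarray) -> ScoreBreakdown:
        """Full weighted score with per-term and per-crosslink breakdown."""
        per_xl = self.crosslink_scores(coords)
        xl = float(per_xl.sum())
        ev = self.excluded_volume_score(coords)
        conn = self.connectivity_score(coords)
        r = self.restraints
        return ScoreBreakdown(
            total=r.w_xl * xl + r.w_ev * ev + r.w_conn * conn,
            crosslink=xl,
            excluded_volume=ev,
            connectivity=conn,
            per_crosslink=per_xl,
        )

    # -- local energy for incremental Monte Carlo --------------------------

    def local_energy(self, coords: np.ndarray, moved: np.ndarray) -> float:
        """Weighted energy of all terms that can change when ``moved`` moves.

        Covers excluded-volume pairs between the moved set and the rest,
        connectivity bonds touching the set, and every crosslink whose
        candidate endpoints intersect it. Terms internal to a rigid body are
        invariant under its moves and may be counted or not; they cancel in
        before/after differences.
        """
        r = self.restraints
        e = 0.0
        moved = np.asarray(moved, dtype=int)
        in_set = np.zeros(len(coords), dtype=bool)
        in_set[moved] = True
        # excluded volume: moved vs outside
        for s in moved:
            dvec = np.linalg.norm(coords - coords[s], axis=1)
            overlap = self.radii + self.radii[s] - r.ev_slack - dvec
            ok = ~in_set
            if self.body[s] >= 0:
                ok &= self.body != self.body[s]
            adj = self._adjacent[s]
            if adj:
                ok[list(adj)] = False
            viol = np.maximum(0.0, overlap[ok])
            e += r.w_ev * r.k_ev * float(np.sum(viol**2))
        # connectivity bonds touching the set
        bond_ids = sorted({k for s in moved for k in self._bonds_of[s]})
        if bond_ids:
            bi = self.bond_i[bond_ids]
            bj = self.bond_j[bond_ids]
            d = np.linalg.norm(coords[bi] - coords[bj], axis=1)
            stretch = np.maximum(0.0, d - self.bond_U[bond_ids])
            e += r.w_conn * r.k_conn * float(np.sum(stretch**2))
        # crosslinks whose ambiguity set touches the moved particles
        link_ids = sorted({li for s in moved for li in self._links_of[s]})
        for li in link_ids:
            p1, p2 = self._xl_p1[li], self._xl_p2[li]
            d = cdist(coords[p1], coords[p2])
            same = p1[:, None] == p2[None, :]
            d = np.where(same, np.inf, d)
            excess = max(0.0, float(d.min()) - self._xl_L[li])
            e += r.w_xl * r.k_xl * excess**2
        return e


# convenience wrappers mirroring the functional interface -------------------


def crosslink_score(
    system: SystemModel,
    coords: np.ndarray,
    crosslink: Crosslink,
    L: float | None = None,
    k: float = 1.0,
) -> float:
    """Flat-bottom harmonic score of one crosslink on one configuration."""
    rs = RestraintSet(crosslinks=(crosslink,), k_xl=k)
    if L is not None:
        rs = RestraintSet(
            crosslinks=(Crosslink(
                crosslink.protein1, crosslink.residue1,
                crosslink.protein2, crosslink.residue2,
                crosslink.linker, crosslink.psm_count, crosslink.q_value,
                threshold_override=L,
            ),),
            k_xl=k,
        )
    return float(Scorer(system, rs).crosslink_scores(coords)[0])


def excluded_volume_score(
    system: SystemModel, coords: np.ndarray, k_ev: float = 1.0, slack: float = 0.0
) -> float:
    rs = RestraintSet(k_ev=k_ev, ev_slack=slack)
    return Scorer(system, rs).excluded_volume_score(coords)


def connectivity_score(
    system: SystemModel, coords: np.ndarray, c: float = CA_STEP_A, k_conn: float = 1.0
) -> float:
    rs = RestraintSet(c=c, k_conn=k_conn)
    return Scorer(system, rs).connectivity_score(coords)


def total_score(
    system: SystemModel, coords: np.ndarray, restraints: RestraintSet
) -> ScoreBreakdown:
    return Scorer(system, restraints).total(coords)
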