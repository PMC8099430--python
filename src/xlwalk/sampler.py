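"""Seeded Metropolis Monte Carlo with simulated annealing.

Move set: Gaussian translations of individual beads, and rigid-body moves
(Gaussian translation plus rotation about the body centroid) for mobile rigid
segments. Fixed particles (the receptor scaffold) never move. Acceptance uses
the Metropolis rule at the current annealing temperature; energies are score
units, so temperature is in score units as well.

One Monte Carlo *step* attempts one randomly chosen move per mover (the
random-scan convention of integrative-modeling samplers), so a step is a
sweep over the system's degrees of freedom regardless of its size. The inner
loop runs in a compiled kernel (:mod:`xlwalk._mc`).

Each run draws from an independent pseudo-random stream derived from
``(master_seed, run_index)``, so a pool of runs is reproducible run-by-run
and independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from xlwalk.representation import SystemModel
from xlwalk.restraints import RestraintSet, ScoreBreakdown, Scorer


class NonFiniteScoreError(RuntimeError):
    """Sampling hit a non-finite energy; carries a diagnostic snapshot."""

    def __init__(self, message: str, coords: np.ndarray, step: int):
        super().__init__(f"{message} at step {step}")
        self.coords = coords
        self.step = step


def geometric_schedule(
    t_start: float = 5.0, t_end: float = 1.0, n_stages: int = 10, n_steps: int = 0
) -> list[tuple[float, int]]:
    """Geometric temperature ladder with ``n_steps`` split evenly over stages."""
    temps = t_start * (t_end / t_start) ** (np.arange(n_stages) / max(1, n_stages - 1))
    base = n_steps // n_stages
    extra = n_steps - base * n_stages
    return [(float(t), base + (1 if i < extra else 0)) for i, t in enumerate(temps)]


@dataclass
class SamplerConfig:
    n_steps: int = 20_000
    schedule: list[tuple[float, int]] | None = None  # derived if None
    t_start: float = 5.0
    t_end: float = 1.0
    n_stages: int = 10
    bead_sigma: float = 2.0
    rigid_trans_sigma: float = 1.0
    rigid_rot_sigma_deg: float = 5.0
    record_every: int = 100
    seed: int = 0
    keep_top: int | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.schedule is None:
            self.schedule = geometric_schedule(
                self.t_start, self.t_end, self.n_stages, self.n_steps
            )
        if any(t <= 0 for t, _ in self.schedule):
            raise ValueError("temperatures must be > 0")


@dataclass
class GoodScoringCriteria:
    """Definition of a good-scoring model.

    A model qualifies when the fraction of crosslinks with ambiguous minimum
    distance <= L + ``tol`` is at least ``min_fraction`` (1.0 means every
    link), and the excluded-volume and connectivity scores do not exceed
    their caps. Caps scale with the number of mobile particles: thermal
    fluctuation at the final sampling temperature deposits about half a score
    unit per soft degree of freedom.
    """

    min_fraction: float = 0.9
    tol: float = 0.0
    ev_cap_per_particle: float = 0.5
    conn_cap_per_particle: float = 0.5


@dataclass
class ModelEnsemble:
    """Immutable pool of coordinate snapshots with scores and provenance."""

    system: SystemModel
    coords: np.ndarray  # (n_models, n_particles, 3)
    scores: list[ScoreBreakdown]
    provenance: list[tuple[int, int]]  # (run_index, step)
    seeds: list[tuple[int, int]] = field(default_factory=list)
    acceptance_rate: float | None = None
    good: np.ndarray | None = None

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def subset(self, idx: np.ndarray) -> "ModelEnsemble":
        idx = np.asarray(idx)
        return ModelEnsemble(
            system=self.system,
            coords=self.coords[idx].copy(),
            scores=[self.scores[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
            seeds=list(self.seeds),
            acceptance_rate=self.acceptance_rate,
            good=None if self.good is None else self.good[idx].copy(),
        )


def _movable_units(system: SystemModel) -> list[np.ndarray]:
    units: list[np.ndarray] = []
    for i in range(system.n_particles):
        if system.body_id[i] < 0 and not system.fixed[i]:
            units.append(np.array([i]))
    for bid, idxs in system.bodies().items():
        if not system.fixed[idxs].any():
            units.append(idxs)
    return units


def _csr(lists: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    ptr = np.zeros(len(lists) + 1, dtype=np.int64)
    for i, lst in enumerate(lists):
        ptr[i + 1] = ptr[i] + len(lst)
    idx = np.empty(ptr[-1], dtype=np.int64)
    for i, lst in enumerate(lists):
        idx[ptr[i]:ptr[i + 1]] = list(lst)
    return ptr, idx


def mc_run(
    system: SystemModel,
    restraints: RestraintSet,
    config: SamplerConfig,
    run_index: int = 0,
) -> ModelEnsemble:
    """One annealed Metropolis run; deterministic given (seed, run_index).

    The initial configuration is always recorded; thereafter one snapshot is
    taken every ``record_every`` steps (accepted or not). Snapshot scores are
    evaluated with the full (vectorized) scorer, so they are exactly the
    restraint-set breakdown, not an incremental estimate.
    """
    from xlwalk._mc import mc_kernel

    scorer = Scorer(system, restraints)
    coords = system.coords.copy()
    units = _movable_units(system)
    if not units and config.n_steps > 0:
        raise ValueError("no mobile particles to sample")

    n_snaps = 1
    if config.record_every and config.n_steps:
        n_snaps += config.n_steps // config.record_every
    snaps = np.empty((n_snaps, system.n_particles, 3))
    snaps[0] = coords
    nonfinite = -1
    n_acc = n_att = 0

    if config.n_steps > 0:
        adj_ptr, adj_idx = _csr([sorted(s) for s in scorer._adjacent])
        l1_ptr, l1_idx = _csr([list(p) for p in scorer._xl_p1])
        l2_ptr, l2_idx = _csr([list(p) for p in scorer._xl_p2])
        mover_ptr, mover_idx = _csr([list(u) for u in units])
        mb_ptr, mb_idx = _csr(
            [sorted({k for s in u for k in scorer._bonds_of[s]}) for u in units]
        )
        ml_ptr, ml_idx = _csr(
            [sorted({li for s in u for li in scorer._links_of[s]}) for u in units]
        )
        temps = np.array([t for t, _ in config.schedule])
        stage_steps = np.array([s for _, s in config.schedule], dtype=np.int64)
        seed32 = int(
            np.random.SeedSequence([config.seed, run_index]).generate_state(1)[0]
        )
        r = restraints
        n_acc, n_att, nonfinite = mc_kernel(
            coords, system.radii, system.body_id.astype(np.int64),
            system.fixed,
            adj_ptr, adj_idx,
            scorer.bond_i.astype(np.int64), scorer.bond_j.astype(np.int64),
            np.asarray(scorer.bond_U, dtype=float),
            l1_ptr, l1_idx, l2_ptr, l2_idx,
            np.asarray(scorer._xl_L, dtype=float),
            mover_ptr, mover_idx, mb_ptr, mb_idx, ml_ptr, ml_idx,
            temps, stage_steps,
            config.bead_sigma, config.rigid_trans_sigma,
            math.radians(config.rigid_rot_sigma_deg),
            r.k_ev, r.ev_slack, r.k_conn, r.k_xl, r.w_ev, r.w_conn, r.w_xl,
            int(config.record_every or 0), snaps, seed32,
        )
        if nonfinite >= 0:
            raise NonFiniteScoreError("non-finite score change", coords.copy(),
                                      int(nonfinite))

    scores = [scorer.total(snaps[i]) for i in range(n_snaps)]
    prov = [(run_index, i * (config.record_every or 0)) for i in range(n_snaps)]
    return ModelEnsemble(
        system=system,
        coords=snaps,
        scores=scores,
        provenance=prov,
        seeds=[(config.seed, run_index)],
        acceptance_rate=n_acc / n_att if n_att else None,
    )


def filter_good_scoring(
    ensemble: ModelEnsemble,
    criteria: GoodScoringCriteria | None = None,
    restraints: RestraintSet | None = None,
) -> ModelEnsemble:
    """Keep models meeting the good-scoring criteria. Idempotent.

    ``restraints`` defaults to reconstructing the crosslink distances from the
    stored per-model scores; passing the original restraint set re-evaluates
    distances explicitly (required when ``tol`` differs from zero).
    """
    crit = criteria or GoodScoringCriteria()
    n_mobile = int((~ensemble.system.fixed).sum())
    ev_cap = crit.ev_cap_per_particle * n_mobile
    conn_cap = crit.conn_cap_per_particle * n_mobile

    keep = []
    if restraints is not None and len(restraints.crosslinks):
        scorer = Scorer(ensemble.system, restraints)
        L = scorer._xl_L
        for m in range(ensemble.n_models):
            d = scorer.crosslink_distances(ensemble.coords[m])
            frac = float(np.mean(d <= L + crit.tol))
            sb = ensemble.scores[m]
            if (
                frac >= crit.min_fraction
                and sb.excluded_volume <= ev_cap
                and sb.connectivity <= conn_cap
            ):
                keep.append(m)
    else:
        # fall back to the stored per-crosslink scores: satisfied <=> zero
        for m in range(ensemble.n_models):
            sb = ensemble.scores[m]
            n_xl = len(sb.per_crosslink)
            frac = float(np.mean(sb.per_crosslink <= 0)) if n_xl else 1.0
            if (
                frac >= crit.min_fraction
                and sb.excluded_volume <= ev_cap
                and sb.connectivity <= conn_cap
            ):
                keep.append(m)
    out = ensemble.subset(np.array(keep, dtype=int))
    out.good = np.ones(len(keep), dtype=bool)
    return out


def pool_runs(ensembles: Sequence[ModelEnsemble]) -> ModelEnsemble:
    """Concatenate run ensembles; order is (run, snapshot), provenance kept."""
    if not ensembles:
        raise ValueError("no ensembles to pool")
    first = ensembles[0]
    for e in ensembles[1:]:
        if e.system.n_particles != first.system.n_particles:
            raise ValueError("topology mismatch between pooled runs")
        if [
            (p.molecule, p.copy, p.res_first, p.res_last)
            for p in e.system.particles
        ] != [
            (p.molecule, p.copy, p.res_first, p.res_last)
            for p in first.system.particles
        ]:
            raise ValueError("topology mismatch between pooled runs")
    nonempty = [e for e in ensembles if e.n_models]
    if not nonempty:
        return ModelEnsemble(first.system, np.empty((0, first.system.n_particles, 3)),
                             [], [], seeds=[s for e in ensembles for s in e.seeds])
    goods = [
        e.good if e.good is not None else np.zeros(e.n_models, dtype=bool)
        for e in nonempty
    ]
    any_good = any(e.good is not None for e in nonempty)
    return ModelEnsemble(
        system=first.system,
        coords=np.concatenate([e.coords for e in nonempty]),
        scores=[s for e in nonempty for s in e.scores],
        provenance=[p for e in nonempty for p in e.provenance],
        seeds=[s for e in ensembles for s in e.seeds],
        acceptance_rate=None,
        good=np.concatenate(goods) if any_good else None,
    )


def sample_ensemble(
    system: SystemModel,
    restraints: RestraintSet,
    config: SamplerConfig,
    n_runs: int = 4,
    criteria: GoodScoringCriteria | None = None,
) -> tuple[ModelEnsemble, ModelEnsemble]:
    """Run ``n_runs`` independent annealing runs; return (all, good) pools.

    Within each run, good-scoring models are selected by ``criteria`` and
    optionally truncated to the ``keep_top`` best by total score before
    pooling.
    """
    all_runs, good_runs = [], []
    for r in range(n_runs):
        ens = mc_run(system, restraints, config, run_index=r)
        all_runs.append(ens)
        good = filter_good_scoring(ens, criteria, restraints)
        if config.keep_top is not None and good.n_models > config.keep_top:
            order = np.argsort([s.total for s in good.scores], kind="stable")
            good = good.subset(order[: config.keep_top])
        good_runs.append(good)
    return pool_runs(all_runs), pool_runs(good_runs)
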