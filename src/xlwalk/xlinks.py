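"""Crosslink identification tables: parsing, FDR/PSM filtering, satisfaction.

Crosslinking mass spectrometry reports residue pairs joined by a chemical
linker (DSS joins lysine amines, EDC joins carboxyls to amines). Each linker
chemistry implies a maximum Calpha-Calpha span; a crosslink is *satisfied* by
a structural model when the minimum Calpha (or bead-center) distance over all
chain-copy combinations -- and, for an ensemble, over all member models --
does not exceed the linker threshold. Evidence filtering follows the standard
proteomics rule: peptide-level q-value at most ``q_max`` and at least
``min_psms`` peptide-spectrum matches per unique residue pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from xlwalk.representation import SystemModel

logger = logging.getLogger(__name__)

LINKERS = ("DSS", "EDC")

#: Default Calpha-Calpha satisfaction thresholds (angstrom) per linker.
#: DSS spans ~11.4 A between primary amines; with two lysine side chains and
#: backbone allowance the customary Calpha cap is 35 A. EDC is zero-length,
#: giving the customary 25 A Calpha cap. Both are configurable per run.
DEFAULT_THRESHOLDS: dict[str, float] = {"DSS": 35.0, "EDC": 25.0}

#: Default CSV column mapping (ProXL-style export).
DEFAULT_COLUMNS: dict[str, str] = {
    "protein1": "protein_1",
    "residue1": "position_1",
    "protein2": "protein_2",
    "residue2": "position_2",
    "linker": "linker",
    "q_value": "q_value",
    "psm_count": "psm_count",
}


class CrosslinkFormatError(ValueError):
    """Malformed table: missing columns or invalid field values."""


class MappingError(KeyError):
    """A crosslink endpoint cannot be resolved to any model particle."""


class ConfigError(ValueError):
    """Inconsistent run configuration (e.g. linker without a threshold)."""


@dataclass(frozen=True)
class PsmRecord:
    """One aggregated peptide-pair row from a crosslink identification table."""

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    linker: str
    q_value: float
    psm_count: int
    source_row: str = ""

    def __post_init__(self) -> None:
        if self.linker not in LINKERS:
            raise CrosslinkFormatError(
                f"unknown linker {self.linker!r} ({self.source_row}); "
                f"expected one of {LINKERS}"
            )
        if not (0.0 <= self.q_value <= 1.0):
            raise CrosslinkFormatError(
                f"q_value {self.q_value} outside [0, 1] ({self.source_row})"
            )
        if self.residue1 < 1 or self.residue2 < 1:
            raise CrosslinkFormatError(
                f"residue positions must be >= 1 ({self.source_row})"
            )
        if self.psm_count < 1:
            raise CrosslinkFormatError(
                f"psm_count must be positive ({self.source_row})"
            )


def _canonical_pair(
    p1: str, r1: int, p2: str, r2: int
) -> tuple[str, int, str, int]:
    """Lexicographic canonical order so A-B and B-A denote the same link."""
    if (p1, r1) <= (p2, r2):
        return p1, r1, p2, r2
    return p2, r2, p1, r1


@dataclass(frozen=True)
class Crosslink:
    """A unique residue-pair distance restraint with aggregated evidence.

    The endpoint pair is stored in canonical (lexicographic) order, so the
    identity of a link does not depend on the orientation it was reported in.
    Self-links (identical protein and residue) are rejected.
    """

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    linker: str
    psm_count: int = 1
    q_value: float = 0.0
    threshold_override: float | None = None

    def __post_init__(self) -> None:
        if (self.protein1, self.residue1) == (self.protein2, self.residue2):
            raise CrosslinkFormatError(
                f"self-link rejected: {self.protein1}:{self.residue1}"
            )
        canon = _canonical_pair(
            self.protein1, self.residue1, self.protein2, self.residue2
        )
        if canon != (self.protein1, self.residue1, self.protein2, self.residue2):
            object.__setattr__(self, "protein1", canon[0])
            object.__setattr__(self, "residue1", canon[1])
            object.__setattr__(self, "protein2", canon[2])
            object.__setattr__(self, "residue2", canon[3])
        if self.linker not in LINKERS:
            raise CrosslinkFormatError(f"unknown linker {self.linker!r}")

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.protein1, self.residue1), (self.protein2, self.residue2)

    def threshold(self, thresholds: Mapping[str, float] | None = None) -> float:
        if self.threshold_override is not None:
            return self.threshold_override
        table = DEFAULT_THRESHOLDS if thresholds is None else thresholds
        if self.linker not in table:
            raise ConfigError(f"no distance threshold configured for {self.linker}")
        return float(table[self.linker])


@dataclass(frozen=True)
class MinDistanceResult:
    """Minimum ambiguous distance and the argmin provenance."""

    distance: float
    copy1: int
    copy2: int
    model_index: int


@dataclass(frozen=True)
class SatisfactionRecord:
    crosslink: Crosslink
    min_distance: float
    threshold: float
    status: str  # "satisfied" | "violated" | "unmappable"
    best_copy_pair: tuple[int, int] = (-1, -1)
    best_model_index: int = -1

    def __post_init__(self) -> None:
        if self.status in ("satisfied", "violated"):
            want = "satisfied" if self.min_distance <= self.threshold else "violated"
            if self.status != want:
                raise ValueError("status inconsistent with distance/threshold")


def parse_psm_table(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[PsmRecord]:
    """Read a crosslink PSM table (CSV/TSV) into records.

    Parameters
    ----------
    path : str or file-like
        Table with one aggregated peptide-pair per row.
    columns : mapping, optional
        Logical-field -> column-name overrides (see ``DEFAULT_COLUMNS``).
    sep : str, optional
        Field separator; inferred from the header when omitted.

    Raises
    ------
    CrosslinkFormatError
        If a required column is missing or any row holds an invalid value;
        the error message lists offending row numbers.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        # still validate the header before returning an empty list
        colmap = dict(DEFAULT_COLUMNS)
        if columns:
            colmap.update(columns)
        missing = [c for c in colmap.values() if c not in df.columns]
        if missing:
            raise CrosslinkFormatError(
                f"missing required column(s): {', '.join(missing)}"
            )
        logger.warning("crosslink table %s contains a header but no rows", path)
        return []
    return parse_psm_table_from_frame(df, columns=columns)


def parse_psm_table_from_frame(
    df: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> list[PsmRecord]:
    """Validate an in-memory crosslink table (same contract as the file parser)."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise CrosslinkFormatError(
            f"missing required column(s): {', '.join(missing)}"
        )

    records: list[PsmRecord] = []
    bad: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        data = dict(zip(df.columns, row))
        try:
            records.append(
                PsmRecord(
                    protein1=str(data[colmap["protein1"]]).strip(),
                    residue1=int(data[colmap["residue1"]]),
                    protein2=str(data[colmap["protein2"]]).strip(),
                    residue2=int(data[colmap["residue2"]]),
                    linker=str(data[colmap["linker"]]).strip().upper(),
                    q_value=float(data[colmap["q_value"]]),
                    psm_count=int(data[colmap["psm_count"]]),
                    source_row=f"row {i}",
                )
            )
        except (CrosslinkFormatError, ValueError, TypeError) as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise CrosslinkFormatError(
            "malformed rows in crosslink table:\n" + "\n".join(bad)
        )
    return records


def filter_psms(
    records: Iterable[PsmRecord],
    q_max: float = 0.01,
    min_psms: int = 2,
) -> list[Crosslink]:
    """Apply the evidence filter and deduplicate to unique residue pairs.

    A unique (canonically ordered) residue pair + linker is kept when its best
    (minimum) q-value is <= ``q_max`` and its total PSM count across all rows
    (both endpoint orientations) is >= ``min_psms``. Defaults reproduce the
    standard rule: peptide-level q <= 0.01 and at least two PSMs.
    """
    agg: dict[tuple, list[PsmRecord]] = {}
    for rec in records:
        key = _canonical_pair(
            rec.protein1, rec.residue1, rec.protein2, rec.residue2
        ) + (rec.linker,)
        agg.setdefault(key, []).append(rec)

    out: list[Crosslink] = []
    for (p1, r1, p2, r2, linker), rows in sorted(agg.items()):
        if (p1, r1) == (p2, r2):
            continue  # self-link: not a distance restraint
        best_q = min(r.q_value for r in rows)
        total_psms = sum(r.psm_count for r in rows)
        if best_q <= q_max and total_psms >= min_psms:
            out.append(
                Crosslink(p1, r1, p2, r2, linker, psm_count=total_psms, q_value=best_q)
            )
    return out


def _endpoint_particles(
    system: "SystemModel", protein: str, residue: int
) -> dict[int, int]:
    """copy index -> particle index for one endpoint; empty if unmapped."""
    out: dict[int, int] = {}
    for copy in range(system.copy_count(protein)):
        idx = system.residue_map.get((protein, copy, residue))
        if idx is not None:
            out[copy] = idx
    return out


def min_pair_distance(
    model_or_ensemble,
    crosslink: Crosslink,
    system: "SystemModel",
    copies1: Sequence[int] | None = None,
    copies2: Sequence[int] | None = None,
) -> MinDistanceResult:
    """Minimum Euclidean endpoint distance over copy pairs (and models).

    Ambiguity rule: a crosslink satisfied by *any* chain copy counts, so the
    relevant distance is the minimum over every combination of copies of the
    two endpoint molecules, and over every member model of an ensemble. Ties
    resolve to the lowest (model, copy1, copy2) tuple.

    Parameters
    ----------
    model_or_ensemble : (n_particles, 3) or (n_models, n_particles, 3) array
        Coordinates in angstrom.
    system : SystemModel
        Supplies the residue -> particle map.
    copies1, copies2 : sequence of int, optional
        Restrict the ambiguity scope to these copy indices (default: all).
    """
    coords = np.asarray(model_or_ensemble, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    cand1 = _endpoint_particles(system, crosslink.protein1, crosslink.residue1)
    cand2 = _endpoint_particles(system, crosslink.protein2, crosslink.residue2)
    if copies1 is not None:
        cand1 = {c: i for c, i in cand1.items() if c in set(copies1)}
    if copies2 is not None:
        cand2 = {c: i for c, i in cand2.items() if c in set(copies2)}
    if not cand1:
        raise MappingError(
            f"endpoint {crosslink.protein1}:{crosslink.residue1} is not mapped"
        )
    if not cand2:
        raise MappingError(
            f"endpoint {crosslink.protein2}:{crosslink.residue2} is not mapped"
        )

    best = MinDistanceResult(math.inf, -1, -1, -1)
    i1 = np.array(sorted(cand1))
    i2 = np.array(sorted(cand2))
    p1 = np.array([cand1[c] for c in i1])
    p2 = np.array([cand2[c] for c in i2])
    for m in range(coords.shape[0]):
        d = np.linalg.norm(
            coords[m, p1][:, None, :] - coords[m, p2][None, :, :], axis=-1
        )
        # exclude the degenerate same-particle combination (intra-molecular
        # link where both endpoints share a copy is fine; same particle is not)
        same = p1[:, None] == p2[None, :]
        d = np.where(same, np.inf, d)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        if d[a, b] < best.distance:
            best = MinDistanceResult(float(d[a, b]), int(i1[a]), int(i2[b]), m)
    if not math.isfinite(best.distance):
        raise MappingError(
            f"no valid copy pair for crosslink {crosslink.pair}"
        )
    return best


def satisfaction_report(
    model_or_ensemble,
    crosslinks: Sequence[Crosslink],
    system: "SystemModel",
    thresholds: Mapping[str, float] | None = None,
) -> tuple[list[SatisfactionRecord], float]:
    """Classify each unique crosslink against a model or ensemble.

    Returns one record per crosslink (input order) plus the satisfied
    fraction. Links whose endpoints cannot be mapped to any particle are
    reported with status ``unmappable`` and excluded from the denominator.
    """
    table = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    for xl in crosslinks:
        xl.threshold(table)  # raises ConfigError early for missing linkers
    records: list[SatisfactionRecord] = []
    n_sat = 0
    n_mappable = 0
    for xl in crosslinks:
        thr = xl.threshold(table)
        try:
            res = min_pair_distance(model_or_ensemble, xl, system)
        except MappingError:
            records.append(
                SatisfactionRecord(xl, math.nan, thr, "unmappable")
            )
            continue
        n_mappable += 1
        status = "satisfied" if res.distance <= thr else "violated"
        n_sat += status == "satisfied"
        records.append(
            SatisfactionRecord(
                xl,
                res.distance,
                thr,
                status,
                best_copy_pair=(res.copy1, res.copy2),
                best_model_index=res.model_index,
            )
        )
    fraction = n_sat / n_mappable if n_mappable else 0.0
    return records, fraction


def satisfaction_table(records: Sequence[SatisfactionRecord]) -> pd.DataFrame:
    """Satisfaction records as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "protein_1": [r.crosslink.protein1 for r in records],
            "position_1": [r.crosslink.residue1 for r in records],
            "protein_2": [r.crosslink.protein2 for r in records],
            "position_2": [r.crosslink.residue2 for r in records],
            "linker": [r.crosslink.linker for r in records],
            "min_distance_A": [r.min_distance for r in records],
            "threshold_A": [r.threshold for r in records],
            "status": [r.status for r in records],
            "best_copy_1": [r.best_copy_pair[0] for r in records],
            "best_copy_2": [r.best_copy_pair[1] for r in records],
            "best_model": [r.best_model_index for r in records],
        }
    )


def pseudobond_lines(
    records: Sequence[SatisfactionRecord],
    chain_of: Mapping[tuple[str, int], str],
    satisfied_color: str = "cyan",
    violated_color: str = "purple",
) -> list[str]:
    """Pseudo-bond annotation lines (atomspec atomspec color) for viewers.

    ``chain_of`` maps (protein, copy) to a chain identifier; the best copy
    pair of each record selects the chains.
    """
    lines = []
    for r in records:
        if r.status == "unmappable":
            continue
        c1 = chain_of[(r.crosslink.protein1, r.best_copy_pair[0])]
        c2 = chain_of[(r.crosslink.protein2, r.best_copy_pair[1])]
        color = satisfied_color if r.status == "satisfied" else violated_color
        lines.append(
            f"/{c1}:{r.crosslink.residue1}@CA /{c2}:{r.crosslink.residue2}@CA {color}"
        )
    return lines
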