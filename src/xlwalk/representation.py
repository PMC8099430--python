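"""Hybrid system representation: rigid bodies plus flexible bead chains.

A molecule is divided into contiguous residue segments. Segments with known
coordinates become *rigid bodies* (one Calpha particle per residue, moving as
a unit); unresolved segments become *bead chains* (one particle per
``residues_per_bead`` residues, each free to move). A global
(molecule, copy, residue) -> particle map supports crosslink restraints and
selections. Coordinates are angstrom, right-handed, in the frame of the
source structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

#: Average amino-acid volume (A^3) used for volume-equivalent bead radii.
RESIDUE_VOLUME_A3 = 132.3

#: Calpha-Calpha virtual bond length (A per residue).
CA_STEP_A = 3.8


class TopologyError(ValueError):
    """Invalid topology: bad ranges, overlaps, or unknown references."""


class ReferenceError_(KeyError):
    """A rigid segment references a missing structure or chain."""


def bead_radius(n_residues: int, v_res: float = RESIDUE_VOLUME_A3) -> float:
    """Radius (A) of a sphere with the volume of ``n_residues`` residues."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return (3.0 * n_residues * v_res / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class Segment:
    """Contiguous residue range with a representation choice.

    ``kind`` is "rigid" (coordinates taken from ``structure``/``chain``) or
    "beads" (coarse-grained spheres, ``residues_per_bead`` residues each).
    """

    start: int
    end: int
    kind: str
    structure: str | None = None
    chain: str | None = None
    residues_per_bead: int = 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise TopologyError(f"invalid residue range [{self.start},{self.end}]")
        if self.kind not in ("rigid", "beads"):
            raise TopologyError(f"unknown segment kind {self.kind!r}")
        if self.kind == "rigid" and (self.structure is None or self.chain is None):
            raise TopologyError("rigid segment requires structure and chain")
        if self.kind == "beads" and self.residues_per_bead < 1:
            raise TopologyError("residues_per_bead must be >= 1")

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Molecule:
    name: str
    length: int
    segments: tuple[Segment, ...]
    copy_count: int = 1
    fixed: bool = False
    anchor_xyz: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.copy_count < 1:
            raise TopologyError("copy_count must be >= 1")
        spans = sorted((s.start, s.end) for s in self.segments)
        prev_end = 0
        for a, b in spans:
            if a <= prev_end:
                raise TopologyError(
                    f"overlapping segments in molecule {self.name!r} at residue {a}"
                )
            if b > self.length:
                raise TopologyError(
                    f"segment [{a},{b}] exceeds molecule length {self.length}"
                )
            prev_end = b


@dataclass(frozen=True)
class Topology:
    molecules: tuple[Molecule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecules", tuple(self.molecules))
        names = [m.name for m in self.molecules]
        if len(set(names)) != len(names):
            raise TopologyError("duplicate molecule names in topology")

    def molecule(self, name: str) -> Molecule:
        for m in self.molecules:
            if m.name == name:
                return m
        raise TopologyError(f"no molecule named {name!r}")


@dataclass
class Particle:
    """Metadata for one particle (rigid Calpha or bead)."""

    molecule: str
    copy: int
    res_first: int
    res_last: int
    kind: str  # "rigid" | "bead"


@dataclass
class SystemModel:
    """Flattened particle system with residue map and body bookkeeping.

    Attributes
    ----------
    coords : (N, 3) float array
    radii : (N,) float array
    particles : list of Particle metadata, index-aligned with coords
    body_id : (N,) int array; particles sharing a non-negative id move as one
        rigid unit, -1 marks independent beads
    fixed : (N,) bool array; fixed particles never move
    residue_map : dict (molecule, copy, residue) -> particle index
    chains : dict (molecule, copy) -> particle indices in sequence order
    """

    topology: Topology
    coords: np.ndarray
    radii: np.ndarray
    particles: list[Particle]
    body_id: np.ndarray
    fixed: np.ndarray
    residue_map: dict[tuple[str, int, int], int]
    chains: dict[tuple[str, int], np.ndarray]

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def copy_count(self, molecule: str) -> int:
        return self.topology.molecule(molecule).copy_count

    def bodies(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        for bid in np.unique(self.body_id):
            if bid >= 0:
                out[int(bid)] = np.flatnonzero(self.body_id == bid)
        return out

    def bounding_box(self, margin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        pad = self.radii.max() + margin
        return self.coords.min(axis=0) - pad, self.coords.max(axis=0) + pad

    def select(
        self,
        molecule: str | None = None,
        copies: Sequence[int] | None = None,
        residues: Iterable[int] | None = None,
    ) -> np.ndarray:
        """Particle indices matching the filters, in system order."""
        res_set = None if residues is None else set(residues)
        copy_set = None if copies is None else set(copies)
        out = []
        for i, p in enumerate(self.particles):
            if molecule is not None and p.molecule != molecule:
                continue
            if copy_set is not None and p.copy not in copy_set:
                continue
            if res_set is not None and not (
                res_set & set(range(p.res_first, p.res_last + 1))
            ):
                continue
            out.append(i)
        return np.array(out, dtype=int)


def _read_rigid_calphas(
    structure: gemmi.Structure, chain: str, start: int, end: int
) -> tuple[np.ndarray, list[int]]:
    model = structure[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ReferenceError_(
            f"chain {chain!r} not found in structure {structure.name!r}"
        )
    coords, resnums = [], []
    for res in ch:
        num = res.seqid.num
        if start <= num <= end:
            atom = res.find_atom("CA", "*")
            if atom is None:
                atom = res.find_atom("BB", "*")
            if atom is None:
                continue
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            resnums.append(num)
    if not coords:
        raise ReferenceError_(
            f"no CA particles for {chain}:{start}-{end} in {structure.name!r}"
        )
    return np.array(coords, dtype=float), resnums


def _load_structures(structures: Mapping[str, object]) -> dict[str, gemmi.Structure]:
    out = {}
    for key, val in (structures or {}).items():
        if isinstance(val, gemmi.Structure):
            out[key] = val
        else:
            out[key] = gemmi.read_structure(str(val))
    return out


def _self_avoiding_extend(
    existing: np.ndarray,
    existing_radii: np.ndarray,
    start: np.ndarray,
    n_steps: int,
    step: float,
    radius: float,
    rng: np.random.Generator,
    overlap_scale: float = 0.8,
    max_tries: int = 200,
) -> np.ndarray:
    """Grow a random walk avoiding existing particles (soft, with fallback)."""
    placed: list[np.ndarray] = []
    pos = np.asarray(start, dtype=float)
    for _ in range(n_steps):
        best, best_clearance = None, -np.inf
        for _attempt in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = pos + step * u
            mind = np.inf
            if existing.size:
                mind = np.min(
                    np.linalg.norm(existing - cand, axis=1)
                    - overlap_scale * (existing_radii + radius)
                )
            if placed:
                mind = min(
                    mind,
                    np.min(np.linalg.norm(np.array(placed) - cand, axis=1))
                    - overlap_scale * 2 * radius,
                )
            if mind > best_clearance:
                best, best_clearance = cand, mind
            if mind > 0:
                break
        placed.append(best)
        pos = best
    return np.array(placed).reshape(n_steps, 3)


def build_system(
    topology: Topology,
    structures: Mapping[str, object] | None = None,
    seed: int = 0,
) -> SystemModel:
    """Instantiate particles for every molecule copy in the topology.

    Rigid segments contribute one Calpha particle per resolved residue,
    grouped into one rigid body per (segment, copy). Bead segments contribute
    ``ceil(n_residues / residues_per_bead)`` spheres placed on a seeded
    self-avoiding random walk anchored to the adjacent rigid particles (or to
    the molecule anchor point for fully flexible chains).
    """
    structs = _load_structures(structures or {})
    rng = np.random.default_rng(seed)

    coords: list[np.ndarray] = []
    radii: list[float] = []
    particles: list[Particle] = []
    body_ids: list[int] = []
    fixed_flags: list[bool] = []
    residue_map: dict[tuple[str, int, int], int] = {}
    chains: dict[tuple[str, int], np.ndarray] = {}
    next_body = 0

    for mol in topology.molecules:
        segments = sorted(mol.segments, key=lambda s: s.start)
        for copy in range(mol.copy_count):
            chain_indices: list[int] = []
            # first pass: rigid segments (their coordinates anchor the beads)
            seg_particles: dict[int, list[int]] = {}
            for si, seg in enumerate(segments):
                if seg.kind != "rigid":
                    continue
                if seg.structure not in structs:
                    raise ReferenceError_(
                        f"structure {seg.structure!r} not provided"
                    )
                xyz, resnums = _read_rigid_calphas(
                    structs[seg.structure], seg.chain, seg.start, seg.end
                )
                idxs = []
                for row, num in zip(xyz, resnums):
                    idx = len(particles)
                    coords.append(row)
                    radii.append(bead_radius(1))
                    particles.append(Particle(mol.name, copy, num, num, "rigid"))
                    body_ids.append(next_body)
                    fixed_flags.append(mol.fixed)
                    residue_map[(mol.name, copy, num)] = idx
                    idxs.append(idx)
                seg_particles[si] = idxs
                next_body += 1
            # second pass: bead segments, anchored to neighbours
            for si, seg in enumerate(segments):
                if seg.kind != "beads":
                    continue
                rpb = seg.residues_per_bead
                n_beads = math.ceil(seg.n_residues / rpb)
                rad = bead_radius(min(rpb, seg.n_residues))
                # anchor: end of previous rigid segment, else start of next,
                # else molecule anchor, else a seeded point near the origin
                anchor = None
                reverse = False
                if si - 1 in seg_particles:
                    anchor = coords[seg_particles[si - 1][-1]]
                elif si + 1 in seg_particles:
                    anchor = coords[seg_particles[si + 1][0]]
                    reverse = True
                elif mol.anchor_xyz is not None:
                    anchor = np.array(mol.anchor_xyz, dtype=float)
                else:
                    anchor = rng.normal(scale=5.0, size=3)
                existing = (
                    np.array(coords) if coords else np.empty((0, 3))
                )
                existing_r = np.array(radii) if radii else np.empty(0)
                walk = _self_avoiding_extend(
                    existing,
                    existing_r,
                    anchor,
                    n_beads,
                    step=CA_STEP_A * rpb,
                    radius=rad,
                    rng=rng,
                )
                if reverse:
                    walk = walk[::-1]
                spans = [
                    (
                        seg.start + b * rpb,
                        min(seg.start + (b + 1) * rpb - 1, seg.end),
                    )
                    for b in range(n_beads)
                ]
                for (ra, rb), row in zip(spans, walk):
                    idx = len(particles)
                    coords.append(np.asarray(row, dtype=float))
                    radii.append(bead_radius(rb - ra + 1))
                    particles.append(Particle(mol.name, copy, ra, rb, "bead"))
                    body_ids.append(-1)
                    fixed_flags.append(mol.fixed)
                    for r in range(ra, rb + 1):
                        residue_map[(mol.name, copy, r)] = idx
            chain_indices = sorted(
                (i for i, p in enumerate(particles)
                 if p.molecule == mol.name and p.copy == copy),
                key=lambda i: particles[i].res_first,
            )
            chains[(mol.name, copy)] = np.array(chain_indices, dtype=int)

    return SystemModel(
        topology=topology,
        coords=np.array(coords, dtype=float).reshape(len(particles), 3),
        radii=np.array(radii, dtype=float),
        particles=particles,
        body_id=np.array(body_ids, dtype=int),
        fixed=np.array(fixed_flags, dtype=bool),
        residue_map=residue_map,
        chains=chains,
    )


def clone_copies(
    system: SystemModel,
    molecule: str,
    n: int,
    transforms: Sequence[object] | None = None,
    seed: int = 0,
) -> SystemModel:
    """Return a system in which ``molecule`` has ``n`` copies in total.

    New copies duplicate the particles of copy 0; their coordinates are
    produced by the supplied rigid ``transforms`` (one per added copy, objects
    with an ``apply(coords)`` method) or, if omitted, by seeded random offsets
    sized to the system bounding box.
    """
    if n < 1:
        raise ValueError("copy count must be >= 1")
    mol = system.topology.molecule(molecule)
    if n < mol.copy_count:
        raise ValueError("cannot reduce copies with clone_copies")
    rng = np.random.default_rng(seed)
    n_new = n - mol.copy_count
    if transforms is not None and len(transforms) != n_new:
        raise ValueError(f"expected {n_new} transforms, got {len(transforms)}")

    new_mols = tuple(
        Molecule(m.name, m.length, m.segments, n if m.name == molecule else m.copy_count,
                 m.fixed, m.anchor_xyz)
        for m in system.topology.molecules
    )
    topo = Topology(new_mols)

    coords = list(system.coords)
    radii = list(system.radii)
    particles = list(system.particles)
    body_ids = list(system.body_id)
    fixed_flags = list(system.fixed)
    residue_map = dict(system.residue_map)
    chains = dict(system.chains)
    next_body = int(system.body_id.max(initial=-1)) + 1

    src_idx = [i for i, p in enumerate(system.particles)
               if p.molecule == molecule and p.copy == 0]
    src_coords = system.coords[src_idx]
    extent = np.ptp(system.coords, axis=0).max() + 20.0

    for k in range(n_new):
        copy = mol.copy_count + k
        if transforms is not None:
            new_xyz = transforms[k].apply(src_coords)
        else:
            new_xyz = src_coords + rng.uniform(-extent, extent, size=3)
        body_remap: dict[int, int] = {}
        chain_indices = []
        for local, i in enumerate(src_idx):
            p = system.particles[i]
            idx = len(particles)
            coords.append(new_xyz[local])
            radii.append(system.radii[i])
            particles.append(Particle(p.molecule, copy, p.res_first, p.res_last, p.kind))
            old_bid = int(system.body_id[i])
            if old_bid >= 0:
                if old_bid not in body_remap:
                    body_remap[old_bid] = next_body
                    next_body += 1
                body_ids.append(body_remap[old_bid])
            else:
                body_ids.append(-1)
            fixed_flags.append(bool(system.fixed[i]))
            for r in range(p.res_first, p.res_last + 1):
                residue_map[(molecule, copy, r)] = idx
            chain_indices.append(idx)
        chains[(molecule, copy)] = np.array(
            sorted(chain_indices, key=lambda j: particles[j].res_first), dtype=int
        )

    return SystemModel(
        topology=topo,
        coords=np.array(coords, dtype=float).reshape(len(particles), 3),
        radii=np.array(radii, dtype=float),
        particles=particles,
        body_id=np.array(body_ids, dtype=int),
        fixed=np.array(fixed_flags, dtype=bool),
        residue_map=residue_map,
        chains=chains,
    )


# ---------------------------------------------------------------------------
# PDB input/output


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def chain_assignment(system: SystemModel) -> dict[tuple[str, int], str]:
    """Stable (molecule, copy) -> single-character chain id mapping."""
    keys = sorted(system.chains)
    if len(keys) > len(_CHAIN_IDS):
        raise ValueError("too many chains for single-character PDB chain ids")
    return {key: _CHAIN_IDS[i] for i, key in enumerate(keys)}


def _system_to_gemmi(
    system: SystemModel, coords_models: np.ndarray
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "xlwalk"
    assign = chain_assignment(system)
    for m in range(coords_models.shape[0]):
        model = gemmi.Model(m + 1)
        for key in sorted(system.chains):
            chain = gemmi.Chain(assign[key])
            for i in system.chains[key]:
                p = system.particles[i]
                res = gemmi.Residue()
                res.name = "ALA" if p.kind == "rigid" else "BEA"
                res.seqid = gemmi.SeqId(p.res_first, " ")
                atom = gemmi.Atom()
                atom.name = "CA" if p.kind == "rigid" else "BB"
                atom.element = gemmi.Element("C")
                x, y, z = coords_models[m, i]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = float(system.radii[i])
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_system_pdb(
    system: SystemModel, path: str | Path, coords_models: np.ndarray | None = None
) -> None:
    """Write the system (or an ensemble of coordinate snapshots) as PDB.

    Beads are emitted as pseudo-atoms named ``BB`` in residues named ``BEA``,
    numbered by the first residue of their span; rigid particles as ``CA``.
    """
    if coords_models is None:
        coords_models = system.coords[None]
    coords_models = np.asarray(coords_models, dtype=float)
    if coords_models.ndim == 2:
        coords_models = coords_models[None]
    st = _system_to_gemmi(system, coords_models)
    st.write_pdb(str(path))


def read_ensemble_coords(path: str | Path, system: SystemModel) -> np.ndarray:
    """Read coordinates written by :func:`write_system_pdb` back in system order."""
    st = gemmi.read_structure(str(path))
    assign = chain_assignment(system)
    rev = {v: k for k, v in assign.items()}
    out = np.zeros((len(st), system.n_particles, 3))
    for m, model in enumerate(st):
        for chain in model:
            key = rev[chain.name]
            order = system.chains[key]
            if len(chain) != len(order):
                raise ValueError(f"chain {chain.name} length mismatch on re-read")
            for res, idx in zip(chain, order):
                atom = res[0]
                out[m, idx] = (atom.pos.x, atom.pos.y, atom.pos.z)
    return out
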