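"""Quantitative comparison of conformational states.

Tools for the questions one asks of two structures of the same assembly:
how do they superpose (least-squares, proper rotation), how far does a
component's center of mass move once a shared frame is established, what
screw motion (twist, rise, axis) relates consecutive filament subunits and
hence the helical pitch, how much surface area is buried at an interface
(Shrake-Rupley solvent accessibility), and how far ring subunits sit from
ideal lattice positions after aligning a subset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

PROBE_RADIUS_A = 1.4
DEFAULT_SPHERE_POINTS = 960
INTERFACE_CUTOFF_A = 4.5

#: Heavy-atom van der Waals radii (A), NACCESS-style united-atom flavor.
ELEMENT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "SE": 1.90, "FE": 1.80, "ZN": 1.39, "MG": 1.73,
}
DEFAULT_RADIUS = 1.70


class DegenerateInputError(ValueError):
    """Too few or collinear points for a well-defined superposition."""


class DegenerateScrewError(ValueError):
    """Near-identity rotation: screw axis undefined."""


@dataclass(frozen=True)
class Transform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray  # (3,3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation matrix must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: x -> self(other(x))."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class ScrewParameters:
    """Screw decomposition of a rigid transform.

    ``twist`` is the rotation angle in degrees, in (0, 180]; ``rise`` the
    translation component along the (unit) rotation ``axis``; ``point`` a
    point on the screw axis (the one minimizing the perpendicular
    translation).
    """

    twist: float
    rise: float
    axis: np.ndarray
    point: np.ndarray

    def to_transform(self) -> Transform:
        R = Rotation.from_rotvec(np.radians(self.twist) * self.axis).as_matrix()
        t = self.rise * self.axis + (np.eye(3) - R) @ self.point
        return Transform(R, t)


@dataclass(frozen=True)
class InterfaceReport:
    buried_area: float  # both-sides: SASA(A)+SASA(B)-SASA(AB)
    sasa_a_free: float
    sasa_b_free: float
    sasa_a_complexed: float
    sasa_b_complexed: float
    interface_residues_a: tuple[tuple[str, int, str], ...]
    interface_residues_b: tuple[tuple[str, int, str], ...]

    @property
    def buried_per_side(self) -> tuple[float, float]:
        return (
            self.sasa_a_free - self.sasa_a_complexed,
            self.sasa_b_free - self.sasa_b_complexed,
        )


# -- superposition and screw geometry ----------------------------------------


def superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[Transform, float]:
    """Least-squares transform mapping B onto A, and the residual RMSD.

    Both inputs are paired point sets; an optional index ``selection``
    restricts the fit to a subset (applied to both). At least three
    non-collinear points are required for a unique rotation.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise DegenerateInputError("paired selections differ in length")
    if len(a) < 3:
        raise DegenerateInputError("need at least 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    sv = np.linalg.svd(a - ca, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("collinear points: rotation underdetermined")
    rot, _ = Rotation.align_vectors(a - ca, b - cb)
    R = rot.as_matrix()
    t = ca - R @ cb
    tr = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(b) - a) ** 2, axis=1))))
    return tr, rmsd


def com_displacement(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    align_selection: np.ndarray,
    component_selection: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Center-of-mass shift of a component between two aligned states.

    State B is superposed onto state A over ``align_selection``; the reported
    value is |COM(component, B aligned) - COM(component, A)|, by default an
    unweighted mean over the selected (Calpha) positions.
    """
    component_selection = np.asarray(component_selection, dtype=int)
    if component_selection.size == 0:
        raise ValueError("empty component selection")
    tr, _ = superpose(coords_a, coords_b, align_selection)
    b_aligned = tr.apply(np.asarray(coords_b, dtype=float)[component_selection])
    a_sel = np.asarray(coords_a, dtype=float)[component_selection]
    w = None if weights is None else np.asarray(weights, dtype=float)[component_selection]
    com_b = np.average(b_aligned, axis=0, weights=w)
    com_a = np.average(a_sel, axis=0, weights=w)
    return float(np.linalg.norm(com_b - com_a))


def screw_parameters(
    transform: Transform, angle_tol_deg: float = 1e-3
) -> ScrewParameters:
    """Decompose a rigid transform into twist, rise, axis and axis point."""
    rotvec = Rotation.from_matrix(transform.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if math.degrees(angle) <= angle_tol_deg:
        raise DegenerateScrewError(
            "rotation angle below tolerance: screw axis undefined"
        )
    axis = rotvec / angle
    t = transform.translation
    rise = float(np.dot(t, axis))
    t_perp = t - rise * axis
    # axis point p solves (I - R) p = t_perp within the plane normal to axis
    point = np.linalg.pinv(np.eye(3) - transform.rotation) @ t_perp
    return ScrewParameters(math.degrees(angle), rise, axis, point)


def helical_pitch(twist: float, rise: float) -> tuple[float, float]:
    """Helical pitch (A/turn) and subunits per turn from twist (deg), rise (A)."""
    if twist <= 0:
        raise ValueError("twist must be > 0")
    return rise * 360.0 / twist, 360.0 / twist


# -- solvent accessibility ----------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS_A,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    Each atom's expanded sphere (radius + probe) is sampled with a fixed
    golden-spiral point set; a point is accessible when it lies outside every
    neighbor's expanded sphere. Area_i = exposed fraction x 4 pi (r_i+probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be > 0")
    n = len(coords)
    unit = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(n)
    rmax = expanded.max()
    for i in range(n):
        ri = expanded[i]
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        pts = coords[i] + ri * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        out[i] = exposed.mean() * 4.0 * np.pi * ri**2
    return out


def _structure_atoms(
    structure, chains: Sequence[str] | None = None, include_h: bool = False
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    """Coordinates, radii and (chain, resnum, resname) labels of atoms."""
    st = _as_structure(structure)
    chain_set = None if chains is None else set(chains)
    coords, radii, labels = [], [], []
    for chain in st[0]:
        if chain_set is not None and chain.name not in chain_set:
            continue
        for res in chain:
            if res.is_water():
                continue
            for atom in res:
                elem = atom.element.name.upper()
                if elem == "H" and not include_h:
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(ELEMENT_RADII.get(elem, DEFAULT_RADIUS))
                labels.append((chain.name, res.seqid.num, res.name))
    return np.array(coords, dtype=float), np.array(radii, dtype=float), labels


def _as_structure(structure) -> gemmi.Structure:
    if isinstance(structure, gemmi.Structure):
        return structure
    return gemmi.read_structure(str(structure))


def buried_area(
    structure,
    chain_set_a: Sequence[str],
    chain_set_b: Sequence[str],
    probe: float = PROBE_RADIUS_A,
    n_points: int = DEFAULT_SPHERE_POINTS,
    cutoff: float = INTERFACE_CUTOFF_A,
) -> InterfaceReport:
    """Interface burial between two disjoint chain sets of one structure.

    The headline number is the both-sides buried area
    SASA(A) + SASA(B) - SASA(A u B); the per-side halves are recoverable from
    the free/complexed chain totals in the report. Interface residues are
    those with any atom within ``cutoff`` of the partner set.
    """
    if set(chain_set_a) & set(chain_set_b):
        raise ValueError("chain sets must be disjoint")
    st = _as_structure(structure)
    ca, ra, la = _structure_atoms(st, chain_set_a)
    cb, rb, lb = _structure_atoms(st, chain_set_b)
    if not len(ca) or not len(cb):
        raise ValueError("empty chain set")
    sasa_a = sasa(ca, ra, probe, n_points)
    sasa_b = sasa(cb, rb, probe, n_points)
    both = sasa(np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, n_points)
    sasa_a_cplx = both[: len(ca)].sum()
    sasa_b_cplx = both[len(ca):].sum()

    tree_b = cKDTree(cb)
    pairs_a = tree_b.query_ball_point(ca, cutoff)
    res_a = sorted({la[i] for i, hits in enumerate(pairs_a) if hits})
    tree_a = cKDTree(ca)
    pairs_b = tree_a.query_ball_point(cb, cutoff)
    res_b = sorted({lb[i] for i, hits in enumerate(pairs_b) if hits})

    return InterfaceReport(
        buried_area=float(sasa_a.sum() + sasa_b.sum() - both.sum()),
        sasa_a_free=float(sasa_a.sum()),
        sasa_b_free=float(sasa_b.sum()),
        sasa_a_complexed=float(sasa_a_cplx),
        sasa_b_complexed=float(sasa_b_cplx),
        interface_residues_a=tuple(res_a),
        interface_residues_b=tuple(res_b),
    )


# -- lattice register and residue context -------------------------------------


def mt_register_displacement(
    ring_positions: np.ndarray,
    reference_positions: np.ndarray,
    align_pairs: Sequence[tuple[int, int]] | Sequence[int],
) -> tuple[np.ndarray, float]:
    """Per-subunit displacement from ideal lattice register after alignment.

    The ring is superposed onto the reference lattice using only the
    ``align_pairs`` (ring index, reference index) correspondences; every ring
    subunit is then compared with its reference site. Returns the per-subunit
    displacements and their maximum.
    """
    ring = np.asarray(ring_positions, dtype=float)
    ref = np.asarray(reference_positions, dtype=float)
    if ring.shape != ref.shape:
        raise ValueError("ring and reference site counts differ")
    pairs = [
        (p, p) if np.isscalar(p) else tuple(p) for p in align_pairs
    ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 alignment pairs")
    ri = np.array([p[0] for p in pairs])
    fi = np.array([p[1] for p in pairs])
    a, b = ref[fi], ring[ri]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 2-point fits leave a free spin
        rot, _ = Rotation.align_vectors(a - ca, b - cb)
    tr = Transform(rot.as_matrix(), ca - rot.as_matrix() @ cb)
    moved = tr.apply(ring)
    disp = np.linalg.norm(moved - ref, axis=1)
    return disp, float(disp.max())


@dataclass(frozen=True)
class SiteContext:
    mapped: bool
    distances: Mapping[str, float]
    within_interface: bool


def site_context(
    structure,
    chain: str,
    residue: int,
    partner_chains: Sequence[str],
    cutoff: float = INTERFACE_CUTOFF_A,
) -> SiteContext:
    """Minimum heavy-atom distance from one residue to each partner chain.

    A residue absent from the model is reported as unmapped rather than
    raising, because annotation sweeps routinely hit unresolved sites.
    """
    st = _as_structure(structure)
    ch = st[0].find_chain(chain)
    site_atoms = []
    if ch is not None:
        for res in ch:
            if res.seqid.num == residue:
                site_atoms.extend(
                    [a.pos.x, a.pos.y, a.pos.z]
                    for a in res
                    if a.element.name.upper() != "H"
                )
    if not site_atoms:
        return SiteContext(False, {}, False)
    site = np.array(site_atoms)
    distances = {}
    for pc in partner_chains:
        coords, _, _ = _structure_atoms(st, [pc])
        if not len(coords):
            distances[pc] = math.inf
            continue
        d = np.linalg.norm(site[:, None, :] - coords[None, :, :], axis=-1)
        distances[pc] = float(d.min())
    within = any(d <= cutoff for d in distances.values())
    return SiteContext(True, distances, within)


# -- selections ---------------------------------------------------------------


def parse_selection(expr: str) -> list[tuple[str, int | None, int | None]]:
    """Parse ``A:52-276+B:178-342`` into (chain, start, end) triples.

    A bare chain id selects the whole chain; ``A:10`` selects one residue.
    """
    out = []
    for part in expr.split("+"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            out.append((part, None, None))
            continue
        chain, rng = part.split(":", 1)
        if "-" in rng:
            a, b = rng.split("-", 1)
            out.append((chain, int(a), int(b)))
        else:
            out.append((chain, int(rng), int(rng)))
    if not out:
        raise ValueError(f"empty selection expression: {expr!r}")
    return out


def select_ca(structure, expr: str) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Calpha coordinates and (chain, resnum) labels for a selection string."""
    st = _as_structure(structure)
    coords, labels = [], []
    for chain_name, start, end in parse_selection(expr):
        ch = st[0].find_chain(chain_name)
        if ch is None:
            raise KeyError(f"chain {chain_name!r} not in structure")
        for res in ch:
            num = res.seqid.num
            if start is not None and not (start <= num <= end):
                continue
            atom = res.find_atom("CA", "*")
            if atom is None:
                atom = res.find_atom("BB", "*")
            if atom is None:
                continue
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            labels.append((chain_name, num))
    return np.array(coords, dtype=float), labels
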