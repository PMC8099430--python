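"""Ensemble analysis: clustering, localization densities, difference maps.

Good-scoring model pools are summarized two ways. First, models are grouped
by structural similarity (RMSD over a particle selection, no superposition --
the receptor frame is shared) with a deterministic greedy centroid algorithm;
cluster occupancies say how much of the ensemble one structural solution
explains. Second, the per-voxel occupancy of a component across the ensemble
("localization density") gives the spatial envelope the component explores;
it is contoured relative to its own maximum and written as MRC for standard
viewers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Clustering:
    labels: np.ndarray  # cluster id per model, 0 = largest-neighborhood first
    sizes: tuple[int, ...]
    occupancies: tuple[float, ...]
    centroid_indices: tuple[int, ...]
    rmsd_threshold: float


@dataclass
class DensityGrid:
    """Voxelized scalar field. ``origin`` is the center of voxel (0,0,0)."""

    origin: np.ndarray  # (3,) angstrom
    voxel: float  # angstrom, isotropic
    values: np.ndarray  # (nx, ny, nz) float32

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.voxel <= 0:
            raise ValueError("voxel size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.voxel * np.arange(self.shape[k])
            for k in range(3)
        )

    def value_at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel lookup; zero outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint((pts - self.origin) / self.voxel).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.zeros(len(pts))
        if ok.any():
            sel = idx[ok]
            out[ok] = self.values[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def normalized(self, divisor: float) -> "DensityGrid":
        """Scaled copy, e.g. counts -> probability with divisor=n_models."""
        return DensityGrid(self.origin.copy(), self.voxel, self.values / divisor)

    def same_geometry(self, other: "DensityGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel - other.voxel) <= tol
            and np.allclose(self.origin, other.origin, atol=tol)
        )


# -- structural similarity ---------------------------------------------------


def pairwise_rmsd(
    model_a: np.ndarray, model_b: np.ndarray, selection: np.ndarray | None = None
) -> float:
    """RMSD over selected particle centers, without superposition."""
    a = np.asarray(model_a, dtype=float)
    b = np.asarray(model_b, dtype=float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise ValueError("selection cardinality mismatch between models")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    m = coords.shape[0]
    flat = coords.reshape(m, -1)
    sq = np.sum(flat**2, axis=1)
    g = flat @ flat.T
    d2 = np.maximum(0.0, sq[:, None] + sq[None, :] - 2 * g) / coords.shape[1]
    return np.sqrt(d2)


def cluster_models(
    models,
    rmsd_threshold: float = 10.0,
    selection: np.ndarray | None = None,
) -> Clustering:
    """Greedy centroid clustering at an RMSD threshold.

    The model with the largest neighborhood (most models within the
    threshold; ties to the lowest index) seeds cluster 0 and claims its
    neighbors; the procedure repeats on the remainder. Deterministic given
    model order and threshold.
    """
    coords = models.coords if hasattr(models, "coords") else np.asarray(models)
    if coords.ndim != 3 or coords.shape[0] < 1:
        raise ValueError("need at least one model of shape (n_particles, 3)")
    sel = coords if selection is None else coords[:, selection]
    m = sel.shape[0]
    dist = _rmsd_matrix(sel)
    within = dist <= rmsd_threshold

    labels = np.full(m, -1, dtype=int)
    remaining = np.ones(m, dtype=bool)
    sizes, centroids = [], []
    cluster = 0
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = within[seed] & remaining
        labels[members] = cluster
        sizes.append(int(members.sum()))
        centroids.append(seed)
        remaining &= ~members
        cluster += 1
    occ = tuple(s / m for s in sizes)
    return Clustering(labels, tuple(sizes), occ, tuple(centroids), rmsd_threshold)


def sampling_precision(
    models,
    half_a: np.ndarray,
    half_b: np.ndarray,
    selection: np.ndarray | None = None,
    thresholds: Sequence[float] | None = None,
    min_cluster: int = 5,
    pvalue: float = 0.05,
    cramers_v: float = 0.10,
    min_clustered_fraction: float = 0.8,
) -> tuple[float, Clustering]:
    """Smallest clustering threshold at which two independent halves agree.

    Following the standard exhaustiveness protocol for integrative-model
    ensembles, the pooled models are clustered at increasing RMSD thresholds;
    the sampling precision is the smallest threshold at which (i) every
    sizeable cluster is populated proportionally by both halves (chi-square
    p > ``pvalue`` or Cramer's V < ``cramers_v``) and (ii) the sizeable
    clusters hold at least ``min_clustered_fraction`` of the models. Returns
    the threshold and the clustering computed at it.
    """
    from scipy import stats

    coords = models.coords if hasattr(models, "coords") else np.asarray(models)
    half_a = np.asarray(half_a, dtype=int)
    half_b = np.asarray(half_b, dtype=int)
    sel = coords if selection is None else coords[:, selection]
    if thresholds is None:
        dist = _rmsd_matrix(sel)
        iu = np.triu_indices(len(sel), 1)
        hi = float(np.percentile(dist[iu], 99)) if iu[0].size else 1.0
        thresholds = np.linspace(max(1.0, hi / 20), hi, 20)
    last = None
    for thr in thresholds:
        cl = cluster_models(coords, float(thr), selection)
        last = (float(thr), cl)
        big = [c for c, s in enumerate(cl.sizes) if s >= min_cluster]
        if not big:
            continue
        n_big = sum(cl.sizes[c] for c in big)
        if n_big / len(sel) < min_clustered_fraction:
            continue
        table = np.array(
            [
                [
                    int(np.isin(half_a, np.flatnonzero(cl.labels == c)).sum()),
                    int(np.isin(half_b, np.flatnonzero(cl.labels == c)).sum()),
                ]
                for c in big
            ]
        )
        if table.shape[0] == 1:
            return float(thr), cl  # single cluster: halves trivially agree
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            continue
        chi2, p, _, _ = stats.chi2_contingency(table)
        n = table.sum()
        v = math.sqrt(chi2 / (n * (min(table.shape) - 1))) if n else 0.0
        if p > pvalue or v < cramers_v:
            return float(thr), cl
    assert last is not None
    return last


# -- densities ---------------------------------------------------------------


def _grid_for_points(
    points: np.ndarray, voxel: float, pad: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel)) + 1 for k in range(3))
    return lo, shape


def localization_density(
    models,
    selection: np.ndarray,
    radii: np.ndarray | None = None,
    voxel: float = 3.0,
    pad_voxels: int = 2,
) -> DensityGrid:
    """Per-voxel occupancy counts of selected particles across an ensemble.

    Each selected particle in each model is rasterized as a solid sphere of
    its radius; counts accumulate over models. The grid covers every model
    with ``pad_voxels`` voxels of padding beyond the largest sphere.
    """
    if hasattr(models, "coords"):
        if radii is None:
            radii = models.system.radii
        models = models.coords
    coords = np.asarray(models, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if voxel <= 0:
        raise ValueError("voxel size must be > 0")
    if radii is None:
        raise ValueError("particle radii required")
    radii = np.asarray(radii, dtype=float)
    sel_r = radii[selection]

    pts = coords[:, selection].reshape(-1, 3)
    pad = sel_r.max() + pad_voxels * voxel
    origin, shape = _grid_for_points(pts, voxel, pad)
    values = np.zeros(shape, dtype=np.float32)

    for center, r in zip(pts, np.tile(sel_r, coords.shape[0])):
        lo_i = np.floor((center - r - origin) / voxel).astype(int)
        hi_i = np.ceil((center + r - origin) / voxel).astype(int)
        lo_i = np.maximum(lo_i, 0)
        hi_i = np.minimum(hi_i, np.array(shape) - 1)
        ax = [origin[k] + voxel * np.arange(lo_i[k], hi_i[k] + 1) for k in range(3)]
        dx2 = (ax[0] - center[0]) ** 2
        dy2 = (ax[1] - center[1]) ** 2
        dz2 = (ax[2] - center[2]) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        values[
            lo_i[0] : hi_i[0] + 1, lo_i[1] : hi_i[1] + 1, lo_i[2] : hi_i[2] + 1
        ] += inside
    return DensityGrid(origin, voxel, values)


def contour_level(grid: DensityGrid, fraction: float = 0.025) -> float:
    """Contour value at ``fraction`` of the grid maximum."""
    vmax = float(grid.values.max())
    if vmax <= 0:
        raise ValueError("contour level undefined for an all-zero grid")
    if fraction == 0:
        logger.warning("contour fraction 0 selects the whole support")
    return fraction * vmax


def rasterize_structure(
    coords: np.ndarray,
    resolution: float,
    voxel: float = 1.0,
    weights: np.ndarray | None = None,
) -> DensityGrid:
    """Sum-of-Gaussians molecular map (sigma = resolution / 2.355).

    Each point contributes a normalized 3D Gaussian, so the map integral
    (sum times voxel volume) approximates the total weight.
    """
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    sigma = resolution / 2.355
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    cut = 4.0 * sigma
    origin, shape = _grid_for_points(pts, voxel, cut + 2 * voxel)
    values = np.zeros(shape, dtype=np.float64)
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    for center, wt in zip(pts, w):
        lo_i = np.maximum(np.floor((center - cut - origin) / voxel).astype(int), 0)
        hi_i = np.minimum(
            np.ceil((center + cut - origin) / voxel).astype(int),
            np.array(shape) - 1,
        )
        ax = [origin[k] + voxel * np.arange(lo_i[k], hi_i[k] + 1) for k in range(3)]
        gx = np.exp(-((ax[0] - center[0]) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ax[1] - center[1]) ** 2) / (2 * sigma**2))
        gz = np.exp(-((ax[2] - center[2]) ** 2) / (2 * sigma**2))
        values[
            lo_i[0] : hi_i[0] + 1, lo_i[1] : hi_i[1] + 1, lo_i[2] : hi_i[2] + 1
        ] += wt * norm * np.einsum("i,j,k->ijk", gx, gy, gz)
    return DensityGrid(origin, voxel, values.astype(np.float32))


def resample_like(grid: DensityGrid, reference: DensityGrid) -> DensityGrid:
    """Trilinear resampling of ``grid`` onto the geometry of ``reference``."""
    axes = reference.axes()
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    frac = (pts - grid.origin) / grid.voxel
    vals = ndimage.map_coordinates(
        grid.values.astype(np.float64), frac.T, order=1, mode="constant", cval=0.0
    )
    return DensityGrid(
        reference.origin.copy(), reference.voxel,
        vals.reshape(reference.shape).astype(np.float32),
    )


def difference_map(
    grid_experimental: DensityGrid,
    grid_model: DensityGrid,
    resample: bool = False,
) -> DensityGrid:
    """Experimental minus amplitude-fitted model density.

    The model grid is scaled by the least-squares amplitude
    ``s = <e, m> / <m, m>`` before subtraction, so the result is invariant to
    any overall scaling of the model map.
    """
    if not grid_experimental.same_geometry(grid_model):
        if not resample:
            raise ValueError(
                "grid geometries differ; pass resample=True to interpolate"
            )
        grid_model = resample_like(grid_model, grid_experimental)
    e = grid_experimental.values.astype(np.float64)
    m = grid_model.values.astype(np.float64)
    denom = float(np.sum(m * m))
    scale = float(np.sum(e * m)) / denom if denom > 0 else 0.0
    return DensityGrid(
        grid_experimental.origin.copy(),
        grid_experimental.voxel,
        (e - scale * m).astype(np.float32),
    )


def convergence_check(
    ensemble_a,
    ensemble_b,
    selection: np.ndarray,
    voxel: float = 3.0,
    radii: np.ndarray | None = None,
) -> float:
    """Pearson correlation of two half-ensemble localization densities.

    Densities are computed on a shared grid; the correlation runs over voxels
    where either map is positive.
    """
    ga = localization_density(ensemble_a, selection, radii=radii, voxel=voxel)
    gb = localization_density(ensemble_b, selection, radii=radii, voxel=voxel)
    # common box
    lo = np.minimum(ga.origin, gb.origin)
    shape = tuple(
        max(
            ga.shape[k] + int(np.rint((ga.origin[k] - lo[k]) / voxel)),
            gb.shape[k] + int(np.rint((gb.origin[k] - lo[k]) / voxel)),
        )
        for k in range(3)
    )
    common = DensityGrid(lo, voxel, np.zeros(shape, dtype=np.float32))
    ra = resample_like(ga, common).values.astype(np.float64)
    rb = resample_like(gb, common).values.astype(np.float64)
    mask = (ra > 0) | (rb > 0)
    if not mask.any():
        raise ValueError("empty overlap between ensemble densities")
    va, vb = ra[mask], rb[mask]
    va = va - va.mean()
    vb = vb - vb.mean()
    denom = np.sqrt(np.sum(va**2) * np.sum(vb**2))
    if denom == 0:
        raise ValueError("degenerate (constant) densities")
    return float(np.sum(va * vb) / denom)


# -- MRC input/output --------------------------------------------------------


def write_mrc(grid: DensityGrid, path: str | Path) -> None:
    """Write the grid as an MRC/CCP4 map (mode 2, float32).

    The grid origin (center of voxel 0,0,0) is stored in the MRC ORIGIN
    header words; the cell is the isotropic voxel times the grid shape.
    """
    fgrid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.shape
    fgrid.set_unit_cell(
        gemmi.UnitCell(nx * grid.voxel, ny * grid.voxel, nz * grid.voxel, 90, 90, 90)
    )
    m = gemmi.Ccp4Map()
    m.grid = fgrid
    m.update_ccp4_header()
    for k in range(3):
        m.set_header_float(50 + k, float(grid.origin[k]))
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityGrid:
    """Read a map written by :func:`write_mrc` (bit-compatible round trip)."""
    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True)
    origin = np.array([m.header_float(50 + k) for k in range(3)])
    cell = m.grid.unit_cell
    voxel = cell.a / m.grid.nu
    return DensityGrid(origin, float(voxel), values)
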