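"""Quantitative microscopy: co-localization statistics and 3D morphometry.

Operates on already-labelled images — the segmentation itself is upstream.
Two worlds:

* 2D label fields: DAPI-detected prokaryote-scale nuclei objects, host-cell
  labels, and binary probe (taxon-specific FISH) / protein (IHC) masks.  An
  object is *positive* for a mask when at least ``min_overlap_fraction`` of
  its pixels fall on it (fraction-of-object, robust to mask dilation).
* 3D voxel models: a cell mask plus labelled intracellular granules, with
  anisotropic voxels (z defaults to the 0.1 um section spacing).  Volumes
  are voxel counts × voxel volume; the equivalent spherical diameter is
  (6V/π)^(1/3); *bipolarity* scores 1 when the two largest granules fall in
  opposite halves of the cell's principal axis.

Synthetic fixture generators close the loop: they emit fields/models with
exactly requested object and overlap counts plus ground-truth tables, so
every quantifier can be validated count-for-count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import CapacityError


# -- 2D label fields -----------------------------------------------------


@dataclass
class LabelField:
    """One imaged area: label images + binary masks on a common grid."""

    field_id: str
    nuclei_labels: np.ndarray
    host_cell_labels: np.ndarray
    probe_mask: np.ndarray
    protein_mask: np.ndarray
    pixel_size: float  # micrometres per pixel
    field_area: float | None = None  # mm^2; derived from the grid if None

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (
                self.nuclei_labels,
                self.host_cell_labels,
                self.probe_mask,
                self.protein_mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError("all images of a field must share one shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.field_area is None:
            h, w = self.nuclei_labels.shape
            self.field_area = h * w * (self.pixel_size / 1000.0) ** 2


@dataclass
class FieldColocalization:
    """Per-field co-localization summary row."""

    field_id: str
    n_nuclei: int
    n_probe_positive: int
    percent_positive: float
    density_per_mm2: float
    cells_per_host: float  # NaN when no host cells (flagged, not raised)
    n_host_cells: int
    positive_labels: frozenset[int] = field(repr=False, default=frozenset())


def _object_mask_fraction(
    labels: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(labels present, fraction of each label's pixels on the mask)."""
    sizes = np.bincount(labels.ravel())
    on_mask = np.bincount(labels[mask.astype(bool)], minlength=sizes.size)
    present = np.nonzero(sizes)[0]
    present = present[present > 0]
    frac = on_mask[present] / sizes[present]
    return present, frac


def density_and_ratio(
    n_positive: int, field_area: float, n_host_cells: int
) -> tuple[float, float]:
    """(cells per mm^2, cells per host cell); ratio NaN when no hosts."""
    if field_area <= 0:
        raise ValueError("field_area must be positive")
    density = n_positive / field_area
    ratio = n_positive / n_host_cells if n_host_cells > 0 else float("nan")
    return density, ratio


def colocalize(
    lf: LabelField, min_overlap_fraction: float = 0.25
) -> FieldColocalization:
    """Probe positivity of every nuclei object + the field summary row."""
    present, frac = _object_mask_fraction(lf.nuclei_labels, lf.probe_mask)
    positive = present[frac >= min_overlap_fraction]
    n_nuclei, n_pos = int(present.size), int(positive.size)
    host_labels = np.unique(lf.host_cell_labels)
    n_host = int((host_labels > 0).sum())
    density, ratio = density_and_ratio(n_pos, lf.field_area, n_host)
    percent = 100.0 * n_pos / n_nuclei if n_nuclei else float("nan")
    return FieldColocalization(
        field_id=lf.field_id,
        n_nuclei=n_nuclei,
        n_probe_positive=n_pos,
        percent_positive=percent,
        density_per_mm2=density,
        cells_per_host=ratio,
        n_host_cells=n_host,
        positive_labels=frozenset(int(x) for x in positive),
    )


def protein_positivity(
    lf: LabelField,
    coloc: FieldColocalization,
    min_overlap_fraction: float = 0.25,
) -> tuple[float, int, int]:
    """Percent of probe-positive objects that also overlap the protein mask.

    Denominator = probe-positive objects only.  Returns (percent, n_protein
    positive, n_probe_positive); percent is NaN when there are no
    probe-positive objects (flagged, not raised).
    """
    present, frac = _object_mask_fraction(lf.nuclei_labels, lf.protein_mask)
    protein_pos = {
        int(lab) for lab, f in zip(present, frac) if f >= min_overlap_fraction
    }
    denom = coloc.positive_labels
    hits = len(denom & protein_pos)
    percent = 100.0 * hits / len(denom) if denom else float("nan")
    return percent, hits, len(denom)


def summarize_fields(rows: Sequence[FieldColocalization]) -> pd.DataFrame:
    """Unweighted mean ± sample s.d. (n−1) of each metric across fields.

    One field gives NaN standard deviations (flagged, not raised).  This is
    the per-area summary; pooled counts can disagree with it whenever field
    sizes differ — report both when that matters.
    """
    if not rows:
        raise ValueError("at least one field required")
    df = pd.DataFrame(
        [
            {
                "n_nuclei": r.n_nuclei,
                "n_probe_positive": r.n_probe_positive,
                "percent_positive": r.percent_positive,
                "density_per_mm2": r.density_per_mm2,
                "cells_per_host": r.cells_per_host,
            }
            for r in rows
        ],
        index=[r.field_id for r in rows],
    )
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


# -- 3D voxel models -----------------------------------------------------


@dataclass
class VoxelModel:
    """A reconstructed cell with labelled intracellular granules."""

    cell_mask: np.ndarray  # 3D bool
    granule_labels: np.ndarray  # 3D int, 0 = background
    voxel_size: tuple[float, float, float] = (0.01, 0.01, 0.1)  # um (x, y, z)

    def __post_init__(self) -> None:
        if self.cell_mask.shape != self.granule_labels.shape:
            raise ValueError("cell and granule arrays must share a shape")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass
class MorphometryResult:
    granule_volumes_um3: dict[int, float]
    granule_diameters_nm: dict[int, float]
    granule_count: int
    cell_volume_um3: float
    volume_fraction: float
    polarity: float | None  # None when fewer than two granules (flagged)


def equivalent_spherical_diameter_nm(volume_um3: float) -> float:
    """Diameter (nm) of the sphere with the given volume (um^3)."""
    return 1000.0 * (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def granule_morphometry(model: VoxelModel) -> MorphometryResult:
    """Volumes, equivalent diameters, volume fraction and bipolarity.

    Granule voxels must lie inside the cell mask (raises otherwise).  The
    polarity score projects granule centroids onto the cell's principal
    axis (PCA of physical voxel coordinates): 1 when the two largest
    granules fall on opposite sides of the cell centroid, else 0; undefined
    (None) with fewer than two granules.
    """
    cell = model.cell_mask.astype(bool)
    if not cell.any():
        raise ValueError("empty cell mask")
    gran = model.granule_labels
    if (gran[~cell] != 0).any():
        raise ValueError("granule voxels outside the cell mask")
    vx = float(np.prod(model.voxel_size))

    counts = np.bincount(gran.ravel())
    labels = [int(l) for l in np.nonzero(counts)[0] if l > 0]
    volumes = {l: counts[l] * vx for l in labels}
    diameters = {l: equivalent_spherical_diameter_nm(v) for l, v in volumes.items()}
    cell_volume = float(cell.sum()) * vx
    fraction = sum(volumes.values()) / cell_volume

    polarity: float | None = None
    if len(labels) >= 2:
        scale = np.asarray(model.voxel_size, dtype=float)
        coords = np.argwhere(cell) * scale
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        cov = centered.T @ centered / len(centered)
        eigvals, eigvecs = np.linalg.eigh(cov)
        axis = eigvecs[:, np.argmax(eigvals)]
        two_largest = sorted(labels, key=lambda l: volumes[l], reverse=True)[:2]
        projections = []
        for l in two_largest:
            c = np.argwhere(gran == l) * scale
            projections.append(float((c.mean(axis=0) - centroid) @ axis))
        polarity = 1.0 if projections[0] * projections[1] < 0 else 0.0

    return MorphometryResult(
        granule_volumes_um3=volumes,
        granule_diameters_nm=diameters,
        granule_count=len(labels),
        cell_volume_um3=cell_volume,
        volume_fraction=fraction,
        polarity=polarity,
    )


# -- synthetic fixture generators ---------------------------------------


def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    keep = yy**2 + xx**2 <= radius**2
    return np.stack([yy[keep], xx[keep]], axis=1)


def generate_label_field(
    n_nuclei: int,
    n_probe_positive: int,
    n_protein_positive: int = 0,
    n_host_cells: int = 0,
    shape: tuple[int, int] = (1200, 1200),
    pixel_size: float = 0.2,
    nucleus_radius: int = 2,
    host_radius: int = 6,
    seed: int = 0,
) -> tuple[LabelField, pd.DataFrame]:
    """Synthetic labelled field with exactly the requested counts.

    Nuclei are non-overlapping discs on a jittered grid; the probe mask
    covers ``n_probe_positive`` randomly chosen nuclei completely and the
    protein mask a random subset of those of size ``n_protein_positive``.
    Host-cell labels live on their own (independent) grid.  Returns the
    field and a ground-truth table (label, probe_positive, protein_positive).
    Raises :class:`CapacityError` when the requested objects do not fit.
    """
    if not (0 <= n_protein_positive <= n_probe_positive <= n_nuclei):
        raise ValueError("need n_protein <= n_probe <= n_nuclei")
    rng = np.random.default_rng(seed)
    h, w = shape

    def _grid_centers(radius: int, n: int) -> np.ndarray:
        cell = 2 * radius + 3
        rows = (h - 2 * radius - 2) // cell
        cols = (w - 2 * radius - 2) // cell
        if rows * cols < n:
            raise CapacityError(
                f"cannot place {n} objects of radius {radius} in {shape}"
            )
        slots = rng.choice(rows * cols, size=n, replace=False)
        rr = radius + 1 + (slots // cols) * cell
        cc = radius + 1 + (slots % cols) * cell
        return np.stack([rr, cc], axis=1)

    nuclei = np.zeros(shape, dtype=np.int32)
    disk = _disk_offsets(nucleus_radius)
    centers = _grid_centers(nucleus_radius, n_nuclei)
    for i, (r, c) in enumerate(centers, start=1):
        nuclei[disk[:, 0] + r, disk[:, 1] + c] = i

    labels = np.arange(1, n_nuclei + 1)
    probe_labels = rng.choice(labels, size=n_probe_positive, replace=False)
    protein_labels = rng.choice(
        probe_labels, size=n_protein_positive, replace=False
    )
    probe = np.isin(nuclei, probe_labels) & (nuclei > 0)
    protein = np.isin(nuclei, protein_labels) & (nuclei > 0)

    hosts = np.zeros(shape, dtype=np.int32)
    if n_host_cells:
        host_disk = _disk_offsets(host_radius)
        host_centers = _grid_centers(host_radius, n_host_cells)
        for i, (r, c) in enumerate(host_centers, start=1):
            hosts[host_disk[:, 0] + r, host_disk[:, 1] + c] = i

    truth = pd.DataFrame(
        {
            "label": labels,
            "probe_positive": np.isin(labels, probe_labels),
            "protein_positive": np.isin(labels, protein_labels),
        }
    )
    lf = LabelField(
        field_id=f"synthetic_seed{seed}",
        nuclei_labels=nuclei,
        host_cell_labels=hosts,
        probe_mask=probe,
        protein_mask=protein,
        pixel_size=pixel_size,
    )
    return lf, truth


def digitize_sphere(
    radius_um: float, voxel_um: float, pad: int = 2
) -> np.ndarray:
    """Boolean voxelisation of a sphere (voxel centres inside the radius)."""
    n = int(math.ceil(radius_um / voxel_um)) + pad
    ax = (np.arange(-n, n + 1) + 0.0) * voxel_um
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= radius_um**2


def generate_voxel_cell(
    cell_semi_axes_um: tuple[float, float, float] = (0.925, 0.525, 0.525),
    granule_radius_um: float = 0.084,
    granule_axial_fraction: float = 0.75,
    voxel_size: tuple[float, float, float] = (0.02, 0.02, 0.02),
    seed: int = 0,
) -> tuple[VoxelModel, pd.DataFrame]:
    """An ellipsoidal cell with two spherical granules planted at its poles.

    ``granule_axial_fraction`` places the granule centres at ±that fraction
    of the long semi-axis, emulating the bipolar arrangement seen in 3D
    reconstructions.  Returns the model plus a truth table of planted
    centres and radii.  The ``seed`` only jitters nothing here (fixtures are
    fully deterministic) but is kept for interface symmetry.
    """
    a, b, c = cell_semi_axes_um
    vx, vy, vz = voxel_size
    nx = int(math.ceil(a / vx)) + 3
    ny = int(math.ceil(b / vy)) + 3
    nz = int(math.ceil(c / vz)) + 3
    xs = (np.arange(-nx, nx + 1)) * vx
    ys = (np.arange(-ny, ny + 1)) * vy
    zs = (np.arange(-nz, nz + 1)) * vz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    cell = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0

    granules = np.zeros(cell.shape, dtype=np.int32)
    centers = [(-granule_axial_fraction * a, 0.0, 0.0),
               (granule_axial_fraction * a, 0.0, 0.0)]
    for i, (cx, cy, cz) in enumerate(centers, start=1):
        ball = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= granule_radius_um**2
        granules[ball & cell] = i
    truth = pd.DataFrame(
        {
            "granule": [1, 2],
            "center_x_um": [c[0] for c in centers],
            "center_y_um": [c[1] for c in centers],
            "center_z_um": [c[2] for c in centers],
            "radius_um": [granule_radius_um] * 2,
        }
    )
    return VoxelModel(cell, granules, voxel_size), truth
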