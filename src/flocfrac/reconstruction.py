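"""Stacking slice masks into a scaled 3D volume and extracting particles.

The binarized optical sections are stacked in acquisition order, spaced by the
z step, into a boolean occupancy grid that is to scale through its attached
:class:`~flocfrac.stack_io.VoxelGeometry`. Connected components of that grid
are the candidate precipitate particles; three exclusion filters follow, in a
fixed order:

1. :func:`remove_small` — very small objects are interference/dust artifacts;
2. :func:`remove_border_touching` — objects on any face of the imaged volume
   are likely truncated;
3. :func:`remove_pillars` — interference spots repeat identically in every
   slice regardless of the focus height and reconstruct as z-spanning columns
   with a near-constant footprint; they are detected by the combination of a
   near-full z extent and a per-slice footprint almost identical to the
   component's overall xy projection.

Filter order is fixed (label → small → border → pillars) and order invariance
is deliberately not assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .segmentation import SliceMask
from .stack_io import VoxelGeometry

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass
class BinaryVolume:
    """3D boolean occupancy grid, axis order (z, y, x), with physical pitch."""

    voxels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("BinaryVolume must be 3D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class LabeledVolume:
    """Integer component labels: 0 background, 1..K particles (compact)."""

    labels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabeledVolume must be 3D (z, y, x)")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> np.ndarray:
        """Voxel count per label, index 0 = label 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)[1:]


@dataclass
class Particle:
    """One connected precipitate object extracted from a labeled volume."""

    label: int
    voxel_indices: np.ndarray          # (n, 3) int (z, y, x)
    bounding_box: tuple[slice, slice, slice]
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    condition: str = ""

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices)
        if self.voxel_indices.size == 0:
            raise ValueError("particle has no voxels")

    @property
    def voxel_count(self) -> int:
        return self.voxel_indices.shape[0]

    def mask(self) -> np.ndarray:
        """Tight boolean array over the bounding box."""
        origin = np.array([s.start for s in self.bounding_box])
        shape = tuple(s.stop - s.start for s in self.bounding_box)
        out = np.zeros(shape, dtype=bool)
        idx = self.voxel_indices - origin
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out

    def centers_um(self) -> np.ndarray:
        """Physical (z, y, x) coordinates of the voxel centres, µm."""
        g = self.geometry
        return self.voxel_indices * np.array([g.dz, g.dy, g.dx])


def stack_masks(masks: Sequence[SliceMask | np.ndarray],
                geometry: VoxelGeometry | None = None) -> BinaryVolume:
    """Stack binarized slices (acquisition order) into a 3D binary volume."""
    if len(masks) == 0:
        raise ValueError("no masks to stack")
    arrays = []
    for k, m in enumerate(masks):
        a = m.pixels if isinstance(m, SliceMask) else np.asarray(m, dtype=bool)
        if arrays and a.shape != arrays[0].shape:
            raise ValueError(
                f"mask {k} has shape {a.shape}, expected {arrays[0].shape}")
        arrays.append(a)
    if geometry is None:
        first = masks[0]
        geometry = first.geometry if isinstance(first, SliceMask) else VoxelGeometry()
    return BinaryVolume(np.stack(arrays), geometry)


def label_components(volume: BinaryVolume, connectivity: int = 26) -> LabeledVolume:
    """Label maximal connected components (6, 18 or 26 neighbourhood).

    The default, 26, is the "standard connectivity" of common 3D object
    detection routines.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    labels, _ = ndi.label(volume.voxels, structure=_STRUCTURES[connectivity])
    return LabeledVolume(labels, volume.geometry)


def _relabel_keep(labeled: LabeledVolume, keep: np.ndarray) -> LabeledVolume:
    """Zero out labels not in ``keep`` and compact the survivors to 1..K."""
    n = labeled.n_labels
    lut = np.zeros(n + 1, dtype=labeled.labels.dtype)
    lut[np.sort(keep)] = np.arange(1, len(keep) + 1)
    return LabeledVolume(lut[labeled.labels], labeled.geometry)


def remove_small(labeled: LabeledVolume, min_voxels: int) -> LabeledVolume:
    """Drop components with fewer than ``min_voxels`` voxels; compact labels."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if labeled.n_labels == 0 or min_voxels == 0:
        return LabeledVolume(labeled.labels.copy(), labeled.geometry)
    sizes = labeled.sizes()
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    return _relabel_keep(labeled, keep)


def remove_border_touching(labeled: LabeledVolume) -> LabeledVolume:
    """Drop components with a voxel on any face of the volume (all six faces,
    including the first/last z slice); compact labels."""
    lab = labeled.labels
    border = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
    ]))
    border = border[border > 0]
    keep = np.setdiff1d(np.arange(1, labeled.n_labels + 1), border)
    return _relabel_keep(labeled, keep)


def remove_pillars(labeled: LabeledVolume, min_z_span_fraction: float = 0.95,
                   max_footprint_jaccard_dev: float = 0.1) -> LabeledVolume:
    """Drop interference-pillar components.

    A component is a pillar iff (a) its z extent covers at least
    ``min_z_span_fraction`` of the slices AND (b) the mean Jaccard similarity
    between its per-slice footprint and its overall xy projection is at least
    ``1 - max_footprint_jaccard_dev`` — i.e. its footprint is nearly identical
    in every slice, as an interference spot's is. Real particles change their
    optical section from slice to slice and fail (b) even if tall.
    """
    for name, v in [("min_z_span_fraction", min_z_span_fraction),
                    ("max_footprint_jaccard_dev", max_footprint_jaccard_dev)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    nz = labeled.labels.shape[0]
    keep = []
    for lab, box in enumerate(ndi.find_objects(labeled.labels), start=1):
        if box is None:
            continue
        comp = labeled.labels[box] == lab
        z_span = comp.shape[0]
        if z_span < min_z_span_fraction * nz:
            keep.append(lab)
            continue
        projection = comp.any(axis=0)
        proj_area = projection.sum()
        jaccards = []
        for k in range(comp.shape[0]):
            foot = comp[k]
            inter = np.logical_and(foot, projection).sum()
            union = foot.sum() + proj_area - inter
            if union > 0:
                jaccards.append(inter / union)
        if np.mean(jaccards) >= 1.0 - max_footprint_jaccard_dev:
            logger.info("removing pillar artifact: label %d (z span %d/%d)",
                        lab, z_span, nz)
        else:
            keep.append(lab)
    return _relabel_keep(labeled, np.asarray(keep, dtype=int))


def extract_particles(labeled: LabeledVolume, condition: str = "") -> list[Particle]:
    """One :class:`Particle` per surviving label, sorted by voxel count
    descending; the particle keeps the label it holds in the volume."""
    boxes = ndi.find_objects(labeled.labels)
    particles = []
    for lab, box in enumerate(boxes, start=1):
        if box is None:
            continue
        local = np.argwhere(labeled.labels[box] == lab)
        origin = np.array([s.start for s in box])
        particles.append(Particle(
            label=lab, voxel_indices=local + origin, bounding_box=box,
            geometry=labeled.geometry, condition=condition))
    particles.sort(key=lambda p: p.voxel_count, reverse=True)
    return particles


def apply_filters(labeled: LabeledVolume, min_voxels: int = 50,
                  pillar_min_z_span: float = 0.95,
                  pillar_max_footprint_dev: float = 0.1) -> LabeledVolume:
    """Fixed-order exclusion: small objects → border-touching → pillars."""
    labeled = remove_small(labeled, min_voxels)
    labeled = remove_border_touching(labeled)
    labeled = remove_pillars(labeled, pillar_min_z_span, pillar_max_footprint_dev)
    return labeled


def resample_isotropic(volume: BinaryVolume) -> BinaryVolume:
    """Replicate slices along z so the grid becomes (near-)cubic.

    Box counting assumes cubic cells while acquisition has dz > dx; each slice
    is replicated round(dz/dx) times (nearest-neighbour in z) and the geometry
    is updated to dz' = dz / factor. Voxel count scales by exactly the factor.
    Already-isotropic volumes pass through unchanged; dz < dx is a warned
    no-op (downsampling is not supported).
    """
    g = volume.geometry
    if g.dz < g.dx:
        logger.warning("dz (%g) < dx (%g): isotropic resampling skipped", g.dz, g.dx)
        return volume
    factor = int(round(g.dz / g.dx))
    if factor <= 1:
        return volume
    voxels = np.repeat(volume.voxels, factor, axis=0)
    new_geom = VoxelGeometry(g.dx, g.dy, g.dz / factor)
    return BinaryVolume(voxels, new_geom)
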