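"""CT preprocessing: masked-tumor network inputs from raw image + contours.

The pipeline mirrors standard masked-CT radiomics preprocessing: isotropic
resampling (linear for the image, shape-based for the binary masks),
Hounsfield-unit windowing to [-500, +500] rescaled to [-1, +1], masking with
the union of primary and nodal gross tumor volumes (GTVs), exclusion of
nodal volumes under 2 cm^3, centering on the tumor centroid, and online
augmentation (random crop with bounded central shift, mirroring, rotation
and elastic deformation).  A "binary" input mode replaces in-tumor
intensities with +1, keeping only volume and shape information — useful for
ablating texture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .synthetic import PatientRecord

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "ExcludedPatient",
    "resample_isotropic",
    "window_rescale",
    "mask_with_gtv",
    "filter_small_nodes",
    "select_max_tumor_slice",
    "center_on_mask",
    "augment",
    "preprocess_record",
]

logger = logging.getLogger(__name__)


class ExcludedPatient(Exception):
    """Raised when a record cannot be preprocessed (e.g. empty mask)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Spatial and intensity normalisation parameters.

    Defaults follow the full-scale protocol (1 mm isotropic grid, HU window
    [-500, +500] mapped to [-1, +1], a 256-voxel canvas randomly cropped to
    128); ``input_extent``/``crop_extent`` scale down for desk-scale work.
    """

    target_spacing: float = 1.0
    hu_window: tuple[float, float] = (-500.0, 500.0)
    rescale_range: tuple[float, float] = (-1.0, 1.0)
    input_extent: int = 256
    crop_extent: int = 128
    input_mode: str = "standard"  # "standard" | "binary"
    min_node_volume_cm3: float = 2.0

    def __post_init__(self) -> None:
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must satisfy low < high")
        if self.crop_extent > self.input_extent:
            raise ValueError("crop_extent must not exceed input_extent")
        if self.input_mode not in ("standard", "binary"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")

    @property
    def background(self) -> float:
        return self.rescale_range[0]


@dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation parameters.

    ``crop_shift_fraction`` bounds the random shift of the crop center as a
    fraction of the canvas extent; mirroring flips left-right; rotation and
    elastic deformation are applied together with probability
    ``rot_elastic_prob`` (0.10 for the binary-classification 3D model, 0.20
    for the time-to-event 3D model, 0.50 for 2D models).
    """

    crop_shift_fraction: float = 0.20
    mirror_prob: float = 0.5
    max_rotation_deg: float = 60.0
    elastic_fraction: float = 0.25
    rot_elastic_prob: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crop_shift_fraction", "mirror_prob", "elastic_fraction",
                     "rot_elastic_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# resampling

def _resample_mask_shape_based(mask: np.ndarray, zoom: np.ndarray) -> np.ndarray:
    """Shape-based mask resampling: interpolate the 3D signed distance map.

    The signed Euclidean distance (positive inside) is interpolated linearly
    on the new grid and re-thresholded at zero, which preserves smooth
    boundaries better than nearest-neighbour label resampling.
    """
    if mask.sum() == 0:
        return ndimage.zoom(mask.astype(np.uint8), zoom, order=0)
    inside = ndimage.distance_transform_edt(mask > 0)
    outside = ndimage.distance_transform_edt(mask == 0)
    signed = inside - outside
    resampled = ndimage.zoom(signed, zoom, order=1)
    return (resampled > 0).astype(np.uint8)


def resample_isotropic(record: PatientRecord, config: PreprocessConfig) -> PatientRecord:
    """Resample image (linear) and masks (shape-based) to an isotropic grid.

    Raises :class:`ExcludedPatient` when the primary mask vanishes after
    resampling; nodal masks that vanish are dropped with a log entry.
    """
    spacing = np.asarray(record.voxel_spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    zoom = spacing / config.target_spacing
    if np.allclose(zoom, 1.0):
        return record

    image = ndimage.zoom(record.image.astype(np.float32), zoom, order=1)
    primary = _resample_mask_shape_based(record.gtv_primary_mask, zoom)
    if primary.sum() == 0:
        logger.warning("patient %s excluded: primary mask empty after resampling",
                       record.patient_id)
        raise ExcludedPatient(
            f"{record.patient_id}: primary mask empty after resampling")
    nodes = []
    for k, node in enumerate(record.gtv_node_masks):
        rn = _resample_mask_shape_based(node, zoom)
        if rn.sum() == 0:
            logger.warning("patient %s: node mask %d empty after resampling, dropped",
                           record.patient_id, k)
            continue
        nodes.append(rn)
    return replace(
        record,
        image=image,
        gtv_primary_mask=primary,
        gtv_node_masks=nodes,
        voxel_spacing=(config.target_spacing,) * 3,
    )


# ---------------------------------------------------------------------------
# intensity operations

def window_rescale(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Clip to the HU window and map it affinely onto the rescale range."""
    lo, hi = config.hu_window
    r0, r1 = config.rescale_range
    clipped = np.clip(np.asarray(image, dtype=np.float32), lo, hi)
    return (clipped - lo) / (hi - lo) * (r1 - r0) + r0


def mask_with_gtv(image: np.ndarray, masks: list[np.ndarray],
                  config: PreprocessConfig) -> np.ndarray:
    """Mask the rescaled image with the union of GTV structures.

    ``standard`` mode keeps rescaled intensities inside the union and sets
    the outside to the background value (-1); ``binary`` mode additionally
    discards texture by setting every in-union voxel above background to +1.
    """
    if not masks:
        raise ValueError("at least one mask required")
    union = np.zeros(image.shape, dtype=bool)
    for m in masks:
        union |= np.asarray(m) > 0
    if not union.any():
        raise ValueError("mask union is empty")
    bg = config.background
    out = np.full(image.shape, bg, dtype=np.float32)
    if config.input_mode == "standard":
        out[union] = image[union]
    else:
        hi = config.rescale_range[1]
        out[union & (image > bg)] = hi
    return out


def filter_small_nodes(node_masks: list[np.ndarray],
                       spacing: tuple[float, float, float],
                       min_volume_cm3: float = 2.0) -> list[np.ndarray]:
    """Drop nodal masks below the volume threshold (inclusive at the boundary:
    a node of exactly ``min_volume_cm3`` is kept)."""
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    return [m for m in node_masks if m.sum() * voxel_cm3 >= min_volume_cm3]


class SliceSelection(NamedTuple):
    data: np.ndarray
    index: int


def select_max_tumor_slice(grid: np.ndarray, masks: list[np.ndarray]) -> SliceSelection:
    """Axial slice with the highest in-mask voxel count (ties: lowest index)."""
    union = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        union |= np.asarray(m) > 0
    if not union.any():
        raise ValueError("mask union is empty")
    counts = union.reshape(union.shape[0], -1).sum(axis=1)
    idx = int(np.argmax(counts))  # argmax takes the first maximum
    return SliceSelection(data=grid[idx], index=idx)


# ---------------------------------------------------------------------------
# spatial normalisation + augmentation

def center_on_mask(grid: np.ndarray, union_mask: np.ndarray, extent: int,
                   fill: float = -1.0) -> np.ndarray:
    """Embed the grid in a cubic canvas centered on the mask centroid."""
    centroid = np.round(ndimage.center_of_mass(union_mask > 0)).astype(int)
    nd = grid.ndim
    out = np.full((extent,) * nd, fill, dtype=np.float32)
    for_axis = []
    for ax in range(nd):
        src_start = centroid[ax] - extent // 2
        dst_start = max(0, -src_start)
        src_start = max(0, src_start)
        length = min(grid.shape[ax] - src_start, extent - dst_start)
        for_axis.append((src_start, dst_start, max(length, 0)))
    src = tuple(slice(s, s + l) for s, _, l in for_axis)
    dst = tuple(slice(d, d + l) for _, d, l in for_axis)
    out[dst] = grid[src]
    return out


def _central_crop(grid: np.ndarray, crop: int) -> np.ndarray:
    slices = tuple(
        slice((n - crop) // 2, (n - crop) // 2 + crop) for n in grid.shape
    )
    return grid[slices]


def _rotation_matrix_3d(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _rotate(grid: np.ndarray, rng: np.random.Generator, max_deg: float,
            fill: float) -> np.ndarray:
    angle = rng.uniform(-max_deg, max_deg)
    if grid.ndim == 2:
        return ndimage.rotate(grid, angle, reshape=False, order=1,
                              mode="constant", cval=fill)
    rot = _rotation_matrix_3d(rng.standard_normal(3), np.deg2rad(angle))
    center = (np.asarray(grid.shape) - 1) / 2.0
    offset = center - rot @ center
    return ndimage.affine_transform(grid, rot, offset=offset, order=1,
                                    mode="constant", cval=fill)


def _elastic(grid: np.ndarray, rng: np.random.Generator, max_fraction: float,
             fill: float) -> np.ndarray:
    """Smooth random displacement field; peak displacement drawn up to
    ``max_fraction`` of the grid extent (scaled down by 8 to keep the field
    in the mild-deformation regime)."""
    extent = grid.shape[0]
    amplitude = rng.uniform(0.0, max_fraction) * extent / 8.0
    coords = np.indices(grid.shape, dtype=np.float32)
    disp = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=extent / 8.0)
        for _ in range(grid.ndim)
    ])
    peak = np.abs(disp).max()
    if peak > 0:
        disp = disp / peak * amplitude
    return ndimage.map_coordinates(grid, coords + disp, order=1,
                                   mode="constant", cval=fill)


def augment(grid: np.ndarray, aug: AugmentConfig, training: bool,
            crop_extent: int, rng: np.random.Generator | None = None,
            fill: float = -1.0) -> np.ndarray:
    """Crop (random in training, central in evaluation) + optional transforms.

    In training the crop center is shifted uniformly by at most
    ``crop_shift_fraction`` of the canvas extent per axis, then mirroring,
    and — with probability ``rot_elastic_prob`` — rotation plus elastic
    deformation are applied.  Evaluation applies a deterministic central
    crop only.  Output extent is ``crop_extent`` per axis.
    """
    if crop_extent > min(grid.shape):
        raise ValueError("crop_extent exceeds grid extent")
    if not training:
        return _central_crop(grid, crop_extent)
    if rng is None:
        rng = np.random.default_rng(aug.seed)

    starts = []
    for n in grid.shape:
        smax = int(aug.crop_shift_fraction * n)
        center = n // 2 + int(rng.integers(-smax, smax + 1)) if smax else n // 2
        starts.append(int(np.clip(center - crop_extent // 2, 0, n - crop_extent)))
    out = grid[tuple(slice(s, s + crop_extent) for s in starts)].copy()

    if rng.uniform() < aug.mirror_prob:
        out = np.flip(out, axis=-1).copy()
    if rng.uniform() < aug.rot_elastic_prob:
        if aug.max_rotation_deg > 0:
            out = _rotate(out, rng, aug.max_rotation_deg, fill)
        if aug.elastic_fraction > 0:
            out = _elastic(out, rng, aug.elastic_fraction, fill)
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# full pipeline

def preprocess_record(record: PatientRecord, config: PreprocessConfig,
                      aug: AugmentConfig | None = None, training: bool = False,
                      dimensionality: str = "3D",
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Raw record → network-ready input grid.

    Resamples to the target spacing, filters sub-threshold nodal volumes,
    windows/rescales, masks with the GTV union, embeds the result in a
    canvas centered on the tumor centroid, selects the maximal axial tumor
    slice for 2D models, and crops (with augmentation when training).
    """
    rec = resample_isotropic(record, config)
    nodes = filter_small_nodes(rec.gtv_node_masks, rec.voxel_spacing,
                               config.min_node_volume_cm3)
    masks = [rec.gtv_primary_mask, *nodes]
    rescaled = window_rescale(rec.image, config)
    masked = mask_with_gtv(rescaled, masks, config)

    union = np.zeros(masked.shape, dtype=bool)
    for m in masks:
        union |= np.asarray(m) > 0
    canvas = center_on_mask(masked, union, config.input_extent, fill=config.background)

    if dimensionality.upper() == "2D":
        mask_canvas = center_on_mask(union.astype(np.float32), union,
                                     config.input_extent, fill=0.0)
        canvas = select_max_tumor_slice(canvas, [mask_canvas]).data

    if aug is None:
        aug = AugmentConfig()
    return augment(canvas, aug, training, config.crop_extent, rng=rng,
                   fill=config.background)
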