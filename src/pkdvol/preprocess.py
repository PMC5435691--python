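"""Slice preprocessing and training-set augmentation.

The pipeline operates slicewise on axial CT sections: each slice is
resampled to the network input size (bicubic for intensities,
nearest-neighbour for labels), its intensity range is normalized to
[0, 255], and the scalar grand mean of the training set is subtracted at
both train and test time.

Two augmentation branches enlarge the training set: (1) a rigid x-y image
shift and (2) a smooth non-rigid deformation combined with a low-frequency
multiplicative intensity variation.  With the default two variants per
slice the training set triples (e.g. 16,000 slices become 48,000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize


@dataclass
class ImageVolume:
    """A slice stack of intensities with acquisition geometry.

    ``voxels`` is ordered (slice, row, col); ``pixel_spacing_mm`` is the
    in-plane (x, y) spacing and ``slice_thickness_mm`` the increment
    between slices — together they convert voxel counts to volume.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (slice, row, col) stack with >= 1 slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        sx, sy = self.pixel_spacing_mm
        if sx <= 0 or sy <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy = self.pixel_spacing_mm
        return sx * sy * self.slice_thickness_mm


@dataclass
class AugmentationConfig:
    """Parameters of the two augmentation branches (pixel units at network
    resolution)."""

    max_shift_px: int = 20
    deform_grid_sigma_px: float = 12.0
    deform_alpha_px: float = 10.0
    intensity_field_amplitude: float = 0.1
    intensity_field_scale_px: float = 50.0
    variants_per_slice: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift_px < 0:
            raise ValueError("max_shift_px must be >= 0")
        if self.deform_grid_sigma_px <= 0 or self.intensity_field_scale_px <= 0:
            raise ValueError("smoothing scales must be > 0")
        if self.deform_alpha_px < 0:
            raise ValueError("deform_alpha_px must be >= 0")
        if self.variants_per_slice < 0:
            raise ValueError("variants_per_slice must be >= 0")
        if not np.isfinite(self.intensity_field_amplitude):
            raise ValueError("intensity_field_amplitude must be finite")


@dataclass
class TrainingSlice:
    """One (image, label) pair at network resolution with provenance."""

    image: np.ndarray
    label: np.ndarray
    provenance: tuple[str, int, str]  # (case_id, slice_index, variant_tag)

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError("image and label shapes must match")
        vals = np.unique(self.label)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("label must be binary")


def resample_slice(image: np.ndarray, target_size: tuple[int, int],
                   order: int = 3) -> np.ndarray:
    """Resample a 2-D slice to ``target_size``.

    ``order=3`` (bicubic) for intensity images; ``order=0``
    (nearest-neighbour) for label maps, which preserves binarity.
    """
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("source slice must be 2-D, at least 2x2")
    rows, cols = target_size
    if rows <= 0 or cols <= 0:
        raise ValueError(f"target size must be positive, got {target_size}")
    if image.shape == (rows, cols):
        return image.copy()
    anti_alias = order > 0 and (rows < image.shape[0] or cols < image.shape[1])
    out = resize(image.astype(np.float64), (rows, cols), order=order,
                 anti_aliasing=anti_alias, preserve_range=True)
    if order == 0:
        return out.astype(image.dtype)
    return out


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Affinely map the intensity range to [0, 255] (min -> 0, max -> 255)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        warnings.warn("constant-intensity image: normalized to all zeros",
                      stacklevel=2)
        return np.zeros_like(image)
    return (image - lo) * (255.0 / (hi - lo))


def compute_mean_and_subtract(slices: list[TrainingSlice]
                              ) -> tuple[float, list[TrainingSlice]]:
    """Scalar grand mean over all training pixels; subtracted from every slice.

    The same scalar must be subtracted from test images before prediction.
    """
    if not slices:
        raise ValueError("empty training set")
    total = sum(float(s.image.sum()) for s in slices)
    count = sum(s.image.size for s in slices)
    mean = total / count
    centered = [TrainingSlice(s.image - mean, s.label, s.provenance)
                for s in slices]
    return mean, centered


def augment_shift(s: TrainingSlice, dx: int, dy: int) -> TrainingSlice:
    """Translate image and label by (dx, dy) = (columns, rows); zero fill.

    Positive dx moves content toward higher column indices (rightward),
    positive dy toward higher row indices (downward).
    """
    h, w = s.image.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift ({dx},{dy}) >= image size {h}x{w}")

    def shift2d(a: np.ndarray, fill=0) -> np.ndarray:
        out = np.full_like(a, fill)
        src_r = slice(max(0, -dy), h - max(0, dy))
        dst_r = slice(max(0, dy), h - max(0, -dy))
        src_c = slice(max(0, -dx), w - max(0, dx))
        dst_c = slice(max(0, dx), w - max(0, -dx))
        out[dst_r, dst_c] = a[src_r, src_c]
        return out

    case_id, idx, _ = s.provenance
    return TrainingSlice(shift2d(s.image), shift2d(s.label),
                         (case_id, idx, f"shift{dx:+d}{dy:+d}"))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to peak magnitude 1."""
    f = gaussian_filter(rng.uniform(-1, 1, size=shape), sigma, mode="reflect")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def augment_deform_intensity(s: TrainingSlice, cfg: AugmentationConfig,
                             seed: int) -> TrainingSlice:
    """Non-rigid warp plus low-frequency multiplicative intensity variation.

    A smooth random displacement field (Gaussian-smoothed noise at scale
    ``deform_grid_sigma_px``, peak magnitude ``deform_alpha_px``) is applied
    identically to image (bicubic) and label (nearest-neighbour); a smooth
    multiplicative field 1 +/- ``intensity_field_amplitude`` then modulates
    the image only.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    h, w = s.image.shape
    dy = cfg.deform_alpha_px * _smooth_field(rng, (h, w), cfg.deform_grid_sigma_px)
    dx = cfg.deform_alpha_px * _smooth_field(rng, (h, w), cfg.deform_grid_sigma_px)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + dy, cc + dx])
    if cfg.deform_alpha_px > 0:
        image = map_coordinates(s.image.astype(np.float64), coords, order=3,
                                mode="reflect")
        label = map_coordinates(s.label, coords, order=0, mode="constant",
                                cval=0).astype(s.label.dtype)
    else:
        image = s.image.astype(np.float64).copy()
        label = s.label.copy()
    if cfg.intensity_field_amplitude > 0:
        gain = 1.0 + cfg.intensity_field_amplitude * _smooth_field(
            rng, (h, w), cfg.intensity_field_scale_px)
        image = image * gain
    case_id, idx, _ = s.provenance
    return TrainingSlice(image, label, (case_id, idx, f"deform{seed}"))


def build_training_set(cases: list[tuple[ImageVolume, np.ndarray]],
                       cfg: AugmentationConfig,
                       network_size: tuple[int, int] | None = None
                       ) -> list[TrainingSlice]:
    """Originals plus ``variants_per_slice`` augmented variants per slice,
    randomly shuffled.

    Each case is an (ImageVolume, binary mask) pair.  Slices are resampled
    to ``network_size`` (if given) and intensity-normalized first, so
    augmentation operates at network resolution.  The default two variants
    are one random shift draw and one deformation/intensity draw; further
    variants alternate between the two branches.
    """
    if not cases:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(cfg.seed)
    out: list[TrainingSlice] = []
    for vol, mask in cases:
        if vol.voxels.shape != mask.shape:
            raise ValueError(f"case {vol.case_id}: image/mask shape mismatch")
        for k in range(vol.n_slices):
            img, lab = vol.voxels[k], mask[k].astype(np.uint8)
            if network_size is not None and img.shape != tuple(network_size):
                img = resample_slice(img, network_size, order=3)
                lab = resample_slice(lab, network_size, order=0)
            img = normalize_intensity(img) if img.max() > img.min() else \
                np.zeros_like(img, dtype=np.float64)
            base = TrainingSlice(img, lab, (vol.case_id, k, "orig"))
            out.append(base)
            for v in range(cfg.variants_per_slice):
                if v % 2 == 0:
                    m = cfg.max_shift_px
                    dx = int(rng.integers(-m, m + 1)) if m else 0
                    dy = int(rng.integers(-m, m + 1)) if m else 0
                    out.append(augment_shift(base, dx, dy))
                else:
                    out.append(augment_deform_intensity(
                        base, cfg, seed=int(rng.integers(0, 2**31 - 1))))
    rng.shuffle(out)
    return out
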