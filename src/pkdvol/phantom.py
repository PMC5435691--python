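"""Seeded generator of synthetic polycystic-abdomen CT volumes.

Each phantom emulates the statistical structure of an axial abdominal CT in
a polycystic-kidney patient: a body outline, two laterally separated
enlarged kidneys built from an ellipsoid carrying many embedded cyst blobs
of variable intensity (dark fluid-filled and bright hemorrhagic), an
adjacent liver that may contain look-alike cysts which do NOT belong to the
kidney mask, and additive acquisition noise.  Intensities live in an
abstract [0, 4095] range; the pipeline later normalizes each slice to
[0, 255], so no Hounsfield calibration is attempted.

Geometry and noise are driven by independent sub-seeds, so the ground-truth
mask is reproducible under noise sweeps, and the stored ``true_tkv_ml`` is
by construction exactly the pixel-count volumetry of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .postprocess import compute_tkv
from .preprocess import ImageVolume

#: fraction of cysts drawn from the bright (hemorrhagic) intensity mode
BRIGHT_CYST_FRACTION = 0.25


@dataclass(frozen=True)
class IntensityLevels:
    """Mean intensities of the phantom tissue classes, abstract units."""

    background: float = 40.0
    body: float = 1000.0
    parenchyma: float = 1500.0
    cyst_fluid: float = 400.0
    cyst_bright: float = 2200.0
    liver: float = 1200.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, composition and noise of the synthetic cohort."""

    matrix_size: int = 512
    n_slices: int = 60
    pixel_spacing_mm: tuple[float, float] = (0.78, 0.78)
    slice_thickness_mm: float = 2.5
    kidney_size_range: tuple[float, float] = (0.16, 0.26)  # fraction of FOV
    n_cysts_per_kidney: tuple[int, int] = (8, 18)
    cyst_radius_range_mm: tuple[float, float] = (3.0, 14.0)
    liver_cyst_probability: float = 0.5
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    noise_sd: float = 40.0
    kidney_aspect: tuple[float, float, float] = (0.62, 0.80, 1.0)
    bilateral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 32:
            raise ValueError("matrix_size must be >= 32")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel_spacing_mm entries must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")
        lo, hi = self.kidney_size_range
        if not (0 < lo <= hi < 1):
            raise ValueError("kidney_size_range must satisfy 0 < low <= high < 1")
        if self.n_cysts_per_kidney[0] < 0 or \
                self.n_cysts_per_kidney[0] > self.n_cysts_per_kidney[1]:
            raise ValueError("n_cysts_per_kidney must be a non-negative range")
        if self.cyst_radius_range_mm[0] <= 0 or \
                self.cyst_radius_range_mm[0] > self.cyst_radius_range_mm[1]:
            raise ValueError("cyst_radius_range_mm must be a positive range")
        if not (0.0 <= self.liver_cyst_probability <= 1.0):
            raise ValueError("liver_cyst_probability must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.kidney_aspect) <= 0:
            raise ValueError("kidney_aspect entries must be > 0")

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.matrix_size * self.pixel_spacing_mm[0],
                self.matrix_size * self.pixel_spacing_mm[1])


@dataclass
class PhantomCase:
    """One synthetic acquisition: image volume, ground-truth mask, true TKV."""

    image: ImageVolume
    mask: np.ndarray
    true_tkv_ml: float
    case_id: str

    def __post_init__(self) -> None:
        if self.image.voxels.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask values must be in {0, 1}")


def _grids_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates in mm, broadcastable over (slice, row, col)."""
    sx, sy = spec.pixel_spacing_mm
    n = spec.matrix_size
    z = (np.arange(spec.n_slices, dtype=np.float64)[:, None, None] + 0.5) \
        * spec.slice_thickness_mm
    y = (np.arange(n, dtype=np.float64)[None, :, None] + 0.5) * sy
    x = (np.arange(n, dtype=np.float64)[None, None, :] + 0.5) * sx
    return z, y, x


def _ellipsoid(z, y, x, center: tuple[float, float, float],
               semiaxes: tuple[float, float, float]) -> np.ndarray:
    """Boolean voxelization of an axis-aligned ellipsoid (mm coordinates)."""
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return (((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2
            + ((x - cx) / ax) ** 2) <= 1.0


def _kidney_semiaxes_mm(spec: PhantomSpec, scale_frac: float
                        ) -> tuple[float, float, float]:
    """Semi-axes (z, y, x) in mm for a kidney whose x half-width is
    ``scale_frac`` of the field of view, at the spec's aspect ratio."""
    fov = min(spec.fov_mm)
    rx, ry, rz = spec.kidney_aspect
    s = scale_frac * fov / rx  # common scale so that x semiaxis = frac * fov
    return (rz * s, ry * s, rx * s)


def _semiaxes_for_volume(spec: PhantomSpec, volume_mm3: float
                         ) -> tuple[float, float, float]:
    rx, ry, rz = spec.kidney_aspect
    s = (volume_mm3 / (4.0 / 3.0 * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
    return (rz * s, ry * s, rx * s)


def _check_fits(spec: PhantomSpec, semiaxes: tuple[float, float, float]) -> None:
    az, ay, ax = semiaxes
    fov_x, fov_y = spec.fov_mm
    z_extent = spec.n_slices * spec.slice_thickness_mm
    max_x = 0.225 * fov_x if spec.bilateral else 0.45 * fov_x
    if ax > max_x or ay > 0.38 * fov_y or az > 0.5 * z_extent:
        raise ValueError(
            "requested kidney size exceeds the geometric limit of the "
            f"field of view: semiaxes (z,y,x)={tuple(round(a, 1) for a in semiaxes)} mm "
            f"vs limits ({0.5 * z_extent:.1f}, {0.38 * fov_y:.1f}, {max_x:.1f}) mm; "
            "increase matrix_size/n_slices or lower the target TKV")


def generate_case(spec: PhantomSpec, case_seed: int,
                  target_tkv_ml: float | None = None,
                  case_id: str | None = None) -> PhantomCase:
    """Build one phantom, deterministic for a fixed (spec, case_seed).

    ``target_tkv_ml`` overrides ``kidney_size_range`` and sizes the kidney
    ellipsoids so the realized TKV lands near the target (cyst blobs may
    bulge slightly beyond the base ellipsoid surface).
    """
    rng_geom = np.random.default_rng([spec.seed, case_seed, 1])
    rng_noise = np.random.default_rng([spec.seed, case_seed, 2])
    lv = spec.intensity_levels
    z, y, x = _grids_mm(spec)
    fov_x, fov_y = spec.fov_mm
    z_extent = spec.n_slices * spec.slice_thickness_mm

    img = np.full((spec.n_slices, spec.matrix_size, spec.matrix_size),
                  lv.background, dtype=np.float32)
    mask = np.zeros(img.shape, dtype=np.uint8)

    # body outline: elliptic cylinder through all slices
    body = _ellipsoid(z, y, x,
                      (z_extent / 2, fov_y / 2, fov_x / 2),
                      (z_extent * 10, 0.42 * fov_y, 0.47 * fov_x))
    img[body] = lv.body

    # liver: ellipsoid in the anterior image-left quadrant
    liver_center = (0.42 * z_extent, 0.36 * fov_y, 0.30 * fov_x)
    liver_axes = (0.34 * z_extent, 0.22 * fov_y, 0.21 * fov_x)
    liver = _ellipsoid(z, y, x, liver_center, liver_axes) & body
    img[liver] = lv.liver

    # kidney base ellipsoids
    if target_tkv_ml is not None:
        n_kid = 2 if spec.bilateral else 1
        semiaxes = _semiaxes_for_volume(spec, target_tkv_ml * 1000.0 / n_kid)
    else:
        frac = rng_geom.uniform(*spec.kidney_size_range) / 2.0
        semiaxes = _kidney_semiaxes_mm(spec, frac)
    _check_fits(spec, semiaxes)
    az, ay, ax = semiaxes
    ky = 0.60 * fov_y
    kz = 0.5 * z_extent
    centers = [(kz, ky, 0.27 * fov_x), (kz, ky, 0.73 * fov_x)] \
        if spec.bilateral else [(kz, ky, 0.5 * fov_x)]

    kidney_region = np.zeros(img.shape, dtype=bool)
    cyst_record: list[tuple[tuple[float, float, float], float, float]] = []
    for c in centers:
        kidney_region |= _ellipsoid(z, y, x, c, semiaxes)
        n_cysts = int(rng_geom.integers(spec.n_cysts_per_kidney[0],
                                        spec.n_cysts_per_kidney[1] + 1))
        for _ in range(n_cysts):
            r_lo, r_hi = spec.cyst_radius_range_mm
            r = rng_geom.uniform(r_lo, min(r_hi, 0.8 * min(semiaxes)))
            # position inside the ellipsoid, surface cysts allowed to bulge
            u = rng_geom.normal(size=3)
            u /= np.linalg.norm(u)
            radial = rng_geom.uniform(0, 0.95) ** (1.0 / 3.0)
            cc = (c[0] + radial * az * u[0], c[1] + radial * ay * u[1],
                  c[2] + radial * ax * u[2])
            bright = rng_geom.uniform() < BRIGHT_CYST_FRACTION
            intensity = lv.cyst_bright if bright else lv.cyst_fluid
            intensity *= rng_geom.uniform(0.85, 1.15)
            cyst_record.append((cc, r, intensity))
            kidney_region |= _ellipsoid(z, y, x, cc, (r, r, r))

    img[kidney_region] = lv.parenchyma
    for cc, r, intensity in cyst_record:
        img[_ellipsoid(z, y, x, cc, (r, r, r))] = intensity
    mask[kidney_region] = 1

    # liver cysts: look-alike blobs that are never part of the kidney mask
    if rng_geom.uniform() < spec.liver_cyst_probability:
        n_lc = int(rng_geom.integers(1, 4))
        for _ in range(n_lc):
            r = rng_geom.uniform(*spec.cyst_radius_range_mm)
            u = rng_geom.normal(size=3)
            u /= np.linalg.norm(u)
            radial = rng_geom.uniform(0, 0.8)
            cc = tuple(np.asarray(liver_center)
                       + radial * np.asarray(liver_axes) * u)
            blob = _ellipsoid(z, y, x, cc, (r, r, r)) & liver & ~kidney_region
            img[blob] = lv.cyst_fluid * rng_geom.uniform(0.85, 1.15)

    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd,
                                     size=img.shape).astype(np.float32)
    np.clip(img, 0.0, 4095.0, out=img)

    cid = case_id if case_id is not None else f"phantom-{case_seed:04d}"
    vol = ImageVolume(voxels=img, pixel_spacing_mm=spec.pixel_spacing_mm,
                      slice_thickness_mm=spec.slice_thickness_mm, case_id=cid)
    tkv = compute_tkv(mask, spec.pixel_spacing_mm, spec.slice_thickness_mm,
                      case_id=cid).tkv_ml
    return PhantomCase(image=vol, mask=mask, true_tkv_ml=tkv, case_id=cid)


def generate_cohort(spec: PhantomSpec, n_cases: int,
                    tkv_range_ml: tuple[float, float]) -> list[PhantomCase]:
    """A cohort whose realized true TKVs span ``tkv_range_ml`` roughly
    uniformly; case seeds derive from ``spec.seed``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    low, high = tkv_range_ml
    if not (0 < low < high):
        raise ValueError("tkv_range_ml must satisfy 0 < low < high")
    step = (high - low) / n_cases
    targets = low + (np.arange(n_cases) + 0.5) * step
    cases = []
    for i, t in enumerate(targets):
        cases.append(generate_case(spec, case_seed=i + 1, target_tkv_ml=float(t),
                                   case_id=f"phantom-{i + 1:04d}"))
    return cases
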