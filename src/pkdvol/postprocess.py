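"""From network probabilities to native-resolution kidney masks and TKV.

The slicewise predictions are thresholded (foreground iff p > t, default
t = 0.5), resampled back to the acquisition matrix with bicubic
interpolation and re-binarized, cleaned up with a per-slice morphological
closing plus small-component removal, and converted to total kidney volume
as  TKV [mL] = sum over slices of (foreground pixels x pixel spacing x x
pixel spacing y x slice thickness) / 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize

from .preprocess import ImageVolume, normalize_intensity, resample_slice


@dataclass
class TKVResult:
    """Volumetry of one binary mask volume."""

    case_id: str
    tkv_ml: float
    per_slice_areas_mm2: list[float]
    threshold_used: float = 0.5
    closing_radius_px: int = 3

    def __post_init__(self) -> None:
        if self.tkv_ml < 0:
            raise ValueError("tkv_ml must be >= 0")


@dataclass
class ThresholdReport:
    """Pixelwise classification metrics per candidate threshold.

    ``table`` has one row per candidate with sensitivity, specificity,
    accuracy, precision, F1 and Youden J = sensitivity + specificity - 1;
    ``selected`` maximizes J (ties resolve toward 0.5).
    """

    table: pd.DataFrame
    selected: float


def threshold_probabilities(prob: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Binary mask: foreground iff probability strictly greater than ``t``."""
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob > t).astype(np.uint8)


def select_threshold(prob_maps: list[np.ndarray], reference_masks: list[np.ndarray],
                     candidates: np.ndarray | None = None) -> ThresholdReport:
    """ROC-space threshold selection over pooled pixels.

    For each candidate the pooled confusion matrix yields sensitivity,
    specificity, accuracy, precision, F1 and the Youden index; the
    candidate maximizing J is selected.  A candidate is excluded from the
    ranking if sensitivity is undefined (no positive reference pixels).
    """
    if candidates is None:
        candidates = np.round(np.arange(0.05, 1.0, 0.05), 10)
    candidates = np.asarray(candidates, dtype=float)
    if np.any((candidates <= 0) | (candidates >= 1)):
        raise ValueError("candidate thresholds must lie in (0, 1)")
    if len(prob_maps) != len(reference_masks) or not prob_maps:
        raise ValueError("need equally many probability maps and reference masks")
    p = np.concatenate([np.asarray(m, dtype=float).ravel() for m in prob_maps])
    y = np.concatenate([np.asarray(m).astype(bool).ravel()
                        for m in reference_masks])
    if p.shape != y.shape:
        raise ValueError("probability map / reference mask shapes do not match")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    rows = []
    for t in candidates:
        pred = p > t
        tp = int(np.count_nonzero(pred & y))
        fp = int(np.count_nonzero(pred & ~y))
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos if n_pos else np.nan
        spec = tn / n_neg if n_neg else np.nan
        acc = (tp + tn) / y.size
        prec = tp / (tp + fp) if tp + fp else np.nan
        f1 = (2 * prec * sens / (prec + sens)
              if np.isfinite(prec) and np.isfinite(sens) and prec + sens > 0
              else np.nan)
        j = sens + spec - 1 if np.isfinite(sens) and np.isfinite(spec) else np.nan
        rows.append(dict(threshold=t, tp=tp, fp=fp, tn=tn, fn=fn,
                         sensitivity=sens, specificity=spec, accuracy=acc,
                         precision=prec, f1=f1, youden_j=j))
    table = pd.DataFrame(rows)
    ranked = table.dropna(subset=["youden_j"])
    if ranked.empty:
        raise ValueError("no candidate has a defined Youden index "
                         "(reference contains no positive pixels)")
    best_j = ranked["youden_j"].max()
    tied = ranked[np.isclose(ranked["youden_j"], best_j)]
    selected = float(tied.loc[(tied["threshold"] - 0.5).abs().idxmin(),
                              "threshold"])
    return ThresholdReport(table=table, selected=selected)


def restore_resolution(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bicubic resampling of a binary mask back to the acquisition matrix,
    re-binarized at 0.5.  Accepts a single slice or a slice stack."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("restore_resolution expects a binary mask")
    single = mask.ndim == 2
    stack = mask[None] if single else mask
    out = np.empty((stack.shape[0], *target), dtype=np.uint8)
    for k, sl in enumerate(stack):
        if sl.shape == tuple(target):
            out[k] = sl
            continue
        up = resize(sl.astype(np.float64), target, order=3,
                    anti_aliasing=False, preserve_range=True)
        out[k] = (up >= 0.5).astype(np.uint8)
    return out[0] if single else out


def morphological_close_and_denoise(mask: np.ndarray, closing_radius_px: int = 3,
                                    min_component_px: int = 50) -> np.ndarray:
    """Per-slice binary closing (disc element) then removal of connected
    components smaller than ``min_component_px`` pixels."""
    mask = np.asarray(mask).astype(bool)
    single = mask.ndim == 2
    stack = mask[None] if single else mask
    selem = disk(closing_radius_px) if closing_radius_px > 0 else None
    out = np.empty_like(stack, dtype=np.uint8)
    for k, sl in enumerate(stack):
        cl = ndimage.binary_closing(sl, structure=selem) \
            if selem is not None else sl
        if min_component_px > 1:
            labels, n = ndimage.label(cl)
            if n:
                sizes = np.bincount(labels.ravel())
                keep = sizes >= min_component_px
                keep[0] = False
                cl = keep[labels]
        out[k] = cl.astype(np.uint8)
    return out[0] if single else out


def compute_tkv(mask: np.ndarray, pixel_spacing_mm: tuple[float, float],
                slice_thickness_mm: float, case_id: str = "",
                **meta) -> TKVResult:
    """Pixel-count volumetry: foreground count x spacing_x x spacing_y x
    thickness, summed over slices, in millilitres."""
    sx, sy = pixel_spacing_mm
    if sx <= 0 or sy <= 0 or slice_thickness_mm <= 0:
        raise ValueError("pixel spacing and slice thickness must be > 0")
    mask = np.asarray(mask)
    stack = mask[None] if mask.ndim == 2 else mask
    counts = stack.reshape(stack.shape[0], -1).astype(bool).sum(axis=1)
    areas = [float(c * sx * sy) for c in counts]
    tkv_ml = float(counts.sum()) * sx * sy * slice_thickness_mm / 1000.0
    return TKVResult(case_id=case_id, tkv_ml=tkv_ml,
                     per_slice_areas_mm2=areas, **meta)


@dataclass
class KidneySegmenter:
    """A trained network bundled with its preprocessing mean and
    post-processing parameters; the unit that predicts whole cases."""

    net: "object"           # segnet.SegNet
    mean_value: float
    threshold: float = 0.5
    closing_radius_px: int = 3
    min_component_px: int = 50

    @property
    def input_size(self) -> tuple[int, int]:
        return tuple(self.net.spec.input_size)

    def predict_slice_probabilities(self, image: np.ndarray) -> np.ndarray:
        """Foreground probability map for one raw slice, at network resolution."""
        x = resample_slice(np.asarray(image, dtype=np.float64), self.input_size,
                           order=3)
        if x.max() > x.min():
            x = normalize_intensity(x)
        else:
            x = np.zeros_like(x)
        x = x - self.mean_value
        prob = self.net.forward(x[None].astype(np.float32))
        return prob[0, 1]

    def predict_slice(self, image: np.ndarray) -> np.ndarray:
        """Binary kidney mask for one raw slice, restored to its native size."""
        prob = self.predict_slice_probabilities(image)
        mask = threshold_probabilities(prob, self.threshold)
        mask = restore_resolution(mask, image.shape)
        return morphological_close_and_denoise(
            mask, self.closing_radius_px, self.min_component_px)


def predict_case(model: KidneySegmenter, image: ImageVolume
                 ) -> tuple[np.ndarray, np.ndarray, TKVResult]:
    """Slicewise resample -> normalize -> mean-subtract -> forward ->
    threshold -> restore -> close -> TKV for one CT volume.

    Returns (probability volume at network resolution, binary mask at
    native resolution, TKVResult).
    """
    if image.pixel_spacing_mm is None or image.slice_thickness_mm is None:
        raise ValueError("geometry metadata required for TKV computation")
    probs = np.stack([model.predict_slice_probabilities(sl)
                      for sl in image.voxels])
    masks = threshold_probabilities(probs, model.threshold)
    native = restore_resolution(masks, image.voxels.shape[1:])
    native = morphological_close_and_denoise(
        native, model.closing_radius_px, model.min_component_px)
    tkv = compute_tkv(native, image.pixel_spacing_mm, image.slice_thickness_mm,
                      case_id=image.case_id, threshold_used=model.threshold,
                      closing_radius_px=model.closing_radius_px)
    return probs, native, tkv
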