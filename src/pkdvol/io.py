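"""NIfTI and manifest I/O.

Volumes are written as NIfTI-1 with the in-plane pixel spacing and slice
thickness stored in the header zooms; the on-disk axis order is
(col, row, slice) so the zooms read (x, y, z).  Cohort manifests are plain
CSV files (case_id, seed, true_tkv_ml).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomCase
from .preprocess import ImageVolume


def save_volume(path: str | Path, volume: ImageVolume) -> None:
    """Write an ImageVolume as NIfTI with geometry in the header."""
    sx, sy = volume.pixel_spacing_mm
    data = np.asarray(volume.voxels).transpose(2, 1, 0)  # (x, y, z) on disk
    affine = np.diag([sx, sy, volume.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((sx, sy, volume.slice_thickness_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path, case_id: str | None = None) -> ImageVolume:
    img = nib.load(str(path))
    sx, sy, dz = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    cid = case_id if case_id is not None else Path(path).stem.split(".")[0]
    return ImageVolume(voxels=np.ascontiguousarray(data),
                       pixel_spacing_mm=(float(sx), float(sy)),
                       slice_thickness_mm=float(dz), case_id=cid)


def save_mask(path: str | Path, mask: np.ndarray,
              pixel_spacing_mm: tuple[float, float],
              slice_thickness_mm: float) -> None:
    sx, sy = pixel_spacing_mm
    data = np.asarray(mask, dtype=np.uint8).transpose(2, 1, 0)
    affine = np.diag([sx, sy, slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, slice_thickness_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    return (data > 0).astype(np.uint8)


def save_cohort(out_dir: str | Path, cases: list[PhantomCase],
                seed: int | None = None) -> Path:
    """Write per-case image/mask NIfTI pairs plus a manifest CSV; returns
    the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        save_volume(out / f"{case.case_id}_image.nii.gz", case.image)
        save_mask(out / f"{case.case_id}_mask.nii.gz", case.mask,
                  case.image.pixel_spacing_mm, case.image.slice_thickness_mm)
        rows.append(dict(case_id=case.case_id, seed=seed,
                         true_tkv_ml=case.true_tkv_ml))
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(in_dir: str | Path) -> list[PhantomCase]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    cases = []
    for row in manifest.itertuples():
        vol = load_volume(in_dir / f"{row.case_id}_image.nii.gz", row.case_id)
        mask = load_mask(in_dir / f"{row.case_id}_mask.nii.gz")
        cases.append(PhantomCase(image=vol, mask=mask,
                                 true_tkv_ml=float(row.true_tkv_ml),
                                 case_id=str(row.case_id)))
    return cases
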