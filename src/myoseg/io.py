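"""Dataset I/O: 16-bit grayscale PNG or float NIfTI images, {0,1} masks,
and a CSV manifest tying slices to subjects and domains."""

from __future__ import annotations

import os

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import DomainDataset, PhantomSlice

MANIFEST_COLUMNS = ["subject_id", "slice_idx", "image_path", "mask_path",
                    "domain", "infiltration_fraction"]


def write_image(path: str, image: np.ndarray) -> None:
    """Write a [0,1] float image as 16-bit PNG or float32 NIfTI by extension."""
    if path.endswith(".png"):
        iio.imwrite(path, np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16))
    elif path.endswith(".nii") or path.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(image.astype(np.float32), affine=np.eye(4)), path)
    else:
        raise ValueError(f"unknown image format: {path}")


def read_image(path: str) -> np.ndarray:
    if path.endswith(".png"):
        arr = iio.imread(path)
        if arr.dtype == np.uint16:
            return arr.astype(np.float64) / 65535.0
        return arr.astype(np.float64) / 255.0
    if path.endswith(".nii") or path.endswith(".nii.gz"):
        return np.asarray(nib.load(path).dataobj, dtype=np.float64)
    raise ValueError(f"unknown image format: {path}")


def write_mask(path: str, mask: np.ndarray) -> None:
    if path.endswith(".png"):
        iio.imwrite(path, mask.astype(np.uint8))
    elif path.endswith(".nii") or path.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), path)
    else:
        raise ValueError(f"unknown mask format: {path}")


def read_mask(path: str) -> np.ndarray:
    if path.endswith(".png"):
        return iio.imread(path).astype(np.uint8) > 0
    if path.endswith(".nii") or path.endswith(".nii.gz"):
        return np.asarray(nib.load(path).dataobj) > 0
    raise ValueError(f"unknown mask format: {path}")


def write_dataset(dataset: DomainDataset, directory: str, fmt: str = "png") -> pd.DataFrame:
    """Write one image + one muscle-mask file per slice plus a CSV manifest.

    Returns the manifest as a DataFrame; it is also saved as
    ``manifest.csv`` inside ``directory``.
    """
    if fmt not in ("png", "nifti"):
        raise ValueError(f"unknown format: {fmt}")
    ext = "png" if fmt == "png" else "nii"
    os.makedirs(directory, exist_ok=True)
    rows = []
    for idx, sl in enumerate(dataset.slices):
        img_path = os.path.join(directory, f"{sl.subject_id}_{idx:04d}_img.{ext}")
        msk_path = os.path.join(directory, f"{sl.subject_id}_{idx:04d}_mask.{ext}")
        write_image(img_path, sl.image)
        write_mask(msk_path, sl.muscle_mask)
        rows.append({
            "subject_id": sl.subject_id, "slice_idx": idx,
            "image_path": img_path, "mask_path": msk_path,
            "domain": dataset.domain_label,
            "infiltration_fraction": sl.realized_infiltration_fraction,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest


def read_dataset(directory: str) -> DomainDataset:
    """Read a dataset back from a directory written by :func:`write_dataset`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    slices = []
    domain = str(manifest["domain"].iloc[0])
    empty = None
    for _, row in manifest.iterrows():
        img = read_image(row["image_path"])
        mask = read_mask(row["mask_path"])
        if empty is None:
            empty = np.zeros_like(mask, dtype=bool)
        slices.append(PhantomSlice(
            image=img, muscle_mask=mask, fat_mask=empty, bone_mask=empty,
            infiltration_mask=empty,
            realized_infiltration_fraction=float(row["infiltration_fraction"]),
            subject_id=str(row["subject_id"]),
        ))
    return DomainDataset(slices=slices, domain_label=domain)
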