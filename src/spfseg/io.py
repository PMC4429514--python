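"""Image and volume I/O.

Grayscale PNG/TIFF images are read through imageio and min–max rescaled to
[0, 1] (the scale every solver default is calibrated to); NIfTI volumes are
read through nibabel, normalized once per volume, and segmented slice-wise.
Label maps are written as 8-bit PNG (raw label values) or integer NIfTI.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "normalize_intensity",
    "load_image",
    "save_image",
    "load_labels",
    "save_labels",
    "load_volume",
    "save_volume",
    "get_slice",
]

logger = logging.getLogger(__name__)

NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path) -> bool:
    name = str(path).lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def normalize_intensity(values: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; constant inputs map to 0.5 with a warning."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        logger.warning("constant-intensity input; mapping to 0.5 everywhere")
        return np.full_like(values, 0.5)
    return (values - vmin) / (vmax - vmin)


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG/TIFF as a [0, 1] float field."""
    path = Path(path)
    if not path.exists():
        raise ValueError(f"no such image file: {path}")
    if _is_nifti(path):
        raise ValueError(f"{path} is a NIfTI volume; use load_volume/get_slice")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise ValueError(f"unreadable image {path} ({path.suffix or 'no suffix'}): {exc}") from exc
    if raw.ndim == 3:
        raise ValueError(
            f"{path} is multichannel ({raw.shape[-1]} channels); "
            "convert to single-channel grayscale first"
        )
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {raw.shape}")
    return normalize_intensity(raw)


def save_image(path, values: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] float field as 8- or 16-bit grayscale PNG/TIFF."""
    values = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(values * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(values * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), data)


def load_labels(path) -> np.ndarray:
    """Read an integer label map (8-bit PNG) without intensity rescaling."""
    raw = iio.imread(Path(path))
    if raw.ndim != 2:
        raise ValueError(f"{path}: label maps must be single-channel, got shape {raw.shape}")
    return raw.astype(np.int32)


def save_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("labels must fit in uint8")
    iio.imwrite(Path(path), labels.astype(np.uint8))


def load_volume(path):
    """Read a NIfTI volume; returns ``(data, affine)`` with data in [0, 1]."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return normalize_intensity(data), img.affine


def save_volume(path, data: np.ndarray, affine=None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def get_slice(volume: np.ndarray, axis: int, index: int) -> np.ndarray:
    """Extract one 2-D plane from a 3-D volume along ``axis``."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={volume.ndim}")
    if not 0 <= axis < 3:
        raise ValueError("axis must be 0, 1 or 2")
    return np.take(volume, index, axis=axis)
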