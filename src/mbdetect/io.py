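"""Readers and writers for grayscale slices (PNG, single-slice NIfTI)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_png", "write_nifti"]

logger = logging.getLogger("mbdetect")

_PNG_SUFFIXES = {".png"}


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path) -> np.ndarray:
    """Read a grayscale 2-D slice scaled to [0, 1].

    PNG images are de-quantised by the integer dtype maximum.  NIfTI
    volumes with more than one slice yield the middle slice along the last
    axis (with a warning).  Float-valued NIfTI data already in [0, 1] is
    passed through; other float ranges are scaled by their maximum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # RGB(A): luminance of the first three channels
            arr = arr[..., :3].mean(axis=-1)
        if np.issubdtype(arr.dtype, np.integer):
            return arr.astype(float) / np.iinfo(arr.dtype).max
        return np.clip(arr.astype(float), 0.0, 1.0)
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).get_fdata())
        data = np.squeeze(data)
        if data.ndim == 3:
            mid = data.shape[-1] // 2
            logger.warning(
                "%s has %d slices; using middle slice %d", path.name, data.shape[-1], mid
            )
            data = data[..., mid]
        if data.ndim != 2:
            raise IOError(f"NIfTI file {path} does not contain a 2-D slice")
        data = data.astype(float)
        mx = data.max()
        if mx > 1.0 + 1e-6:
            data = data / mx
        return np.clip(data, 0.0, 1.0)
    raise IOError(f"unsupported image format {path.suffix!r} for {path}")


def write_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_nifti(path, image: np.ndarray, mm_per_pixel: float = 2.0) -> None:
    """Write a [0, 1] float image as a single-slice NIfTI volume."""
    import nibabel as nib

    arr = np.asarray(image, dtype=np.float32)[..., None]
    affine = np.diag([mm_per_pixel, mm_per_pixel, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
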