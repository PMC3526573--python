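"""Image loading, greyscale conversion and spatial calibration.

Phase-contrast micrographs arrive as 8- or 16-bit RGB or greyscale PNG/TIFF.
All downstream texture analysis operates on a double-precision luminance
plane carrying an area-per-pixel calibration so that pixel counts convert
to physical colony areas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRAYSCALE_WEIGHTS",
    "CALIBRATION_PROFILES",
    "GrayImage",
    "to_grayscale",
    "load_image",
    "save_image",
]

#: Channel weights for luminance conversion (red, green, blue).  They sum to
#: 1.0 and are deliberately not renormalised.
GRAYSCALE_WEIGHTS: tuple[float, float, float] = (0.290, 0.570, 0.140)

#: Named calibration profiles mapping acquisition setup -> area per pixel in
#: µm².  The 4x objective at 1280x960 is the reference setup; other setups
#: must supply an explicit calibration.
CALIBRATION_PROFILES: dict[str, float] = {
    "4x_1280x960": 2.86,
}

DEFAULT_PROFILE = "4x_1280x960"


@dataclass
class GrayImage:
    """A 2-D luminance image with spatial calibration.

    Parameters
    ----------
    pixels
        H x W array of real-valued luminance (arbitrary camera units).
    area_per_pixel_um2
        Physical area covered by one pixel, in µm².  Must be positive.
    magnification
        Free-form tag describing the acquisition setup (e.g. ``"4x"``).
    """

    pixels: np.ndarray
    area_per_pixel_um2: float = CALIBRATION_PROFILES[DEFAULT_PROFILE]
    magnification: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"GrayImage expects a 2-D array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if not (self.area_per_pixel_um2 > 0):
            raise ValueError("calibration (area per pixel) must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def to_grayscale(
    pixels: np.ndarray,
    weights: tuple[float, float, float] = GRAYSCALE_WEIGHTS,
    *,
    area_per_pixel_um2: float = CALIBRATION_PROFILES[DEFAULT_PROFILE],
    magnification: str | None = None,
) -> GrayImage:
    """Convert an RGB image to a weighted-average luminance plane.

    Each output pixel is ``w_r*R + w_g*G + w_b*B`` in double precision; no
    re-quantisation takes place.  A 2-D input is assumed to be luminance
    already and is passed through unchanged.

    Raises
    ------
    ValueError
        If the input is not H x W or H x W x 3, or a weight is negative.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if any(w < 0 for w in weights):
        raise ValueError("greyscale weights must be non-negative")
    if arr.ndim == 2:
        return GrayImage(arr, area_per_pixel_um2, magnification)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB array, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)) or arr.min() < 0:
        raise ValueError("RGB intensities must be finite and non-negative")
    gray = arr[..., 0] * weights[0] + arr[..., 1] * weights[1] + arr[..., 2] * weights[2]
    return GrayImage(gray, area_per_pixel_um2, magnification)


def _resolve_calibration(profile: str | None, calibration: float | None) -> float:
    if calibration is not None:
        if not calibration > 0:
            raise ValueError("explicit calibration must be positive")
        return float(calibration)
    if profile is None:
        profile = DEFAULT_PROFILE
    try:
        return CALIBRATION_PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown calibration profile {profile!r}; supply calibration= "
            f"explicitly or one of {sorted(CALIBRATION_PROFILES)}"
        ) from None


def load_image(
    path: str | os.PathLike,
    profile: str | None = DEFAULT_PROFILE,
    *,
    calibration: float | None = None,
    weights: tuple[float, float, float] = GRAYSCALE_WEIGHTS,
) -> GrayImage:
    """Read a PNG/TIFF micrograph and return a calibrated greyscale image.

    RGB inputs are converted with :func:`to_grayscale`; RGBA alpha is
    dropped; single-channel inputs pass through unchanged.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    cal = _resolve_calibration(profile, calibration)
    return to_grayscale(arr, weights, area_per_pixel_um2=cal)


def save_image(path: str | os.PathLike, img: GrayImage | np.ndarray) -> None:
    """Write a greyscale image as TIFF (float32) or PNG (8/16-bit).

    PNG output scales floats into the 16-bit range only when values exceed
    the 8-bit range; integer arrays are written as-is.
    """
    path = os.fspath(path)
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.float32))
        return
    import imageio.v3 as iio

    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == np.uint8:
        iio.imwrite(path, arr)
    else:
        lo, hi = float(arr.min()), float(arr.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        iio.imwrite(path, ((arr - lo) * scale).astype(np.uint16))
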