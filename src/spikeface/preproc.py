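"""Image loading, masking, illumination normalization and the retina stage.

The retina stage models ON/OFF ganglion cells with a center–surround
operator: the Laplacian-of-Gaussian–form kernel

    K(x, y) = g · (x² + y² − σ²)/σ⁴ · exp(−(x² + y²) / (2σ²))

evaluated on an integer grid, DC-corrected so a uniform field produces no
response.  Positive rectified responses form the ON map, negative ones the
OFF map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import exposure

from ._filters import correlate2d_reflect
from .errors import InputError, ParameterError, SizeError

MIN_SIDE = 16

__all__ = [
    "GrayImage",
    "RetinaKernelParams",
    "RetinaMaps",
    "load_gray_image",
    "apply_face_mask",
    "normalize_illumination",
    "retina_kernel",
    "retina_response",
]


@dataclass(frozen=True)
class GrayImage:
    """A single grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ParameterError("GrayImage expects a 2-D intensity array")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise SizeError(
                f"image {px.shape} smaller than minimum "
                f"{MIN_SIDE}x{MIN_SIDE} face crop"
            )
        if not np.all(np.isfinite(px)):
            raise ParameterError("image intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ParameterError("image intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_gray_image(path) -> GrayImage:
    """Load a raster image as a [0, 1]-scaled grayscale array.

    RGB(A) input is collapsed to luminance (ITU-R 601 weights); integer
    bit depths are rescaled by their maximum representable value.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise InputError(f"cannot read image file: {path}") from exc
    if arr.dtype == np.uint16 or (arr.dtype.kind == "i" and arr.dtype.itemsize > 1):
        scale = 65535.0
    elif arr.dtype.kind == "f":
        scale = 1.0
    else:
        scale = 255.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    px = np.clip(arr / scale, 0.0, 1.0)
    return GrayImage(px)


def apply_face_mask(img: GrayImage, margin_frac: float = 0.0) -> GrayImage:
    """Zero out pixels outside an inscribed axis-aligned ellipse.

    The ellipse is inscribed in the image and shrunk by ``margin_frac``
    per axis, removing background and hair from a roughly centred face
    crop.  The operation is idempotent.
    """
    if not (0.0 <= margin_frac <= 0.4):
        raise ParameterError("margin_frac must lie in [0, 0.4]")
    h, w = img.pixels.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a = (w / 2.0) * (1.0 - margin_frac)
    b = (h / 2.0) * (1.0 - margin_frac)
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return GrayImage(np.where(inside, img.pixels, 0.0))


def normalize_illumination(img: GrayImage, method: str = "histeq") -> GrayImage:
    """Normalize global illumination.

    ``histeq``
        histogram equalization (flattens the intensity distribution).
    ``meanvar``
        standardize to zero mean / unit variance, then rescale affinely
        into [0, 1]; a constant image maps to constant 0.5.
    """
    px = img.pixels
    if method == "histeq":
        if np.ptp(px) == 0.0:
            return img
        return GrayImage(np.clip(exposure.equalize_hist(px), 0.0, 1.0))
    if method == "meanvar":
        sd = px.std()
        if sd < 1e-12 or np.ptp(px) == 0.0:
            return GrayImage(np.full_like(px, 0.5))
        z = (px - px.mean()) / sd
        z = (z - z.min()) / (z.max() - z.min())
        return GrayImage(z)
    raise ParameterError(f"unknown illumination method: {method!r}")


@dataclass(frozen=True)
class RetinaKernelParams:
    """Parameters of the center–surround retina kernel.

    sigma : spatial scale of the Gaussian (pixels)
    gain : output gain g
    support_radius : integer truncation radius; default ceil(3·sigma)
    """

    sigma: float
    gain: float = 1.0
    support_radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.gain <= 0:
            raise ParameterError("gain must be positive")
        r_min = math.ceil(3.0 * self.sigma)
        if self.support_radius is None:
            object.__setattr__(self, "support_radius", r_min)
        elif int(self.support_radius) < r_min:
            raise ParameterError(
                f"support_radius must be >= ceil(3*sigma) = {r_min}"
            )
        else:
            object.__setattr__(self, "support_radius", int(self.support_radius))


@dataclass(frozen=True)
class RetinaMaps:
    """Rectified ON/OFF contrast maps (non-negative, same shape as input)."""

    on_map: np.ndarray
    off_map: np.ndarray


def retina_kernel(params: RetinaKernelParams) -> np.ndarray:
    """Evaluate the center–surround kernel on [−r, r]², zero-DC corrected.

    After truncation the analytic zero integral no longer holds exactly,
    so a constant is subtracted to make the entries sum to zero.
    """
    r = params.support_radius
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    r2 = x * x + y * y
    s2 = params.sigma**2
    k = params.gain * (r2 - s2) / (s2 * s2) * np.exp(-r2 / (2.0 * s2))
    return k - k.mean()


def retina_response(img: GrayImage, params: RetinaKernelParams) -> RetinaMaps:
    """ON/OFF maps: same-size correlation with the retina kernel, rectified.

    Reflective border handling keeps the output the size of the input and
    avoids spurious edge responses from zero padding.
    """
    kern = retina_kernel(params)
    resp = correlate2d_reflect(img.pixels, kern)
    return RetinaMaps(on_map=np.maximum(resp, 0.0), off_map=np.maximum(-resp, 0.0))
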