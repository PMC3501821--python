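"""Shared 2-D correlation helper with reflective border handling."""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .errors import SizeError


def correlate2d_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size 2-D correlation of ``img`` with ``kernel``.

    The image is padded with edge-inclusive symmetric reflection so the
    output has the input's shape and constant regions stay constant at the
    border.  ``kernel`` must have odd side lengths.  Complex kernels are
    supported; the output is then complex.
    """
    img = np.asarray(img)
    kernel = np.asarray(kernel)
    kh, kw = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise SizeError("kernel sides must be odd")
    if kh > img.shape[0] or kw > img.shape[1]:
        raise SizeError(
            f"kernel {kernel.shape} larger than image {img.shape}"
        )
    ry, rx = kh // 2, kw // 2
    padded = np.pad(img, ((ry, ry), (rx, rx)), mode="symmetric")
    # correlation == convolution with the doubly flipped kernel
    return fftconvolve(padded, kernel[::-1, ::-1], mode="valid")
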