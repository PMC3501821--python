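"""Gabor-wavelet V1 stage: 8 orientation maps per frequency scale.

Simple cells are modelled by the complex Gabor kernel

    ψ_{μ,ν}(z) = (‖k‖²/σ²) · exp(−‖k‖²‖z‖²/(2σ²)) · [e^{i k·z} − e^{−σ²/2}]

with wave vector k = k_ν (cos ψ_μ, sin ψ_μ), k_ν = k_max / f^ν and
ψ_μ = πμ/8, μ = 0..7.  The modulus of the complex response models the
phase-invariant behaviour of complex cells and feeds the later stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._filters import correlate2d_reflect
from .errors import ParameterError

N_ORIENTATIONS = 8

__all__ = [
    "GaborParams",
    "OrientationMaps",
    "gabor_kernel",
    "filter_bank",
    "gabor_response_complex",
    "v1_response",
]


@dataclass(frozen=True)
class GaborParams:
    """One (orientation, scale) cell of the Gabor filter bank.

    mu : orientation index in 0..7 (angle ψ_μ = πμ/8)
    nu : scale index (k_ν = kmax / spacing^ν)
    sigma : dimensionless envelope width σ
    kmax : peak spatial frequency (radians / pixel)
    spacing : frequency spacing factor f (> 1)
    support_radius : truncation radius in pixels; defaults to three
        envelope standard deviations, ceil(3σ/k_ν)
    """

    mu: int
    nu: int
    sigma: float = 2.0 * math.pi
    kmax: float = math.pi / 2.0
    spacing: float = math.sqrt(2.0)
    support_radius: int | None = None

    def __post_init__(self) -> None:
        if self.mu not in range(N_ORIENTATIONS):
            raise ParameterError("mu must be an integer in 0..7")
        if self.nu < 0 or int(self.nu) != self.nu:
            raise ParameterError("nu must be a non-negative integer")
        if self.sigma <= 0 or self.kmax <= 0:
            raise ParameterError("sigma and kmax must be positive")
        if self.spacing <= 1:
            raise ParameterError("spacing must exceed 1")
        if self.support_radius is None:
            object.__setattr__(
                self, "support_radius", math.ceil(3.0 * self.sigma / self.k_mag)
            )
        else:
            object.__setattr__(self, "support_radius", int(self.support_radius))

    @property
    def k_mag(self) -> float:
        """Wave-vector magnitude k_ν = kmax / spacing^ν."""
        return self.kmax / self.spacing**self.nu

    @property
    def angle(self) -> float:
        """Orientation angle ψ_μ = πμ/8 in radians."""
        return math.pi * self.mu / N_ORIENTATIONS

    @property
    def kvec(self) -> tuple[float, float]:
        return (self.k_mag * math.cos(self.angle), self.k_mag * math.sin(self.angle))


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Complex Gabor kernel on the grid [−r, r]².

    The e^{−σ²/2} term cancels the DC component analytically on the
    continuous plane; a small envelope-weighted correction removes the
    residual DC introduced by truncation and sampling, so uniform input
    produces (numerically) zero response.
    """
    r = params.support_radius
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    k2 = params.k_mag**2
    s2 = params.sigma**2
    env = (k2 / s2) * np.exp(-k2 * (x * x + y * y) / (2.0 * s2))
    kx, ky = params.kvec
    carrier = np.exp(1j * (kx * x + ky * y))
    kern = env * (carrier - math.exp(-s2 / 2.0))
    return kern - env * (kern.sum() / env.sum())


def filter_bank(
    n_scales: int,
    sigma: float = 2.0 * math.pi,
    kmax: float = math.pi / 2.0,
    spacing: float = math.sqrt(2.0),
) -> list[GaborParams]:
    """All 8·n_scales (scale, orientation) kernels, scale-major order."""
    if n_scales < 1:
        raise ParameterError("n_scales must be >= 1")
    return [
        GaborParams(mu=mu, nu=nu, sigma=sigma, kmax=kmax, spacing=spacing)
        for nu in range(n_scales)
        for mu in range(N_ORIENTATIONS)
    ]


@dataclass(frozen=True)
class OrientationMaps:
    """Modulus responses indexed (scale, orientation, row, col)."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=np.float64)
        if m.ndim != 4 or m.shape[1] != N_ORIENTATIONS:
            raise ParameterError(
                "maps must have shape (n_scales, 8, height, width)"
            )
        if not np.all(np.isfinite(m)) or m.min() < 0:
            raise ParameterError("responses must be finite and non-negative")
        object.__setattr__(self, "maps", m)

    @property
    def n_scales(self) -> int:
        return self.maps.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.maps.shape[1]


def gabor_response_complex(img: np.ndarray, params: GaborParams) -> np.ndarray:
    """Complex (simple-cell-like) response; real/imag are the two phases."""
    return correlate2d_reflect(np.asarray(img, dtype=np.float64), gabor_kernel(params))


def v1_response(img: np.ndarray, bank: list[GaborParams]) -> OrientationMaps:
    """Modulus (complex-cell-like) responses for every kernel in the bank."""
    img = np.asarray(img, dtype=np.float64)
    scales = sorted({p.nu for p in bank})
    if scales != list(range(len(scales))):
        raise ParameterError("bank must cover scales 0..n_scales-1")
    out = np.zeros((len(scales), N_ORIENTATIONS) + img.shape)
    for p in bank:
        out[p.nu, p.mu] = np.abs(gabor_response_complex(img, p))
    return OrientationMaps(out)
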