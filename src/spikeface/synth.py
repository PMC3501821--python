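"""Synthetic face-like images and TICA benchmark sources.

The face generator stands in for labelled expression photographs: an oval
face on a dark background, two eye ellipses whose height tracks
``eye_openness``, mirrored eyebrow segments rotated by ``brow_angle`` and
a quadratic mouth curve with signed ``mouth_curvature``.  Five expression
classes (happy, sad, surprise, anger, neutral) are defined by disjoint
sampling ranges of those three shape parameters, so the classes are
separable by construction and any end-to-end failure is a pipeline
fault, not a data fault.  An optional multiplicative lateral illumination
ramp (0° frontal … 90° fully lateral) and additive Gaussian noise emulate
acquisition nuisances.

The TICA source generator produces either independent unit-variance
Laplacian sources or Gaussian sources whose variance field is shared
within index neighborhoods of width m — exactly the higher-order energy
dependency the topographic model assumes — mixed through a seeded
well-conditioned square matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DataError, ParameterError
from .preproc import GrayImage
from .tica import neighborhood_matrix

EXPRESSIONS = ("anger", "happy", "neutral", "sad", "surprise")

# Class-conditional sampling ranges for (mouth_curvature, eye_openness,
# brow_angle).  Chosen disjoint enough that a threshold rule on the
# manifest recovers the labels exactly (see oracle_classify).
_CLASS_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "happy": {"curv": (0.55, 0.90), "eye": (0.40, 0.65), "brow": (-0.06, 0.06)},
    "sad": {"curv": (-0.90, -0.55), "eye": (0.40, 0.65), "brow": (-0.06, 0.06)},
    "surprise": {"curv": (-0.10, 0.10), "eye": (0.85, 1.00), "brow": (0.25, 0.45)},
    "anger": {"curv": (-0.20, -0.02), "eye": (0.30, 0.50), "brow": (-0.50, -0.28)},
    "neutral": {"curv": (-0.08, 0.08), "eye": (0.45, 0.62), "brow": (-0.05, 0.05)},
}

__all__ = [
    "EXPRESSIONS",
    "SyntheticFaceSpec",
    "TicaSourceSpec",
    "sample_face_spec",
    "make_face",
    "make_dataset",
    "oracle_classify",
    "make_tica_sources",
]


@dataclass(frozen=True)
class SyntheticFaceSpec:
    """Parametric description of one generated face-like image."""

    expression: str
    size: int = 64
    mouth_curvature: float = 0.0
    eye_openness: float = 0.5
    brow_angle: float = 0.0
    illum_angle: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expression not in EXPRESSIONS:
            raise ParameterError(f"unknown expression {self.expression!r}")
        if self.size < 32:
            raise ParameterError("size must be at least 32 pixels")
        if not (0.0 < self.eye_openness <= 1.0):
            raise ParameterError("eye_openness must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def sample_face_spec(
    expression: str,
    rng: np.random.Generator,
    size: int = 64,
    illum_angle: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticFaceSpec:
    """Draw shape parameters from the expression's class ranges."""
    if expression not in _CLASS_RANGES:
        raise ParameterError(f"unknown expression {expression!r}")
    r = _CLASS_RANGES[expression]
    return SyntheticFaceSpec(
        expression=expression,
        size=size,
        mouth_curvature=float(rng.uniform(*r["curv"])),
        eye_openness=float(rng.uniform(*r["eye"])),
        brow_angle=float(rng.uniform(*r["brow"])),
        illum_angle=illum_angle,
        noise_sd=noise_sd,
        seed=seed,
    )


def _segment_mask(
    xx: np.ndarray,
    yy: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    thickness: float,
) -> np.ndarray:
    """Pixels within ``thickness`` of the segment p0–p1 (x, y coords)."""
    px = xx - p0[0]
    py = yy - p0[1]
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    L2 = dx * dx + dy * dy
    t = np.clip((px * dx + py * dy) / L2, 0.0, 1.0)
    d2 = (px - t * dx) ** 2 + (py - t * dy) ** 2
    return d2 <= thickness**2


def make_face(spec: SyntheticFaceSpec) -> tuple[GrayImage, str]:
    """Render the face described by ``spec``; deterministic given seed.

    With ``illum_angle = 0`` and ``noise_sd = 0`` the image is exactly
    symmetric about the vertical midline (all features are mirrored).
    """
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cx = cy = (s - 1) / 2.0
    img = np.full((s, s), 0.05)

    # face oval
    fa, fb = 0.42 * s, 0.46 * s
    face = ((xx - cx) / fa) ** 2 + ((yy - cy) / fb) ** 2 <= 1.0
    img[face] = 0.80

    # eyes: height proportional to eye_openness
    ex, ey = 0.16 * s, cy - 0.12 * s
    ea, eb = 0.07 * s, 0.06 * s * spec.eye_openness
    for sign in (-1.0, 1.0):
        eye = ((xx - (cx + sign * ex)) / ea) ** 2 + ((yy - ey) / eb) ** 2 <= 1.0
        img[eye] = 0.15

    # eyebrows: mirrored segments rotated by brow_angle
    by = cy - 0.24 * s
    bl = 0.09 * s
    bt = 0.012 * s
    for sign in (-1.0, 1.0):
        bx = cx + sign * ex
        dx = bl * float(np.cos(spec.brow_angle))
        dy = bl * float(np.sin(spec.brow_angle))
        # mirrored: the outer end rises with positive brow_angle on both sides
        inner = (bx - sign * dx, by + dy)
        outer = (bx + sign * dx, by - dy)
        img[_segment_mask(xx, yy, inner, outer, bt)] = 0.15

    # mouth: quadratic curve, signed curvature (positive = smile)
    my = cy + 0.24 * s
    halfw = 0.16 * s
    u = (xx - cx) / halfw
    row_c = my - 0.16 * s * spec.mouth_curvature * (u * u - 1.0 / 3.0)
    mouth = (np.abs(xx - cx) <= halfw) & (np.abs(yy - row_c) <= 0.022 * s)
    img[mouth] = 0.15

    # multiplicative lateral illumination ramp
    if spec.illum_angle != 0.0:
        ramp = 1.0 + 0.5 * np.sin(np.deg2rad(spec.illum_angle)) * (xx - cx) / cx
        img = img * ramp

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    return GrayImage(np.clip(img, 0.0, 1.0)), spec.expression


def oracle_classify(
    mouth_curvature: float, eye_openness: float, brow_angle: float
) -> str:
    """Threshold rule on the generating parameters; exact by construction."""
    if eye_openness >= 0.80:
        return "surprise"
    if brow_angle <= -0.20:
        return "anger"
    if mouth_curvature >= 0.40:
        return "happy"
    if mouth_curvature <= -0.40:
        return "sad"
    return "neutral"


def make_dataset(
    root,
    n_per_class: int = 20,
    classes: tuple[str, ...] = EXPRESSIONS,
    size: int = 64,
    illum_angles: tuple[float, ...] = (0.0,),
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``<root>/<class>/<name>.png`` images plus a manifest CSV.

    Within-class variation is drawn from the class parameter ranges with
    a per-image seed derived from ``seed``, so the same seed reproduces
    the identical manifest and images bit for bit.  Illumination angles
    cycle over ``illum_angles``.
    """
    if n_per_class < 2:
        raise DataError("need at least 2 images per class")
    root = Path(root)
    rng = np.random.default_rng(seed)
    rows = []
    for cls in classes:
        (root / cls).mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            child = int(rng.integers(0, 2**31 - 1))
            crng = np.random.default_rng(child)
            spec = sample_face_spec(
                cls,
                crng,
                size=size,
                illum_angle=float(illum_angles[i % len(illum_angles)]),
                noise_sd=noise_sd,
                seed=child,
            )
            img, label = make_face(spec)
            name = f"{cls}_{i:03d}_{child:08x}.png"
            path = root / cls / name
            Image.fromarray((img.pixels * 255).round().astype(np.uint8)).save(path)
            row = {"path": str(path), "class": label}
            row.update(asdict(spec))
            rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


@dataclass(frozen=True)
class TicaSourceSpec:
    """Benchmark source model for the TICA recovery tests."""

    n_sources: int
    n_samples: int
    m: int = 1
    base_dist: str = "laplace"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ParameterError("need at least 2 sources")
        if self.n_samples < 10 * self.n_sources:
            raise ParameterError("need n_samples >= 10 * n_sources")
        if self.base_dist not in ("laplace", "gauss_variance_modulated"):
            raise ParameterError(f"unknown base_dist {self.base_dist!r}")


def make_tica_sources(
    spec: TicaSourceSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (S, A_true, X) with X = A_true · S.

    ``laplace`` draws independent unit-variance Laplacian sources;
    ``gauss_variance_modulated`` draws s_i = σ_i·g_i with iid standard
    normal g_i and a variance field σ² shared within index neighborhoods
    of width m, creating dependent energies between neighbors while the
    sources stay uncorrelated.  A_true is a seeded random square matrix
    with condition number below 20.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_sources, spec.n_samples
    if spec.base_dist == "laplace":
        S = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, T))
    else:
        H = neighborhood_matrix(n, spec.m, "line").h
        # heavy-tailed variance components: neighbors share most of their
        # variance field, giving clearly dependent energies
        u = rng.lognormal(0.0, 2.0, size=(n, T))
        var = H @ u
        S = np.sqrt(var) * rng.standard_normal((n, T))
        S /= S.std(axis=1, keepdims=True)
    while True:
        A = rng.standard_normal((n, n))
        if np.linalg.cond(A) < 20.0:
            break
    return S, A, A @ S
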