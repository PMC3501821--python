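"""Topographic independent component analysis (TICA).

The model assumes whitened observations z = Vx generated by mixing sparse
sources whose *energies* are dependent within a fixed topographic
neighborhood.  With unmixing rows w_i and binary neighborhood function
h(i, j), the neighborhood energy is

    G_j = Σ_i h(i, j) (w_iᵀ z)²

and the (approximate) log-likelihood per sample is

    L(W) = E[ Σ_j P(G_j) ] + log|det W|

where P is a smooth sparsity nonlinearity, here P(y) = −α·sqrt(y + ε) + β
with derivative p(y) = −α / (2·sqrt(y + ε)).  Maximisation proceeds by
gradient ascent

    Δw_i ∝ E[ z (w_iᵀ z) r_i ],   r_i = Σ_k h(i, k) p(G_k)

followed by symmetric orthogonalization W ← (WWᵀ)^{−1/2} W after every
step, which keeps W exactly orthonormal on the whitened space.  The
mixing matrix is recovered as A = (WV)⁻¹ (pseudo-inverse when the
whitening retains fewer dimensions than the data has).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DataError,
    DimensionError,
    NumericalError,
    ParameterError,
    RankError,
    StateError,
)

ENERGY_EPS = 1e-3
EIG_FLOOR = 1e-12

__all__ = [
    "NeighborhoodMatrix",
    "WhiteningModel",
    "TicaModel",
    "neighborhood_matrix",
    "fit_whitening",
    "neighborhood_energy",
    "tica_log_likelihood",
    "tica_gradient_step",
    "fit_tica",
    "recover_mixing",
    "transform",
    "amari_index",
]


@dataclass(frozen=True)
class NeighborhoodMatrix:
    """Binary symmetric neighborhood function h(i, j) with h(i, i) = 1."""

    h: np.ndarray
    width: int
    topology: str

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64)
        object.__setattr__(self, "h", h)

    @property
    def n(self) -> int:
        return self.h.shape[0]


def neighborhood_matrix(n: int, m: int, topology: str = "line") -> NeighborhoodMatrix:
    """Build h(i, j) = 1 iff d(i, j) <= m under the chosen index distance.

    ``line`` uses |i − j|, ``ring`` circular distance, ``grid`` Chebyshev
    distance on a sqrt(n) × sqrt(n) lattice (n must be a perfect square).
    """
    if n < 1 or m < 0:
        raise ParameterError("need n >= 1 and m >= 0")
    idx = np.arange(n)
    if topology == "line":
        d = np.abs(idx[:, None] - idx[None, :])
    elif topology == "ring":
        d = np.abs(idx[:, None] - idx[None, :])
        d = np.minimum(d, n - d)
    elif topology == "grid":
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ParameterError("grid topology needs n to be a perfect square")
        r, c = np.divmod(idx, side)
        d = np.maximum(
            np.abs(r[:, None] - r[None, :]), np.abs(c[:, None] - c[None, :])
        )
    else:
        raise ParameterError(f"unknown topology: {topology!r}")
    return NeighborhoodMatrix(h=(d <= m).astype(np.float64), width=m, topology=topology)


@dataclass(frozen=True)
class WhiteningModel:
    """PCA whitening: z = V (x − mean), cov(z) = I on the training data."""

    V: np.ndarray
    mean_vec: np.ndarray
    n_keep: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.mean_vec.size:
            raise DimensionError(
                f"expected {self.mean_vec.size} features, got {X.shape[1]}"
            )
        return (X - self.mean_vec) @ self.V.T


def fit_whitening(X: np.ndarray, n_keep: int) -> WhiteningModel:
    """Whiten via the top-``n_keep`` eigenpairs of the sample covariance."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DimensionError("X must be observations x dimensions")
    T, d = X.shape
    if n_keep < 1 or n_keep > d:
        raise ParameterError("n_keep must be in 1..n_dims")
    if T <= n_keep:
        raise DataError("need more observations than retained dimensions")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, bias=False)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:n_keep]
    lam = evals[order]
    if np.any(lam <= 1e-10 * evals.max()):
        raise RankError(
            f"data rank below n_keep={n_keep}: smallest retained "
            f"eigenvalue {lam.min():.3e}"
        )
    V = (evecs[:, order] / np.sqrt(lam)).T
    return WhiteningModel(V=V, mean_vec=mean, n_keep=n_keep)


def _P(y: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return -alpha * np.sqrt(y + ENERGY_EPS) + beta


def _p(y: np.ndarray, alpha: float) -> np.ndarray:
    return -alpha / (2.0 * np.sqrt(y + ENERGY_EPS))


def neighborhood_energy(
    W: np.ndarray, H: NeighborhoodMatrix, z: np.ndarray
) -> np.ndarray:
    """G_j = Σ_i h(i, j) (w_i · z)² for one whitened sample."""
    W = np.asarray(W, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64).ravel()
    if W.shape[1] != z.size or W.shape[0] != H.n:
        raise DimensionError("W, H and z shapes do not conform")
    y2 = (W @ z) ** 2
    return H.h.T @ y2


def tica_log_likelihood(
    W: np.ndarray,
    H: NeighborhoodMatrix,
    Z: np.ndarray,
    alpha: float = 1.0,
    beta: float = 0.0,
) -> float:
    """Mean per-sample log-likelihood Σ_j P(G_j) + log|det W|.

    ``Z`` is a whitened sample set, observations x dimensions.
    """
    W = np.asarray(W, dtype=np.float64)
    sign, logdet = np.linalg.slogdet(W)
    if sign == 0:
        raise NumericalError("W is singular")
    Y = W @ np.asarray(Z, dtype=np.float64).T
    G = H.h.T @ (Y * Y)
    return float(np.mean(np.sum(_P(G, alpha, beta), axis=0)) + logdet)


def _sym_orth(W: np.ndarray) -> np.ndarray:
    """Symmetric orthogonalization W ← (WWᵀ)^{−1/2} W via eigh."""
    M = W @ W.T
    evals, evecs = np.linalg.eigh(M)
    evals = np.maximum(evals, EIG_FLOOR)
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return inv_sqrt @ W


@dataclass
class TicaModel:
    """Fitted TICA stage: whitening, unmixing, neighborhood and mixing."""

    W: np.ndarray
    H: NeighborhoodMatrix
    whitening: WhiteningModel
    A: np.ndarray | None
    alpha: float = 1.0
    beta: float = 0.0
    learn_rate: float = 0.25
    n_iter: int = 500
    seed: int = 0
    likelihood_trace: list[float] = field(default_factory=list)


def tica_gradient_step(model: TicaModel, Z_batch: np.ndarray) -> TicaModel:
    """One fixed-step gradient ascent update followed by orthogonalization.

    ``Z_batch`` is whitened, observations x dimensions.  The returned
    model satisfies W·Wᵀ = I to numerical precision and has A refreshed.
    """
    Zt = np.asarray(Z_batch, dtype=np.float64).T
    W = model.W
    Y = W @ Zt
    G = model.H.h.T @ (Y * Y)
    R = model.H.h @ _p(G, model.alpha)
    grad = (R * Y) @ Zt.T / Zt.shape[1]
    if not np.all(np.isfinite(grad)):
        raise NumericalError("non-finite TICA gradient")
    W_new = _sym_orth(W + model.learn_rate * grad)
    model.W = W_new
    model.A = recover_mixing(model)
    return model


def fit_tica(
    X: np.ndarray,
    n_components: int,
    m: int = 1,
    topology: str = "ring",
    alpha: float = 1.0,
    beta: float = 0.0,
    learn_rate: float = 0.25,
    n_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> TicaModel:
    """Fit the TICA stage on ``X`` (observations x dimensions).

    The unmixing matrix starts from a seeded random orthogonal matrix and
    follows the likelihood gradient; a backtracking halving of the step
    keeps the likelihood trace non-decreasing (within 1e-9 per step),
    and the run stops when the relative likelihood change falls below
    ``tol`` or after ``n_iter`` iterations.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DimensionError("X must be observations x dimensions")
    if X.shape[0] < 10 * n_components:
        raise DataError(
            f"need at least {10 * n_components} samples for "
            f"{n_components} components, got {X.shape[0]}"
        )
    whitening = fit_whitening(X, n_components)
    Z = whitening.transform(X)
    H = neighborhood_matrix(n_components, m, topology)
    rng = np.random.default_rng(seed)
    W = _sym_orth(rng.standard_normal((n_components, n_components)))
    model = TicaModel(
        W=W,
        H=H,
        whitening=whitening,
        A=None,
        alpha=alpha,
        beta=beta,
        learn_rate=learn_rate,
        n_iter=n_iter,
        seed=seed,
    )
    Zt = Z.T
    lik = tica_log_likelihood(W, H, Z, alpha, beta)
    model.likelihood_trace.append(lik)
    step = learn_rate
    for it in range(n_iter):
        Y = model.W @ Zt
        G = H.h.T @ (Y * Y)
        R = H.h @ _p(G, alpha)
        grad = (R * Y) @ Zt.T / Zt.shape[1]
        if not np.all(np.isfinite(grad)):
            raise NumericalError(f"non-finite TICA gradient at iteration {it}")
        # backtracking: shrink the step until the likelihood does not drop
        accepted = False
        for _ in range(40):
            W_try = _sym_orth(model.W + step * grad)
            lik_try = tica_log_likelihood(W_try, H, Z, alpha, beta)
            if lik_try >= lik - 1e-9:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        model.W = W_try
        model.likelihood_trace.append(lik_try)
        rel = abs(lik_try - lik) / max(abs(lik), 1e-12)
        lik = lik_try
        step = min(step * 1.2, learn_rate)
        if rel < tol:
            break
    model.A = recover_mixing(model)
    return model


def recover_mixing(model: TicaModel) -> np.ndarray:
    """A = (W V)⁻¹, via pseudo-inverse when whitening reduced dimension."""
    M = model.W @ model.whitening.V
    s = np.linalg.svd(M, compute_uv=False)
    if s.min() <= 1e-12 * s.max():
        raise RankError("W·V is numerically singular; cannot recover mixing")
    return np.linalg.pinv(M)


def transform(model: TicaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Component responses s = WV(x − mean) and energies G, per sample.

    Returns ``(S, G)`` with shape (observations, n_components) each; the
    energies are the feature output handed to the spiking layer.
    """
    if model.W is None or model.whitening is None:
        raise StateError("TICA model is not fitted")
    S = model.whitening.transform(X) @ model.W.T
    G = (model.H.h.T @ (S.T**2)).T
    return S, G


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P from a scaled permutation.

    Zero iff P is a permutation of a diagonal matrix; used to score how
    well W·V·A_true approaches the identity up to permutation and sign.
    """
    Pa = np.abs(np.asarray(P, dtype=np.float64))
    n = Pa.shape[0]
    rows = (Pa / Pa.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (Pa / Pa.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))
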