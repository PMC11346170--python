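"""Gaussian-copula machinery: nearest correlation matrix and rank-target calibration.

The cohort generator plants Spearman correlations between *observed*
variables, some of which are coarse ordinal scores (4-level ICsc, binary
NDsc, 0-5 Oxford).  Discretisation attenuates rank correlation, so the
latent Gaussian correlation that reproduces a target Spearman rho on the
observed scale must be found numerically.  :func:`calibrate_latent_correlation`
does this by bisection on the latent rho, re-simulating the transformed pair
with common random numbers (which makes the achieved rho monotone and smooth
in the latent rho, so bisection is safe).

For two *continuous* margins the classical bivariate-normal identity
``rho_latent = 2 sin(pi * rho_s / 6)`` is exact and the search simply
recovers it; callers may use :func:`latent_from_spearman_continuous` directly.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats


class CalibrationError(RuntimeError):
    """Target rank correlation is unreachable for the given margins."""


def latent_from_spearman_continuous(rho_s: float) -> float:
    """Latent Pearson rho giving Spearman ``rho_s`` for continuous margins."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _validate_square_symmetric(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    return a


def nearest_positive_definite(
    a: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Nearest unit-diagonal positive semidefinite matrix (Higham 2002).

    Alternating projections with Dykstra correction onto the PSD cone and the
    unit-diagonal affine set.  Idempotent (to ``tol``) on matrices that are
    already valid correlation matrices.
    """
    a = _validate_square_symmetric(a)
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - r
        y_prev = y
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.max(np.abs(y - y_prev)) < tol and np.linalg.eigvalsh(y).min() > -tol:
            break
    # final exact projection: clip residual negative eigenvalues, renormalise
    w, v = np.linalg.eigh((y + y.T) / 2.0)
    x = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(x), 1e-12, None))
    x = x / np.outer(d, d)
    np.fill_diagonal(x, 1.0)
    return (x + x.T) / 2.0


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def calibrate_latent_correlation(
    target_rho: float,
    transform_a: Callable[[np.ndarray], np.ndarray] | None = None,
    transform_b: Callable[[np.ndarray], np.ndarray] | None = None,
    *,
    n_calib: int = 50_000,
    seed: int = 0,
    tol: float = 0.02,
    max_iter: int = 60,
) -> float:
    """Latent Gaussian rho such that Spearman of the transformed pair hits target.

    ``transform_*`` map standard-normal latents to the observed scale
    (``None`` means identity, i.e. a continuous margin).  Deterministic for a
    given ``seed``; raises :class:`CalibrationError`, naming the maximum
    achievable rho, when discretisation caps the rank correlation below the
    target.
    """
    if abs(target_rho) >= 0.95:
        raise ValueError(f"|target_rho| must be < 0.95, got {target_rho}")
    if n_calib < 10_000:
        raise ValueError(f"n_calib must be >= 10000, got {n_calib}")
    ta = transform_a or (lambda z: z)
    tb = transform_b or (lambda z: z)

    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_calib)
    e = rng.standard_normal(n_calib)
    xa = ta(z1)

    def achieved(rho: float) -> float:
        z2 = rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * e
        return _spearman(xa, tb(z2))

    lo, hi = -0.995, 0.995
    f_lo, f_hi = achieved(lo), achieved(hi)
    increasing = f_hi >= f_lo
    f_min, f_max = min(f_lo, f_hi), max(f_lo, f_hi)
    if not (f_min - tol <= target_rho <= f_max + tol):
        raise CalibrationError(
            f"target Spearman {target_rho:+.3f} unreachable; achievable range "
            f"is [{f_min:+.3f}, {f_max:+.3f}] for these margins"
        )

    mid = 0.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        f_mid = achieved(mid)
        if abs(f_mid - target_rho) <= tol / 4.0 or (hi - lo) < 1e-4:
            return float(mid)
        if (f_mid < target_rho) == increasing:
            lo = mid
        else:
            hi = mid
    return float(mid)


def _sample_from_corr(e: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Map iid standard normals through an eigen factor of ``corr``.

    Eigenvalues are clipped at zero so that near-boundary candidate matrices
    explored during bisection never abort the search.
    """
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return e @ factor.T


def calibrate_joint_correlation(
    corr_builder: Callable[[float], np.ndarray],
    score_fn: Callable[[np.ndarray], np.ndarray],
    partner_fn: Callable[[np.ndarray], np.ndarray],
    target_rho: float,
    *,
    n_calib: int = 50_000,
    seed: int = 0,
    tol: float = 0.02,
    lo: float = -0.95,
    hi: float = 0.95,
    max_iter: int = 60,
) -> float:
    """Bisection on a shared latent-correlation parameter of a composite score.

    Used when the observed variable is a *sum* over several latents (the
    nerve-morphology subscore over tortuosity+reflectivity, or the total
    score over all morphometric latents): ``corr_builder(b)`` returns the
    candidate latent correlation matrix, ``score_fn``/``partner_fn`` map the
    sampled latent block to the two observed variables being correlated.
    """
    k = corr_builder(0.0).shape[0]
    rng = np.random.default_rng(seed)
    e = rng.standard_normal((n_calib, k))

    def achieved(b: float) -> float:
        z = _sample_from_corr(e, corr_builder(b))
        return _spearman(score_fn(z), partner_fn(z))

    f_lo, f_hi = achieved(lo), achieved(hi)
    increasing = f_hi >= f_lo
    f_min, f_max = min(f_lo, f_hi), max(f_lo, f_hi)
    if not (f_min - tol <= target_rho <= f_max + tol):
        raise CalibrationError(
            f"composite target Spearman {target_rho:+.3f} unreachable; "
            f"achievable range is [{f_min:+.3f}, {f_max:+.3f}]"
        )
    mid = 0.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        f_mid = achieved(mid)
        if abs(f_mid - target_rho) <= tol / 4.0 or (hi - lo) < 1e-4:
            return float(mid)
        if (f_mid < target_rho) == increasing:
            lo = mid
        else:
            hi = mid
    return float(mid)
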