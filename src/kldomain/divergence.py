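"""Closed-form Kullback-Leibler divergence between Gaussian processes on a grid.

Two Gaussian processes observed on a common discrete grid reduce to two
multivariate normal laws; their KL divergence has the classical closed form

    KL(X||Y) = 1/2 [ tr(Sy^-1 Sx) - p + d' Sy^-1 d + ln det Sy - ln det Sx ],

with d = mu_Y - mu_X.  The *local* divergence restricts both laws to a subset
A of the grid (mean sub-vector, principal covariance sub-matrix) and applies
the same formula, which makes it a monotone, nonnegative set function: the
engine behind interval-of-maximum-divergence selection.

All evaluations go through triangular (Cholesky) factorizations; no explicit
matrix inverse is ever formed, and log-determinants come from factor
diagonals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import InvalidParameterError, NotPositiveDefiniteError

__all__ = [
    "GridDomain",
    "GaussianGridParams",
    "kl_gaussian_univariate",
    "kl_gaussian_multivariate",
    "kl_local",
    "kl_symmetrized",
]

# tiny negative KL values are floating-point noise and clamped to zero;
# anything below -_NEG_TOL signals an internal inconsistency
_NEG_TOL = 1e-8
_SYM_RTOL = 1e-8


@dataclass(frozen=True)
class GridDomain:
    """Equally spaced (or at least strictly increasing) grid on a compact interval.

    The canonical design is left-closed with the right endpoint excluded:
    ``points[k] = t_min + k * (t_max - t_min) / p`` for ``k = 0..p-1``,
    so a grid on [0, pi] with p points is {0, pi/p, ..., (p-1)pi/p}.
    """

    t_min: float
    t_max: float
    p: int
    points: np.ndarray = field(repr=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.p < 1 or pts.shape != (self.p,):
            raise InvalidParameterError(
                f"grid needs p >= 1 points, got p={self.p}, shape={pts.shape}"
            )
        if self.t_max <= self.t_min:
            raise InvalidParameterError("grid requires t_max > t_min")
        if self.p > 1 and not np.all(np.diff(pts) > 0):
            raise InvalidParameterError("grid points must be strictly increasing")

    @classmethod
    def regular(cls, t_min: float, t_max: float, p: int) -> "GridDomain":
        """Left-closed equally spaced grid; the right endpoint is excluded."""
        if p < 1:
            raise InvalidParameterError(f"p must be >= 1, got {p}")
        pts = t_min + np.arange(p) * (t_max - t_min) / p
        return cls(t_min=float(t_min), t_max=float(t_max), p=int(p), points=pts)

    @property
    def length(self) -> float:
        """Lebesgue measure of the underlying interval, lambda(T)."""
        return self.t_max - self.t_min


@dataclass(frozen=True)
class GaussianGridParams:
    """Mean vector and covariance matrix of one process restricted to a grid.

    The covariance must be symmetric; positive definiteness is only required
    at factorization time (sample covariances of finite-rank processes are
    legitimately singular and are handled upstream by shrinkage).
    """

    grid: GridDomain
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        p = self.grid.p
        if mean.shape != (p,):
            raise InvalidParameterError(
                f"mean has shape {mean.shape}, expected ({p},)"
            )
        if cov.shape != (p, p):
            raise InvalidParameterError(
                f"cov has shape {cov.shape}, expected ({p}, {p})"
            )
        scale = max(1.0, float(np.abs(cov).max()))
        if not np.allclose(cov, cov.T, rtol=_SYM_RTOL, atol=_SYM_RTOL * scale):
            raise InvalidParameterError("cov is not symmetric within tolerance")

    @property
    def p(self) -> int:
        return self.grid.p

    def restrict(self, indices: np.ndarray) -> "GaussianGridParams":
        """Restriction to a subset of grid points (0-based indices)."""
        idx = _check_indices(indices, self.p)
        idx = np.sort(idx)
        sub_pts = self.grid.points[idx]
        t_lo = float(sub_pts[0])
        # sub-grid spans its own points; a singleton needs a nonempty interval
        t_hi = float(sub_pts[-1]) if idx.size > 1 else t_lo + 1.0
        sub_grid = GridDomain(t_lo, t_hi, idx.size, sub_pts)
        return GaussianGridParams(
            grid=sub_grid,
            mean=self.mean[idx],
            cov=self.cov[np.ix_(idx, idx)],
        )


def _check_indices(indices, p: int) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    if idx.ndim != 1 or idx.size == 0:
        raise InvalidParameterError("index set must be a nonempty 1-d sequence")
    if np.any(idx < 0) or np.any(idx >= p):
        raise InvalidParameterError(
            f"indices must lie in [0, {p - 1}], got range "
            f"[{idx.min()}, {idx.max()}]"
        )
    if np.unique(idx).size != idx.size:
        raise InvalidParameterError("index set contains duplicates")
    return idx


def _chol(cov: np.ndarray, name: str):
    try:
        return cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError
        raise NotPositiveDefiniteError(name, str(exc)) from exc
    except ValueError as exc:
        raise NotPositiveDefiniteError(name, str(exc)) from exc


def _logdet_from_factor(factor) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(factor[0]))))


def _finalize(value: float) -> float:
    if value < -_NEG_TOL:
        raise RuntimeError(
            f"KL divergence evaluated to {value}, below the -{_NEG_TOL} "
            "internal-consistency floor; covariance inputs are inconsistent"
        )
    # values within floating-point noise of zero are reported as exactly zero
    if abs(value) <= 1e-12:
        return 0.0
    return max(value, 0.0)


def kl_gaussian_univariate(
    mean_x: float, var_x: float, mean_y: float, var_y: float
) -> float:
    """KL divergence between two univariate normal laws N(mean_x, var_x) || N(mean_y, var_y).

    Closed form ``1/2 [ var_x/var_y - 1 + (mean_x-mean_y)^2/var_y + ln(var_y/var_x) ]``.
    """
    if var_x <= 0 or var_y <= 0:
        raise InvalidParameterError(
            f"variances must be positive, got var_x={var_x}, var_y={var_y}"
        )
    ratio = var_x / var_y
    value = 0.5 * (ratio - 1.0 + (mean_x - mean_y) ** 2 / var_y + math.log(1.0 / ratio))
    return _finalize(value)


def kl_gaussian_multivariate(
    params_x: GaussianGridParams, params_y: GaussianGridParams
) -> float:
    """KL divergence between two p-variate normal laws on a common grid.

    Computed via Cholesky factorization of both covariances; log-determinants
    are read off the factor diagonals, and the quadratic form and trace use
    triangular solves rather than explicit inverses.
    """
    if params_x.p != params_y.p:
        raise InvalidParameterError(
            f"dimension mismatch: {params_x.p} vs {params_y.p}"
        )
    p = params_x.p
    if p == 1:
        return kl_gaussian_univariate(
            float(params_x.mean[0]), float(params_x.cov[0, 0]),
            float(params_y.mean[0]), float(params_y.cov[0, 0]),
        )
    delta = params_y.mean - params_x.mean
    fy = _chol(params_y.cov, "cov_y")
    fx = _chol(params_x.cov, "cov_x")
    trace_term = float(np.trace(cho_solve(fy, params_x.cov)))
    maha = float(delta @ cho_solve(fy, delta))
    logdet = _logdet_from_factor(fy) - _logdet_from_factor(fx)
    return _finalize(0.5 * (trace_term - p + maha + logdet))


def kl_local(
    params_x: GaussianGridParams,
    params_y: GaussianGridParams,
    indices,
) -> float:
    """Local KL divergence: KL between the restrictions of X and Y to ``indices``.

    ``indices`` are 0-based grid positions (any nonempty duplicate-free
    subset, not necessarily contiguous).  Singleton subsets reduce to the
    univariate closed form.
    """
    if params_x.p != params_y.p:
        raise InvalidParameterError(
            f"dimension mismatch: {params_x.p} vs {params_y.p}"
        )
    idx = _check_indices(indices, params_x.p)
    if idx.size == 1:
        i = int(idx[0])
        return kl_gaussian_univariate(
            float(params_x.mean[i]), float(params_x.cov[i, i]),
            float(params_y.mean[i]), float(params_y.cov[i, i]),
        )
    return kl_gaussian_multivariate(params_x.restrict(idx), params_y.restrict(idx))


def kl_symmetrized(
    params_x: GaussianGridParams,
    params_y: GaussianGridParams,
    indices,
) -> float:
    """Jeffreys-style symmetrization: average of the two directed local divergences."""
    return 0.5 * (
        kl_local(params_x, params_y, indices) + kl_local(params_y, params_x, indices)
    )
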