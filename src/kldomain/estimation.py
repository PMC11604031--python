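"""Estimation of Gaussian grid parameters from curve samples.

Given n curves recorded on a common grid, the maximum-likelihood estimates
are the sample mean and the divisor-n sample covariance.  When the grid is
fine relative to the sample size the covariance estimate is rank deficient,
so a shrinkage-toward-the-diagonal estimator

    Sigma_eta = eta * Sigma_hat + (1 - eta) * diag(Sigma_hat),  eta in [0, 1],

restores positive definiteness while leaving the pointwise variances intact.
The shrinkage weight can be fixed or selected by K-fold cross-validation on
held-out Gaussian log-density.  Irregularly sampled curves are projected onto
a common grid with a Nadaraya-Watson (Gaussian kernel, local constant)
smoother before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.model_selection import KFold

from .divergence import GaussianGridParams, GridDomain
from .exceptions import (
    EstimationFailureError,
    InsufficientSampleError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "CurveSet",
    "ShrinkageConfig",
    "estimate_gaussian_params",
    "shrink_covariance",
    "select_shrinkage_cv",
    "resolve_eta",
    "smooth_to_common_grid",
]

DEFAULT_ETA_GRID = np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass(frozen=True)
class CurveSet:
    """A sample of curves on a common grid: rows are curves, columns grid points."""

    grid: GridDomain
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[1] != self.grid.p:
            raise InvalidInputError(
                f"curve matrix has shape {vals.shape}, expected (n, {self.grid.p})"
            )
        if vals.shape[0] < 1:
            raise InvalidInputError("curve set must contain at least one curve")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("curve matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.grid.p


@dataclass(frozen=True)
class ShrinkageConfig:
    """How to pick the covariance shrinkage weight eta.

    ``eta`` is either a number in [0, 1] or the string ``"cv"`` requesting
    K-fold cross-validation over ``eta_grid`` scored by per-curve held-out
    Gaussian log-density.  Ties favour the smaller (more regularized) eta.
    """

    eta: float | str = "cv"
    eta_grid: np.ndarray = field(default_factory=lambda: DEFAULT_ETA_GRID.copy())
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.eta_grid, dtype=float)
        object.__setattr__(self, "eta_grid", grid)
        if isinstance(self.eta, str):
            if self.eta != "cv":
                raise InvalidParameterError(
                    f'eta must be a number in [0, 1] or "cv", got {self.eta!r}'
                )
        elif not 0.0 <= float(self.eta) <= 1.0:
            raise InvalidParameterError(f"eta must lie in [0, 1], got {self.eta}")
        if grid.size == 0 or np.any(grid < 0) or np.any(grid > 1):
            raise InvalidParameterError("eta_grid must be a nonempty subset of [0, 1]")
        if self.folds < 2:
            raise InvalidParameterError(f"folds must be >= 2, got {self.folds}")


def estimate_gaussian_params(curves: CurveSet) -> GaussianGridParams:
    """Maximum-likelihood mean and covariance (divisor n, not n-1)."""
    if curves.n < 2:
        raise InsufficientSampleError(
            f"need at least 2 curves to estimate a covariance, got {curves.n}"
        )
    x = curves.values
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / curves.n
    cov = 0.5 * (cov + cov.T)  # exact symmetry
    return GaussianGridParams(grid=curves.grid, mean=mean, cov=cov)


def shrink_covariance(cov: np.ndarray, eta: float) -> np.ndarray:
    """Convex combination eta*cov + (1-eta)*diag(cov); diagonal is unchanged."""
    cov = np.asarray(cov, dtype=float)
    if not 0.0 <= eta <= 1.0:
        raise InvalidParameterError(f"eta must lie in [0, 1], got {eta}")
    d = np.diag(cov)
    if np.any(d <= 0):
        raise InvalidParameterError(
            "covariance diagonal must be strictly positive for shrinkage"
        )
    out = eta * cov + (1.0 - eta) * np.diag(d)
    np.fill_diagonal(out, d)
    return out


def _heldout_loglik(train: np.ndarray, test: np.ndarray, eta: float) -> float:
    """Mean per-curve Gaussian log-density of ``test`` under the eta-shrunken
    MLE fitted on ``train``; -inf when the shrunken covariance is not PD."""
    n, p = train.shape
    mean = train.mean(axis=0)
    centered = train - mean
    cov = centered.T @ centered / n
    cov = 0.5 * (cov + cov.T)
    if np.any(np.diag(cov) <= 0):
        return -np.inf
    cov = shrink_covariance(cov, eta)
    try:
        factor = cho_factor(cov, lower=True)
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    resid = test - mean
    quad = np.einsum("ij,ij->i", resid, cho_solve(factor, resid.T).T)
    ll = -0.5 * (p * np.log(2 * np.pi) + logdet + quad)
    return float(ll.mean())


def select_shrinkage_cv(curves: CurveSet, config: ShrinkageConfig) -> float:
    """Cross-validated shrinkage weight, maximizing held-out log-density.

    Ties (within 1e-10) are broken toward the smaller eta, i.e. toward more
    regularization.
    """
    if curves.n < 2 * config.folds:
        raise InsufficientSampleError(
            f"need n >= 2*folds = {2 * config.folds} curves, got {curves.n}"
        )
    grid = np.sort(np.asarray(config.eta_grid, dtype=float))
    if grid.size == 1:
        return float(grid[0])
    splitter = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    scores = np.zeros(grid.size)
    for train_idx, test_idx in splitter.split(curves.values):
        train = curves.values[train_idx]
        test = curves.values[test_idx]
        for j, eta in enumerate(grid):
            scores[j] += _heldout_loglik(train, test, eta)
    if not np.any(np.isfinite(scores)):
        raise EstimationFailureError(
            "every candidate eta produced a non-positive-definite training covariance"
        )
    best = np.max(scores)
    winners = np.nonzero(scores >= best - 1e-10)[0]
    return float(grid[winners[0]])


def resolve_eta(curves: CurveSet, config: ShrinkageConfig) -> float:
    """Fixed eta as given, or the CV-selected value when config.eta == "cv"."""
    if isinstance(config.eta, str):
        return select_shrinkage_cv(curves, config)
    return float(config.eta)


def _silverman_bandwidth(times: np.ndarray) -> float:
    n = times.size
    sd = float(np.std(times, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(times, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-8)
    return 0.9 * spread * n ** (-0.2)


def smooth_to_common_grid(
    raw_curves: Sequence[tuple[np.ndarray, np.ndarray]],
    target: GridDomain,
    bandwidth: float | str = "auto",
    label: str = "",
) -> CurveSet:
    """Project irregularly sampled curves onto a common grid.

    Each curve, given as a ``(times, values)`` pair, is smoothed independently
    with a Gaussian-kernel local-constant (Nadaraya-Watson) estimator and
    evaluated at ``target.points``.  ``bandwidth="auto"`` applies the
    Silverman rule-of-thumb to each curve's own observation times.  Boundary
    bias of the local-constant estimator is accepted by design.
    """
    if not isinstance(bandwidth, str) and bandwidth <= 0:
        raise InvalidParameterError(f"bandwidth must be positive, got {bandwidth}")
    rows = []
    for i, (times, values) in enumerate(raw_curves):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        inside = (times >= target.t_min) & (times <= target.t_max)
        times, values = times[inside], values[inside]
        if times.size < 2:
            raise InvalidInputError(
                f"curve {i} has fewer than 2 observations inside "
                f"[{target.t_min}, {target.t_max}]"
            )
        h = _silverman_bandwidth(times) if isinstance(bandwidth, str) else float(bandwidth)
        # weights_{gj} = K((t_g - s_j)/h); local-constant fit at each grid point
        z = (target.points[:, None] - times[None, :]) / h
        w = np.exp(-0.5 * z**2)
        wsum = w.sum(axis=1)
        # far outside the data support all weights underflow; fall back to the
        # nearest observation rather than dividing by zero
        degenerate = wsum <= 0
        if np.any(degenerate):
            nearest = np.abs(
                target.points[degenerate, None] - times[None, :]
            ).argmin(axis=1)
            fit = np.empty(target.p)
            fit[~degenerate] = (w[~degenerate] @ values) / wsum[~degenerate]
            fit[degenerate] = values[nearest]
        else:
            fit = (w @ values) / wsum
        rows.append(fit)
    return CurveSet(grid=target, values=np.vstack(rows), label=label)
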