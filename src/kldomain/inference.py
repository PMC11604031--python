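"""Bootstrap uncertainty quantification for the selected interval.

The selected window is summarized by the time coordinate of its center; a
nonparametric bootstrap (resampling n curves from group X and m from group Y
with replacement, independently within group) yields an empirical
distribution of centers, a percentile confidence interval for the center,
and — by sweeping a ball of the window's half-width along that interval — a
confidence *set* of intervals on the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import CurveSet, ShrinkageConfig
from .exceptions import EstimationFailureError, InvalidInputError, InvalidParameterError
from .selection import SelectionResult, select_interval

__all__ = [
    "BootstrapResult",
    "bootstrap_interval_centers",
    "center_confidence_interval",
    "confidence_set",
    "bootstrap_selection",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap distribution of interval centers with CI and confidence set."""

    centers: np.ndarray
    B: int
    alpha: float
    ci: tuple[float, float]
    confidence_set: tuple[float, float]
    c: float
    radius_time: float

    def to_dict(self) -> dict:
        qs = np.quantile(self.centers, [0.05, 0.25, 0.5, 0.75, 0.95])
        return {
            "B": self.B,
            "alpha": self.alpha,
            "c": self.c,
            "radius_time": self.radius_time,
            "centers_summary": {
                "median": float(np.median(self.centers)),
                "quantiles": {
                    "q05": float(qs[0]),
                    "q25": float(qs[1]),
                    "q50": float(qs[2]),
                    "q75": float(qs[3]),
                    "q95": float(qs[4]),
                },
            },
            "ci": list(self.ci),
            "confidence_set": list(self.confidence_set),
        }


def bootstrap_interval_centers(
    curves_x: CurveSet,
    curves_y: CurveSet,
    c: float,
    B: int,
    seed: int,
    shrinkage: ShrinkageConfig | None = None,
) -> np.ndarray:
    """Center times of the selected interval across B bootstrap resamples.

    Each replicate draws n curves with replacement from group X and m from
    group Y (independently within group) and reruns the full selection.  The
    shrinkage weight is resolved once on the original data and held fixed
    across replicates.
    """
    if B < 1:
        raise InvalidParameterError(f"B must be >= 1, got {B}")
    shrinkage = shrinkage or ShrinkageConfig()
    # resolve CV shrinkage once on the original data; replicates reuse it
    from .divergence import GaussianGridParams
    from .estimation import estimate_gaussian_params, resolve_eta, shrink_covariance
    from .selection import _argmax_result, divergence_profile

    eta_x = resolve_eta(curves_x, shrinkage)
    eta_y = resolve_eta(curves_y, shrinkage)
    rng = np.random.default_rng(seed)
    centers = np.empty(B)
    for b in range(B):
        ix = rng.integers(0, curves_x.n, size=curves_x.n)
        iy = rng.integers(0, curves_y.n, size=curves_y.n)
        try:
            params = []
            for sub, eta, src in (
                (ix, eta_x, curves_x),
                (iy, eta_y, curves_y),
            ):
                est = estimate_gaussian_params(
                    CurveSet(grid=src.grid, values=src.values[sub], label=src.label)
                )
                params.append(
                    GaussianGridParams(
                        grid=est.grid,
                        mean=est.mean,
                        cov=shrink_covariance(est.cov, eta),
                    )
                )
            profile = divergence_profile(params[0], params[1], c)
            result = _argmax_result(
                profile, params[0].grid, c, eta_x=eta_x, eta_y=eta_y
            )
        except Exception as exc:
            raise EstimationFailureError(
                f"bootstrap replicate {b} failed: {exc}"
            ) from exc
        centers[b] = result.window.center_time
    return centers


def center_confidence_interval(centers, alpha: float) -> tuple[float, float]:
    """Percentile bootstrap CI: empirical alpha/2 and 1-alpha/2 quantiles.

    Quantiles use the linear-interpolation convention of ``numpy.quantile``.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise InvalidInputError("centers vector is empty")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    lo, hi = np.quantile(centers, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def confidence_set(
    ci: tuple[float, float],
    radius_time: float,
    t_min: float | None = None,
    t_max: float | None = None,
) -> tuple[float, float]:
    """Union of balls of the window half-width over the CI: [lo - r, hi + r].

    Optionally clipped to the domain [t_min, t_max].
    """
    lo, hi = float(ci[0]), float(ci[1])
    if lo > hi:
        raise InvalidParameterError(f"CI must satisfy lo <= hi, got ({lo}, {hi})")
    if radius_time < 0:
        raise InvalidParameterError(f"radius must be >= 0, got {radius_time}")
    out_lo, out_hi = lo - radius_time, hi + radius_time
    if t_min is not None:
        out_lo = max(out_lo, t_min)
    if t_max is not None:
        out_hi = min(out_hi, t_max)
    return out_lo, out_hi


def bootstrap_selection(
    curves_x: CurveSet,
    curves_y: CurveSet,
    c: float,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    shrinkage: ShrinkageConfig | None = None,
) -> tuple[SelectionResult, BootstrapResult]:
    """Full-data selection plus bootstrap CI and confidence set for its center."""
    shrinkage = shrinkage or ShrinkageConfig()
    full = select_interval(curves_x, curves_y, c, shrinkage=shrinkage)
    centers = bootstrap_interval_centers(
        curves_x, curves_y, c, B=B, seed=seed, shrinkage=shrinkage
    )
    ci = center_confidence_interval(centers, alpha)
    radius = float(full.window.radius_time)
    cs = confidence_set(
        ci, radius, t_min=curves_x.grid.t_min, t_max=curves_x.grid.t_max
    )
    boot = BootstrapResult(
        centers=centers,
        B=B,
        alpha=alpha,
        ci=ci,
        confidence_set=cs,
        c=c,
        radius_time=radius,
    )
    return full, boot
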