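"""Synthetic Gaussian-process scenarios and the Monte Carlo recovery study.

Curves are built from a nine-term Fourier basis on [0, pi],

    Phi(t) = (1, cos t, cos 2t, cos 3t, cos 4t, sin t, sin 2t, sin 3t, sin 4t),

with Gaussian coefficient noise: each X-curve is (beta_X + eps + gamma*g(t))'Phi(t)
with eps ~ N9(0, noise_sd2 * I) drawn fresh per curve, and an optional
Gaussian-bump variance inflation g(t) = exp(-(t - bump_center)^2) carried by
gamma ~ N9(0, tau2 * I); Y-curves are (beta_Y + eps)'Phi(t).  Three canonical
scenarios: A (mean difference only, tau2 = 0; the mean gap peaks at t = pi/2,
grid point 50 of 100), B (equal means, variance bump at t = 3pi/4, grid point
75), and C (both at once).

Because curves live in a finite-dimensional coefficient span (9 for Y, 18
for a bump-carrying X), covariance matrices — true and estimated alike — are
singular on windows wider than that rank.  The study therefore evaluates
both the population optimum and the estimates on shrinkage-regularized
covariances with a common fixed weight (default eta = 0.9), which keeps
"estimate converges to truth" a meaningful consistency statement.

Recovery is scored by the average integrated Jaccard distance (AIJD): one
minus the Jaccard index between the estimated and true optimal windows,
integrated over a uniform grid of length fractions c by the trapezoidal
rule; 0 means perfect recovery at every c, 1 total disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .divergence import GaussianGridParams, GridDomain
from .estimation import CurveSet, estimate_gaussian_params, shrink_covariance
from .exceptions import InvalidInputError, InvalidParameterError
from .selection import SelectionResult, Window, select_from_params

__all__ = [
    "ScenarioSpec",
    "MonteCarloResult",
    "scenario",
    "fourier_basis",
    "true_params",
    "simulate_scenario",
    "true_optimal_interval",
    "jaccard_distance",
    "aijd",
    "run_monte_carlo",
    "DEFAULT_C_GRID",
    "MC_ETA",
]

BETA_X = np.array([1.0, -2.0, -1.0, 1.0, 2.0, -1.0, 2.0, 3.0, -0.5])
BETA_Y = np.array([-1.0, -2.0, -1.0, 1.0, 2.0, -1.0, 2.0, 5.0, -0.5])

DEFAULT_C_GRID = np.round(np.arange(1, 20) * 0.05, 10)

# fixed shrinkage weight of the simulation study (see module docstring)
MC_ETA = 0.9


@dataclass(frozen=True)
class ScenarioSpec:
    """Data-generating parameters of one simulation scenario."""

    name: str
    beta_x: np.ndarray
    beta_y: np.ndarray
    noise_sd2: float = 0.25
    tau2: float = 1.0
    bump_center: float = 3 * np.pi / 4
    t_min: float = 0.0
    t_max: float = np.pi

    def __post_init__(self):
        object.__setattr__(self, "beta_x", np.asarray(self.beta_x, dtype=float))
        object.__setattr__(self, "beta_y", np.asarray(self.beta_y, dtype=float))
        if self.beta_x.shape != self.beta_y.shape or self.beta_x.ndim != 1:
            raise InvalidParameterError("beta_x and beta_y must be 1-d and equal-length")
        if self.beta_x.size % 2 == 0:
            raise InvalidParameterError("basis dimension must be odd")
        if self.noise_sd2 <= 0 or self.tau2 < 0:
            raise InvalidParameterError("noise_sd2 must be > 0 and tau2 >= 0")

    @property
    def n_basis(self) -> int:
        return self.beta_x.size

    def grid(self, p: int) -> GridDomain:
        return GridDomain.regular(self.t_min, self.t_max, p)


def scenario(name: str) -> ScenarioSpec:
    """Canonical scenario A (mean shift), B (variance bump) or C (both)."""
    name = name.upper()
    if name == "A":
        return ScenarioSpec(name="A", beta_x=BETA_X, beta_y=BETA_Y, tau2=0.0)
    if name == "B":
        return ScenarioSpec(name="B", beta_x=BETA_X, beta_y=BETA_X, tau2=1.0)
    if name == "C":
        return ScenarioSpec(name="C", beta_x=BETA_X, beta_y=BETA_Y, tau2=1.0)
    raise InvalidParameterError(f"unknown scenario {name!r}; expected A, B or C")


def fourier_basis(times, K: int = 9) -> np.ndarray:
    """Fourier design matrix: constant, then cosines, then sines.

    Columns are (1, cos t, ..., cos kt, sin t, ..., sin kt) with
    k = (K - 1) / 2 and unit angular frequencies, evaluated at ``times``.
    """
    if K < 1 or K % 2 == 0:
        raise InvalidParameterError(f"K must be odd and >= 1, got {K}")
    t = np.asarray(times, dtype=float)
    k = (K - 1) // 2
    cols = [np.ones_like(t)]
    cols += [np.cos(j * t) for j in range(1, k + 1)]
    cols += [np.sin(j * t) for j in range(1, k + 1)]
    return np.column_stack(cols)


def _bump(spec: ScenarioSpec, times: np.ndarray) -> np.ndarray:
    return np.exp(-((times - spec.bump_center) ** 2))


def true_params(
    spec: ScenarioSpec, grid: GridDomain
) -> tuple[GaussianGridParams, GaussianGridParams]:
    """Closed-form population mean vectors and covariance matrices on the grid.

    mu_l(t) = beta_l' Phi(t);  sigma_Y(t,s) = noise_sd2 * Phi(t)'Phi(s);
    sigma_X adds the bump term tau2 * g(t) g(s) * Phi(t)'Phi(s).
    These matrices have finite rank (the coefficient dimension) and are
    intentionally *not* positive definite for fine grids; shrink before
    factorizing.
    """
    B = fourier_basis(grid.points, spec.n_basis)
    gram = B @ B.T
    mean_x = B @ spec.beta_x
    mean_y = B @ spec.beta_y
    cov_y = spec.noise_sd2 * gram
    g = _bump(spec, grid.points)
    cov_x = cov_y + spec.tau2 * np.outer(g, g) * gram
    return (
        GaussianGridParams(grid=grid, mean=mean_x, cov=cov_x),
        GaussianGridParams(grid=grid, mean=mean_y, cov=cov_y),
    )


def simulate_scenario(
    spec: ScenarioSpec,
    n: int,
    m: int,
    seed: int | np.random.Generator = 0,
    p: int = 100,
) -> tuple[CurveSet, CurveSet]:
    """Draw n X-curves and m Y-curves on a p-point grid.

    Every curve gets a fresh coefficient noise draw eps (and, when tau2 > 0,
    a fresh bump coefficient gamma), which is what produces the nondegenerate
    between-curve covariance.
    """
    if n < 1 or m < 1:
        raise InvalidParameterError(f"n and m must be >= 1, got ({n}, {m})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = spec.grid(p)
    B = fourier_basis(grid.points, spec.n_basis)
    sd = np.sqrt(spec.noise_sd2)
    eps_x = rng.normal(0.0, sd, size=(n, spec.n_basis))
    x = (spec.beta_x + eps_x) @ B.T
    if spec.tau2 > 0:
        gamma = rng.normal(0.0, np.sqrt(spec.tau2), size=(n, spec.n_basis))
        x = x + (gamma @ B.T) * _bump(spec, grid.points)
    eps_y = rng.normal(0.0, sd, size=(m, spec.n_basis))
    y = (spec.beta_y + eps_y) @ B.T
    return (
        CurveSet(grid=grid, values=x, label="X"),
        CurveSet(grid=grid, values=y, label="Y"),
    )


def _shrunken(params: GaussianGridParams, eta: float) -> GaussianGridParams:
    return GaussianGridParams(
        grid=params.grid, mean=params.mean, cov=shrink_covariance(params.cov, eta)
    )


def true_optimal_interval(
    spec: ScenarioSpec, grid: GridDomain, c: float, eta: float = MC_ETA
) -> Window:
    """Population optimum: the argmax window of the true-parameter profile.

    Defined on the eta-shrunken true covariances (the unshrunken ones are
    finite-rank, see module docstring); deterministic and independent of any
    sample size.
    """
    px, py = true_params(spec, grid)
    result = select_from_params(_shrunken(px, eta), _shrunken(py, eta), c)
    return result.window


def jaccard_distance(a, b) -> float:
    """1 - |a & b| / |a | b| on grid-index sets."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa or not sb:
        raise InvalidInputError("jaccard_distance requires nonempty index sets")
    return 1.0 - len(sa & sb) / len(sa | sb)


def aijd(estimated: dict, truth: dict, c_grid) -> float:
    """Average integrated Jaccard distance over the length-fraction grid.

    ``estimated`` and ``truth`` map each c to a Window; the per-c Jaccard
    distances of their index sets are integrated by the trapezoidal rule and
    normalized by the grid span, so the result lies in [0, 1].
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if c_grid.size < 2:
        raise InvalidInputError("c_grid needs at least two points")
    steps = np.diff(c_grid)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
        raise InvalidInputError("c_grid must be uniform and ascending")
    keys = [float(c) for c in c_grid]
    if set(keys) - set(estimated) or set(keys) - set(truth):
        raise InvalidInputError("estimated and truth must cover every c in c_grid")
    d = np.array(
        [
            jaccard_distance(estimated[c].indices0, truth[c].indices0)
            for c in keys
        ]
    )
    return float(np.trapezoid(d, c_grid) / (c_grid[-1] - c_grid[0]))


@dataclass(frozen=True)
class MonteCarloResult:
    """AIJD sample of one Monte Carlo cell (scenario, n, m, p, M)."""

    scenario: str
    n: int
    m: int
    p: int
    M: int
    aijd_values: np.ndarray
    c_grid: np.ndarray = field(repr=False)

    def summary(self) -> dict:
        qs = np.quantile(self.aijd_values, [0.05, 0.25, 0.5, 0.75, 0.95])
        return {
            "scenario": self.scenario,
            "n": self.n,
            "m": self.m,
            "p": self.p,
            "M": self.M,
            "mean": float(self.aijd_values.mean()),
            "quantiles": {
                "q05": float(qs[0]),
                "q25": float(qs[1]),
                "q50": float(qs[2]),
                "q75": float(qs[3]),
                "q95": float(qs[4]),
            },
        }


def run_monte_carlo(
    spec: ScenarioSpec,
    n: int,
    m: int,
    p: int,
    M: int,
    c_grid=None,
    seed: int = 0,
    eta: float = MC_ETA,
) -> MonteCarloResult:
    """M-replicate recovery study: AIJD of the estimated vs true windows.

    Per replicate (with its own seed spawned from ``seed``, so results are
    reproducible regardless of execution order): simulate the scenario,
    estimate group parameters once, select the maximum-divergence window for
    every c in ``c_grid``, and score AIJD against the population optima.
    """
    if M < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    c_grid = DEFAULT_C_GRID if c_grid is None else np.asarray(c_grid, dtype=float)
    grid = spec.grid(p)
    truth = {
        float(c): true_optimal_interval(spec, grid, float(c), eta=eta) for c in c_grid
    }
    child_seeds = np.random.SeedSequence(seed).spawn(M)
    values = np.empty(M)
    for i in range(M):
        rng = np.random.default_rng(child_seeds[i])
        curves_x, curves_y = simulate_scenario(spec, n, m, seed=rng, p=p)
        params_x = _shrunken(estimate_gaussian_params(curves_x), eta)
        params_y = _shrunken(estimate_gaussian_params(curves_y), eta)
        estimated = {
            float(c): select_from_params(params_x, params_y, float(c)).window
            for c in c_grid
        }
        values[i] = aijd(estimated, truth, c_grid)
    return MonteCarloResult(
        scenario=spec.name, n=n, m=m, p=p, M=M, aijd_values=values, c_grid=c_grid
    )
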