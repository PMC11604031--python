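# kldomain

**Domain selection for Gaussian-process data via local Kullback–Leibler
divergence.**

Given two groups of curves recorded on a common time grid — say healthy and
infarcted ECG heartbeats, or any other two-sample functional data — this
package finds the *contiguous time interval of a given length where the two
groups differ the most in distribution*, quantifies the uncertainty of that
interval by the bootstrap, and (optionally) classifies new curves using only
the selected interval.

## The method

Model each group as a Gaussian process observed on a grid of `p` points, so
each group reduces to a multivariate normal law `N(μ_ℓ, Σ_ℓ)`, `ℓ ∈ {X, Y}`.
For any subset `A` of the grid, the **local KL divergence** is the KL
divergence of the restrictions:

    KL_A(X‖Y) = ½ [ tr(Σ_{A,Y}⁻¹ Σ_{A,X}) − |A| + Δ_Aᵀ Σ_{A,Y}⁻¹ Δ_A
                    + ln det Σ_{A,Y} − ln det Σ_{A,X} ],    Δ = μ_Y − μ_X.

It is nonnegative, zero exactly when the restricted parameters agree, and
*monotone* in `A`. The **interval of local maximum divergence** `A*(c)` is
the contiguous window spanning a fraction `c` of the domain that maximizes
`KL_A`; by monotonicity the length budget always saturates, so the search
enumerates the `p − w + 1` windows of `w = round(c·p)` points and is exact.

Estimation plugs in the group-wise MLEs (sample mean, divisor-`n`
covariance); in high dimension the covariances are shrunk toward their
diagonal, `Σ̂_η = η Σ̂ + (1−η) diag(Σ̂)`, with `η` fixed or selected by
cross-validated held-out log-density. Uncertainty in the selected interval
comes from a nonparametric bootstrap of its center; classification restricts
the Gaussian (QDA) log-likelihood-ratio rule to the selected window.

## Worked example

Simulate the canonical mean-shift scenario (two groups of Fourier-basis
curves on `[0, π]` whose mean functions differ most near `t = π/2`, grid
point 50 of 100), select the 10%-length interval, and bootstrap its center:

```python
from kldomain import (scenario, simulate_scenario, select_interval,
                      bootstrap_selection, ShrinkageConfig)

spec = scenario("A")
curves_x, curves_y = simulate_scenario(spec, n=200, m=200, seed=7, p=100)
cfg = ShrinkageConfig(eta=0.9)

result = select_interval(curves_x, curves_y, c=0.1, shrinkage=cfg)
w = result.window
print(f"selected window: grid points [{w.start}, {w.end}]  "
      f"(center index {w.center_index}, center time {w.center_time:.4f})")
print(f"local KL divergence: {result.kl_value:.3f}")

full, boot = bootstrap_selection(curves_x, curves_y, c=0.1, B=200,
                                 alpha=0.05, seed=7, shrinkage=cfg)
print(f"95% CI for the center time: [{boot.ci[0]:.4f}, {boot.ci[1]:.4f}]")
```

Output:

```
selected window: grid points [47, 56]  (center index 51.5, center time 1.5865)
local KL divergence: 6.359
95% CI for the center time: [1.4923, 1.6493]
```

The selected window `[47, 56]` straddles grid point 50 (`t = π/2`), where
the generating mean functions differ the most; the KL value is the estimated
divergence on that window, and the bootstrap CI says the interval center is
located to within about ±0.08 time units.

The same machinery is available as scikit-learn estimators —
`DomainSelector` (a transformer: `fit(X, y)` on a labeled curve matrix, then
`transform` restricts curves to the selected window) and
`LocalGaussianClassifier` (QDA on the selected window) — and as a CLI:

```bash
kldomain simulate --scenario A --n 200 --m 200 --p 100 --seed 7 --out data
kldomain select --input data/curves.csv --c 0.1 --eta 0.9 --out results
kldomain bootstrap --input data/curves.csv --c 0.1 --B 1000 --out results
kldomain montecarlo --scenario A --n 250 --m 250 --p 50 --M 50 --out mc
```

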