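# Methods

## Model and procedure

Two groups of curves, recorded on a common equally spaced grid
`T = (t_1, …, t_p)` on a compact interval, are modeled as Gaussian
processes; their restrictions to the grid are `p`-variate normal laws
`N(μ_{T,ℓ}, Σ_{T,ℓ})`, `ℓ ∈ {X, Y}`. The canonical grid is left-closed with
the right endpoint excluded: `t_k = t_min + (k−1)(t_max−t_min)/p`.

For a subset `A` of grid points, the local KL divergence is the KL
divergence between the restricted laws (mean sub-vector, principal
covariance sub-matrix). As a set function it is nonnegative, zero iff the
restricted parameters agree, monotone under set inclusion, and reduces to
half the squared Mahalanobis distance when the two covariances coincide.
All evaluations use Cholesky factorizations: log-determinants come from the
factor diagonals, quadratic forms and the trace term from triangular
solves; no explicit inverse is formed. Results within `1e−12` of zero are
reported as exactly zero; a value below `−1e−8` raises an
internal-consistency error rather than being clamped.

The interval of local maximum divergence at length fraction `c ∈ (0, 1]` is
found by exhaustive search over all contiguous windows of
`w = round-half-up(c·p)` points (clipped to `[1, p]`). Because the local
divergence is monotone, the length constraint always binds at the optimum,
so only maximal-length windows are enumerated — `p − w + 1` candidates, an
exact search with a `p`-fold saving over enumerating all shorter windows
too. Ties are broken toward the smallest start index so results are
deterministic. Windows are reported with 1-based inclusive grid indices
(`[start, end]`), plus center and half-width in both index and time units;
the programmatic API otherwise uses 0-based numpy indexing.

The window-size rule `w = round-half-up(c·p)` is the convention that makes
the standard worked figures come out right: 91 candidate intervals on a
100-point grid at `c = 0.1` and 11 at `c = 0.9`, and window lengths
10/19/24/29/38/48/58/67/72/77/86/96 points on a 96-point grid for
`c = 0.1 … 1.0`.

Sequential selection of `K` disjoint intervals proceeds greedily: after
each selection the chosen indices are removed and subsequent searches run
only inside remaining contiguous segments of length ≥ `w`; fewer than `K`
intervals are returned once no segment can host a full window.

## Estimation and shrinkage

Group parameters are the maximum-likelihood estimates: sample mean and
divisor-`n` sample covariance (not `n−1`). When `p` is large relative to
the sample size — or when curves live in a low-dimensional function span,
see below — the sample covariance is singular on large windows. The remedy
is linear shrinkage toward the diagonal,

    Σ̂_η = η Σ̂ + (1 − η) diag(Σ̂),   η ∈ [0, 1],

which preserves pointwise variances and is positive definite for every
`η < 1` whenever the diagonal is strictly positive. The weight `η` can be
fixed or selected by K-fold cross-validation (default 5 folds, candidate
grid `{0, 0.1, …, 1}`), scoring each candidate by the mean per-curve
held-out Gaussian log-density; candidates whose training covariance fails
to factorize score `−∞`, and ties go to the smaller (more regularized)
`η`. `η` is selected once per group on the full grid and reused for every
window restriction and every bootstrap replicate; selecting per window or
per replicate would multiply the cost quadratically for no qualitative
gain. The two groups' weights are selected independently — nothing couples
them.

Irregularly sampled curves are projected onto a common grid by a
Gaussian-kernel local-constant (Nadaraya–Watson) smoother applied per
curve, with Silverman's rule-of-thumb bandwidth on each curve's own
observation times unless a bandwidth is given. Local-constant smoothing has
boundary bias; this is accepted, as the projection step only needs a
reasonable common-grid representation. Curve registration/alignment is
*not* performed; misaligned inputs should be synchronized upstream.

## Bootstrap inference

The selected window is summarized by its center time `t*_c`. A
nonparametric bootstrap draws `n` curves with replacement from group X and
`m` from group Y (independently within group, exactly `n` and `m` per
replicate), reruns the full selection, and records the center. The
percentile CI uses the empirical `α/2` and `1−α/2` quantiles
(linear-interpolation convention); defaults are `B = 1000`, `α = 0.05`.
The confidence *set* for the interval itself is the union of balls of the
window half-width `r_c` over the CI — `[lo − r_c, hi + r_c]`, clipped to
the domain. As `c → 1` the number of candidate windows shrinks to 1, so the
CI collapses; this variance–length trade-off is exercised in the tests.

## Classification

For two Gaussian classes the Bayes rule is the sign of the log-likelihood
ratio

    D(z) = ½(z−μ_Y)ᵀΣ_Y⁻¹(z−μ_Y) − ½(z−μ_X)ᵀΣ_X⁻¹(z−μ_X)
           − ½ ln(det Σ_X / det Σ_Y) + ln(π_X/π_Y),

positive for class X (quadratic discriminant analysis). The package
implements exactly this form — including the ½ on the log-determinant term,
which Bayes optimality requires. Restricting `D` to the selected window
gives domain-restricted QDA. Error-versus-`c` evaluation re-splits the data
per replicate (stratified, default 50/50), selects the window on the
training half only, and scores the held-out half; the re-splitting reading
is the conservative interpretation of a bootstrap over train/test
partitions. Priors default to the training class proportions. The
scikit-learn wrapper `LocalGaussianClassifier` follows the sklearn sign
convention (`decision_function > 0` votes for `classes_[1]`), the
functional API the domain convention (positive means group X).

## Synthetic scenarios

Curves are random Fourier-coefficient expansions on `[0, π]`:

    X(t) = (β_X + ε + γ·g(t))ᵀ Φ(t),   Y(t) = (β_Y + ε)ᵀ Φ(t),

with `Φ(t) = (1, cos t, cos 2t, cos 3t, cos 4t, sin t, sin 2t, sin 3t,
sin 4t)`, fresh `ε ~ N₉(0, 0.25·I)` per curve, optional bump
`g(t) = exp(−(t − 3π/4)²)` carried by fresh `γ ~ N₉(0, τ²·I)`, and

* scenario A: `β_X = (1,−2,−1,1,2,−1,2,3,−0.5)`,
  `β_Y = (−1,−2,−1,1,2,−1,2,5,−0.5)`, `τ² = 0` — mean difference only;
* scenario B: `β_X = β_Y`, `τ² = 1` — variance difference only;
* scenario C: both.

The basis ordering (constant, then cosines, then sines, unit angular
frequencies, unnormalized) is the package's convention, chosen because it
gives the scenarios their intended geometry: the scenario-A mean gap
`2 − 2·sin 3t` has its unique maximum at `t = π/2` (grid point 50 of 100)
and the profile of windowed divergences is unimodal there, while the
scenario-B covariance difference `τ² g(t) g(s) Φ(t)ᵀΦ(s)` peaks at
`t = 3π/4` (grid point 75). An interleaved sine/cosine ordering would
scatter the scenario-A gap across four symmetric peaks and destroy this
geometry. The basis lives behind a single function so the convention can be
swapped.

A structural consequence: every curve lies in the 9-dimensional span of
`Φ` (18-dimensional for a bump-carrying group), so *both the true and the
sample covariances have that finite rank*, and their restrictions to
windows wider than the rank are exactly singular at every sample size —
for the bump scenarios the directed divergence on the unregularized truth
is not even finite, since the X-restriction's range exceeds the
Y-restriction's. The simulation study therefore evaluates both the
population optimum and the estimates on shrinkage-regularized covariances
with a common fixed weight `η = 0.9`; with truth and estimate regularized
identically, the estimated window still converges to the population window
and recovery error goes to zero. The selected peak locations are
insensitive to `η` across `[0.3, 0.9]`.

## Recovery metric and Monte Carlo study

Recovery of the population window is scored by the average integrated
Jaccard distance: `1 − |A*∩Â*|/|A*∪Â*|` per length fraction, integrated
over a uniform `c`-grid (default `{0.05, …, 0.95}`) by the trapezoidal rule
and normalized by the grid span, so AIJD ∈ [0, 1] with 0 = perfect
recovery at every `c`. Each Monte Carlo replicate gets its own seed spawned
from the master seed (`SeedSequence.spawn`), so results are reproducible
regardless of execution order. The default study sizes used in the tests
(`M = 50` replicates, `p = 50`, `n = m ∈ {50, 250, 1000}`) are the
package's choice of a cell size large enough for the consistency trend —
mean AIJD strictly decreasing in `n` — to be stable across seeds; larger
sweeps are available through the CLI.

## What the synthetic tests do and do not show

The generator reproduces localized mean and variance differences with a
known population optimum, which is what the selector and the recovery study
need. It does **not** emulate two features of real curve data: observation
noise on top of the functional signal (curves are exactly finite-rank), and
a genuinely high-dimensional covariance. One visible consequence: because
all grid points share the same 9 coefficients, the full grid is *more*
informative for classification than any window — restricting QDA to the
selected interval helps on data whose covariance has `O(p²)` effective
parameters (as in real ECG signals, or the full-rank-noise setting used in
the classification tests), not on these low-rank scenarios. Passing tests
therefore validate the selector, the bootstrap, and the classifier
mechanics, but quantitative error rates on the scenarios do not transfer
to real data.

## Numerical choices and degenerate inputs

* Cholesky failure raises a not-positive-definite error naming the
  offending matrix; an optional jitter repair is deliberately absent —
  errors are preferred to silent fixes, and shrinkage is the sanctioned
  regularizer.
* Singleton windows delegate to the univariate closed form.
* `estimate_error` refuses splits leaving fewer than 2 curves per group per
  side; bootstrap failures abort with the replicate index.
* All index sets are validated (nonempty, in range, duplicate-free).
* The choice of `c` is left to the user: `divergence_vs_length` supports an
  elbow-style choice, `estimate_error` a predictive one; no automatic
  selection is performed.

## Known limitations

* Non-contiguous subset optimization is out of scope (the contiguous
  relaxation is the point of the method); so are divergences other than KL
  and non-Gaussian processes.
* The exhaustive search is O(p·w³) per profile; fine for `p` up to a few
  thousand, but no accelerated search is provided.
* Percentile bootstrap only; no Student-t, parametric, or double bootstrap.
* Local-constant smoothing biases boundary estimates for irregular designs.
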