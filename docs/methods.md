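# Methods

This note documents the models implemented in `bayesmech`, the numerical
choices behind them, what the synthetic fixtures do and do not emulate,
and the design decisions taken where more than one construction was
defensible.

## State partition and steady state

All computations use the canonical coordinate order `x = (η, s, a, μ)`
with blanket `b = (s, a)`; blanket-only analyses set `d_a = 0`. One fixed
order for every matrix, sample array and serialized file removes an
entire class of block-indexing errors; `BlanketPartition.slices()` is
the single source of truth for index ranges.

The steady state is `p = N(m, Π⁻¹)` with Π symmetric positive-definite.
Σ is computed once by dense inversion and cached; the construction
rejects inputs whose inverse residual `‖ΠΣ − I‖_max` exceeds tolerance
(default 10⁻⁸ relative to `‖Π‖_max` — double-precision headroom for the
well-conditioned, low-dimensional matrices this package targets).
Nonzero means are supported throughout: a set-point other than the
origin is the same model in a translated frame, so every block formula
is applied to centered coordinates.

A Markov blanket is declared when the (η, μ) block of Π vanishes to the
same relative tolerance. The conditional-independence residual
`Σ_ημ − Σ_ηb Σ_b⁻¹ Σ_bμ` is the covariance-side diagnostic of the same
property and is exercised against the precision-side test on random
fixtures.

## Fixture generator

`sample_blanket_precision` draws a dense symmetric Gaussian matrix,
zeroes the (η, μ) block, and shifts the diagonal by
`max(0, −λ_min) + scale`. The shift cannot reintroduce η–μ coupling, so
the blanket sparsity is exact by construction, and positive-definiteness
holds for every seed. This is the simplest generator that cannot violate
the blanket condition; it makes no attempt to produce realistic spectra,
sparsity patterns, or near-degenerate cross-blocks — degenerate cases
are covered by dedicated presets (`fig2_degenerate`) rather than by the
random generator, whose cross-blocks are full-rank with probability one.
Consequently, passing property tests on these fixtures demonstrates the
algebraic identities on generic well-conditioned problems, not numerical
robustness at the edge of rank deficiency.

## Synchronization map

Existence is decided by the kernel-inclusion test
`‖Σ_ηb (I − Σ_μb⁻ Σ_μb)‖_max ≤ tol`, i.e. the external cross-block must
annihilate the orthogonal projector onto `ker Σ_μb`. The same test on
the precision blocks is computed as a cross-check and the two verdicts
are compared on every call. Pseudo-inverses use SVD with singular values
below `rank_tol × s_max` treated as zero (`rank_tol = 10⁻¹⁰`):
scale-invariant rank decisions drive both the kernel test and `Σ_μb⁻`.

Both construction forms are always returned, even when existence fails
(the map is always definable; it is only *faithful* under the kernel
inclusion). When the internal space is strictly larger than the blanket,
the two matrix representations are free to differ off the map's domain
`Image(μ(·)) = range(Σ_μb)`; they agree to machine precision *on* that
image, which is what the invariant tests assert. The basis of the image
is carried on the `SyncMap` object for exactly this purpose.

The empirical binning check uses equal-probability (quantile) bins over
the sampled blanket values — 20 bins, minimum 100 samples per bin by
default — rather than equal-width bins, which stabilizes the tail bins.
Per-bin standard errors are reported for both the external and internal
empirical means; the agreement criterion compares the prediction gap to
the combined standard error of the two quantities entering it.

## Diffusions

The drift is assembled as `−(Γ+Q)(x) Π (x − m) + ∇·(Γ+Q)(x)` with
`Γ = ςςᵀ/2` and Q antisymmetric (checked at every probed state). The
divergence of a matrix field is row-wise, `(∇·M)_i = Σ_j ∂_j M_ij`:
exactly zero for constant fields, user-supplied in analytic mode, or
central finite differences with step `10⁻⁵(1 + |x_j|)` otherwise.
Smoothness of user-supplied fields is assumed, not verified.

Integration is fixed-step Euler–Maruyama. Noise uses one substream per
path keyed by `(seed, path_index)` and drawn in fixed-size chunks, so a
path's realization is independent of how many paths are batched
alongside it. Divergence of a path is detected by a finiteness check at
every recorded step and reported with the offending step index; numpy
overflow warnings are suppressed in favour of that explicit error.
Noise-free conservative runs (ς ≡ 0) additionally support a classical
4th-order Runge–Kutta step, used to verify that solenoidal flow
conserves the quadratic form xᵀΠx along trajectories.

For constant fields the closed-form transition
(`mean = e^{Bt}x₀`, `cov = Σ − e^{Bt}Σe^{Bᵀt}`) serves as the simulation
oracle, and the Lyapunov residual `BΣ + ΣBᵀ + ςςᵀ` is exposed as an
exact (algebraic) stationarity diagnostic.

**Problem sizes.** The ergodic check of the time-average covariance uses
a single trajectory of 2×10⁶ steps at dt = 10⁻³ (2000 time units) and a
Frobenius-norm relative tolerance of 5%. The autocorrelation time of the
worked 3-variable model is ≈ 2 time units, so a 1000-unit trajectory has
only a few hundred effective samples and entrywise 5% agreement is not
statistically guaranteed at that length; the doubled horizon and
norm-level comparison give a comfortable (≈3×) margin without weakening
the scientific claim.

**Non-Gaussian transitions.** The `transition_nongaussian` preset uses
`ς(x) = √(2c(x)) I` with `c(x) = 0.05 + 2 tanh(x₀)²`, a ~40-fold noise
amplitude contrast across typical states. Transition densities from a
point mass are then mixtures over noise histories (strongly
leptokurtic, normality rejected at p < 10⁻²) while the time-marginal
remains consistent with N(0, Σ) — the demonstration that a Gaussian
steady state does not imply a Gaussian process. The assertion is
qualitative by design; no quantitative transition-density comparison is
attempted.

## Free energy

`F(b, μ) = KL[q_μ ‖ p(η|b)] − log p(b, μ)` is computed with all additive
constants, so the two decompositions — evidence-bound form and
energy − entropy form — are exact identities tested to ~10⁻¹⁰ rather
than "up to a constant" conventions. For equal-covariance Gaussians the
KL term reduces to `½(σ(μ) − η(b))ᵀ Π_η (σ(μ) − η(b))`, directly linking
the variational and predictive-coding readings. The minimizer over μ is
obtained by the closed-form convex quadratic solve (Hessian
`σᵀΠ_ησ + K_μ`, with K the (b, μ)-marginal precision); tests cross-check
it against a generic quasi-Newton optimizer run on the black-box
objective.

Prediction errors `ξ = Π_η(η − σ(μ))` support both conventions for the
internal argument: `expected` substitutes μ(b_t) (the event-average
protocol), `realized` uses the simulated internal coordinate. With
realized η and expected internals at steady state, ξ is exactly
N(0, Π_η); under the fully-expected convention ξ vanishes identically,
so the realized-η reading is the default for ξ statistics.

## Relaxation experiments

The perturb-and-relax protocol initializes an ensemble from the steady
state conditioned on a clamped blanket (or sensory) state — legal
because the blanket renders η and μ conditionally independent, so they
are drawn from their separate conditionals; conditioning on s alone uses
generic Gaussian conditioning of (η, a, μ). The default "improbable"
perturbation is +3 marginal standard deviations along the first clamped
coordinate: far enough for an unambiguous transient, near enough that
the linearized relaxation times still apply.

Ensemble free energy is reported with per-time standard errors. Two
caveats documented by the tests: (i) the mean free energy need not fall
monotonically — solenoidal flow can transiently climb the free-energy
landscape — so only the start-versus-end decrease and the terminal
agreement with the stationary expectation (two-estimator comparison
against direct sampling from p) are asserted; (ii) clamping the blanket
*at its mode* is not the stationary joint — the series starts slightly
below the stationary mean and rises as the blanket re-disperses, so
"flat" for a typical start means "no elevated transient", not
constancy.

Default experiment sizes (500 paths, dt = 0.01, 10–12 time units) put
terminal Monte-Carlo standard errors near 0.05 nat on the fixtures
shipped, against initial elevations of several nats.

The active variant records realized active states against the optimal
action `a(s) = Σ_as Σ_s⁻¹ s`. The `fig8_like` fixture carries a
structured antisymmetric sensory–active circulation (±1.5) on top of a
weak random solenoidal component: that coupling is what produces the
reaction-time signature — realized actions tracking the optimal action
with a positive cross-correlation lag (≈0.3 time units on this
fixture). A purely random solenoidal field of the same scale does not
produce a detectable lag; the structured fixture makes the demonstrated
phenomenon explicit rather than incidental.

## Integrator chains and gains

Chains are stacked linear diffusions with block upper-bidiagonal drift
(level i couples only to level i+1); stability is enforced at
construction with an eigenvalue report, and the stationary covariance
comes from the continuous Lyapunov equation. The output map is a list of
per-level matrices `F_i` with `s = Σ_i F_i s(i)`; the default selects
the proportional level, all `F_i` configurable.

Analytic output autocovariance is `C(τ) = F e^{Aτ} Σ̃ Fᵀ`. Empirical
autocovariances come from a single stationary path; because the chain is
linear, the simulator defaults to the *exact* Gaussian transition
(`x' = e^{A dt} x + w`, `cov(w) = Σ̃ − e^{A dt} Σ̃ e^{Aᵀ dt}`), which
removes discretization bias from the comparison; Euler–Maruyama remains
available. Empirical-versus-analytic comparisons use lags up to ~1.5
correlation times — beyond that the autocovariance is small and relative
error is dominated by Monte-Carlo noise rather than by anything the
model controls.

Per-order feedback gains are **defined** as the coefficients of the
closed-form minimizer of the extended objective: the minimizer over
(a, μ) at fixed s̃ is `z*(s̃) = −K_zz⁻¹ K_zs Σ_i F_i s(i)`, and
`L_i = [K_zz⁻¹ K_zs F_i]_a` gives `a*(s̃) = −Σ_i L_i s(i)`. This is the
unique linear feedback consistent with the quadratic objective; for a
three-level chain the gains are labelled integral, proportional,
derivative. The extraction is validated against a derivative-free
numeric argmin of the black-box objective (central differences are
exact for quadratics, making the 10⁻⁸ agreement a genuine
implementation check, not a tolerance fudge).

## Experiment runner

Every experiment is fully determined by its config: seeds are mandatory,
defaults are filled during validation, and the canonical config plus its
hash are written into the output manifest. CSV floats are serialized at
17 significant digits so identical configs reproduce identical bytes.
Logging goes to standard error; tables are never interleaved with logs.

## Known limitations

- Dense linear algebra throughout: intended for the low-dimensional
  (d ≲ 100) models of this theory, not for large graphical models.
- State-dependent fields are integrated path-by-path in Python; large
  ensembles with non-constant fields are slow. Constant-field (OU)
  ensembles are vectorized and fast.
- Estimation of Π from empirical data is out of scope: fixtures and
  user-supplied matrices only.
- Binning diagnostics are one-dimensional in the blanket, matching the
  protocols they implement.
- Nonlinear synchronization maps (Laplace-approximated non-Gaussian
  steady states) and jump-process realizations are not implemented.
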