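# Methods

## Model and assumptions

The package implements the rate-based BCM plasticity system for a single
linear neuron with `N` synapses on a ring.  Output: `y = Σᵢ wᵢxᵢ`.  Weight
update per stimulus presentation: `Δwᵢ = (1/τ_w) xᵢ y (y − θ)`.  The
sliding threshold has two implementations:

* **averaged** (default): `θ = (1/K) Σₖ (yᵏ)²`, recomputed from all K
  stimuli before every update.  This is the quasi-static limit τ_θ ≪ τ_w in
  which the (N+1)-dimensional system reduces to N dimensions; the whole
  spectral analysis lives in this limit.
* **online**: `Δθ = (1/τ_θ)(−θ + y²)` with the current stimulus only, θ
  updated before the weight update within a step (one order had to be fixed
  for determinism; with τ_θ ≪ τ_w the choice is immaterial).  Default
  τ_θ = τ_w/20 when unspecified; the mode-agreement tests use τ_w/100.

Assumptions inherited from the model class: linear transfer, discrete
stimulus set presented in randomly permuted epochs (each stimulus exactly
once per epoch), weights unconstrained in sign and magnitude — the
selective fixed points `w* = N X⁻¹eₖ` contain negative entries, so clipping
or normalisation would destroy them.  Time is discretised as one
presentation = one unit step (forward Euler, Δt = 1); τ_w is counted in
presentation steps.

## Stimulus ensembles

All inputs are generated internally.  An ensemble is the `N × K` matrix of
one symmetric bump profile evaluated at K equi-spaced centres `cₖ = kN/K`:

* von Mises `f(d) = exp{[cos(2πd/N) − 1]/ω}`, default ω = 0.5 (smooth);
* triangular `f(d) = max(1 − d/(ωN), 0)`, default ω = 0.38 (non-smooth),
  with d the circular distance; ω < 0.5 is enforced so the support does not
  wrap.

These widths, τ_w = 1000 steps, the mixing ε = 0.1 and the N range 8–18 are
the study conditions and are the package defaults.  The von Mises formula
is evaluated at the circular distance rather than the raw offset (the
cosine makes the two equivalent) so that profile symmetry `f_{N−j} = f_j`
and the circulant structure of the square ensemble hold bit-exactly.
Non-square ensembles (K = N/2 under-complete, K = 2N over-complete with
half-integer centres) evaluate the same formulas at real offsets; their
column norms agree only up to resampling (~0.2% for K = 2N, N = 8).

**Singularity flag.** A square ensemble is marked singular when
σ_min/σ_max < 1e−12.  A determinant-based measure (|det X| relative to the
product of column norms) was rejected: det X equals the product of all N
Fourier coefficients, so it underflows exponentially in N for smooth
profiles (1.6e−16 already at N = 14, where cond(X) is only ~5×10³) and
would misclassify precisely the slow regime the package exists to study.
The condition number of X is reported with every fixed-point solve because
ill-conditioning *is* the slowdown diagnostic.

## Fixed points and stability

With det X ≠ 0 every equilibrium of the averaged dynamics is labelled by
its active set S: responses are K/|S| on S and 0 elsewhere (θ = K/|S|
follows from the threshold definition), and the weights solve `Xᵀw = y*`
via LU factorisation.  Stability is classified from the eigenvalues of a
central-finite-difference Jacobian of the drift (step h = 1e−5·(1+|wᵢ|),
O(h²) accurate on this polynomial field), with tolerance 1e−7·N on the real
parts: all < −tol → stable, any > +tol → unstable, else marginal.  The
empty-set equilibrium w = 0 has an identically vanishing linearisation and
is classified marginal.  Brute-force enumeration of all 2^K active sets is
provided for small K; at K = N = 4 it confirms that exactly the N selective
equilibria are stable.

## Spectral analysis and the time-unit convention

For square ensembles the Jacobian at a selective fixed point is
`J = −NXX`; since X is symmetric circulant its eigenvalues are the cosine
coefficients `aₘ = Σⱼ fⱼ cos(2πjm/N)` and `λₘ = −Naₘ²` with degeneracy
(1, 2, …, 2, 1) over m = 0, …, N/2.  The spectrum is computed from cosine
sums (exact for circulant matrices); dense diagonalisation serves only as
an independent test oracle.  `a_{N/2}` is additionally computed as the
alternating sum `f₀ − 2f₁ + 2f₂ − …` and as half the sum of discrete second
differences `f″ᵢ = f_{i−1} − 2fᵢ + f_{i+1}` over odd i; the three routes
agree to 1e−12 and the second-difference form explains *why* smoothness
matters.

**Sum-vs-mean convention.** `J = −NXX` is exactly the Jacobian of the drift
summed over the K stimuli (the θ-dependence term cancels the selective
stimulus's contribution; verified analytically and by finite differences).
One time unit of this drift therefore corresponds to one sweep of K
presentations, and `τ_crit = τ_w/|λ_crit|` is in sweeps.  Quantities are
compared with stochastic simulations via `τ_steps = K·τ_crit` presentation
steps; the measured/predicted ratios come out at 0.98–0.99 for N = 8–12.
Ties for the critical mode break toward the smallest non-negative m.

## Convergence measurement

Convergence is the angle between w(t) and the target steady state —
scale-invariant, insensitive to the unconstrained weight norm.  The time
constant is an OLS fit of log(angle) against time restricted to records
where the normalised angle lies in [0.05, 0.5] of its initial value
(default window): the upper cut removes the early multi-mode transient,
the lower cut the schedule-noise floor.  At least 10 in-window records are
required and non-decaying fits are rejected rather than extrapolated.  On
pure exponentials the estimator recovers τ to <0.1% over three decades.
The deterministic cross-check perturbs a selective fixed point by 1e−3
(relative to ‖w*‖) along the analytic critical eigenvector `cos(πi)` and
integrates the summed drift directly, isolating λ_crit from schedule noise.

For K ≠ N runs (no closed-form target) the target is the weight vector at
the final recorded step, and the summary statistic is the first recorded
step from which the angle to it stays below 0.05 rad; the winning stimulus
(largest final response) is reported alongside.

## Problem sizes and budgets

Step budgets scale with the prediction: `steps_per_tau × K × τ_crit`
presentation steps (doubled for K = 2N, where convergence is empirically
about twice as slow), capped by the config.  The test suite and the
acceptance script run the stochastic sweeps at N ∈ {8, 10, 12} with
steps_per_tau = 3.5 — enough for the default fit window, since the angle
must fall to 5% ≈ 3 time constants — and the completeness sweep at
N ∈ {8, 12}; the full N = 8…18 theory table is instantaneous, but
stochastic runs beyond N = 14 are impractical *because of the phenomenon
itself* (τ ≈ 1.4×10⁹ steps at N = 14).  The inner presentation loop is
numba-compiled with responses `r = Xᵀw` maintained incrementally via the
Gram matrix and refreshed at every epoch boundary; schedules come from a
seeded numpy Generator in epoch-aligned chunks, so runs are bit-reproducible
given (config, seed).  A run aborts loudly if ‖w‖ exceeds 10⁶ × ‖w(0)‖.

## What the generator does and does not emulate

The synthetic ensembles are noise-free, perfectly symmetric, identical
across stimuli and equi-spaced — exactly the analysed setting.  Passing
tests therefore validate the mechanism (high-frequency stimulus content
controls BCM convergence speed), not robustness to stimulus noise,
heterogeneous profiles, continuous stimulus distributions, nonlinear
transfer or multi-neuron circuits, all of which are out of scope.
Far-from-equilibrium behaviour is likewise untested: the fit window
deliberately restricts claims to the linearised neighbourhood of the fixed
point.

## Known limitations

* The theory covers K = N only; K ≠ N results are simulation-based with a
  post-hoc convergence target, and the K = 2N budget factor is empirical.
* The fit-window estimator is this package's choice; other read-offs of
  "convergence time" shift absolute numbers (not the growth trends).
* For K = N/2 the converged state depends on the random initial vector's
  component orthogonal to the stimulus span, which the dynamics never
  changes; the convergence *speed* statements are unaffected.
* At N ≳ 16 (von Mises) cond(X) ≳ 4×10⁴ starts to erode the 1e−10
  round-trip accuracy of fixed-point solves; condition numbers are reported
  so users can judge.
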