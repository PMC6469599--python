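# bcmring

**BCM synaptic plasticity on a ring of synapses: simulation and spectral
convergence analysis.**

`bcmring` is for computational neuroscientists who simulate unsupervised
receptive-field development with the Bienenstock–Cooper–Munro (BCM) rule and
wonder why their simulations crawl when they add synapses.  It implements
the single-neuron BCM system together with a circulant-matrix eigenvalue
analysis that predicts the convergence time constant exactly — and shows
that for smooth stimulus profiles the time constant grows *exponentially*
with the number of synapses, while a minor change of stimulus shape
(triangular instead of von Mises) removes the slowdown.

## The model

A linear neuron with `N` synapses responds to stimulus `x` with
`y = Σᵢ wᵢxᵢ`.  Each presentation updates the weights by the BCM rule

```
Δwᵢ = (1/τ_w) xᵢ y (y − θ),        θ = (1/K) Σₖ (yᵏ)²
```

where the sliding threshold θ tracks the average squared response over the
`K` stimuli (the fast-threshold limit; an online θ with its own time
constant τ_θ is also provided).  The stimuli are circular shifts of one
symmetric bump profile `f` — von Mises `f_j = exp{[cos(2πj/N) − 1]/ω}` or
triangular `f_j = max(1 − d(j)/(ωN), 0)` — so for `K = N` the stimulus
matrix `X` is symmetric circulant.  Its eigenvalues are the cosine Fourier
coefficients `aₘ = Σⱼ fⱼ cos(2πjm/N)`, and near a selective fixed point
`w* = N X⁻¹ eₖ` the dynamics linearise with Jacobian `J = −NXX`, whose
eigenvalues are `λₘ = −N aₘ²`.  The smallest `|λₘ|` sets the slowest time
constant

```
τ_crit = τ_w / |λ_crit| ,    a_{N/2} = f₀ − 2f₁ + 2f₂ − …
```

For smooth profiles `a_{N/2}` (an alternating sum, equivalently a sum of
discrete second differences) vanishes rapidly as `N` grows: the learning
slows down exponentially.  For the triangular profile it does not — and the
critical mode need not be `m = N/2` at all.

## Worked example

`python examples/simulate_and_fit.py` simulates N = 8 von Mises stimuli from
the mixed start `w(0) = 0.9 w¹* + 0.1 w²*` and compares the fitted
convergence time constant against the spectral prediction:

```
critical mode            m = 4 (of N/2 = 4)
lambda_crit              -0.09653
predicted tau            82,877 presentation steps
fitted tau (simulation)  82,288 steps  (R^2 = 0.999999)
ratio sim/theory         0.993
final angle to target    2.72e-03 rad (started at 0.059 rad)
```

The predicted τ is `K·τ_w/|λ_crit|` presentation steps (one unit of the
linearised theory's time equals one sweep of all K stimuli); the stochastic
permuted-schedule simulation reproduces it to within 1%.

`python examples/spectral_slowdown.py` prints the theory table for
N = 8…18: τ_crit for von Mises ω = 0.5 grows from 1.0×10⁴ to 2.5×10¹¹ sweeps
(ratio ~2.4×10⁷), while the triangular profile stays within a factor ~32 and
its critical mode sits below N/2 for four of the six N values.
`python examples/fixed_point_landscape.py` classifies all 16 equilibria at
N = 4 (exactly the 4 selective ones are stable), and
`python examples/completeness_sweep.py` shows the slowdown is present for
K = N and K = 2N stimuli but not for K = N/2 (growth factors 363×, 287× and
3× respectively from N = 8 to 12).

The same functionality is available from the shell:

```bash
bcmring spectrum --n 12
bcmring slowdown --n-values 8 --n-values 10 --seed 0 --output-dir out/
```

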