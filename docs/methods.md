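# Methods

## Model and assumptions

The package studies the SIR model with recruitment by birth, vaccination of
a fraction ν of newborns, per-capita mortality μ, recovery γ, frequency-free
mass-action transmission βSI and a per-susceptible sparking rate η of
infection imported from outside the population. Time is measured in years
and every rate is per year. The expected population size N = b/μ is fixed;
the model does not track the recovered class because S and I close the
dynamics.

β is never supplied directly: the basic reproduction number R0 = Nβ/(γ+μ)
is the epidemiologically meaningful control, so parameter sets carry R0 and
the package derives β = R0(γ+μ)μ/b. The product R0(1−ν) controls the
transcritical bifurcation at the immunization threshold ν_c = 1 − 1/R0.

Equilibria:

* closed model (η = 0): disease-free (N(1−ν), 0) always; endemic
  (N/R0, (μ/β)(R0(1−ν)−1)) when R0(1−ν) > 1.
* open model (η > 0): a single equilibrium with I* > 0 at every uptake,
  obtained in closed form as the unique nonnegative root of the quadratic
  β(γ+μ)I² + [(μ+η)(γ+μ) − βb(1−ν)]I − ηb(1−ν) = 0 (the constant term is
  negative, so exactly one root is positive). The closed form was preferred
  over ODE relaxation because it is exact, fast, and directly testable; the
  relaxed noise-free flow is used as an independent check in the tests.

Linear stability is reported through the Jacobian's trace τ and determinant
Δ, its eigenvalues, the damping ratio ζ = −τ/√(4Δ) (the standard
damped-oscillator definition; ζ < 1 ⇔ complex eigenvalues ⇔ oscillatory
return), the modulus √Δ of a complex pair, and the oscillation period
2π/Im(λ). The sign convention of the reduced oscillator is
z″ − τ z′ + Δ z = 0, so τ < 0 at stable equilibria gives positive damping.

## Fluctuation theory

Demographic stochasticity enters as the event-rate bookkeeping matrix B
(each diagonal entry sums the rates of all events that move that variable;
the off-diagonal carries the infection events that move both). Near a
stable equilibrium the deviations form a two-dimensional Ornstein–Uhlenbeck
process, whose stationary covariance Σ solves JΣ + ΣJᵀ + B = 0. The solver
writes the symmetric 2×2 case as an exact 3-unknown linear system rather
than calling a general Lyapunov routine; the general routine and an exactly
discretized OU simulation serve as independent cross-checks in the test
suite.

Derived summaries: the generalized variance det Σ; the 95% concentration
ellipse, defined through the 0.95 quantile of the chi-square law with 2
degrees of freedom (q ≈ 5.991, area πq√(det Σ) — so area² ∝ det Σ); and the
lagged autocovariance C(ℓ) = exp(Jℓ)Σ for ℓ ≥ 0, with C(−ℓ) = C(ℓ)ᵀ and
per-variable normalization by the stationary variances.

## Simulators

* **Gillespie**: exact simulation of the six-event jump process (birth of a
  susceptible at b(1−ν(t)), death of S, transmission, sparking, recovery,
  death of I). Recovery and death of I are separate events; together they
  contribute the (γ+μ)I diffusion term. Time-varying uptake is handled by
  capping holding times at one day and refreshing rates — exact for
  constant ν and negligibly biased at ramp rates of order 0.025/year.
* **Euler–Maruyama**: the diffusion approximation with state-dependent
  noise B(state)·dt, factorized by Cholesky with an eigenvalue square root
  as fallback near semidefinite states; states are floored at zero after
  each step (the standard truncation fix, adequate away from the
  near-extinction regime).
* **OU sampling**: the exactly discretized linearized process, propagator
  exp(J·dt) and innovation covariance Σ − exp(J·dt)Σexp(J·dt)ᵀ, initialized
  from Σ so series are stationary from the first sample. This is the
  preferred generator for long stationary series because it has no
  discretization error.
* **ODE**: adaptive-step (LSODA) integration of the drift, used for
  relaxation experiments and recovery-rate estimation.

Defaults: initial condition at the equilibrium of the initial uptake,
sampling interval one week, a single integer seed recorded in the series
metadata (ensembles use seed + replicate index).

## Estimators

Windowed indicators use deviations about the window mean — no smoothing —
because the linearized theory is near-stationary on windows short relative
to an uptake trend; default window 10 years, stride 1 year, ACF lag 1 year,
which exceeds the correlation time at the reference measles-like parameters
except very near the threshold. Lag-autocorrelations use the biased
normalizer (so |acf| ≤ 1) and interpolate linearly between the two
neighbouring lag multiples of the sampling interval.

The damped-cosine ACF fit estimates (|Re λ|, Im λ) by nonlinear least
squares on A·e^{−aℓ}cos(ωℓ+φ). A free amplitude is included because a
normalized ACF fixes only A·cosφ = 1 at ℓ = 0. Multi-start: ω from the
first zero crossing of the ACF and harmonically related guesses, φ on a
coarse grid; ties resolved by lowest residual, then lowest frequency. A
fitted frequency collapsing to zero flags an overdamped (pure-exponential)
ACF.

The recovery rate λ = d ln r/dt regresses the log of successive
oscillation-peak amplitudes of |I − I*|/N on the peak times; peaks are
discrete local maxima refined by quadratic interpolation, plateaus taking
the leftmost point, and at least three peaks are required.

The distance estimator inverts the eigenvalue-modulus relation
|λ|² = det J = μ(μ+γ)(R0(1−ν)−1), so (damping² + frequency²)/(μ(μ+γ))
estimates R0(1−ν) − 1 without knowing ν or R0 separately.

## What the generator emulates — and what it does not

The simulators generate weekly-sampled prevalence-like series under
demographic stochasticity alone, at the measles-like reference conditions
(b = 2×10⁵/y, μ = 0.02/y, γ = 365/22/y, η = 2×10⁻⁵/y, R0 = 17) and, for
uptake trends, a linear ramp of 0.025/year beginning in year 20. Real
surveillance data additionally carry reporting noise, aggregation into
incidence rather than prevalence, seasonal forcing and slow demographic
change, none of which are modelled; passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not performance on
field data.

## Numerical choices and problem sizes

* Underdamped-boundary root-finding brackets ζ(ν) = 1 on
  [0.9·ν_c, ν_c − 10⁻⁶] by Brent's method, absolute tolerance 10⁻⁶.
* Stationarity checks pool post-burn-in samples across replicate runs;
  burn-in is at least two to three relaxation times 1/|Re λ|. Tolerances on
  Monte-Carlo comparisons are set from effective sample sizes (samples per
  correlation time), typically three standard errors.
* Stochastic validation runs use a reduced population (b = 2×10³, N = 10⁵)
  or a strongly damped small-CV parameter set (b = 5×10³, μ = 0.05, γ = 2,
  R0 = 5) so that exact ensembles of a few hundred replicates finish in
  seconds to minutes.

## Known limitations

* The linear-noise approximation requires fluctuations small relative to
  I*. At the reduced validation scale (N = 10⁵) the measles-like system has
  I* ≈ 5–50 and the exact process is boom–bust: prevalence is frequently
  zero and bursts dominate the variance, so the stationary Var(I) of the
  jump process sits tens of percent away from the Lyapunov prediction (and
  orders of magnitude away at intermediate uptake). The OU theory should be
  trusted only when the predicted coefficient of variation of I is well
  below one — which holds at the full N = 10⁷ reference scale near the
  threshold but not at aggressively reduced population sizes.
* The Euler–Maruyama floor-at-zero truncation biases the process in the
  same near-extinction regime.
* The disease-free dominant eigenvalue saturates at −μ just above the
  threshold, so "speed of return" there is informative about the distance
  to threshold only through the transmission eigenvalue (γ+μ)(R0(1−ν)−1).
* The ACF decay rate of I, not S, is the better proxy for the critical
  eigenvalue; the package computes both and leaves the comparison to the
  user.
* Out of scope by design: the SEIR latent class (the simulate module is the
  natural extension point), age-structured mixing, seasonal forcing,
  spatial or network transmission, estimation of R0 from data, and
  significance testing of indicator trends.
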