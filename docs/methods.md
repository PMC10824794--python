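# Methods

## Model and reductions

**Neural-mass columns.** Each column layer is a second-order neural mass
with intrinsic angular frequency ω, written in the complexified state
`z = q + i·p/ω` so that free motion is clockwise rotation at ω.
Intrinsic coupling uses two odd kernels: the potential-to-current
S-kernel, `S(x) = tanh(s_gain·x)` (positive near 0; at first order it
only shifts phase per cycle), and the current-to-current P-kernel,
`P(y) = -c1·y + c3·y³ - c5·y⁵` with `c1 > 0` (negative near 0; it alone
shapes the amplitude flow). Kernel inputs are clipped at a saturation
bound (default 10) so both kernels stay bounded.

**Cycle averaging.** Averaging the radial component of the motion over
one period gives the reduced amplitude flow `dR/dt = ω·μ·p_ii·f(R)` with

    f(R) = (1/2π) ∫ sin(ψ) P(R sin ψ) dψ
         = -c1 R/2 + (3c3/8) R³ - (5c5/16) R⁵,

i.e. half the first-harmonic content of the kernel under sinusoidal
drive. The closed form and adaptive quadrature agree to 1e-10 and the
full simulator reproduces the per-cycle drift to within 2% of its scale
(see Numerical choices for how that comparison is defined). The default
coefficients (1, 1, 0.2) are the minimal odd polynomial whose flow has
the root pattern {0 stable, R_u = √2 unstable, R_s = 2 stable}: a
monotone (linear) kernel has only the stable rest state and no limit
cycle.

**Extrinsic drive and its normalization.** Only homologous layers of
different columns interact at first order. A driver sitting *exactly*
on its limit cycle exerts zero resonant drive through the intrinsic
quintic kernel — the first harmonic of `P(R_s·sin)` vanishes at R_s by
the very condition that makes R_s stationary. The extrinsic pathway is
therefore modelled with a separate, monotone current-to-current drive
kernel `D(y) = -2y/R_s`, normalized so the cycle-averaged cross term is

    dR₁/dt ⊃ -h·cos(Δφ)·(R₂/R_s),

exactly `-h·cos(Δφ)` for a driver at R_s. The extrinsic term enters the
equation of motion as `i·h·D(Im z_driver)` *without* an ω prefactor, so
h carries amplitude-per-time (drift-rate) units and the drift relation
μ(t) = μ(0) − h·cos(Δφ)·t holds with h as given. Excitatory links are
negative (the drive kernel is negative near 0): they open the gate at
small lags; positive (inhibitory-signed) links open it near lag π.

**Phase dynamics.** The same averaging applied to the tangential
component gives `dφ¹/dt = C·sin(φ¹ − φ²)` with `C = h/R_s` — the
Kuramoto/XY form. The sign convention keeps the sine of (φ¹ − φ²) with
a positive coefficient; the physics lives in the sign of C, and the
synchronizing regime is C < 0 (excitatory coupling). The
`fit_kuramoto_constant` validation pins the lag, releases, and
regresses the lag velocity on sin(lag); for symmetric bidirectional
coupling the fitted constant is 2h/R_s.

## Seizure propagation and onset detection

A cascading network is a DAG of single-layer bistable columns; the
onset node starts on its limit cycle, all others at rest with driving
noise. The forward model for onset times is event-driven and
piecewise-linear: node j starts drifting when its first parent seizes,
with rate `Σ_k -h[j,k]·cos(Δφ_jk)` over currently seizing parents
(drifts from simultaneous parents add linearly — a first-order
additivity assumption validated against the simulator), and seizes when
its mean has drifted a distance `distance`.

**Commitment point.** Detection and forward model share one threshold,
`distance = R_s/2` by default. Two calibration facts motivate the
half-amplitude choice: (i) in the simulator a child accumulates drive
during its parent's subthreshold amplitude ramp, before the parent's
*detected* onset; (ii) with the threshold at fraction x of R_s, the
measured parent-to-child delay is `x·R_s/|h| − (x − ½)·τ_parent` for a
linearly ramping parent. At x = ½ the ramp term cancels and the delay
is `(R_s/2)/|h|` regardless of the parent's ramp rate, so the
piecewise-linear model is unbiased with respect to the detected onsets.
Detection runs on the cycle-averaged envelope (a one-period moving
average of |z| — the amplitude variable of the adiabatic theory, free
of the deterministic within-cycle modulation), requires the envelope to
hold above half the threshold for 5 periods (commitment, rejecting
transients), and refines the crossing below the recording stride by
linear interpolation. With envelope detection the per-node onset
distributions are unimodal and pass a Kolmogorov–Smirnov comparison
against a fitted normal at distance < 0.1 for 200 trials (the suite's
documented bound; raw-amplitude detection leaves oscillation-induced
multimodality an order of magnitude above this).

## Inversion

Free parameters are log-gains θ_m = log(−h_m) of the permitted
(cascading) links, which keeps estimated couplings sign-consistent.
The observation model is Gaussian on per-node mean onsets with variance
sd²/n_trials. Priors are Gaussian with variance 1/4 per element
(a conventional log-gain scale). Gauss–Newton ascent on the Laplace
free energy

    F = -½ e'Πe + ½ ln|Π| - (n/2) ln 2π - ½ δ'Π₀δ + ½ ln|Σ_θ Π₀|

uses finite-difference Jacobians (central, step 1e-5), Levenberg
damping (reject-and-redamp; accepted steps never decrease F), and stops
at ΔF < 1e-6 or 64 iterations. The Gaussian normalization constants are
included only when every observation precision is finite, so models of
the same data remain comparable. The analytic gradient exposed for
checking differentiates the quadratic objective with the curvature term
held fixed, the standard Gauss–Newton treatment. Uninformed parameters
cost nothing under the Laplace bound (their posterior equals their
prior), so model comparison only discriminates rivals whose extra
parameters the data actually inform.

## Synthetic-data generator

`make_demo_network` draws a seeded 5-node cascade: node 0 is the onset
node, each later node links from its predecessor and, with probability
½, one extra earlier node; magnitudes are uniform on [0.4, 0.9]
(delays of roughly 1–2.5 time units per link at the default threshold);
draws are rejected until predicted onsets are strictly increasing with
gaps ≥ 0.75 (well-separated recruitment). Default dynamics: ω = 2π
(period-1 oscillators), intrinsic coupling scale μ·p_ii = 0.01 (bistable
but weak against the extrinsic drives, honouring h ≫ g), driving noise
0.05 per √time on z, Euler step 1e-3 of a period, 200 trials. Trial k's
noise comes from its own spawned generator, so single trials reproduce
in isolation.

What the generator does *not* emulate: measurement noise and electrode
forward models (onsets are read from the state itself), heterogeneous
node frequencies, multifrequency semi-stable states, bidirectional
connectivity (hence seizure termination), and phase lags other than the
synchronized default. Passing tests therefore demonstrate internal
consistency of simulator, reduction and inversion — not performance on
empirical EEG.

## Numerical choices

- **Integrator** fixed-step Euler–Maruyama; noise is an additive complex
  Gaussian increment on z (σ√dt per component). First-order Euler
  inflates amplitudes by ≈ (ω·dt)²/2 per step; experiments that resolve
  small drifts (the per-cycle oracle, the drift-slope recovery) use
  dt = 1e-4 to 1e-5 of a period so this bias stays well below the
  signal. A guard aborts with the first offending time when |z| exceeds
  1e6.
- **Per-cycle oracle** compares one simulated period against the reduced
  ODE integrated over the same period (removing the O(μ) within-cycle
  drift of f), with error measured relative to the largest predicted
  drift over the amplitude grid, because f has zeros inside the tested
  range where pointwise relative error is undefined.
- **Drift-slope recovery** starts the driven column at R_s/2 so negative
  drifts are measurable (amplitude is nonnegative; a start at 0 would
  clip them), uses a weak driven-side self-coupling (μ = 0.002 ≪ |h|),
  and estimates the slope from consecutive cycle-averaged amplitudes
  per trial, reporting the Monte-Carlo standard error across 200 trials.
- **Root finding** (2-D stationary points): hybr refinement seeded from a
  31×31 grid, residual filter 1e-8, deduplication at 1e-5·r_max,
  Jacobian stability by finite differences; roots with |derivative|
  below 1e-8 are flagged degenerate, not classified. The 1-D flow uses
  the closed-form quartic in R². Basin attractors integrate the field
  from a 21×21 grid with amplitudes clipped at 0 (the flow lives on the
  closed quadrant; boundary-pinned attractors are real attractors that
  pointwise root-finding cannot see), clustering endpoints at 5% of
  r_max.
- **Ties and conventions**: φ = arg z with φ = 0 at z = 0; Δφ = φ_driver −
  φ_driven; lags reported wrapped to (−π, π], unwrapped only inside
  derivative estimation.

## Known limitations

- The reduction is first-order in the coupling: S/P cross terms and
  interlayer coupling (second order) are not represented.
- The forward model ignores drive accumulated while a *child* commits
  during its parent's ramp when the child link is stronger than the
  parent's recruitment rate; measured onsets then lead predictions by
  up to ~15% deep in a cascade, which inversion absorbs as a modest
  upward gain bias.
- With the gate closed (cos Δφ ≈ 0) the transition time falls back to
  the intrinsic rate `distance/(-g)`, the simplest form consistent with
  the reduced flow; noise-activated escape over the basin boundary is
  not modelled.
- The printed free energy depends on priors, data realization and
  implementation constants; only free-energy *differences* between
  models of the same data are meaningful here.
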