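# Methods

## The model system

The package studies manipulation of an underactuated object: a "cup of
coffee" rendered as a point-mass ball sliding inside a semicircular cup
that a hand moves along a horizontal line. Mechanically this is a
cart-pendulum: the cup is a cart of mass `mc = 2.4 kg`, the ball a bob of
mass `mb = 0.6 kg` on a rod of length `l` (0.3, 0.6 or 1.2 m for the
short/medium/long conditions), with gravity `g = 9.81 m/s²`. The hand
forces only the cup; the ball is controlled indirectly through the coupled
dynamics

```
(mc + mb) ẍ = mb l (θ̇² sinθ − θ̈ cosθ) + F_applied
         θ̈ = −ẍ cosθ / l − g sinθ / l
```

These two equations are mutually implicit in `(ẍ, θ̈)`; solving them
simultaneously gives the closed form used throughout (`dynamics.accelerations`):

```
ẍ = [mb (l θ̇² sinθ + g sinθ cosθ) + F] / (mc + mb sin²θ)
θ̈ = −ẍ cosθ / l − g sinθ / l
```

The denominator is bounded below by `mc`, so accelerations are finite for
every finite state. Note the denominator at `θ = 0` is `mc`, not
`mc + mb`: the ball's recoil cancels part of its inertia. The same
structure shortens the free small-oscillation period by the cart-recoil
factor `√(mc/(mc+mb))`, which the integrator tests verify against the
linearised closed form.

### The hand as an impedance controller

The hand is modelled as a spring-damper pulling the cup toward a
sinusoidal equilibrium trajectory `x_d(t) = ±A cos(2πft)`:

```
F_applied = K (x_d − x) + B (v_d − v)
```

This is a restoring law: positive position error produces a force toward
the equilibrium trajectory. (The opposite sign convention is positive
feedback — the linearised cart then has a right-half-plane pole and every
simulation diverges within a second — so the restoring form is the only
physically sensible reading.) The landscape sweeps hold `K = 40 N/m` and
`B = 70 N·s/m`.

Two amplitude conventions coexist in the problem: the target boxes sit at
±0.15 m, so the box-to-box sinusoid has half-excursion `A = 0.15 m`, while
the sweep protocol uses `A = 0.3 m`. Both are exposed; the default
`ControllerSpec` amplitude is 0.3 m (the sweep convention), and the worked
single-trial example uses 0.15 m, which reproduces the reference
variability value (see below). `phase_sign = ±1` selects whether the cup
starts in the left (−A) or right (+A) box; the two are exact mirror images
(negating x, v, θ, ω and F maps one onto the other), so the sign of the
"stable" initial ball angle flips with it.

### Integration

Fixed-step classic Runge-Kutta at `dt = 10 ms` for `15 s`, initial cup
state on the desired trajectory (`x₀ = x_d(0)`, `v₀ = 0`) so there is no
initial force transient, initial ball velocity −4 °/s. The choice of a
fixed step mirrors the discretisation of the original analysis; the test
suite confirms fourth-order convergence (halving `dt` cuts the one-period
error ≈16×) and <0.1% energy drift over 15 s for the unforced system.
A vectorised batch integrator (`simulate_batch`) advances every grid cell
of a sweep simultaneously, which makes a 19×15 landscape a ~1 s
computation instead of minutes.

## Per-trial measures

- **Relative phase / stability.** Instantaneous phases of cup position and
  ball angle from the analytic signal (`scipy.signal.hilbert`) after mean
  removal, unwrapped and subtracted (cup − ball). The circular variance
  `1 − |mean(e^{iφ})|` of the relative phase is the stability proxy:
  0 = perfectly phase-locked, 1 = incoherent. No edge trimming is applied
  by default — the untrimmed convention reproduces the reference value of
  the worked example — but every phase-based function accepts a
  `trim_seconds` (or `freq_hint`, meaning one nominal period) argument
  because analytic-signal edge artifacts do matter for short or noisy
  segments.
- **Effort**: mean |F_applied|.
- **Smoothness**: log dimensionless jerk of the applied force,
  `−log((t_end−t_0)³/F_peak² · ∫F̈²dt)`, computed with central-difference
  second derivatives and a trapezoidal integral; exactly scale- and
  time-reversal-invariant.
- **Escape risk**: ball energy `E = ½ mb l² θ̇² + mb g l (1−cosθ)` against
  the rim energy `E_esc = mb g l (1−cos 60°)`;
  `Risk = 1 − (1/(T·E_esc)) ∫ (E_esc − E) dt`, so a ball resting at the
  bottom scores 0 and a ball held at rim energy scores 1.
- **Stage parsing**: the rhythmic stage begins when the cup first enters
  the right target box (x ≥ 0.15 m minus the box half-width, default
  0.03 m); the boundary is the last cup-velocity zero (sign change or
  |v| < 10⁻³ m/s) before that onset.
- **Time to stable phase**: a window with its right bound pinned to the
  end of preparation grows backward one sample at a time; the first
  left-bound position at which the in-window circular variance exceeds 0.1
  marks the end of the unstable epoch. Windows shorter than 0.5 s are not
  evaluated (the variance of a few samples is meaningless). If no window
  exceeds threshold the trial is flagged stable-from-start and 0 s is
  returned — the procedure is otherwise undefined for such trials.

## Strategy landscapes and KL comparison

Sweeps run one 15 s trial per cell of a grid over initial ball angle
θ₀ ∈ [−90°, 90°] and cup frequency f ∈ [0.3, 1.0] Hz (default 37×36,
acceptance scale 19×15), then score it with one of the four objectives.
Cost-like maps become probability densities by softmin,
`p ∝ exp(−value/τ)`, with τ defaulting to the standard deviation of map
values — smooth, scale-aware, and argmin-consistent as τ→0. Behavioural
choices become a 2-D histogram on the same cells, floored at 10⁻⁶ before
normalisation so divergences stay finite. The comparison statistic is
`D(data ‖ model) = Σ p ln(p/q)`: how badly the model density explains
where the data mass lies. Absolute KL values depend on the binning and
density transform and are not portable across implementations; only the
*ranking* across objectives is meaningful, and that ranking is what the
recovery tests assert.

The medium and long stability maps contain exactly two low-variability
(< 0.1) branches separated by a ridge near the coupled resonance
`(1/2π)·√(g/l·(mc+mb)/mc)`: in-phase coordination below it, anti-phase
above. The short pendulum's resonance (~1.02 Hz) lies above the swept
range, so only the in-phase branch appears there.

## Stochastic open-loop optimal control (SOOC)

Trial-to-trial uncertainty about the pendulum is modelled by promoting `l`
to a state driven by an Ornstein-Uhlenbeck process,
`dl = −α(l − l_mean)dt + σ_ou dW`, with reversion rate `α = 100 s⁻¹` and
`σ_ou = σ_l √(2α)` so the stationary SD is `σ_l`: 0.37 m for the random
protocol (`l_mean = 0.7 m`, the mean and SD of the equiprobable
{0.3, 0.6, 1.2} m distribution) and 0.1 m for blocked blocks
(`l_mean` = the block's length).

The hand becomes an impedance-plus-feedforward controller
`F = K(x_d−x) + k_b K(v_d−v) + F_ff` with `k_b = 0.2`, and the planner
chooses time-varying `K(t) ≥ 0` and `F_ff(t)` through their second
derivatives (pseudo-controls), making the profiles C¹-smooth. The
9-dimensional augmented state `[x, v, θ, ω, l, F_ff, K, Ḟ_ff, K̇]` is
propagated as mean and covariance:

```
ṁ = f(m, u),    Ṗ = F P + P Fᵀ + G Gᵀ,    F = ∂f/∂X |_(m,u)
```

with `G` zero except `σ_ou` in the length row. The Jacobian is analytic
(finite-difference checked to 10⁻⁵). A trial is 2 s of preparation (the
reference is held at the start-of-rhythm state) followed by 6 s of
rhythmic tracking of `x_d = −A cos(2πf t_r)`, `A = 0.15 m`.

**Cost.** Quadratic throughout: rhythmic-stage tracking (`q_pos = 200` on
x, `q_vel = 20` on v), cup-state variance via trace terms
(`qv_pos = 2000`, `qv_vel = 200`), a co-contraction effort price on
stiffness (`q_stiff = 2·10⁻⁴ · K²`, active the whole trial), pseudo-control
effort `r = 10⁻⁶`, a large soft pin (`w = 2000`) of (x, v, θ, ω) to
(−A, 0, θ*, 0) at the end of preparation, and a terminal tracking+variance
cost. Soft penalties rather than hard equality constraints keep the
problem smooth for SQP. The numeric weights are this package's own
calibration: they place the model in the regime where stiffness is worth
buying only insofar as it suppresses uncertainty-driven cup variance.
Within that regime the qualitative predictions — stiffness rising through
preparation and plateauing, higher stiffness under higher σ_l at equal
applied force — are stable; absolute stiffness numbers are not claims.

**Numerics.** α = 100 makes the length subsystem stiff: the covariance
mode decays at 2α = 200 s⁻¹, and explicit RK4 is stable only for
dt < 2.78/200 ≈ 14 ms. Mean and covariance are therefore integrated at
dt = 10 ms (the covariance symmetrised every step), while the
pseudo-controls are piecewise-constant on a 0.5 s grid (16 intervals over
8 s) — a standard control-parameterisation transcription that keeps the
SLSQP problem at 32 decision variables. Initialisation follows the
problem's natural guess: `K(0) = 10`, `K̇(0) = 0`, `K̈ ≡ 0`, and `F̈_ff`
read off a forward simulation of the plain impedance controller at
`K = 10`. Non-negative stiffness is enforced as inequality constraints on
`K` at the control nodes. The propagation core is numba-jitted with a
bit-identical pure-Python reference implementation (they are compared in
the tests); one propagation costs ~3 ms, a full optimisation ~30 s.

**Validity of the linearised propagation.** The drift is multiplicative in
the fluctuating length (`l θ̇² sinθ`, `1/l`, `1/l²` terms), so first-order
covariance propagation carries `O((σ_l/l)²)` error. Against a 2,000-path
Monte-Carlo ensemble of the nonlinear SDE (exact Gaussian transitions for
the stiff OU subsystem, Euler for the mechanical states) the physical-state
variances agree to ≤5% at the blocked long condition (σ_l/l ≈ 8%), ~15–20%
at the medium length (17%), and the linearisation fails entirely at
σ_l/l ≈ 33% (short pendulum, where Monte-Carlo lengths approach zero).
The oracle test therefore runs where the method's own assumption
σ_l ≪ l holds; at the random protocol's σ_l/l ≈ 0.5 the propagated
covariance is a qualitative, not quantitative, object — a limitation
inherent to the mean-covariance approach, not to this implementation.

## Synthetic cohort

The generator emulates the *statistical structure the analysis assumes*,
not raw physiology. A participant is: a preferred coordination branch
(in-phase / anti-phase / mixed), a Gaussian frequency preference, a
softmin choice temperature over the stability landscape, motor noise on
the applied force, and a grip model
`grip = baseline + gain·σ_l(protocol) + coupling·|F| + noise` with the
grip level ramping up through preparation. Strategies are sampled from the
stability density restricted to the preferred branch and to an
escape-feasible mask (cells whose simulated ball stays under the 60° rim,
eroded by one cell so within-cell jitter cannot cross the sharp resonance
boundary — participants do not choose strategies that lose the ball).
Preparation is synthesised jiggling whose cup-ball relative phase is
incoherent in the first half and locks onto the chosen branch in the
second; the rhythmic stage is a true forward simulation at the chosen
(θ₀, f), run at 10 ms and resampled to the 120 Hz recording rate, with
motor noise added to the force channel only.

Ground-truth annotations: the *designed* preparation duration, and the
stage boundary *under the analysis convention* evaluated on the noise-free
kinematics. The two differ by a few samples because the ball's reaction
force produces a brief backward velocity dip at rhythm onset — as it would
in a real recording — so the last velocity zero sits just after the
construction junction.

What passing cohort tests do show: the full pipeline (I/O, stage parsing,
phase metrics, KL ranking) recovers the effects built into the generator —
longer preparation and higher grip under the random protocol, stability as
the lowest-KL objective. What they do not show: anything about real
participants' effect sizes, grip-force newtons, or inferential statistics;
the generator is phenomenological by design, with no learning across
trials and no haptic-perception model.

All randomness derives from one master seed through `numpy.random`
SeedSequence spawning, one stream per trial: cohorts are byte-reproducible
and trials are independent of generation order.

## Problem sizes used by the tests and the reproduction script

Landscape checks use the 19×15 grid; the KL recovery test samples 400
choices; the SOOC directional checks run two optimisations (σ_l = 0.37 vs
0.1 at matched strategy, 120 SLSQP iterations); Monte-Carlo oracles use
2,000–3,000 paths. The default cohort configuration mirrors the full
design (12 participants × 2 protocols × 3 pendulums × 40 trials = 2,880
trials); tests and the demo pipeline run 2–3 participants at 2–5 trials
per condition, which already exercises every code path.

## Known limitations

- First-order covariance propagation degrades with σ_l/l (quantified
  above); the random protocol sits outside its quantitative regime.
- SLSQP at 120 iterations typically stops at the iteration limit rather
  than the `ftol` criterion; the directional conclusions are insensitive
  to further iterations, but reported costs are not certified optima.
- Absolute KL magnitudes depend on binning and the softmin temperature;
  only rankings across objectives are interpreted.
- The stiffness-grip link is ordinal: simulated K (N/m) is never converted
  to grip newtons.
- The branch count at threshold 0.1 is a property of the sweep-convention
  amplitude (0.3 m); at the box-scale amplitude the long pendulum's
  in-phase branch fragments near resonance.
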