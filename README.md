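# cupball

Tools for studying how people manipulate an underactuated object under
dynamic uncertainty — the "cup of coffee" task, in which a hand transports
a cup containing a ball that it cannot control directly. The cup-ball
system is a cart-pendulum: cup position *x* (cart, mass *m_c* = 2.4 kg) and
ball angle *θ* (pendulum bob, mass *m_b* = 0.6 kg, rod length *l*) obey

    (m_c + m_b) ẍ = m_b l (θ̇² sin θ − θ̈ cos θ) + F
              θ̈ = −ẍ cos θ / l − g sin θ / l

with the hand modelled as an impedance controller tracking a box-to-box
sinusoid, F = K(x_d − x) + B(ẋ_d − ẋ). The package is aimed at
computational motor-control researchers who want to simulate this plant,
map which *preparation* (initial ball angle θ₀) and *interaction* (cup
frequency f) strategies yield dynamically stable coordination, model
impedance planning under parameter uncertainty, and run the full
behavioural-metric pipeline on synthetic cohorts.

## What's inside

| Module | Contents |
| --- | --- |
| `cupball.dynamics` | cart-pendulum plant, impedance controller, fixed-step RK4 (scalar and vectorised batch) |
| `cupball.metrics` | Hilbert relative phase, circular variance (stability), instantaneous frequency, mean absolute force, log dimensionless jerk, energy-margin escape risk, stage parsing, time-to-stable-phase |
| `cupball.landscapes` | (θ₀ × f) strategy sweeps, softmin densities, 2-D choice histograms, KL-divergence ranking of objectives |
| `cupball.sooc` | stochastic open-loop optimal control: Ornstein-Uhlenbeck length uncertainty, 9-state mean–covariance propagation, SLSQP transcription of time-varying stiffness + feedforward force |
| `cupball.cohort` | synthetic participant cohort with ground-truth annotations |
| `cupball.io`, `cupball.cli`, `cupball.pipeline` | CSV/YAML formats, `cupball` command-line tool, end-to-end pipeline |

## Worked example

Simulate the stable in-phase strategy on the medium pendulum — ball
prepared at θ₀ = −25° and cup driven at 0.5 Hz between the ±0.15 m boxes —
and measure the stability of the resulting coordination:

```
$ cupball simulate --theta0-deg -25 --amplitude 0.15 --omega0-deg-s 4 \
    --out fig_trial.csv
wrote fig_trial.csv; relative phase variability 0.0116
```

The relative phase variability (circular variance of the Hilbert-phase
difference between cup position and ball angle, 0 = phase-locked,
1 = incoherent) is **0.0116**: the ball swings in phase with the cup and
stays locked for the whole 15 s trial. Driving the same pendulum near its
coupled resonance (≈0.72 Hz) instead yields values an order of magnitude
higher — the instability participants avoid.

Sweeping all strategies shows the structure of the task:

```python
from cupball.dynamics import SystemParams
from cupball.landscapes import StrategyGrid, sweep_stability, count_stability_branches

m = sweep_stability(SystemParams(pendulum_length=0.6), StrategyGrid.with_resolution(19, 15))
print(m.values.shape, count_stability_branches(m), float(m.values.min()))
```

prints `(19, 15) 2 0.0004`: the medium-pendulum landscape holds exactly
two low-variability branches (in-phase below resonance, anti-phase above)
with near-perfect phase locking at their cores. `cupball compare` then
ranks how well each objective map (stability, effort, smoothness, escape
risk) explains a set of behavioural (θ₀, f) choices by KL divergence —
lower is better.

The optimal-control model (`cupball sooc --protocol random ...`) plans
time-varying arm stiffness for a trial with uncertain pendulum length:
stiffness rises through the 2 s preparation stage, plateaus during
rhythmic movement, and settles higher when the length uncertainty is large
(σ_l = 0.37 m, the random protocol) than when it is small (σ_l = 0.1 m) —
at essentially the same applied force. Grip force is the experimental
proxy for this impedance.

A full demo — synthetic cohort, per-trial metrics, landscapes, KL table,
optimal-control runs — is one command:

```
cupball pipeline --n-participants 3 --trials 5 --seed 1 --out-dir artifacts/
```

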