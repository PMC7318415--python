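# Methods

## Models

### Simplest Walker (SW)

A two-link planar walker: point mass *M* at the hip, two massless rigid legs
of length *l*, point feet. State (θ, φ, θ̇, φ̇) with θ the stance-leg angle
from vertical and φ the inter-leg angle, so heel strike lies on the surface
φ − 2θ = 0. Integration is in dimensionless units (lengths in *l*, time in
√(*l*/*g*)); *l*, *g*, *M* enter only when converting to SI in the metrics
layer. Stance is an inverted pendulum, θ̈ = (1 − u) sin θ under constant
force; the counterweight replaces the factor with (1 − u)/(1 + u) and the
tuned spring adds a term in (*l*/*g*) ω² u (1 − cos θ) sin θ; the swing
equation carries the matching coupling terms and the hip-spring torque
−*k*<sub>f</sub> φ. At u = 0 all three strategies reduce to the identical
unsupported walker (bitwise, by construction of the arithmetic).

**Heel strike and powering.** The leg-exchange map swaps leg roles and sets
θ̇⁺ = cos 2θ · θ̇⁻ + sin 2θ · *p*, φ̇⁺ = (1 − cos 2θ) θ̇⁺, where *p* ≥ 0 is an
impulsive toe-off applied along the trailing leg the instant before the
inelastic collision. The unpowered map (*p* = 0) strictly dissipates kinetic
energy at every strike and, on level ground, nothing restores it: *no*
periodic level-ground gait exists for the hip-spring-only walker, and every
unpowered gait decays into ever-shorter steps. The toe-off impulse closes
the energy balance; on a symmetric cycle it follows analytically from
periodicity as *p* = |θ̇| tan θ₀. The impact map and toe-off are applied
unchanged under all unloading strategies: a finite unloading force
contributes no impulse during an instantaneous impact.

**Calibration.** The reference gait is pinned to step length 0.7167 *l*
(θ₀ = asin 0.35835). One parameter remains free — the stance rate θ̇₀, which
sets gait speed. With *p* fixed by periodicity, the hip-spring stiffness is
found by bisection so the swing leg strikes exactly at the mirror angle
−θ₀, closing the cycle (`calibrate_default_gait`). At θ̇₀ = −0.44 the
residual has two roots; the stiffer one, *k*<sub>f</sub> = 1.06264, yields a
*stable* cycle (step length constant over ≥ 30 steps) while the softer root
is unstable and collapses under any unloading. The shipped defaults are
θ̇₀ = −0.44, *k*<sub>f</sub> = 1.0626392482014353, *p* = 0.1688904692855088;
the resulting baseline walks at 0.945 m/s with cadence 1.318 steps/s (for
*l* = 1 m) — within the range of slow human walking.

**Event handling.** The genuine strike is the crossing of φ − 2θ = 0 with
positive slope; crossings with |θ| ≤ 10⁻³ are the spurious mid-swing double
root and are stepped over. Because the post-impact state lies exactly on
the event surface, each step starts with a short guard interval (10⁻⁴ time
units) integrated without the strike event.

**Failure predicates** (all thresholds configurable): hip collapse
(cos θ ≤ 0.5), stance reversal (θ̇ rising through 0 — the vault failed), and
a non-forward step (strike with θ⁻ > 0).

### Bipedal walking SLIP

Point mass *m* = 80 kg on massless linear leg springs, *k* = 14 kN/m,
*l*₀ = 1 m, angle of attack α = 69° from the ground — the parameter set
proposed with the original compliant-leg walking model, together with its
reference speed 1.1185 m/s. The stride cycles single support → touchdown
(COM height falls through *l*₀ sin α; the landing foot is placed
*l*₀ cos α ahead of the COM) → double support → takeoff (trailing spring
back to *l*₀) → single support. Vertical ground reaction force of a leg is
*P*·*y*<sub>c</sub> with *P* = *k*(*l*₀/*l*<sub>leg</sub> − 1). Unloading
only modifies the vertical equation: constant force and counterweight act
as effective-gravity reductions (factors (1 − u) and (1 − u)/(1 + u)); the
tuned spring adds its explicit force at full gravity. The counterweight
dynamics are therefore *identical* to constant-force dynamics under
*g*(1 − u)/(1 + u) — asserted trajectory-for-trajectory in the tests.

**Unilateral legs.** The leg spring pushes while compressed and exerts no
force beyond its rest length (a leg cannot pull on the ground); the foot
stays attached, at zero force, until its phase event fires. This keeps the
loaded-leg-length and GRF-nonnegativity invariants intact. At moderate
unloading the stance leg can reach full length mid-stance and the gait
coasts briefly with zero ground force before re-loading; the feasibility
protocol does not penalise such episodes (only the stated failure
predicates terminate a run), which is why the constant-force strategy
remains feasible to higher unloading here than the other strategies.

**Initial condition.** Standing start: COM atop an uncompressed vertical
stance leg (y = *l*₀, v<sub>y</sub> = 0) with the requested forward speed.
The walk converges to a symmetric limit cycle within ~30 steps
(consecutive-step asymmetry < 10⁻⁷ by step 60).

**Failure predicates:** fall (y ≤ 0.2 *l*₀), backward motion
(v<sub>x</sub> ≤ 0), flight (at takeoff the leading leg is also at rest
length: no loaded leg remains).

### Tuned-spring design

ω = 2π·c with c the *step* cadence of the same model and initial condition
at 0 % BWS, extracted from a baseline run (≥ 5 strides averaged after a
3-stride transient) and cached per initial condition. *k*<sub>s</sub> =
u·m·ω², Δ*l*₀ = g/ω² (independent of u and m); *k*<sub>s</sub>Δ*l*₀ = u·m·g
identically. The spring reference height *y*<sub>c0</sub> is defined as the
average attachment height during unsupported walking; the default mode
(`baseline_mean`) takes the time-averaged COM height of the same baseline
run. For the SLIP's standing start, the initial pose sits ≈ 0.06 m above
the walking mean, which with the stiff tuned spring would more than double
the mean unloading force relative to the intended u·m·g — hence the mean,
not the initial pose, is the default; `initial_pose` and a heavy
first-order low-pass estimator (`lowpass_filtered`, 10–90 % rise time 15 s,
floored at the baseline mean) are selectable. The SW tuned-spring equations
carry the upright pose (y<sub>c0</sub> = *l*) inside their printed form and
are used as such. Forces are returned signed: a counterweight rope or
spring may transiently pull downward (ideal bidirectional pulley); a
warning is logged when the tuned-spring force goes negative.

## Protocol and metrics

Feasibility: levels 0–100 % in 5 % increments; a level is feasible when the
walker completes the step budget (20 steps; the criterion is monotone in
the budget). β<sub>max</sub> is the highest feasible level (−1 sentinel if
none); the feasible set need not be contiguous and is reported in full. An
optional short-circuit skips levels after three consecutive infeasible ones;
reported results use exhaustive sweeps. Sensitivity grids rerun the sweep
over 15 initial conditions (speeds 0.6185–1.6185 m/s for SLIP; step lengths
0.2167–1.2167 for SW).

Gait parameters are averaged over at least 5 strides after discarding the
first 3 (both configurable): cadence = 1/mean step duration; stride length
= same-leg contact-to-contact COM travel; walking speed = total forward
travel over elapsed time; phase fractions from the event log (for the SW,
whose double support is instantaneous, per-leg stance equals one step and
the stance *duration* in seconds is the reported trend, since the stance
fraction is constant at 0.5); vertical-GRF peaks I and II are the first and
last local maxima of each stance profile (SLIP only) — a unimodal profile
yields equal peaks and a degenerate-shape flag.

Trends are normalised by the 0 % value; infeasible levels are penalised as
zero (maximal deviation). mrmse is the RMS of (reference − model) over the
eight levels 5–40 %, × 100; the denominator defaults to the number of
levels and is overridable. Δgd is the RMS change of modela-w over the
feasible levels among 5–35 % relative to 0 %, × 100, with the denominator
equal to the number of levels used. modela-w uses step frequency for its
frequency symbol. Both statistics are permutation-invariant RMS aggregates;
mrmse is zero iff the trends agree at all compared levels.

## Numerics

Adaptive RK45 (`scipy.integrate.solve_ivp`) with rtol 10⁻⁹, atol 10⁻¹²;
feasibility near a threshold is sensitive to drift, and these tolerances
make sweeps bit-reproducible. Events are located by the integrator's root
finder; phase transitions re-enter the loop with the post-transition state
recorded at the shared time stamp. A step without any event within 10 time
units terminates as an integration failure. All CSV writers use a fixed
column order and 12-significant-digit floats, so identical inputs produce
byte-identical files.

## Synthetic reference tables

`generate_reference_fixture` emits normalised trend tables with the
structure of a BWS meta-analysis export (parameter × environment ×
level → mean, std): means ≈ 1 up to a plateau (default 30 %), declining
linearly above it, with seeded Gaussian jitter; the 0 % mean is pinned at 1.
This mimics the empirical observation that moderate unloading changes
spatio-temporal parameters little, but the values are synthetic — tests
passing against them show the pipeline's arithmetic and plumbing, not
agreement with human data. Real tables in other column layouts can be read
with a column mapping.

## Known limitations

* The SW toe-off magnitude is held at its 0 %-BWS calibration across all
  unloading levels; a walker that re-optimised its push-off per level would
  show larger feasible ranges.
* Feasibility is a 20-step criterion, not a stability analysis; gaits
  counted feasible may be long transients near the edge of the basin.
* The SLIP's zero-force coasting episodes at high constant-force unloading
  blur the walk/run distinction; β<sub>max</sub> for that one cell depends
  strongly on how such episodes are treated (see the stance-attachment
  paragraph above).
* Only sagittal-plane dynamics; no horizontal harness forces, no balance in
  other planes, no metabolic cost.
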