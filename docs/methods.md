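# Methods

## Model

The glider is a rigid body restricted to its longitudinal degrees of
freedom: body-x speed `U` (positive out of the beak), body-z speed `W`
(positive down), pitch rate `Q` and pitch angle `Θ`.  Wing shape is
described by two scheduled joint angles, elbow `δe` and wrist `δw`; the
shoulder is fixed.  The model is linear parameter-varying (LPV) in the
stitched sense: the aerodynamic response is linearized about the trim state
of the *current* configuration, while gravity and the kinematic couplings
(−QW, QU) are kept exactly.  Because the entire control vector is
scheduled, no control-derivative terms appear; the effect of moving the
joints is carried entirely by the dependence of the trim state, stability
derivatives and pitch inertia on `(δe, δw)`.

Assumptions inherited from this architecture:

* quasi-steady aerodynamics (verified per run by the reduced-frequency
  advisory, bound 7.5×10⁻⁴);
* symmetric flight, no lateral–directional coupling;
* per-step frozen trim: within one scheduling step (dt = 0.005 s) the trim
  and derivatives of the current configuration are constants;
* the inertia `Iyy` is updated per step, but the dynamics of a moving
  centre of gravity are neglected;
* a trim state exists and is stable at every visited configuration.

One published form of the Ẇ row repeats the x-axis perturbation force; the
standard body-axis longitudinal equations require the z-force there, and
that is what this package integrates (the x-variant appears to be a
typographical slip).

## Aerodynamic surfaces and trim

Eight coefficient surfaces over `(δe, δw)` — `CL0`, `CLα`, `Cm0`, `Cmα`,
`CD0`, `k_ind`, `CLq`, `Cmq` — define a quasi-steady force model

```
CL = CL0 + CLα α + CLq Q c/(2V)      CD = CD0 + k_ind CL²
Cm = Cm0 + Cmα α + Cmq Q c/(2V)
```

rotated from wind to body axes through `α = atan2(W, U)`.  The surfaces are
bivariate polynomials of degree ≤ 2 (configurable); they may be loaded from
a `morphglide-aero-1` JSON file or generated synthetically.  With this
force model the trim is closed-form: `α* = −Cm0/Cmα`, glide-path angle
`tan γ* = −CD/CL`, speed `V* = √(2 m g cos γ* /(ρ S CL))`, pitch
`Θ₀ = α* + γ*`, pitch rate zero.  Stability derivatives are central finite
differences of the force model about trim with step `1e-6·max(1, |U₀|)`;
they agree with symbolic chain-rule differentiation to better than 1e-5
relative (tested on 50 random configurations).

Angle convention: degrees at every public interface and in every file;
radians internally for α and Θ.  Air density defaults to 1.225 kg/m³
(standard sea level; not fixed by the source data).

## The synthetic "gull" preset

The generator emulates the *structure* of a gliding gull's aerodynamic
data — smooth surfaces over the joint range (elbow 105–160°, wrist
105–179°) yielding stable dynamics with trim speed falling monotonically
from 33 m/s at the folded anchor (120.7°, 105.3°) to 17 m/s at the extended
anchor (155.8°, 167.7°) — without reproducing any real gull's coefficient
values.  Construction:

* the trim lift coefficient interpolates linearly along the normalized
  projection onto the start→end chord and is calibrated by a fixed-point
  iteration so the anchor trim speeds match the targets to 1e-6 m/s;
* the trim angle of attack ramps from ~1° to ~3°, enforced through
  `Cm0 = −Cmα α*`;
* `CLα = 5 rad⁻¹`, `Cmα = −0.5 rad⁻¹` (statically stable),
  `Cmq = −12`, `CLq = 3`, `k_ind = 0.05`;
* profile drag `CD0` ramps from 0.030 (folded) to 0.110 (extended).  The
  gradient is deliberate: a uniformly draggy glider cannot hold a 33 m/s
  steady glide without tipping into a near-vertical dive (the `cos γ`
  feedback on the required lift), while a uniformly clean one leaves the
  phugoid so lightly damped that the pitch response cannot settle inside
  the post-extension hold.  The end value is the smallest scanned level at
  which all four response metrics resolve within the default 60 s hold and
  the rate trends (overshoot rising, rise/settling time falling over
  4/8/12 °/s) hold across generator seeds 0–4;
* `Iyy` spans 0.0047–0.0086 kg m² linearly across the validity region;
* the seed applies ±5–10 % deterministic perturbations to the
  non-calibrated constants, so different seeds give distinct but equally
  well-behaved gliders; identical seeds serialize byte-identically.

What the preset does *not* emulate: real coefficient magnitudes (the
synthetic glider is considerably draggier than a gull, with glide ratio
~2–9 rather than ~10+), the sign of the end-configuration trim pitch,
lateral dynamics, and any unsteady or flexible-wing effect.  Tests passing
on this preset therefore validate the machinery (trim solving,
stitching, metrics, optimization) and qualitative rate trends, not a
specific bird's numbers.

## Trajectories and scheduling

Extension paths are wrist-vs-elbow curves: a cubic
`δw = c0 + c1 δe + c2 δe² + c3 δe³` with `(c0, c1)` always re-solved so the
endpoints are exact (a compensated polish keeps the endpoint residual
≲1e-11 deg even at optimizer-scale coefficients), or a tabulated point
list with piecewise-linear interpolation.  The packaged `linkage`
trajectory — the coupled elbow–wrist path of a wing skeletal linkage driven
at the wrist — is a synthetic reconstruction: published curvature
coefficients are printed too coarsely to pass through the printed
endpoints, so the curvature terms (c2 = 0.222, c3 = −0.0005) are kept and
the affine terms re-solved, then tabulated at 41 stations.

Scheduling discretizes a path at 2000 elbow stations (arc-length
accumulation on a 4× finer grid), inverts cumulative arc length with
monotone PCHIP interpolation, and samples so that joint-space Euclidean
arc length grows at exactly `rate·t`; the per-step speed error is < 1 %
except for the final partial step, which lands exactly on the end
configuration.  Speed is measured along the curved path (not the endpoint
chord).  The reduced frequency of one extend-and-fold cycle is
`k = f·c_max/(2 U_min)` with `f = rate/(2·path_length)`.

## Numerical integration

Each scheduling step advances the state with an adaptive embedded
Dormand–Prince 5(4) pair at rtol 1e-8 / atol 1e-10; the per-step loop over
the whole extension is JIT-compiled (numba), with an identical interpreted
fallback.  After the extension the final configuration is held for
`settle_horizon` (default 60 s, chosen so all four metrics resolve for the
default preset); the hold is time-invariant and is integrated in a single
LSODA pass sampled on the same dt grid — LSODA because the short-period
mode (pitch inertia of order 0.005 kg m²) is orders of magnitude faster
than the phugoid and throttles explicit methods.  Divergence guards
(non-finite state, `U ≤ 0`, airspeed > 200 m/s, |Q| > 100 rad/s) convert
runaway trajectories into a typed error carrying the failure time.

## Response metrics

Settled values are the end configuration's trim (`U₀` for speed, `Θ₀` for
pitch) — the end configuration is stable, so its trim is the asymptote —
never the last sample.  Overshoot is the maximum excursion past the settled
value *in the direction of approach* (the raw series maximum would be
dominated by the initial dive speed), as a percentage of the settled value.
Rise time is the first entry into the ±2 % band.  Settling time is the time
of the first oscillation peak after which every later peak stays inside the
band (peaks from discrete-derivative sign changes with a plateau guard, no
sub-sample refinement at dt = 0.005 s); non-oscillatory signals fall back
to the last exit from the band, and a signal still outside the band at the
end of the series is flagged unresolved rather than assigned a number.

## Trajectory optimization

Free variables are `(c2, c3)`; the endpoint equalities are eliminated
inside the objective.  The objective schedules the cubic, simulates, and
returns the selected metric; any trajectory that breaks the dynamics model
(leaves the validity region, loses trim, diverges, or leaves the metric
unresolved) returns the sum of all scheduled wrist angles as a penalty, so
the objective is total over the bound box `c2 ∈ [−1000, 1000]`,
`c3 ∈ [−50000, 50000]` (for paths so long that the schedule would exceed
10⁶ steps the sum is evaluated in its dense-sampling limit).  Wrist bounds
(min 105°, max 179°) are imposed at 20 cosine-spaced (Chebyshev–Lobatto)
elbow stations — clustered toward both ends — with the minimum constraint
on the 10 stations nearest the start and the maximum on the 10 nearest the
end; these constraints are linear in `(c2, c3)`.

Minimization is SLSQP from the feasible linear guess `(0, 0)`.  Two
numerical choices matter: (i) the two cubic basis functions (with endpoints
pinned) are nearly collinear over the elbow interval and differ in natural
scale by ~400×, so the variables are rescaled so one optimizer unit moves
the peak wrist deviation by 15°; (ii) the metrics vary by only a few
percent across the feasible set, so the optimizer minimizes the percent
change from the baseline value.  The finite-difference step is 0.1 unit
(1.5° of peak deviation — large enough to move dt-quantized time metrics),
`ftol` 1e-4, iteration cap 200.  If SLSQP ends on a line-search status,
polish restarts from the best iterate with the step divided by 5 and then
multiplied by 3 are attempted; regardless of termination status the
reported optimum is the best *feasible* evaluation seen, so the optimized
objective never exceeds the baseline.  The whole pipeline is deterministic.

The campaign runs all four objectives at 4, 8 and 12 °/s (12 cells),
tabulates coefficients next to the linear and linkage baseline rows, and
reports baseline metrics per rate for comparison.

## Problem sizes and tolerances used in the test suite

Unit oracles run on constant-coefficient models (closed forms), symbolic
differentiation (sympy), dense grid searches with iterative zoom, and
independent matrix algebra.  The acceptance-style checks use the default
preset at full fidelity: dt = 0.005 s, 60 s hold, 10 s trim-persistence
runs, 50-configuration derivative scans, perturbation scales
ε ∈ {0.5, 0.25, 0.125} for the quadratic-convergence check of the
linearization, and the complete 12-cell campaign.  Regression tests that
require the study's deposited aerodynamic surfaces activate automatically
when a `morphglide-aero-1` file is placed at `data/deposited_model.json`;
they are skipped otherwise.

## Known limitations

* The force model is quasi-steady and linear in α within a ±15° band;
  trims outside the band are rejected rather than extrapolated.
* The synthetic preset's end-configuration trim pitch is negative
  (nose-down descent); matching a published positive pitch at the extended
  configuration would require the deposited aerodynamic data and their
  axis conventions.
* Settling times are quantized by the oscillation half-period (peak-based
  definition) and by dt.
* The optimizer is local; with a nearly flat objective valley different
  numerically equivalent runs can stop at different points of the valley
  floor.  The improvement contract (optimum ≤ baseline, feasible) is
  guaranteed; global optimality is not.
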