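# Methods

This note records the model structure, the defaults and why they were
chosen, the numerical choices, and the known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pharmacokinetics

Racemic ketamine is an equal mixture of the S- and R-enantiomers; each
dose event is split 50:50 at the boundary. Per enantiomer the model is a
two-compartment mammillary system for ketamine plus a two-compartment
system for the metabolite norketamine, linked by a transit stage:

* central ketamine: infusion input, elimination CL·C, exchange
  Q·(C_central − C_peripheral);
* eliminated parent drug enters a transit chain with rate constant
  n/MTT (default one stage, MTT = 26.6 min) feeding central norketamine;
* norketamine exchanges with its peripheral compartment and is cleared to
  a terminal sink.

Amounts are tracked in mg, concentrations reported as amount/volume/1000
in g/L. Mass balance — infused = compartments + sink — is exact up to
floating-point rounding because every flux appears once as a loss and once
as a gain.

Reconstruction choices (the compartment topology of the source model is
published only as parameter names):

* **Transit stages:** a single stage matches a stated *mean* transit time
  with the simplest structure; the count is configurable (`n_transit`).
* **Norketamine central volume** is not identifiable from the published
  table; it defaults to the ketamine central volume (25.8 L), the common
  pharmacometric convention for metabolite models, and is configurable.
* **Fraction metabolized** defaults to 1 (all eliminated ketamine forms
  norketamine); configurable. This is the conservative reading of a table
  that prints no fraction, but it makes late norketamine exposure an
  upper bound — see "Known limitations".

## Pharmacodynamics

MAP: sigmoid Emax in the driving plasma concentration (total racemic by
default; `driving="s_only"` selects S-ketamine). Effect at C50 is exactly
Emax/2 and the effect saturates at Emax = 51.6 mmHg.

CO: linear fractional effects of the S-ketamine and S-norketamine
*effect-site* concentrations, ±25% at the respective C25 values, with
norketamine opposing ketamine (the source literature reports norketamine
decreases CO). Both the sign and the linear-vs-multiplicative combination
are configurable; a floor of 0.1·baseline guards against nonphysical
nonpositive targets under extreme parameter draws (never active at nominal
parameters and analgesic doses). Effect compartments are first order with
k_e0 = ln 2 / t_half.

**Magnitude gap.** With the nominal table, a 0.25 mg/kg bolus peaks total
plasma ketamine near 6×10⁻⁴ g/L, an order of magnitude below the MAP C50
(4.68×10⁻³ g/L), so the direct MAP_PD rise is of order 1 mmHg — whereas
the source publication reports nominal peak MAP near 120 mmHg for the same
dose. Either the PD input units or the driving species differ in the
original PD source. We do not silently rescale: the table is implemented
as printed, a `concentration_scale` knob (default 1.0) exposes the axis,
and all quantitative checks in this package avoid that pathway.

## Surrogate cardiovascular core

The original cardio-respiratory model (104 equations) is not published
equation-by-equation; the package therefore uses a minimal surrogate that
reproduces the behaviours the coupling method relies on. It is a design
component of this package, documented here in full:

* Two compliant compartments. MAP = (V_a − V_a,unstressed)/C_a; venous
  pressure likewise with C_v = 0.25 L/mmHg.
* Flow-source heart: CO = k_heart · contractility · max(P_v, 0) — a
  linearised Frank–Starling law (k_heart = CO₀/P_v₀ = 1 L·min⁻¹·mmHg⁻¹).
* Neuronal (baroreflex) controller: the fractional MAP error, amplified
  (gain 6) and soft-clipped (amplitude 1.2, knee exponent 2), is low-pass
  filtered (τ = 0.5 min) into an activation x_n that raises HR (weight
  0.45), contractility (0.6), systemic resistance (0.8) and venous tone
  (unstressed-volume recruitment, 0.25). HR is an algebraic output,
  hr₀·(1 + 0.45·x_n), with hr₀ = 70 beats/min.
* Local flow-autoregulation controller: the fractional CO error (gain 4,
  soft-clip amplitude 1.6, knee exponent 4, τ = 2 min) drives peripheral
  conductance.
* Hemorrhage/infusion are volume fluxes on the venous side; blood volume
  below 20% of baseline flags the state nonviable and halts the run.

The baseline geometry (compartment volumes, resistance, heart gain) is
*derived* from the setpoints (MAP 100 mmHg, CO 5 L/min, blood volume 5 L,
venous pressure 5 mmHg), so drug-free, injury-free homeostasis is an exact
fixed point — no residual drift to tune away.

The controller gains, saturation amplitudes and knee exponents are the
tuning surface. They were set, once, so that

1. a 30% blood-volume hemorrhage drops MAP by roughly 30% of baseline
   while a 45% hemorrhage remains viable but severely hypotensive;
2. the offset → steady-state map is near-affine over the calibration grid
   (R² ≈ 1.00 and 0.99 for the MAP and CO fits — the property that makes
   an affine inverse work);
3. baroreflex activation saturates under severe hypovolemia, so identical
   ketamine-driven offsets produce strictly smaller MAP/CO increments as
   hemorrhage severity grows (the sympathetic-saturation mechanism).

The knee exponents matter: the local branch uses a sharp knee (4) because
its error stays small over the calibration grid (closed-loop tracking
keeps it near setpoint) but becomes large under hemorrhage; a sharp knee
therefore preserves calibration affinity while still saturating in shock.
The baroreflex uses a gentler knee (2) so that attenuation of drug
responses begins already at mild (15%) hypovolemia.

Time constants (0.5 / 2 min) give the observed 1–5-min rise of drug
transients; the return time course is dominated by the PK washout, not by
the controllers.

Resuscitation fluid is modelled as fully intravascularly retained volume
(the albumin/hypertonic-saline mixture of the simulated protocols); no
osmotic kinetics. The canonical injury timeline defaults to hemorrhage
over 30 min, a 2-min monitoring gap, resuscitation over 30 min — all
configurable.

## Offset coupling and calibration

`calibrate_offsets` sweeps a uniform offset grid (defaults 100 × 100 over
ΔMAP ∈ [−20, 80] mmHg, ΔCO ∈ [−2, 4] L/min), runs every point to steady
state as one vectorised batch, and fits ΔMAP and ΔCO on (MAP_ss, CO_ss) by
OLS — exactly inverting the forward map. Steady state means the maximum
state derivative over one simulated minute falls below 10⁻⁴ relative to
per-state scales, with a 120-min cap; non-converged points are excluded
(more than 5% excluded aborts the calibration). The published grid
description ("10,000 combinations") is internally inconsistent with its
stated increments (101 × 37); we keep the grid size and ranges
configurable with a 100 × 100 default.

Runtime coefficients default to values calibrated on this surrogate
(`SURROGATE_COEFFS`, regenerable via `ketsim calibrate`); the published
coefficient table belongs to the original core and is available as
`OffsetCoefficients.table_nominal()`.

**Sign resolution.** The published ΔMAP equation prints a minus sign on
the MAP_PD term while the parameter table lists the magnitude 1.47
unsigned. Only +1.47 yields near-zero offsets at the homeostasis point
(−0.85 mmHg, vs −294.85 with the printed sign), so the positive sign is
the default; `table_nominal(strict_printed_sign=True)` preserves the
printed sign for auditability.

**Baseline correction.** An affine fit leaves a small residual at the
homeostasis point (fractions of a mmHg / L·min⁻¹). The coupled stepper
subtracts the transformation's evaluation at the drug-free baseline from
every offset, so zero drug implies offsets of exactly 0.0 and the coupled
trace coincides bitwise with the plain cardiovascular simulation. The
correction is a constant shift of the intercepts, well inside the fit
residual; `baseline_correction=False` restores literal evaluation.

PD baselines (MAP₀, CO₀) are the drug-free steady state of the core at
simulation start, i.e. the setpoints. Hemorrhage does not rescale the PD
targets; attenuation of drug effects under hypovolemia emerges entirely
from controller saturation.

## eFAST and uncertainty

The eFAST implementation follows the standard construction: each
parameter's range is traversed by x = low + (high − low)·(½ +
arcsin(sin(ω s + φ))/π) over s ∈ [−π, π), giving a uniform marginal. The
driven parameter receives the maximum admissible frequency
ω_max = ⌊(Ns − 1)/(2M)⌋ with interference factor M = 4; complementary
parameters sit at low frequencies (≤ ⌊ω_max/2M⌋). With the default
Ns = 73, ω_max = 9 and the Nyquist bound 2·M·ω_max + 1 = 73 is met
exactly. The first-order index is the variance at the driver frequency and
its harmonics through order 4 divided by total variance, averaged over 5
resample curves distinguished by seeded random phases, clipped to [0, 1];
zero-variance curves contribute 0. The estimator is validated against the
closed-form first-order Sobol indices of the Ishigami function (a = 7,
b = 0.1: 0.3139, 0.4424, 0) within ±0.05.

The "peak change after administration" outputs are operationalised as the
maximum over the 60-min window minus the value at t = 0 (for the
concentration output, simply the maximum). The peak-S-ketamine experiment
integrates all 8,760 parameter sets as vectorised Euler batches at a
0.01-min PK step, which leaves the index estimates unchanged at the
reported precision (the PK Euler error at that step is ≪ 0.5%).

Uncertainty envelopes draw PD parameter sets (P12–P18) by Latin hypercube
(scipy's sampler: one sample per equal-probability stratum per dimension).
The source models' 95% confidence intervals are published elsewhere; the
default box is ±20% of nominal, configurable. Envelopes report per-time
min/max of MAP and HR over the sampled runs; collapsed (nonviable) runs
are excluded, more than 2% of them is an error.

## Validation metrics and synthetic studies

Predictions are compared to a study series by linear interpolation to the
observation times, optional baseline normalisation (multiply by
observed/predicted baseline), then RMSE, mean bias error, and the
percentage of points within ±2 SEM of the observed mean. The three
canonical bolus(+infusion) study protocols and the repeated-bolus
battlefield regimen (0.2–0.3 mg/kg every 25 min, first dose 2 min after
hemorrhage end) are provided as regimen builders.

`generate_fixture_study` fabricates a synthetic study — n noisy subject
trajectories (additive i.i.d. Gaussian noise, seeded) around the model's
own output, summarised as mean ± SEM on a 1-min grid. It emulates the
*shape* of a small-cohort vital-sign study; it does not emulate
between-subject physiological variability, autocorrelated measurement
error, or protocol deviations, so tests passing against fixtures
demonstrate the correctness of the pipeline, not agreement with real
experimental data. Users with digitised experimental curves can supply
them as `time_min,mean,sem` CSV.

## Problem sizes used by the shipped checks

The test suite runs the coupled loop at steps of 0.005–0.02 min and the
calibration on 20 × 20–30 × 30 grids; the acceptance script uses the
nominal 4.17×10⁻⁴-min step for the 60-min baseline run, the full 8,760-set
eFAST design at a 0.01-min PK step, and a 25 × 25 calibration grid. These
sizes were chosen as the smallest at which the reported quantities are
stable at their quoted precision.

## Known limitations

* The cardiovascular core is a surrogate: it reproduces the controller
  behaviours the coupling method needs, not the full hemodynamics of the
  original 104-equation model. Its calibrated coefficients accordingly
  differ from the published ones, which are specific to that core. CI
  drops under moderate hemorrhage are somewhat shallower than reported
  experimental swine data.
* Respiratory outputs, pain/nociception, non-intravenous routes and
  fluid-type pharmacology are out of scope.
* With fraction-metabolized = 1 and the opposing norketamine CO effect,
  a single bolus leaves CO ~1–2% below baseline at 60 min post-dose
  (norketamine's terminal phase is hours long); MAP returns within 1%.
  A smaller metabolite fraction shrinks this deficit proportionally.
* The PD magnitude gap described above means absolute MAP excursions at
  analgesic doses are small under the printed parameter table; analyses
  here therefore focus on signs, orderings and normalised responses.
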