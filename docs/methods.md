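# Methods

This note documents the models, numerical choices and limitations behind the
package, in the order the assessment pipeline applies them.

## Muscle layer: duty cycle and maximal acceptable effort

The duty cycle is DC = cycle_duration × repetitions_per_minute / 60, a
fraction of working time under load. The schedule type rejects
cycle_duration × repetitions > 60 s at construction, so DC ∈ [0, 1] by
invariant. The maximal acceptable effort MAE(DC) = 1 − (DC − 1/28800)^0.24
is defined on [1/28800, 1]; the floor is one effort per 8-hour shift
(1 s / 28 800 s), where MAE is exactly 1. Below the floor the fractional
power of a negative base is undefined and the function raises a validation
error rather than extrapolating.

The group rule counts agonists whose *peak* activation strictly exceeds the
MAE; a group of n is at risk when that count reaches ⌈n/2⌉. Choices made
here: "exceeds" is strict (a peak exactly at the MAE does not count — the
boundary is testable); the peak is the raw maximum with no smoothing (model
outputs are already smooth; an optional moving-average window exists for
noisy field data, default off); the ceiling makes single-muscle groups
behave sensibly (1 of 1 must exceed).

## Hip layer

Peak hip contact force (N) over the trial divided by an average femoral head
area of 1610 mm² gives stress in MPa directly (N/mm² = MPa). The endurance
limit is stored canonically as the force, 9434 N; the stress is derived at 4
significant figures (5.860 MPa). Storing the force is deliberate: 5.86 ×
1610 = 9434.6, so the published stress is the rounded quantity and the force
the precise one. The risk rule is strict (stress > limit), and because an
endurance limit is repetition-independent by definition, the schedule plays
no role. When both hip channels are present each is assessed independently
and the report lists both; the top-level field carries the worst one.

## Spine layer

UCS [kN] = (c0 + c_sex·[male] − c_age·age/10) × clip(b0 + b1·BMI, 0.5, 1.5).
The model type rejects coefficient sets that give non-positive strength
anywhere on the subject domain (age 15–100, BMI 12–60, both sexes), and
requires c_age ≥ 0 so strength never increases with age. The BMI factor is
clipped to [0.5, 1.5] because a linear proxy for endplate area is only
credible near the calibration range. Whether BMI enters through endplate
area or as a body-mass proxy is left to the coefficients: the linear-factor
schema covers both readings.

Failure probability is a bilinear interpolation over the S-N table, linear
in %UCS and in log10(cycles) — S-N behaviour is log-linear in cycles, so the
log axis makes interpolation faithful to the curve's shape. Edge rules:
loads below the lowest tabulated level are in the endurance region and
return exactly 0; loads above the highest level clamp to the top row; cycle
counts clamp to the table's cycle range; zero cycles returns 0 (the task is
never performed). Grid nodes reproduce their cell values exactly, and
bilinearity preserves the table invariant that probability is non-decreasing
in both load and cycles. The interpolation is delegated to
`scipy.interpolate.RegularGridInterpolator` with the edge rules applied
around it; the test suite keeps an independent hand-rolled bilinear oracle.

The low/high-risk cutoff on the failure probability defaults to 0.10 and the
comparison is strict (> 0.10 is high risk). Cycle count is
repetitions_per_minute × total_duration rounded to the nearest integer.
Cumulative damage across different tasks in a shift is explicitly
unsupported: the layer evaluates one task schedule at a time, and no
rest/recovery or healing model is included.

`max_cycles_before_risk` inverts the surface: the largest integer cycle
count whose probability stays at or below the cutoff, found by bisection on
the integer range [1, table max] (the probability is monotone in cycles, so
bisection is exact; a brute-force scan oracle confirms it in the tests). It
returns the table maximum when the load never becomes risky and 0 when even
one cycle exceeds the cutoff. Evaluated across ages at a fixed L5 force it
yields the max-cycles-versus-age curves: older workers, having lower UCS,
tolerate fewer cycles.

### Default UCS coefficients and S-N table are synthetic

The shipped defaults (`data/ucs_model_synthetic.yaml`,
`data/fatigue_table_synthetic.yaml`) are representative surfaces, not
transcriptions of published material tests. The UCS coefficients (c0 = 9 kN,
c_age = 0.65 kN/decade, c_sex = 1.5 kN, area factor 0.76 + 0.012·BMI) place
strength in the 2–12 kN range reported for lumbar vertebrae in cadaver
compression testing, declining with age and higher in males. The S-N table
was generated from median log10(cycles to failure) = (100 − S)/12.5 with a
lognormal spread of 0.8 decades and an endurance region below 30 %UCS.
Every test asserting numbers runs on explicit small fixtures, never on these
defaults' absolute values; conclusions about real workers require
study-specific tables, supplied via `--ucs-model` / `--fatigue-table`.

## Cutoff calibration

Tasks with known failure probabilities and epidemiological low/high labels
are classified by "probability > cutoff". Candidate cutoffs are the
midpoints between adjacent distinct probabilities plus 0 and 1: with a
strict decision rule the accuracy is a step function whose steps sit at
observed values, so the midpoint grid attains every achievable
classification exactly — no dense scan can do better, which the tests check
against a brute-force sweep. Ties in overall accuracy prefer higher
sensitivity (missing a high-risk task is the costlier error), then the lower
cutoff. Whether published analyses used a strict or inclusive rule at ties
is generally unknowable from reported accuracies alone, so both conventions
are available (`inclusive=True` counts ties as exceedances); strict is the
default everywhere.

## Classic scales

RWL multipliers follow the published formulas with their domain rules:
H clamps below 25 cm and zeroes beyond 63 cm; V is validated to [0, 175] cm;
D clamps below 25 cm and zeroes beyond 175 cm; A zeroes beyond 135°. FM and
CM are band lookups (nearest tabulated frequency at or above the task's, the
standard's duration classes, and the V < 75 cm split); the standard defines
bands, so no interpolation is applied. When any multiplier is 0 the RWL is 0
and the lifting index is reported as infinite with `rwl_defined=False` — an
overhead or out-of-reach lift is maximally, not minimally, risky, and an
LI of 0 would invert its meaning. RULA and REBA take worksheet category
scores as inputs (the package does not derive categories from joint angles:
that mapping requires conventions beyond the worksheets) and are pure table
lookups stored as explicit matrices in YAML with provenance comments.

## Synthetic data

The trace generator emits baseline + Gaussian bump + seeded white noise per
channel. The risk layers consume only peak values and schedules, so bump
shape realism is irrelevant and exact peak control is what matters; peaks
placed on the sample grid are attained exactly in the noiseless case.
Activations are clipped to [0, 1.2] after noise. What this does *not*
emulate: correlated multi-muscle activation patterns, task-phase structure,
impact transients, or any biomechanical consistency between activation and
force channels — so passing tests demonstrate the correctness of the risk
arithmetic, not the realism of any simulation upstream.

The calibration-set generator draws probabilities uniformly on [0, 1],
labels them by a planted boundary, and flips labels with a given
probability. The default study conditions are n = 148 tasks, boundary 0.10
and 30% label noise: with those, the Bayes-optimal cutoff (the boundary)
achieves 70% expected accuracy, and the calibrated cutoff recovers the
boundary up to sampling noise. Both generators are deterministic under a
fixed seed (numpy PCG64).

## Problem sizes

The test suite works at desk scale throughout: traces of a few hundred
samples, fatigue tables of 2×2 to 8×6 cells, calibration sets of up to 148
tasks with 100 seed replicates for the recovery study. These sizes make the
full suite run in seconds while exercising every code path; nothing in the
method scales worse than linearly in samples or tasks, and the max-cycles
bisection is logarithmic in the table's cycle range.

## Known limitations

- Risk layers exist only for muscles, hip cartilage and the L5-S1 vertebra;
  other joints' contact forces can be read and reported but have no
  threshold model.
- One task schedule at a time: no cumulative damage across task mixes, no
  rest/recovery credit.
- The muscle rule uses peak activation only; duration-weighted or integrated
  activation is out of scope.
- Left/right femoral head area is a single population average; subject-
  specific imaging-based areas must be supplied through `HipThreshold`.
- The calibrated 10% cutoff is only as valid as the labeled task table it
  was derived from; tables dominated by upright standing postures do not
  automatically transfer to other posture families.
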