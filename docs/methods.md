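# Methods

`baricea` implements a lifetime cohort state-transition (Markov) model
comparing bariatric surgery (gastric bypass, GBP; sleeve gastrectomy,
SG; adjustable gastric banding, GB) with optimal medical management
(OMM) in severe obesity, from a health-care payer perspective in a
Swedish setting. This note documents the model, its assumptions, the
parameters that matter, and the boundaries of what the shipped
configuration can and cannot show.

## Model structure

The cohort advances in monthly cycles from entry (age 41 by default) to
an absorbing horizon at age 100. Health states cover entry surgery,
post-surgery or medically managed living states split by diabetes
status, six cardiovascular event pathways — angina, acute and chronic
post-myocardial-infarction (MI), acute stroke, a 12-month post-stroke
tunnel followed by a chronic post-stroke state, transient ischaemic
attack (TIA), heart failure, peripheral arterial disease (PAD) —
surgical complication and conversion-surgery states, and death. The OMM
arm has no surgery-related states. Acute MI, acute stroke, TIA,
complication and conversion states last exactly one cycle; their costs
are one-off tariffs. Post-stroke year 1 is a 12-slot tunnel so that the
three stroke cost levels (acute / year 1 / year 2+) attach to the right
months.

Internally every state carries a three-way diabetes attribute (never
diabetic / diabetic / in remission) so that incidence, net remission
and relapse can be tracked through event states without enlarging the
public 17-state surface. Event-state memory is simplified: a new event
overwrites the current chronic state; cumulative incidence tallies are
preserved but multimorbidity costs are not stacked (the current state's
cost applies, except diabetes care, which follows the diabetic
attribute through every state).

Competing risks within a cycle are resolved by evaluating death first
and scaling the remaining exits proportionally if they would exceed the
surviving mass; with monthly probabilities this correction is
second-order. State membership is counted at cycle end; no half-cycle
correction is applied. Lifetime event "risks" are cumulative expected
first-entries per entering patient (the standard cohort-model
approximation to the ever-affected fraction).

## Risk-factor dynamics

BMI follows cohort-mean paths: registry-observed absolute reductions at
years 1 and 2 by procedure and sex, extrapolated over years 3–15 with a
partial-regain shape (regain to 75% of the 2-year loss by year 10,
stable thereafter — the qualitative long-term pattern of the Swedish
Obese Subjects control/surgery contrast), constant after year 15. The
OMM curve is flat at baseline by default. Monthly values interpolate
the annual anchors linearly; BMI is floored at 18.5. Systolic blood
pressure is coupled to BMI at 0.5 mmHg per kg/m² (configurable),
floored at 110 mmHg. Individual-level weight variability is not
modelled.

## Hazards

Cardiovascular events use a Framingham-type shared log-linear hazard:
each event's annual rate is a baseline rate (at the reference vector:
female, 41 years, BMI 42.8, SBP 140.1, non-diabetic, non-smoking)
multiplied by exp of coefficients × (age − 41, male, SBP − 140.1,
BMI − 42.8, diabetes, smoking). Coefficients (0.07/yr age, 0.40 male,
0.018/mmHg, 0.016/kg·m⁻², 0.65 diabetes, 0.50 smoking) are fixed
fixtures in the published range for general-CVD functions. MI and
stroke carry case-fatality fractions 0.0968 and 0.1481 (the published
fatal/total event patterns). The risk-equation set is a pluggable
registry (`risk_equations.name`), so alternative published equations
can be substituted without touching the engine.

Diabetes incidence is a log-linear function of current BMI. Net
remission follows the published anchors — 72%/36% of the initially
diabetic remitted at 2/10 years after surgery, 21%/13% under OMM — via
a monthly remission/relapse schedule that reproduces the net curve
exactly (linear ramp to the 2-year anchor, log-linear decline to the
10-year anchor, constant afterwards). Only net proportions are
observed, so remission and relapse are not separately identified; the
schedule realizes the net curve with remission flows while the curve
rises and relapse flows while it falls.

All-cause mortality comes from a bundled abridged period life table
(log-interpolated between 5-year anchors, absorbing at age 100),
adjusted by proportional-hazards multipliers for BMI (log-HR 0.015 per
kg/m² above 25) and diabetes (HR 1.8). Annual probabilities convert to
monthly ones as 1 − (1−p)^(1/12).

## Calibration

The cited cardiovascular risk equations are not published in a form
that can be transcribed, so the baseline event rates (and the diabetes
incidence base rate and BMI gradient) are calibrated once, by iterative
proportional fitting on the deterministic mean-characteristic cohort,
to the OMM-arm lifetime risks (angina 13%, MI 31%, stroke 27%, TIA 2%,
heart failure 19%, PAD 11%, diabetes 36%) and the surgical-arm diabetes
incidence (14%). The calibrated values are stored in the shipped
configuration; `baricea calibrate` re-runs the fit and writes the
iteration report as CSV. The relative risks of the six cardiovascular
events (≈0.80) are *not* calibrated — they emerge from the BMI/SBP
coefficients and the trajectories.

## Economics

Costs and outcomes are discounted at 3% per year with the first model
year undiscounted (year Y carries (1.03)^−(Y−1)), matching the Swedish
convention; truncated-horizon analyses reuse the same per-cycle
discounted accruals. Annual state costs accrue monthly; one-off tariffs
(surgery €4915 uncomplicated / €5766 complicated, mixed at the 20%
perioperative complication share; acute MI €4592; acute stroke €7532;
TIA €1928; complication-specific tariffs; conversion surgery) are
charged on state entry. OMM patients accrue a management cost of
€200/yr for life in the living base states; surgical patients accrue a
follow-up programme of €800/yr during the first two post-operative
years. Utilities are EQ-5D-scale values interpolated piecewise-linearly
over BMI knots (0.72 at BMI 25 falling to 0.25 at BMI 60), multiplied
by 0.85 for diabetes and by event-state multipliers; a continuous
BMI–utility mapping is used instead of step bands because scenario
contrasts that shift BMI by ~1 kg/m² (procedure mix) would otherwise
register no utility change. ICERs carry dominance labels (dominant:
cheaper and more effective); the willingness-to-pay threshold is
€35,526/QALY.

## Scenarios

* **Base case** averages both arms over a sampled multiple cohort
  (default 300 profiles) drawn from the candidate-population marginals:
  age ~ N(41, 5) on [25, 65], 24% male, BMI ~ N(42.8, 5.8) on [30, 60],
  18.39% diabetic, SBP ~ Gamma(55.53, scale 2.52) on [125, 200], 14.3%
  smokers, independently (the registry's joint correlation structure is
  not published). Truncation shifts the realized BMI and SBP means
  slightly above the untruncated values (+0.18 and +4.5 respectively);
  tests validate the sampled moments against truncated-distribution
  oracles.
* **Subgroups**: 16 fixed cohorts of 41-year-old non-smokers (sex ×
  BMI class × diabetes), BMI at class representatives 32/37/45/55
  (midpoints; 55 for the >50 class under the configured BMI maximum of 60), SBP
  fixed at the cohort mean to isolate BMI/diabetes effects.
* **Waiting-list delay**: the cohort follows OMM dynamics for the delay
  (default 3 years), then alive mass in the living states undergoes
  surgery with its then-current risk factors; diabetes onset during the
  wait carries into the diabetic surgical pathway. The surgical
  net-remission anchors are attenuated by 4.5% per waiting year
  (duration-of-diabetes effect); without this, restarting the published
  remission schedule would grant delayed patients a late-relapse
  advantage that implausibly offsets their extra diabetic years.
* **Procedure mix** re-runs the surgical arm under an alternative
  procedure mix (default counterfactual 60/30/10 versus 98/1.6/0.4).
* **Population extrapolation** scales per-patient discounted deltas to
  a treated population (default 7900, the 2012 Swedish surgical
  volume).

## Sensitivity analysis

The tornado analysis varies one parameter at a time across its declared
range (published ranges for clinical inputs; ±50% for costs) around the
deterministic base case. The PSA draws, per simulation, a full
parameter set from the declared distributions (BMI deltas: truncated
normals; remission anchors: betas; costs: gammas declared in SEK and
converted at 0.089; baseline proportions: betas) and one patient from
the cohort marginals, runs both arms, and records the incremental cost
and QALYs; a parameters-only mode holds the deterministic cohort fixed.
Parameters are drawn independently. All randomness derives from a
single master seed through named child streams, so identical seeds give
bitwise-identical results and adding a stage never perturbs another's
draws.

## Numerical choices and problem sizes

The cycle kernel is scalar Python over a compact 26-state × 3-attribute
representation (profiled as ~3× faster than the small-array vector
form, with identical output to machine precision). Trace rows conserve
mass to 1e-9 and the engine reproduces pure life-table survival to
1e-9 when event hazards are disabled. Shipped analysis sizes: 300
profiles for the sampled base case, 3000 PSA draws in the acceptance
script (1500 in the test suite), full 5000-draw PSA available via
`baricea psa --n 5000`.

## What the synthetic cohort does and does not show

The generator reproduces the published marginal distributions of the
candidate population, so passing tests demonstrate correct propagation
of those marginals through the model — not fidelity to record-level
registry data: risk-factor correlations (e.g. BMI–SBP, BMI–diabetes),
secular trends, and procedure selection by patient profile are absent.

## Known limitations

* Cohort-level (not individual-level) simulation; no memory of event
  multiplicity beyond cumulative tallies; no stacked multimorbidity
  costs.
* The cardiovascular equations are calibrated surrogates for the cited
  but unpublished originals; absolute event timing (and hence
  early-horizon ICERs) inherits that uncertainty.
* The delay scenario reproduces the published cost pattern but
  understates the published life-year/QALY losses for diabetic males,
  whose published male-female asymmetry implies a sex-specific mortality
  mechanism not recoverable from the available inputs; the directional
  result (every delayed subgroup loses QALYs) holds.
* The procedure-mix QALY loss is directionally correct but smaller than
  the published figure, which sits above the QALY-per-BMI-unit scale
  implied by the base-case results themselves; matching it would require procedure-specific
  remission effects that are not quantified in the source.
* Obstructive sleep apnea, musculoskeletal disease, cancer, indirect
  costs and the supplementary scenario analyses are out of scope.
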