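# baricea

A lifetime Markov cost-utility model of **bariatric surgery versus
optimal medical management (OMM)** in severe obesity, from a health-care
payer perspective in a Swedish setting.

Health-economic decisions about bariatric surgery hinge on a trade-off:
a substantial up-front procedure cost against decades of avoided care
for type 2 diabetes and cardiovascular disease, plus quality-of-life
gains from weight loss. `baricea` is a monthly-cycle cohort
state-transition model for quantifying that trade-off. It is aimed at
health economists and modellers who need a transparent, configurable,
fully tested reimplementation of this class of decision model —
including its waiting-list (surgery delay) scenario, subgroup grids,
and deterministic plus probabilistic sensitivity analysis.

## The model in brief

A cohort with risk factors (age, sex, BMI, systolic blood pressure,
diabetes, smoking) advances monthly through states covering surgery,
post-surgery/OMM living states split by diabetes status, angina,
myocardial infarction (acute → chronic), stroke (acute → year-1 tunnel
→ chronic), transient ischaemic attack, heart failure, peripheral
arterial disease, surgical complications, and death. Per-cycle hazards
come from a Framingham-type log-linear risk function,

&nbsp;&nbsp;&nbsp;&nbsp;rate(event) = base(event) · exp[β_age·Δage + β_male + β_SBP·ΔSBP + β_BMI·ΔBMI + β_dm + β_smoke],

with monthly conversion p = 1 − (1−p_annual)^(1/12). Surgery lowers
BMI (registry-observed reductions by procedure and sex, partial regain,
stable after year 15), which propagates into SBP, event risks, diabetes
incidence and mortality; diabetes remits per the published 2- and
10-year net-remission anchors. Each state carries a cost and an EQ-5D
utility; costs and outcomes are discounted at 3%/year (first year
undiscounted) and summarised as the incremental cost-effectiveness
ratio ΔC/ΔQALY against a willingness-to-pay threshold of €35,526/QALY,
with dominance labels when surgery is both cheaper and more effective.

Because the source risk equations are cited but not published, the
baseline event rates are **calibrated** (once, reproducibly) to the
OMM-arm lifetime event risks; the surgical-arm risk reductions then
*emerge* from the risk-factor dynamics. See `docs/methods.md`.

## Worked example

```python
from baricea import load_parameter_set, run_base_case, extrapolate_to_population

params = load_parameter_set()                      # shipped calibrated defaults
result = run_base_case(params, n_profiles=100, seed=42)
print(f"OMM:     cost EUR {result.omm.total_cost:8.0f}  LY {result.omm.life_years:5.2f}  QALY {result.omm.qalys:5.2f}")
print(f"Surgery: cost EUR {result.surgery.total_cost:8.0f}  LY {result.surgery.life_years:5.2f}  QALY {result.surgery.qalys:5.2f}")
print(f"Incremental: {result.delta_cost:+.0f} EUR, {result.delta_ly:+.2f} LY, {result.delta_qaly:+.2f} QALY -> {result.label}")
pop = extrapolate_to_population(result, 7900)
print(f"2012 cohort (n=7900): {pop['person_years']:.0f} person-years, "
      f"{pop['qaly_person_years']:.0f} QALY-years, EUR {pop['total_savings']/1e6:.0f} million saved")
```

prints

```
OMM:     cost EUR    37925  LY 21.66  QALY  9.25
Surgery: cost EUR    30600  LY 22.52  QALY 13.00
Incremental: -7325 EUR, +0.86 LY, +3.75 QALY -> dominant
2012 cohort (n=7900): 6762 person-years, 29608 QALY-years, EUR 58 million saved
```

Reading: over a lifetime, surgery costs ~€7.3k *less* than continued
medical management while adding ~0.9 discounted life-years and ~3.8
discounted QALYs per patient — surgery *dominates* — and scaling the
per-patient gains to the 7900 patients operated in 2012 yields the
population totals on the last line. (A 100-profile sampled cohort
carries Monte-Carlo noise of a few hundred euro.)

## Command-line interface

Every stage is also a subcommand of `baricea`, writing CSV/JSON plus a
run manifest (config hash, seed, output checksums):

```bash
baricea cohort --n 1000 --seed 42 --out cohort.csv   # synthetic candidates
baricea run --seed 1 --out results/                  # base-case tables
baricea scenarios --name delay|subgroups|mix|population --out results/
baricea dsa --out tornado.csv                        # one-way sensitivity
baricea psa --n 5000 --seed 7 --out psa.csv          # probabilistic SA
baricea calibrate --out calibration.csv              # re-fit risk equations
```

All inputs live in one YAML document (`--params`); the shipped default
is `src/baricea/data/default_config.yaml`.

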