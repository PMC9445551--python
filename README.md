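# wspsignal

Weibull-shape-parameter signal detection for adverse drug reactions
(ADRs) in single-arm exposed cohorts.

## The problem

Once a medicine is on the market, pharmacovigilance has to spot new
adverse drug reactions from observational data. Longitudinal electronic
health records give, for every treated patient, the *time* from
treatment start to each adverse event — information classical
disproportionality methods ignore. The premise of this package: events
unrelated to the drug (background adverse events, AEs) occur at a
roughly **constant hazard**, while a causally drug-related event has a
**time-dependent hazard** (early toxicity, delayed onset, …). Testing
whether the hazard of an event is constant therefore screens drug–event
pairs without needing a comparator cohort.

## The tests

Given per-subject pairs (tᵢ, δᵢ) — event/censoring time and event
indicator — over an observation window [0, T]:

* **WSP** — fit a two-parameter Weibull, hazard
  λ(t) = (α/θᵅ)·t^(α−1). The hazard is constant iff the shape α = 1;
  raise a signal if the 95% Wald CI for α excludes 1.
* **dWSP** — run the WSP twice, on the full window and on the data
  administratively censored at T/2 (this breaks the symmetry that hides
  mid-window reactions from a monotone-hazard model), each component at
  level 0.025; signal if either fires.
* **pWSP** — fit the power generalised Weibull (PgW),
  S(t) = exp{1 − [1 + (t/θ)^ν]^(1/γ)},
  λ(t) = (ν/(γθ^ν))·t^(ν−1)·[1 + (t/θ)^ν]^(1/γ−1),
  whose hazard can be increasing, decreasing, bathtub or unimodal and
  is constant **iff (ν, γ) = (1, 1)**. Signal only if the CIs for both
  ν and γ exclude 1 (intersection–union rule); if the censored MLE does
  not converge or the Hessian is unusable, no signal is raised.
* **combined** — pWSP OR dWSP. The two are complementary: pWSP is
  strongest for reactions early in the window, dWSP for mid- and
  late-window reactions; the combination is reliable regardless of
  ADR timing.

All fitting is censored maximum likelihood over log-parameters with
Wald intervals from the inverted Hessian, back-transformed to the
positive scale. Estimation failures are flags, never exceptions — a
failed fit means "no signal".

A Monte-Carlo module regenerates the tests' operating characteristics:
cohorts with exponential background AEs (1/5/10% per observation
period), ADR records injected at Normal(mean, sd²) times (first
quarter / middle / third quarter of the period), and per-scenario
true-positive rate, false-positive rate and
accuracy = (TP + 1 − FP)/2.

## Worked example

Simulate a 2,500-subject cohort with a 5% background rate and 68
drug-related events clustered at mid-window, write it as CSV, and test
it (library API: `generate_background`, `generate_adrs`, or bring your
own `id,time,event` file):

```sh
$ wspsignal test cohort.csv --test wsp --end 1.0
WSP: no signal [alpha: CI=(0.987005, 1.30292)]

$ wspsignal test cohort.csv --test combined --end 1.0
combined: SIGNAL [nu: CI=(1.36185, 2.21798) *, gamma: CI=(13.0367, 41.1119) *, alpha_full: CI=(0.967522, 1.32916), alpha_half: CI=(1.34719, 2.07017) *]
```

The plain WSP misses the mid-window cluster — its shape CI
(0.99, 1.30) still contains 1 — while the combined test fires twice
over: both PgW shape CIs exclude 1, and the half-window Weibull
component sees a clearly increasing hazard (α CI 1.35–2.07). Starred
components are the ones that fired.

Operating characteristics of that scenario, from the simulation API:

```python
from wspsignal import ScenarioConfig, run_scenario

summary = run_scenario(
    ScenarioConfig(n_subjects=2500, background_rate=0.05, adr_fraction=0.50,
                   adr_time_mean=0.50, adr_time_sd=0.05,
                   n_replicates=200, seed=7),
    tests=("pwsp", "dwsp"),
)
```

prints (via the obvious loop):

```
pwsp: TP=0.890 FP=0.035 accuracy=0.927
dwsp: TP=0.905 FP=0.015 accuracy=0.945
mean background events: 120.7
mean ADR events: 63.0
```

i.e. with ~63 mid-window ADRs hidden among ~121 background events, both
tests detect ~90% of cohorts while staying at or under their 5%
false-positive budget. Full scenario grids run from a YAML config:

```sh
wspsignal simulate --config src/wspsignal/configs/paper_tables.yaml \
    --out results/ --replicates 200
```

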