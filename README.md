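# strandchart

Continuous-time, risk-adjusted, N-strand (STRAND) control charts for
monitoring censored survival outcomes — for example 30-day mortality after
cardiac surgery — together with a run-length simulation engine and an
updating-EWMA (uEWMA) comparator chart.

The package is aimed at biostatisticians and clinical-audit analysts who need
to monitor a stream of surgical (or similar) outcomes *online*, adjusting for
patient case-mix, while keeping patients in surgery order on the chart and
reacting to deaths as soon as their status at each survival horizon resolves.

## The chart

Survival after treatment is watched through N "gates" at
t₁ < t₂ < … < t_N days (default ½, 2, 10, 20, 30 days, censored at d = 30).
Strand n tracks the failure probability at gate n of a *baseline* patient via
a Bayesian Bernoulli risk-adjusted EWMA.  Under the mean-steady model
(prior mean carried forward, prior precision decaying by κ per step) the
posterior mean after outcome i is

    mᵢ = κ·mᵢ₋₁ + (1 − κ)·[ yᵢⱼ − μ̂ᵢⱼ + μ̂ᵢᵦ ],      0 < κ < 1,

where yᵢⱼ ∈ {0, 1} is patient j's failure indicator at the gate, and the
patient's expected rate μ̂ᵢⱼ comes from a per-gate logistic risk model that
scales the current baseline odds (taken as mᵢ₋₁) on the odds scale:

    μ̂ⱼ/(1 − μ̂ⱼ) = μ̂ᵦ/(1 − μ̂ᵦ) · exp(β̂ (zⱼ − zᵦ)),

with zⱼ the patient's integer risk score (e.g. Parsonnet) and zᵦ the pilot
median.  The posterior for the baseline rate is summarised by a conjugate
Beta distribution with mean mᵢ and steady-state precision 1/(1 − κ);
its (α_low, α_high) percentiles act as control limits, and the strand
signals when this credible interval excludes the strand's target rate
(by default the pilot rate m₀).

Each patient produces one event per strand at calendar time
`surgery_time + tₙ` — the moment their status at that gate resolves.  This
keeps patient ordering intact on every strand while remaining a
continuous-time chart: early deaths reach the short-gate strands quickly but
cannot touch a longer gate before that gate's delay has elapsed, so unusually
long survivals are weighed in fairly against early failures in the same
cohort of surgeries.

Everything is calibrated on a pilot block of the data: the per-gate logistic
models (β̂, m₀), the baseline score zᵦ, per-strand κ (by the guide formula
κ = 0.993 − 0.192·m₀, or by minimising one-step prediction MSE on the pilot
stream), and the targets.

## Worked example

```python
import strandchart as sc

# calibrate a 5-strand chart on an in-control synthetic pilot
pilot = sc.synth_cohort(sc.SimConfig(n_patients=20_000, seed=101))
chart = sc.StrandChart().fit(pilot)
print("baseline score z_b:", chart.z_b_)
print("gate rates m0:", [round(m.m0, 4) for m in chart.models_])
print("kappa:", [round(k, 4) for k in chart.kappa_])

# monitor a deteriorated stream: survival times accelerated by q = 2
monitor = sc.synth_cohort(sc.SimConfig(n_patients=2_000, seed=7, q=2.0))
result = chart.transform(monitor)
print("first signals on the 2-day strand:", result.first_signals()[1])
print("earliest signal anywhere:", round(result.first_signal_time(), 1), "days")
```

prints

```
baseline score z_b: 5
gate rates m0: [0.0076, 0.0143, 0.0303, 0.0383, 0.0429]
kappa: [0.9915, 0.9902, 0.9872, 0.9856, 0.9848]
first signals on the 2-day strand: {'up': 50.871386733246645, 'down': None}
earliest signal anywhere: 50.9 days
```

The pilot median risk score is 5; the fitted baseline failure rates rise from
0.8% at the ½-day gate to 4.3% at 30 days, and the guide formula gives a
smoothing parameter close to 0.99 on every strand.  Halving all survival
times (q = 2) pushes early deaths through the short gates, and the chart
flags a credible *rise* in the 2-day failure rate 51 days into monitoring.

A command-line interface wraps the same workflow on CSV/YAML inputs:

```sh
strand fit      --patients patients.csv --config config.yaml --out models.yaml
strand run      --patients patients.csv --config config.yaml --models models.yaml --out out/
strand simulate --config config.yaml --seed 9 --out cohort.csv
strand mrl      --config config.yaml --q-grid 1,1.5,2 --chart strand --out mrl.csv
```

`strand run` writes a per-update chart CSV and an N-panel plot (rate line,
credible band, signal markers, pilot cut-off).

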