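# periopcea

Markov cohort cost-effectiveness model of **perioperative pembrolizumab**
(neoadjuvant pembrolizumab + platinum chemotherapy for 4 cycles, surgery or
radiotherapy, then adjuvant pembrolizumab for up to 13 cycles) versus
**neoadjuvant chemotherapy alone** in resectable early-stage non-small cell
lung cancer, from the United States healthcare-payer perspective.

The package is aimed at health-economics analysts who want a scriptable,
tested implementation of the full pipeline: reconstructing pseudo
individual-patient data from digitized Kaplan–Meier curves, fitting and
selecting parametric survival models, running the five-state cohort model,
and quantifying uncertainty.

## Model

Five health states — neoadjuvant treatment, post-surgery/radiotherapy,
adjuvant treatment, progressive disease (PD), death — evolve in 21-day cycles
over a 10-year horizon (174 cycles). Transition probabilities are
time-varying and derived from parametric survival curves fitted to trial
event-free survival (EFS) and overall survival (OS):

- per-cycle death probability: `p_death(t) = max(1 − S_OS(t+Δ)/S_OS(t), p_background(age))`,
  applied uniformly to all alive states, so cohort survival reproduces the
  fitted OS curve;
- per-cycle progression probability: `p_PD(t) = max(0, [1 − S_EFS(t+Δ)/S_EFS(t)] − p_death(t))`;
- structural windows: neoadjuvant → post-surgery/RT opens only in cycles 5–6
  (scaled by the proportion undergoing local therapy, with 30-day surgical
  mortality 0.023 charged to the movers), post-surgery/RT → adjuvant opens
  only in cycles 6–10 (intervention arm).

Base-case OS/EFS specifications (time in months): intervention OS log-normal
(meanlog 5.023, sdlog 2.074) and EFS generalized gamma (μ 2.866, σ 1.951,
Q −1.399); comparator OS Weibull (shape 1.232, scale 70.275) and EFS
generalized gamma (μ 2.677, σ 1.316, Q −0.498).

Costs (2023 USD) and utilities accrue per cycle with half-cycle correction
and 3%/year discounting. Outcomes are discounted costs and QALYs per arm,
the incremental cost-effectiveness ratio `ICER = ΔC/ΔE`, and net monetary
benefit `NMB = λ·ΔE − ΔC` at λ = $150,000/QALY. One-way sensitivity analysis
(±25% on costs/proportions/BSA, ±10% on utilities, discount rate 0–8%),
probabilistic sensitivity analysis (1,000 draws: gamma for costs, beta for
proportions/utilities, normal for BSA, uniform for the discount rate; sd =
10% of the mean), cost-effectiveness acceptability curves, and scenario
machinery (horizon, unified OS family, drug prices, break-even price search)
sit on top.

## Worked example

```python
from periopcea import run_base_case

res = run_base_case()  # packaged base-case inputs
print(f"intervention: ${res.intervention.total_cost:,.0f}, {res.intervention.total_qaly:.2f} QALYs")
print(f"comparator:   ${res.comparator.total_cost:,.0f}, {res.comparator.total_qaly:.2f} QALYs")
print(f"ICER ${res.icer:,.0f}/QALY, NMB ${res.nmb:,.0f} at ${res.wtp:,.0f}/QALY")
```

prints

```
intervention: $230,332, 4.36 QALYs
comparator:   $110,668, 3.07 QALYs
ICER $93,228/QALY, NMB $72,870 at $150,000/QALY
```

i.e. perioperative pembrolizumab costs ~$119,664 more per patient over ten
years, gains ~1.28 QALYs, and is cost-effective at the conventional US
willingness-to-pay threshold. The same pipeline is scriptable from the shell:

```bash
periop-cea basecase --out basecase.json
periop-cea dsa --out tornado.csv
periop-cea psa --n 1000 --seed 1 --outdir psa_out
periop-cea scenario horizon5 --set horizon_years=5
```

## Layout

| module | contents |
| --- | --- |
| `periopcea.parameters` | typed parameter table, CSV I/O, sensitivity ranges |
| `periopcea.survival_models` | seven parametric families, censored MLE, AIC/BIC selection |
| `periopcea.km_reconstruction` | pseudo-IPD from digitized KM curves + risk tables |
| `periopcea.markov_engine` | five-state, 21-day-cycle cohort engine |
| `periopcea.economics` | cost/QALY accrual, discounting, ICER/NMB |
| `periopcea.uncertainty` | tornado, PSA, CEAC |
| `periopcea.scenarios` | horizon/price/OS-family scenarios, break-even price |
| `periopcea.synthetic_data` | seeded IPD generation and curve digitization |
| `periopcea.cli` | `periop-cea` command-line entry points |

See `docs/methods.md` for the modelling assumptions and their rationale.
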