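# Methods

This note documents the modelling choices in `periopcea`: the cohort model
and its assumptions, the survival layer, the economic accrual rules, the
uncertainty machinery, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Everything stated here is computed by
the package's own code and exercised by the test suite.

## Cohort model

A closed cohort of previously untreated, resectable early-stage NSCLC
patients (age 65, weight 70 kg, body-surface area 1.86 m²) starts in the
neoadjuvant-treatment state and is propagated through five states —
neoadjuvant treatment, post-surgery/radiotherapy, adjuvant treatment,
progressive disease (PD), death — in 21-day cycles (0.6899 months,
0.0575 years). The base-case horizon is 10 years = 174 cycles; horizons are
rounded to whole cycles (5 y → 87, 15 y → 261, 20 y → 348).

**Survival-derived transitions.** The per-cycle probability of death is the
conditional probability `1 − S_OS(t+Δ)/S_OS(t)` from the arm's fitted OS
curve, floored by age-indexed background mortality (see below), and applied
uniformly to every alive state. This uniform-death convention makes
cohort-level survival reproduce the fitted OS curve exactly (verified to
1e-6 with the floor off) and is the least-informative resolution of the
question of how death hazard splits between pre- and post-progression states,
which the inputs do not identify. The per-cycle probability of progression
from any pre-PD state is the EFS-conditional probability minus the death
probability, floored at zero. A corollary worth stating: any model whose
alive fraction tracks S_OS and whose pre-PD residency tracks S_EFS must have
PD occupancy S_OS − S_EFS; PD duration is therefore not a free parameter
here.

**Windows and tunnels.** The neoadjuvant → post-surgery/RT move is open only
in cycles 5–6 (1-based; the move happens at the end of the named cycle) and
is spread evenly so the cumulative moved fraction equals the arm's
surgery-or-radiotherapy proportion. Movers split 90%/10% between surgery and
radiotherapy; the surgical fraction is charged the 30-day postoperative
mortality (0.023) as an extra death flow in that cycle. Post-surgery/RT →
adjuvant (intervention arm only) is open in cycles 6–10 and scaled by the
adjuvant-uptake proportion. Adjuvant residency is modelled with 13 tunnel
sub-states (one per allowed pembrolizumab cycle), after which patients return
to the post-treatment residency; PD is split into 6 chemotherapy tunnel
cycles plus a late-PD state. The public trace collapses the tunnels back to
the five states. Patients who never undergo local therapy remain in a pre-PD
residency governed by EFS (they keep the neoadjuvant state label but accrue
follow-up, not treatment, costs after cycle 4).

**Proportions.** The trial proportions are first-class parameters: 0.821
(intervention) / 0.794 (comparator) undergoing surgery or radiotherapy, and
0.892 starting adjuvant therapy among those who had local therapy (290/325),
with a 0.568 nonsquamous histology share steering the chemotherapy backbone.

**Background mortality.** All-cause US mortality is approximated by a
Gompertz law anchored at 1.31%/year at age 65 with log-slope 0.093/year
(a smooth fit to period life-table annual probabilities), converted to
per-cycle probabilities and applied as a floor via `max()`. It binds only
where the fitted OS hazard falls below population mortality (for the
intervention arm's heavy-tailed log-normal OS this starts around year 9),
and a flag disables it.

## Survival layer

Seven families are implemented with analytic log-survival, log-density and
quantile functions: exponential, Weibull, log-logistic, log-normal, gamma,
Gompertz (real-valued shape; a negative shape yields a survival plateau,
which downstream extrapolation caps with the background-mortality floor),
and the generalized gamma in the Prentice (μ, σ, Q) parameterization, in
which Q → 0 recovers the log-normal and Q = 1 the Weibull; Q < 0 is allowed
and |Q| < 1e-7 is evaluated as the log-normal limit.

Right-censored maximum likelihood maximizes
`Σ [event·ln f(t) + (1−event)·ln S(t)]` over log-transformed positive
parameters with Nelder–Mead from five fixed moment-based starting points
(deterministic; tolerance 1e-8 on the log-likelihood), because generalized
gamma likelihoods are multimodal. Non-convergence of all starts is flagged on
the result, never silent. Model selection ranks by AIC, breaking ties by BIC
and then parameter count.

**Identifiability caveat.** With a Weibull shape near 1 (the comparator OS
has shape 1.232) the Weibull, gamma and generalized-gamma likelihoods are
nearly indistinguishable at trial-scale samples: the truth's expected AIC
margin is smaller than its sampling noise, so top-1 family recovery
stabilizes only at several thousand observed events. The tests therefore
check *parameter* recovery (within 10% through the full
digitize→reconstruct→refit pipeline) for the printed specifications, and
family recovery on designs where the families are actually distinguishable.
Passing tests show the machinery is correct, not that AIC can discriminate
near-exponential families at n = 400.

## Kaplan–Meier reconstruction

`reconstruct_ipd` inverts digitized (time, survival) coordinates plus a
numbers-at-risk table into pseudo patient records: within each risk-table
interval it allocates integer event counts from the KM ratios at the
digitized times and places censorings uniformly, iterating the censoring
count until the implied number at risk matches the table. The initial guess
is the at-risk decline not explained by the expected events in the interval.
Integer rounding on noisy coordinates makes exact matches infeasible in some
intervals; the closest nonnegative allocation is accepted, and only a
mismatch exceeding max(5, 5% of the initial cohort) is treated as a genuinely
inconsistent table and reported with the offending interval. Survivors past
the last observation are administratively censored at the later of the last
digitized time and the last risk-table time. When the total event count is
known it is reconciled by a final proportional trimming pass.

## Economics

All costs are 2023 USD. Per-administration drug costs: pembrolizumab 200 mg
flat ($54.81/mg → $10,962); cisplatin 75 mg/m², paired with pemetrexed
500 mg/m² day 1 (nonsquamous) or gemcitabine 1,000 mg/m² days 1 and 8
(squamous), BSA-scaled and mixed by the nonsquamous fraction; no vial
wastage. Infusion administration is billed per visit: first hour + one
additional hour + one subsequent-infusion hour for multi-agent visits, first
hour only for pembrolizumab monotherapy, plus a single-agent visit for the
gemcitabine day-8 dose. One-off costs: surgery $15,687.42 or radiotherapy
$16,335.11 per local-therapy event; end-of-life $17,909.24 per death;
expected SAE management (arm-specific grade ≥3 anemia/neutropenia/
thrombocytopenia risks × per-event costs) charged once in cycle 1. Utilities
(per year): progression-free 0.75, post-surgery 0.73, post-radiotherapy 0.79
(mixed by the surgery share in the post-local-therapy state), PD 0.65; SAE
disutilities are an expected one-cycle decrement in cycle 1. Discounting is
3%/year as `(1+r)^(−cycle·21/365.25)`, and occupancy accrues with the
half-cycle (life-table) correction; start- and end-of-cycle counting are
available and bracket the half-cycle result.

**Progressive-disease cost attribution.** After progression the model
charges a platinum doublet for the first 6 PD cycles and best supportive
care until death. Three attribution knobs are deliberately exposed because
the inputs do not determine them: the follow-up visit periodicity in pre-PD
residency (default: the $545.92 fee accrues every cycle), whether a
radiotherapy event is charged at PD entry (default: no — progression therapy
beyond the chemotherapy doublet and supportive care is not double-counted),
and the supportive-care billing periodicity (default: one $3,674.65 event
per 3 cycles, i.e. roughly one billing event per two months of PD residency,
amortized per cycle). These three defaults plus the half-cycle correction
were fixed in a single calibration pass against the published base-case cost
decomposition and then frozen for every analysis in this package — the
sensitivity analyses, scenarios and acceptance checks all run the same
frozen configuration. Charging supportive care every cycle is available
(`bsc_every_cycles=1`) and raises the comparator arm's 10-year cost by
roughly $75k, which is incompatible with the published totals given that PD
occupancy is pinned to S_OS − S_EFS (see the corollary above).

## Uncertainty and scenarios

The tornado re-runs the full model at each parameter's bounds, holding the
rest at base. Bounds follow the stated method exactly — ±25% for costs,
proportions and anthropometrics, ±10% for utilities, [0, 0.08] for the
discount rate — rather than the rounded printed ranges. PSA draws all
non-fixed parameters independently (no correlation structure is specified):
gamma for costs and beta for proportions/utilities moment-matched to mean =
base and sd = 10% of base, normal for anthropometrics, uniform for the
discount rate; draws for probabilities and utilities are clipped to [0, 1].
Survival-curve parameters are not varied in the PSA; they move only in
scenarios. The CEAC reports the fraction of draws with positive NMB across a
willingness-to-pay grid.

Scenario machinery re-runs the frozen pipeline under structured overrides:
horizon, any parameter value, or a unified OS family. For the unified-family
scenarios the arm whose base-case OS is the other family gets a
least-squares curve match over months 1–48 (approximately the trial's
observed follow-up), since no refit data ship with the model; the matched
Weibull to the intervention log-normal agrees with it within 0.01 survival
over the window. The break-even drug price bisects the (numerically
verified monotone) ICER–price relation to within $1/QALY of the threshold.

## Synthetic data

The generator emulates what the real analysis starts from: seeded
right-censored samples via inverse-CDF draws from any supported family, with
administrative and/or exponential random censoring; digitization of the
resulting KM curve at quantile-spaced points (denser where the curve drops,
as a human digitizer clicks) with optional monotonicity-preserving Gaussian
jitter; and a numbers-at-risk table at fixed calendar intervals. It does not
emulate pixel-level digitizer artifacts, correlated reading errors along the
curve, or interval-censored event recording; round-trip tests (max KM
deviation < 0.02 at n = 400) therefore bound the algorithmic error of
reconstruction, not the full error of reading a published figure.

## Numerical conventions and sizes

21 days = 21/30.4375 months; probabilities are clipped to [0, 1]; transition
matrix rows are validated to sum to 1 within 1e-12 (property tests sweep all
174 cycles at 1e-10); the trace uses expanded tunnel states and exact linear
algebra, with a seeded 10⁶-walker micro-simulation as an independent oracle
(agreement within 3 standard errors). Problem sizes in the test suite —
1,000 PSA repetitions, 10-replicate recovery studies at n = 400–1,000,
199-draw bootstrap intervals — are the package's chosen defaults for a
laptop-scale run; all are parameters of the respective functions.

## Known limitations

- The uniform death hazard ignores any post-progression excess mortality
  beyond what the OS curve already encodes.
- Adjuvant-window entrants late in cycles 6–10 slightly under-receive the
  uptake proportion because the window closes on them sooner.
- SAE costs and disutilities are expectations charged once, not simulated
  events with timing.
- The PD cost-attribution periodicities are calibrated assumptions, not
  observed billing data; both are exposed as configuration.
- Break-even price search assumes a monotone ICER in the drug price and
  verifies it on a coarse grid only.
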