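# ddmediate

Delay discounting — preferring smaller immediate rewards over larger
delayed ones — is a behavioural index of temporal impulsivity, quantified
per person by the discount rate *k* of the hyperbolic model
SV = A/(1 + kD). `ddmediate` is a reusable, tested implementation of an
analysis chain that asks whether an emotion-regulation strategy
(cognitive reappraisal, measured by the ERQ) relates to temporal
impulsivity, and whether that relationship is statistically mediated by a
scalar brain-structure measure (ventral-striatum gray-matter volume):

1. **dd_model** — joint maximum-likelihood estimation of (k, β) per
   subject from 120 binary intertemporal choices, with a logistic choice
   rule P(delayed) = 1/(1 + e^{−β(SV₁−SV₂)}), deterministic multi-start
   optimisation in log space, and explicit flagging of non-identified
   (boundary) fits.
2. **questionnaire** — ERQ subscale sum scores and Cronbach's alpha.
3. **association** — partial Spearman correlation (rank, residualise on
   covariates, Pearson of residuals) of each subscale with log₁₀k.
4. **mediation** — covariate-adjusted three-regression mediation
   (a, b, c, c′, ab = a·b; c = c′ + a·b exactly) with case-bootstrap
   percentile inference on the indirect effect.
5. **roi** — mean gray-matter value inside a binary NIfTI mask, the
   scalar mediator's provenance.
6. **simulate** — a seeded synthetic-cohort generator (155 subjects,
   planted linear mediation structure, calibrated choice noise) standing
   in for private participant data, with full ground truth retained.
7. **pipeline / CLI** — `ddmediate run-all` orchestrates every stage and
   writes a hash-complete, byte-reproducible manifest.

It is aimed at researchers in decision neuroscience / biostatistics who
want the estimation and inference machinery of this kind of study as a
library, plus a simulation harness to check power, calibration, and
parameter recovery before collecting data.

## Worked example

```python
from ddmediate import (SimulationConfig, simulate_cohort, fit_cohort,
                       MediationDesign, bootstrap_mediation)
from ddmediate.dd_model import k_identified

cohort = simulate_cohort(SimulationConfig(seed=1))   # 155 subjects, 120 trials
fits = fit_cohort(cohort.choices, cohort.trials)     # per-subject ML (k, beta)

table = cohort.cohort[k_identified(fits).to_numpy()].copy()
table["log10_k"] = fits.loc[k_identified(fits), "log10_k"].to_numpy()
res = bootstrap_mediation(table, MediationDesign(), n_boot=10_000, seed=1)
print(f"a = {res.paths.a:.5f}, b = {res.paths.b:.3f}, "
      f"ab = {res.paths.ab:.5f}, p_ab = {res.p_ab:.4f}")
```

Output:

```
a = -0.00209, b = 2.167, ab = -0.00454, p_ab = 0.0026
```

Reading: each extra reappraisal point is associated with a 0.00209-unit
lower mediator value (path a); each mediator unit is associated with a
2.167 higher log₁₀k given reappraisal (path b); the indirect effect
a·b = −0.0045 log₁₀k per reappraisal point is significantly negative by
the 10,000-draw case bootstrap. The generator planted a = −0.002,
b = 2.047, so the fitted paths recover the truth within sampling error.
Four of the 155 simulated subjects chose the delayed option almost
everywhere; their discount rates are below the task's discriminable range,
so their fits are flagged and excluded from inference.

The same chain runs from the shell:

```bash
ddmediate run-all --seed 1 --out-dir run1 --nboot 10000
```

which writes `trials.csv`, `choices.csv`, `erq_items.csv`, `cohort.csv`,
`ddparams.csv`, `descriptives.csv`, `correlations.json`,
`mediation_*.json` (for subscales passing the correlation gate), and a
`manifest.json` whose bytes are identical across reruns with the same
seed.

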