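# ventswitch

Detection and analysis of the switch from controlled to assisted mechanical
ventilation in ICU event logs.

## The problem

For patients with hypoxemic respiratory failure, the moment of transition
from fully controlled ventilation (deep sedation, no patient-triggered
breaths) to assisted ventilation (patient-triggered breaths, e.g. pressure
support) is clinically critical: switching too late prolongs weaning and
sedation, switching too early risks excessive breathing effort and
patient self-inflicted lung injury (P-SILI). Retrospective multi-center ICU
databases record this moment only implicitly, in noisy vendor-specific
ventilator-mode logs sampled at different frequencies per hospital.

`ventswitch` turns such event logs into an analyzable cohort:

1. **Mode harmonization** — raw mode labels are consolidated into four
   functional categories (controlled, combined/assist-control, assisted,
   CPAP) via per-center dialect tables; combined modes are resolved by the
   nearest spontaneous respiratory rate (> 10 breaths/min ⇒ assisted); CPAP
   during invasive ventilation counts as assisted; transitions persisting
   < 1 h are discarded as non-genuine (e.g. procedure-related).
2. **Switch detection and outcome labeling** — a *switch attempt* is a
   controlled→assisted transition on the cleaned timeline. The first
   attempt is a *failure* if the patient returns to controlled ventilation
   or dies within 72 h, and a *success* otherwise.
3. **Feature extraction** — windowed last-observation-carried-forward
   (LOCF, 12 h window) pre-switch vectors; Δ\_h post-switch change vectors
   (default Δ\_3h, restricted to patients still in assisted mode at +3 h);
   derived parameters PaO₂/FiO₂, ΔP = P\_plat − PEEP and
   C\_RS = V\_T / ΔP from nearest-prior pairings within 1 h.
4. **Endpoints and statistics** — 28-day mortality, ventilator-free days
   (VFD-28), MV duration, ICU length of stay; χ²/Fisher and
   Wilcoxon/t group contrasts; and a mixed-effects logistic test of whether
   PEEP (strata ≤ 5, 6–10, > 10 cmH₂O) modifies the association of
   PaO₂/FiO₂ or C\_RS with switch success (random intercept per center,
   likelihood-ratio test of the interaction).
5. **Prediction** — L1-penalized logistic models of switch failure from
   pre-switch features (model 1) and additionally Δ\_3h features (model 2),
   evaluated by nested cross-validated AUC with variable-group attribution.

Because the source databases are access-restricted, the package ships a
**synthetic multi-center event-log generator** (`ventswitch.synthetic_data`)
that emulates their structure — three centers with different mode-label
dialects and logging frequencies, per-variable missingness, a latent
switch-readiness process, a logistic failure mechanism on true pre-switch
features (giving a computable Bayes-optimal AUC), and lognormal
time-to-failure with a median of 8 h. Every pipeline stage is tested
against this known ground truth.

## Worked example

```python
from ventswitch import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(cohort=CohortConfig(n_patients=5000, seed=11),
                out_dir="demo_run", seed=11)
res = run_pipeline(cfg)
print(res["flow_percentages"])
print("model 1 AUC:", round(res["prediction"]["model1"].auc, 3))
```

prints (exact numbers depend on the seed):

```
{'attempted_pct': 91.6, 'no_switch_pct': 8.4, 'success_pct': 31.9,
 'failure_pct': 68.1, 'mode_change_pct': 81.6}
model 1 AUC: 0.698
```

Of 5000 simulated stays, those passing the eligibility screen (hypoxemia
within 48 h of intubation, ≥ 48 h of invasive ventilation, starting in
controlled mode) split into 91.6% attempting a switch and 8.4% never
leaving controlled mode; 68.1% of first attempts fail, 81.6% of attempts
appear as actual mode changes (the rest as spontaneous-rate changes during
combined modes). The nested-CV LASSO AUC of 0.698 sits just below the
Bayes-optimal 0.710 computed from the generator's true failure
probabilities — the model recovers essentially all recoverable signal.

The same pipeline runs on user-supplied data: provide `stays.csv`,
`mode_events.csv`, `airway_events.csv` and `measurements.csv` in the
documented generic schema (see the `synthetic_data` docstrings) and point
`RunConfig.input_dir` (or `ventswitch run --input DIR`) at the directory.

A CLI covers the common paths:

```bash
ventswitch simulate --n 1000 --out cohort/ --seed 1
ventswitch run --input cohort/ --out run/ --seed 1
ventswitch sensitivity --out run_sens/ --seed 1
```

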