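# Methods

This note documents the models, rules and numerical choices implemented in
`ventswitch`, and what the synthetic-data experiments do and do not
establish about real ICU data.

## Time and interval conventions

All event times are real-valued hours since ICU admission (t = 0).
Intervals are half-open `[start, end)`, so a mode ending at t and another
beginning at t never overlap and boundaries are never double-counted.
Invasive-ventilation intervals are built by pairing intubation/extubation
events; an unmatched intubation is closed at the end of follow-up (death or
ICU discharge while ventilated).

## Mode harmonization

Raw ventilator-mode labels are mapped to five functional categories —
controlled, combined (assist-control), assisted, CPAP,
non-invasive/none — through per-center dialect tables (CSV:
`raw_label, category`). The cleaning chain is:

1. **Carry-forward.** Each logged mode extends until the next log,
   extubation, or end of stay. Within an invasive interval the first
   record's category is extended back to the interval start (modes are
   normally charted within minutes of intubation). An invasive interval
   with no mode record at all raises an error rather than guessing.
   Adjacent *combined* records are deliberately kept as separate segments
   so that each can be re-classified on its own evidence (a switch hidden
   between two combined logs would otherwise be unrecoverable).
2. **Combined-mode reassignment.** A combined segment becomes assisted if
   the spontaneous respiratory rate nearest in time to the segment start
   (within ±1 h) is strictly greater than 10 breaths/min, else controlled.
   Ties between equidistant measurements resolve to the earlier one. When
   no spontaneous rate is available within tolerance the segment is
   conservatively classified controlled — no switch attempt is fabricated —
   and the fallback is flagged in the segment's provenance. The total (set)
   respiratory rate is never used as a substitute. The choice of the
   segment *start* as the reference point (rather than the midpoint) is a
   design decision recorded here; the ±1 h tolerance mirrors the pairing
   tolerance used for derived parameters.
3. **CPAP reassignment.** CPAP inside an invasive interval becomes
   assisted; outside, non-invasive/none. A CPAP segment straddling an
   extubation is split at the boundary — the only step that changes
   segment boundaries.
4. **Persistence filter.** A transition counts only if the new mode
   persists for at least 1 h ("at least" inclusive: exactly 1.0 h
   survives). Short runs are absorbed left-to-right into the preceding
   accepted mode, re-checking after each merge; the initial mode of an
   interval is never absorbed. This rule removes abrupt transient mode
   changes (e.g. around bronchoscopy) on both sides of a switch: a return
   to controlled mode lasting under 1 h does not count as a failure either.
   The operation is idempotent, conserves total covered time, and is
   verified against an independent brute-force merge oracle.

## Switch attempts and outcome labeling

Every controlled→assisted boundary on the filtered timeline (within one
invasive interval) is an attempt; boundaries created purely by
combined-mode reassignment are typed `rr_change`, the rest `mode_change`.
Eligibility for the cohort requires: at least one PaO₂/FiO₂ < 300 mmHg
within 48 h of intubation, ≥ 48 h total invasive ventilation, starting in
controlled mode, and first ICU stay of the hospitalization.

Only the first attempt is labeled. It fails if a (persistent) controlled
segment begins, or death occurs, in `(t, t + 72 h]` — the earliest
qualifying event sets the failure cause and time. Design decisions the
horizon definition leaves open, resolved and configurable here:

* events at exactly t + 72 h count as inside the window (closed right end);
* a stay ending alive (discharge) before t + 72 h with no return counts as
  success — liberation is the intended outcome of a switch;
* re-intubation into controlled mode within the horizon counts as a return.

Extending the horizon can only convert success into failure, never the
reverse (tested as a property).

## Derived parameters and feature windows

PaO₂/FiO₂ = PaO₂ / (FiO₂/100) (mmHg), ΔP = P_plat − PEEP (cmH₂O), and
C_RS = V_T / ΔP (mL/cmH₂O) are computed by pairing each primary measurement
with the *nearest prior* partner measurement — at or before the primary
timestamp, within 1 h; simultaneous timestamps count as prior. Points
without a partner are dropped, never extrapolated; negative ΔP and
non-positive denominators are skipped with a warning. FiO₂ values ≤ 1.0
are treated as fractions and scaled to percent on ingest with a warning.

Pre-switch vectors use windowed LOCF: the latest measurement in
`[t − 12 h, t]` (both ends closed; the anchor measurement itself is
pre-switch). Post-switch values are the latest in `(t, t + h]`
(anchor-exclusive, edge-inclusive); Δ_h = post − pre, present only when
both sides exist — no further imputation at this stage. Variables missing
for at least two-thirds of patients are excluded from the pre-switch
analysis (boundary: exactly 2/3 missing is excluded); Δ variables with
data for at least one-third of patients are kept (boundary inclusive).
Patients failing or liberated within the Δ horizon are excluded from the
after-switch analysis; shrinking the horizon can only grow the retained
set (the basis of the Δ1h–Δ8h sensitivity sweep).

## Endpoints

28-day mortality is anchored at ICU admission. VFD-28 is 0 if the patient
dies before day 28 or is still invasively ventilated at day 28, otherwise
28 minus the days of invasive ventilation up to day 28, floored at 0;
re-intubation gaps count as free days. Both anchoring and the VFD
convention are config-exposed choices. Overlapping invasive intervals are
normalized by union with a warning. The follow-up curve for failed
attempts is the empirical fraction still in assisted mode (1 − ECDF of
time to failure); its median read-off equals the sample median.

## Group comparisons and the PEEP interaction

Proportions are compared by χ² without continuity correction, switching to
Fisher's exact test when any expected cell count is below 5; continuous
variables by Wilcoxon rank-sum by default (Student's t for the Δ tables,
which are summarized as mean (SD)). All tests are two-sided; no
multiple-testing correction is applied, matching per-variable reporting.
Quartiles use linear interpolation (type 7).

Whether PEEP modifies the association of PaO₂/FiO₂ or C_RS with switch
success is tested with a random-intercept logistic regression:
`success ~ variable × PEEP stratum + (1 | center)`, strata ≤ 5, 6–10,
> 10 cmH₂O assigned from the PEEP paired to the specific measurement
(nearest prior, not a daily mean). The marginal likelihood is maximized
directly, integrating the center effect by *adaptive* Gauss–Hermite
quadrature (9 nodes centered at each cluster's conditional mode with
Laplace scaling; accurate to < 0.01 log-likelihood units against lme4's
`glmer` at nAGQ = 25, which serves as a cross-check oracle in the test
suite, never as the implementation). The interaction p-value comes from a
likelihood-ratio χ² with one degree of freedom per interaction column.
Strata containing a single outcome class are dropped with a warning; with
a single center the random-effect SD is fixed at zero, reducing exactly to
a plain logistic fit. The random-intercept-only structure and the LRT are
this package's choices; treating PEEP as categorical strata follows the
stratified presentation of the results tables.

## Failure prediction

Model 1 uses pre-switch LOCF features of all included variables; model 2
adds Δ_3h features and restricts rows to patients still in assisted mode at
+3 h. Continuous features are median-imputed with paired missingness
indicator columns, constant columns dropped, and all columns standardized —
each learned on training folds only. The penalty of the L1 logistic
regression is chosen by inner 5-fold stratified CV (8 log-spaced values of
C); the reported AUC comes exclusively from held-out outer-fold predictions
(outer 5-fold, stratified, shuffled with the run seed). Median+indicator
imputation is the deliberate simple default, with the iterative imputer
relegated to a sensitivity role; both are config-switchable. Variable-group
attribution refits the model without one group (gas exchange, ventilatory,
inflammatory, other — following the comparison tables' section headers)
using the same fold seed and reports ΔAUC.

## The synthetic generator: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses rely on,
not physiology:

* **Centers.** Three centers with distinct mode-label dialects (≥ 13 raw
  labels each, covering every category including combined and CPAP
  labels), distinct per-variable logging grids (densest in center 2,
  emulating a high-resolution database; sparser ventilator logging in
  centers 0 and 1) and per-variable missingness (records thinned at
  random).
* **Readiness.** Each patient is intubated at t = 0 in a controlled mode.
  The first attempt occurs at a lognormal readiness time (median 1.5 days,
  σ = 0.7) with 15% log-noise, occasionally scaled down for premature
  attempts (probability 0.10); patients whose readiness exceeds their
  controlled course (lognormal, median 5 days) never attempt, yielding a
  no-switch group of roughly 8%.
* **Failure mechanism.** Failure of the first attempt is Bernoulli with a
  logistic probability in the patient's *true* (noise-free) standardized
  PaO₂/FiO₂ (−0.50), PEEP (+0.35), base excess (−0.30), lactate (+0.45)
  and ΔP (+0.30), intercept +0.78 — giving a failure rate near two-thirds
  and a computable Bayes-optimal AUC (≈ 0.71 at the defaults).
  Measurement noise (small relative to between-patient spread, as for
  calibrated clinical instruments; ventilator settings exact) is added
  afterwards, so the extracted features attenuate the signal only
  marginally.
* **Time to failure.** Lognormal with median 8 h and σ = 1.15 (chosen so
  the quartiles sit near 4 and 19 h), truncated to [1.05, 71.9] h so every
  generated episode respects the 1 h persistence rule and the 72 h
  horizon. Failures are realized as a logged return to controlled mode, or
  with probability 0.10 as death in assisted mode. Failed switches are
  followed by a Poisson (mean 2.2) number of secondary attempts, each
  episode at least 1.05 h long.
* **Mortality.** 28-day death is drawn independently of center with
  baseline probability 0.145, shifted by +0.75 log-odds after a failed
  switch (and +2.0 for the no-switch group), reproducing the
  outcome association without hard-coding causality. Deaths of successful
  switchers are scheduled after t + 72 h so ground-truth labels stay
  consistent.
* **Combined modes.** A configurable fraction (default 0.18) of
  controlled/assisted mode records is rewritten to combined labels, each
  paired with a same-timestamp spontaneous rate on the truth-consistent
  side of the 10/min threshold — so roughly 18% of detected attempts
  surface as `rr_change`.

Deliberately *not* modeled: within-patient physiological trajectories
(latent values are constant per stay apart from a deterministic shift of
ventilatory parameters in assisted mode), correlated missingness,
inter-variable correlation beyond the derived-parameter identities
(PaO₂ = P/F × FiO₂/100, P_plat = ΔP + PEEP, MV = V_T × RR), sedation, and
re-admissions. Consequently, passing tests establish that the *pipeline*
is correct and calibrated (exact ground-truth recovery under dense
logging, Bayes-AUC recovery, nominal type-I error), not that any clinical
effect size generalizes to real data. The generator logs a mode record at
every true change time in addition to periodic re-logs; real databases may
log modes only on a grid, which delays detection — the package measures
that delay (detected vs true failure-time medians) rather than hiding it.

## Numerical choices

* Boundary comparisons use an absolute tolerance of 1e-9 h (~4 µs).
* The GLMM optimizer is L-BFGS-B on (β, σ) with σ ∈ [0, 5], warm-starting
  the full model from the reduced fit; the LRT statistic is floored at 0.
* Nested-CV fold seeds derive deterministically from the run seed; all
  randomness flows from `numpy.random.default_rng(seed)`.
* Problem sizes used by the test suite and acceptance script — n = 5000
  for cohort-level statistics and AUC recovery, n = 1000 for detector
  fidelity under dense logging, 500/200 replicates for interaction-test
  calibration/power — were chosen to keep Monte-Carlo error comfortably
  inside the asserted bands.

## Known limitations

* Dialect tables for real databases must be supplied by the user; the
  shipped dialects are synthetic stand-ins exercising every mapping branch.
* The persistence filter resolves ambiguous alternating blips
  left-to-right; other orders are defensible and would occasionally merge
  differently.
* With only three centers the random-intercept SD is weakly identified;
  the interaction LRT is nevertheless calibrated (both nested models share
  the boundary behavior), as the simulation suite verifies.
* Secondary attempts are detected and counted but not outcome-labeled.
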