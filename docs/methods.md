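# Methods

## Model structure

A Markov cohort model tracks a closed cohort of cancer patients eligible
for primary VTE prophylaxis through monthly cycles. The whole cohort
starts complication-free. Base states: complication-free, DVT, PE, ICH on
continued anticoagulation, ICH off anticoagulation, PTS, CTEPH, death
(absorbing). Strategies differ only in the first-VTE and bleeding risks,
the PE / major-bleeding / ICH branching proportions, and drug costs; all
post-event natural-history inputs are shared.

### Tunnel states

All time dependence in the model is time-since-event, not calendar time:
the 3-month therapeutic anticoagulation window after a VTE, the
year-indexed PTS incidence after DVT (18.0%/y in year 1, 7.9%/y in year
2, 2.3%/y from year 3; the year-3 value is extended unchanged beyond year
5 for the 10-year horizon), the year-indexed CTEPH incidence after PE
(3.1%/y, then 0.7%/y, then 0), and the period-indexed CTEPH mortality
(32.7% over days 1–90, 17.5% over days 91–365, 11.0%/y in year 2, 8.1%/y
from year 3 — the 90- and 275-day windows are converted with period
lengths 3 and 9 months).

These schedules are realized as **month-level tunnel states** (months
1..24 since entry, then a pooled "year 3+" tail) for DVT, PE, and CTEPH.
Month-level tunnels advance deterministically, so period boundaries are
exact; a coarser period-level tunnel cannot know when its period ends.  A
consequence worth noting: the transition matrix is **cycle-invariant**
(the `matrix_at(cycle)` accessor keeps the cycle argument for API
symmetry), and the expanded state space has 80 states.

### Competing events

Within a cycle the monthly probabilities of death, VTE, bleeding, and
sequela progression are treated as mutually exclusive branch masses of a
single chance node, mirroring a decision-tree cycle structure, rather
than as independent hazards. If sampled inputs push the masses above 1
the builder raises (deterministic runs) or proportionally rescales and
counts the draw (probabilistic runs). With base-case inputs the largest
row mass is ≈0.19, far from the boundary.

Bleeding splits into CRNMB and major bleeding; major bleeding into GI
bleeding and ICH. CRNMB and GI bleeds are transient: they charge a
one-time cost ($8.250, $1,876.013) and a one-time QALY decrement (0.013,
0.270) on the event flow and leave the state unchanged. ICH is a state:
entrants split 65.7%/34.3% into off-/on-treatment branches once, on
entry. Off-treatment patients accrue no drug cost and revert to the
no-prophylaxis branching proportions; a further ICH while on treatment
can trigger the same discontinuation split.

Recurrent VTE (from post-VTE and post-ICH states) re-enters the acute
DVT/PE tunnels using the same PE share as first VTE (the recurrent split
is not separately published), resetting the therapeutic window. Re-entry
discards ICH history — a memoryless simplification.

### Mortality composition

The state-specific death probabilities (DVT 0.316/y, PE 0.402/y, ICH on
0.097/y / off 0.191/y, PTS 0.033/y, CTEPH per the period schedule) come
from cohort studies of patients *in those states* and are treated as
**total** mortality there; background cancer mortality (0.153/y) applies
only in the complication-free state. This is switchable
(`MarkovOptions(mortality_mode="additive")`) because the original payoff
wiring is not published; note the PTS figure is *below* background cancer
mortality, which the total-mode reading takes at face value.

## Payoffs

Utilities per year of occupancy: complication-free 0.650, DVT 0.610, PE
0.620, ICH 0.330, PTS 0.500, CTEPH 0.630, death 0; accrued as `u/12` per
cycle on start-of-cycle occupancy. The "permanent disutility" inputs for
these same states are retained only as sensitivity handles: subtracting
them from the baseline utility does not reproduce the explicit state
utilities (0.650 − 0.190 = 0.460 ≠ 0.610), so both cannot apply at once
and the explicit values win.

Drug costs per cycle: prophylactic dose while complication-free, the
3-month therapeutic course spread over its three tunnel cycles after any
VTE, prophylactic dose again afterwards (lifelong), nothing once
treatment stops after ICH. The no-prophylaxis arm pays nothing upfront
but, after a VTE, pays a therapeutic course and secondary prophylaxis
priced at the LMWH standard of care — guideline practice mandates
anticoagulation after any cancer-associated VTE regardless of arm, and
without this the no-prophylaxis arm's published total cost is
unreachable by a factor of ~1.8.

**Reimbursement.** The analysis takes the patient-payer perspective with
a Medicare copay: drug costs (prophylactic and therapeutic) are
multiplied by a self-paid share, default **0.40** (≈60% reimbursement, a
representative Class-B outpatient copay). The base share is not published
anywhere we could verify; 0.40 was fixed a priori on policy grounds. It
is a config parameter (`self_pay_ratio`, DSA range 0.2–0.6) and must be
considered the single most structural unknown in cost comparisons.
Full-price drug spending alone (≈$5,400 for DOACs over 5 discounted
years) would exceed the published 5-year *total* of $3,287.893, so some
reimbursement share is structurally necessary. Event-management and
chronic-care costs are charged at full price.

One-time event costs on entry flows: DVT $693, PE $1,121, ICH $4,378.347,
GI bleed $1,876.013, CRNMB $8.250; annual chronic costs post-ICH $2,527,
PTS $1,872.904, CTEPH $10,747.988, spread per cycle. Costs and QALYs are
discounted at 5%/year, `(1+r)^(−t/12)`, from cycle 0. No half-cycle
correction by default (the comparator model's convention is unknown); the
standard correction is available via `run_cohort(..., half_cycle=True)`.

## Uncertainty analysis

**One-way (DSA):** each parameter varies over its 95% bounds; when bounds
are missing, ±20% for costs and ±10% for probabilities/proportions
(clamped to [0,1]); utilities without bounds are rejected so a range must
be stated. Entries are ranked by the swing of the pairwise ICER. The
threshold search bisects the ICER–WTP difference to $0.01 (or bracket
width 1e-6) and requires a sign change over the supplied bracket; note
the ICER has a singularity where ΔQALY crosses zero, so brackets must
stay on one side of it (the acceptance checks locate the preference
switch on the continuous NMB difference instead).

**Probabilistic (PSA):** beta distributions (method of moments from mean
and SD) for probabilities, proportions, utilities, and disutilities;
log-normal for costs with the printed value as the natural-scale median
and the printed "SD" as the log-scale sigma — this reproduces the printed
asymmetric 95% bounds via `median·exp(±1.96σ)`, which a natural-scale SD
reading grossly fails to do. Parameters are drawn **independently**, per
arm; the analysis being reproduced sampled shared baselines times
relative risks, which correlates arms and shrinks the variance of
between-arm differences. Under independence the acceptance probabilities
at the threshold shift toward the extremes (more wins for DOACs and for
no prophylaxis); the RR-level uncertainty needed to reproduce the
correlated scheme is not published in the material in scope. Draws are
seeded (`numpy.random.default_rng`), bit-reproducible, and an unseeded
run is an error.

## Evidence synthesis

Baseline event rates can be regenerated from arm-level counts by
DerSimonian–Laird random-effects pooling on the logit scale with a 0.5
continuity correction for zero/full cells and tau² truncated at zero.
This stage is a verification path: the packaged table already holds
pooled values, and the pooling scale/estimator of the source synthesis is
not stated, so exact agreement with it cannot be checked. The
`statsmodels` meta-analysis routine serves as an independent cross-check
in the tests (it does not truncate negative tau², hence the in-house
implementation).

## Synthetic data

`fixtures.generate_trial_arms` emulates the evidence base: per-study
control probabilities vary on the logit scale with variance tau² around a
known baseline, a known relative risk scales the treated arm, and event
counts are binomial. It reproduces what matters for testing the pooling
stage (heterogeneity, zero cells, RR recovery); it does **not** emulate
differential follow-up, multi-arm trials, outcome misclassification, or
publication bias, so green tests say nothing about those. Perturbed
parameter sets (`perturb_parameters`) are one-draw PSA samples used to
stress the engine's invariants.

## Problem sizes used in the checks

The shipped checks run the deterministic model at 36/60/120 cycles
(instant), the PSA at 10,000 draws × 3 strategies × 60 cycles (≈40 s),
pooling recovery on up to 20 synthetic studies × 2,000 patients × 500
replicates, and distribution round-trips at 10⁶ draws. These sizes were
chosen to match the published analysis where it states them (10,000 PSA
draws) and otherwise to make Monte Carlo error negligible relative to the
assertion tolerances.

## Known limitations

* The self-paid share (0.40) and the no-prophylaxis arm's post-VTE drug
  pricing are reconstructions of unpublished structure; cost levels (not
  orderings) move with them.
* With the packaged per-arm inputs, LMWHs are slightly dominated by DOACs
  at every horizon (lower QALYs at higher cost). The published analysis
  reports LMWHs with the highest QALYs; no payoff wiring can produce that
  from these inputs, since they make LMWHs worse on every
  mortality-relevant channel (more VTE, more PE-heavy, more ICH). Any
  LMWH-favouring mortality adjustment in the source synthesis is outside
  the packaged table.
* No age dependence, no treatment switching or adherence, no drug–drug
  interactions, no microsimulation-level heterogeneity.
* Post-ICH history is dropped on VTE recurrence; PTS/CTEPH patients face
  only their state-specific mortality.
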