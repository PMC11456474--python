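# cavte-cea

Cost-effectiveness analysis of primary thromboprophylaxis for
**cancer-associated venous thromboembolism (CAVTE)** in China, comparing
direct oral anticoagulants (**DOACs**: apixaban, rivaroxaban),
low-molecular-weight heparins (**LMWHs**), and **no prophylaxis**, from a
payer perspective.

The package is aimed at health-economic modellers and clinical
pharmacologists who want a transparent, fully scripted, testable
re-implementation of a decision model of this class: every input is a
validated parameter in a diffable YAML table, every analysis stage is a
library function with a CLI wrapper, and every run is seeded and
reproducible.

## The model

A Markov cohort model with a 1-month cycle and a default 5-year horizon.
Health states: complication-free (on prophylaxis), acute/post-acute DVT and
PE (month-indexed tunnel states carrying the 3-month therapeutic
anticoagulation window and the year-indexed sequela schedules),
intracranial haemorrhage (ICH) on or off continued anticoagulation
(65.7% stop after ICH), post-thrombotic syndrome (PTS), chronic
thromboembolic pulmonary hypertension (CTEPH), and death.

Probabilities stated over a period *T* months are converted per cycle under
a constant rate, `p_cycle = 1 − (1 − p_T)^(1/T)`. Within a cycle, VTE
(split PE/DVT), bleeding (split CRNMB / GI bleed / ICH), death, and
sequela progression compete as mutually exclusive branch masses; an error
is raised—never a silent renormalization—if they exceed 1. CRNMB and GI
bleeding are transient tolls (one-time cost and QALY decrement on the
event flow), not states.

Payoffs: per-state utilities accrued per cycle (`u/12`), per-cycle drug
costs (prophylactic or therapeutic dose; drug costs carry the Medicare
self-paid share, 0.40 by default), annual chronic-state costs spread per
cycle, and one-time event costs on transition flows. Costs and QALYs are
discounted at 5%/year: `(1+r)^(−t/12)`.

Analyses: pairwise ICERs (`Δcost/ΔQALY`) and an efficiency frontier with
strict and extended dominance; net monetary benefit `NMB = QALY·λ − cost`
at a willingness-to-pay `λ = $37,125.240/QALY` (3× per-capita GDP);
one-way sensitivity with tornado ordering and bisection threshold search;
a seeded 10,000-draw probabilistic sensitivity analysis (beta
distributions for probabilities/proportions/utilities by method of
moments, log-normal for costs with the printed value as median and the SD
column as log-scale sigma) with cost-effectiveness acceptability curves.
A DerSimonian–Laird random-effects pooling stage (logit scale) regenerates
baseline event rates from arm-level trial counts when supplied.

## Worked example

```bash
$ cavte-cea base-case --horizon 60 --out results/base_case
strategy     cost  qaly  icer_vs_placebo  icer_vs_lmwhs
 placebo 2272.416 1.763              NaN   51496.632514
   doacs 3137.386 1.834     12188.866093 -614980.885633
   lmwhs 5711.291 1.830     51496.632514            NaN
```

Reading: over 5 years, no prophylaxis costs $2,272 and yields 1.763 QALYs;
DOAC prophylaxis adds $865 and 0.071 QALYs, an ICER of ≈$12,189/QALY —
far below the $37,125/QALY threshold, so DOACs are cost-effective against
no prophylaxis. LMWHs cost $2,574 more than DOACs while yielding
marginally fewer QALYs (the negative ICER flags the dominated comparison),
so DOACs are the preferred anticoagulant here.

```bash
$ cavte-cea ceac --n 2000 --seed 11 --out results/ceac
P(cost-effective | WTP=37,125.240) placebo      0.276
P(cost-effective | WTP=37,125.240) doacs        0.659
P(cost-effective | WTP=37,125.240) lmwhs        0.065
```

Under joint parameter uncertainty, DOACs attain the maximum net monetary
benefit in about two-thirds of draws at the threshold.

Other subcommands: `scenarios` (3/5/10-year horizons × pooled/original/
generic prices × individual DOACs), `dsa` (tornado CSV/plot),
`psa` (draw-level output and scatterplot), `pool` (random-effects pooling
of arm-level counts). Every run writes a `manifest.json` with the
configuration, package version, and seed.

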