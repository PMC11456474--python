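# Parameter dictionary

The packaged base-case inputs (`src/cavte_cea/data/parameters.yaml`),
one row per parameter. `mean` is the natural-scale median for
log-normal costs and `sd` its log-scale sigma. Periods: the time
window a probability describes before per-cycle conversion.

## Shared inputs

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `wtp_per_qaly` | fixed | 37125.2 |  |  | 0 | fixed | one-time | willingness-to-pay threshold (3x 2022 per-capita GDP) |
| `discount_rate_annual` | fixed | 0.05 |  |  | 0 | fixed | 1 year | annual discount rate for costs and QALYs |
| `cycle_length_months` | fixed | 1 |  |  | 0 | fixed | one-cycle | Markov cycle length |
| `self_pay_ratio` | fixed | 0.4 | 0.2 | 0.6 | 0 | fixed | one-cycle | patient-paid share of anticoagulant drug costs |
| `prop_ich_discontinue` | proportion | 0.657 | 0.591 | 0.722 | 0.034 | beta | one-time | share stopping anticoagulation after ICH |
| `annual_death_rate_cancer` | probability | 0.153 | 0.132 | 0.176 | 0.011 | beta | 1 year | background cancer mortality, complication-free state |
| `prob_recurrent_vte_dvt` | probability | 0.027 | 0.024 | 0.03 | 0.002 | beta | 1 year | recurrent VTE while post-DVT |
| `prob_bleeding_dvt` | probability | 0.054 | 0.048 | 0.06 | 0.003 | beta | 1 year | bleeding while post-DVT |
| `prob_death_dvt` | probability | 0.316 | 0.278 | 0.357 | 0.02 | beta | 1 year | total mortality in the DVT state |
| `prob_recurrent_vte_pe` | probability | 0.057 | 0.052 | 0.063 | 0.003 | beta | 1 year | recurrent VTE while post-PE |
| `prob_bleeding_pe` | probability | 0.069 | 0.062 | 0.076 | 0.004 | beta | 1 year | bleeding while post-PE |
| `prob_death_pe` | probability | 0.402 | 0.362 | 0.443 | 0.021 | beta | 1 year | total mortality in the PE state |
| `prob_recurrent_vte_ich` | probability | 0.035 | 0.032 | 0.039 | 0.002 | beta | 1 year | recurrent VTE after ICH |
| `prob_bleeding_ich_on` | probability | 0.079 | 0.071 | 0.087 | 0.004 | beta | 1 year | bleeding in ICH, anticoagulation continued |
| `prob_bleeding_ich_off` | probability | 0.086 | 0.077 | 0.0946 | 0.004 | beta | 1 year | bleeding in ICH, anticoagulation stopped |
| `prob_death_ich_on` | probability | 0.097 | 0.069 | 0.137 | 0.017 | beta | 1 year | mortality in ICH, anticoagulation continued |
| `prob_death_ich_off` | probability | 0.191 | 0.016 | 0.226 | 0.054 | beta | 1 year | mortality in ICH, anticoagulation stopped |
| `prob_death_pts` | probability | 0.033 | 0.03 | 0.037 | 0.002 | beta | 1 year | mortality in the PTS state |
| `prob_pts_dvt_year1` | probability | 0.18 | 0.109 | 0.251 | 0.036 | beta | 1 year | PTS incidence after treated DVT, year 1 |
| `prob_pts_dvt_year2` | probability | 0.079 | 0.048 | 0.11 | 0.016 | beta | 1 year | PTS incidence after treated DVT, year 2 |
| `prob_pts_dvt_year3plus` | probability | 0.023 | 0.014 | 0.032 | 0.005 | beta | 1 year | PTS incidence after treated DVT, years 3+ |
| `prob_cteph_pe_year1` | probability | 0.031 | 0.019 | 0.043 | 0.006 | beta | 1 year | CTEPH incidence after treated PE, year 1 |
| `prob_cteph_pe_year2` | probability | 0.007 | 0.004 | 0.01 | 0.002 | beta | 1 year | CTEPH incidence after treated PE, year 2 |
| `prob_death_cteph_days_1_90` | probability | 0.327 | 0.202 | 0.499 | 0.076 | beta | 90 days | CTEPH mortality, days 1-90 after entry |
| `prob_death_cteph_days_91_365` | probability | 0.175 | 0.114 | 0.256 | 0.036 | beta | 275 days | CTEPH mortality, days 91-365 after entry |
| `prob_death_cteph_year2` | probability | 0.11 | 0.06 | 0.184 | 0.032 | beta | 1 year | CTEPH mortality, year 2 after entry |
| `prob_death_cteph_year3plus` | probability | 0.081 | 0.048 | 0.129 | 0.021 | beta | 1 year | CTEPH mortality, years 3+ after entry |
| `utility_ich` | utility | 0.33 | 0.26 | 0.4 | 0.036 | beta | 1 year | utility, ICH state |
| `utility_cancer_no_vte` | utility | 0.65 | 0.616 | 0.672 | 0.014 | beta | 1 year | utility, complication-free cancer |
| `utility_dvt` | utility | 0.61 | 0.514 | 0.678 | 0.042 | beta | 1 year | utility, DVT state |
| `utility_pe` | utility | 0.62 | 0.477 | 0.725 | 0.063 | beta | 1 year | utility, PE state |
| `utility_pts` | utility | 0.5 | 0.32 | 0.65 | 0.084 | beta | 1 year | utility, PTS state |
| `utility_cteph` | utility | 0.63 | 0.52 | 0.73 | 0.054 | beta | 1 year | utility, CTEPH state |
| `utility_death` | utility | 0 |  |  | 0 | fixed | 1 year | utility, death |
| `disutility_dvt` | disutility | 0.19 | 0.06 | 0.45 | 0.01 | beta | 1 year | permanent DVT disutility (sensitivity handle only) |
| `disutility_pe` | disutility | 0.25 | 0.09 | 0.55 | 0.117 | beta | 1 year | permanent PE disutility (sensitivity handle only) |
| `disutility_major_bleed` | disutility | 0.27 | 0.246 | 0.294 | 0.012 | beta | one-time | one-time QALY loss per major bleed |
| `disutility_crnmb` | disutility | 0.013 | 0.01 | 0.016 | 0.002 | beta | one-time | one-time QALY loss per CRNMB |
| `disutility_ich` | disutility | 0.47 | 0.34 | 0.6 | 0.066 | beta | 1 year | permanent ICH disutility (sensitivity handle only) |
| `disutility_pts` | disutility | 0.05 | 0.028 | 0.072 | 0.011 | beta | 1 year | permanent PTS disutility (sensitivity handle only) |
| `disutility_cteph` | disutility | 0.36 | 0.344 | 0.376 | 0.008 | beta | 1 year | permanent CTEPH disutility (sensitivity handle only) |
| `cost_event_dvt` | cost | 693 | 329 | 941 | 0.268 | lognormal | one-time | one-time acute DVT management cost |
| `cost_event_pe` | cost | 1121 | 448 | 1793 | 0.354 | lognormal | one-time | one-time acute PE management cost |
| `cost_event_ich` | cost | 4378.35 | 2677.67 | 6066.55 | 0.209 | lognormal | one-time | one-time ICH management cost |
| `cost_event_gib` | cost | 1876.01 | 978.7 | 3209.56 | 0.303 | lognormal | one-time | one-time GI-bleed management cost |
| `cost_event_crnmb` | cost | 8.25 | 5.77 | 10.72 | 0.158 | lognormal | one-time | one-time CRNMB management cost |
| `cost_post_ich_annual` | cost | 2527 | 2269.14 | 2784.86 | 0.052 | lognormal | 1 year | annual post-ICH care cost |
| `cost_pts_annual` | cost | 1872.9 | 1498.32 | 2247.49 | 0.103 | lognormal | 1 year | annual PTS care cost |
| `cost_cteph_annual` | cost | 10748 | 8598.39 | 12897.6 | 0.103 | lognormal | 1 year | annual CTEPH care cost |

## Strategy `placebo`

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `prob_first_vte` | probability | 0.194 | 0.115 | 0.329 | 0.055 | beta | 1 year | first VTE under this strategy |
| `prob_bleeding` | probability | 0.092 | 0.046 | 0.183 | 0.035 | beta | 1 year | any bleeding under this strategy |
| `prop_first_vte_pe` | proportion | 0.456 | 0.41 | 0.501 | 0.023 | beta | one-time | share of first VTE presenting as PE |
| `prop_major_bleed` | proportion | 0.285 | 0.256 | 0.313 | 0.015 | beta | one-time | share of bleeds that are major |
| `prop_ich_in_mb` | proportion | 0.231 | 0.208 | 0.254 | 0.012 | beta | one-time | share of major bleeds that are ICH |
| `cost_prophylaxis_cycle` | cost | 0 |  |  | 0 | fixed | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1547.15 | 1130.17 | 2131.71 | 0.162 | lognormal | 3 months | therapeutic drug cost, 3-month course |
| `cost_secondary_prophylaxis_cycle` | cost | 348.113 | 264.463 | 440.683 | 0.13 | lognormal | one-cycle | post-VTE prophylactic drug cost per cycle |

## Strategy `doacs`

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `prob_first_vte` | probability | 0.105 | 0.062 | 0.178 | 0.03 | beta | 1 year | first VTE under this strategy |
| `prob_bleeding` | probability | 0.144 | 0.072 | 0.285 | 0.055 | beta | 1 year | any bleeding under this strategy |
| `prop_first_vte_pe` | proportion | 0.37 | 0.333 | 0.407 | 0.019 | beta | one-time | share of first VTE presenting as PE |
| `prop_major_bleed` | proportion | 0.357 | 0.321 | 0.393 | 0.018 | beta | one-time | share of bleeds that are major |
| `prop_ich_in_mb` | proportion | 0.125 | 0.113 | 0.138 | 0.006 | beta | one-time | share of major bleeds that are ICH |
| `cost_prophylaxis_cycle` | cost | 160.372 | 100.144 | 275.423 | 0.258 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1048.52 | 654.152 | 1802.82 | 0.259 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `lmwhs`

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `prob_first_vte` | probability | 0.113 | 0.067 | 0.191 | 0.032 | beta | 1 year | first VTE under this strategy |
| `prob_bleeding` | probability | 0.154 | 0.077 | 0.306 | 0.058 | beta | 1 year | any bleeding under this strategy |
| `prop_first_vte_pe` | proportion | 0.441 | 0.397 | 0.485 | 0.023 | beta | one-time | share of first VTE presenting as PE |
| `prop_major_bleed` | proportion | 0.236 | 0.212 | 0.259 | 0.012 | beta | one-time | share of bleeds that are major |
| `prop_ich_in_mb` | proportion | 0.229 | 0.206 | 0.252 | 0.012 | beta | one-time | share of major bleeds that are ICH |
| `cost_prophylaxis_cycle` | cost | 348.113 | 264.463 | 440.683 | 0.13 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1547.15 | 1130.17 | 2131.71 | 0.162 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `apixaban` (inherits `doacs`)

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `prob_first_vte` | probability | 0.072 | 0.043 | 0.122 | 0.02 | beta | 1 year | first VTE under this strategy |
| `prob_bleeding` | probability | 0.143 | 0.071 | 0.284 | 0.054 | beta | 1 year | any bleeding under this strategy |
| `prop_first_vte_pe` | proportion | 0.417 | 0.375 | 0.458 | 0.021 | beta | one-time | share of first VTE presenting as PE |
| `prop_major_bleed` | proportion | 0.324 | 0.292 | 0.357 | 0.017 | beta | one-time | share of bleeds that are major |
| `cost_prophylaxis_cycle` | cost | 222.621 | 144.082 | 364.422 | 0.237 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1439.62 | 931.732 | 2356.6 | 0.237 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `rivaroxaban` (inherits `doacs`)

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `prob_first_vte` | probability | 0.132 | 0.078 | 0.224 | 0.037 | beta | 1 year | first VTE under this strategy |
| `prob_bleeding` | probability | 0.145 | 0.073 | 0.289 | 0.055 | beta | 1 year | any bleeding under this strategy |
| `prop_first_vte_pe` | proportion | 0.333 | 0.3 | 0.367 | 0.017 | beta | one-time | share of first VTE presenting as PE |
| `prop_major_bleed` | proportion | 0.421 | 0.379 | 0.463 | 0.022 | beta | one-time | share of bleeds that are major |
| `cost_prophylaxis_cycle` | cost | 98.122 | 56.205 | 186.424 | 0.306 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 657.415 | 376.572 | 1249.04 | 0.036 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `doacs_original` (inherits `doacs`)

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `cost_prophylaxis_cycle` | cost | 263.927 | 179.172 | 384.985 | 0.195 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1730.32 | 1165.27 | 2537.35 | 0.199 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `doacs_generic` (inherits `doacs`)

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `cost_prophylaxis_cycle` | cost | 91.697 | 46.067 | 133.967 | 0.272 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 599.515 | 300.389 | 877.713 | 0.274 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `lmwhs_original` (inherits `lmwhs`)

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `cost_prophylaxis_cycle` | cost | 350.8 | 277.87 | 440.683 | 0.118 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1590.55 | 1114.71 | 2131.71 | 0.165 | lognormal | 3 months | therapeutic drug cost, 3-month course |

## Strategy `lmwhs_generic` (inherits `lmwhs`)

| name | group | mean | 95% low | 95% high | sd | dist | period | meaning |
|---|---|---|---|---|---|---|---|---|
| `cost_prophylaxis_cycle` | cost | 327.801 | 219.037 | 434.677 | 0.175 | lognormal | one-cycle | prophylactic drug cost per cycle |
| `cost_treatment_3mo` | cost | 1447.07 | 900.384 | 1996.9 | 0.203 | lognormal | 3 months | therapeutic drug cost, 3-month course |
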