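# dyadnorm

Simulation and Bayesian time-series analysis of how perceptual norms emerge
through dyadic interaction in a dot-estimation task.

The package generates complete virtual experiments (laboratory pair /
individual sessions, an fMRI-style session with two programmed partners, and
an online 2×2 design), fits psychophysical estimation weights, quantifies
each participant's weight *stability* with a hierarchical local-level
state-space model, and decomposes estimation during interaction into
Baseline / Atypicality / Similarity components with time-varying
coefficients, WAIC model comparison, and posterior predictive checks.

## Modules

| module | contents |
| --- | --- |
| `dyadnorm.synthetic_data` | trial schedules, virtual participants, dyadic simulation, trial-table CSV I/O |
| `dyadnorm.psychophys` | linear / log-linear weight fits by ML, AIC comparison, trial exclusion, reward rule |
| `dyadnorm.agents` | Asch-type (unresponsive) and Sherif-type (lag-5 reciprocating) computer partners |
| `dyadnorm.stability` | hierarchical Bayesian local-level model; the per-participant stability index σ |
| `dyadnorm.decomposition` | time-varying Baseline + Atypicality + Similarity regression, WAIC ladder, PPC |
| `dyadnorm.convergence` | real vs shuffled pair convergence, ordering accuracy, t-tests / ANOVA / Holm–Bonferroni |

No external probabilistic-programming backend is required: MCMC is
implemented as Kalman-marginalised Metropolis-within-Gibbs (see
`dyadnorm._ssm` and `dyadnorm._mcmc`), with R-hat / ESS diagnostics via
ArviZ.

## CLI

```bash
# simulate an online 2x2 experiment for 8 virtual participants
dyadnorm simulate --design online --n-participants 8 --seed 7 --out trials.csv

# psychophysical weight fits per participant-phase
dyadnorm fit-weights --in trials.csv --out weights.csv --model both

# stability index for the pre-interaction phase
dyadnorm fit-stability --in trials.csv --phase pre --out sigma.csv --seed 1 \
    --chains 4 --draws 1000 --burnin 500

# time-varying decomposition for one participant (add --ladder for WAIC table)
dyadnorm fit-decomposition --in trials.csv --participant P001 \
    --phase interaction --partner-pre 0.61 --out posterior.json --seed 1

# run a programmed partner over a schedule
dyadnorm agents run --type sherif --bias 0.61 --schedule online --seed 1 \
    --out partner.csv

# pair-convergence report (real vs shuffled pairs)
dyadnorm analyze --in trials.csv --weights weights.csv --pairs pairs.json \
    --out report/
```

Trial tables are UTF-8 CSV with the fixed header
`participant_id,condition,phase,trial,dot_count,estimate,partner_estimate`;
missing estimates are empty fields.

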