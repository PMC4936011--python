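# Methods

## The model

`markovcea` evaluates two treatment strategies with a discrete-time Markov
cohort model. A closed cohort is distributed over mutually exclusive health
states; each cycle (1 year by default) it is redistributed by a per-strategy
row-stochastic transition matrix **P**:

```
occupancy[t] = occupancy[t − 1] · P,    occupancy[0] = cohort_size × initial
```

Per cycle t ≥ 1 the cohort accrues

```
cost_t = Σ_s occupancy[t, s] · c_s + Σ_e entries_e[t] · eventcost_e
qaly_t = Σ_s occupancy[t, s] · u_s · cycle_length
```

with `c_s` the strategy-specific annual cost of state *s*, `u_s` its utility
weight, and `entries_e[t]` the flow of persons into each event state (plus
explicit self-loop "repeat" flows, see below). Totals are discounted at an
annual rate *r* with weight `(1 + r)^(−k)`; under the default
`first-cycle-undiscounted` convention cycle 1 carries `k = 0`, under
`first-cycle-discounted` it carries `k = 1`. Cost-effectiveness of an
intervention against a comparator is summarized by the incremental
cost-effectiveness ratio ICER = ΔC/ΔE and the net monetary benefit
NMB(λ) = λ·E − C at willingness-to-pay λ. A negative ICER is never reported
bare: every comparison carries a dominance status and a cost-effectiveness
plane quadrant.

### Modelling assumptions

- **Closed cohort, no entries after cycle 0.** Rows of **P** sum to exactly 1
  (staying probability = 1 − declared exits), so persons are conserved to
  machine precision; the death state is absorbing.
- **Rewards accrue at cycle end** (occupancy after the t-th transition earns
  cycle-t rewards). No half-cycle correction is applied by default; passing
  `half_cycle_correction=True` to `accumulate_outcomes` averages the
  occupancy of adjacent cycles instead.
- **Event states are charged per episode, not per year.** A state with
  `event_cost > 0` charges that cost for every person *entering* it; an
  explicit self-loop transition on such a state is interpreted as a per-cycle
  repeat-episode rate: the flow `rate × occupancy[t−1]` re-incurs the episode
  cost without moving anyone (staying probabilities are unaffected).
- **Time-homogeneous transitions**: no age-dependent mortality, no
  time-varying probabilities, no tunnel-state expansion beyond the explicit
  one-cycle convention used for AUR below.

## The bundled BPH model

The shipped parameterization (`bph_reference_model()`,
`data/bph_model.yaml`) compares fixed-dose dutasteride–tamsulosin (FDCT)
against dutasteride monotherapy (DM) for benign prostatic hyperplasia in a
cohort of 2,862,363 men aged 50, entering in the mild-symptom state
(IPSS 0–7) and followed for ten 1-year cycles at a 6 %/yr discount rate, with
a willingness-to-pay threshold of US$2450/QALY. Seven states: healthy, mild,
moderate, severe (IPSS severity bands), acute urinary retention (AUR),
TURP (transurethral resection of the prostate), death.

Key conventions where the source parameter set is under-determined:

- The combined "moderate/severe → AUR" and "moderate/severe → TURP" rates
  apply identically from both the moderate and the severe state.
- The single background death rate (0.013/yr) applies from every alive
  state under both strategies; no state-specific excess mortality.
- **AUR** is a one-cycle event state: survivors return to the severe state
  the next cycle (AUR → severe = 1 − 0.013). Its utility is the severe-state
  utility plus the AUR disutility (0.382 − 0.145 = 0.237).
- **TURP** is a long-stay state (exits only to death) with utility 0.833; the
  "repeat TURP" rate 0.48 is a per-cycle self-loop flow that re-incurs the
  US$484.97 procedure cost each repeat.
- Annual treatment cost accrues only in the moderate and severe states
  (US$223.53/yr under DM, US$338.82/yr under FDCT — the single printed
  moderate-row value is read as the FDCT column, and the DM moderate cost is
  set equal to its severe value); watchful waiting (mild, healthy) is
  costless, with consultation cost folded into the annual treatment cost.
  AUR episodes cost US$29.41. All values are overridable in the config file.
- An alternative entry preset (`start_state="healthy"`, incidence-driven
  entry with healthy → mild 0.29) and an optional cohort `incidence_scaling`
  multiplier (default off) are provided.

With these conventions the model reproduces every *directional* published
claim — FDCT is more costly and more effective (north-east quadrant), avoids
AUR and TURP events, and its ICER falls when the horizon is extended from 10
to 15 years — but not the published absolute totals, which depend on entry,
aftermath and timing conventions the source tables do not pin down. The
published summary totals are therefore bundled separately
(`reference_reported_results()`) and used only for arithmetic cross-checks
(differences and ratios over the printed table).

### Known limitation

Because the TURP state is near-absorbing with a relatively high utility
(0.833), a large share of the DM cohort accumulates there, and the one-way
sensitivity of the ICER to the TURP-state utility exceeds its sensitivity to
the moderate-state utility. Published sensitivity results for this parameter
set report the moderate-state utility as the most influential utility, which
implies a different (unstated) post-TURP structure; users who need that
behaviour should supply explicit TURP exit transitions in the config.

## Sensitivity analysis

**One-way DSA** (`standard_dsa_scenarios` + `run_dsa`): discount rate over
{0.01, …, 0.06}; entry at moderate and at severe; horizon 5 and 15 cycles;
a 570,000-person cohort variant (immaterial to the ICER — the engine is
linear in cohort size); every non-death utility and every nonzero cost at
±20 %. Utility scenario values are capped at 1.0, the utility upper bound,
so the +20 % scenario on a full-health state is a null scenario. Scenarios
producing an invalid spec are recorded as failed entries and the run
continues. `tornado_table` aggregates scenarios per parameter group into
low/high ICER bars ordered by maximum absolute deviation, with a zero-width
baseline entry always present.

**PSA** (`run_psa`): each uncertain parameter is drawn independently —
probabilities and utilities from beta distributions, costs from gamma
distributions, method-of-moments with mean at the baseline value and SD =
20 % of the mean (matching the DSA span; `sd_fraction` configurable, 0
reproduces the baseline exactly). Degenerate baselines (probabilities or
utilities at 0 or 1, zero costs) are held fixed. Transition parameters that
share a (from, to, baseline) triple across strategies — e.g. the background
death rate — receive a common draw, so strategy-shared uncertainty cancels
in ΔC and ΔE. If a drawn exit row sums above 1 it is rescaled
proportionally (default) or redrawn (`renormalize=False`, bounded, with
proportional scaling as the terminal fallback). Both strategies are
evaluated on the same drawn spec per draw; results are reproducible bitwise
from the seed (numpy `default_rng`).

**CEAC** (`compute_ceac`): at each willingness-to-pay λ, the probability of
cost-effectiveness is the fraction of draws with λ·ΔE − ΔC > 0. With zero
sampling SD the curve is a step function jumping at the deterministic ICER.

## Synthetic models

`generate_random_model` draws structurally valid random specs for property
testing: transition rows are generated directly as normalized weight vectors
(so invalid exit sums cannot occur), utilities are uniform in [0, 1], costs
nonnegative, exactly one absorbing death state, deterministic under a fixed
seed. These models exercise the engine's structural guarantees —
conservation, matrix-power equivalence, discount monotonicity, cohort
linearity, save/load round-trips — but make no attempt at clinical realism:
passing property tests shows the engine is correct, not that any particular
clinical parameterization is.

## Numerical choices and problem sizes

- Row-stochasticity enforced to 1e−12; conservation asserted to 1e−6
  relative; trace vs matrix-power oracle to 1e−9 relative.
- Exit-sum validation tolerance 1e−9; initial-distribution sum tolerance
  1e−9 absolute.
- ICERs are displayed at 2 decimal places; CSVs carry full precision.
- Property suites use 200 random models for the structural guarantees,
  10,000 draws for the sampling moment checks, and 1000 PSA draws for the
  acceptability analyses; the 7-state model evaluates in well under a
  millisecond per strategy, so the whole suite runs in seconds.
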