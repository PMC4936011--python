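# markovcea

A discrete-time Markov cohort engine for cost-effectiveness analysis (CEA)
of competing treatment strategies, aimed at health economists and modellers
who want a declarative, reproducible alternative to spreadsheet Markov
models. Models are plain YAML/JSON documents — health states, per-strategy
annual transition probabilities, per-state costs and utilities, discounting,
cohort — and the package computes cohort traces, discounted costs and
QALYs, incremental cost-effectiveness ratios (ICER), net monetary benefit
(NMB), one-way deterministic sensitivity analysis (DSA) with tornado tables,
and seeded probabilistic sensitivity analysis (PSA) with cost-effectiveness
acceptability curves (CEAC).

The core quantities, in standard CEA notation:

- cohort trace: `x_t = x_{t−1} P`, with `P` the row-stochastic annual
  transition matrix of a strategy and `x_0` the entry distribution;
- discounted totals: `C = Σ_t (1+r)^{−k(t)} cost_t`,
  `E = Σ_t (1+r)^{−k(t)} qaly_t`;
- `ICER = ΔC / ΔE` between intervention and comparator, with explicit
  dominance status and cost-effectiveness-plane quadrant;
- `NMB(λ) = λ·E − C`; CEAC at λ = fraction of PSA draws with `λ·ΔE − ΔC > 0`.

The package ships a fully parameterized benign prostatic hyperplasia (BPH)
model comparing fixed-dose dutasteride–tamsulosin (FDCT) with dutasteride
monotherapy (DM) over a Nigerian cohort of 2,862,363 men aged 50: seven
IPSS-banded states (healthy, mild, moderate, severe, acute urinary
retention, TURP, death), ten 1-year cycles, 6 %/yr discounting, WTP
threshold US$2450/QALY. See `docs/methods.md` for the model conventions and
their limitations.

## Worked example

```python
import markovcea as m

spec = m.bph_reference_model()          # or m.load_model_spec("model.yaml")
dm   = m.evaluate_strategy(spec, "DM")
fdct = m.evaluate_strategy(spec, "FDCT")
res  = m.compute_icer(fdct, dm)
print(f"dC {res.delta_cost:,.2f}  dE {res.delta_effect:,.2f} "
      f"ICER {res.formatted_icer()}  {res.status}")
print(f"TURPs avoided {dm.turp_count - fdct.turp_count:,.0f}  "
      f"AURs avoided {dm.aur_count - fdct.aur_count:,.0f}")
```

prints

```
dC 307,844,488.19  dE 628,320.23 ICER 489.95  trade-off-NE
TURPs avoided 2,003,310  AURs avoided 585,598
```

FDCT costs US$307.8 million more than DM over ten years but yields 628,320
additional discounted QALYs — an ICER of US$489.95 per QALY gained, well
below the US$2450/QALY threshold — while avoiding about 2.0 million TURP
procedures and 0.59 million AUR episodes. (Absolute totals depend on the
entry and aftermath conventions described in `docs/methods.md`; the
direction of every comparison is robust to them.)

The same pipeline from the shell:

```sh
markovcea run --out-dir out            # traces + incremental summary CSVs
markovcea dsa --out-dir out            # one-way scenarios + tornado CSVs
markovcea psa --n-draws 1000 --seed 7 --out-dir out   # draws + CEAC CSVs
markovcea validate --spec model.yaml   # findings, if any
markovcea fixture --out bph.yaml       # dump the bundled BPH model
```

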