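# Methods

## Model structure

`scdsim` implements a discrete-time, individual-level competing-risks
model of progression from subjective cognitive decline (SCD) to mild
cognitive impairment (MCI). Time advances in one-year steps over a
five-year horizon. Each patient occupies one of three states — at risk
(cognitively stable), progressed to MCI, or dropped out — and the two
event states are absorbing. Within a year, progression and dropout are
resolved in a *single* categorical draw with probabilities
`(h_i, d, 1 − h_i − d)`; this competing-risks formulation avoids the
order-dependence that sequential within-year draws would introduce,
and no ordering is part of the model definition.

The per-patient hazard `h_i` is fixed at baseline and constant over
the horizon: the adherence tier and risk-factor profile are drawn once
and never re-randomised, and the intervention's benefit does not
compound over time. Cumulative benefit emerges through cumulative
incidence, not through a time-varying hazard.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `baseline_annual_risk` | 0.10 | annual SCD→MCI progression probability, untreated |
| `pdt_rrr` | 0.30 | relative risk reduction conferred by the therapeutic |
| `adherence_mix` | 0.70 / 0.20 / 0.10 | probability of full / partial / no adherence |
| `adherence_benefit` | 1.0 / 0.5 / 0.0 | fraction of `pdt_rrr` received per tier |
| `dropout_rate` | 0.02 | annual dropout probability among at-risk patients |
| `max_total_reduction` | 0.80 | cap on the combined relative reduction |
| `n_patients`, `years` | 10,000, 5 | cohort size and horizon |
| `seed` | 42 | master RNG seed |
| `mode` | `scaled` | risk-factor modification bookkeeping (see below) |

The packaged risk-factor table (`scdsim/data/risk_factors.tsv`) holds
the twelve 2024 Lancet-Commission factors with published parameters:
per factor a prevalence in adults aged ≥60, the relative risk
reduction attainable by modifying it, a modifiability flag, and an
intervention effectiveness. The Commission's 2024 list names fourteen
factors; the two newest (high LDL cholesterol, untreated vision loss)
lack published modelling parameters and are therefore not shipped —
users can append rows to a copy of the file. All fractions are stored
internally in [0, 1]; the loader accepts both `"30%"` and `0.30`.

Two non-modifiable factors (low education, traumatic brain injury)
carry an RRR in the table but never alter the hazard: the model
applies reductions only where an intervention can act, and models no
risk *elevation* for carriers. They remain in patient profiles for
reporting. Likewise, risk-factor modification is not gated by
adherence tier — only the therapeutic's own RRR is adherence-
modulated; the exploratory switch `gate_factors_by_adherence` scales
factor effects by the tier's benefit fraction for sensitivity use.

### Dropout: 2% vs 5%

The source material states a 5%/year dropout in one place while its
reported outcomes show dropout averaging ~2%/year and accumulating to
~10% over five years — figures only a ~2% annual rate reproduces, and
which a 5% rate would push to ~20% cumulative. The package defaults to
0.02 and exposes the literal 5% reading as
`SimulationConfig.with_methods_literal_dropout()`.

### Modification modes

- **scaled** (default): every present modifiable factor contributes
  the deterministic multiplier `1 − RRR·effectiveness` — the literal
  reading of the published hazard formula.
- **bernoulli**: modification of each present modifiable factor
  succeeds once, at baseline, with probability `effectiveness`; a
  success contributes `1 − RRR`, a failure contributes 1. This is the
  equal-expectation variant needed to give "number of successfully
  modified risk factors" a discrete meaning for subgroup and
  dose-response analyses. The success draw is a stable patient
  attribute, not re-drawn annually.

Per factor the two modes have identical expected multipliers,
`eff·(1−rrr) + (1−eff) = 1 − rrr·eff`, so the population mean hazard
and the entire year-1 trajectory coincide to floating precision.
Beyond year 1 the success mixture enters the survival power
nonlinearly, so the modes differ at second order (~4×10⁻⁵ on year-5
fractions under defaults); the tests assert the exact year-1 and
mean-multiplier identities at 1e-12 and bound the convexity gap.

## Exact enumeration oracle

Factors are assigned independently, so the baseline state space is a
product measure over per-factor ternary states — absent
(`1 − prev`), present-and-modified (`prev·eff`),
present-and-unmodified (`prev·(1−eff)`); scaled mode collapses the
last two — crossed with the three adherence tiers. Under the default
table this is at most 3¹⁰ × 3 ≈ 1.8 × 10⁵ weighted states, each of
which evolves in closed form:

```
stable(t) = (1 − h − d)^t
mci(t)    = h/(h+d) · (1 − (1 − h − d)^t)
```

The weighted mixture is the *exact* expectation of the Monte Carlo
engine's cumulative fractions, which makes the oracle the acceptance
reference for the simulator rather than a second simulation.
Enumeration refuses tables whose state space exceeds ~2 × 10⁷ states
(≈15 modifiable factors in bernoulli mode) and directs users to the
Monte Carlo engine.

Degenerate cases are handled explicitly: `h + d = 0` leaves the whole
cohort stable; a homogeneous untreated cohort reduces to
`1 − (1 − h0)^t`, giving the 40.95% five-year untreated comparator,
and with dropout the absorbed mass splits as `h : d`.

## Randomness and reproducibility

One `numpy.random.default_rng(seed)` stream is consumed in patient
order: per patient, factor-presence draws in table order (plus
success draws in bernoulli mode), one adherence draw, then up to
`years` annual draws, stopping at absorption. Identical seed and
configuration reproduce per-patient records bit for bit, which the
run manifest exploits: every CLI run writes its fully resolved
configuration (including the risk table) to `manifest.json`, and
`config_from_manifest` rebuilds the exact run.

## Numerical choices

- Report tables round percentages half-away-from-zero to integers, so
  a year's row may sum to 100 ± 1; raw fractions are always emitted
  alongside.
- The combined multiplier is floored at `1 − max_total_reduction`.
  No value for the cap was published; 0.80 was chosen and is provably
  non-binding under the default table (the extreme all-success,
  full-adherence multiplier is 0.5097 > 0.20), so it only constrains
  user-supplied tables with aggressive parameters.
- Adherence-mix validity is enforced to 1e-12; hazard + dropout ≤ 1
  is validated both at configuration time (via the baseline, which
  bounds every per-patient hazard) and per annual draw.
- Subgroup bins nobody occupies are reported with `n = 0` and
  progression `NaN` — empty, not zero.

## What the simulation does and does not emulate

The generator emulates the published study conditions: independent
factor carriage at fixed prevalences, a three-tier static adherence
mix, constant hazards, and dropout as a competing event. It does not
model risk-factor co-occurrence or clustering, hazard elevation in
factor carriers, time-varying adherence or factor onset,
re-engagement after dropout, or mortality. Passing tests therefore
certify internal consistency of this idealised model — simulator
against exact expectation — not calibration to any real cohort.

Two reported figures are not recoverable from the published
parameters and are deliberately not fitted: the year-5
65 / 25 / 10% stable / MCI / dropout split (the implemented model's
exact expectation is 61.7 / 30.0 / 8.3%, and no stated dropout
reading closes the gap) and the 18% five-year progression among
fully adherent patients with ≥3 modified factors (the analytic
conditional for that stratum is ≈26.6%; the qualitative ordering —
well below the 40.95% untreated rate, decreasing in the number of
modified factors — is reproduced and tested instead). Problem sizes
in the test suite (cohorts of 10,000, a brute-force cross-check at
10⁶ on a two-factor table, a 20-seed dose-response panel) were chosen
to keep three-standard-error checks meaningful at interactive run
times.
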