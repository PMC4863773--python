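# Methods

## Model structure

A discrete-time Markov cohort model with five states — alive in NYHA
functional class I, II, III or IV, and dead — and yearly cycles. Every
living class carries a row of 10 per-cycle outcome probabilities:
transition to each living class split into no-hospitalization and
hospitalization variants (8 entries), cardiovascular death, and
non-cardiovascular death. Deaths within a cycle are mutually exclusive
with the non-fatal hospitalization outcomes; a hospitalization outcome
means at least one heart-failure admission with survival to cycle end.
The NYHA IV row of the shipped table equals the NYHA III row, a structural
assumption carried through everywhere NYHA III inputs are perturbed
(sensitivity analyses mirror IV to III whenever the base table ties them).

The cohort starts 100% in NYHA II at age 68 and runs for a 10-year horizon
(both configurable).

## Treatment effects

Hazard ratios are applied by **direct probability multiplication** to the
per-cycle entries, not through a rate-to-probability conversion. The
transform must redistribute the freed probability mass somewhere for rows
to remain probability rows; the conventions here are:

- hospitalization entries ×HR(hosp); the freed mass moves to the
  *same-destination* no-hospitalization entry, so the class distribution is
  unchanged and only the hospitalization split moves;
- cardiovascular death ×HR(CV death); the freed mass is spread
  proportionally over the eight living entries. In the degenerate case of
  a row with zero living mass, the freed mass stays in the origin class's
  no-hospitalization entry.

Two death-adjustment modes exist: the default `cv-only` (non-CV death
untouched) and `all-cause-split` (total death scaled by the all-cause HR
with cause shares preserved); the choice is a config switch because the
published HRs cover both framings without stating which applies to non-CV
death.

The usual-care arm is the entry-wise convex mixture
`f·treated + (1−f)·placebo` per class, where `f` is the class-specific
spironolactone usage fraction and the treated row carries eplerenone's
efficacy (the conservative assumption that spironolactone is equally
effective). Mixture endpoints are exact: `f = 0` reproduces the placebo
row bit-for-bit, `f = 1` the treated row.

## Age trend

Background ageing is modelled as a relative multiplier per integer year of
age applied to both death entries, with living entries rescaled
proportionally so rows still sum to 1; total death mass is capped at 1.
The multiplier is normalized to 1.0 at the baseline age of 68, so cycle 1
is untouched. The **shipped trend is a stand-in**: a smooth exponential
with a default growth of 9%/year of age, the magnitude of all-cause
mortality growth in late-life national life tables, tabulated for ages
68–110 and extended log-linearly beyond (queries never error below age
110). A transcribed per-age table can be supplied in the config instead.
The trend is applied before the treatment transform each cycle (trend
describes background risk); a config flag flips the order for sensitivity
checking.

## Accrual and discounting

Cycle-start accrual: everyone alive at the start of a cycle earns the full
cycle's life-year, utility-weighted QALY, background cost, and arm-specific
drug/monitoring cost, so deaths during a cycle still accrue that cycle's
person-time. No half-cycle correction is applied; a `cycle-end` accrual
switch exists for sensitivity checking. Event costs (hospitalization,
death) accrue in the cycle the transition occurs.

Discounting is geometric at 5%/year starting from the second cycle: cycle
1 has factor 1, cycle c ≥ 2 has (1.05)^−(c−1). Event counts per 1000
patients are undiscounted; life-years, QALYs and costs are reported both
ways, with discounted values feeding the ICERs.

Monitoring costs for eplerenone follow the convention cycle 1 = 35.60 AUD
(the two initiation tests), cycles ≥ 2 = 71.20 AUD (four yearly tests); a
config switch makes year one accrue both, since the published costing is
ambiguous about year-one totals. Spironolactone users accrue 45.29 AUD
drug and 71.20 AUD monitoring per cycle, weighted by the class's usage
fraction. The hospitalization cost cap (`hosp_events_per_cycle_cap`,
default 1) is a *costing* multiplier only; reported event counts are raw
hospitalization transitions.

Money is carried as floating-point 2014 AUD; unit costs are exact to well
below a cent, and no inflation logic exists in the package.

## Incremental outcomes

ICERs are computed from full-precision discounted deltas (display rounding
happens only in the reporting layer — whole AUD for ICERs, one decimal for
life-years/QALYs/NNT). Dominance is classified from the sign quadrant of
(ΔC, ΔE). A zero effect delta yields an undefined (NaN) ratio, never an
exception. NNT is the reciprocal per-person cumulative risk difference
over the horizon (1000 / events averted per 1000); both raw and
display-rounded values are emitted because rounding conventions for NNT
vary across publications.

## Sensitivity analyses

**DSA** varies one parameter at a time: published 95% CIs for the three
hazard ratios, ±50% of base for utilities (capped at 1), unit costs and
spironolactone fractions, and 0–7.5% for the discount rate. The tornado
table orders parameters by ICER-range width; infeasible bounds are
recorded as NaN and the run continues.

**PSA** samples, per iteration: utilities from beta distributions
(method-of-moments on mean = base, SE = range/3.92; infeasible moments
fall back to uniform with a warning), costs from uniform distributions
over the ±50% range, and each nonzero transition entry of rows I–III from
a triangular distribution with mode at base over the same relative range
(IV mirrors III). Sampled rows are renormalized entry-wise; unchanged
rows are left bit-identical so a zero-width PSA reproduces the base case
exactly. Eplerenone and spironolactone drug/monitoring costs are fixed.
Entries are sampled independently (no Dirichlet coupling) because no joint
uncertainty structure is published for such tables; renormalization keeps
every draw a valid probability row.

Each iteration draws from its own counter-derived substream
(`SeedSequence([seed, i])`), so runs are bit-reproducible given the seed
and independent of execution order. Outputs: the incremental scatter, the
CEAC over a 0–100k AUD threshold grid (nondecreasing by construction),
the fraction cost-effective at 50,000 AUD/QALY, percentile (2.5, 97.5)
ICER intervals computed over the positive-effect quadrant (with the
quadrant composition reported), and net-monetary-benefit intervals —
quadrant-restricted ICER percentiles are the transparent reading of a
"95% interval of iteration ICERs", which is otherwise ill-defined when
effect deltas change sign.

## Scenarios

Registered, pre-declared transforms of the base case: 3% discounting;
2- and 4-year horizons; all hazard ratios reverting to 1 from cycle 2
(effect waning — interpreted as *all three* HRs since the published
description does not name one, with a per-HR variant available via
`hr_unity_from_cycle` plus custom HR sets); two hospitalization events
costed per hospitalization cycle; every CV death costed at a full
admission (3642 AUD); and per-year placebo tables for cycles 1–4 with the
weighted average thereafter (errors cleanly when the pack carries no
per-year tables, as the shipped one does not).

## Synthetic microsimulation and parameter recovery

The microsimulator draws individual patient trajectories with per-cycle
multinomial draws over the same 10 outcomes, from the same per-cycle
tables the cohort engine builds — no latent competing-risk times — so the
cohort trace is the exact expectation of simulated state frequencies and
the two implementations check each other. Event logs are flat CSV tables
(patient_id, cycle, from_state, to_state, hospitalized, death_cause).

The estimator recovers transition rows by maximum-likelihood multinomial
counting over at-risk person-cycles; never-observed rows are flagged
missing, not invented. The recovery suite simulates from the *raw*
(constant, untrended) placebo table so the weighted-average estimator
targets exactly the configured table, then reruns the full pipeline on the
estimate and reports relative errors of per-arm outcomes and the ICER.

What the synthetic generator emulates: the per-cycle multinomial
transition structure, class-dependent event rates, absorbing death. What
it does not: enrolment waves, censoring, covariate heterogeneity,
within-cycle event timing. Passing oracle tests therefore demonstrates
internal consistency of the model machinery, not fidelity of the shipped
stand-in inputs to any real cohort.

## Numerical choices

- Row validation tolerance 1e-9; transforms renormalize to hold 1e-12.
- Rows whose transcription misses 1 by ≤ 0.005 (printed rounding) are
  proportionally renormalized at load with a logged warning; larger
  deficits are hard errors naming the row and its sum.
- The oracle agreement test applies the 3-SE binomial band per occupancy
  entry with multiplicity control (across ~110 simultaneous comparisons a
  handful of 3-SE exceedances are expected under the null; 5 SE marks
  genuine bias).
- Identity transforms (all HRs = 1, trend multiplier 1, mixture fractions
  0/1, zero-width PSA draws) are guaranteed bit-exact by early-exit paths.

## Problem sizes

The base case is a 10-cycle × 4-row recursion (milliseconds). Default
analysis sizes: PSA 10,000 iterations (~1 minute on one CPU), oracle
comparison and parameter recovery at 50,000 simulated patients (~10 s
each). Unit tests use smaller sizes chosen to keep binomial error bounds
meaningful.

## Known limitations

- The shipped transition table and age trend are synthetic stand-ins;
  headline numbers from the shipped pack characterize the machinery, not a
  published analysis. Exact reproduction of a specific study requires
  transcribing its per-class table and age-trend values into a config.
- Direct HR-on-probability multiplication is faithful to common modelling
  practice for such analyses but is not invariant to cycle length; rates
  would be.
- No utility decrement for hospitalization (by design), no within-cycle
  event sequencing, no heterogeneity in the cohort engine.
- NNT published alongside event counts in the literature often follows
  rounding conventions that cannot be reproduced from the printed counts;
  both raw and rounded NNTs are emitted instead of guessing.
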