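# chf-cea

A Markov cohort cost-effectiveness model of **eplerenone versus usual care
in chronic heart failure with NYHA class II symptoms**, from an Australian
healthcare-system perspective (2014 AUD), with deterministic and
probabilistic sensitivity analysis, scenario analyses, and a patient-level
microsimulation that serves as the model's independent oracle.

## Who this is for

Health-economics modellers and biostatisticians who want a tested,
scriptable implementation of the classic decision-analytic pipeline for
heart-failure disease progression: a five-state NYHA Markov model with
hospitalization and death events, treatment effects applied as hazard
ratios, a mixed-comparator ("usual care") arm, and the standard
cost-effectiveness outputs (ICERs, NNT, tornado diagrams, CEAC).

## The model

Five health states: alive in NYHA class I, II, III or IV, and dead
(absorbing). From each living class a patient faces **10 mutually exclusive
yearly outcomes** — move to any of the four living classes either without or
with a heart-failure hospitalization (8 outcomes), cardiovascular death, or
non-cardiovascular death. The cohort starts 100% in NYHA II at age 68 and
is propagated for 10 one-year cycles:

- **Eplerenone arm (EG)** — placebo transition rows transformed by hazard
  ratios: HF-hospitalization entries ×0.58 (95% CI 0.47–0.70), CV death
  ×0.76 (0.61–0.94); freed hospitalization mass returns to the matching
  no-hospitalization entry, freed death mass is spread proportionally over
  living entries so each row still sums to 1.
- **Usual-care arm (UCG)** — a per-class convex mixture: the fraction on
  spironolactone (0% / 43.7% / 93.7% / 93.7% for classes I–IV) is assigned
  eplerenone's efficacy, the rest behaves as placebo.
- **Age trend** — CV and non-CV death risks are scaled by a relative
  mortality multiplier per year of age, normalized to 1.0 at 68.
- **Accrual** — everyone alive at cycle start earns that cycle's life-year,
  utility-weighted QALY (utilities 0.815 / 0.720 / 0.590 / 0.508),
  background cost (151 / 175 / 226 / 242 AUD) and drug/monitoring costs;
  hospitalization transitions cost 7136 AUD, deaths 1821 AUD
  (= 0.5 × 3642, half of deaths occurring in hospital). Costs and effects
  are discounted at 5%/year from the second cycle.

Incremental results are reported as ICERs — ΔC/ΔE in AUD per year of life
saved and per QALY gained — plus events averted per 1000 patients and NNT.

> **Stand-in inputs.** The per-class placebo transition table and the
> age-trend table shipped in the base-case pack are clearly-flagged
> synthetic stand-ins (see `src/chf_cea/data/base_case.yaml`); all scalar
> inputs (HRs, mixture, utilities, unit costs, discounting) are the
> published base-case values. Swap in transcribed tables via your own YAML
> pack to reproduce a specific published analysis.

## Worked example

```bash
python examples/base_case.py
```

prints (shipped stand-in pack):

```
                        eplerenone  usual care
life-years (disc.)            5.37        5.23
QALYs (disc.)                 3.71        3.61
total cost (AUD)             12900        6178
hospitalizations/1000          493         597
deaths/1000                    780         802

incremental cost   :     6722 AUD per person
incremental LY     :    0.136 years
incremental QALYs  :    0.094
ICER               :    49488 AUD per year of life saved
                        71355 AUD per QALY gained
events averted/1000: 104 hospitalizations, 22 deaths (NNT 9.6 and 45.7)
```

Adding eplerenone on top of a usual-care arm that already gives most
severe-class patients spironolactone (assumed equally effective) buys a
modest survival/QALY gain at the drug's full cost — hence a per-QALY ICER
well above the per-YoLS one, and both sensitive to the transition inputs.

Other examples: `sensitivity_analysis.py` (tornado + PSA/CEAC),
`scenario_analyses.py` (discounting, horizons, effect waning, costing
variants), `microsimulation_oracle.py` (patient-level simulation and
parameter recovery).

The same capabilities are exposed as a CLI:

```bash
chf-cea run --out results/
chf-cea psa --iterations 10000 --seed 1 --threshold 50000
chf-cea scenario --name horizon_4y
chf-cea simulate --n 10000 --seed 1 --arm UCG
chf-cea validate --config my_pack.yaml
```

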