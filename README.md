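# pvsignal

Disproportionality signal detection for spontaneous adverse-event reports,
built around the analysis of cardiovascular events reported under inhaled
long-acting muscarinic antagonists (LAMAs — aclidinium, glycopyrronium,
tiotropium, umeclidinium) in a FAERS-like database. It is written for
pharmacovigilance analysts and biostatisticians who need the full chain —
case deduplication, drug-name normalization, event-term grouping,
active-comparator 2×2 tables and reporting odds ratios — as tested,
scriptable library code rather than a spreadsheet.

## The statistic

For a target exposure and a comparator, deduplicated reports are
cross-classified by exposure and by whether any of their preferred terms
falls in the event group of interest (case-level counting: a report with
three cardiac terms counts once):

|            | event | no event |
|------------|-------|----------|
| target     | a     | b        |
| comparator | c     | d        |

The reporting odds ratio is `ROR = (a/b)/(c/d)` with the 95% Wald interval
on the log scale,

```
exp( ln(ROR) ± 1.959964 · sqrt(1/a + 1/b + 1/c + 1/d) ),
```

and a *signal* is declared when the CI lower bound exceeds 1 and a ≥ 3.
Zero cells are a hard error by default; an optional Haldane–Anscombe 0.5
correction is available for exploratory output.

## Layout

- `src/pvsignal/` — the library: `report_model` (report I/O, dedup, date
  window), `vocabulary` (drug dictionary, event groups), `disprop_stats`
  (2×2 tables, ROR/CI/signal, stratification), `study_pipeline`
  (config-driven end-to-end runs), `synthetic_data` (ground-truth
  generator and the deterministic published-marginals fixture).
- `analysis/` — numbered drivers that produce the tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline estimates (below).

## Worked example

```python
from pvsignal import TwoByTwo, ror, round_half_up

# aclidinium vs tiotropium, cardiac-disorder cases: 188/1254 vs 1238/12472
res = ror(TwoByTwo(188, 1254 - 188, 1238, 12472 - 1238))
print(round_half_up(res.ror), round_half_up(res.ci_lower),
      round_half_up(res.ci_upper), res.is_signal)
# 1.6 1.36 1.89 True
```

i.e. cardiac-disorder events are reported ~1.6× more often (odds scale)
under aclidinium than under tiotropium, the interval excludes 1, and with
188 cases the result qualifies as a signal. The same result comes from the
shell: `pvsignal ror --a 188 --b 1066 --c 1238 --d 11234` prints
`ROR 1.60 (95% CI 1.36-1.89) n_cases=188 signal=yes`.

Running `python analysis/01_reproduce_published_results.py` executes the
whole pipeline on the deterministic fixture and prints

```
reports examined: 18208, cardiac-disorder cases: 2261 (12.4%)

forest table (vs tiotropium):
  aclidinium_vs_tiotropium         ROR 1.60 (1.36-1.89)  n_cases=188  signal=yes
  glycopyrronium_vs_tiotropium     ROR 2.26 (1.99-2.57)  n_cases=376  signal=yes
  umeclidinium_vs_tiotropium       ROR 1.95 (1.73-2.19)  n_cases=459  signal=yes
```

`analysis/02_synthetic_combination_study.py` runs the comparison designs
that have no published component counts (combination products vs
monotherapy, tiotropium vs ipratropium) on synthetic data with known odds
multipliers, and `analysis/03_calibration_and_recovery.py` checks CI
coverage, parameter recovery and the null false-signal rate of the signal
rule.

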