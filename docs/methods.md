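# Methods

## Study design

The package implements an active-comparator disproportionality analysis of
spontaneous adverse-event reports. Reports mentioning an inhaled muscarinic
antagonist (alone or in fixed-dose combination with a long-acting
β2-agonist and, for triple therapy, an inhaled corticosteroid) are
extracted by generic-name matching, deduplicated to one record per case,
restricted to a receipt-date window (default January 2020 – 30 September
2023), and cross-classified against a comparator cohort for each event
group. The headline contrasts compare each newer LAMA (aclidinium,
glycopyrronium, umeclidinium) against tiotropium, the oldest and most
widely reported product in the class; combination products are compared
against their LAMA monocomponent; a rest-of-database comparator is also
available.

## The estimator

The reporting odds ratio for a 2×2 table (a, b, c, d) is
`(a/b)/(c/d)`, with the log-scale Wald 95% interval
`exp(ln ROR ± 1.959964·SE)`, `SE = sqrt(1/a + 1/b + 1/c + 1/d)`.
A result is a *signal* when the lower bound strictly exceeds 1 and a ≥ 3.
Counting is case-level: a report with several qualifying terms contributes
one case, because spontaneous reports routinely list more than one event.
The direction convention puts the comparator (tiotropium, or the
monocomponent) in the denominator; with that convention the published
forest values reproduce exactly from the published cohort counts.

Numerical choices:

- **CI method.** The Wald interval on the log scale with z = 1.959964 was
  chosen because it reproduces, from cohort counts alone, all published CI
  bounds after half-up rounding to 2 decimals. Score or exact intervals
  would differ in the third decimal at these counts.
- **Zero cells.** A zero cell makes the estimate or its SE undefined; the
  default is a hard error naming the cell (the ≥3-case rule makes tiny
  counts uninformative for signals anyway). `correction="haldane_half"`
  adds 0.5 to all four cells whenever any cell is zero, for exploratory
  output; the reported case count stays uncorrected.
- **Rounding.** Half-up (via `decimal`), 2 decimals for RORs/CIs and 1 for
  percentages, display only — internal values are never rounded.
- **Multiplicity.** No adjustment is made across the many drug–event
  contrasts; forest tables are screening output, not confirmatory tests.
- **Stratification.** Per-stratum tables (sex or age band) are estimated
  independently; no Mantel–Haenszel pooling. Strata with an empty cohort
  produce no row; strata with a zero cell are reported with their counts
  and a degeneracy reason but no estimate.

## Data handling

- **Deduplication.** Spontaneous cases are resubmitted as versions. One
  report per case is kept: highest version, ties broken by latest receipt
  date, then largest report id. The rule is idempotent and deterministic.
  Whether and how the original analysis deduplicated is not stated in the
  source; latest-wins is standard practice for FAERS-like data.
- **Age bands.** Ages are stored as bands (<18, 18–64, 65–85, >85, NS)
  because that is how the source tabulates them; an age-in-years column is
  binned with 85 assigned to the 65–85 band. Unparseable sex/age map to NS.
- **Partial dates.** Dates missing a day (or month) are coerced to the
  first of the period so window filtering is total.
- **Exposure roles.** By default only suspect-role mentions (primary,
  secondary, or unknown) define exposure; concomitants are excluded, the
  standard disproportionality convention. Combination exposure is
  recognized only through combination-product dictionary entries, not
  inferred from co-occurring monocomponents; each report contributes to at
  most one cohort of a contrast, and reports exposed to both sides are
  dropped (`exclusive=True`, logged) since the source does not state its
  handling.
- **Vocabulary.** MedDRA is licensed, so event groups are user-supplied
  configuration. The bundled demo vocabulary carries ~27 cardiac preferred
  terms assigned to a broad cardiac-disorders group and three narrower
  subgroups (arrhythmias, cardiac failure, ischemic heart disease, the
  subgroup terms being subsets of the broad group); it preserves the
  structure, not the licensed content, of the real terminology.

## Subgroup percentages

Per-drug subgroup percentages are denominated by the **sum over the three
subgroups**, not by the drug's total cardiac cases: that is the only
denominator under which the published percentage cells reproduce (e.g.
373/1001 = 37.3%). Because a case may fall in two subgroups, the subgroup
sum can exceed the distinct-case count. Two published cells resist exact
rounding reproduction under any denominator (one prints 41.6 where the
count ratio gives 41.7, another 51.4 vs 51.3); the computed values are kept.

## Synthetic data

The generator emulates the structure of the real database — per-product
cohorts, sex/age mixtures, synonym-laden verbatim names, multiple event
terms per case (1 + Poisson extra cardiac terms), duplicate case versions,
occasional dual exposure — with ground truth defined on the odds scale: a
reference product has baseline odds w (default 0.111, event probability
≈ 0.1) and each product's odds are w × multiplier, so the requested
multiplier equals the expected ROR of that product against the reference
exactly. Defaults: sex mixture 54% F / 34% M / 12% NS and a broad age
mixture (reflecting the overall composition of the studied reports), 0.3
mean extra cardiac terms per case, 5% duplicate-version rate, no dual
exposure. Identical parameters and seed give byte-identical output.

What it does **not** emulate: reporting delays, stimulated reporting,
masking by competing signals, narrative text, or confounding by indication
or comorbidity. Passing recovery and calibration checks therefore show the
estimator is correct for the sampling model, not that real-world RORs are
unbiased effect estimates.

`table1_fixture` is a separate deterministic construction whose per-drug
totals equal the published cohort table exactly (12,472/1,238 tiotropium;
1,254/188 aclidinium; 1,883/376 glycopyrronium; 2,599/459 umeclidinium),
with cardiac cases carrying subgroup terms so case-level subgroup counts
match the published breakdown (overlaps realized where a subgroup sum
exceeds the cardiac total) and sex assigned to match the published cells.
The extracted source table's per-drug age cells are internally inconsistent
(they do not sum to the cardiac totals), so the fixture leaves age bands
unspecified; age-stratified behaviour is exercised on generator output
instead.

## Problem sizes for the statistical checks

CI coverage uses 1,000 tables at cohorts of 600 and event probability
0.08; parameter recovery uses 200 seeds per multiplier {0.5, 1, 2} at
cohorts of 5,000; null calibration uses 400 replicates at cohorts of
1,000. These sizes give Monte-Carlo error well below the decision margins
(e.g. coverage SE ≈ 0.7 percentage points) while each check completes in
about a minute.

## Known limitations

- The Wald interval undercovers at very small counts; the ≥3-case rule
  mitigates but does not remove this.
- No PRR, information-component or empirical-Bayes estimators, and no
  pooled stratified estimate.
- The FAERS ASCII reader covers the DEMO/DRUG/REAC columns the data model
  needs, not the full quarterly layout, and there is no download client.
- Drug matching is exact (case-insensitive); misspelled verbatim names are
  left unmatched rather than fuzzily resolved.
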