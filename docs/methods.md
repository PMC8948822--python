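# Methods

## Data model and units

A databank row describes one food or drink item per 100 g: Eatwell-style
food group and sub-group labels, a NOVA processing category (1–4), a
food/drink flag, energy (kcal), nutrient amounts, greenhouse-gas emissions
(g CO2e) and cost (GBP). Nutrient units are declared per nutrient in the
configuration (g, mg or µg); NRF reference values are interpreted in the
same unit as the nutrient they refer to. Per-100 kcal values are never
stored in input files — they are always derived — which prevents accidental
double normalisation.

Salt and sodium are reconciled on load with the standard UK conversion
salt (g) = 2.5 × sodium (g), applied through each column's declared unit.
When both columns are present and disagree by more than 5%, a warning is
raised and the salt column wins (sodium is recomputed from it), because the
front-of-pack guide is expressed in salt.

Two pre-analysis labels may appear in the food-group column: `irrelevant`
(out-of-scope product classes) and `unlinked` (items not mapped to any food
group). They are counted as their own exclusion reasons so the manifest can
reconcile every stage: loaded = excluded-by-reason + retained, always
checked at run time.

## Indicators

NRF8.3 on a 100-kcal basis: qualifying percent-DV terms are truncated at
`cap_pct` (default 100) before summing; the limiting sum is uncapped, which
keeps the penalty sensitive to extreme fat/salt/sugar densities. The
default qualifying set is protein, fibre, vitamin A, vitamin C, vitamin E,
calcium, iron and potassium (DVs 50 g, 30 g, 800 µg, 80 mg, 12 mg, 800 mg,
14 mg, 3500 mg — EU/UK adult reference intakes); limiting: saturated fat
20 g, total sugar 90 g, sodium 2400 mg. The NRF family admits several
qualifying sets; this one is fully configurable and the tests exercise the
formula, not the particular table. Total sugar (not free sugar) is used in
both the limiting set and the FoP classifier.

The FoP classifier is inclusive at the printed boundaries (≥) and monotone
by construction. Items with zero energy cannot be expressed per 100 kcal;
they are dropped from indicator computation, counted, and logged.

## Exclusions and strata

Food groups dominated by one NOVA category are excluded from the stratified
comparison — drinks, oils & spreads, and (by the same rationale, and
configurable) miscellaneous items — followed by all NOVA 2 items; the group
rule takes precedence over the NOVA rule in the accounting. The retained
four groups are stratified by NOVA {1, 3, 4} × FSS {all, low, high}; a
pooled `all_items` pseudo-group is their union, and the protein group is
additionally split into plant-based (beans and pulses; seeds and nuts) and
animal-based sub-groups. Partition invariants (each retained item in
exactly one group × NOVA cell, its FSS cell and the pooled cell) are
property-tested on generated databanks.

## Resampling

Each stratum median is bootstrapped with B same-size resamples with
replacement (default B = 10,000; tests use B ∈ [50, 2000] to keep the suite
fast). The point estimate is the median of the B draws; the interval is the
percentile CI at level 1 − α (α = 0.05). For the NOVA 3 − 1 and 4 − 1
contrasts the arms are resampled independently — they are disjoint item
sets — and the per-category draws are shared across the two contrasts, so a
difference draw is m_k,b − m_1,b. A contrast is significant when its CI
excludes zero. The plain sample median is reported alongside the bootstrap
median (even n: mean of the central order statistics). Percentile rather
than BCa intervals are the default because the estimand is a plain median
difference; measured coverage on lognormal data (n = 500/arm, 200 repeats)
is 96%.

Determinism: one seeded generator per `summarize_stratum` call, strata
processed in sorted key order, and within-cell values sorted before
resampling, so results are independent of databank row order.

Kruskal–Wallis (tie-corrected mid-ranks, chi-square p) and Shapiro–Wilk
delegate to scipy.stats behind the package's interfaces; an independent
hand-computed rank formula serves as the test oracle. Shapiro–Wilk input is
capped at n = 5000 (its small-sample calibration degrades far beyond that);
larger strata are subsampled with the run seed.

## Composite score

One point each for GHGE under, cost under, and NRF8.3 over the medians of
the item's food group (FSS strata and NOVA categories pooled). Inequalities
are strict, so ties at a median score zero — real cost data can tie, and
this is the conservative reading of "under/above the median". A
`global_medians` switch scores against pooled medians instead, for the
alternative "overall medians" reading. Percentages in the distribution
summaries are rounded half-up to one decimal.

## Synthetic databank generator

The generator defines the study conditions for all tests: 4,912 items by
default, group proportions 800/1378/1689/380/301/86/278 across fruit &
vegetables, starchy carbohydrates, proteins, dairy, drinks, oils & spreads
and miscellaneous, with sub-group and per-group NOVA mixtures matching a
published distribution table of the emulated databank (the drinks NOVA
percentages print to 105 and are normalised).

All value fields are lognormal: per-group baseline medians (chosen once as
realistic per-100 g values for each group), log-scales σ = 0.6 for
nutrients, 0.35 for energy and 0.5 for emissions and cost, and
multiplicative NOVA median shifts. The default shifts encode the real-data
pattern — processed/ultra-processed items are more energy-dense (×1.3/×1.6),
carry more fat/salt/sugar, fewer micronutrients, and slightly lower
per-100 g emissions and cost — which, per 100 kcal, yields lower NRF8.3,
GHGE and cost for NOVA 3/4, matching the qualitative published gradient.

High-FSS status is emergent, not assigned: a latent mixture component
(weight 0.25 per group) multiplies the fat/saturated-fat/sugar/sodium
medians (×3.5/×4/×4/×5), and the FoP classifier is then run on the drawn
composition. The realised high share is therefore approximate (~0.4 overall
under the defaults, near the ~0.36 of the emulated databank) and varies by
group, as in real data.

Stream order is field-major and documented: group, sub-group, NOVA and
FSS-component uniforms, then one standard-normal vector per value field in
fixed order. Appending a new field therefore never perturbs earlier draws,
and identical configs (including seed) give byte-identical databanks.

Ground truth: the lognormal median is exp(location), and the ratio of two
independent lognormals is lognormal, so the per-100 kcal emission and cost
medians per (group, NOVA, FSS component) are exact. The NRF8.3 ground truth
evaluates the index at the median composition — an approximation (sum of
capped, energy-correlated terms), verified empirically to hold within 10%
at small log-scales. The `all` FSS entry uses the component-weighted mean
of log-medians, also an approximation.

What the generator does not emulate: real food names, fortification spikes,
extreme micronutrient densities (synthetic NRF levels are lower than real
published medians), within-group nutrient correlations beyond the shared
energy denominator and FSS component, and measurement error in emission or
price matching. Passing tests therefore validate the pipeline's arithmetic
and inference, not the published medians themselves, which require the
restricted databank.

## Test design notes

* The type-I check of the bootstrap contrast machinery uses a fully
  exchangeable null: identical baseline medians across groups and all NOVA
  shifts at 1. With group-specific baselines the pooled-stratum contrasts
  are genuinely non-null even without NOVA effects, because NOVA composition
  differs across groups (a Simpson-style confounding of the pooled
  estimand, not a resampling error). Under the exchangeable null the
  measured significant-row share is ~6% at the nominal 5%.
* Heavy simulations are sized to finish in seconds to a few minutes on one
  CPU: coverage at 200 repeats × n = 500/arm × B = 2000; recovery at
  n = 5000, B = 2000 over 5 seeds; convergence checks at n = 50,000.
* Known limitations: percentile CIs on very small strata (n < ~10) are
  lumpy and can under-cover; empty strata are reported as n = 0 rows, not
  errors; the pipeline assumes one row per item (no recipe disaggregation,
  price scraping or life-cycle matching — those are inputs).
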