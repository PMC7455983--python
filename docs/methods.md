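# Methods

This note documents the models, parameters and design choices behind
the database construction pipeline, in the package's own terms.

## Quantities and bases

Capsaicinoid content means capsaicin + dihydrocapsaicin, in mg per
100 g. Every `CompoundAmount` declares its basis — dry weight or wet
(as-consumed) weight — and cross-basis arithmetic is a type error.
Conversion uses the moisture correction factor
f = (100 − fresh water %)/(100 − dried water %): dry→wet multiplies by
f, wet→dry divides. The conversion is exactly invertible (round-trip
error below 1e−12) and linear in the amount.

Dihydrocapsaicin imputation (for studies that measured capsaicin only)
multiplies capsaicin by a cultivar-specific dihydrocapsaicin:capsaicin
ratio. The ratios are configuration data, not computed: the shipped
values (0.5 for red Korean chili pepper, 0.3 for the one Cheongyang
study that lacks the measurement) are the ratios implied by the
reference cultivar table itself, since no single published ratio
reproduces both imputed cells. Study means are unweighted.

## The five-level spiciness scale

Literature capsaicinoid values for red pepper powder are first trimmed
by fixed thresholds (< 10 and > 220 mg/100 g are discarded). Trimming
is threshold-based rather than count-based so it generalizes beyond any
one collection size. The retained values are binned into five groups
whose boundaries are configuration — no boundary-selection rule is
published, so the ranges are taken as given:

| level | range (mg/100 g) | mean conc (default) |
|---|---|---|
| mild | 10.54–36.81 | 26.6 |
| slightly hot | 40.29–50.04 | 45.8 |
| medium hot | 53.99–68.8 | 59.0 |
| very hot | 77.7–102.3 | 86.6 |
| extremely hot | 113.52–203.8 | 153.8 |

Two mean sets ship in config. The *narrative* set (26.2, 45.8, 59.1,
86.6, 153.8) matches the scale as first described; the
*computation-consistent* set above is the one that reproduces every
downstream food table cell-for-cell and is therefore the default for
database construction.

A value falling in the gap between two ranges is assigned to the level
with the nearest range endpoint, ties to the milder level. This rule
keeps known market samples (70.9 → medium hot, 106.7 → very hot) in
their declared classes. Values below the first lower bound or above the
last upper bound are flagged unclassifiable, never force-assigned, so
assignment is always a partition of its input.

## Source fractions and processing corrections

A recipe's source fraction is 100 × source weight / total ingredient
weight, with salted vegetables (cabbage, radish) pre-corrected for 10%
draining water loss when the recipe lists fresh weights. Fermentation
degrades capsaicinoids; the terminal loss factors are per-category
configuration: 20% for kimchi, 10% for red pepper paste, 0 elsewhere.
Only the terminal factor is modelled — no fermentation kinetics.

**Staged rounding.** Recipe-derived fractions are rounded to one
decimal *before* cross-recipe averaging and *before* the fermentation
correction; this is the only order of operations that reproduces the
published corrected fractions (two napa recipes at 2.9% and 1.4%
average to 2.2% and correct to exactly 1.76%). Label-derived fractions
and all downstream arithmetic are carried at full precision and rounded
only for display. Both behaviors are explicit flags
(`rounded=True/False`). Display rounding is half-up (decimal), not
banker's: 2.15 must round to 2.2.

Other rules: kimchi without a standardized recipe inherits a donor
kimchi's corrected fraction (explicit surrogate map; unmapped foods
raise, never default silently). Salted seafood other than pollock roe
uses an assumed 5% powder fraction (configuration, flagged
`assumed_default` in the entry). Paste blends scale the label fraction
by the paste share (80% with vinegar, 25% with soybean paste) before
the fermentation correction. Composite foods chain fractions:
powder-in-dumpling = kimchi-in-dumpling × powder-in-kimchi / 100. The
watery-kimchi ingredient total is the sum of the printed addends
(177.6 g), which disagrees with the tabled total by 1 g; the resulting
fraction rounds to 0.4% either way.

## Profiles, classification, validation

A food's five-level profile evaluates Σ fraction × concentration / 100
once per level with the red-pepper-powder concentration swapped per
level and other sources (e.g. chili sauce at 1.6 mg/100 g) held fixed.
Because level means increase, profiles are monotone non-decreasing, and
because the formula is linear, the profile of mean fractions equals the
mean of per-product profiles. Foods with one published value (Tabasco
sauce, each noodle product) carry a degenerate one-level profile so
downstream arithmetic is uniform. Chicken seasoning sauce reuses the
sweet-hot-chili-sauce mean (similar spiciness); canning is treated as
lossless (capsaicinoid degradation is negligible below ~190 °C).

NAQS certification classes for napa kimchi: mild < 0.4, moderately hot
0.4–1.2 (closed interval), hot > 1.2 mg/100 g. Calculated profiles are
validated against published measurement ranges (napa kimchi 0.2–1.35,
red pepper paste 2.46–9.64 mg/100 g); a profile passes if any level
falls inside, and the build report records which.

## HPLC quantification

Calibration is unweighted ordinary least squares with free intercept
(neither weighting nor a forced origin is specified for the assay), on
standards at 0.313–80 µg/ml (capsaicin) and 0.625–40 µg/ml
(dihydrocapsaicin). Quantification inverts the line and applies the
dimensional chain (area − intercept)/slope × extract volume / sample
mass / 10 → mg/100 g, with the defaults of the assay protocol (25 ml
final volume; 3 g powder or 1 g liquid samples; the three sequential
extractions are pooled into the single adjusted volume). Areas below
the intercept are flagged below-range and clamped to zero, never
reported negative. QC: spike recovery = 100 × (measured − baseline) /
spike; replicate summaries are mean ± sample SD (n−1).

Category summaries are unweighted means per (noodle type, flavor) cell.
The published cup-noodle summary row equals the cup hot-flavor mean —
the single mild cup product stands alone — so the flavor-cell means are
the summary statistics of record.

## Intake estimation

Intake per subject-day = Σ consumed grams × content(food, level) / 100
under a scenario (one level for all level-structured foods, or a
per-food map). The computation is deterministic: no usual-intake
modelling or within-person variance correction. Foods absent from the
database contribute zero and are listed in a coverage report, never
imputed. High-consumer ranking uses the inclusive (R type 7) empirical
quantile, all ties included, for cross-implementation reproducibility.

## Synthetic data

Generators are pure functions of (seed, parameters) using numpy's
`default_rng`; no hidden global state. They emulate the pipeline's
input classes: literature collections (uniform over 10.54–203.8
mg/100 g by default — no distributional form is published — with
configurable counts of below/above-cut outliers, default 94 values with
3 + 3 outliers), recipes and labels constructed to recover a known true
fraction exactly before rounding, calibration peak areas with relative
Gaussian noise, and recall records with gamma-distributed portions
(shape 2, scale 50 g — a right-skewed portion distribution with a
100 g mean) over uniformly sampled database foods. They do not mimic
real consumption frequencies, label-transcription errors, or
chromatographic artifacts, so passing tests demonstrate arithmetic
correctness of the pipeline, not robustness to real survey data.

Simulation sizes used in the test and acceptance suites (200
calibration/sample replicates; recalls of a few dozen subject-days) are
chosen to make Monte-Carlo error comfortably smaller than the asserted
tolerances while keeping the suites quick to run. The
parameter-recovery check quantifies each synthetic sample as a
triplicate-mean area, mirroring the triplicate assay protocol, and
draws samples inside the calibration interpolation range; with
single-injection samples the calibration-curve error alone pushes the
median relative error to ~1.05× the injected noise.

## Known limitations

- The food list covers the named foods of the source tables, not the
  full survey-derived food inventory.
- Two published seafood table cells (pollock roe 1.87 and 2.74) differ
  by 0.01 from every consistent recomputation from the label mean
  (3.157…%); they are treated as rounding noise and the recomputed
  values (1.86, 2.73) are used.
- One published cultivar-summary cell (Cheongyang dry capsaicin mean)
  is internally inconsistent with its own rows; the recomputed
  unweighted mean is used.
- The supplementary 94-value literature collection is not bundled; the
  binning behavior is exercised on synthetic collections with the same
  structure.
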