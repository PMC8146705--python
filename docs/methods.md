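# Methods

This note documents the models, conventions and design choices behind
mrmkit, in the order of the pipeline.

## Mass arithmetic

All masses are monoisotopic. Residue masses are the standard 20-residue
table (five decimal places); proton 1.007276 Da, water 18.010565 Da,
carbon monoxide 27.994915 Da. Fixed modifications are applied once per
matching residue; carbamidomethylation of cysteine (+57.021464 Da) is on
by default, matching the usual reduction/alkylation sample preparation —
though no shipped marker contains cysteine, so it never affects the
reference panel. Only the a, b and y series are implemented (the only
series appearing in the reference method); requests for other series
raise rather than silently returning nothing. Average-mass mode is a
deliberate non-goal.

Printed one-decimal m/z values are matched at ±0.05 where possible and
±0.1 as the acceptance tolerance, since the rounding convention of
instrument software is not standardized.

**Known discrepancy.** The published Chickpea 3 (SSNPFTFLVPPR) precursor
value, 681.8 (2+), is not the monoisotopic [M+2H]²⁺ (681.364; pyteomics
agrees) but coincides with the *average-mass* value (681.78). Its three
product ions all match the monoisotopic sequence within 0.05. The shipped
panel keeps the published value; `validate_method` flags exactly this row,
and the corresponding acceptance case fails by design. All other 26
precursors and all 81 products reproduce within ±0.1.

## Digestion

Cleavage is C-terminal of K/R; the Keil proline rule (no cut before P) is
on by default and exposed as a flag, because the panel method names only
"trypsin" while all 27 reference markers are consistent with the
P-blocking convention (two contain internal K·P / R·P junctions that must
*not* be cut for the peptides to be fully tryptic). The digestion is
implemented in-package as a cut-site scan rather than through
`pyteomics.parser`, whose built-in trypsin rule adds the WKP/MRP
exceptions of the full Keil rules; the simple toggle semantics and
1-based inclusive peptide coordinates are needed by the specificity
screen. Tests verify the digest against a brute-force substring oracle
and the mass arithmetic against pyteomics.

Peptides containing ambiguous residues (X/B/Z/U) are indexed but flagged
and excluded from marker candidacy.

## Marker selection

Uniqueness is exact full-length sequence identity over the user-supplied
panel — the in-repo equivalent of a 100 %-coverage / 100 %-identity
homology search; no alignment engine is embedded. I and L are distinct at
this stage (as in sequence databases); a separate isobaric check reports
I↔L collisions because MS cannot distinguish them and such pairs must be
resolved chromatographically. A peptide occurring in a panel species and
any non-panel collection is simply not unique; one occurring in ≥2 panel
species is recorded as shared.

Background-matrix hits *flag* a candidate instead of excluding it: whether
a hit (e.g. a spice ingredient sharing a marker) disqualifies the marker
is a quantitative judgement, not a set operation. Heat stability is an
experimental property and is not modeled.

The final pick takes the top 3 candidates by supplied intensity
(lexicographic tie-break). When the plain top-3 all come from one protein
and another protein has candidates, the weakest pick is swapped so
markers span ≥2 source proteins — protecting the assay against a single
protein being lost to processing.

## Transition design and scheduling

Candidates are all a/b/y fragments at product charges up to the precursor
charge with m/z strictly greater than 250 (strict inequality; the cutoff
excludes the immonium/chemical-noise region). The default maximum product
charge equals the precursor charge because the reference panel itself
contains 3+ fragments of 3+ precursors. Detection windows are centered on
t_R (40 s total by default). The concurrency report sweeps window
boundaries (half-open intervals) and returns the maximum number of
simultaneously monitored transitions. DP/CE/CXP voltages are carried as
opaque per-transition metadata; no instrument-optimization model is
included.

Transition-list CSVs are UTF-8 with a header row and '.' decimals; times
in minutes, windows in seconds (the method table's mixed units,
kept deliberately). Import recomputes every product m/z from sequence +
label and rejects rows deviating beyond ±0.1.

## Quantification statistics

- Calibration: OLS with free intercept (`scipy.stats.linregress`); a
  forced-through-origin option exists. R² is the squared Pearson
  correlation; 2-point curves are flagged `low_n` since their R² is 1 by
  construction.
- Quantification uses the most intense transition's area per marker
  (configurable to the 3-transition sum). Negative inverse predictions
  are reported as-is with a flag.
- Recovery = 100·estimated/true; the 80–120 % band is inclusive at both
  ends. CV uses the n−1 sample standard deviation; the transition ratio
  is lowest-rank over highest-rank area in the method's declared
  intensity order.
- Detection: a marker requires all three transitions at S/N ≥ 3
  (inclusive); the species rule defaults to all-three-markers ("clear
  evidence") with an `any1` screening alternative. The LOD is the lowest
  tested level detected, with a warning when the ladder is non-monotone.
- S/N estimator: peak height (maximum of a lightly moving-average-smoothed
  trace, ~1/8 of the peak window, minus the baseline median) over the raw
  noise-window SD. The smoothing suppresses the upward bias of a pointwise
  maximum over noise (~+1 SD for unsmoothed windows of a few hundred
  points) while attenuating peaks much wider than the smoothing span by
  <5 %; across 100 simulated traces at height = 3×noise SD the mean
  estimate is within ~2 % of 3. Instrument vendors do not share a single
  S/N definition; this one is documented as the package's convention.
- Box-plot components use 1.5·IQR whiskers clamped to the most extreme
  inlying points, matching matplotlib's `boxplot_stats` (the test oracle).

## Synthetic data: what it emulates, what it does not

`make_proteomes` builds random backbones over the 20-letter alphabet with
K/R frequencies tuned so tryptic peptides average ~10–14 residues, and
plants criteria-conforming markers (8–18 aa, no C, K/R-flanked, fully
tryptic) in exactly one species each, plus configurable shared and
background-hit peptides. The manifest carries an intensity table that
ranks planted markers above everything else, making the cascade's
expected output fully determined. Real proteomes differ in homology
structure (near-identical isoforms across related species) and amino-acid
composition; passing the planted-recovery test shows the set logic and
filters are correct, not that marker selection on real databases will be
unambiguous.

`simulate_area_table` uses the matrix-calibration design: standards at
0.1–2.5 % substitution in 0.3 steps (three replicate preparations each —
a pragmatic choice keeping simulated campaigns small), unknowns at 0.0 /
0.85 / 1.75 / 2.35 % with twelve replicates, area = slope·level (+
intercept, default 0) scaled per transition by fixed rank factors
(1.0/0.6/0.3), times lognormal noise of stated CV (default 10 %).
Multiplicative noise was chosen over additive because peak areas are
positive and repeatability is expressed as CVs. Unknown levels are applied
uniformly across species per sample (the real unknowns varied species by
batch); this does not affect any per-marker statistic. The S/N column is
area over a constant baseline-noise unit — a simplification standing in
for per-trace noise estimation. Matrix effects beyond a per-marker slope,
ionization efficiency and retention-time drift are not modeled.

The formulation helper defines substitution % on the control recipe's
pork share (50 %): flour% = substitution/100 · pork_share ·
pork_protein_fraction (0.195) / flour_protein_fraction, with the exact
inverse provided.

## Problem sizes in tests

The test suite and acceptance checks run on: 100 random sequences for the
digestion oracle; nine synthetic proteomes of 20 proteins (~150–400
residues) for selection; the 27-marker panel for all m/z checks; 21
markers × 3 levels × 12 replicates (756 recoveries) for the calibration
property; and 100 seeded traces of 1200 points for the S/N boundary.
These sizes were chosen so the whole suite completes in well under a
minute while keeping binomial noise on the recovery fraction (~±2 %)
far from the 90 % acceptance threshold.

## Known limitations

- No missed-cleavage-aware marker candidacy (markers are 0-missed by
  definition here, matching the panel's selection rules).
- No retention-time or collision-energy prediction; scheduling requires
  measured t_R values.
- The uniqueness screen is exact-match only; single-residue variants
  (other than I/L isomerism) are not surfaced.
- Quantification assumes a linear response over the calibrated range;
  no weighting or isotope-dilution support.
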