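# Methods

This note documents the models implemented in `aromakey`, the choices made
where the underlying study leaves the procedure open, and what the
synthetic data do and do not establish.

## Semi-quantification

Relative concentration is computed per injection and compound as

    conc = area_compound × m_IS / (area_IS × m_sample)

with `m_IS = 400 ng` ethyl decanoate (20 µL of a 0.02 mg/mL solution) and
`m_sample` the dry tea mass in grams (1.5 g in the emulated design, carried
per injection so unbalanced designs remain valid). The formula is the only
parenthesization of the published expression with ng/g units. It assumes a
common detector response factor across compounds, so values are *relative*
concentrations: comparable across runs and districts, not absolute amounts.

District means average over all injections (samples × replicates). With
balanced replicate counts this equals the mean of per-sample means; for
unbalanced inputs every injection counts once (documented behaviour, second
order in practice). Class shares are computed on district-mean
concentrations: `share(class, district) = 100 × Σ_class mean / Σ_all mean`.

## PLS-DA

The discriminant model regresses a dummy-coded district matrix Y (n × G,
one column per district) on the concentration matrix X (n × p) using NIPALS
PLS2. Each replicate injection is a row; replicates of one sample are
expected to cluster, and cross-validation folds deliberately mix them into
training (replicate-level modeling, as in the emulated study).

Choices where the procedure was open:

- **Scaling.** X is autoscaled (column mean 0, sample SD 1, ddof = 1) —
  concentrations span four orders of magnitude, and unit-variance scaling is
  the standard chemometrics default. Zero-variance columns map to zeros and
  are flagged. Y is mean-centered but *not* unit-variance scaled: in the
  default unbalanced design (12-sample YJ-Yingde vs three single-sample
  districts) UV-scaling Y would upweight the smallest classes roughly
  12-fold and let a single tea dominate the projection.
- **NIPALS.** Start vector: the Y column with the largest variance;
  convergence when the weight vector changes by < 1e-10, cap 500
  iterations; deflation of X and Y after each component. Deterministic by
  construction. Sign convention: each weight vector's largest-magnitude
  element is made positive, so score plots are reproducible.
- **Diagnostics.** `ssy_a = (tᵀt)(cᵀc)` is the Y sum of squares captured by
  component a; `R²Y = Σ ssy_a / SS(Y_centered)`, likewise R²X from
  `(tᵀt)(pᵀp)`. Scores are mutually orthogonal and weights unit-norm
  (asserted at 1e-8 in the tests).
- **Cross-validation.** Q² = 1 − PRESS/SS with interleaved
  ("venetian-blind") folds — row i goes to fold `i mod k`, k = 7 by
  default. Scaling parameters and the model are re-estimated inside each
  training split; SS accumulates held-out deviations from the training
  mean. A fold that loses an entire class triggers a warning.
- **Component count.** `auto` adds components while Q² improves by more
  than 0.01, capped at min(10, n − 1, p, G).
- **Permutation validation.** District labels are permuted jointly,
  the model refit at fixed A, and R²Y/Q² recorded against the label
  correlation (mean absolute column-wise Pearson correlation between the
  permuted and original dummy matrices; 1 for the original). Intercepts are
  least-squares lines through all n_perm + 1 points evaluated at
  correlation 0. A sound model keeps every permuted Q² below the original
  and has a negative Q² intercept.
- **Hotelling's T² ellipse.** For the first two score columns, semi-axis
  `s_k · sqrt(2(n−1)(n+1)/(n(n−2)) · F_{1−α}(2, n−2))` with `s_k` the score
  SD; α = 0.05 gives the conventional 95% region (coverage verified by
  Monte Carlo at n = 10⁴).

VIP scores use `VIP_j = sqrt(p · Σ_a ssy_a w_aj² / Σ_a ssy_a)`. With
unit-norm weights, `Σ_j VIP_j² = p` identically, so VIP > 1 marks
above-average contribution to the discrimination; these are the
differential compounds.

## OAV screening and district flags

`OAV(c, g) = mean_conc(c, g) / OT(c)` with OT the odor threshold in air on
the same ng/g basis. Compounds without a threshold are excluded and listed,
never imputed. The key active differential odorants satisfy VIP > 1 *and*
max-district OAV > 1 (both strict, following the "greater than 1" wording);
the screen also records, per compound, every district with OAV above the
cutoff. OAVs use district-mean concentrations because the reference table
prints one OAV per district.

Group differences per compound use classical one-way fixed-effects ANOVA on
injection-level concentrations (identical values return F = 0, p = 1 rather
than an error). The claim "highest in district g, significantly above all
others" is operationalized as: g is the argmax of district means, and
one-sided Welch t tests of g against every other district are all
significant after Holm correction — at α = 0.01 for `**`, α = 0.05 for
`*`. Exact mean ties yield no flag. Districts represented by a single tea
sample still contribute six replicate injections; their within-group spread
is technical (injection-level), not biological, and flags involving them
should be read accordingly.

## Heat-map export and clustering

The heat-map contract is data, not a figure: replicate-averaged
per-sample concentrations of the VIP-selected compounds, column z-scored
(ddof = 1) and clipped to ±4 (the conventional display range), with both
axes clustered agglomeratively — euclidean distance, average linkage by
default (the most common metabolomics choice; correlation distance and
complete/Ward linkage are available). Correlation distance on a constant
vector falls back to euclidean with a warning. Leaf order is the
deterministic left-before-right dendrogram traversal; trees are exported as
Newick text.

## Synthetic-data generator

The generator emulates the study design: 31 samples in 8 districts
(12 + 3 + 4 + 6 + 3 + 1 + 1 + 1), 6 replicate injections each
(186 injections), 135 compounds in 12 classes
(24/25/9/17/10/6/9/17/9/3/5/1). Concentrations are positive and
multiplicative, so noise is lognormal at two levels, each with unit mean:
a between-sample factor (CV 0.25, independent per sample and compound,
shared by that sample's injections) and an injection-level factor
(CV 0.08, matching tight replicate clustering). Internal-standard areas
are lognormal around 10⁶ counts (CV 0.10) and cancel exactly in
semi-quantification; peak areas are emitted by inverting the
semi-quantification formula, so the pipeline identity
`quantify(generate(cfg, cv→0)) = configured concentration field` holds
exactly in the noise-free limit.

Calibration:

- **Key odorants.** Eight compounds carry district-specific means. Odor
  thresholds in air are not published, so each key compound's threshold is
  back-derived as anchor mean ÷ published district OAV (e.g. phenylethyl
  alcohol 1621.01/10.13 → 160.02 ng/g; linalool 2066.04/42.48 → 48.64
  ng/g). District means are then published OAV × threshold, overridden by
  the eleven printed concentration anchors. Cells censored as "<1" are
  simulated at OAV 0.5. Two compounds have mutually inconsistent printed
  (concentration, OAV) pairs: geraniol (Meizhou 1891.58 ng/g vs the
  Lianshan-derived threshold) and methyl salicylate (HY-Yingde 996.06 ng/g
  vs the Renhua-derived threshold); the thresholds follow the Lianshan and
  Renhua pairs respectively and the conflicting concentrations are kept as
  printed overrides. The reference table's phenylethyl-alcohol OAV is
  10.13; the running text's 10.31 is treated as a typographical variant and
  not used. Benzaldehyde's Luokeng mean (2221.96 ng/g) is the average of
  the two printed sample values.
- **Baseline compounds.** The other 127 compounds (including beta-ionone,
  which additionally gets the printed 278.91 ng/g Meizhou elevation) are
  district-flat. Per-compound baselines are drawn once from per-class
  budgets (uniform 0.5–1.5× the class average, normalized to the class
  total) under a fixed internal seed, independent of the simulation seed,
  and are therefore constants of the default profile. The class budgets
  (total 30 000 ng/g) were calibrated once against the marker class totals
  so that every district's alcohol share sits mid-band in the published
  31.40–44.43% interval (held across 20 seeds in the tests) and the
  published ester, aldehyde, ketone and acid bands hold in expectation.
  Baseline thresholds default to 10× the compound's global mean (OAV 0.1),
  which keeps the aroma-active set exactly the calibrated eight.

What the generator does **not** emulate: retention behaviour, co-elution
and deconvolution artefacts, censoring at the detection limit, compound
correlations within biosynthetic pathways, per-compound response factors,
and any within-district structure beyond lognormal scatter (the real
Luokeng teas, for instance, split into almond-like and woody sub-types).
Passing tests therefore demonstrate that the pipeline's statistics behave
correctly under the declared noise model at the study's sample sizes — not
that they would recover markers from arbitrary real chromatograms.

## Problem sizes and numerical tolerances

The default test and acceptance runs use the full emulated design
(186 injections × 135 compounds), 7-fold cross-validation, and 200 label
permutations. Exact identities (VIP normalization, ANOVA sums of squares,
round-trips) are asserted at 1e-8–1e-12; Monte-Carlo quantities (ellipse
coverage, marker-mean recovery) at the sampling error of the stated sizes.
Degenerate inputs are defined rather than crashed where a convention
exists: constant columns autoscale to zeros, identical ANOVA groups give
p = 1, ties yield no district flag.

## Known limitations

- Semi-quantification inherits the single-response-factor assumption;
  between-compound comparisons of concentration are indicative only.
- Q² on dummy responses saturates below 1 even for perfectly separated
  classes, because predictions are continuous.
- The permutation p-value is implicit (rank of the original among
  permutations); the SIMCA-style intercepts are descriptive, not a test.
- With single-sample districts, "significantly highest" flags compare
  technical replicates and should be treated as screening evidence, not
  inference about the district population.
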