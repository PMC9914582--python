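# Methods

## The analysis chain

`honeyvola` models the volatilome-based origin analysis of honey as five
composable stages over a samples × compounds concentration table
(mg/kg, one group label per sample):

1. **Semi-quantification.** Each chromatographic run reports peak areas.
   Concentrations are computed relative to the benzophenone internal
   standard, `C = A_analyte / A_IS * C_IS`, with a response factor fixed at
   1 — so values are *semi*-quantitative: comparable within the study, not
   calibrated absolute amounts. Duplicate runs of a sample are combined by
   the arithmetic mean; a compound absent from one run counts as 0 in that
   run. Retention indices use linear interpolation in retention time
   between consecutive n-alkanes (the temperature-programmed convention;
   the packaged table's furfural row, RI 837 from the octane/nonane
   anchors, is consistent with the linear rather than the logarithmic
   isothermal form). Peaks eluting outside the C8–C20 ladder get a
   below-/above-range marker instead of an extrapolated number.

2. **Screening.** Per-compound one-way fixed-effects ANOVA; compounds with
   p < 0.05 feed the discriminant stage (no multiplicity correction by
   default — the reference workflow reports raw per-compound tests; a
   Bonferroni option exists). The joint group effect is tested by one-way
   MANOVA from the eigenvalues λᵢ of W⁻¹B: Wilks' Λ = Π 1/(1+λᵢ) with
   Rao's F approximation, Pillai's trace V = Σ λᵢ/(1+λᵢ) with its standard
   F approximation. A compound constant in every sample is excluded from
   MANOVA with a logged notice; if the candidate set exceeds the
   within-group degrees of freedom, the caller must thin it (the pipeline
   uses the tolerance screen for that).

3. **Canonical LDA.** Discriminant functions are eigenvectors of W⁻¹B
   (solved as the symmetric-definite problem `eigh(B, W)`), scaled to unit
   pooled within-group score variance and oriented so each function's
   largest-|structure| entry is positive (deterministic sign). Reported per
   function: eigenvalue, % of the eigenvalue sum, canonical correlation
   √(λ/(1+λ)), and Bartlett's sequential test
   χ² = −(N−1−(p+g)/2)·ln Λ_k with df = (p−k+1)(g−k) for the functions
   from k on. The structure matrix holds pooled within-group correlations
   of each input variable with each canonical score; a variable's
   *discrimination power* is its largest absolute structure coefficient,
   ranked descending with ties broken by table order. Before fitting,
   variables are screened by tolerance — 1 − R² of each variable on the
   other candidates within pooled groups, equivalently 1/diag(R⁻¹) of the
   pooled within-group correlation matrix — excluding variables below
   0.001 iteratively, lowest first (the default of mainstream discriminant
   software). Classification is nearest group centroid in canonical score
   space, which equals the Mahalanobis rule in raw space for nonsingular
   pooled covariance; priors are equal by default (proportional by flag).
   Leave-one-out cross-validation refits the canonical functions without
   each case; the once-computed significance filter is *not* redone per
   fold, a known optimism source, and a fold whose refit scatter is
   singular is flagged and counted unclassifiable rather than silently
   pseudo-inverted (a pseudo-inverse fit exists only behind an explicit
   `allow_pinv` flag).

4. **PCA** (for comparison): eigendecomposition of the correlation matrix
   by default, loadings = eigenvector·√eigenvalue, Kaiser retention
   (eigenvalue > 1), same deterministic sign convention.

5. **Marker-ratio index.** R = (Σ marker concentrations) / TSQVC, where
   TSQVC is the sum over all compounds ("nd" cells contribute 0 to both).
   R ∈ [0,1], is invariant under global rescaling of concentrations, and
   never decreases when a marker is added. The default marker set is
   frozen to the seven reference compounds so the headline index is
   reproducible without refitting; top-k selection from a fitted model's
   discrimination-power ranking is opt-in. By default R is computed on
   group means, which reproduces the published group values exactly; a
   per-sample mode supports group-difference testing, summarized as a
   compact letter display (pairwise Welch t-tests at p < 0.001; groups not
   distinguished share a letter; letters follow descending mean R; the
   published "one-sample t-test" lettering is under-specified, so pairwise
   testing is this package's documented choice). Values are reported
   rounded half-up to 2 decimals; comparisons keep full precision.

## The packaged reference summary

The fixture is the published group-level summary: 41 compounds × 5 groups
(Egypt, Morocco, Greece, Spain citrus honey; "Nectar" = flower+thyme
validation honeys), mean and SD in mg/kg, retention time, retention index,
per-compound F and star code. Editorial choices:

* "nd" cells are mean 0, SD 0 — the source does not distinguish
  below-LOD from absent, and this encoding makes TSQVC and R sums exact.
* RI printed "<800" (2-methylbutanal, heptane) is stored as a below-range
  flag, not a number.
* Herboxide isomer II sits under terpenes, following the summary table's
  own placement even though it is chemically an ether.
* Compound names are the table's exact strings; lookup is case-insensitive
  after whitespace collapse.

Recomputing the published totals from this fixture: TSQVC matches to
±0.005 in every group; R matches 0.35/0.29/0.04/0.08 at two decimals for
Egypt/Morocco/Greece/Nectar. **Spain is a genuine discrepancy**: the seven
printed marker means sum to 0.314, and 0.314/0.874 = 0.36, not the
published 0.27 (0.27 would require dropping herboxide II from the marker
sum). The report writer flags this row instead of matching it, and no
group-difference letters are claimed for recomputed per-group values.

## The synthetic generator

The generator exists because the study's per-sample matrix was never
deposited; it emulates the *reported statistical structure*, nothing more:

* Group sizes default to the study design (7/6/17/8/6), duplicate runs per
  sample, internal standard at 1 mg/kg.
* Concentrations are drawn per compound from Normal(mean, SD) of the
  fixture cell. Because many printed SDs equal or exceed their means, an
  unconstrained normal would go negative; the default **censored-normal**
  model clamps negatives to 0. Censoring shifts the realized mean upward
  by up to ~0.4·SD for the worst cells — declared, not hidden; a
  zero-truncated normal and a plain uncensored normal (used by the
  convergence tests, where sample means must converge to the fixture
  means) are selectable.
* Compounds are drawn independently — the source reports no covariance. An
  equicorrelation hook (`within_group_corr`) exists for robustness checks.
* Duplicate-run noise is multiplicative log-normal with unit mean and
  relative SD `duplicate_cv` (default 0.05, typical HS-SPME repeatability);
  retention times jitter uniformly by ≤0.02 min. Peak areas invert the
  semi-quantification equation, so quantify∘simulate is the identity at
  zero noise.
* One master seed; per-group streams are derived from (seed, group label),
  so resizing one group never reshuffles another.

What passing tests on synthetic data do **not** show: real honey
volatilomes have correlated compounds, non-normal (skewed, zero-inflated)
concentrations, batch effects, and co-elution artifacts. Synthetic results
validate the *computations*, not the authentication claim.

## Numerical conventions and edge cases

* Observed power uses the plug-in noncentrality λ = F·df1 (the convention
  of mainstream GLM software, biased but matching published "observed
  power" figures); power → α as the effect vanishes.
* Prospective sample size treats the effect size as the root-mean-square
  standardized effect (RMSSE) and maps it to λ = N·(g−1)/g·RMSSE²
  (equal-magnitude standardized deviations); the smallest total N with
  noncentral-F power ≥ target is returned, subject to every group getting
  ≥1 sample under the allocation weights. The published power-analysis
  inputs are not mutually consistent (an RMSSE of 535.413 forces the df
  floor regardless of α), so they are treated as inputs, not targets.
* A compound identical in all samples: ANOVA F = 0, p = 1, flagged
  degenerate; zero within- but nonzero between-variance: F = ∞, p = 0.
* Eigenvalues are clipped at 0 against round-off; ties in rankings resolve
  by input-table order; all report writers are deterministic given equal
  inputs (the pipeline manifest records SHA-256 of every output).
* Default problem sizes everywhere follow the study design (44 samples);
  convergence checks use n = 2000 per group, which bounds Monte-Carlo
  error at ~3 standard errors of the printed SDs.

## Known limitations

* The published per-sample results (97.7%/77.3% classification rates, the
  eigenvalue chain 195.319/8.956/7.329/3.393, PCA loadings, centroids)
  depend on the unpublished raw matrix and cannot be reproduced; the test
  suite instead verifies the computations against independent oracles
  (determinant/trace identities, brute-force eigenproblems, exhaustive
  distance classification, statsmodels MANOVA, scikit-learn LDA
  predictions) on random instances.
* With ~30 retained variables and 44 samples the pooled scatter is close
  to singular; the tolerance screen is the only guard used by default, and
  some LOOCV folds can legitimately fail (flagged, never silently fixed).
* The index is a descriptive ratio; nothing here validates it as a
  stand-alone authentication test.
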