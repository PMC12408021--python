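# Methods

This note documents the statistical procedures implemented in `gutstrain`,
the synthetic cohort that exercises them, and the design choices made where
the analysis design was genuinely open.

## Cohort model

A cohort is a pair of tables: one row per infant (group, sex, delivery
mode, initial feeding, first-year probiotic use) and one row per stool
sample (collection age in months, symptom state). Symptom states for
affected infants must follow pre-symptomatic → symptomatic → resolved along
age; control infants carry only the "control" state. When onset and
resolution ages are present (the synthetic path), states are derived from
them; otherwise the metadata column is authoritative — samples collected on
the exact onset day cannot be phased automatically and must be
disambiguated in the metadata.

Ages are binned into half-open intervals [lo, hi) around scheduled
pediatric visits, thresholds 0, 0.35, 0.75, 1.5, 3, 5, 8, 10.5, 14 months,
lower edge inclusive. The half-open convention makes boundary behaviour
deterministic; ages ≥ 14 months are an error rather than a silent clamp.

Disease-state subsets keep at most one sample per affected infant per
phase: the oldest pre-symptomatic sample, the youngest symptomatic sample,
and the youngest resolved sample, with age ties broken by lexicographic
sample id. Case samples are matched one-to-one to control samples by
minimising the total absolute age difference (linear sum assignment). When
the sides are unequal the surplus on the larger side is left unmatched and
reported. Demographic 2×2 tables use the exact two-sided Fisher test; odds
ratios apply the Haldane–Anscombe 0.5 correction when a cell is zero.

## Community metrics

Chao1 is S_obs + f1²/(2 f2) with singletons f1 and doubletons f2, falling
back to the bias-corrected S_obs + f1(f1−1)/2 when f2 = 0. It needs integer
counts; on relative abundances it degrades to observed richness with a
warning (profiler output tables carry no counts, so richness from such
tables should be interpreted accordingly). Shannon diversity uses natural
logarithms after renormalisation.

Aitchison distance is the Euclidean distance between centred log-ratio
transformed compositions after zero replacement; the default pseudocount is
half the minimum non-zero value in the table (configurable). Principal
coordinates are computed by the classical double-centred Gram
eigendecomposition; negative eigenvalues are dropped from both the axes and
the explained-variance denominator, and each axis is oriented so its
largest-magnitude loading is positive, making the output deterministic.
Group separation is assessed by one-way ANOVA of axis-1 scores.

The stability analysis compares, for each pair of consecutive age bins,
within-infant to between-infant Bray–Curtis distances. When an infant has
several samples in a bin, the sample closest to the bin's target visit age
represents it (ties by sample id). Welch (unequal-variance) t-tests are
used throughout — the test variant was an open choice and Welch is the
safer default for unequal group sizes and spreads.

## Differential abundance model

Relative abundances are arcsine-square-root transformed
(y = arcsin(√x), variance-stabilising for proportions) and regressed by OLS
on treatment-coded fixed effects: group (control reference), delivery
(vaginal reference), age in months, and probiotic use (non-user reference).
Features must reach 0.1% relative abundance in at least 10% of samples; the
prevalence threshold completes the one-sided abundance rule and both are
exposed in the API. Per covariate, p-values are Benjamini–Hochberg adjusted
across features; the significance convention is p < 0.05 and q < 0.25.

Longitudinal handling: the disease-state subsets are one-sample-per-infant
by construction. For age-window analyses the default aggregates to one
sample per infant (the sample closest to the window midpoint), which keeps
observations independent; an optional per-infant random-intercept mode
(statsmodels MixedLM) fits all window samples instead. Neither mode is
claimed to be uniquely correct — the aggregation default is the more
conservative of the two.

Calibration on null synthetic cohorts (no planted effects): the
group-covariate type-I error at p < 0.05 is ≈ 0.05, and the realised FDR of
the q < 0.25 rule stays within the BH bound up to Monte-Carlo error. The
far tail of the per-feature p-values is mildly anti-conservative —
AST-transformed zero-inflated compositions are not exactly normal — which
is inherent to this model family and visible in the null-FDR estimate the
acceptance script reports.

## MinHash sketches and Mash distances

A sketch keeps the s smallest 64-bit hashes over the canonical k-mers of a
genome (canonical = lexicographic minimum of the 2-bit encodings of the
k-mer and its reverse complement; windows containing ambiguous bases are
skipped). The hash is the splitmix64 finalizer with fixed constants, chosen
for cross-platform determinism; bit compatibility with external sketching
tools is explicitly not promised, only metric equivalence (the sketch
Jaccard estimate is within 0.05 of the exact k-mer Jaccard at s = 1000 on
the test genomes). Defaults k = 21, s = 1000 follow the external tool's
documented defaults and are configurable. The Mash distance is
d = −ln(2j/(1+j))/k with j estimated from the s smallest hashes of the
sketch union; j = 0 saturates to d = 1.

Per species, genome-pair distances are stratified into related (same
infant) and unrelated (different infants) and compared by two-sided
Mann–Whitney U; within related pairs, case vs control likewise. Species are
ranked by genome count with lexicographic tie-break and the top 20 are
tested. Mann–Whitney was chosen over a t-test because distance
distributions are bounded and skewed.

## Strain trees

Marker-haplotype distances are normalised Hamming distances over positions
where both rows are unambiguous (N, -, ?, X are masked). Gene-content
distances are Jaccard distances on gene sets — robust to genome-size
differences caused by MAG incompleteness, which plain Hamming is not.
Trees are built by neighbour joining; negative branch lengths are clamped
to zero with the deficit transferred to the sibling edge. Topology, not
branch lengths, is the contract: NJ is exact on additive matrices and
label-permutation invariant, and trees round-trip through Newick.

## Clade enrichment scan

For every internal node with at least `min_leaves` = 6 leaves, the observed
(case, control) leaf split is tested against the expected split with a 1-df
chi-square goodness-of-fit statistic, no continuity correction. The
expected case fraction defaults to the observed fraction over all leaves; a
balanced case-control selection makes this 0.5, and an `--even` flag forces
0.5 explicitly — the two differ on unbalanced inputs, which is why both
exist. Nodes below the size threshold are reported without a test. All
significant nodes are reported by default, including nested ones; a
`--maximal` flag keeps only significant nodes whose parent is not
significant. No multiple-testing correction is applied across nodes by
default (matching the per-node p < 0.05 reporting convention); BH across
tested nodes is available as an option. Under label permutation the
fraction of tested nodes at p < 0.05 is close to, and slightly below, 0.05
— the chi-square is approximate and discrete at small n.

A clade is "infant-oriented" when all its leaves derive from a single
infant's samples; single-leaf nodes are infant-oriented by definition.

Clade-unique genes are genes present in ≥ 95% of clade genomes and ≤ 5% of
the complement. The 0.95/0.05 thresholds tolerate MAG incompleteness and
contamination; with exact presence/absence they reduce to "all in, none
out". Term enrichment is a one-sided hypergeometric over-representation
test per term against a user-supplied gene→term map and gene universe, BH
adjusted across terms; no curated database content ships with the package.

## Classification protocol

Features are relative abundances with mean > 1%, with therapeutically
administered probiotic species excluded by default (their abundance
reflects treatment assignment, not endogenous community state, and inflates
apparent performance). Evaluation is stratified 5-fold cross-validation.
Inside each training fold — never on the full data — features are
standardised and a random forest (500 trees, √p features per split,
unlimited depth, inverse-class-frequency weights) is fit; the
lowest-Gini-importance ⌈10%⌉ of features is dropped per iteration until at
most 120 remain; the refit forest predicts the held-out fold. The leakage
guarantee is tested directly: a feature equal to the label yields perfect
accuracy, while a feature informative only on held-out rows yields chance
accuracy. Age strata are ≤ 4 months and > 6 months at collection; samples
in (4, 6] appear only in the all-samples stratum.

Attribution is signed permutation importance on the final full-data model:
the mean increase in log loss of the predicted class probabilities when a
feature is permuted, signed by the correlation between the feature and the
predicted case probability. Log loss rather than a ranking score is used so
that duplicated or correlated informative features each retain measurable
importance instead of silently compensating for one another. This is an
attribution contract (ranking plus direction), not an exact Shapley-value
computation; an adapter point is left where one could be plugged in. Forest
size, depth, and the elimination step are exposed in the API; no
per-stratum hyperparameter search is performed.

## Synthetic cohort

The generator's defaults are the study conditions the package is tested
under: 163 infants with an 84/163 case split; visits scheduled at ~birth,
0.5, 1, 2, 4, 6, 9, and 12 months with Gaussian jitter (sd 0.15 months,
truncated at zero); each visit attended with probability 0.5 (attendance is
not reported for the emulated design, so missingness is a free parameter;
0.5 reproduces the median of ~4 samples per infant). Onset ages are
log-normal (median 1.2 months, σ = 0.6) and resolution ages add a
log-normal duration (median 4.5 months, σ = 0.4); with the visit schedule
this places the pre-symptomatic / symptomatic / resolved sample medians
near 0.5, 2 and 8–9 months. Probiotic use is assigned at 85.7% in cases vs
20.3% in controls, sex at 50%/40.5% female, vaginal delivery at 66.7%/62%,
and feeding at the corresponding group-specific proportions.

Abundances are Dirichlet-multinomial: 60 taxa with log-normal base weights,
an exponential age-maturation trend per taxon, colonisation onset ages for
half of the filler taxa (absent before 3–10 months, so richness accumulates
over the first year), a log-normal per-infant intercept (σ = 0.45), planted
multiplicative group effects within age windows, a 25× weight multiplier on
the probiotic species in probiotic users, and an emergence-age/feeding rule
for the planted subspecies. Counts are multinomial draws at 50,000 reads
with Dirichlet concentration 50. The intercept and concentration defaults
were set so the generator satisfies its stated recovery calibration — a
2-fold planted effect at ~160 infants is recovered at q < 0.25 in ≥ 90% of
seeds — while keeping within-infant samples markedly more similar than
between-infant samples (stability p ≪ 10⁻³). Colonisation onsets start at
3 months so that the earliest analysis window is not dominated by
zero-inflated partially colonised taxa, whose AST-OLS p-values have heavy
tails.

Strain data cover two species. The probiotic species: carriers are drawn
from probiotic users (85%) and non-users (15%); exposed carriers receive
near-clonal haplotypes (per-lineage divergence 5% of
`probiotic_strain_divergence`, i.e. ~0.0005 by default, giving pairwise SNV
distances ≲ 0.001), unexposed carriers drift at the full rate (default
0.01); each carrier contributes up to two samples so related/unrelated
distance strata are populated. The planted-clade species: 40 genomes from
20 case and 20 control infants (a balanced selection, one per infant); 12
clade genomes share 223 genes absent outside the clade, on top of 600 core
and 400 independent 30%-prevalence accessory genes, and are drawn from a
common ancestor at a tenth of the background SNV divergence. The default
`clade_case_fraction` is 1.0 — a fully case-associated clade. At fractions
below 1 the minimum-p node of the scan is generically a pure-case sub-clade
excluding the interior control leaves rather than the planted clade itself
(whenever a control leaf lands in a cherry), so "recover the planted clade"
stops being a well-posed target; the fraction remains configurable for
studying exactly that behaviour.

MAG records draw a tier from configurable tier fractions (default
36.6/20.8/42.6%) and then completeness/contamination from Beta
distributions scaled into the tier's region, so records are
threshold-consistent by construction; 1.6% of samples yield no MAG.

All randomness descends from a single integer seed through spawned
generator streams (cohort, abundances, strains, MAGs), so stages are
individually reproducible and byte-identical across runs.

### What the generator does and does not emulate

It reproduces the *shapes* the analyses assume: compositionality,
longitudinal correlation, age-dependent richness and composition,
confounding between probiotic use and case status, near-clonal probiotic
lineages, a case-enriched clade with private gene content, and realistic
MAG quality mixtures. It does not emulate read-level noise, assembly or
binning artefacts, chimeric MAGs, strain replacement within an infant,
horizontal gene transfer, or realistic feeding biochemistry. Passing tests
therefore demonstrate that the estimators recover planted structure under
their own model assumptions — not that those assumptions hold in any
particular real cohort.

## Numerical conventions

Proportions (0–1) are the internal unit everywhere; percentages appear only
at I/O boundaries. Relative tables must close to 1 ± 10⁻⁶ at construction;
feature subsets intentionally do not re-impose closure. Distance matrices
are validated for symmetry, zero diagonal, and non-negativity. Tied ages
are always broken by lexicographic sample id. The degenerate inputs each
operation rejects (empty strata, all-zero samples, fully ambiguous
haplotype overlap, clades equal to the whole genome set, rank-deficient
designs) raise named errors rather than propagating NaN.

## Problem sizes used in the test and acceptance runs

Simulated cohorts use the default 163 infants (~640 samples, 60 taxa);
recovery and calibration rates are estimated over 20 seeds (10 for the
type-I error in the test suite); the clade-scan calibration uses a 96-leaf
tree × 80 label permutations; oracle equivalences use ≤ 8 samples per side
for matching, ≤ 20 p-values for BH, and 5-kb genomes for sketch accuracy.
These sizes were chosen to estimate each rate with a Monte-Carlo standard
error comfortably below the decision margin of the corresponding check.
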