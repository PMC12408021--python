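# gutstrain

Longitudinal case-control analysis of the infant gut microbiome at species
and strain resolution.

`gutstrain` is built for cohorts in which stool samples are collected from
infants at scheduled visits across the first year of life, a subset of the
infants develops a clinically defined condition (the motivating use case is
food protein-induced allergic proctocolitis, AP — a non-IgE-mediated food
allergy), and the question is whether microbial composition, strains, and
gene content differ between affected and unaffected infants before, during,
and after the symptomatic period. Everything is exercisable without access
to cohort data: a first-class synthetic generator produces metadata,
taxonomic profiles, strain haplotypes, pangenomes, genomes, and MAG quality
records with the statistical structure the analyses assume.

## What it computes

**Cohort structure.** Half-open age bins around scheduled visits
(thresholds 0, 0.35, 0.75, 1.5, 3, 5, 8, 10.5, 14 months); symptom-state
labels (pre-symptomatic / symptomatic / resolved); one-sample-per-infant
disease-state subsets (last pre-symptomatic, first symptomatic, first
resolved); optimal one-to-one case/control age matching by the Hungarian
method (minimising the total absolute age difference); and Fisher exact
contingency tests on demographics.

**Community metrics.** Chao1 richness (S_obs + f1²/2f2, with the
bias-corrected form at f2 = 0), natural-log Shannon diversity, Bray–Curtis
and Aitchison (CLR-Euclidean) distances, classical-MDS principal
coordinates with a one-way ANOVA of axis-1 scores by group,
diversity–age Pearson correlations, top-15 taxon summaries with an
"Others" remainder, subspecies prevalence curves, and a longitudinal
stability analysis comparing within-infant to between-infant Bray–Curtis
distances across consecutive age bins (Welch t-tests, plus a case-vs-control
comparison of within-infant distances).

**Differential abundance.** Per-feature multivariable linear models of
arcsine-square-root transformed relative abundances, y = arcsin(√x), on the
fixed effects group, delivery mode, age, and probiotic use; features
filtered at ≥0.1% relative abundance in ≥10% of samples; per-covariate Wald
p-values with Benjamini–Hochberg q across features; significance at p<0.05
and q<0.25. Taxonomic and pathway tables are handled identically.

**Strain distances and trees.** Bottom-s MinHash sketches of genomes
(canonical k-mers, fixed 64-bit mixing hash, k=21, s=1000 by default) and
the Mash distance d = −ln(2j/(1+j))/k; related (same-infant) vs unrelated
MAG distance comparisons per species with Mann–Whitney tests, over the
top-20 species by MAG count; normalised Hamming distances over marker-SNV
haplotypes; Jaccard distances over pangenome gene content; and
neighbour-joining trees with Newick round-trip IO.

**Clade enrichment scan.** Every internal node of a strain tree is tested
for case/control enrichment of its leaves with a 1-df chi-square
goodness-of-fit against the expected case fraction (nodes with fewer than 6
leaves are not tested); single-infant ("infant-oriented") clades are
flagged; clade-unique genes (present in ≥95% of clade genomes, ≤5%
outside) are extracted; and a generic hypergeometric term-enrichment test
runs against a user-supplied gene→term map.

**Classification.** A random-forest case/control classifier on features
with >1% mean relative abundance (optionally excluding therapeutically
administered probiotic species), class-weighted training, iterative
elimination of the lowest-Gini decile of features down to 120, stratified
5-fold cross-validation with in-fold standardisation, per-class accuracy
for the ≤4-month, >6-month, and all-samples strata, and signed permutation
attribution of the selected features.

**MAG quality tiers.** High: completeness ≥85 and contamination <5;
medium: 50 ≤ completeness < 85 and contamination <5; low otherwise.

## Worked example

```python
import numpy as np
from gutstrain import (SimulationConfig, generate_cohort, generate_abundances,
                       generate_strain_data, fit_associations, scan_tree,
                       clade_unique_genes)
from gutstrain.trees import build_tree, gene_content_distance

cfg = SimulationConfig(seed=42)          # 163 infants, 84/79 case split
cohort = generate_cohort(cfg)
counts, rel = generate_abundances(cohort, cfg)

res = fit_associations(rel, cohort, age_window=(0.0, 2.0))
print(res[(res.covariate == "group") & res.significant]
      [["feature", "coefficient", "p", "q", "direction"]].head(4))

strain = generate_strain_data(cohort, cfg, with_sequences=False).clade
tree = build_tree(gene_content_distance(strain.gene_presence))
tree.annotate(strain.genome_map.set_index("genome_id"))
best = next(r for r in scan_tree(tree, expected_case_fraction=0.5)
            if not np.isnan(r.p))
print(best.n_case, best.n_control, round(best.chi2, 1), f"{best.p:.2e}")
print(len(clade_unique_genes(strain.gene_presence, best.leaves)))
```

prints

```
                 feature  coefficient        p        q        direction
        Escherichia_coli     0.135488 0.000014 0.000439    case-enriched
Klebsiella_michiganensis    -0.106533 0.000057 0.000876 control-enriched
             Species_021    -0.029408 0.003193 0.032998 control-enriched
             Species_026    -0.035419 0.005770 0.044716 control-enriched
12 0 12.0 5.32e-04
223
```

The generator plants a 2-fold early-life case enrichment of *E. coli* (and
a control enrichment of *K. michiganensis*); the model recovers both with
the right sign on the arcsine-sqrt scale at q < 0.25. The pangenome-tree
scan finds the planted all-case clade (12 case / 0 control leaves,
χ² = 12, p ≈ 5×10⁻⁴) and the unique-gene extraction recovers exactly the
223 genes planted into it. The two marginally significant filler species
are the expected compositional spillover of the planted effects.

There is also a CLI (`gutstrain simulate | subset | match | diversity |
stability | ordinate | differential | sketch | magdist | tree | cladescan |
magtier | classify | run`); `gutstrain run --out out/ --seed 1` executes
the whole pipeline on a synthetic cohort and writes a manifest with output
hashes.

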