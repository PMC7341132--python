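# Methods

This note documents the models, algorithms and design choices behind
`haplogs`, in the order the pipeline runs them.

## Scope and model overview

`haplogs` analyses panels of (near-)fully inbred crop lines for genomic
selection.  The phenotype side adjusts multi-trial field data for spatial
trends and estimates broad-sense heritability; the genotype side applies
marker QC, imputation and map ordering; structure analysis derives
genomic relationships, clusters and linkage disequilibrium; and the
prediction core fits GBLUP with either single-SNP or multi-allelic
haplotype design matrices, evaluated by cross-validation schemes that do
or do not respect population structure.

The central mixed model is

    y = 1μ + Wα + e,   Var(α) = I σα²,   Var(e) = I σe²,

with W an n × m centred additive model matrix.  For single SNPs, the
entry for a line at a marker is x₁ − 2p₁ (x₁ = copies of allele 1, p₁
its panel frequency), i.e. 2p₂, p₂ − p₁, −2p₁ for the three genotypes.
For haplotype analysis, each block of L adjacent mapped markers is
treated as one multi-allelic locus whose alleles are the distinct
L-marker homozygous dosage vectors observed in the panel; W then has one
column per (block, allele) with entries x_k − 2p_k.  This equals the
conventional printed element set (2p_k, −(1−2p_k), −2(1−p_k)) up to a
global sign; because GBLUP predictions are invariant to the sign (and
any scalar rescaling) of W, the choice is a labelling convention, not a
modelling one.  The package verifies this invariance by test.

## Synthetic panel generator (`simdata`)

The generator is first-class, tested code: it produces the structured
panels every downstream property is verified against.

Mechanism.  For each chromosome a pool of `n_clusters ×
founder_count_per_cluster` founder haplotypes is generated by an
allele-copying Markov chain along the genetic map: the allele at the next
marker repeats the previous one with probability `exp(-ld_decay · d)`
(d = interval in cM) and is otherwise drawn fresh at the marker's
ancestral frequency (uniform on 0.1–0.9).  Lines are homozygous mosaics
over this pool: each cluster draws segments with weights
`(1 − divergence)` uniform over all founders plus `divergence`
concentrated on its own block of founders, and the mosaic switches
founder at rate `0.02 · ld_decay` per cM.  Divergence 0 therefore gives
statistically identical clusters; divergence 1 gives disjoint founder
sets, the pedigree-style stratification of a breeding programme.

An earlier design drew per-cluster Balding–Nichols allele frequencies
with an independent founder pool per cluster.  That reproduces the
marker-level structure but not the haplotype-level diversity: with
disjoint pools, every 5-marker block carries an allele per founder per
cluster (10–15 alleles/block), whereas real inbred panels share long IBD
segments across pedigree groups and carry far fewer (a handful per
5-marker block, with rare recombinants).  The shared-pool mosaic with a
low switch rate reproduces both levels at once, which is why it was
adopted.

Defaults are the study conditions the package targets: 383 lines in
clusters of 176/89/118; 21 chromosomes × 100 markers over 150 cM; founder
pool 3 × 4 with `ld_decay = 0.3` and `divergence = 0.5`, giving
genome-mean adjacent r² ≈ 0.56–0.57 and K-means cluster recovery with
adjusted Rand index above 0.9; two traits at entry-mean heritabilities
0.3 and 0.7; two trials on a 20 × 20 grid with a quadratic spatial
surface of half-range 1 genetic SD.

Traits.  QTL are placed at mapped markers (`qtl_mode="snp"`, additive
dosage effects) or on local haplotype windows (`qtl_mode="haplotype"`:
every distinct dosage vector over a `hap_qtl_span`-marker window gets an
iid normal effect; windows are aligned to span multiples so fixed-length
blocks of the same width can capture them exactly).  True additive
values are standardised to unit variance per trait, and residual
variance is set from the realized genetic variance so the expected
entry-mean heritability H = σg²/(σg² + σe²/n_trials) hits the target.
Trial effects are fixed offsets (SD 0.5 genetic units).

What the generator does not emulate: genotyping error, residual
heterozygosity, allele-frequency ascertainment of array SNPs,
non-additive trait architecture beyond the local-haplotype mode, and
trial-specific genotype × environment variance.  Passing tests therefore
demonstrate correctness of the algorithms under a faithful but idealised
population model, not performance claims about any real panel.

## Genotype I/O, QC, imputation (`genio`)

HapMap (TASSEL dialect) text is the interchange format: 11 metadata
columns then one genotype column per line, with single-letter IUPAC
calls (ambiguity codes = heterozygotes), two-letter diplotypes, and
N/NN as missing; readers accept gzip.  The A allele is the first listed
in the `alleles` column — a deterministic, file-derived convention.

QC removes markers with minor-allele frequency strictly below the
threshold (default 0.05; MAF computed on non-missing calls) or missing
fraction strictly above it (default 0.10), both evaluated on the raw
matrix in one pass.  Imputation follows the LD-kNNi recipe with the
method's published defaults k = 5, l = 30: for each missing call the l
markers most correlated with the target marker define a local similarity
space, the k nearest lines with observed calls vote with weight
1/(distance + 1e-6), and the result is rounded to {0, 2} (the panel is
inbred, so residual heterozygotes resolve to the nearest homozygote
before haplotype construction; ties round up to 2).  Observed calls are
never altered.  Map ordering sorts by (chromosome, cM, marker id) —
the marker-id tie-break makes block construction reproducible — and
drops unmapped markers with a logged count.

## Field adjustment and heritability (`fieldadj`)

The moving-grid adjustment computes, per plot, the mean of observed
values in the surrounding 3 × 3 ring (8 plots, shrinking at field
edges; a 5 × 5 ring is available via `window=24`), regresses plot value
on this covariate with a single slope, and subtracts the fitted,
centred covariate term.  Regression on the covariate — rather than
direct subtraction of the moving mean — keeps genetic signal that is
spatially smooth from being removed twice and preserves each trial's
grand mean exactly.  A covariate with (near-)zero variance (constant
field) skips adjustment with a warning.

Trial combination centres each trial at zero and averages a line's
centred values over the trials it appears in.  Variance components for
value = trial (fixed) + line (random) + residual are estimated by REML
via `statsmodels` MixedLM with a derivative-free (Powell) optimiser —
the gradient-based default can hit singular information matrices when
σg² is small.  Residual variance is identified by replication of lines
across trials, so a single unreplicated trial is an error; the
augmented-design check structure is not modelled.  Broad-sense
heritability is H = σg²/(σg² + σe²/n) on an entry-mean basis over n
trials.

## Haplotype blocks (`hapblocks`)

Each chromosome with m markers yields floor(m/L) consecutive,
non-overlapping blocks of exactly L map-ordered markers; the trailing
m mod L markers are dropped with a log entry.  Dropping (rather than
keeping a short final block) is what the fixed-length description and
genome-wide block counts of published analyses imply.  Blocks never
span chromosomes.  Alleles are numbered by first appearance in line
order — deterministic and order-stable — and rare alleles are never
collapsed, since observed analyses report raw allele counts into the
hundreds.  Summaries report per-chromosome and total block counts,
max/mean allele counts, and mean block span in cM averaged within
chromosomes first, then across.

## Population structure (`popstruct`)

The GRM is VanRaden method 1 exactly as written above; the IBS distance
is 1 − mean shared-allele proportion.  K-means requires coordinates, so
the 1 − IBS matrix is embedded by classical multidimensional scaling
(top 10 principal coordinates by default) and clustered by Lloyd
iterations restarted from 100 seeded initialisations, keeping the lowest
within-cluster sum of squares — operationally equivalent to repeated
Hartigan–Wong local search.  Cluster labels are renumbered by
decreasing size.  K defaults to 3 (pedigree-informed) and is exposed.
PCA is on the column-centred, unscaled dosage matrix (standard for
dosage data), with the largest-magnitude loading of each component made
positive for sign stability.

Adjacent-marker r² is computed from two-locus haplotype frequencies
read directly off homozygous genotypes — valid because inbred lines
expose gametic phase — and equals the squared Pearson correlation of
dosage vectors on such data (asserted to 1e-12 in tests).  Monomorphic
pairs are skipped; the genome mean is the mean of per-chromosome means.

## GBLUP and genomic REML (`gblup`)

Design-matrix frequencies default to the full genotyped panel (training
plus candidates): genotypes of selection candidates are always available
in genomic selection, and a panel-wide frequency reference keeps
training and validation rows in the same column space.  A training-only
reference is available for sensitivity checks.  Haplotype alleles
observed only outside the reference keep their columns with p_k = 0 —
no column is silently dropped.

REML uses the kernel form: Var(y) = G_W σα² + I σe² with
G_W = W_train W_train′, so the marker-effect variance is estimated
directly.  The kernel is normalised to mean diagonal 1 (restoring the
original scale on output), the fixed effect (intercept) is projected
out with an orthonormal complement, G_W is eigendecomposed once, and
the restricted likelihood — profiled over σe² — is maximised over
log λ (λ = σα²/σe²) by bounded scalar search on [−20, 20], then
polished by a root-find on the analytic score.  This one-dimensional
spectral formulation was chosen over EM iterations because it cannot
diverge, costs one symmetric eigendecomposition, and the score polish
pins the optimum to the precision of the estimating equation rather
than of likelihood comparisons (which flatten near the optimum at
~√machine-epsilon).  The kernel normalisation also makes the fit
exactly invariant to rescaling W → cW.  A constant phenotype collapses
both components to zero and is flagged unconverged; a λ estimate at the
search bound is likewise flagged.

Prediction is train-then-project: μ̂ is the GLS intercept,
α̂ = σ̂α² W_train′ V⁻¹ (y_train − 1μ̂), and additive values a = Wα̂ for
all lines through the same frequency-referenced W.  This is
algebraically identical to the joint mixed-model equations with
unobserved phenotypes, and tests assert agreement with an explicit
effect-level MME solve to 1e-8.  When σ̂e² is (numerically) zero, V is
inverted by pseudo-inverse, which reproduces centred training
phenotypes exactly when W has full row rank.

## Validation schemes and comparisons (`crossval`)

k-fold: shuffle, cut into k near-equal folds (sizes differ by ≤ 1),
rotate; defaults k = 4 with 4 repetitions, so every line validates once
per repetition.  Stratified sampling: round-half-up(fraction × cluster
size) lines drawn from each cluster without replacement (clamped so
both sets stay nonempty); defaults 75% and 16 replicates.  The
per-cluster round-half-up rule with no total reconciliation is used
because, for a 383-line panel in clusters of 176/89/118 at 75%, it
yields the canonical 288-line calibration set (132 + 67 + 89) and 95
validation lines — published totals for this layout are internally
inconsistent (288 + 94 ≠ 383), so a deterministic rule had to be fixed.
Leave-cluster-out holds out each cluster in turn.

Predictive ability is the Pearson correlation between observed adjusted
phenotypes and predicted additive values in the validation set.  The
T statistic r√(n−2)/√(1−r²) is referred to t with n − 2 degrees of
freedom, with n the validation-set size (the standard reading of the
formula).  Model comparisons work on the Fisher-Z scale: per-replicate
z differences go into a paired t-test, and the effect is reported as
percent change in mean r.  Aggregation reports both the mean of r and
the inverse-transformed mean Z.

## Numerical choices and degenerate inputs

- REML: λ searched on log scale in [−20, 20]; score root-find tolerance
  1e-14; eigenvalues clipped at 0; variance floor 0.
- Imputation rounding: weighted mean dosage ≥ 1 → 2, else 0.
- Map positions are compared after 4-decimal formatting in HapMap files.
- Degenerate inputs raise informative errors rather than warnings where
  the result would be undefined: all markers removed by QC, a marker
  missing in every line, monomorphic panels in the GRM, constant
  vectors in correlations, singleton clusters in within-cluster means
  (reported as missing, not an error).

## Known limitations

- The phenotype model has no genotype × environment interaction; trials
  differ only by offsets and independent residuals.
- The moving grid assumes plot values on a (near-)complete rectangular
  grid; highly fragmented layouts reduce the covariate's neighbour count
  and its value.
- Spectral REML scales with the cube of the training-set size (one
  eigendecomposition); panels of a few thousand lines are fine, hundreds
  of thousands are not the target.
- Heterozygotes are tolerated through QC but not through haplotype
  construction; the package is built for inbred material.
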