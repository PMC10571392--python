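# Methods

`metasig` implements the downstream analytical machinery of a two-cohort
case/control gut-metagenome study of chronic kidney disease: genome-catalog
bookkeeping for metagenome-assembled genomes (MAGs), cross-cohort
differential-abundance signature calling, genome-centric functional
configuration, microbiome-based explainability models for serum uremic
toxins, community ordination and variance partitioning, and disease
classification with severity generalization.  Everything is exercisable on
synthetic cohorts with planted, recoverable ground truth; this note records
the models, the parameters that matter, and the design decisions taken where
the design was genuinely open.

## MAG catalog rules

A genome bin's quality score is `QS = completeness − 5 × contamination`
(percent units); QS is always recomputed from completeness and
contamination, never read from an input file.  MIMAG tiers: *high* requires
completeness > 90%, contamination < 5%, presence of all of the 5S/16S/23S
rRNA genes and ≥ 18 tRNAs; *medium* requires completeness ≥ 70% and
contamination < 10%.  The catalog filter keeps bins with completeness > 70%,
contamination < 5% and QS > 60 (all strict inequalities).

Within-sample bin merging treats two bins as candidate fragments of one
genome when they have approximately equal sequencing depth and GC content
and an identical, non-empty species label.  "Approximately equal" is
interpreted as: relative depth difference `|d1−d2| / mean(d1,d2)` ≤ 10%
(depth spans orders of magnitude, so a relative scale is the natural one)
and absolute GC difference ≤ 2 percentage points (GC is already a bounded
percentage; a `gc_relative` switch is provided for the other reading).
Because pairwise mergeability is not transitive, merge groups are the
connected components of the mergeability graph (single linkage) — a
deterministic, input-order-independent closure.  Merged depth and GC are
size-weighted means; completeness and contamination of a merged record
cannot be derived from its parts and are flagged for re-estimation instead.

Dereplication is greedy leader clustering on a precomputed pairwise
nucleotide-identity matrix: records are visited in decreasing QS order (ties
broken lexicographically by id for determinism); each joins the first
cluster whose *representative* it matches at identity > 0.95, else founds a
new cluster.  Visiting order guarantees every representative is the
highest-QS member of its cluster.  Sequence-level average-nucleotide-identity
computation is out of scope (an external aligner's job); a toy k-mer
containment index is included only to build self-consistent fixtures.
Taxon abundance at any rank is the sum of member-species relative
abundances, which conserves per-sample totals exactly.

## Cross-cohort signature discovery

Within each cohort every feature is tested case vs control with the
two-sided Wilcoxon rank-sum test: exact by enumeration when the smaller
group has ≤ 8 samples and the pooled values are tie-free, otherwise the
normal approximation with tie and continuity corrections (the exact path is
verified against a full enumeration oracle in the test suite).  Fold change
is the ratio of group means with a table-global pseudocount of half the
smallest nonzero abundance — means rather than medians because zero-heavy
features have degenerate medians, and a shared pseudocount so fold changes
are comparable across features.  A feature with fold change exactly 1 has no
direction and is never called.

The two cohorts are combined by Fisher's method (χ², 4 degrees of freedom);
a feature is called a signature only when (1) q < 0.2 and fold change > 1.2
in *each* cohort with a coherent enrichment direction (the fold-change
criterion is applied symmetrically: > 1.2 for case-enriched, < 1/1.2 for
control-enriched), and (2) the FDR-adjusted combined p is < 0.05, computed
across the full feature universe rather than only per-cohort survivors so
that criterion (2) is a property of every feature.  The default q-value is
Benjamini–Hochberg; an Efron-style empirical-null estimate is also offered
(probit-transformed p-values, empirical-null density fit, local estimates
converted to tail-area q by running means in significance order) because
local-FDR-style tools are common in this literature and the two can differ.

Covariate adjustment uses a rank linear model per feature: abundances are
rank-transformed and regressed on the group indicator plus sex, age and BMI;
the group coefficient's two-sided p is reported.  This is a documented
stand-in — simple, monotone-invariant, and well calibrated in the planted
simulations — not a claim about any particular published analysis.

## Genome-centric function

Module definitions are boolean step expressions over KO identifiers:
top-level space-separated blocks are sequential steps, commas separate
alternatives, `+` joins complex members (both required), `-`-prefixed
components are optional and ignored (a fully optional step is dropped), and
parentheses nest arbitrarily.  Completeness of a genome for a module is the
fraction of satisfied steps; "complete" means all steps satisfied
(a `min_completeness` override exists).  The parser round-trips its own
serialization and reports positions on malformed input.

Occurrence contrasts compare presence of a function between case-enriched
and control-enriched species sets by the two-sided Fisher exact test — the
sum of probabilities of all tables with the observed margins whose point
probability does not exceed the observed one — BH-adjusted across
functions; completeness contrasts apply the same machinery to the
complete/incomplete dichotomy.  Functions present in every species or in
none carry no information and get p = 1 by convention.

Biosynthesis capabilities (short-chain fatty acids, secondary bile acids,
uremic-toxin precursors) are flagged by the presence of at least one marker
synthetase.  The shipped rule table (`data/capability_rules.tsv`, versioned,
editable) maps each capability to enzyme names and representative KO
identifiers — e.g. tryptophanase/K01667 for the indoxyl-sulfate precursor,
choline trimethylamine-lyase/K20038 for the TMAO precursor.  It is a
best-effort configuration meant to be inspected and edited, not an
authoritative accession list.

Gene-centric functional abundance is the per-sample sum of the relative
abundances of a function's member genes; unmapped genes are ignored and
duplicate gene ids rejected.

## Toxin explainability

For each toxin (indoxyl sulfate, p-cresyl sulfate, phenylacetylglutamine,
trimethylamine N-oxide) a random-forest regressor is trained on species
relative abundances.  Concentrations are log-transformed and z-scored within
cohort before modeling: concentrations are positive and right-skewed
(log-normal-like), the planted generative signal is linear on the log
scale, and within-cohort scaling removes between-cohort quantification
batch effects; predictions are thereby invariant to affine rescaling of the
assay.

Explainability is the squared Pearson correlation between leave-one-out
cross-validated predictions and observations (1 − SSE/SST is reported
alongside for transparency).  Species are ranked by out-of-bag IncMSE: for
every tree, each species' values are permuted within that tree's out-of-bag
samples and the OOB MSE increase is averaged over trees (effective number of
permutation draws = trees × repeats).  Out-of-bag evaluation matters: the
same permutation measured on training data is systematically inflated for
overfit forests and mis-ranks null features.  Sequential selection refits
the model on growing top-k prefixes (default grid 1–30 by 1, then to 150 by
5, spanning well past the contributor-set sizes of interest) and picks the
smallest k maximizing LOOCV R².  Transfer evaluation trains on one cohort
and predicts the other (or a 70/30 within-cohort split); train/test sample
overlap is rejected.

Forest defaults follow the regression conventions of the R randomForest
implementation that the IncMSE measure comes from — 500 trees, p/3 features
per split — with a leaf size of 2: on continuous, moderately noisy targets
the larger classical leaf of 5 over-smooths at the n ≈ 150 sample sizes this
package targets, measurably attenuating LOOCV R²; leaf size 2 recovers that
loss without destabilizing the importance ranking.  A seed is required for
every stochastic stage.

Known limitation: a forest is a piecewise-constant approximator, so its
LOOCV R² systematically under-reads the planted signal fraction when the
signal is spread over several comparable contributors; the attenuation
grows with the number of nuisance species and with the evenness of
contributor weights, and is insensitive to tree count, features-per-split
and leaf size within the random-forest family.  Ordinary least squares on
the true contributors recovers the planted fraction (the generator's own
calibration check), so the gap is model-approximation error, not a defect
of the LOOCV machinery.  The calibration checks run at 30 species to keep
that error small; at 300 species the same pipeline still ranks and selects
contributors correctly but reports lower absolute R².

## Community statistics

Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` is the sample-space metric
(bounded in [0,1], not a metric in the triangle-inequality sense; the suite
asserts identity and symmetry only).  PCoA eigendecomposes the
double-centered Gower matrix; negative eigenvalues are retained in the
report but excluded from coordinates and from the variance-explained
denominator, the common convention for "percent variance" statements.

PERMANOVA uses Anderson's pseudo-F on the Gower-centered matrix via a
model-matrix (hat-matrix) formulation, which handles categorical factors
(dummy-coded) and continuous covariates (centered) uniformly.  Marginal
(each factor alone) is the default; sequential mode attributes each term
the increment of explained sum of squares over the preceding model against
the full-model residual.  p-values come from permutations of sample
identity, `p = (1 + #{F ≥ F_obs}) / (n_perm + 1)` with 1000 permutations by
default; an exhaustive mode enumerates all distinct label assignments for
tiny designs and is checked against an independent enumeration oracle.

Ordination axes are screened by two clauses: variance contribution > 3% and
a Tracy–Widom statistic above the tabulated TW1 1−α quantile
(0.9793 at α = 0.05).  The statistic normalizes the leading eigenvalue
Patterson-style; the effective sample size is moment-estimated from the
eigenvalues *below* the tested one — so a dominant axis cannot distort its
own null scale — and clipped at the true sample count, falling back to it
when the moment estimate is degenerate.  A permutation fallback
(independent column shuffles) is provided and is what the null-calibration
tests exercise, since the analytic normalization is approximate for
non-Gaussian compositional data.

The Mantel statistic is the Pearson correlation of off-diagonal distances,
with rows/columns of the second matrix permuted jointly (9999 permutations
by default, exhaustive enumeration for n ≤ 6).  Alpha diversity reports
richness (features above a detection threshold, default 0), Shannon entropy
(natural log, proportions renormalized over detected features — hence scale
invariance), and Pielou evenness H/ln(richness), undefined at richness ≤ 1.

## Classification

A random-forest classifier (500 trees, √p features per split — the
classification conventions) discriminates cases from controls.  Reported
discrimination is the AUC with a DeLong 95% confidence interval computed
from the structural components on the midrank representation (logit-free,
clipped to [0,1]; coverage is verified at ≈95% in simulation).  Designs:
stratified 70/30 split; cross-cohort transfer (train on the entirety of one
cohort, test on the other, feature intersection only, no zero-filling —
silently zero-filled features distort forests); and CKD generalization —
train on 70% of healthy controls plus all ESRD patients, test CKD3/4 and
CKD5N each against the held-out 30% of controls.  Severity trends sum
case-enriched and control-enriched signature abundances per sample, compare
consecutive severity groups by t-tests (BH-adjusted) and report a Spearman
trend over the ordered group codes.

## The synthetic-cohort generator

The generator emulates the statistical structure of the study, not any real
cohort's parameter values:

* **Composition.** Per species, a base log-abundance from a power-law-like
  mean spectrum (`−1.5 · ln rank`, rank decoupled from species id), sample
  noise log-SD 1.0, per-species prevalence drawn uniformly from [0.7, 1.0]
  and shared by all arms (zero-inflation), then row renormalization to
  relative abundances.  This reproduces the heavy-tailed, sparse,
  compositional character of gut-metagenome tables.
* **Disease effect.** A fraction of species (default 50 of 300) is shifted
  in cases by ±`effect_log2fc · ln 2` (default 1.5), scaled by a severity
  gradient over HC < CKD3/4 < CKD5N < ESRD (multipliers 0, 0.5, 0.8, 1.0).
* **Cohort effect.** Species-level random log offsets (SD 0.5) shared by
  cases and controls of a cohort — "cohort origin" as an independent
  variance component that the two-cohort coherence rule must overcome.
* **Toxins.** A weighted sum of contributor-species log-abundances,
  standardized, plus Gaussian noise on the log scale, then exponentiated for
  positivity; the realized signal fraction is recorded in the ground truth.
  Weight magnitudes are drawn uniformly from [0.5, 1.5] with random sign:
  a planted "contributor" must carry recoverable weight by construction,
  otherwise contributor-recall statements are ill-posed (a weight near zero
  plants a contributor in name only).  Contributors are drawn from the
  high-prevalence stratum
  (prevalence ≥ 0.9): real toxin producers are prevalent commensals, and a
  contributor absent from half the samples would make the planted "linear
  signal" an artifact of the pseudocount.  The pseudocount for the signal is
  per-species (half the species' own smallest nonzero abundance) so an
  absence is a mild shortfall, not an extreme leverage point.
* **Functions.** Planted KOs co-occur with the planted enrichment direction
  (presence 0.9 in same-direction species, 0.1 elsewhere) on a background
  presence of 0.35.
* **Bins.** Identity-clustered genome records (within 0.98, between 0.85)
  with cluster-coherent depth/GC/species labels, exercising both merging and
  dereplication.

What the generator does **not** emulate: phylogenetic correlation between
species, co-abundance network structure, sequencing-depth-dependent
detection, compositional feedback between planted effects beyond
renormalization, longitudinal structure, or the real cohorts' effect-size
spectra.  Passing the planted-truth tests therefore shows the machinery is
correct and calibrated under its stated model, not that the real biological
effect sizes are recoverable at these sample sizes.

## Problem sizes and numerical choices

Simulation-backed checks are sized for a single CPU: the full-scale
signature recovery runs at the study design's defaults (two cohorts,
300 species, 100 samples/arm); null calibrations use 20 replicates for call
rates, 300–500 replicates for rejection rates, and 99–199 permutations
where a permutation p is only thresholded; toxin-model calibration uses
30 species, 150 samples, 5 contributors, 150–300 trees and 2–5 replicates
per signal fraction; classification checks use 60–100 species and 40–60
samples/arm.  Ties in greedy ordering break lexicographically; exhaustive
permutation comparisons use a relative tolerance of 1e−9 on the test
statistic (dummy-coding order changes the floating-point sum); p-values of
0 are clamped to the smallest positive float before Fisher combination,
with a warning.
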