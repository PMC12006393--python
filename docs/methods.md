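# Methods

`cocpipe` reimplements, as a tested library, the computational analysis of
paired oocyte–granulosa cumulus-oocyte complexes (COCs) from superovulated
and naturally ovulated mice of two ages, together with a synthetic paired
cohort generator that plants every effect the analysis stages are meant to
recover. This note documents the models, the generator's assumptions, the
numerical choices, and the known limitations.

## The synthetic cohort

### Design

Four condition groups — naturally ovulated young (NY), superovulated young
(SY), naturally ovulated old (NO), superovulated old (SO) — each with
`n_mice_per_condition` mice (default 4) contributing `cocs_per_mouse` COCs
(default 8). Every COC yields one oocyte sample and one granulosa bulk, so
pairing information is exact. Counts are negative-binomial with a single
global dispersion (default 0.1, variance μ + 0.1 μ²): real datasets show
gene-specific dispersion, but a global value keeps the generator a
two-parameter noise model and is sufficient for calibration testing.
Expected per-sample totals equal a drawn library size (uniform in
50 000–100 000 reads) times a per-mouse log-normal depth multiplier
(sd 0.1), the generator's replicate-level random effect. About 1% of genes
are mitochondrial and pinned to 2% of the expected mass, so the 5% QC gate
passes for healthy samples.

Two seeds control the randomness. `biology_seed` (default 0) draws the
*study*: gene allocation, baseline abundances, per-gene effect sizes, and
which ligand-receptor pairs and regulons respond to superovulation. `seed`
draws the *samples*: mice, subgroup assignment, library sizes and counts.
Changing only `seed` therefore resamples a new cohort from the same
underlying study — which is what lets a classifier trained on one cohort be
evaluated on an independently resampled one.

### Planted effects

* **Condition shifts.** 200 genes carry a superovulation log2 shift (sign
  random, magnitude uniform in [1, 2] at the default scale 2); 150 genes an
  aging shift (magnitude [0.5, 1]). Old superovulated samples receive only
  `interaction_attenuation` (default 0.5) of the superovulation shift — the
  planted non-additivity.
* **Latent subgroups.** Each superovulated COC belongs to S_N (receiving
  `sn_effect_fraction` = 0.3 of the full superovulation shift, hence
  resembling natural ovulation) or S (the full shift); `sn_fraction`
  controls the split (default 0.5).
* **Communication.** 60 ligand-receptor pairs, 30% with 2–3 receptor
  subunits. All pair genes share a per-COC log-normal co-expression factor
  (sd 0.2 log2), and 80% of pairs additionally carry an upward communication
  shift (3 log2 units, scaled by the COC's superovulation response). The
  shift is applied to the ligand and all subunits in *both* compartments of
  the COC, so all four signaling directions are informative. Ligand and
  receptor baselines are boosted 8-fold: the top-expressed filter of the
  scoring method presumes communication genes are robustly expressed, and
  near-zero counts would otherwise make product scores collapse to zero.
* **Regulons.** 20 disjoint regulons of 40 targets. True activity is 0.2 at
  baseline; 80% of regulons are condition-responsive, rising by 0.6 times
  the superovulation response (S ≈ 0.8, S_N ≈ 0.38). Target expression
  scales by 4 log2 units per unit of activity (the TF gene itself by half
  that).
* **Expression variability.** 100 genes (drawn from robustly detected
  baselines) get a mean-preserving bimodal log2 shift ±δ in superovulated
  oocytes, with δ solved in closed form so the total variance is multiplied
  by `entropy_inflation` (default 4) given the NB dispersion. A pure scale
  inflation would be invisible to a range-normalized entropy; heterogeneous
  sub-states are both detectable and a biologically sensible reading of
  "increased transcriptional heterogeneity".

The effect scales above were designed jointly so that the planted
three-group structure (N / S_N / S) is clearly separable — between-cluster
separation comfortably above within-cluster spread for both the
communication and the activity views — matching a study in which the
subgroups emerge as clean dendrogram clades. They are study-condition
definitions, not fitted quantities.

### Dual-protocol maturation experiment

Each gene carries one maternal-remodeling class (8% re-poly-adenylated, 8%
de-adenylated stable, 8% de-adenylated degraded, rest unclassified) with
tail lengths, read counts and adjusted p values planted at least twice
beyond every classification threshold (tail change ≥ 40 nt vs the 20 nt
gate; padj ≤ 5·10⁻⁴ vs 10⁻³; ≥ 100 reads vs 50; log read ratio ≤ −4 vs −2).
Degraded genes are kept modest in abundance (100–400 reads) and stable
genes' abundance drift small (ln ratio ≤ 0.1) so per-sample depth
normalization does not convert their mass changes into spurious shifts of
the other classes. Expected counts follow abundance for the total-RNA
protocol and abundance × capture for the poly-A protocol, with capture =
tail/(tail + 25 nt) — a saturating one-parameter curve. Immature
("maturation-disrupted") samples retain the GV state.

### Embryo series

Reference embryos span 2-cell to blastocyst (stage scores 1–5, six embryos
per stage). 150 marker genes have log2 expression linear in stage with
|slope| uniform in [1.2, 2.2] log2 per stage — deliberately clearing the
downstream |lfc| > 1 selection gate with margin, so a marker's recovery is
not a coin flip against estimation noise — plus Gaussian log-noise
(sd 0.1) and small NB dispersion (0.02). Test embryos carry groups NY
(n = 22, mean stage 4.2), S_N (17, 3.6) and S (21, 3.0) with stage-score
sd 0.3, clipped to [1, 5].

## Analysis stages

**QC** keeps a sample iff total reads ≥ 5000, detected genes ≥ 1000 and
mitochondrial fraction ≤ 5%; exclusions are reported per criterion, and the
mitochondrial gate is skipped (with a warning) when no flags exist.

**Normalization.** Log2 counts-per-million with pseudocount 1 for ranking
and classification; a length-scaled, depth-scaled rate (TPM-style) for
communication scoring, which multiplies expressions across genes and so
needs length-comparable units. These are deliberate, fully specified
stand-ins for heavier variance-stabilizing transforms: every downstream
stage needs only monotone, depth-corrected expression.

**Differential expression** is pseudo-bulk (counts summed per mouse), with
median-of-ratios size factors (renormalized to geometric mean 1;
total-count fallback when no gene is positive everywhere), a gene-wise NB
GLM with log link and size-factor offsets fitted by batched IRLS, and
two-tailed Wald tests with BH adjustment per contrast. Dispersion is a
residual method-of-moments estimate from a Poisson pre-fit (df = n − p),
floored at 10⁻⁸ and shrunk halfway toward an a₀ + a₁/mean trend fitted
across genes by non-negative least squares. This scheme works for any
full-rank design, including two-group designs with mouse-of-origin
covariates. The default design is age × treatment with an interaction;
"superovulation in old" is tested as the treatment + interaction linear
combination. Genes with NA p values (non-converged) are dropped from the
BH family; all-constant genes are flagged with p = 1. There is no outlier
replacement, no independent filtering and no fold-change shrinkage — the
aim is calibrated calls on synthetic data, not bit-compatibility with any
particular package. At the calibration condition (1000 null genes, 4 vs 4
pseudo-bulks) the empirical type-I error at nominal 0.05 is ≈ 0.064; the
residual inflation is the familiar cost of plugging an estimated dispersion
into normal Wald quantiles at 6 residual degrees of freedom.

**Communication scoring.** Score = ligand expression (sender) × minimum
subunit expression (receiver), per COC and per direction (OC→GC, GC→OC,
GC→GC, OC→OC; autocrine directions reuse the same cell for both roles).
Pairs are pre-filtered to the top-k (default 100) expressed ligands and
receptors, ranked per role in the relevant cell type with lexicographic tie
breaks; never-expressed genes cannot rank. Pair screening is
Kruskal–Wallis across cluster labels with Holm adjustment over the whole
screen. Profile clustering is complete-linkage on Euclidean distances of
z-scaled log1p scores; the pipeline clusters at k = 3.

**Activity scoring** ranks a sample's genes by expression (ties by gene id)
and integrates the gene set's recovery curve over the top 20%, normalized
by the best possible curve — a rank-based score in [0, 1], invariant to
monotone transforms. Regulon–pathway association uses Jaccard overlap plus
an upper-tail hypergeometric test, BH-adjusted. Differential activity is a
two-tailed permutation test on the difference of group means: mouse labels
are permuted when mice are nested in groups; otherwise labels are permuted
within mice. The null is enumerated exhaustively when the assignment count
permits (≤ 50 000), giving p = #{|Δ| ≥ |Δobs|}/total; Monte-Carlo sampling
with the add-one correction otherwise. Because the score is rank-based and
ranks are compositional, a strong planted program in one gene set can shift
the measured activity of unrelated sets; this is a property of the score,
not of the generator.

**Consensus subgroups and the dual classifier.** Cluster labelings from
the two views are aligned to {N, S_N, S} — N is the cluster most dominated
by naturally ovulated samples, S_N the remaining cluster whose centroid is
nearer N's (a tie raises, requiring manual mapping) — and intersected;
disagreements become `excluded`. The expression view selects genes by
baseMean > 50, adjusted p < 0.01 and |log2FC| > 0.7 from an S_N-vs-S NB
Wald fit with mouse-of-origin in the design, keeps genes with |PC1 loading|
> 0.09, prunes near-zero-variance, correlated (|r| > 0.9, drop the feature
with larger mean absolute correlation) and exactly linearly dependent
features (rank-revealing QR), and runs a genetic algorithm (inclusion
bitmasks; fitness = mean stratified-CV accuracy of a linear SVM minus
0.001 × subset size; tournament k = 3, uniform crossover 0.5, bit-flip
mutation 1/n, elitism 1; empty chromosomes repaired). The activity view
uses regulons whose permutation-test activity difference is BH-significant
at 0.05. Each view trains a soft-margin linear SVM with the cost chosen by
exhaustive stratified grid CV over {0.01, 0.1, 1, 10} (ties prefer the
smaller cost; adaptive resampling is deliberately replaced by the
exhaustive grid — a four-point grid makes it affordable and deterministic).
Predictions require agreement of the two views; disagreement yields NA.
When consensus labeling cannot produce at least four training samples per
subgroup, the classifier abstains entirely (NA rate 1) rather than train on
noise.

**Remodeling classification** applies the tail gate (|Δtail| > 20 nt,
padj < 0.001, |Δtail| ≥ 0.7 × max of the two tails — read as per-gene
across the two stages — and ≥ 50 reads in the higher-expressed stage), then
signs: lengthening → re-poly-adenylated; shortening with log read ratio
> 0 → stable, < −2 → degraded, otherwise unclassified. Zero GV reads get a
pseudocount of 1 with a warning. The concordance test computes per-sample
log2 fold changes of the disrupted group against the mature group's mean
(pseudocount 1, on depth-normalized linear expression), takes the
per-sample median across each class's genes, tests it against zero with a
two-sided Wilcoxon signed-rank test, and BH-adjusts within the six-test
family. A protocol counts as changed only when the adjusted p is below
0.05 *and* the |median lfc| is at least 0.25: a statistically significant
but negligible shift — the inevitable composition artifact of per-sample
depth normalization when degraded genes lose mass — is not a pattern
violation. Verdicts: re-poly-adenylated requires a drop in the poly-A
protocol only; stable a rise in the poly-A protocol only; degraded a
same-direction change in both; classes under five genes are underpowered.

**Pseudotime.** Markers are selected by (i) membership in the top 30% most
variable genes (a size-scaled stand-in for a top-3000 highly-variable list
on a transcriptome-sized universe), (ii) |Spearman ρ| > 0.85 vs ordinal
stage at BH-adjusted p < 0.01 (the absolute value makes down-regulated
markers eligible, consistent with the sign-matched fold-change criterion),
and (iii) |log2FC| > 1 across both 8-cell→morula and morula→blastocyst with
the sign of ρ. The principal curve starts at PC1 of the panel PCA,
alternates projecting embryos onto the current polyline and smoothing each
PC coordinate against the arc-length ordering (local averaging, fixed span
0.6) until the mean projection distance changes by < 10⁻⁴ (≤ 50
iterations; non-convergence returns the last iterate, flagged). End
segments are extended linearly, so collinear data reproduce the
least-squares line projection exactly. Pseudotime is normalized arc length
in [0, 1], oriented so the earliest reference stage maps low. Group
comparisons are pairwise two-sided rank tests (exact when n + m ≤ 20
without ties).

**Variability and interaction.** Per-gene entropy uses 10 equal-width bins
over the value range: −Σ p log₂ p / log₂ 10, zero for constant input, one
for uniform occupancy; it is affine-invariant for a single vector. For
*differential* entropy the two conditions share one bin grid spanning the
pooled range (the wider-spread condition occupies more bins — without a
shared grid a pure variability difference would be invisible); p values
come from label permutations (the pooled grid is permutation-invariant, so
binning is done once), BH-adjusted, with all-zero genes excluded. The
interaction decomposition fits a PCA on young samples restricted to the
superovulation-responsive genes (centered on young means), projects all
samples with the same centering and loadings, orients PC1 so SY exceeds NY,
and reports SY−NY, SO−NO, NO−NY, SO−SY and the interaction
(SO−NO)−(SY−NY) — identically equal to the difference of the two
superovulation effects. Confidence intervals are percentile bootstrap over
mice resampled within condition (samples from one animal are technical
replicates); with fewer than two mice in any condition only point
estimates are returned.

## Problem sizes used by the acceptance battery

Type-I calibration: 10 replicates × 1000 null genes, 4 vs 4 mice. Consensus
recovery: 20 resampled cohorts of 10 + 10 + 10 young COCs. Classifier:
train and test cohorts of 20 superovulated COCs each; GA population 24 for
8 generations. Interaction calibration: 50 runs × 800 genes, 16 mice, 1000
bootstrap draws. Remodeling: 2000 genes, 16 + 16 samples per protocol.
Pseudotime: 30 reference + 60 test embryos. These sizes were chosen as the
smallest at which the measured rates are stable against the assertion
thresholds; the full battery runs in about two minutes on one CPU.

## Limitations

* The generator plants log-linear shifts on independent NB genes; it has no
  gene–gene correlation beyond the explicit ligand-receptor and regulon
  structure, no realistic mean–dispersion trend, no zero inflation and no
  batch structure. Passing recovery tests show the *methods* are wired
  correctly and calibrated under the model they assume, not that they are
  robust to everything real data does.
* Rank-based activity scores are compositional: large planted programs
  shift the measured activity of unrelated gene sets. Interpret activity
  differences of small sets near strong programs with care.
* The NB Wald test is mildly anticonservative at very small replicate
  counts (≈ 0.064 at nominal 0.05 for 4 vs 4) — inherent to estimated
  dispersions with normal quantiles and the single moderation step.
* Regulon inference, read-level simulation, copy-number analysis and
  cross-species comparisons are out of scope; regulons and ligand-receptor
  pairs are inputs.
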