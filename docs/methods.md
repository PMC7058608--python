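# Methods

## The staging axis

Samples from a multi-donor regional expression atlas are assigned to one of
six Braak stage-related region groups via their anatomical structure
(structure → region map; unmapped structures stay unassigned and are
ignored).  The region index 1–6 is treated as an equally spaced ordinal
label: correlations are plain Pearson correlations against the integers
1–6, with no rank transform.  All expression is assumed log2-scale and
normalized on input (a `log2(x+1)` flag exists for count-like matrices).

## Per-donor statistics and meta-analysis

Donors are analyzed separately to avoid capturing donor-specific offsets,
then pooled.  For each gene and donor:

* stage correlation r across the donor's labeled samples; genes with zero
  variance in a donor contribute no estimate there and genes with fewer
  than two usable donor estimates are dropped (and counted);
* fold change FC = mean(R6) − mean(R1) on the log2 scale (orientation:
  genes rising along the axis have positive FC and positive r), with the
  non-pooled variance s²₁/n₁ + s²₆/n₆ and a Welch t-test.

Pooling uses DerSimonian–Laird: fixed weights wᵢ = 1/vᵢ, heterogeneity
Q = Σwᵢ(eᵢ−ē)², tau² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), summary effect
Σeᵢ/(vᵢ+tau²) / Σ1/(vᵢ+tau²), se = (Σ1/(vᵢ+tau²))^(−1/2), and a two-sided
t-test with k−1 degrees of freedom (5 for six donors).  Correlations are
pooled in Fisher-z space (var 1/(n−3)) and the summary is back-transformed
with tanh, so the pooled correlation stays in (−1, 1).  When Q ≤ k−1 the
estimator reduces exactly to fixed-effect inverse-variance pooling.  BH
correction is applied separately to the correlation and fold-change
p-value columns, each across all retained genes (the two families answer
different questions; correcting them jointly would couple their thresholds
for no gain).

## BRG selection

Three rankings over the gene summary — descending |r|, descending |FC|,
ascending BH-corrected FC p-value — are each cut at exactly
⌊fraction·G⌋ genes (default fraction 0.10; boundary ties broken by gene
id, making the selection a fixed-count rule and fully deterministic).  The
BRG set is the three-way intersection, split by the sign of the pooled r.
The reported thresholds are the boundary values of each top list (the least
extreme value still included), which is how the implied cutoffs should be
read.

## Consensus modules

Per-donor correlation matrices over the staged samples are averaged
element-wise (genes with zero variance in any donor are excluded from
clustering and reported).  Dissimilarity is d = 1 − r on [0, 2], so
negatively co-expressed genes are maximally dissimilar and modules are
positively co-expressed by construction.  Average linkage is the default;
single and complete linkage are available for comparison.

Modules are extracted by a bottom-up dynamic cut of the dendrogram
(`cut_dendrogram`): merges are visited in height order, and a merge is
refused — both sides finalized — when either side already holds at least
`min_size` leaves (default 50) and the merge height jumps more than
`split_gap` (default 0.1) above that side's *median* internal merge
height.  The rationale: within a coherent module, average-linkage merge
heights concentrate near 1 − r_within, while the join to another module or
to the background arrives at a markedly larger height, so a large jump
above a grown cluster's typical height marks a module boundary.  The
median (rather than the most recent merge) is used as the reference
because a module's last internal merges — weakly co-expressed stragglers —
sit well above its core and would otherwise mask the boundary jump.  Merges above the absolute ceiling
`max_height` (default 0.99, i.e. clusters may only join through positive
co-expression) are always refused.  Finalized clusters below `min_size`
become unassigned (label 0); modules are relabeled 1..m by decreasing
size.  The defaults were chosen from this geometry: with within-module
correlation ≈ 0.7 estimated over ~36 samples per donor and averaged over
six donors, within-module merge gaps stay below ~0.05 while module–module
and module–background joins jump by ≥ 0.15.  Like any tree cut, weakly
loaded members that join a module only far above its core are left
unassigned ("missing genes"); noise genes can chain into large,
stage-unassociated background clusters, which inflates the module count m
used by BH — the stage-association test tolerates this.

The module eigengene per donor is the first principal component over
samples of the module's row-standardized (zero mean, unit variance per
gene; standardization chosen because eigengenes should weight genes by
co-variation pattern, not expression level) submatrix, unit norm, with the
sign flipped if needed so it correlates positively with the module's mean
expression; the explained-variance fraction is reported.  Eigengene–stage
correlations are pooled across donors exactly as gene-level correlations
and BH-corrected across all modules; modules with q < 1e−4 (configurable)
form the significant set.

## PSEA

Markers: gene g marks cell type c iff its linear-scale reference expression
in c is at least `fold` (default 20) times the mean of the other types; a
positive value over an all-zero complement counts as an infinite ratio
(marker), 0/0 does not.  The rule is scale-invariant.  Uniqueness of the
marked type is guaranteed only when fold exceeds the number of other types.

Signals: per sample, the mean linear-scale expression of each type's
present markers (absent markers dropped with a warning; a type with no
present markers is an error).

Test: per gene × cell type, ordinary least squares of linear-scale
expression on {signal, signal × 1[group B]} without intercept; the
interaction coefficient ("slope change") is the cell-type-specific fold
change, tested two-sided with n−2 residual degrees of freedom.  Collinear
designs are flagged untestable instead of raising.  BH runs across genes
within each (cell type, contrast) stratum.  The no-intercept, one-signal
form follows the mixture logic: for a gene expressed exclusively in type c,
expression is proportional to that type's abundance, so composition shifts
move samples *along* the fitted line and only intrinsic regulation changes
its slope.  For genes substantially expressed in several types a single
signal is misspecified and the test can pick up composition effects; the
calibration claims below are therefore stated for type-specific genes.
Linear vs log regression scale is a config flag (`scale`), linear by
default.

## Enrichment

One-sided hypergeometric tail P(X ≥ k) for k of n module genes falling in a
size-K set from an N-gene background (exact, via the survival function).
Collections are first intersected with the background and sets below 10
genes dropped.  BH is applied jointly over all module × set pairs within a
collection (not globally across collections — collections answer separate
questions and are typically reported separately); significance at q < 0.05,
with an optional minimum-overlap filter (e.g. ≥ 20 genes) for large
ontology-style collections.

## Synthetic data

`generate_atlas` emulates the statistical shape of a six-donor regional
atlas on the log2 scale:

* **Gradient genes** — mean = baseline + donor intercept ± effect·(region−1)
  + N(0, noise_sd).  Defaults: effect 0.5 log2 units per stage step, noise
  s.d. 0.5, donor intercept s.d. 0.3 and a 10% relative donor perturbation
  of the slope, so between-donor heterogeneity (tau² > 0) is genuinely
  exercised.  Per-donor correlation of a planted positive gene is then
  ≈ 0.86 in expectation.
* **Module genes** — gene = baseline + loading·factor + √(1−loading²)·noise
  with unit variances, so within-module correlation = loading² (loading
  √0.7 ≈ 0.837 gives r ≈ 0.7).  The factor's correlation with the region
  label is *exact* in every donor (its noise component is residualized
  against the label), so the planted `stage_correlation` is directly the
  quantity the eigengene meta-analysis estimates.
* **Cell-type genes** — exclusive markers whose linear expression is
  proportional to the sample's cell-type proportion (Dirichlet around a
  region-varying mixing profile), plus log2-scale measurement noise.
* **Null genes** — baseline + noise.

One integer seed drives everything; per-donor streams are spawned from
(seed, donor index), so the data cannot depend on donor iteration order.
`generate_panel` plants exclusive markers at 1.05 × fold × mean(other
types) (the 5% margin guards the ≥-rule against floating-point
re-evaluation).  `generate_case_control` adds a condition axis: planted
gradient slopes are multiplied by (1 − disruption(condition)), emulating
progressive flattening of healthy regional gradients in disease, and an
optional cell-type spec makes the groups differ in composition only —
the setting in which PSEA should not, and a naive t-test does, declare
expression change.

What the generator does **not** emulate: probe-level structure, array batch
effects, heavy-tailed or count noise, correlated noise between gene
families, and realistic gene-gene correlation beyond the single-factor
module model.  Passing tests therefore demonstrate correctness of the
statistics and recoverability of planted structure under the stated model,
not performance on real atlas data.

## Study conditions used by the acceptance checks

BRG recovery: 6 donors × 36 samples, 5000 genes, 200+200 gradient genes,
effect 0.5, noise 0.5.  Module recovery: 3000 genes, five modules of
100/90/80/70/60 genes at loading √0.7, factor stage correlations
(0.9, 0.9, −0.9, 0, 0) — the tied values chosen by an a-priori power
computation for a q < 1e−4 call with se_z = √(1/(33·6)) under BH across
~20 modules.  PSEA: 2000 null regressions at 40 samples per group for
type-I error; 500 replicates for slope-change bias; the composition
demonstration uses 40+40 samples with neuronal fraction 0.45 vs 0.30 and
200 exclusive marker genes.  These sizes keep a full run at a few minutes
on one core while leaving comfortable statistical margins.

## Numerical choices and degenerate inputs

* Fisher transform refuses |r| ≥ 1 (no silent clipping); donors with
  |r| = 1 or zero variance contribute no estimate for that gene.
* Welch contrasts with zero pooled variance return p = 1 when the means
  agree and p = 0 otherwise, and such genes are excluded from FC pooling
  (their sampling variance is not positive).
* BH uses the step-up running minimum with a stable sort; ties are
  handled identically to the reference implementations.
* Top-decile cuts use ⌊fraction·G⌋ with ties at the boundary broken by
  gene id (fixed-count rule, deterministic).
* All tie-breaks in probe collapsing use the lexicographically smallest
  probe id.

## Known limitations

* The dynamic tree cut is a deliberately simple variant; on real atlas
  data its module count is sensitive to `split_gap` and `max_height`, and
  no claim is made that it reproduces any particular published module
  count.
* PSEA here fits one cell-type signal at a time (matching the per-type
  fits the method is usually displayed with); a joint fit over all five
  signals is not implemented.
* RNA-seq count modeling is out of scope: validation-style contrasts use
  Welch t-tests on log-scale values.
* ID mapping between platforms is consumed (tables), never built.
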