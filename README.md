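# braakmap

Ranking brain regions' transcriptomic vulnerability along the Parkinson's
disease (PD) Braak staging axis.

In PD, Lewy body pathology spreads through the brain in a stereotyped
caudal-to-rostral order described by the six Braak stages.  Groups of
anatomical structures can be assigned to the stage at which they are first
affected (R1 = medulla … R6 = frontal/parietal cortex), turning a regional
expression atlas from neurologically healthy donors into an ordinal axis of
vulnerability.  `braakmap` implements the full analysis that asks *which
genes, gene modules and cell types track that axis*:

* **Braak stage-related genes (BRGs).**  Per donor, each gene's expression
  is correlated with the region labels 1–6 (Pearson r) and contrasted
  between the axis endpoints (fold change FC = difference of mean log2
  expression, default R1 vs R6, Welch t-test).  Effects are pooled across
  donors by DerSimonian–Laird random-effects meta-analysis — correlations in
  Fisher-z space (z = arctanh r, var = 1/(n−3)), fold changes with their
  non-pooled variance — and tested with a two-sided t-test on k−1 degrees of
  freedom (5 for six donors); p-values are Benjamini–Hochberg corrected.
  BRGs are the intersection of the top decile by |r|, by |FC| and by
  smallest corrected FC p-value, split into negatively and positively
  correlated sets.
* **Consensus co-expression modules.**  Per-donor gene–gene correlation
  matrices over the staged samples are averaged element-wise into a
  consensus network, converted to the dissimilarity d = 1 − r, clustered by
  average-linkage hierarchical clustering and cut into modules by a
  bottom-up dynamic tree cut with a minimum module size (default 50).  Each
  module is summarized per donor by its eigengene (first principal
  component, sign-aligned with the module mean), and eigengene–stage
  correlations are pooled with the same meta-analysis; modules with
  BH-corrected p < 1e−4 are stage-associated.
* **PSEA (population-specific expression analysis).**  Marker genes are
  selected from a sorted-cell reference panel by a 20-fold rule, per-sample
  cell-type signals are the mean expression of each type's markers, and each
  gene is regressed (no intercept) on one signal plus a signal-by-group
  interaction.  The interaction coefficient is the cell-type-specific fold
  change: it tests whether expression differs between groups beyond what
  cell-type abundance explains.
* **Hypergeometric enrichment.**  Modules (or BRG sets) are tested against
  gene-set collections (GMT) with a one-sided hypergeometric test, sets
  filtered to the analysis background and ≥ 10 genes, BH over all
  module × set pairs per collection.
* **Synthetic data.**  A generator plants all of this structure — monotone
  expression gradients, latent-factor modules with configurable stage
  correlation, cell-type mixtures with exclusive markers, disease-dependent
  gradient disruption — with full ground truth, so every stage of the
  pipeline is validated end to end without any download.

## Worked example

```python
from braakmap.simulate import SimulationConfig, ModuleSpec, generate_atlas
from braakmap.braak import BraakGeneModel
from braakmap.coexpression import ConsensusModuleModel

config = SimulationConfig(
    n_genes=1500, n_pos_gradient=80, n_neg_gradient=80,
    module_spec=(ModuleSpec(60, 0.9, 0.837), ModuleSpec(60, 0.0, 0.837)),
    seed=42,
)
donor_expr, samples, truth = generate_atlas(config)
expr = {d: e.data for d, e in donor_expr.items()}

results = BraakGeneModel(expr, samples).fit()
print(results.summary())

modules = ConsensusModuleModel(expr, samples).fit()
print(modules.summary())
```

prints

```
Braak stage-related gene analysis
========================================
genes analyzed:        1500
donors:                6
contrast:              R1 vs R6
selection fraction:    0.10
|r| threshold:         0.841
|FC| threshold:        2.335
q_FC threshold:        0.000337
BRGs selected:         101 (45 negative, 56 positive)

Consensus co-expression module analysis
========================================
genes clustered:       1500
modules found:         3
genes assigned:        280
largest module size:   140
significant modules:   2 (q < 0.0001)
top modules by |stage correlation|:
  M2: size=80 r=-1.00 q=3.30e-07
  M1: size=140 r=+0.98 q=7.24e-07
  M3: size=60 r=+0.01 q=9.19e-01
```

The 160 planted gradient genes dominate the BRG selection (101 of 150 top
slots, the thresholds being the boundary values of each top-decile list).
The module analysis finds the stage-tied planted module merged with the
80 positive gradient genes (M1 — they are genuinely co-expressed along the
axis), the negative gradient genes as their own anti-correlated module
(M2), and correctly reports the factor-free planted module (M3) as not
stage-associated.

The same stages run from the shell:

```bash
braakmap simulate --seed 42 --out sim/
braakmap brg --expr-dir sim/ --samples sim/samples.tsv --region-map sim/region_map.tsv --out-dir out/
braakmap modules --expr-dir sim/ --samples sim/samples.tsv --out-dir out/
braakmap psea --expr sim/expr_donor1.tsv --samples sim/samples.tsv --panel sim/panel.tsv --out-dir out/
braakmap run --seed 42 --out-dir run/     # full pipeline + manifest
```

## Layout

| module | contents |
| --- | --- |
| `braakmap.atlas_io` | TSV/GMT readers and writers, probe filtering and collapsing, region assignment |
| `braakmap.stats` | Fisher transform, DerSimonian–Laird pooling, BH, Welch contrasts |
| `braakmap.braak` | `BraakGeneModel` / `BraakGeneResults`, BRG selection |
| `braakmap.coexpression` | `ConsensusModuleModel` / `ModuleResults`, dynamic tree cut, eigengenes |
| `braakmap.psea` | `PSEAModel` / `PSEAResults`, marker selection, signals |
| `braakmap.enrichment` | hypergeometric enrichment of modules against collections |
| `braakmap.simulate` | synthetic atlas / panel / case-control generators with ground truth |
| `braakmap.pipeline`, `braakmap.cli` | YAML-driven orchestration and the `braakmap` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
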