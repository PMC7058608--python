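"""Synthetic multi-donor expression data with planted, recoverable structure.

The generator emulates the statistical shape of a regional brain
transcriptome atlas: six donors, samples labeled with ordinal Braak
stage-related regions 1-6, and four gene families on the log2 scale —

* gradient genes whose mean rises (or falls) linearly with the region label,
  with donor-specific random intercepts and slope perturbations so that
  between-donor heterogeneity (tau^2 > 0) is exercised;
* module genes driven by a donor-level latent factor whose correlation
  with the region label is exactly the configured value in every donor
  (the factor's noise component is residualized against the label); with
  unit-variance construction the within-module gene-gene correlation
  equals loading^2;
* cell-type genes whose linear-scale expression is proportional to a
  sample's (region-varying) cell-type proportion — markers are exclusive
  to one type;
* null genes: Gaussian noise around a baseline.

Every dataset is reproducible from a single integer seed; per-donor random
streams are spawned deterministically from (seed, donor index) so donor
iteration order cannot change the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas_io import ExpressionMatrix
from .psea import DEFAULT_CELL_TYPES

__all__ = [
    "ModuleSpec",
    "CellTypeSpec",
    "SimulationConfig",
    "CaseControlConfig",
    "GroundTruth",
    "generate_atlas",
    "generate_panel",
    "generate_case_control",
    "brg_recovery_config",
    "module_recovery_config",
    "composition_confound_config",
]

# Region-varying cell-type mixing: neuronal fraction rises toward the
# cortical (late-stage) regions, glial fractions fall; columns follow
# DEFAULT_CELL_TYPES order and each row sums to 1.
DEFAULT_REGION_MIXING = {
    r: (
        0.30 + 0.04 * (r - 1),
        0.25 - 0.01 * (r - 1),
        0.20 - 0.01 * (r - 1),
        0.15 - 0.01 * (r - 1),
        0.10 - 0.01 * (r - 1),
    )
    for r in range(1, 7)
}


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``loading`` is the factor loading shared by all member genes; the
    implied within-module gene-gene correlation is loading**2.
    ``stage_correlation`` is the correlation of the module's latent factor
    with the region label (0 = factor free of the staging axis).
    """

    size: int
    stage_correlation: float
    loading: float


@dataclass(frozen=True)
class CellTypeSpec:
    """Planted cell-type structure: exclusive markers and mixing profiles."""

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 40
    planted_fold: float = 50.0
    low_level: float = 2.0
    marker_level: tuple[float, float] = (50.0, 200.0)  # uniform range, linear scale
    concentration: float = 300.0  # Dirichlet concentration of per-sample mixing
    log2_noise_sd: float = 0.15


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic six-donor atlas."""

    n_donors: int = 6
    samples_per_region: tuple[int, ...] = (6, 6, 6, 6, 6, 6)
    n_genes: int = 5000
    n_pos_gradient: int = 200
    n_neg_gradient: int = 200
    gradient_effect: float = 0.5  # log2 units per stage step
    module_spec: tuple[ModuleSpec, ...] = ()
    celltype_spec: CellTypeSpec | None = None
    noise_sd: float = 0.5  # residual s.d., log2 units
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    donor_intercept_sd: float = 0.3
    donor_effect_sd: float = 0.1  # relative perturbation of planted slopes
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be positive")
        if len(self.samples_per_region) != 6 or any(
            m < 2 for m in self.samples_per_region
        ):
            raise ValueError("samples_per_region must give >= 2 samples for each of R1-R6")
        if min(self.n_genes, self.n_pos_gradient + 1, self.n_neg_gradient + 1) <= 0:
            raise ValueError("gene counts must be non-negative and n_genes positive")
        if self.gradient_effect < 0 or self.noise_sd <= 0:
            raise ValueError("gradient_effect must be >= 0 and noise_sd > 0")
        for spec in self.module_spec:
            if spec.size < 2:
                raise ValueError("module size must be >= 2")
            if not 0.0 <= spec.loading <= 1.0:
                raise ValueError("module loading must be in [0, 1]")
            if not -1.0 < spec.stage_correlation < 1.0:
                raise ValueError("stage_correlation must be in (-1, 1)")
        if self._n_planted() > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.celltype_spec is not None:
            spec = self.celltype_spec
            if spec.planted_fold <= 1:
                raise ValueError("planted_fold must exceed 1")
            for profile in DEFAULT_REGION_MIXING.values():
                assert abs(sum(profile) - 1.0) < 1e-9

    def _n_planted(self) -> int:
        n = self.n_pos_gradient + self.n_neg_gradient
        n += sum(s.size for s in self.module_spec)
        if self.celltype_spec is not None:
            n += self.celltype_spec.markers_per_type * len(self.celltype_spec.cell_types)
        return n


@dataclass(frozen=True)
class CaseControlConfig:
    """Regions x conditions cohort with condition-dependent gradient disruption.

    ``disruption`` gives, per condition, the fraction by which planted
    gradient slopes are flattened (0 = intact, 1 = fully disrupted).  When a
    ``celltype_spec`` is supplied, cell-type genes are added whose mixing
    proportions depend on the condition (``mixing_by_condition``), so that
    composition alone separates the groups; ``intrinsic_shift`` optionally
    adds a true log2 expression shift to a few markers of one type in the
    non-control conditions.
    """

    conditions: tuple[str, ...] = ("control", "iLBD", "PD")
    disruption: tuple[float, ...] = (0.0, 0.5, 1.0)
    regions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    samples_per_region_per_condition: int = 4
    n_genes: int = 2000
    n_pos_gradient: int = 100
    n_neg_gradient: int = 100
    gradient_effect: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    subject_sd: float = 0.2
    celltype_spec: CellTypeSpec | None = None
    mixing_by_condition: dict | None = None
    intrinsic_shift: tuple[str, int, float] | None = None  # (cell type, n genes, log2 shift)
    seed: int = 0

    def validate(self) -> None:
        if len(self.disruption) != len(self.conditions):
            raise ValueError("one disruption value per condition is required")
        if any(not 0.0 <= d <= 1.0 for d in self.disruption):
            raise ValueError("disruption fractions must be in [0, 1]")
        if self.samples_per_region_per_condition < 2:
            raise ValueError("need >= 2 samples per region per condition")
        n_planted = self.n_pos_gradient + self.n_neg_gradient
        if self.celltype_spec is not None:
            n_planted += self.celltype_spec.markers_per_type * len(
                self.celltype_spec.cell_types
            )
            if self.mixing_by_condition is None:
                raise ValueError("celltype_spec requires mixing_by_condition")
            for cond in self.conditions:
                profile = self.mixing_by_condition[cond]
                if abs(sum(profile) - 1.0) > 1e-9:
                    raise ValueError(f"mixing for {cond!r} must sum to 1")
        if n_planted > self.n_genes:
            raise ValueError("planted genes exceed n_genes")


@dataclass
class GroundTruth:
    """Planted structure: per-gene class, per-module factor, true composition."""

    genes: pd.DataFrame = field(repr=False)
    modules: pd.DataFrame = field(repr=False)
    markers: dict[str, list[str]] = field(default_factory=dict, repr=False)
    composition: pd.DataFrame | None = field(default=None, repr=False)
    region_map: dict[str, int] = field(default_factory=dict, repr=False)

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.genes.index[self.genes["class"] == cls])


def _gene_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"G{i:0{width}d}" for i in range(n)], name="gene_id")


def _layout(config) -> pd.DataFrame:
    """Deterministic gene classes shared by the atlas and panel generators."""
    ids = _gene_ids(config.n_genes)
    cls = np.array(["null"] * config.n_genes, dtype=object)
    module = np.zeros(config.n_genes, dtype=int)
    pos = 0
    cls[pos:pos + config.n_pos_gradient] = "pos_gradient"
    pos += config.n_pos_gradient
    cls[pos:pos + config.n_neg_gradient] = "neg_gradient"
    pos += config.n_neg_gradient
    for m, spec in enumerate(getattr(config, "module_spec", ()), start=1):
        cls[pos:pos + spec.size] = f"module_{m}"
        module[pos:pos + spec.size] = m
        pos += spec.size
    if config.celltype_spec is not None:
        for ct in config.celltype_spec.cell_types:
            cls[pos:pos + config.celltype_spec.markers_per_type] = f"marker_{ct}"
            pos += config.celltype_spec.markers_per_type
    return pd.DataFrame({"class": cls, "module": module}, index=ids)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _region_map(regions) -> tuple[dict[str, int], dict[int, list[str]]]:
    mapping: dict[str, int] = {}
    per_region: dict[int, list[str]] = {}
    for r in regions:
        names = [f"structure_{r}a", f"structure_{r}b"]
        per_region[r] = names
        for name in names:
            mapping[name] = r
    return mapping, per_region


def generate_atlas(config: SimulationConfig):
    """Simulate per-donor log2 expression with planted gradients and modules.

    Returns ``(donor_expr, samples, truth)`` where ``donor_expr`` maps donor
    id to an :class:`ExpressionMatrix`, ``samples`` is a sample table with
    assigned ``braak_region`` labels, and ``truth`` records every planted
    gene class.
    """
    config.validate()
    layout = _layout(config)
    genes = layout.index
    rng_global = np.random.default_rng([config.seed, 1])
    baseline = rng_global.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    region_map, per_region = _region_map(range(1, 7))
    spec_ct = config.celltype_spec
    marker_levels: dict[str, np.ndarray] = {}
    if spec_ct is not None:
        for ct in spec_ct.cell_types:
            idx = layout.index[layout["class"] == f"marker_{ct}"]
            marker_levels[ct] = rng_global.uniform(*spec_ct.marker_level, len(idx))

    donor_expr: dict[str, ExpressionMatrix] = {}
    sample_rows = []
    comp_rows = []
    is_pos = (layout["class"] == "pos_gradient").to_numpy()
    is_neg = (layout["class"] == "neg_gradient").to_numpy()
    is_null = (layout["class"] == "null").to_numpy()

    for d in range(config.n_donors):
        donor = f"donor{d + 1}"
        rng = np.random.default_rng([config.seed, 1000 + d])
        labels = np.repeat(np.arange(1, 7), config.samples_per_region)
        n_samples = labels.size
        sample_ids = [f"{donor}_s{j:03d}" for j in range(n_samples)]
        structures = [per_region[r][j % 2] for j, r in enumerate(labels)]

        x = np.tile(baseline[:, None], (1, n_samples))
        x += rng.normal(0.0, config.donor_intercept_sd, config.n_genes)[:, None]

        step = (labels - 1).astype(float)
        for rows, sign in ((is_pos, 1.0), (is_neg, -1.0)):
            n_rows = int(rows.sum())
            if n_rows:
                slopes = sign * config.gradient_effect * (
                    1.0 + rng.normal(0.0, config.donor_effect_sd, n_rows)
                )
                x[rows] += slopes[:, None] * step[None, :]
        noise_rows = is_pos | is_neg | is_null
        x[noise_rows] += rng.normal(0.0, config.noise_sd, (int(noise_rows.sum()), n_samples))

        z_label = _standardize(step)
        for m, spec in enumerate(config.module_spec, start=1):
            rows = (layout["module"] == m).to_numpy()
            rho = spec.stage_correlation
            # residualize the factor's noise against the label so the
            # factor-label correlation is exactly rho in every donor
            u = rng.normal(size=n_samples)
            u = _standardize(u - (u @ z_label) / n_samples * z_label)
            factor = rho * z_label + math.sqrt(1 - rho**2) * u
            load = spec.loading
            x[rows] += load * factor[None, :] + math.sqrt(1 - load**2) * rng.normal(
                size=(int(rows.sum()), n_samples)
            )

        if spec_ct is not None:
            props = np.vstack([
                rng.dirichlet(np.asarray(DEFAULT_REGION_MIXING[r]) * spec_ct.concentration)
                for r in labels
            ])  # samples x types
            for j, ct in enumerate(spec_ct.cell_types):
                rows = (layout["class"] == f"marker_{ct}").to_numpy()
                linear = props[:, j][None, :] * marker_levels[ct][:, None]
                x[rows] = np.log2(np.maximum(linear, 1e-6)) + rng.normal(
                    0.0, spec_ct.log2_noise_sd, (int(rows.sum()), n_samples)
                )
            comp_rows.append(pd.DataFrame(
                props, index=sample_ids, columns=list(spec_ct.cell_types)
            ))

        donor_expr[donor] = ExpressionMatrix(
            pd.DataFrame(x, index=genes, columns=sample_ids)
        )
        sample_rows.append(pd.DataFrame({
            "sample_id": sample_ids,
            "donor_id": donor,
            "structure_name": structures,
            "braak_region": labels,
        }))

    samples = pd.concat(sample_rows, ignore_index=True)
    samples["braak_region"] = samples["braak_region"].astype("Int64")
    modules = pd.DataFrame(
        {
            "size": [s.size for s in config.module_spec],
            "stage_correlation": [s.stage_correlation for s in config.module_spec],
            "loading": [s.loading for s in config.module_spec],
        },
        index=pd.Index(range(1, len(config.module_spec) + 1), name="module"),
    )
    truth = GroundTruth(
        genes=layout,
        modules=modules,
        markers={
            ct: list(layout.index[layout["class"] == f"marker_{ct}"])
            for ct in (spec_ct.cell_types if spec_ct else ())
        },
        composition=pd.concat(comp_rows) if comp_rows else None,
        region_map=region_map,
    )
    return donor_expr, samples, truth


def generate_panel(config) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Reference panel (genes x cell types, linear scale) with planted markers.

    Marker genes are expressed in their own type at ``planted_fold`` times
    the mean of the other types' (low) levels, with a 5% safety margin so
    the fold rule holds under floating-point re-evaluation; all other genes
    are near-uniform across types, far below any sensible fold rule.
    Returns the panel and the planted marker sets.
    """
    spec = config.celltype_spec
    if spec is None:
        spec = CellTypeSpec()
        config = replace(config, celltype_spec=spec)
    config.validate()
    layout = _layout(config)
    rng = np.random.default_rng([config.seed, 2])
    n_types = len(spec.cell_types)
    ref = spec.low_level * rng.uniform(0.9, 1.1, (config.n_genes, n_types))
    markers: dict[str, list[str]] = {}
    for j, ct in enumerate(spec.cell_types):
        rows = (layout["class"] == f"marker_{ct}").to_numpy()
        other_mean = (ref[rows].sum(axis=1) - ref[rows, j]) / (n_types - 1)
        ref[rows, j] = 1.05 * spec.planted_fold * other_mean
        markers[ct] = list(layout.index[rows])
    return pd.DataFrame(ref, index=layout.index, columns=list(spec.cell_types)), markers


def generate_case_control(config: CaseControlConfig):
    """Simulate a regions x conditions cohort with planted disease effects.

    Gradient genes keep their slope in controls and have it flattened by the
    per-condition disruption fraction in patient groups.  With a cell-type
    spec, marker genes' linear expression tracks per-sample cell-type
    proportions drawn from condition-specific mixing, so group differences
    in those genes are purely compositional unless an ``intrinsic_shift``
    is planted.
    """
    config.validate()
    layout = _layout(config)
    genes = layout.index
    rng = np.random.default_rng([config.seed, 3])
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    region_map, per_region = _region_map(config.regions)

    spec_ct = config.celltype_spec
    marker_levels: dict[str, np.ndarray] = {}
    shifted: list[str] = []
    if spec_ct is not None:
        for ct in spec_ct.cell_types:
            idx = layout.index[layout["class"] == f"marker_{ct}"]
            marker_levels[ct] = rng.uniform(*spec_ct.marker_level, len(idx))
        if config.intrinsic_shift is not None:
            ct, n_shift, _ = config.intrinsic_shift
            shifted = list(layout.index[layout["class"] == f"marker_{ct}"][:n_shift])

    is_pos = (layout["class"] == "pos_gradient").to_numpy()
    is_neg = (layout["class"] == "neg_gradient").to_numpy()
    is_null = (layout["class"] == "null").to_numpy()

    columns: list[np.ndarray] = []
    sample_rows = []
    comp_rows = []
    for cond, disrupt in zip(config.conditions, config.disruption):
        for i in range(config.samples_per_region_per_condition):
            subject = f"{cond}_subj{i:02d}"
            subj_shift = rng.normal(0.0, config.subject_sd)
            for r in config.regions:
                sample_id = f"{subject}_R{r}"
                col = baseline + subj_shift
                step = float(r - 1)
                col = col.copy()
                col[is_pos] += config.gradient_effect * (1 - disrupt) * step
                col[is_neg] -= config.gradient_effect * (1 - disrupt) * step
                noise_rows = is_pos | is_neg | is_null
                col[noise_rows] += rng.normal(0.0, config.noise_sd, int(noise_rows.sum()))
                if spec_ct is not None:
                    profile = np.asarray(config.mixing_by_condition[cond])
                    props = rng.dirichlet(profile * spec_ct.concentration)
                    for j, ct in enumerate(spec_ct.cell_types):
                        rows = (layout["class"] == f"marker_{ct}").to_numpy()
                        linear = props[j] * marker_levels[ct]
                        vals = np.log2(np.maximum(linear, 1e-6)) + rng.normal(
                            0.0, spec_ct.log2_noise_sd, int(rows.sum())
                        )
                        if shifted and cond != config.conditions[0]:
                            ct_shift, _, shift = config.intrinsic_shift
                            if ct == ct_shift:
                                in_shift = layout.index[rows].isin(shifted)
                                vals = vals + shift * in_shift
                        col[rows] = vals
                    comp_rows.append((sample_id, props))
                columns.append(col)
                sample_rows.append({
                    "sample_id": sample_id,
                    "donor_id": subject,
                    "structure_name": per_region[r][0],
                    "braak_region": r,
                    "condition": cond,
                })

    samples = pd.DataFrame(sample_rows)
    samples["braak_region"] = samples["braak_region"].astype("Int64")
    expr = ExpressionMatrix(pd.DataFrame(
        np.column_stack(columns), index=genes,
        columns=[row["sample_id"] for row in sample_rows],
    ))
    layout = layout.copy()
    layout["intrinsic_shift"] = layout.index.isin(shifted)
    composition = None
    if comp_rows:
        composition = pd.DataFrame(
            [p for _, p in comp_rows],
            index=[s for s, _ in comp_rows],
            columns=list(spec_ct.cell_types),
        )
    truth = GroundTruth(
        genes=layout,
        modules=pd.DataFrame(
            columns=["size", "stage_correlation", "loading"],
            index=pd.Index([], name="module"),
        ),
        markers={
            ct: list(layout.index[layout["class"] == f"marker_{ct}"])
            for ct in (spec_ct.cell_types if spec_ct else ())
        },
        composition=composition,
        region_map=region_map,
    )
    return expr, samples, truth


def brg_recovery_config(seed: int = 1) -> SimulationConfig:
    """Study conditions for gradient-gene (BRG) recovery: 6 donors,
    6 samples/region, 5000 genes, 200 positive + 200 negative gradient genes
    at 0.5 log2 units per stage with residual s.d. 0.5."""
    return SimulationConfig(
        n_genes=5000, n_pos_gradient=200, n_neg_gradient=200,
        gradient_effect=0.5, noise_sd=0.5, seed=seed,
    )


def module_recovery_config(seed: int = 1) -> SimulationConfig:
    """Study conditions for module recovery: 5 planted modules (sizes
    60-100, within-module r ~= 0.7, i.e. loading sqrt(0.7)), three factors
    tied to the staging axis (|rho| = 0.9, powered for a q < 1e-4 call at
    six donors of 36 staged samples) and two factor-free, among 3000
    genes."""
    loading = math.sqrt(0.7)
    return SimulationConfig(
        n_genes=3000, n_pos_gradient=0, n_neg_gradient=0,
        module_spec=(
            ModuleSpec(100, 0.90, loading),
            ModuleSpec(90, 0.90, loading),
            ModuleSpec(80, -0.90, loading),
            ModuleSpec(70, 0.0, loading),
            ModuleSpec(60, 0.0, loading),
        ),
        noise_sd=0.5, seed=seed,
    )


def composition_confound_config(seed: int = 1) -> CaseControlConfig:
    """Two groups that differ only in cell-type composition (neuronal loss
    with glial expansion), 40 samples each; marker genes are exclusive to
    one type, so any rejection of an intrinsic expression change is a false
    positive."""
    return CaseControlConfig(
        conditions=("control", "PD"),
        disruption=(0.0, 0.0),
        regions=(3,),
        samples_per_region_per_condition=40,
        n_genes=400,
        n_pos_gradient=0,
        n_neg_gradient=0,
        celltype_spec=CellTypeSpec(),
        mixing_by_condition={
            "control": (0.45, 0.20, 0.15, 0.12, 0.08),
            "PD": (0.30, 0.26, 0.19, 0.16, 0.09),
        },
        seed=seed,
    )
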