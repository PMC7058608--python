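"""End-to-end orchestration: simulate -> BRGs -> modules -> PSEA -> enrichment.

A single YAML config (validated, unknown keys rejected) drives every stage;
all stage outputs are plain TSV/JSON files and a manifest records a sha256
checksum per file, so a rerun with the same config and seed reproduces the
run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atlas_io
from .braak import BraakGeneModel
from .coexpression import ConsensusModuleModel
from .enrichment import enrich
from .psea import PSEAModel
from .simulate import (
    CellTypeSpec,
    GroundTruth,
    ModuleSpec,
    SimulationConfig,
    generate_atlas,
    generate_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_simulation", "sha256_file"]

_DEFAULTS = {
    "schema": 1,
    "seed": 1,
    "simulate": {
        "n_genes": 1200,
        "n_pos_gradient": 60,
        "n_neg_gradient": 60,
        "gradient_effect": 0.5,
        "noise_sd": 0.5,
        "samples_per_region": [6, 6, 6, 6, 6, 6],
        "module_spec": [[60, 0.9, 0.837], [60, -0.85, 0.837], [60, 0.0, 0.837]],
        "celltype": True,
    },
    "brg": {"fraction": 0.10, "contrast": [1, 6]},
    "modules": {"min_size": 50, "linkage": "average", "alpha": 1e-4,
                "split_gap": 0.1, "max_height": 0.99},
    "psea": {"fold": 20.0, "scale": "linear", "contrast": [1, 6]},
    "enrich": {"alpha": 0.05, "set_min_size": 10, "min_overlap": 0},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with per-stage parameter blocks."""

    seed: int = 1
    simulate: dict = field(default_factory=lambda: dict(_DEFAULTS["simulate"]))
    brg: dict = field(default_factory=lambda: dict(_DEFAULTS["brg"]))
    modules: dict = field(default_factory=lambda: dict(_DEFAULTS["modules"]))
    psea: dict = field(default_factory=lambda: dict(_DEFAULTS["psea"]))
    enrich: dict = field(default_factory=lambda: dict(_DEFAULTS["enrich"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("schema", 1) != 1:
            raise ValueError("unsupported config schema version")
        config = cls(seed=int(raw.get("seed", _DEFAULTS["seed"])))
        for section in ("simulate", "brg", "modules", "psea", "enrich"):
            merged = dict(_DEFAULTS[section])
            extra = set(raw.get(section, {})) - set(merged)
            if extra:
                raise ValueError(f"unknown keys in {section!r}: {sorted(extra)}")
            merged.update(raw.get(section, {}))
            setattr(config, section, merged)
        return config

    def simulation_config(self) -> SimulationConfig:
        sim = self.simulate
        return SimulationConfig(
            n_genes=sim["n_genes"],
            n_pos_gradient=sim["n_pos_gradient"],
            n_neg_gradient=sim["n_neg_gradient"],
            gradient_effect=sim["gradient_effect"],
            noise_sd=sim["noise_sd"],
            samples_per_region=tuple(sim["samples_per_region"]),
            module_spec=tuple(ModuleSpec(*row) for row in sim["module_spec"]),
            celltype_spec=CellTypeSpec() if sim["celltype"] else None,
            seed=self.seed,
        )


def sha256_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_simulation(
    donor_expr, samples, truth: GroundTruth, out_dir: Path
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for donor, expr in donor_expr.items():
        path = out_dir / f"expr_{donor}.tsv"
        atlas_io.write_expression(expr, path)
        written.append(path)
    path = out_dir / "samples.tsv"
    atlas_io.write_sample_table(samples, path)
    written.append(path)
    path = out_dir / "region_map.tsv"
    atlas_io.write_region_map(truth.region_map, path)
    written.append(path)
    path = out_dir / "truth.tsv"
    truth.genes.to_csv(path, sep="\t")
    written.append(path)
    return written


def _truth_collections(truth: GroundTruth) -> dict[str, set[str]]:
    """Gene sets derived from the planted structure, for enrichment."""
    sets: dict[str, set[str]] = {}
    for cls in sorted(truth.genes["class"].unique()):
        if cls == "null":
            continue
        sets[f"planted_{cls}"] = set(truth.genes_of_class(cls))
    return sets


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages in dependency order and return the run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}

    stage = "simulate"
    try:
        sim_config = config.simulation_config()
        donor_expr, samples, truth = generate_atlas(sim_config)
        written += write_simulation(donor_expr, samples, truth, out_dir)
        counts["samples_assigned"] = int(samples["braak_region"].notna().sum())
        counts["genes"] = sim_config.n_genes

        stage = "brg"
        model = BraakGeneModel(
            {d: e.data for d, e in donor_expr.items()}, samples,
            contrast=tuple(config.brg["contrast"]),
        )
        brg_results = model.fit()
        selection = brg_results.select_brgs(fraction=config.brg["fraction"])
        path = out_dir / "gene_summary.tsv"
        brg_results.gene_summary.to_csv(path, sep="\t", float_format="%.6g")
        written.append(path)
        brgs = pd.DataFrame({
            "gene_id": list(selection.negative_genes) + list(selection.positive_genes),
            "direction": ["negative"] * len(selection.negative_genes)
            + ["positive"] * len(selection.positive_genes),
        }).sort_values("gene_id")
        path = out_dir / "brgs.tsv"
        brgs.to_csv(path, sep="\t", index=False)
        written.append(path)
        path = out_dir / "brg_thresholds.json"
        path.write_text(json.dumps({
            "fraction": selection.fraction, "r_cut": selection.r_cut,
            "fc_cut": selection.fc_cut, "p_cut": selection.p_cut,
        }, indent=2))
        written.append(path)
        counts["genes_retained"] = len(brg_results.gene_summary)
        counts["brgs_selected"] = len(selection)
        logger.info("BRG thresholds: |r|>=%.3f |FC|>=%.3f q<=%.3g",
                    selection.r_cut, selection.fc_cut, selection.p_cut)

        stage = "modules"
        module_model = ConsensusModuleModel(
            {d: e.data for d, e in donor_expr.items()}, samples,
            min_size=config.modules["min_size"],
            linkage=config.modules["linkage"],
            split_gap=config.modules["split_gap"],
            max_height=config.modules["max_height"],
            alpha=config.modules["alpha"],
        )
        module_results = module_model.fit()
        path = out_dir / "modules.tsv"
        module_results.partition.to_frame().to_csv(path, sep="\t")
        written.append(path)
        path = out_dir / "module_summary.tsv"
        module_results.association.to_csv(path, sep="\t", float_format="%.6g")
        written.append(path)
        for donor, table in module_results.eigengenes.items():
            path = out_dir / f"eigengenes_{donor}.tsv"
            table.to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")
            written.append(path)
        counts["modules_found"] = int(module_results.partition.max())
        counts["significant_modules"] = len(module_results.significant_modules)

        stage = "psea"
        if sim_config.celltype_spec is not None:
            panel, _ = generate_panel(sim_config)
            path = out_dir / "panel.tsv"
            panel.to_csv(path, sep="\t", float_format="%.6g")
            written.append(path)
            merged = pd.concat([e.data for e in donor_expr.values()], axis=1)
            psea_results = PSEAModel(
                merged, samples, panel,
                contrast=tuple(config.psea["contrast"]),
                fold=config.psea["fold"], scale=config.psea["scale"],
            ).fit()
            path = out_dir / "psea.tsv"
            psea_results.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
            counts["psea_tests"] = len(psea_results.table)

        stage = "enrich"
        collections = {"planted": _truth_collections(truth)}
        gmt_path = out_dir / "planted_sets.gmt"
        atlas_io.write_gmt(collections["planted"], gmt_path)
        written.append(gmt_path)
        background = set(brg_results.gene_summary.index)
        tested = module_results.significant_modules or list(
            module_results.association.index
        )
        gene_lists = {
            int(m): set(module_results.partition.index[module_results.partition == m])
            for m in tested
        }
        table = enrich(
            gene_lists, collections, background,
            alpha=config.enrich["alpha"],
            set_min_size=config.enrich["set_min_size"],
            min_overlap=config.enrich["min_overlap"],
        )
        path = out_dir / "enrichment.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
        counts["enriched_pairs"] = int(table["significant"].sum())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {"seed": config.seed, "simulate": config.simulate,
                   "brg": config.brg, "modules": config.modules,
                   "psea": config.psea, "enrich": config.enrich},
        "counts": counts,
        "files": {p.name: sha256_file(p) for p in sorted(written)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", json.dumps(counts))
    return manifest
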