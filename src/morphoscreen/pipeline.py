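"""Declarative end-to-end pipeline over the library stages.

A :class:`PipelineConfig` (usually parsed from a YAML document) drives the
full synthetic demonstration: generate a screen, expand to single cells,
aggregate to wells, annotate with the plate map, label injuries, normalize
against the DMSO reference, feature-select, carve out the plate/treatment/
well holdouts, split, train, and evaluate (optionally against the
shuffled-label baseline).  Every stage's artifact is persisted under the
output directory with a provenance sidecar, and two runs with identical
config and seed produce identical artifacts and report numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .core import AggregationSpec, aggregate, annotate, apply_normalization, fit_normalization
from .exceptions import ValidationError
from .injury import (
    EvaluationReport,
    InjuryModelBundle,
    SearchGrid,
    evaluate,
    label_wells,
    make_holdouts,
    split_train_test,
    train_classifier,
)
from .io import ProfileTable, write_platemap, write_profiles
from .selection import FeatureSelectionConfig, feature_select
from .synth import ScreenDesign, cells_from_wells, generate_screen, label_scheme

STAGE_ORDER = (
    "synth",
    "aggregate",
    "annotate",
    "label",
    "normalize",
    "feature_select",
    "train",
    "evaluate",
)


@dataclass
class PipelineConfig:
    """Validated parameters for one end-to-end run."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    from_cells: bool = True
    cell_noise_sd: float = 1.0
    aggregation_statistic: str = "median"
    normalization_method: str = "mad_robustize"
    reference_query: str = "Metadata_compound == 'DMSO'"
    feature_selection: dict = field(default_factory=dict)
    holdouts: dict = field(default_factory=dict)
    test_fraction: float = 0.2
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    shuffled_baseline: bool = True
    profile_format: str = "parquet"

    def __post_init__(self) -> None:
        if self.profile_format not in ("parquet", "csv"):
            raise ValidationError("profile_format must be 'parquet' or 'csv'")
        # validate nested configs eagerly so failures precede any execution
        self.screen_design()
        self.selection_config()
        self.search_grid()
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def screen_design(self) -> ScreenDesign:
        params = dict(self.design)
        params.setdefault("seed", self.seed)
        if "classes" in params:
            params["classes"] = tuple(params["classes"])
        return ScreenDesign(**params)

    def selection_config(self) -> FeatureSelectionConfig:
        return FeatureSelectionConfig(**self.feature_selection)

    def search_grid(self) -> SearchGrid:
        params = dict(self.grid)
        for key in ("penalties", "strengths", "tolerances", "elasticnet_ratios", "solvers"):
            if key in params:
                params[key] = tuple(params[key])
        return SearchGrid(**params)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Artifacts of a completed run."""

    out_dir: Path
    bundle: InjuryModelBundle
    report: EvaluationReport
    n_wells: int
    n_features_selected: int
    split_sizes: dict[str, int]


# ----------------------------------------------------------------------
# Provenance


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_provenance(
    artifact: Path, params: dict, inputs: list[Path], seed: int
) -> Path:
    """Write a ``<artifact>.provenance.json`` sidecar recording the tool
    version, a hash of the parameters, the seed, and input digests."""
    doc = {
        "tool": "morphoscreen",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
    }
    sidecar = artifact.with_name(artifact.name + ".provenance.json")
    sidecar.write_text(json.dumps(doc, indent=1))
    return sidecar


# ----------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage in order, persisting intermediates under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "parquet" if config.profile_format == "parquet" else "csv"
    params = config.to_dict()
    seed = config.seed

    def persist(table: ProfileTable, name: str, inputs: list[Path]) -> Path:
        path = out_dir / f"{name}.{ext}"
        write_profiles(table, path)
        write_provenance(path, params, inputs, seed)
        return path

    design = config.screen_design()
    well_profiles, platemap, truth = generate_screen(design)
    pm_path = out_dir / "platemap.csv"
    write_platemap(platemap, pm_path)
    truth.to_json(out_dir / "ground_truth.json")
    scheme = label_scheme(truth)
    scheme.to_json(out_dir / "label_scheme.json")

    if config.from_cells:
        cells = cells_from_wells(well_profiles, design, config.cell_noise_sd)
        cells_path = persist(cells, "cells", [])
        wells = aggregate(
            cells,
            AggregationSpec(["Metadata_Plate", "Metadata_Well"], config.aggregation_statistic),
        )
        wells_path = persist(wells, "wells", [cells_path])
    else:
        wells = well_profiles
        wells_path = persist(wells, "wells", [])

    annotated, _ = annotate(wells, platemap)
    ann_path = persist(annotated, "annotated", [wells_path, pm_path])

    labeled, _ = label_wells(annotated, scheme)

    model = fit_normalization(
        labeled, method=config.normalization_method, reference=config.reference_query
    )
    model.to_json(out_dir / "normalization_model.json")
    normalized = apply_normalization(labeled, model)
    norm_path = persist(normalized, "normalized", [ann_path])

    selected, sel_report = feature_select(normalized, config.selection_config())
    sel_report.to_json(out_dir / "feature_selection_report.json")
    sel_path = persist(selected, "selected", [norm_path])

    partition = make_holdouts(selected, seed=seed, **config.holdouts)
    splits = partition.splits(selected)
    train, test = split_train_test(
        splits.pop("modeling"), test_fraction=config.test_fraction, seed=seed
    )
    splits = {"train": train, "test": test, **splits}

    bundle = train_classifier(
        train, grid=config.search_grid(), cv_folds=config.cv_folds, seed=seed
    )
    bundle.save(out_dir / "injury_model")

    report = evaluate(
        bundle, splits, shuffled_baseline=config.shuffled_baseline, seed=seed
    )
    report.to_json(out_dir / "evaluation_report.json")
    report.to_csv(out_dir / "evaluation_metrics.csv")
    write_provenance(out_dir / "evaluation_report.json", params, [sel_path], seed)

    summary = {
        "n_wells": len(selected),
        "n_features_selected": len(selected.feature_columns),
        "split_sizes": {name: len(t) for name, t in splits.items()},
        "best_hyperparameters": bundle.hyperparameters,
        "cv_score": bundle.cv_score,
        "macro_f1": {
            name: report.macro_f1(name) for name in splits if len(splits[name])
        },
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))

    return PipelineResult(
        out_dir=out_dir,
        bundle=bundle,
        report=report,
        n_wells=len(selected),
        n_features_selected=len(selected.feature_columns),
        split_sizes={name: len(t) for name, t in splits.items()},
    )
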