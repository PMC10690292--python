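"""Synthetic screens with known ground truth.

Every other module is tested against screens generated here: multi-plate
layouts with DMSO control wells and treatment wells spanning the injury
classes, informative features carrying class-specific mean shifts plus
additive per-plate batch offsets, near-constant and duplicated and
high-missing feature columns for the selection rules to find, single-cell
compartment stores for the merge path, and external-style screens sharing
InChIKeys with the label scheme for the cross-dataset application.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` child streams (spawn keys in
``_STREAMS``), so an entire fixture is reproducible from that one
integer; in particular the per-class shift vectors depend only on the
design's seed and feature composition, which is what lets an external
screen generated from the same seed share the training screen's class
geometry.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import CompartmentStore, PlateMap, ProfileTable
from .injury import INJURY_CLASSES, InjuryLabelScheme

_STREAMS = (
    "compounds",
    "layout",
    "shifts",
    "values",
    "plate_offsets",
    "missing",
    "cells",
    "external",
)

#: vehicle control compound and its (real, public) InChIKey
DMSO = "DMSO"
DMSO_INCHIKEY = "IAZDPXIOMUYVGZ-UHFFFAOYSA-N"

_DEFAULT_CLASSES = tuple(c for c in INJURY_CLASSES if c != "Control")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


@dataclass
class ScreenDesign:
    """Parameters of a synthetic screen.

    Feature composition: ``n_informative`` Gaussian features (unit
    variance) carrying the class shifts, ``n_near_constant`` features with
    a dominant value at frequency ``near_constant_dominant_freq``,
    ``n_duplicated`` copies of informative parents plus noise of SD
    ``duplicate_noise_sd``, and ``n_high_missing`` features with values
    missing completely at random at ``nan_rate``.  ``effect_size`` is the
    class mean shift in units of the unit feature SD, applied to a random
    fraction ``shifted_fraction`` of informative features per class.
    Per-plate batch offsets act along one shared random direction over the
    informative features, with entries marginally Normal(0,
    ``plate_effect_sd``); the low-rank structure is what makes the batch
    effect removable by control-fitted whitening.
    """

    n_plates: int = 30
    plate_rows: int = 8
    plate_cols: int = 12
    control_fraction: float = 0.25
    classes: tuple[str, ...] = _DEFAULT_CLASSES
    treatments_per_class: int = 12
    n_informative: int = 90
    n_near_constant: int = 10
    n_duplicated: int = 10
    n_high_missing: int = 10
    effect_size: float = 3.0
    shifted_fraction: float = 0.5
    plate_effect_sd: float = 0.5
    nan_rate: float = 0.2
    near_constant_dominant_freq: float = 0.97
    duplicate_noise_sd: float = 1e-6
    cells_per_well: int = 50
    cell_count_distribution: str = "poisson"
    compartment_features: int = 4
    orphan_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        if self.n_plates < 1 or self.plate_rows < 1 or self.plate_cols < 1:
            raise ValidationError("plate counts and dimensions must be positive")
        for name in ("control_fraction", "nan_rate", "shifted_fraction",
                     "near_constant_dominant_freq", "orphan_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_informative < 1:
            raise ValidationError("need at least one informative feature")
        if self.n_duplicated > self.n_informative:
            raise ValidationError("cannot have more duplicates than informative parents")
        if not self.classes:
            raise ValidationError("at least one injury class required")
        unknown = set(self.classes) - set(INJURY_CLASSES)
        if unknown:
            raise ValidationError(f"classes outside the injury vocabulary: {sorted(unknown)}")
        if "Control" in self.classes:
            raise ValidationError("'Control' is implicit (control wells); list injuries only")
        if self.cell_count_distribution not in ("poisson", "fixed"):
            raise ValidationError("cell_count_distribution must be 'poisson' or 'fixed'")

    @property
    def wells_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    @property
    def n_features(self) -> int:
        return (
            self.n_informative
            + self.n_near_constant
            + self.n_duplicated
            + self.n_high_missing
        )


@dataclass
class GroundTruth:
    """Everything the generator injected, keyed the way tests need it."""

    well_classes: dict[tuple[str, str], str]
    well_compounds: dict[tuple[str, str], str]
    compound_classes: dict[str, str]
    compound_inchikeys: dict[str, str]
    feature_roles: dict[str, str]
    duplicate_parent: dict[str, str]
    class_shifts: dict[str, np.ndarray]
    plate_offsets: dict[str, np.ndarray]
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "well_classes": {f"{p}/{w}": c for (p, w), c in self.well_classes.items()},
            "well_compounds": {f"{p}/{w}": c for (p, w), c in self.well_compounds.items()},
            "compound_classes": self.compound_classes,
            "compound_inchikeys": self.compound_inchikeys,
            "feature_roles": self.feature_roles,
            "duplicate_parent": self.duplicate_parent,
            "class_shifts": {c: np.asarray(v).tolist() for c, v in self.class_shifts.items()},
            "plate_offsets": {p: np.asarray(v).tolist() for p, v in self.plate_offsets.items()},
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ----------------------------------------------------------------------
# Naming helpers

_FEATURE_GROUPS = (
    ("Cells", "Intensity"),
    ("Cytoplasm", "AreaShape"),
    ("Nuclei", "Texture"),
    ("Cells", "Granularity"),
)


def feature_names(design: ScreenDesign) -> dict[str, list[str]]:
    """Deterministic feature names per role (depends only on composition)."""
    names: dict[str, list[str]] = {}
    counter = 0

    def take(n: int) -> list[str]:
        nonlocal counter
        out = []
        for _ in range(n):
            comp, group = _FEATURE_GROUPS[counter % len(_FEATURE_GROUPS)]
            out.append(f"{comp}_{group}_{counter:03d}")
            counter += 1
        return out

    names["informative"] = take(design.n_informative)
    names["near_constant"] = take(design.n_near_constant)
    names["duplicated"] = take(design.n_duplicated)
    names["high_missing"] = take(design.n_high_missing)
    return names


def _well_ids(design: ScreenDesign) -> list[str]:
    rows = string.ascii_uppercase[: design.plate_rows]
    return [f"{r}{c:02d}" for r in rows for c in range(1, design.plate_cols + 1)]


def _fake_inchikey(rng: np.random.Generator) -> str:
    letters = np.array(list(string.ascii_uppercase))
    a = "".join(rng.choice(letters, size=14))
    b = "".join(rng.choice(letters, size=8))
    return f"{a}-{b}SA-N"


def _compound_catalog(
    design: ScreenDesign, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, str]]:
    """(compound -> class, compound -> InChIKey) for all treatments."""
    compound_classes: dict[str, str] = {}
    inchikeys: dict[str, str] = {DMSO: DMSO_INCHIKEY}
    for cls in design.classes:
        tag = cls.replace(" ", "")
        for k in range(design.treatments_per_class):
            cmpd = f"{tag}-{k:02d}"
            compound_classes[cmpd] = cls
            inchikeys[cmpd] = _fake_inchikey(rng)
    return compound_classes, inchikeys


def class_shift_vectors(design: ScreenDesign) -> dict[str, np.ndarray]:
    """Per-class mean-shift vectors over the informative features.

    Derived from the design seed alone (dedicated stream), so two designs
    sharing seed and feature composition share the same class geometry.
    """
    rng = _streams(design.seed)["shifts"]
    n = design.n_informative
    k = max(1, round(design.shifted_fraction * n))
    shifts: dict[str, np.ndarray] = {"Control": np.zeros(n)}
    for cls in design.classes:
        vec = np.zeros(n)
        idx = rng.choice(n, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        vec[idx] = design.effect_size * signs
        shifts[cls] = vec
    return shifts


# ----------------------------------------------------------------------
# Well-level screen


def generate_screen(
    design: ScreenDesign,
) -> tuple[ProfileTable, PlateMap, GroundTruth]:
    """Generate a well-level synthetic screen.

    Returns the profile table (plate/well metadata plus features), the
    plate map (compound, InChIKey, concentration, perturbation type), and
    the injected ground truth.
    """
    streams = _streams(design.seed)
    compound_classes, inchikeys = _compound_catalog(design, streams["compounds"])
    names = feature_names(design)
    shifts = class_shift_vectors(design)

    wells = _well_ids(design)
    n_wells = design.wells_per_plate
    n_ctrl = round(design.control_fraction * n_wells)
    plates = [f"plate_{i + 1:03d}" for i in range(design.n_plates)]

    layout_rng = streams["layout"]
    well_classes: dict[tuple[str, str], str] = {}
    well_compounds: dict[tuple[str, str], str] = {}
    rows_meta = []
    by_class = {
        cls: [c for c, k in compound_classes.items() if k == cls]
        for cls in design.classes
    }
    treated_counter = 0
    for plate in plates:
        shuffled = list(layout_rng.permutation(wells))
        for j, well in enumerate(shuffled):
            if j < n_ctrl:
                cls, cmpd, conc, ptype = "Control", DMSO, 0.0, "control"
            else:
                cls = design.classes[treated_counter % len(design.classes)]
                treated_counter += 1
                cmpd = by_class[cls][int(layout_rng.integers(len(by_class[cls])))]
                conc = float(layout_rng.choice([0.1, 1.0, 10.0]))
                ptype = "chemical"
            well_classes[(plate, well)] = cls
            well_compounds[(plate, well)] = cmpd
            rows_meta.append((plate, well, cmpd, inchikeys[cmpd], conc, ptype, cls))
    meta = pd.DataFrame(
        rows_meta,
        columns=["plate", "well", "compound", "inchikey", "concentration",
                 "perturbation_type", "_class"],
    )
    # rows in plate-major, well-sorted order for a stable table
    meta = meta.sort_values(["plate", "well"], kind="mergesort").reset_index(drop=True)

    n_rows = len(meta)
    vrng = streams["values"]
    informative = vrng.standard_normal((n_rows, design.n_informative))
    shift_matrix = np.stack([shifts[c] for c in meta["_class"]])
    informative += shift_matrix

    # batch effects are low-dimensional: every plate shifts along one shared
    # random direction, so entries are marginally Normal(0, plate_effect_sd)
    # but whitening fitted on controls can undo them
    offs_rng = streams["plate_offsets"]
    direction = offs_rng.standard_normal(design.n_informative)
    direction /= np.linalg.norm(direction)
    plate_offsets = {
        p: float(offs_rng.standard_normal())
        * design.plate_effect_sd
        * np.sqrt(design.n_informative)
        * direction
        for p in plates
    }
    informative += np.stack([plate_offsets[p] for p in meta["plate"]])

    near_constant = vrng.standard_normal((n_rows, design.n_near_constant))
    dominant = vrng.random((n_rows, design.n_near_constant)) < design.near_constant_dominant_freq
    near_constant[dominant] = 0.0

    parent_idx = vrng.choice(
        design.n_informative, size=design.n_duplicated, replace=False
    )
    duplicated = informative[:, parent_idx] + vrng.normal(
        0.0, design.duplicate_noise_sd, size=(n_rows, design.n_duplicated)
    )

    high_missing = vrng.standard_normal((n_rows, design.n_high_missing))
    miss = streams["missing"].random((n_rows, design.n_high_missing)) < design.nan_rate
    high_missing[miss] = np.nan

    frame = pd.DataFrame(
        {
            "Metadata_Plate": meta["plate"],
            "Metadata_Well": meta["well"],
        }
    )
    blocks = [
        (names["informative"], informative),
        (names["near_constant"], near_constant),
        (names["duplicated"], duplicated),
        (names["high_missing"], high_missing),
    ]
    for cols, block in blocks:
        frame = pd.concat([frame, pd.DataFrame(block, columns=cols)], axis=1)
    profiles = ProfileTable.from_dataframe(frame)

    platemap = PlateMap(
        meta.drop(columns="_class"), plate_column="plate", well_column="well"
    )

    roles: dict[str, str] = {}
    for role, cols in names.items():
        for c in cols:
            roles[c] = role
    dup_parent = {
        dup: names["informative"][p]
        for dup, p in zip(names["duplicated"], parent_idx)
    }
    truth = GroundTruth(
        well_classes=well_classes,
        well_compounds=well_compounds,
        compound_classes=compound_classes,
        compound_inchikeys=inchikeys,
        feature_roles=roles,
        duplicate_parent=dup_parent,
        class_shifts=shifts,
        plate_offsets=plate_offsets,
        seed=design.seed,
    )
    return profiles, platemap, truth


def label_scheme(truth: GroundTruth) -> InjuryLabelScheme:
    """The label scheme implied by a generated screen's compound catalog."""
    return InjuryLabelScheme(
        compound_to_injury=dict(truth.compound_classes),
        inchikey_to_injury={
            truth.compound_inchikeys[c]: cls
            for c, cls in truth.compound_classes.items()
        },
        control_compounds=frozenset({DMSO}),
    )


def cells_from_wells(
    profiles: ProfileTable,
    design: ScreenDesign,
    cell_noise_sd: float = 1.0,
) -> ProfileTable:
    """Expand well profiles into single-cell rows.

    Each well contributes ``cells_per_well`` cells (Poisson-distributed
    unless the design says fixed) whose feature values are the well value
    plus Normal(0, *cell_noise_sd*) noise; missing well values yield
    missing cell values.  Aggregating the result back by plate and well
    recovers the well profiles up to sampling noise.
    """
    rng = _streams(design.seed)["cells"]
    counts = (
        np.full(len(profiles), design.cells_per_well)
        if design.cell_count_distribution == "fixed"
        else np.maximum(1, rng.poisson(design.cells_per_well, size=len(profiles)))
    )
    meta = profiles.metadata.reset_index(drop=True)
    values = profiles.features.to_numpy(dtype=float)
    expanded = np.repeat(values, counts, axis=0)
    noise = rng.normal(0.0, cell_noise_sd, size=expanded.shape)
    expanded = expanded + noise  # NaN well values propagate to cells
    meta_rep = meta.loc[np.repeat(meta.index.to_numpy(), counts)].reset_index(drop=True)
    frame = pd.concat(
        [meta_rep, pd.DataFrame(expanded, columns=profiles.feature_columns)], axis=1
    )
    return ProfileTable(
        frame, list(profiles.metadata_columns), list(profiles.feature_columns)
    )


# ----------------------------------------------------------------------
# Single-cell compartment stores


@dataclass
class StoreTruth:
    """Cell counts injected into a generated compartment store."""

    cells_per_image: dict[int, int]
    n_orphans: int

    @property
    def total_cells(self) -> int:
        return sum(self.cells_per_image.values())


def generate_compartment_store(
    design: ScreenDesign, path: str | Path
) -> tuple[CompartmentStore, StoreTruth]:
    """Write a single-cell relational store in SQLite format.

    One image per (plate, well); per-image cell counts follow the design's
    distribution.  Nuclei object numbers are a random permutation of the
    cell object numbers, linked through the cytoplasm table's
    ``Parent_Cells``/``Parent_Nuclei`` columns.  A fraction
    ``orphan_fraction`` of cells is present in the nuclei table only
    (their cells and cytoplasm rows are withheld), exercising the orphan
    accounting of the merge.
    """
    rng = _streams(design.seed)["cells"]
    wells = _well_ids(design)
    plates = [f"plate_{i + 1:03d}" for i in range(design.n_plates)]
    image_rows, cells_rows, cyto_rows, nuc_rows = [], [], [], []
    cells_per_image: dict[int, int] = {}
    n_orphans = 0
    image_number = 0
    feat_names = [f"Feat_{i}" for i in range(design.compartment_features)]
    for plate in plates:
        for well in wells:
            image_number += 1
            n = (
                design.cells_per_well
                if design.cell_count_distribution == "fixed"
                else max(1, int(rng.poisson(design.cells_per_well)))
            )
            image_rows.append((image_number, plate, well))
            nuc_order = rng.permutation(np.arange(1, n + 1))
            orphan = rng.random(n) < design.orphan_fraction
            kept = 0
            for obj in range(1, n + 1):
                nuc_obj = int(nuc_order[obj - 1])
                feats = {
                    "cells": rng.standard_normal(design.compartment_features),
                    "cytoplasm": rng.standard_normal(design.compartment_features),
                    "nuclei": rng.standard_normal(design.compartment_features),
                }
                nuc_rows.append((image_number, nuc_obj, *feats["nuclei"]))
                if orphan[obj - 1]:
                    n_orphans += 1
                    continue
                kept += 1
                cells_rows.append((image_number, obj, *feats["cells"]))
                cyto_rows.append((image_number, obj, obj, nuc_obj, *feats["cytoplasm"]))
            cells_per_image[image_number] = kept
    image = pd.DataFrame(
        image_rows, columns=["ImageNumber", "Metadata_Plate", "Metadata_Well"]
    )
    cells = pd.DataFrame(cells_rows, columns=["ImageNumber", "ObjectNumber", *feat_names])
    cyto = pd.DataFrame(
        cyto_rows,
        columns=["ImageNumber", "ObjectNumber", "Parent_Cells", "Parent_Nuclei", *feat_names],
    )
    nuclei = pd.DataFrame(nuc_rows, columns=["ImageNumber", "ObjectNumber", *feat_names])
    store = CompartmentStore.write(
        path, image, {"cells": cells, "cytoplasm": cyto, "nuclei": nuclei}
    )
    return store, StoreTruth(cells_per_image=cells_per_image, n_orphans=n_orphans)


# ----------------------------------------------------------------------
# External screens


def generate_external_screen(
    design: ScreenDesign,
    scheme: InjuryLabelScheme,
    overlap: int,
    injury_class: str = "Cytoskeletal",
    n_extra_features: int = 15,
) -> tuple[ProfileTable, PlateMap, GroundTruth]:
    """An external-style screen sharing InChIKeys with the label scheme.

    Exactly *overlap* wells carry InChIKeys that map to *injury_class* in
    the scheme (their features follow that class's shift vector, derived
    from the design seed); all other wells are control-like with foreign
    InChIKeys.  The feature set is a strict superset of the design's
    feature names (``External_Extra_*`` columns added) so the intersection
    step has work to do.
    """
    wells_total = design.n_plates * design.wells_per_plate
    if overlap > wells_total:
        raise ValidationError(
            f"overlap {overlap} exceeds available wells ({wells_total})"
        )
    matching_keys = sorted(
        k for k, cls in scheme.inchikey_to_injury.items() if cls == injury_class
    )
    if overlap > 0 and not matching_keys:
        raise ValidationError(f"scheme has no InChIKeys for class {injury_class!r}")
    rng = _streams(design.seed)["external"]
    shifts = class_shift_vectors(design)
    if injury_class not in shifts:
        raise ValidationError(f"design does not generate class {injury_class!r}")
    names = feature_names(design)
    shared = [c for cols in names.values() for c in cols]
    extra = [f"External_Extra_{i:03d}" for i in range(n_extra_features)]

    plates = [f"ext_plate_{i + 1:03d}" for i in range(design.n_plates)]
    wells = _well_ids(design)
    all_positions = [(p, w) for p in plates for w in wells]
    overlap_pos = {
        tuple(all_positions[i])
        for i in rng.choice(len(all_positions), size=overlap, replace=False)
    }

    rows_meta = []
    well_classes, well_compounds = {}, {}
    x = rng.standard_normal((wells_total, len(shared)))
    inf_slice = slice(0, design.n_informative)
    for i, (plate, well) in enumerate(all_positions):
        if (plate, well) in overlap_pos:
            key = matching_keys[int(rng.integers(len(matching_keys)))]
            cmpd = f"ext-{injury_class.replace(' ', '')}-{i:04d}"
            x[i, inf_slice] += shifts[injury_class]
            cls = injury_class
        else:
            key = _fake_inchikey(rng)
            cmpd = f"ext-unknown-{i:04d}"
            cls = "Control"
        rows_meta.append((plate, well, cmpd, key, 1.0, "chemical"))
        well_classes[(plate, well)] = cls
        well_compounds[(plate, well)] = cmpd
    meta = pd.DataFrame(
        rows_meta,
        columns=["plate", "well", "compound", "inchikey", "concentration",
                 "perturbation_type"],
    )
    extra_vals = rng.standard_normal((wells_total, len(extra)))
    frame = pd.concat(
        [
            pd.DataFrame(
                {"Metadata_Plate": meta["plate"], "Metadata_Well": meta["well"]}
            ),
            pd.DataFrame(x, columns=shared),
            pd.DataFrame(extra_vals, columns=extra),
        ],
        axis=1,
    )
    profiles = ProfileTable.from_dataframe(frame)
    platemap = PlateMap(meta, plate_column="plate", well_column="well")
    roles = {c: ("extra" if c in extra else "shared") for c in shared + extra}
    truth = GroundTruth(
        well_classes=well_classes,
        well_compounds=well_compounds,
        compound_classes={},
        compound_inchikeys={},
        feature_roles=roles,
        duplicate_parent={},
        class_shifts=shifts,
        plate_offsets={},
        seed=design.seed,
    )
    return profiles, platemap, truth
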