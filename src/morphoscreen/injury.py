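"""Cell-injury phenotype classification from well-level profiles.

A screen of cytotoxic ("nuisance") compounds is labeled with one of 15
injury classes (vehicle-control wells are ``Control``), three holdout sets
are carved out in a fixed sequence (whole plates, whole treatments,
individual wells), the remainder is split 80/20 stratified by class, and a
class-weighted multinomial logistic regression is trained with a
randomized hyperparameter search.  Evaluation reports per-class
precision/recall/F1 and confusion matrices per data split, optionally
against a label-permutation (shuffled) baseline, and the trained model can
be applied to an external profile table sharing the model's feature set
(matched by feature-name intersection and, for treatments, by InChIKey).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)

from .exceptions import EmptyResultError, SchemaError, ValidationError
from .io import PlateMap, ProfileTable

#: the 15 injury classes of the cell-injury screen
INJURY_CLASSES = (
    "Control",
    "Cytoskeletal",
    "Hsp90",
    "Kinase",
    "Genotoxin",
    "Miscellaneous",
    "Redox",
    "HDAC",
    "mTOR",
    "Proteasome",
    "Saponin",
    "Mitochondria",
    "Ferroptosis",
    "Tannin",
    "Nonspecific Reactive",
)

LABEL_COLUMN = "Metadata_injury"
COMPOUND_COLUMN = "Metadata_compound"
PLATE_COLUMN = "Metadata_Plate"
WELL_COLUMN = "Metadata_Well"


def intersect_features(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Features present in both lists, in *a*'s order.

    Raises :class:`EmptyResultError` when the intersection is empty (a
    model trained on it would be degenerate).
    """
    bset = set(b)
    shared = [f for f in a if f in bset]
    if not shared:
        raise EmptyResultError("feature name intersection is empty")
    return shared


# ----------------------------------------------------------------------
# Labeling


@dataclass
class InjuryLabelScheme:
    """Compound-to-injury mapping over a fixed class vocabulary.

    ``control_compounds`` (DMSO by default) are labeled ``Control``;
    ``inchikey_to_injury`` supports cross-dataset treatment matching.
    """

    compound_to_injury: dict[str, str] = field(default_factory=dict)
    inchikey_to_injury: dict[str, str] = field(default_factory=dict)
    control_compounds: frozenset[str] = frozenset({"DMSO"})
    class_vocabulary: tuple[str, ...] = INJURY_CLASSES

    def __post_init__(self) -> None:
        self.control_compounds = frozenset(self.control_compounds)
        vocab = set(self.class_vocabulary)
        for mapping in (self.compound_to_injury, self.inchikey_to_injury):
            bad = sorted(set(mapping.values()) - vocab)
            if bad:
                raise ValidationError(f"injuries outside the vocabulary: {bad}")
        for c in self.control_compounds:
            if self.compound_to_injury.get(c, "Control") != "Control":
                raise ValidationError(
                    f"control compound {c!r} mapped to a non-Control injury"
                )

    def label_for(self, compound: str) -> str | None:
        if compound in self.control_compounds:
            return "Control"
        return self.compound_to_injury.get(compound)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "class_vocabulary": list(self.class_vocabulary),
            "control_compounds": sorted(self.control_compounds),
            "compound_to_injury": self.compound_to_injury,
            "inchikey_to_injury": self.inchikey_to_injury,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "InjuryLabelScheme":
        doc = json.loads(Path(path).read_text())
        return cls(
            compound_to_injury=doc["compound_to_injury"],
            inchikey_to_injury=doc.get("inchikey_to_injury", {}),
            control_compounds=frozenset(doc.get("control_compounds", ["DMSO"])),
            class_vocabulary=tuple(doc.get("class_vocabulary", INJURY_CLASSES)),
        )


def label_wells(
    profiles: ProfileTable,
    scheme: InjuryLabelScheme,
    compound_column: str = COMPOUND_COLUMN,
    label_column: str = LABEL_COLUMN,
) -> tuple[ProfileTable, int]:
    """Attach injury labels; drop wells whose compound the scheme does not know.

    Returns the labeled table and the number of excluded wells.
    """
    if compound_column not in profiles.metadata_columns:
        raise SchemaError(f"profiles lack compound column {compound_column!r}")
    labels = profiles.data[compound_column].map(scheme.label_for)
    keep = labels.notna()
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError("no wells with a known injury label remain")
    data = profiles.data.loc[keep].copy()
    data[label_column] = labels[keep]
    meta = list(profiles.metadata_columns) + [label_column]
    data = data[meta + list(profiles.feature_columns)]
    return ProfileTable(data, meta, list(profiles.feature_columns)), n_excluded


def match_treatments(
    scheme: InjuryLabelScheme,
    external_platemap: PlateMap,
    inchikey_column: str = "inchikey",
) -> pd.DataFrame:
    """Wells of an external plate map whose InChIKey maps to a known injury.

    Returns the matching plate-map rows with an ``injury`` column attached
    (empty result allowed).
    """
    if inchikey_column not in external_platemap.data.columns:
        raise SchemaError(f"plate map lacks InChIKey column {inchikey_column!r}")
    df = external_platemap.data.copy()
    df["injury"] = df[inchikey_column].map(scheme.inchikey_to_injury)
    return df[df["injury"].notna()].reset_index(drop=True)


# ----------------------------------------------------------------------
# Holdouts and splitting


@dataclass
class HoldoutPartition:
    """Row-index sets for the three holdouts and the modeling remainder.

    Holdouts were removed in the order plate -> treatment -> well, so the
    four sets are pairwise disjoint and together cover all labeled wells.
    """

    plate_holdout: pd.Index
    treatment_holdout: pd.Index
    well_holdout: pd.Index
    modeling: pd.Index
    held_plates: list = field(default_factory=list)
    held_treatments: dict[str, list[str]] = field(default_factory=dict)
    control_shortfalls: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, pd.Index]:
        return {
            "plate_holdout": self.plate_holdout,
            "treatment_holdout": self.treatment_holdout,
            "well_holdout": self.well_holdout,
            "modeling": self.modeling,
        }

    def splits(self, profiles: ProfileTable) -> dict[str, ProfileTable]:
        return {name: profiles.subset_rows(idx) for name, idx in self.as_dict().items()}


def make_holdouts(
    profiles: ProfileTable,
    n_plates: int = 10,
    min_treatments: int = 10,
    treatments_per_injury: int = 1,
    control_wells_per_plate: int = 5,
    injury_wells_per_plate: int = 10,
    seed: int = 0,
    plate_column: str = PLATE_COLUMN,
    compound_column: str = COMPOUND_COLUMN,
    label_column: str = LABEL_COLUMN,
) -> HoldoutPartition:
    """Carve out plate, treatment, and well holdouts in that order.

    * plate holdout: all wells of *n_plates* randomly selected plates;
    * treatment holdout: for every injury with more than *min_treatments*
      distinct treatments, all remaining wells of *treatments_per_injury*
      randomly chosen treatments;
    * well holdout: from each non-held-out plate, *control_wells_per_plate*
      control wells plus *injury_wells_per_plate* injury wells at random
      (a plate short of controls contributes all it has; the shortfall is
      recorded).

    Wells eligible for several holdouts are assigned to the earliest one in
    the sequence.  The same seed reproduces the same partition.
    """
    for col in (plate_column, compound_column, label_column):
        if col not in profiles.metadata_columns:
            raise SchemaError(f"profiles lack metadata column {col!r}")
    rng = np.random.default_rng(seed)
    df = profiles.data
    plates = np.array(sorted(df[plate_column].unique()))
    if len(plates) < n_plates:
        raise ValidationError(
            f"{len(plates)} plates present; cannot hold out {n_plates}"
        )
    held_plates = sorted(rng.choice(plates, size=n_plates, replace=False).tolist())
    in_held_plate = df[plate_column].isin(held_plates)
    plate_idx = df.index[in_held_plate]

    # treatment qualification is assessed over the full labeled set
    held_treatments: dict[str, list[str]] = {}
    treated = df[df[label_column] != "Control"]
    for injury in sorted(treated[label_column].unique()):
        compounds = np.array(
            sorted(treated.loc[treated[label_column] == injury, compound_column].unique())
        )
        if len(compounds) > min_treatments:
            k = min(treatments_per_injury, len(compounds))
            held_treatments[injury] = sorted(
                rng.choice(compounds, size=k, replace=False).tolist()
            )
    held_compounds = {c for cs in held_treatments.values() for c in cs}
    in_held_treatment = df[compound_column].isin(held_compounds) & ~in_held_plate
    treatment_idx = df.index[in_held_treatment]

    remaining = df.loc[~in_held_plate & ~in_held_treatment]
    well_rows: list = []
    shortfalls: dict = {}
    for plate in sorted(remaining[plate_column].unique()):
        on_plate = remaining[remaining[plate_column] == plate]
        controls = np.array(sorted(on_plate.index[on_plate[label_column] == "Control"]))
        injuries = np.array(sorted(on_plate.index[on_plate[label_column] != "Control"]))
        n_ctrl = min(control_wells_per_plate, len(controls))
        if n_ctrl < control_wells_per_plate:
            shortfalls[plate] = control_wells_per_plate - n_ctrl
        if n_ctrl:
            well_rows.extend(rng.choice(controls, size=n_ctrl, replace=False).tolist())
        n_inj = min(injury_wells_per_plate, len(injuries))
        if n_inj:
            well_rows.extend(rng.choice(injuries, size=n_inj, replace=False).tolist())
    well_idx = df.index[df.index.isin(well_rows)]
    modeling_idx = df.index.difference(plate_idx.union(treatment_idx).union(well_idx))

    return HoldoutPartition(
        plate_holdout=plate_idx,
        treatment_holdout=treatment_idx,
        well_holdout=well_idx,
        modeling=modeling_idx,
        held_plates=held_plates,
        held_treatments=held_treatments,
        control_shortfalls=shortfalls,
    )


def split_train_test(
    modeling: ProfileTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    label_column: str = LABEL_COLUMN,
) -> tuple[ProfileTable, ProfileTable]:
    """Stratified train/test split preserving class-label proportions.

    The test partition size is ``ceil(test_fraction * n)``; per-class
    proportions match the global split within rounding.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    labels = modeling.data[label_column]
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValidationError(
            f"classes with fewer than 2 wells cannot be stratified: {sorted(singletons.index)}"
        )
    train_idx, test_idx = train_test_split(
        modeling.data.index,
        test_size=test_fraction,
        stratify=labels,
        random_state=int(seed) % (2**32),
    )
    return modeling.subset_rows(train_idx), modeling.subset_rows(test_idx)


# ----------------------------------------------------------------------
# Training


_PENALTY_SOLVERS = {
    "l1": ("liblinear", "saga"),
    "l2": ("newton-cg", "lbfgs", "liblinear", "sag", "saga"),
    "elasticnet": ("saga",),
}


@dataclass
class SearchGrid:
    """Hyperparameter grid for the randomized logistic-regression search.

    Only valid penalty/solver combinations are sampled (L1 needs
    liblinear or saga; Elastic Net needs saga with an l1_ratio); the
    liblinear solver fits one-vs-rest rather than a joint multinomial
    model and is kept in the grid for completeness.
    """

    penalties: tuple[str, ...] = ("l1", "l2", "elasticnet")
    strengths: tuple[float, ...] = (0.0001, 0.01, 0.1, 1.0, 10.0, 100.0)
    tolerances: tuple[float, ...] = (1e-6, 1e-3)
    elasticnet_ratios: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    solvers: tuple[str, ...] = ("newton-cg", "lbfgs", "liblinear", "sag", "saga")
    n_candidates: int = 50
    max_iter: int = 200

    def __post_init__(self) -> None:
        unknown = set(self.penalties) - set(_PENALTY_SOLVERS)
        if unknown:
            raise ValidationError(f"unknown penalties: {sorted(unknown)}")
        if self.n_candidates < 1:
            raise ValidationError("n_candidates must be positive")

    @staticmethod
    def validate_combination(penalty: str, solver: str) -> None:
        if solver not in _PENALTY_SOLVERS.get(penalty, ()):
            raise ValidationError(
                f"solver {solver!r} does not support penalty {penalty!r}"
            )

    def parameter_space(self, multiclass: bool = False) -> list[dict]:
        """Sub-grids of mutually compatible parameter choices.

        Penalties are expressed through ``l1_ratio`` (0 = L2, 1 = L1,
        in-between = Elastic Net), the non-deprecated parameterization.
        With ``multiclass=True`` the liblinear solver is excluded: it only
        fits binary problems (its one-vs-rest wrapper was removed from
        scikit-learn), so it can participate only in two-class searches.
        """
        space = []
        ratio_for = {"l1": [1.0], "l2": [0.0], "elasticnet": list(self.elasticnet_ratios)}
        for penalty in self.penalties:
            solvers = [s for s in self.solvers if s in _PENALTY_SOLVERS[penalty]]
            if multiclass:
                solvers = [s for s in solvers if s != "liblinear"]
            if not solvers:
                continue
            space.append(
                {
                    "l1_ratio": ratio_for[penalty],
                    "solver": solvers,
                    "C": list(self.strengths),
                    "tol": list(self.tolerances),
                }
            )
        if not space:
            raise ValidationError("grid contains no valid penalty/solver combination")
        return space


@dataclass
class InjuryModelBundle:
    """A trained injury classifier with everything needed to reuse it."""

    classes: list[str]
    coefficients: np.ndarray
    intercepts: np.ndarray
    hyperparameters: dict
    shared_features: list[str]
    seed: int
    n_train: int
    cv_score: float
    convergence_warned: bool = False
    estimator: LogisticRegression | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape[1] != len(self.shared_features):
            raise ValidationError(
                "coefficient matrix width must equal the shared-feature count"
            )

    @property
    def penalty(self) -> str:
        """Penalty family implied by the chosen l1_ratio."""
        ratio = float(self.hyperparameters.get("l1_ratio", 0.0))
        return {0.0: "l2", 1.0: "l1"}.get(ratio, "elasticnet")

    def _build_estimator(self) -> LogisticRegression:
        params = dict(self.hyperparameters)
        est = LogisticRegression(class_weight="balanced", random_state=self.seed, **params)
        est.classes_ = np.asarray(self.classes, dtype=object)
        est.coef_ = self.coefficients
        est.intercept_ = self.intercepts
        est.n_features_in_ = len(self.shared_features)
        return est

    @property
    def model(self) -> LogisticRegression:
        if self.estimator is None:
            self.estimator = self._build_estimator()
        return self.estimator

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.json`` (parameters) and ``<prefix>.coef.csv``
        (classes x features coefficient matrix plus intercept column)."""
        prefix = Path(prefix)
        doc = {
            "classes": list(self.classes),
            "hyperparameters": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.hyperparameters.items()
            },
            "shared_features": list(self.shared_features),
            "penalty": self.penalty,
            "seed": int(self.seed),
            "n_train": int(self.n_train),
            "cv_score": float(self.cv_score),
            "convergence_warned": bool(self.convergence_warned),
        }
        json_path = prefix.with_suffix(".json")
        json_path.write_text(json.dumps(doc, indent=1))
        coef = pd.DataFrame(self.coefficients, index=self.classes, columns=self.shared_features)
        coef.insert(0, "__intercept__", self.intercepts)
        coef_path = prefix.with_suffix(".coef.csv")
        coef.to_csv(coef_path, index_label="class")
        return json_path, coef_path

    @classmethod
    def load(cls, prefix: str | Path) -> "InjuryModelBundle":
        prefix = Path(prefix)
        doc = json.loads(prefix.with_suffix(".json").read_text())
        coef = pd.read_csv(prefix.with_suffix(".coef.csv"), index_col="class")
        intercepts = coef.pop("__intercept__").to_numpy()
        return cls(
            classes=doc["classes"],
            coefficients=coef.to_numpy(),
            intercepts=intercepts,
            hyperparameters=doc["hyperparameters"],
            shared_features=doc["shared_features"],
            seed=doc["seed"],
            n_train=doc["n_train"],
            cv_score=doc["cv_score"],
            convergence_warned=doc["convergence_warned"],
        )


def _feature_matrix(table: ProfileTable, features: Sequence[str]) -> np.ndarray:
    absent = [f for f in features if f not in table.feature_columns]
    if absent:
        raise ValidationError(f"table lacks model features: {absent}")
    x = table.data[list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError(
            "feature matrix contains missing values; run feature selection "
            "(drop_na_columns) or impute before training/prediction"
        )
    return x


def train_classifier(
    train: ProfileTable,
    grid: SearchGrid | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    label_column: str = LABEL_COLUMN,
    scoring: str = "f1_macro",
) -> InjuryModelBundle:
    """Class-weighted multinomial logistic regression with randomized search.

    Class weights are inversely proportional to class frequencies
    (``class_weight='balanced'``); hyperparameters are chosen by
    randomized search over the valid grid combinations with stratified
    cross-validation scored by macro-F1.  Non-convergence is recorded as a
    warning flag on the returned bundle, not an error.
    """
    grid = grid or SearchGrid()
    y = train.data[label_column].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("training data must contain at least 2 classes")
    features = list(train.feature_columns)
    empty = [f for f in features if train.data[f].isna().all()]
    if empty:
        raise ValidationError(f"all-missing feature columns: {empty}")
    x = _feature_matrix(train, features)

    seed = int(seed) % (2**31)
    base = LogisticRegression(
        class_weight="balanced", max_iter=grid.max_iter, random_state=seed
    )
    search = RandomizedSearchCV(
        base,
        grid.parameter_space(multiclass=len(classes) > 2),
        n_iter=grid.n_candidates,
        scoring=scoring,
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        random_state=seed,
        refit=True,
        n_jobs=None,
        error_score="raise",
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        search.fit(x, y)
    convergence_warned = any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )
    best = search.best_estimator_
    return InjuryModelBundle(
        classes=[str(c) for c in best.classes_],
        coefficients=best.coef_,
        intercepts=best.intercept_,
        hyperparameters=dict(search.best_params_),
        shared_features=features,
        seed=seed,
        n_train=len(train),
        cv_score=float(search.best_score_),
        convergence_warned=convergence_warned,
        estimator=best,
    )


# ----------------------------------------------------------------------
# Evaluation and prediction


@dataclass
class EvaluationReport:
    """Per-class metrics, confusion matrices, and well probabilities.

    ``metrics`` has one row per (split, class, shuffled-flag) with
    precision/recall/F1/support; ``confusion`` maps split name (suffixed
    ``:shuffled`` for the baseline) to a true-by-predicted count matrix;
    ``probabilities`` holds the per-well class-probability table.
    """

    metrics: pd.DataFrame
    confusion: dict[str, pd.DataFrame]
    probabilities: pd.DataFrame

    def macro_f1(self, split: str, shuffled: bool = False) -> float:
        sub = self.metrics[
            (self.metrics["split"] == split) & (self.metrics["shuffled"] == shuffled)
        ]
        present = sub[sub["support"] > 0]
        return float(present["f1"].mean())

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "metrics": self.metrics.to_dict(orient="records"),
            "confusion": {
                name: {"classes": list(m.index), "matrix": m.to_numpy().tolist()}
                for name, m in self.confusion.items()
            },
        }
        text = json.dumps(doc, indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> Path:
        self.metrics.to_csv(path, index=False)
        return Path(path)


def _score_split(
    estimator: LogisticRegression,
    name: str,
    table: ProfileTable,
    features: Sequence[str],
    classes: Sequence[str],
    label_column: str,
    shuffled: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    x = _feature_matrix(table, features)
    y_true = table.data[label_column].to_numpy()
    y_pred = estimator.predict(x)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0
    )
    metrics = pd.DataFrame(
        {
            "split": name,
            "class": list(classes),
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": support,
            "shuffled": shuffled,
        }
    )
    cm = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=list(classes)),
        index=list(classes),
        columns=list(classes),
    )
    proba = pd.DataFrame(
        estimator.predict_proba(x), columns=[f"prob_{c}" for c in estimator.classes_]
    )
    proba.insert(0, "split", name)
    proba.insert(1, "shuffled", shuffled)
    proba.insert(2, "true_label", y_true)
    proba.insert(3, "predicted_label", y_pred)
    return metrics, cm, proba


def evaluate(
    bundle: InjuryModelBundle,
    splits: Mapping[str, ProfileTable],
    shuffled_baseline: bool = False,
    seed: int = 0,
    label_column: str = LABEL_COLUMN,
) -> EvaluationReport:
    """Score the model on each named split.

    With ``shuffled_baseline=True`` a second model with the same chosen
    hyperparameters is refit on label-permuted training data (the
    ``train`` split must be provided) and evaluated identically; its rows
    carry ``shuffled=True``.
    """
    features = bundle.shared_features
    classes = bundle.classes
    metric_frames, proba_frames, confusion = [], [], {}
    for name, table in splits.items():
        if len(table) == 0:
            continue
        m, cm, p = _score_split(
            bundle.model, name, table, features, classes, label_column, shuffled=False
        )
        metric_frames.append(m)
        proba_frames.append(p)
        confusion[name] = cm

    if shuffled_baseline:
        if "train" not in splits:
            raise ValidationError("shuffled baseline requires a 'train' split")
        rng = np.random.default_rng(seed)
        train = splits["train"]
        x = _feature_matrix(train, features)
        y = rng.permutation(train.data[label_column].to_numpy())
        null_est = LogisticRegression(
            class_weight="balanced",
            max_iter=200,
            random_state=int(seed) % (2**31),
            **bundle.hyperparameters,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            null_est.fit(x, y)
        for name, table in splits.items():
            if len(table) == 0:
                continue
            m, cm, p = _score_split(
                null_est, name, table, features, classes, label_column, shuffled=True
            )
            metric_frames.append(m)
            proba_frames.append(p)
            confusion[f"{name}:shuffled"] = cm

    return EvaluationReport(
        metrics=pd.concat(metric_frames, ignore_index=True),
        confusion=confusion,
        probabilities=pd.concat(proba_frames, ignore_index=True),
    )


def predict_injury(
    bundle: InjuryModelBundle,
    external: ProfileTable,
    predicted_column: str = "Metadata_predicted_injury",
) -> pd.DataFrame:
    """Per-well class probabilities (summing to 1) plus the argmax label.

    The external table must contain every model feature (apply
    :func:`intersect_features` and re-train on the shared space first when
    datasets differ).
    """
    x = _feature_matrix(external, bundle.shared_features)
    est = bundle.model
    proba = est.predict_proba(x)
    out = external.data[external.metadata_columns].copy()
    for i, c in enumerate(est.classes_):
        out[f"prob_{c}"] = proba[:, i]
    out[predicted_column] = est.predict(x)
    return out
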