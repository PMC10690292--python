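"""Core profile-processing operations.

The canonical image-based profiling sequence is: aggregate single cells to
well-level profiles, annotate wells with the plate map, normalize features
against a reference population (typically the vehicle-control wells), and
optionally sphere (ZCA-whiten) the profiles against that same reference as
a batch correction.  Consensus collapses replicate wells per perturbation.

Normalization is fit/apply: :func:`fit_normalization` estimates per-feature
location/scale (or a whitening transform) on the reference rows only, and
:func:`apply_normalization` applies the frozen model to any table sharing
the fitted features.  This separation is what makes control-referenced
normalization auditable: the model records the reference selector it was
fitted with.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .io import METADATA_PREFIX, PlateMap, ProfileTable

#: consistency constant making the median absolute deviation an unbiased
#: estimator of the standard deviation under a Gaussian model
MAD_CONSISTENCY = 1.4826

NORMALIZATION_METHODS = ("standardize", "mad_robustize", "spherize")
AGGREGATION_STATISTICS = ("median", "mean")


# ----------------------------------------------------------------------
# Aggregation


@dataclass
class AggregationSpec:
    """Grouping columns and the per-group statistic for aggregation."""

    strata: list[str]
    statistic: str = "median"

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValidationError("aggregation strata must be non-empty")
        if self.statistic not in AGGREGATION_STATISTICS:
            raise ValidationError(
                f"unknown statistic {self.statistic!r}; choose from {AGGREGATION_STATISTICS}"
            )


def aggregate(
    cells: ProfileTable,
    spec: AggregationSpec,
    count_column: str = "Metadata_Object_Count",
) -> ProfileTable:
    """Collapse observations to one row per distinct strata combination.

    Feature statistics ignore missing values (the statistic is taken over
    the observed cells of each group).  Strata metadata are retained, all
    other metadata are dropped, and a per-group observation count is
    appended as metadata.
    """
    missing = [c for c in spec.strata if c not in cells.metadata_columns]
    if missing:
        raise ValidationError(f"strata not in metadata columns: {missing}")
    if len(cells) == 0:
        raise ValidationError("cannot aggregate an empty table")
    grouped = cells.data.groupby(spec.strata, sort=True, dropna=False, observed=True)
    agg = grouped[cells.feature_columns].agg(spec.statistic)
    counts = grouped.size().rename(count_column)
    out = pd.concat([counts, agg], axis=1).reset_index()
    return ProfileTable(
        out, metadata_columns=list(spec.strata) + [count_column],
        feature_columns=list(cells.feature_columns),
    )


def consensus(
    profiles: ProfileTable,
    strata: Sequence[str],
    statistic: str = "median",
    count_column: str = "Metadata_Replicate_Count",
) -> ProfileTable:
    """Collapse replicate profiles per perturbation (aggregate over
    perturbation-level strata, e.g. compound id + concentration)."""
    return aggregate(
        profiles, AggregationSpec(list(strata), statistic), count_column=count_column
    )


# ----------------------------------------------------------------------
# Annotation


@dataclass
class AnnotationReport:
    n_rows: int
    unmatched: int


def annotate(
    profiles: ProfileTable,
    platemap: PlateMap,
    on: tuple[str | None, str] = ("Metadata_Plate", "Metadata_Well"),
    prefix: str = METADATA_PREFIX,
) -> tuple[ProfileTable, AnnotationReport]:
    """Left-join plate-map annotations onto profiles.

    Every profile row is retained; matched rows gain the plate map's
    annotation columns as new metadata (prefixed to satisfy the metadata
    convention), unmatched rows gain missing annotations and are counted
    in the returned report.
    """
    plate_col, well_col = on
    join_left = [c for c in (plate_col, well_col) if c is not None]
    for c in join_left:
        if c not in profiles.metadata_columns:
            raise SchemaError(f"join column {c!r} not in profile metadata")

    right = platemap.data.copy()
    join_right = []
    if plate_col is not None:
        if platemap.plate_column is None:
            raise SchemaError("plate map has no plate column to join on")
        join_right.append(platemap.plate_column)
    join_right.append(platemap.well_column)

    rename = {}
    for c in platemap.annotation_columns:
        new = c if c.startswith(prefix) else f"{prefix}{c}"
        if new in profiles.data.columns:
            raise SchemaError(
                f"annotation column {c!r} collides with existing column {new!r}"
            )
        rename[c] = new
    right = right.rename(columns=rename)

    indicator = "__pm_merge__"
    merged = profiles.data.merge(
        right,
        how="left",
        left_on=join_left,
        right_on=join_right,
        indicator=indicator,
        suffixes=(None, "__pm__"),
    )
    unmatched = int((merged[indicator] == "left_only").sum())
    drop = [indicator] + [c for c in join_right if c not in profiles.data.columns]
    merged = merged.drop(columns=[c for c in set(drop) if c in merged.columns])
    new_meta = list(profiles.metadata_columns) + list(rename.values())
    # keep metadata first, features after, original order within each block
    merged = merged[new_meta + list(profiles.feature_columns)]
    out = ProfileTable(merged, new_meta, list(profiles.feature_columns))
    return out, AnnotationReport(n_rows=len(out), unmatched=unmatched)


# ----------------------------------------------------------------------
# Normalization

ReferenceSelector = "str | Callable[[pd.DataFrame], pd.Series] | pd.Series | None"


def _reference_mask(profiles: ProfileTable, reference) -> tuple[pd.Series, str]:
    if reference is None:
        return pd.Series(True, index=profiles.data.index), "all rows"
    if isinstance(reference, str):
        mask = profiles.data.eval(reference)
        return mask.astype(bool), reference
    if callable(reference):
        mask = reference(profiles.data)
        return pd.Series(mask, index=profiles.data.index).astype(bool), repr(reference)
    mask = pd.Series(reference, index=profiles.data.index).astype(bool)
    return mask, "boolean mask"


@dataclass
class NormalizationModel:
    """Frozen per-feature normalization parameters or a whitening transform.

    For ``standardize`` and ``mad_robustize`` the model holds per-feature
    ``location`` and ``scale`` vectors (scales floored at ``epsilon``); for
    ``spherize`` it holds a ``center`` vector and a square ``whitening``
    matrix.  ``feature_columns`` records the features the model was fitted
    on, in order; ``reference`` describes the rows used for fitting.
    """

    method: str
    feature_columns: list[str]
    reference: str = "all rows"
    epsilon: float = 1e-18
    regularization: float = 1e-6
    location: np.ndarray | None = None
    scale: np.ndarray | None = None
    center: np.ndarray | None = None
    whitening: np.ndarray | None = None
    n_reference_rows: int = 0

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValidationError(f"unknown normalization method {self.method!r}")
        if self.scale is not None and np.any(np.asarray(self.scale) <= 0):
            raise ValidationError("per-feature scales must be strictly positive")
        if self.whitening is not None:
            w = np.asarray(self.whitening)
            if w.shape != (len(self.feature_columns),) * 2:
                raise ValidationError(
                    "whitening matrix must be square with dimension = n features"
                )

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        doc = {
            "method": self.method,
            "feature_columns": self.feature_columns,
            "reference": self.reference,
            "epsilon": self.epsilon,
            "regularization": self.regularization,
            "location": arr(self.location),
            "scale": arr(self.scale),
            "center": arr(self.center),
            "whitening": arr(self.whitening),
            "n_reference_rows": self.n_reference_rows,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NormalizationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)

        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            method=doc["method"],
            feature_columns=list(doc["feature_columns"]),
            reference=doc["reference"],
            epsilon=doc["epsilon"],
            regularization=doc["regularization"],
            location=arr(doc["location"]),
            scale=arr(doc["scale"]),
            center=arr(doc["center"]),
            whitening=arr(doc["whitening"]),
            n_reference_rows=doc["n_reference_rows"],
        )


def spherize_transform(covariance: np.ndarray, regularization: float) -> np.ndarray:
    """ZCA whitening transform of a covariance matrix.

    Returns ``W = E diag(1/sqrt(lambda + regularization)) E^T`` from the
    eigendecomposition of the (symmetric) covariance.  The regularization
    floors small or zero eigenvalues so rank-deficient covariances still
    yield a finite transform.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValidationError("covariance must be a square matrix")
    scale = max(1.0, float(np.abs(cov).max()))
    if np.abs(cov - cov.T).max() > 1e-8 * scale:
        raise ValidationError("covariance is not symmetric within tolerance")
    if regularization < 0:
        raise ValidationError("regularization must be non-negative")
    eigval, eigvec = np.linalg.eigh((cov + cov.T) / 2.0)
    inv_sqrt = 1.0 / np.sqrt(np.clip(eigval, 0.0, None) + regularization)
    w = (eigvec * inv_sqrt) @ eigvec.T
    return (w + w.T) / 2.0


def fit_normalization(
    profiles: ProfileTable,
    method: str = "mad_robustize",
    reference=None,
    epsilon: float = 1e-18,
    regularization: float = 1e-6,
) -> NormalizationModel:
    """Fit a normalization model on the reference rows of *profiles*.

    Parameters
    ----------
    method
        ``standardize`` (mean / population standard deviation),
        ``mad_robustize`` (median / consistency-scaled median absolute
        deviation), or ``spherize`` (regularized ZCA whitening of the
        reference covariance).
    reference
        Which rows define the reference population: ``None`` (all rows), a
        pandas ``eval`` expression on the table's columns (e.g.
        ``"Metadata_compound == 'DMSO'"``), a callable returning a boolean
        mask, or a boolean mask.  Only these rows contribute statistics.
    epsilon
        Scale floor guaranteeing strictly positive per-feature scales.
    regularization
        Eigenvalue floor for the spherize covariance.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValidationError(f"unknown normalization method {method!r}")
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    mask, description = _reference_mask(profiles, reference)
    ref = profiles.features.loc[mask]
    if len(ref) < 2:
        raise ValidationError(
            f"reference population has {len(ref)} rows; at least 2 required"
        )
    all_missing = [c for c in ref.columns if ref[c].isna().all()]
    if all_missing:
        raise ValidationError(
            f"features entirely missing in the reference: {all_missing}"
        )

    model = NormalizationModel(
        method=method,
        feature_columns=list(profiles.feature_columns),
        reference=description,
        epsilon=epsilon,
        regularization=regularization,
        n_reference_rows=int(len(ref)),
    )
    if method == "standardize":
        model.location = ref.mean(skipna=True).to_numpy(dtype=float)
        model.scale = np.maximum(ref.std(ddof=0, skipna=True).to_numpy(dtype=float), epsilon)
    elif method == "mad_robustize":
        med = ref.median(skipna=True)
        mad = (ref - med).abs().median(skipna=True)
        model.location = med.to_numpy(dtype=float)
        model.scale = np.maximum(
            MAD_CONSISTENCY * mad.to_numpy(dtype=float), epsilon
        )
    else:  # spherize
        complete = ref.dropna(axis=0, how="any")
        if len(complete) < 2:
            raise ValidationError(
                "spherize needs at least 2 complete reference rows"
            )
        x = complete.to_numpy(dtype=float)
        model.center = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        model.whitening = spherize_transform(cov, regularization)
    model.__post_init__()  # re-check invariants now that vectors are filled
    return model


def apply_normalization(
    profiles: ProfileTable, model: NormalizationModel
) -> ProfileTable:
    """Apply a fitted normalization model.

    Location-scale methods map each feature value ``x`` to
    ``(x - location) / scale``; spherize maps each complete row vector
    ``v`` to ``(v - center) @ W``.  Metadata are untouched; missing values
    stay missing (for spherize, a row with any missing feature yields
    missing outputs).  Output feature columns follow the model's fitted
    order; features absent from the model are dropped.
    """
    absent = [c for c in model.feature_columns if c not in profiles.feature_columns]
    if absent:
        raise ValidationError(f"profiles lack model features: {absent}")
    x = profiles.data[model.feature_columns].to_numpy(dtype=float)
    if model.method == "spherize":
        out = (x - model.center) @ model.whitening
    else:
        out = (x - model.location) / model.scale
    meta = profiles.data[profiles.metadata_columns]
    frame = pd.concat(
        [
            meta.reset_index(drop=True),
            pd.DataFrame(out, columns=model.feature_columns),
        ],
        axis=1,
    )
    frame.index = profiles.data.index
    return ProfileTable(
        frame, list(profiles.metadata_columns), list(model.feature_columns)
    )
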