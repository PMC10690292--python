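"""Profile tables, plate maps, and single-cell compartment stores.

The central container is :class:`ProfileTable`, a thin wrapper around a
pandas DataFrame that partitions columns into *metadata* (identifiers and
annotations, by convention prefixed ``Metadata_``) and numeric morphology
*features*.  Every downstream stage (aggregation, normalization, feature
selection, classification) operates on this partition and never touches
metadata numerically.

Single-cell measurements arrive as a relational store in SQLite format with
one image table and one object table per cellular compartment (cells,
cytoplasm, nuclei), mirroring the schema that high-content image analysis
software emits.  :func:`load_single_cells` merges the compartments into one
row per cell using the parent-object links carried by the cytoplasm table.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, SchemaError, ValidationError

METADATA_PREFIX = "Metadata_"

#: tokens read as missing from delimited files (written back as empty fields)
NA_TOKENS = ["", "NA", "NaN", "nan"]

_WELL_RE = re.compile(r"^\s*([A-Za-z]{1,2})\s*0*([0-9]{1,2})\s*$")


def normalize_well(well: str) -> str:
    """Normalize a well identifier to the canonical form (e.g. ``a1`` -> ``A01``).

    Raises :class:`ValidationError` for identifiers that do not look like a
    row letter (one or two characters) followed by a column number.
    """
    m = _WELL_RE.match(str(well))
    if m is None:
        raise ValidationError(f"malformed well identifier: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col == 0:
        raise ValidationError(f"malformed well identifier: {well!r} (column 0)")
    return f"{row}{col:02d}"


def split_columns(
    columns: Sequence[str], metadata_prefix: str = METADATA_PREFIX
) -> tuple[list[str], list[str]]:
    """Partition column names into (metadata, feature) lists by prefix."""
    meta = [c for c in columns if str(c).startswith(metadata_prefix)]
    feat = [c for c in columns if not str(c).startswith(metadata_prefix)]
    return meta, feat


@dataclass
class ProfileTable:
    """A rectangular table of observations with a metadata/feature partition.

    Parameters
    ----------
    data
        The underlying DataFrame.  Column order is preserved through
        read/write round-trips.
    metadata_columns, feature_columns
        Disjoint lists that together cover ``data.columns``.  Feature
        columns must be numeric (missing values permitted).
    """

    data: pd.DataFrame
    metadata_columns: list[str]
    feature_columns: list[str]

    def __post_init__(self) -> None:
        self.metadata_columns = list(self.metadata_columns)
        self.feature_columns = list(self.feature_columns)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        cols = list(self.data.columns)
        meta, feat = set(self.metadata_columns), set(self.feature_columns)
        if meta & feat:
            raise SchemaError(f"columns in both partitions: {sorted(meta & feat)}")
        if meta | feat != set(cols) or len(meta) + len(feat) != len(cols):
            raise SchemaError(
                "metadata and feature columns must disjointly cover the table"
            )
        for c in self.feature_columns:
            if not pd.api.types.is_numeric_dtype(self.data[c]):
                raise SchemaError(f"feature column {c!r} is not numeric")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metadata_prefix: str = METADATA_PREFIX
    ) -> "ProfileTable":
        """Build a table by partitioning columns on *metadata_prefix*.

        Feature columns are coerced to numeric; unparseable cells become
        missing.  Raises :class:`SchemaError` if no feature column remains.
        """
        meta, feat = split_columns(df.columns, metadata_prefix)
        if not feat:
            raise SchemaError(
                f"no feature columns found with metadata prefix {metadata_prefix!r}"
            )
        df = df.copy()
        for c in feat:
            if not pd.api.types.is_numeric_dtype(df[c]):
                df[c] = pd.to_numeric(df[c], errors="coerce")
        return cls(df, meta, feat)

    # ------------------------------------------------------------------
    @property
    def features(self) -> pd.DataFrame:
        """Numeric feature block, in feature-column order."""
        return self.data[self.feature_columns]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.data[self.metadata_columns]

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "ProfileTable":
        return ProfileTable(
            self.data.copy(), list(self.metadata_columns), list(self.feature_columns)
        )

    def subset_features(self, names: Iterable[str]) -> "ProfileTable":
        """Keep only the named features, preserving original column order."""
        keep = set(names)
        missing = keep - set(self.feature_columns)
        if missing:
            raise SchemaError(f"unknown feature columns: {sorted(missing)}")
        feat = [c for c in self.feature_columns if c in keep]
        cols = [c for c in self.data.columns if c in self.metadata_columns or c in keep]
        return ProfileTable(self.data[cols], list(self.metadata_columns), feat)

    def subset_rows(self, index) -> "ProfileTable":
        return ProfileTable(
            self.data.loc[index], list(self.metadata_columns), list(self.feature_columns)
        )

    def equals(self, other: "ProfileTable", rtol: float = 0.0) -> bool:
        """Compare tables; *rtol* > 0 allows float round-trip noise."""
        if (
            self.metadata_columns != other.metadata_columns
            or self.feature_columns != other.feature_columns
            or list(self.data.columns) != list(other.data.columns)
            or len(self) != len(other)
        ):
            return False
        if not self.metadata.reset_index(drop=True).astype(str).equals(
            other.metadata.reset_index(drop=True).astype(str)
        ):
            return False
        a = self.features.to_numpy(dtype=float)
        b = other.features.to_numpy(dtype=float)
        if rtol == 0.0:
            return np.array_equal(a, b, equal_nan=True)
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=0.0, equal_nan=True)
        return bool(np.all(both_nan | close))


# ----------------------------------------------------------------------
# Profile table I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    mapping = {".csv": "csv", ".tsv": "tsv", ".parquet": "parquet", ".pq": "parquet"}
    if suffix not in mapping:
        raise ValidationError(f"cannot infer format from extension {suffix!r}")
    return mapping[suffix]


def read_profiles(
    path: str | Path,
    metadata_prefix: str = METADATA_PREFIX,
    fmt: str | None = None,
) -> ProfileTable:
    """Read a profile table from CSV, TSV, or Parquet.

    Columns are partitioned by *metadata_prefix*; feature columns are
    coerced to numeric with unparseable cells becoming missing.  The
    missing-value tokens for delimited files are ``""``, ``"NA"``,
    ``"NaN"``, and ``"nan"``.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, na_values=NA_TOKENS, keep_default_na=False)
    return ProfileTable.from_dataframe(df, metadata_prefix)


def write_profiles(
    table: ProfileTable, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a profile table; format inferred from the extension.

    CSV/TSV serialize missing values as empty fields; Parquet uses snappy
    compression (recorded in the file metadata) and round-trips exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "parquet":
        table.data.to_parquet(path, engine="pyarrow", compression="snappy", index=False)
    else:
        sep = "," if fmt == "csv" else "\t"
        table.data.to_csv(path, sep=sep, index=False, na_rep="")
    return path


# ----------------------------------------------------------------------
# Plate maps


@dataclass
class PlateMap:
    """Mapping from (plate, well) to perturbation metadata.

    ``data`` holds one row per (plate, well) with normalized well
    identifiers; all other columns are annotations (compound, InChIKey,
    concentration, perturbation type, ...).
    """

    data: pd.DataFrame
    plate_column: str | None = "plate"
    well_column: str = "well"

    def __post_init__(self) -> None:
        if self.well_column not in self.data.columns:
            raise SchemaError(f"plate map lacks well column {self.well_column!r}")
        if self.plate_column is not None and self.plate_column not in self.data.columns:
            raise SchemaError(f"plate map lacks plate column {self.plate_column!r}")
        self.data = self.data.copy()
        self.data[self.well_column] = [
            normalize_well(w) for w in self.data[self.well_column]
        ]
        keys = (
            self.data[[self.plate_column, self.well_column]]
            if self.plate_column is not None
            else self.data[[self.well_column]]
        )
        dup = keys[keys.duplicated(keep=False)]
        if len(dup):
            pairs = sorted(set(map(tuple, dup.to_numpy().tolist())))
            raise ValidationError(f"duplicate plate-map keys: {pairs}")
        if not self.annotation_columns:
            raise SchemaError("plate map has no annotation columns")

    @property
    def annotation_columns(self) -> list[str]:
        keys = {self.well_column}
        if self.plate_column is not None:
            keys.add(self.plate_column)
        return [c for c in self.data.columns if c not in keys]

    def __len__(self) -> int:
        return len(self.data)


def read_platemap(
    path: str | Path,
    plate_column: str | None = "plate",
    well_column: str = "well",
) -> PlateMap:
    """Read a delimited plate map (CSV or TSV by extension).

    Well identifiers are normalized (uppercase row letter, zero-padded
    column); duplicate (plate, well) keys raise :class:`ValidationError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, na_values=NA_TOKENS, keep_default_na=False)
    return PlateMap(df, plate_column=plate_column, well_column=well_column)


def write_platemap(platemap: PlateMap, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    platemap.data.to_csv(path, sep=sep, index=False, na_rep="")
    return path


# ----------------------------------------------------------------------
# Single-cell compartment stores

IMAGE_TABLE = "image"
PARENT_COLUMNS = {"cells": "Parent_Cells", "nuclei": "Parent_Nuclei"}


class CompartmentStore:
    """A single-cell relational store in SQLite format.

    Schema: one ``image`` table keyed by ``ImageNumber`` carrying
    ``Metadata_``-prefixed plate/well metadata, and one table per
    compartment keyed by ``(ImageNumber, ObjectNumber)`` with numeric
    feature columns.  The cytoplasm table additionally carries
    ``Parent_Cells`` and ``Parent_Nuclei`` link columns referencing the
    object numbers of its parent cell and nucleus; multi-compartment
    merges follow these links rather than assuming equal object numbers.
    Image and object numbers are 1-based and never renumbered.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(self.path)

    def table_names(self) -> list[str]:
        with sqlite3.connect(self.path) as con:
            rows = con.execute(
                "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
            ).fetchall()
        return [r[0] for r in rows]

    def read_table(self, name: str) -> pd.DataFrame:
        if name not in self.table_names():
            raise SchemaError(f"store has no table {name!r}")
        with sqlite3.connect(self.path) as con:
            return pd.read_sql_query(f'SELECT * FROM "{name}"', con)

    @staticmethod
    def write(
        path: str | Path, image: pd.DataFrame, compartments: Mapping[str, pd.DataFrame]
    ) -> "CompartmentStore":
        """Create a store from an image table and compartment object tables."""
        path = Path(path)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            image.to_sql(IMAGE_TABLE, con, index=False)
            for name, df in compartments.items():
                df.to_sql(name, con, index=False)
        return CompartmentStore(path)


@dataclass
class MergeReport:
    """Bookkeeping from a compartment merge: rows kept and orphans excluded."""

    n_cells: int
    orphans: dict[str, int] = field(default_factory=dict)

    @property
    def total_orphans(self) -> int:
        return sum(self.orphans.values())


def load_single_cells(
    store: CompartmentStore,
    compartments: Sequence[str] = ("cells", "cytoplasm", "nuclei"),
    image_table: str = IMAGE_TABLE,
) -> tuple[ProfileTable, MergeReport]:
    """Merge compartment object tables into one row per cell.

    The cytoplasm table's parent links drive the merge, so requesting more
    than one compartment requires cytoplasm among them.  Feature columns
    are prefixed with the capitalized compartment name; image-level
    metadata is attached to every cell.  Objects present in only some
    compartments are excluded and counted per compartment in the report.
    """
    compartments = [c.lower() for c in compartments]
    available = store.table_names()
    missing = [c for c in compartments if c not in available]
    if missing:
        raise SchemaError(f"store lacks compartment tables: {missing}")
    image = store.read_table(image_table)
    if "ImageNumber" not in image.columns:
        raise SchemaError("image table lacks ImageNumber")

    def featurize(df: pd.DataFrame, comp: str, drop: Sequence[str]) -> pd.DataFrame:
        feats = [c for c in df.columns if c not in drop]
        return df.rename(columns={c: f"{comp.capitalize()}_{c}" for c in feats})

    tables = {c: store.read_table(c) for c in compartments}
    for name, df in tables.items():
        for key in ("ImageNumber", "ObjectNumber"):
            if key not in df.columns:
                raise SchemaError(f"compartment {name!r} lacks {key}")
        bad = df["ObjectNumber"].to_numpy()
        if (bad < 1).any():
            raise SchemaError(f"compartment {name!r} has non-positive object numbers")
        orphan_images = set(df["ImageNumber"]) - set(image["ImageNumber"])
        if orphan_images:
            raise SchemaError(
                f"compartment {name!r} references unknown images: {sorted(orphan_images)[:5]}"
            )

    report = MergeReport(n_cells=0)
    if len(compartments) == 1:
        comp = compartments[0]
        df = tables[comp].copy()
        df = df.rename(columns={"ObjectNumber": f"Metadata_{comp.capitalize()}_ObjectNumber"})
        keys = ["ImageNumber", f"Metadata_{comp.capitalize()}_ObjectNumber"]
        merged = featurize(df, comp, keys)
    else:
        if "cytoplasm" not in compartments:
            raise SchemaError(
                "merging multiple compartments requires 'cytoplasm' (it carries the parent links)"
            )
        cyto = tables["cytoplasm"].copy()
        keys = ["ImageNumber", "ObjectNumber"]
        merged = cyto.rename(
            columns={"ObjectNumber": "Metadata_Cytoplasm_ObjectNumber"}
        )
        link_cols = []
        for comp in compartments:
            if comp == "cytoplasm":
                continue
            parent = PARENT_COLUMNS.get(comp)
            if parent is None or parent not in cyto.columns:
                raise SchemaError(
                    f"cytoplasm table lacks parent link for compartment {comp!r}"
                )
            obj = tables[comp].rename(
                columns={"ObjectNumber": f"Metadata_{comp.capitalize()}_ObjectNumber"}
            )
            obj = featurize(obj, comp, ["ImageNumber", f"Metadata_{comp.capitalize()}_ObjectNumber"])
            before = len(merged)
            merged = merged.merge(
                obj,
                how="inner",
                left_on=["ImageNumber", parent],
                right_on=["ImageNumber", f"Metadata_{comp.capitalize()}_ObjectNumber"],
            )
            # objects of this compartment never matched by a cytoplasm parent
            matched = set(
                map(tuple, merged[["ImageNumber", f"Metadata_{comp.capitalize()}_ObjectNumber"]].to_numpy())
            )
            allobj = set(
                map(tuple, obj[["ImageNumber", f"Metadata_{comp.capitalize()}_ObjectNumber"]].to_numpy())
            )
            report.orphans[comp] = len(allobj - matched)
            link_cols.append(parent)
        report.orphans["cytoplasm"] = len(cyto) - len(merged)
        merged = merged.drop(columns=link_cols)
        merged = merged.rename(
            columns={
                c: f"Cytoplasm_{c}"
                for c in merged.columns
                if not c.startswith(("Metadata_", "ImageNumber"))
                and not any(c.startswith(p.capitalize() + "_") for p in compartments)
            }
        )

    merged = merged.merge(image, how="inner", on="ImageNumber")
    merged = merged.rename(columns={"ImageNumber": "Metadata_ImageNumber"})
    if merged.empty:
        raise EmptyResultError("compartment merge produced zero cells")
    # stable order: metadata first
    meta, feat = split_columns(merged.columns)
    merged = merged[meta + feat]
    table = ProfileTable.from_dataframe(merged)
    report.n_cells = len(table)
    return table, report
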