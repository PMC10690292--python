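"""Feature selection: drop uninformative or redundant morphology features.

Four rules are available, applied in a configurable order with
first-rule-wins attribution in the report:

* ``variance_threshold`` — near-zero-variance filter.  For each feature,
  compute the count ratio r = (2nd most frequent value) / (most frequent
  value) over non-missing entries and the distinct-value fraction
  u = n_distinct / n_non_missing; the feature is dropped when
  r <= freq_cut or u <= unique_cut.
* ``drop_na_columns`` — drop a feature when its missing fraction strictly
  exceeds na_cutoff (a feature at exactly the cutoff is kept).
* ``correlation_threshold`` — greedily break up feature pairs whose
  absolute Pearson correlation reaches the threshold, dropping the member
  with the larger mean absolute correlation to all remaining features.
* ``blocklist`` — drop features whose names match shell-style patterns
  (known-unreliable feature families).
"""

from __future__ import annotations

import fnmatch
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ProfileTable

OPERATIONS = ("variance_threshold", "drop_na_columns", "correlation_threshold", "blocklist")

#: execution order used when none is given: cheap filters first
DEFAULT_OPERATIONS = (
    "variance_threshold",
    "drop_na_columns",
    "correlation_threshold",
    "blocklist",
)


@dataclass
class FeatureSelectionConfig:
    """Ordered feature-selection operations and their thresholds.

    Defaults follow common profiling practice: count-ratio cutoff
    ``freq_cut=0.05`` (drop at or below), distinct-fraction cutoff
    ``unique_cut=0.01``, missingness cutoff ``na_cutoff=0.05`` (drop
    strictly above), and absolute-correlation bound ``corr_threshold=0.9``.
    """

    operations: tuple[str, ...] = DEFAULT_OPERATIONS
    freq_cut: float = 0.05
    unique_cut: float = 0.01
    na_cutoff: float = 0.05
    corr_threshold: float = 0.9
    blocklist: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.operations = tuple(self.operations)
        if not self.operations:
            raise ValidationError("operations list must be non-empty")
        unknown = [op for op in self.operations if op not in OPERATIONS]
        if unknown:
            raise ValidationError(f"unknown operations: {unknown}")
        for name in ("freq_cut", "unique_cut", "na_cutoff", "corr_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        self.blocklist = tuple(self.blocklist)


@dataclass
class SelectionFragment:
    """Dropped features from one rule, with the statistic that fired."""

    rule: str
    dropped: dict[str, float | str] = field(default_factory=dict)


@dataclass
class FeatureSelectionReport:
    """Per-feature disposition after running a selection config.

    Every input feature appears exactly once: either kept, or dropped with
    the single (first) rule and statistic responsible.
    """

    input_features: list[str]
    fragments: list[SelectionFragment]

    @property
    def dropped(self) -> dict[str, tuple[str, float | str]]:
        out: dict[str, tuple[str, float | str]] = {}
        for frag in self.fragments:
            for feat, stat in frag.dropped.items():
                out.setdefault(feat, (frag.rule, stat))
        return out

    @property
    def kept(self) -> list[str]:
        dropped = self.dropped
        return [f for f in self.input_features if f not in dropped]

    @property
    def counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for feat, (rule, _) in self.dropped.items():
            counts[rule] = counts.get(rule, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        dropped = self.dropped
        rows = []
        for feat in self.input_features:
            if feat in dropped:
                rule, stat = dropped[feat]
                rows.append((feat, "dropped", rule, stat))
            else:
                rows.append((feat, "kept", "", np.nan))
        return pd.DataFrame(rows, columns=["feature", "status", "rule", "statistic"])

    def to_csv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, index=False)
        return Path(path)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kept": self.kept,
            "dropped": {f: {"rule": r, "statistic": s} for f, (r, s) in self.dropped.items()},
            "counts": self.counts,
        }
        text = json.dumps(doc, indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


# ----------------------------------------------------------------------
# Individual rules


def variance_threshold(
    table: ProfileTable, freq_cut: float = 0.05, unique_cut: float = 0.01
) -> SelectionFragment:
    """Near-zero-variance filter on count ratio and distinct fraction."""
    if len(table) < 2:
        raise ValidationError("variance_threshold needs at least 2 rows")
    frag = SelectionFragment("variance_threshold")
    for feat in table.feature_columns:
        col = table.data[feat].dropna()
        if len(col) == 0:
            frag.dropped[feat] = 0.0
            continue
        counts = col.value_counts()
        ratio = 0.0 if len(counts) < 2 else counts.iloc[1] / counts.iloc[0]
        unique_frac = len(counts) / len(col)
        if ratio <= freq_cut:
            frag.dropped[feat] = float(ratio)
        elif unique_frac <= unique_cut:
            frag.dropped[feat] = float(unique_frac)
    return frag


def drop_na_columns(table: ProfileTable, na_cutoff: float = 0.05) -> SelectionFragment:
    """Drop features whose missing fraction strictly exceeds *na_cutoff*."""
    frag = SelectionFragment("drop_na_columns")
    n = len(table)
    if n == 0:
        return frag
    for feat in table.feature_columns:
        frac = float(table.data[feat].isna().sum()) / n
        if frac > na_cutoff:
            frag.dropped[feat] = frac
    return frag


def correlation_threshold(
    table: ProfileTable, corr_threshold: float = 0.9, min_periods: int = 3
) -> SelectionFragment:
    """Greedy decorrelation of the feature set.

    Pairwise Pearson correlations use pairwise-complete observations; a
    pair with fewer than *min_periods* complete observations, or involving
    a zero-variance feature, is treated as uncorrelated.  While any pair
    reaches the threshold, the pair with the largest absolute correlation
    is found and the member with the larger mean absolute correlation to
    all remaining features is dropped (ties drop the later column in
    original order).
    """
    if len(table) < min_periods:
        raise ValidationError(
            f"correlation_threshold needs at least {min_periods} rows"
        )
    frag = SelectionFragment("correlation_threshold")
    feats = list(table.feature_columns)
    if len(feats) < 2:
        return frag
    corr = table.features.corr(method="pearson", min_periods=min_periods)
    cmat = corr.abs().to_numpy()
    cmat[np.isnan(cmat)] = 0.0  # zero variance or too few complete pairs
    np.fill_diagonal(cmat, 0.0)

    order = {f: i for i, f in enumerate(feats)}
    alive = list(range(len(feats)))
    while len(alive) > 1:
        sub = cmat[np.ix_(alive, alive)]
        peak = sub.max()
        if peak < corr_threshold:
            break
        i_s, j_s = np.unravel_index(int(np.argmax(sub)), sub.shape)
        i, j = alive[min(i_s, j_s)], alive[max(i_s, j_s)]
        mean_i = cmat[i, alive].sum() / (len(alive) - 1)
        mean_j = cmat[j, alive].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:  # tie: drop the later column in original order
            victim = max(i, j, key=lambda k: order[feats[k]])
        frag.dropped[feats[victim]] = float(peak)
        alive.remove(victim)
    return frag


def blocklist_filter(
    table: ProfileTable, patterns: Sequence[str]
) -> SelectionFragment:
    """Drop features whose names match any shell-style pattern."""
    frag = SelectionFragment("blocklist")
    compiled = []
    for pat in patterns:
        if not isinstance(pat, str):
            raise ValidationError(f"blocklist pattern must be a string: {pat!r}")
        try:
            compiled.append((pat, re.compile(fnmatch.translate(pat))))
        except re.error as exc:  # pragma: no cover - fnmatch rarely fails
            raise ValidationError(f"invalid blocklist pattern {pat!r}: {exc}") from exc
    for feat in table.feature_columns:
        for pat, rx in compiled:
            if rx.match(feat):
                frag.dropped[feat] = pat
                break
    return frag


# ----------------------------------------------------------------------
# Driver


def feature_select(
    table: ProfileTable, config: FeatureSelectionConfig
) -> tuple[ProfileTable, FeatureSelectionReport]:
    """Apply the configured operations in order, each on the survivors of
    the previous, and return the filtered table plus an auditable report.

    The returned table keeps the original column order among survivors;
    each dropped feature is attributed to the first rule that fired.
    """
    current = table
    fragments: list[SelectionFragment] = []
    for op in config.operations:
        if op == "variance_threshold":
            frag = variance_threshold(current, config.freq_cut, config.unique_cut)
        elif op == "drop_na_columns":
            frag = drop_na_columns(current, config.na_cutoff)
        elif op == "correlation_threshold":
            frag = correlation_threshold(current, config.corr_threshold)
        else:
            frag = blocklist_filter(current, config.blocklist)
        fragments.append(frag)
        if frag.dropped:
            survivors = [f for f in current.feature_columns if f not in frag.dropped]
            if not survivors:
                raise ValidationError(
                    f"operation {op!r} dropped every remaining feature"
                )
            current = current.subset_features(survivors)
    report = FeatureSelectionReport(list(table.feature_columns), fragments)
    return current, report
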