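"""In-memory containers shared across the pipeline.

The central objects are :class:`ExpressionMatrix` (a validated gene-by-sample
table of non-negative normalized expression values), :class:`GeneSetCollection`
(named sets of gene symbols, the in-memory form of a GMT file) and
:class:`CorrelationTable` (one target gene's Pearson r against every other
gene, ranked). Annotations and sample metadata travel as plain pandas
DataFrames with fixed column names, validated by the readers in
:mod:`coexmap.io`.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, MissingFeatureError

#: Required columns of a gene annotation table.
ANNOTATION_COLUMNS = ("gene", "chromosome", "cytoband", "tss_bp")

#: Required leading columns of a sample metadata table.
METADATA_COLUMNS = ("sample_id", "participant_tag", "condition")

#: Allowed values of the metadata ``condition`` column.
CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative, finite expression values.

    Rows are features (gene symbols), columns are sample identifiers.
    Values are normalized expression on an RSEM-like linear scale
    (dimensionless). Identifiers must be unique on both axes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def vector(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across all samples."""
        if feature_id not in self.data.index:
            raise MissingFeatureError(f"feature {feature_id!r} not in matrix")
        return self.data.loc[feature_id].to_numpy(dtype=float)

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise MissingFeatureError(f"features not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[feature_ids])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise MissingFeatureError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[sample_ids])


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (one GMT line)."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection(Mapping):
    """Ordered mapping set_id -> :class:`GeneSet`."""

    def __init__(self, sets: list[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self._sets:
                raise FormatError(f"duplicate set id: {s.set_id!r}")
            self._sets[s.set_id] = s

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass
class CorrelationTable:
    """Pearson correlations of one target gene against every other gene.

    ``frame`` has columns ``feature``, ``r``, ``p``, ``n`` (and ``rank``
    once an order is applied). The target itself is never a row: its r
    would be identically 1 and downstream enrichment statistics require
    its removal.
    """

    target_id: str
    frame: pd.DataFrame
    order: str = "unsorted"  # by_r_desc | by_abs_r_desc | unsorted

    def __post_init__(self) -> None:
        if (self.frame["feature"] == self.target_id).any():
            raise FormatError("target gene must not appear among table rows")
        r = self.frame["r"].to_numpy()
        if (np.abs(r) > 1 + 1e-12).any():
            raise FormatError("|r| > 1 in correlation table")

    @property
    def features(self) -> list[str]:
        return list(self.frame["feature"])

    @property
    def n_rows(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene location/spread summary: mean, sample sd, and cv = sd/mean.

    ``cv`` is NaN (and ``cv_defined`` False) when the mean is zero.
    """

    feature_id: str
    mean: float
    sd: float
    cv: float = field(default=float("nan"))

    @property
    def cv_defined(self) -> bool:
        return not np.isnan(self.cv)
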