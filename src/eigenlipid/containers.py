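"""Core in-memory containers shared across the pipeline.

The central object is :class:`FeatureTable`, a lipid × sample intensity
matrix carried as a :class:`pandas.DataFrame` together with a view tag
(``raw``, ``relative`` or ``clr``), the lipid annotation table and the
sample metadata table. Views are produced by :mod:`eigenlipid.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


class EigenlipidError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(EigenlipidError):
    """Invalid configuration."""


class AlignmentError(EigenlipidError):
    """Tables that must share ids do not."""


class DegenerateDataError(EigenlipidError):
    """Input data violates a numerical precondition (all-zero sample, ...)."""


class AnnotationError(EigenlipidError):
    """A lipid name or annotation could not be interpreted."""


VALID_VIEWS = ("raw", "relative", "clr")


@dataclass
class FeatureTable:
    """Lipid × sample intensity matrix with linked metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id, columns are sample ids.
    view:
        One of ``raw`` (arbitrary units ≥ 0), ``relative`` (per-sample
        fractions of total annotated intensity) or ``clr`` (centered
        log-ratio values, per-sample sum 0).
    annotations:
        Optional DataFrame indexed by feature id with at least a ``name``
        column (lipid shorthand) and optionally ``annotation_tier`` and
        ``chains``.
    metadata:
        Optional DataFrame indexed by sample id (station, depth, province,
        temperature, po4, fluorescence, mixed_layer_depth, region, ...).
    """

    data: pd.DataFrame
    view: str = "raw"
    annotations: Optional[pd.DataFrame] = None
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.view not in VALID_VIEWS:
            raise ConfigurationError(f"unknown view {self.view!r}; expected one of {VALID_VIEWS}")
        if self.view in ("raw", "relative") and (self.data.values < 0).any():
            raise DegenerateDataError(f"{self.view} view must be non-negative")
        if self.annotations is not None:
            missing = self.data.index.difference(self.annotations.index)
            if len(missing):
                raise AlignmentError(f"{len(missing)} features lack annotations (e.g. {list(missing[:3])})")
        if self.metadata is not None:
            missing = self.data.columns.difference(self.metadata.index)
            if len(missing):
                raise AlignmentError(f"{len(missing)} samples lack metadata (e.g. {list(missing[:3])})")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, view: Optional[str] = None) -> "FeatureTable":
        """Return a copy carrying new values (and optionally a new view tag)."""
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[self.annotations.index.intersection(data.index)]
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[self.metadata.index.intersection(data.columns)]
        return FeatureTable(data=data, view=view or self.view, annotations=ann, metadata=meta)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = [s for s in sample_ids if s in self.data.columns]
        return self.with_data(self.data.loc[:, sample_ids])

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = [f for f in feature_ids if f in self.data.index]
        return self.with_data(self.data.loc[feature_ids])
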