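"""Blank filtering and compositional transformation of the feature table.

Mass-spectrometry feature tables carry contaminant signals that are also
present in procedural blanks, and their intensities are compositional
(closed) once normalized. The pipeline therefore (1) removes features whose
sample median intensity is less than ``fold``-times (default 20×) their
blank median, (2) normalizes each sample to the total intensity of all
annotated lipids, and (3) applies a centered log-ratio (CLR) transform so
downstream correlation analysis is free of closure artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AlignmentError, DegenerateDataError, FeatureTable


def blank_subtract(
    features: FeatureTable,
    blanks: pd.DataFrame,
    fold: float = 20.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove features that are not sufficiently above blank levels.

    A feature is retained iff median(sample intensities) ≥ ``fold`` ×
    median(blank intensities). The boundary belongs to the kept side
    (features *less than* ``fold``-fold above blanks are excluded), and a
    zero blank median always retains the feature. Returns the filtered
    table and a removal report with one row per shared feature.
    """
    if features.view != "raw":
        raise DegenerateDataError("blank_subtract expects the raw view")
    if fold <= 0:
        raise ValueError("fold must be positive")
    shared = features.data.index.intersection(blanks.index)
    if len(shared) == 0:
        raise AlignmentError("feature table and blank table share no feature ids")
    sample_median = features.data.loc[shared].median(axis=1)
    blank_median = blanks.loc[shared].median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample_median / blank_median
    kept = (blank_median == 0) | (sample_median >= fold * blank_median)
    report = pd.DataFrame(
        {
            "sample_median": sample_median,
            "blank_median": blank_median,
            "fold": ratio.replace([np.inf], np.nan),
            "kept": kept,
        }
    )
    report.index.name = "feature_id"
    filtered = features.subset_features(list(shared[kept]))
    return filtered, report


def normalize_total(features: FeatureTable) -> FeatureTable:
    """Normalize each sample to the total intensity of all annotated lipids."""
    if features.view != "raw":
        raise DegenerateDataError("normalize_total expects the raw view")
    totals = features.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateDataError(f"samples with zero total intensity: {list(zero.index[:5])}")
    return features.with_data(features.data.div(totals, axis=1), view="relative")


def clr_transform(features: FeatureTable) -> FeatureTable:
    """Centered log-ratio transform of the relative view.

    Zeros are replaced multiplicatively per sample with δ = half the
    smallest nonzero relative intensity of that sample (standard
    compositional practice), after which clr_i = ln(x_i / g(x)) with g the
    per-sample geometric mean. Each CLR column sums to 0.
    """
    if features.view != "relative":
        raise DegenerateDataError("clr_transform expects the relative view")
    values = features.data.to_numpy(dtype=float).copy()
    if (values < 0).any():
        raise DegenerateDataError("negative relative intensities")
    for j in range(values.shape[1]):
        col = values[:, j]
        zeros = col == 0
        if zeros.any():
            nonzero = col[~zeros]
            if nonzero.size == 0:
                raise DegenerateDataError(f"sample {features.data.columns[j]!r} is all zero")
            delta = nonzero.min() / 2.0
            # multiplicative replacement preserves the unit sum
            col = np.where(zeros, delta, col * (1 - delta * zeros.sum()))
            values[:, j] = col
    log_values = np.log(values)
    clr = log_values - log_values.mean(axis=0, keepdims=True)
    return features.with_data(
        pd.DataFrame(clr, index=features.data.index, columns=features.data.columns),
        view="clr",
    )


def preprocess(
    features: FeatureTable,
    blanks: pd.DataFrame | None = None,
    fold: float = 20.0,
) -> tuple[FeatureTable, pd.DataFrame | None]:
    """Blank filter (optional) → total normalization → CLR; returns (clr, report)."""
    report = None
    if blanks is not None:
        features, report = blank_subtract(features, blanks, fold=fold)
    rel = normalize_total(features)
    return clr_transform(rel), report
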