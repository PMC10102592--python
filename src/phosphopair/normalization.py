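"""Per-sample global normalization of label-free intensities.

Label-free peak areas carry per-sample multiplicative biases (loading,
ionisation efficiency, gradient drift).  Working in log2 space these become
additive offsets; median-centering each sample to the grand median of the
pre-normalization sample medians removes them without touching within-sample
ranks and is robust to intensity-dependent missingness.  A total-intensity
variant is available behind the ``method`` switch.  Medians/sums use each
sample's present values only; missing cells never enter the computation and
are left missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import IntensityMatrix


@dataclass(frozen=True)
class NormalizationReport:
    """Per-sample log2 offsets applied and the number of features they
    were estimated from."""

    offsets: pd.DataFrame  # columns: sample_id, offset_log2, n_features_used


def to_log2(X: IntensityMatrix) -> IntensityMatrix:
    """Linear -> log2; missing cells stay missing.

    Zeros must already have been converted to missing by the reader; a
    present value <= 0 is an upstream error, not data.
    """
    if X.scale != "linear":
        raise ValueError("to_log2 expects a linear-scale matrix")
    values = X.data.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if (values[present] <= 0).any():
        raise ValueError("present value <= 0; zeros must be marked missing before log2")
    return IntensityMatrix(pd.DataFrame(
        np.log2(values, where=present, out=np.full_like(values, np.nan)),
        index=X.data.index, columns=X.data.columns), "log2")


def to_linear(X: IntensityMatrix) -> IntensityMatrix:
    if X.scale != "log2":
        raise ValueError("to_linear expects a log2-scale matrix")
    return IntensityMatrix(2.0 ** X.data, "linear")


def _sample_stat(col: pd.Series, method: str) -> float:
    present = col.dropna()
    if method == "median":
        return float(present.median())
    # total: log2 of the summed linear intensity
    return float(np.log2(np.sum(2.0 ** present.to_numpy())))


def global_normalize(
    X: IntensityMatrix, method: str = "median"
) -> tuple[IntensityMatrix, NormalizationReport]:
    """Align samples in log2 space to the grand median of per-sample stats.

    After normalization every sample's statistic (median of present log2
    values by default) equals the grand median of the pre-normalization
    statistics, which makes the operation idempotent.
    """
    if X.scale != "log2":
        raise ValueError("global_normalize expects a log2-scale matrix")
    if method not in ("median", "total"):
        raise ValueError(f"unknown normalization method {method!r}")
    if X.data.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    n_present = X.data.notna().sum(axis=0)
    empty = n_present[n_present == 0]
    if len(empty):
        raise ValueError(f"sample {empty.index[0]!r} has no present values")

    stats = pd.Series({sid: _sample_stat(X.data[sid], method) for sid in X.sample_ids})
    target = float(stats.median())
    offsets = target - stats
    normalized = X.data.add(offsets, axis=1)
    report = NormalizationReport(pd.DataFrame(
        {
            "sample_id": X.sample_ids,
            "offset_log2": offsets.loc[X.sample_ids].to_numpy(),
            "n_features_used": n_present.loc[X.sample_ids].to_numpy(),
        }
    ))
    return IntensityMatrix(normalized, "log2"), report
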