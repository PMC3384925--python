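"""Semiquantitative normalization and autoscaling of peak tables.

Raw peak areas are converted to semiquantitative concentrations as the
ratio of each metabolite's peak area to the internal-standard area of the
same sample, then standardized column-wise to zero mean and unit variance
(autoscaling). The scaler retains training-column statistics so held-out
samples can be transformed without information leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaktable import PeakTable


@dataclass
class ConcentrationMatrix:
    """Area ratios (sample x metabolite), dimensionless and strictly positive."""

    values: np.ndarray
    labels: np.ndarray
    metabolite_names: list[str]
    sample_ids: list[str] = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.metabolite_names)
        df.insert(0, "label", self.labels)
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df


def normalize_internal_standard(table: PeakTable) -> ConcentrationMatrix:
    """Divide every peak area by the sample's internal-standard area.

    The PeakTable contract already rejects non-positive internal-standard
    areas, naming the offending sample.
    """
    table.validate()
    values = table.areas / table.is_area[:, None]
    return ConcentrationMatrix(
        values=values,
        labels=table.labels,
        metabolite_names=list(table.metabolite_names),
        sample_ids=list(table.sample_ids),
    )


class AutoScaler:
    """Column-wise (x - mean) / sd transform with stored training statistics.

    Uses the sample SD (n-1 denominator). ``fit`` must see the training rows
    only; ``transform`` then applies the stored statistics to any matrix with
    the same columns, including held-out samples.
    """

    def __init__(self) -> None:
        self.column_means: np.ndarray | None = None
        self.column_sds: np.ndarray | None = None
        self._names: list[str] | None = None

    def fit(self, X: np.ndarray, names: list[str] | None = None) -> "AutoScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        self.column_means = X.mean(axis=0)
        self.column_sds = X.std(axis=0, ddof=1)
        self._names = list(names) if names is not None else None
        zero = np.flatnonzero(self.column_sds == 0)
        if zero.size:
            which = (
                [self._names[j] for j in zero] if self._names else list(map(int, zero))
            )
            raise ValueError(f"constant column(s), autoscaling undefined: {which}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.column_means is None:
            raise RuntimeError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.column_means.size:
            raise ValueError("column count does not match fitted statistics")
        return (X - self.column_means) / self.column_sds

    def fit_transform(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        return self.fit(X, names).transform(X)


@dataclass
class ScaledMatrix:
    """Autoscaled intensities with the training column statistics retained."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    labels: np.ndarray
    metabolite_names: list[str]
    sample_ids: list[str] = field(default=None)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Scale new samples with the stored training statistics."""
        return (np.asarray(X_new, dtype=float) - self.column_means) / self.column_sds

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.metabolite_names)
        df.insert(0, "label", self.labels)
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df


def autoscale(conc: ConcentrationMatrix) -> ScaledMatrix:
    """Standardize each metabolite to zero mean and unit variance."""
    scaler = AutoScaler().fit(conc.values, conc.metabolite_names)
    return ScaledMatrix(
        values=scaler.transform(conc.values),
        column_means=scaler.column_means,
        column_sds=scaler.column_sds,
        labels=conc.labels,
        metabolite_names=list(conc.metabolite_names),
        sample_ids=conc.sample_ids,
    )
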