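"""Container and TSV I/O for GC/MS peak tables.

A peak table holds raw integrated ion peak areas for a panel of metabolites
(samples in rows), the per-sample internal-standard peak area, and a binary
group label per sample. Areas are in arbitrary instrument units and must be
strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IS_COLUMN = "is_area"
LABEL_COLUMN = "label"
ID_COLUMN = "sample_id"


@dataclass
class PeakTable:
    """Raw peak areas plus internal standard and group labels.

    Attributes
    ----------
    sample_ids : list of str
        One identifier per sample.
    labels : ndarray
        Binary group label per sample (exactly two distinct values).
    metabolite_names : list of str
        Column names for the metabolite panel.
    areas : ndarray, shape (n_samples, n_metabolites)
        Raw integrated peak areas, strictly positive.
    is_area : ndarray, shape (n_samples,)
        Internal-standard peak area per sample, strictly positive.
    """

    sample_ids: list[str]
    labels: np.ndarray
    metabolite_names: list[str]
    areas: np.ndarray
    is_area: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.areas = np.asarray(self.areas, dtype=float)
        self.is_area = np.asarray(self.is_area, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, p = self.areas.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length does not match areas")
        if len(self.metabolite_names) != p:
            raise ValueError("metabolite_names length does not match areas")
        if self.is_area.shape != (n,):
            raise ValueError("is_area must have one entry per sample")
        if not np.all(np.isfinite(self.areas)) or not np.all(np.isfinite(self.is_area)):
            raise ValueError("peak table contains missing or non-finite values")
        if np.any(self.areas <= 0):
            raise ValueError("all peak areas must be strictly positive")
        if np.any(self.is_area <= 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(self.is_area <= 0)]
            raise ValueError(f"non-positive internal-standard area for samples: {bad}")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("labels must take exactly two values")

    @property
    def n_samples(self) -> int:
        return self.areas.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.areas.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.areas, columns=self.metabolite_names)
        df.insert(0, LABEL_COLUMN, self.labels)
        df.insert(0, ID_COLUMN, self.sample_ids)
        df[IS_COLUMN] = self.is_area
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakTable":
        for col in (ID_COLUMN, LABEL_COLUMN, IS_COLUMN):
            if col not in df.columns:
                raise ValueError(f"peak table is missing required column {col!r}")
        names = [c for c in df.columns if c not in (ID_COLUMN, LABEL_COLUMN, IS_COLUMN)]
        return cls(
            sample_ids=[str(s) for s in df[ID_COLUMN]],
            labels=df[LABEL_COLUMN].to_numpy(),
            metabolite_names=names,
            areas=df[names].to_numpy(dtype=float),
            is_area=df[IS_COLUMN].to_numpy(dtype=float),
        )


def write_peak_table(table: PeakTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> PeakTable:
    return PeakTable.from_frame(pd.read_csv(path, sep="\t"))
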