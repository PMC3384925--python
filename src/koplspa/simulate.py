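"""Synthetic two-group urinary-carbohydrate cohorts.

Generates peak tables with the statistical structure the downstream
analysis assumes: log-normal raw areas, a spiked internal-standard channel
independent of class, and planted group effects that are either a log-scale
mean shift or a radially separable (hence linearly inseparable) structure.
A companion generator produces clinical covariate tables from per-variable
group summaries.

Raw areas are modelled log-normal because integrated GC/MS peak areas are
positive and right-skewed; planted effects act on the log scale so that
positivity is preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaktable import PeakTable

#: Carbohydrate panel measured in urine; index order is the variable-index
#: convention used throughout (1-based in design specifications).
DEFAULT_METABOLITES = (
    "C4_sugar_1",
    "inositol_C",
    "talose",
    "mannose",
    "inositol_D",
    "glucose",
    "inositol_A",
    "arabinose",
    "xylose",
    "C4_sugar_2",
)

#: Width (SD) of the radial shell around the target radius, in standardized
#: coordinate units. Kept small so the two groups stay radially separated.
RADIAL_SHELL_SD = 0.15


@dataclass
class SyntheticDesign:
    """Parameters of a synthetic two-group cohort.

    ``informative_indices`` are 1-based metabolite indices (the variable-index
    convention of the panel). ``effect_size`` is a standardized log-scale mean
    difference for ``mean_shift``, or the shell radius (in standardized
    coordinates) separating group 2 from group 1 for ``radial_nonlinear``.
    ``area_scale`` is the log-scale location of raw areas, ``noise_sd`` the
    log-scale SD; ``is_mean``/``is_cv`` give the internal standard's mean area
    and coefficient of variation.
    """

    n_group1: int = 308
    n_group2: int = 58
    n_metabolites: int = 10
    informative_indices: tuple[int, ...] = (1, 2, 4, 5, 6, 10)
    effect_type: str = "mean_shift"
    effect_size: float = 2.0
    area_scale: float = 13.0
    noise_sd: float = 0.4
    is_mean: float = 4.0e5
    is_cv: float = 0.1
    seed: int = 0
    metabolite_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        idx = tuple(sorted(set(int(i) for i in self.informative_indices)))
        if idx and (idx[0] < 1 or idx[-1] > self.n_metabolites):
            raise ValueError(
                f"informative_indices must lie in 1..{self.n_metabolites}, got {idx}"
            )
        self.informative_indices = idx
        if self.effect_type not in ("mean_shift", "radial_nonlinear"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.is_mean <= 0:
            raise ValueError("is_mean must be positive")
        if self.noise_sd <= 0 or self.is_cv < 0:
            raise ValueError("noise_sd must be > 0 and is_cv >= 0")
        if self.metabolite_names is None:
            if self.n_metabolites == len(DEFAULT_METABOLITES):
                self.metabolite_names = DEFAULT_METABOLITES
            else:
                self.metabolite_names = tuple(
                    f"M{j + 1:02d}" for j in range(self.n_metabolites)
                )
        elif len(self.metabolite_names) != self.n_metabolites:
            raise ValueError("metabolite_names length mismatch")


def _standardized_effects(design: SyntheticDesign, rng: np.random.Generator) -> np.ndarray:
    """Standardized (unit-SD) log-scale coordinates with the planted effect.

    Returns an (n, p) matrix z; raw log areas are area_scale + noise_sd * z.
    """
    n1, n2 = design.n_group1, design.n_group2
    n, p = n1 + n2, design.n_metabolites
    z = rng.standard_normal((n, p))
    info = [i - 1 for i in design.informative_indices]
    if not info or design.effect_size == 0:
        return z
    if design.effect_type == "mean_shift":
        # symmetric shift: group 1 up, group 2 down, total gap = effect_size
        z[:n1, info] += design.effect_size / 2.0
        z[n1:, info] -= design.effect_size / 2.0
    else:  # radial_nonlinear
        d = len(info)
        # group 1 keeps its isotropic normal core; group 2 is re-drawn on a
        # thin shell of radius effect_size, uniform in direction, so that no
        # linear separator beats chance by construction.
        dirs = rng.standard_normal((n2, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = np.abs(design.effect_size + RADIAL_SHELL_SD * rng.standard_normal(n2))
        z[n1:, info] = dirs * radii[:, None]
    return z


def generate_peak_table(design: SyntheticDesign) -> PeakTable:
    """Draw a peak table from a :class:`SyntheticDesign`.

    Identical design (including seed) gives bit-identical output. Group 1
    samples come first and carry label 1; group 2 follows with label 0.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_group1 + design.n_group2
    z = _standardized_effects(design, rng)
    areas = np.exp(design.area_scale + design.noise_sd * z)
    # internal standard: log-normal, class-independent, mean is_mean, CV is_cv
    sigma_is = math.sqrt(math.log(1.0 + design.is_cv**2))
    is_area = design.is_mean * np.exp(
        sigma_is * rng.standard_normal(n) - 0.5 * sigma_is**2
    )
    labels = np.concatenate(
        [np.ones(design.n_group1, dtype=int), np.zeros(design.n_group2, dtype=int)]
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return PeakTable(
        sample_ids=sample_ids,
        labels=labels,
        metabolite_names=list(design.metabolite_names),
        areas=areas,
        is_area=is_area,
    )


@dataclass
class ClinicalVariableSpec:
    """Group-wise summary defining one simulated clinical covariate.

    For ``kind='continuous'`` supply (mean, sd) per group; for
    ``kind='binary'`` supply the success proportion per group.
    """

    name: str
    kind: str
    group1: tuple[float, float] | float
    group2: tuple[float, float] | float

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "continuous":
            for g in (self.group1, self.group2):
                if len(g) != 2 or g[1] <= 0:
                    raise ValueError(f"{self.name}: need (mean, sd) with sd > 0")
        else:
            for g in (self.group1, self.group2):
                if not 0.0 <= float(g) <= 1.0:
                    raise ValueError(f"{self.name}: proportion must be in [0, 1]")


def generate_clinical_table(
    variables: list[ClinicalVariableSpec],
    n_group1: int,
    n_group2: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a clinical covariate table from per-variable group summaries.

    Continuous variables are drawn normal with the stated group mean/SD,
    binary variables Bernoulli with the stated proportion. The returned frame
    has a leading ``label`` column (group 1 → 1, group 2 → 0).
    """
    if n_group1 < 1 or n_group2 < 1:
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_group1, dtype=int), np.zeros(n_group2, dtype=int)])
    data = {"label": labels}
    for var in variables:
        cols = []
        for params, size in ((var.group1, n_group1), (var.group2, n_group2)):
            if var.kind == "continuous":
                mean, sd = params
                cols.append(rng.normal(mean, sd, size=size))
            else:
                cols.append((rng.random(size) < float(params)).astype(int))
        data[var.name] = np.concatenate(cols)
    return pd.DataFrame(data)
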