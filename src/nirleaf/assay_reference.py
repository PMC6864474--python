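"""Wet-chemistry arithmetic and summary statistics over the reference tables.

The microplate assays behind the reference values (Folin-Ciocalteu for total
phenolics, aluminium-chloride for flavonoids, ABTS decolorization for
antioxidant capacity) are calibrated against standard curves of gallic acid,
catechin and Trolox respectively.  Extract concentrations read off those
curves convert to per-gram dry-leaf contents through the extraction constants:
50 mg of milled leaf in 20 mL of 50/50 ethanol/water, with 50×, 10× and 50×
dilution for TPC, TFC and TAC.

Group comparisons use Welch's two-sample t-test computed from summary
statistics (mean, SD, n) — the robust default when only quadruplicate
mean ± SD values are available and variances may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ReferenceTable

__all__ = [
    "CalibrationCurve",
    "ExtractionSpec",
    "fit_standard_curve",
    "concentration_to_content",
    "summarize_table",
    "compare_groups",
    "CompareResult",
]


@dataclass
class CalibrationCurve:
    slope: float  # absorbance per concentration unit
    intercept: float
    standard: str = ""
    concentration_units: str = ""
    residual_sd: float = 0.0
    n_levels: int = 0

    def absorbance(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def concentration(self, absorbance):
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


def fit_standard_curve(
    levels, responses, standard: str = "", concentration_units: str = ""
) -> CalibrationCurve:
    """Ordinary least-squares line response = slope·conc + intercept."""
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if levels.size != responses.size:
        raise ValueError("levels and responses must have equal length")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct standard levels")
    slope, intercept = np.polyfit(levels, responses, 1)
    resid = responses - (slope * levels + intercept)
    dof = max(levels.size - 2, 1)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        standard=standard,
        concentration_units=concentration_units,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        n_levels=int(np.unique(levels).size),
    )


@dataclass
class ExtractionSpec:
    """Extraction and dilution constants of the assay protocol."""

    leaf_mass_g: float = 0.050
    solvent_volume_l: float = 0.020
    dilution: dict = field(
        default_factory=lambda: {"TPC": 50.0, "TFC": 10.0, "TAC": 50.0}
    )

    def __post_init__(self) -> None:
        if self.leaf_mass_g <= 0 or self.solvent_volume_l <= 0:
            raise ValueError("mass and volume must be positive")
        if any(d <= 0 for d in self.dilution.values()):
            raise ValueError("dilution factors must be positive")


def concentration_to_content(
    diluted_conc: float, spec: ExtractionSpec, parameter: str
) -> float:
    """Per-gram dry-leaf content from a diluted-extract concentration.

    content = conc × dilution × solvent volume / leaf mass; units follow the
    assay (mg gallic acid or catechin per g, mM Trolox per g).
    """
    if diluted_conc < 0:
        raise ValueError("concentration must be >= 0")
    if parameter not in spec.dilution:
        raise ValueError(f"unknown parameter {parameter!r}")
    return (
        diluted_conc
        * spec.dilution[parameter]
        * spec.solvent_volume_l
        / spec.leaf_mass_g
    )


@dataclass
class TableSummary:
    parameter: str
    n_cells: int
    min: float
    max: float
    range: tuple
    argmin: dict
    argmax: dict
    by_season: pd.Series
    by_region: pd.Series


def summarize_table(
    reference: ReferenceTable,
    parameter: str,
    seasons=None,
    regions=None,
    cultivars=None,
) -> TableSummary:
    """Extrema and per-season/region means of one parameter's table cells.

    Everything is computed from the table rows; missing cells are simply not
    present.  Raises if the filters leave nothing.
    """
    sub = reference.df[reference.df["parameter"] == parameter]
    if seasons is not None:
        sub = sub[sub["season"].isin(seasons)]
    if regions is not None:
        sub = sub[sub["region"].isin(regions)]
    if cultivars is not None:
        sub = sub[sub["cultivar"].isin(cultivars)]
    if sub.empty:
        raise ValueError(f"no {parameter} cells match the filters")
    i_min = sub["mean"].idxmin()
    i_max = sub["mean"].idxmax()
    keys = ["cultivar", "region", "season"]
    return TableSummary(
        parameter=parameter,
        n_cells=len(sub),
        min=float(sub.loc[i_min, "mean"]),
        max=float(sub.loc[i_max, "mean"]),
        range=(float(sub["mean"].min()), float(sub["mean"].max())),
        argmin=sub.loc[i_min, keys].to_dict(),
        argmax=sub.loc[i_max, keys].to_dict(),
        by_season=sub.groupby("season")["mean"].mean(),
        by_region=sub.groupby("region")["mean"].mean(),
    )


@dataclass
class CompareResult:
    statistic: float
    df: float
    p_value: float
    significant: bool
    alpha: float


def compare_groups(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> CompareResult:
    """Welch two-sample t-test from summary statistics.

    Degenerate zero-variance inputs follow the documented convention:
    equal means → p = 1; unequal means → p = 0.  ``bonferroni_m`` divides the
    significance level for simple multiple-comparison control (default: none,
    matching raw p < 0.05 reporting).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be >= 0")
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    level = alpha / bonferroni_m
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    if va + vb == 0:
        if mean_a == mean_b:
            return CompareResult(0.0, float(n_a + n_b - 2), 1.0, False, level)
        stat = np.inf if mean_a > mean_b else -np.inf
        return CompareResult(stat, float(n_a + n_b - 2), 0.0, True, level)
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CompareResult(float(t), float(df), float(p), bool(p < level), level)
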