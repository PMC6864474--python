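"""Synthetic NIR spectra and reference values with the study's structure.

No raw leaf spectra were ever deposited, so the pipeline is exercised on
simulated data that reproduces the statistical structure the analysis relies
on: 27 cultivars, three regions, three seasons, five replicate diffuse-
reflectance spectra per sample on a 10000–4000 cm⁻¹ grid at 8 cm⁻¹ spacing,
with reference values spanning the printed TPC/TFC/TAC ranges.

The spectral model is deliberately simple (this is not radiative transfer):

    A(ν) = (1 + m) · [ Σ_p c_p Σ_j a_pj G(ν; μ_pj, σ_pj)
                       + Σ_k g_k G(ν; μ_k, σ_k) + shift_season(ν) ]
           + α + β·ν̃ + ε(ν)

with Gaussian bands G, per-replicate multiplicative scatter m, baseline
intercept/slope α, β (ν̃ normalised to [-1, 1]) and white noise ε.  Analyte
band positions default to the two windows (6315–5390 and 4925–4073 cm⁻¹)
where the real calibrations found their signal, so the exhaustive region
search has a recoverable ground truth.  Interferent bands (water/background
analogues) sit outside those windows and dominate the spectrum's scale; their
amplitudes jitter slightly between replicate scans, the way repacking a
powdered sample perturbs its moisture/matrix signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .data_model import (
    PARAMETERS,
    UNITS,
    ReferenceTable,
    SpectraSet,
)

__all__ = [
    "Band",
    "SimulationConfig",
    "simulate_reference_values",
    "simulate_spectra",
    "simulate_dataset",
    "load_fixture_tables",
    "FixtureTables",
]


@dataclass(frozen=True)
class Band:
    """A Gaussian absorption band: center and width in cm⁻¹, amplitude in
    absorbance units (per unit concentration for analyte bands)."""

    center: float
    width: float
    amplitude: float

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        return self.amplitude * np.exp(
            -((wn - self.center) ** 2) / (2.0 * self.width ** 2)
        )


def _default_analyte_bands() -> dict:
    # Each parameter's signature is a zero-net-area doublet (one positive and
    # one equal-area negative Gaussian lobe), both lobes inside 6315–5390 or
    # 4925–4073 cm⁻¹, peaking near 0.1 AU at the top of the value range.  The
    # zero net area reflects mass closure in a powdered mixture: more of one
    # constituent displaces matrix absorbance, so constituent signatures are
    # difference spectra.  It also keeps the per-spectrum SNV scale
    # independent of composition, which is what confines the predictive
    # information to the two analyte windows.
    # Phenolic-family absorbers overlap heavily, so the lobe at 6000 cm⁻¹ is
    # shared by TPC and TFC and the lobe at 4500 cm⁻¹ by TPC and TAC: no
    # single window identifies TPC on its own, and the exhaustive region
    # search genuinely needs both windows — mirroring why the real
    # calibrations settled on the pair.
    return {
        "TPC": (Band(6000.0, 60.0, 4.0e-4), Band(4500.0, 50.0, -4.8e-4)),
        "TFC": (Band(6000.0, 60.0, 3.4e-4), Band(4300.0, 45.0, -4.5333333e-4)),
        "TAC": (Band(5700.0, 50.0, 8.0e-4), Band(4500.0, 50.0, -8.0e-4)),
    }


def _default_interferent_bands() -> tuple:
    # Water combination/overtone analogues plus a broad short-wavelength
    # background: the matrix bands that dominate leaf NIR spectra.  All sit
    # well inside the uninformative base regions (≥ ~5 band widths from any
    # analyte-window edge) so their position jitter never bleeds into the
    # informative windows.
    return (
        Band(6900.0, 110.0, 2.4),
        Band(5157.0, 45.0, 3.0),
        Band(8500.0, 250.0, 1.6),
    )


def _default_value_ranges() -> dict:
    # The printed min–max of each assay across all cultivars/seasons/regions.
    return {
        "TPC": (39.6, 272.8),
        "TFC": (41.2, 269.1),
        "TAC": (22.6, 124.8),
    }


@dataclass
class SimulationConfig:
    seed: int = 2017
    n_cultivars: int = 27
    regions: tuple = ("RA", "RB", "RC")
    seasons: tuple = ("spring", "fall", "winter")
    replicates_per_sample: int = 5
    grid_start: float = 10000.0
    grid_end: float = 4000.0
    grid_step: float = 8.0
    analyte_bands: dict = field(default_factory=_default_analyte_bands)
    interferent_bands: tuple = field(default_factory=_default_interferent_bands)
    interferent_amplitude_sd: float = 0.0  # relative, per replicate scan
    interferent_center_sample_sd: float = 5.0  # cm⁻¹, per sample
    interferent_center_jitter_sd: float = 2.0  # cm⁻¹, per replicate scan
    analyte_center_sample_sd: float = 2.0  # cm⁻¹, per sample
    background_level: float = 0.5  # constant absorbance pedestal
    baseline_intercept_sd: float = 0.01
    baseline_slope_sd: float = 0.005
    scatter_sd: float = 0.02
    noise_sd: float = 0.001
    value_ranges: dict = field(default_factory=_default_value_ranges)
    season_offset: dict = field(
        default_factory=lambda: {"fall": -20.0, "winter": 40.0}
    )
    region_offset: dict = field(default_factory=lambda: {"RA": 10.0})
    season_shift_bands: dict = field(default_factory=dict)
    replicate_sd_range: tuple = (0.01, 0.04)  # assay SD as fraction of the mean
    full_crossing: bool = False

    # -- derived -----------------------------------------------------------

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_end - 1e-9, -self.grid_step)

    def design_pairs(self) -> list[tuple[str, str]]:
        """(region, season) pairs actually sampled.

        Default mimics the study layout: the first region is sampled in every
        season, the remaining regions only in the first season.  With
        ``full_crossing=True`` every region × season cell is sampled.
        """
        pairs = []
        for r in self.regions:
            for s in self.seasons:
                if self.full_crossing or r == self.regions[0] or s == self.seasons[0]:
                    pairs.append((r, s))
        return pairs

    def validate(self) -> None:
        if self.grid_start <= self.grid_end:
            raise ValueError("grid_start must exceed grid_end")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.wavenumbers.size < 2:
            raise ValueError("grid must contain at least 2 points")
        if self.n_cultivars < 1:
            raise ValueError("n_cultivars must be >= 1")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if not self.design_pairs():
            raise ValueError("empty design: no region/season combinations")
        for param, bands in self.analyte_bands.items():
            if param not in self.value_ranges:
                raise ValueError(f"no value range for analyte {param!r}")
            for b in bands:
                if not self.grid_end <= b.center <= self.grid_start:
                    raise ValueError(
                        f"band center {b.center} outside the grid for {param!r}"
                    )
        for lo, hi in self.value_ranges.values():
            if not lo < hi:
                raise ValueError("value_ranges need min < max")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        for name in (
            "interferent_amplitude_sd",
            "interferent_center_sample_sd",
            "interferent_center_jitter_sd",
            "analyte_center_sample_sd",
            "baseline_intercept_sd",
            "baseline_slope_sd",
            "scatter_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.replicate_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("replicate_sd_range must be 0 <= lo <= hi")


def _cultivar_names(n: int) -> list[str]:
    return [f"CV{i + 1:02d}" for i in range(n)]


def _species_labels(n: int) -> list[str]:
    # roughly the study's 24:3 corymbosum:ashei proportion
    n_ashei = max(1, round(n / 9)) if n >= 9 else 0
    return ["V. corymbosum"] * (n - n_ashei) + ["V. ashei"] * n_ashei


def simulate_reference_values(config: SimulationConfig) -> ReferenceTable:
    """Draw a reference table for every sample in the simulated design.

    Each cultivar gets one uniform base value per parameter inside the
    configured range; season/region offsets shift it and the result is clipped
    back into the range.  Replicate (assay) SDs are a small random fraction of
    the mean.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    cultivars = _cultivar_names(config.n_cultivars)
    species = _species_labels(config.n_cultivars)
    params = list(config.value_ranges)
    base = {
        p: rng.uniform(*config.value_ranges[p], size=config.n_cultivars)
        for p in params
    }
    sd_frac = {
        p: rng.uniform(*config.replicate_sd_range, size=config.n_cultivars)
        for p in params
    }
    rows = []
    for ci, (cv, sp) in enumerate(zip(cultivars, species)):
        for region, season in config.design_pairs():
            sample_id = f"{cv}_{region}_{season}"
            for p in params:
                lo, hi = config.value_ranges[p]
                mean = base[p][ci]
                mean += config.season_offset.get(season, 0.0)
                mean += config.region_offset.get(region, 0.0)
                mean = float(np.clip(mean, lo, hi))
                rows.append(
                    {
                        "sample_id": sample_id,
                        "cultivar": cv,
                        "species": sp,
                        "region": region,
                        "season": season,
                        "plant_id": f"{cv}_{region}",
                        "parameter": p,
                        "mean": mean,
                        "sd": mean * float(sd_frac[p][ci]),
                        "units": UNITS.get(p, "a.u."),
                    }
                )
    return ReferenceTable(pd.DataFrame(rows))


def simulate_spectra(
    reference: ReferenceTable, config: SimulationConfig
) -> SpectraSet:
    """Generate replicate spectra for every sample in ``reference``.

    Deterministic given ``config.seed``.  Raises if the reference table lacks
    a parameter the analyte bands need.
    """
    config.validate()
    if len(reference) == 0:
        raise ValueError("empty reference table")
    rng = np.random.default_rng([config.seed, 2])
    wn = config.wavenumbers
    nu_norm = (wn - wn.mean()) / ((wn.max() - wn.min()) / 2.0)

    wide = reference.df.pivot_table(
        index="sample_id", columns="parameter", values="mean", sort=False
    )
    # preserve first-appearance order of samples
    sample_order = list(dict.fromkeys(reference.df["sample_id"]))
    wide = wide.loc[sample_order]
    missing = [p for p in config.analyte_bands if p not in wide.columns]
    if missing:
        raise ValueError(f"reference table lacks parameters: {missing}")
    if wide[list(config.analyte_bands)].isna().any().any():
        bad = wide.index[wide[list(config.analyte_bands)].isna().any(axis=1)]
        raise ValueError(f"missing analyte values for samples: {list(bad)}")

    meta_by_sample = (
        reference.df.drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[sample_order]
    )
    n_samples = len(sample_order)
    R = config.replicates_per_sample
    n_pts = wn.size


    # Interferent (water/matrix) band jitter.  Band positions drift between
    # samples with moisture state and hydrogen bonding, and a little more
    # between replicate scans; repacking also perturbs amplitudes slightly.
    # Position shifts leave the spectrum's overall variance (hence the SNV
    # scale) essentially unchanged, so these bands carry no analyte
    # information — they are pure structured nuisance, which is what makes
    # the uninformative base regions genuinely harmful to include.
    n_intf = len(config.interferent_bands)
    if n_intf:
        intf_factors = 1.0 + rng.normal(
            0.0, config.interferent_amplitude_sd, size=(n_samples, R, n_intf)
        )
        intf_shifts = rng.normal(
            0.0, config.interferent_center_sample_sd, size=(n_samples, 1, n_intf)
        ) + rng.normal(
            0.0, config.interferent_center_jitter_sd, size=(n_samples, R, n_intf)
        )
    else:
        intf_factors = np.zeros((n_samples, R, 0))
        intf_shifts = np.zeros((n_samples, R, 0))

    # analyte band positions also drift a little with the sample's matrix
    # state; this, not instrument noise, is what bounds attainable accuracy
    # in the noise-free limit
    n_analyte_bands = sum(len(b) for b in config.analyte_bands.values())
    analyte_shifts = rng.normal(
        0.0, config.analyte_center_sample_sd, size=(n_samples, n_analyte_bands)
    )

    # per-replicate nuisance draws
    m = rng.normal(0.0, config.scatter_sd, size=(n_samples, R))
    alpha = rng.normal(0.0, config.baseline_intercept_sd, size=(n_samples, R))
    beta = rng.normal(0.0, config.baseline_slope_sd, size=(n_samples, R))
    eps = (
        rng.normal(0.0, config.noise_sd, size=(n_samples, R, n_pts))
        if config.noise_sd > 0
        else np.zeros((n_samples, R, n_pts))
    )

    season_shift = {
        season: sum((b.profile(wn) for b in bands), np.zeros(n_pts))
        for season, bands in config.season_shift_bands.items()
    }

    intensities = np.empty((n_samples * R, n_pts))
    meta_rows = []
    for i, sid in enumerate(sample_order):
        sample_signal = np.full(n_pts, config.background_level)
        bi = 0
        for p, bands in config.analyte_bands.items():
            conc = float(wide.loc[sid, p])
            for band in bands:
                shifted = Band(
                    band.center + analyte_shifts[i, bi], band.width, band.amplitude
                )
                sample_signal += conc * shifted.profile(wn)
                bi += 1
        season = meta_by_sample.loc[sid, "season"]
        if season in season_shift:
            sample_signal = sample_signal + season_shift[season]
        for r in range(R):
            signal = sample_signal
            for k, band in enumerate(config.interferent_bands):
                shifted = Band(
                    band.center + intf_shifts[i, r, k], band.width, band.amplitude
                )
                signal = signal + intf_factors[i, r, k] * shifted.profile(wn)
            row = i * R + r
            intensities[row] = (
                (1.0 + m[i, r]) * signal
                + alpha[i, r]
                + beta[i, r] * nu_norm
                + eps[i, r]
            )
            meta_rows.append(
                {
                    "sample_id": sid,
                    "replicate": r + 1,
                    "cultivar": meta_by_sample.loc[sid, "cultivar"],
                    "species": meta_by_sample.loc[sid, "species"],
                    "region": meta_by_sample.loc[sid, "region"],
                    "season": season,
                    "plant_id": meta_by_sample.loc[sid, "plant_id"],
                }
            )
    return SpectraSet(wn, intensities, pd.DataFrame(meta_rows))


def simulate_dataset(config: SimulationConfig) -> tuple[SpectraSet, ReferenceTable]:
    """Convenience wrapper: reference values plus their spectra."""
    ref = simulate_reference_values(config)
    return simulate_spectra(ref, config), ref


# ---------------------------------------------------------------------------
# Packaged fixture tables (transcriptions of the printed reference tables)
# ---------------------------------------------------------------------------


@dataclass
class FixtureTables:
    tpc: ReferenceTable
    tfc: ReferenceTable
    tac: ReferenceTable
    plants: pd.DataFrame

    def combined(self) -> ReferenceTable:
        return self.tpc.concat(self.tfc).concat(self.tac)


def load_fixture_tables() -> FixtureTables:
    """The packaged transcriptions of the printed assay tables.

    One row per non-missing table cell (cultivar × region × season); missing
    cells are absent rows, never zeros.  The plants table carries species,
    plant counts and harvest months per cultivar; berry presence was printed
    as cell shading and is not recoverable from the source text, so that
    column is present but empty.
    """
    root = resources.files("nirleaf") / "fixtures"
    with resources.as_file(root) as path:
        tpc = ReferenceTable.from_fixture_csv(path / "tpc.csv", "TPC")
        tfc = ReferenceTable.from_fixture_csv(path / "tfc.csv", "TFC")
        tac = ReferenceTable.from_fixture_csv(path / "tac.csv", "TAC")
        plants = pd.read_csv(path / "plants.csv")
    return FixtureTables(tpc=tpc, tfc=tfc, tac=tac, plants=plants)
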