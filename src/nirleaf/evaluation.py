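"""Calibration/prediction splitting, figures of merit and transferability.

Figures of merit follow standard NIR-calibration reporting: RMSEC/RMSECV/RMSEP
and R²_C/R²_CV/R²_P on the calibration, cross-validation and prediction sets,
plus the range error ratio RER = Δy / RMSEP, where Δy is the reference-value
range of the prediction set.  RER ≥ 10 marks a model acceptable for quality
control and RER ≥ 15 a model suitable for quantification.

The 70/30 calibration/prediction split is drawn at the *sample* level (all
replicate spectra of a sample stay on one side) and stratified by reference
value quartile, so the prediction range sits inside the calibration range.
A spectrum-level split is available behind ``split_unit="spectrum"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    DataSetDesign,
    ReferenceTable,
    SpectraSet,
    align_reference,
    build_dataset,
    get_design,
)
from .preprocessing import PreprocessConfig, preprocess_chain
from .pls_calibration import (
    PLSModel,
    RegionScheme,
    SpectralRegion,
    default_scheme,
    fit_pls,
    loocv,
    optimize_model,
    select_lv,
)

QUALITY_LABELS = ("insufficient", "quality_control", "quantification")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    calibration: tuple
    prediction: tuple
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        if set(self.calibration) & set(self.prediction):
            raise ValueError("calibration and prediction sets overlap")


def split_calibration_prediction(
    sample_ids,
    y,
    fraction: float = 0.70,
    seed: int = 2017,
    stratify: bool = True,
) -> SplitResult:
    """Random sample-level split into calibration and prediction sets.

    Deterministic given ``seed``; with ``stratify=True`` samples are binned by
    reference-value quartile and split proportionally within each bin.
    ``|calibration| = round(fraction · n_samples)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    sample_ids = list(sample_ids)
    y = np.asarray(y, dtype=float)
    n = len(sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if y.size != n:
        raise ValueError("y must give one value per sample")
    rng = np.random.default_rng(seed)
    n_cal = int(round(fraction * n))
    n_cal = min(max(n_cal, 1), n - 1)

    order = np.argsort(y, kind="stable")
    if stratify:
        bins = np.array_split(order, 4)
    else:
        bins = [order]
    floors, remainders = [], []
    for b in bins:
        target = fraction * len(b)
        floors.append(int(np.floor(target)))
        remainders.append(target - np.floor(target))
    deficit = n_cal - sum(floors)
    # hand the leftover calibration slots to the bins with the largest
    # fractional targets (deterministic tie-break by bin index)
    for i in sorted(range(len(bins)), key=lambda i: (-remainders[i], i)):
        if deficit <= 0:
            break
        if floors[i] < len(bins[i]):
            floors[i] += 1
            deficit -= 1
    cal_idx: list[int] = []
    for b, take in zip(bins, floors):
        perm = rng.permutation(len(b))
        cal_idx.extend(b[perm[:take]])
    cal = tuple(sample_ids[i] for i in sorted(cal_idx))
    pred = tuple(s for s in sample_ids if s not in set(cal))
    return SplitResult(calibration=cal, prediction=pred, seed=seed, fraction=fraction)


# ---------------------------------------------------------------------------
# Figures of merit
# ---------------------------------------------------------------------------


def rmse(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_hat) ** 2)))


def r_squared(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum((y_true - y_hat) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def classify_quality(rer: float) -> str:
    """Map a range error ratio onto the standard NIR model-quality bands."""
    if np.isnan(rer) or rer < 0:
        raise ValueError("RER must be non-negative")
    if rer >= 15:
        return "quantification"
    if rer >= 10:
        return "quality_control"
    return "insufficient"


@dataclass
class FiguresOfMerit:
    rmsec: float
    r2_c: float
    rmsecv: float
    r2_cv: float
    rmsep: float
    r2_p: float
    rer: float
    n_lv: int
    region: str = ""
    dataset_id: int | None = None
    parameter: str = ""
    quality: str = ""

    def to_row(self) -> dict:
        """One report row in the conventional column order."""
        return {
            "Parameter": self.parameter,
            "Set": self.dataset_id,
            "Spectral Range": self.region,
            "LVs": self.n_lv,
            "RMSEC": self.rmsec,
            "R2C": self.r2_c,
            "RMSECV": self.rmsecv,
            "R2CV": self.r2_cv,
            "RMSEP": self.rmsep,
            "R2P": self.r2_p,
            "RER": self.rer,
            "Quality": self.quality,
        }


def figures_of_merit(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    rmsecv: float,
    *,
    rer_range: str = "prediction",
    dataset_id: int | None = None,
    parameter: str = "",
) -> FiguresOfMerit:
    """Assemble one report row from a fitted model and its two data splits.

    ``rer_range`` selects the reference set whose span defines Δy in
    RER = Δy / RMSEP: "prediction" (default), "calibration" or "all".
    """
    yc_hat = model.predict(X_cal)
    yp_hat = model.predict(X_pred)
    rmsec = rmse(y_cal, yc_hat)
    rmsep = rmse(y_pred, yp_hat)
    n_cal = len(np.asarray(y_cal))
    ss_tot = float(np.sum((y_cal - np.mean(y_cal)) ** 2))
    r2_cv = 1.0 - (rmsecv ** 2 * n_cal) / ss_tot if ss_tot > 0 else np.nan
    ranges = {
        "prediction": np.asarray(y_pred, dtype=float),
        "calibration": np.asarray(y_cal, dtype=float),
        "all": np.concatenate([np.asarray(y_cal), np.asarray(y_pred)]),
    }
    if rer_range not in ranges:
        raise ValueError(f"rer_range must be one of {sorted(ranges)}")
    span = float(ranges[rer_range].max() - ranges[rer_range].min())
    if rmsep == 0:
        warnings.warn("RMSEP is zero; RER reported as +inf", stacklevel=2)
        rer = np.inf
    else:
        rer = span / rmsep
    fom = FiguresOfMerit(
        rmsec=rmsec,
        r2_c=r_squared(y_cal, yc_hat),
        rmsecv=float(rmsecv),
        r2_cv=r2_cv,
        rmsep=rmsep,
        r2_p=r_squared(y_pred, yp_hat),
        rer=rer,
        n_lv=model.n_lv,
        region=model.region.label if model.region is not None else "full",
        dataset_id=dataset_id,
        parameter=parameter,
        quality=classify_quality(rer),
    )
    return fom


# ---------------------------------------------------------------------------
# End-to-end pipeline per design, and transferability
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs besides the data."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scheme: RegionScheme | None = None  # None -> default five-region scheme
    region: SpectralRegion | None = None  # fixed region bypasses the search
    max_lv: int = 10
    lv_tolerance: float = 0.02
    fraction: float = 0.70
    seed: int = 2017  # harvest-year default, overridable
    rer_range: str = "prediction"
    average_replicates: bool = False
    group_folds: bool = True


@dataclass
class RunResult:
    """Output of one end-to-end design run (one report row plus audit data)."""

    fom: FiguresOfMerit
    model: PLSModel
    split: SplitResult
    report: pd.DataFrame
    X: np.ndarray  # preprocessed rows for the whole design
    y: np.ndarray
    groups: np.ndarray
    wavenumbers: np.ndarray


def run_design(
    spectra: SpectraSet,
    reference: ReferenceTable,
    design: int | DataSetDesign,
    parameter: str,
    config: PipelineConfig | None = None,
) -> RunResult:
    """Filter → preprocess → split → optimize (regions + LVs on calibration
    rows only) → final fit → figures of merit: one report row."""
    if config is None:
        config = PipelineConfig()
    design = get_design(design)
    sub_spectra, sub_ref = build_dataset(spectra, reference, design)
    Xp, wn = preprocess_chain(
        sub_spectra.intensities, sub_spectra.wavenumbers, config.preprocess
    )
    _, y, groups = align_reference(
        sub_spectra, sub_ref, parameter, average_replicates=False
    )
    if config.average_replicates:
        uniq = list(dict.fromkeys(groups.tolist()))
        Xp = np.vstack([Xp[groups == g].mean(axis=0) for g in uniq])
        y = np.array([y[groups == g][0] for g in uniq])
        groups = np.array(uniq)

    samples = list(dict.fromkeys(groups.tolist()))
    sample_y = np.array([y[groups == s][0] for s in samples])
    split = split_calibration_prediction(
        samples, sample_y, fraction=config.fraction, seed=config.seed
    )
    cal_rows = np.isin(groups, split.calibration)
    pred_rows = ~cal_rows

    scheme = config.scheme or default_scheme()
    if config.region is None:
        model, report = optimize_model(
            Xp[cal_rows],
            y[cal_rows],
            groups[cal_rows],
            wn,
            scheme=scheme,
            max_lv=config.max_lv,
            lv_tolerance=config.lv_tolerance,
            group_folds=config.group_folds,
        )
        winner = report.loc[report["region"] == model.region.label].iloc[0]
        rmsecv_val = float(winner["rmsecv"])
    else:
        cols = config.region.mask(wn)
        curve = loocv(
            Xp[cal_rows][:, cols],
            y[cal_rows],
            groups[cal_rows],
            config.max_lv,
            group_folds=config.group_folds,
        )
        k = select_lv(curve, tolerance=config.lv_tolerance)
        rmsecv_val = float(curve[k - 1])
        model = fit_pls(
            Xp[cal_rows][:, cols], y[cal_rows], n_lv=k, region=config.region
        )
        report = pd.DataFrame(
            [
                {
                    "combo_index": 0,
                    "region": config.region.label,
                    "n_intervals": len(config.region.intervals),
                    "n_lv": k,
                    "rmsecv": rmsecv_val,
                    "rmsecv_min": float(np.nanmin(curve)),
                }
            ]
        )
    cols = model.region.mask(wn)
    fom = figures_of_merit(
        model,
        Xp[cal_rows][:, cols],
        y[cal_rows],
        Xp[pred_rows][:, cols],
        y[pred_rows],
        rmsecv_val,
        rer_range=config.rer_range,
        dataset_id=design.id,
        parameter=parameter,
    )
    return RunResult(
        fom=fom,
        model=model,
        split=split,
        report=report,
        X=Xp,
        y=y,
        groups=groups,
        wavenumbers=wn,
    )


@dataclass
class TransferabilityResult:
    designs: tuple
    foms: dict  # (train_design_id, eval_design_id) -> FiguresOfMerit
    runs: dict  # design id -> RunResult

    def rmsep_matrix(self) -> np.ndarray:
        n = len(self.designs)
        M = np.full((n, n), np.nan)
        for a, i in enumerate(self.designs):
            for b, j in enumerate(self.designs):
                if (i, j) in self.foms:
                    M[a, b] = self.foms[(i, j)].rmsep
        return M

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), fom in self.foms.items():
            row = fom.to_row()
            row["Train Set"] = i
            row["Eval Set"] = j
            rows.append(row)
        return pd.DataFrame(rows)


def transferability_matrix(
    spectra: SpectraSet,
    reference: ReferenceTable,
    designs,
    parameter: str,
    config: PipelineConfig | None = None,
) -> TransferabilityResult:
    """Cross-apply design-wise calibrations: entry (i, j) evaluates the model
    trained under design i's calibration protocol on design j's prediction
    samples.  Diagonal entries equal ``run_design`` outputs.  A design that is
    empty for the supplied data is dropped with a warning.
    """
    if config is None:
        config = PipelineConfig()
    design_ids = []
    runs: dict = {}
    for d in designs:
        d = get_design(d)
        try:
            runs[d.id] = run_design(spectra, reference, d, parameter, config)
            design_ids.append(d.id)
        except ValueError as exc:
            warnings.warn(f"design {d.id} skipped: {exc}", stacklevel=2)
    if len(design_ids) < 2:
        raise ValueError("transferability needs at least 2 non-empty designs")
    foms: dict = {}
    for i in design_ids:
        run_i = runs[i]
        for j in design_ids:
            if i == j:
                foms[(i, j)] = run_i.fom
                continue
            run_j = runs[j]
            pred_rows = np.isin(run_j.groups, run_j.split.prediction)
            cols = run_i.model.region.mask(run_j.wavenumbers)
            y_hat = run_i.model.predict(run_j.X[pred_rows][:, cols])
            y_true = run_j.y[pred_rows]
            rmsep = rmse(y_true, y_hat)
            span = float(y_true.max() - y_true.min())
            rer = np.inf if rmsep == 0 else span / rmsep
            foms[(i, j)] = FiguresOfMerit(
                rmsec=run_i.fom.rmsec,
                r2_c=run_i.fom.r2_c,
                rmsecv=run_i.fom.rmsecv,
                r2_cv=run_i.fom.r2_cv,
                rmsep=rmsep,
                r2_p=r_squared(y_true, y_hat),
                rer=rer,
                n_lv=run_i.model.n_lv,
                region=run_i.model.region.label,
                dataset_id=j,
                parameter=parameter,
                quality=classify_quality(rer),
            )
    return TransferabilityResult(
        designs=tuple(design_ids), foms=foms, runs=runs
    )
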