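"""PLS1 regression (NIPALS) with LOOCV model selection and region search.

A single-response partial least squares calibration is fitted by the NIPALS
algorithm with deflation of X only.  The number of latent variables (LVs) is
chosen by leave-one-*sample*-out cross-validation (all replicate spectra of a
sample leave together — leaving a single replicate out while its siblings stay
in the training set leaks information).  The informative spectral window is
found by exhaustively testing every non-empty combination of five base regions
spanning the 10000–4000 cm⁻¹ grid (2⁵ − 1 = 31 candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpectralRegion",
    "RegionScheme",
    "PLSModel",
    "fit_pls",
    "predict",
    "loocv",
    "select_lv",
    "enumerate_region_combinations",
    "optimize_model",
    "default_scheme",
]


# ---------------------------------------------------------------------------
# Spectral regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralRegion:
    """A union of closed wavenumber intervals [low, high] in cm⁻¹."""

    intervals: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        ivs = tuple(tuple(map(float, iv)) for iv in self.intervals)
        if not ivs:
            raise ValueError("a spectral region needs at least one interval")
        for low, high in ivs:
            if not low < high:
                raise ValueError(f"interval needs low < high, got ({low}, {high})")
        ordered = sorted(ivs, key=lambda iv: -iv[1])  # descending, instrument order
        for (lo1, _), (_, hi2) in zip(ordered, ordered[1:]):
            if hi2 >= lo1:
                raise ValueError("intervals must not overlap")
        object.__setattr__(self, "intervals", tuple(ordered))
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        return " and ".join(f"{high:g}–{low:g}" for low, high in self.intervals)

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        m = np.zeros(wn.shape, dtype=bool)
        for low, high in self.intervals:
            m |= (wn >= low) & (wn <= high)
        return m


@dataclass(frozen=True)
class RegionScheme:
    """The base regions the exhaustive search combines (canonically five)."""

    regions: tuple[SpectralRegion, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("scheme needs at least one base region")

    def __len__(self) -> int:
        return len(self.regions)


def default_scheme() -> RegionScheme:
    """Five contiguous base regions covering 10000–4073 cm⁻¹.

    The third and fifth regions are the windows (6315–5390 and 4925–4073 cm⁻¹)
    where C-H/O-H combination and overtone bands of phenolic compounds fall.
    """
    bounds = [
        (7501.0, 10000.0),
        (6316.0, 7500.0),
        (5390.0, 6315.0),
        (4926.0, 5389.0),
        (4073.0, 4925.0),
    ]
    return RegionScheme(tuple(SpectralRegion((b,)) for b in bounds))


def enumerate_region_combinations(scheme: RegionScheme) -> list[SpectralRegion]:
    """All non-empty subsets of the base regions, in binary-counting order.

    Bit ``i`` of the subset code selects base region ``i``.  Contiguous
    intervals (gap ≤ 1 cm⁻¹) are merged in the combined region.
    """
    n = len(scheme)
    combos = []
    for code in range(1, 2 ** n):
        chosen = [scheme.regions[i] for i in range(n) if code >> i & 1]
        intervals = sorted(
            (iv for r in chosen for iv in r.intervals), key=lambda iv: -iv[1]
        )
        merged: list[list[float]] = []
        for low, high in intervals:
            if merged and high >= merged[-1][0] - 1.0:
                merged[-1][0] = min(merged[-1][0], low)
            else:
                merged.append([low, high])
        combos.append(SpectralRegion(tuple((lo, hi) for lo, hi in merged)))
    return combos


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """A fitted PLS1 calibration.

    Prediction on rows preprocessed like the training data:
    ``y_hat = (X - x_mean) @ b + y_mean`` with ``b = W (PᵀW)⁻¹ q``.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, shape (p, k)
    x_loadings: np.ndarray  # P, shape (p, k)
    y_loadings: np.ndarray  # q, shape (k,)
    coef: np.ndarray  # b, shape (p,)
    region: "SpectralRegion | None" = None
    preprocess: object | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coef.size:
            raise ValueError(
                f"column count mismatch: model has {self.coef.size} variables, "
                f"input has {X_new.shape[1]}"
            )
        return (X_new - self.x_mean) @ self.coef + self.y_mean


def _nipals_components(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Extract up to n_lv NIPALS PLS1 components from centered X, y.

    Deflates X only (deflating y as well provably yields the same weight
    sequence for a single response).  Returns W, P, q and the number of
    components actually extracted (rank exhaustion truncates with a warning).
    """
    X = np.array(Xc, dtype=float)
    y = np.asarray(yc, dtype=float)
    n, p = X.shape
    k_max = min(n_lv, n - 1 if n > 1 else 1, p)
    if k_max < n_lv:
        warnings.warn(
            f"n_lv={n_lv} exceeds the data rank bound; truncated to {k_max}",
            stacklevel=3,
        )
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    tol = 1e-12 * max(1.0, float(np.abs(X).max() * np.abs(y).max()))
    k = 0
    for a in range(k_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= tol:
            warnings.warn(
                f"X-y covariance exhausted after {k} components "
                f"(requested {n_lv}); truncating",
                stacklevel=3,
            )
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        W[:, a] = w
        P[:, a] = X.T @ t / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, P[:, a])
        k += 1
    return W[:, :k], P[:, :k], q[:k], k


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    center: bool = True,
    region: SpectralRegion | None = None,
    preprocess: object | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    With ``center=True`` (default) column/response means are computed here and
    stored so the model predicts from uncentered (but otherwise preprocessed)
    spectra.  Pass ``center=False`` for already-centered input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 calibration rows")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    x_mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    y_mean = float(y.mean()) if center else 0.0
    W, P, q, k = _nipals_components(X - x_mean, y - y_mean, n_lv)
    b = _regression_vector(W, P, q)
    return PLSModel(
        n_lv=k,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=b,
        region=region,
        preprocess=preprocess,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    return model.predict(X_new)


def _path_predictions(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, max_lv: int
) -> np.ndarray:
    """Test-set predictions for every LV count 1..max_lv from one NIPALS pass.

    Centering is computed on the training rows.  Columns for LV counts beyond
    the extractable rank repeat the last valid prediction (callers mask them).
    """
    xm = X_train.mean(axis=0)
    ym = float(y_train.mean())
    Xa = X_train - xm
    yc = y_train - ym
    Xt = np.atleast_2d(X_test) - xm
    n_test = Xt.shape[0]
    preds = np.empty((n_test, max_lv))
    yhat = np.zeros(n_test)
    tol = 1e-12 * max(1.0, float(np.abs(Xa).max(initial=0.0)))
    for a in range(max_lv):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw <= tol:
            preds[:, a:] = yhat[:, None]
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= tol:
            preds[:, a:] = yhat[:, None]
            break
        p_load = Xa.T @ t / tt
        q_a = float(yc @ t) / tt
        t_test = Xt @ w
        yhat = yhat + q_a * t_test
        Xa -= np.outer(t, p_load)
        Xt -= np.outer(t_test, p_load)
        preds[:, a] = yhat
    return preds + ym


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    max_lv: int,
    group_folds: bool = True,
) -> np.ndarray:
    """RMSECV for each LV count 1..max_lv under leave-one-sample-out CV.

    All replicate spectra sharing a group (sample id) are held out together;
    centering is recomputed on each fold's training rows.  With
    ``group_folds=False`` every spectrum is its own fold (the leakage-prone
    variant, kept for fidelity experiments).  LV counts no fold can support
    come back as NaN with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    fold_ids = groups if group_folds else np.arange(len(y))
    uniq = list(dict.fromkeys(fold_ids.tolist()))
    if len(uniq) < 3:
        raise ValueError("grouped LOOCV needs at least 3 groups")
    sq_err = np.zeros(max_lv)
    valid = np.zeros(max_lv, dtype=bool)
    total = np.zeros(max_lv)
    for g in uniq:
        test = fold_ids == g
        train = ~test
        n_train = int(train.sum())
        k_fold = min(max_lv, n_train - 1, X.shape[1])
        if k_fold < max_lv:
            warnings.warn(
                f"fold {g!r} supports only {k_fold} LVs; higher counts skipped",
                stacklevel=2,
            )
        if k_fold < 1:
            continue
        preds = _path_predictions(X[train], y[train], X[test], k_fold)
        err = (preds - y[test][:, None]) ** 2
        sq_err[:k_fold] += err.sum(axis=0)
        total[:k_fold] += err.shape[0]
        valid[:k_fold] = True
    rmsecv = np.full(max_lv, np.nan)
    rmsecv[valid] = np.sqrt(sq_err[valid] / total[valid])
    return rmsecv


def select_lv(rmsecv_curve: np.ndarray, tolerance: float = 0.02) -> int:
    """Parsimonious LV choice: the smallest k with
    RMSECV(k) ≤ (1 + tolerance) · min RMSECV.  Returns a 1-based count."""
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0 or np.all(np.isnan(curve)):
        raise ValueError("empty RMSECV curve")
    thr = (1.0 + tolerance) * np.nanmin(curve)
    for k, v in enumerate(curve, start=1):
        if np.isfinite(v) and v <= thr:
            return k
    raise AssertionError("unreachable: minimum always satisfies the rule")


# ---------------------------------------------------------------------------
# Exhaustive region / LV optimization
# ---------------------------------------------------------------------------


def optimize_model(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    wavenumbers: np.ndarray,
    scheme: RegionScheme | None = None,
    max_lv: int = 10,
    lv_tolerance: float = 0.02,
    group_folds: bool = True,
) -> tuple[PLSModel, pd.DataFrame]:
    """Search every base-region combination; pick the lowest-RMSECV model.

    For each of the 2ⁿ − 1 combinations the columns are masked to the
    combination, grouped LOOCV is run, and the LV count is selected by the
    parsimony rule.  The winner is the combination with the lowest RMSECV at
    its selected LV count; exact ties break toward fewer intervals, then fewer
    LVs, then enumeration order.  The final model is refitted on all supplied
    rows.  Returns (model, report) where the report has one row per evaluated
    combination.
    """
    if scheme is None:
        scheme = default_scheme()
    wn = np.asarray(wavenumbers, dtype=float)
    combos = enumerate_region_combinations(scheme)
    records = []
    best = None  # (rmsecv, n_intervals, n_lv, index)
    for idx, combo in enumerate(combos):
        cols = combo.mask(wn)
        if not cols.any():
            warnings.warn(
                f"combination {combo.label!r} covers no grid points; skipped",
                stacklevel=2,
            )
            continue
        curve = loocv(X[:, cols], y, groups, max_lv, group_folds=group_folds)
        if np.all(np.isnan(curve)):
            continue
        k = select_lv(curve, tolerance=lv_tolerance)
        rmsecv_k = float(curve[k - 1])
        records.append(
            {
                "combo_index": idx,
                "region": combo.label,
                "n_intervals": len(combo.intervals),
                "n_lv": k,
                "rmsecv": rmsecv_k,
                "rmsecv_min": float(np.nanmin(curve)),
            }
        )
        key = (rmsecv_k, len(combo.intervals), k, idx)
        if best is None or key < best[0]:
            best = (key, combo, k, cols, curve)
    if best is None:
        raise ValueError("no region combination could be evaluated")
    _, combo, k, cols, curve = best
    model = fit_pls(X[:, cols], y, n_lv=k, region=combo)
    report = pd.DataFrame.from_records(records)
    return model, report
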