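"""Spectral pre-treatment: SNV, Savitzky-Golay derivative, mean centering.

The chain mirrors common diffuse-reflectance practice: standard normal variate
(per-spectrum standardisation, removing multiplicative scatter and additive
offsets), then a Savitzky-Golay first derivative (window 15, 2nd-order
polynomial by default, removing residual baseline slope), then mean centering
computed on the calibration rows at model-fit time.

Savitzky-Golay edge handling: the first and last (window-1)/2 points are
dropped rather than extrapolated, and the wavenumber grid shrinks accordingly.
The derivative is expressed per index step of the stored grid (constant
spacing makes this proportional to the per-cm⁻¹ derivative; the scale is
irrelevant to PLS after centering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter


@dataclass
class PreprocessConfig:
    apply_snv: bool = True
    savgol_window: int = 15
    savgol_polyorder: int = 2
    savgol_derivative: int = 1
    apply_savgol: bool = True
    mean_center: bool = True
    snv_first: bool = True  # False applies the derivative before SNV

    def validate(self, n_points: int | None = None) -> None:
        if self.apply_savgol:
            if self.savgol_window % 2 != 1:
                raise ValueError("savgol_window must be odd")
            if self.savgol_window <= self.savgol_polyorder:
                raise ValueError("savgol_window must exceed polyorder")
            if self.savgol_derivative > self.savgol_polyorder:
                raise ValueError("derivative order cannot exceed polyorder")
            if n_points is not None and self.savgol_window > n_points:
                raise ValueError(
                    f"savgol_window {self.savgol_window} exceeds spectrum "
                    f"length {n_points}"
                )


def snv(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, sample sd (n-1).

    Accepts a single spectrum (1-D) or a matrix with one spectrum per row.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance (constant) spectrum cannot be SNV-scaled")
    out = (X - mu) / sd
    return out[0] if one_d else out


def savgol(
    x: np.ndarray,
    window: int = 15,
    polyorder: int = 2,
    derivative: int = 1,
) -> np.ndarray:
    """Savitzky-Golay derivative filter with edge points dropped.

    Each surviving point is the ``derivative``-order derivative (per index
    step) of the local least-squares polynomial of order ``polyorder`` fitted
    over the centered window.  Output length shrinks by window - 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    cfg = PreprocessConfig(
        savgol_window=window, savgol_polyorder=polyorder, savgol_derivative=derivative
    )
    cfg.validate(n_points=n)
    half = (window - 1) // 2
    full = savgol_filter(x, window, polyorder, deriv=derivative, delta=1.0, axis=-1)
    return full[..., half : n - half]


def trim_grid(wavenumbers: np.ndarray, window: int) -> np.ndarray:
    half = (window - 1) // 2
    return np.asarray(wavenumbers)[half : len(wavenumbers) - half]


class Centerer:
    """Column mean centering fitted on calibration rows only."""

    def __init__(self) -> None:
        self.means_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Centerer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("cannot fit centering on an empty matrix")
        self.means_ = X.mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("Centerer not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means_.size:
            raise ValueError(
                f"column count mismatch: {X.shape[1]} vs fitted {self.means_.size}"
            )
        return X - self.means_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("Centerer not fitted")
        return np.atleast_2d(np.asarray(X, dtype=float)) + self.means_


def mean_center(X_train: np.ndarray, X_apply: np.ndarray | None = None) -> np.ndarray:
    """Center ``X_apply`` (default: the training matrix itself) by the
    column means of ``X_train``."""
    c = Centerer().fit(X_train)
    return c.transform(X_train if X_apply is None else X_apply)


def preprocess_chain(
    X: np.ndarray, wavenumbers: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Apply SNV then the Savitzky-Golay derivative to every spectrum.

    Mean centering is *not* applied here: its mean must come from the
    calibration rows only and is handled inside the PLS fit.  Returns the
    transformed matrix and the surviving wavenumber grid.
    """
    if config is None:
        config = PreprocessConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    config.validate(n_points=X.shape[1])
    wn = np.asarray(wavenumbers, dtype=float)

    def _snv(M):
        return snv(M) if config.apply_snv else M

    def _sg(M, grid):
        if not config.apply_savgol:
            return M, grid
        out = savgol(
            M,
            window=config.savgol_window,
            polyorder=config.savgol_polyorder,
            derivative=config.savgol_derivative,
        )
        return out, trim_grid(grid, config.savgol_window)

    if config.snv_first:
        X = _snv(X)
        X, wn = _sg(X, wn)
    else:
        X, wn = _sg(X, wn)
        X = _snv(X)
    return X, wn
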