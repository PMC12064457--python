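"""Deterministic spectral conditioning.

The chain applied to every replicate-averaged, water-subtracted spectrum:

1. repeated Savitzky-Golay smoothing (``sg_passes`` passes, derivative 0),
2. one Savitzky-Golay first-derivative pass for baseline correction,
3. standard normal variate (SNV) row normalisation.

Savitzky-Golay filtering is local least-squares polynomial fitting expressed
as a convolution; with a second-degree polynomial and derivative 0 it smooths
without distorting band shapes of degree <= 2, and with derivative 1 it
removes additive baselines.  SNV removes the multiplicative scatter and
offset differences that uncontrolled effective path length introduces in
ATR measurements of liquids.

Derivatives are reported with respect to the *wavenumber* axis: on the
descending storage convention the index-space derivative is negated once per
derivative order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .errors import DegenerateSpectrumError, ParameterError, SizeError
from .spectra import SpectraSet

__all__ = [
    "PreprocConfig",
    "savgol_coefficients",
    "savgol_apply",
    "snv",
    "preprocess_chain",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the deterministic preprocessing chain.

    Defaults follow the study protocol: ten smoothing passes, one
    first-derivative pass with a second-degree polynomial, then SNV.  The
    window length is not fixed by the protocol; 11 points is the package
    default.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    sg_passes: int = 10
    derivative_order: int = 1
    snv_enabled: bool = True
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ParameterError("sg_window must be odd and > sg_polyorder")
        if self.sg_passes < 0:
            raise ParameterError("sg_passes must be >= 0")
        if self.derivative_order not in (0, 1, 2):
            raise ParameterError("derivative_order must be in {0, 1, 2}")
        if self.snv_ddof not in (0, 1):
            raise ParameterError("snv_ddof must be 0 or 1")


def savgol_coefficients(window: int, polyorder: int, deriv: int = 0,
                        spacing: float = 1.0) -> np.ndarray:
    """Savitzky-Golay weights, dot-product ordered.

    ``weights @ y[window]`` equals the ``deriv``-th derivative of the local
    least-squares polynomial of degree ``polyorder`` evaluated at the window
    centre, scaled by ``spacing**-deriv``.
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError("window must be odd and positive")
    if polyorder >= window:
        raise ParameterError("polyorder must be < window")
    if deriv > polyorder:
        raise ParameterError("deriv must be <= polyorder")
    return savgol_coeffs(window, polyorder, deriv=deriv, delta=spacing, use="dot")


def savgol_apply(y: np.ndarray, window: int, polyorder: int, deriv: int = 0,
                 spacing: float = 1.0, descending: bool = True) -> np.ndarray:
    """Apply a Savitzky-Golay pass to one or more spectra (last axis).

    Edges are handled by fitting the polynomial to the first/last full
    window (polynomial extension), so any signal of degree <= ``polyorder``
    is reproduced exactly everywhere.  With ``descending=True`` derivatives
    are given with respect to the wavenumber axis, i.e. negated once per
    derivative order relative to index space.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] < window:
        raise SizeError(f"vector length {y.shape[-1]} < window {window}")
    out = savgol_filter(y, window, polyorder, deriv=deriv, delta=spacing,
                        mode="interp", axis=-1)
    if descending and deriv % 2 == 1:
        out = -out
    return out


def snv(row: np.ndarray, ddof: int = 1, patient_id: str = "") -> np.ndarray:
    """Standard normal variate: centre a spectrum and scale to unit sd.

    Invariant to multiplicative scatter and additive offset, which is the
    reason it is applied to path-length-uncontrolled ATR liquid spectra.
    """
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise SizeError("SNV needs at least 2 points")
    sd = row.std(ddof=ddof)
    if sd <= 0.0:
        raise DegenerateSpectrumError(
            f"zero-variance spectrum{f' for patient {patient_id}' if patient_id else ''}"
        )
    return (row - row.mean()) / sd


def preprocess_chain(sset: SpectraSet, config: PreprocConfig = PreprocConfig()) -> SpectraSet:
    """Run the full conditioning chain on every row of a SpectraSet.

    Order: ``sg_passes`` smoothing passes, then one derivative pass (skipped
    when ``derivative_order`` is 0, so the zero-work configuration is the
    identity), then SNV.  Deterministic; labels and ids unchanged.
    """
    X = sset.matrix.copy()
    spacing = sset.grid.spacing
    for _ in range(config.sg_passes):
        X = savgol_apply(X, config.sg_window, config.sg_polyorder, deriv=0,
                         spacing=spacing)
    if config.derivative_order > 0:
        X = savgol_apply(X, config.sg_window, config.sg_polyorder,
                         deriv=config.derivative_order, spacing=spacing)
    if config.snv_enabled:
        X = np.vstack([
            snv(X[i], ddof=config.snv_ddof, patient_id=sset.patient_ids[i])
            for i in range(X.shape[0])
        ])
    return sset.with_matrix(X)
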