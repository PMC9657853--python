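"""Model evaluation: RMSE, R-squared, band-windowed Pearson correlation, reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError, ParameterError
from .hsi_io import MeanSpectrum
from .models import ResponseVector

__all__ = [
    "CorrelationResult",
    "rmse",
    "r_squared",
    "cross_correlation",
    "build_report",
    "REPORT_COLUMNS",
]

#: Blue-green window where leaf and solution reflectance co-vary.
DEFAULT_CORRELATION_WINDOW_NM = (390.57, 554.48)

REPORT_COLUMNS = [
    "cultivar",
    "system",
    "response_name",
    "method",
    "R2",
    "RMSE",
    "n_samples",
    "h_used",
    "best",
]


@dataclass(frozen=True)
class CorrelationResult:
    r_corr: float
    band_window_nm: tuple
    leaf_label: str = ""
    solution_label: str = ""

    def __post_init__(self) -> None:
        if abs(self.r_corr) > 1 + 1e-12:
            raise ParameterError(f"|r_corr| > 1: {self.r_corr}")


def _paired(measured: ResponseVector, predicted: ResponseVector):
    y, yhat = measured.y, predicted.y
    if y.size != yhat.size:
        raise ContractError(f"length mismatch: measured {y.size}, predicted {yhat.size}")
    return y, yhat


def rmse(measured: ResponseVector, predicted: ResponseVector) -> float:
    """sqrt(mean squared prediction error)."""
    y, yhat = _paired(measured, predicted)
    if y.size < 1:
        raise ParameterError("need at least one sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(measured: ResponseVector, predicted: ResponseVector) -> float:
    """1 - SS_resid / SS_total; can be negative for models worse than the mean."""
    y, yhat = _paired(measured, predicted)
    if y.size < 2:
        raise ParameterError("need at least two samples for R^2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateInputError("zero-variance measured response")
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def cross_correlation(
    x: MeanSpectrum,
    y: MeanSpectrum,
    window_nm: tuple = DEFAULT_CORRELATION_WINDOW_NM,
) -> CorrelationResult:
    """Zero-lag Pearson correlation of two spectra inside a wavelength window.

    Bands are chosen by wavelength (inclusive endpoints), so non-uniform grids
    behave correctly.
    """
    if x.grid.n_bands != y.grid.n_bands or not np.allclose(
        x.grid.wavelengths_nm, y.grid.wavelengths_nm
    ):
        raise ContractError("spectra must share a wavelength grid")
    lo, hi = float(window_nm[0]), float(window_nm[1])
    wl = x.grid.wavelengths_nm
    sel = (wl >= lo) & (wl <= hi)
    if sel.sum() < 3:
        raise ParameterError(f"fewer than 3 bands in window [{lo}, {hi}] nm")
    a = x.values[sel] - x.values[sel].mean()
    b = y.values[sel] - y.values[sel].mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise DegenerateInputError("flat spectrum inside the correlation window")
    r = float(np.clip((a @ b) / denom, -1.0, 1.0))
    return CorrelationResult(
        r_corr=r, band_window_nm=(lo, hi), leaf_label=y.label, solution_label=x.label
    )


def build_report(fits: list) -> pd.DataFrame:
    """Assemble the per-(cultivar, system, response, method) accuracy table.

    ``fits`` rows are dicts with keys cultivar, system, response_name, method,
    measured, predicted (ResponseVector), h_used. The best method per
    (cultivar, system, response) is flagged by highest R2; RMSE breaks ties.
    """
    rows = []
    seen = set()
    for fit in fits:
        key = (fit["cultivar"], fit["system"], fit["response_name"], fit["method"])
        if key in seen:
            raise ContractError(f"duplicate report row {key}")
        seen.add(key)
        measured, predicted = fit["measured"], fit["predicted"]
        rows.append(
            {
                "cultivar": fit["cultivar"],
                "system": fit["system"],
                "response_name": fit["response_name"],
                "method": fit["method"],
                "R2": r_squared(measured, predicted),
                "RMSE": rmse(measured, predicted),
                "n_samples": int(measured.y.size),
                "h_used": int(fit.get("h_used", 0)),
                "best": False,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if report.empty:
        return report
    for _, group in report.groupby(["cultivar", "system", "response_name"], sort=False):
        ranked = group.sort_values(["R2", "RMSE"], ascending=[False, True], kind="mergesort")
        report.loc[ranked.index[0], "best"] = True
    return report
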