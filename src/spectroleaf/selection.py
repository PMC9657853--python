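"""Waveband selection: FDR-region representatives, |beta| peaks, VIP scores.

All three strategies reduce a per-band importance curve to a short, sorted,
deduplicated list of band indices so downstream models see a common shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .models import PLSModel, RegressionCoefficients

__all__ = [
    "VIPScores",
    "WavebandSelection",
    "compute_vip",
    "select_by_vip",
    "select_by_coefficients",
    "select_by_fdr",
    "selection_to_csv",
]


@dataclass
class VIPScores:
    """Variable-importance-in-projection scores of a fitted PLS model."""

    scores: np.ndarray
    band_nm: np.ndarray
    h_used: int
    source: str = "PLSR"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if np.any(s < 0):
            raise ParameterError("VIP scores must be non-negative")
        self.scores = s


@dataclass
class WavebandSelection:
    method: str  # "FDR" | "COEF" | "VIP"
    band_indices: np.ndarray  # 0-based, strictly increasing
    band_nm: np.ndarray
    scores_at_selection: np.ndarray
    warning: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.band_indices, dtype=int)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ParameterError("selected band indices must be strictly increasing")
        self.band_indices = idx
        self.band_nm = np.asarray(self.band_nm, dtype=float)
        self.scores_at_selection = np.asarray(self.scores_at_selection, dtype=float)

    @property
    def is_empty(self) -> bool:
        return self.band_indices.size == 0


def compute_vip(model: PLSModel) -> VIPScores:
    """VIP_j = sqrt( p * sum_i SS_i (w_ji/||w_i||)^2 / sum_i SS_i ).

    ``SS_i = b_i^2 t_i' t_i`` is the response sum of squares captured by
    component i. By construction the squared scores average to 1.
    """
    p = model.W.shape[0]
    ss = model.b**2 * (model.T**2).sum(axis=0)
    total = float(ss.sum())
    if total <= 0:
        raise DegenerateInputError("no component captures any response variance")
    w_norm2 = (model.W**2).sum(axis=0)
    w_norm2[w_norm2 == 0] = 1.0
    scores = np.sqrt(p * (model.W**2 / w_norm2) @ ss / total)
    return VIPScores(scores=scores, band_nm=model.band_nm.copy(), h_used=model.h)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices where the curve is >= both neighbours (edges use one neighbour)."""
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        return np.array([0])
    ge_left = np.empty(v.size, dtype=bool)
    ge_right = np.empty(v.size, dtype=bool)
    ge_left[0], ge_left[1:] = True, v[1:] >= v[:-1]
    ge_right[-1], ge_right[:-1] = True, v[:-1] >= v[1:]
    return np.nonzero(ge_left & ge_right)[0]


def _top_k(candidates: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Top-k candidate indices by score; ties resolved toward lower wavelength."""
    order = sorted(candidates, key=lambda i: (-scores[i], i))
    return np.array(sorted(order[:k]), dtype=int)


def select_by_vip(vip: VIPScores, threshold: float = 1.0, max_bands: int = 6) -> WavebandSelection:
    """Bands with VIP strictly above ``threshold``, thinned to local maxima.

    If more than ``max_bands`` maxima survive, the top ``max_bands`` by score
    are kept. An empty selection is returned flagged, not raised.
    """
    peaks = _local_maxima(vip.scores)
    candidates = peaks[vip.scores[peaks] > threshold]
    if candidates.size == 0:
        return WavebandSelection(
            method="VIP",
            band_indices=np.array([], dtype=int),
            band_nm=np.array([]),
            scores_at_selection=np.array([]),
            warning=f"no band exceeds VIP threshold {threshold}",
        )
    chosen = _top_k(candidates, vip.scores, max_bands)
    return WavebandSelection(
        method="VIP",
        band_indices=chosen,
        band_nm=vip.band_nm[chosen],
        scores_at_selection=vip.scores[chosen],
    )


def select_by_coefficients(coeffs: RegressionCoefficients, k: int) -> WavebandSelection:
    """Top-k local maxima of |beta| over a full-spectrum model."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    mag = np.abs(coeffs.beta)
    peaks = _local_maxima(mag)
    warning = ""
    if k > peaks.size:
        warning = f"requested {k} bands but |beta| has only {peaks.size} local maxima"
        k = peaks.size
    chosen = _top_k(peaks, mag, k)
    return WavebandSelection(
        method="COEF",
        band_indices=chosen,
        band_nm=coeffs.band_nm[chosen],
        scores_at_selection=mag[chosen],
        warning=warning,
    )


def select_by_fdr(regions: list, grid) -> WavebandSelection:
    """One band per dynamic region: the grid band nearest its representative."""
    if not regions:
        return WavebandSelection(
            method="FDR",
            band_indices=np.array([], dtype=int),
            band_nm=np.array([]),
            scores_at_selection=np.array([]),
            warning="no dynamic regions supplied",
        )
    idx = []
    mags = {}
    for region in regions:
        b = grid.nearest_band(region.representative_nm)
        idx.append(b)
        mags[b] = region.peak_magnitude
    chosen = np.array(sorted(set(idx)), dtype=int)
    return WavebandSelection(
        method="FDR",
        band_indices=chosen,
        band_nm=grid.wavelengths_nm[chosen],
        scores_at_selection=np.array([mags[b] for b in chosen]),
    )


def selection_to_csv(selections: list, path: str) -> None:
    import pandas as pd

    rows = []
    for sel in selections:
        for i in range(sel.band_indices.size):
            rows.append(
                {
                    "method": sel.method,
                    "band_idx": int(sel.band_indices[i]),
                    "band_nm": float(sel.band_nm[i]),
                    "score": float(sel.scores_at_selection[i]),
                }
            )
    pd.DataFrame(rows, columns=["method", "band_idx", "band_nm", "score"]).to_csv(
        path, index=False, float_format="%.9g"
    )
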