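"""Spectral preprocessing: smoothing, normalization, derivatives, region detection.

The processing chain mirrors common chemometric practice: a centred moving
average tames sensor noise, the spectrum is min-max normalized (NDS), the
first-order derivative with respect to wavelength (FDR, units 1/nm) is taken,
and contiguous stretches of large |FDR| are reported as dynamic waveband
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .hsi_io import MeanSpectrum, WavelengthGrid

__all__ = [
    "DerivativeSpectrum",
    "WavebandRegion",
    "smooth_moving_average",
    "compute_nds",
    "compute_fdr",
    "detect_dynamic_regions",
    "regions_to_csv",
]


@dataclass
class DerivativeSpectrum:
    """d(reflectance)/d(wavelength) on a shared grid, in 1/nm."""

    values: np.ndarray
    grid: WavelengthGrid
    source_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != self.grid.n_bands:
            raise ParameterError("derivative length does not match grid")
        if not np.all(np.isfinite(v)):
            raise ParameterError("derivative contains non-finite values")
        self.values = v


@dataclass(frozen=True)
class WavebandRegion:
    """A contiguous run of bands with significant spectral dynamics."""

    start_nm: float
    end_nm: float
    start_idx: int  # 0-based, inclusive
    end_idx: int  # 0-based, inclusive
    representative_nm: float
    peak_magnitude: float

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ParameterError("region start_nm must be < end_nm")
        if not (self.start_nm <= self.representative_nm <= self.end_nm):
            raise ParameterError("representative_nm outside region bounds")

    @property
    def width_bands(self) -> int:
        return self.end_idx - self.start_idx + 1

    def contains_nm(self, wavelength_nm: float) -> bool:
        return self.start_nm <= wavelength_nm <= self.end_nm


def smooth_moving_average(spectrum: MeanSpectrum, window: int = 13) -> MeanSpectrum:
    """Centred moving average with a window that shrinks at the edges.

    Edge windows are truncated rather than padded, so no data is invented at
    the blue or NIR extremes; constants pass through unchanged.
    """
    n = spectrum.grid.n_bands
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    if window > n:
        raise ParameterError(f"window {window} exceeds the {n}-band spectrum")
    half = window // 2
    v = spectrum.values
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return MeanSpectrum(values=out, grid=spectrum.grid, label=spectrum.label)


def compute_nds(spectrum: MeanSpectrum) -> MeanSpectrum:
    """Per-spectrum min-max normalization to [0, 1].

    Affine-invariant: ``a*v + b`` (a > 0) yields the same output as ``v``.
    """
    v = spectrum.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise DegenerateInputError("flat spectrum: min-max normalization undefined")
    return MeanSpectrum(values=(v - vmin) / (vmax - vmin), grid=spectrum.grid, label=spectrum.label)


def compute_fdr(nds: MeanSpectrum) -> DerivativeSpectrum:
    """First-order derivative on the actual (possibly non-uniform) grid.

    Central differences ``(v[b+1]-v[b-1])/(wl[b+1]-wl[b-1])`` at interior
    bands, one-sided differences at both ends; exact for affine spectra.
    """
    n = nds.grid.n_bands
    if n < 3:
        raise ParameterError("need at least 3 bands for a derivative")
    v = nds.values
    wl = nds.grid.wavelengths_nm
    out = np.empty(n)
    out[1:-1] = (v[2:] - v[:-2]) / (wl[2:] - wl[:-2])
    out[0] = (v[1] - v[0]) / (wl[1] - wl[0])
    out[-1] = (v[-1] - v[-2]) / (wl[-1] - wl[-2])
    return DerivativeSpectrum(values=out, grid=nds.grid, source_label=nds.label)


def detect_dynamic_regions(
    fdr: DerivativeSpectrum,
    threshold_factor: float = 1.0,
    min_width_bands: int = 5,
    merge_gap_bands: int = 3,
    search_max_nm: float = 850.0,
) -> list:
    """Find contiguous runs of large |FDR| below ``search_max_nm``.

    The threshold is ``mean(|FDR|) + threshold_factor * SD(|FDR|)`` over the
    searched bands. Runs separated by at most ``merge_gap_bands`` are merged,
    then runs narrower than ``min_width_bands`` are dropped. Each region's
    representative waveband is its |FDR| argmax.
    """
    if threshold_factor <= 0 or min_width_bands <= 0 or merge_gap_bands < 0:
        raise ParameterError("detection parameters must be positive")
    wl = fdr.grid.wavelengths_nm
    searched = wl <= search_max_nm
    if not searched.any():
        return []
    cap = int(np.nonzero(searched)[0][-1]) + 1
    mag = np.abs(fdr.values[:cap])
    tau = float(mag.mean() + threshold_factor * mag.std())
    above = mag >= tau
    if tau <= 0 or not above.any():
        return []

    # Contiguous runs of above-threshold bands as (start, end) inclusive.
    runs = []
    idx = np.flatnonzero(above)
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((int(run_start), int(prev)))
            run_start = i
        prev = i
    runs.append((int(run_start), int(prev)))

    # Merge runs whose gaps are small, then enforce the width floor.
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] - 1 <= merge_gap_bands:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    kept = [(s, e) for s, e in merged if e - s + 1 >= min_width_bands]

    regions = []
    for s, e in kept:
        peak = s + int(np.argmax(mag[s : e + 1]))
        regions.append(
            WavebandRegion(
                start_nm=float(wl[s]),
                end_nm=float(wl[e]),
                start_idx=s,
                end_idx=e,
                representative_nm=float(wl[peak]),
                peak_magnitude=float(mag[peak]),
            )
        )
    return regions


def regions_to_csv(regions: list, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "start_nm": r.start_nm,
                "end_nm": r.end_nm,
                "start_idx": r.start_idx,
                "end_idx": r.end_idx,
                "representative_nm": r.representative_nm,
                "peak_magnitude": r.peak_magnitude,
            }
            for r in regions
        ]
    ).to_csv(path, index=False, float_format="%.9g")
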