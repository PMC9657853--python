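"""ENVI cube I/O, ROI spectra, and sample-table handling.

The supported ENVI dialect is deliberately narrow: BIL or BIP interleave,
32-bit little-endian IEEE float (data type 4), wavelength list in nanometres.
Anything else is rejected with a clear error rather than guessed at.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError, EnviFormatError, EnviIOError, ParameterError

__all__ = [
    "WavelengthGrid",
    "SpectralCube",
    "MeanSpectrum",
    "SAMPLE_TABLE_COLUMNS",
    "read_envi_cube",
    "write_envi_cube",
    "roi_mean_spectrum",
    "nir_threshold_mask",
    "read_sample_table",
    "write_sample_table",
    "validate_sample_table",
]

#: Wavelength sanity bounds for the instrument family this package targets.
_WL_MIN_NM = 380.0
_WL_MAX_NM = 1100.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 1:
            raise ParameterError("wavelength grid must be a non-empty 1-D vector")
        if not np.all(np.isfinite(wl)):
            raise ParameterError("wavelength grid contains non-finite values")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN_NM or wl[-1] > _WL_MAX_NM:
            raise ParameterError(
                f"wavelengths must lie in [{_WL_MIN_NM}, {_WL_MAX_NM}] nm; got "
                f"[{wl[0]:.2f}, {wl[-1]:.2f}]"
            )

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.size)

    @classmethod
    def linspace(cls, start_nm: float, end_nm: float, n_bands: int) -> "WavelengthGrid":
        return cls(np.linspace(start_nm, end_nm, n_bands))

    def nearest_band(self, target_nm: float) -> int:
        """0-based index of the band centre closest to ``target_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - target_nm)))


@dataclass
class SpectralCube:
    """3-D reflectance array (rows x cols x bands) with grid and ROI mask."""

    reflectance: np.ndarray
    grid: WavelengthGrid
    roi_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance)
        if refl.ndim != 3:
            raise ParameterError(f"reflectance must be 3-D, got shape {refl.shape}")
        if refl.shape[2] != self.grid.n_bands:
            raise ContractError(
                f"band dimension {refl.shape[2]} != grid.n_bands {self.grid.n_bands}"
            )
        self.reflectance = refl
        if self.roi_mask is None:
            self.roi_mask = np.ones(refl.shape[:2], dtype=bool)
        else:
            mask = np.asarray(self.roi_mask, dtype=bool)
            if mask.shape != refl.shape[:2]:
                raise ContractError(
                    f"roi_mask shape {mask.shape} != spatial shape {refl.shape[:2]}"
                )
            self.roi_mask = mask

    @property
    def shape(self) -> tuple:
        return self.reflectance.shape


@dataclass
class MeanSpectrum:
    """One reflectance value per band, typically an ROI average."""

    values: np.ndarray
    grid: WavelengthGrid
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ParameterError("spectrum values must be 1-D")
        if v.size != self.grid.n_bands:
            raise ContractError(f"{v.size} values for {self.grid.n_bands} bands")
        if not np.all(np.isfinite(v)):
            raise ParameterError("spectrum contains non-finite values")
        self.values = v


# --------------------------------------------------------------------------
# ENVI cube I/O
# --------------------------------------------------------------------------

_SUPPORTED_INTERLEAVES = ("bil", "bip")
_ENVI_DTYPE = np.dtype("<f4")  # ENVI data type 4


def _binary_path(header_path: str) -> str:
    if header_path.endswith(".hdr"):
        return header_path[:-4]
    return header_path + ".img"


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict = {}
    # Collapse brace-delimited multi-line values onto single lines first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_cube(header_path: str) -> SpectralCube:
    """Read an ENVI header + raw binary into a :class:`SpectralCube`.

    The returned cube has ``roi_mask`` all-true; reflectance values are
    taken verbatim from the file (no scaling).
    """
    if not os.path.exists(header_path):
        raise EnviIOError(f"header not found: {header_path}")
    with open(header_path, "r") as fh:
        fields = _parse_envi_header(fh.read())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise EnviFormatError(f"ENVI header missing required field '{key}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    data_type = int(fields["data type"])
    byte_order = int(fields.get("byte order", "0"))

    if data_type != 4:
        raise EnviFormatError(f"unsupported ENVI data type {data_type}; only 4 (float32) is supported")
    if byte_order != 0:
        raise EnviFormatError(f"unsupported byte order {byte_order}; only 0 (little-endian)")
    if interleave not in _SUPPORTED_INTERLEAVES:
        raise EnviFormatError(
            f"unsupported interleave '{interleave}'; supported: {_SUPPORTED_INTERLEAVES}"
        )
    if "wavelength" not in fields:
        raise EnviFormatError("ENVI header has no wavelength list")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise EnviFormatError("malformed wavelength list (expected brace-delimited values)")
    wavelengths = np.array([float(tok) for tok in wl_text[1:-1].split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"wavelength list has {wavelengths.size} entries for {bands} bands"
        )

    bin_path = _binary_path(header_path)
    if not os.path.exists(bin_path):
        raise EnviIOError(f"companion binary not found: {bin_path}")
    expected = lines * samples * bands * _ENVI_DTYPE.itemsize
    actual = os.path.getsize(bin_path)
    if actual != expected:
        raise EnviIOError(
            f"binary size mismatch for {bin_path}: expected {expected} bytes "
            f"({lines}x{samples}x{bands} float32), found {actual}"
        )

    raw = np.fromfile(bin_path, dtype=_ENVI_DTYPE)
    if interleave == "bip":
        refl = raw.reshape(lines, samples, bands)
    else:  # bil: (lines, bands, samples)
        refl = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    return SpectralCube(reflectance=refl, grid=WavelengthGrid(wavelengths))


def write_envi_cube(cube: SpectralCube, header_path: str, interleave: str = "bil") -> None:
    """Write ``cube`` as an ENVI header + float32 raw binary.

    The ROI mask is not serialized. ``read_envi_cube(write_envi_cube(...))``
    is the identity for float32 reflectance arrays.
    """
    interleave = interleave.lower()
    if interleave not in _SUPPORTED_INTERLEAVES:
        raise ParameterError(f"interleave must be one of {_SUPPORTED_INTERLEAVES}")
    rows, cols, bands = cube.reflectance.shape
    wl = ", ".join(f"{w:.9g}" for w in cube.grid.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {spectroleaf export}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    data = np.ascontiguousarray(cube.reflectance, dtype=_ENVI_DTYPE)
    if interleave == "bil":
        data = np.ascontiguousarray(data.transpose(0, 2, 1))
    try:
        with open(header_path, "w") as fh:
            fh.write(header)
        data.tofile(_binary_path(header_path))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise EnviIOError(f"cannot write ENVI pair at {header_path}: {exc}") from exc


# --------------------------------------------------------------------------
# ROI operations
# --------------------------------------------------------------------------

def roi_mean_spectrum(cube: SpectralCube, label: str = "") -> MeanSpectrum:
    """Per-band arithmetic mean of the reflectance over masked pixels."""
    n_masked = int(cube.roi_mask.sum())
    if n_masked == 0:
        raise DegenerateInputError("ROI mask has no true pixels")
    values = cube.reflectance[cube.roi_mask].astype(np.float64).mean(axis=0)
    return MeanSpectrum(values=values, grid=cube.grid, label=label)


def nir_threshold_mask(cube: SpectralCube, threshold: float = 0.3, nir_nm: float = 800.0) -> np.ndarray:
    """Leaf/background mask by thresholding the band nearest ``nir_nm``.

    Vegetation is bright on the NIR plateau while background stays dark, so a
    single-band threshold separates them on this package's imagery.
    """
    band = cube.grid.nearest_band(nir_nm)
    return np.asarray(cube.reflectance[:, :, band] > threshold)


# --------------------------------------------------------------------------
# Sample tables
# --------------------------------------------------------------------------

SAMPLE_TABLE_COLUMNS = [
    "sample_id",
    "cultivar",
    "system",
    "applied_N_ppm",
    "NO3_ppm",
    "K_ppm",
    "Ca_ppm",
    "SPAD",
    "pH",
    "brix_pct",
    "fresh_weight_g",
    "dry_weight_g",
]

_TUB_TREATMENTS = {0, 50, 100, 150, 200, 250, 300, 350}
_NFT_TREATMENTS = {50, 100, 200, 400}


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check column names and value-domain invariants; return the frame."""
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ContractError(f"sample table missing columns: {missing}")
    bad_system = set(df["system"].unique()) - {"tub", "NFT"}
    if bad_system:
        raise ContractError(f"unknown system labels: {sorted(bad_system)}")
    for system, allowed in (("tub", _TUB_TREATMENTS), ("NFT", _NFT_TREATMENTS)):
        vals = set(df.loc[df["system"] == system, "applied_N_ppm"].astype(float))
        extra = vals - {float(v) for v in allowed}
        if extra:
            raise ContractError(f"invalid applied_N_ppm for {system}: {sorted(extra)}")
    for col in ("NO3_ppm", "K_ppm", "Ca_ppm"):
        if (df[col].dropna() < 0).any():
            raise ContractError(f"negative concentrations in {col}")
    ph = df["pH"].dropna()
    if ((ph <= 0) | (ph >= 14)).any():
        raise ContractError("pH outside (0, 14)")
    return df


def read_sample_table(path: str) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path))


def write_sample_table(df: pd.DataFrame, path: str) -> None:
    validate_sample_table(df)
    df.to_csv(path, index=False, float_format="%.9g")
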