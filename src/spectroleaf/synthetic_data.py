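"""Synthetic lettuce-like hyperspectral studies with known ground truth.

The generator produces leaf reflectance with realistic morphology: a low blue
plateau, a green peak near 550 nm built from opposing transitions at ~523 and
~568 nm, a sharp red edge at ~714 nm rising to the NIR plateau, and small NIR
features near 812/829 nm. Nutrient information enters through Gaussian bumps
co-located with those transitions, whose amplitudes are linear in the
(standardized) nutrient vector.

Internally each study is driven by one latent factor per spectral feature.
Nutrient responses are affine in the factors and the factor-to-amplitude map
is invertible, so a noise-free study is exactly linearly recoverable from any
full-rank band subset — which is what makes parameter-recovery and noiseless
pipeline tests meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .hsi_io import MeanSpectrum, SpectralCube, WavelengthGrid, validate_sample_table
from .preprocess import smooth_moving_average

__all__ = [
    "RESPONSES",
    "SyntheticConfig",
    "GroundTruth",
    "StudyData",
    "generate_leaf_spectrum",
    "generate_solution_spectrum",
    "generate_cube",
    "generate_study",
]

RESPONSES = [
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

# Affine response model: z = _RESPONSE_BASE + _RESPONSE_LOADINGS[:, :n_factors] @ u.
# Trends follow the qualitative behaviour of hydroponic lettuce: nitrate,
# SPAD and biomass rise with applied N, K and Ca stay roughly level, pH dips
# slightly, Brix is highest for starved plants.
_RESPONSE_BASE = np.array([0.0, 2200.0, 4200.0, 250.0, 18.0, 6.0, 11.5, 8.0, 0.5])
_RESPONSE_LOADINGS = np.array(
    [
        [350.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3000.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 400.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 60.0, 0.0, 0.0, 0.0],
        [22.0, 0.0, 0.0, 3.0, 0.0, 0.0],
        [-0.3, 0.0, 0.0, 0.0, 0.15, 0.0],
        [-5.0, 0.0, 0.0, 0.0, 0.0, 1.0],
        [80.0, 0.0, 8.0, 0.0, 0.0, 0.0],
        [4.0, 0.0, 0.0, 0.0, 0.4, 0.0],
    ]
)

_MAX_FACTORS = _RESPONSE_LOADINGS.shape[1]


def _factor_basis(t_norm: float, n_factors: int) -> np.ndarray:
    """Distinct bounded treatment-trend functions, one per latent factor."""
    t = float(t_norm)
    g = np.array(
        [
            t,
            t * t,
            np.sqrt(t),
            np.exp(-3.0 * t),
            np.cos(np.pi * t),
            np.log1p(9.0 * t) / np.log(10.0),
        ]
    )
    return g[:n_factors]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study generator.

    ``effect_matrix`` maps the standardized nutrient vector to per-feature
    bump amplitudes; the default is derived so amplitudes are an invertible
    linear image of the latent factors.
    """

    n_bands: int = 462
    wl_start_nm: float = 390.57
    wl_end_nm: float = 1008.6
    system: str = "tub"
    cultivars: tuple = ("Black Seeded Simpson", "Parris Island", "Rex RZ", "Tacitus")
    treatments_ppm: tuple = (0, 50, 100, 150, 200, 250, 300, 350)
    n_replicates: int = 4
    noise_sd: float = 0.01
    factor_sd: float = 0.15
    feature_centers_nm: tuple = (410.0, 523.0, 568.0, 714.0, 812.0, 829.0)
    transition_scales_nm: tuple = (3.0, 4.0, 4.0, 20.0, 2.5, 2.5)
    base_amplitudes: tuple = (0.09, 0.12, -0.10, 0.38, 0.10, -0.10)
    bump_sd_nm: float = 5.0
    amp_gains: tuple = (0.05, 0.09, 0.08, 0.10, 0.11, 0.11)
    effect_matrix: np.ndarray = None  # type: ignore[assignment]
    # Per-cultivar optics are identical by default: systematic amplitude or
    # offset differences between cultivars bias pooled regressions, which
    # recovery tests rely on. Dial these up for more heterogeneous studies.
    cultivar_amp_scale: tuple = (1.0, 1.0, 1.0, 1.0)
    cultivar_offset: tuple = (0.0, 0.0, 0.0, 0.0)
    smoothing_window: int = 13
    solution_window_nm: tuple = (390.57, 554.48)
    water_baseline: float = 0.03
    cube_shape: tuple = None  # type: ignore[assignment]
    pixel_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_start_nm >= self.wl_end_nm:
            raise ParameterError("wl_start_nm must be < wl_end_nm")
        if self.n_bands < 8:
            raise ParameterError("need at least 8 bands")
        if self.noise_sd < 0 or self.factor_sd < 0 or self.pixel_noise_sd < 0:
            raise ParameterError("noise levels must be >= 0")
        nf = len(self.feature_centers_nm)
        if nf < 1 or nf > _MAX_FACTORS:
            raise ParameterError(f"1..{_MAX_FACTORS} feature centers supported")
        if len(self.transition_scales_nm) != nf or len(self.base_amplitudes) != nf:
            raise ParameterError("per-feature parameter lists must match feature_centers_nm")
        for c in self.feature_centers_nm:
            if not (self.wl_start_nm < c < self.wl_end_nm):
                raise ParameterError(f"feature center {c} nm outside the grid")
        if len(self.cultivar_amp_scale) < len(self.cultivars) or len(self.cultivar_offset) < len(
            self.cultivars
        ):
            raise ParameterError("cultivar variation lists shorter than cultivar list")
        self._finalize_model()

    # -- derived model pieces ------------------------------------------------

    def _finalize_model(self) -> None:
        nf = self.n_factors
        max_t = float(max(self.treatments_ppm))
        basis = np.array([_factor_basis(t / max_t, nf) for t in self.treatments_ppm])
        self.factor_mean = basis.mean(axis=0)  # study-average latent factors
        loadings = _RESPONSE_LOADINGS[:, :nf]
        spread = basis.std(axis=0)
        self.response_scale = np.maximum(np.abs(loadings) @ np.maximum(spread, 0.05), 1e-3)
        self.response_ref = _RESPONSE_BASE + loadings @ self.factor_mean

        mix = np.eye(nf)
        mix[:, 0] += 0.25  # every feature responds to the nitrogen-status factor
        for f in range(nf):
            mix[f, (f + 1) % nf] += 0.15
        self.factor_to_amplitude = np.diag(np.asarray(self.amp_gains[:nf])) @ mix
        if np.linalg.cond(self.factor_to_amplitude) > 1e6:
            raise ParameterError("factor-to-amplitude map is ill-conditioned")

        if self.effect_matrix is None:
            loadings_std = loadings / self.response_scale[:, None]
            self.effect_matrix = self.factor_to_amplitude @ np.linalg.pinv(loadings_std)
        else:
            self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
            if self.effect_matrix.shape != (nf, len(RESPONSES)):
                raise ParameterError(
                    f"effect_matrix must be {nf}x{len(RESPONSES)}, got {self.effect_matrix.shape}"
                )

    @property
    def n_factors(self) -> int:
        return len(self.feature_centers_nm)

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.linspace(self.wl_start_nm, self.wl_end_nm, self.n_bands)

    def standardize(self, nutrients: np.ndarray) -> np.ndarray:
        return (np.asarray(nutrients, dtype=float) - self.response_ref) / self.response_scale

    @classmethod
    def tub_default(cls, **overrides) -> "SyntheticConfig":
        return cls(**overrides)

    @classmethod
    def nft_default(cls, **overrides) -> "SyntheticConfig":
        params = dict(
            system="NFT",
            treatments_ppm=(50, 100, 200, 400),
            feature_centers_nm=(410.0, 521.0, 572.0, 714.0),
            transition_scales_nm=(3.0, 4.0, 4.0, 20.0),
            base_amplitudes=(0.09, 0.12, -0.10, 0.38),
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruth:
    """Everything a recovery test needs: factors, betas, informative bands."""

    informative_band_indices: np.ndarray
    informative_band_nm: np.ndarray
    true_beta: dict  # response_name -> coefficient vector over informative bands
    true_intercept: dict
    factors: pd.DataFrame  # per-sample latent factors
    nutrients: pd.DataFrame  # per-sample continuous nutrient vector

    def to_json(self, path: str) -> None:
        import json

        payload = {
            "informative_band_indices": self.informative_band_indices.tolist(),
            "informative_band_nm": self.informative_band_nm.tolist(),
            "true_beta": {k: v.tolist() for k, v in self.true_beta.items()},
            "true_intercept": self.true_intercept,
            "factors": self.factors.to_dict(orient="list"),
            "nutrients": self.nutrients.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            informative_band_indices=np.asarray(payload["informative_band_indices"], dtype=int),
            informative_band_nm=np.asarray(payload["informative_band_nm"], dtype=float),
            true_beta={k: np.asarray(v) for k, v in payload["true_beta"].items()},
            true_intercept=payload["true_intercept"],
            factors=pd.DataFrame(payload["factors"]),
            nutrients=pd.DataFrame(payload["nutrients"]),
        )


@dataclass
class StudyData:
    samples: pd.DataFrame
    spectra: list  # MeanSpectrum per samples row
    solution_spectra: dict  # applied_N_ppm -> MeanSpectrum
    ground_truth: GroundTruth
    config: SyntheticConfig
    cubes: dict = field(default_factory=dict)  # sample_id -> SpectralCube


# --------------------------------------------------------------------------
# Spectral shapes
# --------------------------------------------------------------------------

def _baseline(wl: np.ndarray, offset: float = 0.0) -> np.ndarray:
    # Blue plateau + gentle broad green Gaussian + slow red-edge ramp; the
    # sharp transitions live in the features, not here.
    return (
        0.08
        + 0.04 * np.exp(-((wl - 550.0) ** 2) / (2 * 60.0**2))
        + 0.06 * _sigmoid((wl - 700.0) / 45.0)
        + offset
    )


def _feature_steps(wl: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, s, a in zip(cfg.feature_centers_nm, cfg.transition_scales_nm, cfg.base_amplitudes):
        out += a * _sigmoid((wl - c) / s)
    return out


def _bump_shapes(wl: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """(n_bands, n_features) unit-amplitude Gaussian bumps at the centers."""
    centers = np.asarray(cfg.feature_centers_nm)
    return np.exp(-((wl[:, None] - centers[None, :]) ** 2) / (2 * cfg.bump_sd_nm**2))


def _leaf_values(nutrients: np.ndarray, cfg: SyntheticConfig, cultivar_idx: int) -> np.ndarray:
    """Noise-free leaf reflectance for one nutrient vector."""
    nutrients = np.asarray(nutrients, dtype=float).ravel()
    if nutrients.size != len(RESPONSES):
        raise ContractError(
            f"nutrient vector must have {len(RESPONSES)} entries ({RESPONSES}), got {nutrients.size}"
        )
    wl = cfg.grid.wavelengths_nm
    amp_delta = cfg.effect_matrix @ cfg.standardize(nutrients)
    scale = cfg.cultivar_amp_scale[cultivar_idx]
    values = (
        _baseline(wl, cfg.cultivar_offset[cultivar_idx])
        + scale * _feature_steps(wl, cfg)
        + scale * (_bump_shapes(wl, cfg) @ amp_delta)
    )
    return values


def generate_leaf_spectrum(
    nutrients: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    cultivar_idx: int = 0,
    label: str = "",
) -> MeanSpectrum:
    """Leaf reflectance whose feature amplitudes are linear in the nutrients.

    Additive Gaussian noise with SD proportional to the local signal; values
    clipped to [0, 1.2].
    """
    values = _leaf_values(nutrients, cfg, cultivar_idx)
    noise = rng.standard_normal(values.size) * (cfg.noise_sd * np.abs(values))
    return MeanSpectrum(values=np.clip(values + noise, 0.0, 1.2), grid=cfg.grid, label=label)


def generate_solution_spectrum(
    applied_N_ppm: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    label: str = "",
) -> MeanSpectrum:
    """Nutrient-solution reflectance sharing the leaf blue-green shape.

    Inside the blue-green window the spectrum is the reference leaf shape
    scaled monotonically with applied N on top of a flat water baseline;
    outside the window it is the bare baseline.
    """
    if applied_N_ppm < 0:
        raise ContractError(f"applied N must be >= 0 ppm, got {applied_N_ppm}")
    wl = cfg.grid.wavelengths_nm
    ref = _leaf_values(cfg.response_ref, cfg, cultivar_idx=0)
    lo, hi = cfg.solution_window_nm
    window = (wl >= lo) & (wl <= hi)
    values = np.full(wl.size, cfg.water_baseline)
    if window.any():
        shape = ref[window] - ref[window].min()
        scale = applied_N_ppm / max(max(cfg.treatments_ppm), 1.0)
        values[window] += scale * shape
    noise = rng.standard_normal(values.size) * (cfg.noise_sd * np.abs(values))
    return MeanSpectrum(values=np.clip(values + noise, 0.0, 1.2), grid=cfg.grid, label=label)


def generate_cube(
    spectrum: MeanSpectrum,
    spatial_shape: tuple,
    pixel_noise_sd: float,
    rng: np.random.Generator,
) -> SpectralCube:
    """Expand a spectrum into a cube: elliptical leaf ROI over a dark floor."""
    rows, cols = int(spatial_shape[0]), int(spatial_shape[1])
    if rows < 1 or cols < 1:
        raise ContractError(f"spatial shape must be positive, got {spatial_shape}")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    # Semi-axes chosen so the ellipse covers ~40% of the frame.
    a, b = max(0.36 * rows, 0.5), max(0.36 * cols, 0.5)
    mask = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
    refl = np.full((rows, cols, spectrum.grid.n_bands), 0.02)
    n_masked = int(mask.sum())
    noise = rng.standard_normal((n_masked, spectrum.grid.n_bands)) * pixel_noise_sd
    refl[mask] = spectrum.values[None, :] + noise
    return SpectralCube(reflectance=refl, grid=spectrum.grid, roi_mask=mask)


# --------------------------------------------------------------------------
# Study generation
# --------------------------------------------------------------------------

def _sample_rng(cfg: SyntheticConfig, *key: int) -> np.random.Generator:
    # Keyed spawning: a sample's stream depends on its identity, not on how
    # many other samples exist, so growing the design leaves existing draws
    # untouched.
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def _ground_truth(cfg: SyntheticConfig, factors: pd.DataFrame, nutrients: pd.DataFrame) -> GroundTruth:
    grid = cfg.grid
    info_idx = np.array([grid.nearest_band(c) for c in cfg.feature_centers_nm])
    # The recovery target is defined on the same smoothed reflectance the
    # pipeline models, so smooth the unit bump shapes identically.
    bumps = _bump_shapes(grid.wavelengths_nm, cfg)
    smoothed = np.column_stack(
        [
            smooth_moving_average(MeanSpectrum(bumps[:, f], grid), cfg.smoothing_window).values
            for f in range(cfg.n_factors)
        ]
    )
    G = smoothed[info_idx, :]  # (n_info, n_features)
    H = G @ cfg.factor_to_amplitude  # latent factors -> informative-band reflectance
    loadings = _RESPONSE_LOADINGS[:, : cfg.n_factors]
    x_const = (
        _baseline(grid.wavelengths_nm)[info_idx]
        + smooth_moving_average(
            MeanSpectrum(_feature_steps(grid.wavelengths_nm, cfg), grid), cfg.smoothing_window
        ).values[info_idx]
    )
    true_beta = {}
    true_intercept = {}
    for r, name in enumerate(RESPONSES):
        beta = np.linalg.solve(H.T, loadings[r])
        true_beta[name] = beta
        y_ref = _RESPONSE_BASE[r] + float(loadings[r] @ cfg.factor_mean)
        true_intercept[name] = y_ref - float(x_const @ beta)
    return GroundTruth(
        informative_band_indices=info_idx,
        informative_band_nm=grid.wavelengths_nm[info_idx],
        true_beta=true_beta,
        true_intercept=true_intercept,
        factors=factors,
        nutrients=nutrients,
    )


def generate_study(cfg: SyntheticConfig) -> StudyData:
    """Simulate a full cultivar x treatment x replicate study.

    Returns the sample table (discrete applied-N labels), per-sample leaf
    spectra, per-treatment solution spectra, optional cubes, and ground truth.
    """
    max_t = float(max(cfg.treatments_ppm))
    nf = cfg.n_factors
    loadings = _RESPONSE_LOADINGS[:, :nf]

    rows = []
    spectra = []
    cubes = {}
    factor_rows = []
    nutrient_rows = []
    for ci, cultivar in enumerate(cfg.cultivars):
        for ti, treatment in enumerate(cfg.treatments_ppm):
            g = _factor_basis(treatment / max_t, nf)
            for rep in range(cfg.n_replicates):
                rng = _sample_rng(cfg, 0, ci, ti, rep)
                # Factor 0 tracks applied N deterministically so the discrete
                # treatment label stays an exact affine function of the
                # latents; the remaining factors carry per-sample variation.
                noise_mask = np.ones(nf)
                noise_mask[0] = 0.0
                u = g + rng.standard_normal(nf) * cfg.factor_sd * noise_mask
                z = _RESPONSE_BASE + loadings @ u
                # Concentrations cannot go negative, pH stays physical; at the
                # default noise levels these clips never trigger.
                z[1:4] = np.maximum(z[1:4], 0.0)
                z[5] = np.clip(z[5], 0.1, 13.9)
                sample_id = f"{cfg.system}-c{ci}-n{int(treatment)}-r{rep}"
                spectrum = generate_leaf_spectrum(z, cfg, rng, cultivar_idx=ci, label=sample_id)
                spectra.append(spectrum)
                if cfg.cube_shape is not None:
                    pixel_rng = np.random.default_rng(
                        np.random.SeedSequence(cfg.seed, spawn_key=(2, ci, ti, rep))
                    )
                    cubes[sample_id] = generate_cube(
                        spectrum, cfg.cube_shape, cfg.pixel_noise_sd, pixel_rng
                    )
                row = {
                    "sample_id": sample_id,
                    "cultivar": cultivar,
                    "system": cfg.system,
                    "applied_N_ppm": float(treatment),
                }
                row.update({name: float(z[r]) for r, name in enumerate(RESPONSES) if r > 0})
                rows.append(row)
                factor_rows.append({"sample_id": sample_id, **{f"u{k}": u[k] for k in range(nf)}})
                nutrient_rows.append(
                    {"sample_id": sample_id, **{name: float(z[r]) for r, name in enumerate(RESPONSES)}}
                )

    solution_spectra = {}
    for ti, treatment in enumerate(cfg.treatments_ppm):
        rng = _sample_rng(cfg, 1, ti)
        solution_spectra[float(treatment)] = generate_solution_spectrum(
            treatment, cfg, rng, label=f"solution-{int(treatment)}ppm"
        )

    samples = validate_sample_table(pd.DataFrame(rows))
    truth = _ground_truth(cfg, pd.DataFrame(factor_rows), pd.DataFrame(nutrient_rows))
    return StudyData(
        samples=samples,
        spectra=spectra,
        solution_spectra=solution_spectra,
        ground_truth=truth,
        config=cfg,
        cubes=cubes,
    )
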