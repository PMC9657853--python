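"""End-to-end orchestration: simulate -> preprocess -> select -> fit -> evaluate.

Each stage reads and writes plain-text artifacts (CSV/JSON) in a shared run
directory, so stages can be executed in isolation or via :func:`run`, which
simply composes them. All floats are serialized with enough digits to make
re-runs byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParameterError
from .evaluation import DEFAULT_CORRELATION_WINDOW_NM, build_report, cross_correlation
from .hsi_io import MeanSpectrum, WavelengthGrid, read_sample_table, write_sample_table
from .models import (
    PredictorMatrix,
    ResponseVector,
    extract_regression,
    fit_plsr,
    predict,
    select_components,
)
from .preprocess import compute_fdr, compute_nds, detect_dynamic_regions, regions_to_csv, smooth_moving_average
from .selection import compute_vip, select_by_coefficients, select_by_fdr, select_by_vip, selection_to_csv
from .synthetic_data import RESPONSES, SyntheticConfig, StudyData, generate_study

__all__ = [
    "RunConfig",
    "run",
    "stage_simulate",
    "stage_preprocess",
    "stage_select",
    "stage_fit",
    "stage_evaluate",
    "stage_report",
]

log = logging.getLogger("spectroleaf")

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    synthetic: dict = field(default_factory=dict)
    profile: str = "tub"  # "tub" | "nft"
    window: int = 13
    use_nds: bool = True
    threshold_factor: float = 1.0
    min_width_bands: int = 5
    merge_gap_bands: int = 3
    search_max_nm: float = 850.0
    methods: tuple = ("FDR", "COEF", "VIP")
    k: int = None  # type: ignore[assignment]  # bands per selection; default = feature count
    vip_threshold: float = 1.0
    selection_variance_pct: float = 95.0
    reference_response: str = "NO3_ppm"
    h: int = None  # type: ignore[assignment]  # latent variables; default 6 tub / 3 NFT
    correlation_window_nm: tuple = DEFAULT_CORRELATION_WINDOW_NM
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ParameterError("smoothing window must be odd and >= 3")
        if self.profile not in ("tub", "nft"):
            raise ParameterError("profile must be 'tub' or 'nft'")
        if self.k is None:
            self.k = 6 if self.profile == "tub" else 4
        if self.h is None:
            self.h = 6 if self.profile == "tub" else 3
        if self.k < 1:
            raise ParameterError("k must be >= 1")

    def synthetic_config(self) -> SyntheticConfig:
        params = dict(self.synthetic)
        params.setdefault("seed", self.seed)
        maker = SyntheticConfig.tub_default if self.profile == "tub" else SyntheticConfig.nft_default
        return maker(**params)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "correlation_window_nm" in raw:
            raw["correlation_window_nm"] = tuple(raw["correlation_window_nm"])
        return cls(**raw)


# --------------------------------------------------------------------------
# Artifact helpers
# --------------------------------------------------------------------------

def _spectra_path(out: str, name: str) -> str:
    return os.path.join(out, name)


def _write_spectra(path: str, spectra: list, grid: WavelengthGrid) -> None:
    frame = pd.DataFrame(
        np.vstack([s.values for s in spectra]),
        columns=[f"{w:.17g}" for w in grid.wavelengths_nm],
    )
    frame.insert(0, "sample_id", [s.label for s in spectra])
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_spectra(path: str) -> tuple:
    frame = pd.read_csv(path)
    grid = WavelengthGrid(np.array([float(c) for c in frame.columns[1:]]))
    spectra = [
        MeanSpectrum(values=row[1:].to_numpy(dtype=float), grid=grid, label=str(row.iloc[0]))
        for _, row in frame.iterrows()
    ]
    return spectra, grid


def _setup_logging(level: str) -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO), format="%(name)s %(message)s")


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: str) -> StudyData:
    os.makedirs(out, exist_ok=True)
    syn = cfg.synthetic_config()
    study = generate_study(syn)
    _write_spectra(_spectra_path(out, "spectra.csv"), study.spectra, syn.grid)
    solutions = [study.solution_spectra[t] for t in sorted(study.solution_spectra)]
    _write_spectra(_spectra_path(out, "solution_spectra.csv"), solutions, syn.grid)
    write_sample_table(study.samples, os.path.join(out, "table.csv"))
    study.ground_truth.to_json(os.path.join(out, "ground_truth.json"))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "profile": cfg.profile,
        "config": {
            f.name: _jsonable(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("simulate: %d samples, %d solution spectra", len(study.spectra), len(solutions))
    return study


def _jsonable(value):
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value


def stage_preprocess(cfg: RunConfig, out: str) -> list:
    spectra, grid = _read_spectra(_spectra_path(out, "spectra.csv"))
    smoothed = [smooth_moving_average(s, cfg.window) for s in spectra]
    _write_spectra(_spectra_path(out, "smoothed.csv"), smoothed, grid)

    grand = MeanSpectrum(
        values=np.mean([s.values for s in smoothed], axis=0), grid=grid, label="grand-mean"
    )
    curve = compute_nds(grand) if cfg.use_nds else grand
    fdr = compute_fdr(curve)
    pd.DataFrame({"wavelength_nm": grid.wavelengths_nm, "fdr": fdr.values}).to_csv(
        os.path.join(out, "fdr.csv"), index=False, float_format=_FLOAT_FMT
    )
    regions = detect_dynamic_regions(
        fdr,
        threshold_factor=cfg.threshold_factor,
        min_width_bands=cfg.min_width_bands,
        merge_gap_bands=cfg.merge_gap_bands,
        search_max_nm=cfg.search_max_nm,
    )
    regions_to_csv(regions, os.path.join(out, "regions.csv"))
    log.info("preprocess: smoothed %d spectra, detected %d regions", len(smoothed), len(regions))
    return regions


def _load_regions(out: str) -> list:
    from .preprocess import WavebandRegion

    frame = pd.read_csv(os.path.join(out, "regions.csv"))
    return [
        WavebandRegion(
            start_nm=row.start_nm,
            end_nm=row.end_nm,
            start_idx=int(row.start_idx),
            end_idx=int(row.end_idx),
            representative_nm=row.representative_nm,
            peak_magnitude=row.peak_magnitude,
        )
        for row in frame.itertuples()
    ]


def _pooled_matrix(smoothed: list, grid: WavelengthGrid) -> PredictorMatrix:
    return PredictorMatrix(
        X=np.vstack([s.values for s in smoothed]),
        band_nm=grid.wavelengths_nm,
        sample_ids=[s.label for s in smoothed],
    )


def stage_select(cfg: RunConfig, out: str) -> list:
    smoothed, grid = _read_spectra(_spectra_path(out, "smoothed.csv"))
    table = read_sample_table(os.path.join(out, "table.csv"))
    regions = _load_regions(out)

    selections = []
    if "FDR" in cfg.methods:
        selections.append(select_by_fdr(regions, grid))
    if {"COEF", "VIP"} & set(cfg.methods):
        X = _pooled_matrix(smoothed, grid)
        y = ResponseVector(
            y=table.set_index("sample_id").loc[X.sample_ids, cfg.reference_response].to_numpy(),
            response_name=cfg.reference_response,
        )
        # The band-selection model uses the component count indicated by the
        # cumulative response-variance curve: late components mostly chase
        # noise and would blur the |beta| peaks.
        h_max = min(cfg.h, X.n - 1, X.p)
        profile = select_components(X, y, h_max, cfg.selection_variance_pct)
        model = fit_plsr(X, y, profile.chosen_h)
        if "COEF" in cfg.methods:
            selections.append(select_by_coefficients(extract_regression(model), cfg.k))
        if "VIP" in cfg.methods:
            selections.append(select_by_vip(compute_vip(model), cfg.vip_threshold, cfg.k))
    selection_to_csv(selections, os.path.join(out, "selections.csv"))
    for sel in selections:
        log.info("select[%s]: %d bands %s", sel.method, sel.band_indices.size, sel.warning)
    return selections


def stage_fit(cfg: RunConfig, out: str) -> pd.DataFrame:
    smoothed, grid = _read_spectra(_spectra_path(out, "smoothed.csv"))
    table = read_sample_table(os.path.join(out, "table.csv")).set_index("sample_id")
    sel_frame = pd.read_csv(os.path.join(out, "selections.csv"))
    models_dir = os.path.join(out, "models")
    os.makedirs(models_dir, exist_ok=True)

    spectra_by_id = {s.label: s for s in smoothed}
    rows = []
    for method, group in sel_frame.groupby("method", sort=False):
        band_idx = np.sort(group["band_idx"].to_numpy(dtype=int))
        if band_idx.size == 0:
            log.warning("fit: skipping %s (empty selection)", method)
            continue
        for cultivar, cultivar_table in table.groupby("cultivar", sort=False):
            ids = [sid for sid in cultivar_table.index if sid in spectra_by_id]
            X_full = np.vstack([spectra_by_id[sid].values for sid in ids])
            for response in RESPONSES:
                y_all = cultivar_table.loc[ids, response].to_numpy(dtype=float)
                keep = np.isfinite(y_all)
                dropped = int((~keep).sum())
                if dropped:
                    log.info(
                        "fit[%s/%s/%s]: dropped %d rows with missing response",
                        method, cultivar, response, dropped,
                    )
                X = PredictorMatrix(
                    X=X_full[keep][:, band_idx],
                    band_nm=grid.wavelengths_nm[band_idx],
                    sample_ids=[i for i, k in zip(ids, keep) if k],
                )
                y = ResponseVector(y=y_all[keep], response_name=response)
                h = min(cfg.h, X.n - 1, X.p)
                model = fit_plsr(X, y, h)
                coeffs = extract_regression(model)
                yhat = predict(coeffs, X)
                tag = f"{method}_{cultivar}_{response}".replace(" ", "_")
                coeffs.to_json(
                    os.path.join(models_dir, f"{tag}.json"),
                    method=method,
                    cultivar=cultivar,
                    h=model.h,
                    band_idx=[int(b) for b in band_idx],
                )
                for sid, yt, yp in zip(X.sample_ids, y.y, yhat.y):
                    rows.append(
                        {
                            "sample_id": sid,
                            "cultivar": cultivar,
                            "system": str(cultivar_table.loc[sid, "system"]),
                            "response_name": response,
                            "method": method,
                            "measured": yt,
                            "predicted": yp,
                            "h_used": model.h,
                        }
                    )
    predictions = pd.DataFrame(rows)
    predictions.to_csv(os.path.join(out, "predictions.csv"), index=False, float_format=_FLOAT_FMT)
    log.info("fit: %d prediction rows", len(predictions))
    return predictions


def stage_evaluate(cfg: RunConfig, out: str) -> pd.DataFrame:
    predictions = pd.read_csv(os.path.join(out, "predictions.csv"))
    fits = []
    keys = ["cultivar", "system", "response_name", "method"]
    for key, group in predictions.groupby(keys, sort=False):
        fits.append(
            {
                **dict(zip(keys, key)),
                "measured": ResponseVector(group["measured"].to_numpy()),
                "predicted": ResponseVector(group["predicted"].to_numpy()),
                "h_used": int(group["h_used"].iloc[0]),
            }
        )
    report = build_report(fits)
    report.to_csv(os.path.join(out, "report.csv"), index=False, float_format="%.9g")

    # Leaf-vs-solution correlation per (treatment, cultivar), blue-green window.
    smoothed, _grid = _read_spectra(_spectra_path(out, "smoothed.csv"))
    solutions, _ = _read_spectra(_spectra_path(out, "solution_spectra.csv"))
    table = read_sample_table(os.path.join(out, "table.csv"))
    spectra_by_id = {s.label: s for s in smoothed}
    sol_by_ppm = {float(s.label.split("-")[1].replace("ppm", "")): s for s in solutions}
    corr_rows = []
    for (treatment, cultivar), group in table.groupby(["applied_N_ppm", "cultivar"], sort=True):
        solution = sol_by_ppm.get(float(treatment))
        if solution is None:
            continue
        leaf_values = np.mean(
            [spectra_by_id[sid].values for sid in group["sample_id"] if sid in spectra_by_id],
            axis=0,
        )
        leaf = MeanSpectrum(leaf_values, solution.grid, label=f"{cultivar}-{treatment}")
        result = cross_correlation(solution, leaf, cfg.correlation_window_nm)
        corr_rows.append(
            {"applied_N_ppm": treatment, "cultivar": cultivar, "r_corr": result.r_corr}
        )
    corr = pd.DataFrame(corr_rows).pivot(index="applied_N_ppm", columns="cultivar", values="r_corr")
    corr.to_csv(os.path.join(out, "correlations.csv"), float_format="%.9g")
    log.info("evaluate: %d report rows, %d correlation cells", len(report), corr.size)
    return report


def stage_report(out: str) -> str:
    report = pd.read_csv(os.path.join(out, "report.csv"))
    lines = ["best method per (cultivar, response):"]
    for _, row in report[report["best"]].iterrows():
        lines.append(
            f"  {row.cultivar:<24s} {row.response_name:<16s} {row.method:<5s} "
            f"R2={row.R2:.4f} RMSE={row.RMSE:.4g}"
        )
    text = "\n".join(lines) + "\n"
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(text)
    return text


def run(cfg: RunConfig, out: str) -> pd.DataFrame:
    """Execute all stages in order; equivalent to running them individually."""
    _setup_logging(cfg.log_level)
    stage_simulate(cfg, out)
    stage_preprocess(cfg, out)
    stage_select(cfg, out)
    stage_fit(cfg, out)
    report = stage_evaluate(cfg, out)
    stage_report(out)
    return report
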