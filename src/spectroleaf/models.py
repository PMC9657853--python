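"""Latent-variable regression models: NIPALS PLS1 and joint YX-PCA.

Both models reduce to a linear predictor ``y_hat = X @ beta + C`` via
:func:`extract_regression`; component counts are chosen from the cumulative
response-variance curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateInputError, ParameterError

__all__ = [
    "PredictorMatrix",
    "ResponseVector",
    "PLSModel",
    "JointPCAModel",
    "RegressionCoefficients",
    "VarianceProfile",
    "fit_plsr",
    "fit_joint_pca",
    "extract_regression",
    "predict",
    "select_components",
]


@dataclass
class PredictorMatrix:
    """n_samples x p matrix of mean reflectance at the modelled wavebands."""

    X: np.ndarray
    band_nm: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        band_nm = np.asarray(self.band_nm, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D")
        n, p = X.shape
        if p < 1 or n < 2:
            raise ParameterError(f"need n >= 2 and p >= 1, got {X.shape}")
        if band_nm.size != p:
            raise ContractError(f"{band_nm.size} wavelengths for {p} columns")
        if band_nm.size > 1 and not np.all(np.diff(band_nm) > 0):
            raise ParameterError("predictor columns must be ordered by wavelength")
        if not np.all(np.isfinite(X)):
            raise ParameterError("X contains non-finite values")
        self.X, self.band_nm = X, band_nm
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(n)]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ResponseVector:
    """A single laboratory-measured response aligned with a PredictorMatrix."""

    y: np.ndarray
    response_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise ParameterError("response contains non-finite values")
        self.y = y


@dataclass
class PLSModel:
    T: np.ndarray  # n x h scores
    U: np.ndarray  # n x h response scores
    P: np.ndarray  # p x h X-loadings
    Q: np.ndarray  # h response loadings
    W: np.ndarray  # p x h unit weight vectors
    b: np.ndarray  # h inner regression coefficients
    X_resid: np.ndarray
    Y_resid: np.ndarray
    X_mean: np.ndarray
    Y_mean: float
    h: int
    band_nm: np.ndarray
    response_name: str = ""


@dataclass
class JointPCAModel:
    """PCA of the autoscaled joint matrix Z = [Y X]."""

    T_z: np.ndarray  # n x h scores
    P_z: np.ndarray  # (1+p) x h orthonormal directions; row 0 is the Y column
    Z_resid: np.ndarray
    Z_mean: np.ndarray
    Z_scale: np.ndarray
    explained_var: np.ndarray  # eigenvalues, descending, all components
    h: int
    band_nm: np.ndarray
    response_name: str = ""


@dataclass
class RegressionCoefficients:
    """beta and intercept of the reduced linear predictor, in raw units."""

    beta: np.ndarray
    intercept: float
    band_nm: np.ndarray
    source: str  # "PLSR" | "YX-PCA"
    response_name: str = ""

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float).ravel()
        band_nm = np.asarray(self.band_nm, dtype=float).ravel()
        if beta.size != band_nm.size:
            raise ContractError("beta length does not match band list")
        if not np.all(np.isfinite(beta)) or not np.isfinite(self.intercept):
            raise ParameterError("non-finite regression coefficients")
        self.beta, self.band_nm = beta, band_nm

    def to_json(self, path: str, **metadata) -> None:
        payload = {
            "source": self.source,
            "response_name": self.response_name,
            "intercept": self.intercept,
            "band_nm": self.band_nm.tolist(),
            "beta": self.beta.tolist(),
            **metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class VarianceProfile:
    x_var_pct: np.ndarray  # per-component % of X variance
    y_var_pct: np.ndarray  # per-component % of Y variance
    cum_x_pct: np.ndarray
    cum_y_pct: np.ndarray
    chosen_h: int


def _validate_fit_inputs(X: PredictorMatrix, Y: ResponseVector, h: int, p_eff: int) -> None:
    if Y.y.size != X.n:
        raise ContractError(f"response length {Y.y.size} != n_samples {X.n}")
    if h < 1 or h > min(X.n - 1, p_eff):
        raise ParameterError(f"h={h} outside [1, min(n-1, p)] = [1, {min(X.n - 1, p_eff)}]")
    if np.var(Y.y) == 0:
        raise DegenerateInputError("zero-variance response")


def fit_plsr(X: PredictorMatrix, Y: ResponseVector, h: int) -> PLSModel:
    """NIPALS PLS1 with mean-centred X and y.

    Per component: ``w = X'y/||X'y||``, ``t = Xw``, ``p = X't/t't``,
    ``b = y't/t't``, then deflate ``X -= t p'`` and ``y -= b t``. For a
    univariate response each component converges in a single pass, so no
    inner iteration is required.
    """
    _validate_fit_inputs(X, Y, h, X.p)
    Xc = X.X - X.X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise DegenerateInputError("all predictor columns are constant")
    x_mean = X.X.mean(axis=0)
    y_mean = float(Y.y.mean())
    yc = Y.y - y_mean

    n, p = Xc.shape
    T = np.zeros((n, h))
    U = np.zeros((n, h))
    P = np.zeros((p, h))
    W = np.zeros((p, h))
    b = np.zeros(h)
    Xd, yd = Xc.copy(), yc.copy()
    h_eff = 0
    for i in range(h):
        cov = Xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm < 1e-14 * max(1.0, np.abs(yc).max()):
            break  # remaining X carries no covariance with y
        w = cov / norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-300:
            break
        p_i = Xd.T @ t / tt
        b_i = float(yd @ t / tt)
        W[:, i], T[:, i], P[:, i], b[i] = w, t, p_i, b_i
        # PLS1 inner relation u_i = b_i t_i; storing t_i with Q = b keeps the
        # decomposition Y_centred = U Q' + Y_resid exact at every h.
        U[:, i] = t
        Xd = Xd - np.outer(t, p_i)
        yd = yd - b_i * t
        h_eff = i + 1

    if h_eff == 0:
        raise DegenerateInputError("response is uncorrelated with every predictor column")
    T, U, P, W, b = T[:, :h_eff], U[:, :h_eff], P[:, :h_eff], W[:, :h_eff], b[:h_eff]
    return PLSModel(
        T=T,
        U=U,
        P=P,
        Q=b.copy(),  # PLS1 response loadings coincide with the inner coefficients
        W=W,
        b=b,
        X_resid=Xd,
        Y_resid=yd,
        X_mean=x_mean,
        Y_mean=y_mean,
        h=h_eff,
        band_nm=X.band_nm.copy(),
        response_name=Y.response_name,
    )


def fit_joint_pca(X: PredictorMatrix, Y: ResponseVector, h: int) -> JointPCAModel:
    """PCA of the autoscaled joint matrix ``Z = [Y X]``.

    Columns are centred and scaled to unit variance (Y and X carry
    incommensurate units), then the top-``h`` principal directions are taken
    from the SVD of the scaled matrix.
    """
    _validate_fit_inputs(X, Y, h, X.p + 1)
    Z = np.column_stack([Y.y, X.X])
    z_mean = Z.mean(axis=0)
    z_scale = Z.std(axis=0, ddof=0)
    if np.any(z_scale == 0):
        raise DegenerateInputError("constant column in the joint [Y X] matrix")
    Zs = (Z - z_mean) / z_scale
    _, s, Vt = np.linalg.svd(Zs, full_matrices=False)
    P_z = Vt[:h].T
    T_z = Zs @ P_z
    resid = Zs - T_z @ P_z.T
    return JointPCAModel(
        T_z=T_z,
        P_z=P_z,
        Z_resid=resid,
        Z_mean=z_mean,
        Z_scale=z_scale,
        explained_var=(s**2) / max(Z.shape[0] - 1, 1),
        h=h,
        band_nm=X.band_nm.copy(),
        response_name=Y.response_name,
    )


def extract_regression(model) -> RegressionCoefficients:
    """Reduce a fitted latent-variable model to ``beta`` and intercept.

    PLSR: ``beta = W (P'W)^-1 b`` mapped back to raw units. YX-PCA: the Y
    column of Z is regressed on its projection onto the top-h directions and
    the result reduced algebraically to coefficients over X alone.
    """
    if isinstance(model, PLSModel):
        PtW = model.P.T @ model.W
        try:
            inner = np.linalg.solve(PtW, model.b)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(f"singular P'W in PLSR reduction: {exc}") from exc
        beta = model.W @ inner
        intercept = model.Y_mean - float(model.X_mean @ beta)
        return RegressionCoefficients(
            beta=beta,
            intercept=intercept,
            band_nm=model.band_nm,
            source="PLSR",
            response_name=model.response_name,
        )
    if isinstance(model, JointPCAModel):
        # Reconstruction of the scaled Y column: y_s_hat = T_z @ P_z[0]
        #   = y_s * ||P_z[0]||^2 + X_s @ (P_z[1:] @ P_z[0])
        # Solving y_s = y_s_hat for y_s gives coefficients over X_s alone.
        y_row = model.P_z[0, :]
        denom = 1.0 - float(y_row @ y_row)
        if abs(denom) < 1e-10:
            raise DegenerateInputError(
                "joint PCA retains the full Y direction; cannot reduce to X-only "
                "coefficients (decrease h)"
            )
        beta_scaled = (model.P_z[1:, :] @ y_row) / denom
        sd_y = model.Z_scale[0]
        sd_x = model.Z_scale[1:]
        beta = beta_scaled * sd_y / sd_x
        intercept = float(model.Z_mean[0]) - float(model.Z_mean[1:] @ beta)
        return RegressionCoefficients(
            beta=beta,
            intercept=intercept,
            band_nm=model.band_nm,
            source="YX-PCA",
            response_name=model.response_name,
        )
    raise ParameterError(f"cannot extract regression from {type(model).__name__}")


def predict(coeffs: RegressionCoefficients, X: PredictorMatrix) -> ResponseVector:
    """Apply the linear predictor ``y_hat = X @ beta + C``."""
    if coeffs.band_nm.size != X.band_nm.size or not np.allclose(
        coeffs.band_nm, X.band_nm, atol=1e-9
    ):
        mismatched = _band_mismatch(coeffs.band_nm, X.band_nm)
        raise ContractError(f"band list mismatch between coefficients and predictors: {mismatched}")
    yhat = X.X @ coeffs.beta + coeffs.intercept
    return ResponseVector(y=yhat, response_name=coeffs.response_name)


def _band_mismatch(a: np.ndarray, b: np.ndarray) -> str:
    sa, sb = set(np.round(a, 6)), set(np.round(b, 6))
    only_a = sorted(sa - sb)[:5]
    only_b = sorted(sb - sa)[:5]
    return f"coeff-only {only_a} nm, X-only {only_b} nm"


def select_components(
    X: PredictorMatrix,
    Y: ResponseVector,
    h_max: int,
    variance_threshold_pct: float = 95.0,
) -> VarianceProfile:
    """Cumulative explained-variance profile of PLS1 at h = 1..h_max.

    ``chosen_h`` is the smallest component count whose cumulative explained
    Y-variance reaches the threshold, else ``h_max``. NIPALS components are
    nested, so a single fit at ``h_max`` yields the whole curve.
    """
    model = fit_plsr(X, Y, h_max)
    yc = Y.y - Y.y.mean()
    Xc = X.X - X.X.mean(axis=0)
    ss_y = float(yc @ yc)
    ss_x = float((Xc**2).sum())
    tt = (model.T**2).sum(axis=0)
    y_var = (model.b**2) * tt / ss_y * 100.0
    x_var = tt * (model.P**2).sum(axis=0) / ss_x * 100.0
    cum_y = np.cumsum(y_var)
    cum_x = np.cumsum(x_var)
    reached = np.nonzero(cum_y >= variance_threshold_pct)[0]
    chosen = int(reached[0]) + 1 if reached.size else model.h
    return VarianceProfile(
        x_var_pct=x_var, y_var_pct=y_var, cum_x_pct=cum_x, cum_y_pct=cum_y, chosen_h=chosen
    )
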