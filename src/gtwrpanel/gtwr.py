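"""Geographically and temporally weighted regression (GTWR).

Each observation i at planar location (u_i, v_i) and time t_i receives its own
coefficient vector, estimated by weighted least squares with kernel weights
that decay in the combined space-time squared distance

    d_ij^2 = lambda * [(u_i-u_j)^2 + (v_i-v_j)^2] + mu * (t_i-t_j)^2.

Only the ratio tau = mu/lambda is identifiable jointly with the bandwidth, so
lambda is fixed to 1 and tau is searched over a grid while the bandwidth h is
calibrated by leave-one-out cross-validation with a golden-section search.
tau = 0 recovers purely spatial GWR; a very large bandwidth recovers global
OLS. Temporal weighting is symmetric (past and future neighbors); a causal
past-only option is available but off by default.

Diagnostics follow the GWR conventions: effective number of parameters is the
hat-matrix trace tr(S) with s_ii = w_ii * x_i' (X'W_i X)^{-1} x_i;
adjusted R^2 = 1 - [RSS/(n - tr(S))] / [TSS/(n - 1)];
AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S)).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import PanelDataset

__all__ = [
    "KernelSpec",
    "GTWRFit",
    "OLSFit",
    "BandwidthSearchResult",
    "SingularFitError",
    "UnderdeterminedFitError",
    "st_distance_sq",
    "kernel_weight",
    "fit_pointwise",
    "fit_gtwr",
    "cv_score",
    "optimize_bandwidth",
    "fit_ols",
    "nonstationarity_test",
    "DEFAULT_TAU_GRID",
]

logger = logging.getLogger(__name__)

_FAMILIES = ("gaussian", "bisquare")

#: Dimensionless tau candidates; tau = 1 balances the spatial and temporal
#: metrics after rescaling by the data's median pairwise distances.
DEFAULT_TAU_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

_RIDGE = 1e-8


class SingularFitError(np.linalg.LinAlgError):
    """A local weighted design is rank deficient beyond ridge repair."""


class UnderdeterminedFitError(ValueError):
    """Fewer positively weighted observations than parameters at a fit point."""


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Space-time kernel configuration.

    ``bandwidth`` is the kernel scale h in combined-distance units (or a
    neighbor count when ``adaptive``); ``spatial_scale`` (lambda) and
    ``temporal_scale`` (mu) weight the squared spatial and temporal distances.
    mu = 0 degenerates to purely spatial GWR weighting.
    """

    family: str = "gaussian"
    bandwidth: float = 1.0
    spatial_scale: float = 1.0
    temporal_scale: float = 0.0
    adaptive: bool = False
    causal: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"kernel family must be one of {_FAMILIES}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.spatial_scale <= 0:
            raise ValueError("spatial_scale (lambda) must be positive")
        if self.temporal_scale < 0:
            raise ValueError("temporal_scale (mu) must be non-negative")

    @property
    def tau(self) -> float:
        return self.temporal_scale / self.spatial_scale


@dataclasses.dataclass
class GTWRFit:
    """Local coefficients plus fit diagnostics for one GTWR estimation."""

    coefficients: pd.DataFrame  # n rows; columns: intercept + variable names
    fitted: np.ndarray
    residuals: np.ndarray
    hat_trace: float
    adjusted_r2: float
    aicc: float
    cv_score: float | None
    kernel: KernelSpec
    variable_names: list[str]
    index: pd.DataFrame  # city_id, year per observation

    @property
    def n(self) -> int:
        return len(self.coefficients)

    def to_csv(self, path) -> None:
        out = pd.concat([self.index.reset_index(drop=True), self.coefficients.reset_index(drop=True)], axis=1)
        out["fitted"] = self.fitted
        out["residual"] = self.residuals
        out.to_csv(path, index=False)


@dataclasses.dataclass
class OLSFit:
    """Global least-squares baseline."""

    coefficients: pd.Series  # intercept + variables
    std_errors: pd.Series
    adjusted_r2: float
    r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    variable_names: list[str]


@dataclasses.dataclass
class BandwidthSearchResult:
    kernel: KernelSpec
    cv_score: float
    converged: bool
    trace: pd.DataFrame  # tau, bandwidth, cv per evaluation


def st_distance_sq(p_i, p_j, lam: float = 1.0, mu: float = 0.0) -> float:
    """Combined squared space-time distance between points (u, v, t)."""
    if lam <= 0 or mu < 0:
        raise ValueError("need lambda > 0 and mu >= 0")
    du = p_i[0] - p_j[0]
    dv = p_i[1] - p_j[1]
    dt = p_i[2] - p_j[2]
    return float(lam * (du * du + dv * dv) + mu * dt * dt)


def kernel_weight(d_sq, spec: KernelSpec):
    """Kernel weight in [0, 1] for squared distance(s) d_sq.

    gaussian: exp(-d^2 / h^2); bisquare: (1 - d^2/h^2)^2 inside h, 0 beyond.
    """
    d_sq = np.asarray(d_sq, dtype=float)
    h2 = spec.bandwidth**2
    if spec.family == "gaussian":
        w = np.exp(-d_sq / h2)
    else:
        w = np.where(d_sq < h2, (1.0 - d_sq / h2) ** 2, 0.0)
    return float(w) if w.ndim == 0 else w


def fit_pointwise(X_design: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve one local weighted least-squares problem.

    beta = (X' W X)^{-1} X' W y with W = diag(w), via a symmetric solve with a
    trace-scaled ridge fallback (1e-8) when the weighted normal matrix is
    numerically singular.
    """
    X = np.asarray(X_design, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p = X.shape[1]
    if int((w > 0).sum()) < p:
        raise UnderdeterminedFitError(
            f"only {(w > 0).sum()} positively weighted observations for {p} parameters"
        )
    Xw = X * w[:, None]
    A = Xw.T @ X
    b = Xw.T @ y
    try:
        beta = np.linalg.solve(A, b)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        ridge = _RIDGE * np.trace(A) / p
        try:
            beta = np.linalg.solve(A + ridge * np.eye(p), b)
            logger.debug("applied ridge %.3e to a singular local fit", ridge)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise SingularFitError(f"local design singular beyond ridge repair: {exc}") from exc
        if not np.all(np.isfinite(beta)):
            raise SingularFitError("local design singular beyond ridge repair")
    return beta


def _st_dist_sq_matrices(coords: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    du = coords[:, 0][:, None] - coords[:, 0][None, :]
    dv = coords[:, 1][:, None] - coords[:, 1][None, :]
    dt = t[:, None] - t[None, :]
    return du * du + dv * dv, dt * dt


def _weight_matrix(Dsp: np.ndarray, Dt2: np.ndarray, spec: KernelSpec, t: np.ndarray | None = None) -> np.ndarray:
    d2 = spec.spatial_scale * Dsp + spec.temporal_scale * Dt2
    W = kernel_weight(d2, spec)
    if spec.causal:
        if t is None:
            raise ValueError("causal weighting needs the time vector")
        future = t[None, :] > t[:, None]
        W = np.where(future, 0.0, W)
    return W


def _batched_local_fits(
    X: np.ndarray, y: np.ndarray, Wmat: np.ndarray, need_hat: bool
) -> tuple[np.ndarray, np.ndarray]:
    """All local fits at once: beta (n, p) and hat diagonal s_ii (n,).

    Mirrors :func:`fit_pointwise` (same ridge fallback) but batches the
    normal-equation assembly and solves for speed.
    """
    n, p = X.shape
    A = np.einsum("in,nj,nk->ijk", Wmat, X, X, optimize=True)
    b = np.einsum("in,nj,n->ij", Wmat, X, y, optimize=True)
    try:
        beta = np.linalg.solve(A, b[:, :, None]).squeeze(-1)
        bad = ~np.all(np.isfinite(beta), axis=1)
    except np.linalg.LinAlgError:
        beta = np.full((n, p), np.nan)
        bad = np.ones(n, dtype=bool)
    if bad.any():
        for i in np.flatnonzero(bad):
            beta[i] = fit_pointwise(X, y, Wmat[i])
        # refresh A for hat computation on repaired rows handled below
    s_ii = np.zeros(n)
    if need_hat:
        try:
            c = np.linalg.solve(A, X[:, :, None]).squeeze(-1)  # A_i^{-1} x_i
        except np.linalg.LinAlgError:
            ridge = _RIDGE * np.einsum("ijj->i", A) / p
            c = np.linalg.solve(A + ridge[:, None, None] * np.eye(p)[None], X[:, :, None]).squeeze(-1)
        s_ii = np.einsum("ij,ij->i", X, c) * np.diag(Wmat)
    return beta, s_ii


def fit_gtwr(
    panel: PanelDataset,
    kernel: KernelSpec,
    compute_cv: bool = False,
) -> GTWRFit:
    """Fit GTWR over every observation of a panel.

    Each observation's coefficients come from a weighted least-squares fit
    using kernel weights from all observations (self included). Raises
    :class:`UnderdeterminedFitError` naming the observation when a bisquare
    bandwidth leaves a point with fewer weighted neighbors than parameters.
    """
    X, y, coords, t = panel.design_arrays()
    n, p = X.shape
    if n <= p:
        raise UnderdeterminedFitError(f"n={n} observations cannot support {p} parameters")
    Dsp, Dt2 = _st_dist_sq_matrices(coords, t)
    Wmat = _weight_matrix(Dsp, Dt2, kernel, t)
    counts = (Wmat > 0).sum(axis=1)
    if (counts < p).any():
        i = int(np.argmax(counts < p))
        raise UnderdeterminedFitError(
            f"observation {panel.data['city_id'].iloc[i]}/{int(panel.data['year'].iloc[i])} has "
            f"{counts[i]} weighted neighbors for {p} parameters (bandwidth too small)"
        )
    beta, s_ii = _batched_local_fits(X, y, Wmat, need_hat=True)
    fitted = np.einsum("ij,ij->i", X, beta)
    resid = y - fitted
    tr_S = float(s_ii.sum())
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    denom = n - tr_S
    adj_r2 = 1.0 - (rss / denom) / (tss / (n - 1)) if denom > 0 and tss > 0 else np.nan
    sigma = math.sqrt(rss / n) if rss > 0 else 0.0
    if n - 2 - tr_S > 0 and sigma > 0:
        aicc = 2 * n * math.log(sigma) + n * math.log(2 * math.pi) + n * (n + tr_S) / (n - 2 - tr_S)
    else:
        aicc = np.nan

    names = ["intercept"] + list(panel.variable_names)
    fit = GTWRFit(
        coefficients=pd.DataFrame(beta, columns=names),
        fitted=fitted,
        residuals=resid,
        hat_trace=tr_S,
        adjusted_r2=float(adj_r2),
        aicc=float(aicc),
        cv_score=None,
        kernel=kernel,
        variable_names=list(panel.variable_names),
        index=panel.data[["city_id", "year"]].copy(),
    )
    if compute_cv:
        fit.cv_score = cv_score(panel, kernel)
    return fit


def cv_score(panel: PanelDataset, kernel: KernelSpec) -> float:
    """Leave-one-out cross-validation score sum_i (y_i - yhat_(i))^2.

    Each observation is re-predicted with its own weight forced to zero. An
    observation left underdetermined (e.g. bisquare bandwidth so small that
    fewer weighted neighbors than parameters remain) makes the score infinite
    — that bandwidth is invalid, never silently trimmed.
    """
    X, y, coords, t = panel.design_arrays()
    n, p = X.shape
    Dsp, Dt2 = _st_dist_sq_matrices(coords, t)
    Wmat = _weight_matrix(Dsp, Dt2, kernel, t)
    np.fill_diagonal(Wmat, 0.0)
    if ((Wmat > 0).sum(axis=1) < p).any():
        return float("inf")
    try:
        beta, _ = _batched_local_fits(X, y, Wmat, need_hat=False)
    except (UnderdeterminedFitError, SingularFitError):
        return float("inf")
    pred = np.einsum("ij,ij->i", X, beta)
    if not np.all(np.isfinite(pred)):
        return float("inf")
    return float(((y - pred) ** 2).sum())


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 60):
    """Deterministic golden-section minimization on [lo, hi]; returns
    (x_best, f_best, evaluations, converged)."""
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    evals = []

    def ev(x):
        val = f(x)
        evals.append((x, val))
        return val

    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = ev(c), ev(d)
    it = 0
    while abs(b - a) > tol and it < max_iter:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = ev(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = ev(d)
        it += 1
    xs, fs = zip(*evals)
    i_best = int(np.argmin(fs))
    return xs[i_best], fs[i_best], evals, it < max_iter


def _scale_ratio(coords: np.ndarray, t: np.ndarray) -> float:
    """(median nonzero spatial distance / median nonzero temporal distance)^2
    — converts the dimensionless tau grid into mu values on the data's scale."""
    Dsp, Dt2 = _st_dist_sq_matrices(coords, t)
    iu = np.triu_indices(len(coords), k=1)
    sp = np.sqrt(Dsp[iu])
    tm = np.sqrt(Dt2[iu])
    sp_med = np.median(sp[sp > 0]) if (sp > 0).any() else 1.0
    tm_med = np.median(tm[tm > 0]) if (tm > 0).any() else 0.0
    if tm_med == 0.0:
        return 0.0
    return float((sp_med / tm_med) ** 2)


def optimize_bandwidth(
    panel: PanelDataset,
    family: str = "gaussian",
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    h_search: tuple[float, float] | None = None,
    tol: float = 0.02,
    causal: bool = False,
) -> BandwidthSearchResult:
    """Calibrate the space-time kernel by leave-one-out cross-validation.

    For each dimensionless tau candidate (mu = tau * scale_ratio, with
    scale_ratio matching the data's median spatial and temporal pairwise
    distances), a golden-section search on log-bandwidth minimizes
    :func:`cv_score` over [min nonzero pairwise distance, 2 x max pairwise
    distance] in the combined metric. Fully deterministic. Returns the global
    best with the full evaluation trace.
    """
    if not tau_grid:
        raise ValueError("tau_grid must be non-empty")
    X, y, coords, t = panel.design_arrays()
    ratio = _scale_ratio(coords, t)
    Dsp, Dt2 = _st_dist_sq_matrices(coords, t)
    iu = np.triu_indices(len(coords), k=1)

    rows = []
    best = None
    all_converged = True
    for tau in tau_grid:
        mu = float(tau) * ratio
        d2 = Dsp[iu] + mu * Dt2[iu]
        d = np.sqrt(d2)
        d_pos = d[d > 0]
        if d_pos.size == 0:
            continue
        lo, hi = float(d_pos.min()), 2.0 * float(d.max())
        if h_search is not None:
            lo, hi = h_search

        def f(log_h, _mu=mu):
            spec = KernelSpec(
                family=family, bandwidth=float(np.exp(log_h)),
                temporal_scale=_mu, causal=causal,
            )
            return cv_score(panel, spec)

        log_h, cv_best, evals, conv = _golden_section(f, math.log(lo), math.log(hi), tol=tol)
        all_converged &= conv
        for lh, val in evals:
            rows.append({"tau": tau, "mu": mu, "bandwidth": float(np.exp(lh)), "cv": val})
        cand = KernelSpec(
            family=family, bandwidth=float(np.exp(log_h)), temporal_scale=mu, causal=causal
        )
        logger.info("tau=%.3g (mu=%.4g): best h=%.4g, CV=%.6g", tau, mu, cand.bandwidth, cv_best)
        if best is None or cv_best < best[1]:
            best = (cand, cv_best)

    if best is None:
        raise ValueError("bandwidth search found no valid candidate")
    return BandwidthSearchResult(
        kernel=best[0],
        cv_score=float(best[1]),
        converged=bool(all_converged and np.isfinite(best[1])),
        trace=pd.DataFrame(rows),
    )


def fit_ols(panel: PanelDataset) -> OLSFit:
    """Global OLS baseline with conventional standard errors."""
    X, y, _, _ = panel.design_arrays()
    names = ["intercept"] + list(panel.variable_names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    return OLSFit(
        coefficients=pd.Series(res.params, index=names),
        std_errors=pd.Series(res.bse, index=names),
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        variable_names=list(panel.variable_names),
    )


def nonstationarity_test(gtwr_fit: GTWRFit, ols_fit: OLSFit) -> pd.DataFrame:
    """Flag spatially/temporally varying coefficients.

    A variable is non-stationary when the interquartile range of its local
    GTWR coefficients strictly exceeds twice its OLS standard error. Quartiles
    use linear interpolation (numpy default, type 7).

    Returns a frame indexed by variable: iqr_gtwr, two_se_ols, nonstationary.
    """
    names = list(gtwr_fit.coefficients.columns)
    if names != list(ols_fit.coefficients.index):
        raise ValueError("GTWR and OLS fits carry different variables")
    q1 = gtwr_fit.coefficients.quantile(0.25, interpolation="linear")
    q3 = gtwr_fit.coefficients.quantile(0.75, interpolation="linear")
    iqr = q3 - q1
    two_se = 2.0 * ols_fit.std_errors
    return pd.DataFrame(
        {
            "iqr_gtwr": iqr,
            "two_se_ols": two_se,
            "nonstationary": iqr > two_se,
        }
    )
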