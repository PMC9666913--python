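"""Spatial error models, all-subsets AICc model averaging, diagnostics.

The spatial error model (SEM) is y = Xβ + u with u = λWu + ε,
ε ~ N(0, σ²I): the regression trend is non-spatial, but the errors are
spatially autocorrelated through the weight matrix W.  The model is
fitted by maximum likelihood: for a candidate λ the spatially filtered
regression (I − λW)y on (I − λW)X concentrates β and σ² out, leaving a
1-D profile likelihood in λ whose Jacobian term ln|I − λW| is computed
from the eigenvalues of W.  All 2^p predictor subsets are fitted, ranked
by small-sample AICc, and averaged with Akaike weights (absent
predictors contribute zero — full/shrinkage averaging); fit quality is
the pseudo-R², the squared Pearson correlation of weighted fitted
values with observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .spatial_stats import SpatialWeights

logger = logging.getLogger(__name__)

__all__ = [
    "SARFit",
    "AveragedModel",
    "weights_eigenvalues",
    "fit_sar_error",
    "all_subsets",
    "aicc",
    "model_average",
    "pseudo_r2",
    "zscore",
    "drop_genera",
    "sensitivity_rerun",
    "SensitivityResult",
]


def zscore(a) -> np.ndarray:
    a = np.asarray(a, float)
    sd = a.std(axis=0, ddof=1)
    return (a - a.mean(axis=0)) / sd


def weights_eigenvalues(W: SpatialWeights | np.ndarray) -> np.ndarray:
    """Real eigenvalue spectrum of a spatial weight matrix.

    A row-standardised matrix built from a symmetric neighbour structure
    is similar to the symmetric D^(-1/2) A D^(-1/2), so its spectrum is
    real; complex parts beyond tolerance raise.
    """
    Wm = W.matrix if isinstance(W, SpatialWeights) else np.asarray(W, float)
    ev = np.linalg.eigvals(Wm)
    if np.abs(ev.imag).max() > 1e-8:
        raise ValueError("weight matrix has a substantially complex spectrum")
    return np.sort(ev.real)


@dataclass(frozen=True)
class SARFit:
    """One maximum-likelihood spatial-error fit.

    ``coefficients`` maps predictor name → β̂ (intercept under
    "intercept"); ``K`` counts every free parameter of the likelihood:
    the intercept, each β, λ, and σ².
    """

    predictors: tuple
    coefficients: dict
    lambda_: float
    sigma2: float
    log_likelihood: float
    n: int
    fitted: np.ndarray = field(repr=False)

    @property
    def K(self) -> int:
        return len(self.predictors) + 3  # betas + intercept + lambda + sigma^2

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.K, self.n)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2logL + 2K + 2K(K+1)/(n−K−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, K={k} (need n > K + 1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _profile_loglik(lam, eigs, ys, Xs_base, Wy, WX, n):
    """Concentrated log-likelihood at λ (β, σ² profiled out by GLS)."""
    y_f = ys - lam * Wy
    X_f = Xs_base - lam * WX
    beta, *_ = np.linalg.lstsq(X_f, y_f, rcond=None)
    e = y_f - X_f @ beta
    sigma2 = (e @ e) / n
    if sigma2 <= 0:
        return -np.inf, beta, sigma2
    jac = np.log(1.0 - lam * eigs)
    if not np.isfinite(jac).all():
        return -np.inf, beta, sigma2
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + jac.sum()
    return ll, beta, sigma2


def fit_sar_error(
    y,
    X,
    W: SpatialWeights,
    eigs: np.ndarray | None = None,
    fixed_lambda: float | None = None,
    xtol: float = 1e-8,
) -> SARFit:
    """ML fit of the spatial error model y = Xβ + u, u = λWu + ε.

    ``X`` holds the predictors only (a DataFrame gives them names); an
    intercept is added internally.  λ is profiled over the interval
    (1/ω_min, 1/ω_max) set by the extreme eigenvalues of W; β and σ² are
    concentrated out by generalised least squares.  Fitted values are
    trend + signal: Xβ̂ + λ̂W(y − Xβ̂).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.atleast_2d(X).shape[1])]
    Xa = np.asarray(X, float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    y = np.asarray(y, float).ravel()
    n = y.size
    Xb = np.hstack([np.ones((n, 1)), Xa])
    if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
        raise ValueError("design matrix is rank deficient")
    k = Xb.shape[1] + 2
    if n <= k + 1:
        raise ValueError(f"too few observations (n={n}) for K={k}")
    Wm = W.matrix if isinstance(W, SpatialWeights) else np.asarray(W, float)
    if eigs is None:
        eigs = weights_eigenvalues(Wm)
    Wy = Wm @ y
    WX = Wm @ Xb
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -5.0
    hi = 1.0 / eigs.max() if eigs.max() > 0 else 5.0
    margin = 1e-6 * (hi - lo)
    if fixed_lambda is not None:
        lam_hat = float(fixed_lambda)
        ll, beta, sigma2 = _profile_loglik(lam_hat, eigs, y, Xb, Wy, WX, n)
    else:
        res = minimize_scalar(
            lambda lam: -_profile_loglik(lam, eigs, y, Xb, Wy, WX, n)[0],
            bounds=(lo + margin, hi - margin),
            method="bounded",
            options={"xatol": xtol},
        )
        lam_hat = float(res.x)
        ll, beta, sigma2 = _profile_loglik(lam_hat, eigs, y, Xb, Wy, WX, n)
        if min(lam_hat - lo, hi - lam_hat) < 10 * margin:
            logger.warning("lambda estimate %.4f at search boundary (%.4f, %.4f)", lam_hat, lo, hi)
    trend = Xb @ beta
    fitted = trend + lam_hat * (Wm @ (y - trend))
    coefs = {"intercept": float(beta[0])}
    coefs.update({nm: float(b) for nm, b in zip(names, beta[1:])})
    return SARFit(tuple(names), coefs, lam_hat, float(sigma2), float(ll), n, fitted)


def all_subsets(
    y,
    X: pd.DataFrame,
    W: SpatialWeights,
    include_intercept_only: bool = True,
    max_predictors: int = 15,
) -> list[SARFit]:
    """Fit the SEM for every predictor subset (all 2^p − 1 plus intercept-only).

    ``max_predictors`` is a combinatorial guardrail; fits that fail are
    logged and excluded (their count is reported).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    p = X.shape[1]
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors would require {2**p} models; screen the predictor set first"
        )
    eigs = weights_eigenvalues(W)
    fits, n_failed = [], 0
    sizes = range(0 if include_intercept_only else 1, p + 1)
    for size in sizes:
        for subset in combinations(X.columns, size):
            try:
                fits.append(fit_sar_error(y, X[list(subset)], W, eigs=eigs))
            except Exception as exc:  # noqa: BLE001
                n_failed += 1
                logger.warning("subset %s failed: %r", subset, exc)
    if n_failed:
        logger.warning("all_subsets: %d fit(s) failed and were excluded", n_failed)
    if not fits:
        raise RuntimeError("every subset fit failed")
    return fits


@dataclass(frozen=True)
class AveragedModel:
    """AICc-weighted average over a model set.

    ``coefficients`` are full (shrinkage) averages — a model not
    containing a variable contributes zero; ``importance`` is the summed
    Akaike weight of models containing each variable.
    """

    table: pd.DataFrame = field(repr=False)
    coefficients: pd.Series
    importance: pd.Series
    weighted_fitted: np.ndarray = field(repr=False)
    pseudo_r2: float | None = None


def model_average(fits: list[SARFit], observed=None) -> AveragedModel:
    """Akaike-weight averaging across fitted models.

    w_m = exp(−Δ_m/2) / Σ exp(−Δ/2) with Δ_m = AICc_m − min AICc.
    """
    if not fits:
        raise ValueError("no successful fits to average")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    variables = sorted({v for f in fits for v in f.predictors})
    coefs = pd.Series(0.0, index=variables)
    imp = pd.Series(0.0, index=variables)
    for f, wm in zip(fits, w):
        for v in f.predictors:
            coefs[v] += wm * f.coefficients[v]
            imp[v] += wm
    fitted = np.sum([wm * f.fitted for f, wm in zip(fits, w)], axis=0)
    table = pd.DataFrame(
        {
            "predictors": ["+".join(f.predictors) or "(intercept)" for f in fits],
            "K": [f.K for f in fits],
            "logL": [f.log_likelihood for f in fits],
            "AICc": aiccs,
            "delta_AICc": delta,
            "weight": w,
        }
    ).sort_values("AICc", ignore_index=True)
    r2 = pseudo_r2(fitted, observed) if observed is not None else None
    return AveragedModel(table, coefs, imp, fitted, r2)


def pseudo_r2(fitted, observed) -> float:
    """Squared Pearson correlation between fitted and observed values."""
    fitted = np.asarray(fitted, float).ravel()
    observed = np.asarray(observed, float).ravel()
    if fitted.size != observed.size or fitted.size < 3:
        raise ValueError("need >= 3 matching cells")
    if np.ptp(fitted) == 0 or np.ptp(observed) == 0:
        raise ValueError("pseudo-R² undefined for constant vectors")
    return float(np.corrcoef(fitted, observed)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# sensitivity rerun: excluding predominantly arboreal genera


def drop_genera(pam, genera):
    """Remove all species whose genus (the id prefix before '_') is listed."""
    genera = set(genera)
    keep = [s for s in pam.species if s.split("_")[0] not in genera]
    if not keep:
        raise ValueError("excluding these genera removes every species")
    if len(keep) == len(pam.species):
        return pam
    return pam.subset_species(keep)


@dataclass(frozen=True)
class SensitivityResult:
    main: AveragedModel
    reduced: AveragedModel
    excluded_species: tuple
    main_cells: tuple
    reduced_cells: tuple


def _run_metric_analysis(pam, metrics, env, grid_coords, null_spec, d_star, weight_fn, min_richness):
    from .assemblage_grid import filter_sparse_cells
    from .null_ses import ses_field
    from .spatial_stats import build_weights, moran_profile

    pam_f = filter_sparse_cells(pam, min_richness)
    ses = ses_field(pam_f, metrics, null_spec)
    y = ses["ses"].to_numpy()
    cells = list(pam_f.cells)
    coords = grid_coords.loc[cells].to_numpy(float)
    if d_star is None:
        d_star = moran_profile(y, coords, n_perm=0).d_star
    W = build_weights(coords, d_star, fn=weight_fn, allow_islands=True)
    Xz = pd.DataFrame(zscore(env.loc[cells]), columns=env.columns)
    fits = all_subsets(zscore(y), Xz, W)
    return model_average(fits, observed=zscore(y)), cells


def sensitivity_rerun(
    pam,
    metrics: pd.Series,
    env: pd.DataFrame,
    grid_coords: pd.DataFrame,
    exclude_genera,
    null_spec=None,
    d_star: float | None = None,
    weight_fn: str = "binary",
    min_richness: int = 5,
) -> SensitivityResult:
    """Re-run the environmental-driver analysis without selected genera.

    Drops every species of the listed genera, rebuilds and re-filters the
    assemblage matrix, recomputes the null-model SES and refits the
    all-subsets averaged model; returns main and reduced runs side by
    side.  ``grid_coords`` is a cell_id-indexed frame with x, y columns.
    """
    from .null_ses import NullSpec

    null_spec = null_spec or NullSpec(n_reps=200)
    main, main_cells = _run_metric_analysis(
        pam, metrics, env, grid_coords, null_spec, d_star, weight_fn, min_richness
    )
    reduced_pam = drop_genera(pam, exclude_genera)
    excluded = tuple(s for s in pam.species if s not in reduced_pam.species)
    reduced, reduced_cells = _run_metric_analysis(
        reduced_pam, metrics, env, grid_coords, null_spec, d_star, weight_fn, min_richness
    )
    return SensitivityResult(main, reduced, excluded, tuple(main_cells), tuple(reduced_cells))
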