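"""Spatial autocorrelation statistics and spatial weight matrices.

Moran's I with permutation inference, distance-class correlograms for
choosing the neighbourhood radius at which autocorrelation is strongest,
and construction of (row-standardised) spatial weight matrices under
several distance-weighting functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "MoranProfile",
    "moran_i",
    "moran_profile",
    "build_weights",
    "select_weighting",
]


@dataclass(frozen=True)
class SpatialWeights:
    """A spatial weight matrix with provenance.

    ``matrix`` has a zero diagonal and non-negative entries; when
    ``style == "row_standardized"`` every non-island row sums to one.
    ``islands`` indexes cells with no neighbour under the construction.
    """

    matrix: np.ndarray
    style: str
    distance_threshold: float | None = None
    weight_fn: str | None = None
    islands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    p_value: float
    n_perm: int


@dataclass(frozen=True)
class MoranProfile:
    """Moran's I per distance class and the strongest-autocorrelation radius."""

    class_bounds: np.ndarray  # upper bound of each distance class
    I: np.ndarray
    p_values: np.ndarray
    d_star: float  # upper bound of the class with strongest I


def _check_values(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.ptp(v) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    return v


def _moran_stat(z: np.ndarray, W: np.ndarray, s0: float) -> float:
    n = z.size
    return float(n / s0 * (z @ W @ z) / (z @ z))


def moran_i(
    values: np.ndarray,
    weights: SpatialWeights | np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MoranResult:
    """Global Moran's I with a permutation test.

    I = (n / S0) * (z' W z) / (z' z) with z the mean-centred values.  The
    p-value is two-sided on |I - E[I]| under random permutation of the
    values across cells; E[I] = -1/(n-1).
    """
    W = weights.matrix if isinstance(weights, SpatialWeights) else np.asarray(weights, float)
    v = _check_values(values)
    n = v.size
    if W.shape != (n, n):
        raise ValueError(f"weights shape {W.shape} does not match {n} values")
    if n < 3:
        raise ValueError("need at least 3 cells")
    s0 = float(W.sum())
    if s0 <= 0:
        raise ValueError("weight matrix has zero total weight")
    z = v - v.mean()
    I_obs = _moran_stat(z, W, s0)
    expected = -1.0 / (n - 1)
    if n_perm <= 0:
        return MoranResult(I_obs, expected, float("nan"), 0)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    zz = z @ z
    for k in range(n_perm):
        zp = rng.permutation(z)
        perms[k] = n / s0 * (zp @ W @ zp) / zz
    extreme = np.abs(perms - expected) >= np.abs(I_obs - expected) - 1e-15
    p = (1.0 + extreme.sum()) / (n_perm + 1.0)
    return MoranResult(I_obs, expected, float(p), n_perm)


def moran_profile(
    values: np.ndarray,
    coords: np.ndarray,
    n_classes: int = 10,
    n_perm: int = 199,
    seed: int | np.random.Generator | None = None,
    positive_only: bool = False,
) -> MoranProfile:
    """Moran's I correlogram over equal-width distance classes.

    Classes span from the smallest pairwise distance to half the maximum
    pairwise distance (standard correlogram practice).  ``d_star`` is the
    upper bound of the class with the strongest autocorrelation — maximum
    |I| by default, maximum I when ``positive_only`` — ties resolved to
    the smallest distance.
    """
    v = _check_values(values)
    coords = np.atleast_2d(np.asarray(coords, float))
    n = v.size
    if coords.shape[0] != n:
        raise ValueError("coords must have one row per value")
    if n < n_classes + 1:
        raise ValueError(f"need at least {n_classes + 1} cells for {n_classes} classes")
    D = squareform(pdist(coords))
    off = D[np.triu_indices(n, k=1)]
    d_min, d_max = off.min(), off.max() / 2.0
    if d_max <= d_min:
        d_max = off.max()
    bounds = np.linspace(d_min, d_max, n_classes + 1)[1:]
    rng = np.random.default_rng(seed)
    lower = d_min - 1e-12  # include the closest pair in the first class
    I_vals = np.full(n_classes, np.nan)
    p_vals = np.full(n_classes, np.nan)
    for k, ub in enumerate(bounds):
        Wk = ((D > lower) & (D <= ub + 1e-12)).astype(float)
        np.fill_diagonal(Wk, 0.0)
        lower = ub
        if Wk.sum() == 0:
            continue
        res = moran_i(v, Wk, n_perm=n_perm, seed=rng)
        I_vals[k] = res.I
        p_vals[k] = res.p_value
    score = I_vals if positive_only else np.abs(I_vals)
    best = int(np.nanargmax(score))
    return MoranProfile(bounds, I_vals, p_vals, float(bounds[best]))


_WEIGHT_FNS = {
    "binary": lambda d: np.ones_like(d),
    "inv_distance": lambda d: 1.0 / d,
    "inv_distance_sq": lambda d: 1.0 / d**2,
}


def build_weights(
    coords: np.ndarray,
    d_star: float,
    fn: str = "binary",
    style: str = "row_standardized",
    allow_islands: bool = False,
) -> SpatialWeights:
    """Distance-band spatial weights: w_ij = fn(d_ij) for 0 < d_ij <= d_star.

    ``style`` is ``row_standardized`` (rows sum to one) or ``binary``
    (weights as returned by ``fn``).  Cells with no neighbour within
    ``d_star`` are islands: an error unless ``allow_islands``.
    """
    if d_star <= 0:
        raise ValueError("d_star must be positive")
    if fn not in _WEIGHT_FNS:
        raise ValueError(f"unknown weighting function {fn!r}; choose from {sorted(_WEIGHT_FNS)}")
    if style not in ("row_standardized", "binary"):
        raise ValueError(f"unknown style {style!r}")
    coords = np.atleast_2d(np.asarray(coords, float))
    D = squareform(pdist(coords))
    mask = (D > 0) & (D <= d_star + 1e-12)
    W = np.zeros_like(D)
    W[mask] = _WEIGHT_FNS[fn](D[mask])
    rowsum = W.sum(axis=1)
    islands = np.flatnonzero(rowsum == 0)
    if islands.size == coords.shape[0]:
        raise ValueError("d_star smaller than every pairwise distance: all cells are islands")
    if islands.size and not allow_islands:
        raise ValueError(
            f"{islands.size} island cell(s) under d_star={d_star}; "
            "increase d_star or pass allow_islands=True"
        )
    if style == "row_standardized":
        nz = rowsum > 0
        W[nz] = W[nz] / rowsum[nz, None]
    return SpatialWeights(W, style, float(d_star), fn, islands)


def select_weighting(y, X, candidates, fit_fn=None):
    """Pick the candidate weight matrix whose SAR fit leaves the least
    residual spatial autocorrelation.

    Fits the full model under each candidate ``SpatialWeights`` and scores
    its residuals by the worst (largest) |Moran's I| measured under every
    candidate structure — judging residuals only under a fit's own matrix
    would let a mismatched neighbourhood hide the autocorrelation it fails
    to absorb.  Returns the ``(spec, fit)`` pair with the smallest score
    (ties broken by higher log-likelihood, then first listed).
    """
    from . import sar_inference  # deferred: avoids an import cycle

    if fit_fn is None:
        fit_fn = sar_inference.fit_sar_error
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate weight specifications")
    best = None
    failures = []
    for idx, w in enumerate(candidates):
        try:
            fit = fit_fn(y, X, w)
            resid = np.asarray(y, float) - fit.fitted
            score = max(abs(moran_i(resid, wc, n_perm=0).I) for wc in candidates)
        except Exception as exc:  # noqa: BLE001 - collected for diagnostics
            failures.append((idx, repr(exc)))
            continue
        key = (score, -fit.log_likelihood, idx)
        if best is None or key < best[0]:
            best = (key, w, fit)
    if best is None:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    return best[1], best[2]
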