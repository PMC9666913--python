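"""Richness-preserving null models and standardized effect sizes.

For each grid cell the observed assemblage metric (mean verticality,
tail proportion or fossoriality score of the species present) is
compared against a null distribution built by redrawing, for every
replicate, the same number of species from the regional pool without
replacement — by default with probability proportional to each species'
grid occupancy, which controls the influence of widespread species.
The standardized effect size is SES = (observed − null mean) / null SD;
positive verticality SES means an assemblage more arboreal than
expected at its richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage_grid import PresenceAbsenceMatrix

__all__ = ["NullSpec", "observed_metric", "build_null", "compute_ses", "ses_field"]

WEIGHTINGS = ("occupancy_proportional", "uniform", "inverse_occupancy", "shuffle")


@dataclass(frozen=True)
class NullSpec:
    """Null-model settings: replicate count, sampling weights, aggregation."""

    n_reps: int = 1000
    weighting: str = "occupancy_proportional"
    aggregation: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")


def _metric_vector(pam: PresenceAbsenceMatrix, metrics: pd.Series) -> np.ndarray:
    missing = [s for s in pam.species if s not in metrics.index]
    if missing:
        raise ValueError(f"species lacking metric values: {missing}")
    vals = metrics.loc[list(pam.species)].to_numpy(float)
    if np.isnan(vals).any():
        bad = [s for s, v in zip(pam.species, vals) if np.isnan(v)]
        raise ValueError(f"species with missing metric values: {bad}")
    return vals


def observed_metric(
    pam: PresenceAbsenceMatrix, metrics: pd.Series, aggregation: str = "mean"
) -> np.ndarray:
    """Per-cell aggregate (mean by default) of a species-level metric."""
    vals = _metric_vector(pam, metrics)
    totals = pam.matrix @ vals
    if aggregation == "sum":
        return totals
    rich = pam.richness
    if (rich == 0).any():
        raise ValueError("empty assemblage(s): filter cells first")
    return totals / rich


def _weights(pam: PresenceAbsenceMatrix, weighting: str) -> np.ndarray:
    occ = pam.matrix.sum(axis=0).astype(float)
    if weighting == "occupancy_proportional":
        w = occ
    elif weighting == "inverse_occupancy":
        w = 1.0 / occ
    else:  # uniform
        w = np.ones_like(occ)
    if not (w > 0).all() or w.sum() <= 0:
        raise ValueError("null-model weights must be strictly positive")
    return w


def build_null(
    pam: PresenceAbsenceMatrix, metrics: pd.Series, spec: NullSpec
) -> np.ndarray:
    """Null matrix of shape (n_reps, n_cells).

    Each replicate redraws, for every cell of richness S, S distinct
    species from the pool without replacement with probability
    proportional to the sampling weights (Gumbel-top-k successive
    sampling), then aggregates exactly as ``observed_metric`` does.
    Per-cell richness is preserved in every replicate.  The ``shuffle``
    weighting instead permutes metric values across species labels.
    """
    vals = _metric_vector(pam, metrics)
    rich = pam.richness
    n_cells, n_species = pam.matrix.shape
    assert (rich <= n_species).all()
    rng = np.random.default_rng(spec.seed)
    null = np.empty((spec.n_reps, n_cells))
    if spec.weighting == "shuffle":
        rich_safe = rich.astype(float)
        for r in range(spec.n_reps):
            perm_vals = vals[rng.permutation(n_species)]
            totals = pam.matrix @ perm_vals
            null[r] = totals if spec.aggregation == "sum" else totals / rich_safe
        return null
    w = _weights(pam, spec.weighting)
    logw = np.log(w)
    take = rich - 1  # index of the S-th best key per cell
    full = rich == n_species  # exhaustive draws are order-independent
    total_all = vals.sum()
    for r in range(spec.n_reps):
        keys = logw + rng.gumbel(size=(n_cells, n_species))
        order = np.argsort(-keys, axis=1)
        csum = np.cumsum(vals[order], axis=1)
        totals = csum[np.arange(n_cells), take]
        totals[full] = total_all
        null[r] = totals if spec.aggregation == "sum" else totals / rich
    return null


def compute_ses(observed: np.ndarray, null: np.ndarray, cell_ids=None) -> pd.DataFrame:
    """SES field: (observed − null mean) / null SD per cell.

    SD uses the sample (n−1) denominator.  Cells with zero null SD get
    NaN SES and ``undefined=True`` rather than an infinite score.
    """
    observed = np.asarray(observed, float)
    null = np.asarray(null, float)
    if null.ndim != 2 or null.shape[0] < 2:
        raise ValueError("null matrix must be (n_reps >= 2) × n_cells")
    if null.shape[1] != observed.size:
        raise ValueError("null matrix and observed vector disagree on cell count")
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    # a column of identical values is degenerate even when floating-point
    # round-off in the mean leaves a tiny nonzero std; conversely the std
    # of near-identical denormals can underflow to exactly zero
    undefined = (np.ptp(null, axis=0) == 0) | (sd == 0)
    sd[undefined] = 0.0
    ses = np.full(observed.size, np.nan)
    ok = ~undefined
    ses[ok] = (observed[ok] - mean[ok]) / sd[ok]
    idx = pd.Index(cell_ids if cell_ids is not None else range(observed.size), name="cell_id")
    return pd.DataFrame(
        {"observed": observed, "null_mean": mean, "null_sd": sd, "ses": ses, "undefined": undefined},
        index=idx,
    )


def ses_field(
    pam: PresenceAbsenceMatrix, metrics: pd.Series, spec: NullSpec | None = None
) -> pd.DataFrame:
    """Observed metric, null distribution and SES for one species metric."""
    spec = spec or NullSpec()
    obs = observed_metric(pam, metrics, spec.aggregation)
    null = build_null(pam, metrics, spec)
    return compute_ses(obs, null, cell_ids=list(pam.cells))
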