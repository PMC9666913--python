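"""Species-level vertical-stratification metrics.

Three metrics summarise where a snake species sits on the underground ↔
canopy axis:

* **verticality** — an ordinal coding of the habit category, fossorial
  (0) to arboreal (1);
* **tail proportion** — tail length over total length, TL/TT, since
  arboreal species carry proportionally longer (prehensile) tails;
* **fossoriality score** — the species score on the first axis of a PCA
  of body mass, eye diameter, verticality and tail proportion, with the
  sign fixed so positive = arboreal, negative = fossorial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HABIT_VERTICALITY",
    "HABIT_ORDER",
    "code_verticality",
    "compute_tail_proportion",
    "trait_pca",
    "species_metrics",
    "summarize_trait_table",
    "PCAResult",
]

# Evenly spaced ordinal in [0, 1] along the fossorial -> arboreal axis;
# aquatic sits at ground level (0.5) with terrestrial.
HABIT_VERTICALITY = {
    "fossorial": 0.00,
    "semifossorial": 0.25,
    "terrestrial": 0.50,
    "aquatic": 0.50,
    "semiarboreal": 0.75,
    "arboreal": 1.00,
}
HABIT_ORDER = ("fossorial", "semifossorial", "terrestrial", "aquatic", "semiarboreal", "arboreal")


def code_verticality(habit: str, merge_aquatic: bool = False) -> float:
    """Ordinal verticality score of a habit category.

    ``merge_aquatic`` folds aquatic into terrestrial (the same 0.5 score
    either way; the flag exists so category summaries can replicate
    five-category tabulations).
    """
    key = "terrestrial" if (merge_aquatic and habit == "aquatic") else habit
    if key not in HABIT_VERTICALITY:
        raise ValueError(f"unknown habit {habit!r}; valid categories: {sorted(HABIT_VERTICALITY)}")
    return HABIT_VERTICALITY[key]


def compute_tail_proportion(tl, tt, species: str = "?") -> float:
    """Tail proportion TL/TT; requires TT > 0 and 0 <= TL < TT."""
    if tt <= 0 or not (0 <= tl < tt):
        raise ValueError(f"invalid tail/total length for species {species}: TL={tl}, TT={tt}")
    return tl / tt


@dataclass(frozen=True)
class PCAResult:
    scores: pd.Series  # axis-1 score per species (arboreal-positive)
    loadings: pd.DataFrame  # variables × axes
    variance_fraction: np.ndarray


def trait_pca(table: pd.DataFrame, log_mass: bool = True) -> PCAResult:
    """PCA of mass, eye diameter, verticality and tail proportion.

    Standardised (correlation-matrix) PCA; the axis-1 sign is fixed so
    the verticality loading is positive, making positive scores mean
    greater arboreality.  Body mass is log-transformed by default since
    snake masses span orders of magnitude.  Missing values are a hard
    error (no imputation).
    """
    need = ["mass_g", "eye_mm", "verticality", "tail_proportion"]
    missing_cols = [c for c in need if c not in table.columns]
    if missing_cols:
        raise ValueError(f"trait table lacks columns {missing_cols}")
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 species")
    X = table[need].astype(float).copy()
    bad = X.index[X.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing trait values for species: {list(bad)}")
    if log_mass:
        X["mass_g"] = np.log10(X["mass_g"])
    Z = X.to_numpy()
    sd = Z.std(axis=0, ddof=1)
    zero = [need[j] for j in np.flatnonzero(sd == 0)]
    if zero:
        raise ValueError(f"zero-variance PCA input variable(s): {zero}")
    Z = (Z - Z.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (len(X) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    vert_row = need.index("verticality")
    for k in range(evecs.shape[1]):  # arboreal-positive convention
        if evecs[vert_row, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = Z @ evecs
    loadings = pd.DataFrame(evecs, index=need, columns=[f"PC{k+1}" for k in range(len(need))])
    return PCAResult(
        scores=pd.Series(scores[:, 0], index=table.index, name="fossoriality_score"),
        loadings=loadings,
        variance_fraction=np.clip(evals, 0, None) / evals.sum(),
    )


def species_metrics(traits: pd.DataFrame, log_mass: bool = True) -> pd.DataFrame:
    """Per-species metric table (verticality, tail_proportion, fossoriality_score).

    ``traits`` is indexed by species with columns habit, TT_mm, TL_mm,
    mass_g, eye_mm (SVL_mm is carried but unused by the metrics).
    """
    vert = traits["habit"].map(lambda h: code_verticality(h))
    tail = pd.Series(
        [compute_tail_proportion(tl, tt, sp) for sp, tl, tt in zip(traits.index, traits["TL_mm"], traits["TT_mm"])],
        index=traits.index,
    )
    base = pd.DataFrame(
        {
            "verticality": vert,
            "tail_proportion": tail,
            "mass_g": traits["mass_g"],
            "eye_mm": traits["eye_mm"],
        }
    )
    pca = trait_pca(base, log_mass=log_mass)
    return pd.DataFrame(
        {
            "verticality": vert,
            "tail_proportion": tail,
            "fossoriality_score": pca.scores,
        }
    )


def summarize_trait_table(traits: pd.DataFrame) -> dict:
    """Headline counts and extrema of a trait table.

    Returns species counts per habit category plus total/tail length
    extrema (mm) and the maximum tail proportion — the numbers a dataset
    description reports.
    """
    counts = traits["habit"].value_counts().to_dict()
    out = {"n_species": int(len(traits))}
    for h in HABIT_ORDER:
        out[f"n_{h}"] = int(counts.get(h, 0))
    out["total_length_min_mm"] = float(traits["TT_mm"].min())
    out["total_length_max_mm"] = float(traits["TT_mm"].max())
    out["tail_length_min_mm"] = float(traits["TL_mm"].min())
    out["tail_length_max_mm"] = float(traits["TL_mm"].max())
    out["tail_proportion_max"] = float((traits["TL_mm"] / traits["TT_mm"]).max())
    return out
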