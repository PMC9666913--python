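"""Synthetic stand-in for the Chacoan snake trait compilation.

The real compilation covers 140 species with habit categories and
morphometrics (70 terrestrial, 22 fossorial, 21 semifossorial,
17 arboreal, 10 semiarboreal; total length 103–4000 mm, tail length
2–900 mm, tail proportion approaching 50%).  That table is not
redistributable here, so this module builds a SYNTHETIC table with the
same published marginals — category counts, length extrema, and
habit-typical morphometric structure — for demonstrations and for
exercising the trait-summary and sensitivity machinery.  Every value is
generated; no row corresponds to a real species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trait_metrics import HABIT_VERTICALITY

__all__ = ["synthetic_chaco_trait_table", "ARBOREAL_GENERA"]

# Genera treated as predominantly arboreal in sensitivity reruns.
ARBOREAL_GENERA = (
    "Chironius",
    "Corallus",
    "Dipsas",
    "Imantodes",
    "Leptodeira",
    "Leptophis",
    "Siphlophis",
    "Spillotes",
)

_COUNTS = {
    "terrestrial": 70,
    "fossorial": 22,
    "semifossorial": 21,
    "arboreal": 17,
    "semiarboreal": 10,
}


def synthetic_chaco_trait_table(seed: int = 2022) -> pd.DataFrame:
    """A 140-row synthetic trait table with the published marginals.

    Columns: habit, TT_mm, TL_mm, SVL_mm, mass_g, eye_mm; index
    "Genus_species" ids (arboreal rows draw their genus from
    ``ARBOREAL_GENERA`` so genus-exclusion reruns have targets).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for habit, count in _COUNTS.items():
        v = HABIT_VERTICALITY[habit]
        for i in range(count):
            if habit == "arboreal":
                genus = ARBOREAL_GENERA[i % len(ARBOREAL_GENERA)]
            else:
                genus = f"{habit[:4].capitalize()}us"
            tt = float(10 ** rng.normal(2.55 + 0.35 * v, 0.15))
            ratio = float(np.clip(rng.normal(0.07 + 0.28 * v, 0.04), 0.015, 0.46))
            mass = float(10 ** rng.normal(1.9 - 0.7 * v, 0.3))
            eye = float(max(0.8, rng.normal(2.0 + 3.0 * v, 0.6)))
            rows.append((f"{genus}_{habit[:3]}{i+1:02d}", habit, tt, ratio, mass, eye))
    df = pd.DataFrame(rows, columns=["species", "habit", "TT_mm", "ratio", "mass_g", "eye_mm"])
    df = df.set_index("species")

    # pin the published extrema onto fixed rows
    fos = df.index[df["habit"] == "fossorial"]
    arb = df.index[df["habit"] == "arboreal"]
    ter = df.index[df["habit"] == "terrestrial"]
    df.loc[fos[0], ["TT_mm", "ratio"]] = [103.0, 2.0 / 103.0]  # smallest: TT 103, TL 2
    df.loc[ter[0], ["TT_mm", "ratio"]] = [4000.0, 900.0 / 4000.0]  # largest: TT 4000, TL 900
    df.loc[arb[0], "ratio"] = 0.47  # tail approaching half the total length
    df["TT_mm"] = df["TT_mm"].clip(103.0, 4000.0)
    df["TL_mm"] = (df["TT_mm"] * df["ratio"]).clip(lower=2.0)
    df.loc[ter[0], "TL_mm"] = 900.0
    df["TL_mm"] = df[["TL_mm", "TT_mm"]].min(axis=1) - np.where(
        df["TL_mm"] >= df["TT_mm"], 1.0, 0.0
    )
    df["TL_mm"] = df["TL_mm"].clip(2.0, 900.0)
    df["SVL_mm"] = df["TT_mm"] - df["TL_mm"]
    return df[["habit", "TT_mm", "TL_mm", "SVL_mm", "mass_g", "eye_mm"]]
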