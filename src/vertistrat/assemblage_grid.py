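"""Equal-area grids, presence–absence matrices, and predictor screening.

The central object of the pipeline is the presence–absence matrix (PAM):
a binary cells × species table on a projected equal-area lattice.  This
module builds the PAM from occurrence points or per-species cell lists,
filters species-poor cells, aggregates gridded environmental values to
cells, and screens the predictor table for multicollinearity (stepwise
VIF elimination plus a pairwise Pearson screen).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "PresenceAbsenceMatrix",
    "VifReport",
    "PearsonReport",
    "make_grid",
    "rasterize_occurrences",
    "pam_from_cell_lists",
    "filter_sparse_cells",
    "aggregate_env",
    "vif_filter",
    "pearson_screen",
]


@dataclass(frozen=True)
class Grid:
    """A planar lattice of square cells in projected km coordinates.

    Row 0 is the northernmost row; centroids are spaced ``cell_size`` km
    apart.  ``cells`` holds one row per cell, ordered row-major, with
    columns cell_id, row, col, x, y.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    cells: pd.DataFrame

    def __post_init__(self):
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return self.cells["cell_id"].tolist()

    def coords(self, cell_ids=None) -> np.ndarray:
        """Centroid (x, y) array, optionally restricted/ordered by cell_ids."""
        df = self.cells.set_index("cell_id")
        if cell_ids is not None:
            df = df.loc[list(cell_ids)]
        return df[["x", "y"]].to_numpy(float)

    def to_geojson(self, path) -> None:
        """Write cell polygons as a GeoJSON FeatureCollection."""
        s = self.cell_size
        feats = []
        for rec in self.cells.itertuples():
            x0, y0 = rec.x - s / 2, rec.y - s / 2
            ring = [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0]]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": rec.cell_id, "row": rec.row, "col": rec.col},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def grid_from_geojson(path) -> Grid:
    """Rebuild a Grid from a GeoJSON written by :meth:`Grid.to_geojson`."""
    with open(path) as fh:
        gj = json.load(fh)
    recs = []
    for feat in gj["features"]:
        ring = feat["geometry"]["coordinates"][0]
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        recs.append(
            {
                "cell_id": feat["properties"]["cell_id"],
                "row": feat["properties"]["row"],
                "col": feat["properties"]["col"],
                "x": (min(xs) + max(xs)) / 2.0,
                "y": (min(ys) + max(ys)) / 2.0,
                "_size": max(xs) - min(xs),
            }
        )
    df = pd.DataFrame(recs).sort_values(["row", "col"], ignore_index=True)
    size = float(df["_size"].iloc[0])
    return Grid(int(df["row"].max()) + 1, int(df["col"].max()) + 1, size, df.drop(columns="_size"))


def make_grid(n_rows: int, n_cols: int, cell_size: float = 55.0) -> Grid:
    """Construct an ``n_rows`` × ``n_cols`` lattice of ``cell_size``-km cells."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{r}_{c}" for r, c in zip(rows, cols)],
            "row": rows,
            "col": cols,
            "x": (cols + 0.5) * cell_size,
            "y": (n_rows - rows - 0.5) * cell_size,
        }
    )
    return Grid(n_rows, n_cols, float(cell_size), df)


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary cells × species occurrence matrix.

    ``matrix[i, j] == 1`` iff species j occurs in cell i.  Construction
    drops all-zero species columns (a species must occur somewhere).
    """

    cells: tuple
    species: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (len(self.cells), len(self.species)):
            raise ValueError("matrix shape does not match cells × species")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @classmethod
    def build(cls, cells, species, matrix) -> "PresenceAbsenceMatrix":
        matrix = np.asarray(matrix, dtype=np.int8)
        keep = matrix.sum(axis=0) > 0
        if not keep.all():
            dropped = [s for s, k in zip(species, keep) if not k]
            logger.warning("dropping %d species with no occurrences: %s", len(dropped), dropped)
        species = tuple(s for s, k in zip(species, keep) if k)
        return cls(tuple(cells), species, matrix[:, keep])

    @property
    def richness(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def occupancy(self) -> np.ndarray:
        """Per-species fraction of cells occupied."""
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.cells), columns=list(self.species))

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(self.matrix)
        return pd.DataFrame(
            {"cell_id": [self.cells[a] for a in i], "species": [self.species[b] for b in j], "value": 1}
        )

    def subset_species(self, species) -> "PresenceAbsenceMatrix":
        idx = [self.species.index(s) for s in species]
        return PresenceAbsenceMatrix.build(self.cells, [self.species[k] for k in idx], self.matrix[:, idx])


def rasterize_occurrences(records: pd.DataFrame, grid: Grid) -> PresenceAbsenceMatrix:
    """Build a PAM from occurrence points (columns: species, x, y).

    A species is present in a cell iff at least one record falls in it;
    duplicate records are idempotent.  Records outside the grid extent are
    skipped and counted in a warning.
    """
    need = {"species", "x", "y"}
    if not need.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    s = grid.cell_size
    col = np.floor(records["x"].to_numpy(float) / s).astype(int)
    row = grid.n_rows - 1 - np.floor(records["y"].to_numpy(float) / s).astype(int)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("skipped %d occurrence record(s) outside the grid extent", n_out)
    species = sorted(records["species"].unique())
    sp_idx = {sp: k for k, sp in enumerate(species)}
    mat = np.zeros((grid.n_cells, len(species)), dtype=np.int8)
    flat = row[inside] * grid.n_cols + col[inside]
    for cell, sp in zip(flat, records["species"].to_numpy()[inside]):
        mat[cell, sp_idx[sp]] = 1
    return PresenceAbsenceMatrix.build(grid.cell_ids, species, mat)


def pam_from_cell_lists(cell_lists: dict, grid: Grid) -> PresenceAbsenceMatrix:
    """Build a PAM from {species: [cell_id, ...]} lists."""
    species = sorted(cell_lists)
    cid = {c: i for i, c in enumerate(grid.cell_ids)}
    mat = np.zeros((grid.n_cells, len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        for c in cell_lists[sp]:
            mat[cid[c], j] = 1
    return PresenceAbsenceMatrix.build(grid.cell_ids, species, mat)


def filter_sparse_cells(pam: PresenceAbsenceMatrix, min_richness: int = 5) -> PresenceAbsenceMatrix:
    """Drop species-poor cells (richness < ``min_richness``).

    Species left with no occurrences after the cell filter are dropped as
    well (and excluded from all downstream species pools).  Raises if no
    cell survives.
    """
    keep = pam.richness >= min_richness
    if not keep.any():
        raise ValueError(f"no cell has richness >= {min_richness}: empty result")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_sparse_cells: dropped %d of %d cells", n_drop, len(pam.cells))
    cells = [c for c, k in zip(pam.cells, keep) if k]
    return PresenceAbsenceMatrix.build(cells, pam.species, pam.matrix[keep])


def aggregate_env(pixels: pd.DataFrame, grid: Grid, statistic: str = "mean") -> pd.DataFrame:
    """Aggregate pixel-centre values (columns: x, y, variables...) to cells.

    Returns one row per grid cell (grid order, indexed by cell_id); cells
    covered by no pixel get NaN.  A variable with no finite value anywhere
    raises an error naming it.
    """
    if statistic != "mean":
        raise ValueError("only statistic='mean' is supported")
    variables = [c for c in pixels.columns if c not in ("x", "y")]
    if not variables:
        raise ValueError("no variable columns in pixel table")
    s = grid.cell_size
    col = np.floor(pixels["x"].to_numpy(float) / s).astype(int)
    row = grid.n_rows - 1 - np.floor(pixels["y"].to_numpy(float) / s).astype(int)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    flat = row[inside] * grid.n_cols + col[inside]
    out = pd.DataFrame(index=pd.Index(grid.cell_ids, name="cell_id"), columns=variables, dtype=float)
    sub = pixels.loc[inside, variables].copy()
    sub["_cell"] = flat
    means = sub.groupby("_cell").mean()
    for v in variables:
        if means[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no data over the grid")
        out.iloc[means.index, out.columns.get_loc(v)] = means[v].to_numpy()
    n_missing = int(out.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("aggregate_env: %d cell(s) with no covering pixel flagged missing", n_missing)
    return out


@dataclass(frozen=True)
class VifReport:
    """Record of stepwise VIF elimination.

    ``steps`` lists (variable, vif) in removal order; ``history`` maps each
    elimination step to the full VIF table before that removal.
    ``one_shot_flagged`` lists the variables whose *initial* VIF exceeded
    the threshold (the non-stepwise reading of the screen).
    """

    retained: tuple
    steps: tuple
    history: tuple
    one_shot_flagged: tuple
    threshold: float
    pearson: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": i, "removed": v, "vif": vif} for i, (v, vif) in enumerate(self.steps)]
        return pd.DataFrame(rows, columns=["step", "removed", "vif"])


def _vif_table(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R²_j) from regressing column j on the others (+ intercept)."""
    vifs = {}
    arr = X.to_numpy(float)
    n = arr.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.hstack([ones, np.delete(arr, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        if ss_tot == 0:
            raise ValueError(f"variable {name!r} has zero variance")
        r2 = 1.0 - (resid @ resid) / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def vif_filter(env: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Stepwise variance-inflation-factor screening.

    Iteratively removes the variable with the largest VIF until all
    retained variables have VIF <= ``threshold``.  Perfectly collinear
    variables have infinite VIF and are removed first.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two variables")
    if env.shape[0] <= env.shape[1]:
        raise ValueError("need more cells than variables")
    if not np.isfinite(env.to_numpy(float)).all():
        raise ValueError("non-finite values in predictor table")
    X = env.copy()
    steps, history = [], []
    initial = _vif_table(X)
    one_shot = tuple(initial.index[initial > threshold])
    while X.shape[1] >= 2:
        vifs = _vif_table(X)
        worst = vifs.idxmax()
        if vifs[worst] <= threshold:
            break
        history.append(vifs.copy())
        steps.append((worst, float(vifs[worst])))
        logger.info("vif_filter: removing %s (VIF=%.3g)", worst, vifs[worst])
        X = X.drop(columns=[worst])
    return VifReport(
        retained=tuple(X.columns),
        steps=tuple(steps),
        history=tuple(history),
        one_shot_flagged=one_shot,
        threshold=float(threshold),
        pearson=env.corr(),
    )


@dataclass(frozen=True)
class PearsonReport:
    matrix: pd.DataFrame
    flagged_pairs: tuple  # (var_a, var_b, r) with |r| > limit
    undefined: tuple  # zero-variance variables
    limit: float


def pearson_screen(env: pd.DataFrame, limit: float = 0.8) -> PearsonReport:
    """Pairwise Pearson screen: report pairs with |r| > ``limit``.

    Zero-variance variables have undefined correlations and are flagged
    separately rather than silently dropped.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two variables")
    sd = env.std(ddof=0)
    undefined = tuple(sd.index[sd == 0])
    corr = env.corr()
    flagged = []
    cols = list(env.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) > limit:
                flagged.append((cols[i], cols[j], float(r)))
    return PearsonReport(corr, tuple(flagged), undefined, float(limit))
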