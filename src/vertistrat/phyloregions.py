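"""Phylogenetic regionalization of grid-cell assemblages.

Pairwise phylogenetic beta diversity (phylo-Sørensen) between cell
assemblages is computed sparsely from per-branch cell incidence,
clustered by UPGMA, cut at the optimal number of regions (elbow of the
explained-dissimilarity curve), summarised by region-level evolutionary
distinctness (mean between-region dissimilarity), and ordinated by
non-metric multidimensional scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS

from .assemblage_grid import PresenceAbsenceMatrix

__all__ = [
    "BetaMatrix",
    "Phyloregionalization",
    "prune_tree",
    "phylo_beta",
    "cluster_regions",
    "optimal_k",
    "region_ed",
    "nmds",
    "regionalize",
]


@dataclass(frozen=True)
class BetaMatrix:
    """Symmetric cells × cells phylogenetic dissimilarity in [0, 1]."""

    cells: tuple
    matrix: np.ndarray = field(repr=False)
    index: str = "phylo_sorensen"

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.cells):
            raise ValueError("beta matrix must be square over the cells")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("beta matrix must be symmetric")
        if np.abs(np.diag(m)).max() > 1e-12:
            raise ValueError("beta matrix diagonal must be zero")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("beta values must lie in [0, 1]")


def prune_tree(tree: dendropy.Tree, species) -> dendropy.Tree:
    """Restrict a tree to a species set, preserving path lengths.

    Degree-2 nodes left by the pruning are collapsed with their branch
    lengths summed, so every retained tip-to-tip path length is exactly
    that of the original tree.
    """
    species = set(species)
    tips = {t.label for t in tree.taxon_namespace}
    missing = sorted(species - tips)
    if missing:
        raise ValueError(f"species not in the tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(labels=species)
    pruned.migrate_taxon_namespace(dendropy.TaxonNamespace())  # drop unused taxa
    pruned.is_rooted = True
    return pruned


def _branch_incidence(tree: dendropy.Tree, species: list[str]):
    """(lengths, tip-incidence) over all branches except the root edge.

    Row e of the boolean incidence matrix marks the species subtended by
    branch e; paths are measured to the root (the species pool's MRCA),
    root edge excluded.
    """
    sp_idx = {s: j for j, s in enumerate(species)}
    lengths, rows = [], []
    below = {}
    for node in tree.postorder_node_iter():
        mask = np.zeros(len(species), dtype=bool)
        if node.is_leaf():
            label = node.taxon.label
            if label not in sp_idx:
                raise ValueError(f"tree tip {label!r} not in the species set")
            mask[sp_idx[label]] = True
        else:
            for ch in node.child_nodes():
                mask |= below[id(ch)]
        below[id(node)] = mask
        if node.parent_node is not None:  # exclude the root edge
            lengths.append(node.edge.length or 0.0)
            rows.append(mask)
    return np.asarray(lengths, float), np.asarray(rows, bool)


def phylo_beta(
    pam: PresenceAbsenceMatrix, tree: dendropy.Tree, index: str = "phylo_sorensen"
) -> BetaMatrix:
    """Pairwise phylogenetic beta diversity between cell assemblages.

    With a = shared branch length and b, c the branch lengths unique to
    each assemblage: Sørensen = (b+c)/(2a+b+c); Simpson =
    min(b,c)/(a+min(b,c)).  Computed from the branches × cells incidence
    (a branch is in a cell iff any tip below it occurs there).
    """
    if index not in ("phylo_sorensen", "phylo_simpson"):
        raise ValueError("index must be 'phylo_sorensen' or 'phylo_simpson'")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(pam.species):
        raise ValueError("tree tip set must equal the PAM species set (prune first)")
    if (pam.richness == 0).any():
        raise ValueError("empty assemblages present; filter cells first")
    lengths, B = _branch_incidence(tree, list(pam.species))
    C = (B @ pam.matrix.T.astype(bool)) > 0  # branches × cells
    Cf = C.astype(float)
    pd_cells = lengths @ Cf
    shared = Cf.T @ (lengths[:, None] * Cf)
    if index == "phylo_sorensen":
        denom = pd_cells[:, None] + pd_cells[None, :]
        D = 1.0 - 2.0 * shared / denom
    else:
        unique_i = pd_cells[:, None] - shared
        unique_j = pd_cells[None, :] - shared
        m = np.minimum(unique_i, unique_j)
        D = m / (shared + m)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return BetaMatrix(tuple(pam.cells), D, index)


_LINKAGES = ("average", "complete", "ward")


def cluster_regions(beta: BetaMatrix, k: int, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of cells into k regions (UPGMA by default)."""
    n = len(beta.cells)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    if method not in _LINKAGES:
        raise ValueError(f"method must be one of {_LINKAGES}")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(squareform(beta.matrix, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def _explained(beta: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(beta.shape[0], k=1)
    all_d = beta[iu]
    same = labels[iu[0]] == labels[iu[1]]
    overall = all_d.mean()
    if overall == 0:
        return 0.0
    within = all_d[same].mean() if same.any() else 0.0
    return 1.0 - within / overall


def optimal_k(beta: BetaMatrix, k_max: int, method: str = "average"):
    """Optimal number of regions by the elbow of explained dissimilarity.

    Explained dissimilarity at k is 1 − (mean within-region
    dissimilarity / mean overall dissimilarity); k* maximises the
    perpendicular distance to the chord from (1, e₁) to (k_max, e_kmax).
    Returns (k*, curve) with the curve indexed by k.
    """
    n = len(beta.cells)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, n)
    ks = np.arange(1, k_max + 1)
    curve = np.empty(len(ks))
    Z = linkage(squareform(beta.matrix, checks=False), method=method)
    for i, k in enumerate(ks):
        labels = np.arange(1, n + 1) if k == n else fcluster(Z, t=k, criterion="maxclust")
        curve[i] = _explained(beta.matrix, labels)
    if np.ptp(curve) == 0:
        warnings.warn("flat explained-dissimilarity curve: no regional structure", stacklevel=2)
        return 1, pd.Series(curve, index=ks, name="explained_dissimilarity")
    p0 = np.array([ks[0], curve[0]])
    p1 = np.array([ks[-1], curve[-1]])
    chord = p1 - p0
    chord = chord / np.linalg.norm(chord)
    pts = np.column_stack([ks, curve]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
    k_star = int(ks[np.argmax(dist)])
    return k_star, pd.Series(curve, index=ks, name="explained_dissimilarity")


def region_ed(beta: BetaMatrix, labels: np.ndarray) -> pd.Series:
    """Region-level evolutionary distinctness.

    ED of region r = mean between-region dissimilarity from r to every
    other region, where a region pair's dissimilarity is the mean of its
    cell-pair dissimilarities.
    """
    labels = np.asarray(labels)
    regions = np.unique(labels)
    if regions.size < 2:
        raise ValueError("ED needs at least two regions")
    R = np.zeros((regions.size, regions.size))
    for a in range(regions.size):
        for b in range(a + 1, regions.size):
            block = beta.matrix[np.ix_(labels == regions[a], labels == regions[b])]
            R[a, b] = R[b, a] = block.mean()
    ed = {reg: R[i][np.arange(regions.size) != i].mean() for i, reg in enumerate(regions)}
    return pd.Series(ed, name="evolutionary_distinctness")


@dataclass(frozen=True)
class NMDSResult:
    coords: np.ndarray
    stress: float


def nmds(beta: BetaMatrix | np.ndarray, dims: int = 2, n_starts: int = 20, seed: int = 0) -> NMDSResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Kruskal stress-1 minimised by iterative majorization with monotone
    regression (SMACOF); best of ``n_starts`` seeded restarts; the
    returned coordinates are centred.
    """
    D = beta.matrix if isinstance(beta, BetaMatrix) else np.asarray(beta, float)
    if D.shape[0] < 3:
        raise ValueError("NMDS needs at least 3 objects")
    if np.all(D == 0):
        raise ValueError("degenerate all-zero dissimilarities")
    model = MDS(
        n_components=dims,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_starts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    return NMDSResult(coords, float(model.stress_))


@dataclass(frozen=True)
class Phyloregionalization:
    """Full regionalization result for one assemblage matrix."""

    k: int
    labels: pd.Series
    ed: pd.Series
    nmds_coords: pd.DataFrame
    stress: float
    curve: pd.Series
    beta: BetaMatrix = field(repr=False)


def regionalize(
    pam: PresenceAbsenceMatrix,
    tree: dendropy.Tree,
    k_max: int = 16,
    k: int | None = None,
    index: str = "phylo_sorensen",
    method: str = "average",
    seed: int = 0,
) -> Phyloregionalization:
    """End-to-end regionalization: prune, beta diversity, cluster, ED, NMDS."""
    pruned = prune_tree(tree, set(pam.species))
    beta = phylo_beta(pam, pruned, index=index)
    k_star, curve = optimal_k(beta, k_max, method=method)
    k_use = k if k is not None else max(k_star, 1)
    labels = cluster_regions(beta, k_use, method=method)
    ed = region_ed(beta, labels) if k_use >= 2 else pd.Series(dtype=float)
    # ordinate regions by their mean pairwise dissimilarity
    regions = np.unique(labels)
    if regions.size >= 3:
        R = np.zeros((regions.size, regions.size))
        for a in range(regions.size):
            for b in range(a + 1, regions.size):
                block = beta.matrix[np.ix_(labels == regions[a], labels == regions[b])]
                R[a, b] = R[b, a] = block.mean()
        nm = nmds(R, seed=seed)
        coords = pd.DataFrame(nm.coords, index=regions, columns=["nmds1", "nmds2"])
        stress = nm.stress
    else:
        coords = pd.DataFrame(columns=["nmds1", "nmds2"])
        stress = float("nan")
    return Phyloregionalization(
        k=k_use,
        labels=pd.Series(labels, index=list(pam.cells), name="region"),
        ed=ed,
        nmds_coords=coords,
        stress=stress,
        curve=curve,
        beta=beta,
    )
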