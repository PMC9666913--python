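"""Tree pruning, phylogenetic beta diversity, clustering, ED and NMDS."""

import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import random_pam
from vertistrat.assemblage_grid import PresenceAbsenceMatrix
from vertistrat.phyloregions import (
    BetaMatrix,
    cluster_regions,
    nmds,
    optimal_k,
    phylo_beta,
    prune_tree,
    region_ed,
    regionalize,
)


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


def _tip_distance(tree, a, b):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return pdm.distance(taxa[a], taxa[b])


class TestPruneTree:
    def test_prune_to_all_tips_is_identity(self):
        tree = _tree("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        pruned = prune_tree(tree, {"A", "B", "C", "D"})
        total = sum(e.length for e in pruned.preorder_edge_iter() if e.length)
        assert np.isclose(total, 5.5)  # 1+1+1 + 0.5+0.5+1.5, no root edge
        assert _tip_distance(pruned, "A", "C") == _tip_distance(tree, "A", "C")

    def test_path_length_conserved_after_collapse(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        pruned = prune_tree(tree, {"A", "C"})
        assert {t.label for t in pruned.taxon_namespace} == {"A", "C"}
        assert np.isclose(_tip_distance(pruned, "A", "C"), 4.0)

    def test_missing_species_listed(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="Z"):
            prune_tree(tree, {"A", "Z"})

    def test_prune_to_single_species_preserves_depth(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        pruned = prune_tree(tree, {"A"})
        leaf = next(pruned.leaf_node_iter())
        assert leaf.taxon.label == "A"
        assert np.isclose(leaf.distance_from_root(), 2.0)


def _brute_force_beta(pam, tree):
    """Dense oracle: explicit per-cell branch sets via root paths."""
    # branch identified by its head node id; root edge excluded
    paths = {}
    for leaf in tree.leaf_node_iter():
        branches = {}
        node = leaf
        while node.parent_node is not None:
            branches[id(node)] = node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = branches
    n = len(pam.cells)
    D = np.zeros((n, n))
    cell_branches = []
    for i in range(n):
        present = [pam.species[j] for j in np.flatnonzero(pam.matrix[i])]
        merged = {}
        for sp in present:
            merged.update(paths[sp])
        cell_branches.append(merged)
    for i in range(n):
        for j in range(n):
            bi, bj = cell_branches[i], cell_branches[j]
            pdi, pdj = sum(bi.values()), sum(bj.values())
            shared = sum(l for b, l in bi.items() if b in bj)
            D[i, j] = 1 - 2 * shared / (pdi + pdj)
    return D


class TestPhyloBeta:
    def test_identical_assemblages_zero(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        mat = np.array([[1, 1, 0], [1, 1, 0]], np.int8)
        pam = PresenceAbsenceMatrix.build(["x", "y"], ["A", "B", "C"], mat)
        beta = phylo_beta(pam, prune_tree(tree, set(pam.species)))
        assert beta.matrix[0, 1] == 0.0

    def test_star_tree_reduces_to_taxonomic_sorensen(self):
        # equal-length star phylogeny: shared branch length is proportional
        # to shared species, so the index equals 1 - Sorensen similarity
        n_sp = 8
        newick = "(" + ",".join(f"sp_{j:03d}:1" for j in range(n_sp)) + ");"
        tree = _tree(newick)
        rng = np.random.default_rng(0)
        pam = random_pam(rng, 10, n_sp, min_richness=1)
        beta = phylo_beta(pam, prune_tree(tree, set(pam.species)))
        for i in range(10):
            for j in range(10):
                a = set(np.flatnonzero(pam.matrix[i]))
                b = set(np.flatnonzero(pam.matrix[j]))
                sor = 1 - 2 * len(a & b) / (len(a) + len(b))
                assert abs(beta.matrix[i, j] - sor) < 1e-12

    def test_matches_brute_force_oracle_on_random_instances(self):
        from vertistrat.synthetic_world import WorldConfig, simulate_phylogeny

        rng = np.random.default_rng(1)
        for seed in range(3):
            full = simulate_phylogeny(WorldConfig(n_species=10, seed=seed))
            mat = random_pam(rng, 15, 10, min_richness=1).matrix
            pam = PresenceAbsenceMatrix.build(
                [f"c{i}" for i in range(15)], [f"sp_{j:03d}" for j in range(1, 11)], mat
            )
            tree = prune_tree(full, set(pam.species))
            beta = phylo_beta(pam, tree)
            oracle = _brute_force_beta(pam, tree)
            assert np.abs(beta.matrix - oracle).max() < 1e-12

    def test_bounds_symmetry_enforced(self, default_world):
        from vertistrat.assemblage_grid import filter_sparse_cells
        from vertistrat.phyloregions import prune_tree

        pam = filter_sparse_cells(default_world.pam, 5)
        tree = prune_tree(default_world.tree, set(pam.species))
        beta = phylo_beta(pam, tree)  # BetaMatrix validates on construction
        assert beta.matrix.max() <= 1.0
        assert np.all(np.diag(beta.matrix) == 0)

    def test_tip_mismatch_rejected(self, toy_pam):
        tree = _tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="prune"):
            phylo_beta(toy_pam, tree)


def _block_beta(sizes, within, between):
    n = sum(sizes)
    D = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        D[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(D, 0.0)
    return BetaMatrix(tuple(f"c{i}" for i in range(n)), D)


class TestClustering:
    def test_two_blocks_recovered(self):
        beta = _block_beta([6, 6], 0.1, 0.9)
        labels = cluster_regions(beta, 2)
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_k_one_and_k_n(self):
        beta = _block_beta([4, 4], 0.1, 0.9)
        assert len(set(cluster_regions(beta, 1))) == 1
        assert len(set(cluster_regions(beta, 8))) == 8

    def test_k_out_of_range(self):
        beta = _block_beta([3, 3], 0.1, 0.9)
        with pytest.raises(ValueError):
            cluster_regions(beta, 0)
        with pytest.raises(ValueError):
            cluster_regions(beta, 7)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        base = _block_beta([5, 5, 5], 0.1, 0.8)
        jitter = rng.uniform(0, 0.01, base.matrix.shape)
        D = base.matrix + (jitter + jitter.T) / 2
        np.fill_diagonal(D, 0.0)
        beta = BetaMatrix(base.cells, np.clip(D, 0, 1))
        labels = cluster_regions(beta, 3)
        perm = rng.permutation(15)
        beta_p = BetaMatrix(
            tuple(beta.cells[i] for i in perm), beta.matrix[np.ix_(perm, perm)]
        )
        labels_p = cluster_regions(beta_p, 3)
        # same partition up to label renaming
        from sklearn.metrics import rand_score

        assert rand_score(labels[perm], labels_p) == 1.0


class TestOptimalK:
    def test_two_separated_blocks_give_k_two(self):
        beta = _block_beta([6, 6], 0.05, 0.9)
        k, curve = optimal_k(beta, 6)
        assert k == 2
        assert curve.loc[2] > 0.9

    def test_flat_curve_warns_and_returns_one(self):
        n = 8
        D = np.full((n, n), 0.5)
        np.fill_diagonal(D, 0.0)
        beta = BetaMatrix(tuple(f"c{i}" for i in range(n)), D)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            k, curve = optimal_k(beta, 5)
        assert k == 1
        assert any("structure" in str(w.message) for w in rec)

    def test_curve_non_decreasing(self):
        rng = np.random.default_rng(3)
        D = rng.uniform(0.2, 0.9, (12, 12))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        beta = BetaMatrix(tuple(f"c{i}" for i in range(12)), D)
        _, curve = optimal_k(beta, 12)
        assert (np.diff(curve.to_numpy()) > -1e-9).all()


class TestRegionEd:
    def test_two_regions_share_the_single_between_value(self):
        beta = _block_beta([4, 4], 0.1, 0.6)
        labels = np.array([1] * 4 + [2] * 4)
        ed = region_ed(beta, labels)
        assert np.isclose(ed[1], 0.6) and np.isclose(ed[2], 0.6)

    def test_identical_region_has_zero_ed(self):
        n = 6
        D = np.zeros((n, n))
        D[:4, 4:] = D[4:, :4] = 0.0  # region 2 identical to region 1
        beta = BetaMatrix(tuple(f"c{i}" for i in range(n)), D)
        ed = region_ed(beta, np.array([1, 1, 1, 1, 2, 2]))
        assert ed[2] == 0.0

    def test_three_region_arithmetic(self):
        # between-region means {12: 0.2, 13: 0.4, 23: 0.6}
        beta = _block_beta([2, 2, 2], 0.0, 0.0)
        D = beta.matrix.copy()
        D[0:2, 2:4] = D[2:4, 0:2] = 0.2
        D[0:2, 4:6] = D[4:6, 0:2] = 0.4
        D[2:4, 4:6] = D[4:6, 2:4] = 0.6
        ed = region_ed(BetaMatrix(beta.cells, D), np.array([1, 1, 2, 2, 3, 3]))
        assert np.allclose([ed[1], ed[2], ed[3]], [0.3, 0.4, 0.5])

    def test_single_region_rejected(self):
        beta = _block_beta([4], 0.1, 0.1)
        with pytest.raises(ValueError):
            region_ed(beta, np.ones(4, dtype=int))


class TestNmds:
    def test_three_equidistant_objects_embed_exactly(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        res = nmds(D, seed=0)
        assert res.stress < 0.01
        d01 = np.linalg.norm(res.coords[0] - res.coords[1])
        d02 = np.linalg.norm(res.coords[0] - res.coords[2])
        d12 = np.linalg.norm(res.coords[1] - res.coords[2])
        assert np.isclose(d01, d02, rtol=0.05) and np.isclose(d01, d12, rtol=0.05)

    def test_euclidean_input_low_stress(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = nmds(D, seed=1)
        assert res.stress < 0.01
        assert np.allclose(res.coords.mean(axis=0), 0.0, atol=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((4, 4)))


class TestRegionalizePipeline:
    def test_planted_split_recovered(self):
        from sklearn.metrics import rand_score

        from vertistrat.assemblage_grid import filter_sparse_cells
        from vertistrat.synthetic_world import WorldConfig, make_split_world

        world = make_split_world(WorldConfig(seed=3, n_species=60, range_fill=0.35))
        pam = filter_sparse_cells(world.pam, 5)
        res = regionalize(pam, world.tree, k_max=8, seed=0)
        truth = world.truth.region_label.loc[list(pam.cells)]
        assert res.k == 2
        assert rand_score(truth, res.labels.to_numpy()) > 0.9
        assert (res.ed > 0).all()
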