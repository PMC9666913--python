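"""Synthetic study systems with recorded ground truth.

Generates everything the analysis pipeline consumes — an equal-area
lattice, spatially autocorrelated environmental gradients with a
dominant latitudinal axis, an ultrametric Yule phylogeny, habit and
morphometric traits with tunable phylogenetic signal (arboreal = long
tail, large eyes; fossorial = small body, short tail), and contiguous
spreading-dye species ranges driven by each species' niche — so that
every downstream stage can be tested against known truth.

Randomness comes from a single seed split into named substreams
(env, tree, traits, ranges): adding or re-running one stage never
perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .assemblage_grid import Grid, PresenceAbsenceMatrix, make_grid
from .trait_metrics import HABIT_ORDER, HABIT_VERTICALITY

__all__ = [
    "WorldConfig",
    "GroundTruth",
    "SyntheticWorld",
    "generate_grid",
    "simulate_environment",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_ranges",
    "generate_world",
    "make_split_world",
    "simulate_sar_field",
    "ENV_VARIABLES",
]

ENV_VARIABLES = (
    "annual_mean_temperature",
    "precipitation_seasonality",
    "aet",
    "npp",
    "ndvi",
    "evenness",
    "homogeneity",
    "tree_cover",
    "frag",
    "sand",
)

# Habit frequencies follow the observed Chacoan snake fauna
# (70 terrestrial, 22 fossorial, 21 semifossorial, 17 arboreal,
# 10 semiarboreal of 140; aquatic not tabulated separately).
DEFAULT_HABIT_PROPORTIONS = {
    "fossorial": 22 / 140,
    "semifossorial": 21 / 140,
    "terrestrial": 70 / 140,
    "aquatic": 0.0,
    "semiarboreal": 10 / 140,
    "arboreal": 17 / 140,
}


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic study system.

    ``trait_signal`` scales the phylogenetic signal of the habit latent
    trait (0 = independent of the tree, 1 = pure Brownian motion);
    ``env_gradient_strength`` scales the latitudinal gradients;
    ``range_fill`` is the mean fraction of the grid occupied per species.
    """

    n_rows: int = 12
    n_cols: int = 10
    cell_size: float = 55.0
    n_species: int = 80
    birth_rate: float = 1.0
    trait_signal: float = 0.8
    env_gradient_strength: float = 1.0
    range_fill: float = 0.25
    noise_sd: float = 0.3
    seed: int = 0
    habit_proportions: tuple = tuple(sorted(DEFAULT_HABIT_PROPORTIONS.items()))
    collinear: bool = False

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.n_species < 1:
            raise ValueError("n_rows, n_cols, n_species must be positive")
        if not (0 < self.range_fill < 1):
            raise ValueError("range_fill must be in (0, 1)")
        if not (0 <= self.trait_signal <= 1):
            raise ValueError("trait_signal must be in [0, 1]")

    def proportions(self) -> dict:
        return dict(self.habit_proportions)

    def substreams(self) -> dict:
        """Named, order-stable child generators of the world seed."""
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("env", "tree", "traits", "ranges", "extra")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    verticality: pd.Series = None  # true ordinal score per species
    habit: pd.Series = None
    niche_optimum: pd.Series = None  # preferred tree_cover per species
    clade: pd.Series = None  # for split worlds
    region_label: pd.Series = None  # per-cell planted region (split worlds)
    sar_params: dict = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    grid: Grid
    env: pd.DataFrame
    tree: dendropy.Tree
    traits: pd.DataFrame
    pam: PresenceAbsenceMatrix
    truth: GroundTruth

    def validate(self) -> None:
        tips = {t.label for t in self.tree.taxon_namespace}
        assert tips == set(self.traits.index) == set(self.pam.species), "species sets disagree"
        assert set(self.pam.cells) <= set(self.grid.cell_ids)


def generate_grid(config: WorldConfig) -> Grid:
    return make_grid(config.n_rows, config.n_cols, config.cell_size)


def simulate_environment(grid: Grid, config: WorldConfig, rng=None) -> pd.DataFrame:
    """Per-cell environmental predictor table.

    Temperature and tree cover decline strictly with row index (row 0 is
    north) before noise; sand is Gaussian-smoothed white noise (spatially
    autocorrelated); the remaining variables are independent smoothed
    fields with mild gradients.  ``config.collinear`` appends a
    near-duplicate of tree cover to exercise the VIF screen.
    """
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    rng = rng if rng is not None else config.substreams()["env"]
    g = config.env_gradient_strength
    ns = config.noise_sd
    nr, nc = grid.n_rows, grid.n_cols
    rows = grid.cells["row"].to_numpy()
    cols = grid.cells["col"].to_numpy()
    r = rows / max(nr - 1, 1)  # 0 at north, 1 at south
    c = cols / max(nc - 1, 1)  # 0 at west, 1 at east

    def smooth(sigma, scale=1.0):
        f = gaussian_filter(rng.standard_normal((nr, nc)), sigma=sigma, mode="nearest")
        sd = f.std()
        if sd > 0:
            f = f / sd
        return scale * f.ravel()

    noise = lambda scale: ns * scale * rng.standard_normal(grid.n_cells)
    env = pd.DataFrame(index=pd.Index(grid.cell_ids, name="cell_id"))
    env["annual_mean_temperature"] = 28.0 - 10.0 * g * r + ns * 2.0 * smooth(1.0) + noise(0.5)
    env["precipitation_seasonality"] = 60.0 + 15.0 * smooth(1.0) + 2.0 * g * (r - 0.5) + noise(2.0)
    env["aet"] = 900.0 + 150.0 * smooth(1.2) - 30.0 * g * (r - 0.5) + noise(20.0)
    env["npp"] = 0.6 + 0.15 * smooth(1.0) + 0.1 * g * (r - 0.5) + noise(0.02)
    env["ndvi"] = 0.55 + 0.1 * smooth(0.8) + noise(0.02)
    env["evenness"] = 0.5 + 0.12 * smooth(1.0) + noise(0.02)
    env["homogeneity"] = 0.4 + 0.1 * smooth(1.2) + noise(0.02)
    # latitudinal plus a longitudinal component, so tree cover tracks the
    # north-south gradient without duplicating temperature
    env["tree_cover"] = 65.0 - 30.0 * g * r - 25.0 * (c - 0.5) + noise(2.0)
    env["frag"] = 20.0 + 8.0 * smooth(0.8) + noise(1.0)
    env["sand"] = 50.0 + 15.0 * smooth(1.2) + noise(1.0)
    if config.collinear:
        env["tree_cover_dup"] = env["tree_cover"] + noise(0.05) + 1e-9 * rng.standard_normal(grid.n_cells)
    assert np.isfinite(env.to_numpy()).all()
    return env


def _yule_newick(n_species: int, birth_rate: float, rng: np.random.Generator) -> str:
    """Forward pure-birth (Yule) simulation; returns an ultrametric newick."""
    # node: [children or tip-label, birth_time, split_time]
    root = {"t0": 0.0, "children": None, "label": None}
    active = [root]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        parent["t1"] = t
        kids = [{"t0": t, "children": None, "label": None} for _ in range(2)]
        parent["children"] = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    counter = [0]

    def emit(node):
        if node["children"] is None:
            counter[0] += 1
            node["label"] = f"sp_{counter[0]:03d}"
            return f"{node['label']}:{t_end - node['t0']:.10f}"
        inner = ",".join(emit(c) for c in node["children"])
        edge = node["t1"] - node["t0"]
        return f"({inner}):{edge:.10f}"

    if n_species == 1:
        return f"(sp_001:{t_end:.10f});"
    body = emit(root)
    # drop the root's zero-length stem: root node edge length is t0=0 -> first split
    return body.rsplit(":", 1)[0] + ";"


def simulate_phylogeny(config: WorldConfig, rng=None) -> dendropy.Tree:
    """Ultrametric Yule tree with tips sp_001..sp_N and positive branch lengths."""
    if config.n_species < 2:
        raise ValueError("need at least 2 species for a phylogeny")
    rng = rng if rng is not None else config.substreams()["tree"]
    newick = _yule_newick(config.n_species, config.birth_rate, rng)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _brownian_tips(tree: dendropy.Tree, rng: np.random.Generator) -> pd.Series:
    """Brownian-motion trait simulated down the tree; one value per tip."""
    values = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = 0.0 if parent is None else values[id(parent)]
        edge = node.edge.length or 0.0
        values[id(node)] = base + rng.standard_normal() * np.sqrt(max(edge, 0.0))
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    return pd.Series(tips).sort_index()


def simulate_traits(tree: dendropy.Tree, config: WorldConfig, rng=None) -> pd.DataFrame:
    """Habit categories and morphometrics with phylogenetic signal.

    A latent trait blends a Brownian-motion component on the tree
    (weight ``trait_signal``) with independent noise; habit categories
    are assigned by latent-rank thresholds at the configured proportions,
    ordered fossorial → arboreal.  Morphometrics follow the verticality
    score in expectation: tail proportion and eye diameter increase,
    body mass decreases, and TL < TT always.
    """
    rng = rng if rng is not None else config.substreams()["traits"]
    bm = _brownian_tips(tree, rng)
    species = bm.index
    n = len(species)
    z_phylo = (bm - bm.mean()) / (bm.std(ddof=0) or 1.0)
    z_iid = rng.standard_normal(n)
    s = config.trait_signal
    latent = np.sqrt(s) * z_phylo.to_numpy() + np.sqrt(1 - s) * z_iid

    props = config.proportions()
    counts = _exact_counts([props[h] for h in HABIT_ORDER], n)
    order = np.argsort(latent, kind="stable")
    habit = np.empty(n, dtype=object)
    pos = 0
    for h, c in zip(HABIT_ORDER, counts):
        habit[order[pos : pos + c]] = h
        pos += c
    habit = pd.Series(habit, index=species, name="habit")
    v = habit.map(HABIT_VERTICALITY).to_numpy()

    ns = config.noise_sd
    log_tt = 2.45 + 0.45 * v + 0.15 * ns * rng.standard_normal(n)
    tt = 10.0**log_tt
    ratio = np.clip(0.06 + 0.30 * v + 0.05 * ns * rng.standard_normal(n), 0.01, 0.48)
    tl = ratio * tt
    mass = 10.0 ** (2.2 - 0.9 * v + 0.2 * ns * rng.standard_normal(n))
    eye = np.maximum(0.5, 2.0 + 3.5 * v + 0.4 * ns * rng.standard_normal(n))
    traits = pd.DataFrame(
        {
            "habit": habit,
            "TT_mm": tt,
            "TL_mm": tl,
            "SVL_mm": tt - tl,
            "mass_g": mass,
            "eye_mm": eye,
        },
        index=pd.Index(species, name="species"),
    )
    assert (traits["TL_mm"] < traits["TT_mm"]).all()
    return traits


def _exact_counts(proportions, n: int) -> list[int]:
    """Largest-remainder apportionment of n among the proportions."""
    raw = np.asarray(proportions, float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    frac_order = np.argsort(-(raw - base), kind="stable")
    for k in frac_order[:rem]:
        base[k] += 1
    return base.tolist()


def _grow_range(
    seed_cell: int, size: int, suit: np.ndarray, nbrs: list, rng, allowed: np.ndarray | None = None
) -> np.ndarray:
    """Spreading-dye growth: contiguous (4-connected) range of ``size`` cells.

    ``allowed`` (boolean) is a hard constraint the dye never crosses.
    """
    n = suit.size
    ok = np.ones(n, bool) if allowed is None else allowed
    in_range = np.zeros(n, bool)
    in_range[seed_cell] = True
    frontier = {c for c in nbrs[seed_cell] if ok[c]}
    while in_range.sum() < size and frontier:
        cand = np.fromiter(frontier, int)
        w = suit[cand] + 1e-9
        pick = cand[rng.choice(len(cand), p=w / w.sum())]
        in_range[pick] = True
        frontier.discard(pick)
        frontier.update(c for c in nbrs[pick] if ok[c] and not in_range[c])
    return in_range


def _rook_neighbors(n_rows: int, n_cols: int) -> list:
    nbrs = []
    for i in range(n_rows * n_cols):
        r, c = divmod(i, n_cols)
        cur = []
        if r > 0:
            cur.append(i - n_cols)
        if r < n_rows - 1:
            cur.append(i + n_cols)
        if c > 0:
            cur.append(i - 1)
        if c < n_cols - 1:
            cur.append(i + 1)
        nbrs.append(cur)
    return nbrs


def simulate_ranges(
    grid: Grid,
    env: pd.DataFrame,
    traits: pd.DataFrame,
    config: WorldConfig,
    rng=None,
    cell_mask: dict | None = None,
) -> tuple[PresenceAbsenceMatrix, pd.Series]:
    """Niche-driven contiguous ranges; returns (PAM, niche optimum per species).

    Each species prefers the tree-cover level at the quantile given by its
    verticality score (arboreal species aggregate where vertical habitat
    structure is high); the range is seeded at the most suitable cell and
    grown by spreading dye to a size drawn around range_fill × n_cells.
    ``cell_mask`` optionally restricts a species to a subset of cells
    (used to plant regionalisation structure).
    """
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    rng = rng if rng is not None else config.substreams()["ranges"]
    tc = env["tree_cover"].to_numpy(float)
    nbrs = _rook_neighbors(grid.n_rows, grid.n_cols)
    n_cells = grid.n_cells
    mat = np.zeros((n_cells, len(traits)), dtype=np.int8)
    optima = {}
    bandwidth = max(tc.std(), 1e-6) * 0.35
    for j, (sp, row) in enumerate(traits.iterrows()):
        v = HABIT_VERTICALITY[row["habit"]]
        q = np.clip(v + 0.05 * rng.standard_normal(), 0.02, 0.98)
        opt = float(np.quantile(tc, q))
        optima[sp] = opt
        suit = np.exp(-0.5 * ((tc - opt) / bandwidth) ** 2)
        allowed = None
        if cell_mask is not None and sp in cell_mask:
            allowed = np.asarray(cell_mask[sp], bool)
            suit = np.where(allowed, suit, 0.0)
        size = int(np.clip(round(n_cells * config.range_fill * rng.lognormal(0.0, 0.35)), 1, n_cells))
        jitter = 1e-9 * rng.random(n_cells)
        seed_scores = np.where(allowed, suit + jitter, -1.0) if allowed is not None else suit + jitter
        seed_cell = int(np.argmax(seed_scores))
        mat[:, j] = _grow_range(seed_cell, size, suit, nbrs, rng, allowed)
    pam = PresenceAbsenceMatrix.build(grid.cell_ids, list(traits.index), mat)
    return pam, pd.Series(optima, name="niche_optimum")


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic study system with ground truth."""
    streams = config.substreams()
    grid = generate_grid(config)
    env = simulate_environment(grid, config, streams["env"])
    tree = simulate_phylogeny(config, streams["tree"])
    traits = simulate_traits(tree, config, streams["traits"])
    pam, optima = simulate_ranges(grid, env, traits, config, streams["ranges"])
    truth = GroundTruth(
        verticality=traits["habit"].map(HABIT_VERTICALITY),
        habit=traits["habit"],
        niche_optimum=optima,
    )
    world = SyntheticWorld(config, grid, env, tree, traits, pam, truth)
    world.validate()
    return world


def _balanced_two_clade_tree(n_species: int, birth_rate: float, rng) -> tuple[dendropy.Tree, set]:
    """Ultrametric tree whose two basal clades hold n/2 species each."""
    n1 = n_species // 2
    n2 = n_species - n1
    parts = []
    for n_sub, offset in ((n1, 0), (n2, n1)):
        sub = dendropy.Tree.get(data=_yule_newick(n_sub, birth_rate, rng), schema="newick", preserve_underscores=True)
        depth = sub.max_distance_from_root()
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / depth
        for k, taxon in enumerate(sorted(sub.taxon_namespace, key=lambda t: t.label)):
            taxon.label = f"sp_{offset + int(taxon.label[3:]):03d}"
        s = sub.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip().rstrip(";")
        parts.append(s)
    tree = dendropy.Tree.get(data=f"({parts[0]}:0.5,{parts[1]}:0.5);", schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    clade_a = {f"sp_{i:03d}" for i in range(1, n1 + 1)}
    return tree, clade_a


def make_split_world(config: WorldConfig) -> SyntheticWorld:
    """A world with a planted two-clade, two-halves structure.

    The phylogeny's two balanced basal clades are tied to the grid's
    latitudinal halves: one clade's species can only occupy northern
    rows, the other southern rows.  Ground truth records each species'
    clade and each cell's planted region, the target of
    regionalisation-recovery tests.

    Recovery studies use ``range_fill`` around 0.35: with much smaller
    ranges, subclades develop their own regional turnover inside each
    half, and that legitimate substructure competes with the planted
    two-region signal.
    """
    streams = config.substreams()
    grid = generate_grid(config)
    env = simulate_environment(grid, config, streams["env"])
    tree, clade_a = _balanced_two_clade_tree(config.n_species, config.birth_rate, streams["tree"])
    traits = simulate_traits(tree, config, streams["traits"])
    rows = grid.cells["row"].to_numpy()
    half = config.n_rows // 2
    north = (rows < half).astype(float)
    south = (rows >= half).astype(float)
    masks = {sp: (north if sp in clade_a else south) for sp in traits.index}
    pam, optima = simulate_ranges(grid, env, traits, config, streams["ranges"], cell_mask=masks)
    clade = pd.Series({sp: ("A" if sp in clade_a else "B") for sp in traits.index}, name="clade")
    region = pd.Series(np.where(rows < half, 1, 2), index=grid.cell_ids, name="region")
    truth = GroundTruth(
        verticality=traits["habit"].map(HABIT_VERTICALITY),
        habit=traits["habit"],
        niche_optimum=optima,
        clade=clade,
        region_label=region,
    )
    world = SyntheticWorld(config, grid, env, tree, traits, pam, truth)
    world.validate()
    return world


def simulate_sar_field(W, X, beta, lam: float, sigma: float, rng) -> np.ndarray:
    """Draw y = Xβ + u with u = λWu + ε, ε ~ N(0, σ²I).

    The response surface of the spatial error model, used for
    parameter-recovery studies; (β, λ, σ) are the recoverable truth.
    """
    Wm = W.matrix if hasattr(W, "matrix") else np.asarray(W, float)
    n = Wm.shape[0]
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    rng = np.random.default_rng(rng)
    eps = sigma * rng.standard_normal(n)
    u = np.linalg.solve(np.eye(n) - lam * Wm, eps)
    return X @ beta + u
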