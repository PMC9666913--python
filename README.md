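# vertistrat

Macroecology of **vertical stratification** in snake assemblages: where on
the underground ↔ canopy axis do the species of each grid cell live, and
what drives that pattern across a region?

The package implements, end to end and on fully synthetic data with known
ground truth, the analysis workflow used to study vertical niche structure
in assemblages of Chacoan snakes:

1. **Assemblage construction** — a presence–absence matrix (PAM) of cells ×
   species on an equal-area lattice (55 × 55 km by default), discarding
   species-poor cells (fewer than 5 species).
2. **Species metrics** — an ordinal *verticality* score from the habit
   category (fossorial 0 → arboreal 1), the *tail proportion* TL/TT, and a
   *fossoriality score*: the species score on the first axis of a
   correlation-matrix PCA of body mass, eye diameter, verticality and tail
   proportion, sign-fixed so positive = arboreal.
3. **Null models and SES** — per-cell observed mean metric compared with a
   richness-preserving null that redraws each cell's species from the pool
   without replacement, weighted by grid occupancy (1000 replicates);
   SES = (observed − mean(null)) / SD(null).
4. **Environmental drivers** — spatial error models y = Xβ + u,
   u = λWu + ε fitted by maximum likelihood for **all predictor subsets**,
   ranked by AICc, averaged with Akaike weights
   w_m = exp(−Δ_m/2)/Σexp(−Δ/2); variable importance is the summed weight
   of models containing the variable; fit quality is the pseudo-R², the
   squared Pearson correlation of weighted fitted values with
   observations. The neighbourhood radius of W comes from the distance
   class where Moran's I is strongest.
5. **Phylogenetic regionalization** — pairwise phylo-Sørensen beta
   diversity (1 − 2·shared branch length/(PD₁+PD₂)) between cell
   assemblages, UPGMA clustering with the optimal number of regions from
   the explained-dissimilarity elbow, region-level evolutionary
   distinctness (mean between-region beta), and NMDS ordination.

A synthetic-world generator (`vertistrat.synthetic_world`) produces the
grid, latitudinal environmental gradients, a Yule phylogeny, habit and
morphometric traits with tunable phylogenetic signal, and contiguous
spreading-dye ranges, recording the ground truth every stage must recover.

## Who this is for

Macroecologists and community phylogeneticists who want a tested,
reproducible Python implementation of assemblage null-model SES mapping,
spatially explicit multimodel inference, and phyloregion delineation —
or who want a controlled synthetic benchmark for those methods.

## Worked example

```python
import numpy as np
from vertistrat.assemblage_grid import filter_sparse_cells
from vertistrat.null_ses import NullSpec, ses_field
from vertistrat.synthetic_world import WorldConfig, generate_world
from vertistrat.trait_metrics import species_metrics

world = generate_world(WorldConfig(seed=42))          # 12×10 grid, 80 species
pam = filter_sparse_cells(world.pam, min_richness=5)
metrics = species_metrics(world.traits.loc[list(pam.species)])
field = ses_field(pam, metrics["verticality"], NullSpec(n_reps=1000, seed=42))
print(field.head(3).round(3))
r = np.corrcoef(field["ses"], world.env.loc[list(pam.cells), "tree_cover"])[0, 1]
print(f"corr(SES verticality, tree cover) = {r:.3f}")
```

prints

```
         observed  null_mean  null_sd    ses  undefined
cell_id
c0_0          1.0      0.457    0.089  6.126      False
c0_1          1.0      0.451    0.083  6.626      False
c0_2          1.0      0.452    0.087  6.333      False
corr(SES verticality, tree cover) = 0.966
```

The northern cells (row 0) hold purely arboreal assemblages — observed
mean verticality 1.0 against a null expectation near 0.45, hence strongly
positive SES — and across all cells the verticality SES tracks tree cover
(r = 0.97), the planted niche-environment link.

The same analysis runs from the shell:

```bash
vertistrat all --seed 42 --out runs/demo
```

which reports `completed stages: simulate, assemble, metrics, ses, sar,
phyloregion` and writes every intermediate artifact (PAM, SES fields,
per-model AICc tables, averaged coefficients, region labels, NMDS
coordinates) as CSV plus a `manifest.json` with checksums; on this demo
the averaged spatial-error models reach pseudo-R² ≈ 0.99 for the
verticality SES with a neighbourhood radius d* ≈ 89 km. Individual
stages are available as `vertistrat simulate/assemble/metrics/ses/sar/
phyloregion`.

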