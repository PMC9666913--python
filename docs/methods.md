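# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the design decisions behind `vertistrat`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The scientific setting

Snake species differ in vertical niche: fossorial species live underground
(small bodies, short tails, reduced eyes), arboreal species in vegetation
(long tails, large eyes, slender bodies). At the assemblage level this
produces geographic structure — more arboreal assemblages where habitat is
vertically stratified (high tree cover, warm and stable climate), more
fossorial assemblages where soils and open habitat favour burrowing. The
package quantifies that structure on an equal-area grid and asks which
environmental variables explain it, and whether phylogeny mirrors it.

## Species-level metrics

* **Verticality** is an evenly spaced ordinal coding of the six habit
  categories: fossorial 0.00, semifossorial 0.25, terrestrial 0.50,
  aquatic 0.50, semiarboreal 0.75, arboreal 1.00. The literature that
  uses this metric never prints its numeric coding; even spacing preserves
  the fossorial → arboreal ordering every downstream interpretation relies
  on, and aquatic maps to ground level (0.50). The coding is a function
  argument, not a constant, so alternatives are one keyword away.
* **Tail proportion** is TL/TT exactly, with hard validation
  (TT > 0, 0 ≤ TL < TT, errors name the species).
* **Fossoriality score** is the species score on the first axis of a PCA
  of body mass, eye diameter, verticality and tail proportion. The PCA is
  on the correlation matrix (the inputs are on incommensurate scales);
  body mass is log10-transformed by default (snake masses span orders of
  magnitude; switchable); the axis-1 sign is fixed so the verticality
  loading is positive, making positive scores mean greater arboreality.
  Missing morphometrics are a hard error — no silent imputation.

## Null models and standardized effect sizes

The null preserves each cell's species richness: for every replicate and
every cell of richness S, S distinct species are redrawn from the regional
pool without replacement, with draw probability proportional to a weight.
The default weight is each species' grid occupancy — widespread species
enter null assemblages about as often as they enter observed ones, which
is the point of occupancy weighting: a cosmopolitan species should not
make every cell look unusual. Uniform and inverse-occupancy weights, and
a label-shuffle variant (permuting metric values across species), are
provided because the literature's verbal description ("weighted sampling
to control the influence of widespread species") does not pin down one
scheme; the occupancy-proportional default is our interpretation.

Sampling without replacement with probability proportional to weight is
implemented by the Gumbel-top-k device: per cell, add standard Gumbel
noise to log-weights and take the S largest keys. This is exactly
successive sampling (Plackett–Luce) and vectorises over cells.

SES = (observed − mean(null)) / SD(null), with the sample (n−1)
denominator for SD. A cell whose null distribution is degenerate (all
replicate values identical — e.g. a constant metric, or richness equal to
the pool size) is flagged `undefined` rather than given an infinite
score; degeneracy is detected by zero range, since floating-point
round-off in the mean can leave a ~1e-16 SD on a constant column.
Aggregation is the assemblage mean by default (sum by option).

Calibration is the core correctness property: when observed assemblages
are themselves draws from the null, SES across cells has mean ≈ 0 and
variance ≈ 1. The acceptance suite checks this at 200 cells × 60 species
× 500 replicates.

## Spatial statistics

Moran's I is I = (n/S0)·(zᵀWz)/(zᵀz) with z the centred values; the
expectation under no autocorrelation is −1/(n−1); inference is by
permutation of values across cells, two-sided on |I − E[I]|. The
correlogram (`moran_profile`) uses 10 equal-width distance classes from
the smallest pairwise distance to half the maximum (standard correlogram
practice), binary weights per class; the neighbourhood radius d* is the
upper bound of the class with the largest |I| (absolute value, because
negative structure is also structure; a `positive_only` flag restricts to
positive peaks). Ties go to the smallest distance.

Spatial weights are distance-band matrices w_ij = f(d_ij) for
0 < d_ij ≤ d*, with f ∈ {binary, 1/d, 1/d²}, row-standardised by default.
Cells with no neighbour (islands) are an error unless explicitly allowed.
`select_weighting` fits the full model under each candidate matrix and
keeps the one whose residuals show the least autocorrelation — scored as
the **worst** |Moran's I| of the residuals across *all* candidate
structures, because judging each fit only under its own matrix lets a
mismatched long-range neighbourhood hide exactly the short-range residual
structure it failed to absorb.

## Spatial error models and multimodel inference

The response (a per-cell SES field) and all predictors are z-standardised,
so coefficients are standardized effects. The spatial error model (SEM)

    y = Xβ + u,  u = λWu + ε,  ε ~ N(0, σ²I)

is fitted by maximum likelihood: for fixed λ, (I − λW) filters both sides
and β, σ² are concentrated out by least squares on the filtered system;
the profile log-likelihood

    ℓ(λ) = −(n/2)(log 2πσ̂²(λ) + 1) + Σᵢ log(1 − λωᵢ)

uses the eigenvalues ωᵢ of W for the Jacobian term, and λ is maximised by
bounded Brent search over (1/ω_min, 1/ω_max) with tolerance 1e-8.
Row-standardised matrices built from symmetric neighbourhoods have real
spectra (similarity to D^(−1/2)AD^(−1/2)); a substantially complex
spectrum raises. Fitted values are trend + signal,
Xβ̂ + λ̂W(y − Xβ̂). The error form (SEM) rather than the lag model is
used because the residual-autocorrelation-removal and pseudo-R² workflow
this package follows is the SAR-error standard in the macroecological
literature.

All 2^p predictor subsets (including the intercept-only model; p ≤ 15 as
a combinatorial guardrail) are fitted and ranked by AICc,

    AICc = −2ℓ + 2K + 2K(K+1)/(n − K − 1),

where K counts every free parameter: each β, the intercept, λ, and σ².
Akaike weights are exp(−Δ/2) normalised; coefficients are averaged with
zeros for models not containing a variable (full/shrinkage averaging, the
common default of the multimodel-inference framework; conditional
averaging would be a one-line change); importance is the summed weight of
models containing the variable; pseudo-R² is the squared Pearson
correlation between the weight-averaged fitted values and the
observations. The sensitivity rerun drops all species of listed genera
(ids follow the `Genus_species` convention), re-filters cells, recomputes
SES and refits everything, returning main and reduced analyses side by
side.

## Phylogenetic regionalization

Phylo-Sørensen dissimilarity between cells i, j is (b+c)/(2a+b+c), with
a the branch length shared by the two assemblages and b, c their unique
branch lengths; equivalently 1 − 2a/(PDᵢ+PDⱼ). It is computed sparsely
from the branches × cells incidence (a branch is in a cell iff any tip
below it occurs there). The root edge is excluded and paths are measured
to the species pool's most recent common ancestor — including a root stem
would make fully disjoint assemblages spuriously similar. On a star tree
the index reduces exactly to taxonomic Sørensen, a key identity the tests
assert at 1e-12 against a brute-force branch-set oracle.

Cells are clustered by UPGMA (average linkage, the default of the
regionalization tools this mirrors; complete and Ward available). The
number of regions k* is chosen by the elbow of the explained-dissimilarity
curve e(k) = 1 − (mean within-region dissimilarity)/(mean overall
dissimilarity): the k maximising perpendicular distance to the chord from
(1, e₁) to (k_max, e_kmax); a flat curve warns and returns k* = 1.
Region-level evolutionary distinctness is the mean between-region
dissimilarity (region pairs averaged over their cell pairs, not
centroids). Regions are ordinated by non-metric MDS (SMACOF with monotone
regression, 20 seeded restarts, best Kruskal stress-1 kept, coordinates
centred).

## The synthetic world

The generator emulates the inputs of the real analysis with one seed
split into named substreams (env, tree, traits, ranges), so re-running or
extending one stage never perturbs another.

* **Grid**: planar row-major lattice, 55-km cells by default, row 0 north.
* **Environment**: ten predictors named after the real candidate set
  (annual mean temperature, precipitation seasonality, AET, NPP, NDVI,
  EVI evenness, homogeneity, tree cover, coarse fragments, sand).
  Temperature and tree cover decline strictly with row index before
  noise (the dominant latitudinal axis); tree cover also carries a
  longitudinal component so the two are correlated but not collinear;
  sand and the remaining fields are Gaussian-smoothed white noise
  (spatially autocorrelated; smoothing σ ≈ 1 cell keeps chance
  collinearity among ten variables below the VIF threshold on small
  grids). A `collinear` flag appends a near-duplicate of tree cover to
  exercise the VIF screen.
* **Phylogeny**: forward pure-birth (Yule) simulation to n tips, one
  further exponential waiting time to the present, giving an ultrametric
  tree with positive branch lengths, tips `sp_001…`.
* **Traits**: a latent trait blends a Brownian-motion realisation on the
  tree (weight = `trait_signal`) with independent noise; habit categories
  come from latent-rank thresholds at configured proportions, ordered
  fossorial → arboreal, so habits are phylogenetically clustered exactly
  to the degree requested. Default proportions follow the published
  Chacoan fauna (70 terrestrial, 22 fossorial, 21 semifossorial,
  17 arboreal, 10 semiarboreal per 140; aquatic 0 by default and
  configurable). Morphometrics follow the verticality score in
  expectation — tail proportion and eye diameter increase, body mass
  decreases — with lognormal-scale noise and TL < TT enforced.
* **Ranges**: spreading dye. Each species prefers the tree-cover level at
  the quantile given by its verticality score; the range seeds at the
  most suitable cell and grows through 4-connected neighbours with
  probability proportional to suitability until a size drawn around
  `range_fill` × n_cells. Ranges are therefore contiguous, spatially
  autocorrelated, and niche-linked — arboreal species aggregate where
  tree cover is high, which is what the SES and SAR stages must detect.
* **Planted regionalization** (`make_split_world`): two balanced Yule
  clades joined at the root, each confined to one latitudinal half of the
  grid (a hard mask the dye cannot cross). Ground truth records clades
  and cell regions. These recovery studies use `range_fill` ≈ 0.35:
  with much smaller ranges each half develops legitimate subclade
  turnover of its own, which competes with the planted two-region signal
  in the elbow criterion.
* **SAR ground truth** (`simulate_sar_field`): draws y = Xβ + (I−λW)⁻¹ε
  for parameter-recovery studies; the stored (β, λ, σ) are the targets.

What the generator does **not** emulate: real geometry (coastlines,
irregular region outlines), range-size frequency distributions fitted to
real faunas, observational error in occurrences, trait measurement error,
and non-ultrametric or dated phylogenies. Passing tests therefore show
the machinery is correct and calibrated under clean, known-truth
conditions; they do not certify conclusions about any real fauna.

## Problem sizes and numerical choices

The default demo world is a 12 × 10 grid with 80 species; the SES stage
uses 1000 replicates (500 in the acceptance script's calibration study,
which matches its published condition of 200 cells × 60 species); SAR
recovery uses 100 replicates of a 20 × 20 lattice with λ = 0.6,
β = (1.5, −1.0), σ = 1. These sizes were chosen as the smallest at which
the statistical properties under test are comfortably identifiable.
Other pinned choices: λ-search tolerance 1e-8 with a warning at the
boundary; VIF elimination is stepwise (drop the worst, recompute) rather
than one-shot, because one-shot removal can discard variables that become
acceptable after a single elimination — the report records both readings;
aggregation of pixel values to cells is the mean over contained pixel
centres; distance-class ties and identical-candidate ties resolve to the
first/smallest deterministically; all CSV output uses a fixed float
format so manifests are byte-stable.

## Known limitations

* The SEM eigenvalue Jacobian is dense (O(n³) once per weight matrix);
  fine to a few thousand cells, not for continental rasters.
* Occupancy weighting is one reading of "weighted sampling"; results for
  real data should be checked under the alternative weightings provided.
* The elbow rule for k* is a heuristic; the explained-dissimilarity curve
  is returned so other rules can be applied.
* NMDS stress is reported but no Shepard diagram is drawn; plotting is
  deliberately out of scope beyond CSV artifacts.
* Raster input is limited to pixel-centre tables and per-cell CSV;
  GeoTIFF I/O is not included.
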