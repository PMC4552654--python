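# Methods

`forestprio` compares coarse (open, satellite-inventory style) and detailed
(stand-level) forest inventory data as inputs to spatial conservation
prioritization. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic landscapes do and do not show
about real data.

## Conservation-value indices

For each tree-species group *s* (pine, spruce, birch, other broadleaved) the
per-pixel index is

    index_s = B_s(D_s) · V_s

with `V_s` the growing-stock volume (m³/ha), `D_s` the mean stem diameter
(cm), and `B_s` a four-parameter logistic benefit

    B(d) = floor + (ceiling − floor) / (1 + exp(−k · (d − d₅₀))).

The sigmoid encodes that structural features valuable for boreal forest
biodiversity (large stems, dead-wood potential, microhabitats) accumulate in
older stands and saturate. Defaults: midpoints `d₅₀` = 30 cm (pine, spruce),
25 cm (birch), 20 cm (other broadleaved); steepness `k` = 0.3/cm; floor 0,
ceiling 1. These are documented stand-ins for expert-elicited curves and are
fully configurable; nothing downstream depends on their exact values beyond
monotonicity.

Crossing the four species indices with the five Finnish site-fertility
classes (herb-rich, herb-rich heath, mesic, sub-xeric, xeric) yields 20
"forest type" features. The split is value-conserving: each pixel's index
mass moves into exactly one fertility layer per species.

Feature weights default to a simple expert-style scheme: forest types on the
two most fertile classes ×2, deciduous species groups ×1.5
(multiplicatively), everything else 1 — deciduous stands on fertile soil are
rarer and ecologically disproportionately valuable.

A condition layer in [0, 1] discounts value where forestry operations are
planned: clear-cut 0.0, heavy thinning 0.3, light thinning 0.6, none 1.0
(the semantics is fixed, the numbers are configurable). In the pipeline the
condition applies only to the detailed-data runs, and only inside the
detailed coverage area, because planned operations are known from the
stand-level inventory alone.

## Stand segmentation (coarse-data preprocessing)

Coarse inventories report a single overall mean diameter, while the index
needs one per species group. Segments are delineated with a directed-trees
algorithm: each pixel links to the 8-neighbour minimising the Euclidean
distance in (weighted) band space; the resulting trees are the initial
segments. Two deterministic merge phases follow:

1. adjacent segments whose mean vectors are closer than `max_heterogeneity`
   merge (smallest distance first, ties toward the smaller label pair);
2. segments below `min_segment_px` merge into their most similar 4-adjacent
   neighbour, globally smallest segment first, until the floor is met or a
   segment spans an entire connected component of the mask.

Design choices worth noting:

* A pixel whose finite neighbour distances are all equal (a plateau,
  including constant regions) becomes a tree root; this avoids link cycles
  and makes constant inputs collapse to one segment after merging.
* The spec of the final product requires 4-connected segments, but 8-way
  links can produce diagonally connected trees; initial trees are therefore
  split into 4-connected components before merging. Merging is 4-adjacent,
  which preserves 4-connectivity.
* The small-segment merge chain pops the globally smallest segment
  regardless of the floor, so the floor only sets the stopping point — this
  makes the segment count exactly non-increasing in `min_segment_px`.
* `min_segment_px` targets stands of ~1–2 ha: 25 px at 20 m resolution, 3 px
  at the 60 m pipeline resolution.

Per-group segment attributes: volume = plain mean over pixels; diameter =
volume-weighted mean of the pixel overall diameters,
`Σ(d·V_s)/Σ V_s`, zero where the group is absent. The pipeline segments on
five bands — overall mean diameter plus the four per-group volumes; the
diameter band stands in for stand mean height, which the synthetic coarse
data does not carry (the two are strongly collinear in practice).

## Greedy complementarity ranking

The ranker iteratively removes the least valuable cell (additive benefit
function). With `p_j` the remaining proportion of feature *j*'s
condition-adjusted landscape total and `q_ij` cell *i*'s fixed share of that
total, the marginal loss is

    δ_i = Σ_j w_j · (p_j^z − (p_j − q_ij)^z),     0 < z ≤ 1.

The concave power (default z = 0.25, the usual convention for this removal
rule; not a calibrated value) implements repeated range-size normalization:
as a feature is depleted, further losses of it cost more, so rarity raises
priority. Removing cells in batches (`removal_batch`) is supported as a
speed option but the default — and everything reported — uses batch 1.

Numerical and determinism choices:

* Ties in δ break toward the lowest row-major cell index; together with a
  from-scratch brute-force reference sharing the tie-break this makes the
  implementation exactly testable on small instances.
* `p − q` is clipped at 0 before the power to guard against one-ulp
  negatives from incremental subtraction; `p` itself is likewise clipped.
* δ is recomputed for all remaining cells each iteration over a sparse
  cell×feature layout (classified stacks are ~4/20 sparse); arrays are
  compacted whenever more than half the cells have been removed, keeping the
  per-iteration cost proportional to the remaining problem.
* z = 0.25 and z = 0.5 are evaluated with nested square roots rather than
  `pow`, which roughly halves the ranking time.
* Performance curves are suffix sums of the removed values divided by their
  own total, so they start at exactly 1.0, are non-increasing, and end at
  exactly 0.0; a feature whose total is zero gets NaN curves rather than an
  invented value.
* An all-zero stack still ranks (pure tie-break order) with a warning.
* The rank raster maps the N valid cells bijectively onto {1/N, …, 1};
  NaN outside the mask.

## Matrix connectivity

The connectivity-transformed value of feature *r* at cell *i* is

    Σ_c M[r][c] · Σ_j exp(−α_c · d(i, j)) · layer_c(j) · cell_area,

a negative-exponential kernel smoothing mixed across features by the
multiplier matrix M (asymmetry allowed: columns give, rows receive). The
kernel scale follows the standard convention α = 2 / (mean dispersal
distance); 2.0 km ⇒ α = 0.001 m⁻¹. The default M has 1 on the diagonal, 0.5
between fertility classes of the same species group and 0.2 across species
groups, so every forest type aids every other's connectivity a little.

Choices:

* The kernel is truncated where it falls below `kernel_truncation` (default
  1e-6) relative to its peak; no toroidal wrap, so border cells see fewer
  contributors (documented edge bias).
* After mixing, values outside the valid mask are dropped and each layer is
  rescaled to its pre-transform landscape total: connectivity redistributes
  value rather than inflating it, keeping representation fractions
  comparable across runs. Whether to rescale is a genuinely open design
  point; conservation was chosen and is part of the package contract.
* Grids with ≤ 4096 valid cells are evaluated by an exact pairwise distance
  matrix; larger grids use FFT convolution. The switch only changes
  floating-point round-off (~1e-11 at landscape magnitudes).

## Comparison battery

* **Decile Jaccard matrices**: each rank raster is cut into ten equal rank
  intervals [0, 0.1), …, [0.9, 1.0] and every interval pair across two runs
  is scored with the Jaccard coefficient |A∩B|/|A∪B| (0 for an empty
  union). Binning is by rank *value*; for a bijective batch-1 ranking this
  equals equal cell counts up to rounding, which resolves the value-vs-count
  ambiguity in the cheapest testable way. Two independent random rankings
  give entries near 1/19 (two random 10% subsets).
* **Validation overlays**: the distribution (median, quartiles, n) of rank
  values inside each validation mask; empty masks are flagged absent rather
  than reported as zeros.
* **Cross-loading**: the representation of one stack's features inside the
  top fraction of another run's ranking, summarised per feature, per
  fertility class, and overall — the cost of ranking with coarser data.

## Synthetic landscapes

The generator emulates the statistical structure of Finnish inventory data:

* Stationary Gaussian random fields with an exponential correlogram
  (circulant embedding on a doubled grid; negative embedding eigenvalues
  clipped — the approximation error is negligible at the default 600 m
  range). Fields drive volumes (lognormal, conifer-dominated means 60/50/
  20/10 m³/ha), diameters (truncated normal, partially correlated with
  volume), fertility classes (quantile-thresholded at prevalences
  0.05/0.15/0.50/0.20/0.10 — herb-rich and xeric rare), water (~12 %), and
  planned operations (15 % of managed land).
* Validation patches are rejection-sampled disjoint quasi-circular blobs:
  protected-area analogues (mean 13.54 ha), acquisition analogues (5.36 ha)
  and woodland-key-habitat analogues (0.61 ha ≈ 1–2 cells at 60 m), with
  within-patch diameters and volumes boosted ×1.5–1.8 to represent old,
  high-value forest.
* The coarse variant applies a disk mean filter (strict-inequality disk, so
  radius = cell size is the identity; mask-aware normalized convolution, so
  shorelines are not diluted) plus zero-truncated Gaussian noise, and
  collapses the per-species diameters into one volume-weighted overall
  diameter before smoothing. Smoothing with zero noise conserves landscape
  totals to well under 1 % (interior exactly; edges approximately).
* Default extent 200×200 cells at 60 m (144 km²), a desk-scale stand-in for
  a province-scale analysis.

What the generator does **not** emulate: real satellite-estimate error
distributions (the noise SDs are placeholders, not calibrated), mire/
peatland typology, temporal forest growth, and land-ownership structure.
Passing tests therefore demonstrate the *mechanics and direction* of the
coarse-vs-detailed comparison — small high-value patches losing contrast
under degradation, coarse-derived rankings covering less of the detailed
features — not its real-world effect sizes.

## Pipeline and problem sizes

The default experiment grid is six runs: three input data sets (`coarse` 4
features, `coarseClass` 20, `detailClass` 20 + condition layer) × with/
without connectivity. `detailClass` is a composite: detailed indices inside
a spatially coherent coverage mask (default 45 % of land, mirroring the
partial availability of stand-level data), coarse indices elsewhere.

Reported computations use 100×100-cell landscapes for the full six-run grid
and the default 200×200 landscape for the two-run directional comparison —
sizes chosen so a complete analysis runs in minutes on one core while
keeping ≥ 40 independent autocorrelation ranges per side. Everything is
deterministic under a fixed config + seed; artifacts are stamped with a
config hash and reruns against a mismatched output directory are rejected.

## Known limitations

* The greedy ranker is a heuristic; no optimality claims.
* Border cells are biased low under connectivity (truncated kernel, no
  wrap).
* The directed-trees merge criterion (nearest segment-mean vector) is a
  documented choice among several defensible ones; no claim is made that it
  reproduces any particular production segmentation tool.
* Benefit-curve parameters, feature weights, condition effects and
  connectivity multipliers are configurable conventions, not fitted values;
  conclusions from the synthetic experiments are directional only.
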