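# Methods

This note documents the models and procedures implemented in `divmap`,
the defaults and why they were chosen, the numerical conventions, and
what results on the synthetic landscape do and do not demonstrate.

## Grid and circular-neighborhood re-sampling

The analysis grid is a regular lon/lat grid in WGS84 decimal degrees
with half-open cells [x₀, x₀+Δ) × [y₀, y₀+Δ); a point on a boundary
belongs to the cell on its east/north side. The origin snaps down to a
multiple of the cell size, so cell boundaries — and hence every per-cell
statistic — do not depend on the sampling extent. All distances are in
degree space; no geodesic correction is applied (at the default scale,
1° ≈ 111 km in latitude).

Re-sampling copies each tree into every cell of a circular neighborhood.
Two anchoring rules are provided:

- **node-anchored (default):** the tree snaps to its nearest grid node
  (ties east/north) and a fixed stencil is applied — all cells whose
  centers lie *strictly* within diameter/2 of the node. For Δ = 1/6° and
  diameter 1° this is the 6×6 node block minus its four corners, exactly
  32 cells, so record totals are exact multiples of the tree count
  (1,504 trees → 48,128 records → 866,304 allele copies at 9 complete
  diploid loci). This is the only simple geometric rule consistent with
  a constant 32 cells per tree, and it makes the stencil independent of
  where the tree sits inside its cell.
- **tree-centered (`anchor="tree"`):** the circle is centered on the
  tree itself; the cell count then varies with position, 26–32 cells for
  the default geometry with mean π(d/2)²/Δ² ≈ 28.3. Provided for
  sensitivity analysis; totals are no longer exact multiples.

The grid is extended, never clipped, so border trees contribute a full
stencil. The strict (center *inside* the open disk) rule means a
diameter equal to the cell size yields an empty stencil; this degenerate
case is exercised in tests rather than forbidden.

## Per-cell statistics

Statistics are computed over the *re-sampled* trees of each cell — one
tree legitimately contributes to up to 32 cells; no de-duplication is
applied, since smoothing over the neighborhood is the point of the
design. Cells with fewer than `min_n = 20` re-sampled trees report only
Na and locally common alleles; rarefied Na, He, Ho, F and GD are NA
there (not interpretable at small n).

- **Na**: mean over data-bearing loci of the number of distinct alleles.
- **Rarefied Na**: hypergeometric rarefaction to `g = 40` genes.
  "Minimum sample size of 20 trees" is interpreted as 20 diploid
  individuals = 40 genes, matching gene-based rarefaction software
  conventions; override with `rarefaction_g`. Computed via log-gamma
  binomials for numerical stability; the exact-fraction combinatorial
  value is the test oracle. A cell's value is NA unless *every*
  data-bearing locus reaches g genes, so the rarefied and raw means run
  over the same locus set and rarefied Na ≤ Na holds cell-wise (with
  per-locus NAs the two means could otherwise cross for contrived
  missing-data patterns).
- **Locally common alleles**: counted when within-cell frequency is
  strictly > 5 % (the strict reading of "higher than 5 %") and the
  allele is present in ≤ 25 % of *occupied* cells. Empty cells carry no
  frequency information, hence the occupancy denominator is occupied
  cells, not the full grid.
- **He, Ho**: per locus then averaged over loci with data; He uses the
  plain plug-in 1 − Σp̂² (no small-sample correction), the convention of
  the spreadsheet tools this pipeline mirrors.
- **F** = 1 − Ho/He per *polymorphic* locus, then averaged — not
  computed from cell-mean He and Ho. Loci with He = 0 are excluded; a
  cell monomorphic at every locus has F = NA.
- **GD** to reference: the squared codominant single-locus distance
  (0/1/2/3/4 by shared-allele pattern) summed over loci where both
  genotypes are present, averaged over the cell's re-sampled trees.

Missing genotypes are whole-locus (a half-missing pair is a hard parse
error, preventing biased gene counts); per-locus gene counts exclude
them and statistics average over loci with data.

## Coordinate cleaning

The climate screen samples each tree's cell in a stack of bioclim-style
rasters and flags reverse-jackknife outliers. The critical threshold is
t = (0.95·√n + 0.2)·(range/50); a value at either extreme of the sorted
sample separated from the body by a gap > t is an outlier, working
outward from the most extreme qualifying gap per tail. If the rule would
flag half the sample or more there is no meaningful "body" and nothing
is flagged — this guard handles small symmetric samples (e.g. {−1,0,1})
where every inter-point gap formally exceeds the range-scaled threshold.
The screen is affine-invariant. A sample is excluded when outlying on
≥ 2 layers (one layer is allowed as ordinary climatic extremeness).
The admin check (distance from the declared level-1 polygon > 1/3°,
i.e. 20 arcminutes, using shapely planar distance) is optional and only
runs when polygons are supplied; unknown admin names flag as
unresolvable without excluding.

## Admixture model and ΔK

The clustering model is the standard admixture likelihood: each of the
2 allele copies of individual i at locus l is drawn from
Σ_k Q_ik P_{k,l,·}. It is fitted by EM (exact E-step over per-copy
responsibilities; closed-form M-step) with `n_runs` random restarts
(Dirichlet(1) memberships, perturbed pooled frequencies), replacing
Bayesian MCMC samplers with a deterministic desk-scale estimator that
has the same Q/P semantics. Frequencies are floored at 10⁻⁶ and
renormalized, preventing −∞ log-likelihoods from private alleles; the
log-likelihood is non-decreasing across iterations. K = 1 collapses to
the pooled multinomial in a single iteration.

Evanno's ΔK = |L′(K+1) − L′(K)| / sd L(K) is computed from the restart
log-likelihoods (an MCMC-based tool would use estimated ln P(D) across
runs — a documented deviation). Deterministic restarts introduce one
edge case MCMC never shows: at a strongly identified K every restart can
converge to the bitwise-identical optimum, making sd = 0 exactly while
the second difference is large. Since shrinking run-to-run spread at
fixed curvature *increases* support, sd = 0 with nonzero curvature is
reported as ΔK = +∞ (ties broken toward the smallest K); sd = 0 with
zero curvature, or a single run, leaves ΔK undefined and excluded.

Cluster probability maps average Q over the re-sampled trees per cell,
NA below `min_n`; the maps sum to 1 across clusters cell-wise. The
"unassigned" band for map classification defaults to membership
0.4–0.6 and affects display classes only.

## Conservation gap analysis and coverage

Missing alleles are the set difference of per-locus allele sets between
in situ and ex situ samples; the richness map counts distinct missing
alleles among each cell's re-sampled trees (0 on occupied cells with
none, NA off the sampled area).

The distribution surface may be any user raster; the built-in scorer is
a transparent percentile climate envelope (fraction of variables inside
the presence envelope) — a stand-in for external niche-modeling tools,
which are out of scope. The 10-percentile training presence threshold
is the largest observed training score with ≤ 10 % of training
presences strictly below it (so the binary map keeps ≥ 90 % of training
presences; pct = 0 gives the minimum score). Pseudo-absences are drawn
uniformly in the presence bounding box expanded by 10 % per side, 5 per
presence; the 80/20 train/test split is seeded. AUC is rank-based with
ties at ½ (delegated to scikit-learn; brute-force pairwise comparison
is the test oracle), and κ is Cohen's kappa at the supplied threshold,
or maximized over observed scores when none is given (reporting the
maximizer), since a single κ without a stated threshold is otherwise
not reproducible. Coverage percentages are computed over
modeled-present cells: ≥ 20 trees / 1–19 / 0.

## Synthetic landscape

The generator draws clumped tree locations (cluster centers plus
Gaussian scatter, with dedicated clusters at every planted feature),
then genotypes per locus from mixture frequencies
p = q·p_A + (1−q)·p_B, where q follows a logistic north–south cline.
Inbreeding uses the F-mixture law — with probability F one draw is
duplicated — giving P(hom ii) = p_i² + F·p_i(1−p_i) and
E[1 − Ho/He] = F_true, which turns fixation-index recovery into a
quantitative test. Defaults mirror the canonical study scale: 1,504
trees, 9 loci, 71 core alleles (8,8,…,7 per locus, Dirichlet(0.5)
frequencies), ~33 % of trees ex situ, and **no missing data** — the
canonical 27,072-allele identity implies a complete table, so complete
data is the default condition (the GenAlEx `0/0` missing convention is
still supported on input, and `missing_rate` masks whole genotypes when
set). Planted features add alleles beyond the 71: a hotspot injects 2
rare alleles per locus at 6 % probability inside its radius, and the
first 3 loci carry a gap-region private allele (30 % inside the circle,
zero elsewhere) whose carriers are forced in situ, so the withheld set
is recoverable exactly. A clonal patch copies a reference cultivar
genotype heterozygous at 8 of 9 loci into ~80 % of its trees,
reproducing the heterozygote-excess (F < 0) signature of clonal
cultivation. Environmental layers are random linear gradients plus a
low-frequency sinusoid and mild noise.

What the generator does *not* emulate: coalescent genealogies, drift,
mutation models, linkage, genotyping error, null alleles, and any real
correlation between climate and tree density. Passing recovery tests
therefore certifies the pipeline's arithmetic and estimator behavior
under its own model assumptions, not the biology of any particular
dataset.

## Problem sizes and determinism

Bundled tests and the acceptance script run at the full canonical scale
for the counting identities (1,504 trees × 32 cells) and at reduced
scale where the full sweep adds nothing: the clustering-recovery check
uses 600 trees, K = 1…6 and 6–8 EM restarts (a production sweep would
use K = 1…10 with 20 restarts, `divmap structure --k-range 1:10 --runs
20`); the gap-recovery check uses even allele frequencies
(Dirichlet(2), 6 alleles/locus, hotspot off) so that every non-withheld
allele appears ex situ with overwhelming probability and recovery is
exact rather than probabilistic. Every stochastic step — landscape,
restarts, pseudo-absences, splits — is driven by explicit seeds;
`divmap run` writes a sha256 manifest and is checksum-identical under a
fixed seed.

## Known limitations

- Degree-space geometry: neighborhoods are circles in lon/lat, not on
  the sphere; at high latitudes they are geographically anisotropic.
- One tree feeding 32 cells induces strong spatial autocorrelation in
  the maps by design; per-cell values are not independent samples and
  no confidence intervals are provided.
- The EM fit can hit local optima at large K; restarts mitigate but do
  not guarantee the global maximum.
- The climate-envelope scorer is deliberately simple; its AUC/κ on the
  synthetic landscape is modest because simulated tree density is not
  climate-driven. Supply an externally modeled surface for real use.
- Rasters are unprojected ESRI ASCII grids; no GeoTIFF support.
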