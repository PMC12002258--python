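# Methods

This note documents the models and procedures implemented in `paleosar`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real fossil data.

## Spatial extent and nested regions

Spatial extent ("area") of a set of fossil-bearing grid cells is the summed
length, in great-circle kilometers, of the minimum spanning tree (MST) over
the cell midpoints.  MST length is preferred over polygon area because
fossil localities form sinuous, gappy point clouds for which hull areas are
dominated by empty space.

Coordinates are binned into an equal-area latitude-band grid before any
spatial analysis: latitude rings of ~100 km height, each divided into
~100 km-wide cells at the ring's central latitude.  Only cell midpoints
feed the downstream mathematics, so any ~100 km equal-area tessellation
gives equivalent results; the band grid was chosen because it is exactly
reproducible with no third-party grid engine.  Distances are spherical
(radius 6371.0088 km); paleocoordinate uncertainty (>100 km) makes
ellipsoidal corrections meaningless.  Grid spacing is validated to
[25, 500] km.

Nested regions are enumerated per contiguous subtree of the per-bin MST
(subtrees arise by deleting branches > `cutoff_km`, default 1,000 km, and
dropping components with fewer than `min_nodes`, default 10).  From every
starting cell, the cell nearest to the current set (minimum distance to any
member — single-linkage) is added one at a time; each intermediate set is a
candidate region; duplicates (identical unordered cell sets) are removed.
Two useful consequences of this construction:

- The accretion order from a given start is exactly Prim's algorithm, so
  the running sum of accretion distances *is* the MST length of each
  intermediate region, computed on the region's own cells.  MST length is
  therefore monotone along every growth path.
- Exactly tied distances are common on a regular grid (cells sit on
  latitude rings), so tie-breaks are drawn from a seeded RNG and the seed
  is part of a run's identity; identical seeds reproduce identical region
  sets bit for bit.

Regions whose largest nearest-neighbour distance among members is
≥ `max_nn_km` (strict `<` keeps; default 1,000 km) are screened out, so no
retained region contains widely separated subclusters.

## Coverage-standardized richness (SQS)

Richness per region is standardized to a fixed *coverage* — the fraction of
the underlying species-abundance distribution represented in a sample —
rather than to a fixed count.  The implementation is the standard
abundance-based machinery:

- Full-sample coverage: `1 − (f1/n)·[(n−1)f1 / ((n−1)f1 + 2 f2)]`
  (Good–Turing with the Chao–Jost correction), where `f1`, `f2` are
  singleton and doubleton counts.
- Interpolation: exact hypergeometric expectations of richness and
  coverage at integer subsample sizes, with the target coverage (quorum,
  default 0.8) located by bisection and linear interpolation between the
  bracketing integers.
- Extrapolation (needed when full-sample coverage < quorum): the
  asymptotic geometric form with the Chao1 unseen-species estimate
  `f0 = ((n−1)/n)·f1²/(2 f2)`, switching to the bias-corrected
  `((n−1)/n)·f1(f1−1)/(2(f2+1))` when `f2 = 0` (flagged in the estimate's
  metadata).

Estimates are flagged unusable when the region is too sparse
(`n < 10` occurrences or `S_obs < 2`, configurable) or when reaching the
quorum would require extrapolating beyond 2× the observed sample size (the
conventional reliability limit); unusable estimates are excluded from SAR
fits.  Raw ("face-value") species counts are carried alongside for
comparison — the null-model results below are the reason they should not
be interpreted.

For *fully censused* synthetic communities the correct standard is not the
finite-sample estimator but the infinite-community identity: with true
relative abundances `p_i`, a sample of `m` individuals has expected
coverage `Σ p_i (1−(1−p_i)^m)` and expected richness `Σ (1−(1−p_i)^m)`;
solving the first for `m` at the quorum and evaluating the second defines
the true coverage-standardized richness.  Truth baselines for synthetic
SARs use this quantity, so estimator fidelity is measured against the
target the estimator actually pursues (census richness is systematically
higher than richness at 80% coverage, by an amount that depends on the
evenness of the abundance distribution).

## SAR model and contrasts

`SpeciesAreaModel.fit()` performs OLS of `log10(richness)` on
`log10(MST km)` and returns a results object with the slope `z`, its SE and
normal-theory 95% CI, `R²`, and the intercept evaluated at 100 km
(`c100 = 10^fit(log10 100)`) with a mean-prediction interval obtained from
the parameter covariance at that abscissa.  The intercept is never reported
at zero: a slope change mechanically shifts the zero intercept even when
richness at the smallest measured scale is unchanged.  Nested regions are
treated as independent observations — a deliberate simplification inherited
from the estimation design; the point clouds are strongly autocorrelated
along growth paths, so SEs are optimistic and should be read as
descriptive.  Log base 10 is a reporting convention; the slope is
base-invariant.

Slope differences between time bins come from a single pooled cell-means
model (`log10 S ~ log10 A × bin`, one intercept and one slope per bin) with
t-contrasts of consecutive-bin slopes on the pooled residual degrees of
freedom.  Family-wise multiplicity is adjusted by Monte-Carlo evaluation of
the joint multivariate-t distribution of the contrast statistics (20,000
draws, seeded), with Bonferroni as a degenerate-covariance fallback; a
single contrast is reported unadjusted.

## Scrambled-coordinate null

Within a time bin, the paleocoordinates of collections are permuted among
collections (a bijection — "without replacement"), leaving each
collection's species composition and the multiset of occupied coordinates
untouched.  Any SAR surviving this scramble is a sampling artifact, because
no spatial structure remains.  Since coordinates move only among occupied
positions, the occupied cell set is identical in every replicate and only
cell *contents* change; region enumeration is nevertheless re-run per
replicate (tie-breaks may differ), and the fixed-geometry property is
recorded in the output.  Default: 100 replicates; per-replicate slope
distributions are summarized as 2.5/50/97.5% envelopes.

Face-value richness rises with region size purely because bigger regions
hold more occurrences, so the face-value null slope is strongly positive.
Coverage-standardized richness removes this accumulation signal almost
entirely; the residual null slope (~0.03 under the default synthetic
conditions) has two small, well-understood sources: finite-sample bias of
coverage inversion for the smallest regions, and the cluster structure of
collection sampling (occurrences within a collection are drawn from one
locality, so pooled region samples are cluster samples, not multinomial
ones).  The second term shrinks as the number of collections per cell
grows.

## Spatially explicit neutral model

The SENM is a zero-sum neutral community on a lattice of cells with fixed
per-cell density `J`.  Each generation, every individual is replaced by a
child that, with probability `nu`, founds a new species (point speciation)
and otherwise copies a parent whose cell is drawn through a dispersal
kernel centred on the child's cell and whose slot is uniform within that
cell.  Kernels: Gaussian (default; scale `dispersal_sigma` in km, edges
reflecting), fat-tailed (t with 3 df per axis), or global (uniform over the
landscape — the well-mixed limit).

Samples are simulated backward in time by the exact coalescent dual: each
sampled individual starts a lineage; per generation a lineage speciates
with probability `nu` or jumps to a parent cell/slot, and lineages landing
on the same slot coalesce.  Because forward and backward use the *same*
child-centred kernel, the dual is exact, including at reflecting edges.
Two distributionally exact shortcuts keep the geometric tail cheap: a lone
final lineage immediately receives a new species, and (global kernel only)
the final pair resolves by a competing-geometric draw between
speciation-first and coalescence-first.  In the well-mixed limit the mean
sampled richness follows the Ewens sampling formula with
`theta = 2·J_total·nu`; the spatial sampler is additionally validated
against an explicit forward-time simulation, which refuses lattices above
15×15 cells to prevent misuse as a production engine.

`fossilize` subsamples a simulated assemblage to a *template* of
collections (cell, collection id, occurrence count), drawing occurrences
with replacement from per-cell abundances, and emits a PBDB-dialect table
with the lattice embedded on the equator, so neutral worlds flow through
the identical empirical pipeline.  `senm_experiment` compares, per
parameter set and replicate, the pipeline estimate against the true SAR of
the fully censused sampled cells (coverage-standardized as above, screened
at the standard 1,000 km unless configured otherwise).  Two qualitative
behaviours are exercised by the tests: slope-estimate dispersion shrinks as
dispersal increases (more homogeneous communities are easier to estimate),
and grouping in a sparsely sampled cluster more than 1,000 km away degrades
both slope and intercept fidelity — the justification for the long-branch
screen.  The direction of the residual slope bias under fossil-structure
subsampling depends on the sampling-depth regime (deep clustered
collections push estimates up via the cluster-sample effect; very sparse
data pushes them down via bounded extrapolation), so experiment templates
should match the intensity of the record being emulated.

## Synthetic communities with known truth

`generate_power_law_community` places `n_species` disc-shaped ranges with
uniform random centres on a flat landscape embedded on the equator (where
planar and great-circle distances agree to first order), assigns
abundances from a skewed SAD (lognormal by default), rasterizes presence to
the analysis grid (a species occupies a cell iff its disc reaches the cell
midpoint — so occurrence tables and truth record agree exactly by
construction), and samples clustered collections from their cell's species
pool, weighted by abundance.  Spatially aggregated ranges are what make
nested SARs follow a power law, so this is the minimal generator with a
nontrivial true SAR.

Defaults emulate one well-sampled continental time bin of a vertebrate
record: 3000×1200 km landscape, 250 species (lognormal SAD, σ=1.2), range
radii lognormal with ~450 km median, and 700 collections averaging ~4
occurrences each in 8 clusters of 60 km spread, giving ~75 occupied cells
holding on the order of ten collections apiece.  The occurrence-to-
collection ratio (~4) matches what vertebrate occurrence databases
typically deliver, and the collections-per-cell density is what makes the
scrambled SQS null flat (see above): both are properties of the record
being emulated, not tuning knobs.  What the synthetic tests demonstrate is
estimator correctness *under these conditions* — real data add temporal
mixing within bins, taxonomic error, and non-disc ranges that no test here
exercises.

## Problem sizes and runtime

The test suite and acceptance script run entirely on synthetic data at
desk scale, chosen so a full run completes in minutes on one CPU: 20
replicate communities for power-law recovery, 100 scrambled replicates for
the null, 300+ replicates for each neutral-model comparison, and 500
replicates for contrast calibration.  Region enumeration is O(N³) per
subtree in the number of occupied cells and is the dominant cost on
empirical-scale data; a few hundred cells per bin remains comfortable.

## Known limitations

- Nested-region non-independence is not propagated into SAR uncertainty
  (by design, for comparability); a growth-path-aware resampling mode
  would be the natural extension.
- Incidence-based (presence per collection) standardization is not
  implemented; abundance mode treats occurrence counts as abundances.
- The time-bin schemes ship with standard stage/NALMA memberships and are
  fully user-configurable; interval synonymy beyond those lists must be
  supplied by the user.
- No paleorotation: input tables must already carry paleocoordinates.
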