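# Methods

## Scope and data model

The package analyses collections of bacterial strains sequenced at
several pre-aligned loci, each tagged as housekeeping (`hkg`,
chromosomal core genes such as 16S rRNA, *dnaK*, *gltA*, *glnII*) or
symbiotic (`sym`, accessory genes such as *nodA*, *nodC*, *nodD*,
*nifH*), with strain metadata giving a group label (e.g. host-defined
groups Vaf/Rlv/Rlt), an optional population, and optional WGS84
coordinates. Alignment itself is out of scope: inputs are assumed
consistently trimmed. Category concatenates join loci column-wise over
the strains present in *every* member locus (missing strains are
dropped with a warning rather than gap-padded, so all pairwise
distances stay defined); partition bounds are recorded 0-based,
half-open.

## Distances

Genetic distances default to the **p-distance** with *pairwise
deletion*: a column contributes to a pair only when both strains carry
an unambiguous A/C/G/T there; gaps and IUPAC ambiguity codes are
excluded from the comparable-site count, and a pair with zero
comparable sites raises an error — an undefined distance is never
silently zero. Complete-deletion behaviour can be emulated upstream;
pairwise deletion is the default because it preserves signal on
partially sequenced loci. Corrected distances are available:
JC69, d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4; and K2P,
d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) from transition/transversion
proportions P and Q. K2P is the default for tree building — a
maximum-composite-likelihood distance is deliberately not implemented,
K2P being the closest fully documented standard model. Geographic
distances are haversine great-circle kilometres on a spherical Earth,
R = 6371 km; geodesic refinements are irrelevant at the resolution of a
permutation test on inter-site distances.

## Nucleotide differentiation (N_st)

For two groups on one locus or concatenate:

- R_t = mean pairwise p-distance over the pooled sample (all pairs,
  within and between groups);
- R_s = combined within-group diversity. Default weighting is
  **pair-weighted** (every within-group pair counts once, so a larger
  group contributes more pairs); an unweighted `group_mean` option
  averages the two group diversities instead — the two coincide for
  equal group sizes.
- N_st = (R_t − R_s)/R_t, requiring R_t > 0.

Sampling noise can make R_s exceed R_t; negative N_st values are
reported, not clipped. Uncertainty comes from a nonparametric bootstrap
that resamples **alignment columns** with replacement to the original
length (the convention for sequence-diversity bootstraps; a
strain-resampling unit is available behind a flag), recomputing N_st
per replicate; the 95% interval is the 2.5/97.5 percentile of the
replicate values, with the point estimate always taken from the
unresampled data. Replicates with R_t = 0 (or a pair losing all
comparable sites) are counted as undefined and excluded; more than 50%
undefined aborts with an error. Default 1000 replicates.

The **hkg/sym diversity ratio** (mean sym diversity over mean hkg
diversity, per group) gets its interval from a hierarchical bootstrap:
loci are resampled with replacement within each category and, inside
each sampled locus, strains are resampled and the mean pairwise
distance recomputed from the retained pairwise matrix. This replaces
parametric significance testing with a reproducible, seeded resampling
scheme.

## Jackknife group assignment and CAD

Each strain is left out and assigned to the group with the highest
*mean* similarity, similarity being 100·(1 − p-distance) percent; the
tested strain is excluded from its own group's mean (otherwise
self-similarity would trivially dominate). A nearest-single-neighbour
mode exists for sensitivity analysis. Exact ties (within 1e-12) are
broken uniformly at random from a seeded generator, and strains are
processed in sorted-id order, so results are independent of input order
and fully reproducible; the number of ties is reported and every
assignment is logged in an audit table with all per-group mean
similarities.

The assignment-percentage matrix is row-stochastic (rows sum to 100)
and deliberately *not* symmetric — asymmetry is informative: a straggly
group's members can sit closer to a compact neighbouring group than to
each other. The **coefficient of average divergence** is defined from
the similarity matrix diagonal, CAD(g) = 100 − mean leave-one-out
within-group similarity of g; the alternative reading
100 − diagonal assignment % is exposed as a config option since the
phrase "100 minus JK values" is ambiguous between the two matrices.

## Mantel test

The statistic is the Pearson correlation over the n(n−1)/2
upper-triangle entries of the genetic and geographic matrices after
aligning both to the same sorted strain order. The null permutes rows
and columns of one matrix simultaneously; the p-value uses the add-one
convention p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), one-sided against
positive association by default (two-sided by flag). The default
n_perm = 9999 makes p-values down to 1e-4 attainable. Sorting ids
before permuting makes the p-value invariant to input order at a fixed
seed. A panel over loci derives per-locus seeds as seed + index so a
subset rerun reproduces the full panel.

## Neighbour-joining and bootstrap supports

Saitou–Nei agglomeration with the standard Q-criterion. Ties in Q are
broken on the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest leaf id), making the tree
deterministic even on degenerate inputs. Branch lengths follow the
standard NJ formulas; negative estimates are clamped to zero with the
deficit added to the sister branch, and the raw values are retained in
an audit map. Trees are unrooted (final trifurcation). On additive
matrices the recovered path-length matrix reproduces the input to
numerical precision — this is property-tested against randomly
generated trees up to 12 taxa and cross-checked against an independent
NJ implementation.

Supports resample alignment columns with replacement, rebuild the tree,
and report for each internal edge of the point-estimate tree the
fraction of replicates containing the same leaf-set bipartition
(annotated on the single point tree, not a consensus). Replicates with
undefined distances are skipped and counted; more than 20% skipped is
an error. An all-identical alignment yields an empty support map, since
its topology is pure tie-break artefact.

## Synthetic data generator

Each locus evolves by an independent-site Jukes–Cantor process with
Poisson(d) substitutions per site (each jump uniform over the three
other bases), so a total branch length d gives expected p-distance
p = (3/4)(1 − e^(−4d/3)) — the closed form used to validate the
generator against itself. The tree is known by construction: per locus,
one root sequence; per group, a lineage from the root to the group
ancestor of length `between_group_divergence` × locus rate ×
per-category multiplier × per-group multiplier; per strain, a tip of
length `within_group_divergence` × locus rate × a per-strain depth
factor (all 1 under `tip_length_model="fixed"`, Exp(1) under
`"exponential"`).

Each strain attaches to its group lineage at a fraction
u ~ Uniform(coherence, 1) from the root, drawn once per strain and gene
category. Coherence 1 gives a star-like monophyletic group; low
coherence makes a group straggly, with early-attaching members nearly
equidistant to all groups — the structure that makes leave-one-out
assignment genuinely asymmetric and per-strain rather than
all-or-nothing. Geography places each strain at its group centroid
(defaults approximate three Caucasus-like mountain regions, design
shape only) plus Gaussian km jitter. With `ibd_coupling` c > 0,
group-ancestor branches scale with relative centroid separation and
per-strain depth factors are rank-matched to each strain's distance
from its centroid with blend weight c, so at c = 1 genetic distance
tracks geographic distance up to noise. No indels are simulated; gap
handling is exercised by hand-written micro-fixtures in the tests.

### Canonical scenarios

| scenario | groups (sizes) | loci | between | within | notes |
|---|---|---|---|---|---|
| `separated` | 3 (5/5/5) | 2 hkg + 2 sym × 600 bp | 0.08 | 0.003 | fixed tips, coherence 1 |
| `null` | 3 (9/7/6) | 2 hkg × 800 bp | 0 | 0.01 | exchangeable null, fixed tips |
| `ibd` | 3 (8/7/7) | 4 hkg, 600–900 bp | 0.02 | 0.008 | coupling 1, study-like centroids |
| `paperlike` | 3 (9/7/6) | 4 hkg + 4 sym, 550–900 bp | 0.008 (sym ×2, third group ×3) | 0.02, Exp tips | coherence 0.5/0.0/0.9 |

Divergences are expected substitutions per site on the respective
branch. The `paperlike` design mirrors a 22-strain, 8-locus study
layout: a compact focal group and a straggly related reference group
whose ancestors sit close on hkg loci but twice as far apart on sym
loci, plus a distant, tight third group; 16S gets rate 0.5 to reflect
its conservation. These values are the package's fixed reference
conditions — simulation-based tests state properties of data generated
under them.

What the generator does *not* emulate: recombination and horizontal
transfer, indels, rate heterogeneity across sites, selection, and
coalescent genealogy within groups. Passing tests therefore demonstrate
correctness and calibration of the statistics under a clean
substitution model, not robustness to those processes in real data.

## Numerical and reproducibility conventions

- All randomness (simulation, bootstraps, permutations, tie-breaks)
  flows from explicit integer seeds; sub-seeds are derived by a stable
  CRC-based hash of (seed, analysis, locus), so any subset rerun
  reproduces the full run's values, and outputs are byte-identical
  across reruns.
- Tie detection uses absolute tolerance 1e-12; similarity/assignment
  matrices are reported in percent; supports are serialized to three
  decimals.
- Undefined quantities (no comparable sites, zero pooled diversity,
  saturated corrections, zero-variance Mantel input) raise typed errors
  at the library level; the pipeline collects per-locus errors into the
  run manifest and continues with the remaining loci, failing only when
  nothing succeeds.
- Problem sizes used by the verification surface: bootstrap supports
  are computed at 200 replicates and calibration loops at 50 datasets
  (500 for the Mantel type-I rate) — sizes at which the Monte-Carlo
  error of each checked quantity is far below its acceptance margin,
  while N_st/JK point statistics and the worked examples use the full
  1000-replicate default.

## Known limitations

- N_st here is a distance-based differentiation coefficient; it is not
  an allele-frequency F_st and no AMOVA-style variance partition is
  attempted.
- The JK classifier's "average similarity" is the arithmetic mean of
  pairwise similarities; proprietary implementations of the same idea
  may use centroid or consensus comparisons, which are not recoverable
  from published descriptions.
- K2P substitutes for composite-likelihood distances, so tree topology
  agreement with analyses using the latter is expected to be
  qualitative, not bit-exact.
- Mantel results depend on user-supplied coordinates; strains sharing a
  site are allowed (zero geographic distance), but a panel where all
  strains share one site errors out with zero variance.
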