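# Methods

## Setting

Somatic microsatellite (MS) slippage mutations accumulate at each cell
division, so the vector of MS repeat counts of a single cell — its genomic
signature — records its history since the zygote.  `mslineage` implements
a benchmark for distance-based reconstruction of cell lineage trees from
such signatures: it parses single-cell allele tables, computes pairwise
distances under several models of the mutational process, builds rooted
trees, and quantifies two biologically interpretable aspects of the
result: the *clustering* of predefined cell groups (individuals or cell
types) and the *depth separation* between groups known to have divided a
different number of times.  A forward simulator generates data under the
same mutational model so every statistic can be validated against a known
truth.

Units: branch lengths and depths are numbers of cell divisions, mutation
rates are per locus per division, repeat counts are integer MS repeat
units.

## Signatures and locus validity

Tables carry one row per cell and two columns per locus (the two
alleles); `X` marks amplification failure, a blank an unmeasured locus.
Because all loci in a cell lineage are completely linked, the two alleles
of an autosomal locus are treated as two independent single-allele loci.
Three validity rules are applied per cell:

* **Allelic dropout.** An autosomal locus with exactly one surviving
  allele call is discarded for that cell: the lone call may sit at the
  wrong allele and cannot be trusted.  Chromosome-X loci of males are
  exempt (one allele is expected); the principle is to keep a locus only
  when the expected number of alleles amplified.
* **Phasing.** Heterozygous autosomal alleles are assigned to the two
  columns by sorted value.  This is only well defined when the two repeat
  numbers are clearly distinct; below a configurable gap (default 2
  repeat units) the locus is dropped for that cell.  Homozygous loci need
  no phasing and are kept.
* **Shared-allele floor.** A pairwise distance uses only the alleles
  valid in both cells; pairs sharing fewer than `min_shared` (default 25)
  alleles are flagged unreliable.

The root of every tree is the *putative zygote* signature: bulk tail DNA
for mice (`tail_sample`), the per-locus lower median over all cells for
humans (`median_of_cells` — the lower median keeps repeat counts
integral), and a weighted mean of the individual zygotes for
multi-individual trees (weights default to each individual's cell
count).

## Distance measures

With `x_i^k` the repeat count of allele `k` in cell `i` and `S_ij` the
shared valid alleles of a pair:

* **Absolute**: `mean_k |x_i - x_j|`.
* **Normalized absolute**: `mean_k |x_i - x_j| / ((x_i + x_j)/2)`.  MS
  slippage rates grow roughly linearly with repeat number, so dividing
  each allele's difference by the pair-mean repeat count gives the loci
  expected to mutate rarely a larger weight and suppresses the
  length-driven component of divergence.  Branch lengths under this
  measure are not interpretable as divisions; trees built from it take
  their depths from the absolute measure (below).
* **Euclidean**: root-*mean*-square difference over `S_ij` (the mean, not
  the raw sum, keeps pairs with different shared-locus counts
  comparable; `normalize=False` gives the raw root-sum-of-squares).
* **Equal-or-not**: the number of shared alleles whose counts differ.
* **ML (SMM / MMM)**: the maximum-likelihood number of divisions
  separating the pair.  Per division each locus mutates with probability
  `mu`; given a mutation the signed step is ±1 with equal probability
  (stepwise model, SMM) or drawn from a symmetric truncated-geometric
  law over ±1..±5 with p = 0.5 (multistep model, MMM; the multistep law
  is a standard parameterization, configurable).  The net-change pmf
  after `t` divisions is computed by iterated discrete convolution of
  the per-division change distribution on a window wide enough that the
  truncated mass is negligible (mean + 10 SD of the step count).  Loci
  are independent, log-likelihoods are summed, and the estimate is the
  argmax over the integer grid `t = 0..t_max` (default 1000).  Divisions
  are integral in this model, so no sub-integer refinement is performed.

Per-locus rates come from one of three models (defaults from
MMR-deficient mouse panels, overridable): one shared rate 1/30;
unit-specific rates 1/22 (mono-) and 1/32 (di-nucleotide); or a linear
length law `mu = 0.0183 * repeats + 1/2000`, parameterized by the
pair-mean repeat count at the allele.  Human panels use 1/1000.

## Tree building

**Neighbor joining** follows the standard agglomeration with a
non-negativity correction: a negative branch produced during a join is
set to zero and the deficit moved to its sibling, preserving the
cherry's total path length and (since the topology depends only on the
distance matrix) the inferred topology.  **UPGMA** is average-linkage
agglomeration and yields an ultrametric tree, appropriate only when all
cells have similar depths.  Both break ties on the lexicographically
smallest label pair, so results are exactly reproducible.  Rooting uses
a pseudo-leaf carrying the putative-zygote signature as an outgroup: the
tree is re-rooted at its attachment node, the pseudo-leaf removed, and
its inferred branch length discarded.

**Depths for normalized-absolute trees.**  The topology comes from the
normalized-absolute matrix; depths are re-estimated bottom-up from the
absolute matrix (with the root pseudo-leaf): a leaf's depth is its
absolute distance to the root, and an internal node's depth is the
three-point estimate `(dbar(A, r) + dbar(B, r) - dbar(A, B))/2` over its
children's leaf sets, with means over all leaf pairs (average linkage).
Negative estimates are clamped to zero and child depths floored at the
parent's.  These depths are in absolute-distance units (mean |net repeat
change| per locus); they are proportional to divisions only while back
mutations are rare, and slightly compressed otherwise — which is the
reason the depth statistics below compare distributions rather than
absolute values.

## Clustering statistics

All three scores take a rooted tree and a leaf→group labeling; every
node (including single leaves — a one-cell group is perfectly clustered
at its own leaf) is a candidate clade.

* **QLC** (quality of the largest cluster).  For a group `c`, a node
  containing `b` of the group's `n_c` cells among `n_sub` descendants has
  recall `a = b/n_c` and purity `p = b/n_sub`; its degree is `a*p`, or 0
  when `p <= 1/2` (a candidate clade must be majority-pure).  The group's
  score is the best degree over nodes and the tree's QLC the mean over
  groups; 1 iff every group is a clade.
* **TE** (tree entropy).  For each unordered pair of groups, leaves of
  other groups are ignored and each group's count of maximal
  monochromatic clades (`c_a`, `c_b`) is taken.  The number of
  equally-fragmented configurations is the composition count
  `C(n_a-1, c_a-1) * C(n_b-1, c_b-1)` and the pair's entropy its natural
  log; the scalar TE is the mean over pairs.  0 iff every group is one
  clade.  Note the composition count is maximal at intermediate
  fragmentation and returns to 1 when every cell is its own cluster, so
  TE is a mixing statistic, not a metric; in practice reconstructed
  trees never reach that boundary.  For reporting, higher-is-better
  values use the negation; figure-level normalization (relative to the
  best method) lives in the ranking layer.
* **HS** (hypergeometric score).  Each node × group test computes the
  exact upper-tail hypergeometric probability of seeing at least `b`
  group cells among `n_sub` drawn from `N`.  Benjamini–Hochberg FDR at
  q = 0.20 over all tests yields the significant clades; the tree score
  is the mean over groups of each group's most significant p-value
  (lower is better).

## Depth statistics

Reconstructed depths vary within a group, so groups are compared as
distributions: the two-sample Kolmogorov–Smirnov test (statistic and
p-value); the normalized distance `|mean_x - mean_y| /
sqrt(sd_x^2 + sd_y^2)` (sample SDs, higher = better separated; +inf when
both spreads vanish but the means differ); and the overlap percentage —
of the `n_x * n_y` cross pairs, the fraction (×100) in which the groups
interpenetrate, taken as the minimum over the two orientations of the
count of pairs with `x_i >= y_j`, ties counting as penetration
(conservative: reports more overlap).  Disjoint supports give exactly 0;
lower = better separated.  Orientation conventions (KS p lower-better,
ND higher-better, overlap lower-better) are applied by the ranking
layer.

## Simulator

A replicate is a scaffold tree — root → individual zygotes → cell-type
MRCAs → random binary subtrees to the leaves — with branch lengths in
divisions, on which each locus accrues `Binomial(t, mu)` mutations per
branch, each adding a step from the step model.  Repeat counts are
reflected at the one-repeat floor.  Per-branch applied net changes are
recorded, so replaying them from the root must reproduce every leaf
exactly (a conservation test).  Ancestral repeat counts are drawn
uniformly from 10–30 repeats (only the length-dependent rate model and
the normalized measures are sensitive to this choice; the range covers
typical mono/di-nucleotide panels).  The random subtrees use sequential
random pair joins with internal nodes placed proportionally between the
MRCA and the (equal-depth) leaves, rounded to integer divisions.

Scaffold presets: topology **A** (root→zygote 5, zygote→MRCA 5,
MRCA→leaf 50) has deep leaves below shallow MRCAs; topology **B** (50,
50, 5) the reverse.  Default study sizes are 3 individuals × 5 cell
types × 5 cells, rates 1/100–1/10000 and 50–500 loci.

Two special designs:

* **Two-stage ("brothers")**: two individuals diverge from their
  mother's zygote after `stage1` divisions (default 40); each sampled
  cell then accrues `stage2` divisions independently from its
  individual's zygote.  The API takes `ratio = stage2/stage1`; the
  alternative convention `divergence_over_depth` reads the ratio as
  `stage1/stage2`, so a divergence/depth ratio of 0.2 with stage1 = 40
  means stage2 = 200.  A replicate counts as *fully separated* when an
  edge of the reconstructed tree splits each individual's cells from all
  other cells (monophyly in the unrooted sense — the zygote pseudo-leaf
  used for rooting is not a cell, so its attachment point cannot turn a
  separated pair into a mixed one).
* **Depth pair**: two cohorts under one zygote at known depths, shallow
  (20 vs 50 divisions) or deep (250 vs 300).

What the simulator does *not* emulate: PCR/amplification noise and
allelic dropout beyond a uniform missingness mask, cell-type-specific
rate variation, and CNV/aneuploidy.  Green synthetic tests therefore
show correctness of the algorithms under the stated mutational model,
not robustness to every noise source in real capillary data.

## Ranking and reliability

Scores are compared across datasets per measure: raw averages; per-
dataset relative-to-best scores (orientation-aware: `v/best` for
higher-is-better, `best/v` for lower-is-better, 1 = the dataset's best
method) averaged across datasets; average ranks (rank 1 = best, ties
share the better rank); and times-ranked-best counts.

Reliability uses two procedures.  The *locus bootstrap* resamples loci
with replacement (allele pairs stay together), reconstructs each of
`n_boot = 100` resampled datasets and reports the support of every
original bipartition plus the distribution of the clustering scores; a
resample that leaves some cell pair without usable loci is dropped and
logged.  The *permutation test* shuffles whole-cell group labels on a
fixed topology and reports `p = (1 + #{at least as good}) / (1 + n_perm)`
for QLC, TE or HS under their orientations.

## Numerical and design notes

* Transition tables are cached per (rate, step model, grid); probability
  comparisons use log-likelihood sums to avoid underflow.
* Tie-breaks in NJ/UPGMA and all stochastic components are deterministic
  given a seed; every simulation entry point takes an explicit seed.
* Degenerate inputs: a pair with no shared valid allele is an error (no
  distance exists); 2-leaf trees are handled as explicit special cases;
  a star tree has no internal bipartitions and compares as fully similar
  to another star.
* Problem sizes in the shipped tests and the acceptance script (for
  example 200 two-stage replicates with 200 loci, 200 ML-recovery pairs
  with 100 loci, 100 bootstrap resamples) were chosen as the smallest
  sizes at which the Monte-Carlo error is comfortably below the decision
  thresholds being tested.
* Known limitations: the exact published forms of the normalized-
  absolute normalizer, the QLC zero-condition, the TE state count and
  reporting transform, the HS combination across groups, and the
  normalized-distance/overlap denominators are not uniquely determined
  by prose descriptions; the definitions above are this package's own,
  chosen to satisfy every stated boundary condition (QLC = 1 and TE = 0
  exactly on monophyletic trees, HS in [0, 1], overlap 0 on disjoint
  supports) and kept fixed throughout.
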