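# mslineage

Benchmarking cell-lineage-tree reconstruction from single-cell
microsatellite (MS) mutation signatures.

Every cell of an organism descends from the zygote through binary
divisions, and slippage mutations in microsatellite loci (inserted or
deleted repeat units, at rates up to ~10⁻² per locus per division in
mismatch-repair-deficient mice) stamp each cell with a near-unique
genomic signature.  Distances between signatures can be fed to standard
phylogenetic algorithms to reconstruct the cell lineage tree — but cell
populations violate many of the assumptions those algorithms were built
on (shallow trees, stem cells, fully linked loci, wildly unequal
depths).  `mslineage` is a toolkit for asking *which* distance measure
and tree-building algorithm best recover known biology from such data:
it implements the full pipeline from allele tables to ranked method
comparisons, for both real single-cell tables and simulated ones.  It is
aimed at researchers developing or validating lineage-reconstruction
methods.

## What is inside

- **Signatures** (`mslineage.signatures`): parsing of cell × locus
  allele tables (`X` = failed amplification, blank = unmeasured), allelic
  dropout and phasing rules, putative-zygote root signatures (tail
  sample / per-locus median / weighted mean).
- **Distances** (`mslineage.distances`): absolute, normalized absolute
  (each allele's difference scaled by the pair-mean repeat count),
  RMS Euclidean, equal-or-not, and maximum-likelihood division counts
  under stepwise (±1) or multistep symmetric mutation models with three
  per-locus rate models (equal, mono/di, length-dependent).
- **Reconstruction** (`mslineage.reconstruction`): neighbor joining with
  a non-negative branch correction (deficit moved to the sibling),
  UPGMA, outgroup rooting on a zygote pseudo-leaf, and bottom-up depth
  assignment for normalized-absolute topologies from the absolute
  matrix.
- **Scores**: clustering quality — QLC (best recall×purity clade per
  group), tree entropy (log of the number of equally-fragmented
  configurations), hypergeometric clade enrichment with BH-FDR at 20% —
  and depth separation — Kolmogorov–Smirnov, normalized mean distance,
  overlap percentage.
- **Simulator** (`mslineage.simulate`): forward MS mutation accrual on
  configurable lineage scaffolds, including the two-stage
  "brother individuals" design and known-depth cohort pairs; replicates
  record every mutation event and replay exactly.
- **Evaluation** (`mslineage.evaluate`): bipartition similarity between
  trees, per-dataset method ranking with shared ties, locus bootstrap
  supports, and leaf-permutation significance tests.

A thin CLI (`mslineage simulate|distances|reconstruct|score-clustering|
score-depth|benchmark|bootstrap|permute`) wraps the library; all outputs
are tab-delimited text or Newick.

## Worked example

Simulate two sibling individuals whose zygotes diverged 40 divisions
after their mother's zygote, sample 3 cells per individual after 200
further divisions (divergence/depth ratio 0.2), mutate 200 loci at
1/100 per division, and ask how often NJ on the normalized-absolute
distance separates the two individuals:

```python
from mslineage import (build_distance_matrix, reconstruct,
                       score_clustering, separation_fraction,
                       simulate_two_stage)

reps = simulate_two_stage(0.2, ratio_convention="divergence_over_depth",
                          n_cells_per_individual=3, n_loci=200, mu=0.01,
                          n_replicates=50, seed=7)

rep = reps[0]
D = build_distance_matrix(rep.dataset, "normabs", include_root=True,
                          min_shared=1)
tree = reconstruct(D, "nj")
report = score_clustering(tree, rep.labels)
print(report.qlc, report.te_scalar, report.hs)
# 1.0 0.0 0.05000000000000001

print(separation_fraction(reps, "normabs", "nj"))
# 0.98
```

The first replicate separates perfectly: QLC = 1 (each individual's
cells form a pure clade containing all of them), TE = 0 (one cluster
per individual), and HS = 0.05 — the most significant tail probability
achievable with two groups of three cells is 1/C(6,3) = 1/20 for each
group, and HS is their mean.  Across 50 replicates, 98% are fully
separated — noise from the 200 within-individual divisions only rarely
overwhelms the 40-division zygote signal.

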