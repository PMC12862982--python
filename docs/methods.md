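# Methods

## Model and assumptions

The imputer rests on one assumption: gene expression in tissue is
spatially smooth at the scale of a few neighboring spots. If a gene is
expressed throughout a spot's immediate neighborhood but reads zero at
the spot itself, that zero is more plausibly a capture failure than real
absence; if the neighborhood is mostly silent for the gene, the zero is
more plausibly biological. The zero ratio — the fraction of a spot's k
nearest spatial neighbors at which the gene is also zero — quantifies
this, and the dropout threshold δ converts it into a decision. Detected
dropouts are filled with the arithmetic mean of the neighbors' non-zero
values; everything else is left untouched.

Consequences of the design: the method never densifies the matrix (most
zeros survive), never alters observed non-zero values, and its output is
monotone (entrywise ≥ input). It has no notion of transcriptome
similarity — neighbors are purely spatial — so it will smooth across a
sharp tissue boundary that falls inside a k-neighborhood; small k limits
this.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 6 | spatial neighbors per spot. 6 is the contact number of a hexagonal spot lattice; useful range 3–11. Larger k adds robustness but dilutes local structure. |
| δ (delta) | 0.4 | maximum zero ratio at which a zero still counts as a dropout. Smaller δ is more conservative (fewer imputations); useful range 0.04–0.40. |
| sequential | off | when on, spots are processed in row order and later spots read earlier imputations. |

`pipeline.sweep_hyperparameters` grids (k, δ) and returns the decision
counts and sparsity accounting for each combination.

## Numerical and semantic choices

* **Frozen-snapshot semantics (default).** Every imputation reads the
  pre-imputation matrix, so the result is independent of spot order and
  equals a naive per-entry evaluation; row-permuting spots and
  coordinates together permutes the output identically. The sequential
  variant is kept behind a flag because the order-dependence makes it
  harder to reason about, not because it is cheaper.
* **Exact-zero tests, no epsilon.** Total-count scaling and log1p map 0
  to exactly 0, so zeros remain exactly representable after
  normalization and the candidate set is well defined.
* **Neighbor ties.** Distances are compared exactly; equal distances are
  broken by ascending spot index (stable argsort over exact pairwise
  distances, computed in bounded-memory chunks). Duplicate coordinates
  are allowed.
* **Zero-ratio denominator** is the realized neighbor count
  min(k, n−1), so datasets with n ≤ k behave sensibly; k ≥ n is reduced
  to n−1 with a warning.
* **Threshold comparison is inclusive** (ratio ≤ δ). At δ=1 an entry
  whose whole neighborhood is zero is still skipped (the mean is
  undefined), and is counted separately from retained biological zeros.
* **Degenerate metric inputs.** A single-class labeling makes NMI/AMI
  undefined (defined here as 0, with a warning) and homogeneity trivial
  (defined as 1, with a warning). Entropies are in nats; every reported
  ratio is base-invariant. The expected mutual information in AMI uses
  the standard hypergeometric (fixed-marginals permutation) model. NMI
  normalizes by the geometric mean of the entropies and AMI by the
  arithmetic mean — deliberately mixed conventions, kept as such.
* **Unannotated spots** are dropped from both label vectors before any
  clustering metric is computed.

## Preprocessing

QC runs on raw counts in a fixed order: total-count window
(default 50–35 000 UMIs) → mitochondrial fraction (> 20% removed; mito
genes recognized by a case-insensitive "MT-" id prefix) → gene detection
breadth (< 10 spots removed). The defaults sit at the permissive end of
the ranges in common use and are all overridable. Normalization scales
each spot to the median pre-scaling total (or a fixed target) and
applies log1p. Whether gene-breadth filtering should precede or follow
normalization is genuinely open; filtering on raw counts first was
chosen so that detection thresholds refer to actual counts.

Variable-gene selection ranks genes by dispersion (variance/mean of the
de-logged data). The conventional genome-scale refinement — z-scoring
dispersion within ~20 mean bins to remove the mean–dispersion trend —
is available (`n_bins=20`) but is **not** the default: on panels of a
few hundred genes, domain-marker genes occupy entire mean bins by
themselves, and within-bin standardization cancels exactly the
between-domain variability the selection should keep (scanpy's
equivalent flavor shows the same behavior on such panels). The default
`n_bins=1` ranks by dispersion directly. Ties keep the earlier column;
selection preserves column order.

## Synthetic data: what it emulates, and what it does not

The generator emulates layered tissue: spots on a square or hexagonal
lattice; domains as contiguous y-axis bands (grid) or multi-source-BFS
grown cells (hex) — BFS growth rather than true Voronoi cells because
Voronoi cells need not be connected on a lattice graph; counts from a
negative binomial with shape `dispersion` (default 1) and mean
`base_mean` (default 2), elevated `marker_fold`-fold (default 5) for a
domain's 10 marker genes; uniform or expression-dependent dropout
(default 30%, uniform) applied only to non-zero truth and recorded in a
mask, keeping "technical dropout" and "biological zero" distinct by
construction. The expression-dependent mode decays dropout probability
as exp(−value/s) with s defaulting to the median non-zero value, so
low-expression entries drop out more, then rescales to hit the marginal
rate.

Not emulated: platform artifacts (barcode diffusion, bead geometry, UMI
saturation), gene–gene correlation beyond the domain programs, gradual
expression gradients, batch effects. Passing tests on this generator
shows the algorithm implements its contract and improves clustering
under spatially structured dropout; it does not certify performance on
any real platform.

At the default settings the observed matrix is ~53% zeros, of which
~32 points are biological (the NB at mean 2 produces P(zero)=1/3 for
background genes). A typical gene's neighborhood zero-ratio therefore
sits near 0.55 — above δ=0.4 — so the imputer classifies only about a
quarter of held-out non-zero entries as recoverable dropouts. That is
the intended conservative behavior on data this sparse, and it is why
held-out-recovery correlations on this generator are modest even though
downstream clustering improves markedly (see
`scripts/acceptance.py` output: ARI rises from ~0.77 to ~0.96 at
seed 1).

## Problem sizes

The test suite and the acceptance script use the generator's default
problem size (2000 spots × 200 genes) for end-to-end checks and smaller
instances (≤ 200 spots, ≤ 60 genes) for oracle-equivalence and property
tests, which keeps the whole suite comfortably fast on a single CPU.

## Known limitations

* Neighbor search materializes chunked exact distance blocks — fine up
  to tens of thousands of spots, not designed for millions.
* The imputer holds a dense (n × k × g) float block in memory during the
  vectorized pass; very large matrices should be processed with smaller
  k or in gene chunks.
* A single global δ is applied; no per-gene or per-dataset adaptation.
* Distance-weighted means, transcriptome-similarity neighbors and
  iterative refinement are deliberately out of scope.
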