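# spamean

Spatially aware dropout detection and mean imputation for spatially
resolved transcriptomics (SRT).

## The problem

Spot-based SRT platforms (10x Genomics Visium, Stereo-seq, Slide-seqV2,
sci-Space) produce spot × gene count matrices that are extremely sparse —
often 85–95% zeros. Part of that sparsity is biology (the gene is simply
not expressed at that location); part is *technical dropout* (an expressed
transcript that failed to be captured). Generic imputation methods tend to
fill in *every* zero, erasing biologically meaningful sparsity. This
package exploits the one signal those methods ignore — the physical
position of each spot in the tissue — to decide, zero by zero, whether to
impute.

It is intended for computational biologists who analyze spot-level SRT
matrices and want a fast, transparent, tunable imputation step between
normalization and clustering.

## The method

Given a log-normalized expression matrix **X′** ∈ ℝⁿˣᵍ′ (spots × genes)
and spot coordinates **S** ∈ ℝⁿˣ²:

1. **Zero indexing.** Remove genes that are zero in every spot, then
   record 𝒵ᵢ = { j : X′ᵢⱼ = 0 } for every spot *i*.
2. **Spatial neighbors.** For each spot, find its *k* nearest other
   spots 𝒩ᵢ⁽ᵏ⁾ by Euclidean distance dᵢⱼ = ‖Sᵢ − Sⱼ‖₂ (ties broken by
   ascending spot index).
3. **Zero ratio.** For each candidate (i, j):
   zero_ratioᵢⱼ = |{ m ∈ 𝒩ᵢ⁽ᵏ⁾ : X′ₘⱼ = 0 }| / k.
   A high ratio means the gene is locally silent (a likely biological
   zero); a low ratio means the neighborhood expresses the gene and the
   zero is a likely technical dropout.
4. **Mean imputation.** If zero_ratioᵢⱼ ≤ δ (the dropout threshold,
   default 0.4) and at least one neighbor is non-zero, replace X′ᵢⱼ by
   the arithmetic mean of the neighbors' *non-zero* values of gene *j*.
   If every neighbor is zero the entry is skipped; if the ratio exceeds
   δ the zero is retained as biological. Non-zero entries are never
   modified.

Sensible operating ranges are k ∈ 3–11 (default 6, the contact number of
a hexagonal spot lattice) and δ ∈ 0.04–0.40.

Downstream quality is evaluated by comparing Leiden clusters of the
imputed matrix against ground-truth domain labels with ARI, NMI, AMI and
homogeneity (all implemented here from their contingency-table
definitions), by zero-sparsity accounting, and by masked-entry recovery
(hide a fraction of non-zero entries, impute, correlate with the truth
via Pearson/Spearman/Kendall).

A built-in generator simulates layered-tissue SRT data — contiguous
spatial domains with disjoint marker-gene programs, negative-binomial
counts, and recorded technical dropout — so every stage is testable
without downloading data.

## Worked example

```python
import numpy as np
from spamean import make_dataset, normalize_log1p, impute
from spamean.types import SpotGeneMatrix, SpatialMap, ImputationConfig

ds = make_dataset(seed=0, n_spots=400, n_genes=100)   # 4 domains, 30% dropout
obs = normalize_log1p(SpotGeneMatrix.from_array(ds.observed_matrix))
imputed, report, decisions = impute(obs, SpatialMap(ds.coords),
                                    ImputationConfig(k=6, delta=0.4))
print(f"zero sparsity before: {report.zero_sparsity_before_pct:.2f}%")
print(f"zero sparsity after:  {report.zero_sparsity_after_pct:.2f}%")
print(f"dropout detected:     {report.dropout_detected_pct:.2f}%")
```

prints

```
zero sparsity before: 51.51%
zero sparsity after:  35.48%
dropout detected:     16.02%
```

Of the 20 604 zero entries, 6 410 were classified as dropouts and filled
with a neighborhood mean, 13 771 were kept as biological zeros (zero
ratio above δ), and 423 had an all-zero neighborhood and were skipped.
The 16.02 points of sparsity removed is exactly the before/after
difference — the method leaves most zeros alone by design.

The same workflow is available from the shell:

```bash
spamean simulate --n-spots 400 --n-genes 100 --seed 0 --output sim.h5ad
spamean impute --input sim.h5ad --raw --k 6 --delta 0.4 \
       --output imputed.h5ad --report report.json
spamean run --input sim.h5ad --outdir run1   # full QC→impute→cluster→metrics
```

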