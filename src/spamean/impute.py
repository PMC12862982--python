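"""Spatial mean imputation with dropout/biological-zero discrimination.

The method treats each zero entry of a log-normalized spots x genes
matrix as a candidate dropout. For spot *i* and gene *j* it inspects the
*k* nearest spatial neighbors of *i* (Euclidean distance on the slide
coordinates, self excluded) and computes the **zero ratio**: the fraction
of those neighbors at which gene *j* is also zero. A low ratio suggests
the gene is expressed in the local tissue context and the zero is a
technical dropout; a high ratio suggests genuine local absence. Zeros
with ratio <= ``delta`` are replaced by the arithmetic mean of the
neighbors' non-zero values for that gene; zeros with ratio > ``delta``
are retained as biological; zeros whose entire neighborhood is zero are
skipped (the mean would be undefined). Non-zero entries are never
touched.

By default all reads come from a frozen snapshot of the input matrix, so
the result does not depend on spot iteration order; a sequential variant
that lets later spots see earlier imputations is available via
``ImputationConfig(sequential=True)``.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    DECISION_BIOLOGICAL,
    DECISION_IMPUTED,
    DECISION_NONZERO,
    DECISION_SKIPPED,
    ImputationConfig,
    ImputationReport,
    SpatialMap,
    SpotGeneMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "drop_allzero_genes",
    "index_zeros",
    "build_neighbor_index",
    "zero_ratio",
    "impute",
]


def drop_allzero_genes(matrix: SpotGeneMatrix) -> tuple[SpotGeneMatrix, list]:
    """Remove genes with zero expression across all spots.

    Returns the reduced matrix (original column order preserved) and the
    list of removed gene ids.
    """
    keep = np.asarray((matrix.values != 0).sum(axis=0) > 0)
    if not keep.any():
        raise ValueError("all genes are zero across all spots: empty matrix")
    removed = matrix.gene_ids[~keep].tolist()
    if not removed:
        return matrix, []
    return matrix.subset_genes(keep), removed


def index_zeros(matrix: SpotGeneMatrix) -> list[np.ndarray]:
    """Per-spot sorted arrays of gene column indices with value exactly 0.

    Zeros are exact: log-normalization maps 0 to 0 with no rounding, so no
    tolerance is needed. All-zero genes are expected to have been removed
    already (see :func:`drop_allzero_genes`).
    """
    return [np.flatnonzero(row == 0) for row in matrix.values]


def build_neighbor_index(coords: SpatialMap, k: int) -> np.ndarray:
    """The ``min(k, n-1)`` nearest other spots for every spot.

    Neighbors are ordered by ascending Euclidean distance with ties broken
    by ascending spot index; the spot itself is always excluded. Returns
    an ``(n, min(k, n-1))`` integer array.
    """
    if isinstance(coords, np.ndarray):
        coords = SpatialMap(coords)
    pts = coords.coords
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to define neighbors")
    if k < 1:
        raise ValueError("k must be positive")
    k_eff = min(k, n - 1)

    # Exact pairwise distances + stable argsort give a deterministic order
    # regardless of any spatial-index internals; ties fall back to index
    # order because the stable sort preserves it. Chunked to bound memory.
    out = np.empty((n, k_eff), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = pts[start:stop]
        d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        for r in range(stop - start):
            d2[r, start + r] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k_eff]
    return out


def zero_ratio(
    matrix: SpotGeneMatrix,
    neighbors: np.ndarray,
    spot: int,
    gene: int,
) -> float:
    """Fraction of ``spot``'s neighbors at which ``gene`` is exactly zero.

    The denominator is the realized neighbor-list length ``min(k, n-1)``.
    """
    nbr = neighbors[spot]
    vals = matrix.values[nbr, gene]
    return float(np.count_nonzero(vals == 0) / len(nbr))


def impute(
    matrix: SpotGeneMatrix,
    coords: SpatialMap,
    cfg: ImputationConfig | None = None,
) -> tuple[SpotGeneMatrix, ImputationReport, np.ndarray]:
    """Run spatial mean imputation over every zero entry.

    Parameters
    ----------
    matrix
        Log-normalized spots x genes matrix (``is_normalized`` must be
        True). Genes that are zero everywhere are removed internally.
    coords
        Spot coordinates aligned with ``matrix`` rows.
    cfg
        ``k``, ``delta`` and the snapshot/sequential switch.

    Returns
    -------
    imputed : SpotGeneMatrix
        Same shape as the (all-zero-gene-reduced) input; non-zero entries
        bit-identical to the input.
    report : ImputationReport
        Zero-entry decision counts and sparsity accounting.
    decisions : (n, g) int8 array
        Per-entry code: 0 non-zero, 1 imputed, 2 retained biological,
        3 skipped (all-zero neighborhood).
    """
    cfg = cfg or ImputationConfig()
    if isinstance(coords, np.ndarray):
        coords = SpatialMap(coords)
    if not matrix.is_normalized:
        raise ValueError("impute expects a log-normalized matrix; run "
                         "normalize_log1p first")
    if coords.n_spots != matrix.n_spots:
        raise ValueError(
            f"coords rows ({coords.n_spots}) do not match matrix rows "
            f"({matrix.n_spots})"
        )
    matrix, removed = drop_allzero_genes(matrix)
    if removed:
        logger.info("dropped %d all-zero genes before imputation", len(removed))
    n = matrix.n_spots
    k = cfg.k
    if k >= n:
        logger.warning("k=%d >= n=%d spots; reduced to %d", k, n, n - 1)
        k = n - 1
    neighbors = build_neighbor_index(coords, k)
    k_eff = neighbors.shape[1]

    X = matrix.values.astype(float, copy=True)
    before = 100.0 * np.count_nonzero(X == 0) / X.size

    if cfg.sequential:
        decisions = _impute_sequential(X, neighbors, cfg.delta)
    else:
        decisions = _impute_snapshot(X, neighbors, cfg.delta)

    after = 100.0 * np.count_nonzero(X == 0) / X.size
    report = ImputationReport(
        n_zero_candidates=int(np.count_nonzero(decisions != DECISION_NONZERO)),
        n_imputed=int(np.count_nonzero(decisions == DECISION_IMPUTED)),
        n_retained_biological=int(np.count_nonzero(decisions == DECISION_BIOLOGICAL)),
        n_skipped_allzero_neighborhood=int(
            np.count_nonzero(decisions == DECISION_SKIPPED)
        ),
        zero_sparsity_before_pct=before,
        zero_sparsity_after_pct=after,
        dropout_detected_pct=before - after,
        k=k_eff,
        delta=cfg.delta,
    )
    out = SpotGeneMatrix(X, matrix.spot_ids, matrix.gene_ids, is_normalized=True)
    return out, report, decisions


def _impute_snapshot(X: np.ndarray, neighbors: np.ndarray, delta: float) -> np.ndarray:
    """Vectorized frozen-snapshot pass; mutates ``X`` in place."""
    k_eff = neighbors.shape[1]
    zero_here = X == 0
    decisions = np.full(X.shape, DECISION_NONZERO, dtype=np.int8)

    # neighbor statistics per (spot, gene) from the frozen input
    nbr_vals = X[neighbors]  # (n, k_eff, g)
    nbr_nonzero = nbr_vals != 0
    nz_count = nbr_nonzero.sum(axis=1)  # (n, g)
    ratio = (k_eff - nz_count) / k_eff
    with np.errstate(invalid="ignore"):
        nz_mean = np.where(nz_count > 0, nbr_vals.sum(axis=1) / np.maximum(nz_count, 1), 0.0)

    eligible = zero_here & (ratio <= delta)
    fill = eligible & (nz_count > 0)
    skip = zero_here & (nz_count == 0)  # all-zero neighborhood
    # an all-zero neighborhood has ratio 1; it is "eligible" only at delta=1,
    # but the skip rule takes precedence either way
    retained = zero_here & ~fill & ~skip

    X[fill] = nz_mean[fill]
    decisions[fill] = DECISION_IMPUTED
    decisions[skip] = DECISION_SKIPPED
    decisions[retained] = DECISION_BIOLOGICAL
    return decisions


def _impute_sequential(X: np.ndarray, neighbors: np.ndarray, delta: float) -> np.ndarray:
    """Spot-by-spot pass where imputed values feed later spots."""
    k_eff = neighbors.shape[1]
    decisions = np.full(X.shape, DECISION_NONZERO, dtype=np.int8)
    for i in range(X.shape[0]):
        zeros = np.flatnonzero(X[i] == 0)
        if zeros.size == 0:
            continue
        sub = X[np.ix_(neighbors[i], zeros)]
        nz = sub != 0
        nz_count = nz.sum(axis=0)
        ratio = (k_eff - nz_count) / k_eff
        fill = (ratio <= delta) & (nz_count > 0)
        skip = nz_count == 0
        means = sub.sum(axis=0)[fill] / nz_count[fill]
        X[i, zeros[fill]] = means
        decisions[i, zeros[fill]] = DECISION_IMPUTED
        decisions[i, zeros[skip]] = DECISION_SKIPPED
        rest = ~fill & ~skip
        decisions[i, zeros[rest]] = DECISION_BIOLOGICAL
    return decisions
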