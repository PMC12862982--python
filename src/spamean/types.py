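"""Core data containers shared across the package.

The in-memory model is deliberately small: a spots-by-genes matrix with
string identifiers, a parallel n-by-2 coordinate array, and a handful of
config/report records. AnnData is used at the I/O boundary
(:mod:`spamean.io`); the algorithmic modules operate on these plain
containers so every contract is checkable with numpy alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpotGeneMatrix",
    "SpatialMap",
    "QCConfig",
    "ImputationConfig",
    "ImputationReport",
    "SyntheticDataset",
    "DatasetBundle",
    "DECISION_NONZERO",
    "DECISION_IMPUTED",
    "DECISION_BIOLOGICAL",
    "DECISION_SKIPPED",
]

# Per-entry decision codes written into the imputation decision mask.
DECISION_NONZERO = 0  # entry was non-zero: not a candidate
DECISION_IMPUTED = 1  # zero classified as technical dropout and filled
DECISION_BIOLOGICAL = 2  # zero retained: zero_ratio > delta
DECISION_SKIPPED = 3  # zero with an all-zero neighborhood: left untouched


def _as_str_array(ids: Sequence[str], what: str, n: int) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(f"{what} must be a 1-D sequence of length {n}")
    if len(set(arr.tolist())) != n:
        raise ValueError(f"{what} must be unique")
    return arr


@dataclass
class SpotGeneMatrix:
    """A spots x genes expression matrix with aligned identifiers.

    ``values`` holds raw counts while ``is_normalized`` is False and
    log-normalized expression afterwards. Entries are never negative.
    """

    values: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (spots x genes)")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        n, g = self.values.shape
        self.spot_ids = _as_str_array(self.spot_ids, "spot_ids", n)
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids", g)

    @classmethod
    def from_array(
        cls, values: np.ndarray, is_normalized: bool = False
    ) -> "SpotGeneMatrix":
        """Wrap a bare array, synthesizing ``spot_0..`` / ``gene_0..`` ids."""
        values = np.asarray(values)
        n, g = values.shape
        return cls(
            values=values,
            spot_ids=np.array([f"spot_{i}" for i in range(n)], dtype=object),
            gene_ids=np.array([f"gene_{j}" for j in range(g)], dtype=object),
            is_normalized=is_normalized,
        )

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_spots(self, mask_or_idx: np.ndarray) -> "SpotGeneMatrix":
        return SpotGeneMatrix(
            self.values[mask_or_idx],
            self.spot_ids[mask_or_idx],
            self.gene_ids,
            self.is_normalized,
        )

    def subset_genes(self, mask_or_idx: np.ndarray) -> "SpotGeneMatrix":
        return SpotGeneMatrix(
            self.values[:, mask_or_idx],
            self.spot_ids,
            self.gene_ids[mask_or_idx],
            self.is_normalized,
        )


@dataclass
class SpatialMap:
    """Planar spot coordinates, row-aligned with a :class:`SpotGeneMatrix`."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an n x 2 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    def subset(self, mask_or_idx: np.ndarray) -> "SpatialMap":
        return SpatialMap(self.coords[mask_or_idx])


@dataclass
class QCConfig:
    """Spot- and gene-level quality-control thresholds.

    Defaults sit at the permissive end of the ranges commonly used for
    spot-based platforms: ``min_counts=50``, ``max_counts=35000`` UMIs per
    spot, at most 20% mitochondrial counts, and genes detected in at least
    10 spots. Mitochondrial genes are recognized by a case-insensitive
    gene-id prefix (default ``"MT-"``).
    """

    min_counts: int = 50
    max_counts: int = 35000
    max_mito_pct: float = 20.0
    min_cells: int = 10
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_counts < 0:
            raise ValueError("min_counts must be non-negative")
        if self.max_counts <= self.min_counts:
            raise ValueError("min_counts must be strictly below max_counts")
        if not 0.0 <= self.max_mito_pct <= 100.0:
            raise ValueError("max_mito_pct must be within [0, 100]")
        if self.min_cells < 0:
            raise ValueError("min_cells must be non-negative")


@dataclass
class ImputationConfig:
    """Hyperparameters of the spatial mean imputer.

    ``k`` is the number of nearest spatial neighbors consulted per spot;
    the default 6 matches the contact number of a hexagonal spot lattice.
    ``delta`` is the dropout threshold: a zero entry is imputed only when
    the fraction of neighbors that are also zero for that gene is <= delta.
    ``sequential=True`` switches from frozen-snapshot reads (the default,
    order-invariant) to in-place updates where later spots see earlier
    imputations.
    """

    k: int = 6
    delta: float = 0.4
    sequential: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be within [0, 1]")


@dataclass
class ImputationReport:
    """Aggregate accounting of one imputation run.

    ``dropout_detected_pct`` equals the drop in zero sparsity, i.e.
    ``zero_sparsity_before_pct - zero_sparsity_after_pct``.
    """

    n_zero_candidates: int
    n_imputed: int
    n_retained_biological: int
    n_skipped_allzero_neighborhood: int
    zero_sparsity_before_pct: float
    zero_sparsity_after_pct: float
    dropout_detected_pct: float
    k: int
    delta: float

    def __post_init__(self) -> None:
        parts = (
            self.n_imputed
            + self.n_retained_biological
            + self.n_skipped_allzero_neighborhood
        )
        if parts != self.n_zero_candidates:
            raise ValueError("zero-entry decision counts do not sum to candidates")
        if self.dropout_detected_pct < -1e-9:
            raise ValueError("dropout_detected_pct must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """A simulated spatial dataset with known truth.

    ``observed_matrix`` equals ``true_matrix`` except at positions where
    ``dropout_mask`` is True, which were non-zero in truth and zeroed to
    emulate technical dropout.
    """

    true_matrix: np.ndarray
    observed_matrix: np.ndarray
    dropout_mask: np.ndarray
    coords: np.ndarray
    domain_labels: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        t, o, m = self.true_matrix, self.observed_matrix, self.dropout_mask
        if not (t.shape == o.shape == m.shape):
            raise ValueError("matrix/mask shapes disagree")
        if np.any(o[m] != 0):
            raise ValueError("observed must be zero where the dropout mask is set")
        if np.any(o[~m] != t[~m]):
            raise ValueError("observed must equal truth off the dropout mask")
        if np.any(m & (t == 0)):
            raise ValueError("dropouts may only hit non-zero truth")
        if self.coords.shape != (t.shape[0], 2):
            raise ValueError("coords misaligned with matrix rows")
        if self.domain_labels.shape != (t.shape[0],):
            raise ValueError("domain labels misaligned with matrix rows")


@dataclass
class DatasetBundle:
    """Everything the pipeline carries for one dataset.

    ``layers`` holds named auxiliary matrices shaped like ``matrix.values``
    (true counts, dropout mask, decision mask, ...). ``provenance`` is an
    append-only record of source paths and processing steps.
    """

    matrix: SpotGeneMatrix
    coords: Optional[SpatialMap]
    true_labels: Optional[np.ndarray] = None
    layers: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.matrix.n_spots
        if self.coords is not None and self.coords.n_spots != n:
            raise ValueError("coords misaligned with expression matrix")
        if self.true_labels is not None and len(self.true_labels) != n:
            raise ValueError("labels misaligned with expression matrix")
        for name, layer in self.layers.items():
            if np.asarray(layer).shape != self.matrix.values.shape:
                raise ValueError(f"layer {name!r} shape mismatch")

    @property
    def has_coords(self) -> bool:
        return self.coords is not None

    def log(self, step: str, **info) -> None:
        self.provenance.append({"step": step, **info})
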