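"""Clustering-agreement metrics, sparsity accounting, recovery statistics.

The four clustering metrics (ARI, NMI, AMI, homogeneity) are implemented
directly from their contingency-table definitions:

* ARI — pair counting with chance correction,
* MI/NMI — Shannon mutual information (nats), normalized by the geometric
  mean sqrt(H(T)*H(P)),
* AMI — MI corrected by its expectation under the permutation model with
  fixed marginals, normalized by the arithmetic mean of the entropies,
* homogeneity — 1 - H(T|P)/H(T).

Note the mixed normalizations: NMI uses the geometric mean while AMI uses
the arithmetic mean. Entropies are in natural log; every ratio reported
here is base-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import gammaln
from scipy.stats import kendalltau, pearsonr, spearmanr

__all__ = [
    "LabelPair",
    "contingency",
    "ari",
    "entropy",
    "mutual_information",
    "expected_mutual_information",
    "nmi",
    "ami",
    "homogeneity",
    "metric_set",
    "zero_sparsity",
    "recovery_stats",
    "RecoveryStats",
]


@dataclass
class LabelPair:
    """Aligned true/predicted label vectors; unannotated spots dropped.

    Entries where ``true_labels`` is None/NaN/empty are removed from both
    vectors before any metric is computed.
    """

    true_labels: np.ndarray
    predicted_labels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.true_labels, dtype=object).ravel()
        p = np.asarray(self.predicted_labels, dtype=object).ravel()
        if t.shape[0] != p.shape[0]:
            raise ValueError(
                f"label lengths differ: {t.shape[0]} true vs {p.shape[0]} predicted"
            )
        keep = np.array([not _missing(v) for v in t], dtype=bool)
        t, p = t[keep], p[keep]
        if t.shape[0] == 0:
            raise ValueError("no annotated spots left after filtering")
        self.true_labels = t
        self.predicted_labels = p

    @property
    def n(self) -> int:
        return self.true_labels.shape[0]


def _missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _codes(labels: np.ndarray) -> np.ndarray:
    """Integer codes by first appearance."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, v in enumerate(labels):
        out[i] = seen.setdefault(v, len(seen))
    return out


def contingency(pair: LabelPair) -> np.ndarray:
    """Counts ``n_ij`` of spots in true class i and predicted cluster j.

    Categories are ordered by first appearance in each vector.
    """
    t = _codes(pair.true_labels)
    p = _codes(pair.predicted_labels)
    table = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(table, (t, p), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def ari(pair: LabelPair) -> float:
    """Adjusted Rand index: pair-counting agreement corrected for chance.

    1 for any relabeling of the truth, about 0 for independent labelings.
    """
    if pair.n < 2:
        raise ValueError("ARI is undefined for fewer than 2 spots")
    table = contingency(pair)
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    n = table.sum()
    sum_ij = _comb2(table.astype(float)).sum()
    sum_a = _comb2(a.astype(float)).sum()
    sum_b = _comb2(b.astype(float)).sum()
    expected = sum_a * sum_b / _comb2(np.float64(n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions are trivial (all-singleton or single-class): the
        # index is degenerate; perfect agreement by convention
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def entropy(labels) -> float:
    """Shannon entropy (nats) of the empirical label distribution."""
    labels = np.asarray(labels, dtype=object).ravel()
    if labels.size == 0:
        raise ValueError("entropy of an empty label vector is undefined")
    _, counts = np.unique(labels.astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(pair: LabelPair) -> float:
    """MI(T, P) = H(T) - H(T|P), evaluated from the contingency table."""
    table = contingency(pair).astype(float)
    n = table.sum()
    a = table.sum(axis=1, keepdims=True)
    b = table.sum(axis=0, keepdims=True)
    nz = table > 0
    return float(
        (table[nz] / n * np.log(n * table[nz] / (a @ b / 1.0)[nz])).sum()
    )


def expected_mutual_information(table: np.ndarray) -> float:
    """E[MI] under the permutation model with fixed marginals.

    Sums, for every cell (i, j), the MI contribution of each feasible
    cell count weighted by its hypergeometric probability.
    """
    table = np.asarray(table)
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    n = int(table.sum())
    ln_fact = gammaln(np.arange(n + 2) + 1.0)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_p = (
                    ln_fact[ai]
                    + ln_fact[bj]
                    + ln_fact[n - ai]
                    + ln_fact[n - bj]
                    - ln_fact[n]
                    - ln_fact[nij]
                    - ln_fact[ai - nij]
                    - ln_fact[bj - nij]
                    - ln_fact[n - ai - bj + nij]
                )
                emi += (nij / n) * np.log(n * nij / (ai * bj)) * np.exp(log_p)
    return float(emi)


def nmi(pair: LabelPair) -> float:
    """Normalized mutual information with geometric-mean normalization."""
    h_t = entropy(pair.true_labels)
    h_p = entropy(pair.predicted_labels)
    if h_t == 0.0 or h_p == 0.0:
        warnings.warn(
            "NMI undefined for a single-class labeling; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(mutual_information(pair) / np.sqrt(h_t * h_p))


def ami(pair: LabelPair) -> float:
    """Adjusted mutual information (arithmetic-mean normalization)."""
    h_t = entropy(pair.true_labels)
    h_p = entropy(pair.predicted_labels)
    if h_t == 0.0 or h_p == 0.0:
        warnings.warn(
            "AMI undefined for a single-class labeling; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    mi = mutual_information(pair)
    emi = expected_mutual_information(contingency(pair))
    denom = 0.5 * (h_t + h_p) - emi
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return float((mi - emi) / denom)


def homogeneity(pair: LabelPair) -> float:
    """1 - H(T|P)/H(T): 1 iff every predicted cluster is pure."""
    h_t = entropy(pair.true_labels)
    if h_t == 0.0:
        warnings.warn(
            "homogeneity undefined for single-class truth; returning 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    h_t_given_p = h_t - mutual_information(pair)
    return float(1.0 - h_t_given_p / h_t)


def metric_set(true_labels, predicted_labels) -> dict:
    """ARI, NMI, AMI and homogeneity for one label pair, as a dict."""
    pair = LabelPair(true_labels, predicted_labels)
    return {
        "ari": ari(pair),
        "nmi": nmi(pair),
        "ami": ami(pair),
        "homo": homogeneity(pair),
    }


def zero_sparsity(matrix) -> float:
    """Percentage of exactly-zero entries, in [0, 100]."""
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("zero sparsity of an empty matrix is undefined")
    return float(100.0 * np.count_nonzero(values == 0) / values.size)


@dataclass
class RecoveryStats:
    """Agreement between true and imputed values at held-out positions."""

    pcc: float
    src: float
    ktc: float
    recovered_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def recovery_stats(
    true_values: np.ndarray,
    imputed_values: np.ndarray,
    eval_mask: dict | None = None,
) -> RecoveryStats:
    """Pearson/Spearman/Kendall correlation over masked positions.

    ``true_values`` and ``imputed_values`` are either full matrices — in
    which case ``eval_mask`` (from :func:`spamean.synthetic.mask_nonzero`)
    selects the held-out positions — or already-extracted aligned vectors.
    ``recovered_fraction`` is the share of masked positions assigned a
    non-zero imputed value. Correlations over constant vectors are
    reported as NaN with a warning.
    """
    t = np.asarray(true_values, dtype=float)
    m = np.asarray(imputed_values, dtype=float)
    if eval_mask is not None:
        r, c = eval_mask["rows"], eval_mask["cols"]
        t = t[r, c] if t.ndim == 2 else t
        m = m[r, c]
    t, m = t.ravel(), m.ravel()
    if t.shape != m.shape:
        raise ValueError("true and imputed vectors are misaligned")
    if t.size == 0:
        raise ValueError("evaluation mask is empty")

    recovered = float(np.count_nonzero(m > 0) / m.size)
    if np.all(t == t[0]) or np.all(m == m[0]):
        warnings.warn(
            "constant vector: correlations are undefined", RuntimeWarning,
            stacklevel=2,
        )
        nan = float("nan")
        return RecoveryStats(nan, nan, nan, recovered)
    return RecoveryStats(
        pcc=float(pearsonr(t, m).statistic),
        src=float(spearmanr(t, m).statistic),
        ktc=float(kendalltau(t, m).statistic),
        recovered_fraction=recovered,
    )
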