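"""Shared fixtures and independent reference implementations.

The reference implementations here are deliberately naive (pure-Python
loops, exhaustive search) so they stay independent of the vectorized
code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from spamean.synthetic import make_dataset


def reference_neighbors(coords: np.ndarray, k: int) -> list[list[int]]:
    """Exhaustive O(n^2) nearest-neighbor search, ties by ascending index."""
    n = coords.shape[0]
    out = []
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = math.hypot(coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1])
            cand.append((d, j))
        cand.sort()
        out.append([j for _, j in cand[: min(k, n - 1)]])
    return out


def reference_impute(X: np.ndarray, coords: np.ndarray, k: int, delta: float) -> np.ndarray:
    """Direct loop transcription of the imputation procedure.

    Frozen-snapshot semantics: every read comes from the input matrix.
    For each spot, for each zero-valued gene: compute the fraction of the
    spot's nearest neighbors at which the gene is zero; if the fraction
    is <= delta and at least one neighbor is non-zero, replace the zero
    with the mean of the neighbors' non-zero values, else leave it.
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    nbrs = reference_neighbors(coords, k)
    n, g = X.shape
    for i in range(n):
        for j in range(g):
            if X[i, j] != 0:
                continue
            vals = [X[m, j] for m in nbrs[i]]
            n_zero = sum(1 for v in vals if v == 0)
            ratio = n_zero / len(vals)
            nonzero = [v for v in vals if v != 0]
            if ratio <= delta and nonzero:
                out[i, j] = sum(nonzero) / len(nonzero)
    return out


def flood_fill_components(coords: np.ndarray, labels: np.ndarray) -> int:
    """Number of connected label components under lattice adjacency.

    Two spots are adjacent when their distance is within 1% of the
    minimal positive spacing of the point set.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    spacing = float(np.min(d[:, 1]))
    pairs = tree.query_pairs(spacing * 1.01, output_type="ndarray")
    n = coords.shape[0]
    adj = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(n, dtype=bool)
    components = 0
    for start in range(n):
        if seen[start]:
            continue
        components += 1
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v] and labels[v] == labels[u]:
                    seen[v] = True
                    stack.append(v)
    return components


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (2000 spots, 200 genes, 4 domains,
    30% dropout), generated once per session at a pinned seed."""
    return make_dataset(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
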