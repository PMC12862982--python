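"""Tests of the core imputer: zero indexing, neighbors, zero ratio, impute."""

import numpy as np
import pytest

from spamean.impute import (
    build_neighbor_index,
    drop_allzero_genes,
    impute,
    index_zeros,
    zero_ratio,
)
from spamean.types import (
    DECISION_BIOLOGICAL,
    DECISION_IMPUTED,
    DECISION_NONZERO,
    DECISION_SKIPPED,
    ImputationConfig,
    SpatialMap,
    SpotGeneMatrix,
)
from conftest import reference_impute, reference_neighbors


def norm_matrix(values):
    return SpotGeneMatrix.from_array(np.asarray(values, dtype=float),
                                     is_normalized=True)


class TestDropAllzeroGenes:
    def test_single_allzero_column_removed(self):
        m = norm_matrix([[1, 0, 2], [3, 0, 0]])
        out, removed = drop_allzero_genes(m)
        assert removed == ["gene_1"]
        np.testing.assert_array_equal(out.values, [[1, 2], [3, 0]])

    def test_dense_identity(self):
        m = norm_matrix([[1, 2], [3, 4]])
        out, removed = drop_allzero_genes(m)
        assert removed == []
        assert out is m

    def test_matches_bruteforce_on_random_binary(self, rng):
        X = (rng.random((5, 5)) > 0.6).astype(float)
        X[:, 2] = 0
        m = norm_matrix(X)
        _, removed = drop_allzero_genes(m)
        expected = [f"gene_{j}" for j in range(5) if X[:, j].sum() == 0]
        assert removed == expected

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            drop_allzero_genes(norm_matrix(np.zeros((3, 3))))


class TestIndexZeros:
    def test_examples(self):
        m = norm_matrix([[0, 1.2, 0], [1, 1, 1]])
        zi = index_zeros(m)
        np.testing.assert_array_equal(zi[0], [0, 2])
        assert zi[1].size == 0

    def test_matches_bruteforce_on_random_sparse(self, rng):
        X = rng.random((20, 30))
        X[X < 0.5] = 0
        zi = index_zeros(norm_matrix(X))
        for i in range(20):
            assert zi[i].tolist() == [j for j in range(30) if X[i, j] == 0]


class TestNeighborIndex:
    def test_collinear_k1(self):
        nbr = build_neighbor_index(SpatialMap([[0, 0], [1, 0], [3, 0]]), k=1)
        np.testing.assert_array_equal(nbr, [[1], [0], [1]])

    def test_k_at_least_n_gives_all_others(self):
        coords = SpatialMap([[0, 0], [1, 0], [0, 1], [2, 2]])
        nbr = build_neighbor_index(coords, k=10)
        assert nbr.shape == (4, 3)
        for i in range(4):
            assert i not in nbr[i]
            assert sorted(nbr[i]) == sorted(set(range(4)) - {i})

    def test_tie_broken_by_ascending_index(self):
        # spots 1 and 2 are equidistant from spot 0
        nbr = build_neighbor_index(SpatialMap([[0, 0], [1, 0], [0, 1]]), k=2)
        np.testing.assert_array_equal(nbr[0], [1, 2])

    def test_duplicate_coordinates_allowed(self):
        nbr = build_neighbor_index(SpatialMap([[0, 0], [0, 0], [1, 1]]), k=2)
        np.testing.assert_array_equal(nbr[0], [1, 2])
        np.testing.assert_array_equal(nbr[1], [0, 2])

    def test_fewer_than_two_spots_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_neighbor_index(SpatialMap([[0.0, 0.0]]), k=1)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(10):
            coords = rng.integers(0, 8, size=(60, 2)).astype(float)  # many ties
            nbr = build_neighbor_index(SpatialMap(coords), k=7)
            ref = reference_neighbors(coords, 7)
            for i in range(60):
                assert nbr[i].tolist() == ref[i]


class TestZeroRatio:
    @pytest.mark.parametrize(
        "neighbor_vals, expected",
        [((0, 0, 2, 3, 0), 0.6), ((1, 2, 3, 4, 5), 0.0), ((0, 0, 0, 0, 0), 1.0)],
    )
    def test_fraction_of_zero_neighbors(self, neighbor_vals, expected):
        # spot 0 sits at the center; its 5 neighbors carry the gene values
        vals = np.zeros((6, 1))
        vals[1:, 0] = neighbor_vals
        m = norm_matrix(vals)
        coords = SpatialMap(
            [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1]]
        )
        nbr = build_neighbor_index(coords, k=5)
        assert zero_ratio(m, nbr, spot=0, gene=0) == pytest.approx(expected)


def star_case(neighbor_vals):
    """Spot 0 at the origin surrounded by 5 equidistant-ish neighbors."""
    vals = np.zeros((6, 1))
    vals[1:, 0] = neighbor_vals
    coords = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [0.5, 0.5]])
    return norm_matrix(vals), SpatialMap(coords)


class TestImpute:
    def test_low_ratio_zero_imputed_to_nonzero_neighbor_mean(self):
        m, coords = star_case((0, 2, 4, 6, 8))
        out, report, dec = impute(m, coords, ImputationConfig(k=5, delta=0.4))
        assert out.values[0, 0] == pytest.approx(5.0)
        assert dec[0, 0] == DECISION_IMPUTED

    def test_high_ratio_zero_retained_as_biological(self):
        m, coords = star_case((0, 0, 2, 4, 0))
        out, report, dec = impute(m, coords, ImputationConfig(k=5, delta=0.4))
        assert out.values[0, 0] == 0
        assert dec[0, 0] == DECISION_BIOLOGICAL
        assert report.n_retained_biological >= 1

    def test_delta_one_imputes_every_recoverable_zero(self, rng):
        X = rng.random((30, 20))
        X[X < 0.4] = 0
        m = norm_matrix(X)
        coords = SpatialMap(rng.random((30, 2)) * 10)
        out, report, dec = impute(m, coords, ImputationConfig(k=5, delta=1.0))
        ref = reference_impute(X, coords.coords, k=5, delta=1.0)
        np.testing.assert_allclose(out.values, ref)
        # remaining zeros are exactly the all-zero neighborhoods
        assert (out.values == 0).sum() == report.n_skipped_allzero_neighborhood

    def test_delta_zero_only_dense_neighborhood_zeros(self, rng):
        X = rng.random((25, 10))
        X[X < 0.3] = 0
        coords = SpatialMap(rng.random((25, 2)))
        out, _, dec = impute(norm_matrix(X), coords, ImputationConfig(k=4, delta=0.0))
        ref = reference_impute(X, coords.coords, k=4, delta=0.0)
        np.testing.assert_allclose(out.values, ref)

    def test_requires_normalized_matrix(self):
        m = SpotGeneMatrix.from_array(np.ones((3, 2)), is_normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            impute(m, SpatialMap([[0, 0], [1, 0], [0, 1]]))

    def test_misaligned_coords_error(self):
        m = norm_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="match"):
            impute(m, SpatialMap([[0, 0], [1, 0]]))

    def test_k_reduced_when_too_large(self, caplog):
        m = norm_matrix([[0.0, 1], [1, 1], [1, 0]])
        out, report, _ = impute(m, SpatialMap([[0, 0], [1, 0], [0, 1]]),
                                ImputationConfig(k=10, delta=1.0))
        assert report.k == 2

    def test_decision_mask_covers_every_entry(self, rng):
        X = rng.random((40, 15))
        X[X < 0.5] = 0
        coords = SpatialMap(rng.random((40, 2)))
        _, report, dec = impute(norm_matrix(X), coords)
        assert np.all((dec == DECISION_NONZERO) == (X != 0))
        assert report.n_zero_candidates == (X == 0).sum()


class TestImputeProperties:
    def test_nonzero_preservation_and_monotonicity(self, rng):
        for _ in range(10):
            X = rng.random((35, 12))
            X[X < rng.uniform(0.2, 0.7)] = 0
            coords = SpatialMap(rng.random((35, 2)))
            out, _, _ = impute(norm_matrix(X), coords,
                               ImputationConfig(k=4, delta=0.5))
            nz = X != 0
            assert np.array_equal(out.values[nz], X[nz])  # bit-identical
            assert np.all(out.values >= X)

    def test_sparsity_accounting_identity(self, rng):
        from spamean.metrics import zero_sparsity

        X = rng.random((50, 20))
        X[X < 0.6] = 0
        coords = SpatialMap(rng.random((50, 2)))
        out, report, _ = impute(norm_matrix(X), coords)
        before = zero_sparsity(X)
        after = zero_sparsity(out.values)
        assert report.zero_sparsity_before_pct == pytest.approx(before, abs=1e-12)
        assert report.zero_sparsity_after_pct == pytest.approx(after, abs=1e-12)
        assert before - after == pytest.approx(report.dropout_detected_pct,
                                               abs=1e-9)

    def test_imputed_count_nondecreasing_in_delta(self, rng):
        X = rng.random((40, 15))
        X[X < 0.5] = 0
        coords = SpatialMap(rng.random((40, 2)))
        counts = []
        for delta in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            _, report, _ = impute(norm_matrix(X), coords,
                                  ImputationConfig(k=5, delta=delta))
            counts.append(report.n_imputed)
        assert counts == sorted(counts)

    def test_permutation_equivariance(self, rng):
        X = rng.random((30, 10))
        X[X < 0.5] = 0
        coords = rng.random((30, 2)) * 100  # generic: no distance ties
        out, _, _ = impute(norm_matrix(X), SpatialMap(coords),
                           ImputationConfig(k=4, delta=0.5))
        perm = rng.permutation(30)
        out_p, _, _ = impute(norm_matrix(X[perm]), SpatialMap(coords[perm]),
                             ImputationConfig(k=4, delta=0.5))
        np.testing.assert_allclose(out_p.values, out.values[perm])

    def test_snapshot_semantics_ignore_spot_order(self, rng):
        """Frozen-snapshot output equals the loop oracle; the sequential
        variant can differ because later spots see earlier imputations."""
        X = rng.random((30, 8))
        X[X < 0.55] = 0
        coords = SpatialMap(rng.random((30, 2)))
        snap, _, _ = impute(norm_matrix(X), coords,
                            ImputationConfig(k=3, delta=0.8))
        ref = reference_impute(X, coords.coords, k=3, delta=0.8)
        np.testing.assert_allclose(snap.values, ref)
        seq, _, _ = impute(norm_matrix(X), coords,
                           ImputationConfig(k=3, delta=0.8, sequential=True))
        assert np.all(seq.values >= X)  # still monotone even when it diverges

    def test_recovery_beats_leaving_zeros(self, default_dataset):
        """Imputed values at injected-dropout positions correlate with truth."""
        from spamean.preprocessing import normalize_log1p

        ds = default_dataset
        obs = normalize_log1p(SpotGeneMatrix.from_array(ds.observed_matrix))
        true = normalize_log1p(SpotGeneMatrix.from_array(ds.true_matrix))
        out, _, _ = impute(obs, SpatialMap(ds.coords))
        r, c = np.nonzero(ds.dropout_mask)
        imputed_vals = out.values[r, c]
        true_vals = true.values[r, c]
        filled = imputed_vals > 0
        assert filled.any()
        corr = np.corrcoef(true_vals[filled], imputed_vals[filled])[0, 1]
        # leaving the entries at zero has zero covariance by construction,
        # so any positive correlation beats that baseline
        assert corr > 0
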