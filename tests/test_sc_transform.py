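"""SC log transform, common-edge mask, and structural row-correlation."""

import itertools

import numpy as np
import pytest

from hconnica import (
    Connectome,
    ConnectomeError,
    Modality,
    common_edge_mask,
    log_transform,
    structural_correlation,
    upper_pairs,
)
from conftest import make_sc, sc_from_edges


class TestLogTransform:
    @pytest.mark.parametrize("raw,expected", [
        (0.0, 0.0),
        (99.0, 2.0),
        (9.0, 1.0),
        (10**5 - 1, 5.0),  # streamline counts up to ~1e5 map into [0, 5]
    ])
    def test_values(self, raw, expected):
        sc = make_sc([[0, raw], [raw, 0]])
        out = log_transform(sc)
        assert out.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_sparsity_and_monotonicity(self, rng):
        w = np.sort(rng.uniform(0, 1e4, 50))
        f = np.log10(1 + w)
        assert np.all(np.diff(f) > 0)
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 7.0
        out = log_transform(make_sc(m))
        assert (out.matrix == 0).sum() == 14  # zeros stay zero

    def test_negative_rejected(self):
        sc = make_sc([[0, 1], [1, 0]])
        sc.matrix[0, 1] = -0.5  # bypass constructor validation
        sc.matrix[1, 0] = -0.5
        with pytest.raises(ConnectomeError):
            log_transform(sc)


class TestCommonEdgeMask:
    def test_single_sc_mask_is_its_pattern(self):
        sc = sc_from_edges(4, [(0, 1), (2, 3)])
        mask = common_edge_mask([sc])
        assert mask.count == 2
        assert {tuple(p) for p in mask.pairs()} == {(0, 1), (2, 3)}

    def test_disjoint_edge_sets_give_empty_mask(self):
        a = sc_from_edges(4, [(0, 1)])
        b = sc_from_edges(4, [(2, 3)])
        assert common_edge_mask([a, b]).count == 0

    def test_intersection_example(self):
        # nodes 1,2,3 -> indices 0,1,2
        sc1 = sc_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        sc2 = sc_from_edges(3, [(0, 1), (1, 2)])
        mask = common_edge_mask([sc1, sc2])
        assert {tuple(p) for p in mask.pairs()} == {(0, 1), (1, 2)}

    def test_brute_force_intersection_oracle(self, rng):
        n, n_subj = 8, 5
        scs, edge_sets = [], []
        for s in range(n_subj):
            edges = {tuple(sorted(e)) for e in
                     rng.integers(0, n, (10, 2)) if e[0] != e[1]}
            edge_sets.append(edges)
            scs.append(sc_from_edges(n, edges, subject_id=f"S{s}"))
        expected = set.intersection(*edge_sets)
        for k in range(1, n_subj + 1):
            mask = common_edge_mask(scs[:k])
            assert {tuple(p) for p in mask.pairs()} == set.intersection(
                *edge_sets[:k])
            # adding a subject can only shrink the mask
            if k > 1:
                prev = common_edge_mask(scs[:k - 1])
                assert mask.count <= prev.count
        assert {tuple(p) for p in common_edge_mask(scs).pairs()} == expected

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConnectomeError):
            common_edge_mask([sc_from_edges(3, [(0, 1)]),
                              sc_from_edges(4, [(0, 1)])])


class TestStructuralCorrelation:
    def test_identical_rows_give_r_one(self):
        # nodes 0 and 1 connect identically to every other node, so their
        # full rows coincide; the pair is masked by hand since the mutual
        # weight is zero
        from hconnica import EdgeMask
        m = np.zeros((4, 4))
        for j, w in ((2, 1.0), (3, 2.0)):
            m[0, j] = m[j, 0] = w
            m[1, j] = m[j, 1] = w
        sc = make_sc(m)
        ind = np.zeros(6, dtype=bool)
        ind[0] = True  # pair (0, 1) in canonical order
        mask = EdgeMask(n_nodes=4, indicator=ind)
        out = structural_correlation(sc, mask)
        assert out.matrix[0, 1] == pytest.approx(1.0)

    def test_identical_profiles_r_one_excluding_mutual_entries(self):
        m = np.zeros((4, 4))
        for j, w in ((2, 1.0), (3, 2.0)):
            m[0, j] = m[j, 0] = w
            m[1, j] = m[j, 1] = w
        m[0, 1] = m[1, 0] = 3.0
        sc = make_sc(m)
        mask = common_edge_mask([sc])
        out = structural_correlation(sc, mask, exclude_pair_entries=True)
        assert out.matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_anticorrelation(self):
        # rows (0,2,1) vs (2,0,1) correlate at exactly -1
        sc = make_sc([[0, 2, 1], [2, 0, 1], [1, 1, 0]])
        mask = common_edge_mask([sc])
        out = structural_correlation(sc, mask)
        assert out.matrix[0, 1] == pytest.approx(-1.0)
        assert out.modality is Modality.SC_CORR

    def test_output_bounded_symmetric_zero_diagonal(self, rng):
        m = np.abs(rng.normal(1, 1, (12, 12)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        sc = make_sc(m)
        out = structural_correlation(sc, common_edge_mask([sc]))
        assert np.array_equal(out.matrix, out.matrix.T)
        assert np.all(np.diag(out.matrix) == 0)
        assert out.matrix.min() >= -1 and out.matrix.max() <= 1

    def test_permutation_equivariance(self, rng):
        m = np.abs(rng.normal(1, 1, (8, 8)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        sc = make_sc(m)
        order = list(rng.permutation(8))
        mask = common_edge_mask([sc])
        direct = structural_correlation(sc, mask).permuted(order)
        permuted_sc = sc.permuted(order)
        via_perm = structural_correlation(
            permuted_sc, common_edge_mask([permuted_sc]))
        np.testing.assert_allclose(direct.matrix, via_perm.matrix, atol=1e-12)

    def test_zero_variance_row_is_hard_error(self):
        # node 2 is isolated (constant zero row); force a mask that
        # involves it
        from hconnica import EdgeMask
        sc = sc_from_edges(4, [(0, 1), (0, 3)])
        ind = np.zeros(6, dtype=bool)
        ind[5] = True  # canonical pair list: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        mask = EdgeMask(n_nodes=4, indicator=ind)
        with pytest.raises(ConnectomeError, match="zero-variance"):
            structural_correlation(sc, mask)

    def test_exclude_pair_entries_matches_manual(self, rng):
        m = np.abs(rng.normal(1, 1, (7, 7)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        sc = make_sc(m)
        mask = common_edge_mask([sc])
        out = structural_correlation(sc, mask, exclude_pair_entries=True)
        for i, j in mask.pairs():
            keep = [k for k in range(7) if k not in (i, j)]
            expected = np.corrcoef(m[i, keep], m[j, keep])[0, 1]
            assert out.matrix[i, j] == pytest.approx(expected, abs=1e-12)
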