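import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popinfer import (
    CellMatrix,
    CellOrdering,
    ValidationError,
    bin_sizes,
    make_pseudocells,
    make_random_pseudocells,
    select_root_cell,
)


class TestBinSizes:
    @pytest.mark.parametrize(
        "N,n,expected",
        [
            (10, 3, [4, 3, 3]),
            (3, 3, [1, 1, 1]),
            (7, 1, [7]),
        ],
    )
    def test_examples(self, N, n, expected):
        assert bin_sizes(N, n).tolist() == expected

    def test_study_scale_partition(self):
        sizes = bin_sizes(3960, 80)
        assert (sizes[:40] == 50).all() and (sizes[40:] == 49).all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 500), st.data())
    def test_matches_array_split_oracle(self, N, data):
        n = data.draw(st.integers(1, N))
        sizes = bin_sizes(N, n)
        oracle = [len(chunk) for chunk in np.array_split(np.arange(N), n)]
        assert sizes.tolist() == oracle
        assert sizes.sum() == N

    def test_more_bins_than_cells_rejected(self):
        with pytest.raises(ValidationError):
            bin_sizes(3, 5)


class TestRootCell:
    def test_tie_broken_by_cell_order(self):
        m = CellMatrix(np.array([[5.0, 9.0, 9.0, 2.0]]), ["mk"],
                       ["c1", "c2", "c3", "c4"])
        assert select_root_cell(m, ["mk"], rank=1) == "c2"

    def test_lowest_rank(self):
        m = CellMatrix(np.array([[5.0, 9.0, 9.0, 2.0]]), ["mk"],
                       ["c1", "c2", "c3", "c4"])
        assert select_root_cell(m, ["mk"], rank=4) == "c4"

    def test_single_cell_identity(self):
        m = CellMatrix(np.array([[1.0]]), ["mk"], ["only"])
        assert select_root_cell(m, ["mk"]) == "only"

    def test_sum_over_multiple_markers(self):
        m = CellMatrix(np.array([[1.0, 0.0], [0.0, 5.0]]), ["Mecom", "Mpl"],
                       ["c1", "c2"])
        assert select_root_cell(m, ["Mecom", "Mpl"], rank=1) == "c2"

    def test_rank_out_of_range(self):
        m = CellMatrix(np.array([[1.0]]), ["mk"], ["c"])
        with pytest.raises(ValidationError):
            select_root_cell(m, ["mk"], rank=2)

    def test_missing_marker(self):
        m = CellMatrix(np.array([[1.0]]), ["mk"], ["c"])
        with pytest.raises(ValidationError):
            select_root_cell(m, ["absent"])


def _random_matrices(rng, n_genes, n_cells):
    expr = CellMatrix(rng.normal(size=(n_genes, n_cells)),
                      [f"g{i}" for i in range(n_genes)],
                      [f"c{i}" for i in range(n_cells)])
    access = CellMatrix(rng.uniform(size=(n_genes, n_cells)),
                        expr.gene_ids, expr.cell_ids, "accessibility")
    return expr, access


class TestMakePseudocells:
    def test_identity_partition_when_n_equals_cells(self):
        rng = np.random.default_rng(0)
        expr, access = _random_matrices(rng, 3, 5)
        pt = rng.permutation(5).astype(float)
        ordering = CellOrdering.from_pseudotime(expr.cell_ids, pt)
        pc = make_pseudocells(expr, access, ordering, 5)
        assert all(len(b) == 1 for b in pc.bins)
        sorted_expr = expr.reorder_cells(ordering.cell_ids)
        np.testing.assert_allclose(pc.x_p, sorted_expr.to_dense())

    def test_aggregation_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(1)
        expr, access = _random_matrices(rng, 4, 11)
        ordering = CellOrdering.from_pseudotime(expr.cell_ids, rng.uniform(size=11))
        pc = make_pseudocells(expr, access, ordering, 3)
        pos = {c: i for i, c in enumerate(expr.cell_ids)}
        for j, members in enumerate(pc.bins):
            for gi in range(4):
                expected = np.mean([expr.to_dense()[gi, pos[c]] for c in members])
                assert pc.x_p[gi, j] == pytest.approx(expected, rel=1e-12)

    def test_bins_are_contiguous_and_monotone_in_pseudotime(self):
        rng = np.random.default_rng(2)
        expr, access = _random_matrices(rng, 2, 23)
        pt = rng.uniform(size=23)
        ordering = CellOrdering.from_pseudotime(expr.cell_ids, pt)
        pc = make_pseudocells(expr, access, ordering, 5)
        ptmap = dict(zip(expr.cell_ids, pt))
        for left, right in zip(pc.bins[:-1], pc.bins[1:]):
            assert max(ptmap[c] for c in left) <= min(ptmap[c] for c in right)

    def test_pseudocell_value_within_member_range(self):
        rng = np.random.default_rng(3)
        expr, access = _random_matrices(rng, 3, 17)
        ordering = CellOrdering.from_pseudotime(expr.cell_ids, rng.uniform(size=17))
        pc = make_pseudocells(expr, access, ordering, 4)
        pos = {c: i for i, c in enumerate(expr.cell_ids)}
        dense = expr.to_dense()
        for j, members in enumerate(pc.bins):
            vals = dense[:, [pos[c] for c in members]]
            assert np.all(pc.x_p[:, j] >= vals.min(axis=1) - 1e-12)
            assert np.all(pc.x_p[:, j] <= vals.max(axis=1) + 1e-12)

    def test_constant_gene_stays_constant(self, small_expr, small_ordering):
        pc = make_pseudocells(small_expr, None, small_ordering, 2)
        np.testing.assert_allclose(pc.x_p[2], [5.0, 5.0])  # gC constant at 5

    def test_aggregation_permutation_invariant_within_bin(self):
        rng = np.random.default_rng(4)
        expr, access = _random_matrices(rng, 2, 8)
        pt = np.zeros(8)  # all tied: single pseudotime value
        o1 = CellOrdering.from_pseudotime(expr.cell_ids, pt)
        pc1 = make_pseudocells(expr, access, o1, 1)
        shuffled = [expr.cell_ids[i] for i in rng.permutation(8)]
        o2 = CellOrdering(shuffled)  # no pseudotime: order as given
        pc2 = make_pseudocells(expr, access, o2, 1)
        np.testing.assert_allclose(pc1.x_p, pc2.x_p, rtol=1e-12)

    def test_ordering_matrix_mismatch_rejected(self, small_expr):
        ordering = CellOrdering.from_pseudotime(["c1", "c9"], [0.1, 0.2])
        with pytest.raises(ValidationError):
            make_pseudocells(small_expr, None, ordering, 2)


class TestRandomPseudocells:
    def _setup(self, seed=0, n_cells=12):
        rng = np.random.default_rng(seed)
        expr, access = _random_matrices(rng, 3, n_cells)
        labels = {c: ("A" if i < n_cells // 2 else "B")
                  for i, c in enumerate(expr.cell_ids)}
        return expr, access, labels

    def test_sizes_deterministic_composition_seeded(self):
        expr, access, labels = self._setup()
        pc1 = make_random_pseudocells(expr, access, labels, bin_size=2, seed=7)
        pc2 = make_random_pseudocells(expr, access, labels, bin_size=2, seed=7)
        assert pc1.bins == pc2.bins
        assert sorted(len(b) for b in pc1.bins) == [2] * 6

    def test_different_seeds_differ(self):
        expr, access, labels = self._setup()
        pc1 = make_random_pseudocells(expr, access, labels, bin_size=2, seed=1)
        pc2 = make_random_pseudocells(expr, access, labels, bin_size=2, seed=2)
        assert pc1.bins != pc2.bins

    def test_bins_never_mix_clusters(self):
        expr, access, labels = self._setup(n_cells=24)
        pc = make_random_pseudocells(expr, access, labels, bin_size=3, seed=0)
        for members in pc.bins:
            assert len({labels[c] for c in members}) == 1

    def test_partition_covers_all_cells(self):
        expr, access, labels = self._setup(n_cells=14)
        pc = make_random_pseudocells(expr, access, labels, bin_size=3, seed=0)
        flat = [c for b in pc.bins for c in b]
        assert sorted(flat) == sorted(expr.cell_ids)

    def test_bin_size_exceeding_smallest_cluster_rejected(self):
        expr, access, labels = self._setup()
        with pytest.raises(ValidationError, match="smallest cluster"):
            make_random_pseudocells(expr, access, labels, bin_size=10, seed=0)
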