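"""Movement matrices, percentile pair calls, shifted/stable classification."""

import numpy as np
import pytest

from funcmap.fmm import FMM, AnnotationEmbedding
from funcmap.graph_io import DataError
from funcmap.movement import (
    classify_shifted_stable,
    gene_movement_scores,
    pairwise_movement,
    significant_pairs,
    total_movement,
)
from funcmap.nmtf import TriFactorization


def fmm_of(values, names=None):
    names = names or tuple(f"a{i}" for i in range(values.shape[0]))
    return FMM(values=values, annotation_order=tuple(names))


def random_fmm(n, seed, names=None):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 1, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return fmm_of(v, names)


class TestPairwiseMovement:
    def test_identical_spaces_give_zero(self):
        f = random_fmm(6, 0)
        d = pairwise_movement(f, f)
        assert np.allclose(d.D, 0.0)

    def test_swapping_inputs_negates(self):
        f1, f2 = random_fmm(6, 1), random_fmm(6, 2)
        assert np.allclose(
            pairwise_movement(f1, f2).D, -pairwise_movement(f2, f1).D
        )

    def test_hand_computed_differences(self):
        c = fmm_of(np.array([[0, 0.8, 0.4], [0.8, 0, 0.6], [0.4, 0.6, 0]]))
        x = fmm_of(np.array([[0, 0.5, 0.9], [0.5, 0, 0.6], [0.9, 0.6, 0]]))
        d = pairwise_movement(c, x).D
        assert d[0, 1] == pytest.approx(0.3)  # closer in the case space
        assert d[0, 2] == pytest.approx(-0.5)  # farther in the case space
        assert d[1, 2] == pytest.approx(0.0)

    def test_unaligned_orders_error(self):
        with pytest.raises(DataError):
            pairwise_movement(random_fmm(4, 0), random_fmm(4, 0, names="wxyz"))


class TestSignificantPairs:
    def test_five_percent_each_side_for_continuous_movements(self):
        d = pairwise_movement(random_fmm(150, 3), random_fmm(150, 4))
        sp = significant_pairs(d)
        n_pairs = 150 * 149 // 2
        assert sp.n_pairs == n_pairs
        # inclusive linear-interpolation percentiles: ~5% of pairs per tail
        assert abs(len(sp.closer) / n_pairs - 0.05) < 0.005
        assert abs(len(sp.apart) / n_pairs - 0.05) < 0.005
        assert not sp.degenerate

    def test_all_equal_movements_degenerate(self):
        base = random_fmm(10, 5)
        # dyadic entries keep the constant offset exact in floating point
        base = fmm_of(np.round(base.values * 8) / 8)
        shifted = fmm_of(np.where(np.eye(10) == 1, 0.0, base.values + 0.25))
        sp = significant_pairs(pairwise_movement(base, shifted))
        assert sp.degenerate
        assert len(sp.closer) == len(sp.apart) == sp.n_pairs

    def test_zero_movement_degenerate(self):
        f = random_fmm(10, 6)
        sp = significant_pairs(pairwise_movement(f, f))
        assert sp.degenerate

    def test_too_few_pairs_error(self):
        d = pairwise_movement(random_fmm(5, 7), random_fmm(5, 8))
        with pytest.raises(DataError):
            significant_pairs(d)

    def test_invariant_to_common_permutation(self):
        f1, f2 = random_fmm(30, 9), random_fmm(30, 10)
        sp = significant_pairs(pairwise_movement(f1, f2))
        rng = np.random.default_rng(11)
        perm = rng.permutation(30)
        names = tuple(f1.annotation_order[i] for i in perm)
        p1 = FMM(values=f1.values[np.ix_(perm, perm)], annotation_order=names)
        p2 = FMM(values=f2.values[np.ix_(perm, perm)], annotation_order=names)
        sp_p = significant_pairs(pairwise_movement(p1, p2))
        canon = lambda s: {tuple(sorted(p)) for p in s}
        assert canon(sp.closer) == canon(sp_p.closer)
        assert canon(sp.apart) == canon(sp_p.apart)


class TestTotalMovement:
    def test_zero_matrix_gives_zero_totals(self):
        f = random_fmm(5, 0)
        totals = total_movement(pairwise_movement(f, f))
        assert all(v == 0 for v in totals.values())

    def test_three_four_five_row(self):
        names = ("a", "b", "c")
        c = fmm_of(np.array([[0, 3.0, 4.0], [3, 0, 0], [4, 0, 0]]) / 2, names)
        x = fmm_of(np.zeros((3, 3)), names)
        totals = total_movement(pairwise_movement(c, x))
        assert totals["a"] == pytest.approx(2.5)  # hypot(1.5, 2.0)

    def test_matches_elementwise_oracle(self):
        d = pairwise_movement(random_fmm(5, 1), random_fmm(5, 2))
        totals = total_movement(d)
        for i, a in enumerate(d.annotation_order):
            oracle = np.sqrt(sum(d.D[i, j] ** 2 for j in range(5) if j != i))
            assert totals[a] == pytest.approx(oracle, abs=1e-12)

    def test_swap_of_inputs_preserves_totals(self):
        f1, f2 = random_fmm(8, 3), random_fmm(8, 4)
        assert total_movement(pairwise_movement(f1, f2)) == pytest.approx(
            total_movement(pairwise_movement(f2, f1))
        )


class TestClassifyShiftedStable:
    def test_all_equal_totals_yield_empty_sets(self):
        cls = classify_shifted_stable({"a": 1.0, "b": 1.0, "c": 1.0})
        assert cls.shifted == cls.stable == frozenset()
        assert cls.degenerate

    def test_single_outlier_at_exact_threshold(self):
        # mean 20, population sd 40 -> threshold 100, inclusive
        totals = dict(zip("abcde", [0.0, 0.0, 0.0, 0.0, 100.0]))
        cls = classify_shifted_stable(totals)
        assert cls.shifted == frozenset({"e"})
        assert cls.mean == pytest.approx(20.0)
        assert cls.sd == pytest.approx(40.0)

    def test_gaussian_tail_mass(self):
        rng = np.random.default_rng(12)
        totals = {f"a{i}": v for i, v in enumerate(rng.normal(0, 1, 10_000))}
        cls = classify_shifted_stable(totals)
        frac = len(cls.shifted) / len(totals)
        assert 0.018 <= frac <= 0.028  # ~2.3% beyond two standard deviations

    def test_needs_three_annotations(self):
        with pytest.raises(DataError):
            classify_shifted_stable({"a": 1.0, "b": 2.0})


def space_pair(n_genes=100, k=6, move=None, seed=0):
    """Two factorizations + embeddings; ``move`` shifts some case gene rows."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i:03d}" for i in range(n_genes))

    def factor(p):
        return TriFactorization(
            P=p, S=np.eye(k), G=np.abs(rng.normal(size=(n_genes, k))),
            k=k, rse_trace=(0.1,), node_order=genes,
        )

    p_control = np.abs(rng.normal(size=(n_genes, k))) + 0.1
    p_case = p_control.copy()
    if move is not None:
        idx, delta = move
        p_case[idx] = p_case[idx] + delta
    u = rng.normal(size=(5, k))
    emb = AnnotationEmbedding(U=u, annotation_order=tuple("abcde"), k=k)
    return factor(p_control), factor(p_case), emb, emb


class TestGeneMovementScores:
    def test_identical_spaces_degenerate_empty_prediction(self):
        fc, fx, ec, ex = space_pair()
        fx = TriFactorization(
            P=fc.P, S=fc.S, G=fc.G, k=fc.k, rse_trace=fc.rse_trace,
            node_order=fc.node_order,
        )
        rep = gene_movement_scores(fc, fx, ec, ex, {"a", "b"})
        assert rep.degenerate
        assert rep.predicted == frozenset()

    def test_continuous_scores_select_five_percent(self):
        fc, fx, ec, ex = space_pair()
        rng = np.random.default_rng(42)
        fx = TriFactorization(
            P=fc.P + np.abs(rng.normal(scale=0.3, size=fc.P.shape)),
            S=fc.S, G=fc.G, k=fc.k, rse_trace=fc.rse_trace, node_order=fc.node_order,
        )
        rep = gene_movement_scores(fc, fx, ec, ex, {"a", "b", "c"})
        assert len(rep.predicted) == 5  # 5% of 100 genes, inclusive threshold

    def test_moved_block_occupies_top_scores(self):
        idx = np.arange(10)
        fc, fx, ec, ex = space_pair(move=(idx, 3.0), seed=5)
        rep = gene_movement_scores(fc, fx, ec, ex, {"a", "b"})
        top = sorted(rep.scores, key=rep.scores.get, reverse=True)[:10]
        moved = {fc.node_order[i] for i in idx}
        assert len(set(top) & moved) >= 8

    def test_empty_shifted_errors(self):
        fc, fx, ec, ex = space_pair()
        with pytest.raises(DataError):
            gene_movement_scores(fc, fx, ec, ex, set())

    def test_unknown_shifted_annotation_errors(self):
        fc, fx, ec, ex = space_pair()
        with pytest.raises(DataError):
            gene_movement_scores(fc, fx, ec, ex, {"zzz"})
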