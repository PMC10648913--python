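import numpy as np
import pytest

from refstab.stability import (
    bestkeeper,
    delta_ct_method,
    genorm,
    genorm_pairwise_variation,
    normfinder,
    to_relative_quantity,
)

from conftest import make_matrix


def brute_force_m(ct: np.ndarray) -> np.ndarray:
    """Independent GeNorm M: mean over partners of SD of log2 expression
    ratios, computed directly from Ct differences (log2 Q_j - log2 Q_k
    equals Ct_k - Ct_j up to a constant)."""
    g = ct.shape[0]
    m = np.zeros(g)
    for j in range(g):
        sds = [np.std(ct[k] - ct[j], ddof=1) for k in range(g) if k != j]
        m[j] = np.mean(sds)
    return m


class TestRelativeQuantity:
    def test_powers_of_two(self):
        q = to_relative_quantity(make_matrix([[20.0, 21.0, 22.0], [20, 20, 20], [1, 2, 3]]))
        assert np.allclose(q.q[0], [1.0, 0.5, 0.25])

    def test_constant_row_is_all_ones(self):
        q = to_relative_quantity(make_matrix([[20.0, 20.0, 20.0]]))
        assert np.allclose(q.q, 1.0)

    def test_fractional_delta(self):
        q = to_relative_quantity(make_matrix([[18.5, 20.0]]))
        assert q.q[0, 1] == pytest.approx(2 ** -1.5)

    def test_bounded_and_max_one_per_gene(self):
        rng = np.random.default_rng(1)
        q = to_relative_quantity(make_matrix(rng.uniform(15, 35, (5, 8))))
        assert (q.q > 0).all() and (q.q <= 1).all()
        assert np.allclose(q.q.max(axis=1), 1.0)

    def test_missing_cells_rejected(self):
        m = make_matrix([[20.0, np.nan], [21.0, 22.0]])
        with pytest.raises(ValueError, match="missing"):
            to_relative_quantity(m)


class TestGenorm:
    def test_hand_computed_three_gene_example(self, abc_matrix):
        r = genorm(to_relative_quantity(abc_matrix))
        sd = np.std([20.0, 21, 22, 23], ddof=1)  # 1.29099
        assert r.m_full["A"] == pytest.approx(sd / 2, abs=1e-12)
        assert r.m_full["B"] == pytest.approx(sd / 2, abs=1e-12)
        assert r.m_full["C"] == pytest.approx(sd, abs=1e-12)
        # C excluded first; A and B are the final pair sharing rank 1
        assert r.exclusion_rank == {"A": 1, "B": 1, "C": 3}
        assert r.m_stepwise["C"] == pytest.approx(sd, abs=1e-12)
        assert r.m_stepwise["A"] == r.m_stepwise["B"] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_gene_survives_to_final_pair(self):
        rng = np.random.default_rng(2)
        ct = rng.uniform(18, 30, (4, 6))
        ct[3] = ct[0]  # exact duplicate of gene 0
        r = genorm(to_relative_quantity(make_matrix(ct)))
        assert r.exclusion_rank["G0"] == 1 and r.exclusion_rank["G3"] == 1

    def test_identical_rows_give_zero_m(self):
        ct = np.tile([20.0, 22.0, 19.0, 25.0], (3, 1))
        r = genorm(to_relative_quantity(make_matrix(ct)))
        assert all(abs(v) < 1e-12 for v in r.m_full.values())

    def test_m_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ct = rng.uniform(15, 32, (4, 6))
            r = genorm(to_relative_quantity(make_matrix(ct)))
            brute = brute_force_m(ct)
            for i in range(4):
                assert r.m_full[f"G{i}"] == pytest.approx(brute[i], abs=1e-10)

    def test_requires_three_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            genorm(to_relative_quantity(make_matrix([[20.0, 21], [22, 23.0]])))


class TestPairwiseVariation:
    def test_proportional_genes_give_zero_v(self):
        base = np.array([20.0, 21.0, 19.0, 23.0])
        ct = np.vstack([base, base + 2, base + 5, base - 1])
        q = to_relative_quantity(make_matrix(ct))
        r = genorm(q)
        assert np.allclose(r.v_values, 0.0, atol=1e-12)

    def test_matches_definition_brute_force(self, abc_matrix):
        q = to_relative_quantity(abc_matrix)
        r = genorm(q)
        order = [q.genes.index(g) for g in r.exclusion_order]
        log2q = np.log2(q.q)
        nf2 = log2q[order[:2]].mean(axis=0)
        nf3 = log2q[order[:3]].mean(axis=0)
        expected = np.std(nf2 - nf3, ddof=1)
        v = genorm_pairwise_variation(q, r)
        assert len(v) == 1
        assert v[0] == pytest.approx(expected, abs=1e-12)


class TestNormfinder:
    def test_constant_centered_gene_single_subgroup(self):
        # gene 0 co-varies exactly with the per-sample mean once gene
        # structure is symmetric: build z_0 constant by construction
        ct = np.array([[20.0, 21.0, 22.0],
                       [25.0, 26.0, 27.0],
                       [30.0, 31.0, 32.0]])
        r = normfinder(to_relative_quantity(make_matrix(ct)))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in r.stability.values())

    def test_two_subgroup_closed_form(self):
        # gene A shifts by h between subgroups; others flat.  After
        # per-sample centering, delta(A) = 2h/3 and stability(A) = h/3.
        h = 3.0
        ct = np.array([[20.0, 20.0, 20.0 - h, 20.0 - h],   # lower Ct = higher x
                       [25.0, 25.0, 25.0, 25.0],
                       [30.0, 30.0, 30.0, 30.0]])
        m = make_matrix(ct, genes=["A", "B", "C"])
        sub = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        r = normfinder(to_relative_quantity(m), sub)
        assert r.stability["A"] == pytest.approx(h / 3, abs=1e-12)
        assert r.stability["B"] == pytest.approx(h / 6, abs=1e-12)
        assert r.stability["C"] == pytest.approx(h / 6, abs=1e-12)

    def test_additive_gene_offset_leaves_scores_unchanged(self):
        rng = np.random.default_rng(4)
        ct = rng.uniform(18, 30, (4, 8))
        sub = {f"s{j}": ("a" if j < 4 else "b") for j in range(8)}
        r1 = normfinder(to_relative_quantity(make_matrix(ct)), sub)
        ct2 = ct.copy()
        ct2[1] += 5.0
        r2 = normfinder(to_relative_quantity(make_matrix(ct2)), sub)
        for g in r1.genes:
            assert r1.stability[g] == pytest.approx(r2.stability[g], abs=1e-10)

    def test_subgroup_of_one_rejected(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4) + 20)
        sub = {"s0": "a", "s1": "a", "s2": "a", "s3": "b"}
        with pytest.raises(ValueError, match="< 2 samples"):
            normfinder(to_relative_quantity(m), sub)


class TestBestkeeper:
    def test_hand_computed_mad_and_cv(self):
        r = bestkeeper(make_matrix([[20.0, 21.0, 22.0, 23.0]]))
        assert r.ct_mean["G0"] == pytest.approx(21.5)
        assert r.sd["G0"] == pytest.approx(1.0)       # mean |x - mean|
        assert r.cv_pct["G0"] == pytest.approx(100.0 / 21.5)

    def test_constant_row(self):
        r = bestkeeper(make_matrix([[20.0, 20.0, 20.0]]))
        assert r.sd["G0"] == 0.0 and r.cv_pct["G0"] == 0.0

    def test_ranking_ascending_by_sd(self):
        ct = np.array([[20.0, 24.0, 20.0, 24.0],
                       [22.0, 22.5, 22.0, 22.5],
                       [25.0, 25.0, 25.0, 25.0]])
        r = bestkeeper(make_matrix(ct))
        assert r.ranking() == ["G2", "G1", "G0"]

    def test_sample_sd_flag(self):
        m = make_matrix([[20.0, 21.0, 22.0, 23.0]])
        r = bestkeeper(m, use_sample_sd=True)
        assert r.sd["G0"] == pytest.approx(np.std([20, 21, 22, 23.0], ddof=1))

    def test_format_pairs_cv_with_sd(self):
        r = bestkeeper(make_matrix([[20.0, 21.0, 22.0, 23.0]]))
        assert r.format_cv_sd("G0") == "4.65 ± 1.00"


class TestDeltaCt:
    def test_hand_computed_scores(self, abc_matrix):
        r = delta_ct_method(abc_matrix)
        sd = np.std([20.0, 21, 22, 23], ddof=1)
        assert r.score["A"] == pytest.approx(sd / 2, abs=1e-12)
        assert r.score["B"] == pytest.approx(sd / 2, abs=1e-12)
        assert r.score["C"] == pytest.approx(sd, abs=1e-12)

    def test_identical_rows_score_zero(self):
        ct = np.tile([20.0, 23.0, 21.0], (3, 1))
        r = delta_ct_method(make_matrix(ct))
        assert all(abs(v) < 1e-12 for v in r.score.values())

    def test_per_gene_constant_invariance(self):
        rng = np.random.default_rng(5)
        ct = rng.uniform(18, 30, (4, 6))
        r1 = delta_ct_method(make_matrix(ct))
        r2 = delta_ct_method(make_matrix(ct + rng.uniform(-3, 3, (4, 1))))
        for g in r1.genes:
            assert r1.score[g] == pytest.approx(r2.score[g], abs=1e-10)


class TestCrossMethodAgreement:
    def test_deltact_equals_full_set_genorm_m(self):
        """Both statistics are means of pairwise SDs of Ct differences."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            ct = rng.uniform(15, 32, (4, 6))
            m = make_matrix(ct)
            gm = genorm(to_relative_quantity(m)).m_full
            dc = delta_ct_method(m).score
            for g in m.genes:
                assert gm[g] == pytest.approx(dc[g], abs=1e-10)


class TestInvariance:
    def test_gene_shift_invariance_and_bestkeeper_sensitivity(self):
        rng = np.random.default_rng(7)
        ct = rng.uniform(18, 30, (5, 8))
        shift = np.zeros((5, 1))
        shift[2, 0] = 4.0
        m1, m2 = make_matrix(ct), make_matrix(ct + shift)
        sub = {f"s{j}": ("a" if j < 4 else "b") for j in range(8)}

        g1, g2 = genorm(to_relative_quantity(m1)), genorm(to_relative_quantity(m2))
        n1 = normfinder(to_relative_quantity(m1), sub)
        n2 = normfinder(to_relative_quantity(m2), sub)
        d1, d2 = delta_ct_method(m1), delta_ct_method(m2)
        for g in m1.genes:
            assert g1.m_full[g] == pytest.approx(g2.m_full[g], abs=1e-10)
            assert n1.stability[g] == pytest.approx(n2.stability[g], abs=1e-10)
            assert d1.score[g] == pytest.approx(d2.score[g], abs=1e-10)

        b1, b2 = bestkeeper(m1), bestkeeper(m2)
        assert b1.cv_pct["G2"] != pytest.approx(b2.cv_pct["G2"], abs=1e-6)
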