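import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domgen.band_data import BandMatrix, maf_filter
from domgen.ld import ld_summary, pairwise_r2, r2_significance, stratified_ld
from domgen.synthetic import SimConfig, simulate_dataset

from conftest import small_sim_config


def matrix_from_columns(cols):
    X = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    n, L = X.shape
    return BandMatrix(
        [f"s{i}" for i in range(n)], [f"b{i}" for i in range(L)],
        ["P1"] * L, ["ISSR"] * L, X,
    )


class TestPairwiseR2:
    def test_identical_columns(self):
        m = matrix_from_columns([[1, 0, 1, 0], [1, 0, 1, 0]])
        res = pairwise_r2(m)
        assert res.r2[0] == pytest.approx(1.0)

    def test_complementary_columns(self):
        m = matrix_from_columns([[1, 0, 1, 0], [0, 1, 0, 1]])
        res = pairwise_r2(m)
        assert res.r2[0] == pytest.approx(1.0)

    def test_two_by_two_table_worked_example(self):
        """n11=30, n10=20, n01=20, n00=30 over n=100:
        r^2 = (0.30 - 0.25)^2 / (0.25 * 0.25) = 0.04."""
        a = [1] * 30 + [1] * 20 + [0] * 20 + [0] * 30
        b = [1] * 30 + [0] * 20 + [1] * 20 + [0] * 30
        res = pairwise_r2(matrix_from_columns([a, b]))
        assert res.r2[0] == pytest.approx(0.04)
        assert res.n_samples[0] == 100

    def test_monomorphic_column_rejected(self):
        m = matrix_from_columns([[1, 1, 1], [1, 0, 1]])
        with pytest.raises(ValueError, match="MAF filter"):
            pairwise_r2(m)

    def test_brute_force_oracle_small_instances(self):
        """For every polymorphic pair of 5-sample binary columns, the
        frequency formula equals the squared Pearson correlation by
        direct summation."""
        n = 5
        cols = [c for c in itertools.product([0, 1], repeat=n) if 0 < sum(c) < n]
        rng = np.random.default_rng(0)
        pick = rng.choice(len(cols), size=12, replace=False)
        chosen = [cols[i] for i in pick]
        for x, y in itertools.combinations(chosen, 2):
            m = matrix_from_columns([x, y])
            r2 = pairwise_r2(m).r2[0]
            xa, ya = np.array(x, float), np.array(y, float)
            sxy = np.sum((xa - xa.mean()) * (ya - ya.mean()))
            sxx = np.sum((xa - xa.mean()) ** 2)
            syy = np.sum((ya - ya.mean()) ** 2)
            assert r2 == pytest.approx(sxy**2 / (sxx * syy), abs=1e-12)

    def test_symmetric_and_bounded(self, two_pop_dataset):
        m, _, _ = two_pop_dataset
        f, _ = maf_filter(m, 0.05, two_sided=True)
        sub = f.select_loci(np.arange(30))
        res = pairwise_r2(sub)
        assert ((res.r2 >= 0) & (res.r2 <= 1)).all()
        assert res.n_pairs == 30 * 29 // 2

    def test_flip_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=40).astype(float)
        y = rng.integers(0, 2, size=40).astype(float)
        if x.var() == 0 or y.var() == 0:
            pytest.skip("degenerate draw")
        r_a = pairwise_r2(matrix_from_columns([x, y])).r2[0]
        r_b = pairwise_r2(matrix_from_columns([1 - x, y])).r2[0]
        assert r_a == pytest.approx(r_b, abs=1e-12)

    def test_inter_primer_restriction(self):
        X = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        m = BandMatrix(
            ["s0", "s1", "s2", "s3"], ["b0", "b1", "b2"],
            ["P1", "P1", "P2"], ["ISSR", "ISSR", "SCoT"], X,
        )
        res = pairwise_r2(m, inter_primer_only=True)
        pairs = {(res.band_ids[i], res.band_ids[j]) for i, j in zip(res.pair_i, res.pair_j)}
        assert pairs == {("b0", "b2"), ("b1", "b2")}


class TestSignificance:
    def test_extreme_statistic_tiny_p(self):
        x = np.tile([1.0, 0.0], 50)
        r2, p = r2_significance(x, x, method="chi2")
        assert r2 == pytest.approx(1.0)
        assert p < 1e-20

    def test_p_monotone_decreasing_in_r2(self):
        from scipy import stats

        n = 80
        r2_grid = np.linspace(0.01, 0.9, 10)
        ps = stats.chi2.sf(n * r2_grid, df=1)
        assert np.all(np.diff(ps) < 0)

    def test_permutation_deterministic(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 30).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        _, p1 = r2_significance(x, y, method="permutation", n_perm=199, seed=3)
        _, p2 = r2_significance(x, y, method="permutation", n_perm=199, seed=3)
        assert p1 == p2

    def test_type_one_error_calibrated(self):
        """Independent columns: chi-square rejection rate at alpha=0.001
        is ~0.001 over ~100k pairs."""
        rng = np.random.default_rng(101)
        n, L = 200, 460
        X = (rng.random((n, L)) < 0.5).astype(float)
        # regenerate any accidentally monomorphic column
        for j in range(L):
            while X[:, j].var() == 0:
                X[:, j] = (rng.random(n) < 0.5).astype(float)
        m = BandMatrix(
            [f"s{i}" for i in range(n)], [f"b{j}" for j in range(L)],
            ["P1"] * L, ["ISSR"] * L, X,
        )
        res = pairwise_r2(m)
        assert res.n_pairs >= 100_000
        rate = float((res.p_value < 0.001).mean())
        assert 0.0004 <= rate <= 0.0025


class TestSummaries:
    def test_all_zero_r2(self):
        x = [1, 1, 0, 0]
        y = [1, 0, 1, 0]
        res = pairwise_r2(matrix_from_columns([x, y]))
        summ = ld_summary(res)
        assert summ["n_significant"] == 0
        assert summ["mean_r2_all"] == pytest.approx(0.0)

    def test_block_copied_loci_within_block_r2_one(self):
        cfg = small_sim_config(ld_block_size=5, ld_copy_prob=1.0, seed=23)
        m, _, _ = simulate_dataset(cfg)
        f, _ = maf_filter(m, 0.05, two_sided=True)
        res = pairwise_r2(f)
        anchors = {}
        for idx, b in enumerate(f.band_ids):
            src = m.band_ids.index(b)
            anchors[idx] = src // 5
        within = np.array(
            [anchors[i] == anchors[j] for i, j in zip(res.pair_i, res.pair_j)]
        )
        assert within.any()
        np.testing.assert_allclose(res.r2[within], 1.0)
        assert res.r2[~within].mean() < 0.2

    def test_stratum_with_larger_blocks_has_higher_ld(self):
        """LD copying restricted to subpopulation 2 produces a higher
        mean r^2 in that stratum."""
        cfg = small_sim_config(
            n_samples=100, group_sizes=(50, 50), seed=29,
            ld_block_size=6, ld_copy_prob=0.9, ld_groups=(1,),
        )
        m, _, truth = simulate_dataset(cfg)
        strata = {
            "G1": [s for s, g in zip(m.samples, truth.origin) if g == 0],
            "G2": [s for s, g in zip(m.samples, truth.origin) if g == 1],
        }
        out = stratified_ld(m, strata)
        assert out["G2"]["mean_r2_all"] > out["G1"]["mean_r2_all"]

    def test_counts_bounded_by_total(self, two_pop_dataset):
        m, _, _ = two_pop_dataset
        f, _ = maf_filter(m, 0.05, two_sided=True)
        summ = ld_summary(pairwise_r2(f))
        assert summ["n_r2_and_significant"] <= summ["n_significant"] <= summ["n_pairs"]


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_r2_flip_invariance_property(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=25).astype(float)
    y = rng.integers(0, 2, size=25).astype(float)
    if x.var() == 0 or y.var() == 0:
        return
    r_a = r2_significance(x, y)[0]
    r_b = r2_significance(1 - x, 1 - y)[0]
    assert r_a == pytest.approx(r_b, abs=1e-12)
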