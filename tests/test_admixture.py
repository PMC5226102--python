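import numpy as np
import pytest

from domgen.admixture import (
    StructureFit,
    align_runs,
    assign_membership,
    evanno_delta_k,
    gibbs_admixture,
)
from domgen.band_data import maf_filter
from domgen.synthetic import simulate_dataset

from conftest import small_sim_config


@pytest.fixture(scope="module")
def filtered_two_pop():
    m, meta, truth = simulate_dataset(small_sim_config(seed=7))
    f, _ = maf_filter(m, 0.05, two_sided=True)
    return f, truth


def make_fit(K, ln_p_d, n=4):
    Q = np.full((n, K), 1.0 / K)
    P = np.full((K, 3), 0.5)
    return StructureFit(
        K=K, samples=[f"s{i}" for i in range(n)], Q=Q, P=P,
        lnl_trace=np.array([ln_p_d]), ln_p_d=ln_p_d,
    )


class TestGibbs:
    def test_k1_degenerate(self, filtered_two_pop):
        f, _ = filtered_two_pop
        fit = gibbs_admixture(f, K=1, burn_in=20, n_iter=40, thin=2, seed=0)
        np.testing.assert_allclose(fit.Q, 1.0)
        assert np.isfinite(fit.lnl_trace).all()
        assert np.isfinite(fit.ln_p_d)

    def test_invalid_k(self, filtered_two_pop):
        f, _ = filtered_two_pop
        with pytest.raises(ValueError):
            gibbs_admixture(f, K=0)

    def test_deterministic_under_seed(self, filtered_two_pop):
        f, _ = filtered_two_pop
        kw = dict(K=2, burn_in=30, n_iter=60, thin=2, seed=5)
        fit1 = gibbs_admixture(f, **kw)
        fit2 = gibbs_admixture(f, **kw)
        np.testing.assert_array_equal(fit1.Q, fit2.Q)
        np.testing.assert_array_equal(fit1.P, fit2.P)
        np.testing.assert_array_equal(fit1.lnl_trace, fit2.lnl_trace)

    def test_q_rows_sum_to_one(self, filtered_two_pop):
        f, _ = filtered_two_pop
        fit = gibbs_admixture(f, K=3, burn_in=30, n_iter=60, thin=2, seed=1)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert ((fit.P > 0) & (fit.P < 1)).all()

    def test_two_population_recovery(self, filtered_two_pop):
        """fst = 0.3, no admixture: >= 95 % of samples assigned to their
        true cluster at threshold 0.75."""
        f, truth = filtered_two_pop
        fit = gibbs_admixture(f, K=2, burn_in=200, n_iter=400, thin=2, seed=2)
        assign = assign_membership(fit, threshold=0.75)
        label = assign["max_membership_group"].to_numpy()
        # align labels: majority vote of subpopulation 0
        maj0 = "G1" if (label[truth.origin == 0] == "G1").mean() >= 0.5 else "G2"
        correct = (
            (label[truth.origin == 0] == maj0).sum()
            + (label[truth.origin == 1] != maj0).sum()
        )
        assigned = (assign["assignment"] != "admixed").to_numpy()
        assert correct / len(label) >= 0.95
        assert (assigned & (assign["max_membership"] >= 0.75)).sum() == assigned.sum()

    def test_recovered_frequencies_close_to_truth(self):
        """No-admixture data at n=200: posterior mean P within 0.05 MAE
        of the true subpopulation band frequencies."""
        cfg = small_sim_config(
            n_samples=200, group_sizes=(100, 100), seed=19,
            n_primers={"ISSR": 8}, bands_per_primer={"ISSR": 14.0},
        )
        m, _, truth = simulate_dataset(cfg)
        f, removed = maf_filter(m, 0.05, two_sided=True)
        keep = [i for i, b in enumerate(m.band_ids) if b not in set(removed)]
        fit = gibbs_admixture(f, K=2, burn_in=200, n_iter=400, thin=2, seed=4)
        true_band_freq = np.vstack(
            [
                (truth.genotypes[truth.origin == k][:, keep] >= 1).mean(axis=0)
                for k in range(2)
            ]
        )
        # label alignment: choose the permutation with smaller error
        mae_id = np.abs(fit.P - true_band_freq).mean()
        mae_sw = np.abs(fit.P[::-1] - true_band_freq).mean()
        assert min(mae_id, mae_sw) < 0.05

    def test_trace_reaches_stationary_band(self, filtered_two_pop):
        """No monotone drift: first and second half means of the
        retained log-likelihood trace agree within 2 posterior sds."""
        f, _ = filtered_two_pop
        fit = gibbs_admixture(f, K=2, burn_in=200, n_iter=600, thin=2, seed=6)
        trace = fit.lnl_trace
        half = len(trace) // 2
        sd = trace.std()
        assert abs(trace[:half].mean() - trace[half:].mean()) < 2 * max(sd, 1e-9)


class TestEvanno:
    def test_hand_arithmetic_on_supplied_table(self):
        """Means (-1000, -800, -790, -788) with sd 1 at each K:
        ΔK(2) = 190, ΔK(3) = 8, argmax K = 2."""
        d = 2**-0.5  # two replicates at mean +/- d have sample sd exactly 1
        runs = {
            K: [make_fit(K, mean - d), make_fit(K, mean + d)]
            for K, mean in zip((1, 2, 3, 4), (-1000.0, -800.0, -790.0, -788.0))
        }
        table = evanno_delta_k(runs).set_index("K")
        assert table.loc[2, "delta_k"] == pytest.approx(190.0)
        assert table.loc[3, "delta_k"] == pytest.approx(8.0)

    def test_argmax_reported(self):
        d = 2**-0.5
        runs = {
            K: [make_fit(K, mean - d), make_fit(K, mean + d)]
            for K, mean in zip((1, 2, 3, 4), (-1000.0, -800.0, -790.0, -788.0))
        }
        table = evanno_delta_k(runs)
        assert table.attrs["best_k"] == 2

    def test_linear_lnpd_gives_zero_delta_k(self):
        d = 2**-0.5
        runs = {
            K: [make_fit(K, -1000.0 + 10.0 * K - d), make_fit(K, -1000.0 + 10.0 * K + d)]
            for K in (1, 2, 3, 4)
        }
        table = evanno_delta_k(runs).set_index("K")
        assert table.loc[2, "delta_k"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[3, "delta_k"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_raises(self):
        runs = {K: [make_fit(K, -100.0), make_fit(K, -100.0)] for K in (1, 2, 3)}
        with pytest.raises(ValueError, match="replicates"):
            evanno_delta_k(runs)

    def test_non_contiguous_range_rejected(self):
        runs = {K: [make_fit(K, -100.0), make_fit(K, -99.0)] for K in (1, 3, 5)}
        with pytest.raises(ValueError, match="contiguous"):
            evanno_delta_k(runs)


class TestAssignment:
    def _fit(self, rows):
        Q = np.asarray(rows, dtype=float)
        return StructureFit(
            K=Q.shape[1], samples=[f"s{i}" for i in range(len(Q))],
            Q=Q, P=np.full((Q.shape[1], 2), 0.5), lnl_trace=np.zeros(1),
        )

    def test_threshold_rule_including_boundary(self):
        fit = self._fit([[0.8, 0.2], [0.6, 0.4], [0.75, 0.25]])
        out = assign_membership(fit, threshold=0.75)
        assert list(out["assignment"]) == ["G1", "admixed", "G1"]
        assert list(out["max_membership_group"]) == ["G1", "G1", "G1"]

    def test_invalid_threshold(self):
        fit = self._fit([[0.8, 0.2]])
        with pytest.raises(ValueError):
            assign_membership(fit, threshold=0.4)


class TestAlignRuns:
    def _fit_from_q(self, Q):
        Q = np.asarray(Q, dtype=float)
        return StructureFit(
            K=Q.shape[1], samples=[f"s{i}" for i in range(len(Q))],
            Q=Q, P=np.tile(np.arange(Q.shape[1], dtype=float)[:, None], (1, 3)),
            lnl_trace=np.zeros(1),
        )

    def test_label_swap_resolved(self):
        Q = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9]])
        a = self._fit_from_q(Q)
        b = self._fit_from_q(Q[:, ::-1])
        aligned = align_runs([a, b])
        np.testing.assert_allclose(aligned[1].Q, Q)
        np.testing.assert_allclose(aligned[1].P, b.P[[1, 0]])

    def test_single_run_unchanged(self):
        a = self._fit_from_q([[0.7, 0.3]])
        (out,) = align_runs([a])
        assert out is a
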