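"""Contact calling: ICE fixed points, ZiNB fit/p-values, BH selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromosteer import contacts as cc
from chromosteer.errors import DegenerateDataError, FormatError
from chromosteer.hic import ContactMatrix
from chromosteer.synthetic import sample_zinb


def _matrix_from_dense(dense):
    m = ContactMatrix.from_dense("chrT", 100_000, np.asarray(dense, float))
    return m


class TestICE:
    def test_balanced_matrix_is_fixed_point(self):
        # doubly-balanced: all row sums equal
        dense = np.array([[0, 2, 1], [2, 0, 1], [1, 1, 1]], float)
        corrected, biases, mask = cc.ice_normalize(_matrix_from_dense(dense))
        assert mask.all()
        assert np.allclose(biases, biases[0], atol=1e-6)

    def test_unequal_marginals_equalized(self):
        dense = np.array([[0, 4, 2], [4, 0, 1], [2, 1, 0]], float)
        corrected, biases, mask = cc.ice_normalize(_matrix_from_dense(dense))
        s = corrected.to_dense().sum(axis=1)
        assert np.abs(s - s.mean()).max() / s.mean() < 1e-6

    def test_marginal_cv_below_tolerance_random_sparse(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            dense = rng.poisson(1.2, (40, 40)).astype(float)
            dense = np.triu(dense, 1)
            dense = dense + dense.T
            m = _matrix_from_dense(dense)
            corrected, biases, mask = cc.ice_normalize(m)
            s = corrected.to_dense()[np.ix_(mask, mask)].sum(axis=1)
            assert s.std() / s.mean() < 1e-4

    def test_biases_multiply_back_to_raw(self):
        rng = np.random.default_rng(6)
        dense = rng.poisson(3.0, (20, 20)).astype(float)
        dense = np.triu(dense, 1) + np.triu(dense, 1).T
        m = _matrix_from_dense(dense)
        corrected, biases, mask = cc.ice_normalize(m)
        recon = np.outer(biases, biases) * corrected.to_dense()
        assert np.allclose(recon[np.ix_(mask, mask)],
                           dense[np.ix_(mask, mask)], rtol=1e-6)

    def test_zero_marginal_bin_masked(self):
        dense = np.array([[0, 3, 0], [3, 1, 0], [0, 0, 0]], float)
        corrected, biases, mask = cc.ice_normalize(_matrix_from_dense(dense))
        assert mask.tolist() == [True, True, False]
        assert np.isnan(biases[2])

    def test_all_zero_matrix_rejected(self):
        m = ContactMatrix("chrT", 100_000, 4, [], [], [])
        with pytest.raises(DegenerateDataError):
            cc.ice_normalize(m)


class TestCollectByDistance:
    def test_pair_counts_per_delta(self):
        dense = np.zeros((5, 5))
        obs = cc.collect_by_distance(_dense5(dense))
        assert len(obs[4]) == 1
        assert len(obs[1]) == 4

    def test_large_matrix_counts(self):
        m = ContactMatrix("chrT", 100_000, 100, [0], [1], [3.0])
        obs = cc.collect_by_distance(m, mask=np.ones(100, bool))
        assert len(obs[1]) == 99

    def test_sums_match_bruteforce(self):
        rng = np.random.default_rng(3)
        dense = rng.poisson(2, (12, 12)).astype(float)
        dense = np.triu(dense, 1) + np.triu(dense, 1).T
        obs = cc.collect_by_distance(_dense12(dense))
        for d in range(1, 12):
            brute = [dense[i, i + d] for i in range(12 - d)]
            assert np.allclose(sorted(obs[d]), sorted(brute))

    def test_masked_bins_excluded(self):
        dense = np.ones((6, 6)) - np.eye(6)
        mask = np.array([True, False, True, True, True, True])
        m = ContactMatrix.from_dense("chrT", 100_000, dense)
        obs = cc.collect_by_distance(m, mask=mask)
        assert len(obs[1]) == 3  # pairs (2,3),(3,4),(4,5)


def _dense5(dense):
    m = ContactMatrix.from_dense("chrT", 100_000, dense)
    m.n_bins = 5
    return m


def _dense12(dense):
    m = ContactMatrix.from_dense("chrT", 100_000, dense)
    m.n_bins = 12
    return m


class TestZiNBFit:
    def test_all_zero_vector_degenerate(self):
        row = cc.fit_zinb(np.zeros(100, dtype=int))
        assert row.status == "degenerate"
        with pytest.raises(DegenerateDataError):
            cc.zinb_pvalue(3, row)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        pi, theta, mu, n = 0.3, 2.0, 5.0, 10_000
        x = sample_zinb(rng, pi, theta, mu, size=n)
        row = cc.fit_zinb(x)
        # crude SEs for ZiNB MLE at this n; 3-sigma bands
        assert abs(row.pi - pi) < 3 * 0.02
        assert abs(row.theta - theta) < 3 * 0.15
        assert abs(row.mu - mu) < 3 * 0.1

    def test_nested_nb_recovery(self):
        rng = np.random.default_rng(12)
        theta, mu = 5.0, 10.0
        x = rng.negative_binomial(theta, theta / (theta + mu), size=10_000)
        row = cc.fit_zinb(x)
        assert row.pi < 0.05
        assert abs(row.theta - theta) / theta < 0.1
        assert abs(row.mu - mu) / mu < 0.1

    def test_loglik_at_optimum_beats_moment_init(self):
        rng = np.random.default_rng(13)
        x = sample_zinb(rng, 0.4, 1.5, 8.0, size=2000)
        row = cc.fit_zinb(x)
        # moment-style reference point
        ll_ref = cc.zinb_loglik(x, 0.4, 1.5, 8.0)
        assert row.loglik >= ll_ref - 1e-6

    def test_order_invariance(self):
        rng = np.random.default_rng(14)
        x = sample_zinb(rng, 0.2, 2.0, 6.0, size=500)
        a = cc.fit_zinb(x)
        b = cc.fit_zinb(x[::-1])
        assert a.pi == b.pi and a.theta == b.theta and a.mu == b.mu

    def test_agrees_with_statsmodels_oracle(self):
        # independent implementation check: statsmodels ZINB MLE
        from statsmodels.discrete.count_model import (
            ZeroInflatedNegativeBinomialP)
        rng = np.random.default_rng(15)
        x = sample_zinb(rng, 0.35, 2.0, 6.0, size=4000)
        row = cc.fit_zinb(x)
        exog = np.ones((len(x), 1))
        sm = ZeroInflatedNegativeBinomialP(x, exog, exog_infl=exog, p=2).fit(
            disp=0, maxiter=200)
        ll_sm = float(sm.llf)
        assert row.loglik >= ll_sm - 0.5  # our optimum is no worse

    def test_censored_fit_resists_contamination(self):
        rng = np.random.default_rng(16)
        x = sample_zinb(rng, 0.4, 2.0, 10.0, size=200)
        x_cont = x.copy()
        x_cont[:8] = rng.negative_binomial(2.0, 2.0 / (2.0 + 500.0), 8)
        plain = cc.fit_zinb(x_cont)
        robust = cc.fit_zinb_robust(x_cont)
        clean = cc.fit_zinb(x)
        # robust dispersion stays near the clean fit; plain collapses
        assert abs(np.log(robust.theta / clean.theta)) < abs(
            np.log(plain.theta / clean.theta))


class TestZiNBPvalue:
    def _params(self, pi, theta, mu):
        return cc.ZiNBParams(1, 1, pi, theta, mu, 100, 50, 0.0, "ok")

    def test_zero_gives_one(self):
        assert cc.zinb_pvalue(0, self._params(0.5, 1.0, 2.0)) == 1.0

    def test_matches_tail_sum_oracle(self):
        p = self._params(0.5, 1.0, 2.0)
        # brute-force pmf summation: P(X >= 1) = (1-pi)(1 - NB(0))
        nb0 = (1.0 / (1.0 + 2.0)) ** 1.0
        expect = 0.5 * (1 - nb0)
        assert abs(cc.zinb_pvalue(1, p) - expect) < 1e-14

    @pytest.mark.parametrize("pi,theta,mu", [
        (0.0, 1.0, 2.0), (0.3, 0.5, 10.0), (0.8, 5.0, 1.0), (0.5, 2.0, 50.0),
    ])
    def test_tail_sum_grid(self, pi, theta, mu):
        params = self._params(pi, theta, mu)
        p_nb = theta / (theta + mu)
        ks = np.arange(0, 1001)
        pmf = np.where(ks == 0, pi + (1 - pi) * stats.nbinom.pmf(0, theta, p_nb),
                       (1 - pi) * stats.nbinom.pmf(ks, theta, p_nb))
        for x in (0, 1, 5, 17, 100, 500, 1000):
            brute = pmf[x:].sum() + (1 - pi) * stats.nbinom.sf(1000, theta, p_nb)
            assert abs(cc.zinb_pvalue(x, params) - brute) < 1e-12

    def test_monotone_nonincreasing(self):
        params = self._params(0.4, 1.3, 7.0)
        pv = cc.zinb_pvalue(np.arange(51), params)
        assert np.all(np.diff(pv) <= 1e-15)


class TestBH:
    def test_empty_input_empty_selection(self):
        out = cc.bh_select(pd.DataFrame(columns=[
            "chrom", "bin_i", "bin_j", "delta", "delta_group", "p_value"]))
        assert len(out) == 0

    def test_step_up_rule_by_hand(self):
        pv = pd.DataFrame({
            "chrom": "c", "bin_i": range(4), "bin_j": range(1, 5),
            "delta": 1, "delta_group": "1-1",
            "p_value": [0.001, 0.004, 0.03, 0.5]})
        out = cc.bh_select(pv, alpha=0.01)
        # step-up: p_(2)=0.004 <= 0.01*2/4 = 0.005 -> two smallest selected
        assert sorted(out.p_value) == [0.001, 0.004]

    def test_all_ones_nothing_selected(self):
        pv = pd.DataFrame({
            "chrom": "c", "bin_i": range(10), "bin_j": range(1, 11),
            "delta": 1, "delta_group": "1-1", "p_value": [1.0] * 10})
        assert len(cc.bh_select(pv, alpha=0.01)) == 0

    def test_groups_corrected_separately(self):
        # identical p in a small group is selected, in a big group is not
        rows = [{"chrom": "c", "bin_i": i, "bin_j": i + 1, "delta": 1,
                 "delta_group": "g1", "p_value": 0.004} for i in range(2)]
        rows += [{"chrom": "c", "bin_i": i, "bin_j": i + 5, "delta": 5,
                  "delta_group": "g2",
                  "p_value": 0.004 if i == 0 else 0.9} for i in range(20)]
        out = cc.bh_select(pd.DataFrame(rows), alpha=0.01)
        assert set(out.delta_group) == {"g1"}


class TestPipeline:
    def test_planted_contacts_recovered_null_controlled(self, small_spec):
        from chromosteer import synthetic
        truth = synthetic.gen_truth(small_spec, 21, n_planted_per_chrom=15)
        m = synthetic.gen_hic_matrix(small_spec, truth, 31, "chr1")
        res = cc.call_significant_contacts(m)
        tp = set(map(tuple,
                     truth.pairs_for("chr1")[["bin_i", "bin_j"]].values))
        called = set(map(tuple, res.contacts[["bin_i", "bin_j"]].values))
        assert len(called & tp) >= 1          # some power
        assert len(called - tp) <= max(2, len(called) // 5)  # mostly true
        assert (res.contacts.q_value <= res.alpha).all()

    def test_rows_are_cis_and_sorted(self, small_spec):
        from chromosteer import synthetic
        truth = synthetic.gen_truth(small_spec, 22, n_planted_per_chrom=10)
        m = synthetic.gen_hic_matrix(small_spec, truth, 32, "chr1")
        res = cc.call_significant_contacts(m)
        df = res.contacts
        assert (df.chrom == "chr1").all()
        assert (df.bin_i < df.bin_j).all()
        assert df[["bin_i", "bin_j"]].apply(tuple, axis=1).is_monotonic_increasing
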