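"""Forward likelihood, profiles, LRT and the pathological-trajectory filter."""

import numpy as np
import pytest
from scipy import stats

from wfhmm import (
    LikelihoodProfile,
    PopulationParams,
    TimeSeries,
    default_nes_grid,
    detection_outcome,
    emission,
    forward_loglik,
    is_one_step_fixation,
    likelihood_profile,
    one_step_matrix,
    profile_batch,
)


class TestEmission:
    @pytest.mark.parametrize("x,n,y,expected", [
        (0.0, 30, 0, 1.0), (1.0, 30, 30, 1.0), (0.5, 2, 1, 0.5), (0.0, 30, 3, 0.0),
    ])
    def test_values(self, x, n, y, expected):
        assert emission(x, n, y) == pytest.approx(expected, abs=1e-15)

    def test_normalises_over_counts(self):
        total = sum(emission(0.37, 12, y) for y in range(13))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_count_exceeding_size_raises(self):
        with pytest.raises(ValueError):
            emission(0.5, 10, 11)


class TestForward:
    def test_tiny_exhaustive_oracle(self):
        # brute-force sum over all hidden paths of a 3-date, Ne=10 instance
        Ne, p = 10, PopulationParams(10, 0.25)
        ts = TimeSeries("t", [0, 3, 7], [20, 20, 20], [8, 11, 15])
        ll = forward_loglik(ts, "WF", p)
        lat = np.arange(Ne + 1) / Ne
        P = one_step_matrix(p).probs
        Q1, Q2 = np.linalg.matrix_power(P, 3), np.linalg.matrix_power(P, 4)
        prior = np.full(Ne + 1, 1 / Ne)
        prior[0] = prior[-1] = 0.5 / Ne
        tot = 0.0
        for i in range(Ne + 1):
            for j in range(Ne + 1):
                for k in range(Ne + 1):
                    tot += (prior[i] * stats.binom.pmf(8, 20, lat[i]) * Q1[i, j]
                            * stats.binom.pmf(11, 20, lat[j]) * Q2[j, k]
                            * stats.binom.pmf(15, 20, lat[k]))
        assert ll == pytest.approx(np.log(tot), abs=1e-10)

    def test_single_date_beta_binomial(self, neutral100):
        # integral of the binomial pmf against the uniform prior is 1/(n+1)
        ts = TimeSeries("t", [0], [30], [15])
        ll = forward_loglik(ts, "BwS", neutral100)
        assert np.exp(ll) == pytest.approx(1 / 31, abs=1e-12)

    @pytest.mark.parametrize("model", ["WF", "BwS", "NG", "Ga", "Be"])
    def test_likelihood_monotone_under_data_extension(self, model, neutral100):
        dates = [0, 5, 10, 15]
        sizes = [30, 30, 30, 30]
        counts = [12, 18, 9, 25]
        lls = [forward_loglik(TimeSeries("t", dates[:k], sizes[:k], counts[:k]),
                              model, neutral100) for k in range(1, 5)]
        assert np.all(np.diff(lls) < 0)


class TestProfile:
    def test_default_nes_grid(self):
        g = default_nes_grid()
        assert len(g) == 600
        assert g[0] == -100.0 and g[-1] == 300.0
        assert np.any(g == 0.0)

    def test_grid_without_zero_rejected(self):
        ts = TimeSeries("t", [0, 5], [30, 30], [10, 20])
        with pytest.raises(ValueError):
            likelihood_profile(ts, "BwS", 100, nes_grid=np.array([-5.0, 5.0]))

    def test_lambda_nonnegative_and_pvalue(self):
        ts = TimeSeries("t", [0, 5, 10], [30, 30, 30], [14, 16, 15])
        prof = likelihood_profile(ts, "BwS", 100, nes_grid=default_nes_grid(121))
        assert prof.lam >= 0.0
        assert prof.pvalue == pytest.approx(stats.chi2.sf(prof.lam, 1))
        assert prof.loglik_mle >= prof.loglik0

    def test_rising_trajectory_gives_positive_s(self):
        dates = np.arange(0, 50, 5)
        freq = np.linspace(0.1, 0.9, 10)
        counts = np.round(freq * 30).astype(int)
        ts = TimeSeries("t", dates, np.full(10, 30), counts)
        prof = likelihood_profile(ts, "BwS", 100)
        assert prof.s_hat > 0
        assert prof.pvalue < 0.05

    def test_batch_matches_single(self):
        grid = default_nes_grid(61)
        ts1 = TimeSeries("a", [0, 5, 10], [30, 30, 30], [10, 14, 20])
        ts2 = TimeSeries("b", [0, 7], [20, 20], [5, 5])
        batch = profile_batch([ts1, ts2], "BwS", 100, nes_grid=grid)
        for ts, got in zip([ts1, ts2], batch):
            single = likelihood_profile(ts, "BwS", 100, nes_grid=grid)
            np.testing.assert_allclose(got.loglik, single.loglik, atol=1e-12)
            assert got.s_hat == single.s_hat


class TestFilters:
    @pytest.mark.parametrize("counts,expected", [
        ((12, 0, 0, 0), True),     # lost after the first date
        ((12, 30, 30, 30), True),  # fixed after the first date
        ((12, 0, 3, 0), False),    # revisits segregation
        ((0, 0, 0, 0), True),      # monomorphic is also constant after date 1
    ])
    def test_one_step_fixation(self, counts, expected):
        ts = TimeSeries("t", [0, 5, 10, 15], [30] * 4, counts)
        assert is_one_step_fixation(ts) is expected

    def test_detection_outcome(self):
        def prof(s_hat, lam):
            return LikelihoodProfile("t", np.array([0.0]), np.array([0.0]),
                                     s_hat, 0.0, lam / 2, lam,
                                     float(stats.chi2.sf(lam, 1)))
        assert detection_outcome(prof(-0.2, 50.0), 0.05) == "wrong_sign"
        assert detection_outcome(prof(0.08, 6.6), 0.05) == "detected"
        assert detection_outcome(prof(0.3, 0.0), 0.05) == "not_detected"
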