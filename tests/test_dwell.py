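"""Empirical survival estimation and exponential-mixture fitting of bond
lifetimes."""

import warnings

import numpy as np
import pytest

from bondkin import (
    LifetimeDataset,
    empirical_survival,
    fit_apparent,
    ks_gof,
    select_n_states,
)


def mixture_sample(rng, k, w, n):
    comp = rng.choice(len(k), size=n, p=w)
    return rng.exponential(1.0 / np.asarray(k)[comp])


@pytest.fixture(scope="module")
def three_component_data():
    rng = np.random.default_rng(42)
    t = mixture_sample(rng, [10.0, 1.0, 0.1], [0.6, 0.3, 0.1], 5000)
    return LifetimeDataset.from_arrays(5.0, t)


class TestLifetimeDataset:
    def test_rejects_nonpositive_lifetimes(self):
        with pytest.raises(ValueError, match="non-positive"):
            LifetimeDataset.from_arrays(5.0, [1.0, 0.0, 2.0])

    def test_rejects_unknown_condition(self):
        with pytest.raises(ValueError, match="condition"):
            LifetimeDataset.from_arrays(5.0, [1.0], condition="Zn")

    def test_single_force_guard(self):
        d = LifetimeDataset.from_arrays([5.0, 10.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="force bins"):
            d.single_force()
        assert d.at_force(5.0).single_force() == 5.0


class TestEmpiricalSurvival:
    def test_complement_of_ecdf_without_censoring(self):
        d = LifetimeDataset.from_arrays(5.0, [1.0, 2.0, 3.0])
        c = empirical_survival(d)
        assert np.allclose(c.times, [1.0, 2.0, 3.0])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(c.at_risk, [3, 2, 1])

    def test_all_censored_rejected(self):
        d = LifetimeDataset.from_arrays(5.0, [1.0, 2.0],
                                        censored=[True, True])
        with pytest.raises(ValueError, match="censored"):
            empirical_survival(d)

    def test_empty_rejected(self):
        d = LifetimeDataset.from_arrays(5.0, np.ones(0))
        with pytest.raises(ValueError, match="empty"):
            empirical_survival(d)

    def test_ks_band_against_true_exponential(self):
        rng = np.random.default_rng(7)
        n = 10_000
        d = LifetimeDataset.from_arrays(5.0, rng.exponential(0.5, size=n))
        c = empirical_survival(d)
        true_s = np.exp(-2.0 * c.times)
        sup = np.abs(c.survival - true_s).max()
        assert sup < 1.628 / np.sqrt(n)  # 99% Kolmogorov band

    def test_censoring_keeps_curve_above_naive_ecdf(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(1.0, size=500)
        cens = t > 1.0
        d = LifetimeDataset.from_arrays(5.0, np.minimum(t, 1.0), cens)
        c = empirical_survival(d)
        # product-limit estimate with censoring ends above zero
        assert c.survival[-1] > 0


class TestFitApparent:
    def test_single_exponential_consistency(self):
        rng = np.random.default_rng(123)
        n = 5000
        d = LifetimeDataset.from_arrays(5.0, rng.exponential(1.0, size=n))
        res = fit_apparent(d, 1, seed=0)
        se = 1.0 / np.sqrt(n)
        assert abs(res.params.k1 - 1.0) < 3 * se
        assert res.params.w1 == 1.0

    def test_three_component_recovery(self, three_component_data):
        res = fit_apparent(three_component_data, 3, seed=0)
        k_true = np.array([10.0, 1.0, 0.1])
        w_true = np.array([0.6, 0.3, 0.1])
        assert res.n_components == 3
        assert np.all(np.abs(res.params.rates - k_true) / k_true < 0.15)
        assert np.all(np.abs(res.params.weights - w_true) < 0.05)

    def test_minimum_events_guard(self):
        d = LifetimeDataset.from_arrays(5.0, [0.5, 1.0, 1.5, 2.0, 2.5])
        with pytest.raises(ValueError, match="rupture events"):
            fit_apparent(d, 3)

    def test_multi_force_bin_rejected(self, three_component_data):
        other = three_component_data.table.copy()
        other.loc[other.index[:10], "force_pN"] = 9.0
        with pytest.raises(ValueError, match="force bins"):
            fit_apparent(LifetimeDataset(other), 3)

    def test_censoring_aware_likelihood(self):
        # heavy right-censoring at t=1: a censoring-blind fit would
        # overestimate the rate substantially
        rng = np.random.default_rng(5)
        n = 4000
        t = rng.exponential(1.0, size=n)
        cens = t > 1.0
        d = LifetimeDataset.from_arrays(5.0, np.minimum(t, 1.0), cens)
        res = fit_apparent(d, 1, seed=0)
        n_events = (~cens).sum()
        se = 1.0 / np.sqrt(n_events)
        assert abs(res.params.k1 - 1.0) < 3 * se

    def test_likelihood_never_decreases_with_components(
            self, three_component_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lls = [fit_apparent(three_component_data, n, seed=0).log_likelihood
                   for n in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_label_switching_immunity(self, three_component_data):
        a = fit_apparent(three_component_data, 3, seed=1)
        b = fit_apparent(three_component_data, 3, seed=2)
        assert np.allclose(a.params.rates, b.params.rates, rtol=1e-2)
        assert np.allclose(a.params.weights, b.params.weights, atol=1e-2)

    def test_overfit_request_reduces_with_warning(self):
        rng = np.random.default_rng(9)
        d = LifetimeDataset.from_arrays(
            5.0, rng.exponential(1.0, size=2000))
        with pytest.warns(UserWarning):
            res = fit_apparent(d, 3, seed=0)
        assert res.n_components < 3

    def test_log_survival_least_squares_mode(self, three_component_data):
        res = fit_apparent(three_component_data, 3, seed=0,
                           method="ls-logsurv")
        k_true = np.array([10.0, 1.0, 0.1])
        assert np.all(np.abs(res.params.rates - k_true) / k_true < 0.3)


class TestSelectNStates:
    def test_pure_exponential_selects_one(self):
        rng = np.random.default_rng(21)
        d = LifetimeDataset.from_arrays(5.0, rng.exponential(1.0, size=3000))
        assert select_n_states(d, seed=0) == 1

    def test_well_separated_mixture_selects_three(self, three_component_data):
        assert select_n_states(three_component_data, seed=0) == 3

    def test_identical_rate_mixture_selects_one(self):
        rng = np.random.default_rng(22)
        # "mixture" whose components share one rate is a single exponential
        t = mixture_sample(rng, [2.0, 2.0], [0.5, 0.5], 3000)
        d = LifetimeDataset.from_arrays(5.0, t)
        assert select_n_states(d, seed=0) == 1


class TestGoodnessOfFit:
    def test_correct_model_accepted(self, three_component_data):
        res = fit_apparent(three_component_data, 3, seed=0)
        _, _, reject = ks_gof(three_component_data, res.params)
        assert not reject

    def test_four_scale_data_flagged(self):
        rng = np.random.default_rng(33)
        t = mixture_sample(rng, [100.0, 5.0, 0.3, 0.01],
                           [0.25, 0.25, 0.25, 0.25], 5000)
        d = LifetimeDataset.from_arrays(5.0, t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_apparent(d, 3, seed=0)
        _, _, reject = ks_gof(d, res.params)
        assert reject
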