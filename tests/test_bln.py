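"""The binomial logit-normal mixture: pmf correctness and per-sample MLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import binom

from _oracles import bln_log_pmf_quad, mixture_log_pmf_quad
from aseqc.bln import (
    BLNMixture,
    FitConfig,
    bln_log_pmf,
    filter_genes,
    fit_sample,
    mixture_log_pmf,
    negative_log_likelihood,
)
from aseqc.exceptions import InsufficientDataError, ValidationError
from conftest import make_gene_records


class TestFilterGenes:
    def test_bounds_are_inclusive(self):
        rec = make_gene_records([1, 2, 50, 2500, 2501], [4, 5, 100, 5000, 5001])
        kept = filter_genes(rec)
        assert kept.total_count.tolist() == [5, 100, 5000]

    def test_in_range_is_identity_and_empty_ok(self):
        rec = make_gene_records([3, 4], [10, 20])
        pd.testing.assert_frame_equal(filter_genes(rec), rec)
        assert len(filter_genes(rec.iloc[:0])) == 0


class TestBLNLogPmf:
    def test_sigma_to_zero_limit_is_binomial(self):
        # Binomial(6, 1/2) at r=3 is 20/64
        assert bln_log_pmf(3, 6, 0.0, 1e-4) == pytest.approx(np.log(20 / 64), abs=1e-6)

    @given(
        t=st.integers(1, 300),
        frac=st.floats(0, 1),
        mu=st.floats(-3, 3),
        sigma=st.floats(0.01, 3),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reflection_symmetry(self, t, frac, mu, sigma):
        r = int(round(frac * t))
        assert bln_log_pmf(r, t, mu, sigma) == pytest.approx(
            bln_log_pmf(t - r, t, -mu, sigma), abs=1e-9
        )

    @pytest.mark.parametrize("t", [1, 5, 50, 500])
    def test_normalizes_over_support(self, t):
        r = np.arange(t + 1)
        total = np.exp(bln_log_pmf(r, np.full(t + 1, t), 0.7, 0.8)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_adaptive_quadrature_oracle(self):
        for r, t, mu, sigma in [(10, 20, 0.5, 0.8), (0, 100, -1.0, 0.3), (4999, 5000, 0.1, 2.5)]:
            assert bln_log_pmf(r, t, mu, sigma) == pytest.approx(
                bln_log_pmf_quad(r, t, mu, sigma), abs=1e-6
            )

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            bln_log_pmf(5, 4, 0.0, 0.5)
        with pytest.raises(ValidationError):
            bln_log_pmf(0, 0, 0.0, 0.5)
        with pytest.raises(ValidationError):
            bln_log_pmf(1, 2, 0.0, -1.0)

    def test_dispersion_of_ratio_nondecreasing_in_sigma(self):
        t = 200
        r = np.arange(t + 1)
        prev = -1.0
        for sigma in [0.05, 0.2, 0.5, 1.0, 2.0]:
            pmf = np.exp(bln_log_pmf(r, np.full(t + 1, t), 0.0, sigma))
            var = float(np.sum(pmf * (r / t - np.sum(pmf * r / t)) ** 2))
            assert var >= prev
            prev = var


class TestMixtureLogPmf:
    def test_epsilon_zero_collapses_to_bln(self):
        assert mixture_log_pmf(7, 30, 0.2, 0.4, epsilon=0.0) == bln_log_pmf(7, 30, 0.2, 0.4)

    def test_epsilon_one_is_discrete_uniform(self):
        for r in (0, 3, 9):
            assert mixture_log_pmf(r, 9, 0.0, 0.5, epsilon=1.0) == pytest.approx(
                np.log(1 / 10), abs=1e-12
            )

    def test_never_neg_inf_with_positive_epsilon(self):
        lp = mixture_log_pmf(5000, 5000, -4.0, 0.01, epsilon=1e-3)
        assert np.isfinite(lp) and lp >= np.log(1e-3 / 5001) - 1e-9

    def test_default_epsilon_from_config(self):
        assert FitConfig().epsilon == 1e-3


class TestNegativeLogLikelihood:
    def test_single_record_and_additivity(self, quick_config):
        rec = make_gene_records([3, 10, 40], [10, 25, 80])
        single = negative_log_likelihood(rec.iloc[:1], 0.1, 0.4, quick_config)
        assert single == pytest.approx(
            -mixture_log_pmf(3, 10, 0.1, 0.4, epsilon=quick_config.epsilon), abs=1e-12
        )
        whole = negative_log_likelihood(rec, 0.1, 0.4, quick_config)
        parts = sum(
            negative_log_likelihood(rec.iloc[i : i + 1], 0.1, 0.4, quick_config)
            for i in range(3)
        )
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_matches_per_record_oracle(self, quick_config):
        rng = np.random.default_rng(17)
        t = rng.integers(5, 400, size=20)
        r = rng.binomial(t, expit(rng.normal(0, 0.5, size=20)))
        rec = make_gene_records(r, t)
        got = negative_log_likelihood(rec, 0.0, 0.5, quick_config)
        want = -sum(
            mixture_log_pmf_quad(int(ri), int(ti), 0.0, 0.5, quick_config.epsilon)
            for ri, ti in zip(r, t)
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_empty_records_rejected(self, quick_config):
        with pytest.raises(ValidationError):
            negative_log_likelihood(make_gene_records([], []), 0.0, 0.5, quick_config)


class TestFitSample:
    def test_recovers_generating_parameters(self):
        from aseqc.simulate import SimulationConfig, simulate_sample

        rec = simulate_sample(
            SimulationConfig(n_genes=5000, mu=0.1, sigma=0.3, seed=42), "S1"
        )
        fit = fit_sample(rec)
        assert fit.converged
        assert fit.mu_hat == pytest.approx(0.1, abs=0.03)
        assert fit.sigma_hat == pytest.approx(0.3, abs=0.03)

    def test_zero_dispersion_data_hits_lower_bound(self, quick_config):
        t = np.full(100, 60)
        fit = fit_sample(make_gene_records(t // 2, t), quick_config)
        assert abs(fit.mu_hat) < 0.05
        assert fit.sigma_hat <= quick_config.sigma_bounds[0] * 1.5

    def test_too_few_genes_raises_with_sample_name(self):
        rec = make_gene_records([3, 4, 5], [10, 10, 10], sample_id="TINY")
        with pytest.raises(InsufficientDataError, match="TINY"):
            fit_sample(rec, FitConfig(min_genes=50))

    def test_duplicate_gene_ids_rejected(self, quick_config):
        rec = make_gene_records(np.full(30, 5), np.full(30, 10))
        rec.loc[1, "gene_id"] = rec.loc[0, "gene_id"]
        with pytest.raises(ValidationError, match="duplicate gene id"):
            fit_sample(rec, quick_config)

    def test_deterministic_given_records_and_config(self, small_sample, quick_config):
        a = fit_sample(small_sample, quick_config)
        b = fit_sample(small_sample, quick_config)
        assert a == b


class TestBLNMixtureEstimator:
    def test_sklearn_contract(self, small_sample):
        from sklearn.base import clone

        est = BLNMixture(min_genes=20)
        params = est.get_params()
        assert params["epsilon"] == 1e-3
        est2 = clone(est).set_params(epsilon=0.01)
        assert est2.get_params()["epsilon"] == 0.01

        X = small_sample[["ref_count", "total_count"]].to_numpy()
        est.fit(X)
        assert est.converged_ and est.sigma_ > 0
        assert est.n_genes_used_ == len(small_sample)
        lp = est.score_samples(X[:5])
        assert np.all(np.isfinite(lp)) and np.all(lp < 0)

    def test_agrees_with_functional_interface(self, small_sample, quick_config):
        X = small_sample[["ref_count", "total_count"]].to_numpy()
        est = BLNMixture(min_genes=20).fit(X, sample_id="S1")
        fit = fit_sample(small_sample, quick_config)
        assert est.sigma_ == pytest.approx(fit.sigma_hat, abs=1e-9)
        assert est.mu_ == pytest.approx(fit.mu_hat, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            BLNMixture().fit(np.array([[5, 3]] * 60))


def test_binomial_limit_total_variation():
    """At tiny sigma the BLN collapses onto Binomial(t, logistic(mu))."""
    for t, mu in [(50, 0.0), (200, 1.0)]:
        r = np.arange(t + 1)
        bln = np.exp(bln_log_pmf(r, np.full(t + 1, t), mu, 1e-3))
        ref = binom.pmf(r, t, expit(mu))
        assert 0.5 * np.abs(bln - ref).sum() < 1e-4
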