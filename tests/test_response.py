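"""Tumbling-bias response models: Hill algebra, population predictions,
slow adaptation, and parameter recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import runtumble as rt
from runtumble.response import (
    BetaBasal,
    EmpiricalBasal,
    HeterogeneousResponse,
    HomogeneousResponse,
    TBResponseData,
    fit_response_model,
    hill_inhibition,
    population_mean_tb,
    predict_population_tb,
    update_adaptation,
    effective_concentration,
)


class TestHomogeneousResponse:
    @pytest.mark.parametrize("h_r", [0.5, 1.0, 1.5, 4.0, 10.0])
    def test_hill_anchor_points(self, h_r):
        """TB(0) = TB0, TB(K) = midpoint for any exponent, TB(inf) -> TB_inf."""
        m = HomogeneousResponse(tb0=0.3, tb_inf=0.06, k_r=40.0, h_r=h_r)
        assert m.tumbling_bias(0.0) == pytest.approx(0.3)
        assert m.tumbling_bias(40.0) == pytest.approx((0.3 + 0.06) / 2)
        assert m.tumbling_bias(1e12) == pytest.approx(0.06, abs=1e-5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HomogeneousResponse(tb0=0.1, tb_inf=0.3, k_r=10.0, h_r=1.0)
        with pytest.raises(ValueError):
            HomogeneousResponse(tb0=0.3, tb_inf=0.1, k_r=-1.0, h_r=1.0)

    @given(
        tb0=st.floats(0.05, 0.9),
        frac=st.floats(0.0, 1.0),
        k=st.floats(0.1, 1e4),
        h=st.floats(0.1, 12.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, tb0, frac, k, h):
        """Response stays within [0,1] and never increases with attractant."""
        m = HomogeneousResponse(tb0=tb0, tb_inf=tb0 * frac, k_r=k, h_r=h)
        conc = np.logspace(-3, 6, 80)
        tb = m.tumbling_bias(np.concatenate([[0.0], conc]))
        assert np.all((tb >= 0) & (tb <= 1))
        assert np.all(np.diff(tb) <= 1e-12)


class TestHeterogeneousResponse:
    def test_requires_phenotypes(self, r1_het):
        with pytest.raises(ValueError, match="phenotype"):
            r1_het.tumbling_bias(10.0)

    def test_zero_concentration_returns_basal(self, r1_het, rng):
        phen = r1_het.sample_phenotypes(200, rng)
        tb = r1_het.tumbling_bias(0.0, phen)
        assert np.allclose(tb, phen.tb0)

    def test_degenerate_collapses_to_homogeneous(self, rng):
        """Point-mass sensitivity and basal bias reproduce the population
        Hill curve with matched parameters."""
        hom = HomogeneousResponse(tb0=0.3, tb_inf=0.06, k_r=50.0, h_r=3.0)
        het = HeterogeneousResponse(
            mu_log_k=math.log(50.0), sigma_log_k=1e-9, rho=0.2,
            basal=EmpiricalBasal(np.array([0.3])), hill_cell=3.0)
        phen = het.sample_phenotypes(50, rng)
        conc = np.array([0.0, 5.0, 50.0, 500.0, 5e4])
        for c in conc:
            np.testing.assert_allclose(
                het.tumbling_bias(c, phen), hom.tumbling_bias(c), atol=1e-9)

    def test_population_mean_mc_vs_quadrature(self, r1_het):
        """Monte-Carlo population mean agrees with the quadrature oracle."""
        for conc in (0.0, 10.0, 50.0, 500.0):
            mean, samples = predict_population_tb(r1_het, conc, n_mc=40_000,
                                                  rng=7)
            se = samples.std() / math.sqrt(samples.size)
            assert abs(mean - population_mean_tb(r1_het, conc)) < 3 * se

    def test_predicted_distribution_at_zero_is_basal(self, r1_het):
        mean, _ = predict_population_tb(r1_het, 0.0, n_mc=100_000, rng=3)
        assert mean == pytest.approx(r1_het.basal.mean(), abs=0.005)

    def test_lognormal_sensitivity_sample_mean(self, r1_het, rng):
        """Sampled K_i mean matches the closed-form log-normal mean."""
        n = 10_000
        phen = r1_het.sample_phenotypes(n, rng)
        mu, sig = r1_het.mu_log_k, r1_het.sigma_log_k
        expected = math.exp(mu + sig ** 2 / 2)
        sd = math.sqrt((math.exp(sig ** 2) - 1)) * expected
        assert abs(phen.k.mean() - expected) < 3 * sd / math.sqrt(n)


class TestAdaptation:
    def test_exponential_relaxation_limit(self):
        """Euler updates converge to m(t) = L (1 - exp(-t/tau))."""
        tau, L, t_end = 100.0, 50.0, 100.0
        dt = 0.01
        m = 0.0
        for _ in range(int(t_end / dt)):
            m = update_adaptation(m, L, dt, tau)
        assert m == pytest.approx(L * (1 - math.exp(-1.0)), rel=1e-3)
        assert m == pytest.approx(0.632 * L, rel=1e-2)

    def test_infinite_tau_disables(self):
        assert update_adaptation(0.0, 100.0, 1.0, math.inf) == 0.0
        assert effective_concentration(100.0, 0.0) == 100.0

    def test_effective_concentration_clamped(self):
        assert effective_concentration(5.0, 20.0) == 0.0


class TestFitting:
    def test_homogeneous_recovery_within_15_percent(self):
        """Median parameter recovery from noisy mean-bias curves."""
        truth = HomogeneousResponse(tb0=0.25, tb_inf=0.05, k_r=30.0, h_r=1.5)
        conc = np.array([0.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(15):
            tb = np.clip(truth.tumbling_bias(conc) + rng.normal(0, 0.01, conc.size), 0, 1)
            fit = fit_response_model(TBResponseData(conc=conc, mean_tb=tb),
                                     kind="homogeneous")
            assert fit.converged and fit.identifiable
            m = fit.model
            errs.append([abs(m.tb0 / 0.25 - 1), abs(m.tb_inf / 0.05 - 1),
                         abs(m.k_r / 30.0 - 1), abs(m.h_r / 1.5 - 1)])
        med = np.median(errs, axis=0)
        assert np.all(med < 0.15)

    def test_flat_data_flagged_unidentifiable(self):
        conc = np.array([0.0, 10.0, 100.0, 1000.0])
        data = TBResponseData(conc=conc, mean_tb=np.full(4, 0.2))
        fit = fit_response_model(data, kind="homogeneous")
        assert not fit.identifiable and not fit.converged

    def test_heterogeneous_needs_samples(self):
        data = TBResponseData(conc=np.array([0.0, 10.0, 100.0, 1000.0]),
                              mean_tb=np.array([0.3, 0.25, 0.15, 0.08]))
        with pytest.raises(ValueError, match="samples"):
            fit_response_model(data, kind="heterogeneous")

    def test_from_table_duration_weighting(self):
        import pandas as pd

        df = pd.DataFrame({
            "conc_uM": [0.0, 0.0, 10.0, 10.0],
            "traj_id": [1, 2, 3, 4],
            "tumbling_bias": [0.1, 0.4, 0.2, 0.2],
            "duration_s": [10.0, 2.0, 1.0, 1.0],
        })
        data = TBResponseData.from_table(df)
        assert data.mean_tb[0] == pytest.approx((0.1 * 10 + 0.4 * 2) / 12)

    def test_data_validation(self):
        with pytest.raises(ValueError):
            TBResponseData(conc=np.array([10.0, 5.0]), mean_tb=np.array([0.2, 0.3]))
        with pytest.raises(ValueError):
            TBResponseData(conc=np.array([0.0, 5.0]), mean_tb=np.array([0.2, 1.3]))
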