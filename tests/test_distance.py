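"""Distance sampling: detection fits, AICc machinery, abundance, Huggins."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from bearcensus.distance import (
    DetectionFit,
    DetectionModelSpec,
    HugginsFit,
    aicc,
    akaike_weights,
    check_perfect_detection,
    estimate_abundance,
    fit_detection,
    fit_huggins_double_observer,
    goodness_of_fit,
    half_normal_esw,
    model_average,
)
from conftest import SELECTION_TABLE, distances_frame, simulate_truncated_half_normal


def transects_frame(lengths, stratum="rowley"):
    return pd.DataFrame(
        {
            "transect_id": [f"T{i+1:02d}" for i in range(len(lengths))],
            "stratum": stratum,
            "length_km": lengths,
        }
    )


class TestEsw:
    @pytest.mark.parametrize("sigma", [200.0, 800.0, 1000.0, 5000.0])
    def test_closed_form_matches_quadrature(self, sigma):
        w = 2300.0
        quad, _ = integrate.quad(lambda x: np.exp(-(x**2) / (2 * sigma**2)), 0, w, epsrel=1e-10)
        assert abs(half_normal_esw(sigma, w) - quad) < 0.1

    def test_reference_value(self):
        # sigma=1000, w=2300: mu = sigma*sqrt(pi/2)*erf(w/(sigma*sqrt(2)))
        assert half_normal_esw(1000.0, 2300.0) == pytest.approx(1226.0, abs=1.0)

    def test_monotone_in_sigma(self):
        sigmas = np.linspace(100, 3000, 30)
        esws = half_normal_esw(sigmas, 2300.0)
        assert np.all(np.diff(esws) > 0)


class TestFitDetection:
    def test_uniform_key_flat_detection(self):
        rng = np.random.default_rng(0)
        obs = distances_frame(rng.uniform(0, 1000, 60))
        fit = fit_detection(obs, DetectionModelSpec(key="uniform", truncation_m=1000.0))
        assert fit.esw_m == 1000.0
        assert fit.p == 1.0
        assert fit.k == 0
        assert fit.log_likelihood == pytest.approx(-60 * np.log(1000.0))

    def test_half_normal_recovers_sigma_within_2_se(self):
        rng = np.random.default_rng(42)
        x = simulate_truncated_half_normal(rng, 5000, 800.0, 2300.0)
        fit = fit_detection(distances_frame(x), DetectionModelSpec(key="half-normal", truncation_m=2300.0))
        sigma_hat = float(np.exp(fit.params[0]))
        # convert the ESW SE to a scale SE through d(mu)/d(sigma)
        dmu = (half_normal_esw(sigma_hat + 1, 2300.0) - half_normal_esw(sigma_hat - 1, 2300.0)) / 2
        sigma_se = fit.esw_se_m / dmu
        assert abs(sigma_hat - 800.0) < 2 * sigma_se

    @pytest.mark.parametrize(
        "spec",
        [
            DetectionModelSpec(key="half-normal", truncation_m=2300.0),
            DetectionModelSpec(key="hazard-rate", truncation_m=2300.0),
            DetectionModelSpec(key="uniform", cosine_orders=(1,), truncation_m=2300.0),
            DetectionModelSpec(key="half-normal", covariates=("vis",), truncation_m=2300.0),
        ],
    )
    def test_fitted_density_integrates_to_one(self, spec):
        rng = np.random.default_rng(7)
        x = simulate_truncated_half_normal(rng, 300, 900.0, 2300.0)
        obs = distances_frame(x)
        obs["vis"] = np.where(rng.random(len(obs)) < 0.5, "poor/fair", "excellent")
        fit = fit_detection(obs, spec)
        total, _ = integrate.quad(lambda t: float(fit.pdf(t)), 0, 2300.0, limit=200)
        assert abs(total - 1.0) < 1e-4
        assert 0 < fit.p <= 1.0
        assert 0 < fit.esw_m <= 2300.0

    def test_too_few_observations_rejected(self):
        obs = distances_frame(np.linspace(10, 500, 5))
        with pytest.raises(ValueError, match=">= 10"):
            fit_detection(obs, DetectionModelSpec(key="half-normal", truncation_m=1000.0))

    def test_covariates_require_scale_key(self):
        with pytest.raises(ValueError):
            DetectionModelSpec(key="uniform", covariates=("vis",))


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(-100.0, 2, 56) == pytest.approx(204.2264, abs=1e-3)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_single_model_weight_one(self):
        _, w = akaike_weights([123.4])
        assert w[0] == 1.0

    def test_published_deltas_give_hand_computed_weights(self):
        deltas = [row[0] for row in SELECTION_TABLE.values()]
        _, w = akaike_weights([100 + d for d in deltas])
        np.testing.assert_allclose(w, [0.306, 0.284, 0.175, 0.153, 0.082], atol=0.001)
        assert w.sum() == pytest.approx(1.0)

    def test_cutoff_excludes_weak_models(self):
        _, w = akaike_weights([0.0, 5.0], cutoff=3.0)
        assert w[1] == 0.0
        assert w[0] == 1.0


class TestGoodnessOfFit:
    def test_exact_uniform_data_has_tiny_ks(self):
        n = 200
        x = (np.arange(n) + 0.5) / n * 1000.0
        fit = fit_detection(distances_frame(x), DetectionModelSpec(key="uniform", truncation_m=1000.0))
        gof = goodness_of_fit(fit)
        assert gof.ks_stat <= 0.5 / n + 1e-9
        assert gof.chi2_p > 0.99

    def test_misspecified_model_detected(self):
        """Hazard-rate data forced through a narrow half-normal must fail."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(30):
            x = []
            while len(x) < 80:
                c = rng.uniform(0, 2300, 400)
                keep = rng.random(400) < 1 - np.exp(-((c / 900.0) ** -3.0))
                x.extend(c[keep])
            obs = distances_frame(np.array(x[:80]))
            fit = DetectionFit.from_params(
                DetectionModelSpec(key="half-normal"), [np.log(300.0)], obs, truncation_m=2300.0
            )
            ps.append(goodness_of_fit(fit).ks_p)
        assert np.median(ps) < 0.05


class TestEstimateAbundance:
    def _uniform_fit(self, obs, w):
        return fit_detection(obs, DetectionModelSpec(key="uniform", truncation_m=w))

    def test_direct_formula(self):
        # n=30, mu=1 km, L=150 km, A=1000 km2, mean size 1.2 -> N=120
        rng = np.random.default_rng(5)
        obs = distances_frame(rng.uniform(0, 1000, 30))
        obs["group_size"] = [2] * 6 + [1] * 24
        obs["transect_id"] = ["T%02d" % (i % 5 + 1) for i in range(30)]
        fit = self._uniform_fit(obs, 1000.0)
        est = estimate_abundance(fit, obs, transects_frame([30.0] * 5), "rowley", 1000.0)
        assert est.n_hat == pytest.approx(30 / (2 * 1.0 * 150.0) * 1000.0 * 1.2)
        assert est.cv == pytest.approx(est.se / est.n_hat)
        assert est.ci_low <= est.n_hat <= est.ci_high

    def test_empty_stratum_flagged(self):
        rng = np.random.default_rng(6)
        obs = distances_frame(rng.uniform(0, 1000, 30))
        fit = self._uniform_fit(obs, 1000.0)
        est = estimate_abundance(fit, obs, transects_frame([10.0, 10.0], stratum="empty"), "empty", 500.0)
        assert est.n_hat == 0.0
        assert est.cv_components.get("empty_stratum")

    def test_single_transect_requires_override(self):
        rng = np.random.default_rng(7)
        obs = distances_frame(rng.uniform(0, 1000, 30), transect_id="T01")
        fit = self._uniform_fit(obs, 1000.0)
        with pytest.raises(ValueError, match="transects"):
            estimate_abundance(fit, obs, transects_frame([150.0]), "rowley", 1000.0)
        est = estimate_abundance(
            fit, obs, transects_frame([150.0]), "rowley", 1000.0, allow_single_transect=True
        )
        assert est.n_hat > 0


class TestModelAverage:
    def test_published_rows_average_to_102(self):
        deltas, ns, ses = zip(*SELECTION_TABLE.values())
        ma = model_average(list(ns), aicc_values=[100 + d for d in deltas], ses=list(ses))
        assert round(ma.n_bar) == 102
        assert round(ma.ci_high) == 152
        assert round(ma.ci_low) == 69

    def test_single_member_degenerate(self):
        ma = model_average([97.0], aicc_values=[10.0], ses=[17.8])
        assert ma.n_bar == 97.0
        assert ma.se_unconditional == pytest.approx(17.8)

    def test_average_within_member_range(self):
        rng = np.random.default_rng(8)
        ns = rng.uniform(50, 150, 6)
        ma = model_average(list(ns), aicc_values=list(rng.uniform(0, 2.9, 6)), ses=[10.0] * 6)
        assert ns.min() <= ma.n_bar <= ns.max()
        assert ma.members["weight"].sum() == pytest.approx(1.0)

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            model_average([], aicc_values=[])


class TestHuggins:
    @staticmethod
    def records(n_both, n_front_only, n_rear_only):
        return pd.DataFrame(
            {
                "seen_front": [True] * n_both + [True] * n_front_only + [False] * n_rear_only,
                "seen_rear": [True] * n_both + [False] * n_front_only + [True] * n_rear_only,
            }
        )

    def test_hand_arithmetic(self):
        fit = fit_huggins_double_observer(self.records(50, 30, 10))
        assert fit.p_front == pytest.approx(50 / 60)
        assert fit.p_rear == pytest.approx(50 / 80)
        assert fit.p0 == pytest.approx(0.9375)

    def test_all_duplicates_perfect_pooled(self):
        fit = fit_huggins_double_observer(self.records(40, 0, 0))
        assert fit.p0 == 1.0

    def test_zero_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_huggins_double_observer(self.records(0, 5, 5))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(9)
        est = []
        for _ in range(50):
            f = rng.random(500) < 0.95
            r = rng.random(500) < 0.95
            keep = f | r
            fit = fit_huggins_double_observer(
                pd.DataFrame({"seen_front": f[keep], "seen_rear": r[keep]})
            )
            est.append(fit.p0)
        se = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.9975) < 2 * max(se, 1e-4)


class TestPerfectDetectionRule:
    def test_borderline_below_threshold_with_tight_ci(self):
        fit = HugginsFit(80, 60, 50, 50 / 60, 50 / 80, 0.02, 0.02, 0.9375, 0.01)
        decision = check_perfect_detection(fit, threshold=0.95)
        assert not decision.cds_permissible
        assert decision.inflation_factor == pytest.approx(1 / 0.9375)

    def test_exactly_perfect(self):
        fit = HugginsFit(40, 40, 40, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0)
        assert check_perfect_detection(fit).cds_permissible

    def test_above_threshold(self):
        fit = HugginsFit(100, 90, 85, 0.95, 0.85, 0.02, 0.03, 0.99, 0.005)
        assert check_perfect_detection(fit, threshold=0.95).cds_permissible
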