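"""Closed-population mark-recapture: matching, M_t likelihood, intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bearcensus.capture import (
    CaptureSummary,
    IdentifiabilityError,
    chapman,
    concentrated_loglik,
    fit_closed_mt,
    lincoln_petersen,
    lognormal_f0_ci,
    match_observer_points,
    observer_detection_report,
    profile_likelihood_ci,
)
from bearcensus.scene import SimConfig, generate_scene, simulate_observers


def grid_mle_oracle(n1: int, n2: int, m: int, n_max: int) -> int:
    """Exhaustive integer maximisation of the M_t concentrated likelihood,
    written from the closed-form likelihood with plain math (oracle)."""
    m_t1 = n1 + n2 - m
    best_n, best_ll = m_t1, -math.inf
    for n in range(max(m_t1, n1, n2), n_max + 1):
        ll = math.lgamma(n + 1) - math.lgamma(n - m_t1 + 1)
        for nt in (n1, n2):
            p = nt / n
            ll += nt * math.log(p)
            if p < 1.0:
                ll += (n - nt) * math.log(1.0 - p)
        if ll > best_ll:
            best_n, best_ll = n, ll
    return best_n


def points_table(ids, coords, observer):
    return pd.DataFrame(
        {
            "point_id": [f"{observer}{i}" for i in ids],
            "observer": observer,
            "x_m": [c[0] for c in coords],
            "y_m": [c[1] for c in coords],
        }
    )


class TestMatching:
    def test_identical_tables_all_duplicates(self):
        coords = [(i * 1000.0, 0.0) for i in range(10)]
        a = points_table(range(10), coords, "A")
        b = points_table(range(10), coords, "B")
        history, summary = match_observer_points(a, b)
        assert summary.m == summary.n1 == summary.n2 == 10
        assert (history["history"] == "11").all()

    def test_distant_tables_no_duplicates(self):
        a = points_table(range(5), [(i * 1000.0, 0.0) for i in range(5)], "A")
        b = points_table(range(5), [(i * 1000.0 + 500.0, 0.0) for i in range(5)], "B")
        history, summary = match_observer_points(a, b, match_radius_m=30.0)
        assert summary.m == 0
        assert set(history["history"]) == {"10", "01"}

    def test_duplicate_ids_rejected(self):
        a = points_table([1, 1], [(0.0, 0.0), (5.0, 5.0)], "A")
        b = points_table([1], [(0.0, 0.0)], "B")
        with pytest.raises(ValueError, match="duplicate"):
            match_observer_points(a, b)

    def test_greedy_matching_prefers_nearest(self):
        # one B point between two A points: must pair with the closer one
        a = points_table([1, 2], [(0.0, 0.0), (20.0, 0.0)], "A")
        b = points_table([1], [(6.0, 0.0)], "B")
        history, summary = match_observer_points(a, b, match_radius_m=30.0)
        assert summary.m == 1
        matched = history.query("history == '11'").iloc[0]
        assert matched["point_id_a"] == "A1"

    def test_matches_agree_with_identity_oracle(self, rowley_scene):
        """Matched duplicates equal ground-truth joint detections carried
        through the simulator's identity labels."""
        for rep in range(20):
            rng = np.random.default_rng(np.random.SeedSequence([7, rep]))
            tabs = simulate_observers(rowley_scene, rng=rng)
            truth = len(set(tabs["A"]["true_id"]) & set(tabs["B"]["true_id"]))
            _, summary = match_observer_points(tabs["A"], tabs["B"])
            assert summary.m == truth


class TestClosedPopFit:
    def test_complete_enumeration_degenerate(self):
        fit = fit_closed_mt(CaptureSummary(12, 12, 12))
        assert fit.n_hat == 12
        assert fit.p1_hat == pytest.approx(1.0)
        assert fit.p2_hat == pytest.approx(1.0)
        assert (fit.ci_low, fit.ci_high) == (12.0, 12.0)

    def test_fixture_counts_reproduce_census_estimate(self, fixture_summary):
        fit = fit_closed_mt(fixture_summary)
        assert fit.n_hat == 94
        assert fit.n_hat_continuous == pytest.approx(90 * 40 / 38)

    def test_small_instance_against_grid_oracle(self):
        # at small samples the exact concentrated likelihood peaks below the
        # Lincoln-Petersen value (12 here): the factorial term grows slower
        # than its Stirling approximation
        fit = fit_closed_mt(CaptureSummary(6, 4, 2))
        assert fit.n_hat == grid_mle_oracle(6, 4, 2, 200) == 10
        assert fit.n_hat_continuous == pytest.approx(12.0)

    def test_unidentifiable_without_duplicates(self):
        with pytest.raises(IdentifiabilityError):
            fit_closed_mt(CaptureSummary(5, 3, 0))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n1=st.integers(1, 60),
        n2=st.integers(1, 60),
        frac=st.floats(0.01, 1.0),
    )
    def test_estimate_and_interval_respect_distinct_count(self, n1, n2, frac):
        m = max(1, int(round(frac * min(n1, n2))))
        summary = CaptureSummary(n1, n2, m)
        fit = fit_closed_mt(summary)
        assert fit.n_hat >= summary.m_t1
        assert fit.ci_low >= summary.m_t1 - 1e-9
        assert fit.ci_low <= fit.n_hat_continuous <= fit.ci_high + 1e-9
        assert 0 < fit.p1_hat <= 1 and 0 < fit.p2_hat <= 1
        # the exact integer optimum never exceeds the Lincoln-Petersen root
        # (the digamma difference is below its Stirling approximation)
        assert fit.n_hat <= math.ceil(fit.n_hat_continuous)


class TestClosedFormEstimators:
    def test_lincoln_petersen_hand_arithmetic(self, fixture_summary):
        est, var = lincoln_petersen(fixture_summary)
        assert est == pytest.approx(94.7368, abs=1e-3)
        assert var == pytest.approx(6.8232, abs=1e-3)

    def test_chapman_direct_formula(self):
        assert chapman(CaptureSummary(6, 4, 2)) == pytest.approx(7 * 5 / 3 - 1)

    def test_full_overlap_degenerate(self):
        est, var = lincoln_petersen(CaptureSummary(9, 9, 9))
        assert est == 9.0
        assert var == 0.0

    def test_zero_duplicates_raise(self):
        with pytest.raises(IdentifiabilityError):
            lincoln_petersen(CaptureSummary(4, 4, 0))


class TestIntervals:
    def test_zero_variance_collapses(self):
        assert lognormal_f0_ci(92, 2.7, 0.0) == (94.7, 94.7)

    def test_hand_computed_interval(self):
        from statistics import NormalDist

        f0, var = 2.74, 6.82
        z = NormalDist().inv_cdf(0.975)
        c = math.exp(z * math.sqrt(math.log(1 + var / f0**2)))
        lo, hi = lognormal_f0_ci(92, f0, var)
        assert lo == pytest.approx(92 + f0 / c, rel=1e-9)
        assert hi == pytest.approx(92 + f0 * c, rel=1e-9)

    def test_fixture_interval_upper_rounds_to_105(self, fixture_summary):
        fit = fit_closed_mt(fixture_summary)
        assert round(fit.ci_high) == 105

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            lognormal_f0_ci(92, 2.7, -1.0)

    def test_profile_interval_contains_mle(self, fixture_summary):
        lo, hi = profile_likelihood_ci(fixture_summary)
        fit = fit_closed_mt(fixture_summary)
        assert lo <= fit.n_hat <= hi
        assert lo >= fixture_summary.m_t1

    def test_lognormal_coverage_nominal_away_from_boundary(self):
        """With moderate detection (p = 0.80/0.50) the boundary f0=0 has
        negligible probability and the lognormal-f0 interval holds its
        nominal 95% level."""
        rng = np.random.default_rng(555)
        n_true, cover, ok = 94, 0, 0
        for _ in range(1500):
            d1 = rng.random(n_true) < 0.80
            d2 = rng.random(n_true) < 0.50
            m = int((d1 & d2).sum())
            if m == 0:
                continue
            ok += 1
            fit = fit_closed_mt(CaptureSummary(int(d1.sum()), int(d2.sum()), m))
            cover += fit.ci_low <= n_true <= fit.ci_high
        assert 0.90 <= cover / ok <= 0.98

    def test_boundary_mass_degrades_plug_in_coverage(self, rowley_scene):
        """At the study conditions (N=94, p=0.96/0.42) roughly 0.96^n2 of
        replicates put every B detection in A's list, so f0=0 and the
        plug-in interval degenerates to a point; the profile-likelihood
        interval loses less coverage but neither attains the nominal level
        in this boundary-heavy regime."""
        reps = 800
        degenerate = 0
        cover_ln = cover_prof = 0
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([13, rep]))
            tabs = simulate_observers(rowley_scene, rng=rng)
            _, summary = match_observer_points(tabs["A"], tabs["B"])
            if summary.m == 0:
                continue
            fit = fit_closed_mt(summary)
            degenerate += fit.f0 == 0
            cover_ln += fit.ci_low <= 94 <= fit.ci_high
            lo, hi = profile_likelihood_ci(summary)
            cover_prof += lo <= 94 <= hi
        assert degenerate / reps > 0.10
        assert cover_prof > cover_ln
        assert cover_ln / reps < 0.90


class TestDetectionReport:
    def test_fixture_observer_b_is_42_pct(self, fixture_summary):
        fit = fit_closed_mt(fixture_summary)
        rep = observer_detection_report(fixture_summary, fit)
        assert rep["conditional"]["p2_pct"] == 42

    def test_full_overlap_reports_100(self):
        s = CaptureSummary(7, 7, 7)
        rep = observer_detection_report(s, fit_closed_mt(s))
        assert rep["conditional"] == {"p1_pct": 100, "p2_pct": 100}

    def test_small_instance_hand_arithmetic(self):
        s = CaptureSummary(6, 4, 2)
        rep = observer_detection_report(s, fit_closed_mt(s))
        assert rep["conditional"]["p1_pct"] == 50   # 2/4
        assert rep["conditional"]["p2_pct"] == 33   # 2/6


def test_concentrated_loglik_matches_plain_math(fixture_summary):
    val = concentrated_loglik(100.0, fixture_summary)
    n1, n2, m = 90, 40, 38
    expected = math.lgamma(101) - math.lgamma(100 - 92 + 1)
    for nt in (n1, n2):
        expected += nt * math.log(nt / 100) + (100 - nt) * math.log(1 - nt / 100)
    assert float(val) == pytest.approx(expected, rel=1e-12)
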