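"""Percent-scale inference, group comparisons, bootstrap, report tables."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

import lawbend as lb
from lawbend.inference import UNADJUSTED_NOTE
from lawbend.model import KnotPair, PiecewiseNBFit


def _toy_fit(beta1=0.0, gamma1=0.0, gamma2=0.0, se=0.005, converged=True):
    vcov = np.diag([0.01**2, se**2, se**2, se**2])
    return PiecewiseNBFit(
        knots=KnotPair(-12, 12), beta0=-8.5, beta1=beta1, gamma1=gamma1,
        gamma2=gamma2, dispersion=0.3, sigma_b=0.3, loglik=-1000.0,
        vcov=vcov, converged=converged, n_cells=100, n_states=10,
    )


class TestPercentChange:
    @pytest.mark.parametrize(
        "slope, percent",
        [(0.0, 0.0), (math.log(2.0), 100.0), (-math.log(2.0), -50.0)],
    )
    def test_reference_points(self, slope, percent):
        assert lb.percent_change(slope) == pytest.approx(percent)

    def test_bijection(self):
        for b in (-0.05, -0.001, 0.0, 0.02, 0.5):
            assert lb.percent_change_inverse(lb.percent_change(b)) == pytest.approx(b)

    def test_strictly_increasing(self):
        xs = np.linspace(-1, 1, 41)
        ys = [lb.percent_change(x) for x in xs]
        assert np.all(np.diff(ys) > 0)


class TestSlopeWaldCI:
    def test_null_coefficient(self):
        sc = lb.slope_wald_ci(0.0, 0.01)
        assert sc.percent_per_stdm == 0.0
        assert sc.ci_low == pytest.approx(-sc.ci_high / (1 + sc.ci_high / 100), rel=1e-6)
        assert sc.p_value == pytest.approx(1.0)
        assert not sc.significant

    def test_clear_signal_excludes_zero(self):
        # z = 0.0183/0.00343 = 5.33 -> p well under 0.05.
        sc = lb.slope_wald_ci(0.0183, 0.00343)
        assert sc.ci_low > 0
        assert sc.p_value < 0.05
        assert sc.percent_per_stdm == pytest.approx(100 * (math.exp(0.0183) - 1))
        z = 1.959963984540054
        assert sc.ci_low == pytest.approx(
            100 * (math.exp(0.0183 - z * 0.00343) - 1)
        )

    def test_wider_alpha_means_narrower_interval(self):
        narrow = lb.slope_wald_ci(0.01, 0.004, alpha=0.10)
        wide = lb.slope_wald_ci(0.01, 0.004, alpha=0.05)
        assert narrow.ci_low > wide.ci_low
        assert narrow.ci_high < wide.ci_high

    def test_interval_brackets_estimate(self):
        sc = lb.slope_wald_ci(-0.02, 0.01)
        assert sc.ci_low <= sc.percent_per_stdm <= sc.ci_high

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            lb.slope_wald_ci(0.01, 0.0)

    def test_labelled_unadjusted(self):
        assert lb.slope_wald_ci(0.01, 0.004).note == UNADJUSTED_NOTE


class TestCompareSlopes:
    def test_identical_fits_no_difference(self):
        fit = _toy_fit(gamma2=0.01)
        cmp_ = lb.compare_slopes(fit, fit, "gamma2")
        assert cmp_.difference_percent == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_hand_computed_normal_tail(self):
        # (0.02 - 0.00) / sqrt(2 * 0.005^2) = 2.828; two-sided p ~ 0.0047.
        a = _toy_fit(gamma1=0.02, se=0.005)
        b = _toy_fit(gamma1=0.0, se=0.005)
        cmp_ = lb.compare_slopes(a, b, "gamma1")
        assert cmp_.statistic == pytest.approx(2.8284, abs=1e-3)
        assert cmp_.p_value == pytest.approx(0.00468, abs=2e-4)

    def test_antisymmetry(self):
        a = _toy_fit(gamma2=0.02, se=0.004)
        b = _toy_fit(gamma2=-0.01, se=0.006)
        ab = lb.compare_slopes(a, b, "gamma2")
        ba = lb.compare_slopes(b, a, "gamma2")
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.coef_diff == pytest.approx(-ba.coef_diff)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_unconverged_fit_rejected(self):
        good = _toy_fit()
        bad = _toy_fit(converged=False)
        with pytest.raises(ValueError, match="converge"):
            lb.compare_slopes(good, bad, "gamma1")


class TestClusterBootstrap:
    def test_identity_resample_reproduces_fit(self, strong_cells, strong_fit):
        n = strong_cells["state"].nunique()
        summary = lb.cluster_bootstrap(
            strong_cells, KnotPair(-12, 12), n_boot=1,
            samples=[np.arange(n)],
        )
        assert summary.n_converged == 1
        est = summary.estimates.iloc[0]
        for name in ("beta1", "gamma1", "gamma2"):
            assert est[name] == pytest.approx(strong_fit.coef(name), abs=5e-4)

    def test_bootstrap_se_tracks_wald_se(self, strong_cells, strong_fit):
        summary = lb.cluster_bootstrap(
            strong_cells, KnotPair(-12, 12), n_boot=60, seed=4,
        )
        assert summary.n_converged >= 55
        for name in ("gamma1", "gamma2"):
            ratio = summary.se[name] / strong_fit.se(name)
            assert 0.6 < ratio < 1.6, (name, ratio)

    def test_influential_state_flags_skew(self):
        # One state dwarfing the others makes the resampled gamma2
        # distribution bimodal/heavy-tailed -> skew diagnostic must fire.
        cfg = lb.SimulationConfig(
            n_states=10, stdm_range=(-18, 18), beta1=0.0, gamma1=0.0,
            gamma2=0.0, tau1=-6, tau2=6, sigma_b=0.0, dispersion=0.2, seed=6,
        )
        cells, _ = lb.simulate_surveillance(cfg)
        cells = cells[cells["classification"] == "incident"].copy()
        dominant = cells["state"] == cells["state"].iloc[0]
        cells.loc[dominant, "athlete_exposures"] *= 200
        bent = dominant & (cells["stdm"] > 6)
        cells.loc[bent, "event_count"] = (
            cells.loc[bent, "event_count"] * np.exp(0.08 * (cells.loc[bent, "stdm"] - 6))
        ).round().astype(int)
        summary = lb.cluster_bootstrap(
            cells, KnotPair(-6, 6), n_boot=80, seed=1, skew_threshold=1.0,
        )
        assert any(summary.unreliable.values())

    def test_parametric_mode_runs(self, strong_cells):
        summary = lb.cluster_bootstrap(
            strong_cells, KnotPair(-12, 12), n_boot=10, seed=2, mode="parametric",
        )
        assert summary.n_converged + summary.n_failed == 10
        assert summary.mode == "parametric"

    def test_invalid_arguments(self, strong_cells):
        with pytest.raises(ValueError):
            lb.cluster_bootstrap(strong_cells, KnotPair(-12, 12), n_boot=0)
        with pytest.raises(ValueError):
            lb.cluster_bootstrap(strong_cells, KnotPair(-12, 12), mode="weird")


@pytest.fixture(scope="module")
def plan_fits():
    rng = np.random.default_rng(12)
    fits = {}
    for spec in lb.enumerate_model_plan():
        fits[spec.label] = _toy_fit(
            gamma1=rng.normal(0.01, 0.01), gamma2=rng.normal(-0.01, 0.01),
            se=0.004,
        )
    return fits


class TestReportTables:
    def test_stratum_table_shape(self, plan_fits):
        stratum, comparison = lb.report_tables(plan_fits)
        assert len(stratum) == 7  # overall + six law-language groups
        for tag in ("cp1", "cp2"):
            for cls in ("incident", "recurrent"):
                assert f"{tag}_{cls}_percent" in stratum.columns
        assert len(comparison) == 3

    def test_stars_match_interval_exclusion_of_zero(self, plan_fits):
        stratum, comparison = lb.report_tables(plan_fits)
        for table in (stratum, comparison):
            for col in table.columns:
                if not col.endswith("_sig"):
                    continue
                prefix = col[:-4]
                lo = table[f"{prefix}_ci_low"
                           if f"{prefix}_ci_low" in table.columns
                           else f"{prefix}_percent"]
                lo = table[f"{prefix}_ci_low"]
                hi = table[f"{prefix}_ci_high"]
                starred = table[col] == "*"
                excludes = (lo > 0) | (hi < 0)
                assert (starred == excludes).all(), col

    def test_round_trip_preserves_values(self, plan_fits, tmp_path):
        stratum, _ = lb.report_tables(plan_fits)
        path = tmp_path / "stratum.csv"
        stratum.to_csv(path, index=False)
        back = pd.read_csv(path)
        num = stratum.select_dtypes("number")
        pd.testing.assert_frame_equal(back[num.columns], num, check_exact=False)

    def test_missing_plan_entries_leave_gaps_and_warn(self, plan_fits):
        partial = copy.copy(plan_fits)
        partial.pop(lb.ModelSpec("overall", None, "recurrent").label)
        with pytest.warns(UserWarning, match="missing"):
            stratum, _ = lb.report_tables(partial)
        row = stratum[stratum["stratum"] == "overall"].iloc[0]
        assert np.isnan(row["cp1_recurrent_percent"])
        assert not np.isnan(row["cp1_incident_percent"])
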