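"""Unit tests for curve families, anchored fitting, selection and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoperf.errors import (
    AmbiguousCurveError,
    InvalidMetricsError,
    MissingDataError,
    SelectionError,
    UndefinedAICcError,
    ValidationError,
)
from thermoperf.families import CurveFamily, get_family, register_family
from thermoperf.tpc import (
    SpeedObservation,
    ToleranceRecord,
    ToleranceSummary,
    TPCFitResult,
    aicc,
    clamped_curve,
    derive_metrics,
    fit_all_families,
    fit_family,
    select_tpc,
    summarize_tolerance,
    thermal_safety_margin,
    ttb,
)

GUMBEL_PARAMS = (50.0, 28.0, 2.2)  # negligible at anchors (5, 45)
EMG_PARAMS = (300.0, 30.0, 2.0, 0.4)
ASYM_PARAMS = (30.0, 2.0, 28.0, 0.8)


def summary(lo, hi, species="sp"):
    return ToleranceSummary(species=species, ct_min_mean=lo, ct_max_mean=hi)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestToleranceTypes:
    def test_record_rejects_inverted_limits(self):
        with pytest.raises(ValidationError):
            ToleranceRecord("a", "sp", ct_min=30.0, ct_max=10.0)

    def test_record_rejects_nonpositive_rates(self):
        with pytest.raises(ValidationError):
            ToleranceRecord("a", "sp", ct_min=5.0, ct_max=40.0, cooling_rate=0.0)

    def test_summary_requires_nonnegative_sd(self):
        with pytest.raises(ValidationError):
            ToleranceSummary("sp", 5.0, 40.0, ct_min_sd=-1.0)

    def test_summarize_tolerance_means(self):
        recs = [
            ToleranceRecord("a", "sp", ct_min=5.0, ct_max=40.0),
            ToleranceRecord("b", "sp", ct_min=7.0, ct_max=44.0),
        ]
        s = summarize_tolerance(recs)
        assert s.ct_min_mean == pytest.approx(6.0)
        assert s.ct_max_mean == pytest.approx(42.0)
        assert s.n == 2

    def test_summarize_rejects_mixed_species(self):
        recs = [
            ToleranceRecord("a", "sp1", ct_min=5.0, ct_max=40.0),
            ToleranceRecord("b", "sp2", ct_min=7.0, ct_max=44.0),
        ]
        with pytest.raises(ValidationError):
            summarize_tolerance(recs)

    def test_summarize_empty(self):
        with pytest.raises(MissingDataError):
            summarize_tolerance([])

    def test_speed_observation_rejects_negative(self):
        with pytest.raises(ValidationError):
            SpeedObservation("a", "sp", 25.0, -1.0)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


class TestTTB:
    def test_rattlesnake_row(self):
        assert ttb(summary(5.9, 43.1)) == pytest.approx(37.2)

    def test_fossorial_row(self):
        assert ttb(summary(9.3, 41.2)) == pytest.approx(31.9)

    def test_degenerate_equality(self):
        assert ttb(summary(20.0, 20.0)) == 0.0


class TestTSM:
    def test_rattlesnake_row(self):
        assert thermal_safety_margin(43.1, 36.7) == pytest.approx(6.4)

    def test_gartersnake_row(self):
        assert thermal_safety_margin(41.6, 28.6) == pytest.approx(13.0)

    def test_optimum_at_limit(self):
        assert thermal_safety_margin(40.0, 40.0) == 0.0

    def test_optimum_above_limit_errors(self):
        with pytest.raises(InvalidMetricsError):
            thermal_safety_margin(40.0, 41.0)


def test_table1_identities_reproduced():
    """Printed TTB and TSM values follow exactly from the printed means."""
    rows = {
        # species: (ct_min, ct_max, t_o, ttb, tsm)
        "rattlesnake": (5.9, 43.1, 36.7, 37.2, 6.4),
        "fossorial": (9.3, 41.2, 27.8, 31.9, 13.4),
        "gartersnake": (8.5, 41.6, 28.6, 33.1, 13.0),
    }
    for name, (lo, hi, t_o, ttb_ref, tsm_ref) in rows.items():
        assert ttb(summary(lo, hi, name)) == pytest.approx(ttb_ref, abs=1e-9)
        assert thermal_safety_margin(hi, t_o) == pytest.approx(tsm_ref, abs=1e-9)


class TestAICc:
    def test_hand_evaluated_example(self):
        # oracle: n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1) at rss=1, n=10, k=2
        expected = 10 * math.log(0.1) + 4 + 12 / 7
        assert expected == pytest.approx(-17.311565215654746)
        assert aicc(1.0, 10, 2) == pytest.approx(expected)

    def test_doubling_rss_adds_n_log_2(self):
        for n, k in [(10, 2), (33, 4), (150, 3)]:
            delta = aicc(2.0, n, k) - aicc(1.0, n, k)
            assert delta == pytest.approx(n * math.log(2))

    def test_denominator_zero_errors(self):
        with pytest.raises(UndefinedAICcError):
            aicc(1.0, 4, 3)

    def test_nonpositive_rss_errors(self):
        with pytest.raises(UndefinedAICcError):
            aicc(0.0, 10, 2)

    @given(
        rss=st.floats(1e-6, 1e6),
        factor=st.floats(1.001, 100.0),
        n=st.integers(6, 200),
        k=st.integers(1, 4),
    )
    def test_strictly_increasing_in_rss(self, rss, factor, n, k):
        assert aicc(rss * factor, n, k) > aicc(rss, n, k)


# ---------------------------------------------------------------------------
# clamped evaluation
# ---------------------------------------------------------------------------


@given(
    mu=st.floats(15.0, 35.0),
    sigma=st.floats(1.0, 10.0),
    a=st.floats(1.0, 100.0),
)
@settings(max_examples=50, deadline=None)
def test_clamped_gumbel_nonnegative_and_zero_outside(mu, sigma, a):
    fam = get_family("gumbel_peak")
    temps = np.linspace(-10.0, 60.0, 301)
    vals = clamped_curve(fam, (a, mu, sigma), temps, 5.0, 45.0)
    assert np.all(vals >= 0.0)
    outside = (temps <= 5.0) | (temps >= 45.0)
    assert np.all(vals[outside] == 0.0)


@pytest.mark.parametrize("name,params", [
    ("emg_peak", EMG_PARAMS),
    ("asym_logistic_peak", ASYM_PARAMS),
    ("gumbel_peak", GUMBEL_PARAMS),
])
def test_families_unimodal_on_grid(name, params):
    fam = get_family(name)
    grid = np.linspace(5.0, 45.0, 2001)
    vals = fam(grid, params)
    i = int(np.argmax(vals))
    assert np.all(np.diff(vals[: i + 1]) >= -1e-9)
    assert np.all(np.diff(vals[i:]) <= 1e-9)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _noiseless_points(name, params, temps=(12.0, 18.0, 24.0, 28.0, 32.0, 38.0)):
    fam = get_family(name)
    temps = np.asarray(temps)
    return np.column_stack([temps, fam(temps, params)])


class TestFitFamily:
    @pytest.mark.parametrize("name,params", [
        ("emg_peak", EMG_PARAMS),
        ("asym_logistic_peak", ASYM_PARAMS),
        ("gumbel_peak", GUMBEL_PARAMS),
    ])
    def test_noiseless_self_recovery(self, name, params, wide_anchors):
        pts = _noiseless_points(name, params)
        fit = fit_family(pts, name, wide_anchors, n_reported=33, seed=11)
        assert fit.converged
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        for got, want in zip(fit.params, params):
            assert got == pytest.approx(want, rel=1e-3)

    def test_generating_family_ranks_first_by_aicc(self, wide_anchors):
        # oracle: compare rss across families fit to the same gumbel data
        pts = _noiseless_points("gumbel_peak", GUMBEL_PARAMS)
        fits = fit_all_families(pts, wide_anchors, n_reported=33, seed=7)
        by_rss = min(fits, key=lambda f: f.rss)
        by_aicc = min(fits, key=lambda f: f.aicc)
        assert by_rss.family == "gumbel_peak"
        assert by_aicc.family == "gumbel_peak"

    def test_underdetermined_errors(self, wide_anchors):
        pts = _noiseless_points("emg_peak", EMG_PARAMS, temps=(20.0, 25.0, 30.0))
        with pytest.raises(ValidationError):
            fit_family(pts, "emg_peak", wide_anchors, n_reported=33)

    def test_aicc_uses_n_reported(self, wide_anchors):
        pts = _noiseless_points("gumbel_peak", GUMBEL_PARAMS)
        fit = fit_family(pts, "gumbel_peak", wide_anchors, n_reported=38, seed=1)
        assert fit.aicc == pytest.approx(aicc(fit.rss, 38, 3))

    def test_degenerate_tss_errors(self, wide_anchors):
        pts = np.array([[t, 0.0] for t in (10.0, 20.0, 30.0, 40.0)])
        with pytest.raises(Exception):
            fit_family(pts, "gumbel_peak", wide_anchors, n_reported=33)


def _fake_fit(family="gumbel_peak", r2=0.95, crit=10.0, k=3, converged=True):
    anchors = summary(5.0, 45.0)
    return TPCFitResult(
        species="sp", family=family, params=(1.0,) * k, rss=1.0, r2=r2,
        aicc=crit, n_fit_points=7, n_reported=33, converged=converged,
        anchors=anchors,
    )


class TestSelectTPC:
    def test_lowest_aicc_wins(self):
        fits = [_fake_fit(r2=0.95, crit=10.0), _fake_fit(r2=0.92, crit=8.0)]
        assert select_tpc(fits).aicc == 8.0

    def test_floor_filters(self):
        with pytest.raises(SelectionError) as exc:
            select_tpc([_fake_fit(r2=0.85, crit=1.0)])
        assert exc.value.best_r2 == pytest.approx(0.85)

    def test_tie_broken_by_fewer_params(self):
        fits = [
            _fake_fit(family="emg_peak", crit=5.0, k=4),
            _fake_fit(family="gumbel_peak", crit=5.0, k=3),
        ]
        assert select_tpc(fits).family == "gumbel_peak"

    def test_order_invariance(self):
        fits = [
            _fake_fit(family="emg_peak", crit=5.0, k=4),
            _fake_fit(family="gumbel_peak", crit=5.0, k=3),
            _fake_fit(family="asym_logistic_peak", crit=6.0, k=4),
        ]
        winners = {select_tpc(perm).family
                   for perm in (fits, fits[::-1], fits[1:] + fits[:1])}
        assert winners == {"gumbel_peak"}

    def test_nonconverged_excluded(self):
        fits = [
            _fake_fit(crit=1.0, converged=False),
            _fake_fit(family="emg_peak", crit=9.0, k=4),
        ]
        assert select_tpc(fits).family == "emg_peak"

    def test_empty_errors(self):
        with pytest.raises(SelectionError):
            select_tpc([])


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------


def _gaussian_family():
    def eval_fn(t, p):
        a, mu, sigma = p
        return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    return CurveFamily(
        name="gaussian_test",
        param_names=("a", "mu", "sigma"),
        eval_fn=eval_fn,
        bounds_fn=lambda *a: (np.array([0, 0, 0.1]), np.array([100, 50, 20])),
    )


class TestDeriveMetrics:
    def _fit(self, family, params, anchors):
        return TPCFitResult(
            species="sp", family=family, params=params, rss=0.0, r2=1.0,
            aicc=0.0, n_fit_points=7, n_reported=33, converged=True,
            anchors=anchors,
        )

    def test_symmetric_gaussian_b80_symmetric_about_mu(self, wide_anchors):
        register_family(_gaussian_family())
        fit = self._fit("gaussian_test", (10.0, 25.0, 4.0), wide_anchors)
        m = derive_metrics(fit)
        assert m.t_o == pytest.approx(25.0, abs=0.01)
        assert (m.t_o - m.b80_low) == pytest.approx(m.b80_high - m.t_o, abs=0.02)

    def test_optimum_matches_brute_force_grid(self, wide_anchors):
        fam = get_family("gumbel_peak")
        fit = self._fit("gumbel_peak", GUMBEL_PARAMS, wide_anchors)
        m = derive_metrics(fit)
        grid = np.arange(5.0, 45.0, 0.001)  # independent brute-force oracle
        oracle_t_o = grid[int(np.argmax(fam(grid, GUMBEL_PARAMS)))]
        assert m.t_o == pytest.approx(oracle_t_o, abs=0.01)
        assert m.v_max == pytest.approx(GUMBEL_PARAMS[0], rel=1e-6)

    def test_b80_defining_property(self, wide_anchors):
        fit = self._fit("emg_peak", EMG_PARAMS, wide_anchors)
        m = derive_metrics(fit)
        curve = fit.curve
        assert curve(m.b80_low) / m.v_max == pytest.approx(0.8, abs=1e-3)
        assert curve(m.b80_high) / m.v_max == pytest.approx(0.8, abs=1e-3)
        assert m.b80_low < m.t_o < m.b80_high

    def test_widths_shrink_as_level_rises(self, wide_anchors):
        fit = self._fit("gumbel_peak", GUMBEL_PARAMS, wide_anchors)
        widths = [
            (lambda m: m.b80_high - m.b80_low)(derive_metrics(fit, level=lv))
            for lv in (0.5, 0.7, 0.8, 0.9, 0.97)
        ]
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_v_max_dominates_grid(self, wide_anchors):
        fit = self._fit("asym_logistic_peak", ASYM_PARAMS, wide_anchors)
        m = derive_metrics(fit)
        grid = np.arange(5.0, 45.0, 0.01)
        assert m.v_max >= np.max(fit.curve(grid)) - 1e-9

    def test_boundary_warning_when_level_unreached(self):
        # wide gumbel on a narrow interval stays above 80% at the cold anchor
        anchors = summary(24.0, 45.0)
        fit = self._fit("gumbel_peak", (50.0, 25.0, 12.0), anchors)
        with pytest.warns(UserWarning, match="boundary"):
            m = derive_metrics(fit)
        assert m.boundary_warning
        assert m.b80_low == anchors.ct_min_mean

    def test_multimodal_curve_rejected(self, wide_anchors):
        def eval_fn(t, p):
            return 10.0 + 5.0 * np.sin(t / 2.0)

        register_family(
            CurveFamily(
                name="bimodal_test", param_names=("a",), eval_fn=eval_fn,
                bounds_fn=lambda *a: (np.array([0.0]), np.array([1.0])),
            )
        )
        fit = self._fit("bimodal_test", (1.0,), wide_anchors)
        with pytest.raises(AmbiguousCurveError):
            derive_metrics(fit)

    def test_nonconverged_fit_rejected(self, wide_anchors):
        fit = TPCFitResult(
            species="sp", family="gumbel_peak", params=GUMBEL_PARAMS, rss=1.0,
            r2=0.99, aicc=0.0, n_fit_points=7, n_reported=33, converged=False,
            anchors=wide_anchors,
        )
        with pytest.raises(InvalidMetricsError):
            derive_metrics(fit)

    def test_bad_level_rejected(self, wide_anchors):
        fit = self._fit("gumbel_peak", GUMBEL_PARAMS, wide_anchors)
        with pytest.raises(ValidationError):
            derive_metrics(fit, level=1.5)
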