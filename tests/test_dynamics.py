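"""Lifespan analytics: derivatives, reversals, epoch slopes, snapshots."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tractlat.dynamics import (
    DEFAULT_EPOCHS,
    SNAPSHOT_AGES,
    Epoch,
    detect_reversals,
    epoch_slopes,
    median_derivative,
    snapshot_summary,
)

from conftest import make_constant_model, make_median_chart

PHI_06 = 0.7257468822499265  # standard normal CDF at 0.6


class TestMedianDerivative:
    def test_linear_curve(self):
        grid = np.linspace(0.0, 100.0, 500)
        chart = make_median_chart(grid, 0.001 * grid)
        np.testing.assert_allclose(median_derivative(chart), 0.001, atol=1e-12)

    def test_constant_curve(self):
        grid = np.linspace(0.0, 100.0, 100)
        chart = make_median_chart(grid, np.full_like(grid, 0.02))
        np.testing.assert_allclose(median_derivative(chart), 0.0, atol=1e-15)

    def test_analytic_derivative_oracle(self):
        # median sin(age/20)/50 has derivative cos(age/20)/1000
        grid = np.linspace(0.0, 100.0, 500)
        chart = make_median_chart(grid, np.sin(grid / 20.0) / 50.0)
        expected = np.cos(grid / 20.0) / 1000.0
        assert np.max(np.abs(median_derivative(chart) - expected)) < 1e-5

    def test_grid_too_short(self):
        with pytest.raises(ValueError, match="grid"):
            median_derivative(make_median_chart([0.0, 1.0], [0.0, 0.1]))


class TestReversals:
    def test_linear_root_at_50(self):
        grid = np.linspace(0.0, 100.0, 500)
        events = detect_reversals(make_median_chart(grid, (grid - 50.0) / 1000.0))
        assert len(events) == 1
        assert events[0].age_years == pytest.approx(50.0, abs=1e-9)
        assert events[0].direction == "left_to_right"

    def test_strictly_positive_median_has_no_events(self):
        grid = np.linspace(0.0, 100.0, 200)
        assert detect_reversals(make_median_chart(grid, 0.01 + 0.001 * grid)) == []

    def test_right_to_left_direction(self):
        grid = np.linspace(0.0, 100.0, 500)
        events = detect_reversals(make_median_chart(grid, (30.0 - grid) / 1000.0))
        assert [e.direction for e in events] == ["right_to_left"]

    @given(st.integers(0, 10_000))
    def test_crossing_count_parity_matches_end_signs(self, seed):
        # same sign at both ends -> even number of crossings; opposite -> odd
        rng = np.random.default_rng(seed)
        grid = np.linspace(0.0, 100.0, 301)
        coef = rng.normal(0.0, 0.02, 4)
        median = np.polynomial.polynomial.polyval(grid / 50.0 - 1.0, coef) + 0.005
        if median[0] == 0 or median[-1] == 0:
            return
        events = detect_reversals(make_median_chart(grid, median))
        same_sign = median[0] * median[-1] > 0
        assert (len(events) % 2 == 0) == same_sign

    def test_min_excursion_suppresses_micro_crossings(self):
        grid = np.linspace(0.0, 100.0, 1001)
        median = np.where(grid < 50, -0.05, 0.0005 * np.sin(grid))
        chart = make_median_chart(grid, median)
        assert len(detect_reversals(chart, min_excursion=0.0)) > 1
        # every flanking excursion after the first crossing stays below 1e-3
        kept = detect_reversals(chart, min_excursion=1e-3)
        assert len(kept) == 1

    def test_grid_refinement_stability(self):
        # crossing ages move < 0.25 years under refinement beyond 500 points
        mu = lambda age: 0.0025 * (age - 35.0) + 0.01 * np.sin(age / 15.0)
        coarse = make_median_chart(np.linspace(0, 100, 500), mu(np.linspace(0, 100, 500)))
        fine = make_median_chart(np.linspace(0, 100, 2001), mu(np.linspace(0, 100, 2001)))
        ages_c = [e.age_years for e in detect_reversals(coarse)]
        ages_f = [e.age_years for e in detect_reversals(fine)]
        assert len(ages_c) == len(ages_f)
        np.testing.assert_allclose(ages_c, ages_f, atol=0.25)


class TestEpochSlopes:
    def test_linear_absolute_median(self):
        grid = np.linspace(0.0, 100.0, 2001)
        slopes = epoch_slopes(make_median_chart(grid, 0.001 * grid))
        assert [s.epoch for s in slopes] == [e.name for e in DEFAULT_EPOCHS]
        for s in slopes:
            assert s.slope == pytest.approx(0.001, abs=1e-12)

    def test_constant_median_zero_slopes(self):
        grid = np.linspace(0.0, 100.0, 500)
        for s in epoch_slopes(make_median_chart(grid, np.full_like(grid, -0.03))):
            assert s.slope == 0.0

    def test_v_shape_vertex_at_epoch_midpoint(self):
        # |median| V-shaped with vertex at 30: slope ~ 0 over [20, 40) while
        # the half-epochs recover the leg slopes +-0.002
        grid = np.arange(0.0, 100.0 + 1e-9, 0.1)
        chart = make_median_chart(grid, 0.002 * np.abs(grid - 30.0) + 0.001)
        whole = epoch_slopes(chart, (Epoch("adult", 20.0, 40.0),))[0].slope
        left = epoch_slopes(chart, (Epoch("first", 20.0, 30.0),))[0].slope
        right = epoch_slopes(chart, (Epoch("second", 30.0, 40.0),))[0].slope
        assert whole == pytest.approx(0.0, abs=5e-5)
        assert left == pytest.approx(-0.002, abs=5e-5)
        assert right == pytest.approx(0.002, abs=5e-5)

    def test_symmetric_under_median_negation(self):
        grid = np.linspace(0.0, 100.0, 500)
        rng = np.random.default_rng(0)
        median = np.cumsum(rng.normal(0, 1e-4, grid.size))
        up = epoch_slopes(make_median_chart(grid, median))
        down = epoch_slopes(make_median_chart(grid, -median))
        np.testing.assert_allclose([s.slope for s in up], [s.slope for s in down])

    def test_epoch_outside_grid_rejected(self):
        grid = np.linspace(30.0, 50.0, 50)
        with pytest.raises(ValueError, match="early childhood"):
            epoch_slopes(make_median_chart(grid, np.zeros(50)))

    def test_default_epoch_bounds(self):
        bounds = [(e.lo, e.hi) for e in DEFAULT_EPOCHS]
        assert bounds == [(2, 5), (5, 12), (12, 20), (20, 40), (40, 60), (60, 100)]
        assert DEFAULT_EPOCHS[-1].closed_upper


class TestSnapshots:
    def test_symmetric_model_gives_50_percent(self):
        models = {("AF", "FA"): make_constant_model(0.0, 0.05)}
        table = snapshot_summary(models)
        np.testing.assert_allclose(table.pct_right, 50.0)
        assert len(table) == 6

    def test_planted_prevalence(self):
        # mu = 0.03, sigma = 0.05 -> 100*Phi(0.6)
        models = {("AF", "volume"): make_constant_model(0.03, 0.05)}
        table = snapshot_summary(models, ages=[30.0])
        assert table.pct_right.iloc[0] == pytest.approx(100 * PHI_06, rel=1e-9)
        assert table.median_li.iloc[0] == pytest.approx(0.03)

    def test_six_default_snapshot_ages_per_combination(self):
        models = {
            ("AF", "FA"): make_constant_model(0.01, 0.05),
            ("CST", "volume"): make_constant_model(-0.02, 0.05),
        }
        table = snapshot_summary(models)
        assert sorted(table.age_years.unique()) == list(SNAPSHOT_AGES)
        assert len(table) == 12
        # prevalence > 50 iff median > 0 (sigma > 0)
        assert ((table.pct_right > 50) == (table.median_li > 0)).all()

    def test_age_outside_support_rejected(self):
        models = {("AF", "FA"): make_constant_model(age_range=(5.0, 60.0))}
        with pytest.raises(ValueError, match="support"):
            snapshot_summary(models, ages=[3.0, 80.0])
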