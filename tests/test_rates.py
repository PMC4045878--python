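"""Batch and variable-volume fed-batch rate equations."""

import numpy as np
import pandas as pd
import pytest

from pduflux.rates import (
    FeedStep,
    TimeSeries,
    Window,
    batch_specific_rate,
    batch_volumetric_rate,
    cumulative_molar_yield,
    fedbatch_consumption_rate,
    fedbatch_production_rate,
    fedbatch_specific_rate,
    product_molar_ratio,
    specific_rate,
)


def make_series(times, volumes, mode="fedbatch", biomass=6.0, **conc):
    data = {"time_h": times, "volume_L": volumes}
    defaults = {"glycerol_g_L": 0.0, "hpa_g_L": 0.0, "hp_g_L": 0.0, "pdo_g_L": 0.0}
    defaults.update(conc)
    for col, vals in defaults.items():
        data[col] = np.broadcast_to(np.asarray(vals, float), (len(times),)).copy()
    return TimeSeries(pd.DataFrame(data), mode=mode, biomass=biomass)


class TestTimeSeriesValidation:
    def test_time_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_series([0, 1, 1], [1, 1, 1])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_series([0, 1], [1, 1], glycerol_g_L=[1, -1])

    def test_batch_requires_constant_volume(self):
        with pytest.raises(ValueError, match="constant volume"):
            make_series([0, 1], [1.0, 1.2], mode="batch", biomass=6.0)


class TestBatchRates:
    def test_hpa_production_worked_example(self):
        # 0 -> 26.2 g/L 3HPA over 3 h in a constant 0.5 L reactor
        s = make_series([0, 1.5, 3], [0.5] * 3, mode="batch", hpa_g_L=[0, 13, 26.2])
        Q = batch_volumetric_rate(s, "3hpa", Window(0, 3))
        assert Q == pytest.approx(26.2 / 3, abs=1e-9)
        assert round(Q, 1) == 8.7

    def test_constant_concentration_is_zero(self):
        s = make_series([0, 1, 2], [1] * 3, mode="batch", hp_g_L=2.0)
        assert batch_volumetric_rate(s, "3hp", Window(0, 2)) == 0.0

    def test_glycerol_consumption_negative(self):
        s = make_series([0, 3, 6], [0.5] * 3, mode="batch", glycerol_g_L=[50, 25, 0])
        Q = batch_volumetric_rate(s, "glycerol", Window(0, 6))
        assert Q == pytest.approx(-50 / 6)
        assert batch_specific_rate(Q, 6.0) == pytest.approx(-1388.9, abs=0.1)

    @pytest.mark.parametrize("Q, X, expected", [(26.2 / 3, 6, 1455.6), (0, 6, 0.0)])
    def test_specific_rate(self, Q, X, expected):
        assert batch_specific_rate(Q, X) == pytest.approx(expected, abs=0.05)

    def test_specific_rate_requires_positive_density(self):
        with pytest.raises(ValueError):
            batch_specific_rate(1.0, 0.0)


class TestFedbatchRates:
    def test_production_direct_substitution(self):
        s = make_series([0, 5, 10], [1.0, 1.1, 1.2], hp_g_L=[0, 2, 4])
        r = fedbatch_production_rate(s, "3hp", Window(0, 10))
        assert r == pytest.approx(0.48)

    def test_no_mass_change_is_zero(self):
        # concentration falls exactly as volume rises: P·V constant
        s = make_series([0, 10], [1.0, 2.0], hp_g_L=[4.0, 2.0])
        assert fedbatch_production_rate(s, "3hp", Window(0, 10)) == pytest.approx(0.0)

    def test_complete_consumption_equals_feed(self):
        step = FeedStep(0, 10, 50.0, 0.032)  # 1.6 g/h
        s = make_series([0, 5, 10], [1.0, 1.16, 1.32], glycerol_g_L=0.0)
        r = fedbatch_consumption_rate(s, "glycerol", Window(0, 10), step)
        assert r == pytest.approx(-1.6)

    def test_consumption_direct_substitution(self):
        step = FeedStep(0, 10, 50.0, 0.012)  # 0.6 g/h
        s = make_series([0, 10], [1.0, 1.12], glycerol_g_L=[2.0, 0.0])
        r = fedbatch_consumption_rate(s, "glycerol", Window(0, 10), step)
        assert r == pytest.approx(-0.8)

    def test_zero_feed_constant_substrate_is_zero(self):
        step = FeedStep(0, 10, 0.0, 0.0)
        s = make_series([0, 10], [1.0, 1.0], glycerol_g_L=2.0)
        assert fedbatch_consumption_rate(s, "glycerol", Window(0, 10), step) == 0.0

    def test_window_spanning_feed_change_errors(self):
        step = FeedStep(5, 10, 50.0, 0.012)
        s = make_series([0, 5, 10], [1.0, 1.0, 1.06], glycerol_g_L=0.0)
        with pytest.raises(ValueError, match="feed-rate change"):
            fedbatch_consumption_rate(s, "glycerol", Window(0, 10), step)

    @pytest.mark.parametrize(
        "rate, x, expected", [(-1.6, 6, -266.7), (0.3, 6, 50.0), (-2.5, 6, -416.7)]
    )
    def test_specific_rate(self, rate, x, expected):
        assert fedbatch_specific_rate(rate, x) == pytest.approx(expected, abs=0.05)

    def test_mode_equivalence_on_constant_volume(self):
        # batch formulas and fed-batch formulas agree when V is constant
        # and x = X·V
        X, V = 6.0, 0.5
        batch = make_series([0, 2, 4], [V] * 3, mode="batch", biomass=X,
                            hp_g_L=[0, 1.1, 2.2])
        fed = make_series([0, 2, 4], [V] * 3, mode="fedbatch", biomass=X * V,
                          hp_g_L=[0, 1.1, 2.2])
        w = Window(0, 4)
        q_batch = specific_rate(batch, "3hp", w).specific_mg_gCDW_h
        q_fed = specific_rate(fed, "3hp", w).specific_mg_gCDW_h
        assert q_fed == pytest.approx(q_batch, rel=1e-12)

    def test_endpoint_rate_ignores_interior_samples(self):
        s1 = make_series([0, 10], [1.0, 1.2], hp_g_L=[0, 4])
        s2 = make_series([0, 3, 7, 10], [1.0, 1.06, 1.14, 1.2], hp_g_L=[0, 3.9, 1.2, 4])
        w = Window(0, 10)
        assert fedbatch_production_rate(s1, "3hp", w) == pytest.approx(
            fedbatch_production_rate(s2, "3hp", w)
        )

    def test_regression_matches_endpoint_on_linear_data(self):
        t = np.linspace(0, 10, 21)
        V = 1.0 + 0.012 * t
        s = make_series(t, V, hp_g_L=0.4 * t / V)
        w = Window(0, 10)
        end = fedbatch_production_rate(s, "3hp", w, estimator="endpoint")
        reg = fedbatch_production_rate(s, "3hp", w, estimator="regression")
        assert reg == pytest.approx(end, rel=1e-9)

    def test_window_outside_series(self):
        s = make_series([0, 1], [1, 1])
        with pytest.raises(ValueError):
            fedbatch_production_rate(s, "3hp", Window(5, 6))


class TestYieldAndRatio:
    def _lossless_run(self):
        # 10 g/L glycerol converted equimolarly, constant 1 L
        consumed = 10.0 / 92.09
        hp = consumed / 2 * 90.08
        pdo = consumed / 2 * 76.09
        return make_series(
            [0, 5, 10], [1.0] * 3,
            glycerol_g_L=[10, 5, 0],
            hp_g_L=[0, hp / 2, hp],
            pdo_g_L=[0, pdo / 2, pdo],
        )

    def test_lossless_equimolar_yield_is_one(self):
        s = self._lossless_run()
        assert cumulative_molar_yield(s, Window(0, 10)) == pytest.approx(1.0)
        assert product_molar_ratio(s, Window(0, 10)) == pytest.approx(1.0)

    def test_aldehyde_accumulation_lowers_yield(self):
        consumed = 10.0 / 92.09
        hpa = 0.10 * consumed * 74.08
        hp = 0.45 * consumed * 90.08
        pdo = 0.45 * consumed * 76.09
        s = make_series(
            [0, 10], [1.0, 1.0],
            glycerol_g_L=[10, 0], hpa_g_L=[0, hpa], hp_g_L=[0, hp], pdo_g_L=[0, pdo],
        )
        assert cumulative_molar_yield(s, Window(0, 10)) == pytest.approx(0.90)
        full = cumulative_molar_yield(
            s, Window(0, 10), numerator=("3hp", "13pdo", "3hpa")
        )
        assert full == pytest.approx(1.0)

    def test_final_titer_ratio(self):
        s = make_series([0, 30], [1.0, 1.0], glycerol_g_L=[30, 0],
                        hp_g_L=[0, 10.6], pdo_g_L=[0, 9.0])
        assert product_molar_ratio(s, Window(0, 30)) == pytest.approx(0.995, abs=5e-4)

    def test_zero_pdo_is_an_error(self):
        s = make_series([0, 10], [1.0, 1.0], glycerol_g_L=[10, 5], hp_g_L=[0, 1])
        with pytest.raises(ValueError, match="1,3PDO"):
            product_molar_ratio(s, Window(0, 10))

    def test_zero_consumption_is_an_error(self):
        s = make_series([0, 10], [1.0, 1.0], glycerol_g_L=5.0)
        with pytest.raises(ValueError, match="consumed"):
            cumulative_molar_yield(s, Window(0, 10))

    def test_feed_input_counts_as_consumed(self):
        # all fed substrate consumed, nothing accumulates: yield uses feed mass
        step = FeedStep(0, 10, 50.0, 0.012)
        consumed = 6.0 / 92.09  # 0.6 g/h for 10 h
        s = make_series(
            [0, 10], [1.0, 1.12],
            glycerol_g_L=0.0,
            hp_g_L=[0, consumed / 2 * 90.08 / 1.12],
            pdo_g_L=[0, consumed / 2 * 76.09 / 1.12],
        )
        y = cumulative_molar_yield(s, Window(0, 10), schedule=[step])
        assert y == pytest.approx(1.0, rel=1e-9)
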