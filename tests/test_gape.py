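import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from valvometry import gape as gp
from valvometry import io as vio
from valvometry import qc as vqc
from valvometry.series import EnvSeries, ValveSeries
from valvometry.simulate import SimulationConfig, simulate_dataset

from conftest import make_valve


def _one_day(values, period_s=None):
    period_s = period_s or 86400.0 / len(values)
    return make_valve(values, period_s=period_s)


class TestDailyZscore:
    def test_three_point_day_analytic(self):
        g = gp.daily_zscore(_one_day([2400.0, 2500.0, 2600.0]), min_coverage=0.0)
        np.testing.assert_allclose(g.z.to_numpy(), [-1.0, 0.0, 1.0])
        assert g.day_params.iloc[0]["mu_mv"] == 2500.0
        assert g.day_params.iloc[0]["sd_mv"] == 100.0  # sample SD (n-1)

    def test_constant_day_dropped_with_warning(self):
        vals = np.concatenate([np.full(1440, 2500.0), 2500 + 100 * np.sin(np.arange(1440) / 100)])
        s = make_valve(vals, period_s=60.0)
        with pytest.warns(gp.DegenerateDayWarning, match="zero daily SD"):
            g = gp.daily_zscore(s)
        assert len(g.dropped_days) == 1
        assert len(g.day_params) == 1

    def test_sparse_day_dropped(self):
        vals = np.full(1440 * 2, np.nan)
        vals[:1440] = 2500 + np.sin(np.arange(1440) / 50.0)
        vals[1440:1500] = 2500.0  # 4% coverage on day 2
        s = make_valve(vals, period_s=60.0)
        with pytest.warns(gp.DegenerateDayWarning, match="coverage"):
            g = gp.daily_zscore(s)
        assert len(g.day_params) == 1

    def test_matches_brute_force_per_day_loop(self, small_sim):
        masked, _ = vqc.run_qc(small_sim.valve)
        aligned = vio.align(masked, [], valve_grid_s=60.0)
        v = aligned.valve[1]
        g = gp.daily_zscore(v)
        for day, chunk in v.data.groupby(v.data.index.normalize()):
            vals = chunk.dropna().to_numpy()
            mu, sd = vals.mean(), vals.std(ddof=1)
            expect = (chunk.to_numpy() - mu) / sd
            got = g.z[chunk.index].to_numpy()
            np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_normalization_invariants_per_complete_day(self, small_sim):
        aligned = vio.align(small_sim.valve, [], valve_grid_s=60.0)
        g = gp.percent_closure(gp.daily_zscore(aligned.valve[1]))
        for day, z in g.z.groupby(g.z.index.normalize()):
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1.0) < 1e-9
        for day, pct in g.pct_closure.groupby(g.pct_closure.index.normalize()):
            assert pct.min() == pytest.approx(0.0, abs=1e-9)
            assert pct.max() == pytest.approx(100.0, abs=1e-9)


class TestPercentClosure:
    def test_symmetric_day_analytic(self):
        g = gp.daily_zscore(_one_day([2400.0, 2500.0, 2600.0]), min_coverage=0.0)
        g = gp.percent_closure(g)
        np.testing.assert_allclose(g.pct_closure.to_numpy(), [0.0, 50.0, 100.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1000.0), min_size=4, max_size=60, unique=True),
        st.floats(0.1, 4.0),
        st.floats(0.0, 500.0),
    )
    def test_affine_invariance_with_positive_gain(self, vals, gain, offset):
        """Percent closure only depends on each day's shape, not volts."""
        shifted = [gain * v + offset for v in vals]
        if len(set(shifted)) < len(vals):
            return
        g1 = gp.percent_closure(gp.daily_zscore(_one_day(vals), min_coverage=0.0))
        g2 = gp.percent_closure(gp.daily_zscore(_one_day(shifted), min_coverage=0.0))
        np.testing.assert_allclose(
            g1.pct_closure.to_numpy(), g2.pct_closure.to_numpy(), atol=1e-6
        )

    def test_polarity_flip_mirrors_percent(self):
        vals = [2400.0, 2450.0, 2500.0, 2700.0]
        g_pos = gp.percent_closure(
            gp.daily_zscore(_one_day(vals), "closure_positive", min_coverage=0.0)
        )
        g_neg = gp.percent_closure(
            gp.daily_zscore(_one_day(vals), "closure_negative", min_coverage=0.0)
        )
        np.testing.assert_allclose(
            g_neg.pct_closure.to_numpy(),
            100.0 - g_pos.pct_closure.to_numpy(),
            atol=1e-9,
        )


def _par_series(values, period_s=60.0):
    idx = pd.date_range("2021-05-03", periods=len(values),
                        freq=pd.Timedelta(seconds=period_s))
    return EnvSeries("PAR", pd.Series(np.asarray(values, float), index=idx),
                     nominal_period_s=period_s)


class TestLightPartition:
    def test_zero_par_all_dark(self):
        part = gp.light_partition(_par_series(np.zeros(1440)))
        assert (part.regime == "dark").all()

    def test_high_par_all_bright(self):
        part = gp.light_partition(_par_series(np.full(1440, 600.0)))
        assert (part.regime == "bright").all()

    def test_simulator_boundaries_recovered_within_an_hour(self):
        from valvometry.simulate import simulate_light

        cfg = SimulationConfig(seed=0, n_days=2)
        part = gp.light_partition(simulate_light(cfg))
        reg = part.regime
        hours = reg.index.hour + reg.index.minute / 60.0
        # deep night is dark; the mid-morning solar peak is bright
        assert (reg[(hours >= 21.5) | (hours < 2.5)] == "dark").all()
        assert (reg[(hours >= 8.0) & (hours < 10.0)] == "bright").all()
        # LED-only evening is low light (60 umol < 100)
        assert (reg[(hours >= 15.0) & (hours < 19.5)] == "low_light").all()

    def test_gaps_inherit_nearest_label_and_are_counted(self):
        vals = np.full(1440, 600.0)
        vals[100:130] = np.nan
        part = gp.light_partition(_par_series(vals))
        assert part.n_gap_filled == 30
        assert (part.regime == "bright").all()


class TestClosureByRegime:
    def _toy(self):
        # 3 dark samples then 3 bright samples, one hour apart
        par = _par_series([0, 0, 0, 600, 600, 600], period_s=3600.0)
        part = gp.light_partition(par)
        idx = par.timestamps
        pct = pd.Series([10.0, 20.0, np.nan, 80.0, 80.0, 80.0], index=idx)
        g = gp.GapeSeries(clam_id=1, z=pct * 0, pct_closure=pct)
        return g, part

    def test_two_regime_analytic_means(self):
        g, part = self._toy()
        out = gp.closure_by_regime(g, part, statistic="mean")
        assert out.loc[(1, "dark"), "mean"] == pytest.approx(15.0)
        assert out.loc[(1, "bright"), "mean"] == pytest.approx(80.0)
        assert np.isnan(out.loc[(1, "low_light"), "mean"])

    def test_constant_closure_is_constant_in_every_regime(self):
        g, part = self._toy()
        g.pct_closure = pd.Series(40.0, index=g.pct_closure.index)
        out = gp.closure_by_regime(g, part, statistic="median")
        got = out["median"].dropna()
        assert (got == 40.0).all()

    def test_pooled_equals_brute_force_subset_aggregate(self, small_sim):
        aligned = vio.align(small_sim.valve, [small_sim.env["PAR"]], 60.0, 900.0)
        part = gp.light_partition(aligned.env["PAR"])
        gapes = [
            gp.percent_closure(gp.daily_zscore(v)) for v in aligned.valve.values()
        ]
        out = gp.closure_by_regime(gapes, part, statistic="mean")
        allvals = {"dark": [], "low_light": [], "bright": []}
        for g in gapes:
            reg = part.regime_at(g.pct_closure.index).to_numpy()
            for r in allvals:
                v = g.pct_closure.to_numpy()[reg == r]
                allvals[r].append(v[np.isfinite(v)])
        for r, chunks in allvals.items():
            pooled = np.concatenate(chunks)
            assert out.loc[("pooled", r), "mean"] == pytest.approx(pooled.mean())


class TestAutoPolarity:
    def test_negative_gain_recovered(self):
        cfg = SimulationConfig(seed=21, n_days=4, n_clams=1)
        cfg.sensor.gain_mv = -800.0
        cfg.sensor.offset_mv = 3300.0
        ds = simulate_dataset(cfg)
        aligned = vio.align(ds.valve, [ds.env["PAR"]], 60.0, 900.0)
        part = gp.light_partition(aligned.env["PAR"])
        g = gp.percent_closure(
            gp.daily_zscore(aligned.valve[1], polarity="auto", partition=part)
        )
        pct = g.pct_closure
        reg = part.regime_at(pct.index).to_numpy()
        assert np.nanmedian(pct[reg == "dark"]) > np.nanmedian(pct[reg == "bright"])

    def test_auto_without_partition_is_error(self):
        with pytest.raises(ValueError, match="partition"):
            gp.daily_zscore(_one_day([1.0, 2.0, 3.0]), polarity="auto")
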