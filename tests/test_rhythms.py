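import numpy as np
import pandas as pd
import pytest

from valvometry import rhythms as rh


def _series(hours, values, dt_min=15, start="2021-05-03"):
    idx = pd.date_range(start, periods=len(values),
                        freq=pd.Timedelta(minutes=dt_min))
    return pd.Series(values, index=idx)


def _tone(days=20, dt_min=15, period_h=24.0, amp=1.0, phase_h=0.0):
    n = days * 24 * 60 // dt_min
    h = np.arange(n) * dt_min / 60.0
    idx = pd.date_range("2021-05-03", periods=n, freq=pd.Timedelta(minutes=dt_min))
    return pd.Series(amp * np.cos(2 * np.pi * (h - phase_h) / period_h), index=idx), h


class TestCwtPower:
    def test_diurnal_tone_ridge_at_24h(self):
        x, _ = _tone()
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 120))
        nearest = res.periods_h[np.argmin(np.abs(res.periods_h - 24.0))]
        assert res.peak_period_h() == pytest.approx(nearest)

    def test_two_tone_superposition_shows_both_ridges(self):
        x24, h = _tone()
        x = x24 + 0.8 * pd.Series(np.cos(2 * np.pi * h / 12.0), index=x24.index)
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 120))
        # scale-rectified spectrum (power/scale) removes the large-scale bias
        gp = res.global_power() / res.periods_h
        for target in (24.0, 12.0):
            j = np.argmin(np.abs(res.periods_h - target))
            lo, hi = max(0, j - 4), j + 5
            assert gp[lo:hi].max() > 0.4 * np.nanmax(gp)
        # both are genuine local ridges: power dips in between
        j12 = np.argmin(np.abs(res.periods_h - 12.0))
        j24 = np.argmin(np.abs(res.periods_h - 24.0))
        mid = gp[(j12 + j24) // 2]
        assert mid < gp[j12] and mid < gp[j24]

    def test_white_noise_significant_fraction_near_alpha(self):
        rng = np.random.default_rng(8)
        fracs = []
        for rep in range(3):
            idx = pd.date_range("2021-05-03", periods=12 * 144, freq="10min")
            x = pd.Series(rng.normal(size=len(idx)), index=idx)
            res = rh.cwt_power(x, n_surrogates=50, seed=rep, period_range_h=(1, 72))
            fracs.append(res.signif_mask[res.inside_coi].mean())
        assert 0.005 < np.mean(fracs) < 0.12  # Monte-Carlo band around 0.05

    def test_signif_mask_false_outside_coi(self):
        x, _ = _tone(days=10)
        res = rh.cwt_power(x, n_surrogates=20, seed=0, period_range_h=(4, 96))
        assert not res.signif_mask[~res.inside_coi].any()

    def test_heavy_gaps_are_hard_error(self):
        x, _ = _tone(days=6)
        x.iloc[: len(x) // 3] = np.nan
        with pytest.raises(ValueError, match="gap fraction"):
            rh.cwt_power(x, n_surrogates=0)

    def test_uneven_grid_is_hard_error(self):
        x, _ = _tone(days=4)
        x = x.drop(x.index[100])
        with pytest.raises(ValueError, match="evenly gridded"):
            rh.cwt_power(x, n_surrogates=0)

    def test_parseval_total_power_near_variance(self):
        # band-limited stationary series (all energy inside the analyzed
        # periods): summed wavelet power reproduces the variance; evaluated
        # on the central half of the record to avoid zero-padded edges
        x, h = _tone(days=30)
        x = x + 0.5 * pd.Series(np.cos(2 * np.pi * h / 11.0), index=x.index)
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(0.5, 240))
        ff = rh.fourier_factor()
        scales_s = res.periods_h * 3600.0 / ff
        n = res.power.shape[1]
        central = res.power[:, n // 4 : 3 * n // 4]
        total = (res.params["dj"] * res.params["dt_s"] / rh.C_DELTA
                 * np.sum(central.mean(axis=1) / scales_s))
        assert total == pytest.approx(1.0, rel=0.10)


class TestReconstruction:
    def test_band_reconstruction_recovers_tone(self):
        x, h = _tone()
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 120))
        rec = rh.reconstruct_band(res, x, (18.0, 30.0))
        r = np.corrcoef(rec.reconstructed, x)[0, 1]
        assert r > 0.95
        assert rec.residual.var() < 0.10 * x.var()

    def test_band_excluding_tone_reconstructs_almost_nothing(self):
        x, _ = _tone()
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 120))
        rec = rh.reconstruct_band(res, x, (4.0, 8.0))
        assert rec.reconstructed.var() < 0.05 * x.var()

    def test_reconstruction_plus_residual_is_exact(self):
        x, h = _tone(days=12)
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 96))
        rec = rh.reconstruct_band(res, x, (18.0, 30.0))
        np.testing.assert_allclose(
            (rec.reconstructed + rec.residual).to_numpy(), rec.original.to_numpy(),
            atol=1e-12)

    def test_empty_band_is_hard_error(self):
        x, _ = _tone(days=8)
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 96))
        with pytest.raises(ValueError, match="band"):
            rh.reconstruct_band(res, x, (0.1, 0.2))

    def test_residual_of_mixture_peaks_at_12h(self):
        x24, h = _tone()
        x = x24 + 0.6 * pd.Series(np.cos(2 * np.pi * h / 12.0), index=x24.index)
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 120))
        rec = rh.reconstruct_band(res, x, (18.0, 30.0))
        resid = rh.residual_periodicity(rec, n_surrogates=0, period_range_h=(2, 120))
        assert resid.peak_period_h() == pytest.approx(12.0, rel=0.1)

    def test_zero_residual_has_zero_power(self):
        x, _ = _tone(days=10)
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(2, 96))
        rec = rh.reconstruct_band(res, x, (18.0, 30.0))
        rec.residual[:] = 0.0
        resid = rh.residual_periodicity(rec, n_surrogates=0, period_range_h=(2, 96))
        assert np.all(resid.power == 0.0)


class TestCoherence:
    def test_self_coherence_is_one_inside_coi(self):
        x, _ = _tone()
        res = rh.wavelet_coherence(x, x, n_surrogates=0, period_range_h=(6, 96))
        j = np.argmin(np.abs(res.periods_h - 24.0))
        inside = res.periods_h[j] < res.coi_h
        assert res.coherence[j, inside].min() > 0.999
        assert abs(res.phase_at_period(24.0)) < 1e-6

    def test_antiphase_gives_pi(self):
        x, _ = _tone()
        res = rh.wavelet_coherence(x, -x, n_surrogates=0, period_range_h=(6, 96))
        assert abs(res.phase_at_period(24.0)) == pytest.approx(np.pi, abs=1e-3)

    def test_quarter_cycle_lag_gives_half_pi(self):
        a, _ = _tone()
        b, _ = _tone(phase_h=6.0)  # b lags a by 6 h of a 24-h cycle
        res = rh.wavelet_coherence(a, b, n_surrogates=0, period_range_h=(6, 96))
        assert res.phase_at_period(24.0) == pytest.approx(np.pi / 2, abs=0.1)

    def test_mismatched_grids_are_hard_error(self):
        a, _ = _tone(days=8)
        b, _ = _tone(days=8)
        b.index = b.index + pd.Timedelta(minutes=1)
        with pytest.raises(ValueError, match="grid"):
            rh.wavelet_coherence(a, b, n_surrogates=0)


class TestAgainstPyWavelets:
    def test_power_spectrum_matches_independent_cwt(self):
        """Cross-check the in-house Morlet against PyWavelets' cmor wavelet."""
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(4)
        x, h = _tone(days=15, dt_min=30)
        x = x + 0.3 * rng.normal(size=len(x))
        res = rh.cwt_power(x, n_surrogates=0, period_range_h=(4, 72))
        # cmorB-C with B=2, C=omega0/2pi reproduces the Morlet mother
        c = rh.OMEGA0 / (2 * np.pi)
        dt_h = 0.5
        scales = c * res.periods_h / dt_h
        coeffs, _ = pywt.cwt(x.to_numpy() - x.mean(), scales, f"cmor2.0-{c}",
                             sampling_period=dt_h, method="fft")
        ref_global = (np.abs(coeffs) ** 2).mean(axis=1)
        mine_global = np.nanmean(np.where(res.inside_coi, res.power, np.nan), axis=1)
        j_ref = np.argmax(ref_global)
        j_mine = np.nanargmax(mine_global)
        assert res.periods_h[j_ref] == pytest.approx(res.periods_h[j_mine], rel=0.06)
        # shape agreement: normalized spectra correlate strongly
        r = np.corrcoef(ref_global / ref_global.max(),
                        np.nan_to_num(mine_global / np.nanmax(mine_global)))[0, 1]
        assert r > 0.95
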