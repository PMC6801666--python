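"""Excess Heat Factor computation and severity classification."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import heatcross as hc
from heatcross.ehf import WARMUP_DAYS


def make_temps(tmeans, region="r", spread=10.0, start="2010-01-01"):
    dates = pd.date_range(start, periods=len(tmeans), freq="D")
    tmeans = np.asarray(tmeans, dtype=float)
    return pd.DataFrame(
        {
            "region_id": region,
            "date": dates,
            "tmax": tmeans + spread / 2,
            "tmin": tmeans - spread / 2,
        }
    )


def clim(t95, ehf85, region="r"):
    return hc.EhfClimatology(
        region, t95, ehf85, dt.date(2010, 1, 1), dt.date(2012, 12, 31)
    )


class TestDailyMean:
    def test_hand_series(self):
        temps = pd.DataFrame(
            {
                "region_id": "r",
                "date": pd.date_range("2010-01-01", periods=5),
                "tmax": [22, 24, 26, 28, 30],
                "tmin": [10, 12, 14, 16, 18],
            }
        )
        out = hc.daily_mean_series(temps)
        assert out["tmean"].tolist() == [16, 18, 20, 22, 24]

    def test_constant_identity(self):
        out = hc.daily_mean_series(make_temps([7.0] * 10, spread=0.0))
        assert (out["tmean"] == 7.0).all()

    def test_missing_value_names_date(self):
        temps = make_temps([10.0] * 5)
        temps.loc[2, "tmax"] = np.nan
        with pytest.raises(ValueError, match="2010-01-03"):
            hc.daily_mean_series(temps)

    def test_tmax_below_tmin_rejected(self):
        temps = make_temps([10.0] * 5)
        temps.loc[1, ["tmax", "tmin"]] = [5.0, 8.0]
        with pytest.raises(ValueError, match="tmax < tmin"):
            hc.daily_mean_series(temps)

    def test_date_gap_rejected(self):
        temps = make_temps([10.0] * 5)
        temps = temps.drop(index=2)
        with pytest.raises(ValueError, match="gap"):
            hc.daily_mean_series(temps)


class TestEhfComponents:
    def test_worked_example(self):
        """30 days at 18 C then (24, 26, 28): T3=26, sig=6, accl=8, EHF=48."""
        tmeans = [18.0] * 30 + [24.0, 26.0, 28.0]
        series = hc.compute_ehf_series(make_temps(tmeans), clim(t95=20.0, ehf85=10.0))
        last = series.iloc[-1]
        assert last["ehi_sig"] == pytest.approx(6.0)
        assert last["ehi_accl"] == pytest.approx(8.0)
        assert last["ehf"] == pytest.approx(48.0)

    def test_warmup_window_undefined(self):
        series = hc.compute_ehf_series(make_temps([15.0] * 40), clim(15.0, 1.0))
        assert series["ehf"].iloc[:WARMUP_DAYS].isna().all()
        assert series["ehf"].iloc[WARMUP_DAYS:].notna().all()

    def test_constant_series_is_zero(self):
        series = hc.compute_ehf_series(make_temps([20.0] * 60), clim(t95=20.0, ehf85=1.0))
        defined = series.iloc[WARMUP_DAYS:]
        assert (defined["ehi_sig"] == 0).all()
        assert (defined["ehi_accl"] == 0).all()
        assert (defined["ehf"] == 0).all()

    def test_acclimatized_floor(self):
        """Whenever EHI_accl <= 1 the max(1, .) floor makes EHF = EHI_sig."""
        rng = np.random.default_rng(0)
        tmeans = 15 + rng.normal(0, 3, size=400)
        series = hc.compute_ehf_series(make_temps(tmeans), clim(t95=16.0, ehf85=1.0))
        sub = series[series["ehi_accl"] <= 1].dropna(subset=["ehf"])
        assert len(sub) > 10
        np.testing.assert_allclose(sub["ehf"], sub["ehi_sig"], rtol=1e-12)

    def test_region_mismatch(self):
        with pytest.raises(ValueError, match="no climatology"):
            hc.compute_ehf_series(make_temps([15.0] * 40, region="other"), clim(15.0, 1.0))

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="at least"):
            hc.compute_ehf_series(make_temps([15.0] * 20), clim(15.0, 1.0))


class TestClimatology:
    def _sinusoid(self, n=1200, seed=5, region="r"):
        rng = np.random.default_rng(seed)
        t = np.arange(n)
        tmean = 13 + 6 * np.cos(2 * np.pi * (t - 15) / 365.25) + rng.normal(0, 2.5, n)
        tmean[200:204] += 12  # injected heat episode
        tmean[600:604] += 12
        return make_temps(tmean, region=region)

    def test_matches_brute_force_percentiles(self):
        """t95 and ehf85 equal an independently coded two-pass computation."""
        temps = self._sinusoid()
        fit = hc.fit_climatology(temps)["r"]
        tmean = ((temps["tmax"] + temps["tmin"]) / 2).to_numpy()
        t95 = np.percentile(tmean, 95)
        ehf = []
        for i in range(32, len(tmean)):  # naive loops, independent of the library path
            t3 = tmean[i - 2 : i + 1].mean()
            t30 = tmean[i - 32 : i - 2].mean()
            ehf.append((t3 - t95) * max(1.0, t3 - t30))
        positive = [v for v in ehf if v > 0]
        assert fit.t95 == pytest.approx(t95, abs=1e-12)
        assert fit.ehf85 == pytest.approx(np.percentile(positive, 85), abs=1e-12)

    def test_constant_series_has_no_heat_events(self):
        with pytest.raises(ValueError, match="no heat events"):
            hc.fit_climatology(make_temps([15.0] * 1100))

    def test_short_reference_window_rejected(self):
        with pytest.raises(ValueError, match="at least 730"):
            hc.fit_climatology(self._sinusoid(n=400))

    def test_translation_property(self):
        """Shifting all temperatures by +c shifts t95 by c; EHI_accl and a
        refit EHI_sig are unchanged, so the EHF series is unchanged too."""
        temps = self._sinusoid()
        shifted = temps.assign(tmax=temps["tmax"] + 3.0, tmin=temps["tmin"] + 3.0)
        c0 = hc.fit_climatology(temps)["r"]
        c1 = hc.fit_climatology(shifted)["r"]
        assert c1.t95 == pytest.approx(c0.t95 + 3.0)
        s0 = hc.compute_ehf_series(temps, c0)
        s1 = hc.compute_ehf_series(shifted, c1)
        np.testing.assert_allclose(s0["ehi_accl"], s1["ehi_accl"], atol=1e-9)
        np.testing.assert_allclose(s0["ehi_sig"], s1["ehi_sig"], atol=1e-9)
        np.testing.assert_allclose(s0["ehf"], s1["ehf"], atol=1e-9)

    def test_forward_orientation_differs_but_same_thresholding(self):
        temps = self._sinusoid()
        fwd = hc.fit_climatology(temps, orientation="forward")["r"]
        bwd = hc.fit_climatology(temps)["r"]
        assert fwd.t95 == bwd.t95  # pass 1 identical
        assert fwd.ehf85 > 0 and bwd.ehf85 > 0


class TestSeverity:
    def test_threshold_bands(self):
        """With ehf85=10: (5, 10, 29.9, 30) -> low, severe, severe, extreme."""
        series = pd.DataFrame(
            {
                "region_id": "r",
                "date": pd.date_range("2010-01-01", periods=4),
                "ehf": [5.0, 10.0, 29.9, 30.0],
            }
        )
        out = hc.classify_severity(series, clim(t95=20.0, ehf85=10.0))
        assert out["severity"].astype(str).tolist() == ["low", "severe", "severe", "extreme"]

    def test_nonpositive_and_undefined_are_none(self):
        series = pd.DataFrame(
            {
                "region_id": "r",
                "date": pd.date_range("2010-01-01", periods=3),
                "ehf": [0.0, -4.0, np.nan],
            }
        )
        out = hc.classify_severity(series, clim(20.0, 10.0))
        assert (out["severity"].astype(str) == "none").all()

    def test_extreme_boundary_is_exactly_three_times_severe(self):
        c = clim(20.0, 7.5)
        assert c.extreme_threshold == pytest.approx(3 * c.ehf85)
        series = pd.DataFrame(
            {"region_id": "r", "date": [pd.Timestamp("2010-01-01")], "ehf": [22.5]}
        )
        out = hc.classify_severity(series, c)
        assert out["severity"].astype(str).iloc[0] == "extreme"

    def test_monotone_in_ehf(self):
        rng = np.random.default_rng(1)
        ehf = np.sort(rng.uniform(-5, 50, 200))
        series = pd.DataFrame(
            {
                "region_id": "r",
                "date": pd.date_range("2010-01-01", periods=200),
                "ehf": ehf,
            }
        )
        out = hc.classify_severity(series, clim(20.0, 10.0))
        codes = out["severity"].cat.codes.to_numpy()
        assert (np.diff(codes) >= 0).all()


class TestCalendar:
    def test_exposed_means_severe_or_extreme(self):
        series = pd.DataFrame(
            {
                "region_id": "r",
                "date": pd.date_range("2010-01-01", periods=4),
                "ehf": [5.0, 15.0, 40.0, 0.0],
            }
        )
        cal = hc.heatwave_calendar(hc.classify_severity(series, clim(20.0, 10.0)))
        assert cal["exposed"].tolist() == [False, True, True, False]
        counts = hc.severity_day_counts(cal)
        assert counts.iloc[0][["low_days", "severe_days", "extreme_days"]].tolist() == [1, 1, 1]

    def test_null_calendar(self):
        series = pd.DataFrame(
            {
                "region_id": "r",
                "date": pd.date_range("2010-01-01", periods=3),
                "ehf": [0.0, -1.0, np.nan],
            }
        )
        cal = hc.heatwave_calendar(hc.classify_severity(series, clim(20.0, 10.0)))
        assert not cal["exposed"].any()
        counts = hc.severity_day_counts(cal)
        assert counts.iloc[0][["low_days", "severe_days", "extreme_days"]].sum() == 0

    def test_counts_match_brute_tally(self, small_study):
        _, study = small_study
        cal = study["calendar"]
        counts = hc.severity_day_counts(cal)
        for _, row in counts.iterrows():
            sev = cal.loc[cal["region_id"] == row["region_id"], "severity"].astype(str)
            assert row["low_days"] == sum(1 for s in sev if s == "low")
            assert row["severe_days"] == sum(1 for s in sev if s == "severe")
            assert row["extreme_days"] == sum(1 for s in sev if s == "extreme")

    def test_deterministic(self):
        temps = make_temps([18.0] * 30 + [24.0, 26.0, 28.0] + [18.0] * 10)
        c = clim(20.0, 10.0)
        one = hc.heatwave_calendar(hc.classify_severity(hc.compute_ehf_series(temps, c), c))
        two = hc.heatwave_calendar(hc.classify_severity(hc.compute_ehf_series(temps, c), c))
        pd.testing.assert_frame_equal(one, two)
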