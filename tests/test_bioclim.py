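"""Bioclim derivation: aggregation, the 19 variables, annual series, IDW."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

from climenv import annual_bioclim_series, compute_bioclim, idw_interpolate
from climenv.bioclim import (
    BIOCLIM_VARS,
    IncompleteMonthError,
    PRECIP_SCALE_VARS,
    TEMP_SHIFT_INVARIANT,
    TEMP_SHIFT_VARS,
    aggregate_to_monthly,
)
from oracles import bioclim_oracle, idw_oracle


def _hourly(temp: np.ndarray, prcp: np.ndarray, start="2001-01-01") -> xr.Dataset:
    time = pd.date_range(start, periods=temp.size, freq="h")
    return xr.Dataset(
        {"temp": ("time", temp), "prcp": ("time", prcp)},
        coords={"time": time},
    )


def _random_year(rng) -> tuple[np.ndarray, ...]:
    tmean = rng.normal(8, 7, 12)
    tmin = tmean - np.abs(rng.normal(4, 1, 12))
    tmax = tmean + np.abs(rng.normal(4, 1, 12))
    prcp = np.abs(rng.normal(60, 25, 12))
    return tmin, tmax, tmean, prcp


class TestAggregateToMonthly:
    def test_constant_series(self):
        n = 24 * 31 + 24 * 28  # Jan + Feb 2001, hourly
        ds = _hourly(np.full(n, 5.0), np.zeros(n))
        out = aggregate_to_monthly(ds)
        for v in ("tmin", "tmax", "tmean"):
            np.testing.assert_allclose(out[v].values, 5.0)

    def test_precip_totals_are_sums(self):
        n = 720
        ds = _hourly(np.zeros(n), np.full(n, 0.1), start="2001-04-01")
        out = aggregate_to_monthly(ds)
        np.testing.assert_allclose(out["prcp"].values[0], 72.0)

    def test_sinusoid_extremes_and_mean(self):
        n = 24 * 31
        t = np.arange(n)
        temp = 3.0 + 6.0 * np.sin(2 * np.pi * t / 24.0)
        ds = _hourly(temp, np.zeros(n))
        out = aggregate_to_monthly(ds)
        assert out["tmin"].values[0] == pytest.approx(-3.0, abs=0.05)
        assert out["tmax"].values[0] == pytest.approx(9.0, abs=0.05)
        assert out["tmean"].values[0] == pytest.approx(3.0, abs=0.05)

    def test_missing_month_named_in_error(self):
        time = pd.DatetimeIndex(
            list(pd.date_range("2001-01-01", periods=24, freq="h"))
            + list(pd.date_range("2001-03-01", periods=24, freq="h"))
        )
        ds = xr.Dataset(
            {"temp": ("time", np.zeros(48)), "prcp": ("time", np.zeros(48))},
            coords={"time": time},
        )
        with pytest.raises(IncompleteMonthError, match="2001-02"):
            aggregate_to_monthly(ds)


class TestComputeBioclim:
    def test_constant_temperature(self):
        tmean = np.full(12, 10.0)
        out = compute_bioclim(tmean - 1, tmean + 1, tmean, np.full(12, 50.0))
        assert out["bio01"] == pytest.approx(10.0)
        assert out["bio04"] == pytest.approx(0.0)

    def test_isothermality_is_ratio_of_ranges(self):
        # monthly diurnal range 10 everywhere; annual range 40
        tmean = np.linspace(-10, 25, 12)
        tmin = tmean - 5.0
        tmax = tmean + 5.0
        out = compute_bioclim(tmin, tmax, tmean, np.full(12, 10.0))
        assert out["bio02"] == pytest.approx(10.0)
        if out["bio07"] != 0:
            assert out["bio03"] == pytest.approx(100.0 * out["bio02"] / out["bio07"])

    def test_bio3_flagged_undefined_when_range_zero(self):
        tmean = np.full(12, 4.0)
        out = compute_bioclim(tmean, tmean, tmean, np.full(12, 10.0))
        assert out["bio07"] == 0.0
        assert np.isnan(out["bio03"])
        assert bool(out["bio03_undefined"])

    def test_matches_bruteforce_oracle_on_random_years(self, rng):
        for _ in range(120):
            tmin, tmax, tmean, prcp = _random_year(rng)
            ours = compute_bioclim(tmin, tmax, tmean, prcp)
            ref = bioclim_oracle(tmin, tmax, tmean, prcp)
            for v in BIOCLIM_VARS:
                assert ours[v] == pytest.approx(ref[v], abs=1e-9), v

    def test_internal_identities(self, rng):
        for _ in range(50):
            tmin, tmax, tmean, prcp = _random_year(rng)
            out = compute_bioclim(tmin, tmax, tmean, prcp)
            assert out["bio07"] == pytest.approx(out["bio05"] - out["bio06"], abs=1e-9)
            assert out["bio05"] >= out["bio06"]
            assert out["bio13"] >= out["bio14"] >= 0
            assert out["bio16"] >= out["bio17"] >= 0
            assert out["bio12"] >= 0 and out["bio04"] >= 0 and out["bio15"] >= 0

    def test_incomplete_year_rejected(self):
        x = np.zeros(11)
        with pytest.raises(ValueError, match="12 months"):
            compute_bioclim(x, x, x, x)

    @given(shift=st.floats(-20, 20), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_temperature_shift_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        tmin, tmax, tmean, prcp = _random_year(rng)
        base = compute_bioclim(tmin, tmax, tmean, prcp)
        shifted = compute_bioclim(tmin + shift, tmax + shift, tmean + shift, prcp)
        for v in TEMP_SHIFT_VARS:
            assert shifted[v] == pytest.approx(base[v] + shift, abs=1e-9)
        for v in TEMP_SHIFT_INVARIANT:
            assert shifted[v] == pytest.approx(base[v], abs=1e-9)

    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_precipitation_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        tmin, tmax, tmean, prcp = _random_year(rng)
        base = compute_bioclim(tmin, tmax, tmean, prcp)
        scaled = compute_bioclim(tmin, tmax, tmean, prcp * scale)
        for v in PRECIP_SCALE_VARS:
            assert scaled[v] == pytest.approx(base[v] * scale, rel=1e-9)
        # BIO15 is scale-free except for the +1 mm arid guard: bound the error
        m = prcp.mean()
        expected = base["bio15"] * (m + 1.0) / (m + 1.0 / scale)
        assert scaled["bio15"] == pytest.approx(expected, rel=1e-9)


class TestAnnualSeries:
    def test_identical_years_identical_vectors(self):
        months = pd.date_range("1990-01-01", periods=360, freq="MS")
        one = np.tile(np.linspace(-5, 15, 12), 30)
        ds = xr.Dataset(
            {"tmin": ("time", one - 4), "tmax": ("time", one + 4),
             "tmean": ("time", one), "prcp": ("time", np.tile(np.full(12, 50.0), 30))},
            coords={"time": months},
        )
        out = annual_bioclim_series(ds)
        assert out.sizes["year"] == 30
        for v in BIOCLIM_VARS:
            np.testing.assert_allclose(out[v].values, out[v].values[0])

    def test_uniform_offset_year_shifts_bio1_only(self, small_climate):
        ds = small_climate.copy(deep=True)
        years = ds["time"].dt.year.values
        target = years == 2002
        for v in ("tmin", "tmax", "tmean"):
            vals = ds[v].values.copy()
            vals[target] += 2.0
            ds[v] = (ds[v].dims, vals, ds[v].attrs)
        base = annual_bioclim_series(small_climate)
        bumped = annual_bioclim_series(ds)
        i = list(base["year"].values).index(2002)
        np.testing.assert_allclose(
            bumped["bio01"].values[i], base["bio01"].values[i] + 2.0, atol=1e-9
        )
        np.testing.assert_allclose(
            bumped["bio04"].values[i], base["bio04"].values[i], atol=1e-9
        )

    def test_composition_with_single_year_calls(self, small_climate, small_bioclim):
        years = small_climate["time"].dt.year.values
        for k, y in enumerate(small_bioclim["year"].values):
            sel = small_climate.isel(time=np.flatnonzero(years == y))
            vec = compute_bioclim(
                sel["tmin"].values, sel["tmax"].values,
                sel["tmean"].values, sel["prcp"].values,
            )
            for v in BIOCLIM_VARS:
                np.testing.assert_allclose(
                    small_bioclim[v].values[k], vec[v], atol=1e-12
                )

    def test_partial_years_dropped_with_warning(self, small_climate, caplog):
        trimmed = small_climate.isel(time=slice(3, None))  # 2000 now partial
        with caplog.at_level("WARNING"):
            out = annual_bioclim_series(trimmed)
        assert 2000 not in out["year"].values
        assert any("incomplete" in r.message for r in caplog.records)


class TestIDW:
    def test_exact_at_sample_location(self):
        samples = pd.DataFrame(
            {"lon": [5.0, 6.0], "lat": [50.0, 51.0], "value": [3.0, 9.0]}
        )
        out = idw_interpolate(samples, np.array([50.0]), np.array([5.0]))
        assert out[0, 0] == 3.0

    def test_equidistant_symmetry(self):
        samples = pd.DataFrame(
            {"lon": [4.0, 6.0], "lat": [50.0, 50.0], "value": [0.0, 10.0]}
        )
        out = idw_interpolate(samples, np.array([50.0]), np.array([5.0]))
        assert out[0, 0] == pytest.approx(5.0, abs=1e-9)

    def test_matches_direct_formula_oracle(self, rng):
        lat = rng.uniform(45, 55, 20)
        lon = rng.uniform(0, 10, 20)
        val = rng.normal(0, 5, 20)
        samples = pd.DataFrame({"lon": lon, "lat": lat, "value": val})
        t_lat, t_lon = 50.3, 4.7
        out = idw_interpolate(samples, np.array([t_lat]), np.array([t_lon]),
                              power=2.0, k_neighbors=20)
        ref = idw_oracle(lat, lon, val, t_lat, t_lon, 2.0, 20)
        assert out[0, 0] == pytest.approx(ref, abs=1e-12)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate(pd.DataFrame(columns=["lon", "lat", "value"]),
                            np.array([50.0]), np.array([5.0]))
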