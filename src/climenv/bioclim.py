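"""Bioclimatic variables (BIO1-BIO19) from monthly climate, plus IDW gridding.

The 19 variables are the standard annual summaries of monthly temperature and
precipitation used in ecological niche modelling: annual means and extremes,
seasonality indices, and aggregates over the wettest/driest/warmest/coldest
quarter.  Quarters here are any 3 consecutive calendar months *including
wrap-around* (Nov-Dec-Jan, Dec-Jan-Feb), the convention of the dominant
bioclim implementation lineage; ties between candidate quarters are broken by
the earliest starting month.

Variables and units:

====== ================================================== =====
BIO1   Annual mean temperature                            degC
BIO2   Mean diurnal range, mean of monthly (tmax - tmin)  degC
BIO3   Isothermality, 100 * BIO2 / BIO7                   --
BIO4   Temperature seasonality, 100 * sd(monthly tmean)   degC
BIO5   Max temperature of the warmest month               degC
BIO6   Min temperature of the coldest month               degC
BIO7   Temperature annual range, BIO5 - BIO6              degC
BIO8   Mean temperature of the wettest quarter            degC
BIO9   Mean temperature of the driest quarter             degC
BIO10  Mean temperature of the warmest quarter            degC
BIO11  Mean temperature of the coldest quarter            degC
BIO12  Annual precipitation                               mm
BIO13  Precipitation of the wettest month                 mm
BIO14  Precipitation of the driest month                  mm
BIO15  Precipitation seasonality, 100 * sd / (mean + 1)   --
BIO16  Precipitation of the wettest quarter               mm
BIO17  Precipitation of the driest quarter                mm
BIO18  Precipitation of the warmest quarter               mm
BIO19  Precipitation of the coldest quarter               mm
====== ================================================== =====

Standard deviations use the n-1 (sample) convention.  BIO15 is the
coefficient of variation of monthly precipitation with a +1 mm guard in the
denominator for arid cells; the conventional sd/mean orientation is used.
When BIO7 is zero BIO3 is undefined: it is reported as NaN and flagged
explicitly rather than silently propagated.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.neighbors import BallTree

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: canonical variable names, bio01..bio19
BIOCLIM_VARS = [f"bio{i:02d}" for i in range(1, 20)]

BIOCLIM_UNITS = {
    **{v: "degC" for v in ("bio01", "bio02", "bio04", "bio05", "bio06",
                           "bio07", "bio08", "bio09", "bio10", "bio11")},
    "bio03": "1",
    "bio15": "1",
    **{v: "mm" for v in ("bio12", "bio13", "bio14", "bio16", "bio17",
                         "bio18", "bio19")},
}

#: variables that shift by +c under a uniform +c degC temperature shift
TEMP_SHIFT_VARS = ["bio01", "bio05", "bio06", "bio08", "bio09", "bio10", "bio11"]
#: variables invariant under a uniform temperature shift
TEMP_SHIFT_INVARIANT = ["bio02", "bio04", "bio07"]
#: variables that scale by s under uniform precipitation scaling
PRECIP_SCALE_VARS = ["bio12", "bio13", "bio14", "bio16", "bio17", "bio18", "bio19"]

_QUARTER_WINDOWS = [(m, (m + 1) % 12, (m + 2) % 12) for m in range(12)]


class IncompleteMonthError(ValueError):
    """A calendar month in the aggregation window has no data."""


def aggregate_to_monthly(series: xr.Dataset) -> xr.Dataset:
    """Aggregate a sub-monthly series to the four monthly variables.

    ``series`` must contain ``temp`` (degC per step) and ``prcp`` (mm per
    step) on a ``time`` axis resolvable to calendar months.  The monthly
    output is ``tmin``/``tmax`` (extremes of the steps), ``tmean``
    (arithmetic mean) and ``prcp`` (sum).
    """
    for v in ("temp", "prcp"):
        if v not in series.data_vars:
            raise KeyError(f"input series must contain variable {v!r}")
    grouper = series.resample(time="MS")
    counts = grouper.count()
    n = counts["temp"].fillna(0).values  # empty bins surface as NaN
    empty = ~(n > 0)
    if np.any(empty):
        months = pd.DatetimeIndex(counts["time"].values[
            np.argwhere(empty)[:, 0]
        ])
        where = ""
        if "lat" in counts.dims:
            where = " (gridded input)"
        raise IncompleteMonthError(
            f"months with no data{where}: "
            + ", ".join(m.strftime("%Y-%m") for m in months[:5])
        )
    out = xr.Dataset(
        {
            "tmin": series["temp"].resample(time="MS").min(),
            "tmax": series["temp"].resample(time="MS").max(),
            "tmean": series["temp"].resample(time="MS").mean(),
            "prcp": series["prcp"].resample(time="MS").sum(),
        }
    )
    for v, u in (("tmin", "degC"), ("tmax", "degC"), ("tmean", "degC"),
                 ("prcp", "mm")):
        out[v].attrs["units"] = u
    return out


def compute_bioclim(
    tmin: np.ndarray,
    tmax: np.ndarray,
    tmean: np.ndarray,
    prcp: np.ndarray,
) -> dict[str, np.ndarray]:
    """Compute all 19 bioclim values for one calendar year.

    Inputs are arrays with the 12 months on the leading axis; any trailing
    shape (scalar, grid, ...) is broadcast through.  Returns a dict keyed
    ``bio01``..``bio19`` plus ``bio03_undefined``, a boolean mask flagging
    cells where BIO7 = 0 makes isothermality undefined (BIO3 is NaN there).
    """
    arrs = [np.asarray(a, dtype=float) for a in (tmin, tmax, tmean, prcp)]
    tmin, tmax, tmean, prcp = arrs
    for a in arrs:
        if a.shape[0] != 12:
            raise ValueError("a complete year of 12 months is required on axis 0")
        if a.shape != arrs[0].shape:
            raise ValueError("tmin/tmax/tmean/prcp must share one shape")

    out: dict[str, np.ndarray] = {}
    out["bio01"] = tmean.mean(axis=0)
    out["bio02"] = (tmax - tmin).mean(axis=0)
    out["bio04"] = tmean.std(axis=0, ddof=1) * 100.0
    out["bio05"] = tmax.max(axis=0)
    out["bio06"] = tmin.min(axis=0)
    out["bio07"] = out["bio05"] - out["bio06"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio03 = 100.0 * out["bio02"] / out["bio07"]
    undefined = np.asarray(out["bio07"] == 0)
    if np.any(undefined):
        logger.warning(
            "BIO3 undefined (BIO7 = 0) for %d cell(s); reported as NaN with flag",
            int(undefined.sum()),
        )
    out["bio03"] = np.where(undefined, np.nan, bio03)

    out["bio12"] = prcp.sum(axis=0)
    out["bio13"] = prcp.max(axis=0)
    out["bio14"] = prcp.min(axis=0)
    out["bio15"] = 100.0 * prcp.std(axis=0, ddof=1) / (prcp.mean(axis=0) + 1.0)

    # quarter aggregates over all 12 wrap-around 3-month windows
    q_t = np.stack([tmean[list(w)].mean(axis=0) for w in _QUARTER_WINDOWS])
    q_p = np.stack([prcp[list(w)].sum(axis=0) for w in _QUARTER_WINDOWS])
    wettest = q_p.argmax(axis=0)  # argmax/argmin take the first max: earliest month
    driest = q_p.argmin(axis=0)
    warmest = q_t.argmax(axis=0)
    coldest = q_t.argmin(axis=0)

    def _take(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None, ...], axis=0)[0]

    out["bio08"] = _take(q_t, wettest)
    out["bio09"] = _take(q_t, driest)
    out["bio10"] = _take(q_t, warmest)
    out["bio11"] = _take(q_t, coldest)
    out["bio16"] = _take(q_p, wettest)
    out["bio17"] = _take(q_p, driest)
    out["bio18"] = _take(q_p, warmest)
    out["bio19"] = _take(q_p, coldest)
    out["bio03_undefined"] = undefined
    return out


def annual_bioclim_series(monthly: xr.Dataset) -> xr.Dataset:
    """Per-calendar-year bioclim vectors from a multi-year monthly series.

    Partial leading/trailing years are dropped with a warning.  No smoothing
    across years: each year is summarised independently, so the per-year
    values are exactly what the exceedance stage consumes.
    """
    years = monthly["time"].dt.year.values
    months = monthly["time"].dt.month.values
    uniq = np.unique(years)
    complete = [y for y in uniq if np.sum(years == y) == 12
                and set(months[years == y]) == set(range(1, 13))]
    dropped = sorted(set(uniq.tolist()) - set(complete))
    if dropped:
        logger.warning("dropping incomplete calendar years: %s", dropped)
    if not complete:
        raise ValueError("no complete calendar year in series")

    spatial_dims = [d for d in monthly["tmean"].dims if d != "time"]
    per_year = {v: [] for v in BIOCLIM_VARS}
    for y in complete:
        sel = monthly.isel(time=np.flatnonzero(years == y))
        order = np.argsort(sel["time"].dt.month.values)
        vec = compute_bioclim(
            sel["tmin"].values[order],
            sel["tmax"].values[order],
            sel["tmean"].values[order],
            sel["prcp"].values[order],
        )
        for v in BIOCLIM_VARS:
            per_year[v].append(vec[v])

    coords = {"year": np.asarray(complete)}
    for d in spatial_dims:
        coords[d] = monthly[d].values
    ds = xr.Dataset(
        {
            v: (("year", *spatial_dims), np.stack(per_year[v]),
                {"units": BIOCLIM_UNITS[v]})
            for v in BIOCLIM_VARS
        },
        coords=coords,
    )
    return ds


def climatology(bioclim_years: xr.Dataset) -> xr.Dataset:
    """Mean over years of an annual bioclim series (the historical raster)."""
    out = bioclim_years.mean(dim="year", keep_attrs=True)
    return out


def idw_interpolate(
    samples: pd.DataFrame,
    target_lats: np.ndarray,
    target_lons: np.ndarray,
    power: float = 2.0,
    k_neighbors: int = 12,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation onto a regular grid.

    ``samples`` needs columns ``lon, lat, value``.  Weights are
    ``d**(-power)`` over the ``k_neighbors`` nearest samples, with
    great-circle (haversine) distances in km; a target coinciding with a
    sample (distance < 1 m) returns that sample's value exactly.
    Returns an array of shape ``(len(target_lats), len(target_lons))``.
    """
    if len(samples) == 0:
        raise ValueError("at least one sample is required")
    if power <= 0:
        raise ValueError("power must be positive")
    k = int(min(k_neighbors, len(samples)))
    pts = np.deg2rad(samples[["lat", "lon"]].to_numpy(dtype=float))
    vals = samples["value"].to_numpy(dtype=float)
    tree = BallTree(pts, metric="haversine")
    lon2d, lat2d = np.meshgrid(np.asarray(target_lons), np.asarray(target_lats))
    targets = np.deg2rad(np.column_stack([lat2d.ravel(), lon2d.ravel()]))
    dist, idx = tree.query(targets, k=k)
    dist_km = dist * EARTH_RADIUS_KM
    exact = dist_km[:, 0] < 1e-3  # within one metre: take the sample itself
    with np.errstate(divide="ignore"):
        w = dist_km ** (-power)
    w[~np.isfinite(w)] = 0.0
    num = (w * vals[idx]).sum(axis=1)
    den = w.sum(axis=1)
    out = np.empty(len(targets))
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[~nz] = vals[idx[~nz, 0]]
    out[exact] = vals[idx[exact, 0]]
    return out.reshape(lat2d.shape)


def bioclim_table(vec: Mapping[str, float]) -> pd.Series:
    """One bioclim vector as a labelled Series (bio01..bio19)."""
    return pd.Series({v: float(np.asarray(vec[v])) for v in BIOCLIM_VARS})
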