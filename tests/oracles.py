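"""Independent brute-force oracles used by the tests.

Deliberately naive implementations — explicit loops, direct formulas — kept
separate from the package so the tests compare two independently coded
paths.
"""

from __future__ import annotations

import math

import numpy as np


def bioclim_oracle(tmin, tmax, tmean, prcp) -> dict[str, float]:
    """All 19 bioclim values for one cell-year, by explicit enumeration.

    Quarter aggregates loop over all 12 wrap-around 3-month windows and
    track the best window with earliest-start tie-breaking.
    """
    tmin = [float(v) for v in tmin]
    tmax = [float(v) for v in tmax]
    tmean = [float(v) for v in tmean]
    prcp = [float(v) for v in prcp]
    assert len(tmin) == len(tmax) == len(tmean) == len(prcp) == 12

    def mean(xs):
        return sum(xs) / len(xs)

    def sd(xs):  # sample standard deviation
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    out = {}
    out["bio01"] = mean(tmean)
    out["bio02"] = mean([tmax[i] - tmin[i] for i in range(12)])
    out["bio04"] = sd(tmean) * 100.0
    out["bio05"] = max(tmax)
    out["bio06"] = min(tmin)
    out["bio07"] = out["bio05"] - out["bio06"]
    out["bio03"] = (100.0 * out["bio02"] / out["bio07"]
                    if out["bio07"] != 0 else float("nan"))
    out["bio12"] = sum(prcp)
    out["bio13"] = max(prcp)
    out["bio14"] = min(prcp)
    out["bio15"] = 100.0 * sd(prcp) / (mean(prcp) + 1.0)

    # enumerate all wrap-around quarters; earliest start wins ties
    q_temp, q_prec = [], []
    for start in range(12):
        months = [start % 12, (start + 1) % 12, (start + 2) % 12]
        q_temp.append(mean([tmean[m] for m in months]))
        q_prec.append(sum(prcp[m] for m in months))

    def argbest(values, want_max):
        best = 0
        for i in range(1, 12):
            if (values[i] > values[best]) if want_max else (values[i] < values[best]):
                best = i
        return best

    wettest = argbest(q_prec, True)
    driest = argbest(q_prec, False)
    warmest = argbest(q_temp, True)
    coldest = argbest(q_temp, False)
    out["bio08"] = q_temp[wettest]
    out["bio09"] = q_temp[driest]
    out["bio10"] = q_temp[warmest]
    out["bio11"] = q_temp[coldest]
    out["bio16"] = q_prec[wettest]
    out["bio17"] = q_prec[driest]
    out["bio18"] = q_prec[warmest]
    out["bio19"] = q_prec[coldest]
    return out


def idw_oracle(samples_lat, samples_lon, values, t_lat, t_lon, power, k):
    """Direct-sum IDW at one target with haversine distances in km."""
    r = 6371.0

    def hav(lat1, lon1, lat2, lon2):
        p1, p2 = math.radians(lat1), math.radians(lat2)
        dphi = p2 - p1
        dlmb = math.radians(lon2 - lon1)
        a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
        return 2 * r * math.asin(math.sqrt(a))

    d = [hav(t_lat, t_lon, la, lo) for la, lo in zip(samples_lat, samples_lon)]
    order = sorted(range(len(d)), key=lambda i: d[i])[:k]
    for i in order:
        if d[i] == 0:
            return values[i]
    num = sum(values[i] * d[i] ** (-power) for i in order)
    den = sum(d[i] ** (-power) for i in order)
    return num / den


def two_predictor_regression_oracle(x1, x2, y):
    """Normal-equations solution for y ~ x1 + x2 (all centred), plus R^2."""
    x1 = np.asarray(x1, float) - np.mean(x1)
    x2 = np.asarray(x2, float) - np.mean(x2)
    y = np.asarray(y, float)
    y = (y - y.mean()) / y.std(ddof=1)
    s11, s22 = x1 @ x1, x2 @ x2
    s12 = x1 @ x2
    g1, g2 = x1 @ y, x2 @ y
    det = s11 * s22 - s12 * s12
    b1 = (s22 * g1 - s12 * g2) / det
    b2 = (s11 * g2 - s12 * g1) / det
    resid = y - b1 * x1 - b2 * x2
    r2 = 1.0 - (resid @ resid) / (y @ y)
    return b1, b2, r2


def gwl_window_scan_oracle(years, anomaly, level, window, tol):
    """Brute-force scan: the set of years inside any matching window."""
    pooled = set()
    for i in range(len(years) - window + 1):
        m = sum(anomaly[i:i + window]) / window
        if abs(m - level) <= tol:
            pooled.update(years[i:i + window])
    return pooled
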