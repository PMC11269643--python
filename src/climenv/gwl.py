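"""Global-warming-level (GWL) time sampling of ensemble runs.

Instead of analysing fixed emission scenarios, future periods are indexed by
the global mean surface temperature (GMST) anomaly they represent relative
to the 1850-1900 pre-industrial baseline.  For each warming level (default
1.2 "reference", 1.5, 2.0, 2.5 and 3.0 degC) every 30-year window of a run
whose mean anomaly falls within a tolerance of the level is kept, and the
member years of all matching windows are pooled (deduplicated within a run)
across runs and models.  Pooling years rather than windows avoids double
counting in the exceedance frequencies downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import EnsembleRun

logger = logging.getLogger(__name__)

__all__ = [
    "GWLSpec",
    "GWLWindow",
    "gmst_anomaly",
    "find_gwl_windows",
    "pooled_years",
    "pool_gwl_years",
]

#: the level labelled "(ref)" in outputs
REFERENCE_LEVEL = 1.2


@dataclass(frozen=True)
class GWLSpec:
    """Warming levels, anomaly baseline, window length and match tolerance."""

    levels: tuple[float, ...] = (1.2, 1.5, 2.0, 2.5, 3.0)
    baseline: tuple[int, int] = (1850, 1900)
    window: int = 30
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        lv = list(self.levels)
        if not lv or any(l <= 0 for l in lv) or sorted(lv) != lv or len(set(lv)) != len(lv):
            raise ValueError("levels must be positive and strictly increasing")
        if self.window < 1:
            raise ValueError("window must be >= 1 year")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def label(self, level: float) -> str:
        return f"{level:g} (ref)" if level == REFERENCE_LEVEL else f"{level:g}"


@dataclass(frozen=True)
class GWLWindow:
    """One consecutive-year window of a run matching a warming level."""

    model: str
    run: str
    level: float
    years: tuple[int, ...]
    mean_anomaly: float


def gmst_anomaly(
    gmst: pd.Series,
    baseline: tuple[int, int] = (1850, 1900),
    proxy_baseline_years: int | None = None,
) -> pd.Series:
    """GMST anomaly relative to the mean over the baseline years.

    If the series does not cover the baseline period, a proxy baseline over
    the first ``proxy_baseline_years`` of the series may be declared
    (flagged in the result's attrs); otherwise this is an error.
    """
    years = np.asarray(gmst.index, dtype=int)
    lo, hi = baseline
    mask = (years >= lo) & (years <= hi)
    used_proxy = False
    if not mask.any():
        if proxy_baseline_years is None:
            raise ValueError(
                f"GMST series ({years.min()}-{years.max()}) does not cover the "
                f"baseline {lo}-{hi}; declare a proxy baseline"
            )
        mask = years < years.min() + proxy_baseline_years
        used_proxy = True
        logger.info("using proxy baseline: first %d years of the series",
                    proxy_baseline_years)
    ref = float(gmst[mask].mean())
    anom = gmst - ref
    anom.name = "gmst_anomaly"
    anom.attrs = {"baseline_mean": ref, "proxy_baseline": used_proxy}
    return anom


def find_gwl_windows(
    anomaly: pd.Series,
    spec: GWLSpec,
    model: str = "",
    run: str = "",
) -> dict[float, list[GWLWindow]]:
    """All windows of ``spec.window`` consecutive years matching each level.

    A window matches level L when |mean anomaly - L| <= tolerance.  Every
    matching window is returned; overlapping windows are pooled into year
    sets by :func:`pooled_years`.  An empty result for a level is allowed
    (e.g. a run that never reaches it).
    """
    years = np.asarray(anomaly.index, dtype=int)
    vals = anomaly.to_numpy(dtype=float)
    if years.size < spec.window:
        raise ValueError("anomaly series shorter than the window length")
    if not np.all(np.diff(years) == 1):
        raise ValueError("anomaly series must cover consecutive calendar years")
    w = spec.window
    # running window means
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    means = (csum[w:] - csum[:-w]) / w
    out: dict[float, list[GWLWindow]] = {}
    for level in spec.levels:
        hits = np.flatnonzero(np.abs(means - level) <= spec.tolerance)
        out[level] = [
            GWLWindow(
                model=model,
                run=run,
                level=level,
                years=tuple(range(int(years[i]), int(years[i]) + w)),
                mean_anomaly=float(means[i]),
            )
            for i in hits
        ]
    return out


def pooled_years(windows: list[GWLWindow]) -> set[int]:
    """Union of member years over windows (deduplicated within a run)."""
    out: set[int] = set()
    for win in windows:
        out.update(win.years)
    return out


def pool_gwl_years(
    runs: list[EnsembleRun],
    windows_by_run: dict[tuple[str, str], dict[float, list[GWLWindow]]],
    bioclim_by_run: dict[tuple[str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Pool per-year bioclim vectors over all matching run-years per level.

    ``bioclim_by_run`` maps (model, run) to a per-year bioclim table indexed
    by calendar year.  Returns a long DataFrame with columns ``level, model,
    run, year`` plus the bioclim variables; one row per (model, run, year,
    level), years deduplicated within a run.  A window year missing from a
    run's bioclim table is an error naming the run and year.
    """
    frames = []
    for ens in runs:
        key = (ens.model, ens.run)
        if key not in windows_by_run:
            continue
        bio = bioclim_by_run[key]
        for level, wins in windows_by_run[key].items():
            yrs = sorted(pooled_years(wins))
            if not yrs:
                continue
            missing = [y for y in yrs if y not in bio.index]
            if missing:
                raise KeyError(
                    f"run {ens.model}/{ens.run}: bioclim missing for year(s) "
                    f"{missing[:5]} required by GWL {level:g}"
                )
            block = bio.loc[yrs].copy()
            block.insert(0, "year", yrs)
            block.insert(0, "run", ens.run)
            block.insert(0, "model", ens.model)
            block.insert(0, "level", level)
            frames.append(block.reset_index(drop=True))
    if not frames:
        return pd.DataFrame(columns=["level", "model", "run", "year"])
    return pd.concat(frames, ignore_index=True)
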