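"""Climate envelopes: unimodal occurrence responses and their cutoff bounds.

A species' response to one bioclimatic variable is modelled as a binomial GLM
with linear and quadratic terms on the logit scale,

    logit p(x) = b0 + b1 x + b2 x**2,

the minimal GLM with a unimodal probability response.  The climate envelope
is the interval where the fitted occurrence probability exceeds a cutoff
(default 0.1): its bounds are the two real roots of

    b2 x**2 + b1 x + (b0 - logit(cutoff)) = 0,

solved analytically.  A bound is OPEN (absent) when the fit is not unimodal
(b2 >= 0), when the peak probability never reaches the cutoff (complex
roots), or when a root falls outside the range of the fitting data.  Lower
bounds of physically non-negative variables (all precipitation amounts and
the two seasonality indices) are clamped to zero when the fitted root is
negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseCurve",
    "Envelope",
    "EnvelopeFitError",
    "fit_unimodal_response",
    "envelope_from_response",
    "fit_all_envelopes",
    "PHYSICAL_FLOORS",
]

#: zero floors for variables that cannot be negative
PHYSICAL_FLOORS: dict[str, float] = {
    v: 0.0
    for v in (
        "bio04", "bio12", "bio13", "bio14", "bio15",
        "bio16", "bio17", "bio18", "bio19",
    )
}

OPEN_NON_UNIMODAL = "non-unimodal"
OPEN_BELOW_CUTOFF = "peak-below-cutoff"
OPEN_OUT_OF_RANGE = "no-crossing-in-range"


class EnvelopeFitError(RuntimeError):
    """The occurrence response cannot be estimated from the given data."""


@dataclass(frozen=True)
class ResponseCurve:
    """Fitted quadratic-logit occurrence response for one species x variable."""

    species: str
    variable: str
    intercept: float
    linear: float
    quadratic: float
    p_values: tuple[float, float, float]
    n_obs: int
    x_range: tuple[float, float]

    @property
    def unimodal(self) -> bool:
        return self.quadratic < 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = self.intercept + self.linear * x + self.quadratic * x**2
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class Envelope:
    """Cutoff interval of a response curve; either bound may be OPEN (None)."""

    species: str
    variable: str
    lower: float | None
    upper: float | None
    cutoff: float = 0.1
    clamped: bool = False
    lower_open_reason: str | None = None
    upper_open_reason: str | None = None
    data_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError("finite envelope requires lower < upper")

    @property
    def size(self) -> float | None:
        """Envelope width; defined only when both bounds are finite."""
        if self.lower is None or self.upper is None:
            return None
        return self.upper - self.lower

    @property
    def both_open(self) -> bool:
        return self.lower is None and self.upper is None


def fit_unimodal_response(
    occurrence: np.ndarray,
    x: np.ndarray,
    species: str = "",
    variable: str = "",
) -> ResponseCurve:
    """Fit the quadratic-logit binomial GLM by maximum likelihood.

    ``occurrence`` is per-site presence (0/1) and ``x`` the per-site variable
    value.  Requires at least 30 sites with both presences and absences.
    Complete separation (the quadratic perfectly classifies the sites) is
    reported as :class:`EnvelopeFitError` with a diagnostic.
    """
    y = np.asarray(occurrence, dtype=float).ravel()
    xv = np.asarray(x, dtype=float).ravel()
    if y.size != xv.size:
        raise ValueError("occurrence and x must have equal length")
    if y.size < 30:
        raise EnvelopeFitError(f"{species}/{variable}: needs >= 30 sites, got {y.size}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("occurrence must be 0/1")
    if y.min() == y.max():
        state = "present" if y[0] == 1 else "absent"
        raise EnvelopeFitError(
            f"{species}/{variable}: all sites {state}; no envelope estimable"
        )
    design = np.column_stack([np.ones_like(xv), xv, xv**2])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise EnvelopeFitError(
                f"{species}/{variable}: GLM failed ({exc})"
            ) from exc
    sep = any("separation" in str(w.message).lower() for w in caught)
    if sep or np.max(np.abs(fit.params)) > 1e4:
        raise EnvelopeFitError(
            f"{species}/{variable}: (quasi-)complete separation detected; "
            f"max |coefficient| = {np.max(np.abs(fit.params)):.3g}"
        )
    return ResponseCurve(
        species=species,
        variable=variable,
        intercept=float(fit.params[0]),
        linear=float(fit.params[1]),
        quadratic=float(fit.params[2]),
        p_values=tuple(float(p) for p in fit.pvalues),
        n_obs=int(y.size),
        x_range=(float(xv.min()), float(xv.max())),
    )


def envelope_from_response(
    curve: ResponseCurve,
    cutoff: float = 0.1,
    physical_floor: float | None = None,
) -> Envelope:
    """Extract the envelope bounds at ``cutoff`` from a fitted response.

    Bounds are the analytic roots of the logit quadratic at logit(cutoff).
    Degenerate fits never raise: a non-unimodal fit (quadratic >= 0) or a
    peak below the cutoff yields two OPEN bounds; a root outside the fitting
    data range opens that side.  A finite lower bound below
    ``physical_floor`` is clamped to the floor (``clamped=True``).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    kw = dict(
        species=curve.species,
        variable=curve.variable,
        cutoff=cutoff,
        data_range=curve.x_range,
    )
    if curve.quadratic >= 0:
        return Envelope(lower=None, upper=None,
                        lower_open_reason=OPEN_NON_UNIMODAL,
                        upper_open_reason=OPEN_NON_UNIMODAL, **kw)
    target = np.log(cutoff / (1 - cutoff))
    a, b, c = curve.quadratic, curve.linear, curve.intercept - target
    disc = b * b - 4 * a * c
    if disc < 0:
        return Envelope(lower=None, upper=None,
                        lower_open_reason=OPEN_BELOW_CUTOFF,
                        upper_open_reason=OPEN_BELOW_CUTOFF, **kw)
    sq = np.sqrt(disc)
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    lo, hi = float(roots[0]), float(roots[1])
    lo_reason = hi_reason = None
    x_min, x_max = curve.x_range
    lower: float | None = lo
    upper: float | None = hi
    if lo < x_min or lo > x_max:
        lower, lo_reason = None, OPEN_OUT_OF_RANGE
    if hi > x_max or hi < x_min:
        upper, hi_reason = None, OPEN_OUT_OF_RANGE
    clamped = False
    if physical_floor is not None and lower is not None and lower < physical_floor:
        lower = physical_floor
        clamped = True
    return Envelope(lower=lower, upper=upper, clamped=clamped,
                    lower_open_reason=lo_reason, upper_open_reason=hi_reason, **kw)


def fit_all_envelopes(
    occurrences: pd.DataFrame,
    site_values: pd.DataFrame,
    selected_variables: list[str],
    cutoff: float = 0.1,
    physical_floors: dict[str, float] | None = None,
) -> tuple[dict[tuple[str, str], Envelope], pd.DataFrame]:
    """Fit one envelope per species x selected variable.

    ``occurrences`` is long-format (``lon, lat, species, present``);
    ``site_values`` holds the climatological bioclim value per site with
    columns ``lon, lat`` plus the variables.  Per-pair fit failures are
    recorded as both-OPEN envelopes with the diagnostic, never aborts.

    Returns the envelope mapping plus a summary table (species, variable,
    lower, upper, clamped, notes) mirroring the familiar range-table layout.
    """
    if physical_floors is None:
        physical_floors = PHYSICAL_FLOORS
    missing = [v for v in selected_variables if v not in site_values.columns]
    if missing:
        raise KeyError(f"selected variables missing from site values: {missing}")
    merged = occurrences.merge(site_values, on=["lon", "lat"], how="inner",
                               validate="many_to_one")
    if len(merged) == 0:
        raise ValueError("no occurrence sites intersect the bioclim raster")

    envelopes: dict[tuple[str, str], Envelope] = {}
    rows = []
    for species, grp in merged.groupby("species", sort=True):
        for var in selected_variables:
            try:
                curve = fit_unimodal_response(
                    grp["present"].to_numpy(), grp[var].to_numpy(),
                    species=species, variable=var,
                )
                env = envelope_from_response(
                    curve, cutoff=cutoff,
                    physical_floor=physical_floors.get(var),
                )
            except EnvelopeFitError as exc:
                logger.warning("envelope fit failed for %s/%s: %s",
                               species, var, exc)
                x = grp[var].to_numpy(dtype=float)
                env = Envelope(
                    species=species, variable=var, lower=None, upper=None,
                    cutoff=cutoff, lower_open_reason=f"fit-failed: {exc}",
                    upper_open_reason=f"fit-failed: {exc}",
                    data_range=(float(x.min()), float(x.max())),
                )
            envelopes[(species, var)] = env
            notes = "; ".join(
                s for s in (env.lower_open_reason, env.upper_open_reason) if s
            )
            rows.append((species, var, env.lower, env.upper, env.clamped, notes))
    table = pd.DataFrame(
        rows, columns=["species", "variable", "lower", "upper", "clamped", "notes"]
    )
    return envelopes, table
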