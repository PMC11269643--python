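"""Climate envelope exceedance (CEE): per-year verdicts, bins, risk scores.

A pooled year exceeds a species' envelope for a variable when its annual
bioclim value falls above the upper bound (positive exceedance) or below the
lower bound (negative).  The intensity is the distance beyond the violated
bound as a percentage of the envelope width; intensities are categorised
into bins and the per-level summary is the percentage of pooled years with
any exceedance, split by sign and bin — the "risk factor".  The total
vulnerability score per species and warming level is the loadings-weighted
sum of the per-variable risk factors, the weight of a variable being the
sum of the absolute values of its two ordination-axis loadings (normalized
to sum to one over the scored variables, so scores are comparable across
variable subsets).

When one envelope bound is OPEN, the intensity denominator falls back to the
span between the finite bound and the opposite extreme of the historical
fitting range (flagged per record), so exceedance of the finite bound can
still be graded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envelope import Envelope

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityBins",
    "METHODS_BINS",
    "FIVE_COLOUR_BINS",
    "evaluate_exceedance",
    "bin_intensity",
    "risk_factor",
    "total_score",
    "cee_pipeline",
]


@dataclass(frozen=True)
class IntensityBins:
    """Left-open right-closed intensity bins in % of envelope size.

    ``edges`` are the interior edges starting at 0; the last bin is
    open-ended above the final edge.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = list(self.edges)
        if not e or e[0] != 0 or sorted(set(e)) != e:
            raise ValueError("edges must start at 0 and strictly increase")
        if len(self.labels) != len(e):
            raise ValueError("need one label per bin (last bin is open-ended)")


def _default_labels(edges: tuple[float, ...]) -> tuple[str, ...]:
    labels = [
        f">{edges[i]:g}-{edges[i + 1]:g}" if i == 0 else f"{edges[i]:g}-{edges[i + 1]:g}"
        for i in range(len(edges) - 1)
    ]
    labels.append(f">{edges[-1]:g}")
    return tuple(labels)


#: six contiguous bins: (0,5], (5,10], (10,15], (15,25], (25,30], (30,inf)
METHODS_BINS = IntensityBins(
    edges=(0.0, 5.0, 10.0, 15.0, 25.0, 30.0),
    labels=_default_labels((0.0, 5.0, 10.0, 15.0, 25.0, 30.0)),
)

#: five-colour preset: (0,5], (5,10], (10,15], (15,30], (30,inf)
FIVE_COLOUR_BINS = IntensityBins(
    edges=(0.0, 5.0, 10.0, 15.0, 30.0),
    labels=_default_labels((0.0, 5.0, 10.0, 15.0, 30.0)),
)

BIN_PRESETS = {"methods": METHODS_BINS, "five-colour": FIVE_COLOUR_BINS}


def _envelope_size(env: Envelope) -> tuple[float, bool]:
    """Envelope width, or the finite-bound/data-range proxy (flagged True)."""
    if env.size is not None:
        return env.size, False
    if env.both_open:
        raise ValueError(
            f"{env.species}/{env.variable}: both bounds OPEN; no envelope to exceed"
        )
    if env.data_range is None:
        raise ValueError(
            f"{env.species}/{env.variable}: one bound OPEN and no data range "
            "available for the size proxy"
        )
    if env.upper is None:  # finite lower bound only
        size = env.data_range[1] - env.lower
    else:  # finite upper bound only
        size = env.upper - env.data_range[0]
    if size <= 0:
        raise ValueError(
            f"{env.species}/{env.variable}: degenerate size proxy ({size})"
        )
    return size, True


def evaluate_exceedance(value: float, envelope: Envelope) -> tuple[str, float | None]:
    """Sign and intensity of one annual value against an envelope.

    Returns ``("positive", pct)`` above the upper bound, ``("negative",
    pct)`` below the lower bound, ``("none", None)`` inside.  Intensity is
    100 * distance-beyond-bound / envelope size.  An OPEN bound on a side
    means that side can never be exceeded; both bounds OPEN is an error.
    """
    size, _ = _envelope_size(envelope)
    v = float(value)
    if envelope.upper is not None and v > envelope.upper:
        return "positive", 100.0 * (v - envelope.upper) / size
    if envelope.lower is not None and v < envelope.lower:
        return "negative", 100.0 * (envelope.lower - v) / size
    return "none", None


def bin_intensity(intensity: float, bins: IntensityBins = METHODS_BINS) -> str:
    """Bin label for a positive intensity (left-open, right-closed bins)."""
    if not intensity > 0:
        raise ValueError("only exceedances (intensity > 0) can be binned")
    edges = bins.edges
    for i in range(len(edges) - 1):
        if intensity <= edges[i + 1]:
            return bins.labels[i]
    return bins.labels[-1]


def risk_factor(
    records: pd.DataFrame,
    n_pooled_years: int,
    bins: IntensityBins = METHODS_BINS,
) -> dict:
    """Summarise exceedance records of one species x variable x level.

    ``records`` has one row per pooled year with columns ``sign`` and
    ``intensity`` (a year contributes at most one exceedance per variable).
    Returns the total exceedance frequency in percent of pooled years plus
    the breakdown by sign and by (sign, bin); the splits sum exactly to the
    total.
    """
    if n_pooled_years < 1:
        raise ValueError("pooled year count must be >= 1")
    exceed = records[records["sign"] != "none"]
    freq = 100.0 * len(exceed) / n_pooled_years
    by_sign = {
        s: 100.0 * int((exceed["sign"] == s).sum()) / n_pooled_years
        for s in ("positive", "negative")
    }
    by_bin = {(s, lab): 0.0 for s in ("positive", "negative") for lab in bins.labels}
    for _, row in exceed.iterrows():
        lab = bin_intensity(float(row["intensity"]), bins)
        by_bin[(row["sign"], lab)] += 100.0 / n_pooled_years
    return {
        "frequency": freq,
        "by_sign": by_sign,
        "by_bin": by_bin,
        "n_years": int(n_pooled_years),
    }


def total_score(
    frequencies: pd.Series,
    loadings: pd.DataFrame,
) -> tuple[float, pd.Series, pd.Series]:
    """Ordination-weighted total exceedance score for one species x level.

    ``frequencies`` is indexed by variable (total exceedance frequency, %);
    weights are |load1| + |load2| per variable, normalized to sum to one over
    the scored variables.  Returns (score, per-variable contributions,
    weights).
    """
    missing = [v for v in frequencies.index if v not in loadings.index]
    if missing:
        raise KeyError(f"no ordination loadings for variable(s): {missing}")
    raw = (loadings.loc[frequencies.index, "load1"].abs()
           + loadings.loc[frequencies.index, "load2"].abs())
    if float(raw.sum()) == 0:
        raise ValueError("all loadings are zero; weights undefined")
    w = raw / raw.sum()
    contrib = w * frequencies.abs()
    return float(contrib.sum()), contrib, w


def cee_pipeline(
    envelopes: dict[tuple[str, str], Envelope],
    pooled: pd.DataFrame,
    loadings: pd.DataFrame,
    bins: IntensityBins = METHODS_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every species x variable x warming level on the pooled years.

    ``pooled`` is the long table from GWL pooling (``level, model, run,
    year`` plus bioclim columns).  Species x variable pairs whose envelope
    has both bounds OPEN are skipped with a logged reason.  Returns

    * a long risk table: species, variable, level, sign, bin, frequency_pct,
      n_years (plus sign-total rows with bin = "all"), and
    * a total-score table: species, level, score plus per-variable
      contributions.
    """
    if pooled.empty:
        raise ValueError("pooled sample table is empty")
    species = sorted({sp for sp, _ in envelopes})
    variables = sorted({v for _, v in envelopes})
    risk_rows = []
    score_rows = []
    for level, lv_grp in pooled.groupby("level", sort=True):
        n_years = len(lv_grp)
        for sp in species:
            freqs = {}
            for var in variables:
                env = envelopes.get((sp, var))
                if env is None:
                    continue
                if env.both_open:
                    logger.info("skipping %s/%s at GWL %g: both bounds OPEN (%s)",
                                sp, var, level, env.lower_open_reason)
                    continue
                sign_int = [evaluate_exceedance(v, env) for v in lv_grp[var]]
                rec = pd.DataFrame(
                    {"sign": [s for s, _ in sign_int],
                     "intensity": [i for _, i in sign_int]}
                )
                summary = risk_factor(rec, n_years, bins)
                freqs[var] = summary["frequency"]
                for s in ("positive", "negative"):
                    risk_rows.append((sp, var, level, s, "all",
                                      summary["by_sign"][s], n_years))
                    for lab in bins.labels:
                        risk_rows.append((sp, var, level, s, lab,
                                          summary["by_bin"][(s, lab)], n_years))
            if freqs:
                score, contrib, _w = total_score(pd.Series(freqs), loadings)
                score_rows.append(
                    {"species": sp, "level": level, "score": score,
                     **{f"contrib_{v}": c for v, c in contrib.items()}}
                )
    risk = pd.DataFrame(
        risk_rows,
        columns=["species", "variable", "level", "sign", "bin",
                 "frequency_pct", "n_years"],
    )
    scores = pd.DataFrame(score_rows)
    return risk, scores
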