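"""Species ordination in climate space: Jaccard dissimilarity, NMDS, envfit.

The species' presence-absence footprints are compared with Jaccard
dissimilarity (1 - intersection/union over grid cells), embedded in two
dimensions by non-metric multidimensional scaling (Kruskal stress-1,
isotonic regression of configuration distances on the dissimilarity ranks,
Guttman-transform updates with backtracking so stress never increases within
a restart), and the bioclimatic variables are then fitted onto the ordination
plane as least-squares vectors.  The per-variable axis loadings double as
the weights of the total vulnerability score downstream.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "jaccard_dissimilarity",
    "Ordination",
    "nmds",
    "fit_variable_vectors",
    "select_variables",
]


def jaccard_dissimilarity(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity between the rows of a boolean table.

    ``presence`` is entities x sites (e.g. species x grid cells), truthy
    entries meaning presence.  d(A, B) = 1 - |A&B| / |A|B|; a pair of
    all-empty rows is defined as d = 0 with a warning.
    """
    if presence.shape[0] < 2:
        raise ValueError("at least two entities are required")
    if presence.shape[1] < 1:
        raise ValueError("at least one site is required")
    x = presence.to_numpy().astype(bool)
    empty = ~x.any(axis=1)
    if empty.any():
        warnings.warn(
            "entities with no presences; their mutual dissimilarity is defined as 0",
            stacklevel=2,
        )
    d = squareform(pdist(x, metric="jaccard"))  # scipy defines 0/0 -> 0
    return pd.DataFrame(d, index=presence.index, columns=presence.index)


@dataclass
class Ordination:
    """NMDS result: centred 2-D scores and the Kruskal stress-1 achieved."""

    scores: pd.DataFrame  # entities x n_dimensions
    stress: float
    n_dimensions: int
    converged: bool
    seed: int
    n_restarts: int
    stress_history: list[float] = field(default_factory=list, repr=False)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling used as the NMDS starting configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(dis: np.ndarray, dist: np.ndarray, iso: IsotonicRegression) -> tuple[float, np.ndarray]:
    dhat = iso.fit_transform(dis, dist)
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return np.inf, dhat
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom)), dhat


def nmds(
    d: pd.DataFrame,
    n_dimensions: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Starts from classical (metric) MDS, jittered for restarts 2..n, and
    alternates isotonic regression of the configuration distances on the
    dissimilarities with a Guttman-transform update.  An update that would
    raise stress is halved toward the current configuration (backtracking),
    so stress is non-increasing within a restart; the best restart is
    returned.  Deterministic given ``seed``.
    """
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if np.any(np.abs(np.diag(dm)) > 1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if n_dimensions < 1:
        raise ValueError("n_dimensions must be >= 1")
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    dis = dm[iu]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    init = _classical_mds(dm, n_dimensions)
    scale = max(np.sqrt(np.mean(init ** 2)), 1e-6)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best_x, best_stress, best_hist, best_conv = None, np.inf, [], False
    for restart in range(max(1, n_restarts)):
        x = init.copy()
        if restart > 0:
            x = x + rng.normal(0.0, 0.1 * scale, size=x.shape)
        dist = pdist(x)
        stress, dhat = _stress1(dis, dist, iso)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform toward the isotonically fitted distances
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 1e-12, dhat / dist, 0.0)
            b = squareform(-ratio)
            np.fill_diagonal(b, -b.sum(axis=1))
            x_new = b @ x / n
            dist_new = pdist(x_new)
            stress_new, dhat_new = _stress1(dis, dist_new, iso)
            # backtrack if the normalized stress went up
            tries = 0
            while stress_new > stress and tries < 8:
                x_new = 0.5 * (x + x_new)
                dist_new = pdist(x_new)
                stress_new, dhat_new = _stress1(dis, dist_new, iso)
                tries += 1
            if stress_new > stress:
                converged = True  # no descent direction left
                break
            x, dist, dhat = x_new, dist_new, dhat_new
            history.append(stress_new)
            if stress - stress_new < tol * max(stress, 1e-12):
                stress = stress_new
                converged = True
                break
            stress = stress_new
        if stress < best_stress:
            best_x, best_stress, best_hist, best_conv = x, stress, history, converged

    if not best_conv:
        warnings.warn("NMDS did not converge within max_iter", stacklevel=2)
    best_x = best_x - best_x.mean(axis=0, keepdims=True)
    scores = pd.DataFrame(
        best_x, index=d.index, columns=[f"NMDS{i + 1}" for i in range(n_dimensions)]
    )
    return Ordination(
        scores=scores,
        stress=best_stress,
        n_dimensions=n_dimensions,
        converged=best_conv,
        seed=seed,
        n_restarts=n_restarts,
        stress_history=best_hist,
    )


def fit_variable_vectors(
    ordination: Ordination, variable_values: pd.DataFrame
) -> pd.DataFrame:
    """Fit each variable as a least-squares vector on the ordination plane.

    ``variable_values`` is entities x variables, rows aligned with the
    ordination scores.  Each variable is standardized (zero mean, unit sample
    sd) and regressed on the centred scores; the coefficients are the axis
    loadings and r-squared is the squared multiple correlation.  Zero-variance
    variables get (0, 0) loadings and r2 = 0 with a warning.

    Returns a DataFrame indexed by variable with columns
    ``load1, load2, r2``.
    """
    if list(variable_values.index) != list(ordination.scores.index):
        raise ValueError("variable_values rows must match the ordination entities")
    xc = ordination.scores.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0, keepdims=True)
    rows = []
    for var in variable_values.columns:
        y = variable_values[var].to_numpy(dtype=float)
        sd = y.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"variable {var!r} has zero variance; loadings set to 0",
                          stacklevel=2)
            rows.append((var, 0.0, 0.0, 0.0))
            continue
        z = (y - y.mean()) / sd
        beta, *_ = np.linalg.lstsq(xc, z, rcond=None)
        resid = z - xc @ beta
        sst = float(np.sum(z ** 2))
        r2 = max(0.0, 1.0 - float(np.sum(resid ** 2)) / sst) if sst > 0 else 0.0
        rows.append((var, float(beta[0]), float(beta[1]), r2))
    return pd.DataFrame(
        rows, columns=["variable", "load1", "load2", "r2"]
    ).set_index("variable")


def _bio_index(name: str) -> int:
    m = re.search(r"(\d+)$", name)
    return int(m.group(1)) if m else 10**6


def select_variables(
    loadings: pd.DataFrame,
    defaults: tuple[str, ...] = ("bio01", "bio12"),
    k: int = 5,
) -> list[str]:
    """Default variables plus the top-k by L1 loading norm.

    The annual-mean temperature and precipitation variables enter by default
    as the baseline of comparison; the remaining variables are ranked by
    |load1| + |load2| (descending), ties broken by ascending BIO index.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    defaults = [d for d in defaults]
    missing = [d for d in defaults if d not in loadings.index]
    if missing:
        raise KeyError(f"default variables missing from loadings: {missing}")
    others = [v for v in loadings.index if v not in defaults]
    strength = (loadings["load1"].abs() + loadings["load2"].abs())
    ranked = sorted(others, key=lambda v: (-strength[v], _bio_index(v)))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the {len(ranked)} available non-default variables; "
            "returning all",
            stacklevel=2,
        )
        k = len(ranked)
    return defaults + ranked[:k]
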