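"""Effective MAOC capacity by boundary-line quantile regression.

Three boundary shapes, all fitted at the tau = 0.9 quantile with the intercept
forced to 0, estimate the effective mineral-associated organic carbon (MAOC)
capacity of a pedo-climatic cluster as a function of fine fraction (clay +
silt, %):

* BL  -- a straight line through the origin on the soil basis
         (MAOC g kg-1 soil vs ff %); a constant capacity on the ff basis.
* PBL -- a piecewise line on the ff basis whose second segment is a plateau
         (slope 0); samples below the fitted breakpoint are treated as
         MAOC-saturated.
* NBL -- a logarithmic boundary y = beta * log(ff) (natural log, ff in %) on
         the ff basis.

The through-origin quantile fits are solved exactly: minimizing the pinball
loss over a slope b for points (x_i > 0, y_i) reduces to the x-weighted
tau-quantile of the slopes y_i / x_i.  The piecewise fit profiles the
breakpoint over a 1 % grid, solving the two-parameter quantile fit per
candidate as an exact linear program.

The degree of MAOC saturation is (MAOC / capacity) x 100, capped at 100 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

TAU_DEFAULT = 0.9
#: Left-closed fine-fraction bins: [0,10), ..., [80,90), [90,100].
FF_BIN_EDGES = np.arange(0.0, 101.0, 10.0)


class CapacityError(ValueError):
    """Raised for degenerate boundary-line inputs."""


@dataclass
class CapacityModel:
    """Fitted effective-capacity boundary for one cluster.

    ``alpha`` is 0 for BL and NBL (forced intercept) and the plateau height
    (g MAOC kg-1 ff) for PBL.  ``beta`` is the through-origin slope on the
    soil basis for BL, the segment-1 slope for PBL and the log coefficient for
    NBL.  ``basis`` records which response the model was fitted on.
    """

    method: str
    beta: float
    alpha: float = 0.0
    breakpoint: float | None = None
    tau: float = TAU_DEFAULT
    cluster_id: int | None = None
    basis: str = "fine_fraction"
    loss: float = np.nan


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    """Mean quantile (check) loss of a residual vector."""
    r = np.asarray(residuals, float)
    return float(np.mean(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def to_fine_fraction_basis(maoc_soil, ff):
    """Convert g MAOC kg-1 soil to g MAOC kg-1 fine fraction."""
    maoc_soil = np.asarray(maoc_soil, float)
    ff = np.asarray(ff, float)
    if np.any(ff <= 0):
        raise CapacityError("fine fraction must be positive")
    return maoc_soil / (ff / 100.0)


def origin_quantile_slope(x: np.ndarray, y: np.ndarray, tau: float) -> float:
    """Exact tau-quantile regression slope through the origin (x > 0).

    Minimizing ``sum_i pinball_tau(y_i - b x_i)`` over b: since
    ``y - b x = x (y/x - b)`` for x > 0, the optimum is the x-weighted
    tau-quantile of the pointwise slopes y/x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0):
        raise CapacityError("predictor must be strictly positive")
    s = y / x
    order = np.argsort(s, kind="stable")
    s, w = s[order], x[order]
    cw = np.cumsum(w)
    target = tau * cw[-1]
    idx = int(np.searchsorted(cw, target))
    return float(s[min(idx, len(s) - 1)])


def quantile_linear_fit(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact linear quantile regression via the pinball linear program."""
    from scipy import sparse

    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    # variables: beta+ (p), beta- (p), u (n), v (n);  y - X beta = u - v
    c = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = sparse.hstack(
        [sparse.csc_matrix(X), -sparse.csc_matrix(X), sparse.eye(n),
         -sparse.eye(n)],
        format="csc",
    )
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=[(0, None)] * (2 * p + 2 * n),
                  method="highs")
    if not res.success:
        raise CapacityError(f"quantile LP failed: {res.message}")
    return res.x[:p] - res.x[p : 2 * p]


# ---------------------------------------------------------------------------
# The three fitters
# ---------------------------------------------------------------------------

def fit_bl(
    ff: np.ndarray,
    maoc_soil: np.ndarray,
    tau: float = TAU_DEFAULT,
    cluster_id: int | None = None,
) -> CapacityModel:
    """Boundary line: tau-quantile regression of MAOC (soil basis) on ff
    through the origin.  Capacity on the ff basis is the constant 100*beta."""
    ff = np.asarray(ff, float)
    maoc_soil = np.asarray(maoc_soil, float)
    if ff.size < 20:
        raise CapacityError("BL needs at least 20 points")
    if np.ptp(ff) <= 0 or np.any(ff <= 0):
        raise CapacityError("degenerate fine-fraction spread")
    beta = origin_quantile_slope(ff, maoc_soil, tau)
    loss = pinball_loss(maoc_soil - beta * ff, tau)
    return CapacityModel("BL", beta=beta, tau=tau, cluster_id=cluster_id,
                         basis="soil", loss=loss)


def fit_nbl(
    ff: np.ndarray,
    maoc_ff: np.ndarray,
    tau: float = TAU_DEFAULT,
    cluster_id: int | None = None,
) -> CapacityModel:
    """Logarithmic boundary y = beta * log(ff) at the tau quantile, zero
    intercept.  Points with ff <= 1 (log non-positive) are excluded."""
    ff = np.asarray(ff, float)
    maoc_ff = np.asarray(maoc_ff, float)
    ok = ff > 1.0
    if not ok.all():
        warnings.warn(
            f"fit_nbl: excluded {int((~ok).sum())} points with ff <= 1 %",
            stacklevel=2,
        )
    ff, maoc_ff = ff[ok], maoc_ff[ok]
    if ff.size < 20:
        raise CapacityError("NBL needs at least 20 points with ff > 1 %")
    beta = origin_quantile_slope(np.log(ff), maoc_ff, tau)
    loss = pinball_loss(maoc_ff - beta * np.log(ff), tau)
    return CapacityModel("NBL", beta=beta, tau=tau, cluster_id=cluster_id,
                         basis="fine_fraction", loss=loss)


def fit_pbl(
    ff: np.ndarray,
    maoc_ff: np.ndarray,
    tau: float = TAU_DEFAULT,
    cluster_id: int | None = None,
    breakpoint_grid: np.ndarray | None = None,
) -> CapacityModel:
    """Piecewise boundary on the ff basis: free first segment, plateau after
    the breakpoint.

    The model is ``y = plateau + b1 * min(ff - bp, 0)`` (continuous at the
    breakpoint, slope 0 beyond it).  The breakpoint is profiled over a 1 %
    grid; for each candidate the two-parameter tau-quantile fit is solved
    exactly and the candidate with the lowest pinball loss wins (ties toward
    the smallest breakpoint, which also covers the degenerate flat-boundary
    case).  Samples below the fitted breakpoint are considered MAOC-saturated.
    """
    ff = np.asarray(ff, float)
    maoc_ff = np.asarray(maoc_ff, float)
    if ff.size < 40:
        raise CapacityError("PBL needs at least 40 points")
    if breakpoint_grid is None:
        lo = np.ceil(ff.min()) + 1.0
        hi = np.floor(ff.max()) - 1.0
        if hi <= lo:
            raise CapacityError("fine-fraction range too narrow for a breakpoint")
        breakpoint_grid = np.arange(lo, hi + 0.5, 1.0)

    best = None
    for bp in breakpoint_grid:
        z = np.minimum(ff - bp, 0.0)
        X = np.column_stack([np.ones_like(ff), z])
        params = quantile_linear_fit(X, maoc_ff, tau)
        loss = pinball_loss(maoc_ff - X @ params, tau)
        if best is None or loss < best[0] - 1e-12:
            best = (loss, float(bp), params)
    loss, bp, (plateau, b1) = best
    if bp in (breakpoint_grid[0], breakpoint_grid[-1]):
        warnings.warn(
            "fit_pbl: breakpoint at the edge of the candidate range",
            stacklevel=2,
        )
    return CapacityModel(
        "PBL", beta=float(b1), alpha=float(plateau), breakpoint=bp, tau=tau,
        cluster_id=cluster_id, basis="fine_fraction", loss=loss,
    )


# ---------------------------------------------------------------------------
# Capacity evaluation and saturation
# ---------------------------------------------------------------------------

def capacity_at(model: CapacityModel, ff) -> np.ndarray:
    """Effective capacity (g MAOC kg-1 fine fraction) at fine fraction ff (%).

    BL gives a constant (100 * beta, the soil-basis slope rescaled); PBL gives
    the plateau everywhere (samples below the breakpoint are flagged saturated
    by :func:`saturation_degree`); NBL gives beta * log(ff).
    """
    ff = np.asarray(ff, float)
    if np.any((ff <= 0) | (ff > 100)):
        raise CapacityError("ff must be in (0, 100]")
    if model.method == "BL":
        return np.full(ff.shape, 100.0 * model.beta)
    if model.method == "PBL":
        return np.full(ff.shape, model.alpha)
    if model.method == "NBL":
        return model.beta * np.log(ff)
    raise CapacityError(f"unknown method {model.method!r}")


def saturation_degree(maoc_ff, model: CapacityModel, ff) -> pd.DataFrame:
    """Degree of MAOC saturation, (MAOC / capacity) x 100, capped at 100 %.

    Values above 100 % are considered saturated and stored as 100 with
    ``capped`` set.  For PBL, samples below the breakpoint are saturated by
    construction and stored as 100 %.
    """
    maoc_ff = np.asarray(maoc_ff, float)
    ff = np.asarray(ff, float)
    cap = capacity_at(model, ff)
    if np.any(cap <= 0):
        raise CapacityError("non-positive capacity; cannot compute saturation")
    raw = maoc_ff / cap * 100.0
    capped = raw > 100.0
    sat = np.minimum(raw, 100.0)
    if model.method == "PBL" and model.breakpoint is not None:
        sat = np.where(ff < model.breakpoint, 100.0, sat)
    return pd.DataFrame(
        {"maoc_ff": maoc_ff, "capacity": cap, "saturation_pct": sat,
         "capped": capped}
    )


def ff_bin_index(ff) -> np.ndarray:
    """Left-closed 10 % bin index, 0..9; ff = 100 falls in the last bin."""
    ff = np.asarray(ff, float)
    return np.clip(np.floor(ff / 10.0), 0, 9).astype(int)


def bin_saturation(
    saturation_pct, cluster_id, ff, bin_edges: np.ndarray = FF_BIN_EDGES
) -> pd.DataFrame:
    """Mean +/- sd saturation per (cluster, 10 % fine-fraction bin).

    All 10 bins are reported per cluster; empty bins carry NaN means and
    n = 0.  A single-record bin has sd 0 by convention.
    """
    df = pd.DataFrame(
        {
            "cluster_id": np.asarray(cluster_id),
            "bin": ff_bin_index(ff),
            "sat": np.asarray(saturation_pct, float),
        }
    )
    rows = []
    for cl in np.unique(df["cluster_id"]):
        sub = df[df["cluster_id"] == cl]
        for b in range(10):
            vals = sub.loc[sub["bin"] == b, "sat"].to_numpy()
            rows.append(
                {
                    "cluster_id": cl,
                    "bin_left": bin_edges[b],
                    "bin_right": bin_edges[b + 1],
                    "mean_sat": float(vals.mean()) if vals.size else np.nan,
                    "sd_sat": (
                        float(vals.std(ddof=1)) if vals.size > 1
                        else (0.0 if vals.size == 1 else np.nan)
                    ),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def fit_capacity_by_cluster(
    samples: pd.DataFrame,
    method: str,
    tau: float = TAU_DEFAULT,
    **fit_kwargs,
) -> dict[int, CapacityModel]:
    """Fit one boundary model per cluster, never mixing points across
    clusters.  ``samples`` needs fine_fraction, maoc and cluster_id columns."""
    fitters = {"BL": fit_bl, "PBL": fit_pbl, "NBL": fit_nbl}
    if method not in fitters:
        raise CapacityError(f"unknown method {method!r}")
    models: dict[int, CapacityModel] = {}
    for cl in np.unique(samples["cluster_id"]):
        sub = samples[samples["cluster_id"] == cl]
        ff = sub["fine_fraction"].to_numpy(float)
        maoc = sub["maoc"].to_numpy(float)
        y = maoc if method == "BL" else to_fine_fraction_basis(maoc, ff)
        models[int(cl)] = fitters[method](
            ff, y, tau=tau, cluster_id=int(cl), **fit_kwargs
        )
    return models
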