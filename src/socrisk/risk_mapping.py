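"""The four-class SOC risk index on a raster grid.

Cluster-binned MAOC saturation is transferred to the grid by looking up the
mean saturation of each cell's (cluster, fine-fraction bin); each cell is then
classified by whether its saturation is above or below the median across the
classified domain (vulnerability) and whether its SOC change is negative
(hazard):

    HR  high risk    sat >  median,  dSOC < 0
    HH  high hazard  sat <= median,  dSOC < 0
    NR  no risk      sat <= median,  dSOC >= 0
    NH  no hazard    sat >  median,  dSOC >= 0

Cells exactly at the median go to the "below" branch so the two sides
partition the domain.  Areas are accounted in Mha (100 ha cells) and
cross-method agreement is reported per class against a reference method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .capacity_estimation import ff_bin_index

RISK_CLASSES = ("HR", "HH", "NR", "NH")
CLASS_CODES = {name: i + 1 for i, name in enumerate(RISK_CLASSES)}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}
MISSING = 0


class RiskMappingError(ValueError):
    """Raised for non-co-registered or otherwise invalid grids."""


def _check_shapes(*grids):
    shapes = {np.asarray(g).shape for g in grids}
    if len(shapes) != 1:
        raise RiskMappingError(f"grids are not co-registered: shapes {shapes}")


def map_saturation_to_grid(
    bins: pd.DataFrame, cluster_raster: np.ndarray, ff_raster: np.ndarray
) -> np.ndarray:
    """Per-cell saturation = mean of the cell's (cluster, ff-bin) from
    ``bins``; missing where the cluster label is missing or the bin was empty
    in the samples (those locations are excluded downstream)."""
    _check_shapes(cluster_raster, ff_raster)
    cluster_raster = np.asarray(cluster_raster, float)
    ff_raster = np.asarray(ff_raster, float)

    clusters = np.unique(bins["cluster_id"]).astype(int)
    lut = np.full((clusters.max() + 1, 10), np.nan)
    for _, row in bins.iterrows():
        lut[int(row["cluster_id"]), int(row["bin_left"] // 10)] = row["mean_sat"]

    out = np.full(cluster_raster.shape, np.nan)
    valid = np.isfinite(cluster_raster) & np.isfinite(ff_raster)
    cl = cluster_raster[valid].astype(int)
    known = np.isin(cl, clusters)
    bi = ff_bin_index(ff_raster[valid])
    vals = np.full(cl.shape, np.nan)
    vals[known] = lut[cl[known], bi[known]]
    out[valid] = vals
    return out


def compute_median_saturation(
    saturation_raster: np.ndarray, delta_soc_raster: np.ndarray
) -> float:
    """Median saturation over the classifiable domain (both layers defined)."""
    _check_shapes(saturation_raster, delta_soc_raster)
    ok = np.isfinite(saturation_raster) & np.isfinite(delta_soc_raster)
    if not ok.any():
        raise RiskMappingError("empty classifiable domain")
    return float(np.median(np.asarray(saturation_raster)[ok]))


def classify_risk(
    saturation_raster: np.ndarray,
    delta_soc_raster: np.ndarray,
    median_sat: float,
) -> np.ndarray:
    """Classify each cell into HR/HH/NR/NH (int codes, 0 = missing)."""
    _check_shapes(saturation_raster, delta_soc_raster)
    sat = np.asarray(saturation_raster, float)
    dsoc = np.asarray(delta_soc_raster, float)
    ok = np.isfinite(sat) & np.isfinite(dsoc)
    high = sat > median_sat
    loss = dsoc < 0
    out = np.full(sat.shape, MISSING, dtype=np.int8)
    out[ok & high & loss] = CLASS_CODES["HR"]
    out[ok & ~high & loss] = CLASS_CODES["HH"]
    out[ok & ~high & ~loss] = CLASS_CODES["NR"]
    out[ok & high & ~loss] = CLASS_CODES["NH"]
    return out


def area_by_class(
    class_raster: np.ndarray, cell_area_ha: float = 100.0
) -> pd.DataFrame:
    """Area per risk class in Mha (cell count x cell area)."""
    cls = np.asarray(class_raster)
    rows = []
    for name, code in CLASS_CODES.items():
        n = int((cls == code).sum())
        rows.append({"class": name, "cells": n,
                     "area_mha": n * cell_area_ha / 1e6})
    return pd.DataFrame(rows)


def method_agreement(
    class_rasters: dict[str, np.ndarray], reference: str = "NBL"
) -> pd.DataFrame:
    """Cross-method agreement per risk class, referenced to one method.

    A cell agrees when all methods assign it the same class.  Per class of the
    reference method, the agreement percentage is the agreeing area over the
    total area of that class in the reference raster.
    """
    if reference not in class_rasters:
        raise RiskMappingError(f"reference method {reference!r} not provided")
    grids = list(class_rasters.values())
    _check_shapes(*grids)
    ref = np.asarray(class_rasters[reference])
    stack = np.stack([np.asarray(g) for g in grids])
    defined = np.all(stack != MISSING, axis=0)
    agree = defined & np.all(stack == stack[0], axis=0)

    rows = []
    for name, code in CLASS_CODES.items():
        in_class = (ref == code) & defined
        total = int(in_class.sum())
        n_agree = int((in_class & agree).sum())
        for label, n in (("agreement", n_agree), ("disagreement", total - n_agree)):
            rows.append(
                {
                    "class": name,
                    "status": label,
                    "cells": n,
                    "area_mha": n * 100.0 / 1e6,
                    "pct": 100.0 * n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def overall_agreement_pct(class_rasters: dict[str, np.ndarray]) -> float:
    """Share of the jointly classified area on which all methods agree (%)."""
    grids = list(class_rasters.values())
    _check_shapes(*grids)
    stack = np.stack([np.asarray(g) for g in grids])
    defined = np.all(stack != MISSING, axis=0)
    if not defined.any():
        raise RiskMappingError("no jointly classified cells")
    agree = defined & np.all(stack == stack[0], axis=0)
    return float(100.0 * agree.sum() / defined.sum())


def delta_soc_vs_ratio_fit(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster ordinary least squares of dSOC on the MAOC:SOC ratio.

    Returns intercept, slope and Pearson r per cluster; clusters with fewer
    than 3 points are skipped with a warning, and a constant dSOC yields slope
    0 with r undefined (NaN, flagged)."""
    total = samples["maoc"].to_numpy(float) + samples["poc"].to_numpy(float)
    if np.any(total <= 0):
        raise RiskMappingError("MAOC + POC must be positive")
    ratio = samples["maoc"].to_numpy(float) / total
    dsoc = samples["delta_soc"].to_numpy(float)
    clusters = np.asarray(samples["cluster_id"])
    rows = []
    for cl in np.unique(clusters):
        m = clusters == cl
        if m.sum() < 3:
            warnings.warn(f"cluster {cl}: fewer than 3 points, skipped",
                          stacklevel=2)
            continue
        if np.ptp(dsoc[m]) == 0 or np.ptp(ratio[m]) == 0:
            rows.append({"cluster_id": cl, "intercept": float(np.mean(dsoc[m])),
                         "slope": 0.0, "pearson_r": np.nan, "n": int(m.sum()),
                         "degenerate": True})
            continue
        res = stats.linregress(ratio[m], dsoc[m])
        rows.append(
            {
                "cluster_id": cl,
                "intercept": float(res.intercept),
                "slope": float(res.slope),
                "pearson_r": float(res.rvalue),
                "n": int(m.sum()),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RiskResult:
    """Per-method class rasters plus the area and agreement accounting."""

    class_rasters: dict[str, np.ndarray]
    saturation_rasters: dict[str, np.ndarray]
    medians: dict[str, float]
    areas: pd.DataFrame          # columns: method, class, cells, area_mha
    agreement: pd.DataFrame
    overall_agreement_pct: float


def assess_risk(
    bins_by_method: dict[str, pd.DataFrame],
    cluster_raster: np.ndarray,
    ff_raster: np.ndarray,
    delta_soc_raster: np.ndarray,
    *,
    median_mode: str = "per-method",
    reference: str = "NBL",
) -> RiskResult:
    """Full risk mapping for several capacity methods on one grid.

    ``median_mode`` selects whether the saturation median splitting the
    vulnerability axis is computed per method or shared across methods.
    """
    if median_mode not in ("per-method", "shared"):
        raise RiskMappingError("median_mode must be 'per-method' or 'shared'")
    sats = {
        m: map_saturation_to_grid(b, cluster_raster, ff_raster)
        for m, b in bins_by_method.items()
    }
    if median_mode == "shared":
        pooled = np.concatenate(
            [
                s[np.isfinite(s) & np.isfinite(delta_soc_raster)]
                for s in sats.values()
            ]
        )
        shared = float(np.median(pooled))
        medians = {m: shared for m in sats}
    else:
        medians = {
            m: compute_median_saturation(s, delta_soc_raster)
            for m, s in sats.items()
        }
    classes = {
        m: classify_risk(s, delta_soc_raster, medians[m]) for m, s in sats.items()
    }
    areas = pd.concat(
        [area_by_class(c).assign(method=m) for m, c in classes.items()],
        ignore_index=True,
    )
    ref = reference if reference in classes else next(iter(classes))
    return RiskResult(
        class_rasters=classes,
        saturation_rasters=sats,
        medians=medians,
        areas=areas,
        agreement=method_agreement(classes, ref),
        overall_agreement_pct=overall_agreement_pct(classes),
    )
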