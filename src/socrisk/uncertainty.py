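"""Monte-Carlo propagation of MAOC prediction error.

The spectroscopic MAOC predictions carry a multiplicative error summarized by
the mean absolute log error of predicted POC + MAOC against measured SOC:
MALE = mean |log(pred) - log(obs)|, EMALE = exp(MALE).  Assuming normally
distributed error around the mean prediction with POC and MAOC contributing
equally, the relative standard deviation applied to MAOC is (EMALE - 1) / 2.

``propagate`` redraws the per-sample MAOC predictions ``n_sim`` times
(truncating negative draws at 0), recomputes saturation, its fine-fraction
binning, the gridded risk classification and the per-class areas for each
realization, and reports the mean with the 5th and 95th percentile per class.
Capacity models are held fixed across realizations; only the MAOC predictions
are perturbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capacity_estimation import (
    CapacityModel,
    bin_saturation,
    saturation_degree,
    to_fine_fraction_basis,
)
from .risk_mapping import (
    CLASS_CODES,
    RISK_CLASSES,
    area_by_class,
    classify_risk,
    compute_median_saturation,
    map_saturation_to_grid,
)

logger = logging.getLogger(__name__)

N_SIM_DEFAULT = 500


class UncertaintyError(ValueError):
    """Raised for invalid error-model or simulation inputs."""


@dataclass(frozen=True)
class ErrorModel:
    """Multiplicative prediction-error summary.

    ``half_rel_sd`` = (EMALE - 1) / 2 is the relative sd applied to MAOC under
    the equal POC/MAOC contribution assumption; the unhalved variant
    (EMALE - 1) is available through ``propagate(..., halved=False)``.
    """

    male: float
    emale: float
    half_rel_sd: float


def compute_emale(pred_sum, obs_soc) -> ErrorModel:
    """MALE/EMALE of predicted POC + MAOC against measured SOC."""
    pred = np.asarray(pred_sum, float)
    obs = np.asarray(obs_soc, float)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise UncertaintyError("MALE requires strictly positive pred and obs")
    male = float(np.mean(np.abs(np.log(pred) - np.log(obs))))
    emale = float(np.exp(male))
    return ErrorModel(male=male, emale=emale, half_rel_sd=(emale - 1.0) / 2.0)


@dataclass
class UncertaintySummary:
    """Per-class area mean/Q5/Q95 (Mha) over the Monte-Carlo realizations."""

    class_areas: pd.DataFrame     # columns: class, mean, q5, q95 (Mha)
    point_areas: pd.DataFrame     # unperturbed per-class areas
    n_sim: int
    n_truncated: int              # negative MAOC draws clipped to 0
    saturation_q: pd.DataFrame | None = None  # per-sample saturation Q5/Q95


def propagate(
    samples: pd.DataFrame,
    models: dict[int, CapacityModel],
    cluster_raster: np.ndarray,
    ff_raster: np.ndarray,
    delta_soc_raster: np.ndarray,
    error: ErrorModel,
    *,
    n_sim: int = N_SIM_DEFAULT,
    seed: int = 0,
    halved: bool = True,
    recompute_median: bool = True,
    keep_saturation_quantiles: bool = False,
) -> UncertaintySummary:
    """Propagate MAOC prediction error to risk-class areas.

    ``samples`` needs cluster_id, fine_fraction and maoc (g kg-1 soil)
    columns; ``models`` maps cluster_id to the (fixed) capacity model of one
    boundary method.  Each realization draws
    ``maoc* ~ Normal(maoc, rel_sd * maoc)`` truncated at 0, recomputes
    saturation, bins, the gridded saturation lookup, the median split
    (recomputed per realization unless ``recompute_median=False``) and the
    class areas.
    """
    if n_sim < 2:
        raise UncertaintyError("n_sim must be at least 2")
    rng = np.random.default_rng(seed)
    rel_sd = error.half_rel_sd if halved else (error.emale - 1.0)

    cluster_id = samples["cluster_id"].to_numpy()
    ff = samples["fine_fraction"].to_numpy(float)
    maoc = samples["maoc"].to_numpy(float)

    def one_realization(maoc_r: np.ndarray):
        sat = np.empty_like(maoc_r)
        maoc_ff = to_fine_fraction_basis(maoc_r, ff)
        for cl, model in models.items():
            m = cluster_id == cl
            if m.any():
                sat[m] = saturation_degree(
                    maoc_ff[m], model, ff[m]
                )["saturation_pct"].to_numpy()
        bins = bin_saturation(sat, cluster_id, ff)
        sat_grid = map_saturation_to_grid(bins, cluster_raster, ff_raster)
        med = compute_median_saturation(sat_grid, delta_soc_raster)
        cls = classify_risk(sat_grid, delta_soc_raster, med)
        return sat, area_by_class(cls)["area_mha"].to_numpy(), med

    sat0, areas0, med0 = one_realization(maoc)
    fixed_median = med0

    areas = np.empty((n_sim, len(RISK_CLASSES)))
    sat_all = np.empty((n_sim, len(maoc))) if keep_saturation_quantiles else None
    n_truncated = 0
    for s in range(n_sim):
        draw = maoc + rng.normal(size=maoc.shape) * rel_sd * maoc
        n_truncated += int((draw < 0).sum())
        draw = np.clip(draw, 0.0, None)
        if recompute_median:
            sat_s, a, _ = one_realization(draw)
        else:
            maoc_ff = to_fine_fraction_basis(draw, ff)
            sat_s = np.empty_like(draw)
            for cl, model in models.items():
                m = cluster_id == cl
                if m.any():
                    sat_s[m] = saturation_degree(
                        maoc_ff[m], model, ff[m]
                    )["saturation_pct"].to_numpy()
            bins = bin_saturation(sat_s, cluster_id, ff)
            sat_grid = map_saturation_to_grid(bins, cluster_raster, ff_raster)
            cls = classify_risk(sat_grid, delta_soc_raster, fixed_median)
            a = area_by_class(cls)["area_mha"].to_numpy()
        areas[s] = a
        if sat_all is not None:
            sat_all[s] = sat_s
    if n_truncated:
        logger.info("propagate: %d negative MAOC draws truncated at 0",
                    n_truncated)

    class_areas = pd.DataFrame(
        {
            "class": list(RISK_CLASSES),
            "mean": areas.mean(axis=0),
            "q5": np.percentile(areas, 5, axis=0),
            "q95": np.percentile(areas, 95, axis=0),
        }
    )
    point = pd.DataFrame({"class": list(RISK_CLASSES), "area_mha": areas0})
    sat_q = None
    if sat_all is not None:
        sat_q = pd.DataFrame(
            {
                "q5": np.percentile(sat_all, 5, axis=0),
                "q95": np.percentile(sat_all, 95, axis=0),
            }
        )
    return UncertaintySummary(
        class_areas=class_areas,
        point_areas=point,
        n_sim=n_sim,
        n_truncated=n_truncated,
        saturation_q=sat_q,
    )
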