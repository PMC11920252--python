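"""End-to-end orchestration: simulate -> predict -> cluster -> capacity ->
risk -> uncertainty.

``run_pipeline`` chains the full analysis on a (possibly synthetic) dataset
and optionally writes the table-shaped CSV outputs: per-class areas with
Monte-Carlo Q5/Q95 per method, and the cross-method agreement accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .capacity_estimation import (
    CapacityModel,
    bin_saturation,
    fit_capacity_by_cluster,
    saturation_degree,
    to_fine_fraction_basis,
)
from .pedoclimatic_clustering import ClusterModel, kmeans_ensemble, upscale_clusters
from .risk_mapping import RiskResult, assess_risk, delta_soc_vs_ratio_fit
from .spectral_calibration import (
    MblResult,
    SpectrumSet,
    fit_f_ratio,
    mbl_predict,
    prediction_metrics,
    preprocess_spectra,
)
from .synthetic_data import RasterStack, SimConfig, gen_delta_soc, \
    gen_fractions_and_soc, gen_pedoclimate_sites, gen_rasters, gen_spectra
from .uncertainty import UncertaintySummary, compute_emale, propagate

METHODS = ("BL", "PBL", "NBL")


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    fractions: pd.DataFrame            # measured + in-domain predicted fractions
    mbl: MblResult
    screen: pd.DataFrame
    validation: dict                   # prediction metrics vs measured SOC
    cluster_model: ClusterModel
    capacity_models: dict[str, dict[int, CapacityModel]]
    saturation: pd.DataFrame           # per sample per method
    bins: dict[str, pd.DataFrame]
    rasters: RasterStack
    cluster_raster: np.ndarray
    risk: RiskResult
    uncertainty: dict[str, UncertaintySummary]
    delta_soc_fit: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame


def run_pipeline(
    cfg: SimConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    *,
    methods: tuple[str, ...] = METHODS,
    cluster_seeds: int = 20,
    cluster_starts: int = 10,
    k_max: int = 8,
    n_sim: int = 500,
    median_mode: str = "per-method",
) -> PipelineResult:
    """Run the full analysis on a synthetic dataset.

    The clustering ensemble and the candidate-k ceiling default to reduced
    sizes appropriate for the synthetic problem (the estimator is unchanged;
    only the number of repetitions differs).
    """
    cfg = cfg if cfg is not None else SimConfig(seed=seed)
    if cfg.seed != seed:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})

    # --- simulate -----------------------------------------------------------
    sites = gen_pedoclimate_sites(cfg)
    sites = gen_fractions_and_soc(sites, cfg)
    sites = gen_delta_soc(sites, cfg)
    spectra = gen_spectra(sites, cfg)
    rasters = gen_rasters(cfg)

    # --- spectral prediction ------------------------------------------------
    processed = preprocess_spectra(spectra.to_absorbance())
    calib_mask = sites["is_calibration"].to_numpy(bool)
    id_pos = {sid: i for i, sid in enumerate(processed.ids)}
    order = np.array([id_pos[s] for s in sites["site_id"]])
    calib_spec = processed.subset(order[calib_mask])
    query_spec = processed.subset(order[~calib_mask])
    calib_targets = sites.loc[calib_mask, ["poc", "maoc"]]
    query_soc = sites.loc[~calib_mask, "soc"].to_numpy(float)

    mbl = mbl_predict(calib_spec, calib_targets, query_spec, query_soc)
    fmodel = fit_f_ratio(calib_spec, calib_targets)
    screen = fmodel.screen(query_spec)

    preds = mbl.predictions.merge(
        screen[["site_id", "f_probability", "in_domain"]], on="site_id"
    )
    preds = preds[preds["in_domain"]]

    pred_cols = sites.set_index("site_id")
    pred_soc = pred_cols.loc[preds["site_id"], "soc"].to_numpy(float)
    pred_sum = preds["poc_pred"].to_numpy() + preds["maoc_pred"].to_numpy()
    ok = pred_sum > 0
    validation = {
        "soc_sum": prediction_metrics(pred_soc[ok], pred_sum[ok]),
        "n_in_domain": int(len(preds)),
        "n_excluded_soc_range": int(len(mbl.excluded_ids)),
    }

    # --- combined fraction dataset (measured calibration + predictions) -----
    measured = sites.loc[calib_mask, ["site_id", "fine_fraction", "poc", "maoc",
                                      "delta_soc"]].copy()
    predicted = preds[["site_id"]].copy()
    predicted["fine_fraction"] = pred_cols.loc[
        preds["site_id"], "fine_fraction"
    ].to_numpy()
    predicted["poc"] = preds["poc_pred"].to_numpy()
    predicted["maoc"] = preds["maoc_pred"].to_numpy()
    predicted["delta_soc"] = pred_cols.loc[
        preds["site_id"], "delta_soc"
    ].to_numpy()
    fractions = pd.concat([measured, predicted], ignore_index=True)
    fractions = fractions[fractions["maoc"] > 0]

    # --- clustering ---------------------------------------------------------
    cluster_model = kmeans_ensemble(
        sites, k_max=k_max, seeds=cluster_seeds, starts=cluster_starts,
        base_seed=seed,
    )
    label_of = pd.Series(cluster_model.labels, index=sites["site_id"])
    fractions["cluster_id"] = label_of.loc[fractions["site_id"]].to_numpy()
    cluster_raster = upscale_clusters(
        cluster_model, {c: rasters[c] for c in cluster_model.covariates}
    )

    # --- capacity and saturation -------------------------------------------
    capacity_models: dict[str, dict[int, CapacityModel]] = {}
    bins: dict[str, pd.DataFrame] = {}
    sat_frames = []
    for method in methods:
        models = fit_capacity_by_cluster(fractions, method)
        capacity_models[method] = models
        ff = fractions["fine_fraction"].to_numpy(float)
        maoc_ff = to_fine_fraction_basis(fractions["maoc"].to_numpy(float), ff)
        sat = np.empty(len(fractions))
        for cl, model in models.items():
            m = fractions["cluster_id"].to_numpy() == cl
            sat[m] = saturation_degree(maoc_ff[m], model, ff[m])[
                "saturation_pct"
            ].to_numpy()
        sat_frames.append(
            pd.DataFrame(
                {
                    "site_id": fractions["site_id"],
                    "method": method,
                    "saturation_pct": sat,
                }
            )
        )
        bins[method] = bin_saturation(
            sat, fractions["cluster_id"], ff
        )
    saturation = pd.concat(sat_frames, ignore_index=True)

    # --- risk mapping -------------------------------------------------------
    risk = assess_risk(
        bins, cluster_raster, rasters["fine_fraction"], rasters["delta_soc"],
        median_mode=median_mode,
        reference="NBL" if "NBL" in methods else methods[0],
    )

    # --- uncertainty --------------------------------------------------------
    error = compute_emale(pred_sum[ok], pred_soc[ok])
    uncertainty = {}
    for method in methods:
        uncertainty[method] = propagate(
            fractions, capacity_models[method], cluster_raster,
            rasters["fine_fraction"], rasters["delta_soc"], error,
            n_sim=n_sim, seed=seed,
        )

    dsoc_fit = delta_soc_vs_ratio_fit(fractions)

    table1 = pd.concat(
        [u.class_areas.assign(method=m) for m, u in uncertainty.items()],
        ignore_index=True,
    )[["method", "class", "mean", "q5", "q95"]]
    table2 = risk.agreement

    result = PipelineResult(
        sites=sites, fractions=fractions, mbl=mbl, screen=screen,
        validation=validation, cluster_model=cluster_model,
        capacity_models=capacity_models, saturation=saturation, bins=bins,
        rasters=rasters, cluster_raster=cluster_raster, risk=risk,
        uncertainty=uncertainty, delta_soc_fit=dsoc_fit,
        table1=table1, table2=table2,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.sites.to_csv(outdir / "samples.csv", index=False)
    res.fractions.to_csv(outdir / "fractions.csv", index=False)
    res.saturation.to_csv(outdir / "saturation.csv", index=False)
    res.table1.to_csv(outdir / "table1_class_areas.csv", index=False)
    res.table2.to_csv(outdir / "table2_agreement.csv", index=False)
    res.delta_soc_fit.to_csv(outdir / "delta_soc_vs_ratio.csv", index=False)
    params = []
    for method, models in res.capacity_models.items():
        for cl, m in models.items():
            params.append(
                {"method": method, "cluster_id": cl, "alpha": m.alpha,
                 "beta": m.beta, "breakpoint": m.breakpoint, "tau": m.tau}
            )
    pd.DataFrame(params).to_csv(outdir / "capacity_params.csv", index=False)
    _io.write_ascii_grid(outdir / "cluster.asc", res.cluster_raster)
    for method, grid in res.risk.class_rasters.items():
        _io.write_ascii_grid(
            outdir / f"risk_{method}.asc",
            np.where(grid == 0, np.nan, grid.astype(float)),
        )
    for method, grid in res.risk.saturation_rasters.items():
        _io.write_ascii_grid(outdir / f"saturation_{method}.asc", grid)
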