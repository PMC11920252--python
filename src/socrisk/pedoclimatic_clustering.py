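"""Pedo-climatic zoning by ensemble k-means and raster upscaling.

Sites are clustered on (pH, aridity, NPP, landform), all scaled to unit
variance.  The k-means is repeated over many random seeds, each running
best-of-``starts`` restarts per candidate k; within each repetition the number
of clusters is picked by the elbow of the within-cluster sum-of-squares (WSS)
curve, and the final k is the most frequent choice across repetitions (ties
broken toward smaller k, for parsimony).  Cluster labels are upscaled to a
raster grid by a random-forest classifier trained on the scaled covariates.
Landform is an ordinal class treated as numeric, consistent with its scaled
use alongside the continuous covariates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .synthetic_data import CLUSTER_COVARIATES

K_MAX_DEFAULT = 20


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs."""


@dataclass
class ClusterModel:
    """A fitted pedo-climatic clustering.

    ``centers`` live in the scaled covariate space; ``scaling`` holds the
    per-variable mean/sd used (and required for any raster upscaling);
    ``labels`` are 1..k; ``wss_curve`` is the WSS per candidate k from the
    final repetition; ``k_votes`` counts the k selected in each repetition.
    """

    k: int
    centers: np.ndarray
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    labels: np.ndarray
    wss_curve: dict[int, float]
    k_votes: Counter
    covariates: tuple[str, ...] = CLUSTER_COVARIATES
    X_scaled: np.ndarray | None = None
    random_state: int = 0

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.scale_mean) / self.scale_sd


def elbow_select_k(wss_curve, k_values=None) -> int:
    """Elbow of a WSS curve: the interior k with maximum curvature.

    The discrete second difference ``d(k) = wss(k-1) - 2 wss(k) + wss(k+1)``
    measures how sharply the curve bends at k; the elbow is its maximum over
    interior k -- equivalently the minimum of the second derivative of the
    explained-variance curve.  Ties break toward the smallest interior k.
    """
    wss = np.asarray(list(wss_curve), float)
    if wss.size < 3:
        raise ClusteringError("wss_curve needs at least 3 consecutive k values")
    if k_values is None:
        k_values = np.arange(1, wss.size + 1)
    k_values = np.asarray(list(k_values), int)
    if k_values.size != wss.size:
        raise ClusteringError("k_values must match wss_curve length")
    d = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]
    best = int(np.argmax(np.isclose(d, d.max(), rtol=1e-12, atol=1e-12)))
    return int(k_values[1:-1][best])


def kmeans_ensemble(
    sites: pd.DataFrame,
    *,
    k_max: int = K_MAX_DEFAULT,
    seeds: int = 100,
    starts: int = 100,
    base_seed: int = 0,
    covariates: tuple[str, ...] = CLUSTER_COVARIATES,
) -> ClusterModel:
    """Ensemble k-means with elbow-voted cluster count.

    WSS is evaluated for k = 1..k_max (k = 1 anchors the curve so k = 2 is an
    interior candidate).  Each of ``seeds`` repetitions runs best-of-``starts``
    k-means (Lloyd) per k, selects k by :func:`elbow_select_k`, and votes; the
    most frequent k wins (ties toward smaller k) and the final model is
    refitted at that k.
    """
    for c in covariates:
        if c not in sites:
            raise ClusteringError(f"sites lack covariate {c!r}")
    X = sites.loc[:, list(covariates)].to_numpy(float)
    n = X.shape[0]
    if n < k_max:
        raise ClusteringError(f"n_sites = {n} < k_max = {k_max}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd

    k_values = np.arange(1, k_max + 1)
    votes: Counter = Counter()
    last_wss: dict[int, float] = {}
    for it in range(seeds):
        rs = base_seed + it
        wss = []
        for k in k_values:
            if k == 1:
                wss.append(float(((Xs - Xs.mean(axis=0)) ** 2).sum()))
            else:
                km = KMeans(
                    n_clusters=int(k), n_init=starts, random_state=rs,
                    algorithm="lloyd",
                ).fit(Xs)
                wss.append(float(km.inertia_))
        last_wss = dict(zip(k_values.tolist(), wss))
        votes[elbow_select_k(wss, k_values)] += 1

    k_final = min(
        votes, key=lambda k: (-votes[k], k)
    )  # most frequent, ties toward smaller k
    km = KMeans(
        n_clusters=k_final, n_init=starts, random_state=base_seed,
        algorithm="lloyd",
    ).fit(Xs)
    return ClusterModel(
        k=k_final,
        centers=km.cluster_centers_,
        scale_mean=mean,
        scale_sd=sd,
        labels=km.labels_ + 1,
        wss_curve=last_wss,
        k_votes=votes,
        covariates=tuple(covariates),
        X_scaled=Xs,
        random_state=base_seed,
    )


def upscale_clusters(
    model: ClusterModel,
    covariate_rasters: dict[str, np.ndarray],
    *,
    n_trees: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Predict per-cell cluster labels with a random-forest classifier.

    The forest is trained on the model's scaled training covariates and
    labels.  Cells with any missing covariate get a missing (NaN) label.
    Cluster labels are nominal, so classification (majority vote) is used.
    """
    if model.X_scaled is None:
        raise ClusteringError("model lacks stored training covariates")
    missing = [c for c in model.covariates if c not in covariate_rasters]
    if missing:
        raise ClusteringError(f"covariate rasters missing {missing}")
    shapes = {covariate_rasters[c].shape for c in model.covariates}
    if len(shapes) != 1:
        raise ClusteringError("covariate rasters are not co-registered")
    shape = shapes.pop()

    stack = np.stack(
        [np.asarray(covariate_rasters[c], float).ravel() for c in model.covariates],
        axis=1,
    )
    valid = np.all(np.isfinite(stack), axis=1)
    out = np.full(stack.shape[0], np.nan)
    if valid.any():
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=model.random_state if seed is None else seed,
        )
        rf.fit(model.X_scaled, model.labels)
        out[valid] = rf.predict(model.scale(stack[valid]))
    return out.reshape(shape)
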