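"""Seed-reproducible synthetic soil datasets.

Every downstream stage of the capacity/risk analysis is testable without the
original survey downloads: this module generates cluster-structured
pedo-climatic covariates, carbon fractions bounded above by known capacity
curves, VNIR spectra that are linearly informative about the fractions, SOC
change (dSOC) positively coupled to the MAOC:SOC ratio, and co-registered
spatially autocorrelated raster grids (1 km cells, 100 ha each).

The defaults encode the study conditions the analysis assumes: three
pedo-climatic clusters whose true capacity curves follow, one each, the
constant (BL), piecewise-plateau (PBL) and logarithmic (NBL) boundary shape;
saturation fractions u ~ Beta(5, 2) so the 90th quantile carries mass near the
boundary; reflectance spectra on the 380-2500 nm grid at 0.5 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectral_calibration import SpectrumSet

CAPACITY_METHODS = ("BL", "PBL", "NBL")
#: Covariates entering the pedo-climatic clustering, in column order.
CLUSTER_COVARIATES = ("ph", "aridity", "npp", "landform")
#: Area of one raster cell (1 km grid), in hectares.
CELL_AREA_HA = 100.0


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class ClusterCapacity:
    """True effective MAOC capacity curve of one pedo-climatic cluster.

    ``beta_true`` is on the soil basis for BL (g MAOC kg-1 soil per ff %,
    giving a constant ``100 * beta_true`` on the fine-fraction basis), the
    plateau (g MAOC kg-1 ff) for PBL and the natural-log coefficient for NBL.
    ``low_ff_slope`` (PBL only) is the boundary excess per ff % below the
    breakpoint, emulating POC contamination of coarse soils.
    """

    method_truth: str
    beta_true: float
    breakpoint_true: float | None = None
    low_ff_slope: float = 0.85

    def __post_init__(self) -> None:
        if self.method_truth not in CAPACITY_METHODS:
            raise SimConfigError(f"unknown capacity method {self.method_truth!r}")
        if self.beta_true <= 0:
            raise SimConfigError("beta_true must be positive")
        if self.method_truth == "PBL":
            if self.breakpoint_true is None or not 0 < self.breakpoint_true < 100:
                raise SimConfigError("PBL needs a breakpoint in (0, 100)")

    def capacity_ff(self, ff: np.ndarray) -> np.ndarray:
        """True capacity (g MAOC kg-1 fine fraction) at fine fraction ff (%)."""
        ff = np.asarray(ff, float)
        if self.method_truth == "BL":
            return np.full(ff.shape, 100.0 * self.beta_true)
        if self.method_truth == "PBL":
            return self.beta_true + self.low_ff_slope * np.clip(
                self.breakpoint_true - ff, 0.0, None
            )
        return self.beta_true * np.log(np.clip(ff, 1.5, None))


@dataclass(frozen=True)
class SpectraParams:
    n_wavelengths: int = 4241          # 380-2500 nm at 0.5 nm
    noise_sd: float = 0.0015           # sd of the smooth reflectance noise
    loading_smoothness: float = 150.0  # Gaussian sigma of loadings, grid points


@dataclass(frozen=True)
class DeltaSocParams:
    slope_true: float = 10.0     # g C kg-1 per unit MAOC:SOC ratio
    intercept_true: float = -7.5
    noise_sd: float = 2.0
    cluster_offset_sd: float = 0.5


_DEFAULT_CAPACITIES = (
    ClusterCapacity("BL", 0.45),
    ClusterCapacity("PBL", 34.1, breakpoint_true=30.0),
    ClusterCapacity("NBL", 12.0),
)

# raw-unit cluster centers: pH (H2O), aridity index, NPP (kg C m-2 yr-1),
# landform class -- a humid-north, temperate-lowland and Mediterranean zone
_DEFAULT_CENTERS = np.array(
    [
        [5.0, 1.20, 0.90, 3.0],
        [6.8, 0.90, 0.70, 2.0],
        [7.8, 0.45, 0.40, 4.0],
    ]
)
_DEFAULT_SDS = np.array([0.35, 0.10, 0.10, 0.9])


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; all outputs are reproducible from (cfg, seed)."""

    n_sites: int = 2000
    n_clusters_true: int = 3
    seed: int = 0
    capacity_params: tuple[ClusterCapacity, ...] = _DEFAULT_CAPACITIES
    spectra_params: SpectraParams = SpectraParams()
    delta_soc_params: DeltaSocParams = DeltaSocParams()
    grid_shape: tuple[int, int] = (100, 100)
    n_calibration: int | None = None   # default: min(300, n_sites // 2)
    cluster_centers: tuple | None = None   # (K, 4) raw-unit override
    cluster_sds: tuple | None = None       # (4,) override
    ff_range: tuple[float, float] = (5.0, 95.0)
    ff_beta: tuple[float, float] = (2.0, 2.0)
    u_beta: tuple[float, float] = (5.0, 2.0)
    ratio_range: tuple[float, float] = (0.3, 0.98)

    def validate(self) -> None:
        if self.n_sites <= 0:
            raise SimConfigError("n_sites must be positive")
        if self.n_clusters_true <= 0:
            raise SimConfigError("n_clusters_true must be positive")
        if len(self.capacity_params) != self.n_clusters_true:
            raise SimConfigError(
                "capacity_params must have one entry per true cluster"
            )
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise SimConfigError("grid_shape must be positive")
        if self.n_calibration is not None and self.n_calibration > self.n_sites:
            raise SimConfigError("n_calibration cannot exceed n_sites")
        _ = self.centers  # shape checks

    @property
    def n_calib(self) -> int:
        if self.n_calibration is not None:
            return self.n_calibration
        return max(1, min(300, self.n_sites // 2))

    @property
    def centers(self) -> np.ndarray:
        if self.cluster_centers is not None:
            c = np.asarray(self.cluster_centers, float)
        elif self.n_clusters_true <= 3:
            c = _DEFAULT_CENTERS[: self.n_clusters_true]
        else:
            k = self.n_clusters_true
            c = np.column_stack(
                [
                    np.linspace(4.8, 8.2, k),
                    np.linspace(1.3, 0.35, k),
                    np.linspace(1.0, 0.3, k),
                    1 + np.arange(k) % 6,
                ]
            )
        if c.shape != (self.n_clusters_true, 4):
            raise SimConfigError(
                f"cluster_centers must have shape ({self.n_clusters_true}, 4)"
            )
        return c

    @property
    def sds(self) -> np.ndarray:
        s = np.asarray(
            self.cluster_sds if self.cluster_sds is not None else _DEFAULT_SDS, float
        )
        if s.shape != (4,):
            raise SimConfigError("cluster_sds must have 4 entries")
        return s

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per generation stage, reproducible from seed."""
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# Site covariates
# ---------------------------------------------------------------------------

def gen_pedoclimate_sites(cfg: SimConfig) -> pd.DataFrame:
    """Draw sites from Gaussian blobs in (pH, aridity, NPP, landform) space.

    Fine fraction is drawn per site from a scaled Beta distribution spanning
    roughly 5-95 %, split into clay and silt.  A random subset of
    ``cfg.n_calibration`` sites is flagged as the fraction-calibration set.
    """
    cfg.validate()
    rng = cfg.rng(1)
    k = cfg.n_clusters_true
    labels = rng.integers(0, k, size=cfg.n_sites)
    centers, sds = cfg.centers, cfg.sds

    cov = centers[labels] + rng.normal(size=(cfg.n_sites, 4)) * sds
    ph = np.clip(cov[:, 0], 3.5, 9.5)
    aridity = np.clip(cov[:, 1], 0.05, None)
    npp = np.clip(cov[:, 2], 0.05, None)
    landform = np.clip(np.rint(cov[:, 3]), 1, 6).astype(int)

    lo, hi = cfg.ff_range
    ff = lo + (hi - lo) * rng.beta(*cfg.ff_beta, size=cfg.n_sites)
    clay_share = rng.uniform(0.3, 0.7, size=cfg.n_sites)
    clay = ff * clay_share
    silt = ff - clay

    nrow, ncol = cfg.grid_shape
    calib = np.zeros(cfg.n_sites, bool)
    calib[rng.choice(cfg.n_sites, size=cfg.n_calib, replace=False)] = True

    return pd.DataFrame(
        {
            "site_id": np.arange(cfg.n_sites),
            "x": rng.uniform(0, ncol, cfg.n_sites),
            "y": rng.uniform(0, nrow, cfg.n_sites),
            "ph": ph,
            "aridity": aridity,
            "npp": npp,
            "landform": landform,
            "clay": clay,
            "silt": silt,
            "fine_fraction": ff,
            "cluster_true": labels + 1,
            "is_calibration": calib,
        }
    )


# ---------------------------------------------------------------------------
# Carbon fractions, bounded by the true capacity curves
# ---------------------------------------------------------------------------

def gen_fractions_and_soc(sites: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Fill in POC, MAOC and SOC, with MAOC bounded by the true capacity.

    MAOC on the fine-fraction basis is ``capacity(ff) * u`` with
    ``u ~ Beta(a, b)`` on (0, 1], converted to the soil basis; POC is drawn so
    the MAOC:SOC ratio spans roughly ``cfg.ratio_range``; SOC = POC + MAOC
    exactly (the generator is noiseless in this identity).
    """
    if "fine_fraction" not in sites:
        raise SimConfigError("sites lack fine_fraction; run gen_pedoclimate_sites")
    labels = sites["cluster_true"].to_numpy()
    if labels.min() < 1 or labels.max() > cfg.n_clusters_true:
        raise SimConfigError("unknown cluster label in sites")
    rng = cfg.rng(2)
    ff = sites["fine_fraction"].to_numpy(float)

    cap = np.empty(len(sites))
    for c, params in enumerate(cfg.capacity_params, start=1):
        mask = labels == c
        cap[mask] = params.capacity_ff(ff[mask])

    u = np.clip(rng.beta(*cfg.u_beta, size=len(sites)), 1e-9, 1.0)
    maoc_ff = cap * u
    maoc = maoc_ff * ff / 100.0
    ratio = rng.uniform(*cfg.ratio_range, size=len(sites))
    poc = maoc * (1.0 / ratio - 1.0)

    out = sites.copy()
    out["maoc_capacity_true"] = cap
    out["maoc"] = maoc
    out["poc"] = poc
    out["soc"] = poc + maoc
    return out


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _smooth_noise(rng, shape, sigma):
    """White noise smoothed along the last axis, renormalized to unit sd."""
    z = ndimage.gaussian_filter1d(rng.normal(size=shape), sigma, axis=-1)
    sd = z.std()
    return z / sd if sd > 0 else z


#: reflectance amplitude of each constituent loading (maoc, poc, clay, pH);
#: scaled so baseline + signal stays inside the physical reflectance range
_LOADING_AMPLITUDES = (0.030, 0.020, 0.025, 0.015)


def gen_spectra(sites: pd.DataFrame, cfg: SimConfig) -> SpectrumSet:
    """Reflectance spectra linearly informative about (maoc, poc, clay, pH).

    reflectance = smooth baseline + smooth loading vectors x standardized
    constituents + spatially correlated noise, on the 380-2500 nm grid.
    """
    for col in ("maoc", "poc", "clay", "ph"):
        if col not in sites:
            raise SimConfigError(f"sites lack {col}; run gen_fractions_and_soc")
    rng = cfg.rng(3)
    sp = cfg.spectra_params
    n_wl = sp.n_wavelengths
    wl = 380.0 + 0.5 * np.arange(n_wl)

    consts = sites.loc[:, ["maoc", "poc", "clay", "ph"]].to_numpy(float)
    z = (consts - consts.mean(axis=0)) / np.where(
        consts.std(axis=0) > 0, consts.std(axis=0), 1.0
    )

    loadings = _smooth_noise(rng, (4, n_wl), sp.loading_smoothness)
    loadings *= np.asarray(_LOADING_AMPLITUDES)[:, None]
    baseline = 0.5 + 0.04 * _smooth_noise(rng, n_wl, sp.loading_smoothness * 2)
    if sp.noise_sd > 0:
        # per-sample baseline offsets are part of the stochastic noise model
        offsets = 0.01 * rng.normal(size=(len(sites), 1))
        noise = _smooth_noise(rng, (len(sites), n_wl), 10.0) * sp.noise_sd
    else:
        offsets, noise = 0.0, 0.0
    refl = np.clip(baseline + offsets + z @ loadings + noise, 0.02, 0.98)
    return SpectrumSet(
        wl, refl, sites["site_id"].to_numpy(), {"absorbance": False}
    )


# ---------------------------------------------------------------------------
# SOC change
# ---------------------------------------------------------------------------

def gen_delta_soc(sites: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """SOC change 2009-2018 style: positively coupled to the MAOC:SOC ratio.

    dSOC = intercept + slope * MAOC/(MAOC+POC) + cluster offset + noise, with
    a positive slope so that losses associate with low MAOC:SOC.  Sites with
    MAOC + POC = 0 are excluded with a warning.
    """
    for col in ("maoc", "poc"):
        if col not in sites:
            raise SimConfigError(f"sites lack {col}; run gen_fractions_and_soc")
    rng = cfg.rng(4)
    p = cfg.delta_soc_params
    total = sites["maoc"].to_numpy(float) + sites["poc"].to_numpy(float)
    ok = total > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} sites with MAOC + POC = 0 excluded from dSOC",
            stacklevel=2,
        )
    out = sites.loc[ok].copy()
    ratio = out["maoc"].to_numpy(float) / total[ok]
    k = cfg.n_clusters_true
    offsets = (
        np.linspace(-1.0, 1.0, k) * p.cluster_offset_sd if k > 1 else np.zeros(1)
    )
    cluster_off = offsets[out["cluster_true"].to_numpy() - 1]
    noise = rng.normal(scale=p.noise_sd, size=len(out)) if p.noise_sd > 0 else 0.0
    out["maoc_soc_ratio"] = ratio
    out["delta_soc"] = p.intercept_true + p.slope_true * ratio + cluster_off + noise
    return out


# ---------------------------------------------------------------------------
# Raster grids
# ---------------------------------------------------------------------------

@dataclass
class RasterStack:
    """Co-registered single-band grids on a 1 km lattice (100 ha cells)."""

    grids: dict[str, np.ndarray]
    cell_area_ha: float = CELL_AREA_HA
    cellsize_m: float = 1000.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.grids[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape


def gen_rasters(cfg: SimConfig, capacity_truth=None) -> RasterStack:
    """Co-registered covariate, fine-fraction and dSOC grids.

    A nearest-seed tessellation assigns each cell a true cluster; covariates
    are the cluster center plus smoothed Gaussian noise (spatially
    autocorrelated); dSOC is positively coupled to a smooth latent saturation
    field.  ``capacity_truth`` defaults to ``cfg.capacity_params``.
    """
    cfg.validate()
    rng = cfg.rng(5)
    nrow, ncol = cfg.grid_shape
    k = cfg.n_clusters_true
    centers, sds = cfg.centers, cfg.sds

    seeds = rng.uniform(0, 1, size=(k, 2)) * np.array([nrow, ncol])
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    d2 = (rr[None] - seeds[:, 0, None, None]) ** 2 + (
        cc[None] - seeds[:, 1, None, None]
    ) ** 2
    cluster = np.argmin(d2, axis=0) + 1

    sigma = 3.0
    grids: dict[str, np.ndarray] = {"cluster_true": cluster.astype(float)}
    for i, name in enumerate(CLUSTER_COVARIATES):
        field2d = centers[cluster - 1, i] + sds[i] * _smooth_noise(
            rng, (nrow, ncol), sigma
        )
        if name == "landform":
            field2d = np.clip(np.rint(field2d), 1, 6)
        grids[name] = field2d

    ff = 50.0 + 28.0 * _smooth_noise(rng, (nrow, ncol), sigma)
    grids["fine_fraction"] = np.clip(ff, 0.0, 100.0)

    # latent saturation in (0, 1], smooth; dSOC coupled to it positively
    u01 = ndimage.gaussian_filter(rng.normal(size=(nrow, ncol)), sigma)
    u01 = (u01 - u01.mean()) / (u01.std() or 1.0)
    from scipy.stats import norm

    u_field = np.clip(norm.cdf(u01), 1e-6, 1.0)
    grids["saturation_latent"] = u_field
    p = cfg.delta_soc_params
    ratio_field = 0.3 + 0.68 * u_field
    grids["delta_soc"] = (
        p.intercept_true
        + p.slope_true * ratio_field
        + 0.5 * _smooth_noise(rng, (nrow, ncol), sigma)
    )
    return RasterStack(grids)


def lag1_autocorrelation(grid: np.ndarray) -> float:
    """Mean lag-1 spatial autocorrelation along rows and columns."""
    g = np.asarray(grid, float)
    z = (g - g.mean()) / (g.std() or 1.0)
    r_row = np.mean(z[:, :-1] * z[:, 1:])
    r_col = np.mean(z[:-1, :] * z[1:, :])
    return float(0.5 * (r_row + r_col))
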