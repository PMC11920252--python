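# socrisk

Effective mineral-associated organic carbon (MAOC) capacity, degree of soil
carbon saturation, and a four-class soil-organic-carbon (SOC) risk index for
pedo-climatic clusters.

## The problem

Bulk SOC splits into particulate organic carbon (POC, > 53 µm, labile) and
mineral-associated organic carbon (MAOC, < 53 µm, persistent).  Because MAOC
binds to fine mineral surfaces, a soil's fine fraction (clay + silt, *ff* in
%) imposes an upper bound on how much MAOC it can hold.  Rather than a single
mineralogical maximum, this package estimates an **effective MAOC capacity**
— the biophysically achievable bound within a zone of similar pH, aridity,
net primary productivity (NPP) and landform — and combines the resulting
**degree of MAOC saturation** with SOC change (ΔSOC) into a spatial risk
index for carbon management.  It is aimed at soil scientists and carbon-
monitoring practitioners working with survey data (fractionation subsets,
VNIR spectra, covariate rasters).

## The method

1. **Spectral prediction** (`spectral_calibration`).  POC and MAOC are
   predicted from visible/near-infrared spectra (380–2500 nm) by
   memory-based learning: for each query, the *k* nearest calibration
   spectra under a moving-window correlation dissimilarity are used to fit a
   local partial least squares (PLS) model, and predictions over component
   counts *j* = 5…15 are blended by weighted-average PLS with weights

   *w(j) = 1 / (δ(1:j) · g(j))*,

   where δ(1:j) is the RMSE of the query's spectral reconstruction residual
   and g(j) the RMS of the regression coefficients.  An F-ratio screen,
   F = ‖u − û‖² · n_c / s_c², flags queries outside the calibration
   applicability domain at the 0.99 probability level.
2. **Pedo-climatic clustering** (`pedoclimatic_clustering`).  Ensemble
   k-means on unit-variance (pH, aridity, NPP, landform); the cluster count
   is elbow-selected per repetition and voted across repetitions; labels are
   upscaled to a 1 km raster with a random-forest classifier.
3. **Capacity estimation** (`capacity_estimation`).  Per cluster, three
   boundary-line quantile regressions at τ = 0.9 with intercept forced to 0:
   a straight line through the origin (BL), a piecewise line with a plateau
   after a profiled breakpoint (PBL), and a logarithmic boundary
   y = β·log(*ff*) (NBL).  Saturation = MAOC / capacity × 100, capped at
   100 %.
4. **Risk mapping** (`risk_mapping`).  Cluster-binned mean saturation (10 %
   *ff* bins) is looked up per raster cell; each cell is classified by
   saturation above/below the median and ΔSOC sign into HR (high risk), HH
   (high hazard), NR (no risk), NH (no hazard); areas are accounted in Mha
   and cross-method agreement is tabulated.
5. **Uncertainty** (`uncertainty`).  MAOC prediction error is summarized by
   the mean absolute log error (MALE, with EMALE = exp(MALE)); MAOC is
   resampled 500 times with sd = (EMALE − 1)/2 × MAOC and the 5th/95th
   percentiles of each class area are reported.

A seed-reproducible generator (`synthetic_data`) emulates every input —
cluster-structured covariates, capacity-bounded fractions, linearly
informative spectra, ratio-coupled ΔSOC and autocorrelated rasters — so the
whole chain runs without any survey download.

## Worked example

```python
import numpy as np
from socrisk import *

cfg = SimConfig(n_sites=2000, n_clusters_true=1, seed=11,
                capacity_params=(ClusterCapacity("BL", 0.45),))
sites = gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg)
ff, maoc = sites["fine_fraction"].to_numpy(), sites["maoc"].to_numpy()

model = fit_bl(ff, maoc)
print(f"fitted boundary slope      : {model.beta:.3f} g MAOC kg-1 soil per ff %")
print(f"effective capacity (ff)    : {100*model.beta:.1f} g MAOC kg-1 fine fraction")
print(f"points above the boundary  : {np.mean(maoc > model.beta*ff):.3f}")

sat = saturation_degree(to_fine_fraction_basis(maoc, ff), model, ff)
print(f"median MAOC saturation     : {np.median(sat['saturation_pct']):.1f} %")
print(f"samples at capacity (100 %): {int((sat['saturation_pct'] == 100).sum())}")
```

prints

```
fitted boundary slope      : 0.407 g MAOC kg-1 soil per ff %
effective capacity (ff)    : 40.7 g MAOC kg-1 fine fraction
points above the boundary  : 0.104
median MAOC saturation     : 81.4 %
samples at capacity (100 %): 209
```

The generator drew MAOC under a boundary of 0.45 g kg⁻¹ soil per *ff* %
(45 g kg⁻¹ fine fraction); the 90th-quantile line through the origin
recovers 40.7 — the 0.9 quantile of the fill distribution times the true
boundary — leaving 10.4 % of the points above the fitted line, as a τ = 0.9
fit should.  Saturation is each sample's MAOC relative to that capacity;
samples whose raw ratio exceeds 100 % are treated as saturated.

The same analysis runs from the shell:

```bash
socrisk simulate --out wd --seed 4
socrisk predict --workdir wd
socrisk cluster --workdir wd --seeds 20 --starts 10 --k-max 8 --seed 4
socrisk capacity --workdir wd --method all
socrisk risk --workdir wd
socrisk uncertainty --workdir wd --n-sim 500 --seed 4
```

producing per-class area tables (`table1_class_areas.csv`), the cross-method
agreement table (`table2_agreement.csv`) and ASCII-grid rasters of clusters,
saturation and risk classes.

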