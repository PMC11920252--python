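# Methods

This note documents the models, numerical choices and limitations of the
package: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Boundary-line capacity models

The effective MAOC capacity of a cluster is estimated as a high quantile of
the MAOC–fine-fraction cloud, on the premise that only soils near their
capacity trace the boundary.  All three fitters minimize the τ = 0.9 pinball
(check) loss with the intercept forced to zero:

* **BL** fits MAOC on the soil basis (g kg⁻¹ soil) against *ff* (%) through
  the origin; on the fine-fraction basis the capacity is the constant
  100·β.  The through-origin quantile fit is solved exactly: for x > 0,
  Σ ρ_τ(y − βx) = Σ x·ρ_τ(y/x − β), so the optimum is the x-weighted
  τ-quantile of the pointwise slopes y/x.  The same solver serves NBL with
  x = log *ff*.
* **PBL** fits, on the fine-fraction basis, y = plateau + b₁·min(*ff* − bp, 0):
  a free first segment continuous at the breakpoint bp, constant beyond it.
  The breakpoint is profiled on a 1 % grid; each candidate's two-parameter
  quantile fit is solved as the exact pinball linear program
  (scipy/HiGHS), and the lowest-loss candidate wins, ties toward the
  smaller bp — which also resolves the degenerate flat-boundary case to the
  lower range edge.  Whether the first segment should itself be a quantile
  or a least-squares line was open; quantile is used throughout for
  consistency.  Samples left of the fitted breakpoint are treated as
  MAOC-saturated, reflecting the interpretation that their fine-fraction
  MAOC concentration is inflated by POC contamination or organo-organic
  binding rather than mineral association.
* **NBL** fits y = β·log(*ff*) with the natural logarithm and *ff* in
  percent.  Points with *ff* ≤ 1 % (non-positive log) are excluded with a
  warning; how such soils should enter a log boundary is genuinely
  undetermined, and they are rare in the intended texture range.

A τ-quantile boundary is an estimand below the true physical bound whenever
the fill distribution has mass away from the boundary: with the generator's
Beta(5, 2) saturation fractions, the population value of each fitted
parameter is q₀.₉(Beta(5,2)) ≈ 0.907 times the generating boundary.  Tests
therefore check both recovery of the generating truth (to 10 %) and exact
agreement with an independent pinball grid search (to 2 %), plus the
defining coverage property that ~10 % of points lie above the fit.

Saturation is (MAOC_ff / capacity) × 100, capped at 100 % (values above are
"saturated"); per-cluster fits never pool points across clusters, so one
unusual soil type cannot leverage another zone's boundary.  Fine-fraction
bins are left-closed ([0,10), …, [90,100]); a single-sample bin reports
sd 0, an empty bin is missing and excluded from mapping.

## Spectral calibration

Preprocessing follows the standard chain for this instrument class: every
10th wavelength (0.5 → 5 nm), trim to 400–2450 nm, first difference
quotient on the subsampled grid, excision of the 1350–1460 and 1790–1960 nm
water bands, replicate averaging per site.  The derivative is taken after
subsampling, matching the order in which the operations are listed for the
survey data.

The moving-window correlation dissimilarity between two spectra is
1 − mean over windows of the Pearson correlation of their window segments;
windows are contiguous and non-overlapping (a trailing partial window is
dropped), which keeps the pairwise computation tractable without changing
what the metric responds to.  The window size is chosen from {11, 21, …,
151} points by minimizing the RMSE of single-nearest-neighbor prediction on
the calibration set.  The neighborhood size k ∈ [20, 100] (steps of 10) is
optimized once by nearest-neighbor cross-validation: each calibration
sample is predicted from its own k neighbors and the RMSE is minimized.
Per query, a local PLS (scikit-learn, per-component quantities derived from
the fitted weight/loading/rotation arrays) is fitted on the k neighbors and
combined by WAPLS over j = 5…15 components; the ensemble is a convex
combination of per-component predictions.  A zero WAPLS denominator (an
exact reconstruction) is capped at 10⁶ × the largest finite weight so it
dominates without producing infinities.  Negative fraction predictions are
set to 0, and queries whose measured SOC falls outside the calibration SOC
range are excluded before prediction.  Neighbor ties break by calibration
order under a stable sort.

**Applicability domain.**  F = ‖u − û‖²·n_c / s_c², with û the
reconstruction of the query spectrum from the calibration PLS scores and
s_c² the calibration set's total residual spectral variance.  The
probability attached to F is, by default, the empirical CDF of the
calibration set's own F values, so the 0.99 cut excludes at most ~1 % of
the calibration population by construction.  A parametric F(d₁, d₂) variant
is available (`dof=` argument), but no fixed parametric choice calibrates
well here: spectral residuals are strongly correlated across wavelengths,
so one degree of freedom per retained wavelength (354 after preprocessing)
makes the nominal cut flag ~9 % of the calibration set, and even
moment-matched effective dimensionalities flag 2–3 %.  The empirical null
makes the stated probability mean what it says.

Prediction skill is scored with RMSE, squared Pearson correlation, bias
(mean(pred − obs)), Lin's concordance correlation coefficient, and
RPIQ = IQR(obs)/RMSE.  The conventional RPIQ orientation (larger is better)
is used; descriptions of RPIQ as its reciprocal exist in the literature and
the discrepancy is noted, not resolved.

## Clustering

Sites are clustered on pH (H₂O), aridity index (precipitation over
potential evapotranspiration), NPP (kg C m⁻² yr⁻¹) and an ordinal landform
class treated as numeric, all scaled to unit variance.  Lloyd's k-means
with many random restarts stands in for the Hartigan–Wong algorithm; both
minimize the same within-cluster sum of squares (WSS), and best-of-restarts
makes the difference immaterial at these problem sizes.  The WSS curve is
computed from k = 1 so that k = 2 is an interior candidate; the elbow is
the interior k maximizing the second difference
wss(k−1) − 2·wss(k) + wss(k+1) — equivalently, the minimum of the second
derivative of the explained-variance curve (maximum curvature).  Each of
the ensemble repetitions votes for an elbow and the most frequent k wins,
ties toward smaller k (parsimony).  Note that maximum-curvature elbows
favor coarse partitions when cluster centers are near-collinear: on the
default three-cluster synthetic configuration the ensemble typically
selects k = 2, merging the two most similar zones; the downstream analysis
is defined for whatever k is selected.  Upscaling to the raster uses a
random-forest **classifier** (labels are nominal; the majority vote replaces
a regression on label codes), trained on the scaled covariates; raster
cells missing any covariate get a missing label.

## Risk index

Mean saturation per (cluster, 10 % *ff* bin) is looked up for every raster
cell from the cluster and fine-fraction rasters; cells whose (cluster, bin)
was unobserved in the samples are excluded.  Classification splits on the
median saturation over the classifiable domain (cells at the median go to
the "below" branch so the two sides partition the domain) and on the sign
of ΔSOC (negative = loss): HR = above-median and loss, HH = below-median
and loss, NR = below-median and gain, NH = above-median and gain.  The
median can be computed per method (default) or shared across methods.
Classification is invariant to any strictly monotone transform applied to
both the saturation raster and the median.  Areas are cells × 100 ha
(1 km grid) reported in Mha; cross-method agreement means all methods
assign a cell the same class, and per-class percentages are referenced to
the NBL classification.  A per-cluster ordinary least squares of ΔSOC on
the MAOC:SOC ratio (with Pearson r) summarizes the coupling between
saturation and carbon change.

## Uncertainty propagation

The MAOC prediction error is summarized as MALE = mean |log pred − log obs|
of predicted POC + MAOC against measured SOC, robust to the skewed SOC
distribution; EMALE = exp(MALE) is the multiplicative error.  Under the
equal POC/MAOC contribution assumption the relative sd applied to MAOC is
(EMALE − 1)/2; whether the halving belongs inside the sd was ambiguous, so
the halved form is the default and the unhalved variant is a flag.  Each of
the 500 realizations redraws MAOC ~ Normal(prediction, rel_sd × prediction),
truncates negative draws at 0 (counted and logged), and recomputes
saturation, bins, the gridded lookup, the median (recomputed per
realization by default; a fixed-threshold flag exists) and the class areas;
the per-class mean, Q5 and Q95 are reported.  Capacity models and cluster
labels are held fixed: only MAOC prediction error is propagated.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any real geography: Gaussian covariate blobs define true clusters (default
three zones — humid-north, temperate, Mediterranean — with realistic pH,
aridity, NPP and landform scales); fine fraction is Beta(2,2) scaled to
5–95 %; MAOC on the fine-fraction basis is capacity(*ff*) × u with
u ~ Beta(5,2) on (0,1], so the 90th quantile carries mass near the
boundary; POC is drawn so the MAOC:SOC ratio spans 0.3–0.98 and
SOC = POC + MAOC holds exactly; reflectance spectra on the 380–2500 nm grid
are a smooth baseline plus smooth loading vectors times the standardized
(MAOC, POC, clay, pH) plus spatially correlated noise, scaled to stay
within physical reflectance so the constituent map remains linear; spectra
are converted to apparent absorbance log₁₀(1/R) before preprocessing;
ΔSOC = α + β·(MAOC:SOC) + cluster offset + noise with β > 0 (default 10 g
kg⁻¹ per unit ratio, intercept −7.5, noise sd 2), so losses associate with
low MAOC:SOC; rasters are nearest-seed cluster tessellations with smoothed
Gaussian covariate fields (1 km cells of 100 ha), and the raster ΔSOC is
coupled to a smooth latent saturation field.  The default capacity truths
cover all three boundary shapes (BL slope 0.45 g kg⁻¹ soil per *ff* %, PBL
plateau 34.1 with breakpoint 30 %, NBL log-coefficient 12).

What it does **not** emulate: real spatial patterns, mineralogy,
survey-design stratification, nonlinear spectral responses, instrument
drift, heteroscedastic fractionation error, or geogenic carbon.  Passing
tests therefore demonstrate that the estimators recover known structure
under their own assumptions — not that those assumptions hold for any
particular survey.

## Problem sizes and numerical choices

Tests and the acceptance script use 2 000 samples per boundary-recovery
experiment, 300 calibration + 300 query spectra for the memory-based stage,
a 100 × 100 grid (1 Mha) and 500 Monte-Carlo realizations; the clustering
ensemble runs 20 repetitions × 10 restarts with k ≤ 8 in the pipeline
(the estimator is identical to the 100 × 100 × k ≤ 20 configuration, only
the number of repetitions differs, and the vote is unanimous on separated
synthetic clusters).  Quantile fits are exact (weighted quantile or LP), so
no convergence tolerances arise; LP ties at machine precision resolve to
the smallest breakpoint.  Random streams derive from per-stage seed
sequences, making every artifact reproducible from (config, seed).

## Known limitations

* The effective capacity inherits the τ = 0.9 estimand bias discussed
  above; reported capacities are quantile boundaries, not physical maxima.
* The empirical F-ratio null adapts to whatever heterogeneity the
  calibration set contains; a contaminated calibration set widens the
  domain rather than flagging its own outliers.
* PBL's 1 % breakpoint grid bounds breakpoint resolution at 1 percentage
  point.
* The risk classes depend on a median split, which is relative: they
  compare cells within a map rather than against an absolute saturation
  threshold.
* Uncertainty covers MAOC prediction error only; clustering, ΔSOC and
  covariate rasters are treated as exact.
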