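"""Memory-based spectral prediction of soil carbon fractions.

Predicts particulate (POC) and mineral-associated (MAOC) organic carbon from
VNIR reflectance spectra with a memory-based (local) learning scheme: for each
query spectrum, the k most similar calibration spectra are selected under a
moving-window correlation dissimilarity and a local partial least squares (PLS)
model is fitted.  Predictions over a range of PLS component counts are combined
by weighted-average PLS (WAPLS), where the weight of the j-component model is

    w_j = 1 / (delta_{1:j} * g_j)

with ``delta_{1:j}`` the RMSE of the query's spectral reconstruction residual
from the first j components and ``g_j`` the RMS of the regression coefficient
vector of the j-component model.  An F-ratio applicability-domain screen flags
query spectra whose PLS reconstruction residual is improbably large relative to
the calibration set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger(__name__)

#: Water absorption bands excised during preprocessing (nm).
WATER_BANDS = ((1350.0, 1460.0), (1790.0, 1960.0))
#: Wavelength range retained after trimming (nm).
TRIM_RANGE = (400.0, 2450.0)
#: Candidate moving-window sizes (in retained wavelength points).
WINDOW_CANDIDATES = tuple(range(11, 152, 10))
#: Neighborhood sizes considered for the local models.
K_RANGE = (20, 100)
#: PLS component counts averaged by WAPLS.
J_RANGE = (5, 15)
#: Queries with F-ratio probability above this cut are out of domain.
F_PROBABILITY_CUT = 0.99


class SpectralError(ValueError):
    """Raised for invalid spectra or degenerate calibration inputs."""


# ---------------------------------------------------------------------------
# Spectrum container and preprocessing
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSet:
    """A wavelength grid plus per-sample spectra.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, shape ``(p,)``.
    values
        Per-sample spectra, shape ``(n, p)``.
    ids
        Per-sample identifiers, shape ``(n,)``.
    state
        Preprocessing flags (``subsampled``, ``trimmed``, ``derivative_order``,
        ``water_bands_removed``, ``absorbance``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    ids: np.ndarray
    state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.ids = np.asarray(self.ids)
        if self.values.shape != (len(self.ids), len(self.wavelengths)):
            raise SpectralError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.wavelengths)} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectralError("wavelength grid must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_absorbance(self) -> "SpectrumSet":
        """Convert reflectance to apparent absorbance, log10(1/R)."""
        if self.state.get("absorbance"):
            return self
        vals = np.clip(self.values, 1e-6, None)
        return SpectrumSet(
            self.wavelengths, -np.log10(vals), self.ids,
            {**self.state, "absorbance": True},
        )

    def subset(self, index: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(
            self.wavelengths, self.values[index], self.ids[index], dict(self.state)
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide-format frame: first column site_id, then one column per nm."""
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "site_id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: dict | None = None) -> "SpectrumSet":
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(wl, df.iloc[:, 1:].to_numpy(float), df.iloc[:, 0].to_numpy(),
                   state or {})


def preprocess_spectra(
    raw: SpectrumSet,
    *,
    subsample_step: int = 10,
    trim: tuple[float, float] = TRIM_RANGE,
    water_bands: tuple = WATER_BANDS,
) -> SpectrumSet:
    """Standard VNIR preprocessing chain.

    Replicate spectra (duplicate ids) are averaged, every ``subsample_step``-th
    wavelength is kept, the grid is trimmed to ``trim``, the first derivative
    (difference quotient, assigned to interval midpoints) is taken on the
    subsampled grid, and the water absorption bands are excised.
    """
    wl = raw.wavelengths
    if wl[0] > trim[0] or wl[-1] < trim[1]:
        raise SpectralError(
            f"wavelength grid [{wl[0]}, {wl[-1]}] does not cover trim range {trim}"
        )

    # average replicates per id, preserving first-appearance order
    ids, first_idx, inverse = np.unique(
        raw.ids, return_index=True, return_inverse=True
    )
    if len(ids) < len(raw.ids):
        sums = np.zeros((len(ids), raw.values.shape[1]))
        counts = np.zeros(len(ids))
        np.add.at(sums, inverse, raw.values)
        np.add.at(counts, inverse, 1.0)
        values = sums / counts[:, None]
        order = np.argsort(first_idx)
        ids, values = ids[order], values[order]
    else:
        order = np.argsort(first_idx)
        ids, values = ids[order], raw.values[order]

    keep = slice(None, None, subsample_step)
    wl_s, vals = wl[keep], values[:, keep]
    in_trim = (wl_s >= trim[0]) & (wl_s <= trim[1])
    wl_s, vals = wl_s[in_trim], vals[:, in_trim]

    dv = np.diff(vals, axis=1) / np.diff(wl_s)
    wl_d = 0.5 * (wl_s[:-1] + wl_s[1:])

    keep_bands = np.ones(wl_d.shape, bool)
    for lo, hi in water_bands:
        keep_bands &= ~((wl_d >= lo) & (wl_d <= hi))

    return SpectrumSet(
        wl_d[keep_bands], dv[:, keep_bands], ids,
        {
            **raw.state,
            "subsampled": subsample_step,
            "trimmed": trim,
            "derivative_order": 1,
            "water_bands_removed": True,
        },
    )


# ---------------------------------------------------------------------------
# Moving-window correlation dissimilarity and window selection
# ---------------------------------------------------------------------------

def moving_window_dissimilarity(
    a: np.ndarray, b: np.ndarray, window: int
) -> np.ndarray:
    """1 - mean over windows of the Pearson correlation of window segments.

    Windows are contiguous non-overlapping segments of ``window`` points (a
    trailing partial window is dropped).  Zero-variance segments contribute a
    correlation of 0.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    p = a.shape[1]
    if b.shape[1] != p:
        raise SpectralError("spectra must share a wavelength grid")
    if window < 2:
        raise SpectralError("window must span at least 2 points")
    n_win = p // window
    if n_win == 0:
        n_win, window = 1, p  # single full-length window
    corr_sum = np.zeros((a.shape[0], b.shape[0]))
    for w in range(n_win):
        seg = slice(w * window, (w + 1) * window)
        za = _standardize_rows(a[:, seg])
        zb = _standardize_rows(b[:, seg])
        corr_sum += (za @ zb.T) / window
    return 1.0 - corr_sum / n_win


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def select_window_size(
    calib: SpectrumSet,
    targets: np.ndarray,
    candidates: tuple[int, ...] = WINDOW_CANDIDATES,
) -> int:
    """Choose the moving-window size minimizing nearest-neighbor RMSE.

    For each candidate window, every calibration sample is predicted by its
    single nearest neighbor under the moving-window correlation dissimilarity,
    and the RMSE against the analytical values is computed; the window with the
    lowest RMSE wins (ties go to the smaller window).
    """
    targets = np.atleast_2d(np.asarray(targets, float).T).T
    if calib.n_samples < 3:
        raise SpectralError("need at least 3 calibration samples")
    if len(candidates) == 1:
        return int(candidates[0])
    best_w, best_rmse = None, np.inf
    for w in candidates:
        d = moving_window_dissimilarity(calib.values, calib.values, w)
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        rmse = float(np.sqrt(np.mean((targets[nn] - targets) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_w, best_rmse = int(w), rmse
    return best_w


# ---------------------------------------------------------------------------
# PLS with per-component access, and WAPLS
# ---------------------------------------------------------------------------

class _TruncatablePLS:
    """A fitted PLS model exposing predictions, coefficients and spectral
    reconstructions for every leading number of components 1..j_max."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, j_max: int):
        Y = np.atleast_2d(np.asarray(Y, float).T).T
        j_max = int(min(j_max, X.shape[1], X.shape[0] - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._pls = PLSRegression(n_components=j_max, scale=False).fit(X, Y)
        self.j_max = j_max
        W, P = self._pls.x_weights_, self._pls.x_loadings_
        self.Q = self._pls.y_loadings_          # (n_targets, j_max)
        self.P = P
        self.x_mean = self._pls._x_mean
        self.y_mean = self._pls._y_mean
        # rotations for every truncation: R_j = W_j (P_j^T W_j)^-1
        self._R = [
            W[:, :j] @ np.linalg.inv(P[:, :j].T @ W[:, :j])
            for j in range(1, j_max + 1)
        ]

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) @ self._R[-1]

    def coef(self, j: int) -> np.ndarray:
        """Regression coefficients (p, n_targets) of the j-component model."""
        return self._R[j - 1] @ self.Q[:, :j].T

    def predict(self, X: np.ndarray, j: int) -> np.ndarray:
        Xc = np.atleast_2d(X) - self.x_mean
        return Xc @ self.coef(j) + self.y_mean

    def recon_rmse(self, X: np.ndarray, j: int) -> np.ndarray:
        """Per-sample RMSE of the spectral reconstruction from j components."""
        Xc = np.atleast_2d(X) - self.x_mean
        T = Xc @ self._R[j - 1]
        resid = Xc - T @ self.P[:, :j].T
        return np.sqrt(np.mean(resid**2, axis=1))


@dataclass
class WaplsEnsemble:
    """Per-component predictions and their WAPLS weights for one query set."""

    j_values: np.ndarray          # component counts averaged
    delta: np.ndarray             # (n_query, n_j) spectral residual RMSE
    g: np.ndarray                 # (n_j, n_targets) coefficient RMS
    weights: np.ndarray           # (n_query, n_j, n_targets), normalized
    predictions_j: np.ndarray     # (n_query, n_j, n_targets)
    prediction: np.ndarray        # (n_query, n_targets)


def wapls_weights(delta: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Raw WAPLS weights ``w_j = 1 / (delta_{1:j} * g_j)``.

    Zero denominators (a perfect reconstruction) would make the weight
    infinite; such entries are capped at 1e6 times the largest finite weight so
    they dominate the average while keeping the arithmetic finite.
    """
    delta = np.asarray(delta, float)
    g = np.asarray(g, float)
    denom = delta * g
    with np.errstate(divide="ignore"):
        w = 1.0 / denom
    if np.any(~np.isfinite(w)):
        finite = w[np.isfinite(w)]
        cap = (finite.max() if finite.size else 1.0) * 1e6
        logger.warning(
            "wapls_weights: %d zero denominators capped", int((~np.isfinite(w)).sum())
        )
        w = np.where(np.isfinite(w), w, cap)
    return w


def wapls_predict(
    pls: _TruncatablePLS, X_query: np.ndarray, j_range: tuple[int, int] = J_RANGE
) -> WaplsEnsemble:
    """WAPLS ensemble prediction over component counts ``j_range``."""
    X_query = np.atleast_2d(X_query)
    j_lo, j_hi = j_range
    j_vals = np.arange(max(1, j_lo), min(j_hi, pls.j_max) + 1)
    if j_vals.size == 0:
        j_vals = np.array([pls.j_max])
    n_targets = pls.Q.shape[0]
    preds = np.empty((X_query.shape[0], j_vals.size, n_targets))
    delta = np.empty((X_query.shape[0], j_vals.size))
    g = np.empty((j_vals.size, n_targets))
    for a, j in enumerate(j_vals):
        preds[:, a, :] = pls.predict(X_query, j)
        delta[:, a] = pls.recon_rmse(X_query, j)
        g[a] = np.sqrt(np.mean(pls.coef(j) ** 2, axis=0))
    w = wapls_weights(delta[:, :, None], g[None, :, :])
    w = w / w.sum(axis=1, keepdims=True)
    prediction = (w * preds).sum(axis=1)
    return WaplsEnsemble(j_vals, delta, g, w, preds, prediction)


# ---------------------------------------------------------------------------
# Memory-based local prediction
# ---------------------------------------------------------------------------

@dataclass
class MblResult:
    predictions: pd.DataFrame        # site_id, poc_pred, maoc_pred for in-range queries
    excluded_ids: np.ndarray         # queries outside the calibration SOC range
    k: int                           # selected neighborhood size
    window: int                      # moving-window size used
    k_cv_rmse: dict                  # candidate k -> NN-CV RMSE


def _nn_cv_rmse(
    X: np.ndarray,
    Y: np.ndarray,
    dissim: np.ndarray,
    k: int,
    j_range: tuple[int, int],
) -> float:
    """Leave-one-out nearest-neighbor cross-validation RMSE for one k."""
    n = X.shape[0]
    err2 = 0.0
    order = np.argsort(dissim, axis=1, kind="stable")
    for i in range(n):
        nbrs = [s for s in order[i] if s != i][:k]
        pls = _TruncatablePLS(X[nbrs], Y[nbrs], j_range[1])
        pred = wapls_predict(pls, X[i : i + 1], j_range).prediction[0]
        err2 += float(np.mean((pred - Y[i]) ** 2))
    return np.sqrt(err2 / n)


def mbl_predict(
    calib: SpectrumSet,
    calib_targets: pd.DataFrame,
    query: SpectrumSet,
    query_soc: np.ndarray | None = None,
    *,
    window: int | None = None,
    k_range: tuple[int, int] = K_RANGE,
    k_step: int = 10,
    j_range: tuple[int, int] = J_RANGE,
    target_cols: tuple[str, ...] = ("poc", "maoc"),
) -> MblResult:
    """Predict POC and MAOC for query spectra by local WAPLS regression.

    The neighborhood size k is optimized once by nearest-neighbor
    cross-validation on the calibration set (candidates spanning ``k_range`` in
    steps of ``k_step``); each query is then predicted from its k nearest
    calibration spectra under the moving-window correlation dissimilarity.
    Negative predictions are set to 0.  Queries whose measured SOC falls
    outside the calibration SOC range are excluded.
    """
    Y = calib_targets.loc[:, list(target_cols)].to_numpy(float)
    X = calib.values
    n_calib = X.shape[0]

    if window is None:
        window = select_window_size(calib, Y)

    # gate queries on the calibration SOC range
    soc_calib = Y.sum(axis=1)
    keep = np.ones(query.n_samples, bool)
    if query_soc is not None:
        query_soc = np.asarray(query_soc, float)
        keep = (query_soc >= soc_calib.min()) & (query_soc <= soc_calib.max())
    excluded = query.ids[~keep]
    query_in = query.subset(keep)

    k_cands = [k for k in range(k_range[0], k_range[1] + 1, k_step)]
    clipped = [min(k, n_calib - 1) for k in k_cands]
    if clipped != k_cands:
        warnings.warn(
            f"neighborhood sizes clipped to calibration size - 1 = {n_calib - 1}",
            stacklevel=2,
        )
    k_cands = sorted(set(clipped))

    d_cc = moving_window_dissimilarity(X, X, window)
    k_scores = {k: _nn_cv_rmse(X, Y, d_cc, k, j_range) for k in k_cands}
    k_best = min(k_scores, key=lambda k: (k_scores[k], k))

    d_qc = moving_window_dissimilarity(query_in.values, X, window)
    order = np.argsort(d_qc, axis=1, kind="stable")[:, :k_best]
    preds = np.empty((query_in.n_samples, len(target_cols)))
    for i in range(query_in.n_samples):
        nbrs = order[i]
        pls = _TruncatablePLS(X[nbrs], Y[nbrs], j_range[1])
        preds[i] = wapls_predict(pls, query_in.values[i : i + 1], j_range).prediction[0]
    preds = np.clip(preds, 0.0, None)

    out = pd.DataFrame(preds, columns=[f"{c}_pred" for c in target_cols])
    out.insert(0, "site_id", query_in.ids)
    return MblResult(out, excluded, k_best, window, k_scores)


# ---------------------------------------------------------------------------
# F-ratio applicability domain
# ---------------------------------------------------------------------------

@dataclass
class FRatioModel:
    """F-ratio applicability-domain screen for a fitted calibration set.

    ``F = ||u - u_hat||^2 * n_c / s_c^2`` where ``u_hat`` is the spectrum
    reconstructed from its PLS scores, ``n_c`` the calibration size and
    ``s_c^2`` the total residual spectral variance of the calibration set.

    By default the F-ratio probability is the empirical CDF of the
    calibration set's own F values, so the nominal 0.99 cut flags at most
    ~1 % of the calibration population by construction.  Spectral residuals
    are strongly correlated across neighboring wavelengths and their
    per-sample variance is not chi-square with one degree of freedom per
    retained wavelength, so a parametric F distribution with wavelength-count
    degrees of freedom badly miscalibrates the cut; a parametric variant
    remains available through ``dof``.
    """

    pls: _TruncatablePLS
    n_components: int
    s_c2: float
    n_c: int
    calib_f: np.ndarray
    dof: tuple[float, float] | None = None
    probability_cut: float = F_PROBABILITY_CUT

    def f_ratio(self, queries: SpectrumSet) -> np.ndarray:
        rmse = self.pls.recon_rmse(queries.values, self.n_components)
        p = queries.values.shape[1]
        return rmse**2 * p * self.n_c / self.s_c2

    def screen(self, queries: SpectrumSet) -> pd.DataFrame:
        F = self.f_ratio(queries)
        if self.dof is not None:
            prob = stats.f.cdf(F, *self.dof)
        else:
            prob = np.searchsorted(self.calib_f, F, side="right") / len(
                self.calib_f
            )
        return pd.DataFrame(
            {
                "site_id": queries.ids,
                "f_ratio": F,
                "f_probability": prob,
                "in_domain": prob <= self.probability_cut,
            }
        )


def fit_f_ratio(
    calib: SpectrumSet,
    calib_targets: pd.DataFrame,
    *,
    n_components: int = J_RANGE[1],
    dof: tuple[float, float] | None = None,
    target_cols: tuple[str, ...] = ("poc", "maoc"),
) -> FRatioModel:
    """Fit the global PLS score basis and calibration residual variance.

    ``dof=None`` (default) screens against the empirical calibration F
    distribution; pass explicit degrees of freedom for a parametric screen.
    """
    Y = calib_targets.loc[:, list(target_cols)].to_numpy(float)
    pls = _TruncatablePLS(calib.values, Y, n_components)
    j = pls.j_max
    p = calib.values.shape[1]
    Xc = calib.values - pls.x_mean
    resid = Xc - (Xc @ pls._R[j - 1]) @ pls.P[:, :j].T
    s_c2 = float(np.sum(resid**2))
    if s_c2 <= 1e-10 * float(np.sum(Xc**2)):
        raise SpectralError("degenerate calibration: zero residual spectral variance")
    sse = np.sum(resid**2, axis=1)
    calib_f = np.sort(sse * calib.n_samples / s_c2)
    return FRatioModel(pls, j, s_c2, calib.n_samples, calib_f, dof)


def f_ratio_screen(model: FRatioModel, queries: SpectrumSet) -> pd.DataFrame:
    """Screen query spectra against the calibration applicability domain."""
    return model.screen(queries)


# ---------------------------------------------------------------------------
# Prediction scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionScore:
    rmse: float
    r2: float
    bias: float
    ccc: float
    rpiq: float


def prediction_metrics(obs: np.ndarray, pred: np.ndarray) -> PredictionScore:
    """RMSE, squared Pearson correlation, bias (mean(pred - obs)), Lin's
    concordance correlation coefficient, and RPIQ = IQR(obs) / RMSE."""
    obs = np.asarray(obs, float).ravel()
    pred = np.asarray(pred, float).ravel()
    if obs.size != pred.size or obs.size < 3:
        raise SpectralError("obs and pred must have equal length >= 3")
    if np.var(obs) == 0:
        raise SpectralError("zero variance in observations: r2/ccc undefined")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    r = float(np.corrcoef(obs, pred)[0, 1])
    vo, vp = np.var(obs), np.var(pred)
    ccc = float(
        2 * np.cov(obs, pred, bias=True)[0, 1]
        / (vo + vp + (np.mean(obs) - np.mean(pred)) ** 2)
    )
    iqr = float(np.subtract(*np.percentile(obs, [75, 25])))
    rpiq = float(iqr / rmse) if rmse > 0 else np.inf
    return PredictionScore(rmse=rmse, r2=r * r, bias=bias, ccc=ccc, rpiq=rpiq)
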