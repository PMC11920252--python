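"""Preprocessing chain, WAPLS weighting arithmetic, memory-based prediction
and the F-ratio applicability screen."""

import numpy as np
import pandas as pd
import pytest

from socrisk.spectral_calibration import (
    SpectralError,
    SpectrumSet,
    _TruncatablePLS,
    fit_f_ratio,
    mbl_predict,
    moving_window_dissimilarity,
    prediction_metrics,
    preprocess_spectra,
    select_window_size,
    wapls_predict,
    wapls_weights,
)
from socrisk.synthetic_data import SimConfig, SpectraParams, \
    gen_fractions_and_soc, gen_pedoclimate_sites, gen_spectra


def _raw(values, ids=None):
    n_wl = values.shape[1]
    wl = 380.0 + 0.5 * np.arange(n_wl)
    return SpectrumSet(wl, values, ids if ids is not None else np.arange(len(values)))


class TestPreprocess:
    def test_constant_spectrum_has_zero_derivative(self):
        spec = preprocess_spectra(_raw(np.full((2, 4241), 0.7)))
        assert np.allclose(spec.values, 0.0)

    def test_water_bands_excised_and_range_trimmed(self):
        spec = preprocess_spectra(_raw(np.random.default_rng(0).random((3, 4241))))
        wl = spec.wavelengths
        assert not np.any((wl >= 1350) & (wl <= 1460))
        assert not np.any((wl >= 1790) & (wl <= 1960))
        assert wl.min() >= 400.0 and wl.max() <= 2450.0
        assert spec.state["derivative_order"] == 1

    def test_linear_spectrum_derivative_equals_slope(self):
        wl = 380.0 + 0.5 * np.arange(4241)
        slope = 3e-4
        spec = preprocess_spectra(_raw((slope * wl)[None, :]))
        assert np.allclose(spec.values, slope)

    def test_replicates_averaged_per_site(self):
        vals = np.vstack([np.full(4241, 0.2), np.full(4241, 0.6),
                          np.linspace(0, 1, 4241)])
        out = preprocess_spectra(_raw(vals, ids=np.array([7, 7, 8])))
        assert out.n_samples == 2
        assert list(out.ids) == [7, 8]

    def test_grid_must_cover_trim_range(self):
        wl = np.linspace(500, 2400, 100)
        with pytest.raises(SpectralError, match="trim"):
            preprocess_spectra(SpectrumSet(wl, np.zeros((1, 100)), [0]))


class TestWindowSelection:
    def test_single_candidate_returned_unchanged(self):
        spec = _raw(np.random.default_rng(1).random((5, 600)))
        assert select_window_size(spec, np.arange(5.0), candidates=(31,)) == 31

    def test_returns_candidate_with_lowest_nn_rmse(self):
        """Exhaustive recomputation of the nearest-neighbor RMSE per window
        must agree with the selected window."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 320)).cumsum(axis=1)  # smooth-ish spectra
        y = X[:, 100] + 0.1 * rng.normal(size=30)
        spec = _raw(X)
        candidates = (11, 151)
        rmses = {}
        for w in candidates:
            d = moving_window_dissimilarity(X, X, w)
            np.fill_diagonal(d, np.inf)
            nn = np.argmin(d, axis=1)
            rmses[w] = np.sqrt(np.mean((y[nn] - y) ** 2))
        expected = min(candidates, key=lambda w: rmses[w])
        assert select_window_size(spec, y, candidates=candidates) == expected


class TestWaplsWeights:
    def test_hand_arithmetic(self):
        w = wapls_weights(np.array([2.0, 1.0]), np.array([1.0, 1.0]))
        assert np.allclose(w / w.sum(), [1 / 3, 2 / 3])

    def test_equal_products_give_simple_mean(self):
        w = wapls_weights(np.array([2.0, 1.0, 4.0]), np.array([1.0, 2.0, 0.5]))
        assert np.allclose(w / w.sum(), 1 / 3)

    def test_zero_denominator_capped_dominant(self):
        w = wapls_weights(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert np.all(np.isfinite(w))
        assert w[0] / w.sum() > 0.999


class TestWaplsEnsemble:
    @pytest.fixture()
    def xy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 80))
        Y = X @ rng.normal(size=(80, 2)) + 0.05 * rng.normal(size=(60, 2))
        return X, Y

    def test_single_j_equals_plain_pls(self, xy):
        from sklearn.cross_decomposition import PLSRegression

        X, Y = xy
        pls = _TruncatablePLS(X[:40], Y[:40], 7)
        ens = wapls_predict(pls, X[40:], j_range=(7, 7))
        ref = PLSRegression(n_components=7, scale=False).fit(X[:40], Y[:40])
        assert np.allclose(ens.prediction, ref.predict(X[40:]))

    def test_prediction_is_convex_combination(self, xy):
        X, Y = xy
        pls = _TruncatablePLS(X[:40], Y[:40], 10)
        ens = wapls_predict(pls, X[40:], j_range=(5, 10))
        assert np.all(ens.weights >= 0)
        assert np.allclose(ens.weights.sum(axis=1), 1.0)
        lo = ens.predictions_j.min(axis=1)
        hi = ens.predictions_j.max(axis=1)
        assert np.all(ens.prediction >= lo - 1e-9)
        assert np.all(ens.prediction <= hi + 1e-9)


@pytest.fixture(scope="module")
def small_noiseless():
    cfg = SimConfig(
        n_sites=120, seed=41, n_calibration=60,
        spectra_params=SpectraParams(noise_sd=0.0),
    )
    sites = gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg)
    spec = preprocess_spectra(gen_spectra(sites, cfg).to_absorbance())
    pos = {s: i for i, s in enumerate(spec.ids)}
    order = np.array([pos[s] for s in sites["site_id"]])
    calib = sites["is_calibration"].to_numpy(bool)
    return sites, spec.subset(order[calib]), spec.subset(order[~calib]), calib


class TestMblPredict:
    def test_calibration_spectrum_predicted_near_its_target(self, small_noiseless):
        sites, cs, _, calib = small_noiseless
        targets = sites.loc[calib, ["poc", "maoc"]]
        query = cs.subset(np.arange(3))
        with pytest.warns(UserWarning, match="clipped"):
            res = mbl_predict(cs, targets, query, window=31, k_range=(20, 60))
        truth = targets.iloc[:3].to_numpy()
        assert np.allclose(res.predictions[["poc_pred", "maoc_pred"]], truth,
                           rtol=0.05)

    def test_soc_gate_limits_prediction_length(self, small_noiseless):
        sites, cs, qs, calib = small_noiseless
        targets = sites.loc[calib, ["poc", "maoc"]]
        soc = sites.loc[~calib, "soc"].to_numpy().copy()
        soc[:5] = 1e6  # push five queries outside the calibration SOC range
        calib_soc = (targets["poc"] + targets["maoc"]).to_numpy()
        in_range = (soc >= calib_soc.min()) & (soc <= calib_soc.max())
        res = mbl_predict(cs, targets, qs, soc, window=31, k_range=(20, 40))
        assert len(res.predictions) == in_range.sum()
        assert set(qs.ids[:5]) <= set(res.excluded_ids)

    def test_predictions_are_nonnegative(self, small_noiseless):
        sites, cs, qs, calib = small_noiseless
        targets = sites.loc[calib, ["poc", "maoc"]]
        res = mbl_predict(cs, targets, qs, window=31, k_range=(20, 40))
        assert (res.predictions[["poc_pred", "maoc_pred"]] >= 0).all().all()


@pytest.fixture(scope="module")
def fitted():
    cfg = SimConfig(n_sites=400, seed=43, n_calibration=200)
    sites = gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg)
    spec = preprocess_spectra(gen_spectra(sites, cfg).to_absorbance())
    pos = {s: i for i, s in enumerate(spec.ids)}
    order = np.array([pos[s] for s in sites["site_id"]])
    calib = sites["is_calibration"].to_numpy(bool)
    cs = spec.subset(order[calib])
    return cs, fit_f_ratio(cs, sites.loc[calib, ["poc", "maoc"]])


class TestFRatio:
    def test_mean_spectrum_in_domain(self, fitted):
        cs, model = fitted
        mean_spec = SpectrumSet(
            cs.wavelengths, cs.values.mean(axis=0, keepdims=True), ["mean"]
        )
        out = model.screen(mean_spec)
        assert bool(out["in_domain"].iloc[0])
        assert out["f_ratio"].iloc[0] < 1.0

    def test_self_screen_flags_at_most_one_percent(self, fitted):
        cs, model = fitted
        flagged = ~model.screen(cs)["in_domain"]
        assert flagged.mean() <= 0.01

    def test_inflated_residual_flagged_out(self, fitted):
        cs, model = fitted
        rng = np.random.default_rng(0)
        noisy = SpectrumSet(
            cs.wavelengths,
            cs.values + rng.normal(scale=np.sqrt(10 * model.s_c2
                                                 / model.n_c
                                                 / len(cs.wavelengths)),
                                   size=cs.values.shape),
            cs.ids,
        )
        assert (~model.screen(noisy)["in_domain"]).mean() > 0.99

    def test_degenerate_calibration_rejected(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(30, 2))
        X = t @ rng.normal(size=(2, 50))  # exactly rank 2: zero residuals
        spec = _raw(X)
        y = pd.DataFrame({"poc": t[:, 0], "maoc": t[:, 1]})
        with pytest.raises(SpectralError, match="degenerate"):
            fit_f_ratio(spec, y, n_components=2)


class TestMetrics:
    def test_perfect_prediction(self):
        s = prediction_metrics([1, 2, 3, 4], [1, 2, 3, 4])
        assert s.rmse == 0 and s.bias == 0 and s.ccc == pytest.approx(1.0)

    def test_bias_sign_convention(self):
        s = prediction_metrics([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert s.bias == pytest.approx(2.0)

    def test_hand_computed_scores(self):
        # obs=(1,2,3,4), pred=(2,2,4,4): rmse=sqrt(1/2), bias=1/2, r2=0.8,
        # ccc = 2*cov / (var_o + var_p + dmean^2) = 2/(1.25+1+0.25) = 0.8,
        # rpiq = IQR(obs)/rmse = 1.5/sqrt(0.5)
        s = prediction_metrics([1, 2, 3, 4], [2, 2, 4, 4])
        assert s.rmse == pytest.approx(np.sqrt(0.5))
        assert s.bias == pytest.approx(0.5)
        assert s.r2 == pytest.approx(0.8)
        assert s.ccc == pytest.approx(0.8)
        assert s.rpiq == pytest.approx(1.5 / np.sqrt(0.5))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SpectralError):
            prediction_metrics([1, 1, 1], [1, 2, 3])
        with pytest.raises(SpectralError):
            prediction_metrics([1, 2], [1, 2])
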