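"""Risk-index classification truth table, area accounting, cross-method
agreement and the dSOC ~ MAOC:SOC regression."""

import numpy as np
import pandas as pd
import pytest

from socrisk.risk_mapping import (
    CLASS_CODES,
    RiskMappingError,
    area_by_class,
    assess_risk,
    classify_risk,
    compute_median_saturation,
    delta_soc_vs_ratio_fit,
    map_saturation_to_grid,
    method_agreement,
    overall_agreement_pct,
)


class TestClassification:
    def test_truth_table(self):
        """High/low saturation x negative/non-negative dSOC -> HR/HH/NR/NH."""
        sat = np.array([[80.0, 40.0, 40.0, 80.0]])
        dsoc = np.array([[-1.0, -1.0, 0.0, 0.0]])
        out = classify_risk(sat, dsoc, median_sat=60.0)
        assert list(out.ravel()) == [
            CLASS_CODES["HR"], CLASS_CODES["HH"], CLASS_CODES["NR"],
            CLASS_CODES["NH"],
        ]

    def test_exact_median_goes_to_below_branch(self):
        out = classify_risk(np.array([[60.0]]), np.array([[-1.0]]), 60.0)
        assert out[0, 0] == CLASS_CODES["HH"]

    def test_missing_cells_propagate(self):
        out = classify_risk(np.array([[np.nan, 50.0]]),
                            np.array([[-1.0, np.nan]]), 60.0)
        assert list(out.ravel()) == [0, 0]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        sat = rng.uniform(1, 100, (20, 20))
        dsoc = rng.normal(0, 1, (20, 20))
        med = float(np.median(sat))
        a = classify_risk(sat, dsoc, med)
        b = classify_risk(sat**2, dsoc, med**2)  # strictly monotone on >0
        assert np.array_equal(a, b)


class TestSaturationLookup:
    def _bins(self, mean_by_bin):
        rows = []
        for b, m in mean_by_bin.items():
            rows.append({"cluster_id": 1, "bin_left": b * 10.0,
                         "bin_right": b * 10.0 + 10, "mean_sat": m, "n": 5})
        return pd.DataFrame(rows)

    def test_lookup_returns_bin_mean(self):
        bins = self._bins({2: 72.0})
        out = map_saturation_to_grid(bins, np.ones((1, 1)),
                                     np.array([[25.0]]))
        assert out[0, 0] == 72.0

    def test_missing_cluster_or_bin_is_missing(self):
        bins = self._bins({2: 72.0})
        out = map_saturation_to_grid(
            bins, np.array([[np.nan, 1.0, 2.0]]),
            np.array([[25.0, 55.0, 25.0]]),
        )
        assert np.isnan(out).all()  # missing cluster, empty bin, unknown cluster

    def test_uniform_bins_give_constant_raster(self):
        bins = self._bins({b: 50.0 for b in range(10)})
        ff = np.random.default_rng(0).uniform(0, 100, (5, 5))
        out = map_saturation_to_grid(bins, np.ones((5, 5)), ff)
        assert np.all(out == 50.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(RiskMappingError):
            map_saturation_to_grid(self._bins({1: 10.0}), np.ones((2, 2)),
                                   np.ones((3, 3)))


class TestAreas:
    def test_hundred_cells_are_a_hundredth_mha(self):
        grid = np.full((10, 10), CLASS_CODES["HR"], dtype=np.int8)
        out = area_by_class(grid)
        assert out.loc[out["class"] == "HR", "area_mha"].iloc[0] == 0.01
        assert out.loc[out["class"] == "NR", "area_mha"].iloc[0] == 0.0

    def test_class_areas_sum_to_classified_area(self):
        rng = np.random.default_rng(7)
        grid = rng.integers(0, 5, (30, 30)).astype(np.int8)
        out = area_by_class(grid)
        assert out["cells"].sum() == int((grid != 0).sum())
        assert out["area_mha"].sum() == pytest.approx(
            (grid != 0).sum() * 100 / 1e6
        )


class TestAgreement:
    def test_identical_rasters_agree_everywhere(self):
        rng = np.random.default_rng(9)
        g = rng.integers(1, 5, (8, 8)).astype(np.int8)
        out = method_agreement({"BL": g, "PBL": g.copy(), "NBL": g.copy()})
        agree = out[out["status"] == "agreement"]
        assert np.allclose(agree["pct"].dropna(), 100.0)
        assert overall_agreement_pct({"BL": g, "NBL": g.copy()}) == 100.0

    def test_fully_discordant_rasters_agree_nowhere(self):
        a = np.full((4, 4), CLASS_CODES["HR"], dtype=np.int8)
        b = np.full((4, 4), CLASS_CODES["HH"], dtype=np.int8)
        out = method_agreement({"BL": a, "PBL": a.copy(), "NBL": b},
                               reference="NBL")
        hh = out[(out["class"] == "HH") & (out["status"] == "agreement")]
        assert hh["pct"].iloc[0] == 0.0
        assert overall_agreement_pct({"BL": a, "NBL": b}) == 0.0

    def test_hand_built_three_by_three(self):
        # reference NBL: 5 HR cells agree across methods; the other 4 cells
        # disagree (one method flips them to HH)
        base = np.array(
            [[1, 1, 1], [1, 1, 2], [2, 2, 2]], dtype=np.int8
        )
        other = base.copy()
        other[1, 2] = 1
        other[2, :] = 1  # BL calls the last row + one cell HR instead of HH
        out = method_agreement({"BL": other, "NBL": base}, reference="NBL")
        hr_agree = out[(out["class"] == "HR") & (out["status"] == "agreement")]
        assert hr_agree["cells"].iloc[0] == 5
        assert hr_agree["pct"].iloc[0] == pytest.approx(100.0)
        hh_agree = out[(out["class"] == "HH") & (out["status"] == "agreement")]
        assert hh_agree["cells"].iloc[0] == 0
        assert hh_agree["pct"].iloc[0] == 0.0
        assert out["cells"].sum() == 2 * 9 - 9  # agreement+disagreement = cells


class TestDeltaSocFit:
    def test_noiseless_generator_recovered_exactly(self):
        from socrisk.synthetic_data import DeltaSocParams, SimConfig, \
            gen_delta_soc, gen_fractions_and_soc, gen_pedoclimate_sites

        cfg = SimConfig(
            n_sites=200, seed=51,
            delta_soc_params=DeltaSocParams(slope_true=10.0, noise_sd=0.0),
        )
        sites = gen_delta_soc(
            gen_fractions_and_soc(gen_pedoclimate_sites(cfg), cfg), cfg
        )
        sites["cluster_id"] = sites["cluster_true"]
        fit = delta_soc_vs_ratio_fit(sites)
        assert np.allclose(fit["slope"], 10.0)
        assert (fit["slope"] > 0).all()

    def test_small_cluster_skipped_with_warning(self):
        df = pd.DataFrame(
            {
                "maoc": [1.0, 1, 1, 2, 2],
                "poc": [1.0, 1, 1, 1, 1],
                "delta_soc": [0.1, 0.3, 0.2, 0.5, 0.4],
                "cluster_id": [1, 1, 1, 2, 2],
            }
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            fit = delta_soc_vs_ratio_fit(df)
        assert list(fit["cluster_id"]) == [1]

    def test_constant_delta_soc_flagged_degenerate(self):
        df = pd.DataFrame(
            {
                "maoc": [1.0, 2.0, 3.0],
                "poc": [1.0, 1.0, 1.0],
                "delta_soc": [0.5, 0.5, 0.5],
                "cluster_id": [1, 1, 1],
            }
        )
        fit = delta_soc_vs_ratio_fit(df)
        assert fit["slope"].iloc[0] == 0.0
        assert np.isnan(fit["pearson_r"].iloc[0])
        assert bool(fit["degenerate"].iloc[0])


class TestAssessRisk:
    def test_shared_median_mask_and_conservation(self):
        rng = np.random.default_rng(11)
        bins = pd.DataFrame(
            [
                {"cluster_id": 1, "bin_left": 10.0 * b, "bin_right": 10.0 * b + 10,
                 "mean_sat": 30.0 + 5 * b, "n": 3}
                for b in range(10)
            ]
        )
        cluster = np.ones((12, 12))
        ff = rng.uniform(0, 100, (12, 12))
        dsoc = rng.normal(0, 1, (12, 12))
        res = assess_risk({"BL": bins, "NBL": bins}, cluster, ff, dsoc,
                          median_mode="shared")
        assert len(set(res.medians.values())) == 1
        for m, grid in res.class_rasters.items():
            per = res.areas[res.areas["method"] == m]
            assert per["cells"].sum() == int((grid != 0).sum())
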