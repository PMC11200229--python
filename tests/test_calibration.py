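"""Droplet amounts, calibration fitting, quantification and detection limits."""

import numpy as np
import pandas as pd
import pytest

import mexquant as mq
from mexquant.calibration import (
    CalibrationCurve,
    DropletStandard,
    amount_col,
    amount_histogram,
    currie_false_positive_rate,
    droplet_amount,
    estimate_lod,
    fit_calibration,
    integrate_droplet_windows,
    integrate_droplets,
    quantify_cells,
    quantify_pixels,
)
from mexquant.types import ChannelImage, PixelTable, total_col


def make_curve(slope=50.0, intercept=0.0):
    return CalibrationCurve("59Co", slope, intercept, 1.0, (0.0, 100.0), 6)


class TestDropletAmount:
    @pytest.mark.parametrize(
        "conc,vol,expected",
        [(1.0, 400.0, 0.4), (0.0, 400.0, 0.0), (250.0, 400.0, 100.0)],
    )
    def test_unit_arithmetic(self, conc, vol, expected):
        assert droplet_amount(conc, vol) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            droplet_amount(-1.0, 400.0)


class TestIntegrateDroplets:
    def test_noiseless_array_integrates_to_truth(self, droplets_noiseless):
        image, standards = droplets_noiseless
        regions = integrate_droplets(image, expected_diameter_um=200.0)
        assert len(regions) == len(standards)
        got = sorted(r.integrated_counts for r in regions)
        want = sorted(standards["expected_counts"])
        np.testing.assert_allclose(got, want, rtol=1e-9)
        assert not any(r.flagged for r in regions)

    def test_blank_image_errors(self):
        with pytest.raises(ValueError, match="no droplets"):
            integrate_droplets(ChannelImage(np.zeros((50, 50)), "59Co"))

    def test_merged_droplets_flagged(self):
        # two droplets fused into one oversized region
        yy, xx = np.mgrid[0:200, 0:300]
        px = np.zeros((200, 300))
        px[(yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2] = 5.0
        px[(yy - 100) ** 2 + (xx - 180) ** 2 <= 50**2] = 5.0
        regions = integrate_droplets(
            ChannelImage(px, "59Co"), expected_diameter_um=100.0
        )
        assert len(regions) == 1
        assert regions[0].flagged


class TestFitCalibration:
    def amounts_series(self):
        return [0.0, 2.0, 5.0, 10.0, 20.0, 50.0]

    def test_exact_line_recovered(self):
        stds = [
            DropletStandard("59Co", a / 0.4, 400.0, 50.0 * a)
            for a in self.amounts_series()
        ]
        curve = fit_calibration(stds)
        assert curve.slope == pytest.approx(50.0, abs=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-7)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.n_points == 6
        assert curve.linear_range_fg == (0.0, 50.0)

    def test_intercept_recovered(self):
        stds = [
            DropletStandard("59Co", a / 0.4, 400.0, 30.0 + 50.0 * a)
            for a in self.amounts_series()
        ]
        curve = fit_calibration(stds)
        assert curve.intercept == pytest.approx(30.0, abs=1e-7)

    def test_identical_amounts_rejected(self):
        stds = [DropletStandard("59Co", 10.0, 400.0, 100.0)] * 3
        with pytest.raises(ValueError, match="identical"):
            fit_calibration(stds)

    def test_poisson_perturbed_slope_within_3se(self, rng):
        """Over 100 simulated fits the true slope lies within 3 SE >= 95%."""
        amounts = np.array(self.amounts_series())
        hits = 0
        for _ in range(100):
            counts = rng.poisson(50.0 * amounts)
            curve = fit_calibration(
                [
                    DropletStandard("59Co", a / 0.4, 400.0, c)
                    for a, c in zip(amounts, counts)
                ]
            )
            hits += abs(curve.slope - 50.0) <= 3 * curve.slope_se
        assert hits >= 95


class TestQuantify:
    def cells(self):
        return pd.DataFrame(
            {
                "cell_id": [1, 2, 3],
                "area_px": [4, 4, 4],
                total_col("59Co"): [100.0, 0.0, 30.0],
                total_col("193Ir"): [7.0, 8.0, 9.0],
            }
        )

    def test_affine_inversion(self):
        out = quantify_cells(self.cells(), make_curve(50.0, 0.0))
        np.testing.assert_allclose(out[amount_col("59Co")], [2.0, 0.0, 0.6])

    def test_counts_at_intercept_give_zero_and_floor(self):
        out = quantify_cells(self.cells(), make_curve(50.0, 30.0))
        np.testing.assert_allclose(out[amount_col("59Co")], [1.4, 0.0, 0.0])

    def test_other_channels_untouched(self):
        out = quantify_cells(self.cells(), make_curve())
        np.testing.assert_array_equal(out[total_col("193Ir")], [7.0, 8.0, 9.0])
        assert amount_col("193Ir") not in out.columns

    def test_missing_channel_errors(self):
        curve = CalibrationCurve("64Zn", 10.0, 0.0, 1.0, (0, 10), 3)
        with pytest.raises(KeyError, match="64Zn"):
            quantify_cells(self.cells(), curve)

    def test_recovery_on_synthetic_tissue(self, tissue, tissue_pipeline):
        """Mean absolute relative error < 5% at >= 1000 expected counts."""
        _, truth = tissue
        _, _, cells, match = tissue_pipeline
        out = quantify_cells(cells, make_curve(truth.config.calibration_slope, 0.0))
        hit = match[(match.truth_id > 0) & (match.iou > 0.5)]
        est = out.set_index("cell_id").loc[hit.detected_id, amount_col("59Co")]
        tru = truth.cells.set_index("cell_id").loc[hit.truth_id]
        big = tru["expected_metal_counts"].to_numpy() >= 1000
        rel = np.abs(est.to_numpy()[big] - tru["amount_fg"].to_numpy()[big])
        rel /= tru["amount_fg"].to_numpy()[big]
        assert rel.mean() < 0.05


class TestQuantifyPixels:
    def test_constant_map(self):
        table = PixelTable.from_rasters({"59Co": np.full((4, 4), 50.0)})
        out = quantify_pixels(table, make_curve(50.0, 0.0))
        np.testing.assert_allclose(out, 1.0)

    def test_zero_image_zero_map(self):
        table = PixelTable.from_rasters({"59Co": np.zeros((4, 4))})
        np.testing.assert_array_equal(quantify_pixels(table, make_curve()), 0.0)

    def test_pixel_sum_matches_cell_quantification_when_intercept_zero(
        self, tissue, tissue_pipeline
    ):
        _, truth = tissue
        cleaned, mask, cells, _ = tissue_pipeline
        curve = make_curve(truth.config.calibration_slope, 0.0)
        pixel_map = quantify_pixels(
            PixelTable.from_rasters({"59Co": cleaned.channel("59Co").pixels}), curve
        )
        qcells = quantify_cells(cells, curve).set_index("cell_id")
        for cid in [1, 2, 3]:
            assert pixel_map[mask.labels == cid].sum() == pytest.approx(
                qcells.loc[cid, amount_col("59Co")], rel=1e-9
            )


class TestDetectionLimit:
    def test_zero_blank_limit(self):
        blank = pd.DataFrame({total_col("59Co"): [0.0, 0.0]})
        dl = estimate_lod(blank, make_curve(50.0))
        assert dl.lod_fg_per_cell == pytest.approx(2.71 / 50.0)

    def test_currie_formula_at_b100(self):
        blank = pd.DataFrame({total_col("59Co"): np.full(100, 100.0)})
        dl = estimate_lod(blank, make_curve(50.0))
        assert dl.blank_mean_counts == 100.0
        assert dl.lod_fg_per_cell == pytest.approx((2.71 + 4.65 * 10.0) / 50.0)
        assert dl.lod_fg_per_cell == pytest.approx(0.9842, abs=1e-4)

    def test_empty_blank_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_lod(pd.DataFrame({total_col("59Co"): []}), make_curve())

    def test_decision_threshold_false_positive_rate(self):
        rate = currie_false_positive_rate(100.0, n=100_000, seed=7)
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_lod_monotone_in_slope_and_blank(self):
        blanks = [1.0, 10.0, 100.0]
        slopes = [10.0, 50.0, 200.0]
        for b in blanks:
            table = pd.DataFrame({total_col("59Co"): np.full(10, b)})
            lods = [
                estimate_lod(table, make_curve(s)).lod_fg_per_cell for s in slopes
            ]
            assert lods == sorted(lods, reverse=True)  # higher slope, lower LOD
        for s in slopes:
            lods = [
                estimate_lod(
                    pd.DataFrame({total_col("59Co"): np.full(10, b)}), make_curve(s)
                ).lod_fg_per_cell
                for b in blanks
            ]
            assert lods == sorted(lods)  # higher blank, higher LOD


class TestAmountHistogram:
    def quantified(self):
        return pd.DataFrame({amount_col("59Co"): [1.0, 2.0, 3.0]})

    def test_summary(self):
        h = amount_histogram(self.quantified(), "59Co")
        assert h["mean"] == pytest.approx(2.0)
        assert h["sd"] == pytest.approx(1.0)
        assert h["n"] == 3

    def test_empty_subset_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            h = amount_histogram(
                self.quantified(), "59Co", clusters=np.array([0, 0, 0]), subset=5
            )
        assert h["n"] == 0

    def test_cluster_histograms_partition_population(self, rng):
        amounts = rng.lognormal(0.5, 0.5, 300)
        clusters = rng.integers(0, 3, 300)
        q = pd.DataFrame({amount_col("59Co"): amounts})
        edges = np.linspace(0, amounts.max() + 1, 20)
        whole = amount_histogram(q, "59Co", bins=edges)["counts"]
        parts = sum(
            amount_histogram(q, "59Co", clusters=clusters, subset=k, bins=edges)[
                "counts"
            ]
            for k in range(3)
        )
        np.testing.assert_array_equal(whole, parts)


class TestCalibrationRoundTrip:
    def test_noiseless_round_trip_recovers_nominal_amounts(self):
        amounts = np.array([0.0, 1.0, 5.0, 10.0, 50.0, 100.0])
        stds = [
            DropletStandard("59Co", a / 0.4, 400.0, 20.0 + 80.0 * a) for a in amounts
        ]
        curve = fit_calibration(stds)
        recovered = curve.counts_to_fg(np.array([s.integrated_counts for s in stds]))
        np.testing.assert_allclose(recovered, amounts, atol=1e-9)

    def test_end_to_end_slope_recovery_from_simulated_array(self):
        image, std = mq.simulate_droplets(seed=0, slope=50.0)
        centers = std[["center_row_px", "center_col_px"]].to_numpy()
        counts = integrate_droplet_windows(
            image, centers, radius_px=std["radius_px"].iloc[0] + 2
        )
        curve = fit_calibration(
            [
                DropletStandard("59Co", r.concentration_ug_per_L, r.volume_pL, c)
                for (_, r), c in zip(std.iterrows(), counts)
            ]
        )
        assert curve.slope == pytest.approx(50.0, rel=0.02)
        assert curve.r_squared > 0.999
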