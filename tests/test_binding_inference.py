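"""Binding-curve inference: binning, averaging, the s-ratio statistic,
Hill/linear model fits, and the binding-vs-collision classifier."""

import numpy as np
import pytest

from qf3suite import binding_inference as bi
from qf3suite import synthetic_data as sd

from conftest import curve_from_points


def hill(x, bmax=0.2, kd=16.3):
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def trapezoid_s_ratio(x, y):
    """Independent trapezoid oracle for the shape ratio."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    auc = np.trapezoid(y - y.min(), x)
    box = (x.max() - x.min()) * (y.max() - y.min())
    return auc / (box - auc)


class TestFilterAndBin:
    def test_out_of_gate_donors_leave_nothing(self, binding_config):
        rois = sd.simulate_qf3_dataset(binding_config).rois.copy()
        rois["donor_uM"] = 5.0
        with pytest.raises(ValueError, match="donor gate"):
            bi.filter_and_bin(rois)

    def test_single_bin_mean_equals_sample_mean(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        rois = pd.DataFrame(
            {
                "donor_uM": rng.uniform(1, 3, 100),
                "acceptor_uM": rng.uniform(5.1, 7.4, 100),
                "free_acceptor_uM": rng.uniform(5.1, 7.4, 100),
                "delta_omega": rng.normal(0.05, 0.01, 100),
            }
        )
        curve = bi.filter_and_bin(rois)
        assert len(curve) == 1
        assert curve.n_rois[0] == 100
        assert curve.delta_omega_mean[0] == pytest.approx(rois["delta_omega"].mean())
        assert curve.free_acceptor_uM[0] == pytest.approx(rois["free_acceptor_uM"].mean())

    def test_sparse_bins_are_dropped(self, binding_config):
        curve = bi.filter_and_bin(
            sd.simulate_qf3_dataset(binding_config).rois, min_rois_per_bin=20
        )
        assert (curve.n_rois >= 20).all()

    def test_binned_means_track_noiseless_curve(self, binding_config):
        ds = sd.simulate_qf3_dataset(binding_config)
        curve = bi.filter_and_bin(ds.rois)
        truth = binding_config.delta_omega_max * (
            curve.free_acceptor_uM / (binding_config.kd_uM + curve.free_acceptor_uM)
        )
        resid = np.abs(curve.delta_omega_mean - truth)
        assert (resid <= 3 * np.maximum(curve.sem, 1e-6)).mean() >= 0.8

    def test_empty_input_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            bi.filter_and_bin(pd.DataFrame())


class TestAverageReplicates:
    def test_single_curve_returned_unchanged(self, make_curve):
        c = make_curve([1, 5, 20], [0.01, 0.05, 0.1])
        assert bi.average_replicates([c]) is c

    def test_two_identical_curves_average_to_themselves(self, make_curve):
        c1 = make_curve([1, 5, 20], [0.01, 0.05, 0.1])
        c2 = make_curve([1, 5, 20], [0.01, 0.05, 0.1])
        avg = bi.average_replicates([c1, c2])
        np.testing.assert_allclose(avg.delta_omega_mean, c1.delta_omega_mean)
        np.testing.assert_allclose(avg.n_rois, 2 * c1.n_rois)

    def test_average_closer_to_truth_than_single_replicates(self):
        # Monte-Carlo: averaging replicates reduces RMS error vs the
        # noiseless curve in the (large) majority of seeds
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            cfg = sd.GeneratorConfig(
                seed=seed, kd_uM=16.3, e_fret=sd.e_fret_for_delta_omega_max(0.2), n_rois=400
            )
            curves = [
                bi.filter_and_bin(d.rois, min_rois_per_bin=5)
                for d in sd.simulate_replicates(cfg, 3)
            ]
            avg = bi.average_replicates(curves)

            def rms(c):
                truth = hill(c.free_acceptor_uM, cfg.delta_omega_max, cfg.kd_uM)
                return float(np.sqrt(np.mean((c.delta_omega_mean - truth) ** 2)))

            if rms(avg) < np.mean([rms(c) for c in curves]):
                wins += 1
        assert wins >= 0.7 * n_trials

    def test_incompatible_grids_rejected(self, make_curve):
        c1 = make_curve([1, 5, 20], [0.01, 0.05, 0.1])
        c2 = make_curve([1, 5, 20], [0.01, 0.05, 0.1])
        c2.bin_edges = (0.0, 10.0, 50.0)
        with pytest.raises(ValueError):
            bi.average_replicates([c1, c2])


class TestSRatio:
    def test_straight_line_gives_exactly_one(self):
        x = np.array([0, 5, 10, 20, 35, 50], dtype=float)
        assert bi.s_ratio(x=x, y=0.003 * x + 0.01) == pytest.approx(1.0, rel=1e-12)

    def test_hill_grid_matches_trapezoid_oracle(self):
        # saturating curve sampled at 0, 5, ..., 50 uM
        x = np.arange(0.0, 51.0, 5.0)
        y = hill(x, 0.2, 16.3)
        oracle = trapezoid_s_ratio(x, y)
        assert oracle == pytest.approx(2.5256, abs=2e-4)
        assert bi.s_ratio(x=x, y=y) == pytest.approx(oracle, rel=1e-12)

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            bi.s_ratio(x=[0, 10, 20], y=[0.05, 0.05, 0.05])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bi.s_ratio(x=[0, 10], y=[0.0, 0.1])

    def test_invariant_to_affine_rescaling_of_both_axes(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 50, 8))
        y = hill(x) + rng.normal(0, 0.005, 8)
        base = bi.s_ratio(x=x, y=y)
        assert bi.s_ratio(x=3 * x + 7, y=0.5 * y - 0.2) == pytest.approx(base, rel=1e-9)

    def test_decreasing_in_kd_for_noiseless_hill(self):
        x = np.arange(0.0, 51.0, 5.0)
        vals = [bi.s_ratio(x=x, y=hill(x, 0.2, kd)) for kd in (2, 5, 10, 16.3, 30, 60)]
        assert np.all(np.diff(vals) < 0)


class TestHillFit:
    def test_noiseless_hill_recovered_exactly(self):
        x = np.arange(0.0, 51.0, 5.0)
        fit = bi.fit_hill(curve_from_points(x, hill(x, 0.2, 16.3)))
        assert fit.bmax == pytest.approx(0.2, rel=1e-5)
        assert fit.kd_uM == pytest.approx(16.3, rel=1e-4)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert not fit.kd_at_bound

    def test_linear_data_pins_kd_at_bound_with_flag(self):
        x = np.arange(0.0, 51.0, 5.0)
        fit = bi.fit_hill(curve_from_points(x, 0.003 * x))
        assert fit.kd_at_bound

    def test_background_term_absorbs_collision_slope(self):
        x = np.arange(0.0, 51.0, 5.0)
        y = hill(x, 0.2, 16.3) + 0.001 * x
        fit = bi.fit_hill(curve_from_points(x, y), with_background=True)
        assert fit.kd_uM == pytest.approx(16.3, rel=1e-3)
        assert fit.background_slope == pytest.approx(0.001, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bi.fit_hill(curve_from_points([0, 10], [0, 0.1]))


class TestLinearFit:
    def test_two_points_interpolated_exactly(self):
        fit = bi.fit_linear(x=[0.0, 10.0], y=[0.01, 0.04])
        assert fit.slope == pytest.approx(0.003)
        assert fit.intercept == pytest.approx(0.01)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_collision_simulation_recovers_generating_slope(self, collision_config):
        curve = bi.filter_and_bin(sd.simulate_qf3_dataset(collision_config).rois)
        fit = bi.fit_linear(curve)
        assert fit.slope == pytest.approx(collision_config.collision_coeff, rel=0.1)

    def test_hill_shaped_data_fits_worse_than_hill_model(self):
        x = np.arange(0.0, 51.0, 5.0)
        curve = curve_from_points(x, hill(x, 0.2, 10.0))
        assert bi.fit_linear(curve).rss > bi.fit_hill(curve).rss

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            bi.fit_linear(x=[1.0], y=[0.1])


class TestClassifyInteraction:
    def test_saturating_curve_called_binding(self, binding_config):
        curves = [
            bi.filter_and_bin(d.rois) for d in sd.simulate_replicates(binding_config, 3)
        ]
        call = bi.classify_interaction(bi.average_replicates(curves))
        assert call.verdict == "binding"
        assert call.s_ratio >= 2.0
        assert call.bmax > 0.05

    def test_linear_curve_called_collision(self, collision_config):
        curves = [
            bi.filter_and_bin(d.rois) for d in sd.simulate_replicates(collision_config, 3)
        ]
        call = bi.classify_interaction(bi.average_replicates(curves))
        assert call.verdict == "collision"
        assert call.s_ratio < 2.0

    def test_low_amplitude_saturating_curve_fails_bmax_gate(self):
        # shape passes (s-ratio >= 2) but the amplitude is below the
        # 0.05 rad dynamic-range threshold -> collision
        x = np.arange(0.0, 51.0, 5.0)
        call = bi.classify_interaction(curve_from_points(x, hill(x, 0.03, 10.0)))
        assert call.s_ratio >= 2.0
        assert call.bmax < 0.05
        assert call.verdict == "collision"

    def test_flat_curve_reported_as_degenerate_collision(self):
        call = bi.classify_interaction(curve_from_points([0, 10, 20], [0.02, 0.02, 0.02]))
        assert call.verdict == "collision"
        assert "degenerate" in call.diagnostics


class TestPipeline:
    def test_binding_dataset_end_to_end(self, binding_config):
        reps = [d.rois for d in sd.simulate_replicates(binding_config, 3)]
        call, curve = bi.run_qf3_pipeline(reps)
        assert call.verdict == "binding"
        assert call.kd_uM == pytest.approx(binding_config.kd_uM, rel=0.2)
        report = bi.report_dict(call, curve)
        assert report["verdict"] == "binding"
        assert report["n_rois_used"] == int(curve.n_rois.sum())

    def test_collision_dataset_end_to_end(self, collision_config):
        reps = [d.rois for d in sd.simulate_replicates(collision_config, 3)]
        call, _ = bi.run_qf3_pipeline(reps)
        assert call.verdict == "collision"

    def test_single_table_with_replicate_column(self, binding_config):
        import pandas as pd

        table = pd.concat(
            [d.rois for d in sd.simulate_replicates(binding_config, 3)], ignore_index=True
        )
        call, _ = bi.run_qf3_pipeline(table)
        assert call.verdict == "binding"

    def test_empty_input_names_the_failing_stage(self):
        with pytest.raises(ValueError, match="filter_and_bin"):
            bi.run_qf3_pipeline([])

    def test_kd_bootstrap_ci_covers_the_estimate(self, binding_config):
        reps = [d.rois for d in sd.simulate_replicates(binding_config, 3)]
        call, _ = bi.run_qf3_pipeline(reps, kd_ci=True)
        lo, hi = call.diagnostics["kd_ci"]
        assert lo <= call.kd_uM <= hi
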