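"""Unit tests for scoring, trial classification, sweeps and spectra."""

import numpy as np
import pandas as pd
import pytest

from fullforce import (
    NetworkParams,
    TrainingConfig,
    classify_comparison_trial,
    classify_interval_trial,
    normalized_error,
    run_size_sweep,
    spectrum_analysis,
    success_onset,
)
from fullforce.evaluation import force_anomaly_sizes
from fullforce.tasks import make_comparison_stream, make_interval_stream


class TestNormalizedError:
    def test_perfect_output_scores_zero(self, rng):
        f = rng.normal(size=200)
        assert normalized_error(f, f) == 0.0

    def test_mean_output_scores_one(self, rng):
        f = rng.normal(size=500)
        z = np.full_like(f, f.mean())
        assert normalized_error(z, f) == pytest.approx(1.0)

    def test_constant_offset_scales_with_variance(self, rng):
        f = rng.normal(size=500)
        c = 0.3
        assert normalized_error(f + c, f) == pytest.approx(c**2 / np.var(f))

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            normalized_error(np.zeros(10), np.ones(10))


class TestIntervalClassification:
    @pytest.fixture
    def trial(self):
        return make_interval_stream(3, seed=0, offset=0.25)

    def test_exact_output_is_correct_with_peak_at_expected_time(self, trial):
        for ev in trial.events:
            res = classify_interval_trial(trial.f_out, ev, offset=0.25)
            assert res["correct"]
            assert res["error"] < 1e-12
            assert abs(res["peak_time"] - ev.t_response_peak) <= 1.0

    def test_flat_output_is_incorrect(self, trial):
        z = np.full(trial.n_steps, 0.25)
        for ev in trial.events:
            res = classify_interval_trial(z, ev, offset=0.25)
            assert not res["correct"]
            assert res["error"] >= 0.99

    def test_output_shifted_beyond_window_is_incorrect(self, trial):
        z = np.full(trial.n_steps, 0.25)
        ev = trial.events[0]
        a = int(ev.t_bump_on)
        b = int(ev.t_bump_off)
        shift = 500
        z[a + shift: b + shift] = trial.f_out[a:b]
        assert not classify_interval_trial(z, ev, offset=0.25)["correct"]
        # the same shift inside the window is accepted
        z2 = np.full(trial.n_steps, 0.25)
        z2[a + 200: b + 200] = trial.f_out[a:b]
        res = classify_interval_trial(z2, ev, offset=0.25)
        assert res["correct"] and res["shift_ms"] == pytest.approx(200.0)

    def test_strict_centering_mode_rejects_shifted_output(self, trial):
        ev = trial.events[0]
        a, b = int(ev.t_bump_on), int(ev.t_bump_off)
        z = np.full(trial.n_steps, 0.25)
        z[a + 200: b + 200] = trial.f_out[a:b]
        assert not classify_interval_trial(z, ev, offset=0.25,
                                           strict_center=True)["correct"]


class TestComparisonClassification:
    @pytest.fixture
    def trial(self):
        return make_comparison_stream(6, seed=1, offset=0.25)

    def test_three_way_verdicts(self, trial):
        flipped = 2 * 0.25 - trial.f_out
        flat = np.full(trial.n_steps, 0.25)
        for ev in trial.events:
            assert classify_comparison_trial(trial.f_out, ev,
                                             offset=0.25)["verdict"] == "correct"
            assert classify_comparison_trial(flipped, ev,
                                             offset=0.25)["verdict"] == "incorrect"
            assert classify_comparison_trial(flat, ev,
                                             offset=0.25)["verdict"] == "undetermined"


class TestSpectrum:
    def test_untrained_model_has_zero_spectrum(self):
        from fullforce import train

        model = train(NetworkParams(n_units=20),
                      TrainingConfig(n_batches=0, seed=0))
        report = spectrum_analysis(model)
        assert np.allclose(report.eigs_task, 0.0)
        assert report.summary["task"]["max_modulus"] == 0.0

    def test_random_matrix_radius_near_g(self):
        from fullforce import train

        model = train(NetworkParams(n_units=800),
                      TrainingConfig(n_batches=0, seed=1))
        assert report_radius(model) == pytest.approx(1.5, abs=0.15)

    def test_rank_one_update_trace_identity(self, quick_oscillation_model):
        report = spectrum_analysis(quick_oscillation_model)
        model = quick_oscillation_model
        lhs = report.eigs_effective.sum()
        rhs = report.eigs_driven.sum() + model.weights.u @ model.weights.w
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_summaries_invariant_to_eigenvalue_order(self, quick_oscillation_model):
        from fullforce.evaluation import _eig_summary

        eigs = spectrum_analysis(quick_oscillation_model).eigs_task
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(eigs)
        assert _eig_summary(eigs) == _eig_summary(shuffled)


def report_radius(model):
    return spectrum_analysis(model).summary["driven"]["max_modulus"]


class TestSweeps:
    def test_single_cell_sweep_has_one_record(self, tmp_path):
        cfg = TrainingConfig(n_batches=1, periods_per_batch=5)
        df = run_size_sweep("oscillation", "full-force", [50], 1, cfg,
                            master_seed=3,
                            eval_kwargs={"n_periods": 2, "warmup_periods": 0})
        assert len(df) == 1
        assert df.iloc[0]["N"] == 50

    def test_sweep_resumes_from_csv_without_recomputing(self, tmp_path):
        cfg = TrainingConfig(n_batches=1, periods_per_batch=5)
        out = tmp_path / "sweep.csv"
        kw = dict(master_seed=3, out_csv=out,
                  eval_kwargs={"n_periods": 2, "warmup_periods": 0})
        df1 = run_size_sweep("oscillation", "full-force", [30, 50], 1, cfg, **kw)
        stamp = out.stat().st_mtime_ns
        df2 = run_size_sweep("oscillation", "full-force", [30, 50], 1, cfg, **kw)
        assert out.stat().st_mtime_ns == stamp  # nothing re-run
        pd.testing.assert_frame_equal(
            df1.reset_index(drop=True),
            df2.reset_index(drop=True),
            check_dtype=False,
        )

    def test_cell_seeds_are_order_independent(self):
        cfg = TrainingConfig(n_batches=1, periods_per_batch=5)
        kw = dict(master_seed=9,
                  eval_kwargs={"n_periods": 2, "warmup_periods": 0})
        a = run_size_sweep("oscillation", "full-force", [30, 40], 1, cfg, **kw)
        b = run_size_sweep("oscillation", "full-force", [40], 1, cfg, **kw)
        row_a = a[a["N"] == 40].iloc[0]
        row_b = b.iloc[0]
        assert row_a["seed"] == row_b["seed"]
        assert row_a["normalized_error"] == row_b["normalized_error"]

    def test_empty_sizes_rejected(self):
        cfg = TrainingConfig(n_batches=1)
        with pytest.raises(ValueError):
            run_size_sweep("oscillation", "full-force", [], 1, cfg)

    def test_success_onset_and_anomaly_helpers(self):
        df = pd.DataFrame({
            "N": [100, 100, 200, 200, 300, 300],
            "noise_2D": 0.0,
            "normalized_error": [0.9, 1.1, 0.01, 0.03, 0.001, 0.002],
        })
        assert success_onset(df, 0.05) == 200
        assert success_onset(df, 1e-4) is None
        anomaly = pd.DataFrame({
            "N": [100, 200, 300],
            "noise_2D": 0.1,
            "normalized_error": [0.2, 0.5, 0.1],
        })
        flagged = force_anomaly_sizes(anomaly)
        assert list(flagged["N"]) == [200]
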