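import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlmquant.heterogeneity import (
    FrameStats,
    NoiseModel,
    compute_frame_stats,
    correct_heterogeneity,
    count_modes,
    fit_noise_baseline,
    frame_stats,
    pool_stats,
    summarize_timepoints,
)
from tlmquant.synthetic import simulate_noise_calibration


def fs(index, t, values):
    return frame_stats(values, frame_index=index, time_h=t)


class TestFrameStats:
    def test_constant_values(self):
        s = fs(0, 0.0, [10, 10, 10])
        assert (s.mean_fluor, s.sd_fluor, s.n_cells) == (10.0, 0.0, 3)

    def test_two_values_sample_sd(self):
        s = fs(0, 0.0, [0, 20])
        assert s.mean_fluor == 10.0
        assert s.sd_fluor == pytest.approx(math.sqrt(200))

    def test_single_cell_degenerate(self):
        s = fs(0, 0.0, [42.0])
        assert (s.mean_fluor, s.sd_fluor, s.n_cells) == (42.0, 0.0, 1)

    def test_empty_frames_skipped_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "frame_index": [0, 1],
                "time_h": [0.0, 1.0],
                "mean_normalized": [5.0, np.nan],
            }
        )
        with caplog.at_level("WARNING"):
            stats = compute_frame_stats(df)
        assert [s.frame_index for s in stats] == [0]
        assert "skipped" in caplog.text


def ols_normal_equations(x, y):
    """Closed-form (XᵀX)⁻¹Xᵀy oracle for the straight-line fit."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid**2).sum() / ss_tot
    return beta[1], beta[0], r2


class TestNoiseBaselineFit:
    def test_exact_line_recovered(self):
        pts = [(m, 0.1 * m + 2) for m in (10, 20, 40, 80)]
        model = fit_noise_baseline(pts)
        assert model.slope == pytest.approx(0.1)
        assert model.intercept == pytest.approx(2.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_noise_baseline([(1, 1), (2, 2)])

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_noise_baseline([(5, 1), (5, 2), (5, 3)])

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 100, 40)
            y = rng.normal(0.2 * x + 5, 1.0)
            model = fit_noise_baseline(list(zip(x, y)))
            slope, intercept, r2 = ols_normal_equations(x, y)
            assert model.slope == pytest.approx(slope, rel=1e-10)
            assert model.intercept == pytest.approx(intercept, rel=1e-10)
            assert model.r_squared == pytest.approx(r2, rel=1e-10)

    def test_parameter_recovery_from_simulated_design(self):
        """The four-level induction design recovers the generating line
        within 10% at 500+ frames."""
        pts = simulate_noise_calibration(seed=5)
        model = fit_noise_baseline(pts)
        assert model.n_points >= 500
        assert model.slope == pytest.approx(0.1, rel=0.1)
        assert model.intercept == pytest.approx(2.0, rel=0.1)
        assert model.r_squared > 0.9

    def test_json_roundtrip(self, tmp_path):
        model = NoiseModel(slope=0.1, intercept=2.0, r_squared=0.95, n_points=500)
        model.save(tmp_path / "model.json")
        assert NoiseModel.load(tmp_path / "model.json") == model


class TestCorrection:
    MODEL = NoiseModel(slope=0.1, intercept=2.0, r_squared=0.99, n_points=100)

    def test_exactly_on_the_line_corrects_to_zero(self):
        (rec,) = correct_heterogeneity(
            [FrameStats(0, 0.0, 50, 100.0, 12.0)], self.MODEL
        )
        assert rec.predicted_sd == pytest.approx(12.0)
        assert rec.corrected == pytest.approx(0.0)

    def test_excess_heterogeneity_remains(self):
        (rec,) = correct_heterogeneity(
            [FrameStats(0, 0.0, 50, 100.0, 20.0)], self.MODEL
        )
        assert rec.corrected == pytest.approx(8.0)

    def test_negative_corrected_preserved_and_monotone(self):
        recs = correct_heterogeneity(
            [
                FrameStats(0, 0.0, 50, 100.0, 5.0),
                FrameStats(1, 1.0, 50, 100.0, 11.0),
                FrameStats(2, 2.0, 50, 100.0, 13.0),
            ],
            self.MODEL,
        )
        assert recs[0].corrected == pytest.approx(-7.0)
        assert [r.corrected for r in recs] == sorted(r.corrected for r in recs)

    def test_homogeneous_series_corrects_to_noise_floor(self):
        """A homogeneous series drawn under the model corrects to ~0."""
        train = simulate_noise_calibration(seed=21)
        model = fit_noise_baseline(train)
        held = simulate_noise_calibration(
            mean_levels=(30.0,), n_frames_per_level=14, seed=22
        )
        corrected = np.array([r.corrected for r in correct_heterogeneity(held, model)])
        se = corrected.std(ddof=1) / math.sqrt(len(corrected))
        assert abs(corrected.mean()) < 2 * se


class TestSummaries:
    STATS = [
        FrameStats(0, 0.0, 10, 5.0, 1.0),
        FrameStats(1, 4.9, 20, 8.0, 2.0),
        FrameStats(2, 5.2, 30, 9.0, 3.0),
    ]

    def test_row_per_requested_time(self):
        out = summarize_timepoints(self.STATS, [0.0, 5.0])
        assert len(out) == 2

    def test_nearest_frame_tiebreak_earlier(self):
        out = summarize_timepoints(self.STATS, [5.0])
        assert out.loc[0, "time_h"] == 4.9  # 0.1 h beats 0.2 h
        stats = [FrameStats(0, 4.0, 5, 1.0, 0.0), FrameStats(1, 6.0, 5, 2.0, 0.0)]
        out = summarize_timepoints(stats, [5.0])  # exact tie
        assert out.loc[0, "time_h"] == 4.0

    def test_beyond_span_is_error(self):
        with pytest.raises(ValueError, match="span"):
            summarize_timepoints(self.STATS, [9.0])

    def test_pooling_matches_concatenated_values(self, rng):
        """Combined stats from per-frame summaries equal the statistics of
        the pooled raw values exactly."""
        a, b = rng.normal(10, 3, 17), rng.normal(40, 8, 23)
        pooled = np.concatenate([a, b])
        stats = [fs(0, 0.0, a), fs(1, 1.0, b)]
        n, mean, sd = pool_stats(stats)
        assert n == 40
        assert mean == pytest.approx(pooled.mean(), rel=1e-12)
        assert sd == pytest.approx(pooled.std(ddof=1), rel=1e-12)

    def test_window_pools_neighbouring_frames(self):
        out = summarize_timepoints(self.STATS, [5.0], window=0.5)
        assert out.loc[0, "n_cells"] == 50  # frames at 4.9 and 5.2 pooled


class TestModeCount:
    def test_unimodal_vs_bimodal(self, rng):
        uni = rng.normal(50, 5, 500)
        bi = np.concatenate([rng.normal(10, 3, 300), rng.normal(120, 10, 200)])
        assert count_modes(uni) == 1
        assert count_modes(bi) == 2

    def test_constant_sample_single_mode(self):
        assert count_modes([7.0] * 50) == 1


@settings(max_examples=30, deadline=None)
@given(
    values=st.lists(
        st.floats(-50, 300, allow_nan=False, allow_infinity=False),
        min_size=2,
        max_size=40,
    )
)
def test_frame_stats_matches_numpy(values):
    """Summary statistics agree with direct numpy computation."""
    s = frame_stats(values)
    arr = np.asarray(values)
    assert s.mean_fluor == pytest.approx(arr.mean(), abs=1e-9)
    assert s.sd_fluor == pytest.approx(arr.std(ddof=1), abs=1e-9)
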