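import numpy as np
import pytest

from masticnet.preprocess import (
    LabelMap,
    NuisanceSet,
    PipelineOrderError,
    ROITimeSeries,
    bandpass_filter,
    discard_initial_volumes,
    extract_roi_timeseries,
    linear_detrend,
    nuisance_regress,
    threshold_probabilistic_map,
)

TR = 2.0


def make_series(data, stage="raw", tr=TR):
    data = np.asarray(data, dtype=float)
    labels = tuple(f"n{k}" for k in range(data.shape[1]))
    return ROITimeSeries(data=data, node_labels=labels, sampling_interval_s=tr, stage=stage)


class TestDiscardInitialVolumes:
    def test_183_minus_3_gives_180(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.standard_normal((183, 4)))
        out = discard_initial_volumes(s, 3)
        assert out.n_timepoints == 180
        np.testing.assert_array_equal(out.data, s.data[3:])

    def test_zero_discard_keeps_rows(self):
        s = make_series(np.arange(12.0).reshape(6, 2))
        out = discard_initial_volumes(s, 0)
        np.testing.assert_array_equal(out.data, s.data)

    def test_discarding_all_but_one_rejected(self):
        s = make_series(np.ones((3, 2)) * np.arange(3)[:, None])
        with pytest.raises(ValueError):
            discard_initial_volumes(s, 3)


class TestLinearDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(50.0)
        s = make_series(np.column_stack([2 * t + 5, -0.3 * t + 1]))
        out = linear_detrend(s)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_constant_column_zeroed(self):
        s = make_series(np.full((20, 1), 7.0))
        assert np.max(np.abs(linear_detrend(s).data)) < 1e-10

    def test_matches_explicit_least_squares_fit(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((60, 3))
        s = make_series(y)
        out = linear_detrend(s)
        t = np.arange(60.0)
        X = np.column_stack([np.ones(60), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out.data, y - X @ beta, atol=1e-10)
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-12


class TestBandpassFilter:
    def on_grid(self, k, n):
        return k / (n * TR)

    def test_in_band_sinusoid_preserved(self):
        n = 1024
        f = self.on_grid(102, n)  # ~0.0498 Hz, inside 0.01-0.08
        t = np.arange(n) * TR
        x = np.sin(2 * np.pi * f * t)
        out = bandpass_filter(make_series(x[:, None], stage="detrended"))
        assert np.abs(out.data).max() == pytest.approx(np.abs(x).max(), rel=0.01)
        np.testing.assert_allclose(out.data[:, 0], x, atol=1e-8)

    def test_out_of_band_sinusoid_annihilated(self):
        n = 1024
        f = self.on_grid(410, n)  # ~0.20 Hz, in the stop band
        t = np.arange(n) * TR
        x = np.cos(2 * np.pi * f * t)
        out = bandpass_filter(make_series(x[:, None], stage="detrended"))
        assert np.abs(out.data).max() < 1e-8

    def test_constant_series_zeroed(self):
        s = make_series(np.full((64, 2), 3.5), stage="detrended")
        assert np.abs(bandpass_filter(s).data).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        s = make_series(rng.standard_normal((180, 5)), stage="detrended")
        once = bandpass_filter(s)
        twice = bandpass_filter(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_above_nyquist_rejected(self):
        s = make_series(np.random.default_rng(3).standard_normal((50, 2)), stage="detrended")
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(s, 0.01, 0.3)  # Nyquist at TR=2 is 0.25

    def test_output_is_real(self):
        rng = np.random.default_rng(4)
        out = bandpass_filter(make_series(rng.standard_normal((97, 2)), stage="detrended"))
        assert np.isrealobj(out.data)


class TestNuisanceRegress:
    def filtered(self, data):
        return make_series(data, stage="filtered")

    def test_series_equal_to_regressor_gives_zero_residual(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(40)
        s = self.filtered(z[:, None])
        out = nuisance_regress(s, NuisanceSet(z[:, None], ("z",)))
        assert np.abs(out.data).max() < 1e-10

    def test_empty_nuisance_set_forbidden(self):
        with pytest.raises(ValueError, match="k >= 1"):
            NuisanceSet(np.empty((40, 0)), ())

    def test_constant_regressor_rejected_as_rank_deficient(self):
        # the design always includes an intercept, so a constant regressor
        # is collinear and must be named in the error
        rng = np.random.default_rng(6)
        s = self.filtered(rng.standard_normal((30, 2)))
        with pytest.raises(ValueError, match="const_reg"):
            nuisance_regress(s, NuisanceSet(np.ones((30, 1)), ("const_reg",)))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal((80, 4))
        z = rng.standard_normal((80, 6))
        out = nuisance_regress(self.filtered(y), NuisanceSet(z, tuple("abcdef")))
        X = np.column_stack([np.ones(80), z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out.data, y - X @ beta, atol=1e-8)
        # residuals orthogonal to every regressor
        inner = np.abs(z.T @ out.data)
        norms = np.linalg.norm(z, axis=0)[:, None] * np.linalg.norm(out.data, axis=0)[None, :]
        assert np.max(inner / norms) < 1e-8
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-10

    def test_timepoint_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        s = self.filtered(rng.standard_normal((30, 2)))
        with pytest.raises(ValueError, match="timepoints"):
            nuisance_regress(s, NuisanceSet(rng.standard_normal((29, 2)), ("a", "b")))


class TestExtractRoiTimeseries:
    def test_uniform_label_value_reproduced(self):
        grid = np.zeros((2, 2, 1), dtype=np.int32)
        grid[0, :, 0] = 1
        vol = np.zeros((2, 2, 1, 5))
        signal = np.arange(5.0)
        vol[0, :, 0, :] = signal
        out = extract_roi_timeseries(vol, LabelMap(grid, {1: "roi"}))
        np.testing.assert_array_equal(out.data[:, 0], signal)

    def test_two_voxel_mean(self):
        grid = np.array([[[1], [1]]], dtype=np.int32)
        vol = np.zeros((1, 2, 1, 2))
        vol[0, 0, 0] = [1.0, 1.0]
        vol[0, 1, 0] = [3.0, 3.0]
        out = extract_roi_timeseries(vol, LabelMap(grid, {1: "roi"}))
        np.testing.assert_array_equal(out.data[:, 0], [2.0, 2.0])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        grid = rng.integers(0, 4, size=(5, 4, 3)).astype(np.int32)
        grid[0, 0, 0] = 1; grid[0, 0, 1] = 2; grid[0, 0, 2] = 3  # ensure nonempty
        names = {1: "a", 2: "b", 3: "c"}
        vol = rng.standard_normal((5, 4, 3, 7))
        out = extract_roi_timeseries(vol, LabelMap(grid, names))
        for idx, k in enumerate(sorted(names)):
            acc = np.zeros(7); count = 0
            for i in range(5):
                for j in range(4):
                    for l in range(3):
                        if grid[i, j, l] == k:
                            acc += vol[i, j, l]; count += 1
            np.testing.assert_allclose(out.data[:, idx], acc / count, atol=1e-12)

    def test_empty_label_rejected_by_name(self):
        grid = np.ones((2, 2, 1), dtype=np.int32)
        with pytest.raises(ValueError, match="ghost"):
            extract_roi_timeseries(
                np.zeros((2, 2, 1, 3)), LabelMap(grid, {1: "roi", 2: "ghost"})
            )


class TestThresholdProbabilisticMap:
    def test_above_threshold_included(self):
        assert threshold_probabilistic_map(np.full((2, 2, 2), 0.6)).all()

    def test_below_threshold_excluded(self):
        assert not threshold_probabilistic_map(np.full((2, 2, 2), 0.4)).any()

    def test_boundary_value_included(self):
        assert threshold_probabilistic_map(np.array([[[0.5]]])).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            threshold_probabilistic_map(np.array([[[1.2]]]))


class TestPipelineOrder:
    def test_bandpass_before_detrend_rejected(self):
        s = make_series(np.random.default_rng(10).standard_normal((30, 2)))
        with pytest.raises(PipelineOrderError):
            bandpass_filter(s)

    def test_nuisance_before_bandpass_rejected(self):
        s = make_series(np.random.default_rng(11).standard_normal((30, 2)), stage="detrended")
        with pytest.raises(PipelineOrderError):
            nuisance_regress(s, NuisanceSet(np.random.default_rng(12).standard_normal((30, 1)), ("z",)))

    def test_discard_after_detrend_rejected(self):
        s = make_series(np.random.default_rng(13).standard_normal((30, 2)))
        with pytest.raises(PipelineOrderError):
            discard_initial_volumes(linear_detrend(s), 2)
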