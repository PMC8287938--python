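"""SEC-SAXS reduction: chromatogram, peak/buffer selection, scaling,
averaging and buffer subtraction."""

import numpy as np
import pytest

from oligosaxs.curves import CurveValidationError, ScatteringCurve, SecSeries
from oligosaxs.reduction import (
    ReductionError,
    auto_buffer_frames,
    chromatogram,
    reduce_series,
    scale_and_average,
    select_peak_frames,
    subtract_buffer,
)
from oligosaxs.synth import simulate_sec_series, sphere_curve


@pytest.fixture(scope="module")
def sim():
    protein = sphere_curve(30.0)
    return simulate_sec_series(
        protein,
        elution=(100.0, 12.0, 1.0),
        buffer_level=0.05,
        n_frames=200,
        noise=0.01,
        seed=7,
    )


class TestChromatogram:
    def test_peak_at_elution_center(self, sim):
        series, truth = sim
        chrom = chromatogram(series)
        assert abs(chrom.peak_frame - truth.peak_frame) <= 1

    def test_linearity_under_frame_scaling(self):
        base = sphere_curve(20.0)
        f1 = base
        f2 = base.with_(intensity=2 * base.intensity)
        chrom = chromatogram(SecSeries(frames=(f1, f2)))
        assert chrom.summed_intensity[1] == pytest.approx(
            2 * chrom.summed_intensity[0]
        )

    def test_buffer_only_series_is_flat(self):
        protein = sphere_curve(30.0)
        series, _ = simulate_sec_series(
            protein, elution=(100.0, 12.0, 0.0), n_frames=50, noise=0.01,
            seed=1,
        )
        chrom = chromatogram(series)
        cv = chrom.summed_intensity.std() / chrom.summed_intensity.mean()
        assert cv < 0.01

    def test_s_window_outside_grid_rejected(self, sim):
        series, _ = sim
        with pytest.raises(CurveValidationError):
            chromatogram(series, s_window=(1.0, 2.0))


class TestPeakSelection:
    def test_window_centred_on_gaussian_peak(self, sim):
        series, _ = sim
        chrom = chromatogram(series)
        frames = select_peak_frames(chrom, n=20)
        peak = chrom.peak_frame
        assert frames == list(range(peak - 10, peak + 10))
        # brute force: no other length-20 window sums higher
        sums = np.convolve(chrom.summed_intensity, np.ones(20), "valid")
        assert frames[0] == int(np.argmax(sums))

    @pytest.mark.parametrize("n", [1, 200])
    def test_extreme_window_sizes(self, sim, n):
        series, _ = sim
        chrom = chromatogram(series)
        frames = select_peak_frames(chrom, n=n)
        assert len(frames) == n
        if n == 1:
            assert frames == [chrom.peak_frame]

    def test_invalid_n_rejected(self, sim):
        chrom = chromatogram(sim[0])
        with pytest.raises(CurveValidationError):
            select_peak_frames(chrom, n=0)


class TestScaleAndAverage:
    def test_scalar_multiples_collapse_to_reference(self, s_grid):
        base = sphere_curve(25.0)
        frames = tuple(
            base.with_(intensity=a * base.intensity, sigma=a * base.sigma)
            for a in (0.5, 1.0, 2.0, 4.0)
        )
        series = SecSeries(frames=frames)
        avg = scale_and_average(series, [0, 1, 2, 3], reference=1)
        np.testing.assert_allclose(avg.intensity, base.intensity, rtol=1e-9)

    def test_averaging_noisy_replicates_beats_any_single_frame(self):
        truth = sphere_curve(30.0)
        frames = tuple(
            sphere_curve(30.0, noise=0.02, seed=s) for s in range(20)
        )
        series = SecSeries(frames=frames)
        avg = scale_and_average(series, list(range(20)), reference=0)
        sigma = frames[0].sigma  # common scale: one frame's uncertainty

        def chi2(c):
            return np.mean(((c.intensity - truth.intensity) / sigma) ** 2)

        assert chi2(avg) < min(chi2(f) for f in frames)

    def test_single_frame_passthrough(self):
        base = sphere_curve(25.0)
        series = SecSeries(frames=(base, base.with_(label="b")))
        avg = scale_and_average(series, [0], reference=0)
        np.testing.assert_allclose(avg.intensity, base.intensity)
        np.testing.assert_allclose(avg.sigma, base.sigma)

    def test_zero_intensity_frame_raises(self):
        base = sphere_curve(25.0)
        dead = base.with_(intensity=np.zeros(len(base)))
        series = SecSeries(frames=(base, dead))
        with pytest.raises(ReductionError):
            scale_and_average(series, [0, 1], reference=0)


class TestSubtractBuffer:
    def test_sample_minus_itself_is_zero_with_positive_sigma(self):
        c = sphere_curve(30.0)
        diff = subtract_buffer(c, c)
        assert np.all(diff.intensity == 0)
        assert np.all(diff.sigma > 0)

    def test_sigma_adds_in_quadrature(self, s_grid):
        ones = np.ones_like(s_grid)
        a = ScatteringCurve(s=s_grid, intensity=ones, sigma=ones)
        b = ScatteringCurve(s=s_grid, intensity=ones, sigma=ones)
        diff = subtract_buffer(a, b)
        np.testing.assert_allclose(diff.sigma, np.sqrt(2.0))

    def test_subtracting_zero_curve_is_identity(self, s_grid):
        c = sphere_curve(30.0)
        zero = ScatteringCurve(
            s=s_grid,
            intensity=np.zeros_like(s_grid),
            sigma=np.full_like(s_grid, 1e-9),
        )
        diff = subtract_buffer(c, zero)
        np.testing.assert_allclose(diff.intensity, c.intensity)

    def test_grid_mismatch_rejected(self, s_grid):
        c = sphere_curve(30.0)
        other = sphere_curve(30.0, s_grid=s_grid + 0.01)
        with pytest.raises(CurveValidationError):
            subtract_buffer(c, other)

    def test_protein_recovered_within_propagated_sigma(self, sim):
        series, truth = sim
        chrom = chromatogram(series)
        peak = select_peak_frames(chrom, 20)
        sample = scale_and_average(series, peak)
        buffer_frames = auto_buffer_frames(chrom)
        buffer = scale_and_average(series, buffer_frames)
        diff = subtract_buffer(sample, buffer)
        expected = truth.contributions[peak].mean(axis=0)
        frac_within = np.mean(
            np.abs(diff.intensity - expected) <= 3 * diff.sigma
        )
        assert frac_within >= 0.95


class TestAutoBufferFrames:
    def test_window_precedes_peak_baseline_region(self, sim):
        series, _ = sim
        chrom = chromatogram(series)
        frames = auto_buffer_frames(chrom)
        assert frames
        assert max(frames) < 60
        assert frames == list(range(frames[0], frames[-1] + 1))

    def test_flat_series_has_no_peak(self):
        protein = sphere_curve(30.0)
        series, _ = simulate_sec_series(
            protein, elution=(100.0, 12.0, 0.0), n_frames=50, noise=0.01,
            seed=2,
        )
        with pytest.raises(ReductionError, match="no elution peak"):
            auto_buffer_frames(chromatogram(series))

    def test_monotonically_rising_chromatogram_rejected(self, s_grid):
        frames = tuple(
            ScatteringCurve(
                s=s_grid,
                intensity=np.full_like(s_grid, 1.0 + 3.0 * k),
                sigma=np.full_like(s_grid, 0.01),
            )
            for k in range(30)
        )
        with pytest.raises(ReductionError):
            auto_buffer_frames(chromatogram(SecSeries(frames=frames)))


class TestFullReduction:
    def test_recovers_generator_curve_with_unit_chi2(self, sim):
        # the reduced curve's absolute level is pinned to the reference
        # frame (one noisy draw), so the shape is compared: one free
        # scalar against the generator truth, then reduced chi2 ~ 1
        series, truth = sim
        reduced, info = reduce_series(series)
        expected = truth.contributions[info["peak_frames"]].mean(axis=0)
        w = 1.0 / reduced.sigma**2
        scale = np.sum(w * reduced.intensity * expected) / np.sum(
            w * expected**2
        )
        assert scale == pytest.approx(1.0, abs=0.02)
        chi2 = np.mean(
            ((reduced.intensity - scale * expected) / reduced.sigma) ** 2
        )
        assert chi2 < 1.5
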