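"""SEC-SAXS reduction: chromatogram, peak selection, frame scaling and
averaging, and buffer subtraction.

The reduction recipe mirrors standard beamline practice for in-line
size-exclusion chromatography SAXS: build the total-intensity
chromatogram, pick a contiguous window of frames at the elution peak,
scale each frame onto a reference and average them, do the same for
buffer frames preceding the peak, and subtract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import CurveValidationError, ScatteringCurve, SecSeries

__all__ = [
    "Chromatogram",
    "ReductionError",
    "chromatogram",
    "select_peak_frames",
    "scale_and_average",
    "subtract_buffer",
    "auto_buffer_frames",
    "reduce_series",
]


class ReductionError(RuntimeError):
    """A reduction step could not be completed on the given data."""


@dataclass(frozen=True)
class Chromatogram:
    """Per-frame summed intensity versus SEC-SAXS frame number."""

    frame_index: np.ndarray
    summed_intensity: np.ndarray

    def __post_init__(self) -> None:
        fi = np.asarray(self.frame_index, dtype=int)
        si = np.asarray(self.summed_intensity, dtype=float)
        if len(fi) != len(si):
            raise CurveValidationError("chromatogram arrays length mismatch")
        if not np.all(np.isfinite(si)):
            raise CurveValidationError("summed intensity must be finite")
        object.__setattr__(self, "frame_index", fi)
        object.__setattr__(self, "summed_intensity", si)

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def peak_frame(self) -> int:
        return int(np.argmax(self.summed_intensity))


def chromatogram(
    series: SecSeries, s_window: tuple[float, float] | None = None
) -> Chromatogram:
    """Sum each frame's intensity over ``s_window`` (default: full grid)."""
    s = series.s
    if s_window is None:
        mask = np.ones_like(s, dtype=bool)
    else:
        lo, hi = s_window
        if hi < lo:
            raise CurveValidationError("s_window must be (low, high)")
        if hi < s[0] or lo > s[-1]:
            raise CurveValidationError(
                f"s_window {s_window} lies outside the grid "
                f"[{s[0]:.4g}, {s[-1]:.4g}]"
            )
        mask = (s >= lo) & (s <= hi)
        if not mask.any():
            raise CurveValidationError("s_window contains no grid points")
    sums = series.intensity_matrix()[:, mask].sum(axis=1)
    return Chromatogram(frame_index=series.frame_index, summed_intensity=sums)


def select_peak_frames(chrom: Chromatogram, n: int = 20) -> list[int]:
    """Pick ``n`` contiguous frames centred on the chromatogram maximum.

    Ties in the maximum break toward the lower frame index; the window
    is clipped to the series bounds.  Returned sorted.
    """
    if n < 1:
        raise CurveValidationError("n must be >= 1")
    total = len(chrom)
    if n > total:
        raise CurveValidationError(f"n={n} exceeds frame count {total}")
    peak = chrom.peak_frame  # argmax already breaks ties toward lower index
    start = peak - n // 2
    start = max(0, min(start, total - n))
    return list(range(start, start + n))


def _scale_factor(
    frame: ScatteringCurve,
    reference: ScatteringCurve,
    mask: np.ndarray,
) -> float:
    # ratio of weighted integrated intensities, w = 1/sigma_f^2: the scalar
    # minimizing the weighted squared deviation of the summed intensity from
    # the reference.  Unlike the pointwise LS scalar it is unbiased under
    # noise (E[sum w I] = sum w·signal) and exact for scalar multiples.
    w = 1.0 / frame.sigma[mask] ** 2
    num = float(np.sum(w * reference.intensity[mask]))
    den = float(np.sum(w * frame.intensity[mask]))
    if den <= 0 or not np.isfinite(den) or num == 0.0:
        raise ReductionError("frame has no usable intensity in the scaling range")
    return num / den


def scale_and_average(
    series: SecSeries,
    frames: list[int] | np.ndarray,
    reference: int | None = None,
    scale_range: tuple[float, float] | None = None,
) -> ScatteringCurve:
    """Scale each selected frame onto the reference and average pointwise.

    Each frame is multiplied by the weighted least-squares scalar that
    best matches the reference over ``scale_range`` (default: the upper
    half of the s-grid, where frame-to-frame variation is dominated by
    scale rather than shape).  The σ of the result is the standard
    error of the inverse-variance weighted mean.
    """
    frames = sorted(int(f) for f in frames)
    if not frames:
        raise CurveValidationError("frame selection is empty")
    if reference is None:
        reference = frames[len(frames) // 2]
    if reference not in frames:
        raise CurveValidationError("reference frame must be in the selection")
    s = series.s
    ref = series[reference]
    if scale_range is None:
        # upper half of the grid, restricted to points where the reference
        # has signal well above its uncertainty; scaling on noise-dominated
        # points would be ill-conditioned
        mask = s >= s[len(s) // 2]
        snr_ok = ref.intensity >= 5.0 * ref.sigma
        if (mask & snr_ok).sum() >= 10:
            mask &= snr_ok
        elif snr_ok.sum() >= 10:
            mask = snr_ok
    else:
        mask = (s >= scale_range[0]) & (s <= scale_range[1])
    if not mask.any():
        raise CurveValidationError("scale_range contains no grid points")

    scaled_i = []
    scaled_w = []
    for f in frames:
        fr = series[f]
        a = 1.0 if f == reference else _scale_factor(fr, ref, mask)
        scaled_i.append(a * fr.intensity)
        scaled_w.append(1.0 / (a * fr.sigma) ** 2)
    iw = np.array(scaled_w)
    ii = np.array(scaled_i)
    wsum = iw.sum(axis=0)
    mean = (iw * ii).sum(axis=0) / wsum
    sem = np.sqrt(1.0 / wsum)
    return ScatteringCurve(
        s=s,
        intensity=mean,
        sigma=sem,
        wavelength=ref.wavelength,
        concentration=ref.concentration,
        label=f"avg[{frames[0]}..{frames[-1]}]",
    )


def subtract_buffer(
    sample: ScatteringCurve,
    buffer: ScatteringCurve,
    rescale: bool = False,
) -> ScatteringCurve:
    """Pointwise background subtraction with σ added in quadrature.

    With ``rescale`` the buffer is first scaled onto the sample over
    the top quarter of the s-grid (where solvent scattering dominates);
    this removes the small level mismatch left when sample and buffer
    averages were each pinned to their own reference frame.
    """
    if not sample.same_grid(buffer):
        raise CurveValidationError("sample and buffer are on different s-grids")
    a = 1.0
    if rescale:
        s = sample.s
        mask = s >= s[0] + 0.75 * (s[-1] - s[0])
        w = 1.0 / buffer.sigma[mask] ** 2
        den = float(np.sum(w * buffer.intensity[mask]))
        if den <= 0:
            raise ReductionError("buffer has no usable high-s intensity")
        a = float(np.sum(w * sample.intensity[mask])) / den
    return ScatteringCurve(
        s=sample.s,
        intensity=sample.intensity - a * buffer.intensity,
        sigma=np.sqrt(sample.sigma**2 + (a * buffer.sigma) ** 2),
        wavelength=sample.wavelength,
        concentration=sample.concentration,
        label=f"{sample.label} - {buffer.label}".strip(" -"),
    )


def auto_buffer_frames(
    chrom: Chromatogram,
    margin: int = 5,
    peak_factor: float = 10.0,
    baseline_mads: float = 3.0,
    min_frames: int = 5,
) -> list[int]:
    """Find a contiguous buffer window preceding the elution peak.

    The baseline level is the median of the first decile of frames and
    its scatter the MAD of the same frames.  A peak must exceed the
    baseline by ``peak_factor``·MAD; the buffer window is the longest
    run of frames within ``baseline_mads``·MAD of the baseline that
    ends ``margin`` frames before the first above-baseline frame.
    """
    y = chrom.summed_intensity
    n = len(y)
    n_base = min(max(10, n // 10), n - 1)
    base = y[:n_base]
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    scale = mad if mad > 0 else max(1e-12, 1e-6 * abs(med))
    if y.max() <= med + peak_factor * scale:
        raise ReductionError(
            "no elution peak detected above the baseline; "
            "select buffer frames manually"
        )
    onset_candidates = np.nonzero(y > med + peak_factor * scale)[0]
    onset = int(onset_candidates[0])
    end = onset - margin
    if end <= 0:
        raise ReductionError(
            "no stable baseline region before the peak onset; "
            "select buffer frames manually"
        )
    within = np.abs(y[:end] - med) <= baseline_mads * scale
    # longest contiguous True run ending closest to the peak
    best_start = best_stop = None
    start = None
    for i, ok in enumerate(within):
        if ok and start is None:
            start = i
        if (not ok or i == end - 1) and start is not None:
            stop = i + 1 if ok else i
            if best_start is None or stop - start >= best_stop - best_start:
                best_start, best_stop = start, stop
            start = None
    if best_start is None or best_stop - best_start < min_frames:
        raise ReductionError(
            "no stable baseline region found; select buffer frames manually"
        )
    return list(range(best_start, best_stop))


def reduce_series(
    series: SecSeries,
    n_peak_frames: int = 20,
    buffer_frames: list[int] | None = None,
    buffer_margin: int = 5,
    scale_range: tuple[float, float] | None = None,
) -> tuple[ScatteringCurve, dict]:
    """Full reduction: chromatogram → peak and buffer windows →
    scale/average both → subtract.

    Returns the background-subtracted curve and a provenance record of
    the frame selections.
    """
    chrom = chromatogram(series)
    peak = select_peak_frames(chrom, n=n_peak_frames)
    if buffer_frames is None:
        buffer_frames = auto_buffer_frames(chrom, margin=buffer_margin)
    sample = scale_and_average(series, peak, scale_range=scale_range)
    buffer = scale_and_average(series, buffer_frames, scale_range=scale_range)
    reduced = subtract_buffer(sample, buffer, rescale=True)
    info = {
        "peak_frames": peak,
        "buffer_frames": list(buffer_frames),
        "peak_frame": chrom.peak_frame,
    }
    return reduced, info
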