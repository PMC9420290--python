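"""Adaptive mathematical-morphology (AMM) raw detector.

Activations are extracted with grayscale morphological filtering using a
structuring element (SE) shaped like an atrial activation and continuously
re-fitted to the morphology of each newly detected activation.  The feature
signal is the residue of the average of opening and closing,

    x_MM = x - (opening(x, SE) + closing(x, SE)) / 2,

i.e. the mean of the top-hat (x - opening) and bottom-hat inverted
(x - closing) responses: near zero wherever the signal is locally explained
by the SE shape, and strongly non-zero at activation complexes.

The SE is parameterised by five fiducial points -- onset, the minimum
between onset and peak, the main peak, the minimum between peak and offset,
and offset -- and its sampled profile is the linear interpolation through
them.  After each detected activation the fiducials are blended toward the
extracted activation's fiducials with a learning coefficient alpha
(0.5 by default, damping abrupt morphology or amplitude changes).

Processing is windowed: the record is split into 200 ms non-overlapping
windows; the first window is filtered with a synthesized SE whose amplitude
span equals max - min of the first 500 ms of the signal, later windows with
the SE updated from the last extracted activation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    REFRACTORY_MS,
    ActivationSequence,
    IegmRecord,
    Source,
    ms_to_samples,
)

logger = logging.getLogger(__name__)

_BIG = 1e300  # out-of-bounds surrogate: excluded from every min/max

_FIDUCIAL_NAMES = ("onset", "min1", "peak", "min2", "offset")


@dataclass(frozen=True)
class StructuringElement:
    """Five-fiducial activation template for grayscale morphology.

    ``fiducial_offsets`` are times in ms relative to the SE onset (first
    entry always 0, strictly increasing); ``fiducial_amplitudes`` are the
    corresponding amplitudes in mV.  ``profile`` is the sampled template
    obtained by linear interpolation through the five fiducials.
    """

    fiducial_offsets: np.ndarray
    fiducial_amplitudes: np.ndarray
    fs: float

    def __post_init__(self):
        off = np.asarray(self.fiducial_offsets, dtype=float)
        amp = np.asarray(self.fiducial_amplitudes, dtype=float)
        object.__setattr__(self, "fiducial_offsets", off)
        object.__setattr__(self, "fiducial_amplitudes", amp)
        if off.size != 5 or amp.size != 5:
            raise ValueError("exactly five fiducial points required")
        if off[0] != 0:
            raise ValueError("onset offset must be 0")
        if np.any(np.diff(off) <= 0):
            raise ValueError("fiducial offsets must be strictly increasing")
        if not np.all(np.isfinite(amp)):
            raise ValueError("fiducial amplitudes must be finite")

    @property
    def duration_ms(self) -> float:
        return float(self.fiducial_offsets[-1])

    @property
    def profile(self) -> np.ndarray:
        """Sampled template: linear interpolation through the fiducials."""
        n = ms_to_samples(self.duration_ms, self.fs) + 1
        t = np.arange(n) * (1000.0 / self.fs)
        return np.interp(t, self.fiducial_offsets, self.fiducial_amplitudes)


@dataclass(frozen=True)
class AmmParams:
    """Parameters of the AMM detector.

    ``se_duration`` (ms) is the synthesized-SE length (optimum 20 ms for
    pulmonary-vein electrograms); ``window`` the processing-window length
    (200 ms); ``alpha`` the SE learning coefficient; ``init_span`` the
    leading span whose max-min sets the synthesized SE amplitude (500 ms);
    ``zero_tol`` the relative tolerance below which the feature signal is
    considered zero.
    """

    se_duration: float = 20.0
    window: float = 200.0
    alpha: float = 0.5
    refractory: float = REFRACTORY_MS
    zero_tol: float = 1e-3
    init_span: float = 500.0

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.se_duration < self.window:
            raise ValueError("require 0 < se_duration < window")
        if self.zero_tol <= 0:
            raise ValueError("zero_tol must be positive")


@dataclass
class ExtractedActivation:
    """Fiducials of one activation extracted from the feature signal."""

    lat_ms: float
    offsets_ms: np.ndarray  # relative to the activation onset; onset = 0
    amplitudes: np.ndarray
    peak_mm: float  # |x_MM| at the LAT
    seg_start: int = 0  # segment bounds, indices into the processed array
    seg_end: int = 0


def init_structuring_element(
    rec: IegmRecord, params: AmmParams | None = None
) -> StructuringElement:
    """Synthesize the initial activation-like SE from the record head.

    Amplitude span = max - min of the first 500 ms (``init_span``); the
    template is biphasic: zero at onset/offset, main peak of +span at the
    midpoint, troughs of -0.25*span at the quartile points.
    """
    if params is None:
        params = AmmParams()
    n_init = ms_to_samples(params.init_span, rec.fs) + 1
    if rec.n_samples < n_init:
        raise ValueError(
            f"record shorter than the {params.init_span:g} ms "
            "initialisation span"
        )
    head = rec.samples[:n_init]
    span = float(np.max(head) - np.min(head))
    if span <= 0:
        raise ValueError("flat initialization segment")
    d = params.se_duration
    offsets = np.array([0.0, 0.25 * d, 0.5 * d, 0.75 * d, d])
    amps = np.array([0.0, -0.25 * span, span, -0.25 * span, 0.0])
    return StructuringElement(offsets, amps, fs=rec.fs)


def grey_erode(x: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Grayscale erosion with truncated support at the array edges."""
    return ndimage.grey_erosion(x, structure=profile, mode="constant", cval=_BIG)


def grey_dilate(x: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Grayscale dilation (adjoint of :func:`grey_erode`)."""
    return ndimage.grey_dilation(x, structure=profile, mode="constant", cval=-_BIG)


def mm_filter(x_win: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Feature signal x_MM = x - (opening + closing)/2 on one window.

    Opening and closing use grayscale (non-flat) erosion/dilation with the
    SE profile, origin at the SE centre sample, support truncated at the
    window edges so that opening <= x <= closing holds pointwise.
    """
    x_win = np.asarray(x_win, dtype=float)
    prof = se.profile
    if prof.size > x_win.size:
        raise ValueError("structuring element longer than the window")
    opening = grey_dilate(grey_erode(x_win, prof), prof)
    closing = grey_erode(grey_dilate(x_win, prof), prof)
    return x_win - 0.5 * (opening + closing)


def extract_activations(
    x_mm: np.ndarray,
    x_win: np.ndarray,
    window_t0: float,
    fs: float,
    threshold: float,
    last_lat: float | None = None,
    refractory: float = REFRACTORY_MS,
) -> list[ExtractedActivation]:
    """Extract activations from the feature signal of one window.

    Non-zero segments are maximal runs with |x_MM| > threshold.  Within a
    segment the most significant peak of |x_MM| gives the LAT; segment start
    and end give onset and offset; the raw-signal minima between onset-LAT
    and LAT-offset complete the five fiducials.  A detection closer than the
    refractory period to the previously accepted LAT is suppressed.
    """
    a = np.abs(x_mm)
    above = a > threshold
    if not above.any():
        return []
    # maximal runs of suprathreshold samples
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    out: list[ExtractedActivation] = []
    prev = last_lat
    dt = 1000.0 / fs
    for s0, s1 in zip(starts, ends):
        seg = slice(s0, s1)
        peak_rel = s0 + int(np.argmax(a[seg]))
        lat = window_t0 + peak_rel * dt
        if prev is not None and lat - prev < refractory:
            continue
        onset_i, offset_i = s0, s1 - 1
        # raw-signal minima flanking the peak (degenerate spans collapse
        # onto the single available sample)
        m1 = onset_i + int(np.argmin(x_win[onset_i : peak_rel + 1]))
        m2 = peak_rel + int(np.argmin(x_win[peak_rel : offset_i + 1]))
        idx = np.array([onset_i, m1, peak_rel, m2, offset_i])
        offsets = (idx - onset_i) * dt
        amps = x_win[idx]
        out.append(
            ExtractedActivation(
                lat_ms=lat,
                offsets_ms=offsets,
                amplitudes=np.asarray(amps, dtype=float),
                peak_mm=float(a[peak_rel]),
                seg_start=onset_i,
                seg_end=offset_i,
            )
        )
        prev = lat
    return out


def update_se(
    se: StructuringElement, extracted: ExtractedActivation, alpha: float
) -> StructuringElement:
    """Blend the SE fiducials toward an extracted activation's fiducials.

    new = (1 - alpha) * current + alpha * extracted, applied to both the
    fiducial locations (distances from onset) and amplitudes; the profile is
    re-interpolated afterwards.  If the blended locations are no longer
    strictly increasing (degenerate extraction), the current SE is kept.
    """
    new_off = (1 - alpha) * se.fiducial_offsets + alpha * extracted.offsets_ms
    new_amp = (1 - alpha) * se.fiducial_amplitudes + alpha * extracted.amplitudes
    new_off[0] = 0.0
    # fiducials must stay resolvable on the sampling grid, or the profile
    # degenerates to a near-impulse and the filter response vanishes
    if np.any(np.diff(new_off) < 1000.0 / se.fs - 1e-9):
        logger.debug("degenerate SE update skipped (non-monotone fiducials)")
        return se
    return StructuringElement(new_off, new_amp, fs=se.fs)


def amm_detect(
    rec: IegmRecord, params: AmmParams | None = None
) -> tuple[ActivationSequence, StructuringElement]:
    """Run the full AMM detector over a record.

    The record is processed in 200 ms non-overlapping windows with a
    look-back margin of one SE length (so activations straddling a window
    boundary are not split); detections inside the margin are deduplicated
    against the previous window through the refractory rule.  Returns the
    activation sequence and the final (adapted) SE.
    """
    if params is None:
        params = AmmParams()
    se = init_structuring_element(rec, params)
    win_n = ms_to_samples(params.window, rec.fs)
    margin_n = ms_to_samples(params.refractory, rec.fs)
    dt = 1000.0 / rec.fs
    abs_floor = 1e-12 * float(np.max(np.abs(rec.samples)))
    lats: list[float] = []
    running_max = 0.0
    for w0 in range(0, rec.n_samples, win_n):
        w1 = min(w0 + win_n, rec.n_samples)
        if w1 - w0 < 2:
            break
        # process an extended span so activations straddling a window
        # boundary are seen whole; only core-window LATs are kept
        a0 = max(w0 - margin_n, 0)
        a1 = min(w1 + margin_n, rec.n_samples)
        x_ext = rec.samples[a0:a1]
        if x_ext.size < se.profile.size:
            continue
        x_mm = mm_filter(x_ext, se)
        running_max = max(running_max, float(np.max(np.abs(x_mm))))
        if running_max <= abs_floor:
            continue
        threshold = params.zero_tol * running_max
        t0 = rec.t0 + a0 * dt
        w_start = rec.t0 + w0 * dt
        w_end = rec.t0 + w1 * dt
        acts = extract_activations(
            x_mm,
            x_ext,
            t0,
            rec.fs,
            threshold,
            last_lat=lats[-1] if lats else None,
            refractory=params.refractory,
        )
        core = [a for a in acts if w_start <= a.lat_ms < w_end]
        if core:
            for a in core:
                lats.append(a.lat_ms)
            # update the SE from the last activation whose segment is fully
            # contained in the processed span (edge-clipped segments carry
            # distorted fiducials)
            for a in reversed(core):
                if a.seg_start > 0 and a.seg_end < x_ext.size - 1:
                    se = update_se(se, a, params.alpha)
                    break
    lats_arr = np.asarray(lats)
    # global refractory safety net (windowing should already guarantee it)
    if lats_arr.size > 1:
        keep = [0]
        for i in range(1, lats_arr.size):
            if lats_arr[i] - lats_arr[keep[-1]] >= params.refractory:
                keep.append(i)
        lats_arr = lats_arr[keep]
    seq = ActivationSequence(
        record_id=rec.record_id, lats=lats_arr, source=Source.RAW_AMM
    )
    return seq, se
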