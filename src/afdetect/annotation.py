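"""Barycenter-based correction of local activation times.

Fractionated or multi-peak activation complexes make single-timestamp
annotation unstable: peak picking hops between sub-peaks from beat to beat,
injecting artificial variability into the cycle-length sequence (a
"long-short-long" pattern where the true sequence is "short-long-short").
The correction re-annotates each activation independently:

1. extract a signal portion around the detected LAT;
2. compute the envelope of the absolute value of the signal;
3. reject low-amplitude tails with a cutoff on the envelope;
4. place the corrected LAT at the barycenter of the power of the remaining
   signal, LAT* = sum(t * x(t)^2) / sum(x(t)^2) -- squaring emphasises the
   high-amplitude core of the complex over its tails.

Because the true activation times are unknown on clinical data, the result
is evaluated through the variance of the interval sequence: writing
LAT = LAT0 + e_t + e (true time + annotation imprecision + other errors)
with independent terms, var(LAT) = var(LAT0) + var(e_t) + var(e), so a drop
in the observable interval variance after a correction that acts on each
beat independently indicates a drop in the annotation-imprecision term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.ndimage import maximum_filter1d

from .core import ActivationSequence, IegmRecord, Source, ms_to_samples

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BarycenterParams:
    """Parameters of the annotation correction.

    ``half_window`` (ms) is the half-length of the segment extracted around
    each LAT (default 70 ms, one refractory period, clipped at gap
    midpoints so neighbouring activations never bleed in);
    ``cutoff_frac`` the envelope fraction below which tails are rejected;
    ``envelope_method`` 'analytic_magnitude' (default) or 'sliding_max'
    (5 ms window).
    """

    half_window: float = 70.0
    cutoff_frac: float = 0.2
    envelope_method: str = "analytic_magnitude"

    def __post_init__(self):
        if self.half_window < 10:
            raise ValueError("half_window must be >= 10 ms")
        if not 0 < self.cutoff_frac < 1:
            raise ValueError("cutoff_frac must be in (0, 1)")
        if self.envelope_method not in ("analytic_magnitude", "sliding_max"):
            raise ValueError("unknown envelope method")


@dataclass(frozen=True)
class VarianceReport:
    """Observable interval-variance change due to annotation correction."""

    var_original: float
    var_corrected: float

    @property
    def relative_change(self) -> float:
        if self.var_original == 0:
            return 0.0 if self.var_corrected == 0 else np.inf
        return (self.var_corrected - self.var_original) / self.var_original


def envelope(
    seg: np.ndarray, method: str = "analytic_magnitude", fs: float = 1000.0
) -> np.ndarray:
    """Smooth nonnegative curve tracking the magnitude of ``seg``.

    'analytic_magnitude' returns |hilbert(seg)|; 'sliding_max' a running
    maximum of |seg| over 5 ms.
    """
    seg = np.asarray(seg, dtype=float)
    if seg.size == 0:
        raise ValueError("empty segment")
    if method == "analytic_magnitude":
        return np.abs(hilbert(seg))
    size = max(ms_to_samples(5.0, fs), 1)
    return maximum_filter1d(np.abs(seg), size=size, mode="nearest")


def trim_tails(env: np.ndarray, cutoff_frac: float) -> tuple[int, int]:
    """Indices [start, end] of the retained activation core.

    The retained range is the maximal contiguous run containing the
    envelope maximum on which env >= cutoff_frac * max(env).
    """
    env = np.asarray(env, dtype=float)
    peak = int(np.argmax(env))
    thr = cutoff_frac * env[peak]
    start = peak
    while start > 0 and env[start - 1] >= thr:
        start -= 1
    end = peak
    while end < env.size - 1 and env[end + 1] >= thr:
        end += 1
    return start, end


def barycenter_lat(
    seg: np.ndarray, start: int, end: int, t_axis: np.ndarray
) -> float:
    """Energy barycenter of the retained range: sum(t*x^2)/sum(x^2)."""
    x = np.asarray(seg, dtype=float)[start : end + 1]
    t = np.asarray(t_axis, dtype=float)[start : end + 1]
    e = x**2
    total = e.sum()
    if total <= 0:
        raise ValueError("zero energy in the retained range")
    return float((t * e).sum() / total)


def correct_annotations(
    rec: IegmRecord,
    seq: ActivationSequence,
    bp: BarycenterParams | None = None,
) -> tuple[ActivationSequence, VarianceReport]:
    """Re-annotate every activation at its energy barycenter.

    Each LAT is corrected independently of the others.  Segments are
    clipped at the midpoints toward neighbouring activations (and at the
    record limits).  Zero-energy segments keep their original LAT.  If two
    corrected LATs cross or violate the refractory spacing, the offending
    corrections are reverted to the original values.
    """
    if bp is None:
        bp = BarycenterParams()
    lats = seq.lats
    corrected = np.array(lats, dtype=float)
    for i, lat in enumerate(lats):
        lo = lat - bp.half_window
        hi = lat + bp.half_window
        if i > 0:
            lo = max(lo, (lats[i - 1] + lat) / 2.0)
        if i < len(lats) - 1:
            hi = min(hi, (lat + lats[i + 1]) / 2.0)
        i0 = max(rec.index_at(lo), 0)
        i1 = min(rec.index_at(hi), rec.n_samples - 1)
        if i1 <= i0:
            continue
        seg = rec.samples[i0 : i1 + 1]
        t_axis = rec.t0 + np.arange(i0, i1 + 1) * (1000.0 / rec.fs)
        env = envelope(seg, bp.envelope_method, rec.fs)
        if not np.any(env > 0):
            logger.debug("zero-energy segment at %.1f ms; LAT kept", lat)
            continue
        s, e = trim_tails(env, bp.cutoff_frac)
        try:
            corrected[i] = barycenter_lat(seg, s, e, t_axis)
        except ValueError:
            logger.debug("zero-energy core at %.1f ms; LAT kept", lat)
    # beat-by-beat independence can in principle swap very close
    # annotations; revert any correction that breaks the ordering contract
    if corrected.size > 1:
        for _ in range(corrected.size):
            viol = np.where(np.diff(corrected) < 70.0 - 1e-9)[0]
            if viol.size == 0:
                break
            for idx in viol:
                corrected[idx] = lats[idx]
                corrected[idx + 1] = lats[idx + 1]
    out = ActivationSequence(
        record_id=seq.record_id, lats=corrected, source=Source.BARYCENTER
    )
    report = variance_report(seq, out)
    return out, report


def peak_annotations(
    rec: IegmRecord,
    reference: ActivationSequence,
    search_half: float = 30.0,
) -> ActivationSequence:
    """Conventional peak annotation: largest |x| near each reference LAT.

    The classical baseline the barycenter correction improves on: each
    activation is annotated at the absolute-amplitude peak within
    ``search_half`` ms of its reference time.  On multi-peak or
    fractionated complexes this annotation hops between sub-peaks from
    beat to beat.
    """
    lats = []
    for t in reference.lats:
        j = rec.index_at(t)
        lo = max(j - ms_to_samples(search_half, rec.fs), 0)
        hi = min(j + ms_to_samples(search_half, rec.fs) + 1, rec.n_samples)
        lats.append(rec.time_at(lo + int(np.argmax(np.abs(rec.samples[lo:hi])))))
    return ActivationSequence(
        record_id=rec.record_id,
        lats=np.asarray(lats),
        source=Source.ANNOTATED_TRUTH,
    )


def variance_report(
    original: ActivationSequence, corrected: ActivationSequence
) -> VarianceReport:
    """Population variances of the two interval sequences."""
    if len(original) != len(corrected):
        raise ValueError("correction must not add or remove activations")
    if len(original) < 2:
        return VarianceReport(0.0, 0.0)
    return VarianceReport(
        var_original=float(np.var(original.intervals())),
        var_corrected=float(np.var(corrected.intervals())),
    )
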