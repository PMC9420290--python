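"""Statistics-weighted correction of false and missed detections.

Raw detectors over- and undersense: noise, artifacts and far-field
components are picked up as activations, while low-amplitude or unusually
shaped activations are missed.  This stage exploits the interval statistics
of the raw detection sequence -- meanAA and sigma_AA, the mean and
(population) standard deviation of the activation intervals -- to weight
the signal amplitude around each detection according to how plausible an
activation is at that interval position.

Two weight shapes are available (k is the interval position in ms):

* linear: zero for k < 70 ms (refractory), then a ramp from P_70 at
  k = 70 ms through P_meanAA at k = meanAA, continuing with the same slope;
* nonlinear: zero for k < 70 ms, a truncated Gaussian rising limb centred
  at meanAA with standard deviation enlarged by a factor E, reaching
  P_meanAA at k = meanAA, then flat at P_meanAA.

A weight above 1 amplifies the signal, below 1 dampens it.  Correction runs
in two passes over each sequence: false detections are removed first
(neighbour amplitudes dampened by short intervals fall below the detection
threshold), then gaps are screened for missed activations (the product
W(k) = w(k) * w(K - k) amplifies the centre of long gaps, unmasking
suprathreshold deflections).

Published per-detector optima: Rel-En linear (P_70 = 0, P_meanAA = 2.1),
Rel-En nonlinear (E = 1.25, P_meanAA = 3); AMM linear (P_70 = 0.4,
P_meanAA = 2.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    REFRACTORY_MS,
    ActivationSequence,
    IegmRecord,
    IntervalStats,
    Source,
    interval_stats,
)
from .morphology import AmmParams, StructuringElement, extract_activations, mm_filter
from .relen import EnhancedSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightParams:
    """Parameters of one weight function.

    ``gaussian_mode`` selects between the continuous reading of the
    nonlinear weight (``widened_std``: std = enlarge * sigma_AA, peak
    P_meanAA, continuous at k = meanAA; the default) and the literal
    printed form (amplitude E * P_meanAA / sigma_AA, discontinuous at
    k = meanAA unless E = sigma_AA; retained for audit).
    """

    shape: str = "nonlinear"  # 'linear' | 'nonlinear'
    p70: float = 0.0
    p_mean: float = 3.0
    enlarge: float = 1.25
    gaussian_mode: str = "widened_std"  # 'widened_std' | 'literal'

    def __post_init__(self):
        if self.shape not in ("linear", "nonlinear"):
            raise ValueError("shape must be 'linear' or 'nonlinear'")
        if self.p70 < 0 or self.p_mean <= 0:
            raise ValueError("require p70 >= 0 and p_mean > 0")
        if self.enlarge < 1:
            raise ValueError("enlarge must be >= 1")
        if self.gaussian_mode not in ("widened_std", "literal"):
            raise ValueError("gaussian_mode must be 'widened_std' or 'literal'")


#: Published optima per detector and shape.
RELEN_LINEAR = WeightParams(shape="linear", p70=0.0, p_mean=2.1)
RELEN_NONLINEAR = WeightParams(shape="nonlinear", p_mean=3.0, enlarge=1.25)
AMM_LINEAR = WeightParams(shape="linear", p70=0.4, p_mean=2.2)


def weight_at(k, wp: WeightParams, stats: IntervalStats):
    """Evaluate the weight function at interval position(s) ``k`` (ms).

    Vectorised: ``k`` may be a scalar or array.  Always zero below the
    70 ms refractory limit, for either shape.
    """
    k = np.asarray(k, dtype=float)
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    w = np.zeros_like(k)
    mean, sigma = stats.mean_aa, stats.sigma_aa
    if wp.shape == "linear":
        denom = mean - REFRACTORY_MS
        slope = (wp.p_mean - wp.p70) / denom if denom > 0 else 0.0
        m = k >= REFRACTORY_MS
        w[m] = slope * (k[m] - REFRACTORY_MS) + wp.p70
        w[m] = np.maximum(w[m], 0.0)
    else:
        sig_eff = wp.enlarge * sigma if wp.gaussian_mode == "widened_std" else sigma
        if wp.gaussian_mode == "widened_std":
            amp = wp.p_mean
        else:
            amp = wp.enlarge * wp.p_mean / max(sigma, 1e-12)
        rising = (k >= REFRACTORY_MS) & (k <= mean)
        flat = k > mean
        if sig_eff > 0:
            w[rising] = amp * np.exp(
                -((k[rising] - mean) ** 2) / (2.0 * sig_eff**2)
            )
        else:
            # degenerate perfectly regular rhythm: step at meanAA
            w[rising] = np.where(k[rising] == mean, amp, 0.0)
        w[flat] = wp.p_mean
    return float(w[0]) if scalar else w


@dataclass
class AmmRedetector:
    """Re-runs morphological detection on weighted signal segments.

    Used by the AMM branch of the correction stage: a detection is
    considered false if it disappears when the (dampened) segment is
    reprocessed, and a missed activation is recovered if the (amplified)
    gap produces a new suprathreshold feature lobe.
    """

    rec: IegmRecord
    se: StructuringElement
    params: AmmParams
    threshold: float = 0.0

    def __post_init__(self):
        if self.threshold <= 0:
            x_mm = mm_filter(self.rec.samples, self.se)
            self.threshold = self.params.zero_tol * float(np.max(np.abs(x_mm)))

    def detect_segment(self, x_seg: np.ndarray, t0_ms: float) -> list[float]:
        if x_seg.size < self.se.profile.size:
            return []
        x_mm = mm_filter(x_seg, self.se)
        acts = extract_activations(
            x_mm,
            x_seg,
            t0_ms,
            self.rec.fs,
            self.threshold,
            last_lat=None,
            refractory=self.params.refractory,
        )
        return [a.lat_ms for a in acts]


def _neighbor_weighted_amp(
    es: EnhancedSignal | None,
    redet: AmmRedetector | None,
    lat_neighbor: float,
    interval: float,
    wp: WeightParams,
    stats: IntervalStats,
    detector: str,
    rec: IegmRecord | None,
):
    """True if the neighbour survives weighting; False if it is false."""
    w = weight_at(interval, wp, stats)
    if detector == "relen":
        return es.value_at(lat_neighbor) * w > es.th_p
    # amm: dampen the signal around the neighbour and reprocess
    fs = rec.fs
    half = REFRACTORY_MS  # segment of +/- one refractory around the neighbour
    i0 = max(rec.index_at(lat_neighbor - half), 0)
    i1 = min(rec.index_at(lat_neighbor + half) + 1, rec.n_samples)
    x_seg = rec.samples[i0:i1] * w
    lats = redet.detect_segment(x_seg, rec.time_at(i0))
    return any(abs(l - lat_neighbor) <= 0.5 * REFRACTORY_MS for l in lats)


def remove_false(
    rec: IegmRecord,
    seq: ActivationSequence,
    wp: WeightParams,
    detector: str = "relen",
    es: EnhancedSignal | None = None,
    redetector: AmmRedetector | None = None,
    stats: IntervalStats | None = None,
) -> ActivationSequence:
    """Remove detections whose weighted amplitude falls below threshold.

    For each activation LAT_0 (processed left to right) the weight function
    is evaluated on the preceding [LAT_-1, LAT_0] and succeeding
    [LAT_0, LAT_1] intervals; each neighbour's amplitude is multiplied by
    the weight at its interval length and the neighbour is removed if the
    weighted amplitude no longer qualifies as a detection (flagged from
    either side).
    """
    if detector == "relen" and es is None:
        raise ValueError("relen correction requires the enhanced signal")
    if detector == "amm" and redetector is None:
        raise ValueError("amm correction requires a redetector")
    if stats is None:
        stats = interval_stats(seq)
    lats = list(seq.lats)
    i = 0
    while i < len(lats):
        # succeeding interval [LAT_0, LAT_1]: checked first, so a spurious
        # detection is pruned before it becomes the current activation and
        # can flag its (true) predecessor
        if i + 1 < len(lats) and not _neighbor_weighted_amp(
            es, redetector, lats[i + 1], lats[i + 1] - lats[i], wp, stats,
            detector, rec,
        ):
            del lats[i + 1]
            continue  # re-evaluate with the new right neighbour
        # preceding interval [LAT_-1, LAT_0]
        if i > 0 and not _neighbor_weighted_amp(
            es, redetector, lats[i - 1], lats[i] - lats[i - 1], wp, stats,
            detector, rec,
        ):
            del lats[i - 1]
            i -= 1
            continue
        i += 1
    return seq.replace(lats=np.asarray(lats), source=Source.CORRECTED)


def recover_missed(
    rec: IegmRecord,
    seq: ActivationSequence,
    wp: WeightParams,
    detector: str = "relen",
    es: EnhancedSignal | None = None,
    redetector: AmmRedetector | None = None,
    stats: IntervalStats | None = None,
    excluded: Sequence[float] = (),
) -> ActivationSequence:
    """Screen every gap for a missed activation.

    On a gap of length K the signal is multiplied by the symmetric product
    W(k) = w(k) * w(K - k) (the second factor is the time-reversed weight),
    which is zero within 70 ms of both endpoints and amplifies the centre
    of gaps long relative to meanAA.  Rel-En: a new activation is inserted
    at the argmax of the weighted enhanced amplitude if it exceeds TH_P.
    AMM: the weighted raw segment is reprocessed by the morphological
    detector.  At most one insertion per gap per pass, and an activation
    removed earlier in the same pass (``excluded``) is never re-inserted.
    """
    if detector == "relen" and es is None:
        raise ValueError("relen correction requires the enhanced signal")
    if detector == "amm" and redetector is None:
        raise ValueError("amm correction requires a redetector")
    if stats is None:
        stats = interval_stats(seq)
    lats = list(seq.lats)
    excluded = np.asarray(excluded, dtype=float)

    def _near_excluded(t: float) -> bool:
        return excluded.size > 0 and np.min(np.abs(excluded - t)) < 0.5 * REFRACTORY_MS

    out: list[float] = []
    fs = rec.fs
    for a, b in zip(lats[:-1], lats[1:]):
        out.append(a)
        K = b - a
        if K < 2 * REFRACTORY_MS:
            continue
        i0, i1 = rec.index_at(a), rec.index_at(b)
        k_ms = (np.arange(i0, i1 + 1) - i0) * (1000.0 / fs)
        W = weight_at(k_ms, wp, stats) * weight_at(K - k_ms, wp, stats)
        if detector == "relen":
            y = es.rectified()[i0 : i1 + 1] * W
            j = int(np.argmax(y))
            if y[j] > es.th_p:
                t_new = a + k_ms[j]
                if (
                    t_new - a >= REFRACTORY_MS
                    and b - t_new >= REFRACTORY_MS
                    and not _near_excluded(t_new)
                ):
                    out.append(t_new)
        else:
            x_seg = rec.samples[i0 : i1 + 1] * W
            cands = [
                t
                for t in redetector.detect_segment(x_seg, rec.time_at(i0))
                if t - a >= REFRACTORY_MS
                and b - t >= REFRACTORY_MS
                and not _near_excluded(t)
            ]
            if cands:
                # keep the single candidate nearest the gap centre
                out.append(min(cands, key=lambda t: abs(t - (a + K / 2))))
    if lats:
        out.append(lats[-1])
    return seq.replace(lats=np.asarray(out), source=Source.CORRECTED)


def correct_sequence(
    rec: IegmRecord,
    seq: ActivationSequence,
    wp: WeightParams | None = None,
    detector: str = "relen",
    es: EnhancedSignal | None = None,
    redetector: AmmRedetector | None = None,
) -> ActivationSequence:
    """One two-step correction pass: remove false, then recover missed.

    Interval statistics are computed once from the raw sequence and frozen
    for the whole pass.  Sequences with fewer than three detections are
    returned unchanged (statistics would be meaningless).
    """
    if wp is None:
        wp = RELEN_NONLINEAR if detector == "relen" else AMM_LINEAR
    if len(seq) < 3:
        logger.warning(
            "sequence %s has %d detections; correction skipped",
            seq.record_id,
            len(seq),
        )
        return seq.replace(source=Source.CORRECTED)
    stats = interval_stats(seq)
    if stats.mean_aa < REFRACTORY_MS:  # cannot happen for valid sequences
        return seq.replace(source=Source.CORRECTED)
    pruned = remove_false(
        rec, seq, wp, detector=detector, es=es, redetector=redetector, stats=stats
    )
    if len(pruned) < 2:
        return pruned
    removed = np.setdiff1d(seq.lats, pruned.lats)
    return recover_missed(
        rec,
        pruned,
        wp,
        detector=detector,
        es=es,
        redetector=redetector,
        stats=stats,
        excluded=removed,
    )
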