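"""Core domain types and unit conventions.

All public APIs exchange times in milliseconds; sample indices appear only
inside inner loops.  The single ms->sample conversion rule lives here:
``n = round(t_ms * fs / 1000)``, rounding half away from zero, so that the
same millisecond constraints (70 ms refractory, 200 ms windows, 500 ms
initialisation span) map consistently at 1 kHz and 2 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

#: Shortest physiologically possible interval (ms) between two atrial
#: activations recorded in the pulmonary veins; used as a hard constraint
#: throughout the pipeline.
REFRACTORY_MS = 70.0


def ms_to_samples(t_ms: float, fs: float) -> int:
    """Convert a time offset in ms to a sample count.

    Rounds half away from zero (``round-half-away``), the package-wide
    convention, so 0.5 ms at 1 kHz maps to 1 sample and -0.5 ms to -1.
    """
    x = t_ms * fs / 1000.0
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def samples_to_ms(n: int, fs: float) -> float:
    """Convert a sample count to milliseconds."""
    return n * 1000.0 / fs


class Source(str, Enum):
    """Provenance of an activation sequence."""

    RAW_RELEN = "raw_relen"
    RAW_AMM = "raw_amm"
    CORRECTED = "corrected"
    ANNOTATED_TRUTH = "annotated_truth"
    BARYCENTER = "barycenter"


@dataclass(frozen=True)
class IegmRecord:
    """A single-channel bipolar intracardiac electrogram.

    Parameters
    ----------
    record_id : str
        Identifier used to pair records with annotation files.
    samples : ndarray
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz (clinical systems record at 1 or 2 kHz).
    t0 : float
        Time of the first sample in ms (default 0).
    """

    record_id: str
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) / self.fs * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms, aligned 1:1 with ``samples``."""
        return self.t0 + np.arange(self.n_samples) * (1000.0 / self.fs)

    def index_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` (round half away from zero)."""
        return ms_to_samples(t_ms - self.t0, self.fs)

    def time_at(self, index: int) -> float:
        return self.t0 + samples_to_ms(index, self.fs)


@dataclass(frozen=True)
class ActivationSequence:
    """Ordered local activation times (LATs, ms) on one record.

    For every source other than expert/simulator truth the sequence must
    honour the 70 ms refractory contract: no two detections closer than
    physiologically possible.
    """

    record_id: str
    lats: np.ndarray
    source: Source

    def __post_init__(self):
        lats = np.asarray(self.lats, dtype=float)
        object.__setattr__(self, "lats", lats)
        if lats.ndim != 1:
            raise ValueError("lats must be 1-D")
        if lats.size > 1:
            d = np.diff(lats)
            if np.any(d <= 0):
                raise ValueError("lats must be strictly increasing")
            if self.source != Source.ANNOTATED_TRUTH and np.any(
                d < REFRACTORY_MS - 1e-9
            ):
                raise ValueError(
                    f"intervals below the {REFRACTORY_MS:g} ms refractory "
                    f"limit in a {self.source.value} sequence"
                )

    def __len__(self) -> int:
        return self.lats.size

    def intervals(self) -> np.ndarray:
        """Successive activation intervals (cycle lengths), ms."""
        return np.diff(self.lats)

    def replace(self, lats=None, source=None) -> "ActivationSequence":
        return ActivationSequence(
            record_id=self.record_id,
            lats=self.lats if lats is None else lats,
            source=self.source if source is None else source,
        )


@dataclass(frozen=True)
class IntervalStats:
    """Mean and population standard deviation of activation intervals."""

    mean_aa: float
    sigma_aa: float
    n_intervals: int

    def __post_init__(self):
        if self.n_intervals < 1:
            raise ValueError("need at least one interval")
        if self.mean_aa < REFRACTORY_MS:
            raise ValueError("mean interval below the refractory limit")
        if self.sigma_aa < 0:
            raise ValueError("sigma must be non-negative")


def interval_stats(seq: ActivationSequence) -> IntervalStats:
    """Interval statistics of a sequence (population standard deviation)."""
    if len(seq) < 2:
        raise ValueError("insufficient activations for statistics")
    ivals = seq.intervals()
    return IntervalStats(
        mean_aa=float(np.mean(ivals)),
        sigma_aa=float(np.std(ivals)),
        n_intervals=ivals.size,
    )


@dataclass
class MatchResult:
    """TP/FP/FN bookkeeping from matching detections against a reference."""

    n_truth: int
    n_detected: int
    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)

    def __post_init__(self):
        if self.tp + self.fn != self.n_truth:
            raise ValueError("tp + fn must equal n_truth")
        if self.tp + self.fp != self.n_detected:
            raise ValueError("tp + fp must equal n_detected")


def enforce_refractory(
    times_ms: Sequence[float],
    amplitudes: Sequence[float],
    refractory_ms: float = REFRACTORY_MS,
) -> np.ndarray:
    """Resolve candidate detections closer than the refractory period.

    Among candidates within ``refractory_ms`` of each other the one with the
    larger amplitude is kept; ties are broken in favour of the earlier
    candidate.  Returns the retained times, sorted ascending.
    """
    times = np.asarray(times_ms, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if times.size == 0:
        return times
    # greedy by (descending amplitude, ascending time)
    order = np.lexsort((times, -amps))
    kept: list[float] = []
    for idx in order:
        t = times[idx]
        if all(abs(t - k) >= refractory_ms for k in kept):
            kept.append(t)
    return np.sort(np.asarray(kept))
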