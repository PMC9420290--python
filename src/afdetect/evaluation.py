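"""Detection matching, error-rate metrics, and parameter tuning.

Performance follows the convention used for activation-detection studies:
false negative rate = missed detections / number of reference activations,
false positive rate = false detections / number of reference activations,
total error rate = their sum.  Note both rates share the reference-count
denominator, so the FP rate is *per 100 true activations*, not per 100
detections.

Matching between a detected and a reference sequence is one-to-one,
greedy by increasing |dt| with a configurable tolerance (default 35 ms,
half the physiological refractory period, which guarantees unambiguous
pairing when both sequences honour 70 ms spacing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .annotation import variance_report as variance_change  # noqa: F401
from .core import ActivationSequence, MatchResult

#: default pairing tolerance, ms (half the refractory period)
DEFAULT_TOL_MS = 35.0


@dataclass(frozen=True)
class ErrorRates:
    """Detection error rates, in % of the reference activation count."""

    fn_rate: float
    fp_rate: float

    @property
    def total(self) -> float:
        return self.fn_rate + self.fp_rate


@dataclass(frozen=True)
class GridSpec:
    """Cartesian parameter grid: name -> list of candidate values."""

    axes: Mapping[str, Sequence]

    def __post_init__(self):
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("grid must be non-empty on every axis")

    def points(self):
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, combo))


def match_detections(
    detected: ActivationSequence,
    truth: ActivationSequence,
    tol: float = DEFAULT_TOL_MS,
) -> MatchResult:
    """One-to-one matching of detections against reference annotations.

    Candidate pairs within ``tol`` ms are accepted greedily by increasing
    |dt| (ties: earlier reference, then earlier detection); every truth and
    every detection appears in at most one pair.
    """
    if detected.record_id and truth.record_id and detected.record_id != truth.record_id:
        raise ValueError(
            f"sequences from different records: "
            f"{detected.record_id!r} vs {truth.record_id!r}"
        )
    t = truth.lats
    d = detected.lats
    cands = [
        (abs(t[i] - d[j]), i, j)
        for i in range(t.size)
        for j in range(d.size)
        if abs(t[i] - d[j]) <= tol
    ]
    cands.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for _, i, j in cands:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        pairs.append((float(t[i]), float(d[j])))
    tp = len(pairs)
    return MatchResult(
        n_truth=t.size,
        n_detected=d.size,
        tp=tp,
        fp=d.size - tp,
        fn=t.size - tp,
        pairs=sorted(pairs),
    )


def error_rates(m: MatchResult) -> ErrorRates:
    """FN/FP rates in % of the reference activation count."""
    if m.n_truth == 0:
        raise ValueError("no reference activations")
    return ErrorRates(
        fn_rate=100.0 * m.fn / m.n_truth,
        fp_rate=100.0 * m.fp / m.n_truth,
    )


def pooled_error_rates(matches: Sequence[MatchResult]) -> ErrorRates:
    """Rates pooled over a corpus (sums before division)."""
    n = sum(m.n_truth for m in matches)
    if n == 0:
        raise ValueError("no reference activations in the corpus")
    return ErrorRates(
        fn_rate=100.0 * sum(m.fn for m in matches) / n,
        fp_rate=100.0 * sum(m.fp for m in matches) / n,
    )


def grid_search(
    corpus: Sequence[tuple],
    grid: GridSpec,
    detect_fn: Callable[..., ActivationSequence],
    tol: float = DEFAULT_TOL_MS,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive tuning of detector parameters on a labelled corpus.

    ``corpus`` is a sequence of ``(record, truth)`` pairs; ``detect_fn``
    maps ``(record, **params)`` to an ActivationSequence.  The objective is
    the total error rate pooled over the corpus; ties are broken by lower
    pooled FP rate, then by grid order.  Returns the best parameter dict
    and the full error-vs-parameter table.
    """
    rows = []
    best = None
    for k, params in enumerate(grid.points()):
        matches = []
        for rec, truth in corpus:
            seq = detect_fn(rec, **params)
            matches.append(match_detections(seq, truth, tol))
        rates = pooled_error_rates(matches)
        rows.append({**params, "fn_rate": rates.fn_rate,
                     "fp_rate": rates.fp_rate, "total": rates.total})
        key = (rates.total, rates.fp_rate, k)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1], pd.DataFrame(rows)
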