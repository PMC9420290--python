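"""Seeded generator of AF-like pulmonary-vein electrograms.

The generator is the test substrate for every other module: it produces
single-channel bipolar-like records with exact ground-truth activation
times and per-activation metadata.  It emulates the salient features of
pulmonary-vein recordings during persistent AF:

* irregular activation trains -- renewal process with truncated-normal
  intervals (mean cycle length 150-300 ms typical, hard floor at the 70 ms
  refractory limit);
* heterogeneous activation morphologies -- biphasic (Mexican-hat-like)
  spikes, fractionated complexes of 3-6 jittered sub-deflections spread
  over 30-60 ms, and double-peak complexes with two lobes 10-25 ms apart;
* beat-to-beat amplitude variability (lognormal), optional dropout of
  single activations to near-zero amplitude;
* additive band-limited Gaussian noise shaped to the 30-300 Hz acquisition
  band, Poisson impulsive artifacts, and low-amplitude far-field bumps.

The ground-truth LAT of each activation is defined as the energy
barycenter of its clean (noise-free) template as placed, so the barycenter
annotation stage has a well-defined target and timing errors decompose
cleanly in tests.

It is a renewal-statistics emulator, not a physiological AF propagation
model: it reproduces interval statistics, morphology classes and noise
floors, not wavefront dynamics or catheter-contact effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import ActivationSequence, IegmRecord, Source
from . import io as afio

#: safety margin (ms) added to the interval floor so that barycenter truth
#: LATs of wide fractionated complexes cannot violate the refractory limit
_BARY_MARGIN_MS = 40.0

#: fixed rate of far-field bumps, per second
_FARFIELD_RATE = 0.5

MORPHOLOGIES = ("biphasic", "fractionated", "double_peak")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults emulate a typical PV recording."""

    duration_s: float = 10.0
    fs: float = 1000.0
    mean_cl: float = 170.0  # ms; typical PV cycle length in persistent AF
    cl_sd: float = 30.0  # ms
    min_cl: float = 70.0  # ms, physiological floor
    morphology_mix: dict = field(
        default_factory=lambda: {
            "biphasic": 0.4,
            "fractionated": 0.4,
            "double_peak": 0.2,
        }
    )
    amp_mean: float = 1.0  # mV
    amp_cv: float = 0.2  # lognormal coefficient of variation
    amp_drift: float = 0.0  # slow sinusoidal amplitude modulation depth
    noise_sd: float = 0.005  # mV; bipolar PV recordings show a clear isoline
    artifact_rate: float = 0.0  # impulsive artifacts per second
    farfield_amp: float = 0.0  # mV; 0 disables far-field bumps
    dropout_prob: float = 0.0  # fraction of near-zero-amplitude activations
    seed: int = 0

    def __post_init__(self):
        if self.min_cl < 70:
            raise ValueError("min_cl must be >= 70 ms")
        if self.mean_cl <= self.min_cl:
            raise ValueError("mean_cl must exceed min_cl")
        mix = dict(self.morphology_mix)
        if set(mix) - set(MORPHOLOGIES):
            raise ValueError(f"unknown morphology in mix: {set(mix) - set(MORPHOLOGIES)}")
        total = sum(mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("morphology fractions must sum to 1")


@dataclass
class SynthRecord:
    """A generated record with its ground truth and per-beat metadata."""

    record: IegmRecord
    truth: ActivationSequence
    meta: list  # per activation: morphology, amplitude, sub-peak times


def _ricker(t_ms: np.ndarray, width_ms: float) -> np.ndarray:
    """Mexican-hat wavelet: dominant positive peak with two side troughs."""
    a = width_ms / 6.0
    u = t_ms / a
    return (1 - u**2) * np.exp(-0.5 * u**2)


def _template(kind: str, fs: float, rng: np.random.Generator):
    """Return (waveform, sub_peak_offsets_ms) for one activation, unit peak."""
    dt = 1000.0 / fs
    if kind == "biphasic":
        width = rng.uniform(14.0, 24.0)
        half = width
        t = np.arange(-half, half + dt / 2, dt)
        w = _ricker(t, width)
        return w, [0.0]
    if kind == "double_peak":
        sep = rng.uniform(10.0, 25.0)
        width = rng.uniform(10.0, 16.0)
        half = width + sep
        t = np.arange(-half, half + dt / 2, dt)
        # second lobe dominates on roughly half the beats, so naive peak
        # annotation hops between the two lobes from beat to beat
        a2 = rng.uniform(0.7, 1.3)
        w = _ricker(t + sep / 2, width) + a2 * _ricker(t - sep / 2, width)
        return w, [-sep / 2, sep / 2]
    if kind == "fractionated":
        spread = rng.uniform(30.0, 60.0)
        n_sub = int(rng.integers(3, 7))
        half = spread / 2.0
        t = np.arange(-half, half + dt / 2, dt)
        w = np.zeros_like(t)
        # sub-deflections placed so the whole complex (wavelet tails
        # included) stays within the stated 30-60 ms envelope
        widths = rng.uniform(6.0, 12.0, size=n_sub)
        lim = np.maximum(half - widths, 1.0)
        subs = np.sort(rng.uniform(-1.0, 1.0, size=n_sub) * lim)
        amps = rng.uniform(0.3, 1.0, size=n_sub) * rng.choice(
            [-1.0, 1.0], size=n_sub
        )
        for s, a, wd in zip(subs, amps, widths):
            w += a * _ricker(t - s, wd)
        return w, list(subs)
    raise ValueError(f"unknown morphology: {kind}")


def _bandlimited_noise(n: int, fs: float, sd: float, rng) -> np.ndarray:
    """White Gaussian noise shaped to the 30-300 Hz acquisition band."""
    white = rng.standard_normal(n)
    hi = min(300.0, 0.45 * fs)
    sos = butter(4, [30.0, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sosfiltfilt(sos, white)
    rms = np.std(shaped)
    return shaped * (sd / rms) if rms > 0 else shaped


def generate(cfg: SynthConfig, record_id: str = "synth") -> SynthRecord:
    """Generate one record; deterministic given ``cfg`` (including seed)."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs)) + 1
    dt = 1000.0 / fs
    dur_ms = (n - 1) * dt

    floor = cfg.min_cl + _BARY_MARGIN_MS
    if cfg.mean_cl <= floor - _BARY_MARGIN_MS:
        raise ValueError("infeasible config: mean_cl below the interval floor")

    # renewal process: truncated-normal intervals via rejection sampling
    centers = []
    t = 0.0
    first = True
    while True:
        if first:
            gap = rng.uniform(60.0, cfg.mean_cl)
            first = False
        else:
            gap = rng.normal(cfg.mean_cl, cfg.cl_sd)
            while gap < floor:
                gap = rng.normal(cfg.mean_cl, cfg.cl_sd)
        t += gap
        if t > dur_ms - 60.0:
            break
        centers.append(t)

    kinds = list(cfg.morphology_mix)
    probs = np.array([cfg.morphology_mix[k] for k in kinds])
    # slow amplitude drift (catheter contact variation): sinusoid with a
    # 3-5 s period modulating every activation's amplitude
    if cfg.amp_drift > 0:
        drift_period = rng.uniform(3000.0, 5000.0)
        drift_phase = rng.uniform(0, 2 * np.pi)
    else:
        drift_period = drift_phase = None
    clean = np.zeros(n)
    truth_lats = []
    meta = []
    for c in centers:
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        w, subs = _template(kind, fs, rng)
        amp = cfg.amp_mean * rng.lognormal(
            mean=-0.5 * np.log1p(cfg.amp_cv**2),
            sigma=np.sqrt(np.log1p(cfg.amp_cv**2)),
        )
        if drift_period is not None:
            amp *= 1.0 + cfg.amp_drift * np.sin(
                2 * np.pi * c / drift_period + drift_phase
            )
        dropped = rng.uniform() < cfg.dropout_prob
        if dropped:
            amp *= 0.02
        i_c = int(round(c / dt))
        half = (w.size - 1) // 2
        i0, i1 = i_c - half, i_c - half + w.size
        w_amp = amp * w
        s0, s1 = max(i0, 0), min(i1, n)
        clean_contrib = np.zeros(n)
        clean_contrib[s0:s1] = w_amp[s0 - i0 : s1 - i0]
        clean += clean_contrib
        # ground-truth LAT: energy barycenter of this activation's clean
        # waveform as placed
        e = clean_contrib**2
        lat = float((np.arange(n) * dt * e).sum() / e.sum())
        truth_lats.append(lat)
        meta.append(
            {
                "morphology": kind,
                "amplitude": float(amp),
                "dropped": bool(dropped),
                "sub_peaks_ms": [lat + s for s in subs],
                "nominal_center_ms": float(c),
            }
        )

    x = clean.copy()
    if cfg.noise_sd > 0:
        x += _bandlimited_noise(n, fs, cfg.noise_sd, rng)
    if cfg.artifact_rate > 0:
        # impulsive artifacts (catheter contact, far-field ventricular
        # residue): brief spikes below typical activation amplitude
        n_art = rng.poisson(cfg.artifact_rate * cfg.duration_s)
        for _ in range(n_art):
            i = int(rng.integers(0, n))
            a = rng.uniform(0.2, 0.8) * cfg.amp_mean * rng.choice([-1.0, 1.0])
            wlen = int(rng.integers(1, max(int(2e-3 * fs), 2)))
            x[i : i + wlen] += a
    if cfg.farfield_amp > 0:
        n_ff = rng.poisson(_FARFIELD_RATE * cfg.duration_s)
        tax = np.arange(n) * dt
        for _ in range(n_ff):
            c = rng.uniform(0, dur_ms)
            a = cfg.farfield_amp * rng.uniform(0.5, 1.5)
            x += a * np.exp(-0.5 * ((tax - c) / 8.0) ** 2)

    rec = IegmRecord(record_id=record_id, samples=x, fs=fs, t0=0.0)
    truth_arr = np.asarray(truth_lats)
    if truth_arr.size > 1 and np.any(np.diff(truth_arr) < cfg.min_cl):
        # the interval floor plus barycenter margin should preclude this
        raise RuntimeError("generated truth violates the refractory floor")
    truth = ActivationSequence(
        record_id=record_id, lats=truth_arr, source=Source.ANNOTATED_TRUTH
    )
    return SynthRecord(record=rec, truth=truth, meta=meta)


def clean_benchmark_config() -> SynthConfig:
    """Noise-free biphasic records at 200 ms mean cycle length.

    The reference condition for clean-signal recovery experiments: with no
    noise, artifacts or dropout, the energy-ratio detector at its default
    parameters should recover every activation.
    """
    return SynthConfig(
        duration_s=10.0,
        mean_cl=200.0,
        cl_sd=30.0,
        noise_sd=0.0,
        morphology_mix={"biphasic": 1.0, "fractionated": 0.0, "double_peak": 0.0},
    )


def degraded_benchmark_config() -> SynthConfig:
    """Degraded mixed-morphology records for correction experiments.

    Three independent degradation mechanisms produce a raw detection error
    of a few percent: baseline noise (sd calibrated so that noise peaks sit
    just below the adaptive threshold), impulsive artifacts (oversensing at
    physiologically implausible intervals, removable by the interval-weight
    correction), and occasional near-isoelectric beats (undersensing in
    doubled gaps, recoverable by the same correction).
    """
    return SynthConfig(
        duration_s=10.0,
        mean_cl=170.0,
        cl_sd=30.0,
        noise_sd=0.002,
        artifact_rate=0.4,
        dropout_prob=0.01,
    )


def tuning_benchmark_config() -> SynthConfig:
    """Long-cycle, drifting-amplitude records for window-length tuning.

    Designed so both failure modes of the energy-ratio baseline window are
    expressed: gaps long enough that a +/-200 ms long window sometimes sees
    no activation (its energy ratio then stops suppressing baseline noise),
    and slow amplitude drift that a +/-800 ms window is too sluggish to
    track.  The total-error landscape over l_win then dips at 400 ms.
    """
    return SynthConfig(
        duration_s=10.0,
        mean_cl=260.0,
        cl_sd=60.0,
        noise_sd=0.005,
        artifact_rate=0.2,
        amp_drift=0.7,
    )


def annotation_benchmark_config() -> SynthConfig:
    """Fractionated/double-peak records for annotation-correction studies.

    Complexes with ambiguous peaks (hopping double potentials, jittered
    fractionation) on a nearly regular rhythm, so that the annotation
    imprecision -- not the physiological cycle-length variability --
    dominates the interval-variance budget and the Eq.-style variance
    bookkeeping is observable at desk scale.
    """
    return SynthConfig(
        duration_s=10.0,
        mean_cl=170.0,
        cl_sd=10.0,
        noise_sd=0.001,
        morphology_mix={"biphasic": 0.0, "fractionated": 0.5, "double_peak": 0.5},
    )


def make_corpus(
    cfg: SynthConfig,
    n_records: int,
    seed: int,
    outdir: str | Path | None = None,
) -> list[SynthRecord]:
    """Generate ``n_records`` independent records with derived seeds.

    If ``outdir`` is given, each record is written as CSV, each truth as
    JSON, and a manifest listing the pairs is written alongside.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_records)]
    corpus = []
    for i, s in enumerate(child_seeds):
        rec_cfg = replace(cfg, seed=s)
        corpus.append(generate(rec_cfg, record_id=f"synth_{i:03d}"))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": seed, "n_records": n_records, "records": []}
        for sr in corpus:
            rec_path = outdir / f"{sr.record.record_id}.csv"
            truth_path = outdir / f"{sr.record.record_id}.truth.json"
            afio.write_record(sr.record, rec_path)
            afio.write_annotations(sr.truth, truth_path, format="json")
            manifest["records"].append(
                {"record": rec_path.name, "truth": truth_path.name}
            )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return corpus
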