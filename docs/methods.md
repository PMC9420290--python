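# Methods

`afdetect` detects atrial activations (AAs) in single-channel bipolar
intracardiac electrograms (IEGMs) recorded in the pulmonary veins during
atrial fibrillation (AF), and assigns each a robust local activation time
(LAT). The pipeline has three stages — raw detection, over/undersensing
correction, annotation correction — plus a synthetic-electrogram generator
and an evaluation/tuning harness. This note records the models, the
parameter choices, the numerical decisions, and what the synthetic
experiments do and do not demonstrate.

## Signal model and conventions

An IEGM is a uniformly sampled amplitude series x(n) in mV at 1 or 2 kHz,
band-limited to roughly 30–300 Hz by the acquisition chain. All public APIs
exchange times in **milliseconds**; the single ms→sample rule is
`n = round(t·fs/1000)`, rounding half away from zero. A hard physiological
constraint runs through every stage: two activations in the pulmonary veins
cannot be closer than **70 ms** (the refractory period). Any sequence the
pipeline emits honours that spacing; expert/simulator truth is exempt by
construction of the type system, not by assumption.

## Stage 1a — relative-energy (Rel-En) detection

The electrogram is multiplied by the ratio of its short-term to long-term
energy,

    c(n) = Σ_{i=n−S}^{n+S} |x(i)|^p / Σ_{j=n−L}^{n+L} |h(j−n+L)·x(j)|^p ,
    x_RE(n) = x(n)·c(n),

with S, L the short/long half-windows in samples (defaults 100 ms and
400 ms), h a Hamming window spanning the long window (applied in the
denominator only), and p = 4. Window sums are truncated at the record edges;
the denominator is floored at `1e-12·max|x|^p` so silent records yield
c = 0 rather than NaN. Detections are local maxima of |x_RE| above an
adaptive threshold TH_P, resolved under the 70 ms refractory rule (larger
peak wins; ties go to the earlier candidate).

**Threshold reading.** TH_P is parameterised by a percentile P (default 11,
meaningful range ~6–13). We interpret P as the *fraction of time the signal
spends inside activation complexes*: TH_P is the amplitude exceeded by the
top P% of |x_RE| samples (the 100−P lower percentile, linear-interpolation
convention). At AF cycle lengths of 150–250 ms with 30–60 ms complexes, the
active fraction is 10–15%, so this anchors TH_P at the foot of the
activation amplitude range — just above the baseline, regardless of the
record's absolute scale (detection is exactly scale-invariant). Reading P
as an ordinary lower percentile instead places the threshold deep inside
the baseline amplitude bulk and saturates the detector with false
positives on any record with visible baseline noise; that reading remains
available (`RelEnParams(percentile_from='bottom')`) but is not the default.
Bipolar polarity is arbitrary, so rectification uses |x_RE| by default
(`polarity` flag for single-sided variants).

Known limitation: with p = 4 the energy ratio is quartic in relative
amplitude, so a weak beat adjacent to a ≳3× stronger one can be crushed
below threshold even in noise-free signals; and because the short window
(±100 ms) spans a large part of the cycle, the coefficient does not by
itself suppress baseline between closely spaced activations — separation
rests mostly on the amplitude contrast of x itself.

## Stage 1b — adaptive mathematical morphology (AMM) detection

A structuring element (SE) shaped like an activation — five fiducials:
onset, pre-peak trough, peak, post-peak trough, offset, linearly
interpolated — filters the signal through the mean-residue

    x_MM = x − (x∘SE + x•SE)/2,

where ∘/• are grayscale opening/closing. x_MM is near zero wherever the
signal is locally explained by the SE shape and lobed at activations. The
synthesized SE has duration 20 ms, amplitude span max−min of the first
500 ms, peak at the midpoint and troughs of −0.25·span at the quartiles.
Processing is in 200 ms windows; after each window the SE fiducials
(locations as distances from onset, and amplitudes) are blended toward the
last extracted activation with learning coefficient α = 0.5.

Numerical decisions:

* erosion/dilation use **truncated support** at array edges (implemented
  with constant padding at ∓1e300, which excludes out-of-range samples from
  every min/max). Clamped-edge padding breaks the `opening ≤ x ≤ closing`
  adjunction at the boundaries for non-flat SEs; truncated support
  preserves it everywhere. SE origin is the centre sample (index K//2).
* windows are processed with a one-refractory-period margin on both sides;
  only LATs inside the core window are kept, so boundary-straddling
  activations are seen whole and duplicates are resolved by the refractory
  rule.
* the SE is updated only from activations whose suprathreshold segment is
  fully contained in the processed span, and an update is skipped if the
  blended fiducial spacing would fall below one sample period. Without
  both guards, edge-clipped segments feed the update and the SE collapses
  toward an impulse, for which x_MM is identically zero and detection dies.
* "non-zero" segments of x_MM are runs with |x_MM| above `zero_tol` (1e-3)
  times the running maximum of |x_MM| over the record so far. This is an
  explicit, testable stand-in for the idealised "zero otherwise" feature
  signal; it makes AMM deliberately sensitive, which is visible as a higher
  false-positive rate on noisy records.

## Stage 2 — over/undersensing correction

From the raw sequence we compute meanAA and σ_AA (mean and *population*
standard deviation of the intervals, frozen for the whole pass). Two weight
shapes map an interval position k (ms) to a gain:

* linear: 0 below 70 ms, then the ramp through (70, P_70) and
  (meanAA, P_meanAA), continued with the same slope;
* nonlinear: 0 below 70 ms, a Gaussian rising limb centred at meanAA with
  standard deviation E·σ_AA reaching P_meanAA at k = meanAA, then flat at
  P_meanAA. (The printed closed form with amplitude E·P_meanAA/σ_AA is
  discontinuous at meanAA unless E = σ_AA; we default to the continuous
  reading and keep the literal one under `gaussian_mode='literal'`.)

Defaults are the published per-detector optima: Rel-En nonlinear
(E = 1.25, P_meanAA = 3), Rel-En linear (0, 2.1), AMM linear (0.4, 2.2).

**Removal pass.** For each activation the weights are evaluated on its
preceding and succeeding intervals; a neighbour whose weighted amplitude
(|x_RE| at the detection, for Rel-En) falls below TH_P is deleted.
Processing starts at the first activation and checks the succeeding
neighbour before advancing, so a spurious detection is pruned before it can
flag its true predecessor. **Recovery pass.** Each gap [LAT_i, LAT_i+1] of
length K is screened with the symmetric product W(k) = w(k)·w(K−k) (zero
within 70 ms of both ends, amplifying the centre of long gaps); if the
weighted enhanced amplitude crosses TH_P, one activation is inserted at the
argmax — at most one per gap per pass, never within half a refractory of a
detection removed in the same pass.

The correction's leverage is confined to near-threshold detections (removal
needs w·amp < TH_P) and to gaps whose length makes W > 1 (recovery): it
removes implausibly-timed low-margin detections and recovers beats hidden
in doubled gaps, but cannot reject a high-amplitude artifact at a plausible
interval, and inflated σ_AA (e.g. from many raw errors) broadens W and can
make recovery hallucinate. That failure mode is real in the algorithm and
visible in stress tests beyond the calibrated conditions.

## Stage 3 — barycenter annotation

Peak annotation on fractionated or multi-peak complexes hops between
sub-peaks beat to beat, inflating cycle-length variability (the artificial
"long-short-long" pattern). Each LAT is re-annotated independently:
extract ±70 ms around the detection (clipped at gap midpoints so
neighbours never bleed in), compute the envelope (analytic-signal
magnitude; 5 ms sliding-max alternative), keep the maximal contiguous
envelope run containing its peak above `cutoff_frac` (0.2) of the segment
maximum, and set LAT* = Σ t·x(t)² / Σ x(t)² over the retained range.
Squaring concentrates the estimate on the high-amplitude core. If two
corrected LATs would cross or come closer than 70 ms, both revert to their
originals. With truth unknown, the observable success measure is the drop
in interval variance: with LAT = LAT₀ + e_t + e and independent terms,
var(LAT) decomposes additively, so a beat-by-beat correction that lowers
interval variance has lowered annotation imprecision.

The envelope cutoff and the segment span are engineering choices (the
procedure requires them but no canonical values exist); both are exposed.

## Synthetic electrograms

`afdetect.simulate` generates AF-like PV electrograms with exact truth:
truncated-normal renewal intervals (mean 170 ms, sd 30 ms by default, floor
min_cl + 40 ms so truth LATs can never violate the 70 ms refractory);
three morphology classes — biphasic Mexican-hat spikes (14–24 ms),
fractionated complexes of 3–6 jittered sub-deflections confined to a
30–60 ms envelope, and double potentials with two lobes 10–25 ms apart
whose dominance alternates (second-lobe amplitude U(0.7, 1.3)); lognormal
beat-to-beat amplitude (CV 0.2) with optional slow sinusoidal drift
(3–5 s period) and optional near-isoelectric dropout beats; 30–300 Hz
band-shaped Gaussian noise; Poisson impulsive artifacts at 0.2–0.8× the
mean activation amplitude; optional far-field bumps. The **truth LAT is the
energy barycenter of the clean template as placed**, so annotation error
decomposes cleanly in tests. Everything is deterministic given the seed.

Named benchmark conditions (used by the tests and `scripts/acceptance.py`):

* `clean_benchmark_config` — noise-free biphasic, mean CL 200 ms: the
  Rel-En detector at defaults recovers 100% of activations (±35 ms).
* `degraded_benchmark_config` — mixed morphology with noise_sd 0.002 mV
  (calibrated so the raw pooled error is a few percent), artifacts at
  0.4/s and 1% dropout: the three degradation mechanisms map one-to-one
  onto the correction's removal and recovery paths.
* `tuning_benchmark_config` — long cycles (260 ± 60 ms) with amplitude
  drift 0.7: the l_win = 200 ms grid point fails on long noise-only gaps
  and l_win = 800 ms fails to track the drift, so the tuning landscape dips
  at the interior 400 ms point.
* `annotation_benchmark_config` — fractionated/double-peak beats on a
  nearly regular rhythm (CL sd 10 ms), so annotation imprecision dominates
  the interval-variance budget at desk scale.

The generator reproduces interval statistics, morphology classes, and noise
floors — not wavefront dynamics, catheter motion, inter-channel structure,
or the long-tailed amplitude and fractionation spectra of clinical
recordings. Passing the synthetic benchmarks therefore demonstrates the
mechanisms (enhancement, weighting, barycenter) under controlled
conditions, not clinical-grade error rates.

## Evaluation

Matching is one-to-one, greedy by increasing |Δt| with a 35 ms default
tolerance (half the refractory period, which makes pairing unambiguous when
both sequences honour 70 ms spacing; on such sequences greedy pairing
attains the optimal assignment cardinality, verified against brute force).
Rates follow the field convention: FN and FP counts are both divided by the
number of *reference* activations, and the total error is their sum; corpus
rates pool counts before dividing. Grid search minimises the pooled total
error, breaking ties by lower FP rate and then grid order, and returns the
full error-vs-parameter table.

## Problem sizes

Benchmarks run at desk scale: 10 s records, corpora of 8–40 records,
20-seed repetitions, 9-point tuning grids. These sizes give stable
pooled rates (≈2,000–9,000 reference activations per experiment) while
keeping the full suite and the acceptance script each within a few minutes
on one CPU.
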