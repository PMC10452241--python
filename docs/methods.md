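# Methods

## The sorting model

`multifq` treats spike sorting as four stages over a single-channel
extracellular voltage trace `D` sampled at `rate_hz`:

1. **Multi-band filtering.** A bank of `B` 4th-order Butterworth band-pass
   filters with a shared upper corner and ascending lower corners produces
   traces `D_1 … D_B` (low → high bands). Filters are realized as cascaded
   second-order sections; the design order is the band-pass prototype order,
   so an order-4 band has 8 poles and is −3 dB at both corners. The default
   application mode is a single causal forward pass from zero initial state
   (streaming-compatible, but it delays and reshapes waveforms); a
   `zero_phase` forward–backward mode is available.
2. **Detection on the low band.** The threshold magnitude is
   `multiplier · median(|D_1|)/0.6745` with `multiplier = 4`. The 0.6745
   constant is the median absolute value of a unit Gaussian, so the ratio
   estimates the noise σ robustly — spikes inflate a standard deviation but
   barely move the median. Candidate events are interior local extrema of
   the trace (restricted by the configured polarity) strictly above the
   threshold, plateaus counting once at their first sample. Events closer
   than the censor window keep only the larger-magnitude one (ties go to
   the earlier index); events whose cut window would leave the trace are
   dropped.
3. **Cutting and splicing.** Every retained peak index `P` cuts the window
   `[P−k+1, P+L−k]` (1-based, `L` samples, peak at the `k`-th sample) from
   *every* band at the same indices, keeping rows time-locked across bands;
   the per-band windows are concatenated into one `B·L`-sample composite
   row per event.
4. **Features and clustering.** Composite rows are mean-centered (NOT
   variance-scaled: the bands keep their native amplitude scale, consistent
   with splicing raw filtered waveforms) and projected onto the top 3
   principal components; k-means with caller-supplied `K` partitions the
   scores. PCA signs follow a fixed convention (each eigenvector's
   largest-|loading| entry is positive); k-means uses greedy (k-means++
   style) seeding, 10 restarts, 300 iterations maximum, center-movement
   tolerance 1e-4, and is reproducible given the seed.

A single-band bank makes the pipeline the classical one-filter PCA+k-means
sorter; the composite's value is that higher bands attenuate the common
slow lobes and re-weight fast tail structure, so unit differences invisible
under the low band's variance budget can surface.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| bands (25 kHz profile) | 300/700/1000–6000 | Hz | standard low corner plus two higher corners; shared upper corner set by the sampling rate |
| bands (10 kHz profile) | 300/500/700–3000 | Hz | same structure below the 5 kHz Nyquist |
| filter order | 4 | — | standard; −3 dB at corners |
| threshold multiplier | 4 | σ | classical robust threshold |
| polarity (profiles) | negative | — | see below |
| censor window (profiles) | L samples | — | one detection per cut window |
| L, k | 64, 20 (25 kHz); 32, 11 (10 kHz) | samples | ≈2.5–3.2 ms windows with the peak early enough to capture the tail |
| PCA components | 3 | — | standard discriminative budget for spike waveforms |
| k-means restarts | 10 | — | sklearn default; deterministic given seed |
| match tolerance | 0.5 ms (full truth), 0.3 ms (partial) | s | strict one-to-one event correspondence |
| overlap window | L / rate | s | events closer than a cut window superimpose |

**Signed detection.** The packaged profiles detect on the negative
threshold only. Extracellular somatic spikes deflect downward, and the
absolute-value ("double threshold") reading makes the positive recovery
lobe compete with the trough for the alignment extremum: near-equal rivals
flip under noise and split one unit into two alignment modes. Detecting the
trough keeps the alignment point unique. `DetectionConfig` still defaults
to `polarity="both"` for generic use.

**Censor = L.** A causal-filtered spike can re-cross the threshold several
times inside (and slightly beyond) its own cut window — overshoot,
recovery, ringing. A censor of one cut length suppresses these without a
separate artifact-rejection stage. The config-level default (1 ms) remains
for callers who need to resolve closer events.

**Detection latency.** A causal band-pass delays the detected peak by
roughly its passband group delay (≈0.13 ms for 300–6000 Hz at 25 kHz).
Evaluation subtracts the design-derived mid-band group delay from detected
times before tolerance matching; this is a constant computed from the
filter, not fitted to data. Zero-phase mode gets no correction.

## The simulator

`synthetic` renders ground-truthed recordings with the statistical
structure of the standard simulated benchmark:

* **Templates.** Each unit is a parametric biphasic shape: a fast,
  asymmetric negative depolarization lobe (rise σ 0.05–0.16 ms, fall σ
  0.08–0.32 ms), an optional small positive pre-bump, a prominent slower
  positive recovery lobe (amplitude 0.30–0.65 of the trough, σ
  0.15–0.60 ms, delay 0.25–0.90 ms), and a small smooth random component
  (15% of peak) that individualizes the unit. Templates are peak-normalized
  to |amplitude| 1.
* **Template screening.** Raw draws are rejected unless, after a canonical
  causal detection band (300 Hz to the profile-style upper corner for the
  rate), (i) the filtered trough stays within 0.35 ms of the raw trough
  (otherwise simulated truth times could not be matched), (ii) the trough
  is the absolute filtered extremum (the fixed-point alignment convention
  presupposes it), (iii) rival negative dips stay below 0.6 of the trough
  (near-equal rivals flip alignment under noise and split the unit), and
  (iv) the late undershoot echo — one template length past the trough,
  beyond the censor window — stays below 0.15 of the trough (deeper echoes
  ride over a 4σ threshold and spawn spurious events). About 40% of raw
  draws survive; the screens encode nothing about any particular test
  dataset, only the alignment and detection conventions.
* **Similarity dial.** `make_templates(K, …, similarity)` targets a mean
  pairwise Pearson correlation. Sets of screened draws are rejection-sampled
  until the raw mean correlation lands within ±0.04 of the target;
  blending every shape toward a common base shape is the fallback for
  pulling too-dissimilar draws *up* to the target (blending is not used to
  move downward — it dilutes exactly the shape differences that survive
  filtering). A distinctness floor (minimum pairwise distance 1.2 between
  canonically filtered, trough-aligned templates) rejects sets containing a
  near-duplicate pair, which raw-template correlation cannot see because
  detection's peak re-alignment erases common-mode timing offsets.
* **Spike trains.** Per-unit homogeneous Poisson processes (exponential
  ISIs shifted by a 2 ms refractory floor), default 20 Hz per unit, merged
  and sorted. With `allow_overlap=False` (the default) cross-unit events
  closer than one template length are re-drawn; with `allow_overlap=True`
  they are kept and flagged. Optional extras, off by default: a linear
  amplitude ramp (`drift_ramp`) and short-ISI follower events
  (`burst_prob`).
* **Noise.** The default model superimposes 5000 randomly placed, randomly
  scaled, randomly chosen templates per second — noise whose power spectrum
  resembles the spikes' own (log-spectral correlation ≈0.96 with the mean
  template) — then smooths with a one-sample Gaussian kernel, because
  background spikes come from distant neurons whose high-frequency content
  the tissue attenuates. The superposition is rescaled to the requested
  standard deviation (quoted relative to the unit-peak templates; the
  benchmark ladder spans 0.05–0.40). A `colored` alternative spectrally
  shapes white noise to the mean template spectrum. The rendered recording
  is exactly `clean + noise`, bit-reproducible from the seed.

**Why overlaps default off.** With three 20 Hz units, ~18% of events fall
within one cut window of another event. Their superimposed cuts are far
outliers in feature space, and k-means — which has no outlier model — will
happily park a centroid on a few dozen of them, merging two real units
(measured: the clean events alone sort at ≈1.0 while the full set drops to
≈0.67). That failure is a property of k-means, orthogonal to the filtering
front end this package is about, and the reference evaluations likewise
exclude overlapping spikes from scoring. Overlap generation is therefore an
opt-in stress condition rather than the default.

**What the simulator does not emulate.** Real waveform variability within a
unit (bursting amplitude decrement, electrode drift beyond a linear ramp),
spatial information from multi-site probes, non-stationary noise, and true
overlap decomposition. Passing tests on this simulator show the pipeline's
conventions and the composite mechanism are implemented correctly — not
that any particular accuracy carries over to in vivo data.

## Constructed demonstration fixtures

Two deterministic two-unit fixtures expose band-structure effects:

* `make_tail_difference_pair`: identical sharp depolarization and slow
  recovery; the only difference is a non-negative 2.5 kHz ripple (amplitude
  0.45 before normalization) riding the recovery lobe. Low-band filtered
  waveforms correlate at ≈0.91. Because the shared slow energy is stripped
  by the higher corners while the ripple passes all bands, the three-band
  composite sorts this pair substantially better than the single 300 Hz
  band (e.g. ≈0.98 vs ≈0.76 accuracy at noise 0.20). The comparison is run
  with both arms in `zero_phase` mode: under the causal mode any ripple
  large enough to matter also deepens a rival negative dip, whose
  noise-driven alignment flips generate enough outlier events to capture a
  k-means centroid in *both* arms — the comparison then measures k-means
  outlier sensitivity, not band structure. The ripple is non-negative for
  the same reason: signed detection never sees it.
* `make_slow_difference_pair`: the same skeleton with the recovery-lobe
  depth as the only (slow, ≲600 Hz) difference. A sweep over single-band
  low corners {200, 400, 600, 800} Hz yields accuracies ≈{0.94, 0.52, 0.52,
  0.50}: the lowest corner wins, because higher corners strip exactly the
  discriminative content.

## Numerical choices and degenerate inputs

* Indices are 0-based half-open internally; `k` and all human-facing
  tables use the 1-based convention, converted at the API boundary.
* Ties: censor ties break toward the earlier index; matching ties toward
  the earlier detected event; plateau peaks count at their first sample.
* Tolerance matching is strict (`|Δt| < tol`, not ≤).
* Empty inputs raise; an empty detection result is valid.
* Degenerate thresholds: on (nearly) noise-free data the median-based
  threshold collapses toward zero and float-level filter ringing becomes
  detectable. The pipeline's operating envelope effectively starts at the
  benchmark ladder's lowest noise (σ ≈ 0.05), where the 4σ threshold
  clears the bounded ring echoes; below that, expect spurious events.
* The `similarity` target is declared unreachable (a `ValueError`) if no
  screened draw admits it within the try budget, rather than silently
  returning something else.

## Problem sizes used by the test suite

Unit tests run on traces of 10³–10⁴ samples. End-to-end recovery uses a
60 s, 25 kHz, 3-unit recording at noise 0.05 (accuracy ≥0.95, observed
1.0) and a 20 s ladder over noise {0.05, 0.10, 0.15, 0.20} with 5 seeds
per level (median accuracies observed 1.00 / 1.00 / 0.97 / 0.77,
non-increasing). The oracle-equivalence suites use 200 random traces up to
5000 samples and 500 random label vectors with up to 6 clusters. The whole
suite runs in well under a minute on one core.

## Known limitations

* k-means has no outlier model; any coherent population of distorted events
  (overlaps, artifacts) of even a few percent can capture a centroid. With
  overlaps enabled, accuracy over non-overlap events is the right metric
  but the clustering itself still degrades.
* Causal filtering delays and reshapes waveforms per band; only the
  constant mid-band group delay is compensated. Waveform-dependent residual
  latency (up to ~0.3 ms across realistic shapes) consumes matching
  tolerance.
* Alignment is integer-sample; sub-sample interpolation (common in mature
  sorters) would reduce jitter variance and is deliberately out of scope.
* Single channel only; no probe geometry, no template matching, no overlap
  resolution.
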