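"""Ground-truthed synthetic extracellular recordings.

Emulates the statistical structure of the standard simulated spike-sorting
benchmark: K biphasic spike templates whose mean pairwise correlation is
driven to a target "similarity"; per-unit Poisson spike trains with a
refractory floor; and background noise built by superimposing many randomly
placed, randomly scaled spike shapes, so its power spectrum resembles the
spikes' own — the property that makes naive frequency-domain denoising
ineffective.  Noise amplitude is expressed as a standard deviation relative
to the unit-peak templates (the benchmark ladder spans 0.05–0.40).

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .evaluation import GroundTruth, overlap_mask
from .filtering import RawRecording

__all__ = [
    "TemplateSet",
    "SimulationSpec",
    "SimulatedDataset",
    "make_templates",
    "simulate_spike_trains",
    "render_recording",
    "simulate",
    "make_partial_truth",
    "make_tail_difference_pair",
    "make_slow_difference_pair",
]


@dataclass(frozen=True)
class TemplateSet:
    """K spike templates, each peak-normalized to absolute amplitude 1."""

    templates: np.ndarray  # K x L_t
    rate_hz: float
    similarity: float  # target mean pairwise correlation actually achieved

    def __post_init__(self) -> None:
        tpl = np.asarray(self.templates, dtype=np.float64)
        if tpl.ndim != 2:
            raise ValueError("templates must be a K x L_t matrix")
        object.__setattr__(self, "templates", tpl)

    @property
    def K(self) -> int:
        return int(self.templates.shape[0])

    @property
    def L_t(self) -> int:
        return int(self.templates.shape[1])

    @property
    def peak_offsets(self) -> np.ndarray:
        """Per-template sample index of the absolute extremum."""
        return np.argmax(np.abs(self.templates), axis=1)

    def mean_pairwise_correlation(self) -> float:
        if self.K < 2:
            return 0.0
        C = np.corrcoef(self.templates)
        iu = np.triu_indices(self.K, k=1)
        return float(C[iu].mean())


def _dep_dominant(shape: np.ndarray, rate_hz: float) -> bool:
    """Does the depolarization trough survive the canonical causal
    detection band roughly in place?  Detection aligns events on the
    filtered trough, and simulated truth marks the raw trough time; shapes
    whose filtered minimum wanders far from the raw one would defeat
    tolerance matching and are rejected at draw time.  The canonical band
    (300 Hz to the profile-style upper corner for the rate) mirrors what
    the pipeline actually applies."""
    from scipy.signal import butter, sosfilt

    high = min(6000.0, 0.3 * rate_hz)
    sos = butter(4, [300.0, high], btype="bandpass", fs=rate_hz, output="sos")
    pad = np.zeros(4 * shape.size)
    pad[shape.size : 2 * shape.size] = shape
    filt = sosfilt(sos, pad)
    raw_pk = shape.size + int(np.argmin(shape))
    filt_pk = int(np.argmin(filt))
    if abs(filt_pk - raw_pk) > max(2, int(round(0.35e-3 * rate_hz))):
        return False
    # the trough must also be the raw ABSOLUTE extremum (unit peak = -1)
    if int(np.argmax(np.abs(shape))) != int(np.argmin(shape)):
        return False
    # the trough must remain the ABSOLUTE filtered extremum (the cut-window
    # alignment convention): the causal overshoot may not exceed it
    trough = -filt[filt_pk]
    if filt.max() >= 0.95 * trough:
        return False
    # rival negative dips must stay well below the trough, or noise flips
    # the alignment between them and the unit splits into two waveform
    # modes; positive lobes are otherwise free — signed detection never
    # aligns there
    guard = max(2, int(round(0.12e-3 * rate_hz)))
    rest = np.concatenate([filt[: filt_pk - guard], filt[filt_pk + guard + 1 :]])
    if float(-rest.min()) >= 0.6 * trough:
        return False
    # charge-balance proxy: the filter's slow undershoot recovery must not
    # leave a negative echo, one template-length past the trough, deep
    # enough to ride over a 4-sigma threshold and spawn spurious events
    late = np.concatenate([filt[: filt_pk - shape.size], filt[filt_pk + shape.size :]])
    return float(-late.min()) < 0.15 * trough


def _biphasic(rng: np.random.Generator, L_t: int, rate_hz: float) -> np.ndarray:
    """One random biphasic spike shape: a fast, asymmetric negative
    depolarization lobe (optionally preceded by a small positive bump), a
    slower positive hyperpolarization lobe, plus a small smooth random
    component.  Units differ in fast structure (lobe widths, asymmetry,
    pre-bump) as well as in the slow recovery, so their differences survive
    high-pass filtering.  Draws are screened with :func:`_dep_dominant`."""
    t_ms = np.arange(L_t) / rate_hz * 1e3
    T = t_ms[-1]
    # jitter of the depolarization peak position: a common-mode shift that
    # detection's peak re-alignment erases — it dials the raw pairwise
    # correlation without touching post-alignment distinctness, which the
    # RELATIVE lobe timing and widths carry
    dep_c = rng.uniform(0.25, 0.50) * T
    dep_wl = rng.uniform(0.05, 0.16)  # rise sigma, ms
    dep_wr = rng.uniform(0.08, 0.32)  # fall sigma, ms
    dep_w = np.where(t_ms < dep_c, dep_wl, dep_wr)
    shape = -np.exp(-0.5 * ((t_ms - dep_c) / dep_w) ** 2)
    pre_a = rng.uniform(0.0, 0.30)
    pre_c = dep_c - rng.uniform(0.20, 0.40)
    pre_w = rng.uniform(0.08, 0.18)
    shape += pre_a * np.exp(-0.5 * ((t_ms - pre_c) / pre_w) ** 2)
    # prominent, diverse recovery lobe (still below the trough amplitude):
    # its timing, width and depth carry most of the unit-to-unit shape
    # difference that survives filtering and peak alignment
    hyp_c = dep_c + rng.uniform(0.25, 0.90)
    hyp_w = rng.uniform(0.15, 0.60)
    hyp_a = rng.uniform(0.30, 0.65)
    shape += hyp_a * np.exp(-0.5 * ((t_ms - hyp_c) / hyp_w) ** 2)
    rough = gaussian_filter1d(rng.standard_normal(L_t), sigma=1.0, mode="nearest")
    shape += 0.15 * rough / max(np.max(np.abs(rough)), 1e-12)
    # taper so insertions start/end near zero
    edge = max(2, L_t // 16)
    taper = np.ones(L_t)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    taper[:edge] = ramp
    taper[-edge:] = ramp[::-1]
    shape *= taper
    return shape / np.max(np.abs(shape))


def _draw_shape(rng: np.random.Generator, L_t: int, rate_hz: float) -> np.ndarray:
    for _ in range(100):
        shape = _biphasic(rng, L_t, rate_hz)
        if _dep_dominant(shape, rate_hz):
            return shape
    raise RuntimeError("could not draw a depolarization-dominant shape")


def _filtered_aligned(tpls: np.ndarray, rate_hz: float) -> np.ndarray:
    """Canonically band-passed, peak-aligned template cuts — the shapes as
    the sorter actually sees them, after the common-mode timing shift is
    removed by peak alignment."""
    from scipy.signal import butter, sosfilt

    L_t = tpls.shape[1]
    high = min(6000.0, 0.3 * rate_hz)
    sos = butter(4, [300.0, high], btype="bandpass", fs=rate_hz, output="sos")
    pre, post = L_t // 3, L_t - L_t // 3
    aligned = []
    for shape in tpls:
        pad = np.zeros(4 * L_t)
        pad[L_t : 2 * L_t] = shape
        filt = sosfilt(sos, pad)
        pk = int(np.argmin(filt))  # trough alignment, mirroring detection
        aligned.append(filt[pk - pre : pk + post])
    return np.stack(aligned)


def _min_pairwise_filtered_dist(tpls: np.ndarray, rate_hz: float) -> float:
    """Smallest pairwise Euclidean distance between canonically filtered,
    aligned templates, normalized to a 64-sample window so the floor is
    rate- and length-agnostic."""
    A = _filtered_aligned(tpls, rate_hz)
    K = A.shape[0]
    dmin = np.inf
    for a in range(K):
        for b in range(a + 1, K):
            dmin = min(dmin, float(np.linalg.norm(A[a] - A[b])))
    return dmin * np.sqrt(64.0 / tpls.shape[1])


def _blend(distinct: np.ndarray, base: np.ndarray, alpha: float) -> np.ndarray:
    out = (1.0 - alpha) * distinct + alpha * base[None, :]
    return out / np.max(np.abs(out), axis=1, keepdims=True)


def _mean_corr(tpls: np.ndarray) -> float:
    C = np.corrcoef(tpls)
    iu = np.triu_indices(tpls.shape[0], k=1)
    return float(C[iu].mean())


def make_templates(
    K: int,
    L_t_samples: int,
    rate_hz: float,
    similarity: float = 0.3,
    seed: int = 0,
    max_tries: int = 200,
    distinct_floor: float = 1.2,
) -> TemplateSet:
    """Draw K unit-peak templates with a target mean pairwise correlation.

    Random biphasic shapes are drawn until their raw mean correlation is at
    or below ``similarity``; blending every shape toward a common base shape
    then raises the correlation to the target (bisection on the blend
    weight).  Raises if no draw within ``max_tries`` admits the target.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0.0 <= similarity < 1.0):
        raise ValueError("similarity must lie in [0, 1)")
    rng = np.random.default_rng([int(seed), 0x7E])
    if K == 1:
        return TemplateSet(
            templates=_draw_shape(rng, L_t_samples, rate_hz)[None, :],
            rate_hz=float(rate_hz),
            similarity=0.0,
        )

    # prefer a raw draw that already hits the target band: blending dilutes
    # the shape differences that carry discriminability, so it is only a
    # fallback for pulling too-dissimilar draws UP to the target
    base = _draw_shape(np.random.default_rng([int(seed), 0xBA]), L_t_samples, rate_hz)
    # distinctness floor: the benchmark's units are DISTINCT cells, so no
    # pair may be near-identical once canonically filtered and peak-aligned
    # (raw-template correlation cannot see this, because peak re-alignment
    # during detection erases common-mode timing offsets)
    best_below = None
    for _ in range(max_tries):
        distinct = np.stack([_draw_shape(rng, L_t_samples, rate_hz) for _ in range(K)])
        if K > 1 and _min_pairwise_filtered_dist(distinct, rate_hz) < distinct_floor:
            continue
        c0 = _mean_corr(distinct)
        if abs(c0 - similarity) <= 0.04:
            return TemplateSet(
                templates=distinct, rate_hz=float(rate_hz), similarity=float(similarity)
            )
        if c0 < similarity and (best_below is None or c0 > best_below[1]):
            best_below = (distinct, c0)
    if best_below is None:
        raise ValueError(
            f"similarity target {similarity} unreachable: all {max_tries} draws "
            "stayed above it"
        )

    distinct = best_below[0]
    lo, hi = 0.0, 1.0
    tpls = distinct
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        tpls = _blend(distinct, base, mid)
        c = _mean_corr(tpls)
        if abs(c - similarity) < 0.01:
            break
        if c < similarity:
            lo = mid
        else:
            hi = mid
    achieved = _mean_corr(tpls)
    if abs(achieved - similarity) > 0.05:
        raise ValueError(
            f"similarity target {similarity} unreachable (achieved {achieved:.3f})"
        )
    return TemplateSet(templates=tpls, rate_hz=float(rate_hz), similarity=float(similarity))


def _base_pair_shape(t_ms: np.ndarray, dep_c: float) -> np.ndarray:
    """Shared skeleton for the constructed two-unit fixtures: a SLOW spike
    (spectral content of a few hundred Hz) so that the higher-corner bands
    strip the shared lobes and expose whatever fast structure differs."""
    # sharp depolarization (crisp causal detection and alignment) plus a
    # prominent SLOW recovery lobe — the shared, strippable slow energy
    dep_w = np.where(t_ms < dep_c, 0.08, 0.14)
    shape = -np.exp(-0.5 * ((t_ms - dep_c) / dep_w) ** 2)
    shape += 0.35 * np.exp(-0.5 * ((t_ms - (dep_c + 0.70)) / 0.55) ** 2)
    return shape


def make_tail_difference_pair(
    L_t_samples: int = 64,
    rate_hz: float = 25_000.0,
    ripple_amp: float = 0.45,
    ripple_hz: float = 2500.0,
) -> TemplateSet:
    """Two units identical except for a small fast ripple in the
    hyperpolarization tail.

    The shared lobes dominate every band, so low-band waveforms are
    near-identical; the ripple (well inside the pass band) is the only
    discriminative feature.  Higher-corner bands attenuate the shared slow
    lobes and so raise the ripple's share of the variance — the construction
    that exposes the benefit of splicing multiple bands.
    """
    t_ms = np.arange(L_t_samples) / rate_hz * 1e3
    dep_c = 0.31 * t_ms[-1]
    a = _base_pair_shape(t_ms, dep_c)
    ripple_c = dep_c + 1.0
    window = np.exp(-0.5 * ((t_ms - ripple_c) / 0.45) ** 2)
    # non-negative ripple riding the recovery lobe: signed detection never
    # sees it, so the two units detect and align identically
    osc = 0.5 * (1.0 + np.sin(2 * np.pi * ripple_hz * (t_ms - ripple_c) / 1e3))
    ripple = ripple_amp * osc * window
    b = a + ripple
    tpls = np.stack([a / np.max(np.abs(a)), b / np.max(np.abs(b))])
    return TemplateSet(templates=tpls, rate_hz=float(rate_hz), similarity=0.0)


def make_slow_difference_pair(
    L_t_samples: int = 64,
    rate_hz: float = 25_000.0,
    hyp_amp_delta: float = 0.25,
) -> TemplateSet:
    """Two units whose only difference is the DEPTH of the slow recovery
    lobe — spectral content concentrated below a few hundred Hz, so a sweep
    over high-pass corners favours the lowest corner."""
    t_ms = np.arange(L_t_samples) / rate_hz * 1e3
    dep_c = 0.31 * t_ms[-1]
    a = _base_pair_shape(t_ms, dep_c)
    b = a + hyp_amp_delta * np.exp(-0.5 * ((t_ms - (dep_c + 0.65)) / 0.55) ** 2)
    tpls = np.stack([a / np.max(np.abs(a)), b / np.max(np.abs(b))])
    return TemplateSet(templates=tpls, rate_hz=float(rate_hz), similarity=0.0)


NoiseModel = Literal["spike_superposition", "colored"]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything that determines one synthetic recording.

    ``noise_std`` is the background-noise standard deviation relative to the
    unit-peak templates; ``firing_rates_hz`` gives each unit's mean rate;
    ISIs are exponential shifted by ``refractory_s``.
    """

    templates: TemplateSet
    duration_s: float = 60.0
    firing_rates_hz: tuple[float, ...] = ()
    refractory_s: float = 2e-3
    noise_std: float = 0.10
    noise_model: NoiseModel = "spike_superposition"
    allow_overlap: bool = False
    drift_ramp: float = 0.0  # peak-amplitude fractional ramp over the recording
    burst_prob: float = 0.0  # probability an event spawns a short-ISI follower
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        rates = tuple(self.firing_rates_hz) or tuple([20.0] * self.templates.K)
        if len(rates) != self.templates.K:
            raise ValueError("need one firing rate per template")
        if any(r <= 0 for r in rates):
            raise ValueError("firing rates must be positive")
        object.__setattr__(self, "firing_rates_hz", rates)

    @property
    def rate_hz(self) -> float:
        return self.templates.rate_hz


@dataclass(frozen=True)
class SimulatedDataset:
    """A rendered recording with its full ground truth and components."""

    recording: RawRecording
    truth: GroundTruth
    overlap_flags: np.ndarray
    clean: np.ndarray
    noise: np.ndarray
    spec: SimulationSpec


def _unit_time_window(spec: SimulationSpec, unit: int) -> tuple[float, float]:
    off = int(spec.templates.peak_offsets[unit])
    L_t = spec.templates.L_t
    t_min = off / spec.rate_hz
    t_max = spec.duration_s - (L_t - off) / spec.rate_hz
    return t_min, t_max


def simulate_spike_trains(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-unit Poisson spike trains (exponential ISIs + refractory floor).

    Returns merged, time-sorted event times (of each template's peak) and
    unit labels.  With ``allow_overlap=False``, events of different units
    closer than one template length are re-drawn (bounded retries).
    """
    rng = rng or np.random.default_rng([int(spec.seed), 0])
    times: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for u, r in enumerate(spec.firing_rates_hz):
        t_min, t_max = _unit_time_window(spec, u)
        if t_max <= t_min:
            raise ValueError("recording too short for the template length")
        ts = []
        t = t_min
        while True:
            t += spec.refractory_s + rng.exponential(1.0 / r)
            if t > t_max:
                break
            ts.append(t)
            if spec.burst_prob > 0 and rng.random() < spec.burst_prob:
                tb = t + spec.refractory_s + rng.exponential(3e-3)
                if tb <= t_max:
                    ts.append(tb)
                    t = tb
        times.append(np.asarray(ts))
        labels.append(np.full(len(ts), u, dtype=np.int64))
    t_all = np.concatenate(times) if times else np.empty(0)
    u_all = np.concatenate(labels) if labels else np.empty(0, dtype=np.int64)
    order = np.argsort(t_all, kind="stable")
    t_all, u_all = t_all[order], u_all[order]

    if not spec.allow_overlap and t_all.size > 1:
        window = spec.templates.L_t / spec.rate_hz
        for _ in range(200):
            gaps = np.diff(t_all)
            bad = np.flatnonzero(gaps < window)
            if bad.size == 0:
                break
            for b in bad:
                j = b + 1  # re-draw the later event of each close pair
                t_min, t_max = _unit_time_window(spec, int(u_all[j]))
                t_all[j] = rng.uniform(t_min, t_max)
            order = np.argsort(t_all, kind="stable")
            t_all, u_all = t_all[order], u_all[order]
        else:
            raise ValueError("could not place overlap-free spike trains; lower the rates")
    return t_all, u_all


def _insert_templates(
    out: np.ndarray,
    spec: SimulationSpec,
    times: np.ndarray,
    units: np.ndarray,
    amplitudes: Optional[np.ndarray] = None,
) -> None:
    tpl = spec.templates.templates
    offs = spec.templates.peak_offsets
    L_t = spec.templates.L_t
    n = out.size
    for u in range(spec.templates.K):
        sel = units == u
        if not sel.any():
            continue
        peaks = np.round(times[sel] * spec.rate_hz).astype(np.int64)
        starts = peaks - offs[u]
        ok = (starts >= 0) & (starts + L_t <= n)
        starts = starts[ok]
        amps = np.ones(starts.size) if amplitudes is None else amplitudes[sel][ok]
        idx = starts[:, None] + np.arange(L_t)[None, :]
        np.add.at(out, idx.ravel(), (amps[:, None] * tpl[u][None, :]).ravel())


def _spikelike_noise(spec: SimulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Superposition of many randomly placed, scaled, chosen templates,
    rescaled to the target std — noise whose power spectrum resembles the
    spikes' own.  The superposition is mildly smoothed (one-sample Gaussian
    kernel) because background spikes originate from DISTANT neurons whose
    high-frequency content the tissue attenuates."""
    noise = np.zeros(n)
    density_hz = 5000.0  # noise-spike placement rate; dense enough to look Gaussian
    m = max(50, int(spec.duration_s * density_hz))
    times = rng.uniform(0, spec.duration_s, size=m)
    units = rng.integers(0, spec.templates.K, size=m)
    amps = rng.uniform(0.5, 1.0, size=m)
    order = np.argsort(times, kind="stable")
    _insert_templates(noise, spec, times[order], units[order], amps[order])
    noise = gaussian_filter1d(noise, sigma=1.0, mode="nearest")
    noise -= noise.mean()
    sd = noise.std()
    if sd > 0:
        noise *= spec.noise_std / sd
    return noise


def _colored_noise(spec: SimulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """White noise spectrally shaped to the mean template magnitude spectrum."""
    nfft = 256
    mags = np.abs(np.fft.rfft(spec.templates.templates, n=nfft, axis=1)).mean(axis=0)
    f_tpl = np.fft.rfftfreq(nfft, d=1.0 / spec.rate_hz)
    white = rng.standard_normal(n)
    W = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / spec.rate_hz)
    shape = np.interp(f, f_tpl, mags)
    colored = np.fft.irfft(W * shape, n=n)
    colored -= colored.mean()
    sd = colored.std()
    if sd > 0:
        colored *= spec.noise_std / sd
    return colored


def render_recording(
    spec: SimulationSpec,
    trains: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> SimulatedDataset:
    """Render templates + noise into a recording with full ground truth."""
    if trains is None:
        trains = simulate_spike_trains(spec)
    times, units = trains
    if times.size and times.max() > spec.duration_s:
        raise ValueError("spike train extends beyond the recording duration")
    n = int(round(spec.duration_s * spec.rate_hz))

    clean = np.zeros(n)
    amps = None
    if spec.drift_ramp != 0.0 and times.size:
        amps = 1.0 + spec.drift_ramp * (times / spec.duration_s - 0.5)
    _insert_templates(clean, spec, times, units, amps)

    rng_noise = np.random.default_rng([int(spec.seed), 1])
    if spec.noise_std == 0:
        noise = np.zeros(n)
    elif spec.noise_model == "spike_superposition":
        noise = _spikelike_noise(spec, n, rng_noise)
    elif spec.noise_model == "colored":
        noise = _colored_noise(spec, n, rng_noise)
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")

    recording = RawRecording(samples=clean + noise, rate_hz=spec.rate_hz)
    truth = GroundTruth(spike_times_s=times, unit_labels=units, kind="full")
    flags = overlap_mask(times, units, window_s=spec.templates.L_t / spec.rate_hz)
    return SimulatedDataset(
        recording=recording,
        truth=truth,
        overlap_flags=flags,
        clean=clean,
        noise=noise,
        spec=spec,
    )


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Convenience wrapper: spike trains + rendering from one spec."""
    return render_recording(spec, simulate_spike_trains(spec))


def make_partial_truth(full: GroundTruth, unit: int) -> GroundTruth:
    """Reduce full truth to one marked unit (paired-recording style)."""
    if full.kind != "full":
        raise ValueError("expected full ground truth")
    sel = full.unit_labels == unit
    if not sel.any():
        raise ValueError(f"unit {unit} not present in the ground truth")
    return GroundTruth(
        spike_times_s=full.spike_times_s[sel],
        unit_labels=full.unit_labels[sel],
        kind="partial",
    )
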