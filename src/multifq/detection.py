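"""Spike detection on the low band and composite waveform assembly.

Detection follows the classic robust-threshold recipe: the threshold is
``multiplier * median(|Dl|) / 0.6745`` (the median absolute value of a
zero-mean Gaussian with standard deviation sigma is 0.6745*sigma, so the
denominator turns the median into a noise-sigma estimate that is insensitive
to the spikes themselves).  "Double thresholding" means the trace is tested
against both +Thr and -Thr, i.e. peaks are found on ``|Dl|``, with each
peak's sign recorded.

Every detected peak index ``P`` cuts a fixed window of ``L`` samples from
EVERY band at the SAME indices — ``trace[P-k+1 .. P+L-k]`` in 1-based
notation, placing the detection-band extremum at the k-th sample — and the
per-band windows are spliced side by side into one composite row of ``B*L``
values.  Internally all indices are 0-based half-open; ``k`` and human-facing
reports use the 1-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal as _scipy_signal

__all__ = [
    "DetectionConfig",
    "Threshold",
    "SpikeEvents",
    "WaveformSet",
    "CompositeWaveforms",
    "compute_threshold",
    "detect_peaks",
    "cut_waveforms",
    "assemble_composite",
]

Polarity = Literal["both", "positive", "negative"]

#: median(|X|) for X ~ N(0, 1); divides the median absolute value into a
#: robust estimate of the noise standard deviation.
GAUSSIAN_MEDIAN_ABS = 0.6745


@dataclass(frozen=True)
class DetectionConfig:
    """Detection and cutting parameters.

    Parameters
    ----------
    L
        Cut length in samples.
    k
        1-based position of the detection-band peak within the cut window
        (1 <= k <= L).
    multiplier
        Threshold multiplier (default 4).
    polarity
        Which threshold crossings count: ``both`` (default), ``positive``
        or ``negative``.
    min_peak_spacing_samples
        Censor window: detected events closer than this keep only the
        larger one.  ``None`` resolves to round(1 ms * rate) at detection
        time.
    """

    L: int
    k: int
    multiplier: float = 4.0
    polarity: Polarity = "both"
    min_peak_spacing_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.L):
            raise ValueError(f"alignment index k={self.k} must lie in 1..L={self.L}")
        if not self.multiplier > 0:
            raise ValueError("threshold multiplier must be positive")
        if self.polarity not in ("both", "positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.min_peak_spacing_samples is not None and self.min_peak_spacing_samples < 1:
            raise ValueError("min_peak_spacing_samples must be >= 1")

    def spacing_for_rate(self, rate_hz: float) -> int:
        if self.min_peak_spacing_samples is not None:
            return int(self.min_peak_spacing_samples)
        return max(1, int(round(1e-3 * rate_hz)))


@dataclass(frozen=True)
class Threshold:
    """Detection threshold magnitude; applied as ±value when polarity is both."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold magnitude must be non-negative")


def compute_threshold(detection_trace: Sequence[float], multiplier: float = 4.0) -> Threshold:
    """Robust amplitude threshold: ``multiplier * median(|trace|) / 0.6745``."""
    x = np.asarray(detection_trace, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot compute a threshold from an empty trace")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    if not multiplier > 0:
        raise ValueError("threshold multiplier must be positive")
    return Threshold(value=float(multiplier * np.median(np.abs(x)) / GAUSSIAN_MEDIAN_ABS))


@dataclass(frozen=True)
class SpikeEvents:
    """Detected peak indices (0-based, strictly increasing) with extremum signs."""

    peak_indices: np.ndarray
    peak_signs: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=np.int64)
        sgn = np.asarray(self.peak_signs, dtype=np.int64)
        if idx.shape != sgn.shape:
            raise ValueError("peak_indices and peak_signs must have equal length")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "peak_signs", sgn)

    @property
    def n_events(self) -> int:
        return int(self.peak_indices.size)

    @property
    def peak_times_s(self) -> np.ndarray:
        return self.peak_indices / self.rate_hz


def _candidate_peaks(mag: np.ndarray, thr: float) -> np.ndarray:
    """Interior local maxima of ``mag`` strictly above ``thr``.

    Plateaus count once, at their first sample.  scipy's find_peaks places a
    plateau peak at its midpoint, so plateau left edges are taken instead.
    """
    peaks, props = _scipy_signal.find_peaks(mag, plateau_size=(1, None))
    if peaks.size == 0:
        return peaks
    left = props["left_edges"]
    keep = mag[left] > thr
    return np.asarray(left[keep], dtype=np.int64)


def _censor(candidates: np.ndarray, mag: np.ndarray, spacing: int) -> np.ndarray:
    """Greedy magnitude-ordered censoring: of any two candidates closer than
    ``spacing`` samples, only the larger-magnitude one survives (ties break
    toward the earlier index)."""
    if candidates.size <= 1:
        return candidates
    order = np.lexsort((candidates, -mag[candidates]))
    kept: list[int] = []
    kept_arr = np.empty(candidates.size, dtype=np.int64)
    n_kept = 0
    for c in candidates[order]:
        if n_kept == 0 or np.min(np.abs(kept_arr[:n_kept] - c)) >= spacing:
            kept_arr[n_kept] = c
            n_kept += 1
    kept_sorted = np.sort(kept_arr[:n_kept])
    return kept_sorted


def detect_peaks(
    detection_trace: Sequence[float],
    threshold: Threshold,
    config: DetectionConfig,
    rate_hz: float,
) -> SpikeEvents:
    """Find supra-threshold peaks on the detection band.

    Candidates are local extrema of ``|trace|`` (restricted by polarity) with
    magnitude strictly above the threshold; events closer than the censor
    window keep only the larger one; events whose cut window would leave the
    trace are dropped.
    """
    x = np.asarray(detection_trace, dtype=np.float64)
    if threshold.value < 0:
        raise ValueError("threshold must be non-negative")
    if config.polarity == "both":
        mag = np.abs(x)
    elif config.polarity == "positive":
        mag = np.where(x > 0, x, 0.0)
    else:
        mag = np.where(x < 0, -x, 0.0)

    cands = _candidate_peaks(mag, threshold.value)
    cands = _censor(cands, mag, config.spacing_for_rate(rate_hz))

    # full-window admissibility: 0-based window [P-(k-1), P+L-k]
    lo_ok = cands >= (config.k - 1)
    hi_ok = cands <= (x.size - 1) - (config.L - config.k)
    cands = cands[lo_ok & hi_ok]

    signs = np.sign(x[cands]).astype(np.int64)
    return SpikeEvents(peak_indices=cands, peak_signs=signs, rate_hz=float(rate_hz))


@dataclass(frozen=True)
class WaveformSet:
    """N x L matrix of per-band spike waveforms, time-locked to the
    detection-band peaks."""

    waveforms: np.ndarray
    band_index: int
    config: DetectionConfig

    def __post_init__(self) -> None:
        w = np.asarray(self.waveforms, dtype=np.float64)
        if w.ndim != 2:
            raise ValueError("waveforms must be a 2-D (N x L) matrix")
        if w.shape[1] != self.config.L:
            raise ValueError(f"waveform length {w.shape[1]} != configured L={self.config.L}")
        object.__setattr__(self, "waveforms", w)

    @property
    def n_events(self) -> int:
        return int(self.waveforms.shape[0])


def cut_waveforms(
    band_trace: Sequence[float], events: SpikeEvents, config: DetectionConfig, band_index: int = 0
) -> WaveformSet:
    """Cut L-sample windows around each event from one band's trace.

    Row j covers 1-based samples ``Pj-k+1 .. Pj+L-k`` of the trace, so the
    detection band's absolute extremum lands at 1-based column ``k``.  The
    same event indices are applied to every band, keeping rows time-locked
    across bands.
    """
    x = np.asarray(band_trace, dtype=np.float64)
    P = events.peak_indices
    L, k = config.L, config.k
    if P.size:
        start = P - (k - 1)
        stop = P + (L - k)
        if start.min() < 0 or stop.max() > x.size - 1:
            raise IndexError("event window leaves the trace; events were not pre-filtered")
        rows = x[start[:, None] + np.arange(L)[None, :]]
    else:
        rows = np.empty((0, L), dtype=np.float64)
    return WaveformSet(waveforms=rows, band_index=band_index, config=config)


@dataclass(frozen=True)
class CompositeWaveforms:
    """N x (B*L) splice of the per-band waveform sets, in bank order."""

    matrix: np.ndarray
    band_boundaries: tuple[tuple[int, int], ...]

    @property
    def n_events(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_bands(self) -> int:
        return len(self.band_boundaries)

    def band(self, i: int) -> np.ndarray:
        """Columns of band ``i`` (bank order), recovered bit-exactly."""
        start, stop = self.band_boundaries[i]
        return self.matrix[:, start:stop]


def assemble_composite(per_band: Sequence[WaveformSet]) -> CompositeWaveforms:
    """Concatenate per-band waveform sets row-wise into composite waveforms."""
    if len(per_band) == 0:
        raise ValueError("need at least one waveform set")
    n0, L0 = per_band[0].waveforms.shape
    for ws in per_band[1:]:
        if ws.waveforms.shape != (n0, L0):
            raise ValueError(
                f"waveform set shape {ws.waveforms.shape} does not match {(n0, L0)}"
            )
    matrix = np.hstack([ws.waveforms for ws in per_band])
    bounds = tuple((i * L0, (i + 1) * L0) for i in range(len(per_band)))
    return CompositeWaveforms(matrix=matrix, band_boundaries=bounds)
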