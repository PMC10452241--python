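"""Parallel Butterworth band-pass filtering of extracellular recordings.

The front end of the sorter: the raw voltage trace ``D`` is passed through a
bank of band-pass filters with a shared upper corner and ascending lower
corners (low / medium / high bands, ``Dl``, ``Dm``, ``Dh``).  The lowest band
is the *detection band* — thresholding and peak finding happen there — while
the higher bands progressively attenuate the large, slow depolarization lobe
and emphasise fast structure in the hyperpolarization tail.

Filters are realized as cascaded second-order sections (SOS) for numerical
stability at small corner/Nyquist ratios.  The default application mode is a
single causal forward pass with zero initial state; a ``zero_phase``
(forward-backward) mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "InvalidBandError",
    "RawRecording",
    "BandSpec",
    "FilterBank",
    "FilterCoefficients",
    "FilteredBands",
    "design_bandpass",
    "apply_filter",
    "filter_bank_apply",
]

FilterMode = Literal["causal", "zero_phase"]


class InvalidBandError(ValueError):
    """A band specification is unusable at the given sampling rate."""


@dataclass(frozen=True)
class RawRecording:
    """A sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        Voltage values (arbitrary units, typically µV). Stored as a 1-D
        float64 array; must be finite and of length >= 2.
    rate_hz
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            arr = arr.reshape(-1)
        if arr.size < 2:
            raise ValueError("recording must contain at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("recording contains non-finite samples")
        if not self.rate_hz > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "rate_hz", float(self.rate_hz))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class BandSpec:
    """One band of the filter bank: corner frequencies in Hz and design order."""

    low_cut_hz: float
    high_cut_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if not self.low_cut_hz > 0:
            raise InvalidBandError(f"low corner must be positive, got {self.low_cut_hz}")
        if not self.high_cut_hz > self.low_cut_hz:
            raise InvalidBandError(
                f"high corner ({self.high_cut_hz}) must exceed low corner ({self.low_cut_hz})"
            )
        if self.order < 1:
            raise InvalidBandError(f"filter order must be >= 1, got {self.order}")

    def validate_for_rate(self, rate_hz: float) -> None:
        nyquist = rate_hz / 2.0
        if self.high_cut_hz >= nyquist:
            raise InvalidBandError(
                f"high corner {self.high_cut_hz} Hz is at/above Nyquist "
                f"({nyquist} Hz at {rate_hz} Hz sampling)"
            )

    def __str__(self) -> str:
        return f"{self.low_cut_hz:g}:{self.high_cut_hz:g}"


@dataclass(frozen=True)
class FilterBank:
    """Ordered band specifications; the first (lowest-corner) band is the
    detection band."""

    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        bands = tuple(self.bands)
        if len(bands) < 1:
            raise InvalidBandError("filter bank needs at least one band")
        lows = [b.low_cut_hz for b in bands]
        if lows != sorted(lows):
            raise InvalidBandError("bands must be ordered by ascending low corner")
        object.__setattr__(self, "bands", bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def detection_band(self) -> BandSpec:
        return self.bands[0]

    @classmethod
    def from_string(cls, spec: str, order: int = 4) -> "FilterBank":
        """Parse a ``"LOW:HIGH,LOW:HIGH,..."`` Hz specification string."""
        bands = []
        for part in spec.split(","):
            part = part.strip()
            if not part:
                continue
            try:
                low, high = part.split(":")
                bands.append(BandSpec(float(low), float(high), order=order))
            except ValueError as exc:
                if isinstance(exc, InvalidBandError):
                    raise
                raise InvalidBandError(f"cannot parse band {part!r}; expected LOW:HIGH") from exc
        return cls(tuple(bands))

    def to_string(self) -> str:
        return ",".join(str(b) for b in self.bands)


@dataclass(frozen=True)
class FilterCoefficients:
    """A designed band-pass realization (second-order sections) bound to a rate."""

    sos: np.ndarray
    band: BandSpec
    rate_hz: float

    def frequency_response(self, freqs_hz: Sequence[float]) -> np.ndarray:
        """Complex transfer function evaluated at the given frequencies (Hz)."""
        _, h = signal.sosfreqz(self.sos, worN=np.asarray(freqs_hz, dtype=float), fs=self.rate_hz)
        return h

    def magnitude_db(self, freqs_hz: Sequence[float]) -> np.ndarray:
        h = np.abs(self.frequency_response(freqs_hz))
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(h)

    def midband_group_delay_s(self) -> float:
        """Group delay (seconds) at the geometric mid-band frequency — the
        deterministic detection latency a causal pass introduces."""
        b, a = signal.sos2tf(self.sos)
        mid = float(np.sqrt(self.band.low_cut_hz * self.band.high_cut_hz))
        _, gd = signal.group_delay((b, a), w=np.array([mid]), fs=self.rate_hz)
        return float(gd[0] / self.rate_hz)


def design_bandpass(band: BandSpec, rate_hz: float) -> FilterCoefficients:
    """Design a Butterworth band-pass filter (−3 dB at both corners).

    ``band.order`` is the Butterworth design order of the band-pass prototype
    (an order-4 design yields 8 poles).
    """
    if not rate_hz > 0:
        raise InvalidBandError(f"sampling rate must be positive, got {rate_hz}")
    band.validate_for_rate(rate_hz)
    sos = signal.butter(
        band.order,
        [band.low_cut_hz, band.high_cut_hz],
        btype="bandpass",
        fs=rate_hz,
        output="sos",
    )
    return FilterCoefficients(sos=sos, band=band, rate_hz=float(rate_hz))


def _filter_array(x: np.ndarray, coeffs: FilterCoefficients, mode: FilterMode) -> np.ndarray:
    if mode == "causal":
        return signal.sosfilt(coeffs.sos, x)
    if mode == "zero_phase":
        return signal.sosfiltfilt(coeffs.sos, x)
    raise ValueError(f"unknown filter mode {mode!r}")


def apply_filter(
    recording: RawRecording, coeffs: FilterCoefficients, mode: FilterMode = "causal"
) -> np.ndarray:
    """Apply a designed filter to a recording; returns a same-length trace.

    The default mode is a causal forward pass from zero initial state.
    """
    if recording.n_samples == 0:
        raise ValueError("cannot filter an empty recording")
    if abs(recording.rate_hz - coeffs.rate_hz) > 1e-9 * coeffs.rate_hz:
        raise InvalidBandError(
            f"filter designed for {coeffs.rate_hz} Hz applied to {recording.rate_hz} Hz recording"
        )
    return _filter_array(recording.samples, coeffs, mode)


@dataclass(frozen=True)
class FilteredBands:
    """Per-band filtered traces, in bank order; index 0 is the detection band."""

    traces: tuple[np.ndarray, ...]
    bank: FilterBank
    rate_hz: float

    @property
    def detection_trace(self) -> np.ndarray:
        return self.traces[0]

    @property
    def n_bands(self) -> int:
        return len(self.traces)


def filter_bank_apply(
    recording: RawRecording, bank: FilterBank, mode: FilterMode = "causal"
) -> FilteredBands:
    """Filter a recording through every band of the bank, in bank order."""
    traces = tuple(
        apply_filter(recording, design_bandpass(band, recording.rate_hz), mode)
        for band in bank.bands
    )
    return FilteredBands(traces=traces, bank=bank, rate_hz=recording.rate_hz)
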