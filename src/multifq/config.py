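"""Pipeline configuration and dataset profiles.

A :class:`PipelineConfig` carries everything the runner needs: the filter
bank, detection parameters, feature/cluster settings and evaluation
tolerances.  Two presets ship with the package:

``waveclus25k``
    25 kHz simulated-benchmark convention: bands 300/700/1000–6000 Hz,
    64-sample cuts aligned at the 20th point, 0.5 ms match tolerance.
``hc10k``
    10 kHz paired-recording convention: bands 300/500/700–3000 Hz,
    32-sample cuts aligned at the 11th point, 0.3 ms match tolerance
    (the intracellular-matching rule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import yaml

from .detection import DetectionConfig
from .filtering import BandSpec, FilterBank

__all__ = ["PipelineConfig", "PROFILES", "get_profile"]


@dataclass(frozen=True)
class PipelineConfig:
    rate_hz: float
    bank: FilterBank
    detection: DetectionConfig
    n_components: int = 3
    K: int = 3
    seed: int = 0
    restarts: int = 10
    filter_mode: str = "causal"
    match_tolerance_s: float = 5e-4
    overlap_window_s: Optional[float] = None  # None -> L / rate
    profile: Optional[str] = None

    def __post_init__(self) -> None:
        for band in self.bank.bands:
            band.validate_for_rate(self.rate_hz)
        if self.detection.k > self.detection.L:
            raise ValueError("alignment index k must not exceed cut length L")

    @property
    def resolved_overlap_window_s(self) -> float:
        if self.overlap_window_s is not None:
            return self.overlap_window_s
        return self.detection.L / self.rate_hz

    def to_dict(self) -> dict:
        return {
            "rate_hz": self.rate_hz,
            "bands": self.bank.to_string(),
            "filter_order": self.bank.bands[0].order,
            "detection": {
                "L": self.detection.L,
                "k": self.detection.k,
                "multiplier": self.detection.multiplier,
                "polarity": self.detection.polarity,
                "min_peak_spacing_samples": self.detection.min_peak_spacing_samples,
            },
            "n_components": self.n_components,
            "K": self.K,
            "seed": self.seed,
            "restarts": self.restarts,
            "filter_mode": self.filter_mode,
            "match_tolerance_s": self.match_tolerance_s,
            "overlap_window_s": self.overlap_window_s,
            "profile": self.profile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        det = d.get("detection", {})
        return cls(
            rate_hz=float(d["rate_hz"]),
            bank=FilterBank.from_string(d["bands"], order=int(d.get("filter_order", 4))),
            detection=DetectionConfig(
                L=int(det["L"]),
                k=int(det["k"]),
                multiplier=float(det.get("multiplier", 4.0)),
                polarity=det.get("polarity", "both"),
                min_peak_spacing_samples=det.get("min_peak_spacing_samples"),
            ),
            n_components=int(d.get("n_components", 3)),
            K=int(d.get("K", 3)),
            seed=int(d.get("seed", 0)),
            restarts=int(d.get("restarts", 10)),
            filter_mode=d.get("filter_mode", "causal"),
            match_tolerance_s=float(d.get("match_tolerance_s", 5e-4)),
            overlap_window_s=d.get("overlap_window_s"),
            profile=d.get("profile"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def with_bank(self, bank: FilterBank) -> "PipelineConfig":
        return replace(self, bank=bank)


def _waveclus25k(K: int = 3, seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        rate_hz=25_000.0,
        bank=FilterBank.from_string("300:6000,700:6000,1000:6000"),
        # negative polarity: extracellular somatic spikes deflect downward,
        # and signed detection keeps the alignment point unique (the positive
        # recovery lobe never competes for the extremum).  Censor = L: one
        # detection per cut window, suppressing within-spike re-crossings of
        # the threshold by filter ringing.
        detection=DetectionConfig(L=64, k=20, polarity="negative", min_peak_spacing_samples=64),
        K=K,
        seed=seed,
        match_tolerance_s=5e-4,
        profile="waveclus25k",
    )


def _hc10k(K: int = 3, seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        rate_hz=10_000.0,
        bank=FilterBank.from_string("300:3000,500:3000,700:3000"),
        detection=DetectionConfig(L=32, k=11, polarity="negative", min_peak_spacing_samples=32),
        K=K,
        seed=seed,
        match_tolerance_s=3e-4,
        profile="hc10k",
    )


PROFILES = {"waveclus25k": _waveclus25k, "hc10k": _hc10k}


def get_profile(name: str, K: int = 3, seed: int = 0) -> PipelineConfig:
    """Return a preset configuration by name (``waveclus25k`` or ``hc10k``)."""
    try:
        return PROFILES[name](K=K, seed=seed)
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(PROFILES)}") from None
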