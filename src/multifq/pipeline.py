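"""The end-to-end sorting pipeline and the band-sweep experiment.

``run_pipeline`` chains the stages: multi-band filtering → robust threshold
on the detection band → peak detection → per-band cutting at the shared
peak indices → composite splicing → PCA → k-means, and, when ground truth
is supplied, scores the result.  With a single-band bank the pipeline
reduces exactly to the classical single-filter PCA + k-means sorter, which
is the baseline the composite method is compared against.

``band_sweep`` reruns the single-band pipeline across candidate cut-off
frequencies and tabulates the chosen metric — the "which cut-off is best
for this data?" experiment as a reusable routine.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .config import PipelineConfig
from .detection import (
    CompositeWaveforms,
    SpikeEvents,
    Threshold,
    assemble_composite,
    compute_threshold,
    cut_waveforms,
    detect_peaks,
)
from .evaluation import (
    EventMatching,
    GroundTruth,
    MetricsReport,
    interclass_separation,
    match_events,
    overlap_mask,
    partial_truth_metrics,
    sorting_accuracy,
)
from .features_clustering import (
    ClusterLabels,
    FeatureMatrix,
    kmeans_cluster,
    pca_fit_transform,
)
from .filtering import BandSpec, FilterBank, FilteredBands, RawRecording, filter_bank_apply

__all__ = ["SortingResult", "PipelineStageError", "run_pipeline", "band_sweep"]


class PipelineStageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class SortingResult:
    """Everything one pipeline run produced, keyed consistently by event."""

    events: SpikeEvents
    threshold: Threshold
    filtered: FilteredBands
    composite: CompositeWaveforms
    features: FeatureMatrix
    labels: ClusterLabels
    config: PipelineConfig
    metrics: Optional[MetricsReport] = None
    matching: Optional[EventMatching] = None
    timings_s: Optional[dict] = None


def _evaluate(
    events: SpikeEvents,
    features: FeatureMatrix,
    labels: ClusterLabels,
    truth: GroundTruth,
    config: PipelineConfig,
) -> tuple[MetricsReport, EventMatching]:
    # remove the causal filter bank's deterministic detection latency
    # (design-derived, data-independent) before tolerance matching
    delay_s = 0.0
    if config.filter_mode == "causal":
        from .filtering import design_bandpass

        delay_s = design_bandpass(
            config.bank.detection_band, config.rate_hz
        ).midband_group_delay_s()
    det_times = events.peak_times_s - delay_s
    matching = match_events(det_times, truth.spike_times_s, config.match_tolerance_s)
    n_matched = matching.n_matched
    n_missed = len(matching.unmatched_truth)
    n_spurious = len(matching.unmatched_detected)

    sep_matrix, sep_mean = (None, None)
    if labels.K >= 1 and len(labels.empty_clusters) == 0 and events.n_events > 0:
        sep_matrix, sep_mean = interclass_separation(features, labels)

    if truth.kind == "full":
        overlaps = overlap_mask(
            truth.spike_times_s, truth.unit_labels, config.resolved_overlap_window_s
        )
        pred, true = [], []
        for det_i, tru_j in matching.pairs:
            if not overlaps[tru_j]:
                pred.append(labels.labels[det_i])
                true.append(truth.unit_labels[tru_j])
        accuracy = sorting_accuracy(pred, true) if pred else None
        report = MetricsReport(
            accuracy=accuracy,
            separation_matrix=sep_matrix,
            separation_mean=sep_mean,
            n_matched=n_matched,
            n_missed=n_missed,
            n_spurious=n_spurious,
        )
    else:
        pm = partial_truth_metrics(matching, labels.labels, truth)
        report = MetricsReport(
            separation_matrix=sep_matrix,
            separation_mean=sep_mean,
            precision=pm["precision"],
            recall=pm["recall"],
            f1=pm["f1"],
            tp=pm["tp"],
            fp=pm["fp"],
            tn=pm["tn"],
            fn=pm["fn"],
            n_matched=n_matched,
            n_missed=n_missed,
            n_spurious=n_spurious,
        )
    return report, matching


def run_pipeline(
    recording: RawRecording,
    config: PipelineConfig,
    truth: Optional[GroundTruth] = None,
    feature_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    cluster_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> SortingResult:
    """Run the full sorting pipeline on one recording.

    ``feature_fn`` / ``cluster_fn`` are backend hooks (N x M -> N x d and
    N x d -> labels); by default PCA and seeded k-means are used.  The result
    is fully determined by (recording, config).
    """
    timings: dict[str, float] = {}

    def stage(name: str, fn: Callable, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        return out

    filtered = stage("filtering", filter_bank_apply, recording, config.bank, config.filter_mode)
    threshold = stage(
        "threshold", compute_threshold, filtered.detection_trace, config.detection.multiplier
    )
    events = stage(
        "detection",
        detect_peaks,
        filtered.detection_trace,
        threshold,
        config.detection,
        recording.rate_hz,
    )
    per_band = stage(
        "cutting",
        lambda: [
            cut_waveforms(trace, events, config.detection, band_index=i)
            for i, trace in enumerate(filtered.traces)
        ],
    )
    composite = stage("composite", assemble_composite, per_band)

    if feature_fn is not None:
        scores = stage("features", feature_fn, composite.matrix)
        features = FeatureMatrix(
            scores=np.asarray(scores, dtype=np.float64),
            explained_variance=np.full(np.asarray(scores).shape[1], np.nan),
            mean_vector=composite.matrix.mean(axis=0),
            components=np.empty((0, composite.matrix.shape[1])),
        )
    else:
        features = stage("features", pca_fit_transform, composite, config.n_components)

    if cluster_fn is not None:
        raw_labels = np.asarray(stage("clustering", cluster_fn, features.scores), dtype=np.int64)
        labels = ClusterLabels(
            labels=raw_labels, K=int(raw_labels.max()) + 1 if raw_labels.size else config.K,
            inertia=float("nan"), seed=config.seed,
        )
    else:
        labels = stage(
            "clustering",
            kmeans_cluster,
            features,
            config.K,
            config.seed,
            config.restarts,
        )

    metrics = matching = None
    if truth is not None:
        metrics, matching = stage("evaluation", _evaluate, events, features, labels, truth, config)

    return SortingResult(
        events=events,
        threshold=threshold,
        filtered=filtered,
        composite=composite,
        features=features,
        labels=labels,
        config=config,
        metrics=metrics,
        matching=matching,
        timings_s=timings,
    )


def band_sweep(
    recording: RawRecording,
    candidate_bands: Sequence[Union[BandSpec, float]],
    config: PipelineConfig,
    truth: GroundTruth,
    feature_fn: Optional[Callable] = None,
    cluster_fn: Optional[Callable] = None,
) -> list[tuple[BandSpec, MetricsReport]]:
    """Run the SINGLE-band pipeline once per candidate cut-off and collect
    metrics — the cut-off-frequency sweep experiment.

    Candidates given as bare numbers are low corners paired with the
    configured detection band's upper corner.
    """
    out: list[tuple[BandSpec, MetricsReport]] = []
    ref = config.bank.detection_band
    for cand in candidate_bands:
        band = cand if isinstance(cand, BandSpec) else BandSpec(
            float(cand), ref.high_cut_hz, order=ref.order
        )
        cfg = config.with_bank(FilterBank((band,)))
        result = run_pipeline(recording, cfg, truth, feature_fn=feature_fn, cluster_fn=cluster_fn)
        out.append((band, result.metrics))
    return out
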