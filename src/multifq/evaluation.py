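"""Scoring sorted output against full or partial ground truth.

Detected events are matched to true events one-to-one by time proximity
within a strict tolerance (0.3 ms for intracellularly verified "marked"
spikes; 0.5 ms default for fully simulated truth).  Over matched events,
sorting accuracy is the agreement fraction under the cluster-to-unit
assignment that maximizes total agreement; cluster quality is summarized by
the inter-class separation, the squared Euclidean distance between cluster
centers in feature space.  With partial truth (only one unit's spikes are
verified) the problem is binary: the predicted cluster holding the most
marked spikes is the positive class, scored with precision, recall and F1.
Events with a neighbouring event closer than one cut window are "overlaps"
and are excluded from accuracy scoring rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .features_clustering import ClusterLabels, FeaturesLike, _as_features

__all__ = [
    "GroundTruth",
    "EventMatching",
    "MetricsReport",
    "match_events",
    "sorting_accuracy",
    "interclass_separation",
    "partial_truth_metrics",
    "overlap_mask",
]


@dataclass(frozen=True)
class GroundTruth:
    """True spike times and unit labels.

    ``kind="full"`` labels every event; ``kind="partial"`` marks only one
    verified unit (all events present carry that unit's label), mirroring
    paired intra/extracellular recordings where only one neuron's spikes can
    be confirmed.
    """

    spike_times_s: np.ndarray
    unit_labels: np.ndarray
    kind: Literal["full", "partial"] = "full"
    marked_unit: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=np.float64)
        u = np.asarray(self.unit_labels, dtype=np.int64)
        if t.shape != u.shape:
            raise ValueError("times and unit labels must have equal length")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.kind == "partial":
            units = np.unique(u)
            if units.size != 1:
                raise ValueError("partial ground truth must mark exactly one unit")
            object.__setattr__(self, "marked_unit", int(units[0]))
        elif self.kind != "full":
            raise ValueError(f"unknown ground-truth kind {self.kind!r}")
        object.__setattr__(self, "spike_times_s", t)
        object.__setattr__(self, "unit_labels", u)

    @property
    def n_events(self) -> int:
        return int(self.spike_times_s.size)

    @property
    def units(self) -> np.ndarray:
        return np.unique(self.unit_labels)


@dataclass(frozen=True)
class EventMatching:
    """One-to-one (detected, truth) index pairs within a time tolerance."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_detected: tuple[int, ...]
    unmatched_truth: tuple[int, ...]
    tolerance_s: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_events(
    detected_times_s: Sequence[float],
    truth_times_s: Sequence[float],
    tolerance_s: float,
) -> EventMatching:
    """Greedy nearest-in-time one-to-one matching within a STRICT tolerance.

    Candidate pairs are accepted in order of increasing |dt| (ties break
    toward the earlier detected index, then the earlier truth index); each
    event participates in at most one pair.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance must be non-negative")
    det = np.asarray(detected_times_s, dtype=np.float64)
    tru = np.asarray(truth_times_s, dtype=np.float64)
    if det.size > 1 and np.any(np.diff(det) < 0):
        raise ValueError("detected times must be sorted")
    if tru.size > 1 and np.any(np.diff(tru) < 0):
        raise ValueError("truth times must be sorted")

    # enumerate feasible pairs via a sliding window over the sorted truth times
    cand: list[tuple[float, int, int]] = []
    j0 = 0
    for i, t in enumerate(det):
        while j0 < tru.size and tru[j0] < t - tolerance_s:
            j0 += 1
        j = j0
        while j < tru.size and tru[j] <= t + tolerance_s:
            dt = abs(t - tru[j])
            if dt < tolerance_s:  # strict
                cand.append((dt, i, j))
            j += 1
    cand.sort()

    used_det = np.zeros(det.size, dtype=bool)
    used_tru = np.zeros(tru.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if not used_det[i] and not used_tru[j]:
            used_det[i] = True
            used_tru[j] = True
            pairs.append((i, j))
    pairs.sort()
    return EventMatching(
        pairs=tuple(pairs),
        unmatched_detected=tuple(int(i) for i in np.flatnonzero(~used_det)),
        unmatched_truth=tuple(int(j) for j in np.flatnonzero(~used_tru)),
        tolerance_s=float(tolerance_s),
    )


def sorting_accuracy(pred_labels: Sequence[int], truth_labels: Sequence[int]) -> float:
    """Fraction of events labelled correctly under the best cluster-to-unit map.

    Cluster ids are arbitrary, so agreement is maximized over one-to-one
    assignments of predicted clusters to true units (rectangular assignment
    on the contingency table) before counting matches.
    """
    pred = np.asarray(pred_labels, dtype=np.int64)
    truth = np.asarray(truth_labels, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError("predicted and true label vectors must have equal length")
    n = pred.size
    if n == 0:
        raise ValueError("cannot score an empty label vector")
    pu, pinv = np.unique(pred, return_inverse=True)
    tu, tinv = np.unique(truth, return_inverse=True)
    table = np.zeros((pu.size, tu.size), dtype=np.int64)
    np.add.at(table, (pinv, tinv), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / n)


def interclass_separation(
    features: FeaturesLike, labels: ClusterLabels | Sequence[int]
) -> tuple[np.ndarray, float]:
    """Squared distances between cluster centers in feature space.

    Returns the K x K symmetric zero-diagonal matrix of pairwise squared
    Euclidean distances between cluster mean vectors, and its mean over
    unordered pairs as a scalar summary (0.0 when K == 1).
    """
    X = _as_features(features)
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels, dtype=np.int64)
    if lab.size != X.shape[0]:
        raise ValueError("labels length must match feature rows")
    clusters = np.unique(lab)
    K = clusters.size
    centers = np.empty((K, X.shape[1]))
    for a, c in enumerate(clusters):
        members = lab == c
        if not members.any():
            raise ValueError(f"cluster {c} is empty")
        centers[a] = X[members].mean(axis=0)
    diff = centers[:, None, :] - centers[None, :, :]
    sep = np.einsum("abd,abd->ab", diff, diff)
    if K > 1:
        iu = np.triu_indices(K, k=1)
        mean = float(sep[iu].mean())
    else:
        mean = 0.0
    return sep, mean


def partial_truth_metrics(
    matching: EventMatching,
    pred_labels: Sequence[int],
    truth: GroundTruth,
) -> dict:
    """Binary precision/recall/F1 against a single verified ("marked") unit.

    The positive class is the predicted cluster containing the most marked
    spikes.  TP = marked spikes in that cluster; FP = unmarked spikes in it;
    FN = marked spikes outside it, including marked events never detected;
    TN = unmarked spikes outside it (reported, unused by the three metrics).
    Zero denominators yield 0.
    """
    if truth.kind != "partial":
        raise ValueError("partial_truth_metrics requires partial ground truth")
    if truth.n_events == 0:
        raise ValueError("no marked spikes in the ground truth")
    pred = np.asarray(pred_labels, dtype=np.int64)

    marked_det = np.zeros(pred.size, dtype=bool)
    for i, _ in matching.pairs:
        marked_det[i] = True

    if marked_det.any():
        clusters, counts = np.unique(pred[marked_det], return_counts=True)
        positive = int(clusters[int(np.argmax(counts))])
        in_pos = pred == positive
        tp = int(np.sum(in_pos & marked_det))
        fp = int(np.sum(in_pos & ~marked_det))
        fn_detected = int(np.sum(~in_pos & marked_det))
        tn = int(np.sum(~in_pos & ~marked_det))
    else:
        positive = None
        tp = fp = fn_detected = 0
        tn = int(pred.size)
    fn = fn_detected + len(matching.unmatched_truth)

    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {
        "positive_cluster": positive,
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def overlap_mask(
    truth_times_s: Sequence[float],
    unit_labels: Optional[Sequence[int]] = None,
    window_s: float = 0.0,
) -> np.ndarray:
    """Flag events with ANY neighbouring event (any unit) strictly closer
    than ``window_s``; flagged events are excluded from accuracy scoring."""
    t = np.asarray(truth_times_s, dtype=np.float64)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("truth times must be sorted")
    mask = np.zeros(t.size, dtype=bool)
    if t.size > 1 and window_s > 0:
        gaps = np.diff(t)
        close = gaps < window_s  # strict: spacing == window is not an overlap
        mask[:-1] |= close
        mask[1:] |= close
    return mask


@dataclass(frozen=True)
class MetricsReport:
    """Sorting metrics bundle; fields are None where the truth kind does not
    define them (e.g. precision/recall for full truth)."""

    accuracy: Optional[float] = None
    separation_matrix: Optional[np.ndarray] = None
    separation_mean: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    tp: Optional[int] = None
    fp: Optional[int] = None
    tn: Optional[int] = None
    fn: Optional[int] = None
    n_matched: int = 0
    n_missed: int = 0
    n_spurious: int = 0

    def to_dict(self) -> dict:
        sep = self.separation_matrix
        return {
            "accuracy": self.accuracy,
            "separation_mean": self.separation_mean,
            "separation_matrix": None if sep is None else np.asarray(sep).tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_matched": self.n_matched,
            "n_missed": self.n_missed,
            "n_spurious": self.n_spurious,
        }
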