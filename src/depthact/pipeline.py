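"""Inference protocol and evaluation: per-minute Viterbi decoding of
symbol-duplicated windows, frame accuracy, confusion matrices, aggregation.

Recordings run at 1 fps.  Every five person crops produce one descriptor and
hence one observation symbol; the symbol is duplicated five times so the
observation stream stays frame-aligned (60 frames -> 12 windows -> 60
observations).  Decoding happens once per minute: each 60-frame chunk is an
independent Viterbi run, with no state carried across chunk boundaries.
Frames without a detected person are marked and excluded from both decoding
and scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .actions import ACTION_NAMES, N_STATES, NO_PERSON
from .features import WINDOW_LENGTH, window_descriptor, windows_from_sequence
from .hmm import (
    HmmModel,
    LabeledDescriptors,
    SymbolAssigner,
    TrainingDatasets,
    baum_welch,
    compute_state_templates,
    estimate_emissions,
    estimate_transitions,
    MeanTemplateAssigner,
    train_knn,
    train_svm,
    uniform_pi,
    viterbi,
)

logger = logging.getLogger(__name__)


def _round_half_up(x: float, decimals: int = 2) -> float:
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class ActionSequence:
    """Per-frame action labels (ground truth or predictions) at a fixed rate.

    ``labels`` holds state indices 0..4 or the ``NO_PERSON`` marker (-1).
    """

    labels: np.ndarray
    fps: float = 1.0
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        bad = (self.labels != NO_PERSON) & ((self.labels < 0) | (self.labels >= N_STATES))
        if bad.any():
            raise ValueError("labels must be state indices 0..4 or the no-person marker")

    def __len__(self) -> int:
        return self.labels.size


def frames_to_observations(
    crops: Sequence[np.ndarray],
    assigner: SymbolAssigner,
    epsilon: float = 0.05,
) -> np.ndarray:
    """Frame-aligned observation symbols for a run of person crops.

    Each non-overlapping five-crop window yields one descriptor, the
    assigner turns it into a symbol, and the symbol is duplicated five
    times.  Trailing frames short of a full window inherit the last
    window's symbol, so the output always matches the input length.
    """
    if len(crops) < WINDOW_LENGTH:
        raise ValueError(f"need at least {WINDOW_LENGTH} crops, got {len(crops)}")
    windows = windows_from_sequence(crops)
    symbols = np.array(
        [assigner.assign(window_descriptor(w, epsilon)) for w in windows], dtype=np.int64
    )
    obs = np.repeat(symbols, WINDOW_LENGTH)
    remainder = len(crops) - obs.size
    if remainder:
        obs = np.concatenate([obs, np.full(remainder, symbols[-1])])
    return obs


def predict_actions(
    crops: Sequence[Optional[np.ndarray]],
    model: HmmModel,
    assigner: SymbolAssigner,
    fps: float = 1.0,
    chunk_minutes: float = 1.0,
    epsilon: float = 0.05,
) -> ActionSequence:
    """Decode a full recording, one independent Viterbi run per minute chunk.

    ``crops[i]`` is the normalized depth crop of frame ``i`` or ``None``
    when no person was detected.  Within each chunk the detected frames are
    compacted, converted to duplicated symbols, and decoded; no-person
    frames receive the marker.  A chunk with fewer than five detected
    frames cannot form a window and is emitted as all markers with a
    warning.
    """
    n = len(crops)
    if n == 0:
        raise ValueError("empty recording")
    chunk_len = max(1, int(round(60.0 * fps * chunk_minutes)))
    out = np.full(n, NO_PERSON, dtype=np.int64)
    for lo in range(0, n, chunk_len):
        hi = min(lo + chunk_len, n)
        present = [i for i in range(lo, hi) if crops[i] is not None]
        if len(present) < WINDOW_LENGTH:
            if present or hi - lo > 0:
                logger.warning(
                    "chunk %d-%d has %d detected frames (<%d); emitting no-person markers",
                    lo, hi, len(present), WINDOW_LENGTH,
                )
            continue
        obs = frames_to_observations([crops[i] for i in present], assigner, epsilon)
        path = viterbi(model, obs)
        out[np.asarray(present)] = path
    return ActionSequence(labels=out, fps=fps)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """5 x 5 integer counts; rows = actual action, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STATES, N_STATES):
            raise ValueError(f"confusion matrix must be {N_STATES}x{N_STATES}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")


def accuracy(predicted: ActionSequence, truth: ActionSequence) -> float:
    """Frame accuracy in percent, rounded half-up to 2 decimals.

    Frames carrying the no-person marker in either sequence are excluded
    from numerator and denominator (50 correct of 60 evaluated -> 83.33).
    """
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(truth)}")
    keep = (predicted.labels != NO_PERSON) & (truth.labels != NO_PERSON)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no evaluable frames (all carry the no-person marker)")
    correct = int((predicted.labels[keep] == truth.labels[keep]).sum())
    return _round_half_up(100.0 * correct / n, 2)


def confusion(predicted: ActionSequence, truth: ActionSequence) -> ConfusionMatrix:
    """Per-frame confusion counts, marker frames skipped."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(truth)}")
    keep = (predicted.labels != NO_PERSON) & (truth.labels != NO_PERSON)
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    np.add.at(counts, (truth.labels[keep], predicted.labels[keep]), 1)
    return ConfusionMatrix(counts=counts)


def per_action_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row sum per action, in percent (NaN for empty rows)."""
    row = cm.counts.sum(axis=1).astype(np.float64)
    diag = np.diag(cm.counts).astype(np.float64)
    out = np.full(N_STATES, np.nan)
    nz = row > 0
    out[nz] = [ _round_half_up(v, 2) for v in 100.0 * diag[nz] / row[nz] ]
    return out


def overall_from_confusion(cm: ConfusionMatrix, decimals: int = 2) -> float:
    """Overall accuracy from confusion counts: 100 * trace / total."""
    total = int(cm.counts.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return _round_half_up(100.0 * np.trace(cm.counts) / total, decimals)


def aggregate_rooms(room_accuracies: Sequence[float]) -> float:
    """Unweighted mean of per-room accuracies, 2 decimals."""
    if len(room_accuracies) == 0:
        raise ValueError("no room accuracies to aggregate")
    return _round_half_up(float(np.mean(room_accuracies)), 2)


@dataclass
class EvaluationReport:
    """Overall %, per-action %, and the confusion matrix behind them."""

    overall_accuracy: float
    per_action_accuracy: np.ndarray
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        per_action = {
            ACTION_NAMES[j]: (None if np.isnan(v) else float(v))
            for j, v in enumerate(self.per_action_accuracy)
        }
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_action_accuracy": per_action,
            "confusion": self.confusion.counts.tolist(),
            "actions": ACTION_NAMES,
        }


def evaluate(predicted: ActionSequence, truth: ActionSequence) -> EvaluationReport:
    """Full report: overall accuracy, per-action accuracy, confusion matrix."""
    cm = confusion(predicted, truth)
    return EvaluationReport(
        overall_accuracy=accuracy(predicted, truth),
        per_action_accuracy=per_action_accuracy(cm),
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# model training orchestration
# ---------------------------------------------------------------------------

ASSIGNER_KINDS = ("mean", "knn", "svm")


@dataclass
class TrainedRecognizer:
    """A decodable model plus the symbol assigner it was estimated with."""

    model: HmmModel
    assigner: SymbolAssigner
    assigner_kind: str
    log_likelihoods: List[float]


def train_recognizer(
    datasets: TrainingDatasets,
    transition_labels: Sequence[int],
    assigner_kind: str = "svm",
    alpha_transitions: float = 1e-3,
    alpha_emissions: float = 1e-3,
    knn_k: int = 5,
    seed: int = 0,
    bw_max_iter: int = 100,
    bw_tol: float = 1e-4,
) -> TrainedRecognizer:
    """Estimate λ end-to-end and refine it with Baum-Welch.

    A comes from co-occurrence counts on the long training label sequence;
    the assigner (mean-template, k-NN, or linear SVM) is fitted on the
    training descriptor set; B comes from assigner-labeled held-out
    descriptors; π stays uniform.  Baum-Welch then refines A and B on the
    held-out set's duplicated symbol streams, one sequence per state.
    """
    if assigner_kind not in ASSIGNER_KINDS:
        raise ValueError(f"assigner_kind must be one of {ASSIGNER_KINDS}")
    A = estimate_transitions(transition_labels, alpha=alpha_transitions)
    if assigner_kind == "mean":
        assigner: SymbolAssigner = MeanTemplateAssigner(compute_state_templates(datasets.train))
    elif assigner_kind == "knn":
        assigner = train_knn(datasets.train, k=knn_k)
    else:
        assigner = train_svm(datasets.train, seed=seed)
    B = estimate_emissions(datasets.emission, assigner, alpha=alpha_emissions).B
    model = HmmModel(A=A, B=B, pi=uniform_pi())
    sequences = []
    for j in range(N_STATES):
        sym = assigner.assign_many(datasets.emission.for_state(j))
        sequences.append(np.repeat(sym, WINDOW_LENGTH))
    result = baum_welch(model, sequences, max_iter=bw_max_iter, tol=bw_tol)
    return TrainedRecognizer(
        model=result.model,
        assigner=assigner,
        assigner_kind=assigner_kind,
        log_likelihoods=result.log_likelihoods,
    )
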