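"""Five-state discrete hidden Markov model: estimation, training, decoding.

The action recognizer is a discrete HMM λ = (A, B, π) with five hidden
states (the actions) and five observation symbols v1..v5, one per state
template.  This module provides every estimation path the recognizer uses:

* π fixed uniform at 0.2 per state,
* A from label co-occurrence counts on a long training label sequence,
* B from classifier-assigned symbols on a held-out descriptor set, with
  three interchangeable symbol assigners (mean-template nearest distance,
  k-NN, linear SVM),
* Baum-Welch (EM) refinement of A and B on symbol sequences, and
* Viterbi maximum-probability state decoding.

Viterbi and Baum-Welch are implemented here directly (scaled arithmetic,
π held fixed); classifiers are delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import LinearSVC

from .actions import ACTION_NAMES, N_STATES, N_SYMBOLS, SYMBOL_NAMES

_ROW_SUM_ATOL = 1e-9
#: Probability floor applied after every Baum-Welch update to avoid
#: zero-probability lock-in.
PROB_FLOOR = 1e-8


def _check_stochastic(mat: np.ndarray, name: str) -> None:
    if np.any(mat < 0):
        raise ValueError(f"{name} has negative entries")
    sums = mat.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-8, rtol=0):
        raise ValueError(f"rows of {name} must sum to 1, got {sums}")


@dataclass
class HmmModel:
    """λ = (A, B, π): transition matrix, emission matrix, initial distribution.

    ``A[i, j]`` is P[q_t = S_j | q_{t-1} = S_i]; ``B[j, k]`` is
    P[O_t = v_k | q_t = S_j]; both 5 x 5 and row-stochastic; ``pi`` sums to 1.
    """

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if self.A.shape != (N_STATES, N_STATES):
            raise ValueError(f"A must be {N_STATES}x{N_STATES}, got {self.A.shape}")
        if self.B.shape != (N_STATES, N_SYMBOLS):
            raise ValueError(f"B must be {N_STATES}x{N_SYMBOLS}, got {self.B.shape}")
        if self.pi.shape != (N_STATES,):
            raise ValueError(f"pi must have length {N_STATES}, got {self.pi.shape}")
        _check_stochastic(self.A, "A")
        _check_stochastic(self.B, "B")
        _check_stochastic(self.pi[None, :], "pi")

    def to_dict(self) -> dict:
        return {
            "states": ACTION_NAMES,
            "symbols": SYMBOL_NAMES,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "pi": self.pi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(A=np.asarray(d["A"]), B=np.asarray(d["B"]), pi=np.asarray(d["pi"]))


def uniform_pi() -> np.ndarray:
    """Uniform initial state distribution: every action equally likely a priori."""
    return np.full(N_STATES, 1.0 / N_STATES)


def estimate_transitions(labels: Sequence[int], alpha: float = 0.0) -> np.ndarray:
    """Transition matrix from label co-occurrence counts.

    ``A[i, j] = (count(i->j) + alpha) / (count(i->.) + 5 alpha)`` over all
    consecutive pairs of the training label sequence (self-transitions
    included).  With ``alpha = 0`` a state never seen as a source gets a
    uniform row.
    """
    seq = np.asarray(labels, dtype=np.int64)
    if seq.ndim != 1 or seq.size < 2:
        raise ValueError("need a label sequence of length >= 2")
    if np.any(seq < 0) or np.any(seq >= N_STATES):
        raise ValueError("labels must be state indices in [0, 4]")
    counts = np.zeros((N_STATES, N_STATES), dtype=np.float64)
    np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    A = counts + alpha
    denom = totals + N_STATES * alpha
    empty = denom[:, 0] == 0
    denom[empty] = 1.0
    A = A / denom
    A[empty] = 1.0 / N_STATES
    return A


# ---------------------------------------------------------------------------
# symbol assignment (observation quantization)
# ---------------------------------------------------------------------------

@dataclass
class LabeledDescriptors:
    """Descriptor matrix ``X`` (n, D) with per-row state indices ``y``."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, D) with matching label vector y")

    def for_state(self, j: int) -> np.ndarray:
        return self.X[self.y == j]


@dataclass
class TrainingDatasets:
    """The two class-balanced descriptor sets the recognizer trains on.

    ``train`` fits the symbol assigner (900 sequences per state at full
    scale); ``emission`` is held out to estimate the emission matrix B and to
    drive Baum-Welch (100 per state at full scale).  Both scale down for
    fast tests.
    """

    train: LabeledDescriptors
    emission: LabeledDescriptors


@runtime_checkable
class SymbolAssigner(Protocol):
    """Contract: map descriptors to observation symbols, deterministically."""

    def assign(self, descriptor: np.ndarray) -> int:
        ...

    def assign_many(self, X: np.ndarray) -> np.ndarray:
        ...


@dataclass
class StateTemplates:
    """Per-state mean descriptors M1H..M5H, shape (5, D)."""

    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        if self.means.ndim != 2 or self.means.shape[0] != N_STATES:
            raise ValueError(f"templates must be ({N_STATES}, D), got {self.means.shape}")


def compute_state_templates(train: LabeledDescriptors) -> StateTemplates:
    """Componentwise mean descriptor per state (each state needs >= 1 row)."""
    means = []
    for j in range(N_STATES):
        rows = train.for_state(j)
        if rows.shape[0] == 0:
            raise ValueError(f"no descriptors for state {j} ({ACTION_NAMES[j]})")
        means.append(rows.mean(axis=0))
    return StateTemplates(means=np.stack(means))


@dataclass
class MeanTemplateAssigner:
    """Nearest state template under squared Euclidean distance.

    Ties go to the smallest state index.
    """

    templates: StateTemplates

    def assign(self, descriptor: np.ndarray) -> int:
        d = np.asarray(descriptor, dtype=np.float64)
        dist = ((self.templates.means - d[None, :]) ** 2).sum(axis=1)
        return int(np.argmin(dist))

    def assign_many(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        d2 = (
            (X**2).sum(axis=1, keepdims=True)
            - 2.0 * X @ self.templates.means.T
            + (self.templates.means**2).sum(axis=1)[None, :]
        )
        return np.argmin(d2, axis=1).astype(np.int64)


def assign_symbol_mean(descriptor: np.ndarray, templates: StateTemplates) -> int:
    """Symbol of one descriptor by nearest mean template (functional form)."""
    return MeanTemplateAssigner(templates).assign(descriptor)


@dataclass
class KnnAssigner:
    """k-nearest-neighbor symbol assigner (Euclidean, majority vote).

    Vote ties are broken toward the class with the smaller mean neighbor
    distance, then the smaller index.
    """

    _nn: NearestNeighbors
    _y: np.ndarray
    k: int

    def _vote(self, dist: np.ndarray, idx: np.ndarray) -> int:
        labels = self._y[idx]
        counts = np.bincount(labels, minlength=N_STATES)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if tied.size == 1:
            return int(tied[0])
        mean_d = np.array([dist[labels == c].mean() for c in tied])
        return int(tied[np.argmin(mean_d)])

    def assign(self, descriptor: np.ndarray) -> int:
        d = np.asarray(descriptor, dtype=np.float64)[None, :]
        dist, idx = self._nn.kneighbors(d)
        return self._vote(dist[0], idx[0])

    def assign_many(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        dist, idx = self._nn.kneighbors(X)
        return np.array([self._vote(dist[i], idx[i]) for i in range(X.shape[0])], dtype=np.int64)


def train_knn(train: LabeledDescriptors, k: int = 5) -> KnnAssigner:
    """Fit the k-NN symbol assigner on the training descriptor set."""
    present = np.unique(train.y)
    if present.size < N_STATES:
        raise ValueError(f"training set misses states {sorted(set(range(N_STATES)) - set(present))}")
    nn = NearestNeighbors(n_neighbors=min(k, train.X.shape[0]), metric="euclidean")
    nn.fit(train.X)
    return KnnAssigner(_nn=nn, _y=train.y.copy(), k=k)


@dataclass
class SvmAssigner:
    """Linear one-vs-rest SVM symbol assigner (C = 1, seeded)."""

    _clf: LinearSVC

    def assign(self, descriptor: np.ndarray) -> int:
        return int(self._clf.predict(np.asarray(descriptor, dtype=np.float64)[None, :])[0])

    def assign_many(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict(np.asarray(X, dtype=np.float64)).astype(np.int64)


def train_svm(train: LabeledDescriptors, seed: int = 0) -> SvmAssigner:
    """Fit the linear SVM symbol assigner on the training descriptor set."""
    present = np.unique(train.y)
    if present.size < N_STATES:
        raise ValueError(f"training set misses states {sorted(set(range(N_STATES)) - set(present))}")
    clf = LinearSVC(C=1.0, random_state=seed)
    clf.fit(train.X, train.y)
    return SvmAssigner(_clf=clf)


# ---------------------------------------------------------------------------
# emission estimation
# ---------------------------------------------------------------------------

@dataclass
class EmissionEstimate:
    """Emission matrix B plus the per-state magnitude evidence behind it.

    Each held-out descriptor contributes a unit-mass Gaussian kernel placed
    at its L2 magnitude (common per-state bandwidth = sample std of the
    magnitudes, floored at 1e-6).  Summing same-label kernels and dividing
    by the total mass reduces exactly to per-label relative frequency, which
    is what ``B`` holds; magnitudes and bandwidths are retained so alternate
    density readings can be swapped in.
    """

    B: np.ndarray
    magnitudes: Dict[int, np.ndarray]
    symbols: Dict[int, np.ndarray]
    bandwidths: Dict[int, float]


def estimate_emissions(
    emission: LabeledDescriptors,
    assigner: SymbolAssigner,
    alpha: float = 0.0,
) -> EmissionEstimate:
    """Estimate B row-by-row from assigner-labeled held-out descriptors.

    Row j: assign a symbol to every state-j descriptor, place a unit-mass
    normal at each descriptor's L2 magnitude, sum same-symbol masses and
    normalize — i.e. ``b_j(k) = (n_jk + alpha) / (n_j + 5 alpha)``.
    """
    B = np.zeros((N_STATES, N_SYMBOLS), dtype=np.float64)
    magnitudes: Dict[int, np.ndarray] = {}
    symbols: Dict[int, np.ndarray] = {}
    bandwidths: Dict[int, float] = {}
    for j in range(N_STATES):
        rows = emission.for_state(j)
        if rows.shape[0] == 0:
            raise ValueError(f"no held-out descriptors for state {j} ({ACTION_NAMES[j]})")
        sym = assigner.assign_many(rows)
        mags = np.linalg.norm(rows, axis=1)
        magnitudes[j] = mags
        symbols[j] = sym
        bandwidths[j] = max(float(mags.std()), 1e-6)
        counts = np.bincount(sym, minlength=N_SYMBOLS).astype(np.float64)
        B[j] = (counts + alpha) / (counts.sum() + N_SYMBOLS * alpha)
    return EmissionEstimate(B=B, magnitudes=magnitudes, symbols=symbols, bandwidths=bandwidths)


# ---------------------------------------------------------------------------
# Baum-Welch and Viterbi
# ---------------------------------------------------------------------------

def _validate_obs(obs: Sequence[int], name: str = "sequence") -> np.ndarray:
    o = np.asarray(obs, dtype=np.int64)
    if o.ndim != 1 or o.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D symbol sequence")
    if np.any(o < 0) or np.any(o >= N_SYMBOLS):
        raise ValueError(f"{name} contains symbols outside v1..v{N_SYMBOLS}")
    return o


def _forward_backward(
    A: np.ndarray, B: np.ndarray, pi: np.ndarray, obs: np.ndarray, seq_name: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward; returns (alpha, beta, scale, log-likelihood)."""
    T = obs.size
    alpha = np.zeros((T, N_STATES))
    beta = np.zeros((T, N_STATES))
    scale = np.zeros(T)
    alpha[0] = pi * B[:, obs[0]]
    scale[0] = alpha[0].sum()
    if scale[0] <= 0:
        raise ValueError(f"zero-probability {seq_name} under the model (t=0)")
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[:, obs[t]]
        scale[t] = alpha[t].sum()
        if scale[t] <= 0:
            raise ValueError(f"zero-probability {seq_name} under the model (t={t})")
        alpha[t] /= scale[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = A @ (B[:, obs[t + 1]] * beta[t + 1]) / scale[t + 1]
    return alpha, beta, scale, float(np.log(scale).sum())


@dataclass
class BaumWelchResult:
    """Refined model plus the per-iteration total log-likelihood trace."""

    model: HmmModel
    log_likelihoods: List[float] = field(default_factory=list)

    @property
    def n_iter(self) -> int:
        return len(self.log_likelihoods)


def baum_welch(
    model: HmmModel,
    sequences: Sequence[Sequence[int]],
    max_iter: int = 100,
    tol: float = 1e-4,
) -> BaumWelchResult:
    """EM re-estimation of A and B on discrete symbol sequences.

    π is held fixed (it is an assumption of the model, not a trained
    quantity).  Each iteration runs scaled forward-backward over every
    sequence, re-estimates A from expected transition counts and B from
    expected occupancy counts, floors probabilities at 1e-8 and
    renormalizes.  Stops when the total log-likelihood improves by less
    than ``tol`` or after ``max_iter`` iterations.  The log-likelihood
    trace is non-decreasing (EM guarantee, up to the flooring epsilon).
    """
    if not sequences:
        raise ValueError("need at least one observation sequence")
    obs_list = [_validate_obs(s, f"sequence {i}") for i, s in enumerate(sequences)]
    A, B, pi = model.A.copy(), model.B.copy(), model.pi.copy()
    history: List[float] = []
    for _ in range(max_iter):
        A_num = np.zeros((N_STATES, N_STATES))
        gamma_sum = np.zeros(N_STATES)          # occupancy over t = 0..T-2 (A denominator)
        B_num = np.zeros((N_STATES, N_SYMBOLS))
        B_den = np.zeros(N_STATES)
        total_ll = 0.0
        for i, obs in enumerate(obs_list):
            alpha, beta, scale, ll = _forward_backward(A, B, pi, obs, f"sequence {i}")
            total_ll += ll
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            T = obs.size
            for t in range(T - 1):
                xi = (
                    alpha[t][:, None]
                    * A
                    * (B[:, obs[t + 1]] * beta[t + 1])[None, :]
                    / scale[t + 1]
                )
                A_num += xi
                gamma_sum += gamma[t]
            np.add.at(B_num.T, obs, gamma)
            B_den += gamma.sum(axis=0)
        history.append(total_ll)
        if len(history) > 1 and history[-1] - history[-2] < tol:
            break
        new_A = A_num / np.where(gamma_sum == 0, 1.0, gamma_sum)[:, None]
        new_A[gamma_sum == 0] = A[gamma_sum == 0]
        new_B = B_num / np.where(B_den == 0, 1.0, B_den)[:, None]
        new_B[B_den == 0] = B[B_den == 0]
        A = np.maximum(new_A, PROB_FLOOR)
        A /= A.sum(axis=1, keepdims=True)
        B = np.maximum(new_B, PROB_FLOOR)
        B /= B.sum(axis=1, keepdims=True)
    return BaumWelchResult(model=HmmModel(A=A, B=B, pi=pi), log_likelihoods=history)


def viterbi(model: HmmModel, obs: Sequence[int]) -> np.ndarray:
    """Most probable hidden state path for a symbol sequence (log space).

    Ties break toward the smaller state index; the output has one state per
    observation.
    """
    o = _validate_obs(obs, "observations")
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logB = np.log(model.B)
        logpi = np.log(model.pi)
    T = o.size
    delta = np.zeros((T, N_STATES))
    psi = np.zeros((T, N_STATES), dtype=np.int64)
    delta[0] = logpi + logB[:, o[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA
        psi[t] = np.argmax(cand, axis=0)          # first max -> smallest index
        delta[t] = cand[psi[t], np.arange(N_STATES)] + logB[:, o[t]]
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def path_log_probability(model: HmmModel, obs: Sequence[int], path: Sequence[int]) -> float:
    """Joint log-probability of a state path and an observation sequence."""
    o = _validate_obs(obs, "observations")
    q = np.asarray(path, dtype=np.int64)
    if q.shape != o.shape:
        raise ValueError("path and observations must have equal length")
    with np.errstate(divide="ignore"):
        lp = np.log(model.pi[q[0]]) + np.log(model.B[q[0], o[0]])
        for t in range(1, o.size):
            lp += np.log(model.A[q[t - 1], q[t]]) + np.log(model.B[q[t], o[t]])
    return float(lp)


def sample(model: HmmModel, T: int, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Draw a (states, symbols) pair of length ``T`` from the model."""
    states = np.zeros(T, dtype=np.int64)
    symbols = np.zeros(T, dtype=np.int64)
    states[0] = rng.choice(N_STATES, p=model.pi)
    symbols[0] = rng.choice(N_SYMBOLS, p=model.B[states[0]])
    for t in range(1, T):
        states[t] = rng.choice(N_STATES, p=model.A[states[t - 1]])
        symbols[t] = rng.choice(N_SYMBOLS, p=model.B[states[t]])
    return states, symbols
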