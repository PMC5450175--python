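"""Markov models over adjacency-id states.

A tuple's *local transition matrix* T(V') counts consecutive adjacency-id
pairs over a run of tau snapshots (tau - 1 transitions in total).  Because a
finite run rarely visits all ``|A_k|`` states, a minimal pseudo-count
``P_k = 1 / |A_k|`` may be added to every cell, which makes the chain
irreducible and its stationary distribution unique.

All local matrices whose tuple contains a vertex ``a`` form the transition
tensor C_a(V).  They are combined into the vertex's *global transition
matrix* T_g(a) by weighting each slice's row-conditional transition
probabilities by that slice's share of all observed transitions leaving each
state — which is exactly pooling the counts and row-normalizing, the only
weighting that guarantees a row-stochastic result.

From the row-stochastic T_g(a), the stationary distribution pi (dominant
left eigenvector) gives the long-time occupancy of adjacency states, and its
Shannon entropy H = -sum_i pi_i log2 pi_i (in bits) is the conformational
entropy of the motif ensemble the vertex is immersed in.  The entropy change
upon, e.g., ligand binding is Delta H = H_ref - H_other (positive = loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .stream_ids import TransitionRecord, VertexTuple, n_states

#: relative/absolute tolerance for "rows sum to one" checks
_STOCHASTIC_ATOL = 1e-8


@dataclass(frozen=True)
class TransitionMatrix:
    """Transition counts of one ordered vertex tuple.

    ``counts`` holds raw integer counts plus the pseudo-count (if any) in
    every cell; ``pseudocount`` records what was added so raw counts can be
    recovered exactly.
    """

    counts: np.ndarray
    k: int
    vertex_tuple: VertexTuple | None = None
    pseudocount: float = 0.0

    @property
    def raw(self) -> np.ndarray:
        """Counts with the pseudo-count removed (exact, non-negative)."""
        return self.counts - self.pseudocount

    @property
    def n_transitions(self) -> float:
        """Total raw transition count; equals tau - 1 for a full run."""
        return float(self.raw.sum())


def transition_counts(
    pairs: Iterable[tuple[int, int]],
    n: int,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Count (from, to) pairs into an n x n matrix, plus a per-cell pseudo-count."""
    counts = np.full((n, n), float(pseudocount))
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise InputError(f"transition ({i}, {j}) out of range for {n} states")
        counts[i, j] += 1.0
    return counts


def local_transition_matrix(
    transitions: Sequence,
    k: int,
    pseudocount_mode: bool = True,
    vertex_tuple: VertexTuple | None = None,
) -> TransitionMatrix:
    """Build T(V') from a transition list.

    ``transitions`` may be :class:`TransitionRecord` items or plain
    ``(from_id, to_id)`` pairs.  With ``pseudocount_mode`` on, the minimal
    pseudo-count ``P_k = 1/|A_k|`` is added to every cell.
    """
    size = n_states(k)
    pk = 1.0 / size if pseudocount_mode else 0.0
    pairs = (
        (t.from_id, t.to_id) if isinstance(t, TransitionRecord) else (t[0], t[1])
        for t in transitions
    )
    counts = transition_counts(pairs, size, pseudocount=pk)
    return TransitionMatrix(counts=counts, k=k, vertex_tuple=vertex_tuple, pseudocount=pk)


@dataclass(frozen=True)
class TransitionTensor:
    """All local matrices whose tuple contains one vertex, C_a(V).

    ``state_totals`` is the |A_k| x L matrix S of raw transitions leaving
    each state in each slice (slice row sums), the weighting basis for T_g.
    """

    vertex: int
    slices: tuple[TransitionMatrix, ...]
    state_totals: np.ndarray

    @property
    def k(self) -> int:
        return self.slices[0].k


def assemble_tensor(a: int, matrices: Iterable[TransitionMatrix]) -> TransitionTensor:
    """Collect the local matrices containing vertex ``a`` into a tensor.

    Slices are ordered lexicographically by tuple so the assembly is
    deterministic; every matrix must carry a tuple containing ``a`` and all
    must share the same k.
    """
    mats = sorted(
        matrices,
        key=lambda m: m.vertex_tuple.vertices if m.vertex_tuple else (),
    )
    if not mats:
        raise InputError("tensor needs at least one slice")
    k = mats[0].k
    for m in mats:
        if m.k != k:
            raise InputError(f"mixed adjacency sizes in tensor: {m.k} vs {k}")
        if m.vertex_tuple is not None and a not in m.vertex_tuple:
            raise InputError(
                f"slice tuple {m.vertex_tuple.vertices} does not contain vertex {a}"
            )
    totals = np.column_stack([m.raw.sum(axis=1) for m in mats])
    return TransitionTensor(vertex=a, slices=tuple(mats), state_totals=totals)


def _model_from_counts(vertex: int, pooled: np.ndarray) -> "GlobalModel":
    """Row-normalize pooled counts into a GlobalModel (uniform for empty rows)."""
    pooled = np.asarray(pooled, dtype=float)
    if pooled.ndim != 2 or pooled.shape[0] != pooled.shape[1]:
        raise InputError("pooled counts must be square")
    row_sums = pooled.sum(axis=1)
    matrix = np.empty_like(pooled)
    empty = row_sums == 0
    if empty.any():
        matrix[empty] = 1.0 / pooled.shape[0]
    nz = ~empty
    matrix[nz] = pooled[nz] / row_sums[nz, None]
    pi = stationary_distribution(matrix)
    return GlobalModel(vertex=vertex, matrix=matrix, pi=pi, entropy=entropy(pi))


@dataclass(frozen=True)
class GlobalModel:
    """Per-vertex global transition matrix with its stationary summary."""

    vertex: int
    matrix: np.ndarray  # row-stochastic, |A_k| x |A_k|
    pi: np.ndarray
    entropy: float  # bits


def global_matrix(tensor: TransitionTensor) -> GlobalModel:
    """Combine a vertex's tensor slices into the global matrix T_g(a).

    Implemented as count pooling: row i of T_g is the normalized sum over
    slices of that row's counts.  This equals weighting each slice's
    row-conditional probabilities by the slice's share of all transitions
    leaving state i.  Rows with zero pooled mass (possible only with
    pseudo-counts off) become uniform.
    """
    pooled = np.zeros_like(tensor.slices[0].counts)
    for m in tensor.slices:
        if m.counts.shape != pooled.shape:
            raise InputError("slice dimension mismatch in tensor")
        pooled += m.counts
    return _model_from_counts(tensor.vertex, pooled)


def _validate_stochastic(matrix: np.ndarray) -> np.ndarray:
    T = np.asarray(matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise InputError("transition matrix must be square")
    if not np.isfinite(T).all() or (T < -1e-12).any():
        raise InputError("transition matrix must be finite and non-negative")
    if not np.allclose(T.sum(axis=1), 1.0, atol=_STOCHASTIC_ATOL):
        raise InputError("transition matrix rows must sum to 1")
    return T


def stationary_distribution(matrix: np.ndarray, dense_limit: int = 64) -> np.ndarray:
    """Stationary distribution pi with pi @ T = pi, pi >= 0, sum(pi) = 1.

    Up to ``dense_limit`` states a dense left eigendecomposition is used,
    taking the eigenvector of the largest-magnitude eigenvalue (first in
    stable sort order on ties).  A degenerate dominant eigenvalue — a
    reducible chain, e.g. the identity matrix — triggers a warning and a
    deterministic choice.  Larger chains use damped power iteration on
    (I + T)/2 (same fixed points, immune to periodicity) to 1e-12, at most
    1e5 iterations.  Components below 1e-12 are clipped to zero and the
    vector renormalized.
    """
    T = _validate_stochastic(matrix)
    n = T.shape[0]
    if n <= dense_limit:
        eigvals, eigvecs = np.linalg.eig(T.T)
        order = np.argsort(-np.abs(eigvals), kind="stable")
        if n > 1 and abs(eigvals[order[1]]) > 1.0 - 1e-9:
            warnings.warn(
                "dominant eigenvalue is degenerate (reducible chain); "
                "stationary distribution is not unique",
                RuntimeWarning,
                stacklevel=2,
            )
        pi = np.real(eigvecs[:, order[0]])
        if pi.sum() < 0:
            pi = -pi
    else:
        pi = np.full(n, 1.0 / n)
        for _ in range(100_000):
            nxt = 0.5 * (pi + pi @ T)
            if np.abs(nxt - pi).max() < 1e-12:
                pi = nxt
                break
            pi = nxt
    pi = np.where(pi < 1e-12, 0.0, pi)
    total = pi.sum()
    if total <= 0:
        raise InputError("failed to extract a non-negative stationary vector")
    return pi / total


def entropy(pi: np.ndarray) -> float:
    """Shannon entropy of a probability vector in bits, with 0*log0 := 0."""
    p = np.asarray(pi, dtype=float)
    if (p < -1e-12).any() or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InputError("entropy needs a normalized, non-negative vector")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) + 0.0  # avoid -0.0 at a point mass


def delta_entropy(h_ref: float, h_other: float) -> float:
    """Entropy difference Delta H = H_ref - H_other (positive = entropy loss)."""
    return float(h_ref) - float(h_other)
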