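"""Full per-vertex global-model computation over a dynamic graph.

The full computation enumerates all ordered k-tuples of distinct vertices
(``|V|!/(|V|-k)!`` of them, optionally pruned to tuples containing at least
one residue pair that is ever in contact), maintains every tuple's adjacency
id in a single pass over the batch stream, and pools each tuple's transition
counts into the global count matrix of each of its k member vertices.  Each
tuple is therefore processed once and contributes to k per-vertex models,
which is what makes k = 4 on a 65-vertex graph tractable.

Transitions are recorded lazily: a tuple whose id is untouched by a batch
self-transitions, so only *changes* generate work — when a tuple's id moves
from x to y at snapshot t, the (x, x) self-transitions accumulated since the
id last changed are flushed together with the single (x, y) event.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence
import warnings

import numpy as np

from .dynamic_graph import DynamicGraph
from .errors import InputError, ParameterError, StateCorruptionError
from .markov import GlobalModel, _model_from_counts, delta_entropy
from .stream_ids import n_states
from .trajectory import ContactProbabilityMatrix, Trajectory, delta_rmsf

logger = logging.getLogger(__name__)

#: dense per-vertex accumulators are refused beyond this many bytes
_MEMORY_CEILING = 4 << 30
#: full T_g computation is restricted to this adjacency size
_K_FULL_MAX = 5


def count_tuples(n_vertices: int, k: int, anchored: bool = False) -> int:
    """Closed-form ordered-tuple counts.

    Without anchor: |V|!/(|V|-k)! ordered k-tuples of distinct vertices.
    Anchored at one vertex: k * (|V|-1)!/(|V|-k)! tuples containing it,
    i.e. (k-1)! * C(|V|, k-1) matrices per vertex after grouping.
    """
    if not 2 <= k <= min(n_vertices, 10):
        raise ParameterError(f"k={k} infeasible for {n_vertices} vertices")
    if anchored:
        return k * math.perm(n_vertices - 1, k - 1)
    return math.perm(n_vertices, k)


def enumerate_tuples(
    n_vertices: int, k: int, anchor: int | None = None
) -> Iterator[tuple[int, ...]]:
    """Stream all ordered k-tuples of distinct vertices in lexicographic order.

    With ``anchor`` set, only tuples containing that vertex are yielded.
    Nothing is materialized; counts match :func:`count_tuples`.
    """
    if not 2 <= k <= min(n_vertices, 10):
        raise ParameterError(f"k={k} infeasible for {n_vertices} vertices")
    if anchor is not None and not 0 <= anchor < n_vertices:
        raise ParameterError(f"anchor {anchor} outside [0, {n_vertices})")
    for tup in itertools.permutations(range(n_vertices), k):
        if anchor is None or anchor in tup:
            yield tup


def contact_filter(
    tuples: Iterable[tuple[int, ...]],
    P: ContactProbabilityMatrix | np.ndarray,
    min_contact_prob: float = 0.0,
) -> Iterator[tuple[int, ...]]:
    """Keep only tuples with at least one pair ever in contact (P > threshold).

    Tuples in which every vertex pair has zero contact probability stay in a
    single adjacency state for the whole run and contribute nothing but
    self-transitions; dropping them is the standard pre-computation that
    shrinks the enumeration without changing surviving models.
    """
    entries = P.entries if isinstance(P, ContactProbabilityMatrix) else np.asarray(P)
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        raise InputError("contact probability matrix must be square")
    n = entries.shape[0]
    for tup in tuples:
        if any(v >= n for v in tup):
            raise InputError(
                f"tuple {tup} outside contact-probability dimension {n}"
            )
        if any(
            entries[u, v] > min_contact_prob
            for u, v in itertools.combinations(tup, 2)
        ):
            yield tup


@dataclass(frozen=True)
class RunResult:
    """Per-vertex global models plus the parameters that produced them."""

    models: dict[int, GlobalModel]
    k: int
    tuple_count: int
    n_vertices: int
    params: dict = field(default_factory=dict)

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(sorted(self.models))

    def entropies(self) -> np.ndarray:
        return np.array([self.models[v].entropy for v in self.vertices])


@dataclass(frozen=True)
class ComparisonResult:
    """Per-vertex entropy and RMSF differences between two runs."""

    vertices: tuple[int, ...]
    delta_entropy: np.ndarray  # bits, reference minus other
    delta_rmsf: np.ndarray | None = None  # Angstrom, reference minus other


def _build_pair_index(tup_arr: np.ndarray, n: int):
    """Map each canonical vertex pair to (tuple rows, bit exponents).

    For a fixed pair of tuple *positions* the bit exponent is a constant,
    so the index is assembled position-pair by position-pair and grouped by
    the packed pair key u*n + v.
    """
    m, k = tup_arr.shape
    k2 = k * (k - 1) // 2
    keys, idxs, exps = [], [], []
    rows = np.arange(m, dtype=np.int32)
    for p in range(k):
        for q in range(p + 1, k):
            i, j = p + 1, q + 1
            e = k2 - ((i - 1) * k + j - i * (i + 1) // 2)
            u = np.minimum(tup_arr[:, p], tup_arr[:, q]).astype(np.int64)
            v = np.maximum(tup_arr[:, p], tup_arr[:, q]).astype(np.int64)
            keys.append(u * n + v)
            idxs.append(rows)
            exps.append(np.full(m, e, dtype=np.int8))
    keys = np.concatenate(keys)
    idxs = np.concatenate(idxs)
    exps = np.concatenate(exps)
    order = np.argsort(keys, kind="stable")
    keys, idxs, exps = keys[order], idxs[order], exps[order]
    bounds = np.flatnonzero(np.diff(keys)) + 1
    index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for start, stop in zip(
        itertools.chain([0], bounds), itertools.chain(bounds, [len(keys)])
    ):
        if start < stop:
            index[int(keys[start])] = (idxs[start:stop], exps[start:stop])
    return index


def _accumulate(M, req_index, verts, old, new, selfs):
    """Pool change events into the per-vertex count accumulators.

    Each changed tuple contributes ``selfs`` (old, old) self-transitions and
    one (old, new) transition to every requested member vertex.
    """
    c, k = verts.shape
    rows = req_index[verts]
    ok = rows >= 0
    if not ok.any():
        return
    r = rows[ok]
    ob = np.broadcast_to(old[:, None], (c, k))[ok]
    sb = np.broadcast_to(selfs[:, None], (c, k))[ok]
    np.add.at(M, (r, ob, ob), sb)
    if new is not None:
        nb = np.broadcast_to(new[:, None], (c, k))[ok]
        np.add.at(M, (r, ob, nb), 1.0)


def run_full_computation(
    g: DynamicGraph,
    k: int,
    pseudocounts: bool = True,
    contact_probability: ContactProbabilityMatrix | np.ndarray | None = None,
    min_contact_prob: float = 0.0,
    vertices: Sequence[int] | None = None,
    validate: bool = True,
) -> RunResult:
    """Compute the global model T_g(a) for every requested vertex.

    Enumerates ordered k-tuples (contact-filtered when a contact-probability
    matrix is given), maintains all tuple ids in one pass over the batch
    stream, pools transition counts per vertex, applies the per-slice
    pseudo-count, and row-normalizes into GlobalModels with stationary
    distribution and entropy.  Deterministic for fixed input.
    """
    n = g.n_vertices
    if k > _K_FULL_MAX:
        raise ParameterError(
            f"full computation is restricted to k <= {_K_FULL_MAX}: k={k} means "
            f"{count_tuples(n, k)} tuples over {n_states(k)}x{n_states(k)} states"
        )
    S = n_states(k)
    if vertices is None:
        req = list(range(n))
    else:
        req = sorted(set(int(v) for v in vertices))
        if req and not (0 <= req[0] and req[-1] < n):
            raise ParameterError(f"requested vertices outside [0, {n})")
    needed = len(req) * S * S * 8
    if needed > _MEMORY_CEILING:
        raise ParameterError(
            f"per-vertex accumulators would need {needed / 2**30:.1f} GiB; "
            "restrict `vertices` or lower k"
        )

    stream = enumerate_tuples(n, k)
    if contact_probability is not None:
        stream = contact_filter(stream, contact_probability, min_contact_prob)
    tup_arr = np.array(list(stream), dtype=np.int32).reshape(-1, k)
    m = tup_arr.shape[0]
    logger.info("processing %d ordered %d-tuples on %d vertices", m, k, n)

    req_arr = np.array(req, dtype=np.int64)
    req_index = np.full(n, -1, dtype=np.int64)
    req_index[req_arr] = np.arange(len(req))
    n_slices = np.bincount(tup_arr.ravel(), minlength=n)
    M = np.zeros((len(req), S, S))

    if m > 0:
        pair_index = _build_pair_index(tup_arr, n)
        cur = np.zeros(m, dtype=np.int64)
        since = np.ones(m, dtype=np.int64)
        for u, v in g.initial.edges:
            hit = pair_index.get(u * n + v)
            if hit is not None:
                idx, ev = hit
                cur[idx] += np.left_shift(np.int64(1), ev.astype(np.int64))

        for bi, batch in enumerate(g.batches):
            t = bi + 2
            hits = []
            for edge_set, is_add in ((batch.removals, False), (batch.additions, True)):
                for u, v in edge_set:
                    hit = pair_index.get(u * n + v)
                    if hit is not None:
                        hits.append((hit, is_add, (u, v)))
            if not hits:
                continue
            touched = np.unique(np.concatenate([h[0][0] for h in hits]))
            old = cur[touched].copy()
            for (idx, ev8, is_add, edge) in (
                (h[0][0], h[0][1], h[1], h[2]) for h in hits
            ):
                ev = ev8.astype(np.int64)
                power = np.left_shift(np.int64(1), ev)
                if validate:
                    bits = (cur[idx] >> ev) & 1
                    if is_add and bits.any():
                        raise StateCorruptionError(
                            f"batch {t}: adding edge {edge} already present in a tuple"
                        )
                    if not is_add and not bits.all():
                        raise StateCorruptionError(
                            f"batch {t}: removing edge {edge} absent from a tuple"
                        )
                cur[idx] += power if is_add else -power
            new = cur[touched]
            changed = new != old
            if changed.any():
                ci = touched[changed]
                selfs = (t - 1 - since[ci]).astype(float)
                _accumulate(M, req_index, tup_arr[ci], old[changed], new[changed], selfs)
                since[ci] = t
            if bi % 1000 == 999:
                logger.info("pass: %d/%d batches", bi + 1, len(g.batches))

        # Remaining self-transitions up to the last snapshot.
        selfs = (g.tau - since).astype(float)
        _accumulate(M, req_index, tup_arr, cur, None, selfs)

    pk = 1.0 / S if pseudocounts else 0.0
    models: dict[int, GlobalModel] = {}
    for r, v in enumerate(req):
        slices = int(n_slices[v])
        if slices == 0:
            warnings.warn(
                f"vertex {v} appears in no surviving tuple; its model is uniform",
                RuntimeWarning,
                stacklevel=2,
            )
        models[v] = _model_from_counts(v, M[r] + slices * pk)
    logger.info("reduced %d tuples into %d global models", m, len(models))
    return RunResult(
        models=models,
        k=k,
        tuple_count=m,
        n_vertices=n,
        params={
            "pseudocounts": pseudocounts,
            "filtered": contact_probability is not None,
            "min_contact_prob": min_contact_prob,
        },
    )


def compare_runs(
    reference: RunResult,
    other: RunResult,
    reference_traj: Trajectory | None = None,
    other_traj: Trajectory | None = None,
) -> ComparisonResult:
    """Per-vertex Delta H (and Delta RMSF when trajectories are supplied).

    Both differences are reference minus other, so a positive value means a
    loss of conformational entropy (or fluctuation) in the other run —
    typically the ligand-bound complex measured against the free molecule.
    """
    if reference.vertices != other.vertices:
        raise InputError("runs cover different vertex sets")
    if reference.k != other.k:
        raise InputError(f"runs use different k: {reference.k} vs {other.k}")
    dH = np.array(
        [
            delta_entropy(reference.models[v].entropy, other.models[v].entropy)
            for v in reference.vertices
        ]
    )
    dR = None
    if reference_traj is not None and other_traj is not None:
        dR = delta_rmsf(reference_traj, other_traj)
        if len(dR) != len(reference.vertices):
            raise InputError(
                "trajectory atom count does not match the runs' vertex count"
            )
    return ComparisonResult(
        vertices=reference.vertices, delta_entropy=dH, delta_rmsf=dR
    )
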