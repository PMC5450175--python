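"""Adjacency-id encoding of k-vertex induced subgraphs and streamed updates.

The state of an ordered tuple V' = (v_1, ..., v_k) in a graph is the strict
upper triangle of the adjacency matrix of the V'-induced subgraph, read row
by row as a binary number with the (1,2) entry as the most significant bit.
That integer — the *adjacency id* — labels the Markov state of the tuple.
There are ``|A_k| = 2^(k(k-1)/2)`` possible ids.

Because an edge {a, b} occupies exactly one bit of the id, edge additions
and removals translate to adding or subtracting a power of two, which is
what makes single-pass processing of an edge stream possible: an update only
touches tuples containing both endpoints, and costs O(1) per tuple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .dynamic_graph import Batch, DynamicGraph, Snapshot, canonical_edge
from .errors import InputError, StateCorruptionError

K_MIN = 2
K_MAX = 10  # ids fit in 45 bits, comfortably inside int64


def n_states(k: int) -> int:
    """Size of the adjacency state space, |A_k| = 2^(k(k-1)/2)."""
    if not K_MIN <= k <= K_MAX:
        raise InputError(f"k={k} outside supported range [{K_MIN}, {K_MAX}]")
    return 1 << (k * (k - 1) // 2)


@dataclass(frozen=True)
class VertexTuple:
    """An ordered tuple of k distinct vertex indices.

    The order is significant: it fixes the bit layout of the adjacency id,
    so permutations of the same vertex set are distinct states/models.
    """

    vertices: tuple[int, ...]

    def __init__(self, vertices: Iterable[int]):
        verts = tuple(int(v) for v in vertices)
        if not K_MIN <= len(verts) <= K_MAX:
            raise InputError(
                f"tuple size {len(verts)} outside [{K_MIN}, {K_MAX}]"
            )
        if len(set(verts)) != len(verts):
            raise InputError(f"tuple {verts} has repeated vertices")
        if any(v < 0 for v in verts):
            raise InputError(f"tuple {verts} has negative vertex indices")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "_pos", {v: i + 1 for i, v in enumerate(verts)})

    @property
    def k(self) -> int:
        return len(self.vertices)

    def position(self, vertex: int) -> int:
        """1-based position of a vertex within the tuple."""
        try:
            return self._pos[vertex]
        except KeyError:
            raise InputError(f"vertex {vertex} not in tuple {self.vertices}")

    def __contains__(self, vertex: int) -> bool:
        return vertex in self._pos

    def __iter__(self):
        return iter(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)


def _as_tuple(t) -> VertexTuple:
    return t if isinstance(t, VertexTuple) else VertexTuple(t)


class TransitionRecord(NamedTuple):
    """One adjacency transition (id_t, id_{t+1}) of a tuple at time t."""

    from_id: int
    to_id: int
    time: int


def edge_bit_position(a: int, b: int, vtuple) -> int:
    """Bit position e(a, b, V') of edge {a, b} in the adjacency id.

    With i < j the 1-based tuple positions of a and b, the upper-triangle
    entry (i, j) is the ((i-1)k + j - i(i+1)/2)-th bit of the concatenation,
    counted from the most significant end; its power-of-two exponent is

        e = k(k-1)/2 - [(i-1)k + j - i(i+1)/2]

    so toggling the edge changes the id by +/- 2^e.
    """
    vt = _as_tuple(vtuple)
    k = vt.k
    pa, pb = vt.position(a), vt.position(b)
    if pa == pb:
        raise InputError("edge endpoints must differ")
    i, j = min(pa, pb), max(pa, pb)
    return k * (k - 1) // 2 - ((i - 1) * k + j - i * (i + 1) // 2)


def adjacency_id(snapshot: Snapshot, vtuple) -> int:
    """Encode the induced subgraph of the ordered tuple as an adjacency id.

    Computed from scratch by scanning all vertex pairs of the tuple; use
    :func:`stream_update` / :func:`batch_update` to maintain ids under
    streamed changes instead.
    """
    vt = _as_tuple(vtuple)
    if any(v >= snapshot.n_vertices for v in vt):
        raise InputError(
            f"tuple {vt.vertices} outside vertex range [0, {snapshot.n_vertices})"
        )
    value = 0
    verts = vt.vertices
    for i in range(vt.k):
        for j in range(i + 1, vt.k):
            value <<= 1
            if snapshot.has_edge(verts[i], verts[j]):
                value |= 1
    return value


def _check_id(current_id: int, k: int) -> None:
    if not 0 <= current_id < n_states(k):
        raise InputError(f"id {current_id} out of range for k={k}")


def stream_update(current_id: int, edge, op_type: str, vtuple) -> int:
    """Update an adjacency id for a single edge addition or removal.

    Edges with an endpoint outside the tuple leave the id unchanged.  An
    addition whose bit is already set (or a removal of an unset bit) raises
    :class:`StateCorruptionError` — the stream contradicts the tracked state.
    """
    vt = _as_tuple(vtuple)
    _check_id(current_id, vt.k)
    if op_type not in ("add", "remove"):
        raise InputError(f"op_type must be 'add' or 'remove', got {op_type!r}")
    a, b = canonical_edge(*edge)
    if a not in vt or b not in vt:
        return current_id
    e = edge_bit_position(a, b, vt)
    bit = (current_id >> e) & 1
    if op_type == "add":
        if bit:
            raise StateCorruptionError(
                f"adding edge {(a, b)} but bit {e} of id {current_id} is already set"
            )
        return current_id + (1 << e)
    if not bit:
        raise StateCorruptionError(
            f"removing edge {(a, b)} but bit {e} of id {current_id} is unset"
        )
    return current_id - (1 << e)


def batch_update(current_id: int, batch: Batch, vtuple) -> int:
    """Advance an adjacency id across one batch of removals and additions.

    Equivalent to folding :func:`stream_update` over all removals then all
    additions; order is irrelevant because the two sets are disjoint.
    """
    vt = _as_tuple(vtuple)
    for e in batch.removals:
        current_id = stream_update(current_id, e, "remove", vt)
    for e in batch.additions:
        current_id = stream_update(current_id, e, "add", vt)
    return current_id


def id_series(g: DynamicGraph, vtuple) -> list[int]:
    """Adjacency id of the tuple at every snapshot t in [1, tau]."""
    vt = _as_tuple(vtuple)
    ids = [adjacency_id(g.initial, vt)]
    for batch in g.batches:
        ids.append(batch_update(ids[-1], batch, vt))
    return ids


def transition_list(g: DynamicGraph, vtuple) -> list[TransitionRecord]:
    """All tau - 1 consecutive adjacency transitions of a tuple.

    Record t pairs the ids at snapshots t and t+1; self-transitions (the id
    did not change) are included.  Computed in one pass with batch updates.
    """
    ids = id_series(g, vtuple)
    return [
        TransitionRecord(from_id=ids[t], to_id=ids[t + 1], time=t + 1)
        for t in range(len(ids) - 1)
    ]
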