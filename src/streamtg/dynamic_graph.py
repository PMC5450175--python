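"""Dynamic graphs: snapshots, edge batches, a random generator and file I/O.

A dynamic graph is a fixed vertex set V whose edge set changes over time.
It is stored as an initial snapshot ``G_1`` plus, for every later time step
``t`` in ``[2, tau]``, a *batch* ``(E+_t, E-_t)`` of edges added to and
removed from the previous snapshot.  Graphs are undirected and contain no
self-loops; edges are kept canonically as ``(min, max)`` pairs.

The batch size ``delta_t = |E+_t| + |E-_t|`` measures how much the graph
changes per step; its time average ``delta_avg = sum_t delta_t / tau``
(denominator: the snapshot count tau) characterises a whole run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import GraphFormatError, ParameterError

Edge = tuple[int, int]


def canonical_edge(u: int, v: int) -> Edge:
    """Return the edge as an ordered ``(min, max)`` pair; reject self-loops."""
    u, v = int(u), int(v)
    if u == v:
        raise GraphFormatError(f"self-loop on vertex {u} is not allowed")
    return (u, v) if u < v else (v, u)


def _validate_edges(edges: Iterable[Edge], n_vertices: int) -> frozenset[Edge]:
    out = set()
    for u, v in edges:
        e = canonical_edge(u, v)
        if not (0 <= e[0] and e[1] < n_vertices):
            raise GraphFormatError(
                f"edge {e} outside vertex range [0, {n_vertices})"
            )
        out.add(e)
    return frozenset(out)


@dataclass(frozen=True)
class Snapshot:
    """The edge set of a dynamic graph at one point in time."""

    n_vertices: int
    edges: frozenset[Edge]

    def __init__(self, n_vertices: int, edges: Iterable[Edge] = ()):
        if n_vertices < 0:
            raise GraphFormatError("n_vertices must be non-negative")
        object.__setattr__(self, "n_vertices", int(n_vertices))
        object.__setattr__(self, "edges", _validate_edges(edges, n_vertices))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: int, v: int) -> bool:
        return canonical_edge(u, v) in self.edges


@dataclass(frozen=True)
class Batch:
    """Edge additions and removals between two consecutive snapshots."""

    additions: frozenset[Edge]
    removals: frozenset[Edge]

    def __init__(self, additions: Iterable[Edge] = (), removals: Iterable[Edge] = ()):
        add = frozenset(canonical_edge(u, v) for u, v in additions)
        rem = frozenset(canonical_edge(u, v) for u, v in removals)
        if add & rem:
            raise GraphFormatError(
                f"additions and removals overlap: {sorted(add & rem)}"
            )
        object.__setattr__(self, "additions", add)
        object.__setattr__(self, "removals", rem)

    @property
    def size(self) -> int:
        """Batch size delta_t = |additions| + |removals|."""
        return len(self.additions) + len(self.removals)


def apply_batch(snapshot: Snapshot, batch: Batch) -> Snapshot:
    """Apply a batch to a snapshot, enforcing the update invariants.

    Additions must be absent from and removals present in the snapshot.
    """
    if batch.additions & snapshot.edges:
        raise GraphFormatError(
            f"batch adds edges already present: {sorted(batch.additions & snapshot.edges)}"
        )
    if not batch.removals <= snapshot.edges:
        raise GraphFormatError(
            f"batch removes absent edges: {sorted(batch.removals - snapshot.edges)}"
        )
    return Snapshot(
        snapshot.n_vertices, (snapshot.edges | batch.additions) - batch.removals
    )


@dataclass(frozen=True)
class DynamicGraph:
    """An initial snapshot plus tau - 1 batches of edge updates.

    ``labels`` optionally maps internal vertex indices ``0..n-1`` to the
    external integer labels used in files; ``None`` means identity.
    """

    initial: Snapshot
    batches: tuple[Batch, ...] = ()
    labels: tuple[int, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "batches", tuple(self.batches))
        if self.labels is not None:
            labels = tuple(int(x) for x in self.labels)
            if len(labels) != self.initial.n_vertices or len(set(labels)) != len(labels):
                raise GraphFormatError("labels must be distinct, one per vertex")
            object.__setattr__(self, "labels", labels)

    @property
    def tau(self) -> int:
        """Number of snapshots."""
        return len(self.batches) + 1

    @property
    def n_vertices(self) -> int:
        return self.initial.n_vertices

    def snapshots(self) -> Iterator[Snapshot]:
        """Replay the stream, yielding the snapshot at every t in [1, tau]."""
        snap = self.initial
        yield snap
        for batch in self.batches:
            snap = apply_batch(snap, batch)
            yield snap

    def snapshot_at(self, t: int) -> Snapshot:
        """Snapshot at 1-based time t (replays from the start)."""
        if not 1 <= t <= self.tau:
            raise ParameterError(f"t={t} outside [1, {self.tau}]")
        for i, snap in enumerate(self.snapshots(), start=1):
            if i == t:
                return snap
        raise AssertionError("unreachable")

    def label_of(self, vertex: int) -> int:
        return vertex if self.labels is None else self.labels[vertex]


def snapshots_to_batches(snapshots: Sequence[Snapshot]) -> DynamicGraph:
    """Convert a list of full snapshots into initial-plus-batches form.

    Per-step additions/removals are the minimal set differences
    ``E+_t = E_t \\ E_{t-1}`` and ``E-_t = E_{t-1} \\ E_t``; replaying the
    result reproduces every input snapshot exactly.
    """
    if not snapshots:
        raise GraphFormatError("need at least one snapshot")
    n = snapshots[0].n_vertices
    for i, s in enumerate(snapshots):
        if s.n_vertices != n:
            raise GraphFormatError(
                f"snapshot {i + 1} has {s.n_vertices} vertices, expected {n}"
            )
    batches = [
        Batch(additions=cur.edges - prev.edges, removals=prev.edges - cur.edges)
        for prev, cur in itertools.pairwise(snapshots)
    ]
    return DynamicGraph(initial=snapshots[0], batches=tuple(batches))


def batch_statistics(g: DynamicGraph) -> tuple[list[int], float]:
    """Per-step batch sizes delta_t and their average delta_avg.

    The average divides by tau, the snapshot count, even though only
    tau - 1 batches exist.
    """
    deltas = [b.size for b in g.batches]
    return deltas, sum(deltas) / g.tau


def generate_random_dynamic_graph(
    n_vertices: int,
    n_edges: int,
    batch_size: int,
    tau: int,
    seed: int,
) -> DynamicGraph:
    """Generate a random dynamic graph with fixed |V|, |E| and batch size.

    The initial snapshot holds ``n_edges`` uniformly chosen edges.  Every
    batch removes ``batch_size // 2`` random existing edges and adds
    ``batch_size - batch_size // 2`` random absent ones (an odd batch size
    gives the extra element to the additions), so for even batch sizes the
    edge count stays constant over time.  The same seed reproduces the same
    graph exactly.
    """
    if n_vertices < 0 or n_edges < 0 or batch_size < 0 or tau < 1:
        raise ParameterError("all sizes must be non-negative and tau >= 1")
    max_edges = n_vertices * (n_vertices - 1) // 2
    if n_edges > max_edges:
        raise ParameterError(f"n_edges={n_edges} exceeds maximum {max_edges}")
    n_rem = batch_size // 2
    n_add = batch_size - n_rem
    if n_rem > n_edges:
        raise ParameterError(
            f"batch_size={batch_size} removes more edges than exist ({n_edges})"
        )
    if n_add > max_edges - n_edges:
        raise ParameterError(
            f"batch_size={batch_size} cannot add {n_add} absent edges to a "
            f"graph of {n_edges}/{max_edges} edges"
        )

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_vertices, k=1)
    all_pairs = list(zip(iu.tolist(), ju.tolist()))

    chosen = rng.choice(max_edges, size=n_edges, replace=False) if n_edges else []
    edges = {all_pairs[i] for i in chosen}
    initial = Snapshot(n_vertices, edges)

    batches = []
    current = set(edges)
    for step in range(tau - 1):
        # An odd batch size grows |E| by one per step, so re-check per step.
        if n_rem > len(current) or n_add > max_edges - len(current):
            raise ParameterError(
                f"batch_size={batch_size} infeasible at step {step + 2}: "
                f"{len(current)}/{max_edges} edges present"
            )
        pool = sorted(current)
        rem_idx = rng.choice(len(pool), size=n_rem, replace=False) if n_rem else []
        removals = {pool[i] for i in rem_idx}
        additions: set[Edge] = set()
        if n_add:
            # Rejection sampling is fast for sparse graphs; fall back to an
            # explicit complement when the graph is dense.
            if len(current) < 0.25 * max_edges:
                while len(additions) < n_add:
                    i = int(rng.integers(max_edges))
                    e = all_pairs[i]
                    if e not in current and e not in additions:
                        additions.add(e)
            else:
                absent = [e for e in all_pairs if e not in current]
                add_idx = rng.choice(len(absent), size=n_add, replace=False)
                additions = {absent[i] for i in add_idx}
        batch = Batch(additions=additions, removals=removals)
        batches.append(batch)
        current = (current | additions) - removals
    return DynamicGraph(initial=initial, batches=tuple(batches))


# ---------------------------------------------------------------------------
# Stream file dialect
#
#   # comment
#   nodes <N>
#   snapshot 1
#   e <u> <v>
#   batch 2
#   + <u> <v>
#   - <u> <v>
#   ...
#
# Alternatively a file may give full "snapshot <t>" blocks for every t; these
# are converted with snapshots_to_batches on read.
# ---------------------------------------------------------------------------


def _tokenize(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def _parse_edge_tokens(tokens: list[str], lineno: int) -> tuple[int, int]:
    if len(tokens) != 2:
        raise GraphFormatError("expected two vertex labels", line=lineno)
    try:
        u, v = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise GraphFormatError(f"non-integer vertex label in {tokens}", line=lineno)
    if u == v:
        raise GraphFormatError(f"self-loop on vertex {u}", line=lineno)
    return (u, v) if u < v else (v, u)


def read_dynamic_graph(path) -> DynamicGraph:
    """Read a dynamic graph from the stream dialect (see module docstring).

    External integer labels are mapped to internal indices ``0..n-1``; when
    they are not already the range ``[0, N)``, the sorted distinct labels
    must number exactly N so that every internal vertex has a label.
    """
    n_declared: int | None = None
    mode: str | None = None  # "batch" or "snapshot"
    snapshot_edges: list[set[tuple[int, int]]] = []  # for snapshot mode
    initial_edges: set[tuple[int, int]] | None = None
    raw_batches: list[tuple[set, set]] = []
    section = None  # None | "snapshot" | "batch"
    seen_labels: set[int] = set()
    last_t = 0

    for lineno, tokens in _tokenize(path):
        key = tokens[0]
        if key == "nodes":
            if n_declared is not None:
                raise GraphFormatError("duplicate 'nodes' header", line=lineno)
            try:
                n_declared = int(tokens[1])
            except (IndexError, ValueError):
                raise GraphFormatError("usage: nodes <N>", line=lineno)
        elif key == "snapshot":
            if n_declared is None:
                raise GraphFormatError("'nodes' header must come first", line=lineno)
            try:
                t = int(tokens[1])
            except (IndexError, ValueError):
                raise GraphFormatError("usage: snapshot <t>", line=lineno)
            if t == 1:
                if snapshot_edges or initial_edges is not None:
                    raise GraphFormatError("duplicate 'snapshot 1'", line=lineno)
            else:
                if mode == "batch":
                    raise GraphFormatError(
                        "cannot mix snapshot and batch blocks", line=lineno
                    )
                mode = "snapshot"
            if t != last_t + 1:
                raise GraphFormatError(
                    f"snapshot {t} out of order (expected {last_t + 1})", line=lineno
                )
            last_t = t
            snapshot_edges.append(set())
            section = "snapshot"
        elif key == "batch":
            if mode == "snapshot":
                raise GraphFormatError(
                    "cannot mix snapshot and batch blocks", line=lineno
                )
            if last_t < 1:
                raise GraphFormatError("batch before 'snapshot 1'", line=lineno)
            mode = "batch"
            try:
                t = int(tokens[1])
            except (IndexError, ValueError):
                raise GraphFormatError("usage: batch <t>", line=lineno)
            if t != last_t + 1:
                raise GraphFormatError(
                    f"batch {t} out of order (expected {last_t + 1})", line=lineno
                )
            last_t = t
            raw_batches.append((set(), set()))
            section = "batch"
        elif key == "e":
            if section != "snapshot":
                raise GraphFormatError("'e' line outside a snapshot block", line=lineno)
            e = _parse_edge_tokens(tokens[1:], lineno)
            if e in snapshot_edges[-1]:
                raise GraphFormatError(f"duplicate edge {e}", line=lineno)
            snapshot_edges[-1].add(e)
            seen_labels.update(e)
        elif key in ("+", "-"):
            if section != "batch":
                raise GraphFormatError(
                    f"'{key}' line outside a batch block", line=lineno
                )
            e = _parse_edge_tokens(tokens[1:], lineno)
            add, rem = raw_batches[-1]
            target = add if key == "+" else rem
            if e in add or e in rem:
                raise GraphFormatError(f"duplicate edge {e} in batch", line=lineno)
            target.add(e)
            seen_labels.update(e)
        else:
            raise GraphFormatError(f"unrecognized directive '{key}'", line=lineno)

    if n_declared is None or last_t == 0:
        raise GraphFormatError("file lacks 'nodes' header or 'snapshot 1' block")

    # Label mapping.
    if seen_labels and (min(seen_labels) < 0 or max(seen_labels) >= n_declared):
        ordered = sorted(seen_labels)
        if len(ordered) != n_declared:
            raise GraphFormatError(
                f"labels outside [0, {n_declared}) and only {len(ordered)} distinct "
                "labels seen; cannot infer labels for unreferenced vertices"
            )
        labels: tuple[int, ...] | None = tuple(ordered)
        index = {lab: i for i, lab in enumerate(ordered)}
        remap = lambda e: canonical_edge(index[e[0]], index[e[1]])
    else:
        labels = None
        remap = lambda e: e

    try:
        if mode == "snapshot":
            snaps = [
                Snapshot(n_declared, {remap(e) for e in edges})
                for edges in snapshot_edges
            ]
            g = snapshots_to_batches(snaps)
        else:
            initial = Snapshot(n_declared, {remap(e) for e in snapshot_edges[0]})
            batches = tuple(
                Batch(
                    additions={remap(e) for e in add},
                    removals={remap(e) for e in rem},
                )
                for add, rem in raw_batches
            )
            g = DynamicGraph(initial=initial, batches=batches)
            for _ in g.snapshots():  # validates batch invariants by replay
                pass
    except GraphFormatError as exc:
        raise GraphFormatError(f"invalid stream in {path}: {exc}") from exc
    return DynamicGraph(initial=g.initial, batches=g.batches, labels=labels)


def write_dynamic_graph(g: DynamicGraph, path) -> None:
    """Write a dynamic graph in the stream dialect with canonical ordering.

    Edges are emitted sorted lexicographically on their external labels, so
    write -> read -> write is byte-stable.
    """

    def ext(e: Edge) -> Edge:
        u, v = g.label_of(e[0]), g.label_of(e[1])
        return (u, v) if u < v else (v, u)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"nodes {g.n_vertices}\n")
        fh.write("snapshot 1\n")
        for u, v in sorted(ext(e) for e in g.initial.edges):
            fh.write(f"e {u} {v}\n")
        for t, batch in enumerate(g.batches, start=2):
            fh.write(f"batch {t}\n")
            for u, v in sorted(ext(e) for e in batch.additions):
                fh.write(f"+ {u} {v}\n")
            for u, v in sorted(ext(e) for e in batch.removals):
                fh.write(f"- {u} {v}\n")
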