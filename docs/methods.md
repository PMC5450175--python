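# Methods

## Model

### From trajectory to dynamic graph

Input is a coarse-grained trajectory: one 3-D coordinate per residue per
frame. PDB input selects one atom per residue (default `C3'`, the
standard RNA coarse-graining choice); a plain XYZ-table dialect
(`frame atom x y z`) is also supported for exact round trips.

For frame `t`, the contact matrix is `B_ij(t) = 1` iff the Euclidean
distance between residues `i` and `j` is **strictly** below the cutoff
`d` (Å). A distance exactly equal to `d` is *not* a contact; this makes
the predicate unambiguous and has measure zero for real coordinates.
Averaging `B(t)` over frames gives the contact-probability matrix `P`.
Consecutive contact matrices are differenced into edge-addition /
edge-removal batches, producing a `DynamicGraph`: an initial `Snapshot`
plus `τ − 1` `Batch` objects. The batch size `δ_t = |E⁺_t| + |E⁻_t|` is
summarized as `δ_avg = Σ δ_t / τ` (division by the number of snapshots
`τ`, not by the number of batches).

### Adjacency ids and streamed updates

For an ordered tuple `V' = (v_1, …, v_k)` (with `2 ≤ k ≤ 10`), the
induced subgraph is encoded by reading the strict upper triangle of its
`k × k` adjacency matrix row by row, most significant bit first, so the
pair `(v_1, v_2)` is the highest bit. The state space has
`|A_k| = 2^(k(k−1)/2)` elements. The id is order-dependent, but its
popcount (edge count) is permutation-invariant.

An edge `{a, b}` with both endpoints in the tuple at 1-based positions
`i < j` toggles the bit with exponent
`e = k(k−1)/2 − [(i−1)k + j − i(i+1)/2]`, so a streamed update is
`id ± 2^e`. Adding an edge whose bit is already set (or removing a clear
one) raises `StateCorruptionError` — it means the maintained state has
diverged from the graph. Within one batch, removals are folded before
additions; batches are validated to be disjoint and consistent with the
previous edge set.

### Markov models

For each tuple, consecutive id pairs over the `τ` snapshots are counted
into a `|A_k| × |A_k|` local transition-count matrix. With pseudo-counts
enabled (default), `P_k = 1/|A_k|` is added to **every cell of every
local matrix**, so no transition probability is exactly zero and every
chain is irreducible. All local matrices of tuples containing a vertex
`a` are pooled by summing their counts; the row-normalized pooled matrix
is the global transition matrix `T_g(a)`. Rows with zero total count
(unvisited states, only possible with pseudo-counts off) are set to the
uniform distribution so the matrix stays row-stochastic.

Pooling counts before normalizing is equivalent to a per-state weighted
sum of the slice-conditional probabilities, with weights proportional to
each slice's row counts; a unit test checks this identity explicitly.

### Stationary distribution and entropy

`π` solves `π T = π`, `Σ π = 1`. For state spaces of at most 64 states
the dense left eigendecomposition is used (eigenvalues sorted by
decreasing modulus with a stable argsort; a degenerate dominant
eigenvalue — a reducible/absorbing chain — emits a `RuntimeWarning` and a
deterministic representative is returned). For larger spaces a damped
power iteration on `(I + T)/2` is used (tolerance 1e−12, at most 1e5
iterations); the damping removes period-2 oscillation. Entries below
1e−12 are clipped to zero and the vector renormalized.

Entropy is `H = −Σ π_s log2 π_s` in bits, with `0 log 0 = 0`. Comparing
two runs per vertex uses `ΔH = H_ref − H_other`; positive values mean the
second run lost conformational entropy. Trajectory flexibility is also
available as RMSF, `sqrt(mean_t ‖r_i(t) − mean_t r_i‖²)`, computed
without superposition (the synthetic generator and coarse graphs carry no
global alignment frame), and `ΔRMSF` analogously.

## One-pass pipeline

`run_full_computation(g, k, …)` enumerates ordered tuples
lexicographically, optionally pruned by a contact filter (a tuple
survives iff at least one of its vertex pairs has contact probability
above `min_contact_prob`; default threshold 0, i.e. "ever in contact").
It maintains one integer id per surviving tuple and replays the batch
stream once:

- A precomputed pair index maps each edge to the tuples containing both
  endpoints together with the (constant per position pair) bit exponent,
  so a batch is applied to all affected tuples with vectorized NumPy
  operations.
- Self-transitions are materialized lazily: per tuple only the snapshot
  index at which the current id became current is stored; when the id
  changes at time `t`, `(old, old)` is credited `t − 1 − since` times and
  `(old, new)` once. A final sweep credits the trailing self-run.
- Counts are accumulated directly into one dense `|A_k| × |A_k|` matrix
  per requested vertex (`np.add.at`), i.e. the pooling over slices is
  performed on the fly. This is mathematically identical to building all
  per-tuple matrices first and summing them (the tests verify exact
  agreement with a naive per-tuple replay) but uses memory proportional
  to the number of vertices, not the number of tuples. With
  pseudo-counts, each vertex's pooled matrix receives
  `n_slices · P_k` per cell, where `n_slices` is the number of tuples
  containing that vertex.

The full computation is restricted to `k ≤ 5` (the tuple count grows as
`n!/(n−k)!` and the state space as `2^(k(k−1)/2)`; for a 65-vertex
molecule `k = 5` already means 991,186,560 tuples). A 4 GiB ceiling on
the accumulator allocation is enforced with a clear error. Individual
tuples can still be analyzed at any `k ≤ 10` via `id_series` /
`transition_list` / `local_transition_matrix`.

## Parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| distance cutoff `d` | 13.0 (CLI) | Å | typical residue-contact cutoff for C3′-coarse-grained RNA |
| tuple size `k` | 3 | — | smallest size with non-trivial internal topology; 8 states |
| pseudo-count `P_k` | `1/|A_k|` | counts/cell | vanishes relative to data as `τ → ∞`; guarantees irreducibility |
| `min_contact_prob` | 0.0 | — | keep tuples with any observed contact |
| selector atom | `C3'` | — | one well-defined backbone atom per RNA residue |

Synthetic trajectory generator defaults (`generate_synthetic_trajectory`):
65 residues, 1000 frames, bond length 5.9 Å (typical C3′–C3′ virtual
bond), persistence 0.6 (semi-flexible chain), Gaussian noise σ = 0.8 Å,
sinusoidal "breathing" of relative amplitude 0.03 with period 200
frames. The generator produces a deterministic, seeded chain whose
contact graph fluctuates at realistic rates; it is a *test fixture*, not
a physical model — it has no excluded volume, no base pairing, and no
thermodynamic meaning.

The random dynamic-graph generator draws an initial edge set uniformly
and, per step, removes `⌊δ/2⌋` current edges and adds `δ − ⌊δ/2⌋` absent
ones (drawn from the complement of the previous edge set). Odd `δ` grows
the edge count by one per step; feasibility is therefore re-checked at
every step and violations raise `ParameterError` rather than looping.

## Numerical choices and limitations

- All randomness is explicit via integer seeds (`numpy.random.default_rng`).
- Ties at the distance cutoff count as "no contact" (strict `<`).
- File formats are plain text; XYZ-table floats are written with full
  `repr` precision so write/read round trips are bit-exact.
- Stationary vectors of reducible chains (pseudo-counts disabled, frozen
  dynamics) are not unique; the implementation warns and returns a
  deterministic representative, so comparisons on such chains should be
  interpreted with care.
- Entropy differences between two runs are meaningful only when both use
  the same `k`, cutoff, and pseudo-count setting; `compare_runs` checks
  that the vertex sets and `k` match but cannot check how the inputs
  were produced.
- No trajectory superposition is performed before RMSF; inputs are
  assumed to be free of net translation/rotation or to be used only for
  relative comparisons.
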