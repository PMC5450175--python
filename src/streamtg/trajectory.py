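"""Coordinate trajectories, contact maps, RMSF, and graph conversion.

A trajectory is T frames of n representative atoms (one per residue, by
default the ribose C3' of each nucleotide) in Angstrom.  Two residues are
*in contact* in a frame when their Euclidean distance is strictly below a
cut-off d (10-15 A is typical for C3'-based RNA graphs); per-frame contact
matrices define the snapshots of a dynamic graph, and their time average is
the contact-probability matrix used to prune the tuple enumeration.

RMSF, the conventional per-residue flexibility baseline, is computed about
the time-averaged position without any superposition; pre-align the
trajectory externally if a fitted RMSF is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dynamic_graph import DynamicGraph, Snapshot, snapshots_to_batches
from .errors import InputError, TrajectoryFormatError


@dataclass(frozen=True)
class Trajectory:
    """T frames x n atoms x 3 coordinates (Angstrom) with residue labels."""

    coords: np.ndarray
    labels: tuple[str, ...]

    def __init__(self, coords, labels=None):
        c = np.asarray(coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3 or c.shape[0] < 1:
            raise TrajectoryFormatError(
                f"coords must have shape (T, n, 3), got {c.shape}"
            )
        if not np.isfinite(c).all():
            raise TrajectoryFormatError("coordinates must be finite")
        if labels is None:
            labels = tuple(f"R{i + 1}" for i in range(c.shape[1]))
        labels = tuple(str(x) for x in labels)
        if len(labels) != c.shape[1]:
            raise TrajectoryFormatError(
                f"{len(labels)} labels for {c.shape[1]} atoms"
            )
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "labels", labels)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class ContactMatrix:
    """Binary, symmetric, zero-diagonal contact map of one frame."""

    entries: np.ndarray
    cutoff: float


@dataclass(frozen=True)
class ContactProbabilityMatrix:
    """Per-pair fraction of frames in contact, in [0, 1]."""

    entries: np.ndarray
    cutoff: float


def contact_matrix(frame_coords, d: float) -> ContactMatrix:
    """Binary contact map: entry (i, j) is 1 iff ||r_i - r_j|| < d, i != j.

    The tie case (distance exactly d) counts as no contact; the diagonal is
    zero by definition.
    """
    if d <= 0:
        raise InputError(f"cutoff d must be positive, got {d}")
    X = np.asarray(frame_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise InputError(f"frame coordinates must have shape (n, 3), got {X.shape}")
    if not np.isfinite(X).all():
        raise InputError("frame coordinates must be finite")
    B = (squareform(pdist(X)) < d).astype(np.int8)
    np.fill_diagonal(B, 0)
    return ContactMatrix(entries=B, cutoff=float(d))


def contact_probability(traj: Trajectory, d: float) -> ContactProbabilityMatrix:
    """Fraction of frames each residue pair spends in contact."""
    total = np.zeros((traj.n_atoms, traj.n_atoms))
    for t in range(traj.n_frames):
        total += contact_matrix(traj.coords[t], d).entries
    return ContactProbabilityMatrix(entries=total / traj.n_frames, cutoff=float(d))


def rmsf(traj: Trajectory) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-averaged position.

    RMSF_i = sqrt( (1/T) * sum_t ||r_i(t) - rbar_i||^2 ), in Angstrom.
    No superposition/fitting is applied.
    """
    mean = traj.coords.mean(axis=0)
    sq = ((traj.coords - mean) ** 2).sum(axis=2)
    return np.sqrt(sq.mean(axis=0))


def delta_rmsf(ref: Trajectory, other: Trajectory) -> np.ndarray:
    """RMSF_ref - RMSF_other per atom (positive = loss of fluctuation)."""
    if ref.n_atoms != other.n_atoms:
        raise InputError("trajectories have different atom counts")
    return rmsf(ref) - rmsf(other)


def trajectory_to_dynamic_graph(traj: Trajectory, d: float) -> DynamicGraph:
    """Convert a trajectory to a unit-sphere dynamic graph at cut-off d.

    Snapshot t has edge {i, j} exactly when residues i and j are in contact
    in frame t; the snapshots are converted to initial-plus-batches form.
    """
    snapshots = []
    n = traj.n_atoms
    for t in range(traj.n_frames):
        B = contact_matrix(traj.coords[t], d).entries
        iu, ju = np.nonzero(np.triu(B, k=1))
        snapshots.append(Snapshot(n, set(zip(iu.tolist(), ju.tolist()))))
    return snapshots_to_batches(snapshots)


# ---------------------------------------------------------------------------
# File reading
# ---------------------------------------------------------------------------

DEFAULT_ATOM = "C3'"


def read_trajectory(path, atom_selector: str = DEFAULT_ATOM) -> Trajectory:
    """Read a multi-model PDB or an XYZ-table file into a Trajectory.

    Files ending in ``.pdb`` (case-insensitive) are parsed as multi-model
    PDB, selecting one ``atom_selector`` atom per residue per model (an
    error names the residue if it lacks the atom); anything else is read as
    the whitespace-separated ``frame atom x y z`` table.
    """
    if str(path).lower().endswith(".pdb"):
        return _read_pdb(path, atom_selector)
    return read_xyz_table(path)


def _read_pdb(path, atom_selector: str) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise TrajectoryFormatError(f"{path}: no models found")

    frames = []
    labels_ref: list[str] | None = None
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        coords: list[np.ndarray] = []
        labels: list[str] = []
        seen: list[tuple] = []
        selected: dict[tuple, np.ndarray] = {}
        names: dict[tuple, str] = {}
        for i in range(atoms.array_length()):
            key = (atoms.chain_id[i], int(atoms.res_id[i]))
            if key not in names:
                seen.append(key)
                names[key] = f"{atoms.res_name[i].strip()}{int(atoms.res_id[i])}"
            if atoms.atom_name[i].strip() == atom_selector:
                if key in selected:
                    raise TrajectoryFormatError(
                        f"{path} model {m}: residue {names[key]} has multiple "
                        f"'{atom_selector}' atoms"
                    )
                selected[key] = atoms.coord[i]
        for key in seen:
            if key not in selected:
                raise TrajectoryFormatError(
                    f"{path} model {m}: residue {names[key]} (chain {key[0]}) "
                    f"lacks atom '{atom_selector}'"
                )
            coords.append(selected[key])
            labels.append(names[key])
        if labels_ref is None:
            labels_ref = labels
        elif labels != labels_ref:
            raise TrajectoryFormatError(
                f"{path} model {m}: residue list differs from model 1"
            )
        frames.append(np.array(coords))
    return Trajectory(coords=np.stack(frames), labels=tuple(labels_ref))


def read_xyz_table(path) -> Trajectory:
    """Read the plain XYZ-table dialect: ``frame atom x y z`` per line.

    Frames are ordered by their integer index; every frame must list the
    same atoms in the same order.  '#' starts a comment.
    """
    frames: dict[int, list[tuple[str, tuple[float, float, float]]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) != 5:
                raise TrajectoryFormatError(
                    f"{path} line {lineno}: expected 'frame atom x y z'"
                )
            try:
                t = int(tok[0])
                xyz = (float(tok[2]), float(tok[3]), float(tok[4]))
            except ValueError:
                raise TrajectoryFormatError(
                    f"{path} line {lineno}: malformed numbers in {tok}"
                )
            frames.setdefault(t, []).append((tok[1], xyz))
    if not frames:
        raise TrajectoryFormatError(f"{path}: empty trajectory")
    order = sorted(frames)
    ref = [a for a, _ in frames[order[0]]]
    coords = np.empty((len(order), len(ref), 3))
    for fi, t in enumerate(order):
        atoms = [a for a, _ in frames[t]]
        if atoms != ref:
            raise TrajectoryFormatError(
                f"{path}: frame {t} atom list differs from frame {order[0]}"
            )
        coords[fi] = [xyz for _, xyz in frames[t]]
    return Trajectory(coords=coords, labels=tuple(ref))


def write_xyz_table(traj: Trajectory, path) -> None:
    """Write a Trajectory in the XYZ-table dialect at full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# frame atom x y z\n")
        for t in range(traj.n_frames):
            for i, label in enumerate(traj.labels):
                x, y, z = (float(c) for c in traj.coords[t, i])
                fh.write(f"{t + 1} {label} {x!r} {y!r} {z!r}\n")


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------


def generate_synthetic_trajectory(
    n_residues: int = 65,
    n_frames: int = 1000,
    seed: int = 0,
    bond_length: float = 5.9,
    noise_sd: float = 0.8,
    breathing_amplitude: float = 0.03,
    breathing_period: float = 200.0,
    persistence: float = 0.6,
) -> Trajectory:
    """Generate a coarse-grained RNA-like trajectory for testing and demos.

    The base conformation is a persistent random walk with the ~5.9 A step
    of consecutive C3' atoms, giving a coil that folds back on itself so
    that both sequence-neighbour and tertiary-like contacts occur at the
    usual 10-15 A cut-offs.  Each frame adds isotropic Gaussian thermal
    noise (sd ``noise_sd`` A) and a slow global breathing mode (sinusoidal
    scaling of amplitude ``breathing_amplitude`` about the centroid, period
    ``breathing_period`` frames) so that contacts near the cut-off toggle
    over time.  Deterministic for a fixed seed.
    """
    if n_residues < 2 or n_frames < 1:
        raise InputError("need at least 2 residues and 1 frame")
    rng = np.random.default_rng(seed)

    def unit(v):
        return v / np.linalg.norm(v)

    base = np.zeros((n_residues, 3))
    direction = unit(rng.normal(size=3))
    for i in range(1, n_residues):
        direction = unit(
            persistence * direction + (1.0 - persistence) * unit(rng.normal(size=3))
        )
        base[i] = base[i - 1] + bond_length * direction
    base -= base.mean(axis=0)

    t = np.arange(n_frames)
    scale = 1.0 + breathing_amplitude * np.sin(2.0 * np.pi * t / breathing_period)
    noise = rng.normal(scale=noise_sd, size=(n_frames, n_residues, 3))
    coords = scale[:, None, None] * base[None, :, :] + noise

    alphabet = np.array(list("ACGU"))
    seq = rng.choice(alphabet, size=n_residues)
    labels = tuple(f"{b}{i + 1}" for i, b in enumerate(seq))
    return Trajectory(coords=coords, labels=labels)
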