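import numpy as np
import pytest

from streamtg import Snapshot


def random_snapshots(rng, n_vertices, tau, p=0.3):
    """A list of independent random snapshots on a fixed vertex set."""
    snaps = []
    for _ in range(tau):
        edges = {
            (u, v)
            for u in range(n_vertices)
            for v in range(u + 1, n_vertices)
            if rng.random() < p
        }
        snaps.append(Snapshot(n_vertices, edges))
    return snaps


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element):
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {name_field:<4} {resname:>3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


def write_multimodel_pdb(path, frames, resnames=None, skip=()):
    """Write a minimal multi-model PDB; one P and one C3' atom per residue.

    ``skip`` lists (model, residue) pairs (1-based) whose C3' atom is omitted,
    for exercising missing-atom errors.
    """
    frames = np.asarray(frames, dtype=float)
    n_res = frames.shape[1]
    resnames = resnames or ["G"] * n_res
    lines = []
    for m in range(frames.shape[0]):
        lines.append(f"MODEL     {m + 1:>4}")
        serial = 1
        for r in range(n_res):
            x, y, z = frames[m, r]
            lines.append(
                pdb_atom_line(serial, "P", resnames[r], "A", r + 1, x + 1, y, z, "P")
            )
            serial += 1
            if (m + 1, r + 1) not in skip:
                lines.append(
                    pdb_atom_line(serial, "C3'", resnames[r], "A", r + 1, x, y, z, "C")
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
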