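"""Trajectory and array I/O.

Coordinates come in through mdtraj (PDB topology; XTC/DCD/multi-model PDB
trajectories) with an atom-selection expression defaulting to Cα atoms, or
from an HDF5 container with a ``positions`` dataset (frames x atoms x 3,
Å).  Per-file frame boundaries are preserved so downstream lagged-pair
estimators never straddle trajectory files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .chain import ChainCoordinates


class TrajectoryIOError(IOError):
    """Unreadable files, empty selections, mismatched atom counts."""


def load_trajectory(
    topology: str | None,
    trajectories,
    selection: str = "name CA",
) -> list[ChainCoordinates]:
    """Load one ChainCoordinates per trajectory file (boundaries retained).

    mdtraj works in nm internally; output here is Å.  ``topology`` may be
    None when the trajectory format is self-describing (PDB).
    """
    import mdtraj as md

    paths = trajectories if isinstance(trajectories, (list, tuple)) else [trajectories]
    out = []
    for path in paths:
        if not os.path.exists(path):
            raise TrajectoryIOError(f"trajectory file not found: {path}")
        if topology is not None and not os.path.exists(topology):
            raise TrajectoryIOError(f"topology file not found: {topology}")
        try:
            if topology is None:
                traj = md.load(path)
            else:
                traj = md.load(path, top=topology)
        except Exception as exc:  # mdtraj raises various types
            raise TrajectoryIOError(f"cannot read {path}: {exc}") from exc
        idx = traj.topology.select(selection)
        if len(idx) == 0:
            raise TrajectoryIOError(f"selection {selection!r} matched no atoms")
        sub = traj.atom_slice(idx)
        labels = [
            f"{a.name}:{a.residue.index}" for a in sub.topology.atoms
        ]
        out.append(ChainCoordinates(sub.xyz.astype(np.float64) * 10.0, labels))
    counts = {c.n_atoms for c in out}
    if len(counts) > 1:
        raise TrajectoryIOError(
            f"inconsistent atom counts across trajectory files: {sorted(counts)}"
        )
    return out


def load_positions_h5(path, dataset: str = "positions") -> ChainCoordinates:
    """Read a raw coordinate array (frames x atoms x 3, Å) from HDF5."""
    import h5py

    with h5py.File(path, "r") as h5:
        if dataset not in h5:
            raise TrajectoryIOError(f"dataset {dataset!r} missing in {path}")
        pos = h5[dataset][...]
    return ChainCoordinates(pos)


def save_positions_h5(path, coords: ChainCoordinates) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=coords.positions)
        h5["positions"].attrs["units"] = "angstrom"


def save_multimodel_pdb(path, coords: ChainCoordinates, name: str = "GLY") -> None:
    """Write a Cα trace as a multi-model PDB (one model per frame)."""
    with open(path, "w") as fh:
        for f in range(coords.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, (x, y, z) in enumerate(coords.positions[f]):
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  {name} A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
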