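"""Core containers for Cα-trace coordinates and chain segmentations.

The universal input of the toolkit is a trace of one backbone atom per
residue (by default Cα), stored as a ``frames x atoms x 3`` array in
Ångström.  Segments of *length* ``l`` connect atom ``a`` to atom ``a + l``
along the chain; ``l = 1`` gives the familiar virtual-bond representation
and larger ``l`` smooths the polygonal curve, emphasising global topology
over local structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised when coordinates contain coincident points or zero-length
    segments that make the writhe integrand ill-defined."""


class ParameterError(ValueError):
    """Raised for out-of-range user parameters (segment length, lag, ...)."""


@dataclass
class ChainCoordinates:
    """Per-frame 3D positions of an ordered backbone atom trace.

    Parameters
    ----------
    positions
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.  A single frame of
        shape ``(n_atoms, 3)`` is promoted to one frame.
    atom_labels
        Ordered identifiers of the traced atoms (N-to-C order).  Defaults to
        ``CA:0 ... CA:{n-1}``.
    """

    positions: np.ndarray
    atom_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim == 2:
            pos = pos[None]
        if pos.ndim != 3 or pos.shape[-1] != 3:
            raise ParameterError(
                f"positions must have shape (frames, atoms, 3); got {pos.shape}"
            )
        if pos.shape[1] < 2:
            raise ParameterError("a chain needs at least 2 traced atoms")
        self.positions = pos
        if not self.atom_labels:
            self.atom_labels = [f"CA:{i}" for i in range(pos.shape[1])]
        if len(self.atom_labels) != pos.shape[1]:
            raise ParameterError("atom_labels length must match atom count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def mirrored(self, axis: int = 2) -> "ChainCoordinates":
        """Reflect every frame through the plane normal to ``axis``."""
        pos = self.positions.copy()
        pos[..., axis] *= -1.0
        return ChainCoordinates(pos, list(self.atom_labels))

    def transformed(self, rotation: np.ndarray, translation=0.0) -> "ChainCoordinates":
        """Apply ``x -> x @ R.T + t`` to every frame."""
        rot = np.asarray(rotation, dtype=np.float64)
        pos = self.positions @ rot.T + np.asarray(translation, dtype=np.float64)
        return ChainCoordinates(pos, list(self.atom_labels))


@dataclass
class SegmentTopology:
    """Segmentation of a chain at a fixed segment length ``l``.

    ``pairs[k] = (k, k + l)`` are the atom indices spanned by segment ``k``;
    there are ``n_atoms - l`` segments.
    """

    segment_length: int
    n_atoms: int
    pairs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        l, n = self.segment_length, self.n_atoms
        if not (1 <= l <= n - 1):
            raise ParameterError(f"segment length {l} invalid for {n} atoms")
        starts = np.arange(n - l)
        self.pairs = np.stack([starts, starts + l], axis=1)

    @property
    def n_segments(self) -> int:
        return self.n_atoms - self.segment_length

    def atoms_of_segment(self, k: int) -> tuple[int, int]:
        return int(self.pairs[k, 0]), int(self.pairs[k, 1])

    def segments_incident_to_atom(self, i: int) -> np.ndarray:
        """Segments whose index interval [a, a+l] contains atom ``i``."""
        l = self.segment_length
        lo = max(0, i - l)
        hi = min(self.n_segments - 1, i)
        if hi < lo:
            return np.empty(0, dtype=int)
        return np.arange(lo, hi + 1)


def exclusion_mask(topology: SegmentTopology) -> np.ndarray:
    """Boolean ``n_segments x n_segments`` mask of pairs sharing >= 1 atom.

    Segment ``i`` is the displacement between atoms ``i`` and ``i + l``, so
    segments ``i`` and ``j`` share an endpoint atom iff ``|i - j|`` is 0 or
    ``l``.  The writhe integrand is singular at shared endpoints; those pairs
    are recorded as structural zeros and flagged.
    """
    n = topology.n_segments
    l = topology.segment_length
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    return (diff == 0) | (diff == l)
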