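"""Flat feature matrices from chain trajectories.

Three feature families with distinct parity behaviour:

* multiscale writhe descriptors (parity-odd pseudoscalars),
* all-pairs Euclidean Cα distances (parity-even),
* backbone dihedral sin/cos (sin odd, cos even).

All featurizers return a :class:`FeatureMatrix` — a ``frames x d`` array
with unique string labels — plus an integrated-autocorrelation diagnostic
for comparing how slowly different feature families evolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainCoordinates, ParameterError
from .writhe import writhe_matrix


@dataclass
class FeatureMatrix:
    """``frames x d`` feature values with unique per-column labels."""

    values: np.ndarray
    labels: list[str]
    lag_unit_ns: float = 1.0  # trajectory frame spacing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("feature values must be 2-D (frames x d)")
        if len(self.labels) != self.values.shape[1]:
            raise ParameterError("label count must match feature dimension")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("feature labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature matrix contains NaN/Inf")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if other.n_frames != self.n_frames:
            raise ParameterError("frame counts differ")
        return FeatureMatrix(
            np.hstack([self.values, other.values]),
            self.labels + other.labels,
            self.lag_unit_ns,
        )

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("features/values", data=self.values)
            h5.create_dataset(
                "features/labels",
                data=np.array(self.labels, dtype=h5py.string_dtype()),
            )
            h5["features"].attrs["lag_unit_ns"] = self.lag_unit_ns

    @classmethod
    def load_h5(cls, path) -> "FeatureMatrix":
        import h5py

        with h5py.File(path, "r") as h5:
            values = h5["features/values"][...]
            labels = [s.decode() for s in h5["features/labels"][...]]
            lag_unit = float(h5["features"].attrs.get("lag_unit_ns", 1.0))
        return cls(values, labels, lag_unit)


# ---------------------------------------------------------------------------
# writhe features
# ---------------------------------------------------------------------------

def multiscale_writhe_features(
    coords: ChainCoordinates, lengths, lag_unit_ns: float = 1.0
) -> FeatureMatrix:
    """Flattened writhe matrices at one or more segment lengths.

    For each segment length ``l`` (ascending), the non-excluded upper
    triangle of the per-frame writhe matrix is flattened in fixed ``i < j``
    row-major order; blocks are concatenated across ``l``.  Labels encode
    the segment pair, e.g. ``"wr:l=3:i=4:j=17"``.
    """
    lengths = sorted(set(int(l) for l in lengths))
    if not lengths:
        raise ParameterError("at least one segment length required")
    blocks, labels = [], []
    for l in lengths:
        wm = writhe_matrix(coords, l)
        vals, pairs = wm.upper_triangle()
        blocks.append(vals)
        labels.extend(f"wr:l={l}:i={i}:j={j}" for i, j in pairs)
    return FeatureMatrix(np.hstack(blocks), labels, lag_unit_ns)


# ---------------------------------------------------------------------------
# distance features
# ---------------------------------------------------------------------------

def distance_features(
    coords: ChainCoordinates,
    min_sequence_separation: int = 1,
    lag_unit_ns: float = 1.0,
) -> FeatureMatrix:
    """All pairwise Cα–Cα Euclidean distances with |i−j| >= separation.

    The default separation of 1 keeps truly all pairs (bonded neighbours
    included); distances are parity-even — a structure and its mirror image
    have identical distance features.
    """
    n = coords.n_atoms
    iu, ju = np.triu_indices(n, k=max(1, min_sequence_separation))
    diffs = coords.positions[:, iu, :] - coords.positions[:, ju, :]
    vals = np.linalg.norm(diffs, axis=-1)
    labels = [f"dist:i={i}:j={j}" for i, j in zip(iu, ju)]
    return FeatureMatrix(vals, labels, lag_unit_ns)


# ---------------------------------------------------------------------------
# dihedral features
# ---------------------------------------------------------------------------

def _torsion(p0, p1, p2, p3):
    """Signed dihedral angle (rad, IUPAC convention) for point arrays (..., 3)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components of the outer bonds perpendicular to the central bond
    v = b0 - np.einsum("...i,...i", b0, b1)[..., None] * b1
    w = b2 - np.einsum("...i,...i", b2, b1)[..., None] * b1
    x = np.einsum("...i,...i", v, w)
    y = np.einsum("...i,...i", np.cross(b1, v), w)
    return np.arctan2(y, x)


def dihedral_features(
    backbone: ChainCoordinates, lag_unit_ns: float = 1.0
) -> FeatureMatrix:
    """Sin/cos of φ and ψ backbone dihedrals for interior residues.

    ``backbone`` must carry the full N/CA/C trace in residue order (labels
    ``N:k``, ``CA:k``, ``C:k``); a Cα-only trace is rejected — there is no
    pseudo-dihedral fallback.  φ(k) = C(k−1)–N(k)–CA(k)–C(k) and
    ψ(k) = N(k)–CA(k)–C(k)–N(k+1), both defined for k = 1..n_res−2, so
    d = 4·(n_res − 2).  Dihedrals are parity-odd: mirror reflection negates
    the angles, hence the sin components negate and cos are unchanged.
    """
    labels = backbone.atom_labels
    kinds = [s.split(":")[0] for s in labels]
    if set(kinds) == {"CA"} or "N" not in kinds or "C" not in kinds:
        raise ParameterError(
            "dihedral features need full backbone (N/CA/C) input; "
            "a Cα-only trace is unsupported"
        )
    if kinds[:3] != ["N", "CA", "C"] or len(labels) % 3 != 0:
        raise ParameterError("backbone labels must repeat N, CA, C per residue")
    n_res = len(labels) // 3
    if n_res < 3:
        raise ParameterError("need >= 3 residues for interior dihedrals")
    pos = backbone.positions
    N = pos[:, 0::3]
    CA = pos[:, 1::3]
    C = pos[:, 2::3]
    k = np.arange(1, n_res - 1)
    phi = _torsion(C[:, k - 1], N[:, k], CA[:, k], C[:, k])
    psi = _torsion(N[:, k], CA[:, k], C[:, k], N[:, k + 1])
    blocks = [np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)]
    names = (
        [f"phi_sin:i={i}" for i in k]
        + [f"phi_cos:i={i}" for i in k]
        + [f"psi_sin:i={i}" for i in k]
        + [f"psi_cos:i={i}" for i in k]
    )
    return FeatureMatrix(np.hstack(blocks), names, lag_unit_ns)


# ---------------------------------------------------------------------------
# autocorrelation diagnostics
# ---------------------------------------------------------------------------

def autocorrelation_time(
    fm: FeatureMatrix, max_lag: int | None = None
) -> np.ndarray:
    """Integrated autocorrelation time per feature, in frames.

    ``tau_int = 1 + 2 * sum_k acf(k)`` with the sum truncated at the first
    negative acf value (initial-positive-sequence window, parameter-free).
    Constant features are flagged with NaN rather than raising.
    """
    x = fm.values - fm.values.mean(axis=0)
    n = x.shape[0]
    if max_lag is None:
        max_lag = n // 4
    var = (x**2).mean(axis=0)
    out = np.empty(fm.dim)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acov = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[: max_lag + 1].real
    acov /= n
    for j in range(fm.dim):
        if var[j] < 1e-300:
            out[j] = np.nan
            continue
        acf = acov[1:, j] / var[j]
        neg = np.argmax(acf < 0.0)
        if acf[0] < 0.0:
            k = 0
        elif neg == 0 and acf[-1] >= 0:
            k = len(acf)
        else:
            k = neg
        out[j] = 1.0 + 2.0 * acf[:k].sum()
    return out
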