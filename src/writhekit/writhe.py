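"""Exact discrete writhe of polygonal chains.

The writhe of a curve measures its signed self-crossings averaged over all
viewing directions.  For two straight segments the double Gauss integral has
a closed form: it is the signed solid angle of the spherical quadrilateral
spanned by the four unit view-direction vectors between segment endpoints,
divided by 2π.  This module computes that quantity exactly (vectorized over
frames and segment pairs), assembles per-frame symmetric writhe matrices at
arbitrary segment length ``l``, and provides an independent brute-force
quadrature of the Gauss integral as a correctness oracle.

Conventions
-----------
* A pair value is ``Omega / (2*pi)`` with ``|Omega|`` the quadrilateral's
  solid angle; summing over unordered segment pairs of a discretized curve
  reproduces the Gauss-integral writhe of the curve.
* Crossing sign: ``sign((T_i x T_j) . (mid_j - mid_i))`` — positive when the
  displacement from segment ``i`` to segment ``j`` is along the cross
  product of their tangents.  This component is constant over the pair, so
  any points on the two segments (we use midpoints) give the same sign.
* Open chains only: no virtual closing segments between the termini.
* Writhe is invariant under proper rotations and translations and changes
  sign under reflection (a parity-odd pseudoscalar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chain import (
    ChainCoordinates,
    DegenerateGeometryError,
    ParameterError,
    SegmentTopology,
    exclusion_mask,
)

_MIN_SEPARATION = 1e-8  # Å; endpoint pairs closer than this are degenerate
_PARALLEL_TOL = 1e-12


# ---------------------------------------------------------------------------
# segments and tangents
# ---------------------------------------------------------------------------

def build_segments(
    coords: ChainCoordinates, l: int
) -> tuple[SegmentTopology, np.ndarray]:
    """Segment a chain at length ``l`` and return unit tangent vectors.

    Returns
    -------
    topology : SegmentTopology
    tangents : ndarray, shape (n_frames, n_segments, 3)
        Unit displacement vectors ``positions[a + l] - positions[a]``.
    """
    n = coords.n_atoms
    if not (1 <= l <= n - 1):
        raise ParameterError(f"segment length l={l} requires 1 <= l <= {n - 1}")
    topo = SegmentTopology(segment_length=l, n_atoms=n)
    disp = coords.positions[:, l:, :] - coords.positions[:, :-l, :]
    norms = np.linalg.norm(disp, axis=-1)
    bad = norms < _MIN_SEPARATION
    if np.any(bad):
        f, s = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"zero-length segment: frame {f}, segment ({s}, {s + l})"
        )
    return topo, disp / norms[..., None]


# ---------------------------------------------------------------------------
# pairwise writhe (solid-angle closed form)
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray, guard: bool = True) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if guard:
        n = np.where(n < _PARALLEL_TOL, 1.0, n)
    return v / n


def _solid_angle_writhe(p1, p2, p3, p4):
    """Vectorized signed pair writhe for segment (p1->p2) vs (p3->p4).

    All inputs broadcastable arrays of shape (..., 3).  Returns (..., ).
    """
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = _unit(np.cross(r13, r14))
    n2 = _unit(np.cross(r14, r24))
    n3 = _unit(np.cross(r24, r23))
    n4 = _unit(np.cross(r23, r13))
    area = (
        np.arcsin(np.clip(np.einsum("...i,...i", n1, n2), -1.0, 1.0))
        + np.arcsin(np.clip(np.einsum("...i,...i", n2, n3), -1.0, 1.0))
        + np.arcsin(np.clip(np.einsum("...i,...i", n3, n4), -1.0, 1.0))
        + np.arcsin(np.clip(np.einsum("...i,...i", n4, n1), -1.0, 1.0))
    )
    t1 = p2 - p1
    t2 = p4 - p3
    mid_disp = 0.5 * (p3 + p4) - 0.5 * (p1 + p2)
    sign = np.sign(np.einsum("...i,...i", np.cross(t1, t2), mid_disp))
    return np.abs(area) * sign / (2.0 * np.pi)


def pair_writhe(p_a1, p_a2, p_b1, p_b2) -> float:
    """Signed writhe contribution of one unordered segment pair.

    The value is the solid angle of the spherical quadrilateral whose
    vertices are the unit view directions between the four endpoints,
    normalized by 2π and signed by the crossing orientation.  Its magnitude
    is < 1; parallel tangents give exactly 0.

    Raises
    ------
    DegenerateGeometryError
        If the segments share an endpoint or any inter-endpoint distance is
        below 1e-8 Å.
    """
    pts = [np.asarray(p, dtype=np.float64) for p in (p_a1, p_a2, p_b1, p_b2)]
    for a in range(2):
        for b in range(2, 4):
            if np.linalg.norm(pts[a] - pts[b]) < _MIN_SEPARATION:
                raise DegenerateGeometryError(
                    "segments share an endpoint (or endpoints closer than "
                    f"{_MIN_SEPARATION} Å); this pair must be excluded"
                )
    val = float(_solid_angle_writhe(*pts))
    if not np.isfinite(val):
        raise DegenerateGeometryError("non-finite writhe: degenerate geometry")
    return val


# ---------------------------------------------------------------------------
# writhe matrix
# ---------------------------------------------------------------------------

@dataclass
class WritheMatrix:
    """Per-frame symmetric matrix of pairwise segment writhe.

    ``values[f, i, j]`` is the signed writhe of segments ``i`` and ``j`` in
    frame ``f``; pairs sharing an atom (and the diagonal) are structural
    zeros recorded in ``excluded``.
    """

    values: np.ndarray  # (n_frames, n_segments, n_segments)
    topology: SegmentTopology
    excluded: np.ndarray  # (n_segments, n_segments) bool

    @property
    def segment_length(self) -> int:
        return self.topology.segment_length

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def scaled(self) -> np.ndarray:
        """Display scaling (x2, i.e. Omega/pi).  Never used for features."""
        return 2.0 * self.values

    def upper_triangle(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten non-excluded entries with i < j in fixed row-major order.

        Returns (values: frames x n_kept, index_pairs: n_kept x 2).
        """
        n = self.topology.n_segments
        iu, ju = np.triu_indices(n, k=1)
        keep = ~self.excluded[iu, ju]
        return self.values[:, iu[keep], ju[keep]], np.stack(
            [iu[keep], ju[keep]], axis=1
        )


def writhe_matrix(
    coords: ChainCoordinates, l: int, chunk_frames: int = 256
) -> WritheMatrix:
    """Exact pairwise writhe between all segment pairs at length ``l``.

    Computation is chunked over frames; results are independent of the chunk
    size.  Requires at least 2 segments (``n_atoms - l >= 2``).
    """
    topo, _ = build_segments(coords, l)
    n_seg = topo.n_segments
    if n_seg < 2:
        raise ParameterError("pairwise writhe needs at least 2 segments")
    excl = exclusion_mask(topo)
    iu, ju = np.triu_indices(n_seg, k=1)
    keep = ~excl[iu, ju]
    iu, ju = iu[keep], ju[keep]

    pos = coords.positions
    n_frames = pos.shape[0]
    out = np.zeros((n_frames, n_seg, n_seg), dtype=np.float64)
    a1_idx, a2_idx = topo.pairs[iu, 0], topo.pairs[iu, 1]
    b1_idx, b2_idx = topo.pairs[ju, 0], topo.pairs[ju, 1]
    for start in range(0, n_frames, max(1, chunk_frames)):
        stop = min(start + max(1, chunk_frames), n_frames)
        p = pos[start:stop]
        p1 = p[:, a1_idx]
        p2 = p[:, a2_idx]
        p3 = p[:, b1_idx]
        p4 = p[:, b2_idx]
        # degeneracy guard: any inter-endpoint distance below threshold
        for a_pts in (p1, p2):
            for b_pts in (p3, p4):
                d = np.linalg.norm(a_pts - b_pts, axis=-1)
                if np.any(d < _MIN_SEPARATION):
                    f, k = np.argwhere(d < _MIN_SEPARATION)[0]
                    raise DegenerateGeometryError(
                        f"coincident endpoints in frame {start + f}, "
                        f"segment pair ({iu[k]}, {ju[k]})"
                    )
        vals = _solid_angle_writhe(p1, p2, p3, p4)
        out[start:stop, iu, ju] = vals
        out[start:stop, ju, iu] = vals
    return WritheMatrix(values=out, topology=topo, excluded=excl)


def total_writhe(wm: WritheMatrix) -> np.ndarray:
    """Sum over unordered segment pairs per frame (the chain's total writhe)."""
    n = wm.topology.n_segments
    iu, ju = np.triu_indices(n, k=1)
    return wm.values[:, iu, ju].sum(axis=1)


# ---------------------------------------------------------------------------
# crossing normals
# ---------------------------------------------------------------------------

@dataclass
class CrossingNormals:
    """Unit normals of the planes spanned by segment tangent pairs.

    ``normals[f, i, j]`` is ``unit(T_i x T_j)``; antisymmetric in (i, j).
    Pairs with near-parallel tangents are flagged in ``undefined`` and their
    normal is the zero vector.  Under a proper rotation R the normals map
    through R; under reflection they pick up an extra sign (pseudovectors).
    """

    normals: np.ndarray  # (n_frames, n_seg, n_seg, 3)
    undefined: np.ndarray  # (n_frames, n_seg, n_seg) bool
    topology: SegmentTopology


def crossing_normals(
    coords: ChainCoordinates, l: int, tol: float = 1e-8
) -> CrossingNormals:
    """Normalized cross products of all segment tangent pairs."""
    topo, tangents = build_segments(coords, l)
    cross = np.cross(tangents[:, :, None, :], tangents[:, None, :, :])
    norms = np.linalg.norm(cross, axis=-1)
    undefined = norms < tol
    safe = np.where(undefined, 1.0, norms)
    normals = cross / safe[..., None]
    normals[undefined] = 0.0
    return CrossingNormals(normals=normals, undefined=undefined, topology=topo)


# ---------------------------------------------------------------------------
# quadrature oracle for the Gauss integral
# ---------------------------------------------------------------------------

def gauss_integral_oracle(
    curve: np.ndarray,
    resolution: int | None = None,
    closed: bool = False,
    diagonal_cutoff: int = 1,
) -> float:
    """Brute-force double-sum quadrature of the Gauss writhe integral.

    Evaluates ``(1/4π) ∮∮ (T(s1) x T(s2)) · (r(s2) - r(s1)) / |...|³`` by
    midpoint quadrature on the sampled curve, excluding the singular
    near-diagonal (``|i - j| <= diagonal_cutoff`` sample points, plus the
    wrap-around band for closed curves).  Independent of the solid-angle
    path; serves as the correctness oracle for :func:`pair_writhe` and
    :func:`writhe_matrix`.

    Parameters
    ----------
    curve : (n_points, 3) array
        Dense samples of the curve.  If ``resolution`` is given, the curve
        is re-sampled to that many points by linear interpolation.
    closed : bool
        Treat the last point as connected back to the first.
    """
    pts = np.asarray(curve, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ParameterError("curve must be an (n, 3) point array")
    if resolution is not None:
        if resolution < 64:
            warnings.warn("resolution < 64: quadrature may be inaccurate")
        t_old = np.linspace(0.0, 1.0, len(pts))
        t_new = np.linspace(0.0, 1.0, resolution)
        pts = np.stack([np.interp(t_new, t_old, pts[:, k]) for k in range(3)], axis=1)
    if closed:
        seg = np.roll(pts, -1, axis=0) - pts
        mids = 0.5 * (pts + np.roll(pts, -1, axis=0))
    else:
        seg = np.diff(pts, axis=0)
        mids = 0.5 * (pts[:-1] + pts[1:])
    lens = np.linalg.norm(seg, axis=-1)
    if np.any(lens < _MIN_SEPARATION):
        raise DegenerateGeometryError("repeated sample points on curve")
    m = len(seg)
    diff = mids[None, :, :] - mids[:, None, :]  # r(s2) - r(s1)
    dist = np.linalg.norm(diff, axis=-1)
    idx = np.arange(m)
    gap = np.abs(idx[:, None] - idx[None, :])
    if closed:
        gap = np.minimum(gap, m - gap)
    mask = gap <= diagonal_cutoff
    dist = np.where(mask, 1.0, dist)
    cr = np.cross(seg[:, None, :], seg[None, :, :])
    integrand = np.einsum("ijk,ijk->ij", cr, diff) / dist**3
    integrand[mask] = 0.0
    if np.any(dist[~mask] < _MIN_SEPARATION):
        raise DegenerateGeometryError("self-intersecting sampling")
    return float(integrand.sum() / (4.0 * np.pi))


def cross_curve_writhe_sum(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Sum of pair writhe over all cross-curve segment pairs (closed curves).

    For two disjoint closed polygons this equals twice their Gauss linking
    number — e.g. ±2 for a Hopf link — at any polygon resolution.
    """
    a = np.asarray(curve_a, dtype=np.float64)
    b = np.asarray(curve_b, dtype=np.float64)
    a2 = np.roll(a, -1, axis=0)
    b2 = np.roll(b, -1, axis=0)
    p1 = a[:, None, :]
    p2 = a2[:, None, :]
    p3 = b[None, :, :]
    p4 = b2[None, :, :]
    return float(_solid_angle_writhe(p1, p2, p3, p4).sum())


def gauss_segment_pair_oracle(p_a1, p_a2, p_b1, p_b2, resolution: int = 512) -> float:
    """Quadrature of the Gauss integral restricted to two straight segments.

    The two orderings (s1 on A, s2 on B) and (s1 on B, s2 on A) contribute
    equally, so the pair value is ``2 x (1/4π) ∫_A ∫_B``.
    """
    p_a1, p_a2, p_b1, p_b2 = (
        np.asarray(p, dtype=np.float64) for p in (p_a1, p_a2, p_b1, p_b2)
    )
    t = (np.arange(resolution) + 0.5) / resolution
    a_pts = p_a1 + t[:, None] * (p_a2 - p_a1)
    b_pts = p_b1 + t[:, None] * (p_b2 - p_b1)
    da = (p_a2 - p_a1) / resolution
    db = (p_b2 - p_b1) / resolution
    diff = b_pts[None, :, :] - a_pts[:, None, :]  # r(s2) - r(s1)
    dist = np.linalg.norm(diff, axis=-1)
    if np.any(dist < _MIN_SEPARATION):
        raise DegenerateGeometryError("segments touch: quadrature singular")
    cr = np.cross(da, db)
    integrand = (diff @ cr) / dist**3
    return float(2.0 * integrand.sum() / (4.0 * np.pi))


# ---------------------------------------------------------------------------
# writhe-graph Laplacian: segment-pair writhe -> atom-pair writhe
# ---------------------------------------------------------------------------

def _incidence(topo: SegmentTopology) -> np.ndarray:
    """(n_atoms, n_segments) 0/1 matrix: atom i lies on segment span [a, a+l]."""
    n_atoms, n_seg, l = topo.n_atoms, topo.n_segments, topo.segment_length
    inc = np.zeros((n_atoms, n_seg))
    atoms = np.arange(n_atoms)[:, None]
    segs = np.arange(n_seg)[None, :]
    inc[(atoms >= segs) & (atoms <= segs + l)] = 1.0
    return inc


def writhe_graph_laplacian(wm: WritheMatrix, topo: SegmentTopology | None = None) -> np.ndarray:
    """Map segment-pair writhe to atom-pair writhe by incidence averaging.

    ``w[f, i, j]`` is the mean of ``wm[f, s, t]`` over all segments ``s``
    containing atom ``i`` and ``t`` containing atom ``j`` (degree
    normalization ``1 / (deg_i * deg_j)``).  The map is linear, so the
    result is symmetric, parity-odd, zero for a zero input, and a constant
    matrix maps to that constant on fully incident atom pairs.

    .. note:: This degree-normalized aggregation is this package's declared
       rule for the segment-to-atom feature map; other normalizations of the
       underlying incidence graph are possible.
    """
    if topo is None:
        topo = wm.topology
    if topo.n_segments != wm.values.shape[1]:
        raise ParameterError("topology inconsistent with writhe matrix shape")
    inc = _incidence(topo)
    deg = inc.sum(axis=1)
    norm = np.outer(1.0 / deg, 1.0 / deg)
    return norm[None] * np.einsum("is,fst,jt->fij", inc, wm.values, inc)


def atom_crossing_normals(
    cn: CrossingNormals, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate segment-pair crossing normals to atom pairs.

    Uses the same incidence rule as :func:`writhe_graph_laplacian`: the
    (unnormalized, antisymmetric) cross products are averaged over incident
    segment pairs and re-normalized.  Returns (normals (f, n, n, 3),
    undefined mask).
    """
    topo = cn.topology
    inc = _incidence(topo)
    deg = inc.sum(axis=1)
    norm = np.outer(1.0 / deg, 1.0 / deg)
    agg = np.einsum("is,fstk,jt->fijk", inc, cn.normals, inc) * norm[None, :, :, None]
    mag = np.linalg.norm(agg, axis=-1)
    undefined = mag < tol
    safe = np.where(undefined, 1.0, mag)
    out = agg / safe[..., None]
    out[undefined] = 0.0
    return out, undefined


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------

def save_writhe_h5(path, matrices: list[WritheMatrix]) -> None:
    """Write writhe matrices to HDF5 (upper-triangle storage, i<j order)."""
    import h5py

    with h5py.File(path, "w") as h5:
        for wm in matrices:
            l = wm.segment_length
            vals, pairs = wm.upper_triangle()
            grp = h5.require_group("writhe")
            ds = grp.create_dataset(f"l{l}", data=vals)
            ds.attrs["l"] = l
            ds.attrs["n_atoms"] = wm.topology.n_atoms
            ds.attrs["convention"] = "omega_over_2pi"
            grp.create_dataset(f"l{l}_pairs", data=pairs)
            grp.create_dataset(f"l{l}_mask", data=wm.excluded)


def load_writhe_h5(path, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Read back (values frames x n_kept, index pairs) for segment length l."""
    import h5py

    with h5py.File(path, "r") as h5:
        vals = h5[f"writhe/l{l}"][...]
        pairs = h5[f"writhe/l{l}_pairs"][...]
    return vals, pairs
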