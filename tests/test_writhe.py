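"""Writhe core: solid-angle pair writhe, matrices, oracles, symmetries."""

import numpy as np
import pytest

from writhekit.chain import (
    ChainCoordinates,
    DegenerateGeometryError,
    ParameterError,
    SegmentTopology,
    exclusion_mask,
)
from writhekit.fixtures import canonical_curves, helical_fragment
from writhekit.writhe import (
    atom_crossing_normals,
    build_segments,
    crossing_normals,
    gauss_integral_oracle,
    gauss_segment_pair_oracle,
    load_writhe_h5,
    pair_writhe,
    save_writhe_h5,
    total_writhe,
    writhe_graph_laplacian,
    writhe_matrix,
)

from .conftest import random_rotation


class TestBuildSegments:
    @pytest.mark.parametrize("l,expected_n", [(1, 19), (3, 17), (5, 15)])
    def test_segment_counts_and_pairs(self, helix_chain, l, expected_n):
        topo, tangents = build_segments(helix_chain, l)
        assert topo.n_segments == expected_n
        assert topo.pairs[0].tolist() == [0, l]
        assert topo.pairs[-1].tolist() == [expected_n - 1, expected_n - 1 + l]
        np.testing.assert_allclose(
            np.linalg.norm(tangents, axis=-1), 1.0, atol=1e-12
        )

    def test_l_out_of_range(self, helix_chain):
        with pytest.raises(ParameterError):
            build_segments(helix_chain, 0)
        with pytest.raises(ParameterError):
            build_segments(helix_chain, helix_chain.n_atoms)

    def test_degenerate_segment_raises(self):
        pos = np.zeros((1, 4, 3))
        pos[0] = [[0, 0, 0], [3.8, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]
        with pytest.raises(DegenerateGeometryError):
            build_segments(ChainCoordinates(pos), 1)

    def test_three_atom_chain_single_segment(self):
        coords = ChainCoordinates(np.array([[[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0.5]]]))
        topo, _ = build_segments(coords, 2)
        assert topo.n_segments == 1
        with pytest.raises(ParameterError):
            writhe_matrix(coords, 2)


class TestPairWrithe:
    def test_parallel_segments_zero(self):
        assert pair_writhe((0, 0, 0), (1, 0, 0), (0, 1, 1), (1, 1, 1)) == 0.0

    def test_orthogonal_crossing_matches_quadrature(self):
        args = ((-1, 0, 0), (1, 0, 0), (0, -1, 1), (0, 1, 1))
        val = pair_writhe(*args)
        assert val > 0
        oracle = gauss_segment_pair_oracle(*args, resolution=1200)
        assert abs(val - oracle) <= 1e-6

    @pytest.mark.parametrize("trial", range(5))
    def test_random_pairs_match_quadrature(self, rng, trial):
        pts = rng.normal(size=(4, 3)) * 3.0
        val = pair_writhe(*pts)
        oracle = gauss_segment_pair_oracle(*pts, resolution=1500)
        assert abs(val - oracle) <= 1e-4
        assert abs(val) < 1.0

    def test_mirror_negates_exactly(self, rng):
        pts = rng.normal(size=(4, 3)) * 3.0
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert pair_writhe(*pts) == pytest.approx(-pair_writhe(*mirrored), abs=1e-12)

    def test_shared_endpoint_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            pair_writhe((0, 0, 0), (1, 0, 0), (1, 0, 0), (1, 1, 0))


class TestWritheMatrix:
    def test_planar_chain_all_zero(self):
        zig = canonical_curves("planar_zigzag", 12)
        wm = writhe_matrix(ChainCoordinates(zig[None]), 1)
        np.testing.assert_allclose(wm.values, 0.0, atol=1e-12)

    def test_symmetry_and_exclusion_structure(self, random_chains):
        wm = writhe_matrix(random_chains, 1)
        np.testing.assert_allclose(
            wm.values, np.swapaxes(wm.values, 1, 2), atol=0
        )
        assert np.all(wm.values[:, wm.excluded] == 0.0)
        assert np.all(np.abs(wm.values) < 1.0)

    def test_mirror_pair_negates(self, random_chains):
        wm = writhe_matrix(random_chains, 1)
        wm_m = writhe_matrix(random_chains.mirrored(), 1)
        np.testing.assert_allclose(wm.values, -wm_m.values, atol=1e-12)

    def test_se3_invariance(self, random_chains, rng):
        wm = writhe_matrix(random_chains, 1)
        rot = random_rotation(rng)
        moved = random_chains.transformed(rot, translation=[11.0, -4.0, 2.5])
        wm_r = writhe_matrix(moved, 1)
        assert np.abs(wm.values - wm_r.values).max() <= 1e-10

    def test_chunking_determinism(self, random_chains):
        a = writhe_matrix(random_chains, 1, chunk_frames=1).values
        b = writhe_matrix(random_chains, 1, chunk_frames=1000).values
        np.testing.assert_array_equal(a, b)

    def test_helix_discretization_matches_gauss_quadrature(self):
        pts = canonical_curves("helix", 401, turns=2.0, radius=1.0, pitch=0.1)
        wm = writhe_matrix(ChainCoordinates(pts[None]), 1)
        discrete = total_writhe(wm)[0]
        oracle = gauss_integral_oracle(pts, closed=False)
        assert abs(discrete - oracle) <= 1e-3


class TestTotalWrithe:
    def test_zero_matrix(self):
        zig = canonical_curves("planar_zigzag", 10)
        wm = writhe_matrix(ChainCoordinates(zig[None]), 1)
        assert total_writhe(wm)[0] == 0.0

    def test_mirror_frames_opposite_totals(self, random_chains):
        tot = total_writhe(writhe_matrix(random_chains, 1))
        tot_m = total_writhe(writhe_matrix(random_chains.mirrored(), 1))
        np.testing.assert_allclose(tot, -tot_m, atol=1e-12)

    @pytest.mark.parametrize("resolution", [16, 64, 128])
    def test_hopf_link_sum_is_two(self, resolution):
        from writhekit.writhe import cross_curve_writhe_sum

        a, b = canonical_curves("hopf_link", resolution)
        total = cross_curve_writhe_sum(a, b)
        assert abs(abs(total) - 2.0) <= 1e-9

    def test_cross_curve_sum_matches_pairwise_loop(self):
        """Vectorized cross-curve sum agrees with the scalar pair routine."""
        a, b = canonical_curves("hopf_link", 12)
        from writhekit.writhe import cross_curve_writhe_sum

        seg_a = np.roll(a, -1, axis=0) - a
        seg_b = np.roll(b, -1, axis=0) - b
        loop = sum(
            pair_writhe(a[i], a[i] + seg_a[i], b[j], b[j] + seg_b[j])
            for i in range(12)
            for j in range(12)
        )
        assert cross_curve_writhe_sum(a, b) == pytest.approx(loop, abs=1e-12)


class TestCrossingNormals:
    def test_orthogonal_tangents_give_unit_normal(self):
        pos = np.array([[[0, 0, 0], [1, 0, 0], [1, 1, 0]]], dtype=float)
        cn = crossing_normals(ChainCoordinates(pos), 1)
        np.testing.assert_allclose(cn.normals[0, 0, 1], [0, 0, 1], atol=1e-12)
        assert not cn.undefined[0, 0, 1]

    def test_parallel_tangents_flagged(self):
        pos = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0]]], dtype=float)
        cn = crossing_normals(ChainCoordinates(pos), 1)
        assert cn.undefined[0, 0, 1]
        np.testing.assert_array_equal(cn.normals[0, 0, 1], 0.0)

    def test_rotation_equivariance(self, random_chains, rng):
        rot = random_rotation(rng)
        cn = crossing_normals(random_chains, 1)
        cn_r = crossing_normals(random_chains.transformed(rot), 1)
        expected = cn.normals @ rot.T
        assert np.abs(cn_r.normals - expected).max() <= 1e-10

    def test_unit_norm_where_defined(self, random_chains):
        cn = crossing_normals(random_chains, 1)
        norms = np.linalg.norm(cn.normals, axis=-1)
        assert np.allclose(norms[~cn.undefined], 1.0, atol=1e-12)


class TestGaussOracle:
    def test_planar_circle_zero(self):
        circle = canonical_curves("circle", 256)
        assert abs(gauss_integral_oracle(circle, closed=True)) <= 1e-9

    def test_mirror_negation(self):
        pts = canonical_curves("helix", 256, turns=2.0)
        w = gauss_integral_oracle(pts)
        w_m = gauss_integral_oracle(pts * np.array([1.0, 1.0, -1.0]))
        assert w == pytest.approx(-w_m, abs=1e-12)

    def test_self_convergence_on_helix(self):
        vals = [
            gauss_integral_oracle(canonical_curves("helix", r, turns=2.0))
            for r in (256, 512, 1024)
        ]
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])
        assert abs(vals[2] - vals[1]) < 1e-4


class TestWritheGraphLaplacian:
    def test_zero_maps_to_zero(self):
        zig = canonical_curves("planar_zigzag", 8)
        wm = writhe_matrix(ChainCoordinates(zig[None]), 1)
        w = writhe_graph_laplacian(wm)
        np.testing.assert_allclose(w, 0.0, atol=1e-15)

    def test_parity_preserved(self, random_chains):
        w = writhe_graph_laplacian(writhe_matrix(random_chains, 1))
        w_m = writhe_graph_laplacian(writhe_matrix(random_chains.mirrored(), 1))
        np.testing.assert_allclose(w, -w_m, atol=1e-12)

    def test_single_entry_against_bruteforce_loop(self):
        """5-atom chain, l=1: hand-checkable incidence average."""
        topo = SegmentTopology(segment_length=1, n_atoms=5)
        vals = np.zeros((1, 4, 4))
        vals[0, 0, 3] = vals[0, 3, 0] = 0.5
        from writhekit.writhe import WritheMatrix

        wm = WritheMatrix(values=vals, topology=topo, excluded=exclusion_mask(topo))
        w = writhe_graph_laplacian(wm)
        # brute-force reference loop over incident segment pairs
        expected = np.zeros((5, 5))
        for i in range(5):
            segs_i = topo.segments_incident_to_atom(i)
            for j in range(5):
                segs_j = topo.segments_incident_to_atom(j)
                acc = sum(vals[0, s, t] for s in segs_i for t in segs_j)
                expected[i, j] = acc / (len(segs_i) * len(segs_j))
        np.testing.assert_allclose(w[0], expected, atol=1e-15)
        np.testing.assert_allclose(w[0], w[0].T, atol=1e-15)

    def test_atom_crossing_normals_pseudovector(self, random_chains, rng):
        cn = crossing_normals(random_chains, 1)
        agg, undef = atom_crossing_normals(cn)
        rot = random_rotation(rng)
        cn_r = crossing_normals(random_chains.transformed(rot), 1)
        agg_r, _ = atom_crossing_normals(cn_r)
        assert np.abs(agg_r - agg @ rot.T).max() <= 1e-10


class TestPairWritheProperties:
    """Property-based symmetry contracts on arbitrary segment pairs."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    coords = st.floats(min_value=-8.0, max_value=8.0,
                       allow_nan=False, allow_infinity=False)

    @staticmethod
    def _segments(vals):
        pts = np.array(vals, dtype=np.float64).reshape(4, 3)
        if (np.linalg.norm(pts[1] - pts[0]) < 1e-3
                or np.linalg.norm(pts[3] - pts[2]) < 1e-3):
            return None
        # the contract excludes touching/intersecting segments: reject pairs
        # whose sampled minimum distance is below the grid resolution
        t = np.linspace(0.0, 1.0, 64)
        a_pts = pts[0] + t[:, None] * (pts[1] - pts[0])
        b_pts = pts[2] + t[:, None] * (pts[3] - pts[2])
        gap = np.linalg.norm(a_pts[:, None] - b_pts[None, :], axis=-1).min()
        longest = max(np.linalg.norm(pts[1] - pts[0]),
                      np.linalg.norm(pts[3] - pts[2]))
        if gap < max(2.0 * longest / 63.0, 1e-3):
            return None
        return pts

    @given(st.lists(coords, min_size=12, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_parity_and_swap_symmetry(self, vals):
        pts = self._segments(vals)
        if pts is None:
            return
        w = pair_writhe(*pts)
        assert abs(w) < 1.0
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        assert pair_writhe(*mirrored) == pytest.approx(-w, abs=1e-12)
        # unordered pair: swapping the two segments changes nothing
        swapped = pair_writhe(pts[2], pts[3], pts[0], pts[1])
        assert swapped == pytest.approx(w, abs=1e-12)

    @given(st.lists(coords, min_size=12, max_size=12),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, vals, rot_seed):
        pts = self._segments(vals)
        if pts is None:
            return
        rot = random_rotation(np.random.default_rng(rot_seed))
        moved = pts @ rot.T + np.array([3.0, -7.0, 11.0])
        # hypothesis explores near-degenerate pairs where arcsin rounding
        # amplifies; generic-chain invariance to 1e-10 is asserted elsewhere
        assert pair_writhe(*moved) == pytest.approx(pair_writhe(*pts),
                                                    abs=1e-7)


class TestHDF5RoundTrip:
    def test_save_and_load(self, random_chains, tmp_path):
        path = tmp_path / "writhe.h5"
        mats = [writhe_matrix(random_chains, l) for l in (1, 3)]
        save_writhe_h5(path, mats)
        vals, pairs = load_writhe_h5(path, 1)
        expected, expected_pairs = mats[0].upper_triangle()
        np.testing.assert_array_equal(vals, expected)
        np.testing.assert_array_equal(pairs, expected_pairs)
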