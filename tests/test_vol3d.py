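"""3D linking, morphometrics, spheroid detection, and projections."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import spherotox as st
from spherotox.seg2d import PlaneObject
from spherotox.vol3d import connect_by_best_match, max_projection

from conftest import make_plane_object


def brute_force_best_matching(a_xy, b_xy, cap):
    """Exhaustive oracle: over all injective partial mappings a->b within
    the cap, maximize the number of matches, then minimize total
    distance. Returns (n_matches, total_distance)."""
    na, nb = len(a_xy), len(b_xy)
    best = (0, 0.0)
    k_max = min(na, nb)
    found_any = False
    for k in range(k_max, -1, -1):
        best_cost = None
        for rows in itertools.combinations(range(na), k):
            for cols in itertools.permutations(range(nb), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d = math.dist(a_xy[i], b_xy[j])
                    if d > cap:
                        ok = False
                        break
                    cost += d
                if ok and (best_cost is None or cost < best_cost):
                    best_cost = cost
        if best_cost is not None:
            best = (k, best_cost)
            found_any = True
            break
    return best if found_any else (0, 0.0)


def link_stats(a_xy, b_xy, cap):
    """(n_matches, total_distance) produced by the linker on a 2-plane
    instance."""
    planes = [
        [make_plane_object(i, 0, x, y) for i, (x, y) in enumerate(a_xy)],
        [make_plane_object(i, 1, x, y) for i, (x, y) in enumerate(b_xy)],
    ]
    objs = connect_by_best_match(planes, 10.0, cap)
    pairs = [o for o in objs if o.n_planes == 2]
    total = sum(
        math.dist(o.members[0].centroid_um, o.members[1].centroid_um)
        for o in pairs
    )
    return len(pairs), total


class TestConnectByBestMatch:
    def test_single_plane_objects_become_3d_objects(self):
        planes = [[make_plane_object(1, 0, 10, 10, area_um2=78.5)]]
        objs = connect_by_best_match(planes, 10.0, 7.5)
        assert len(objs) == 1
        assert objs[0].volume_um3 == pytest.approx(785.0)

    def test_aligned_disks_link_into_one_object_with_exact_volume(self):
        """3 vertically aligned sections with 2 um jitter -> one object
        whose volume is exactly sum(area) x z-step."""
        planes = [
            [make_plane_object(1, 0, 50.0, 50.0, area_um2=78.5)],
            [make_plane_object(1, 1, 52.0, 50.0, area_um2=78.5)],
            [make_plane_object(1, 2, 50.0, 48.0, area_um2=78.5)],
        ]
        objs = connect_by_best_match(planes, 10.0, 7.5)
        assert len(objs) == 1
        assert objs[0].volume_um3 == pytest.approx(3 * 78.5 * 10.0)
        assert objs[0].n_planes == 3

    def test_displacement_cap_separates_or_joins_columns(self):
        """Two columns 15 um apart: separate under the nuclei cap
        (7.5 um), linkable under the cytoplasm cap (25 um)."""
        planes = [
            [make_plane_object(1, 0, 50.0, 50.0)],
            [make_plane_object(1, 1, 65.0, 50.0)],
        ]
        assert len(connect_by_best_match(planes, 10.0, 7.5)) == 2
        assert len(connect_by_best_match(planes, 10.0, 25.0)) == 1

    def test_empty_input_empty_output(self):
        assert connect_by_best_match([], 10.0, 7.5) == []
        assert connect_by_best_match([[], []], 10.0, 7.5) == []

    def test_gap_tolerance_bridges_dropout(self):
        planes = [
            [make_plane_object(1, 0, 50.0, 50.0)],
            [],
            [make_plane_object(1, 2, 50.0, 50.0)],
        ]
        assert len(connect_by_best_match(planes, 10.0, 7.5, max_gap_planes=0)) == 2
        assert len(connect_by_best_match(planes, 10.0, 7.5, max_gap_planes=1)) == 1

    def test_max_span_caps_chain_length(self):
        planes = [[make_plane_object(1, z, 50.0, 50.0)] for z in range(6)]
        objs = connect_by_best_match(planes, 10.0, 7.5, max_span_planes=2)
        assert sorted(o.n_planes for o in objs) == [2, 2, 2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            connect_by_best_match([], 10.0, 0.0)
        with pytest.raises(ValueError):
            connect_by_best_match([], 0.0, 7.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hyp.data())
    def test_matches_brute_force_assignment(self, data):
        """On randomized small instances the linker achieves the
        exhaustively-enumerated optimum: maximum number of feasible
        links and minimum total displacement."""
        coord = hyp.floats(0.0, 40.0, allow_nan=False)
        pt = hyp.tuples(coord, coord)
        a = data.draw(hyp.lists(pt, min_size=0, max_size=6))
        b = data.draw(hyp.lists(pt, min_size=0, max_size=6))
        cap = data.draw(hyp.sampled_from([5.0, 12.0, 30.0]))
        n_ours, cost_ours = link_stats(a, b, cap)
        n_oracle, cost_oracle = brute_force_best_matching(a, b, cap)
        assert n_ours == n_oracle
        assert cost_ours == pytest.approx(cost_oracle, abs=1e-6)

    def test_matches_brute_force_on_full_8x8_instance(self):
        """A dense 8-objects-per-plane instance (every pairing feasible)
        is matched at the enumerated minimum total displacement."""
        rng = np.random.default_rng(17)
        a = [tuple(p) for p in rng.uniform(0, 50, (8, 2))]
        b = [tuple(p) for p in rng.uniform(0, 50, (8, 2))]
        n_ours, cost_ours = link_stats(a, b, cap=200.0)
        n_oracle, cost_oracle = brute_force_best_matching(a, b, cap=200.0)
        assert n_ours == n_oracle == 8
        assert cost_ours == pytest.approx(cost_oracle, abs=1e-9)

    def test_no_plane_object_used_twice(self, analyzed_control):
        """Every 2D section belongs to at most one 3D object."""
        nuclei3d, cyto3d, _ = analyzed_control
        for group in (nuclei3d, cyto3d):
            ids = [id(m) for o in group for m in o.members]
            assert len(ids) == len(set(ids))

    def test_members_strictly_increasing_in_z(self, analyzed_control):
        nuclei3d, _, _ = analyzed_control
        for o in nuclei3d:
            zs = o.z_indices
            assert all(b > a for a, b in zip(zs, zs[1:]))


class TestMeasureObject3D:
    def _stack(self, value=10.0, shape=(11, 120, 120)):
        data = np.full((1, *shape), value, dtype=np.uint16)
        return st.ImageStack(data=data, pixel_size_um=1.0, z_step_um=10.0,
                             channel_names=["DAPI"])

    def _sphere_members(self, cx=60.0, cy=60.0, cz=50.0, radius=50.0):
        members = []
        for k in range(11):
            dz = k * 10.0 - cz
            rad2 = radius**2 - dz**2
            if rad2 <= 0:
                continue
            ys, xs = np.mgrid[0:120, 0:120]
            mask = ((ys + 0.5 - cy) ** 2 + (xs + 0.5 - cx) ** 2) < rad2
            coords = np.argwhere(mask)
            members.append(PlaneObject(
                label=1, z_index=k, coords=coords, area_um2=float(mask.sum()),
                centroid_um=(cx, cy)))
        return members

    def test_voxelized_sphere_volume_close_to_closed_form(self):
        """A 100 um sphere sampled at 1 um XY / 10 um Z measures within
        5% of (4/3) pi r^3, equivalent diameter 100 +- 2 um."""
        members = self._sphere_members()
        obj = st.Object3D(label=1, members=members, z_step_um=10.0)
        obj = st.measure_object3d(obj, self._stack())
        true_v = 4.0 / 3.0 * math.pi * 50.0**3
        assert obj.volume_um3 == pytest.approx(true_v, rel=0.05)
        assert obj.equivalent_diameter_um == pytest.approx(100.0, abs=2.0)

    def test_single_pixel_volume_is_voxel_volume(self):
        m = PlaneObject(label=1, z_index=3, coords=np.array([[7, 9]]),
                        area_um2=1.0, centroid_um=(9.5, 7.5))
        obj = st.Object3D(label=1, members=[m], z_step_um=10.0)
        obj = st.measure_object3d(obj, self._stack())
        assert obj.volume_um3 == pytest.approx(10.0)

    def test_uniform_intensity_object_mean_equals_constant(self):
        members = self._sphere_members()
        obj = st.Object3D(label=1, members=members, z_step_um=10.0)
        obj = st.measure_object3d(obj, self._stack(value=137.0))
        assert obj.mean_intensity["DAPI"] == pytest.approx(137.0)
        assert obj.integrated_intensity["DAPI"] == pytest.approx(
            137.0 * obj.volume_um3, rel=1e-9)


class TestFindSphericalObject:
    def test_recovers_220_um_diameter_with_optics_disabled(self):
        """A rendered 1,000-cell spheroid imaged with no depth limit
        measures 220 +- 11 um in equivalent diameter."""
        cfg = st.SyntheticConfig(n_cells=1000, seed=2, n_planes=23,
                                 imaging_depth_cutoff_um=math.inf,
                                 noise_model="none")
        truth = st.generate_spheroid_truth(cfg)
        stack = st.render_stack(truth, cfg)
        region = st.find_spherical_object(stack)
        assert region is not None
        assert region.equivalent_diameter_um == pytest.approx(220.0, abs=11.0)
        assert 0.0 < region.sphericity <= 1.0

    def test_blank_stack_gives_no_spheroid(self):
        data = np.zeros((1, 5, 64, 64), dtype=np.uint16)
        stack = st.ImageStack(data=data, pixel_size_um=1.0, z_step_um=10.0,
                              channel_names=["DAPI"])
        assert st.find_spherical_object(stack) is None

    def test_larger_of_two_spheroids_is_returned(self):
        """Two disjoint blobs: the bigger one is selected (oracle:
        connected components ranked by volume)."""
        from scipy import ndimage as ndi

        data = np.zeros((1, 9, 200, 200), dtype=np.uint16)
        zz, yy, xx = np.mgrid[0:9, 0:200, 0:200]
        big = ((xx - 60) ** 2 + (yy - 100) ** 2 + ((zz - 4) * 10) ** 2) < 45**2
        small = ((xx - 160) ** 2 + (yy - 100) ** 2 + ((zz - 4) * 10) ** 2) < 28**2
        data[0][big | small] = 1000
        stack = st.ImageStack(data=data, pixel_size_um=1.0, z_step_um=10.0,
                              channel_names=["DAPI"])
        region = st.find_spherical_object(stack)
        labels, n = ndi.label(big | small)
        volumes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        assert region.volume_um3 == pytest.approx(10.0 * volumes.max(), rel=0.2)
        cx = region.centroid_um[0]
        assert abs(cx - 60.0) < 10.0

    def test_conservation_nuclei_volume_below_spheroid_volume(
            self, analyzed_control):
        nuclei3d, _, region = analyzed_control
        assert region is not None
        assert sum(o.volume_um3 for o in nuclei3d) <= region.volume_um3


class TestMaxProjection:
    def _stack(self, data):
        return st.ImageStack(data=data[None], pixel_size_um=1.0,
                             z_step_um=10.0, channel_names=["DAPI"])

    def test_identical_planes_project_to_one_plane(self):
        plane = np.random.default_rng(0).integers(0, 100, (20, 20)).astype(np.uint16)
        stack = self._stack(np.stack([plane] * 5))
        np.testing.assert_array_equal(max_projection(stack, "DAPI"), plane)

    def test_single_nonzero_plane_is_the_projection(self):
        data = np.zeros((5, 16, 16), dtype=np.uint16)
        data[3, 4, 7] = 55
        stack = self._stack(data)
        np.testing.assert_array_equal(max_projection(stack, "DAPI"), data[3])

    def test_random_stack_matches_explicit_z_loop(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 5000, (7, 25, 31)).astype(np.uint16)
        stack = self._stack(data)
        proj = max_projection(stack, "DAPI")
        oracle = data[0].copy()
        for k in range(1, 7):
            oracle = np.maximum(oracle, data[k])
        np.testing.assert_array_equal(proj, oracle)

    def test_maxpro_count_is_at_most_3d_count(self, control_stack,
                                              analyzed_control):
        """Nuclei countable on the 2D maximum projection are a fraction
        of nuclei counted by 3D linking on the same stack."""
        from spherotox.seg2d import segment_nuclei_plane

        nuclei3d, _, _ = analyzed_control
        proj = max_projection(control_stack, "DAPI").astype(float)
        objs_2d = segment_nuclei_plane(proj, control_stack.pixel_size_um)
        assert 0 < len(objs_2d) <= len(nuclei3d)
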