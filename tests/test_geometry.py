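import numpy as np
import pytest

from lvflow import geometry as geo, image_io, phantoms


def half_disk_wall(radius, n=101):
    phi = np.linspace(0, np.pi, n)
    return np.column_stack([-radius * np.cos(phi), -radius * np.sin(phi)])


# ------------------------------------------------------------------ cycle time

def test_cycle_phase_basics():
    cp = geo.CyclePhase(0.4)
    assert cp.time_seconds == pytest.approx(0.4)
    assert cp.is_systole
    assert geo.CyclePhase(0.2, heart_rate=120).time_seconds == pytest.approx(0.1)
    with pytest.raises(ValueError):
        geo.CyclePhase(1.2)


def test_systolic_blend_endpoints():
    assert geo.systolic_interp_factor(0.0) == 0.0
    assert geo.systolic_interp_factor(0.4) == 1.0
    assert geo.systolic_interp_factor(1.0) == 0.0
    assert geo.systolic_interp_factor(0.2) == pytest.approx(0.5)
    assert geo.systolic_interp_factor(0.7) == pytest.approx(0.5)


# ------------------------------------------------------------------- 2D motion

class TestMotion2D:
    def test_linear_interpolation_of_radii(self):
        """Concentric half-disks 20 -> 15 mm: T=0.2 is the exact node-wise
        midpoint, i.e. every node sits at radius 17.5 mm (up to polyline
        chord error)."""
        motion = geo.build_motion_2d(
            [half_disk_wall(20.0), half_disk_wall(15.0)], [0.0, 0.4])
        w = motion.wall_at(0.2)
        assert np.allclose(w, 0.5 * (motion.keyframe_walls[0]
                                     + motion.keyframe_walls[1]), atol=1e-12)
        r = np.linalg.norm(w, axis=1)
        assert np.allclose(r, 17.5, atol=5e-3)

    def test_identical_keyframes_zero_motion(self):
        motion = geo.build_motion_2d(
            [half_disk_wall(18.0), half_disk_wall(18.0)], [0.0, 0.4])
        for T in (0.1, 0.5, 0.9):
            assert np.allclose(motion.wall_at(T), motion.wall_at(0.0))
            assert np.allclose(motion.wall_velocity_at(T), 0.0)

    def test_area_continuous_and_matches_shoelace(self):
        """area(T) equals the shoelace area of the interpolated polygon and
        is continuous in T."""
        spec = phantoms.PhantomSpec(kind="half_ellipsoid_lv")
        walls, times = phantoms.long_axis_keyframe_traces(spec)
        motion = geo.build_motion_2d(walls, times)
        Ts = np.linspace(0, 1, 401)
        areas = np.array([motion.area_at(T) for T in Ts])
        assert np.allclose(areas[0], np.pi * 80 * 25 / 2, rtol=1e-3)
        for T in (0.13, 0.57):
            assert motion.area_at(T) == pytest.approx(
                geo.polygon_area(motion.wall_at(T)))
        jumps = np.abs(np.diff(areas))
        assert jumps.max() < 0.01 * (areas.max() - areas.min())

    def test_closed_trace_clipped_at_io(self):
        """A closed trace crossing y=0 is reduced to its wall (y<=0) part."""
        phi = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        closed = np.column_stack([20 * np.cos(phi), 10 - 25 * np.sin(phi)])
        motion = geo.build_motion_2d([closed, closed], [0.0, 0.4])
        w = motion.wall_at(0.0)
        assert np.all(w[:, 1] <= 1e-9)
        assert w[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert w[-1, 1] == pytest.approx(0.0, abs=1e-12)
        assert w[0, 0] < w[-1, 0]

    def test_trace_not_reaching_io_raises(self):
        phi = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        below = np.column_stack([5 * np.cos(phi), -10 + 3 * np.sin(phi)])
        with pytest.raises(ValueError):
            geo.build_motion_2d([below, below], [0.0, 0.4])

    def test_wall_velocity_is_derivative(self):
        motion = geo.build_motion_2d(
            [half_disk_wall(20.0), half_disk_wall(15.0)], [0.0, 0.4])
        v = motion.wall_velocity_at(0.2)     # mm/s at 60 bpm
        dx = (motion.wall_at(0.21) - motion.wall_at(0.19)) / 0.02
        assert np.allclose(v, dx, atol=1e-9)


# ------------------------------------------------------------ 3D reconstruction

class TestReconstruct3D:
    @pytest.fixture(scope="class")
    @staticmethod
    def cylinder_traces(dicom_dir):
        """Circular pixel-space traces of radius 15 mm on each slice."""
        stacks = image_io.load_cine_stack(sorted(dicom_dir.glob("*.dcm")))
        stack = next(s for s in stacks if s.view == "short_axis")
        r_px = 15.0 / stack.pixel_spacing[0]
        th = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        c = (stack.frames.shape[2] - 1) / 2
        # taper the last ring a little so the base end is detectable
        traces = []
        for i in range(stack.n_slices):
            rr = r_px * (1.0 - 0.02 * i)
            pts = np.column_stack([c + rr * np.sin(th), c + rr * np.cos(th)])
            traces.append((i, pts))
        return stack, traces

    def test_cylinder_rings(self, cylinder_traces):
        stack, traces = cylinder_traces
        cs = geo.reconstruct_3d_contours(traces, stack, n_theta=32)
        assert cs.n_rings == stack.n_slices
        # each ring is a circle of ~15 mm; base ring (index 0) is the largest
        for k, ring in enumerate(cs.rings):
            c = ring.mean(axis=0)
            r = np.linalg.norm(ring - c, axis=1)
            assert abs(r.mean() - 15.0 * (1 - 0.02 * 0)) < 0.8 or k > 0
            assert r.std() < 0.5
        assert cs.ring_spacing() == pytest.approx(8.0, abs=1e-6)
        # base first: ring areas non-increasing
        areas = [geo.polygon_area(r[:, :2]) for r in cs.rings]
        assert areas[0] >= areas[-1]

    def test_single_slice_errors(self, cylinder_traces):
        stack, traces = cylinder_traces
        with pytest.raises(ValueError):
            geo.reconstruct_3d_contours(traces[:1], stack)

    def test_out_of_order_warns(self, cylinder_traces):
        stack, traces = cylinder_traces
        with pytest.warns(UserWarning):
            geo.reconstruct_3d_contours(traces[::-1], stack, n_theta=16)


# ------------------------------------------------------ correspondence surfaces

class TestSurfaces:
    @pytest.fixture(scope="class")
    @staticmethod
    def cylinder_surfaces():
        spec = phantoms.PhantomSpec(kind="contracting_cylinder", n_rings=8,
                                    n_theta=32)
        return phantoms.make_benchmark_case(spec)

    def test_correspondence_counts(self, cylinder_surfaces):
        g = cylinder_surfaces.motion
        assert g.nodes_ed.shape == g.nodes_es.shape
        assert len(g.tris) > 0

    def test_radial_correspondence(self, cylinder_surfaces):
        """Cylinder ED r=15 vs ES r=12: corresponding wall nodes differ only
        radially by 3 mm."""
        g = cylinder_surfaces.motion
        d = g.nodes_es - g.nodes_ed
        ring_nodes = g.ring_ids.ravel()
        radial = np.linalg.norm(d[ring_nodes, :2], axis=1)
        assert np.allclose(radial, 3.0, atol=0.1)
        assert np.allclose(d[ring_nodes, 2], 0.0, atol=1e-9)

    def test_enclosed_volume_vs_oracle(self, cylinder_surfaces):
        """Surface-enclosed volume within 2% of the brute-force
        signed-tetrahedra oracle and of the analytic capped cylinder."""
        g = cylinder_surfaces.motion
        vol = geo.enclosed_volume(g.nodes_ed, g.tris, g.io_ring)
        # independent oracle: signed tets from an arbitrary exterior point
        ref_pt = np.array([123.4, -77.0, 55.0])
        ring = g.io_ring
        cap_c = g.nodes_ed[ring].mean(axis=0)
        pts = np.vstack([g.nodes_ed, cap_c])
        cap = [(ring[j], ring[(j + 1) % len(ring)], len(pts) - 1)
               for j in range(len(ring))]
        tris = np.vstack([g.tris, cap])
        total = 0.0
        for t in tris:
            a, b, c = pts[t] - ref_pt
            total += np.dot(np.cross(a, b), c) / 6.0
        assert vol == pytest.approx(abs(total), rel=1e-9)
        case = cylinder_surfaces
        assert vol == pytest.approx(case.reference["V_of_T"](0.0), rel=0.02)

    def test_ring_count_mismatch(self):
        r1 = phantoms._cylinder_rings(10, 40, 5, 16)
        r2 = phantoms._cylinder_rings(10, 40, 6, 16)
        with pytest.raises(ValueError):
            geo.build_corresponding_surfaces(r1, r2)


class TestMotion3D:
    @pytest.fixture(scope="class")
    @staticmethod
    def ell(ellipsoid_case_coarse):
        return ellipsoid_case_coarse.motion

    def test_endpoints(self, ell):
        n0, _ = geo.interpolate_motion_3d(ell, 0.0)
        nes, _ = geo.interpolate_motion_3d(ell, 0.4)
        assert np.allclose(n0, ell.nodes_ed)
        assert np.allclose(nes, ell.nodes_es)

    def test_midpoint(self, ell):
        nm, _ = geo.interpolate_motion_3d(ell, 0.2)
        assert np.allclose(nm, 0.5 * (ell.nodes_ed + ell.nodes_es))

    def test_systolic_velocity(self, ell):
        """|dx/dt| during systole equals |x_ES - x_ED| / (0.4 * cycle)."""
        _, v = geo.interpolate_motion_3d(ell, 0.1)
        expected = (ell.nodes_es - ell.nodes_ed) / 0.4
        assert np.allclose(v, expected)


# --------------------------------------------------------------------- meshing

class TestMeshing:
    def test_2d_boundary_partition(self):
        motion = geo.build_motion_2d(
            [half_disk_wall(20.0), half_disk_wall(16.0)], [0.0, 0.4])
        mesh = geo.mesh_lumen(motion, 2.0)
        tags = set(mesh.boundary_tags)
        assert tags == {"wall", "io"}
        # boundary edges tile the outer loop exactly once
        assert len(mesh.boundary) == len(np.unique(mesh.boundary))
        assert mesh.min_quality() > 0

    def test_2d_refinement_scaling(self):
        motion = geo.build_motion_2d(
            [half_disk_wall(20.0), half_disk_wall(16.0)], [0.0, 0.4])
        n1 = len(geo.mesh_lumen(motion, 2.0).elems)
        n2 = len(geo.mesh_lumen(motion, 1.0).elems)
        assert n2 / n1 == pytest.approx(4.0, rel=0.3)

    def test_3d_mesh_volume_matches_surface(self, ellipsoid_case_coarse):
        g = ellipsoid_case_coarse.motion
        mesh = geo.mesh_lumen(g, 6.0)
        vol_mesh = geo.lumen_measure(mesh)
        vol_surf = geo.enclosed_volume(g.nodes_ed, g.tris, g.io_ring)
        assert vol_mesh == pytest.approx(vol_surf, rel=1e-9)
        assert mesh.min_quality() > 0

    def test_3d_conformity(self, ellipsoid_case_coarse):
        """Every interior face is shared by exactly 2 tets, boundary by 1."""
        mesh = geo.mesh_lumen(ellipsoid_case_coarse.motion, 6.0)
        faces = mesh.elems[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
        key = np.sort(faces.reshape(-1, 3), axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        assert set(counts) <= {1, 2}
        # boundary face count matches the tagged boundary
        assert (counts == 1).sum() == len(mesh.boundary)

    def test_3d_refinement_scaling(self, ellipsoid_case_coarse):
        g = ellipsoid_case_coarse.motion
        n1 = len(geo.mesh_lumen(g, 8.0).elems)
        n2 = len(geo.mesh_lumen(g, 4.0).elems)
        # radial refinement only (rings fixed by the surface): ~2x per halving
        assert n2 > 1.5 * n1


# -------------------------------------------------------------------- measures

class TestMeasure:
    def test_half_disk_area(self):
        wall = half_disk_wall(20.0, n=257)
        assert geo.lumen_measure(wall) == pytest.approx(np.pi * 400 / 2,
                                                        rel=0.005)

    def test_capped_cylinder_volume(self):
        rings = phantoms._cylinder_rings(15.0, 60.0, 30, 128)
        surf = geo.build_corresponding_surfaces(
            rings, rings, apex_ed=[0, 0, -60.0], apex_es=[0, 0, -60.0])
        v = geo.lumen_measure(surf, 0.0)
        assert v == pytest.approx(np.pi * 15 ** 2 * 60, rel=0.01)

    def test_open_polygon_errors(self):
        with pytest.raises(ValueError):
            geo.lumen_measure(np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_volume_continuity_in_time(self, ellipsoid_case_coarse):
        g = ellipsoid_case_coarse.motion
        Ts = np.linspace(0, 1, 50)
        vols = np.array([geo.lumen_measure(g, T) for T in Ts])
        rng = vols.max() - vols.min()
        assert np.abs(np.diff(vols)).max() < 0.06 * rng


def test_no_inverted_elements_over_cycle(ellipsoid_case_coarse):
    """Harmonically extended mesh motion keeps positive Jacobians over 50
    sampled phases."""
    from lvflow._fem import FemSpace
    from lvflow.solver import MM, MotionDriver

    g = ellipsoid_case_coarse.motion
    mesh = geo.mesh_lumen(g, 7.0)
    driver = MotionDriver(mesh, g)
    space = FemSpace(mesh, scale=MM)
    for T in np.linspace(0, 1, 50):
        space.set_coords(driver.positions(T) * MM)   # raises if inverted
        assert np.all(space.detJ > 0)
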