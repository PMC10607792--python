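import numpy as np
import pytest

from lvflow import energetics as en, geometry as geo, phantoms, solver
from lvflow._fem import FemSpace
from lvflow.verification import rectangle_mesh

PROPS = solver.FluidProps()          # 4 cP, 1060 kg/m^3


def make_state(space, velocity_fn=None, pressure=0.0):
    v = np.zeros((space.n_vnodes, space.dim))
    if velocity_fn is not None:
        v = np.asarray(velocity_fn(space.vcoords), float)
    p = np.full(space.n_pnodes, float(pressure))
    return solver.FlowState(verts=space.verts.copy(), v=v, p=p,
                            w=np.zeros_like(v), t=0.0, T=0.0)


@pytest.fixture(scope="module")
def box_io_top():
    """Unit-ish 2D box (0.1 m square), top edge IO, rest wall."""
    mesh = rectangle_mesh(8, 8, 0.1, 0.1, y0=-0.1, io_edge="top")
    return FemSpace(mesh, scale=1.0)


@pytest.fixture(scope="module")
def box_closed():
    mesh = rectangle_mesh(8, 8, 0.1, 0.1, y0=-0.1)
    return FemSpace(mesh, scale=1.0)


# ------------------------------------------------------------------ KE metrics

class TestKineticEnergy:
    def test_zero_field(self, box_io_top):
        st = make_state(box_io_top)
        assert np.all(en.ke_density(st, PROPS) == 0.0)
        assert en.ke_average(box_io_top, st, PROPS) == 0.0

    def test_uniform_one_meter_per_second(self, box_io_top):
        """|v| = 1 m/s at rho = 1060 gives KE = 530 J/m^3 everywhere."""
        st = make_state(box_io_top, lambda x: np.tile([0.6, 0.8], (len(x), 1)))
        assert np.allclose(en.ke_density(st, PROPS), 530.0)
        assert en.ke_average(box_io_top, st, PROPS) == pytest.approx(530.0)

    def test_quadratic_scaling(self, box_io_top):
        st1 = make_state(box_io_top, lambda x: np.tile([0.3, 0.0], (len(x), 1)))
        st2 = make_state(box_io_top, lambda x: np.tile([0.6, 0.0], (len(x), 1)))
        assert np.allclose(en.ke_density(st2, PROPS),
                           4 * en.ke_density(st1, PROPS))

    def test_average_vs_dense_quadrature_oracle(self, box_io_top):
        """Smooth analytic field: element quadrature within 0.1% of a dense
        midpoint-rule integration."""
        f = lambda x: np.stack([np.sin(40 * x[..., 0]) * x[..., 1] * 5,
                                np.cos(30 * x[..., 1])], axis=-1)
        st = make_state(box_io_top, f)
        val = en.ke_average(box_io_top, st, PROPS)
        # dense midpoint oracle on the exact analytic field
        n = 1000
        xs = (np.arange(n) + 0.5) / n * 0.1
        ys = -0.1 + (np.arange(n) + 0.5) / n * 0.1
        X, Y = np.meshgrid(xs, ys)
        vv = f(np.stack([X, Y], axis=-1))
        oracle = 0.5 * PROPS.density * np.mean(np.sum(vv ** 2, axis=-1))
        # the FE field interpolates f; compare at matching accuracy
        assert val == pytest.approx(oracle, rel=2e-3)

    def test_zero_measure_error(self):
        mesh = rectangle_mesh(2, 2, 0.1, 0.1)
        space = FemSpace(mesh, scale=1.0)
        st = make_state(space)
        space.w_detJ = space.w_detJ * 0.0
        with pytest.raises(ValueError):
            en.ke_average(space, st, PROPS)
        space.set_coords(space.verts)     # restore caches


# ------------------------------------------------------------------- vorticity

class TestVorticity:
    def test_rigid_rotation(self, box_io_top):
        """v = omega x r with omega = 1 rad/s: Omega_z = 2 exactly."""
        st = make_state(box_io_top,
                        lambda x: np.stack([-x[..., 1], x[..., 0]], axis=-1))
        om = en.vorticity(box_io_top, st)
        assert np.allclose(om, 2.0, atol=1e-10)
        mag, signed = en.vorticity_averages(box_io_top, st)
        assert mag == pytest.approx(2.0)
        assert signed == pytest.approx(2.0)

    def test_uniform_flow_zero(self, box_io_top):
        st = make_state(box_io_top, lambda x: np.tile([0.4, 0.1], (len(x), 1)))
        assert np.allclose(en.vorticity(box_io_top, st), 0.0, atol=1e-12)

    def test_simple_shear(self, box_io_top):
        """v_x = y (shear rate 1/s): Omega_z = -1."""
        st = make_state(box_io_top,
                        lambda x: np.stack([x[..., 1],
                                            np.zeros_like(x[..., 1])], axis=-1))
        assert np.allclose(en.vorticity(box_io_top, st), -1.0, atol=1e-10)

    def test_mirror_vortex_pair_balance(self):
        """Two mirror-image counter-rotating vortices: signed average
        vanishes, magnitude average does not."""
        mesh = rectangle_mesh(16, 8, 1.0, 0.5)
        space = FemSpace(mesh, scale=1.0)

        def vel(x):
            # psi = sin(2 pi x) sin(pi y): antisymmetric about x = 0.5
            u = np.pi * np.sin(2 * np.pi * x[..., 0]) * np.cos(np.pi * x[..., 1])
            v = -2 * np.pi * np.cos(2 * np.pi * x[..., 0]) * np.sin(np.pi * x[..., 1])
            return np.stack([u, v], axis=-1)

        st = make_state(space, vel)
        mag, signed = en.vorticity_averages(space, st)
        assert mag > 1.0
        assert abs(signed) < 1e-10 * mag

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_triangle_inequality(self, box_io_top, seed):
        rng = np.random.default_rng(seed)
        st = make_state(box_io_top)
        st.v = rng.normal(size=st.v.shape)
        mag, signed = en.vorticity_averages(box_io_top, st)
        assert abs(signed) <= mag + 1e-12


# ---------------------------------------------------------- hemodynamic force

class TestForce:
    def test_closed_boundary_uniform_pressure(self, box_closed):
        """Still fluid at uniform pressure over a closed boundary: F = 0."""
        st = make_state(box_closed, pressure=250.0)
        F, hdf = en.hemodynamic_force(box_closed, st, PROPS)
        assert np.allclose(F, 0.0, atol=1e-10)

    def test_open_top_box(self, box_io_top):
        """Uniform p0 with an open top of width W: wall traction sums to
        p0 * W in +y (per unit depth)."""
        p0, W = 180.0, 0.1
        st = make_state(box_io_top, pressure=p0)
        F, hdf = en.hemodynamic_force(box_io_top, st, PROPS)
        assert F[0] == pytest.approx(0.0, abs=1e-10)
        assert hdf == pytest.approx(p0 * W, rel=1e-12)

    def test_untagged_boundary(self, box_closed):
        st = make_state(box_closed)
        with pytest.raises(ValueError):
            en.hemodynamic_force(box_closed, st, PROPS, tag="io")


# ------------------------------------------------------------ fluxes and power

class TestFluxes:
    def test_plug_flow_rate(self, box_io_top):
        """v.n = c over an IO line of width W: Q' = c * W (in mm^2/s)."""
        c = 0.25
        st = make_state(box_io_top, lambda x: np.tile([0.0, c], (len(x), 1)))
        q = en.flow_rate(box_io_top, st)
        assert q == pytest.approx(c * 0.1 * 1e6, rel=1e-12)

    def test_rest_state_zero(self, box_io_top):
        st = make_state(box_io_top)
        assert en.flow_rate(box_io_top, st) == 0.0
        assert en.io_power(box_io_top, st, PROPS) == 0.0

    def test_plug_power(self, box_io_top):
        """P = 1/2 rho u^3 A for plug outflow through the IO."""
        u = 0.5
        st = make_state(box_io_top, lambda x: np.tile([0.0, u], (len(x), 1)))
        p = en.io_power(box_io_top, st, PROPS)
        assert p == pytest.approx(0.5 * 1060 * u ** 3 * 0.1 * 1e3, rel=1e-12)

    def test_parabolic_power_vs_dense_oracle(self, box_io_top):
        """Parabolic IO profile: quadrature within 0.5% of a dense 1D
        midpoint oracle."""
        W = 0.1
        prof = lambda x: np.stack(
            [np.zeros_like(x[..., 0]),
             x[..., 0] * (W - x[..., 0]) * 4 / W ** 2], axis=-1)
        st = make_state(box_io_top, prof)
        p = en.io_power(box_io_top, st, PROPS)
        xs = (np.arange(200000) + 0.5) / 200000 * W
        u = xs * (W - xs) * 4 / W ** 2
        oracle = np.mean(0.5 * 1060 * u ** 3) * W * 1e3
        assert p == pytest.approx(oracle, rel=0.005)

    def test_untagged_io(self, box_closed):
        st = make_state(box_closed)
        with pytest.raises(ValueError):
            en.flow_rate(box_closed, st)


# ------------------------------------------------------------- frame invariance

def test_rigid_translation_leaves_metrics_unchanged(box_io_top):
    space = box_io_top
    f = lambda x: np.stack([np.sin(20 * x[..., 0]), x[..., 1] * 3], axis=-1)
    st = make_state(space, f)
    st.p = np.linspace(0, 50, space.n_pnodes)
    base = (en.ke_average(space, st, PROPS),
            en.vorticity_averages(space, st),
            en.flow_rate(space, st),
            en.io_power(space, st, PROPS),
            en.hemodynamic_force(space, st, PROPS)[0].copy())
    shifted = solver.FlowState(verts=st.verts + [0.3, -1.2], v=st.v, p=st.p,
                               w=st.w, t=0.0, T=0.0)
    space.set_coords(shifted.verts)
    moved = (en.ke_average(space, shifted, PROPS),
             en.vorticity_averages(space, shifted),
             en.flow_rate(space, shifted),
             en.io_power(space, shifted, PROPS),
             en.hemodynamic_force(space, shifted, PROPS)[0])
    assert moved[0] == pytest.approx(base[0], rel=1e-12)
    assert moved[1] == pytest.approx(base[1], rel=1e-12)
    assert moved[2] == pytest.approx(base[2], rel=1e-12)
    assert moved[3] == pytest.approx(base[3], rel=1e-12)
    assert np.allclose(moved[4], base[4], rtol=1e-12)
    space.set_coords(st.verts)    # restore for other tests


# ---------------------------------------------------------------- stroke volume

class TestStrokeVolume:
    def test_subtraction(self):
        assert en.stroke_volume(100.0, 55.0) == 45.0
        assert en.stroke_volume(80.0, 80.0) == 0.0

    def test_negative_warns(self):
        with pytest.warns(UserWarning):
            en.stroke_volume(50.0, 60.0)

    def test_flux_cross_check(self):
        t = np.linspace(0, 0.4, 41)
        q = np.full_like(t, 50.0)          # constant outflow 50 mL/s
        sv, sv_flux, rel = en.stroke_volume(20.0, 0.0, q, t,
                                            systole_span=(0.0, 0.4))
        assert sv_flux == pytest.approx(20.0)
        assert rel < 1e-12
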