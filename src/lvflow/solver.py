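"""Moving-boundary incompressible flow in the LV lumen (ALE formulation).

The lumen wall moves with the displacement law extracted from images (or a
phantom); blood is Newtonian (default 4 cP, 1060 kg/m^3) and satisfies the
transient incompressible Navier-Stokes equations written on the moving mesh:
the convective velocity is ``v - w`` with ``w`` the mesh velocity.  The wall
carries a kinematic no-slip condition ``v = w`` (direct velocity imposition,
equivalent to the prescribed-displacement wall of the original formulation);
the IO opening carries the natural zero-traction condition ``sigma . n = 0``,
which also sets the pressure gauge (reported pressures are relative to IO).

Time integration is implicit backward Euler with Picard linearization,
assembled on the end-of-step mesh (this discrete form transports uniform
fields on a moving mesh exactly, see the geometric-conservation test).
Interior mesh motion is the harmonic extension of the boundary displacement,
computed once per keyframe and blended in time.

Geometry enters in millimetres and is converted to SI here; velocities are
m/s, pressures Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import geometry as geo
from ._fem import (FemSpace, InvertedElementError, LinearSolverCache,
                   apply_dirichlet, assemble_ns_system, scalar_stiffness,
                   solve_linear)

__all__ = ["FluidProps", "FlowState", "CycleResult", "extend_mesh_motion",
           "step", "solve_cycle", "steady_solve", "ConvergenceError"]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class FluidProps:
    """Newtonian blood: mu = 4 cP, rho = 1060 kg/m^3 by default."""

    dynamic_viscosity: float = 4e-3   # Pa s
    density: float = 1060.0           # kg/m^3

    def __post_init__(self):
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass
class FlowState:
    """Velocity/pressure snapshot on the current deformed mesh (SI units)."""

    verts: np.ndarray          # vertex coordinates, meters
    v: np.ndarray              # (n_vnodes, dim) m/s
    p: np.ndarray              # (n_pnodes,) Pa, gauge at IO
    w: np.ndarray              # mesh velocity at velocity nodes, m/s
    t: float                   # seconds
    T: float                   # normalized cycle time
    wall_reaction: np.ndarray | None = None  # residual-based force on fluid, N (2D: N/m)


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


# -------------------------------------------------------------- mesh motion

def extend_mesh_motion(mesh: geo.LumenMesh, wall_ids, wall_disp,
                       io_normal_axis: int | None = None,
                       check_inversion: bool = True) -> np.ndarray:
    """Harmonic (Laplace) extension of wall displacement into the interior.

    ``wall_disp`` (len(wall_ids), dim) is prescribed on the wall vertices; IO
    vertices keep zero displacement along the IO-plane normal axis (y in 2D,
    z in 3D by default) and are free to slide in-plane.  Returns the (Nv, dim)
    displacement in the same units as the input.
    """
    space = FemSpace(mesh, scale=1.0)
    K = scalar_stiffness(space)
    nv = K.shape[0]
    wall_ids = np.asarray(wall_ids, np.int64)
    io_ids = np.setdiff1d(mesh.io_node_ids, wall_ids)
    if io_normal_axis is None:
        io_normal_axis = mesh.dim - 1
    disp = np.zeros((nv, mesh.dim))
    for c in range(mesh.dim):
        fixed = wall_ids
        vals = np.asarray(wall_disp)[:, c]
        if c == io_normal_axis and len(io_ids):
            fixed = np.concatenate([wall_ids, io_ids])
            vals = np.concatenate([vals, np.zeros(len(io_ids))])
        A_red, b_red, free, xfull = apply_dirichlet(K, np.zeros(nv), fixed, vals)
        xfull[free] = solve_linear(A_red, b_red)
        disp[:, c] = xfull
    if check_inversion:
        moved = geo.LumenMesh(dim=mesh.dim, nodes=mesh.nodes + disp,
                              elems=mesh.elems, elem_type=mesh.elem_type,
                              boundary=mesh.boundary, boundary_tags=mesh.boundary_tags)
        try:
            FemSpace(moved, scale=1.0)
        except InvertedElementError as err:
            raise InvertedElementError(err.elem) from err
    return disp


def _wall_displacement_2d(mesh: geo.LumenMesh, motion: geo.MotionGeometry2D, T):
    """Displacement (mm) of the ordered wall boundary vertices at time T."""
    s = mesh.meta["wall_s"]
    idx = s * (motion.n_points - 1)
    base = np.arange(motion.n_points)
    w0 = motion.keyframe_walls[0]
    wT = motion.wall_at(T)
    out = np.column_stack([
        np.interp(idx, base, wT[:, k]) - np.interp(idx, base, w0[:, k])
        for k in range(2)])
    return out


class MotionDriver:
    """Precomputed interior mesh positions as a function of T (mm)."""

    def __init__(self, mesh: geo.LumenMesh, motion):
        self.mesh = mesh
        self.motion = motion
        x0 = mesh.nodes
        if isinstance(motion, geo.MotionGeometry2D):
            self.kind = "2d"
            wall_ids = mesh.meta["wall_ids_ordered"]
            self.times = np.asarray(motion.keyframe_times, float)
            fields = []
            for Tk in self.times:
                bd = _wall_displacement_2d(mesh, motion, Tk)
                if np.allclose(bd, 0.0):
                    fields.append(np.zeros_like(x0))
                else:
                    fields.append(extend_mesh_motion(mesh, wall_ids, bd))
            self.fields = np.stack(fields)
        elif isinstance(motion, geo.MotionGeometry3D):
            self.kind = "3d"
            ids = mesh.meta["wall_mesh_ids"]
            gids = mesh.meta["wall_geom_ids"]
            bd = (motion.nodes_es - motion.nodes_ed)[gids]
            self.d_es = extend_mesh_motion(mesh, ids, bd)
            self.systole_fraction = motion.systole_fraction
        else:
            raise TypeError(type(motion).__name__)
        self.x0 = x0

    def positions(self, T: float) -> np.ndarray:
        T = float(T) % 1.0
        if self.kind == "3d":
            s = geo.systolic_interp_factor(T, self.systole_fraction)
            return self.x0 + s * self.d_es
        times = np.concatenate([self.times, [1.0]])
        fields = np.concatenate([self.fields, self.fields[:1]], axis=0)
        k = int(np.searchsorted(times, T, side="right") - 1)
        k = max(0, min(k, len(times) - 2))
        t0, t1 = times[k], times[k + 1]
        a = 0.0 if t1 == t0 else (T - t0) / (t1 - t0)
        return self.x0 + (1 - a) * fields[k] + a * fields[k + 1]


# ------------------------------------------------------------------ stepping

def _vertex_to_velnodes(space: FemSpace, field_vert: np.ndarray) -> np.ndarray:
    """Lift a vertex field to the velocity-node set (quadratic midside/center
    nodes are vertex averages, matching the subparametric mesh motion)."""
    if space.mesh.elem_type == "tet4":
        return field_vert
    out = np.zeros((space.n_vnodes, field_vert.shape[1]))
    out[:len(field_vert)] = field_vert
    for (va, vb), idx in space._edge_of.items():
        out[idx] = 0.5 * (field_vert[va] + field_vert[vb])
    if space._has_center:
        out[space.vconn[:, -1]] = field_vert[space.pconn].mean(axis=1)
    return out


def _wall_vel_nodes(space: FemSpace) -> np.ndarray:
    ids = [f.nodes for f in space.facets if f.tag == "wall"]
    return np.unique(np.concatenate(ids)) if ids else np.empty(0, np.int64)


def step(space: FemSpace, props: FluidProps, dt: float, v_old: np.ndarray,
         verts_old_m: np.ndarray, verts_new_m: np.ndarray,
         dirichlet_nodes=None, dirichlet_values=None,
         tol: float = 1e-8, max_iter: int = 20, body_force=None,
         cfl_warn: float = 5.0, lin_cache: LinearSolverCache | None = None):
    """One implicit ALE step from the old to the new mesh configuration.

    By default the no-slip wall moves with the mesh (``v = w`` on wall
    velocity nodes) and IO is traction-free.  ``dirichlet_nodes/values``
    override the Dirichlet set entirely when given (node ids and (n, dim)
    values), which verification problems use to prescribe exact solutions.
    Returns ``(v, p, w_nodes, reaction)`` where ``reaction`` is the
    residual-based force exerted on the fluid through the Dirichlet boundary.
    """
    w_vert = (verts_new_m - verts_old_m) / dt
    space.set_coords(verts_new_m)
    w_nodes = _vertex_to_velnodes(space, w_vert)

    if dirichlet_nodes is None:
        dirichlet_nodes = _wall_vel_nodes(space)
        dirichlet_values = w_nodes[dirichlet_nodes]
    dofs = np.concatenate([space.vel_dof(dirichlet_nodes, c)
                           for c in range(space.dim)])
    vals = np.concatenate([np.asarray(dirichlet_values)[:, c]
                           for c in range(space.dim)])
    pin_pressure = len(dirichlet_nodes) and not any(
        f.tag == "io" for f in space.facets)
    if pin_pressure:
        dofs = np.concatenate([dofs, [space.n_vel_dofs]])
        vals = np.concatenate([vals, [0.0]])

    if lin_cache is None:
        lin_cache = LinearSolverCache()
    v_adv = v_old.copy()
    history = []
    for it in range(max_iter):
        A, b = assemble_ns_system(space, props.density, props.dynamic_viscosity,
                                  dt, v_old, v_adv, w_nodes, body_force=body_force)
        A_red, b_red, free, xfull = apply_dirichlet(A, b, dofs, vals)
        xfull[free] = lin_cache.solve(A_red, b_red)
        v_new = np.column_stack([xfull[c * space.n_vnodes:(c + 1) * space.n_vnodes]
                                 for c in range(space.dim)])
        dv = np.linalg.norm(v_new - v_adv) / max(np.linalg.norm(v_new), 1e-14)
        history.append(dv)
        v_adv = v_new
        if dv < tol:
            break
    else:
        raise ConvergenceError(
            f"Picard iteration did not converge (last rel. change {dv:.2e})",
            history)

    p = xfull[space.n_vel_dofs:]
    resid = A @ xfull - b
    reaction = np.array([resid[space.vel_dof(dirichlet_nodes, c)].sum()
                         for c in range(space.dim)])

    # convective CFL advisory
    hmin = _min_h(space)
    umax = float(np.linalg.norm(v_adv - w_nodes, axis=1).max())
    if umax * dt / hmin > cfl_warn:
        warnings.warn(f"convective CFL {umax * dt / hmin:.1f} exceeds {cfl_warn}")
    return v_adv, p, w_nodes, reaction


def _min_h(space: FemSpace) -> float:
    if space.dim == 2:
        return float(np.sqrt(space.detJ.sum(axis=1).min() *
                             space.qw.sum() / len(space.qw)))
    vol = space.detJ[:, 0].min() / 6.0
    return float((6 * np.sqrt(2) * vol) ** (1 / 3))


@dataclass
class CycleResult:
    """Output of :func:`solve_cycle`: states at every step plus diagnostics."""

    states: list
    mesh: geo.LumenMesh
    space: FemSpace
    props: FluidProps
    dt: float
    periodicity: float | None = None
    log: list = field(default_factory=list)


def solve_cycle(motion, props: FluidProps = FluidProps(), n_steps: int = 200,
                n_cycles: float = 2, target_h: float = 2.0,
                mesh: geo.LumenMesh | None = None, tol: float = 1e-8,
                verbose: bool = False) -> CycleResult:
    """March the flow through ``n_cycles`` cardiac cycles from rest at ED.

    ``n_steps`` is the per-cycle step count (>= 20); ``n_cycles`` may be
    fractional (e.g. 0.5 to simulate systole plus early diastole of a
    benchmark).  Returns every step's :class:`FlowState`; when at least two
    full cycles are run, ``periodicity`` is the relative L2 difference of the
    velocity between the last two cycle ends.
    """
    if n_steps < 20:
        raise ValueError("need at least 20 steps per cycle")
    if mesh is None:
        mesh = geo.mesh_lumen(motion, target_h)
    driver = MotionDriver(mesh, motion)
    space = FemSpace(mesh, scale=MM)
    cycle_duration = motion.cycle_duration
    dt = cycle_duration / n_steps
    total = int(round(n_steps * n_cycles))

    v = np.zeros((space.n_vnodes, space.dim))
    verts_old = driver.positions(0.0) * MM
    t = 0.0
    states = [FlowState(verts=verts_old.copy(), v=v.copy(),
                        p=np.zeros(space.n_pnodes),
                        w=np.zeros_like(v), t=0.0, T=0.0)]
    log = []
    cycle_end_v = []
    lin_cache = LinearSolverCache()
    for n in range(total):
        T_new = ((n + 1) / n_steps) % 1.0
        verts_new = driver.positions((n + 1) / n_steps) * MM
        try:
            v, p, w_nodes, reaction = step(space, props, dt, v, verts_old,
                                           verts_new, tol=tol,
                                           lin_cache=lin_cache)
        except (ConvergenceError, InvertedElementError) as err:
            raise type(err)(f"{err} at T = {T_new:.4f}") from err
        t += dt
        states.append(FlowState(verts=verts_new.copy(), v=v.copy(), p=p,
                                w=w_nodes, t=t, T=T_new,
                                wall_reaction=reaction))
        log.append({"t": t, "T": T_new})
        if verbose:
            print(f"  step {n + 1}/{total}  t={t:.3f}s  T={T_new:.3f}")
        if (n + 1) % n_steps == 0:
            cycle_end_v.append(v.copy())
        verts_old = verts_new

    periodicity = None
    if len(cycle_end_v) >= 2:
        a, b = cycle_end_v[-2], cycle_end_v[-1]
        periodicity = float(np.linalg.norm(b - a) /
                            max(np.linalg.norm(b), 1e-14))
    return CycleResult(states=states, mesh=mesh, space=space, props=props,
                       dt=dt, periodicity=periodicity, log=log)


# ------------------------------------------------------------- steady solver

def steady_solve(space: FemSpace, props: FluidProps, dirichlet_nodes,
                 dirichlet_values, body_force=None, pin_pressure=True,
                 tol: float = 1e-10, max_iter: int = 50):
    """Steady Navier-Stokes with prescribed velocity on given nodes.

    Used for solver verification (Poiseuille, manufactured solutions).
    Returns (v, p).
    """
    dofs = np.concatenate([space.vel_dof(dirichlet_nodes, c)
                           for c in range(space.dim)])
    vals = np.concatenate([np.asarray(dirichlet_values)[:, c]
                           for c in range(space.dim)])
    if pin_pressure:
        dofs = np.concatenate([dofs, [space.n_vel_dofs]])
        vals = np.concatenate([vals, [0.0]])
    v = np.zeros((space.n_vnodes, space.dim))
    w = np.zeros_like(v)
    lin_cache = LinearSolverCache()
    for it in range(max_iter):
        A, b = assemble_ns_system(space, props.density, props.dynamic_viscosity,
                                  1.0, v, v, w, body_force=body_force, steady=True)
        A_red, b_red, free, xfull = apply_dirichlet(A, b, dofs, vals)
        xfull[free] = lin_cache.solve(A_red, b_red)
        v_new = np.column_stack([xfull[c * space.n_vnodes:(c + 1) * space.n_vnodes]
                                 for c in range(space.dim)])
        dv = np.linalg.norm(v_new - v) / max(np.linalg.norm(v_new), 1e-14)
        v = v_new
        if dv < tol:
            return v, xfull[space.n_vel_dofs:]
    raise ConvergenceError(f"steady Picard stalled at rel. change {dv:.2e}")
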