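"""Solver verification: manufactured solutions and the Poiseuille benchmark.

The manufactured case is a steady vortex with homogeneous Dirichlet velocity,

    psi = sin(pi x)^2 sin(pi y)^2 / pi,   v = (d psi/dy, -d psi/dx),
    p = cos(pi x) cos(pi y),

on the unit square; the body force is derived symbolically so that (v, p)
solves steady incompressible Navier-Stokes exactly.  Velocity errors are
measured in the relative L2 norm by element quadrature; halving h on the
Q2/Q1 pair should show order >= 2 (theory: 3).

The Poiseuille channel (height H, force-driven, no-slip walls, exact profile
prescribed at the ends) checks absolute accuracy at the working resolution.
"""

from __future__ import annotations

import numpy as np

from . import geometry as geo
from ._fem import FemSpace
from .solver import FluidProps, steady_solve

__all__ = ["rectangle_mesh", "mms_case", "mms_velocity_error",
           "mms_convergence", "poiseuille_error"]


def rectangle_mesh(nx: int, ny: int, L: float, H: float, y0: float = 0.0,
                   io_edge: str | None = None) -> geo.LumenMesh:
    """Structured quad mesh of [0,L] x [y0, y0+H]; optionally tag one side io.

    ``io_edge`` in {"top", "bottom", "left", "right", None}; everything else
    is tagged wall.
    """
    xs = np.linspace(0, L, nx + 1)
    ys = np.linspace(y0, y0 + H, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):   # i along x, j along y
        return j * (nx + 1) + i

    elems = [(nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1))
             for j in range(ny) for i in range(nx)]
    edges, tags = [], []
    for i in range(nx):
        edges.append((nid(i, 0), nid(i + 1, 0)))
        tags.append("io" if io_edge == "bottom" else "wall")
        edges.append((nid(i, ny), nid(i + 1, ny)))
        tags.append("io" if io_edge == "top" else "wall")
    for j in range(ny):
        edges.append((nid(0, j), nid(0, j + 1)))
        tags.append("io" if io_edge == "left" else "wall")
        edges.append((nid(nx, j), nid(nx, j + 1)))
        tags.append("io" if io_edge == "right" else "wall")
    return geo.LumenMesh(dim=2, nodes=nodes, elems=np.asarray(elems, np.int64),
                         elem_type="quad4",
                         boundary=np.asarray(edges, np.int64),
                         boundary_tags=np.asarray(tags))


def mms_case(rho: float = 1.0, mu: float = 0.1):
    """Symbolically derived manufactured solution; returns vectorized
    callables ``(velocity, pressure, forcing)``."""
    import sympy as sp

    x, y = sp.symbols("x y")
    psi = sp.sin(sp.pi * x) ** 2 * sp.sin(sp.pi * y) ** 2 / sp.pi
    u = sp.diff(psi, y)
    v = -sp.diff(psi, x)
    p = sp.cos(sp.pi * x) * sp.cos(sp.pi * y)
    conv_u = u * sp.diff(u, x) + v * sp.diff(u, y)
    conv_v = u * sp.diff(v, x) + v * sp.diff(v, y)
    fx = rho * conv_u - mu * (sp.diff(u, x, 2) + sp.diff(u, y, 2)) + sp.diff(p, x)
    fy = rho * conv_v - mu * (sp.diff(v, x, 2) + sp.diff(v, y, 2)) + sp.diff(p, y)
    u_fn = sp.lambdify((x, y), u, "numpy")
    v_fn = sp.lambdify((x, y), v, "numpy")
    p_fn = sp.lambdify((x, y), p, "numpy")
    fx_fn = sp.lambdify((x, y), fx, "numpy")
    fy_fn = sp.lambdify((x, y), fy, "numpy")

    def velocity(pts):
        pts = np.asarray(pts, float)
        return np.stack([u_fn(pts[..., 0], pts[..., 1]),
                         v_fn(pts[..., 0], pts[..., 1])], axis=-1)

    def pressure(pts):
        pts = np.asarray(pts, float)
        return p_fn(pts[..., 0], pts[..., 1])

    def forcing(pts):
        pts = np.asarray(pts, float)
        return np.stack([fx_fn(pts[..., 0], pts[..., 1]),
                         fy_fn(pts[..., 0], pts[..., 1])], axis=-1)

    return velocity, pressure, forcing


def _boundary_nodes(space: FemSpace) -> np.ndarray:
    return np.unique(np.concatenate([f.nodes for f in space.facets]))


def mms_velocity_error(n: int, rho: float = 1.0, mu: float = 0.1) -> float:
    """Relative L2 velocity error of the manufactured vortex on an n x n grid."""
    velocity, _, forcing = mms_case(rho, mu)
    mesh = rectangle_mesh(n, n, 1.0, 1.0)
    space = FemSpace(mesh, scale=1.0)
    props = FluidProps(dynamic_viscosity=mu, density=rho)
    bnodes = _boundary_nodes(space)
    bvals = velocity(space.vcoords[bnodes])
    v, p = steady_solve(space, props, bnodes, bvals, body_force=forcing)
    vq = space.interp_vel(v)
    vex = velocity(space.qp_x)
    err2 = space.integrate(np.sum((vq - vex) ** 2, axis=2))
    ref2 = space.integrate(np.sum(vex ** 2, axis=2))
    return float(np.sqrt(err2 / ref2))


def mms_convergence(grids=(8, 16, 32), rho: float = 1.0, mu: float = 0.1):
    """Errors and observed orders across uniform refinements."""
    errs = np.array([mms_velocity_error(n, rho, mu) for n in grids])
    hs = 1.0 / np.asarray(grids, float)
    orders = np.log(errs[:-1] / errs[1:]) / np.log(hs[:-1] / hs[1:])
    return errs, orders


def poiseuille_error(n_across: int = 20, H: float = 0.01, aspect: float = 3.0,
                     reynolds: float = 10.0, props: FluidProps = FluidProps()):
    """Relative L2 velocity error of force-driven Poiseuille channel flow.

    The channel (length aspect*H) carries the exact parabolic profile as a
    Dirichlet condition on all boundaries and a uniform body force
    G = 8 mu u_max / H^2; u_max is set from the target Reynolds number
    rho u_max H / mu.
    """
    mu, rho = props.dynamic_viscosity, props.density
    umax = reynolds * mu / (rho * H)
    G = 8.0 * mu * umax / H ** 2
    L = aspect * H
    mesh = rectangle_mesh(int(round(aspect * n_across)), n_across, L, H)
    space = FemSpace(mesh, scale=1.0)

    def exact(pts):
        pts = np.asarray(pts, float)
        y = pts[..., 1]
        u = 4.0 * umax * y * (H - y) / H ** 2
        return np.stack([u, np.zeros_like(u)], axis=-1)

    bnodes = _boundary_nodes(space)
    v, p = steady_solve(space, FluidProps(mu, rho), bnodes,
                        exact(space.vcoords[bnodes]),
                        body_force=lambda x: np.stack(
                            [np.full(x.shape[:-1], G), np.zeros(x.shape[:-1])],
                            axis=-1))
    vq = space.interp_vel(v)
    vex = exact(space.qp_x)
    err2 = space.integrate(np.sum((vq - vex) ** 2, axis=2))
    ref2 = space.integrate(np.sum(vex ** 2, axis=2))
    return float(np.sqrt(err2 / ref2))
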