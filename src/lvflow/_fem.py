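"""Small finite-element core for the moving-boundary flow solver.

Discretizations:

* 2D, triangles: Taylor-Hood P2/P1 (quadratic velocity, linear pressure) —
  used for the lumen meshes (polar fan around an interior center).
* 2D, quadrilaterals: Taylor-Hood Q2/Q1 — used for structured rectangle
  meshes in solver verification.
* 3D, tetrahedra: equal-order P1/P1 with PSPG pressure stabilization.

The geometry mapping is always (bi/tri)linear from the vertex coordinates
(subparametric for the quadratic velocities).  Everything works in whatever
length unit the node coordinates carry; the solver feeds meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# ------------------------------------------------------------------ quadrature

_G3 = np.sqrt(3.0 / 5.0)
_GAUSS3_PTS = np.array([-_G3, 0.0, _G3])
_GAUSS3_WTS = np.array([5.0, 8.0, 5.0]) / 9.0

#: 3x3 Gauss rule on [-1,1]^2 (degree 5)
QUAD_QP = np.array([[x, y] for y in _GAUSS3_PTS for x in _GAUSS3_PTS])
QUAD_W = np.array([wy * wx for wy in _GAUSS3_WTS for wx in _GAUSS3_WTS])

# 7-point degree-5 rule on the reference triangle (area 1/2)
_T7A, _T7B = 0.059715871789770, 0.470142064105115
_T7C, _T7D = 0.797426985353087, 0.101286507323456
TRI7_QP = np.array([
    [1 / 3, 1 / 3],
    [_T7A, _T7B], [_T7B, _T7A], [_T7B, _T7B],
    [_T7C, _T7D], [_T7D, _T7C], [_T7D, _T7D],
])
TRI7_W = 0.5 * np.array([0.225,
                         0.132394152788506, 0.132394152788506, 0.132394152788506,
                         0.125939180544827, 0.125939180544827, 0.125939180544827])

# 4-point degree-2 rule on the reference tet
_TA, _TB = 0.5854101966249685, 0.1381966011250105
TET_QP = np.array([
    [_TB, _TB, _TB],
    [_TA, _TB, _TB],
    [_TB, _TA, _TB],
    [_TB, _TB, _TA],
])
TET_W = np.full(4, 1.0 / 24.0)   # reference tet volume = 1/6

#: 3-point Gauss on [-1,1] for boundary edges
EDGE_QP = _GAUSS3_PTS
EDGE_W = _GAUSS3_WTS

# 3-point degree-2 rule on the reference triangle (3D boundary faces)
TRI_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
TRI_W = np.full(3, 1.0 / 6.0)


# ------------------------------------------------------------- shape functions

def _lag3(t):
    """1D quadratic Lagrange basis at nodes -1, 0, 1; returns (N, dN)."""
    t = np.asarray(t, float)
    N = np.stack([0.5 * t * (t - 1), 1 - t * t, 0.5 * t * (t + 1)], axis=-1)
    dN = np.stack([t - 0.5, -2 * t, t + 0.5], axis=-1)
    return N, dN


# Q2 node layout on [-1,1]^2: corners 0-3 CCW from (-1,-1), edge midpoints
# 4-7 (edge i joins corners i and (i+1)%4), center 8.
_Q2_IJ = [(0, 0), (2, 0), (2, 2), (0, 2), (1, 0), (2, 1), (1, 2), (0, 1), (1, 1)]


def q2_shape(qp):
    xi, eta = qp[:, 0], qp[:, 1]
    Nx, dNx = _lag3(xi)
    Ny, dNy = _lag3(eta)
    N = np.empty((len(qp), 9))
    dN = np.empty((len(qp), 9, 2))
    for a, (i, j) in enumerate(_Q2_IJ):
        N[:, a] = Nx[:, i] * Ny[:, j]
        dN[:, a, 0] = dNx[:, i] * Ny[:, j]
        dN[:, a, 1] = Nx[:, i] * dNy[:, j]
    return N, dN


_Q1_CORNERS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)


def q1_shape(qp):
    xi, eta = qp[:, 0], qp[:, 1]
    N = np.empty((len(qp), 4))
    dN = np.empty((len(qp), 4, 2))
    for a, (cx, cy) in enumerate(_Q1_CORNERS):
        N[:, a] = 0.25 * (1 + cx * xi) * (1 + cy * eta)
        dN[:, a, 0] = 0.25 * cx * (1 + cy * eta)
        dN[:, a, 1] = 0.25 * cy * (1 + cx * xi)
    return N, dN


def tri6_shape(qp):
    """P2 on the reference triangle: vertices 0-2, midside 3 (0-1), 4 (1-2),
    5 (2-0)."""
    x, y = qp[:, 0], qp[:, 1]
    L = [1 - x - y, x, y]
    dL = [np.array([-1.0, -1.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    N = np.empty((len(qp), 6))
    dN = np.empty((len(qp), 6, 2))
    for i in range(3):
        N[:, i] = L[i] * (2 * L[i] - 1)
        dN[:, i] = (4 * L[i] - 1)[:, None] * dL[i]
    for k, (a, b) in enumerate([(0, 1), (1, 2), (2, 0)]):
        N[:, 3 + k] = 4 * L[a] * L[b]
        dN[:, 3 + k] = 4 * (L[a][:, None] * dL[b] + L[b][:, None] * dL[a])
    return N, dN


def p1_shape2(qp):
    x, y = qp[:, 0], qp[:, 1]
    N = np.stack([1 - x - y, x, y], axis=-1)
    dN = np.broadcast_to(np.array([[-1, -1], [1, 0], [0, 1]], float),
                         (len(qp), 3, 2)).copy()
    return N, dN


def p1_shape3(qp):
    x, y, z = qp[:, 0], qp[:, 1], qp[:, 2]
    N = np.stack([1 - x - y - z, x, y, z], axis=-1)
    dN = np.broadcast_to(np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                                  float), (len(qp), 4, 3)).copy()
    return N, dN


# ----------------------------------------------------------------- FEM spaces

# (corner, corner, quadratic edge-node slot) and reference edge param x(t),
# t in [-1,1], plus d(ref)/dt
_QUAD_EDGES = [(0, 1, 4), (1, 2, 5), (2, 3, 6), (3, 0, 7)]
_QUAD_EDGE_REF = [
    (lambda t: np.stack([t, -np.ones_like(t)], -1), np.array([1.0, 0.0])),
    (lambda t: np.stack([np.ones_like(t), t], -1), np.array([0.0, 1.0])),
    (lambda t: np.stack([-t, np.ones_like(t)], -1), np.array([-1.0, 0.0])),
    (lambda t: np.stack([-np.ones_like(t), -t], -1), np.array([0.0, -1.0])),
]
_TRI_EDGES = [(0, 1, 3), (1, 2, 4), (2, 0, 5)]
_TRI_EDGE_REF = [
    (lambda t: np.stack([(t + 1) / 2, np.zeros_like(t)], -1),
     np.array([0.5, 0.0])),
    (lambda t: np.stack([(1 - t) / 2, (t + 1) / 2], -1),
     np.array([-0.5, 0.5])),
    (lambda t: np.stack([np.zeros_like(t), (1 - t) / 2], -1),
     np.array([0.0, -0.5])),
]

_TET_FACES = [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)]


@dataclass
class BoundaryFacet:
    elem: int
    local: int
    nodes: np.ndarray     # velocity-space node ids on the facet
    tag: str


class FemSpace:
    """Velocity/pressure spaces on a LumenMesh, with quadrature caches.

    Velocity dofs are blocked by component: ``[vx(0..Nv), vy, (vz)]`` followed
    by pressure at the mesh vertices.
    """

    def __init__(self, mesh, scale: float = 1.0):
        self.mesh = mesh
        self.dim = mesh.dim
        self.verts = np.asarray(mesh.nodes, float) * scale
        self.scale = scale
        et = mesh.elem_type
        if et == "quad4":
            self._build_2d(n_corner=4, edges=_QUAD_EDGES, has_center=True,
                           vel_basis=q2_shape, geo_basis=q1_shape,
                           p_basis=q1_shape, qp=QUAD_QP, qw=QUAD_W)
        elif et == "tri3":
            self._build_2d(n_corner=3, edges=_TRI_EDGES, has_center=False,
                           vel_basis=tri6_shape, geo_basis=p1_shape2,
                           p_basis=p1_shape2, qp=TRI7_QP, qw=TRI7_W)
        elif et == "tet4":
            self._build_p1p1()
        else:
            raise ValueError(et)
        self._cache_geometry()

    # -------------------------------------------------- construction
    def _build_2d(self, n_corner, edges, has_center, vel_basis, geo_basis,
                  p_basis, qp, qw):
        elems = np.asarray(self.mesh.elems, np.int64)
        nv = len(self.verts)
        nloc = n_corner + len(edges) + (1 if has_center else 0)
        edge_of = {}
        nxt = nv
        conn = np.empty((len(elems), nloc), np.int64)
        for e, q in enumerate(elems):
            conn[e, :n_corner] = q
            for a, b, slot in edges:
                va, vb = int(q[a]), int(q[b])
                key = (va, vb) if va < vb else (vb, va)
                if key not in edge_of:
                    edge_of[key] = nxt
                    nxt += 1
                conn[e, slot] = edge_of[key]
            if has_center:
                conn[e, nloc - 1] = nxt
                nxt += 1
        self.vconn = conn
        self.n_vnodes = nxt
        self.pconn = elems
        self.n_pnodes = nv
        self.vel_basis = vel_basis
        self.geo_basis = geo_basis
        self.p_basis = p_basis
        self.qp, self.qw = qp, qw
        self._edge_of = edge_of
        self._edges_def = edges
        self._edge_ref = _QUAD_EDGE_REF if n_corner == 4 else _TRI_EDGE_REF
        self._has_center = has_center
        self._refresh_vcoords()
        self._build_boundary_2d(edges)

    def _refresh_vcoords(self):
        if self.mesh.elem_type == "tet4":
            self.vcoords = self.verts
            return
        coords = np.empty((self.n_vnodes, 2))
        coords[:len(self.verts)] = self.verts
        for (va, vb), idx in self._edge_of.items():
            coords[idx] = 0.5 * (self.verts[va] + self.verts[vb])
        if self._has_center:
            coords[self.vconn[:, -1]] = self.verts[self.pconn].mean(axis=1)
        self.vcoords = coords

    def _build_boundary_2d(self, edges):
        own = {}
        for e, q in enumerate(self.mesh.elems):
            for le, (a, b, _) in enumerate(edges):
                own.setdefault(tuple(sorted((int(q[a]), int(q[b])))), []).append((e, le))
        self.facets = []
        for (va, vb), tag in zip(self.mesh.boundary, self.mesh.boundary_tags):
            key = tuple(sorted((int(va), int(vb))))
            owners = own.get(key, [])
            if len(owners) != 1:
                raise ValueError("boundary edge not owned by exactly one element")
            e, le = owners[0]
            mid = self._edge_of[key]
            self.facets.append(BoundaryFacet(e, le,
                                             np.array([va, mid, vb], np.int64),
                                             str(tag)))

    def _build_p1p1(self):
        tets = np.asarray(self.mesh.elems, np.int64)
        self.vconn = tets
        self.n_vnodes = len(self.verts)
        self.pconn = tets
        self.n_pnodes = len(self.verts)
        self.vel_basis = p1_shape3
        self.geo_basis = p1_shape3
        self.p_basis = p1_shape3
        self.qp, self.qw = TET_QP, TET_W
        self.vcoords = self.verts
        own = {}
        for e, t in enumerate(tets):
            for lf, f in enumerate(_TET_FACES):
                key = tuple(sorted(int(t[i]) for i in f))
                own.setdefault(key, []).append((e, lf))
        self.facets = []
        for f, tag in zip(self.mesh.boundary, self.mesh.boundary_tags):
            key = tuple(sorted(int(i) for i in f))
            owners = own.get(key, [])
            if len(owners) != 1:
                raise ValueError("boundary face not owned by exactly one element")
            e, lf = owners[0]
            self.facets.append(BoundaryFacet(e, lf, np.asarray(f, np.int64), str(tag)))

    # -------------------------------------------------- geometry caches
    def set_coords(self, verts_scaled: np.ndarray):
        """Move the mesh (coordinates already in solver units)."""
        self.verts = np.asarray(verts_scaled, float)
        self._refresh_vcoords()
        self._cache_geometry()

    def _cache_geometry(self):
        geoN, geodN = self.geo_basis(self.qp)
        xe = self.verts[self.pconn]                     # (E, ng, dim)
        J = np.einsum("qna,end->eqad", geodN, xe)       # J[e,q,a,d] = dx_d/dxi_a
        self.detJ = np.linalg.det(J)
        if np.any(self.detJ <= 0):
            raise InvertedElementError(int(np.argmax(np.any(self.detJ <= 0, axis=1))))
        # J[a,d] = dx_d/dxi_a, so inv(J)[d,a] = dxi_a/dx_d: contract as "qda"
        self.Jinv = np.linalg.inv(J)
        self.w_detJ = self.detJ * self.qw[None, :]
        velN, veldN = self.vel_basis(self.qp)
        self.velN = velN                                # (q, nloc)
        self.veldN = np.einsum("qna,eqda->eqnd", veldN, self.Jinv)
        pN, pdN = self.p_basis(self.qp)
        self.pN = pN
        self.pdN = np.einsum("qna,eqda->eqnd", pdN, self.Jinv)
        self.qp_x = np.einsum("qn,end->eqd", geoN, xe)  # physical qp coords

    # -------------------------------------------------- dof bookkeeping
    @property
    def n_vel_dofs(self):
        return self.dim * self.n_vnodes

    @property
    def n_dofs(self):
        return self.n_vel_dofs + self.n_pnodes

    def vel_dof(self, node_ids, component):
        return np.asarray(node_ids, np.int64) + component * self.n_vnodes

    # -------------------------------------------------- interpolation helpers
    def interp_vel(self, v_nodal):
        """Velocity at quadrature points; v_nodal is (n_vnodes, dim)."""
        return np.einsum("qn,enc->eqc", self.velN, v_nodal[self.vconn])

    def grad_vel(self, v_nodal):
        """Velocity gradient dv_c/dx_d at qp: (E, q, dim, dim)."""
        return np.einsum("eqnd,enc->eqcd", self.veldN, v_nodal[self.vconn])

    def interp_p(self, p_nodal):
        return np.einsum("qn,en->eq", self.pN, p_nodal[self.pconn])

    def integrate(self, qp_values):
        """Integrate values sampled at quadrature points: (E, q) -> scalar."""
        return float(np.sum(qp_values * self.w_detJ))

    def measure(self):
        return float(self.w_detJ.sum())

    # -------------------------------------------------- boundary quadrature
    def facet_data(self, tag=None):
        """Per-facet quadrature: dicts with qp coords, weights, outward normal,
        velocity basis values/gradients and pressure basis values."""
        out = []
        for f in self.facets:
            if tag is not None and f.tag != tag:
                continue
            out.append(self._facet_data_2d(f) if self.dim == 2
                       else self._facet_data_3d(f))
        return out

    def _facet_data_2d(self, f):
        ref_fn, dref_dt = self._edge_ref[f.local]
        ref = ref_fn(EDGE_QP)
        N, dN = self.vel_basis(ref)
        pN, _ = self.p_basis(ref)
        geoN, geodN = self.geo_basis(ref)
        xe = self.verts[self.pconn[f.elem]]
        J = np.einsum("qna,nd->qad", geodN, xe)
        Jinv = np.linalg.inv(J)
        dphys = np.einsum("qna,qda->qnd", dN, Jinv)
        tang = np.einsum("qad,a->qd", J, dref_dt)
        ds = np.linalg.norm(tang, axis=1)
        nrm = np.stack([tang[:, 1], -tang[:, 0]], axis=1) / ds[:, None]
        cc = xe.mean(axis=0)
        xq = np.einsum("qn,nd->qd", geoN, xe)
        if np.einsum("qd,qd->q", nrm, xq - cc).mean() < 0:
            nrm = -nrm
        return {"facet": f, "x": xq, "w": EDGE_W * ds, "normal": nrm,
                "velN": N, "veldN": dphys, "pN": pN,
                "vconn": self.vconn[f.elem], "pconn": self.pconn[f.elem]}

    def _facet_data_3d(self, f):
        tri = self.verts[f.nodes]
        e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
        nvec = np.cross(e1, e2)
        area2 = np.linalg.norm(nvec)
        nrm = nvec / area2
        xq = tri[0] + TRI_QP @ np.stack([e1, e2])
        w = TRI_W * area2                                  # weights sum to area
        tN, _ = p1_shape2(TRI_QP)
        _, dN = p1_shape3(TET_QP[:1])
        xe = self.verts[self.pconn[f.elem]]
        J = np.einsum("qna,nd->qad", dN, xe)
        dphys = np.einsum("qna,qda->qnd", dN, np.linalg.inv(J))
        dphys = np.broadcast_to(dphys, (3, 4, 3))
        if np.dot(nrm, xq.mean(axis=0) - xe.mean(axis=0)) < 0:
            nrm = -nrm
        elem_nodes = list(self.pconn[f.elem])
        cols = [elem_nodes.index(int(n)) for n in f.nodes]
        N_full = np.zeros((3, 4))
        N_full[:, cols] = tN
        return {"facet": f, "x": xq, "w": w,
                "normal": np.broadcast_to(nrm, (3, 3)).copy(),
                "velN": N_full, "veldN": dphys, "pN": N_full,
                "vconn": self.vconn[f.elem], "pconn": self.pconn[f.elem]}


class InvertedElementError(RuntimeError):
    def __init__(self, elem):
        super().__init__(f"inverted element detected (element {elem})")
        self.elem = elem


# -------------------------------------------------------------- assembly utils

def _scatter(rows_conn, cols_conn, vals, shape):
    """Accumulate (E, na, nb) local blocks into a CSR matrix."""
    E, na, nb = vals.shape
    rows = np.repeat(rows_conn, nb, axis=1).ravel()
    cols = np.tile(cols_conn, (1, na)).ravel()
    return sp.coo_matrix((vals.ravel(), (rows, cols)), shape=shape).tocsr()


def scalar_stiffness(space: FemSpace):
    """Vertex-space Laplace stiffness (for harmonic mesh-motion extension)."""
    loc = np.einsum("eqad,eqbd,eq->eab", space.pdN, space.pdN, space.w_detJ)
    n = space.n_pnodes
    return _scatter(space.pconn, space.pconn, loc, (n, n))


def assemble_ns_system(space: FemSpace, rho, mu, dt, v_old, v_adv, w_mesh,
                       body_force=None, steady=False, pspg=True):
    """Assemble one Picard step of ALE incompressible Navier-Stokes.

    Momentum (stress-divergence viscous form, convective velocity v_adv - w):
      rho/dt (v - v_old) + rho ((v_adv - w).grad) v = div sigma + f
    Continuity: div v = 0 (+ PSPG stabilization for the P1/P1 space).

    All fields nodal: v_old, v_adv, w_mesh are (n_vnodes, dim).
    Returns (A, b) on the full dof vector [vx, vy, (vz), p].
    """
    dim = space.dim
    nvn, npn = space.n_vnodes, space.n_pnodes
    ndof = space.n_dofs
    wq = space.w_detJ
    N, dNx = space.velN, space.veldN

    u_adv = np.einsum("qn,enc->eqc", N, (v_adv - w_mesh)[space.vconn])

    mass = np.einsum("qa,qb,eq->eab", N, N, wq) if not steady else 0.0
    conv = np.einsum("qa,eqc,eqbc,eq->eab", N, u_adv, dNx, wq)
    lap = np.einsum("eqad,eqbd,eq->eab", dNx, dNx, wq)
    # C[i][j][a,b] = int dNa/dx_i dNb/dx_j
    C = [[np.einsum("eqa,eqb,eq->eab", dNx[..., i], dNx[..., j], wq)
          for j in range(dim)] for i in range(dim)]

    blocks = [[None] * (dim + 1) for _ in range(dim + 1)]

    def scat_vv(loc):
        return _scatter(space.vconn, space.vconn, loc, (nvn, nvn))

    for i in range(dim):
        for j in range(dim):
            loc = mu * C[j][i]                       # from the grad v^T term
            if i == j:
                loc = loc + mu * lap + rho * conv
                if not steady:
                    loc = loc + (rho / dt) * mass
            blocks[i][j] = scat_vv(loc)
    for i in range(dim):
        g_loc = -np.einsum("eqa,qb,eq->eab", dNx[..., i], space.pN, wq)
        blocks[i][dim] = _scatter(space.vconn, space.pconn, g_loc, (nvn, npn))
        d_loc = np.einsum("qa,eqb,eq->eab", space.pN, dNx[..., i], wq)
        blocks[dim][i] = _scatter(space.pconn, space.vconn, d_loc, (npn, nvn))

    b = np.zeros(ndof)
    if not steady:
        rhs_loc = (rho / dt) * np.einsum("qa,qb,eq,ebc->eac", N, N, wq,
                                         v_old[space.vconn])
        for c in range(dim):
            np.add.at(b, space.vel_dof(space.vconn, c).ravel(),
                      rhs_loc[..., c].ravel())
    fq = None
    if body_force is not None:
        fq = body_force(space.qp_x)                   # (E, q, dim)
        f_loc = np.einsum("qa,eqc,eq->eac", N, fq, wq)
        for c in range(dim):
            np.add.at(b, space.vel_dof(space.vconn, c).ravel(),
                      f_loc[..., c].ravel())

    # PSPG stabilization for the equal-order 3D pair
    if pspg and space.mesh.elem_type == "tet4":
        vol = space.detJ[:, 0] / 6.0
        h = (6.0 * np.sqrt(2.0) * vol) ** (1.0 / 3.0)
        umag = np.linalg.norm(u_adv, axis=2).mean(axis=1)
        terms = (4.0 * mu / h ** 2) ** 2 + (2.0 * rho * umag / h) ** 2
        if not steady:
            terms = terms + (2.0 * rho / dt) ** 2
        tau = 1.0 / np.sqrt(terms)
        tw = tau[:, None] * wq
        spp = np.einsum("eqad,eqbd,eq->eab", space.pdN, space.pdN, tw)
        blocks[dim][dim] = _scatter(space.pconn, space.pconn, spp, (npn, npn))
        for i in range(dim):
            loc = rho * np.einsum("eqa,eqc,eqbc,eq->eab",
                                  space.pdN[..., i], u_adv, dNx, tw)
            if not steady:
                loc = loc + (rho / dt) * np.einsum("eqa,qb,eq->eab",
                                                   space.pdN[..., i], N, tw)
            blocks[dim][i] = blocks[dim][i] + _scatter(space.pconn, space.vconn,
                                                       loc, (npn, nvn))
        rhsq = np.zeros((len(space.pconn), space.pconn.shape[1]))
        if not steady:
            vo = np.einsum("qn,enc->eqc", N, v_old[space.vconn])
            rhsq = rhsq + (rho / dt) * np.einsum("eqac,eqc,eq->ea",
                                                 space.pdN, vo, tw)
        if fq is not None:
            rhsq = rhsq + np.einsum("eqac,eqc,eq->ea", space.pdN, fq, tw)
        np.add.at(b, space.n_vel_dofs + space.pconn.ravel(), rhsq.ravel())
    else:
        blocks[dim][dim] = sp.csr_matrix((npn, npn))

    A = sp.bmat(blocks, format="csr")
    return A, b


def apply_dirichlet(A, b, dof_ids, values):
    """Row/column elimination; returns reduced (A, b, free_ids, x_full)."""
    ndof = A.shape[0]
    mask = np.zeros(ndof, bool)
    mask[dof_ids] = True
    xfull = np.zeros(ndof)
    xfull[dof_ids] = values
    free = np.where(~mask)[0]
    A_csc = A.tocsc()
    b_red = b[free] - A_csc[free][:, dof_ids] @ np.asarray(values, float)
    A_red = A_csc[free][:, free]
    return A_red.tocsc(), b_red, free, xfull


def solve_linear(A_red, b_red):
    return spla.splu(A_red.tocsc(), permc_spec="COLAMD").solve(b_red)


class LinearSolverCache:
    """Direct solve with factorization reuse.

    The first solve factors the matrix (SuperLU).  Subsequent solves with
    nearby matrices (next Picard iteration, next time step on a slowly moving
    mesh) run GMRES preconditioned by the cached factorization and only
    re-factor when that stalls.  Solutions are refined to a tight residual,
    so the reuse does not change results beyond the stated tolerance.
    """

    def __init__(self, rtol: float = 1e-12, max_gmres: int = 60):
        self.lu = None
        self._shape = None
        self.rtol = rtol
        self.max_gmres = max_gmres

    def solve(self, A, b):
        A = A.tocsc()
        bnorm = np.linalg.norm(b)
        if bnorm == 0:
            return np.zeros_like(b)
        if self.lu is not None and self._shape == A.shape:
            M = spla.LinearOperator(A.shape, self.lu.solve)
            x, info = spla.gmres(A, b, M=M, rtol=self.rtol, atol=0.0,
                                 restart=40, maxiter=self.max_gmres)
            if info == 0 and np.linalg.norm(A @ x - b) <= 10 * self.rtol * bnorm:
                return x
        self.lu = spla.splu(A, permc_spec="COLAMD")
        self._shape = A.shape
        return self.lu.solve(b)


# ----------------------------------------------------- mesh-level diagnostics

def mesh_measure(mesh) -> float:
    """Total area/volume of a LumenMesh, in its native (mm) units."""
    return FemSpace(mesh, scale=1.0).measure()


def element_quality(mesh) -> float:
    """Minimum element-shape quality (1 = ideal, 0 = degenerate).

    Quads: min/mean Jacobian ratio at the Gauss points.  Triangles/tets:
    normalized measure-to-longest-edge ratio (equilateral/regular = 1).
    """
    nodes = np.asarray(mesh.nodes, float)
    if mesh.elem_type == "quad4":
        space = FemSpace(mesh, scale=1.0)
        ratio = space.detJ.min(axis=1) / space.detJ.mean(axis=1)
        return float(ratio.min())
    p = nodes[mesh.elems]
    if mesh.elem_type == "tri3":
        v = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                         - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        edges = [(0, 1), (1, 2), (2, 0)]
        L = np.max([np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in edges],
                   axis=0)
        return float(np.min(4.0 * v / (np.sqrt(3.0) * L ** 2)))
    v = np.einsum("ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                  p[:, 3] - p[:, 0]) / 6.0
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    L = np.max([np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in edges],
               axis=0)
    return float(np.min(6.0 * np.sqrt(2.0) * v / L ** 3))
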