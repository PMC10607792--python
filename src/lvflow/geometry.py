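"""Moving model geometry of the left-ventricle lumen.

Conventions
-----------
* Model frame, 2D (long-axis): the inlet/outlet (IO) line is the segment of
  ``y = 0`` between the two points where the lumen trace meets it; the lumen
  lies in ``y < 0`` and +y points from apex toward base.
* Model frame, 3D (short-axis reconstruction): +z points from apex toward
  base, the most basal ring lies in the plane ``z = 0`` (the open IO disc),
  the apex is at negative z.
* All geometry is in millimetres; the flow solver converts to SI.
* Normalized cycle time ``T`` runs over [0, 1] with end diastole (ED) at both
  ends and end systole (ES) at ``T = systole_fraction`` (default 0.4 — the
  imaged systolic fraction; heart rate default 60 bpm so the cycle lasts 1 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "CyclePhase", "MotionGeometry2D", "MotionGeometry3D", "LumenMesh",
    "systolic_interp_factor", "build_motion_2d", "reconstruct_3d_contours",
    "build_corresponding_surfaces", "interpolate_motion_3d", "mesh_lumen",
    "lumen_measure", "polygon_area", "enclosed_volume", "resample_closed",
]


# ---------------------------------------------------------------- cycle time

@dataclass(frozen=True)
class CyclePhase:
    """A point in the normalized cardiac cycle."""

    T: float
    systole_fraction: float = 0.4
    heart_rate: float = 60.0  # beats per minute

    def __post_init__(self):
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must lie in [0, 1]")

    @property
    def cycle_duration(self) -> float:
        """Cycle period in seconds."""
        return 60.0 / self.heart_rate

    @property
    def time_seconds(self) -> float:
        return self.T * self.cycle_duration

    @property
    def is_systole(self) -> bool:
        return self.T <= self.systole_fraction


def systolic_interp_factor(T, systole_fraction: float = 0.4):
    """Piecewise-linear ED->ES->ED blending factor s(T).

    s(0) = 0 (ED), s(systole_fraction) = 1 (ES), s(1) = 0; contraction during
    systole, relaxation during diastole.
    """
    T = np.asarray(T, dtype=float)
    f = systole_fraction
    s = np.where(T <= f, T / f, (1.0 - T) / (1.0 - f))
    return s if s.ndim else float(s)


# ------------------------------------------------------------ polygon helpers

def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polygon (vertices given once, any orientation)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def signed_polygon_area(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _arclength_param(points: np.ndarray, closed: bool) -> np.ndarray:
    pts = np.asarray(points, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points uniformly by arclength."""
    pts = np.asarray(points, float)
    s = _arclength_param(pts, closed=False)
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, pts[:, k]) for k in range(pts.shape[1])])


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline (first point not repeated) to ``n`` points."""
    pts = np.asarray(points, float)
    loop = np.vstack([pts, pts[:1]])
    s = _arclength_param(pts, closed=True)
    target = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(target, s, loop[:, k]) for k in range(pts.shape[1])])


# ------------------------------------------------------------------ 2D motion

@dataclass
class MotionGeometry2D:
    """Keyframed wall motion of a long-axis lumen boundary.

    ``keyframe_walls[k]`` is the wall polyline at ``keyframe_times[k]``: an
    open polyline from the left IO endpoint to the right IO endpoint, all
    keyframes sharing the point count with index-wise correspondence.  The IO
    segment closing the polygon lies on y = 0.
    """

    keyframe_walls: np.ndarray   # (K, N, 2), mm
    keyframe_times: np.ndarray   # (K,) in [0, 1], sorted, starting at 0
    systole_fraction: float = 0.4
    heart_rate: float = 60.0

    @property
    def n_points(self) -> int:
        return self.keyframe_walls.shape[1]

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.heart_rate

    def _bracket(self, T: float):
        # periodic in T with period 1; keyframes wrap ED->ED
        times = np.concatenate([self.keyframe_times, [1.0 + self.keyframe_times[0]]])
        walls = np.concatenate([self.keyframe_walls, self.keyframe_walls[:1]], axis=0)
        T = float(T) % 1.0
        k = int(np.searchsorted(times, T, side="right") - 1)
        k = max(0, min(k, len(times) - 2))
        t0, t1 = times[k], times[k + 1]
        a = 0.0 if t1 == t0 else (T - t0) / (t1 - t0)
        return walls[k], walls[k + 1], a, (t1 - t0)

    def wall_at(self, T: float) -> np.ndarray:
        """Wall polyline (N, 2) at normalized time T, linear between keyframes."""
        w0, w1, a, _ = self._bracket(T)
        return (1 - a) * w0 + a * w1

    def wall_velocity_at(self, T: float) -> np.ndarray:
        """Nodal wall velocity (N, 2) in mm/s at T (piecewise constant)."""
        w0, w1, _, dT = self._bracket(T)
        return (w1 - w0) / (dT * self.cycle_duration)

    def polygon_at(self, T: float) -> np.ndarray:
        """Closed lumen polygon at T (wall points; the IO chord closes it)."""
        return self.wall_at(T)

    def area_at(self, T: float) -> float:
        return polygon_area(self.wall_at(T))


class SelfIntersectionError(ValueError):
    def __init__(self, T):
        super().__init__(f"interpolated boundary self-intersects at T = {T:.4f}")
        self.T = T


def _wall_from_closed_trace(points: np.ndarray) -> np.ndarray:
    """Extract the y<=0 wall part of a closed trace crossing y=0 twice.

    Returns an open polyline from the left IO endpoint to the right one.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    y = pts[:, 1]
    if not (y < 0).any():
        raise ValueError("trace has no points below y = 0")
    # rotate so the loop starts just before a crossing into y<0
    start = None
    for i in range(n):
        if y[i] >= 0 and y[(i + 1) % n] < 0:
            start = i
            break
    if start is None:
        raise ValueError("trace does not reach the IO line y = 0")
    rolled = np.roll(pts, -start, axis=0)
    yr = rolled[:, 1]
    # entry crossing between rolled[0] and rolled[1]
    p0, p1 = rolled[0], rolled[1]
    a = p0[1] / (p0[1] - p1[1])
    entry = p0 + a * (p1 - p0)
    wall = [entry]
    i = 1
    while i < n and yr[i] < 0:
        wall.append(rolled[i])
        i += 1
    if i >= n:
        raise ValueError("trace does not return to y = 0")
    p0, p1 = rolled[i - 1], rolled[i]
    a = p0[1] / (p0[1] - p1[1])
    wall.append(p0 + a * (p1 - p0))
    wall = np.asarray(wall)
    wall[0, 1] = 0.0
    wall[-1, 1] = 0.0
    if wall[0, 0] > wall[-1, 0]:
        wall = wall[::-1]
    return wall


def build_motion_2d(traces, times, n_points: int = 129,
                    systole_fraction: float = 0.4, heart_rate: float = 60.0,
                    check_times=None) -> MotionGeometry2D:
    """Build a 2D motion law from keyframe lumen traces.

    Parameters
    ----------
    traces : sequence of (Ni, 2) closed polygons (mm) each crossing y = 0
        twice, or open wall polylines with both endpoints on y = 0.
    times : keyframe T values in [0, 1]; must include 0 (ED).
    n_points : common resampling count along the wall (from the left IO
        endpoint, by arclength).
    check_times : T samples at which interpolated polygons are checked to be
        simple (default: 50 uniform samples).
    """
    times = np.asarray(times, float)
    order = np.argsort(times)
    times = times[order]
    traces = [traces[k] for k in order]
    if not np.isclose(times[0], 0.0):
        raise ValueError("keyframes must include T = 0 (end diastole)")
    walls = []
    for tr in traces:
        pts = np.asarray(tr, float)
        endpoints_on_io = np.isclose(pts[0, 1], 0.0) and np.isclose(pts[-1, 1], 0.0)
        if endpoints_on_io and not np.allclose(pts[0], pts[-1]):
            wall = pts if pts[0, 0] < pts[-1, 0] else pts[::-1]
        else:
            wall = _wall_from_closed_trace(pts)
        walls.append(resample_open(wall, n_points))
    geom = MotionGeometry2D(np.stack(walls), times,
                            systole_fraction=systole_fraction, heart_rate=heart_rate)
    if check_times is None:
        check_times = np.linspace(0, 1, 50, endpoint=False)
    for T in check_times:
        poly = geom.wall_at(T)
        if not Polygon(poly).is_simple:
            raise SelfIntersectionError(T)
    return geom


# ----------------------------------------------------------- 3D reconstruction

def _ring_plane_frame(normal: np.ndarray):
    """In-plane orthonormal basis with e1 = patient +x projected on the plane."""
    n = normal / np.linalg.norm(normal)
    ex = np.array([1.0, 0.0, 0.0])
    e1 = ex - np.dot(ex, n) * n
    if np.linalg.norm(e1) < 1e-6:  # plane nearly orthogonal to x: fall back to +y
        ey = np.array([0.0, 1.0, 0.0])
        e1 = ey - np.dot(ey, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _resample_ring(ring3d: np.ndarray, n_theta: int, normal: np.ndarray) -> np.ndarray:
    """Resample a 3D ring to n_theta points with a consistent angular datum.

    Index 0 sits on the ray from the ring centroid along patient +x (projected
    into the ring plane); orientation is counter-clockwise about ``normal``.
    Assumes the ring is star-shaped with respect to its centroid (true for
    lumen cross-sections).
    """
    c = ring3d.mean(axis=0)
    e1, e2 = _ring_plane_frame(normal)
    u = (ring3d - c) @ e1
    v = (ring3d - c) @ e2
    theta = np.unwrap(np.arctan2(v, u))
    if theta[-1] < theta[0]:  # enforce CCW about the normal
        ring3d = ring3d[::-1]
        u, v = u[::-1], v[::-1]
        theta = np.unwrap(np.arctan2(v, u))
    alpha0 = theta[0]
    theta_rel = theta - alpha0                    # increasing from 0 to ~2*pi
    loop = np.vstack([ring3d, ring3d[:1]])
    theta_loop = np.concatenate([theta_rel, [theta_rel[0] + 2 * np.pi]])
    # desired absolute angles k*dtheta measured from the +x datum
    grid_rel = (np.linspace(0, 2 * np.pi, n_theta, endpoint=False) - alpha0) % (2 * np.pi)
    return np.column_stack([np.interp(grid_rel, theta_loop, loop[:, k])
                            for k in range(3)])


@dataclass
class ContourStack:
    """Stacked lumen rings at one phase, in the model frame (+z toward base)."""

    rings: np.ndarray          # (n_rings, n_theta, 3), base (z=0) -> apex
    patient_origin: np.ndarray  # model-frame origin in patient coordinates
    patient_axes: np.ndarray    # (3,3) rows = model ex, ey, ez in patient coords

    @property
    def n_rings(self) -> int:
        return self.rings.shape[0]

    def ring_spacing(self) -> float:
        z = self.rings[:, :, 2].mean(axis=1)
        return float(np.mean(-np.diff(z)))


def reconstruct_3d_contours(traces, stack, n_theta: int = 32) -> ContourStack:
    """Map per-slice traces (one phase) into stacked 3D rings, base to apex.

    ``traces`` is a sequence of objects with ``points`` (pixel row, col) and
    ``plane`` carrying the slice index as its first entry, or bare
    ``(slice_index, points)`` pairs.  The apex end is identified as the tapered
    (smaller mean-ring-area) end of the stack.
    """
    from .image_io import pixel_to_patient

    items = []
    for tr in traces:
        if hasattr(tr, "points"):
            items.append((tr.plane[0], np.asarray(tr.points, float)))
        else:
            items.append((int(tr[0]), np.asarray(tr[1], float)))
    if len(items) < 3:
        raise ValueError("need at least 3 slices with accepted traces")

    normal = stack.normal()
    rings, zpos = [], []
    for slice_index, pix in items:
        ring = pixel_to_patient(stack, slice_index, pix)
        rings.append(ring)
        zpos.append(float(ring.mean(axis=0) @ normal))
    order = np.argsort(zpos)
    if not np.array_equal(order, np.arange(len(order))):
        warnings.warn("rings out of order along the stack normal; re-sorted")
    rings = [rings[k] for k in order]

    # orient so index 0 = base: the base end has larger rings than the apex end
    areas = [polygon_area(_project(r, normal)) for r in rings]
    n_third = max(1, len(rings) // 3)
    if np.mean(areas[:n_third]) < np.mean(areas[-n_third:]):
        rings = rings[::-1]            # first end was the apex
        base_to_apex = -normal
    else:
        base_to_apex = normal

    ez = -base_to_apex / np.linalg.norm(base_to_apex)   # +z toward base
    e1, e2 = _ring_plane_frame(ez)
    origin = rings[0].mean(axis=0)
    axes = np.vstack([e1, e2, ez])

    resampled = np.stack([_resample_ring(np.asarray(r), n_theta, ez) for r in rings])
    model = (resampled - origin) @ axes.T
    # pin base plane at z=0 exactly
    model[..., 2] -= model[0, :, 2].mean()
    return ContourStack(rings=model, patient_origin=origin, patient_axes=axes)


def _project(ring: np.ndarray, normal: np.ndarray) -> np.ndarray:
    e1, e2 = _ring_plane_frame(normal)
    c = ring.mean(axis=0)
    return np.column_stack([(ring - c) @ e1, (ring - c) @ e2])


# --------------------------------------------------- correspondence surfaces

@dataclass
class MotionGeometry3D:
    """Correspondence shell surfaces of the lumen wall at ED and ES.

    ED and ES share nodes and elements index-wise; applying the blending
    factor ``s(T)`` to the nodal displacement ``nodes_es - nodes_ed`` animates
    the wall over the cycle.  The surface is closed except for the IO disc
    spanned by ``ring_ids[0]``.
    """

    nodes_ed: np.ndarray     # (N, 3) mm
    nodes_es: np.ndarray     # (N, 3) mm
    tris: np.ndarray         # (M, 3) wall triangles, outward-oriented
    ring_ids: np.ndarray     # (n_rings, n_theta) node ids, base -> apex
    apex_id: int
    systole_fraction: float = 0.4
    heart_rate: float = 60.0

    @property
    def io_ring(self) -> np.ndarray:
        return self.ring_ids[0]

    @property
    def n_theta(self) -> int:
        return self.ring_ids.shape[1]

    @property
    def n_rings(self) -> int:
        return self.ring_ids.shape[0]

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.heart_rate


def build_corresponding_surfaces(rings_ed, rings_es, apex_ed=None, apex_es=None,
                                 systole_fraction: float = 0.4,
                                 heart_rate: float = 60.0) -> MotionGeometry3D:
    """Build index-corresponding ED/ES wall surfaces from stacked rings.

    The body is a structured cylindrical grid of quads split into triangles;
    the apex cap is a fan of triangles converging to the apex point, grouped
    in four curved patches (the ring count must be divisible by 4).  The same
    construction order at ED and ES guarantees node/element correspondence.

    ``rings_*`` are (n_rings, n_theta, 3) arrays (model frame, base first) or
    :class:`ContourStack` objects.  The apex point defaults to the apical ring
    centroid pushed half an inter-ring spacing along -z.
    """
    r_ed = rings_ed.rings if isinstance(rings_ed, ContourStack) else np.asarray(rings_ed, float)
    r_es = rings_es.rings if isinstance(rings_es, ContourStack) else np.asarray(rings_es, float)
    if r_ed.shape != r_es.shape:
        raise ValueError("ED and ES ring stacks differ in shape")
    n_rings, n_theta, _ = r_ed.shape
    if n_theta % 4:
        raise ValueError("n_theta must be divisible by 4 (apex is built from 4 patches)")

    def default_apex(rings):
        c = rings[-1].mean(axis=0)
        dz = abs(rings[0][:, 2].mean() - rings[-1][:, 2].mean()) / max(n_rings - 1, 1)
        return c + np.array([0.0, 0.0, -0.5 * dz])

    a_ed = np.asarray(apex_ed, float) if apex_ed is not None else default_apex(r_ed)
    a_es = np.asarray(apex_es, float) if apex_es is not None else default_apex(r_es)

    nodes_ed = np.vstack([r_ed.reshape(-1, 3), a_ed])
    nodes_es = np.vstack([r_es.reshape(-1, 3), a_es])
    ring_ids = np.arange(n_rings * n_theta).reshape(n_rings, n_theta)
    apex_id = n_rings * n_theta

    tris = []
    for i in range(n_rings - 1):
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            a, b = ring_ids[i, j], ring_ids[i, jn]
            c, d = ring_ids[i + 1, j], ring_ids[i + 1, jn]
            # outward normals: rings are CCW seen from the base (+z)
            tris.append((a, c, b))
            tris.append((b, c, d))
    for j in range(n_theta):  # apex fan: 4 patches of n_theta/4 triangles each
        jn = (j + 1) % n_theta
        tris.append((ring_ids[-1, j], apex_id, ring_ids[-1, jn]))

    return MotionGeometry3D(nodes_ed=nodes_ed, nodes_es=nodes_es,
                            tris=np.asarray(tris, dtype=np.int64),
                            ring_ids=ring_ids, apex_id=apex_id,
                            systole_fraction=systole_fraction, heart_rate=heart_rate)


def interpolate_motion_3d(geom: MotionGeometry3D, T: float):
    """Displaced wall surface and nodal velocity at normalized time T.

    Returns ``(nodes, velocity)`` with nodes in mm and velocity in mm/s:
    ``x(T) = x_ED + s(T) (x_ES - x_ED)`` with the piecewise-linear systolic
    blending law; the velocity is the exact derivative of that law.
    """
    T = float(T) % 1.0
    f = geom.systole_fraction
    s = systolic_interp_factor(T, f)
    dsdT = 1.0 / f if T < f else -1.0 / (1.0 - f)
    d = geom.nodes_es - geom.nodes_ed
    nodes = geom.nodes_ed + s * d
    vel = d * (dsdT / geom.cycle_duration)
    return nodes, vel


# -------------------------------------------------------------------- meshing

@dataclass
class LumenMesh:
    """A lumen finite-element mesh, geometry in mm.

    2D lumen meshes use triangles (a polar fan handles arbitrary star-shaped
    silhouettes without degenerate cells); 3D lumens use tetrahedra;
    structured rectangle meshes for solver verification use quadrilaterals.
    ``boundary`` lists boundary facets as node-index tuples (edges in 2D,
    triangles in 3D) with tags partitioning the boundary into ``wall`` and
    ``io``.  ``meta`` carries the parametric link back to the motion geometry
    used by the solver to impose boundary displacement.
    """

    dim: int
    nodes: np.ndarray           # (N, dim)
    elems: np.ndarray           # (E, 3|4)
    elem_type: str              # "tri3" | "quad4" | "tet4"
    boundary: np.ndarray        # (B, dim) facet node ids
    boundary_tags: np.ndarray   # (B,) str
    meta: dict = field(default_factory=dict)

    @property
    def wall_node_ids(self) -> np.ndarray:
        return _tagged_nodes(self, "wall")

    @property
    def io_node_ids(self) -> np.ndarray:
        return _tagged_nodes(self, "io")

    def min_quality(self) -> float:
        """Minimum scaled Jacobian over quadrature points (1 = perfect)."""
        from ._fem import element_quality
        return element_quality(self)


def _tagged_nodes(mesh: LumenMesh, tag: str) -> np.ndarray:
    sel = mesh.boundary[mesh.boundary_tags == tag]
    return np.unique(sel)


class MeshingError(RuntimeError):
    pass


def _mesh_polygon_polar(motion: MotionGeometry2D, target_h: float) -> LumenMesh:
    """Structured polar triangle mesh of the 2D lumen at ED.

    The closed boundary (wall + IO chord) is resampled preserving the two IO
    corner points; rings shrink linearly toward an interior center with a
    triangle fan at the center (the domain must be star-shaped with respect
    to that center, which LV long-axis silhouettes are).
    """
    wall = motion.keyframe_walls[0]
    left, right = wall[0], wall[-1]
    wall_len = _arclength_param(wall, closed=False)[-1]
    io_len = abs(right[0] - left[0])
    n_wall = max(8, int(round(wall_len / target_h)))
    n_io = max(2, int(round(io_len / target_h)))
    wall_pts = resample_open(wall, n_wall + 1)
    io_pts = np.column_stack([np.linspace(right[0], left[0], n_io + 1),
                              np.zeros(n_io + 1)])
    # wall left->right through y<0 then IO right->left is CCW
    boundary_loop = np.vstack([wall_pts, io_pts[1:-1]])
    if signed_polygon_area(boundary_loop) < 0:
        raise MeshingError("lumen boundary is not counter-clockwise; "
                           "check the trace orientation")
    nb = len(boundary_loop)

    center = np.array([0.5 * (left[0] + right[0]),
                       np.min(wall[:, 1]) * 0.45])
    depth = float(np.mean(np.linalg.norm(boundary_loop - center, axis=1)))
    n_r = max(3, int(round(depth / target_h)))

    # nodes: center + rings 1..n_r (ring n_r = boundary)
    nodes = [center]
    for k in range(1, n_r + 1):
        f = k / n_r
        nodes.append(center + f * (boundary_loop - center))
    nodes = np.vstack([nodes[0][None, :], np.vstack(nodes[1:])])

    def nid(k, j):
        return 0 if k == 0 else 1 + (k - 1) * nb + (j % nb)

    elems = []
    for j in range(nb):                    # center fan
        elems.append((0, nid(1, j), nid(1, j + 1)))
    for k in range(1, n_r):                # annulus quads split in two
        for j in range(nb):
            a, b = nid(k, j), nid(k, j + 1)
            c, d = nid(k + 1, j), nid(k + 1, j + 1)
            elems.append((a, c, d))
            elems.append((a, d, b))
    elems = np.asarray(elems, dtype=np.int64)

    # boundary facets = outer ring edges; wall vs io by y == 0
    b_edges, b_tags = [], []
    for j in range(nb):
        a, b = nid(n_r, j), nid(n_r, j + 1)
        tag = "io" if (abs(nodes[a, 1]) < 1e-9 and abs(nodes[b, 1]) < 1e-9) else "wall"
        b_edges.append((a, b))
        b_tags.append(tag)

    # parametric link: wall boundary nodes <-> arclength fraction along the wall
    wall_node_ids = np.array([nid(n_r, j) for j in range(n_wall + 1)])
    s_wall = _arclength_param(wall_pts, closed=False)
    s_wall = s_wall / s_wall[-1]
    meta = {"wall_ids_ordered": wall_node_ids, "wall_s": s_wall,
            "io_corner_ids": (wall_node_ids[0], wall_node_ids[-1])}

    mesh = LumenMesh(dim=2, nodes=nodes, elems=elems, elem_type="tri3",
                     boundary=np.asarray(b_edges, dtype=np.int64),
                     boundary_tags=np.asarray(b_tags), meta=meta)
    _orient_2d_ccw(mesh)
    return mesh


def _orient_2d_ccw(mesh: LumenMesh) -> None:
    p = mesh.nodes[mesh.elems]
    x, y = p[..., 0], p[..., 1]
    area = 0.5 * np.sum(x * np.roll(y, -1, axis=1) - y * np.roll(x, -1, axis=1), axis=1)
    flip = area < 0
    mesh.elems[flip] = mesh.elems[flip][:, ::-1]


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _hex_to_tets(hex_nodes):
    """Freudenthal/Kuhn 6-tet split of a hex given as corner ids h[i,j,k]
    indexed by binary coords; degenerate (repeated-node) tets are dropped by
    the caller."""
    tets = []
    for perm in _KUHN_PERMS:
        path = [np.array([0, 0, 0])]
        for axis in perm:
            nxt = path[-1].copy()
            nxt[axis] = 1
            path.append(nxt)
        tets.append(tuple(hex_nodes[tuple(p)] for p in path))
    return tets


def _mesh_lumen_3d(geom: MotionGeometry3D, target_h: float) -> LumenMesh:
    """Structured polar tet mesh of the 3D lumen at ED.

    Volume nodes are laid on a (level x radial x angular) grid: per ring
    level, radial layers shrink from the wall ring to an axis node at the ring
    centroid; the apex collapses to a single point.  Hexes of the grid are
    split by the Freudenthal pattern (conforming); collapsed cells at the axis
    and apex reduce to wedges/pyramids whose degenerate tets are dropped.
    """
    rings = geom.nodes_ed[geom.ring_ids]          # (nz, nt, 3)
    nz, nt = rings.shape[:2]
    apex = geom.nodes_ed[geom.apex_id]
    r_mean = float(np.mean(np.linalg.norm(
        rings[0] - rings[0].mean(axis=0), axis=1)))
    n_r = max(2, int(round(r_mean / target_h)))

    centroids = rings.mean(axis=1)                # (nz, 3)
    nodes = []
    node_id = {}

    def add(p):
        nodes.append(p)
        return len(nodes) - 1

    axis_ids = np.empty(nz, dtype=np.int64)
    grid_ids = np.empty((nz, n_r, nt), dtype=np.int64)  # k = 1..n_r stored as 0..n_r-1
    for i in range(nz):
        axis_ids[i] = add(centroids[i])
        for k in range(1, n_r + 1):
            f = k / n_r
            for j in range(nt):
                grid_ids[i, k - 1, j] = add(centroids[i] + f * (rings[i, j] - centroids[i]))
    apex_vid = add(apex)
    nodes = np.asarray(nodes)

    def vid(i, k, j):
        """Global id at level i (i == nz means apex), radial k (0=axis), angle j."""
        if i == nz:
            return apex_vid
        if k == 0:
            return axis_ids[i]
        return grid_ids[i, k - 1, j % nt]

    tets = []
    geom_wall_of = {}   # mesh node id -> geometry node id (wall surface nodes)
    for i in range(nz - 1):
        for j in range(nt):
            geom_wall_of[vid(i, n_r, j)] = geom.ring_ids[i, j]
    for j in range(nt):
        geom_wall_of[vid(nz - 1, n_r, j)] = geom.ring_ids[nz - 1, j]
    geom_wall_of[apex_vid] = geom.apex_id

    for i in range(nz):          # level gaps, last gap reaches the apex
        for k in range(n_r):
            for j in range(nt):
                h = np.empty((2, 2, 2), dtype=np.int64)
                for a in (0, 1):      # along axis (toward apex)
                    for b in (0, 1):  # radial
                        for c in (0, 1):  # angular
                            h[a, b, c] = vid(i + a, k + b, j + c)
                for t in _hex_to_tets(h):
                    if len(set(t)) == 4:
                        tets.append(t)
    tets = np.asarray(tets, dtype=np.int64)

    # positive orientation
    p = nodes[tets]
    v6 = np.einsum("ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                   p[:, 3] - p[:, 0])
    neg = v6 < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    if np.any(np.abs(v6) < 1e-12 * np.max(np.abs(v6))):
        raise MeshingError("degenerate tetrahedra produced by the structured mesh")

    # boundary faces: appear in exactly one tet
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bfaces = faces[idx[counts == 1]]
    io_nodes = set(axis_ids[:1]) | {int(grid_ids[0, k, j]) for k in range(n_r) for j in range(nt)}
    tags = np.array(["io" if set(map(int, f)) <= io_nodes else "wall" for f in bfaces])

    # orient boundary faces outward (normal away from element centroid)
    owner = {}
    for e, t in enumerate(tets):
        for f in (t[[0, 1, 2]], t[[0, 1, 3]], t[[0, 2, 3]], t[[1, 2, 3]]):
            owner[tuple(sorted(f))] = e
    oriented = []
    for f in bfaces:
        e = owner[tuple(sorted(f))]
        cc = nodes[tets[e]].mean(axis=0)
        n = np.cross(nodes[f[1]] - nodes[f[0]], nodes[f[2]] - nodes[f[0]])
        oriented.append(f if np.dot(n, nodes[f].mean(axis=0) - cc) > 0 else f[[0, 2, 1]])
    bfaces = np.asarray(oriented, dtype=np.int64)

    mesh_ids = np.fromiter(geom_wall_of.keys(), dtype=np.int64)
    gids = np.fromiter(geom_wall_of.values(), dtype=np.int64)
    meta = {"wall_mesh_ids": mesh_ids, "wall_geom_ids": gids,
            "axis_ids": axis_ids, "n_r": n_r}
    return LumenMesh(dim=3, nodes=nodes, elems=tets, elem_type="tet4",
                     boundary=bfaces, boundary_tags=tags, meta=meta)


def mesh_lumen(obj, target_h: float) -> LumenMesh:
    """Mesh the lumen at ED: quads for a 2D motion law, tets for a 3D one."""
    if isinstance(obj, MotionGeometry2D):
        return _mesh_polygon_polar(obj, target_h)
    if isinstance(obj, MotionGeometry3D):
        return _mesh_lumen_3d(obj, target_h)
    raise TypeError(f"cannot mesh object of type {type(obj).__name__}")


# ----------------------------------------------------------------- measures

def enclosed_volume(nodes: np.ndarray, tris: np.ndarray,
                    io_ring: np.ndarray | None = None) -> float:
    """Volume enclosed by an outward-oriented triangle surface (mm^3).

    If ``io_ring`` is given, the open IO ring is capped by a flat fan to its
    centroid before applying the divergence theorem.
    """
    tri_list = [np.asarray(tris, dtype=np.int64)]
    pts = np.asarray(nodes, float)
    if io_ring is not None:
        ring = np.asarray(io_ring, dtype=np.int64)
        c = pts[ring].mean(axis=0)
        pts = np.vstack([pts, c])
        cid = len(pts) - 1
        cap = [(ring[j], ring[(j + 1) % len(ring)], cid) for j in range(len(ring))]
        tri_list.append(np.asarray(cap, dtype=np.int64))
    total = 0.0
    for tr in tri_list:
        p = pts[tr]
        total += np.einsum("ij,ij->", np.cross(p[:, 0], p[:, 1]), p[:, 2]) / 6.0
    return abs(float(total))


def lumen_measure(obj, T: float | None = None) -> float:
    """Lumen area (mm^2, 2D) or volume (mm^3, 3D).

    2D uses the shoelace formula on the interpolated boundary polygon; 3D uses
    the divergence theorem on the displaced wall surface with the IO opening
    capped by its flat spanning fan.  A :class:`LumenMesh` is measured by
    summing its element measures.
    """
    if isinstance(obj, MotionGeometry2D):
        return polygon_area(obj.wall_at(0.0 if T is None else T))
    if isinstance(obj, MotionGeometry3D):
        nodes, _ = interpolate_motion_3d(obj, 0.0 if T is None else T)
        return enclosed_volume(nodes, obj.tris, obj.io_ring)
    if isinstance(obj, LumenMesh):
        from ._fem import mesh_measure
        return mesh_measure(obj)
    pts = np.asarray(obj, float)
    if pts.ndim == 2 and pts.shape[1] == 2:
        if len(pts) < 3:
            raise ValueError("open or degenerate polygon")
        return polygon_area(pts)
    raise TypeError(f"cannot measure object of type {type(obj).__name__}")
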