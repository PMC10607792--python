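"""Synthetic inputs: cine-like DICOM stacks with known lumen masks, and
analytic moving-domain benchmark geometries with closed-form references.

The image phantom emulates the acquisition the pipeline is configured for by
default: 0.7 mm pixels, 8 mm slice planes, 20 phases per cycle, a bright
blood pool (~200) inside a darker myocardial ring (~80) on background (~20).
The lumen radius contracts over systole (40% of the cycle) and tapers toward
the apex; additive Gaussian noise with SNR = (lumen - myocardium) / sigma.
One RNG stream per phantom (seed in the spec): identical spec + seed gives
bit-identical pixel data.

Benchmark kinds:

* ``piston_box``     — 2D box, bottom wall rising: Q' = W * s exactly.
* ``contracting_cylinder`` — 3D cylinder, lateral wall moving radially,
  flat-top IO, shallow apex cone: V = pi R^2 (L + h_apex/3).
* ``half_ellipsoid_lv``    — half-ellipsoid lumen, semi-axis a(T) contracting
  80 -> 64 mm at constant b = 25 mm: V = (2/3) pi a b^2,
  SV = (2/3) pi (a_ED - a_ES) b^2 ≈ 20.9 mL.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geo

__all__ = ["PhantomSpec", "PhantomImageStack", "BenchmarkCase",
           "make_image_stack", "make_benchmark_case", "write_dicom_stack",
           "long_axis_keyframe_traces"]

_KINDS = ("image_stack", "piston_box", "contracting_cylinder", "half_ellipsoid_lv")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom; defaults mirror the imaging setup."""

    kind: str = "image_stack"
    rng_seed: int = 0
    heart_rate: float = 60.0
    systole_fraction: float = 0.4
    # --- image stack ---
    n_slices: int = 6
    n_phases: int = 20
    image_size: int = 128
    pixel_spacing: float = 0.7        # mm
    slice_spacing: float = 8.0        # mm
    lumen_radius: float = 22.0        # mm at the base, ED
    myocardium_thickness: float = 10.0
    apex_taper: float = 0.35          # radius factor at the most apical slice
    contraction: float = 0.25         # fractional radius loss at ES
    intensity_lumen: float = 200.0
    intensity_myocardium: float = 80.0
    intensity_background: float = 20.0
    snr: float = 10.0
    # --- piston box (2D) ---
    width: float = 10.0               # mm
    height: float = 10.0
    piston_speed: float = 10.0        # mm/s upward
    # --- contracting cylinder (3D) ---
    radius: float = 15.0
    radius_es: float = 12.0
    length: float = 60.0
    # --- half-ellipsoid LV (3D) ---
    a_ed: float = 80.0                # long semi-axis, mm
    a_es: float = 64.0
    b: float = 25.0                   # short semi-axis, mm
    # ring resolution: at these defaults the discretized surface volume is
    # within 1% of the analytic value (polygonal rings bias it low)
    n_rings: int = 16
    n_theta: int = 48

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        for name in ("pixel_spacing", "slice_spacing", "lumen_radius", "width",
                     "height", "radius", "length", "a_ed", "a_es", "b", "snr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --------------------------------------------------------------- image stack

@dataclass
class PhantomImageStack:
    """Rendered phantom frames plus ground truth."""

    frames: np.ndarray       # (n_slices, n_phases, H, W) uint16
    masks: np.ndarray        # ground-truth lumen masks, bool
    radii: np.ndarray        # (n_slices, n_phases) lumen radius, mm
    center_px: tuple         # lumen center (row, col)
    spec: PhantomSpec
    paths: list = field(default_factory=list)


def _lumen_radius(spec: PhantomSpec, slice_index: int, phase: int) -> float:
    taper = 1.0 + (spec.apex_taper - 1.0) * slice_index / max(spec.n_slices - 1, 1)
    T = phase / spec.n_phases
    s = geo.systolic_interp_factor(T, spec.systole_fraction)
    return spec.lumen_radius * taper * (1.0 - spec.contraction * s)


def make_image_stack(spec: PhantomSpec, out_dir=None) -> PhantomImageStack:
    """Render the short-axis cine phantom; optionally write DICOM files.

    Edges are anti-aliased over one pixel so sub-pixel trace accuracy is
    measurable; ground-truth masks use the exact analytic disk.
    """
    if spec.kind != "image_stack":
        raise ValueError("spec.kind must be 'image_stack'")
    n = spec.image_size
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    dist_px = np.hypot(rr - c, cc - c)
    dist = dist_px * spec.pixel_spacing

    max_r = spec.lumen_radius + spec.myocardium_thickness
    if max_r >= c * spec.pixel_spacing:
        raise ValueError("lumen + myocardium larger than the field of view")

    rng = np.random.default_rng(spec.rng_seed)
    sigma = (spec.intensity_lumen - spec.intensity_myocardium) / spec.snr
    px = spec.pixel_spacing

    frames = np.empty((spec.n_slices, spec.n_phases, n, n), dtype=np.uint16)
    masks = np.empty((spec.n_slices, spec.n_phases, n, n), dtype=bool)
    radii = np.empty((spec.n_slices, spec.n_phases))
    for i in range(spec.n_slices):
        for ph in range(spec.n_phases):
            r = _lumen_radius(spec, i, ph)
            radii[i, ph] = r
            a_lum = np.clip((r - dist) / px + 0.5, 0.0, 1.0)
            a_myo = np.clip((r + spec.myocardium_thickness - dist) / px + 0.5,
                            0.0, 1.0)
            img = (spec.intensity_background
                   + (spec.intensity_myocardium - spec.intensity_background) * a_myo
                   + (spec.intensity_lumen - spec.intensity_myocardium) * a_lum)
            img = img + rng.normal(0.0, sigma, size=img.shape)
            frames[i, ph] = np.clip(np.round(img), 0, 4095).astype(np.uint16)
            masks[i, ph] = dist <= r
    stack = PhantomImageStack(frames=frames, masks=masks, radii=radii,
                              center_px=(c, c), spec=spec)
    if out_dir is not None:
        stack.paths = write_dicom_stack(stack, out_dir)
    return stack


def _uid(*parts) -> str:
    h = hashlib.sha1("-".join(str(p) for p in parts).encode()).hexdigest()
    return "2.25." + str(int(h[:30], 16))


def write_dicom_stack(stack: PhantomImageStack, out_dir) -> list:
    """Write the phantom as standard single-frame MR DICOM files.

    Short-axis orientation is axial identity: ImageOrientationPatient
    (1,0,0, 0,1,0); slice i sits at z = -i * slice_spacing (base at z = 0);
    TriggerTime encodes the phase.  UIDs are derived deterministically from
    the spec seed so reruns are byte-identical.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian

    spec = stack.spec
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study_uid = _uid("study", spec.rng_seed)
    series_uid = _uid("series", spec.rng_seed)
    cycle_ms = 60000.0 / spec.heart_rate
    paths = []
    for i in range(spec.n_slices):
        for ph in range(spec.n_phases):
            sop_uid = _uid("sop", spec.rng_seed, i, ph)
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
            meta.MediaStorageSOPInstanceUID = sop_uid
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = pydicom.uid.MRImageStorage
            ds.SOPInstanceUID = sop_uid
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "MR"
            ds.PatientName = "PHANTOM"
            ds.PatientID = f"LVPH{spec.rng_seed:04d}"
            ds.Rows, ds.Columns = stack.frames.shape[2:]
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 12
            ds.HighBit = 11
            ds.PixelRepresentation = 0
            ds.PixelSpacing = [spec.pixel_spacing, spec.pixel_spacing]
            ds.SliceThickness = spec.slice_spacing
            ds.ImagePositionPatient = [0.0, 0.0, -i * spec.slice_spacing]
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.InstanceNumber = i * spec.n_phases + ph + 1
            ds.TriggerTime = round(ph * cycle_ms / spec.n_phases, 3)
            ds.PixelData = stack.frames[i, ph].tobytes()
            path = out / f"sl{i:02d}_ph{ph:02d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
    return paths


# ----------------------------------------------------------------- benchmarks

@dataclass
class BenchmarkCase:
    """A benchmark motion geometry plus its closed-form reference record."""

    motion: object                 # MotionGeometry2D | MotionGeometry3D
    reference: dict                # analytic values/callables
    spec: PhantomSpec


def _box_wall(spec: PhantomSpec, height: float, n_side=12, n_bottom=12):
    """Open wall polyline of the piston box (left IO corner -> right)."""
    w2 = spec.width / 2.0
    left = np.column_stack([np.full(n_side, -w2),
                            np.linspace(0.0, -height, n_side, endpoint=False)])
    bottom = np.column_stack([np.linspace(-w2, w2, n_bottom, endpoint=False),
                              np.full(n_bottom, -height)])
    right = np.column_stack([np.full(n_side + 1, w2),
                             np.linspace(-height, 0.0, n_side + 1)])
    return np.vstack([left, bottom, right])


def _ellipsoid_rings(a: float, b: float, n_rings: int, n_theta: int):
    """Rings of the half-ellipsoid x^2/b^2 + y^2/b^2 + z^2/a^2 = 1, z <= 0."""
    zeta = np.arange(n_rings) / n_rings          # normalized depth, apex excluded
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rings = np.empty((n_rings, n_theta, 3))
    for i, zt in enumerate(zeta):
        r = b * np.sqrt(1.0 - zt ** 2)
        rings[i, :, 0] = r * np.cos(theta)
        rings[i, :, 1] = r * np.sin(theta)
        rings[i, :, 2] = -a * zt
    return rings


def _cylinder_rings(R: float, L: float, n_rings: int, n_theta: int):
    z = np.linspace(0.0, -L, n_rings)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rings = np.empty((n_rings, n_theta, 3))
    for i, zi in enumerate(z):
        rings[i, :, 0] = R * np.cos(theta)
        rings[i, :, 1] = R * np.sin(theta)
        rings[i, :, 2] = zi
    return rings


def make_benchmark_case(spec: PhantomSpec) -> BenchmarkCase:
    """Build the benchmark motion law and its analytic reference record."""
    f = spec.systole_fraction
    cycle = 60.0 / spec.heart_rate

    if spec.kind == "piston_box":
        # bottom rises at piston_speed for the first half cycle
        h1 = spec.height
        h2 = spec.height - spec.piston_speed * 0.5 * cycle
        if h2 <= 0:
            raise ValueError("piston travels farther than the box height")
        walls = np.stack([_box_wall(spec, h1), _box_wall(spec, h2)])
        motion = geo.MotionGeometry2D(keyframe_walls=walls,
                                      keyframe_times=np.array([0.0, 0.5]),
                                      systole_fraction=f,
                                      heart_rate=spec.heart_rate)
        ref = {"flow_rate": spec.width * spec.piston_speed,   # mm^2/s, outflow
               "valid_T": (0.0, 0.5),
               "area_of_T": lambda T: spec.width * (h1 + (h2 - h1) * 2 * T)}
        return BenchmarkCase(motion, ref, spec)

    if spec.kind == "contracting_cylinder":
        n_rings, n_theta = spec.n_rings, spec.n_theta
        rings_ed = _cylinder_rings(spec.radius, spec.length, n_rings, n_theta)
        rings_es = _cylinder_rings(spec.radius_es, spec.length, n_rings, n_theta)
        h_apex = 0.25 * spec.length / (n_rings - 1)
        apex_ed = np.array([0.0, 0.0, -spec.length - h_apex])
        apex_es = apex_ed.copy()
        motion = geo.build_corresponding_surfaces(
            rings_ed, rings_es, apex_ed, apex_es,
            systole_fraction=f, heart_rate=spec.heart_rate)

        def R_of_T(T):
            s = geo.systolic_interp_factor(T, f)
            return spec.radius + s * (spec.radius_es - spec.radius)

        def V_of_T(T):
            return np.pi * R_of_T(T) ** 2 * (spec.length + h_apex / 3.0)

        def Q_of_T(T, eps=1e-6):
            # outflow positive: Q = -dV/dt
            return -(V_of_T(min(T + eps, 1.0)) - V_of_T(max(T - eps, 0.0))) \
                / ((min(T + eps, 1.0) - max(T - eps, 0.0)) * cycle) * 1e-3  # mL/s
        ref = {"V_of_T": V_of_T, "Q_of_T": Q_of_T, "R_of_T": R_of_T}
        return BenchmarkCase(motion, ref, spec)

    if spec.kind == "half_ellipsoid_lv":
        rings_ed = _ellipsoid_rings(spec.a_ed, spec.b, spec.n_rings, spec.n_theta)
        rings_es = _ellipsoid_rings(spec.a_es, spec.b, spec.n_rings, spec.n_theta)
        apex_ed = np.array([0.0, 0.0, -spec.a_ed])
        apex_es = np.array([0.0, 0.0, -spec.a_es])
        motion = geo.build_corresponding_surfaces(
            rings_ed, rings_es, apex_ed, apex_es,
            systole_fraction=f, heart_rate=spec.heart_rate)

        def a_of_T(T):
            s = geo.systolic_interp_factor(T, f)
            return spec.a_ed + s * (spec.a_es - spec.a_ed)

        def V_of_T(T):
            return (2.0 / 3.0) * np.pi * a_of_T(T) * spec.b ** 2     # mm^3

        sv = (V_of_T(0.0) - V_of_T(f)) * 1e-3                         # mL
        ref = {"V_of_T": V_of_T, "a_of_T": a_of_T,
               "stroke_volume": sv,                                   # ~20.9 mL
               "peak_Q": sv / (f * cycle),                            # mL/s, systole
               "systole_span_s": (0.0, f * cycle)}
        return BenchmarkCase(motion, ref, spec)

    raise ValueError(f"{spec.kind!r} is not a benchmark kind")


def long_axis_keyframe_traces(spec: PhantomSpec, n_keyframes: int = 8,
                              n_points: int = 129):
    """Half-ellipse long-axis lumen traces at keyframe phases (2D workflow).

    Returns ``(walls, times)`` suitable for :func:`geometry.build_motion_2d`:
    the long-axis silhouette of the half-ellipsoid phantom, semi-axes
    (b, a(T)), IO on y = 0.  Keyframe times follow the imaging protocol: ED,
    two mid-systole phases, ES, then four diastolic phases.
    """
    f = spec.systole_fraction
    times = np.concatenate([np.linspace(0.0, f, 4, endpoint=True),
                            np.linspace(f, 1.0, 5, endpoint=False)[1:]])
    if n_keyframes != 8:
        times = np.linspace(0, 1, n_keyframes, endpoint=False)
    phi = np.linspace(0.0, np.pi, n_points)
    walls, tlist = [], []
    for T in times:
        s = geo.systolic_interp_factor(T, f)
        a = spec.a_ed + s * (spec.a_es - spec.a_ed)
        x = -spec.b * np.cos(phi)
        y = -a * np.sin(phi)
        walls.append(np.column_stack([x, y]))
        tlist.append(float(T))
    return walls, np.asarray(tlist)
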