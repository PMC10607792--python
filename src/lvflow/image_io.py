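"""Reading cine cardiac-MR DICOM stacks.

Frames are organized into one :class:`ImageStack` per distinct view
orientation, indexed by ``(slice, phase)``.  Pixel indices are 0-based
``(row, col)`` with *row* along the image Y (column-direction cosine) axis,
following the DICOM patient-coordinate convention: the first triplet of
``ImageOrientationPatient`` is the direction of increasing column index, the
second the direction of increasing row index, and ``PixelSpacing`` is
``(row_spacing, col_spacing)`` in mm.

Phases within a slice are ordered by ``TriggerTime`` when present and by
``InstanceNumber`` otherwise; phase 0 is taken to be end diastole (the first
acquired frame of the cycle, as in clinical cine protocols).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pydicom

__all__ = ["ImageStack", "MetadataError", "load_cine_stack", "pixel_to_patient",
           "patient_to_pixel"]

#: direction-cosine orthonormality tolerance
ORTHO_TOL = 1e-6

#: angle (degrees) between a stack normal and the reference short-axis normal
#: beyond which the stack is classified as long-axis
VIEW_ANGLE_DEG = 45.0


class MetadataError(ValueError):
    """A DICOM file is missing or carries inconsistent spatial metadata."""


@dataclass
class ImageStack:
    """One cine view: frames on a (slice, phase) grid plus spatial metadata."""

    frames: np.ndarray                 # (n_slices, n_phases, rows, cols)
    pixel_spacing: tuple[float, float]  # mm (row, col)
    slice_positions: np.ndarray        # (n_slices, 3) ImagePositionPatient, mm
    slice_orientations: np.ndarray     # (n_slices, 2, 3) row of cosines: [col-dir, row-dir]
    view: str = "short_axis"           # "short_axis" | "long_axis"
    phase_times: np.ndarray | None = None  # trigger times (ms) if available
    source_files: list = field(default_factory=list, repr=False)

    @property
    def n_slices(self) -> int:
        return self.frames.shape[0]

    @property
    def n_phases(self) -> int:
        return self.frames.shape[1]

    def normal(self, slice_index: int = 0) -> np.ndarray:
        """Unit slice normal (col-direction x row-direction)."""
        x, y = self.slice_orientations[slice_index]
        n = np.cross(x, y)
        return n / np.linalg.norm(n)

    def slice_spacing(self) -> float:
        """Mean spacing between adjacent slice origins along the normal (mm)."""
        if self.n_slices < 2:
            raise ValueError("slice spacing undefined for a single slice")
        n = self.normal()
        d = self.slice_positions @ n
        return float(np.mean(np.diff(np.sort(d))))

    def __post_init__(self):
        for s in range(self.slice_orientations.shape[0]):
            _check_orientation(self.slice_orientations[s])
        if self.frames.ndim != 4:
            raise ValueError("frames must be (slice, phase, row, col)")
        if self.n_phases < 2:
            raise ValueError("a cine stack needs at least 2 phases")


def _check_orientation(orient: np.ndarray) -> None:
    x, y = np.asarray(orient, dtype=float)
    for v in (x, y):
        if abs(np.linalg.norm(v) - 1.0) > ORTHO_TOL:
            raise MetadataError("direction cosines are not unit length")
    if abs(float(np.dot(x, y))) > ORTHO_TOL:
        raise MetadataError("direction cosines are not orthogonal")


_REQUIRED = ("PixelSpacing", "ImagePositionPatient", "ImageOrientationPatient")


def _read_meta(path):
    ds = pydicom.dcmread(str(path))
    for attr in _REQUIRED:
        if getattr(ds, attr, None) is None:
            raise MetadataError(f"{path}: missing {attr}")
    return ds


def load_cine_stack(paths) -> list[ImageStack]:
    """Read DICOM files and group them into per-view cine stacks.

    Returns one :class:`ImageStack` per distinct view orientation.  The stack
    whose orientation groups the most slices defines the reference short-axis
    normal; stacks tilted more than 45 degrees from it are labelled long-axis.
    """
    datasets = [_read_meta(p) for p in paths]
    if not datasets:
        raise ValueError("no DICOM files given")

    # group by orientation (rounded to kill float jitter)
    groups: dict[tuple, list] = {}
    for ds in datasets:
        key = tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 5))
        groups.setdefault(key, []).append(ds)

    stacks = []
    for key, members in groups.items():
        orient = np.asarray(key, float).reshape(2, 3)
        _check_orientation(orient)
        normal = np.cross(orient[0], orient[1])
        # slices by projected position along the normal
        by_slice: dict[float, list] = {}
        for ds in members:
            z = round(float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)), 3)
            by_slice.setdefault(z, []).append(ds)
        slice_keys = sorted(by_slice)
        n_phases = {len(v) for v in by_slice.values()}
        if len(n_phases) != 1:
            raise MetadataError("slices carry different phase counts")
        n_phases = n_phases.pop()

        frames, positions, orients, times = [], [], [], None
        for z in slice_keys:
            dss = by_slice[z]
            spacings = {tuple(np.round(np.asarray(d.PixelSpacing, float), 6)) for d in dss}
            if len(spacings) != 1:
                raise MetadataError("mixed pixel spacings within a slice")
            if all(getattr(d, "TriggerTime", None) is not None for d in dss):
                dss.sort(key=lambda d: float(d.TriggerTime))
                times = np.array([float(d.TriggerTime) for d in dss])
            else:
                dss.sort(key=lambda d: int(d.InstanceNumber))
            shapes = {d.pixel_array.shape for d in dss}
            if len(shapes) != 1:
                raise MetadataError("frames of one slice differ in shape")
            frames.append(np.stack([d.pixel_array.astype(np.float64) for d in dss]))
            positions.append(np.asarray(dss[0].ImagePositionPatient, float))
            orients.append(np.asarray(dss[0].ImageOrientationPatient, float).reshape(2, 3))

        spacing = tuple(float(s) for s in by_slice[slice_keys[0]][0].PixelSpacing)
        stacks.append(ImageStack(
            frames=np.stack(frames),
            pixel_spacing=(spacing[0], spacing[1]),
            slice_positions=np.stack(positions),
            slice_orientations=np.stack(orients),
            phase_times=times,
        ))

    # classify views against the orientation that carries the most slices
    ref = max(stacks, key=lambda s: s.n_slices)
    ref_n = ref.normal()
    for st in stacks:
        cosang = abs(float(np.dot(st.normal(), ref_n)))
        st.view = "short_axis" if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= VIEW_ANGLE_DEG \
            else "long_axis"
    stacks.sort(key=lambda s: (s.view, -s.n_slices))
    return stacks


def _plane_basis(stack: ImageStack, slice_index: int):
    if not 0 <= slice_index < stack.n_slices:
        raise IndexError(f"slice index {slice_index} out of range")
    origin = stack.slice_positions[slice_index]
    col_dir, row_dir = stack.slice_orientations[slice_index]
    d_row, d_col = stack.pixel_spacing
    return origin, col_dir * d_col, row_dir * d_row


def pixel_to_patient(stack: ImageStack, slice_index: int, pixel) -> np.ndarray:
    """Map continuous 0-based ``(row, col)`` indices to patient coordinates (mm).

    Affine per the DICOM convention:
    ``P = ImagePositionPatient + col*Δ_col*X̂ + row*Δ_row*Ŷ``.
    Accepts a single pixel or an (N, 2) array; returns matching shape of 3-vectors.
    """
    origin, ex, ey = _plane_basis(stack, slice_index)
    px = np.atleast_2d(np.asarray(pixel, dtype=float))
    pts = origin + px[:, 1:2] * ex + px[:, 0:1] * ey
    return pts[0] if np.asarray(pixel).ndim == 1 else pts


def patient_to_pixel(stack: ImageStack, slice_index: int, point) -> np.ndarray:
    """Inverse of :func:`pixel_to_patient` on the slice plane (in-plane part)."""
    origin, ex, ey = _plane_basis(stack, slice_index)
    p = np.atleast_2d(np.asarray(point, dtype=float)) - origin
    col = p @ ex / (ex @ ex)
    row = p @ ey / (ey @ ey)
    out = np.stack([row, col], axis=-1)
    return out[0] if np.asarray(point).ndim == 1 else out
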