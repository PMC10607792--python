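"""LV lumen segmentation: diffusion filter, fuzzy c-means, region selection,
trace extraction/filtering, snake refinement, and trace smoothing.

Pixel convention: all point lists are continuous 0-based ``(row, col)``
coordinates.  "Counter-clockwise" for a trace means positive shoelace area in
the (x=col, y=row) axes.

The clustering stage minimizes the fuzzy c-means objective

    J = sum_i sum_j  u_ij^m ||q_i - c_j||^2,

with memberships by the reciprocal-distance rule and centroid updates
weighted by the exact intensity histogram (identical to the per-pixel update,
cheaper on images with repeated intensities).  Cluster centers are
initialized at uniform intervals of the intensity range, which makes the
whole pipeline deterministic ("seedless").
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from shapely.geometry import Polygon
from skimage import measure, morphology

__all__ = ["FcmModel", "Trace", "RejectedTrace", "LumenNotFoundError",
           "anisotropic_diffusion", "fcm_segment", "select_lumen_region",
           "extract_and_filter_traces", "snake_refine", "smooth_traces",
           "dice", "segment_frame", "cluster_count_diagnostic",
           "load_manual_trace", "save_trace_csv"]


# ------------------------------------------------------------------ filtering

def anisotropic_diffusion(image: np.ndarray, iterations: int = 10,
                          conductance: float | None = None) -> np.ndarray:
    """Edge-preserving (gradient anisotropic / Perona-Malik type) smoothing.

    ``conductance`` is the gradient-magnitude scale below which smoothing is
    strong; default 10% of the intensity range.  Intensity extrema are not
    amplified (diffusion obeys a discrete maximum principle).
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D scalar image")
    if conductance is None:
        conductance = 0.1 * max(np.ptp(img), 1e-12)
    f = sitk.GradientAnisotropicDiffusionImageFilter()
    f.SetNumberOfIterations(int(iterations))
    f.SetConductanceParameter(float(conductance))
    f.SetTimeStep(0.124)          # stable for 2D (< 1/2^(d+1))
    out = sitk.GetArrayFromImage(f.Execute(sitk.GetImageFromArray(img)))
    return out


# ----------------------------------------------------------------- clustering

@dataclass
class FcmModel:
    """Converged fuzzy c-means model over image intensities."""

    n_clusters: int
    fuzzy_exponent: float
    centers: np.ndarray                    # sorted ascending
    objective_history: np.ndarray          # J after each iteration (non-increasing)
    converged: bool
    single_cluster: bool = False           # all pixels identical

    @property
    def objective(self) -> float:
        return float(self.objective_history[-1])

    def memberships(self, values: np.ndarray) -> np.ndarray:
        """Reciprocal-distance memberships u_ij for given intensities.

        Returns shape ``values.shape + (C,)``; rows sum to 1.  A value
        coinciding with k cluster centers splits membership equally among
        them.
        """
        return _memberships(np.asarray(values, float), self.centers,
                            self.fuzzy_exponent)

    def labels(self, values: np.ndarray) -> np.ndarray:
        """Hard assignment: max membership, ties broken by lowest index."""
        return np.argmax(self.memberships(values), axis=-1)


def _memberships(values, centers, m):
    d = np.abs(values[..., None] - centers)          # (..., C)
    zero = d < 1e-300
    any_zero = zero.any(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d ** (-2.0 / (m - 1.0))
        u = np.where(any_zero[..., None],
                     zero / np.maximum(zero.sum(axis=-1, keepdims=True), 1),
                     w / w.sum(axis=-1, keepdims=True))
    return u


def fcm_segment(image: np.ndarray, n_clusters: int = 10, m: float = 2.0,
                tol: float = 1e-8, max_iter: int = 300) -> FcmModel:
    """Fuzzy c-means over the image intensity distribution.

    The alternating membership/center updates run on the exact intensity
    histogram (unique values weighted by their counts) until the objective
    changes by less than ``tol`` or ``max_iter`` is reached.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzy exponent must be > 1")
    vals, counts = np.unique(np.asarray(image, float).ravel(), return_counts=True)
    w = counts.astype(float)
    vmin, vmax = vals[0], vals[-1]
    if vmax == vmin:
        return FcmModel(n_clusters, m, np.full(n_clusters, vmin),
                        np.array([0.0]), converged=True, single_cluster=True)
    # centers at uniform intervals of the intensity range
    centers = vmin + (np.arange(n_clusters) + 0.5) * (vmax - vmin) / n_clusters
    history = []
    converged = False
    for _ in range(max_iter):
        u = _memberships(vals, centers, m)           # (B, C)
        um = u ** m
        d2 = (vals[:, None] - centers) ** 2
        wum = w[:, None] * um
        centers = (wum * vals[:, None]).sum(axis=0) / np.maximum(wum.sum(axis=0), 1e-300)
        # objective after both half-updates: monotone non-increasing
        u = _memberships(vals, centers, m)
        d2 = (vals[:, None] - centers) ** 2
        J = float((w[:, None] * u ** m * d2).sum())
        history.append(J)
        if len(history) > 1 and abs(history[-2] - J) < tol:
            converged = True
            break
    order = np.argsort(centers)
    return FcmModel(n_clusters, m, centers[order], np.asarray(history), converged)


def fcm_objective(image, centers, m) -> float:
    """Direct per-pixel evaluation of J (definition check / oracle)."""
    q = np.asarray(image, float).ravel()
    u = _memberships(q, np.asarray(centers, float), m)
    d2 = (q[:, None] - np.asarray(centers)) ** 2
    return float((u ** m * d2).sum())


def fcm_centers_per_pixel(image, centers, m) -> np.ndarray:
    """One per-pixel centroid update (equals the histogram-weighted update)."""
    q = np.asarray(image, float).ravel()
    um = _memberships(q, np.asarray(centers, float), m) ** m
    return (um * q[:, None]).sum(axis=0) / um.sum(axis=0)


def fcm_centers_histogram(image, centers, m) -> np.ndarray:
    """One histogram-weighted centroid update (the production code path)."""
    vals, counts = np.unique(np.asarray(image, float).ravel(),
                             return_counts=True)
    um = _memberships(vals, np.asarray(centers, float), m) ** m
    wum = counts[:, None] * um
    return (wum * vals[:, None]).sum(axis=0) / wum.sum(axis=0)


# ----------------------------------------------------------- region selection

class LumenNotFoundError(RuntimeError):
    """No cluster region lies near the provided ventricle center."""


def select_lumen_region(model: FcmModel, image: np.ndarray, center_hint,
                        search_radius: float = 15.0, decile: float = 0.10,
                        closing_radius: int = 2) -> np.ndarray:
    """Binary lumen mask from the clustered image and a ventricle-center hint.

    Pixels are hard-assigned to their max-membership cluster; connected
    regions of the *bright* clusters (center above the mean image intensity —
    the blood pool is the bright structure) are ranked by their minimum pixel
    distance to the hint, regions within the closest decile of that distance
    are kept and the largest-area one wins.  (Distance to the region, not to
    its centroid: the myocardial ring around the lumen shares the lumen's
    centroid.)  A small morphological closing smooths the result.

    Raises :class:`LumenNotFoundError` when no bright region comes within
    ``search_radius`` pixels of the hint — the manual-retrace path.
    """
    hint = np.asarray(center_hint, float)
    if not (0 <= hint[0] < image.shape[0] and 0 <= hint[1] < image.shape[1]):
        raise ValueError("center hint outside the image")
    img = np.asarray(image, float)
    labels = model.labels(img)
    bright = np.where(model.centers > img.mean())[0]
    if not len(bright):
        bright = [int(np.argmax(model.centers))]
    regions = []
    for j in bright:
        lab = measure.label(labels == j, connectivity=1)
        for r in measure.regionprops(lab):
            dmin = float(np.min(np.linalg.norm(r.coords - hint, axis=1)))
            regions.append((dmin, r.area, lab == r.label))
    if not regions:
        raise LumenNotFoundError("no cluster regions found")
    dists = np.array([r[0] for r in regions])
    if dists.min() > search_radius:
        raise LumenNotFoundError(
            f"no region within {search_radius} px of the hint "
            f"(closest at {dists.min():.1f} px)")
    near = [r for r in regions if r[0] <= search_radius]
    dn = np.array([r[0] for r in near])
    thresh = max(float(np.quantile(dn, decile)), float(dn.min()))
    candidates = [r for r in near if r[0] <= thresh]
    best = max(candidates, key=lambda r: r[1])
    mask = morphology.closing(best[2], morphology.disk(closing_radius))
    return mask


# ------------------------------------------------------------------- tracing

def _shoelace(points) -> float:
    # signed area in (x=col, y=row) axes
    x, y = points[:, 1], points[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _perimeter(points) -> float:
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


@dataclass
class Trace:
    """A closed lumen-wall contour on one image plane.

    ``points`` are continuous (row, col) pixel coordinates, ordered CCW (in
    the (col, row) axes), first point not repeated.  ``plane`` identifies
    (slice, phase, view).
    """

    points: np.ndarray
    plane: tuple = (0, 0, "short_axis")
    patient_points: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if len(self.points) >= 3 and _shoelace(self.points) < 0:
            self.points = self.points[::-1]

    @property
    def area(self) -> float:
        return abs(_shoelace(self.points))

    @property
    def perimeter(self) -> float:
        return _perimeter(self.points)

    @property
    def circularity(self) -> float:
        """4*pi*A/P^2: 1 for a circle, < 1 otherwise."""
        return 4.0 * np.pi * self.area / self.perimeter ** 2

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def is_simple(self) -> bool:
        return Polygon(self.points[:, ::-1]).is_simple


@dataclass
class RejectedTrace:
    """Explicit rejection result carrying the reason (manual-retrace path)."""

    points: np.ndarray
    reason: str
    circularity: float | None = None


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    k = window // 2
    pad = np.vstack([points[-k:], points, points[:k]])
    kernel = np.ones(window) / window
    return np.column_stack([np.convolve(pad[:, c], kernel, mode="valid")
                            for c in range(points.shape[1])])


def extract_and_filter_traces(mask: np.ndarray, circularity_threshold: float = 0.5,
                              centroid_window=None, smooth_window: int = 3,
                              plane=(0, 0, "short_axis")):
    """Sub-pixel boundary of the largest mask component, filtered.

    Marching squares extracts the 0.5-level contour; the trace is lightly
    smoothed and rejected (returned as :class:`RejectedTrace`) if its
    circularity falls below the threshold or its centroid leaves the expected
    window (default: the central third of the image).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = measure.label(mask, connectivity=1)
    largest = max(measure.regionprops(lab), key=lambda r: r.area)
    comp = (lab == largest.label).astype(float)
    contours = measure.find_contours(comp, 0.5)
    if not contours:
        raise ValueError("no contour found")
    pts = max(contours, key=len)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    pts = _smooth_closed(pts, smooth_window)
    trace = Trace(points=pts, plane=plane)
    if centroid_window is None:
        h, w = mask.shape
        centroid_window = ((h / 3, 2 * h / 3), (w / 3, 2 * w / 3))
    circ = trace.circularity
    if circ < circularity_threshold:
        return RejectedTrace(pts, f"circularity {circ:.3f} below "
                                  f"{circularity_threshold}", circ)
    (r0, r1), (c0, c1) = centroid_window
    cen = trace.centroid
    if not (r0 <= cen[0] <= r1 and c0 <= cen[1] <= c1):
        return RejectedTrace(pts, "centroid outside the expected ventricle "
                                  f"window (at {cen[0]:.0f},{cen[1]:.0f})", circ)
    return trace


def snake_refine(trace: Trace, image: np.ndarray, alpha: float = 0.1,
                 beta: float = 0.1, gamma: float = 1.0,
                 iterations: int = 500, convergence: float = 0.01) -> Trace:
    """Active-contour refinement toward image gradients.

    Minimizes tension (alpha) + stiffness (beta) internal energy against the
    image-edge external energy; on collapse (< 8 points) or
    self-intersection the input trace is returned with a warning.  The
    convergence threshold (max point movement per iteration) is deliberately
    tight: the stock 0.1 px stalls well before the gradient ridge.
    """
    from skimage.segmentation import active_contour

    if iterations <= 0:
        raise ValueError("iterations must be positive")
    init = np.asarray(trace.points, float)
    # normalize intensities so the gradient forces are O(0.1) px per step:
    # raw scanner units make every step clamp at max_px_move and oscillate
    img = np.asarray(image, float)
    rng = np.ptp(img)
    img = (img - img.min()) / (rng if rng > 0 else 1.0)
    out = active_contour(img, init, alpha=alpha,
                         beta=beta, gamma=gamma, w_line=0.0, w_edge=1.0,
                         boundary_condition="periodic",
                         max_num_iter=int(iterations), convergence=convergence)
    refined = Trace(points=out, plane=trace.plane)
    if len(refined.points) < 8 or not refined.is_simple():
        warnings.warn("snake collapsed or self-intersected; keeping the "
                      "initial trace")
        return trace
    return refined


def smooth_traces(traces, window_along: int = 3, window_across: int = 3):
    """Average neighboring corresponding trace points along and across slices.

    ``traces`` must share point counts with corresponding indexing (resample
    first).  Along-contour smoothing is circular; across-slice smoothing
    averages the same point index over a sliding window of adjacent traces
    (clipped at the stack ends).
    """
    counts = {len(t.points) for t in traces}
    if len(counts) != 1:
        raise ValueError("traces must share point counts")
    pts = np.stack([t.points for t in traces])       # (S, N, 2)
    if window_along > 1:
        pts = np.stack([_smooth_closed(p, window_along) for p in pts])
    if window_across > 1:
        if len(traces) == 1:
            warnings.warn("single trace: across-slice averaging skipped")
        else:
            k = window_across // 2
            out = np.empty_like(pts)
            for s in range(len(traces)):
                lo, hi = max(0, s - k), min(len(traces), s + k + 1)
                out[s] = pts[lo:hi].mean(axis=0)
            pts = out
    return [Trace(points=p, plane=t.plane) for p, t in zip(pts, traces)]


# ------------------------------------------------------------------- pipeline

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0


def segment_frame(image: np.ndarray, center_hint=None, n_clusters: int = 10,
                  m: float = 2.0, diffusion_iterations: int = 10,
                  snake: bool = True, plane=(0, 0, "short_axis"),
                  circularity_threshold: float = 0.5, **kwargs):
    """Full per-frame pipeline: diffuse -> FCM -> select -> trace -> snake.

    Returns ``(trace_or_rejected, mask)``.  The snake runs on the diffused
    image by default.
    """
    img = anisotropic_diffusion(image, diffusion_iterations)
    if center_hint is None:
        center_hint = (image.shape[0] / 2, image.shape[1] / 2)
    model = fcm_segment(img, n_clusters=n_clusters, m=m)
    mask = select_lumen_region(model, img, center_hint, **kwargs)
    result = extract_and_filter_traces(
        mask, plane=plane, circularity_threshold=circularity_threshold)
    if snake and isinstance(result, Trace):
        result = snake_refine(result, img)
    return result, mask


def cluster_count_diagnostic(image: np.ndarray, center_hint=None,
                             c_range=range(4, 13), m: float = 2.0):
    """Diagnostic table for choosing the cluster count.

    For each candidate C reports the mean inter-cluster center distance and
    the circularity of the lumen region that C produces (no automatic
    selection; the default C = 10 follows the short-axis protocol).
    """
    rows = []
    for C in c_range:
        model = fcm_segment(image, n_clusters=C, m=m)
        cc = model.centers
        dmean = float(np.mean(np.abs(cc[:, None] - cc[None, :])
                              [np.triu_indices(C, 1)]))
        circ = np.nan
        try:
            mask = select_lumen_region(model, image,
                                       center_hint or (image.shape[0] / 2,
                                                       image.shape[1] / 2))
            result = extract_and_filter_traces(mask, circularity_threshold=0.0)
            if isinstance(result, Trace):
                circ = result.circularity
        except LumenNotFoundError:
            pass
        rows.append({"C": C, "mean_intercluster_distance": dmean,
                     "lumen_circularity": circ})
    import pandas as pd
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- trace files

def save_trace_csv(trace: Trace, path) -> None:
    """Write a trace as x,y (col,row) rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y"])
        for r, c in trace.points:
            w.writerow([f"{c:.6f}", f"{r:.6f}"])


def load_manual_trace(path, plane=(0, 0, "long_axis")) -> Trace:
    """Import a manually traced polyline from a CSV sidecar (x,y per row)."""
    pts = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            try:
                x, y = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                continue                                # header or blank line
            pts.append((y, x))                          # store as (row, col)
    if len(pts) < 3:
        raise ValueError(f"{path}: fewer than 3 trace points")
    return Trace(points=np.asarray(pts), plane=plane)
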