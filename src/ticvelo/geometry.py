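"""Vessel geometry: segmentation, centerline extraction, arc lengths, diameters.

The vessel is segmented from *temporal* intensity changes — a pixel
belongs to the vessel if the passing contrast modulates its intensity —
then reduced to a one-pixel centerline by morphological thinning
(skeletonization), pruned to the longest endpoint-to-endpoint path, and
smoothed with a Savitzky–Golay filter so arc lengths are not inflated by
the pixel-lattice staircase.  Diameters are measured as the full width at
half contrast depth (FWHM) of an intensity profile taken perpendicular to
the centerline, the standard angiographic convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import savgol_filter
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .image_io import AngioSequence

__all__ = [
    "VesselMask",
    "Centerline",
    "DiameterMeasurement",
    "extract_vessel_mask",
    "extract_centerline",
    "centerline_from_points",
    "arc_distance",
    "measure_diameter",
    "expansion_percent",
]


@dataclass(frozen=True)
class VesselMask:
    """Boolean vessel segmentation for one sequence."""

    mask: np.ndarray  # 2D bool
    source_frame_range: tuple[int, int]  # [start, stop) frames used

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not mask.any():
            raise ValueError("empty foreground")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class Centerline:
    """Ordered vessel centerline with cumulative arc length.

    ``points`` are sub-pixel (row, col) coordinates after smoothing;
    ``raw_points`` are the integer skeleton pixels before smoothing and
    all lie inside the source mask.  ``cumulative_arc_px`` is the running
    polyline length over the smoothed points, starting at 0.
    """

    points: np.ndarray  # (N, 2) float
    cumulative_arc_px: np.ndarray  # (N,)
    raw_points: np.ndarray | None = None  # (N, 2) int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        arc = np.asarray(self.cumulative_arc_px, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if len(arc) != len(pts):
            raise ValueError("cumulative_arc_px length mismatch")
        if len(pts) >= 2:
            if arc[0] != 0 or np.any(np.diff(arc) <= 0):
                raise ValueError("cumulative_arc_px must start at 0 and strictly increase")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cumulative_arc_px", arc)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_arc_px(self) -> float:
        return float(self.cumulative_arc_px[-1])

    def index_at_fraction(self, fraction: float) -> int:
        """Index of the point closest to ``fraction`` of the total arc length."""
        target = fraction * self.total_arc_px
        return int(np.argmin(np.abs(self.cumulative_arc_px - target)))


@dataclass(frozen=True)
class DiameterMeasurement:
    site: str  # "proximal" | "middle"
    position_arc_fraction: float
    diameter_mm: float
    method: str = "fwhm-perpendicular-profile"

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("diameter must be positive")
        object.__setattr__(self, "diameter_mm", float(self.diameter_mm))


def extract_vessel_mask(
    seq: AngioSequence,
    threshold_mode: str = "temporal_range",
    threshold: float = 0.5,
) -> VesselMask:
    """Segment the vessel from temporal intensity changes.

    ``temporal_range`` scores each pixel by its max−min intensity over
    time; ``min_projection`` by its temporal median minus temporal minimum
    (robust when stray bright transients occur).  Foreground is the set of
    pixels whose score reaches ``threshold`` × the image-wide maximum
    score; only the largest connected component is kept.
    """
    frames = seq.frames.astype(float)
    if threshold_mode == "temporal_range":
        stat = frames.max(axis=0) - frames.min(axis=0)
    elif threshold_mode == "min_projection":
        stat = np.median(frames, axis=0) - frames.min(axis=0)
    else:
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")

    peak = stat.max()
    if peak <= 0:
        raise ValueError("empty foreground: no temporal intensity change in sequence")
    fg = stat >= threshold * peak
    if not fg.any():
        raise ValueError("empty foreground at this threshold")

    labels = cc_label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    return VesselMask(mask=mask, source_frame_range=(0, seq.frame_count))


def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    coords = np.argwhere(skeleton)
    pixel_set = {tuple(c) for c in coords}
    g = nx.Graph()
    g.add_nodes_from(pixel_set)
    for r, c in pixel_set:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pixel_set:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _longest_endpoint_path(g: nx.Graph) -> list[tuple[int, int]]:
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if not endpoints:
        raise ValueError("skeleton has no endpoints (closed loop?)")
    best: tuple[float, tuple | None, tuple | None] = (-1.0, None, None)
    for src in endpoints:
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for dst in endpoints:
            if dst in dist and dist[dst] > best[0]:
                best = (dist[dst], src, dst)
    if best[1] is None:
        raise ValueError("skeleton has no endpoint-to-endpoint path")
    return nx.dijkstra_path(g, best[1], best[2], weight="weight")


def _orient_inflow(path: list[tuple[int, int]], inflow: str) -> list[tuple[int, int]]:
    first, last = path[0], path[-1]
    keys = {
        "left": lambda p: p[1],
        "right": lambda p: -p[1],
        "top": lambda p: p[0],
        "bottom": lambda p: -p[0],
    }
    try:
        key = keys[inflow]
    except KeyError:
        raise ValueError(f"unknown inflow side: {inflow!r}") from None
    return path if key(first) <= key(last) else path[::-1]


def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def extract_centerline(
    mask: VesselMask,
    smooth_window: int = 21,
    smooth_order: int = 3,
    inflow: str = "left",
) -> Centerline:
    """Thin the mask to a single ordered centerline.

    The mask is skeletonized, side-branch spurs are pruned by keeping only
    the longest (geodesic) path between skeleton endpoints, points are
    ordered from the inflow side of the image, and the row/col coordinate
    series are smoothed with a Savitzky–Golay filter of the given window
    and polynomial order.
    """
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if smooth_window <= smooth_order:
        raise ValueError("smooth_window must exceed smooth_order")

    skeleton = skeletonize(mask.mask)
    if not skeleton.any():
        raise ValueError("skeleton is empty")
    g = _skeleton_graph(skeleton)
    path = _orient_inflow(_longest_endpoint_path(g), inflow)
    raw = np.asarray(path, dtype=int)

    n = len(raw)
    window = min(smooth_window, n if n % 2 == 1 else n - 1)
    if window > smooth_order:
        smooth = np.column_stack(
            [
                savgol_filter(raw[:, 0].astype(float), window, smooth_order),
                savgol_filter(raw[:, 1].astype(float), window, smooth_order),
            ]
        )
    else:  # path too short to smooth
        smooth = raw.astype(float)

    # collapse any zero-length segments the smoothing may have produced
    keep = np.concatenate([[True], np.linalg.norm(np.diff(smooth, axis=0), axis=1) > 1e-12])
    smooth = smooth[keep]
    raw = raw[keep]
    return Centerline(
        points=smooth, cumulative_arc_px=_cumulative_arc(smooth), raw_points=raw
    )


def centerline_from_points(points: np.ndarray) -> Centerline:
    """Build a :class:`Centerline` directly from ordered (row, col) points,
    e.g. from phantom ground truth or an analytic curve."""
    pts = np.asarray(points, dtype=float)
    return Centerline(points=pts, cumulative_arc_px=_cumulative_arc(pts))


def arc_distance(cl: Centerline, idx_a: int, idx_b: int, resolution: float) -> float:
    """Distance in mm between two centerline points, along the centerline."""
    n = len(cl)
    if not (0 <= idx_a < n and 0 <= idx_b < n):
        raise IndexError(f"centerline indices out of range: {idx_a}, {idx_b} (n={n})")
    if idx_a > idx_b:
        raise ValueError("idx_a must not exceed idx_b")
    return float(cl.cumulative_arc_px[idx_b] - cl.cumulative_arc_px[idx_a]) * resolution


def _local_tangent(cl: Centerline, index: int, half_span: int = 5) -> np.ndarray:
    lo = max(0, index - half_span)
    hi = min(len(cl) - 1, index + half_span)
    if hi == lo:
        raise ValueError("centerline too short to define a tangent")
    tangent = cl.points[hi] - cl.points[lo]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        raise ValueError("degenerate tangent at this site")
    return tangent / norm


def _fwhm_from_profile(profile: np.ndarray, step_px: float) -> float:
    n = len(profile)
    outer = max(2, n // 8)
    baseline = float(np.median(np.concatenate([profile[:outer], profile[-outer:]])))
    i_min = int(np.argmin(profile))
    depth = baseline - profile[i_min]
    if depth <= 0:
        raise ValueError("no contrast depth in the perpendicular profile")
    level = profile[i_min] + depth / 2.0

    left = right = None
    for i in range(i_min, 0, -1):
        if profile[i - 1] >= level:
            frac = (level - profile[i]) / (profile[i - 1] - profile[i])
            left = i - frac
            break
    for i in range(i_min, n - 1):
        if profile[i + 1] >= level:
            frac = (level - profile[i]) / (profile[i + 1] - profile[i])
            right = i + frac
            break
    if left is None or right is None:
        raise ValueError("profile does not cross half depth on both sides")
    return (right - left) * step_px


def measure_diameter(
    seq: AngioSequence,
    cl: Centerline,
    site_fraction: float,
    profile_frame: int | None = None,
    site: str | None = None,
    profile_halflength_px: float = 40.0,
    step_px: float = 0.25,
) -> DiameterMeasurement:
    """Measure the vessel diameter at a fractional arc position.

    The intensity profile perpendicular to the local centerline tangent is
    sampled (linear interpolation) on the frame of strongest contrast —
    the frame with the lowest mean intensity, unless ``profile_frame`` is
    given — and the diameter is the full width at half the profile's
    contrast depth, converted to mm.
    """
    index = cl.index_at_fraction(site_fraction)
    tangent = _local_tangent(cl, index)
    normal = np.array([-tangent[1], tangent[0]])

    if profile_frame is None:
        profile_frame = int(np.argmin(seq.frames.reshape(seq.frame_count, -1).mean(axis=1)))
    frame = seq.frames[profile_frame].astype(float)

    offsets = np.arange(-profile_halflength_px, profile_halflength_px + step_px, step_px)
    coords = cl.points[index][:, np.newaxis] + normal[:, np.newaxis] * offsets
    profile = map_coordinates(frame, coords, order=1, mode="nearest")
    width_px = _fwhm_from_profile(profile, step_px)

    if site is None:
        site = "proximal" if site_fraction < 0.4 else "middle"
    return DiameterMeasurement(
        site=site,
        position_arc_fraction=float(site_fraction),
        diameter_mm=width_px * seq.resolution,
    )


def expansion_percent(diameter_before: float, diameter_after: float) -> float:
    """Relative diameter increase after stenting, in percent (1 decimal)."""
    if not diameter_before > 0:
        raise ValueError("before-diameter must be positive")
    return round(100.0 * (float(diameter_after) - float(diameter_before)) / float(diameter_before), 1)
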