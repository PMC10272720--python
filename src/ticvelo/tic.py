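"""Time-intensity curves, contrast-peak detection, and peak-shift velocimetry.

A 20 × 20 px region of interest (ROI) on the vessel centerline yields an
area-averaged time-intensity curve (TIC).  Contrast arrival *decreases*
intensity, so a contrast-concentration peak is a relative *minimum* of
the TIC; internally the curve is inverted before extremum detection so
that "peak" language matches the physical bolus.  Two ROIs — proximal
and distal — give two TICs whose corresponding peaks are shifted by the
bolus transit time, and each matched peak pair yields a velocity

    v_k (mm/s) = dx_mm / dt_k(frames) * fps(frame/s)

where ``dx_mm`` is the centerline arc distance between the ROI centers
(pixel arc length × image resolution, mm/px).  Peak pairs are matched
ordinally (k-th to k-th): pulsation peaks are periodic and ordered, so a
one-to-one ordered pairing is implied by per-peak subtraction.  The mean
and the population SD over peaks are reported; with a single usable peak
the SD is 0.  The first pulse of a train may optionally be excluded when
its intensity change is too weak at the distal ROI to time reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, peak_prominences

from .geometry import Centerline, arc_distance
from .image_io import AngioSequence

__all__ = [
    "ROI",
    "TimeIntensityCurve",
    "PeakSet",
    "VelocityEstimate",
    "place_rois",
    "compute_tic",
    "detect_peaks",
    "estimate_velocity",
    "roi_separation_mm",
    "retention_ratio",
]

DEFAULT_ROI_EDGE_PX = 20

#: default prominence floor as a fraction of a TIC's dynamic range
DEFAULT_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class ROI:
    """A square pixel box centered on a centerline point."""

    center_index: int
    bounds: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open

    @property
    def edge_px(self) -> int:
        return self.bounds[1] - self.bounds[0]

    def overlaps(self, other: "ROI") -> bool:
        r0, r1, c0, c1 = self.bounds
        s0, s1, d0, d1 = other.bounds
        return r0 < s1 and s0 < r1 and c0 < d1 and d0 < c1


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Per-frame mean intensity over an ROI."""

    values: np.ndarray
    fps: float
    roi: ROI | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dynamic_range(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass(frozen=True)
class PeakSet:
    """Frame indices of detected contrast peaks (intensity minima)."""

    peak_frames: np.ndarray
    polarity: str = "contrast-max = intensity-min"
    excluded_first: bool = False

    def __post_init__(self) -> None:
        frames = np.asarray(self.peak_frames)
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError("peak frames must be strictly increasing")
        object.__setattr__(self, "peak_frames", frames)

    def __len__(self) -> int:
        return len(self.peak_frames)


@dataclass(frozen=True)
class VelocityEstimate:
    """Per-peak velocities and their summary, from one ROI pair."""

    per_peak_velocities: np.ndarray  # mm/s
    mean_velocity: float  # mm/s
    sd_velocity: float  # mm/s, population SD; 0.0 with one peak
    dx_mm: float
    per_peak_dt_frames: np.ndarray


def _build_roi(
    center_index: int,
    cl: Centerline,
    frame_shape: tuple[int, int],
    edge_px: int,
) -> ROI:
    rows, cols = frame_shape
    if edge_px > rows or edge_px > cols:
        raise ValueError("ROI edge exceeds frame size")
    half = edge_px // 2
    r = int(round(cl.points[center_index][0]))
    c = int(round(cl.points[center_index][1]))
    r0 = min(max(r - half, 0), rows - edge_px)
    c0 = min(max(c - half, 0), cols - edge_px)
    return ROI(center_index=center_index, bounds=(r0, r0 + edge_px, c0, c0 + edge_px))


def compute_tic(seq: AngioSequence, roi: ROI) -> TimeIntensityCurve:
    """Area-averaged intensity per frame over the ROI box (no temporal filtering)."""
    r0, r1, c0, c1 = roi.bounds
    rows, cols = seq.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"ROI bounds {roi.bounds} outside frame {seq.shape}")
    values = seq.frames[:, r0:r1, c0:c1].mean(axis=(1, 2), dtype=float)
    return TimeIntensityCurve(values=values, fps=seq.fps, roi=roi)


def _contrast_peak_prominences(
    tic: TimeIntensityCurve, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Relative minima of the TIC (as maxima of the inverted curve) and
    their prominences."""
    inverted = -tic.values
    (candidates,) = argrelextrema(inverted, np.greater, order=order)
    if len(candidates) == 0:
        return candidates, np.empty(0)
    prominences = peak_prominences(inverted, candidates)[0]
    return candidates, prominences


def default_peak_order(fps: float) -> int:
    """Neighborhood (frames) for relative-extremum detection: ~0.1 s."""
    return max(1, round(fps / 10))


def detect_peaks(
    tic: TimeIntensityCurve,
    order: int | None = None,
    min_prominence: float | None = None,
    exclude_first: bool = False,
) -> PeakSet:
    """Detect contrast peaks as prominent relative minima of the TIC.

    ``order`` is the one-sided neighborhood (frames) a minimum must
    dominate; ``min_prominence`` (intensity units) defaults to 5% of the
    TIC's dynamic range.  ``exclude_first`` drops the first detected peak,
    for trains whose first pulse is too weak distally to time reliably.
    """
    if order is None:
        order = default_peak_order(tic.fps)
    if len(tic) <= 2 * order:
        raise ValueError("TIC too short for the requested detection order")
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRACTION * tic.dynamic_range

    candidates, prominences = _contrast_peak_prominences(tic, order)
    peaks = candidates[prominences >= min_prominence]
    if exclude_first and len(peaks):
        peaks = peaks[1:]
    if len(peaks) < 1:
        raise ValueError("no contrast peak detected after filtering")
    return PeakSet(peak_frames=peaks, excluded_first=exclude_first)


def place_rois(
    cl: Centerline,
    seq: AngioSequence,
    strategy: str = "auto",
    indices: tuple[int, int] | None = None,
    edge_px: int = DEFAULT_ROI_EDGE_PX,
    stride_points: int = 10,
    prominence_fraction: float = 0.2,
    fade_fraction: float = 0.1,
    order: int | None = None,
) -> tuple[ROI, ROI]:
    """Place the proximal and distal ROIs on the centerline.

    ``manual_indices`` centers the ROIs on the two given centerline
    indices.  ``auto`` scans candidate ROIs along the centerline and picks
    as proximal the first position (from the inflow end) whose TIC peak
    prominence reaches ``prominence_fraction`` of the best candidate's,
    and as distal the last position still above ``fade_fraction`` — the
    point where the TIC peak begins to disappear.
    """
    if strategy == "manual_indices":
        if indices is None:
            raise ValueError("manual_indices strategy requires indices=(prox, dist)")
        i_prox, i_dist = indices
    elif strategy == "auto":
        if order is None:
            order = default_peak_order(seq.fps)
        candidate_idx = list(range(0, len(cl), stride_points))
        scores = []
        for i in candidate_idx:
            tic = compute_tic(seq, _build_roi(i, cl, seq.shape, edge_px))
            _, proms = _contrast_peak_prominences(tic, order)
            scores.append(float(proms.max()) if len(proms) else 0.0)
        scores_arr = np.asarray(scores)
        best = scores_arr.max()
        if best <= 0:
            raise ValueError("no candidate ROI shows a TIC peak")
        usable = np.flatnonzero(scores_arr >= prominence_fraction * best)
        fading = np.flatnonzero(scores_arr >= fade_fraction * best)
        if len(usable) == 0 or len(fading) == 0:
            raise ValueError("no candidate ROI satisfies the prominence thresholds")
        i_prox = candidate_idx[usable[0]]
        i_dist = candidate_idx[fading[-1]]
    else:
        raise ValueError(f"unknown ROI strategy: {strategy!r}")

    if not 0 <= i_prox < len(cl) and 0 <= i_dist < len(cl):
        raise IndexError("ROI centerline indices out of range")
    if i_prox >= i_dist:
        raise ValueError("proximal ROI must precede distal ROI along the centerline")
    roi_prox = _build_roi(i_prox, cl, seq.shape, edge_px)
    roi_dist = _build_roi(i_dist, cl, seq.shape, edge_px)
    if roi_prox.overlaps(roi_dist):
        raise ValueError("proximal and distal ROIs overlap; increase their separation")
    return roi_prox, roi_dist


def _refine_subframe(tic: TimeIntensityCurve, frame: int) -> float:
    """Parabolic sub-frame refinement of a contrast-peak location."""
    y = -tic.values
    if not 0 < frame < len(y) - 1:
        return float(frame)
    denom = y[frame - 1] - 2 * y[frame] + y[frame + 1]
    if denom >= 0:
        return float(frame)
    return frame + 0.5 * (y[frame - 1] - y[frame + 1]) / denom


def estimate_velocity(
    tic_prox: TimeIntensityCurve,
    tic_dist: TimeIntensityCurve,
    dx_mm: float,
    fps: float | None = None,
    peaks_prox: PeakSet | None = None,
    peaks_dist: PeakSet | None = None,
    exclude_first: bool = False,
    order: int | None = None,
    min_prominence: float | None = None,
    subframe: bool = False,
    matching: str = "ordinal",
) -> VelocityEstimate:
    """Per-peak peak-shift velocities between a proximal and a distal TIC.

    The k-th proximal peak is matched to the k-th distal peak (lists
    truncated to the shorter one).  Each pair's frame shift dt must be at
    least one frame — a non-positive shift signals mis-matched peaks or
    insufficient ROI separation for this frame rate.  ``subframe`` enables
    optional parabolic refinement of peak locations (off by default; the
    standard estimate uses integer frame counts).
    """
    if matching != "ordinal":
        raise ValueError(f"unknown matching mode: {matching!r}")
    if not dx_mm > 0:
        raise ValueError("dx_mm must be positive")
    if fps is None:
        fps = tic_prox.fps

    if peaks_prox is None:
        peaks_prox = detect_peaks(tic_prox, order, min_prominence, exclude_first)
    if peaks_dist is None:
        peaks_dist = detect_peaks(tic_dist, order, min_prominence, exclude_first)

    k = min(len(peaks_prox), len(peaks_dist))
    if k < 1:
        raise ValueError("need at least one matched peak pair")
    p = peaks_prox.peak_frames[:k].astype(float)
    d = peaks_dist.peak_frames[:k].astype(float)
    if subframe:
        p = np.array([_refine_subframe(tic_prox, int(f)) for f in p])
        d = np.array([_refine_subframe(tic_dist, int(f)) for f in d])
    dt = d - p
    if np.any(dt < (0.5 if subframe else 1.0)):
        raise ValueError(
            "non-positive peak delay: mis-matched peaks or insufficient ROI "
            "separation for this frame rate"
        )
    velocities = dx_mm / dt * fps
    return VelocityEstimate(
        per_peak_velocities=velocities,
        mean_velocity=float(velocities.mean()),
        sd_velocity=float(velocities.std(ddof=0)),
        dx_mm=float(dx_mm),
        per_peak_dt_frames=dt if subframe else dt.astype(int),
    )


def roi_separation_mm(cl: Centerline, roi_prox: ROI, roi_dist: ROI, resolution: float) -> float:
    """Arc distance between the two ROI centers along the centerline, in mm."""
    return arc_distance(cl, roi_prox.center_index, roi_dist.center_index, resolution)


def retention_ratio(mean_before: float, mean_after: float) -> float:
    """Velocity retention after stenting: 100 × after / before, % (1 decimal)."""
    if not mean_before > 0:
        raise ValueError("before-velocity must be positive")
    return round(100.0 * float(mean_after) / float(mean_before), 1)
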