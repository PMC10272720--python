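"""Synthetic angiographic phantom sequences with known bolus kinematics.

The phantom emulates the signal structure that TIC velocimetry relies on:
a dark contrast bolus advected along a vessel at a known speed, arriving
as a pulsatile train of concentration peaks (one per heartbeat), with a
leading edge that disperses as it travels, on a constant background with
optional additive Gaussian noise.

Inside the rasterized vessel tube the intensity model is

    I(pixel, t) = background_level - bolus_depth * C(s, t) * w(d) + noise

where ``s`` is the arc-length position of the pixel's nearest centerline
point, ``d`` its lateral distance from the centerline, ``w`` a 1-px
anti-aliased lateral profile (1 inside the lumen, 0 outside, half level
exactly at the configured radius), and ``C`` a sum of Gaussian pulses in
arc length whose centers travel at ``bolus_velocity`` (converted to
px/frame via ``resolution`` and ``fps``) and whose widths grow by
``dispersion_px_per_frame``.  Outside the vessel the intensity is
``background_level + noise``.  Identical config and seed give bit-identical
frames.

A helically deformed artery is rendered as its 2D projection, i.e. a
sinusoidal centerline, since the analysis operates on 2D angiograms.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .image_io import AngioSequence, write_sequence

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "generate_paired_case",
    "save_phantom",
]

#: Arc fractions at which a paired (before/after stenting) phantom applies
#: the proximal and middle radius multipliers exactly; between them the
#: multiplier is interpolated linearly, emulating inhomogeneous expansion.
PROXIMAL_FRACTION = 0.25
MIDDLE_FRACTION = 0.5

RadiusSpec = float | list[tuple[float, float]]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic angiographic sequence.

    Defaults reflect a typical carotid cine acquisition: 30 fps, 0.2 mm/px,
    a ~3.2 mm diameter vessel (radius 8 px), a 300 mm/s bolus and a
    three-beat pulse train at 0.8 s period (≈75 bpm).
    """

    shape: tuple[int, int] = (96, 512)
    fps: float = 30.0
    resolution: float = 0.2
    path_kind: str = "straight"  # "straight" | "sinusoid"
    path_amplitude_px: float = 12.0  # sinusoid only
    path_period_px: float = 160.0  # sinusoid only
    vessel_radius_px: RadiusSpec = 8.0
    bolus_velocity: float = 300.0  # mm/s
    n_pulses: int = 3
    pulse_period_s: float = 0.8
    pulse_sigma_s: float = 0.15  # temporal half-width of one pulse at a fixed point
    dispersion_px_per_frame: float = 0.0
    background_level: float = 3000.0
    bolus_depth: float = 2000.0
    noise_sd: float = 0.0
    margin_px: float = 28.0  # inset of the path endpoints from the frame border
    frame_count: int | None = None  # None: long enough for the full train to exit
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bolus_velocity > 0:
            raise ValueError("bolus_velocity must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.path_kind not in ("straight", "sinusoid"):
            raise ValueError(f"unknown path_kind: {self.path_kind!r}")

    @property
    def px_per_frame(self) -> float:
        """Bolus advance per frame: velocity / (resolution * fps)."""
        return self.bolus_velocity / (self.resolution * self.fps)

    @property
    def pulse_sigma_px(self) -> float:
        """Spatial pulse width: the bolus is injected over a fixed duration,
        so its length in px scales with velocity / resolution."""
        return self.pulse_sigma_s * self.bolus_velocity / self.resolution

    def radius_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Radius as (arc fractions, radii px) ready for ``np.interp``."""
        spec = self.vessel_radius_px
        if np.isscalar(spec):
            return np.array([0.0, 1.0]), np.array([float(spec)] * 2)
        pairs = sorted((float(f), float(r)) for f, r in spec)
        fracs = np.array([p[0] for p in pairs])
        radii = np.array([p[1] for p in pairs])
        return fracs, radii

    def radius_at(self, arc_fraction: np.ndarray | float) -> np.ndarray | float:
        fracs, radii = self.radius_profile()
        return np.interp(arc_fraction, fracs, radii)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth emitted alongside each synthetic sequence."""

    bolus_velocity: float  # mm/s
    centerline_points: np.ndarray  # (N, 2) float (row, col), ~1 px arc spacing
    cumulative_arc_px: np.ndarray  # (N,)
    arc_length_mm: float
    peak_pass_times: np.ndarray  # (n_pulses, N) int frame index of max concentration

    def to_json(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "bolus_velocity": self.bolus_velocity,
                    "arc_length_mm": self.arc_length_mm,
                    "centerline_points": self.centerline_points.tolist(),
                    "cumulative_arc_px": self.cumulative_arc_px.tolist(),
                    "peak_pass_times": self.peak_pass_times.tolist(),
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            bolus_velocity=d["bolus_velocity"],
            centerline_points=np.asarray(d["centerline_points"], dtype=float),
            cumulative_arc_px=np.asarray(d["cumulative_arc_px"], dtype=float),
            arc_length_mm=d["arc_length_mm"],
            peak_pass_times=np.asarray(d["peak_pass_times"], dtype=int),
        )


def _fine_path(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled (row, col) path and its cumulative arc length (px)."""
    rows, cols = config.shape
    span = cols - 1 - 2 * config.margin_px
    if span <= 0:
        raise ValueError("frame too narrow for the configured margin")
    u = np.arange(0.0, span + 0.25, 0.25)
    col = config.margin_px + u
    if config.path_kind == "straight":
        row = np.full_like(col, (rows - 1) / 2.0)
    else:
        row = (rows - 1) / 2.0 + config.path_amplitude_px * np.sin(
            2.0 * np.pi * u / config.path_period_px
        )
    pts = np.column_stack([row, col])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, arc


def _validate_path_inside(config: PhantomConfig, pts: np.ndarray, arc: np.ndarray) -> None:
    rows, cols = config.shape
    r = np.asarray(config.radius_at(arc / arc[-1]))
    pad = r + 1.0
    if (
        np.any(pts[:, 0] - pad < 0)
        or np.any(pts[:, 0] + pad > rows - 1)
        or np.any(pts[:, 1] - pad < 0)
        or np.any(pts[:, 1] + pad > cols - 1)
    ):
        raise ValueError("vessel path exits the frame for this configuration")


def _pulse_concentration(
    config: PhantomConfig, s: np.ndarray, frame: float, pulse: int
) -> np.ndarray:
    """Concentration of one pulse at arc positions ``s`` (px) at ``frame``."""
    v = config.px_per_frame
    period_frames = config.pulse_period_s * config.fps
    t0 = pulse * period_frames
    # the pulse center starts 3 sigma upstream of the inlet so the bolus
    # enters the field of view smoothly
    center = v * (frame - t0) - 3.0 * config.pulse_sigma_px
    sigma = config.pulse_sigma_px + config.dispersion_px_per_frame * max(frame - t0, 0.0)
    return np.exp(-0.5 * ((s - center) / sigma) ** 2)


def _concentration(config: PhantomConfig, s: np.ndarray, frame: float) -> np.ndarray:
    total = np.zeros_like(s, dtype=float)
    for k in range(config.n_pulses):
        total += _pulse_concentration(config, s, frame, k)
    return np.minimum(total, 1.0)


def _auto_frame_count(config: PhantomConfig, total_arc_px: float) -> int:
    v = config.px_per_frame
    period_frames = config.pulse_period_s * config.fps
    lead = 3.0 * config.pulse_sigma_px
    tail_sigma = config.pulse_sigma_px  # dispersion growth adds a little; pad below
    travel = (total_arc_px + 2.0 * lead + 3.0 * tail_sigma) / v
    n = math.ceil((config.n_pulses - 1) * period_frames + travel) + 3
    return max(n, 2)


def generate_phantom(config: PhantomConfig) -> tuple[AngioSequence, PhantomTruth]:
    """Render a synthetic sequence and its ground truth.

    Raises if the path (including its radius) does not fit in the frame or
    if the bolus would traverse the whole path in fewer than 2 frames, in
    which case no peak shift is resolvable at this frame rate.
    """
    pts_fine, arc_fine = _fine_path(config)
    _validate_path_inside(config, pts_fine, arc_fine)
    total_arc = float(arc_fine[-1])

    if total_arc / config.px_per_frame < 2.0:
        raise ValueError(
            "bolus traverses the whole path in < 2 frames; "
            "velocity too high for this frame rate and geometry"
        )

    n_frames = config.frame_count or _auto_frame_count(config, total_arc)
    rows, cols = config.shape

    # static geometry: nearest path sample for every pixel
    tree = cKDTree(pts_fine)
    grid = np.stack(
        np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    dist, idx = tree.query(grid, workers=-1)
    s_pix = arc_fine[idx]
    r_pix = np.asarray(config.radius_at(s_pix / total_arc))
    # anti-aliased lateral profile: half level exactly at the radius
    weight = np.clip(r_pix + 0.5 - dist, 0.0, 1.0)
    vessel = weight > 0.0
    s_v = s_pix[vessel]
    w_v = weight[vessel]
    flat_index = np.flatnonzero(vessel)

    rng = np.random.default_rng(config.seed)
    frames = np.empty((n_frames, rows, cols), dtype=np.uint16)
    for t in range(n_frames):
        frame = np.full(rows * cols, config.background_level, dtype=float)
        conc = _concentration(config, s_v, t)
        frame[flat_index] = config.background_level - config.bolus_depth * conc * w_v
        if config.noise_sd > 0:
            frame += config.noise_sd * rng.standard_normal(rows * cols)
        frames[t] = np.clip(np.rint(frame), 0, 65535).reshape(rows, cols)

    # truth at ~1 px arc spacing
    s_truth = np.arange(0.0, total_arc, 1.0)
    take = np.searchsorted(arc_fine, s_truth)
    cl_points = pts_fine[take]
    seg = np.linalg.norm(np.diff(cl_points, axis=0), axis=1)
    cum_arc = np.concatenate([[0.0], np.cumsum(seg)])

    t_axis = np.arange(n_frames, dtype=float)
    peak_pass = np.empty((config.n_pulses, len(s_truth)), dtype=int)
    for k in range(config.n_pulses):
        # (N, T) concentration of pulse k, argmax over frames
        conc_kt = np.stack(
            [_pulse_concentration(config, cum_arc, t, k) for t in t_axis], axis=1
        )
        peak_pass[k] = np.argmax(conc_kt, axis=1)

    seq = AngioSequence(frames=frames, fps=config.fps, resolution=config.resolution)
    truth = PhantomTruth(
        bolus_velocity=config.bolus_velocity,
        centerline_points=cl_points,
        cumulative_arc_px=cum_arc,
        arc_length_mm=float(cum_arc[-1]) * config.resolution,
        peak_pass_times=peak_pass,
    )
    return seq, truth


def _scaled_radius_spec(
    config: PhantomConfig, proximal_factor: float, middle_factor: float
) -> list[tuple[float, float]]:
    """Radius profile multiplied by a site-dependent expansion factor.

    The multiplier equals ``proximal_factor`` for arc fractions up to
    ~0.35, ``middle_factor`` from :data:`MIDDLE_FRACTION` on, with a linear
    blend in between, so diameter measurements at the proximal and middle
    site fractions see exactly the configured factors.
    """
    mult_fracs = np.array([0.0, 0.35, MIDDLE_FRACTION, 1.0])
    mult_vals = np.array([proximal_factor, proximal_factor, middle_factor, middle_factor])
    base_fracs, _ = config.radius_profile()
    fracs = np.union1d(np.union1d(base_fracs, mult_fracs), [PROXIMAL_FRACTION])
    base = np.asarray(config.radius_at(fracs))
    mult = np.interp(fracs, mult_fracs, mult_vals)
    return [(float(f), float(r)) for f, r in zip(fracs, base * mult)]


def generate_paired_case(
    config_before: PhantomConfig,
    expansion_factor: tuple[float, float] = (1.0, 1.0),
    velocity_factor: float = 1.0,
) -> tuple[
    tuple[AngioSequence, PhantomTruth], tuple[AngioSequence, PhantomTruth]
]:
    """Generate a before/after stenting pair sharing one vessel path.

    The "after" sequence has the vessel radius scaled by
    ``expansion_factor = (proximal, middle)`` multipliers and the bolus
    velocity scaled by ``velocity_factor``, giving an end-to-end fixture
    for expansion and velocity-retention recovery.
    """
    prox_f, mid_f = expansion_factor
    if not (prox_f > 0 and mid_f > 0 and velocity_factor > 0):
        raise ValueError("expansion and velocity factors must be positive")
    before = generate_phantom(config_before)
    config_after = replace(
        config_before,
        vessel_radius_px=_scaled_radius_spec(config_before, prox_f, mid_f),
        bolus_velocity=config_before.bolus_velocity * velocity_factor,
        seed=config_before.seed + 1,
    )
    after = generate_phantom(config_after)
    return before, after


def save_phantom(
    seq: AngioSequence,
    truth: PhantomTruth,
    path: str | os.PathLike,
    format: str = "image_stack",
) -> Path:
    """Write a phantom sequence plus a ``truth.json`` sidecar."""
    path = Path(path)
    if format == "image_stack":
        write_sequence(seq, path, format="image_stack")
        truth.to_json(path / "truth.json")
    elif format == "dicom":
        path.mkdir(parents=True, exist_ok=True)
        write_sequence(seq, path / "sequence.dcm", format="dicom")
        truth.to_json(path / "truth.json")
    else:
        raise ValueError(f"unsupported format: {format!r}")
    return path
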