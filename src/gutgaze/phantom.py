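"""Synthetic CT phantoms with known bowel geometry.

No public CT cohort with gaze annotations exists, so every downstream stage
is exercised on phantoms: CT-like volumes containing non-overlapping tubes
of known centerline, diameter profile and gut label, embedded in a
heterogeneous abdomen-like background (fat with soft-tissue regions).  Tube
lumina are gas or fluid and walls are soft tissue, mimicking the unprepared
bowel of acute abdominal CT; Gaussian noise stands in for quantum noise.

The same module simulates the annotation process itself: a 60 Hz gaze
recording along the true centerlines (isotropic jitter, 0.75 s block
averaging, knob-quantized diameters) and manual caliper pairs placed on
en-face tube cross-sections.  Ground truth labels/diameters are produced by
the reconstruction contract applied to the exact centerlines, so phantom
truth and reconstructed annotations live on exactly the same footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import (
    CaliperMeasurement,
    GazePoint,
    ScanAnnotation,
    VisualSegment,
)
from .reconstruction import (
    DiameterMap,
    LabelVolume,
    VolumeGrid,
    distance_fields,
)

__all__ = [
    "TubeSpec",
    "PhantomVolume",
    "GazeNoiseModel",
    "IntensityParams",
    "default_grid",
    "generate_phantom",
    "tubes_to_annotation",
    "simulate_gaze_recording",
    "simulate_calipers",
]

#: Raw gaze samples averaged into one gaze point: round(60 Hz * 0.75 s).
RAW_PER_GAZE_POINT = 45


def default_grid() -> VolumeGrid:
    """1 mm isotropic 128^3 grid, the default desk-scale phantom canvas."""
    return VolumeGrid((128, 128, 128), (1.0, 1.0, 1.0))


@dataclass(frozen=True)
class TubeSpec:
    """One synthetic bowel loop: centerline control points with diameters."""

    control_points: np.ndarray  # (K, 3) world mm
    diameter_profile: np.ndarray  # (K,) mm
    label: int
    lumen_hu: float
    wall_hu: float = 40.0

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        dp = np.asarray(self.diameter_profile, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or cp.shape[0] < 2:
            raise ValueError("control_points must be (K>=2, 3)")
        if dp.shape != (cp.shape[0],) or (dp <= 0).any():
            raise ValueError("diameter_profile must be positive, one value per control point")
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "diameter_profile", dp)

    def arclengths(self) -> np.ndarray:
        steps = np.sqrt(((self.control_points[1:] - self.control_points[:-1]) ** 2).sum(axis=1))
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arclengths()[-1])

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Linear interpolation of the centerline at arclength(s) ``s`` (mm)."""
        arcs = self.arclengths()
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.stack(
            [np.interp(s, arcs, self.control_points[:, c]) for c in range(3)], axis=-1
        )

    def diameter_at(self, s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.arclengths(), self.diameter_profile)

    def tangent_at(self, s: float, h: float = 1.0) -> np.ndarray:
        lo = max(0.0, s - h)
        hi = min(self.length, s + h)
        p = self.point_at(np.array([lo, hi]))
        d = p[1] - p[0]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class IntensityParams:
    """HU values painted into the phantom (approximate tissue attenuations)."""

    fat_hu: float = -100.0
    soft_tissue_hu: float = 40.0
    wall_hu: float = 40.0
    gas_hu: float = -1000.0
    fluid_hu: float = 10.0
    wall_thickness_mm: float = 3.0
    fluid_fraction: float = 0.5  # probability a tube's lumen is fluid vs gas


@dataclass(frozen=True)
class PhantomVolume:
    """A synthetic CT volume plus its exact ground truth."""

    ct: np.ndarray
    grid: VolumeGrid
    truth_labels: LabelVolume
    truth_diameters: DiameterMap
    tubes: tuple[TubeSpec, ...]
    scan_id: str = "phantom"

    def __post_init__(self) -> None:
        if tuple(self.ct.shape) != self.grid.shape:
            raise ValueError("ct shape does not match grid")
        if self.truth_labels.grid != self.grid or self.truth_diameters.grid != self.grid:
            raise ValueError("truth volumes must share the ct grid")
        object.__setattr__(self, "tubes", tuple(self.tubes))


@dataclass(frozen=True)
class GazeNoiseModel:
    """Error model of the simulated gaze recording.

    Raw 60 Hz samples are jittered isotropically (``jitter_sd``) and averaged
    over ``dwell`` seconds into gaze points; recorded diameters get Gaussian
    error (``diameter_error_sd``) and are quantized to the rotary-knob step.
    """

    jitter_sd: float = 1.0  # mm, per raw sample, isotropic
    diameter_error_sd: float = 1.0  # mm
    knob_step: float = 1.0  # mm
    raw_rate: float = 60.0  # Hz
    dwell: float = 0.75  # s
    step_along_centerline: float = 7.0 / RAW_PER_GAZE_POINT  # mm per raw sample

    def __post_init__(self) -> None:
        for name in ("jitter_sd", "diameter_error_sd", "knob_step", "raw_rate", "dwell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.step_along_centerline <= 0:
            raise ValueError("step_along_centerline must be > 0")
        if self.raw_rate * self.dwell < 1:
            raise ValueError("raw_rate * dwell must be >= 1")

    @property
    def samples_per_gaze_point(self) -> int:
        return int(round(self.raw_rate * self.dwell))


def tubes_to_annotation(
    tubes: Sequence[TubeSpec], scan_id: str = "phantom", repetition: int = 1
) -> ScanAnnotation:
    """Exact centerlines as a (noise-free, control-point resolution) annotation."""
    segments = tuple(
        VisualSegment.from_arrays(t.control_points, t.diameter_profile, t.label)
        for t in tubes
    )
    return ScanAnnotation(scan_id, repetition, segments)


def _propose_tube(
    rng: np.random.Generator,
    grid: VolumeGrid,
    diameter_range: tuple[float, float],
    wall_thickness: float,
    label: int,
    lumen_hu: float,
    wall_hu: float,
    n_control: int = 25,
) -> TubeSpec:
    """A smooth random tube running the grid in z with a slowly varying diameter."""
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    base_d = rng.uniform(*diameter_range)
    # slowly varying profile: smoothed noise, +-20% around the base, clipped
    wiggle = rng.normal(0.0, 1.0, n_control)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    kernel /= kernel.sum()
    wiggle = np.convolve(wiggle, kernel, mode="same")
    profile = np.clip(base_d * (1.0 + 0.2 * wiggle), *diameter_range)
    margin = profile.max() / 2.0 + wall_thickness + 1.0
    span = hi - lo
    if (span[:2] <= 2 * margin).any() or span[2] <= 2 * wall_thickness:
        raise ValueError(
            f"a tube of diameter {profile.max():.1f} mm cannot fit the grid"
        )
    z = np.linspace(lo[2] + 2.0, hi[2] - 2.0, n_control)
    # lateral path: smoothed random walk, reflected into the allowed box
    xy0 = rng.uniform(lo[:2] + margin, hi[:2] - margin)
    steps = rng.normal(0.0, 3.0, (n_control, 2))
    path = xy0 + np.cumsum(steps, axis=0)
    for c in range(2):
        path[:, c] = np.convolve(path[:, c], kernel, mode="same")
        path[:4, c] = path[4, c]
        path[-4:, c] = path[-5, c]
        path[:, c] = np.clip(path[:, c], lo[c] + margin, hi[c] - margin)
    cp = np.column_stack([path, z])
    return TubeSpec(cp, profile, label, lumen_hu, wall_hu)


def _tubes_clear(a: TubeSpec, b: TubeSpec, clearance: float = 1.0) -> bool:
    sa = np.arange(0.0, a.length, 2.0)
    sb = np.arange(0.0, b.length, 2.0)
    pa, pb = a.point_at(sa), b.point_at(sb)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    min_sep = (a.diameter_profile.max() + b.diameter_profile.max()) / 2.0 + clearance
    return bool(d2.min() >= min_sep**2)


def generate_phantom(
    n_tubes: int = 3,
    grid: VolumeGrid | None = None,
    intensity_params: IntensityParams | None = None,
    noise_sd: float = 15.0,
    seed: int = 0,
    diameter_range: tuple[float, float] = (10.0, 60.0),
    scan_id: str | None = None,
    max_attempts: int = 200,
) -> PhantomVolume:
    """Generate a phantom: tubes in a heterogeneous background, plus exact truth.

    Tubes are placed by rejection sampling so they never overlap (real bowel
    loops touch, but non-overlap keeps the ground truth unambiguous).  The CT
    is fat background with random soft-tissue regions, overwritten by tube
    wall and lumen (gas or fluid per tube), plus Gaussian noise.  Truth
    labels/diameters follow the reconstruction contract applied to the exact
    control points.  Deterministic for a given seed.
    """
    grid = grid or default_grid()
    ip = intensity_params or IntensityParams()
    rng = np.random.default_rng(seed)
    if n_tubes < 1:
        raise ValueError("n_tubes must be >= 1")

    labels = rng.choice(np.arange(1, 14), size=n_tubes, replace=False)
    tubes: list[TubeSpec] = []
    for i in range(n_tubes):
        lumen = ip.fluid_hu if rng.random() < ip.fluid_fraction else ip.gas_hu
        placed = False
        for _ in range(max_attempts):
            cand = _propose_tube(
                rng, grid, diameter_range, ip.wall_thickness_mm, int(labels[i]), lumen, ip.wall_hu
            )
            if all(_tubes_clear(cand, t) for t in tubes):
                tubes.append(cand)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place tube {i + 1}/{n_tubes} in the grid after {max_attempts} attempts"
            )

    # background: fat with random soft-tissue ellipsoids
    ct = np.full(grid.shape, ip.fat_hu)
    px, py, pz = grid.voxel_center_components()
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    for _ in range(rng.integers(3, 7)):
        center = rng.uniform(lo, hi)
        axes = rng.uniform(10.0, 40.0, 3)
        r2 = (
            ((px - center[0]) / axes[0]) ** 2
            + ((py - center[1]) / axes[1]) ** 2
            + ((pz - center[2]) / axes[2]) ** 2
        )
        ct[r2 <= 1.0] = ip.soft_tissue_hu

    # tubes: exact distance fields drive both truth and CT painting
    truth_annotation = tubes_to_annotation(tubes, scan_id or f"phantom-{seed}")
    dist, diam, lab = distance_fields(truth_annotation, grid)
    radius = diam / 2.0
    in_lumen = dist <= radius
    in_wall = ~in_lumen & (dist <= radius + ip.wall_thickness_mm)
    ct[in_wall] = ip.wall_hu
    lumen_by_label = {t.label: t.lumen_hu for t in tubes}
    for lbl, lumen_hu in lumen_by_label.items():
        ct[in_lumen & (lab == lbl)] = lumen_hu
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, grid.shape)

    truth_labels = LabelVolume(grid, np.where(in_lumen, lab, 0), scheme="13")
    truth_diameters = DiameterMap(grid, np.where(in_lumen, diam, 0.0), units="mm", masked=True)
    return PhantomVolume(
        ct, grid, truth_labels, truth_diameters, tuple(tubes), scan_id or f"phantom-{seed}"
    )


def simulate_gaze_recording(
    phantom: PhantomVolume,
    noise: GazeNoiseModel | None = None,
    repetition: int = 1,
    seed: int = 0,
) -> ScanAnnotation:
    """Simulate one repetition of visual annotation of a phantom.

    Raw samples are taken every ``step_along_centerline`` mm along each true
    centerline with isotropic Gaussian jitter; consecutive blocks of
    round(raw_rate * dwell) samples are averaged into gaze points.  The
    recorded diameter is the true local diameter at the block center plus
    Gaussian error, quantized to the knob step (floored at one step).

    Unit normal deviates are drawn in an order independent of the noise
    magnitudes and scaled afterwards, so recordings with the same seed but
    different noise levels share their underlying randomness (common random
    numbers: repeatability-vs-noise curves are smooth per seed).
    """
    noise = noise or GazeNoiseModel()
    rng = np.random.default_rng(seed)
    m = noise.samples_per_gaze_point
    segments = []
    for tube in phantom.tubes:
        s = np.arange(0.0, tube.length, noise.step_along_centerline)
        raw = tube.point_at(s)
        jitter_units = rng.standard_normal(raw.shape)
        raw = raw + jitter_units * noise.jitter_sd
        # average in dwell-sized blocks; the trailing partial block is kept
        # (the end of a traced segment still contributes a gaze point)
        bounds = np.arange(0, len(s), m)
        gaze_pos = np.stack([raw[b : b + m].mean(axis=0) for b in bounds])
        s_centers = np.array([s[b : b + m].mean() for b in bounds])
        true_d = tube.diameter_at(s_centers)
        diam_units = rng.standard_normal(len(bounds))
        d = true_d + diam_units * noise.diameter_error_sd
        if noise.knob_step > 0:
            d = np.maximum(np.round(d / noise.knob_step) * noise.knob_step, noise.knob_step)
        else:
            d = np.maximum(d, 1e-6)
        segments.append(VisualSegment.from_arrays(gaze_pos, d, tube.label))
    return ScanAnnotation(phantom.scan_id, repetition, tuple(segments))


def simulate_calipers(
    phantom: PhantomVolume,
    n_sites: int = 20,
    axis_noise_sd: float = 0.05,
    seed: int = 0,
    max_angle_deg: float = 30.0,
    max_attempts: int = 2000,
) -> list[CaliperMeasurement]:
    """Simulate manual caliper pairs on en-face tube cross-sections.

    Sites are random centerline locations where the tube runs within
    ``max_angle_deg`` of the z-axis (so the true diameter lies in the axial
    plane).  Short and long axes are the true diameter times independent
    relative errors ``1 + N(0, axis_noise_sd)``, swapped so short <= long.
    """
    if not phantom.tubes:
        raise ValueError("phantom has no tubes")
    rng = np.random.default_rng(seed)
    cos_max = math.cos(math.radians(max_angle_deg))
    out: list[CaliperMeasurement] = []
    attempts = 0
    while len(out) < n_sites:
        if attempts >= max_attempts:
            raise ValueError(
                f"found only {len(out)}/{n_sites} en-face sites after {max_attempts} attempts"
            )
        attempts += 1
        tube = phantom.tubes[rng.integers(len(phantom.tubes))]
        s = rng.uniform(0.0, tube.length)
        tangent = tube.tangent_at(s)
        if abs(tangent[2]) < cos_max:
            continue
        d = float(tube.diameter_at(s))
        e1, e2 = rng.normal(0.0, 1.0, 2) * axis_noise_sd
        a = d * max(1.0 + e1, 0.05)
        b = d * max(1.0 + e2, 0.05)
        short, long = (a, b) if a <= b else (b, a)
        loc = tuple(tube.point_at(s)[0])
        out.append(CaliperMeasurement(phantom.scan_id, tube.label, loc, short, long))
    return out
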