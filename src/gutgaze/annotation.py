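"""Data model for gaze-based bowel annotations.

An annotator traces the centerline of the gastrointestinal tract with an eye
tracker while turning a knob that encodes the local bowel diameter.  Each
0.75 s of 60 Hz gaze samples is averaged into one 3-D *gaze point* carrying a
diameter, and an ordered run of gaze points with a single anatomical label is
a *visual segment*.  A scan is covered by recording segments until the whole
tract has been traced, and the procedure is repeated twice per scan so that
repeatability can be quantified.

Coordinates are physical world coordinates in millimetres, never voxel
indices: distances, segment lengths, and geometric augmentation must respect
the anisotropic voxels of thick-slice CT, and only the reconstruction step
knows about a voxel grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazePoint",
    "VisualSegment",
    "ScanAnnotation",
    "CaliperMeasurement",
    "PARTS_13",
    "PART_CODES",
    "PART_NAMES",
    "FOREGUT",
    "MIDGUT",
    "HINDGUT",
    "PARTS_3",
    "reduce_label",
    "segment_length",
    "annotation_summary",
    "summaries_frame",
    "load_annotation",
    "save_annotation",
    "load_calipers",
    "save_calipers",
    "DEFAULT_DWELL_S",
]

#: Seconds of eye-tracker data averaged into one gaze point.
DEFAULT_DWELL_S = 0.75

# 13-part labelling of the gastrointestinal tract; 0 is background.
PARTS_13: tuple[str, ...] = (
    "esophagus",
    "stomach",
    "duodenum",
    "jejunum",
    "ileum",
    "cecum",
    "appendix",
    "ascending_colon",
    "transverse_colon",
    "descending_colon",
    "sigmoid_colon",
    "rectum",
    "anus",
)
PART_CODES: Mapping[str, int] = {name: i + 1 for i, name in enumerate(PARTS_13)}
PART_NAMES: Mapping[int, str] = {i + 1: name for i, name in enumerate(PARTS_13)}

# 3-part grouping chosen for obstruction diameter thresholds (~3 cm small
# bowel, ~6 cm large bowel), not embryologic boundaries: the duodenum goes
# with the foregut and the whole colon with the hindgut.
FOREGUT, MIDGUT, HINDGUT = 1, 2, 3
PARTS_3: Mapping[int, str] = {0: "background", FOREGUT: "foregut", MIDGUT: "midgut", HINDGUT: "hindgut"}

_MAP_13_TO_3: dict[int, int] = {0: 0}
for _name, _code in PART_CODES.items():
    if _name in ("esophagus", "stomach", "duodenum"):
        _MAP_13_TO_3[_code] = FOREGUT
    elif _name in ("jejunum", "ileum"):
        _MAP_13_TO_3[_code] = MIDGUT
    else:
        _MAP_13_TO_3[_code] = HINDGUT


def reduce_label(code13: int) -> int:
    """Map a 13-part gut code (or 0) to the 3-part foregut/midgut/hindgut code.

    Esophagus through duodenum -> foregut, jejunum and ileum -> midgut,
    cecum through anus -> hindgut; background stays background.
    """
    try:
        return _MAP_13_TO_3[int(code13)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"unknown 13-part label code: {code13!r}") from None


@dataclass(frozen=True)
class GazePoint:
    """One time-averaged gaze location (world mm) with its recorded diameter."""

    position: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        pos = tuple(float(c) for c in self.position)
        if len(pos) != 3 or not all(math.isfinite(c) for c in pos):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "diameter", float(self.diameter))
        if not (self.diameter > 0 and math.isfinite(self.diameter)):
            raise ValueError(f"diameter must be positive and finite, got {self.diameter!r}")


@dataclass(frozen=True)
class VisualSegment:
    """An ordered run of gaze points along one piece of bowel, with its part label."""

    points: tuple[GazePoint, ...]
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if not self.points:
            raise ValueError("a visual segment needs at least one gaze point")
        if int(self.label) not in PART_NAMES:
            raise ValueError(f"label must be a 13-part code in 1..13, got {self.label!r}")
        object.__setattr__(self, "label", int(self.label))

    @classmethod
    def from_arrays(
        cls, positions: np.ndarray, diameters: np.ndarray | float, label: int
    ) -> "VisualSegment":
        positions = np.asarray(positions, dtype=float)
        diam = np.broadcast_to(np.asarray(diameters, dtype=float), (positions.shape[0],))
        pts = tuple(GazePoint(tuple(p), d) for p, d in zip(positions, diam))
        return cls(pts, label)

    def positions(self) -> np.ndarray:
        """(P, 3) float64 array of gaze positions in mm."""
        return np.array([p.position for p in self.points], dtype=float)

    def diameters(self) -> np.ndarray:
        return np.array([p.diameter for p in self.points], dtype=float)


@dataclass(frozen=True)
class ScanAnnotation:
    """All visual segments recorded for one scan in one repetition (1 or 2)."""

    scan_id: str
    repetition: int
    segments: tuple[VisualSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if int(self.repetition) not in (1, 2):
            raise ValueError(f"repetition must be 1 or 2, got {self.repetition!r}")
        object.__setattr__(self, "repetition", int(self.repetition))


@dataclass(frozen=True)
class CaliperMeasurement:
    """A manual short/long-axis caliper pair placed on an en-face bowel segment."""

    scan_id: str
    label: int
    location: tuple[float, float, float]
    short_axis: float
    long_axis: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", tuple(float(c) for c in self.location))
        if int(self.label) not in PART_NAMES:
            raise ValueError(f"label must be a 13-part code, got {self.label!r}")
        if not (0 < self.short_axis <= self.long_axis):
            raise ValueError(
                f"need 0 < short_axis <= long_axis, got {self.short_axis}, {self.long_axis}"
            )


def segment_length(segment: VisualSegment) -> float:
    """Length of a segment in mm: sum of distances between sequential gaze points.

    A single-point segment has length 0.
    """
    pos = segment.positions()
    if pos.shape[0] < 2:
        return 0.0
    return float(np.sqrt(((pos[1:] - pos[:-1]) ** 2).sum(axis=1)).sum())


def recording_time(n_gaze_points: float, dwell: float = DEFAULT_DWELL_S) -> float:
    """Seconds of eye-tracker recording represented by ``n_gaze_points`` points.

    Each gaze point stands for one ``dwell``-second averaging window, so this
    also applies to fractional (mean) gaze-point counts.
    """
    return float(n_gaze_points) * float(dwell)


def annotation_summary(
    annotation: ScanAnnotation, dwell: float = DEFAULT_DWELL_S
) -> dict[str, float]:
    """Per-scan accounting: segment/point counts, traced length, recording time.

    ``recording_time`` counts only the retained gaze points (each representing
    ``dwell`` seconds); time spent redoing segments or navigating is not
    represented in the annotation and is not counted.
    """
    n_points = sum(len(s.points) for s in annotation.segments)
    return {
        "n_segments": len(annotation.segments),
        "n_gaze_points": n_points,
        "total_length": float(sum(segment_length(s) for s in annotation.segments)),
        "recording_time": recording_time(n_points, dwell),
    }


def summaries_frame(
    annotations: Iterable[ScanAnnotation], dwell: float = DEFAULT_DWELL_S
) -> pd.DataFrame:
    """Tidy per-(scan, repetition) summary table, one row per annotation."""
    rows = []
    for ann in annotations:
        row = {"scan_id": ann.scan_id, "repetition": ann.repetition}
        row.update(annotation_summary(ann, dwell))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk formats: annotations as JSON, calipers as CSV.

def save_annotation(annotation: ScanAnnotation, path: str | Path) -> None:
    obj = {
        "scan_id": annotation.scan_id,
        "repetition": annotation.repetition,
        "segments": [
            {
                "label": seg.label,
                "points": [
                    {"xyz_mm": list(p.position), "diameter_mm": p.diameter}
                    for p in seg.points
                ],
            }
            for seg in annotation.segments
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def load_annotation(path: str | Path) -> ScanAnnotation:
    obj = json.loads(Path(path).read_text())
    segments = tuple(
        VisualSegment(
            tuple(GazePoint(tuple(p["xyz_mm"]), p["diameter_mm"]) for p in seg["points"]),
            seg["label"],
        )
        for seg in obj["segments"]
    )
    return ScanAnnotation(obj["scan_id"], obj["repetition"], segments)


_CALIPER_COLUMNS = ["scan_id", "label", "x_mm", "y_mm", "z_mm", "short_axis_mm", "long_axis_mm"]


def save_calipers(measurements: Sequence[CaliperMeasurement], path: str | Path) -> None:
    rows = [
        [m.scan_id, m.label, *m.location, m.short_axis, m.long_axis] for m in measurements
    ]
    pd.DataFrame(rows, columns=_CALIPER_COLUMNS).to_csv(path, index=False)


def load_calipers(path: str | Path) -> list[CaliperMeasurement]:
    df = pd.read_csv(path)
    return [
        CaliperMeasurement(
            str(r.scan_id),
            int(r.label),
            (float(r.x_mm), float(r.y_mm), float(r.z_mm)),
            float(r.short_axis_mm),
            float(r.long_axis_mm),
        )
        for r in df.itertuples()
    ]
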