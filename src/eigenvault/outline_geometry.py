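"""Baseline orientation, vault segmentation, and semi-landmark resampling.

The cranial vault outline is anchored by four landmarks traversed
anti-clockwise: the occiput baseline point, lambda, bregma and glabella.
The vault is split at the landmarks into three topologically homologous
open curves -- occipital (occiput to lambda), parietal (lambda to bregma)
and frontal (bregma to glabella) -- while the straight inferior base
segment from glabella back to the occiput is excluded, as it carries no
curvature information.  Each segment is then resampled to equidistant
semi-landmarks, with the per-segment point count harmonized across
specimens (by default to the maximum raw count, so the most complex
curve sets the sampling density).

Arc length is measured on the piecewise-linear polyline; at the working
density of ~200 points per outline this differs negligibly from a spline
fit and keeps resampling exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tps_io import OutlineSpecimen

__all__ = [
    "OpenSegment",
    "SegmentedOutlineSet",
    "SEGMENT_NAMES",
    "orient_to_baseline",
    "split_segments",
    "resample_equal_arc",
    "harmonize_counts",
]

SEGMENT_NAMES = ("occipital", "parietal", "frontal")


@dataclass
class OpenSegment:
    """One open vault curve (frontal, parietal or occipital) of a specimen."""

    name: str
    points: np.ndarray  # (m, 2)
    source_id: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"segment {self.name}: points must be (m, 2)")
        if len(self.points) < 2:
            raise ValueError(
                f"segment {self.name} of {self.source_id!r}: fewer than 2 points"
            )
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        total = steps.sum()
        if total <= 0 or np.any(steps <= 1e-12 * total):
            raise ValueError(
                f"segment {self.name} of {self.source_id!r}: coincident consecutive points"
            )

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SegmentedOutlineSet:
    """All specimens' segments after harmonization to common counts."""

    specimens: list[tuple[str, str, OpenSegment, OpenSegment, OpenSegment]]
    counts: dict[str, int]  # harmonized point count per segment name

    def groups(self) -> list[str]:
        return [g for _, g, *_ in self.specimens]


def _rotation(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def orient_to_baseline(
    specimen: OutlineSpecimen,
    baseline_ref: int | tuple[float, float],
) -> OutlineSpecimen:
    """Rigidly rotate the specimen so its cranial base line is horizontal.

    The base line runs from glabella through the second baseline reference
    (porion, given as a point index, or an explicit (x, y) point).  After
    orientation the vault lies above the base line.  Rotation is about
    glabella, so the operation is idempotent and reflection-free.
    """
    pts = np.asarray(specimen.points, dtype=float)
    glabella = pts[specimen.landmarks[3]]
    if isinstance(baseline_ref, (int, np.integer)):
        ref = pts[int(baseline_ref)]
    else:
        ref = np.asarray(baseline_ref, dtype=float)
    d = ref - glabella
    if np.linalg.norm(d) < 1e-12:
        raise ValueError(
            f"specimen {specimen.id!r}: baseline points coincide, direction undefined"
        )
    theta = math.atan2(d[1], d[0])
    rotated = (pts - glabella) @ _rotation(-theta).T + glabella
    # place the vault above the base line; a half-turn keeps handedness
    base_y = rotated[specimen.landmarks[3], 1]
    if rotated[:, 1].mean() < base_y:
        rotated = (rotated - glabella) @ _rotation(math.pi).T + glabella
    return OutlineSpecimen(
        points=[tuple(p) for p in rotated],
        landmarks=specimen.landmarks,
        group=specimen.group,
        id=specimen.id,
    )


def split_segments(
    specimen: OutlineSpecimen,
) -> tuple[OpenSegment, OpenSegment, OpenSegment]:
    """Split the vault at its landmarks into (occipital, parietal, frontal).

    Segments share their joint landmarks: lambda ends the occipital and
    starts the parietal, bregma ends the parietal and starts the frontal.
    The base segment (glabella back to the occiput) is never produced.
    """
    specimen.validate()
    pts = np.asarray(specimen.points, dtype=float)
    i0, i1, i2, i3 = specimen.landmarks
    bounds = {"occipital": (i0, i1), "parietal": (i1, i2), "frontal": (i2, i3)}
    segments = []
    for name in SEGMENT_NAMES:
        a, b = bounds[name]
        if b - a + 1 < 2:
            raise ValueError(
                f"segment {name} of {specimen.id!r} has fewer than 2 points"
            )
        segments.append(OpenSegment(name, pts[a : b + 1].copy(), specimen.id))
    return tuple(segments)


def resample_equal_arc(segment: OpenSegment, m: int) -> OpenSegment:
    """Resample to ``m`` points at equal arc-length spacing.

    Endpoints are preserved bit-exactly; interior points are linearly
    interpolated on the polyline.  Idempotent at fixed ``m``.
    """
    if m < 2:
        raise ValueError(f"resample count must be >= 2, got {m}")
    pts = segment.points
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    if total <= 0:
        raise ValueError(f"segment {segment.name}: zero arc length")
    targets = np.linspace(0.0, total, m)
    new = np.empty((m, 2))
    new[:, 0] = np.interp(targets, cum, pts[:, 0])
    new[:, 1] = np.interp(targets, cum, pts[:, 1])
    new[0] = pts[0]
    new[-1] = pts[-1]
    return OpenSegment(segment.name, new, segment.source_id)


def harmonize_counts(
    specimens: list[tuple[str, str, OpenSegment, OpenSegment, OpenSegment]],
    policy: str = "max",
) -> SegmentedOutlineSet:
    """Resample homologous segments to a common point count per segment.

    ``policy='max'`` (default) uses the maximum raw count observed for each
    segment across specimens, so no specimen's curve is undersampled.
    ``policy='fixed:<m>'`` forces every segment to ``m`` points.
    """
    if not specimens:
        raise ValueError("no specimens to harmonize")
    if policy == "max":
        counts = {
            name: max(len(entry[2 + k].points) for entry in specimens)
            for k, name in enumerate(SEGMENT_NAMES)
        }
    elif policy.startswith("fixed:"):
        m = int(policy.split(":", 1)[1])
        counts = {name: m for name in SEGMENT_NAMES}
    else:
        raise ValueError(f"unknown harmonization policy {policy!r}")
    out = []
    for sid, group, occ, par, fro in specimens:
        resampled = [
            resample_equal_arc(seg, counts[seg.name]) for seg in (occ, par, fro)
        ]
        out.append((sid, group, *resampled))
    return SegmentedOutlineSet(specimens=out, counts=counts)
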