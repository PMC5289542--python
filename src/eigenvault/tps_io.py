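"""Reading and writing TPS landmark/outline files (tpsDig dialect).

The TPS format is a plain-text block format: each specimen starts with an
``LM=<n>`` line, followed by ``n`` whitespace-separated ``x y`` coordinate
lines, optionally followed by ``CURVES=<k>``/``POINTS=<m>`` outline blocks
(digitized curves), and trailing ``ID=``, ``IMAGE=``, ``SCALE=`` metadata
lines.  Curve points, when present, are concatenated after the landmark
points in file order, which matches how tpsDig interleaves outline
digitizing with landmark placement.

The format carries no convention for *which* points are the anatomical
anchors of an outline, so anchor indices and group labels are supplied by a
sidecar config and attached with :func:`attach_metadata`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

__all__ = [
    "TpsRecord",
    "OutlineSpecimen",
    "TpsParseError",
    "MetadataError",
    "read_tps",
    "write_tps",
    "attach_metadata",
]

PathOrStream = Union[str, Path, TextIO]


class TpsParseError(ValueError):
    """Malformed TPS input (count mismatch, non-numeric coordinate, ...)."""


class MetadataError(ValueError):
    """Sidecar metadata does not cover or does not fit the records."""


@dataclass
class TpsRecord:
    """One specimen block of a TPS file."""

    points: list[tuple[float, float]]
    id: str = ""
    image: str | None = None
    scale: float | None = None
    extras: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for i, (x, y) in enumerate(self.points):
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(
                    f"record {self.id!r}: non-finite coordinate at point {i}"
                )
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"record {self.id!r}: SCALE must be positive")


@dataclass
class OutlineSpecimen:
    """An outline with its four anchor landmarks and a group label.

    ``landmarks`` holds indices into ``points`` for, in traversal order,
    the occiput baseline point, lambda, bregma and glabella.  The outline
    runs anti-clockwise from the occiput over the vault to glabella.
    """

    points: list[tuple[float, float]]
    landmarks: tuple[int, int, int, int]
    group: str
    id: str

    def validate(self) -> None:
        n = len(self.points)
        if n < 4:
            raise ValueError(f"specimen {self.id!r}: fewer than 4 points")
        i0, i1, i2, i3 = self.landmarks
        if not (0 <= i0 < i1 < i2 < i3 < n):
            raise ValueError(
                f"specimen {self.id!r}: landmark indices {self.landmarks} must be "
                f"strictly increasing within [0, {n})"
            )
        for i, (x, y) in enumerate(self.points):
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"specimen {self.id!r}: non-finite point {i}")


_KEY_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*)\s*=\s*(.*?)\s*$")


def _open_source(source: PathOrStream) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_tps(source: PathOrStream) -> list[TpsRecord]:
    """Parse a TPS file or stream into a list of :class:`TpsRecord`.

    Accepts both ``LM=`` and ``POINTS=``-headed blocks; curve points from
    ``CURVES``/``POINTS`` sub-blocks are appended to the landmark points in
    file order.  SCALE, when present, multiplies coordinates on load so all
    records are in canonical units.  Unrecognized ``KEY=value`` lines are
    preserved verbatim in ``extras``.
    """
    stream, close = _open_source(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()

    records: list[TpsRecord] = []
    i = 0
    n_lines = len(lines)

    def parse_coords(count: int, start: int, ctx: str) -> tuple[list[tuple[float, float]], int]:
        pts: list[tuple[float, float]] = []
        j = start
        while len(pts) < count:
            if j >= n_lines:
                raise TpsParseError(
                    f"{ctx}: declared {count} points but file ended after {len(pts)}"
                )
            line = lines[j].strip()
            j += 1
            if not line:
                continue
            if _KEY_RE.match(line):
                raise TpsParseError(
                    f"{ctx}: declared {count} points but found only {len(pts)} "
                    f"before line {j} ({line!r})"
                )
            parts = line.split()
            if len(parts) < 2:
                raise TpsParseError(f"{ctx}: malformed coordinate line {j}: {line!r}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TpsParseError(
                    f"{ctx}: non-numeric coordinate on line {j}: {line!r}"
                ) from exc
            pts.append((x, y))
        return pts, j

    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if m is None or m.group(1).upper() not in ("LM", "LM3", "POINTS"):
            raise TpsParseError(f"line {i + 1}: expected an LM=/POINTS= header, got {line!r}")
        header_key = m.group(1).upper()
        try:
            lm_count = int(m.group(2))
        except ValueError as exc:
            raise TpsParseError(f"line {i + 1}: bad count in {line!r}") from exc
        rec_index = len(records)
        ctx = f"record {rec_index}"
        points, i = parse_coords(lm_count, i + 1, ctx)

        rec = TpsRecord(points=points)
        # trailing metadata / curve blocks until the next LM header
        while i < n_lines:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            m = _KEY_RE.match(line)
            if m is None:
                raise TpsParseError(f"{ctx}: unexpected line {i + 1}: {line!r}")
            key, value = m.group(1).upper(), m.group(2)
            if key in ("LM", "LM3") or (key == "POINTS" and header_key == "POINTS"):
                break  # next record
            i += 1
            if key == "CURVES":
                n_curves = int(value)
                for c in range(n_curves):
                    while i < n_lines and not lines[i].strip():
                        i += 1
                    pm = _KEY_RE.match(lines[i].strip()) if i < n_lines else None
                    if pm is None or pm.group(1).upper() != "POINTS":
                        raise TpsParseError(f"{ctx}: expected POINTS= for curve {c}")
                    c_count = int(pm.group(2))
                    c_pts, i = parse_coords(c_count, i + 1, f"{ctx} curve {c}")
                    rec.points.extend(c_pts)
            elif key == "ID":
                rec.id = value
            elif key == "IMAGE":
                rec.image = value
            elif key == "SCALE":
                try:
                    rec.scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(f"{ctx}: bad SCALE {value!r}") from exc
            else:
                rec.extras.append(f"{m.group(1)}={value}")
        if rec.scale is not None:
            rec.points = [(x * rec.scale, y * rec.scale) for x, y in rec.points]
        rec.validate()
        records.append(rec)
    return records


def _fmt(v: float) -> str:
    # shortest representation that round-trips the float exactly
    return repr(float(v))


def write_tps(records: Iterable[TpsRecord], sink: PathOrStream) -> None:
    """Write records as TPS text.  Round-trips through :func:`read_tps`.

    Coordinates are emitted in canonical units (SCALE already applied on
    load), so SCALE is re-emitted as 1.0 when it was set, keeping
    read(write(R)) an identity on the stored points.
    """
    buf = StringIO()
    for rec in records:
        rec.validate()
        buf.write(f"LM={len(rec.points)}\n")
        for x, y in rec.points:
            buf.write(f"{_fmt(x)} {_fmt(y)}\n")
        if rec.image is not None:
            buf.write(f"IMAGE={rec.image}\n")
        buf.write(f"ID={rec.id}\n")
        if rec.scale is not None:
            buf.write("SCALE=1.0\n")
        for extra in rec.extras:
            buf.write(extra + "\n")
    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def _resolve_group(rec_id: str, groups_cfg: Mapping) -> str | None:
    by_id = groups_cfg.get("by_id", {})
    if rec_id in by_id:
        return str(by_id[rec_id])
    for prefix, grp in groups_cfg.get("by_prefix", {}).items():
        if rec_id.startswith(prefix):
            return str(grp)
    default = groups_cfg.get("default")
    return None if default is None else str(default)


def attach_metadata(
    records: Sequence[TpsRecord], config: Mapping
) -> list[OutlineSpecimen]:
    """Attach landmark indices and group labels from a sidecar config.

    Config layout::

        landmarks:
          default: [0, 60, 130, 199]     # occiput, lambda, bregma, glabella
          SOME-ID: [0, 55, 120, 180]     # per-record override
        groups:
          by_prefix: {GEO: georgia, HUN: hungary}
          by_id: {X-12: modern}
          default: modern                # optional fallback

    Records whose id has no group mapping, or whose landmark indices violate
    the ordering invariant, are collected and reported together rather than
    silently dropped.
    """
    lm_cfg = config.get("landmarks", {})
    groups_cfg = config.get("groups", {})
    default_lms = lm_cfg.get("default")

    specimens: list[OutlineSpecimen] = []
    unmapped: list[str] = []
    bad: list[str] = []
    for rec in records:
        group = _resolve_group(rec.id, groups_cfg)
        if group is None:
            unmapped.append(rec.id)
            continue
        lms = lm_cfg.get(rec.id, default_lms)
        if lms is None:
            bad.append(f"{rec.id!r}: no landmark indices configured")
            continue
        spec = OutlineSpecimen(
            points=list(rec.points),
            landmarks=tuple(int(i) for i in lms),
            group=group,
            id=rec.id,
        )
        try:
            spec.validate()
        except ValueError as exc:
            bad.append(str(exc))
            continue
        specimens.append(spec)
    if unmapped:
        raise MetadataError("ids with no group mapping: " + ", ".join(map(repr, unmapped)))
    if bad:
        raise MetadataError("invalid specimens: " + "; ".join(bad))
    return specimens
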