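"""Parametric synthetic cranial-vault outlines.

Generates 2D vault outlines in left-lateral view that emulate the three
morphologies of interest in intentional-cranial-modification studies:

* **unmodified** — a smooth, shallow, antero-posteriorly wide vault;
* **annular (circumferential) modification** — circular bandaging of the
  infant head, producing vaults ranging from tall with vertical frontal and
  occipital profiles to low with obliquely sloping profiles; emulated by a
  vault-height multiplier (*elongation*) and a postero-superior shear
  (*obliquity*);
* **two-bandage modification** — annular binding plus a vertical
  crown-to-chin bandage that restricts vault height and leaves a bregmatic
  (or pre/post-bregmatic) depression; emulated by a smooth localized dent
  of given depth and width centered near bregma.

The vault is parameterized as a half-oval above a horizontal baseline,
traversed anti-clockwise from the occiput baseline point through lambda and
bregma to glabella.  Deformations are applied to a dense version of the
curve and the result is re-sampled to the standard 200 semi-landmarks with
fixed per-segment counts, which guarantees landmark homology for any
parameter draw.  Per-point radial jitter stands in for digitizing error.

Default cohort presets encode the group contrasts of the study system:
the two-bandage group ("hungary") is morphologically restricted, the
single-binding group ("georgia") is a mixture of tall-vertical and oblique
styles with wide parameter spreads plus a minority depressed component, and
the unmodified group ("modern") varies only by small normal-range noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d

from .outline_geometry import SEGMENT_NAMES, resample_equal_arc, split_segments
from .tps_io import OutlineSpecimen, TpsRecord, write_tps

__all__ = [
    "ModificationParams",
    "CohortSpec",
    "DEFAULT_PRESETS",
    "SEGMENT_COUNTS",
    "baseline_vault",
    "apply_modification",
    "generate_cohort",
    "cohort_to_tps",
]

# per-segment semi-landmark counts used when re-sampling generated outlines;
# joints are shared, so the concatenated outline has 61 + 71 + 70 - 2 = 200
# points with anchors at indices (0, 60, 130, 199)
SEGMENT_COUNTS = {"occipital": 61, "parietal": 71, "frontal": 70}

# arc fractions (from the occiput, anti-clockwise) of lambda and bregma on
# the unmodified half-oval, and its height/half-length ratio
_LAMBDA_FRAC = 0.30
_BREGMA_FRAC = 0.65
_BASE_HEIGHT = 0.85


@dataclass
class ModificationParams:
    """Deformation parameters for one specimen.

    elongation
        Vault-height multiplier about the baseline; 1 leaves height
        unchanged, values > 1 produce the tall profiles of annular binding.
    obliquity
        Shear angle (radians) tilting the vault postero-superiorly,
        emulating obliquely bound crania.
    depression_depth
        Depth of the bandage dent as a fraction of vault height, in
        [0, 0.5]; 0 disables the dent.
    depression_center
        Arc-fraction position of the dent center; the bregma sits at
        ~0.65, so values below/above emulate pre-/post-bregmatic bandage
        placement.
    depression_width
        Arc-fraction standard deviation of the Gaussian dent profile.
    noise_sd
        Per-point radial jitter, as a fraction of vault scale.
    """

    elongation: float = 1.0
    obliquity: float = 0.0
    depression_depth: float = 0.0
    depression_center: float = _BREGMA_FRAC
    depression_width: float = 0.07
    noise_sd: float = 0.0

    def validate(self) -> None:
        if self.elongation <= 0:
            raise ValueError("elongation must be positive")
        if not 0 <= self.depression_depth <= 0.5:
            raise ValueError("depression_depth must be in [0, 0.5]")
        if self.depression_width <= 0:
            raise ValueError("depression_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class CohortSpec:
    """Recipe for one synthetic group."""

    group: str
    n: int
    param_distributions: dict
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        comps = self.param_distributions.get("components", [])
        if not comps:
            raise ValueError("param_distributions needs at least one component")
        for comp in comps:
            if comp.get("weight", 1.0) < 0:
                raise ValueError("component weights must be non-negative")
            for key, val in comp.items():
                if key == "weight":
                    continue
                if len(val) != 2 or val[1] < 0:
                    raise ValueError(f"{key}: expected (mean, spread >= 0)")


def baseline_vault(total_points: int = 200) -> OutlineSpecimen:
    """An unmodified vault: a half-oval arc over a horizontal baseline.

    Points run anti-clockwise from the occiput baseline point at (1, 0)
    through lambda and bregma to glabella at (-1, 0), with the four anchor
    indices placed at fixed arc fractions.
    """
    if total_points < 8:
        raise ValueError("total_points must be >= 8")
    # sample the half-ellipse at equal arc length, then pin landmarks
    dense = 4096
    theta = np.linspace(0.0, math.pi, dense)
    xy = np.column_stack([np.cos(theta), _BASE_HEIGHT * np.sin(theta)])
    arcs = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    arcs /= arcs[-1]
    i_lambda = max(1, round(_LAMBDA_FRAC * (total_points - 1)))
    i_bregma = round(_BREGMA_FRAC * (total_points - 1))
    i_bregma = min(max(i_bregma, i_lambda + 1), total_points - 2)
    targets = np.linspace(0.0, 1.0, total_points)
    # snap the lambda/bregma samples onto their exact arc fractions
    targets[i_lambda] = _LAMBDA_FRAC
    targets[i_bregma] = _BREGMA_FRAC
    pts = np.column_stack(
        [np.interp(targets, arcs, xy[:, 0]), np.interp(targets, arcs, xy[:, 1])]
    )
    pts[0] = (1.0, 0.0)
    pts[-1] = (-1.0, 0.0)
    return OutlineSpecimen(
        points=[tuple(p) for p in pts],
        landmarks=(0, i_lambda, i_bregma, total_points - 1),
        group="unmodified",
        id="baseline",
    )


def apply_modification(
    specimen: OutlineSpecimen,
    params: ModificationParams,
    rng: np.random.Generator | None = None,
) -> OutlineSpecimen:
    """Deform a vault outline according to the modification parameters.

    Heights are scaled about the baseline, the bandage dent is subtracted,
    the postero-superior shear is applied, and radial jitter is added last.
    Landmark indices are preserved; with all-identity parameters and zero
    noise the specimen is returned unchanged.
    """
    params.validate()
    pts = np.asarray(specimen.points, dtype=float)
    y_base = pts[specimen.landmarks[3], 1]  # glabella sits on the baseline

    height = pts[:, 1] - y_base
    height *= params.elongation

    if params.depression_depth > 0:
        arcs = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        s = arcs / arcs[-1]
        vault_h = height.max()
        dent = params.depression_depth * vault_h * np.exp(
            -0.5 * ((s - params.depression_center) / params.depression_width) ** 2
        )
        # taper the dent with local height so baseline endpoints stay put
        height -= dent * np.clip(height / vault_h, 0.0, 1.0)

    x = pts[:, 0] + math.tan(params.obliquity) * height
    new = np.column_stack([x, height + y_base])

    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        center = 0.5 * (new[specimen.landmarks[0]] + new[specimen.landmarks[3]])
        radial = new - center
        # Radial jitter with per-point sd noise_sd, smoothly correlated along
        # the outline (correlation length ~2% of the trace): digitizing error
        # follows the traced curve rather than scattering adjacent points
        # independently, which would swamp the tangent-angle signal.
        eps = rng.normal(0.0, 1.0, size=len(new))
        eps = gaussian_filter1d(eps, sigma=max(2.0, 0.02 * len(new)), mode="nearest")
        sd = eps.std()
        if sd > 0:
            eps *= params.noise_sd / sd
        new = new + radial * eps[:, None]

    return OutlineSpecimen(
        points=[tuple(p) for p in new],
        landmarks=specimen.landmarks,
        group=specimen.group,
        id=specimen.id,
    )


def _segment_counts(total_points: int) -> dict[str, int]:
    """Per-segment counts summing (with shared joints) to ``total_points``."""
    if total_points == 200:
        return dict(SEGMENT_COUNTS)
    i_lambda = max(1, round(_LAMBDA_FRAC * (total_points - 1)))
    i_bregma = min(
        max(round(_BREGMA_FRAC * (total_points - 1)), i_lambda + 1), total_points - 2
    )
    return {
        "occipital": i_lambda + 1,
        "parietal": i_bregma - i_lambda + 1,
        "frontal": total_points - i_bregma,
    }


def _resample_standard(
    specimen: OutlineSpecimen, counts: dict[str, int] | None = None
) -> OutlineSpecimen:
    """Re-sample a deformed outline to the standard semi-landmark budget."""
    counts = counts or SEGMENT_COUNTS
    segs = split_segments(specimen)
    pieces = [resample_equal_arc(seg, counts[seg.name]) for seg in segs]
    pts = [pieces[0].points]
    for piece in pieces[1:]:
        pts.append(piece.points[1:])
    pts = np.vstack(pts)
    i1 = counts["occipital"] - 1
    i2 = i1 + counts["parietal"] - 1
    return OutlineSpecimen(
        points=[tuple(p) for p in pts],
        landmarks=(0, i1, i2, len(pts) - 1),
        group=specimen.group,
        id=specimen.id,
    )


# Default presets for the three study groups; see the module docstring.
# Modification status is definitional on morphology -- a vault only counts
# as modified when it is visibly elongated -- so the modified groups'
# elongation draws are truncated above the unmodified normal range and the
# unmodified group below it.
_MODIFIED_ELONGATION = (1.22, 2.0)

DEFAULT_PRESETS: dict[str, dict] = {
    "modern": {
        "components": [
            {
                "weight": 1.0,
                "elongation": (1.0, 0.04),
                "elongation_bounds": (0.90, 1.06),
                "obliquity": (0.0, 0.02),
            },
        ],
        "noise_sd": 0.005,
    },
    "hungary": {
        "components": [
            {
                "weight": 1.0,
                "elongation": (1.25, 0.04),
                "elongation_bounds": _MODIFIED_ELONGATION,
                "obliquity": (0.04, 0.02),
                "depression_depth": (0.10, 0.02),
                "depression_center": (0.65, 0.03),
                "depression_width": (0.12, 0.02),
            },
        ],
        "noise_sd": 0.005,
    },
    "georgia": {
        "components": [
            # tall, vertical profile (several circular bandages)
            {
                "weight": 0.45,
                "elongation": (1.45, 0.15),
                "elongation_bounds": _MODIFIED_ELONGATION,
                "obliquity": (0.0, 0.05),
            },
            # oblique profile (circular bandages applied obliquely)
            {
                "weight": 0.40,
                "elongation": (1.28, 0.10),
                "elongation_bounds": _MODIFIED_ELONGATION,
                "obliquity": (0.30, 0.08),
            },
            # minority two-bandage style
            {
                "weight": 0.15,
                "elongation": (1.25, 0.08),
                "elongation_bounds": _MODIFIED_ELONGATION,
                "obliquity": (0.05, 0.04),
                "depression_depth": (0.10, 0.03),
                "depression_center": (0.65, 0.04),
                "depression_width": (0.12, 0.02),
            },
        ],
        "noise_sd": 0.005,
    },
}


def _draw_params(dist: dict, rng: np.random.Generator) -> ModificationParams:
    comps = dist["components"]
    weights = np.array([c.get("weight", 1.0) for c in comps], dtype=float)
    weights /= weights.sum()
    comp = comps[int(rng.choice(len(comps), p=weights))]
    draw = {}
    for key in (
        "elongation",
        "obliquity",
        "depression_depth",
        "depression_center",
        "depression_width",
    ):
        if key in comp:
            mean, sd = comp[key]
            value = float(rng.normal(mean, sd))
            bounds = comp.get(f"{key}_bounds")
            if bounds is not None:
                lo, hi = bounds
                # reflect at the lower bound (no probability atom at the
                # boundary), then clip at the upper
                if value < lo:
                    value = lo + (lo - value)
                value = float(min(value, hi))
            draw[key] = value
    params = ModificationParams(
        noise_sd=float(dist.get("noise_sd", 0.0)), **draw
    )
    params.depression_depth = float(np.clip(params.depression_depth, 0.0, 0.5))
    params.depression_width = max(params.depression_width, 0.02)
    params.elongation = max(params.elongation, 0.5)
    return params


def generate_cohort(
    spec: CohortSpec,
    total_points: int = 200,
    return_params: bool = False,
) -> list[OutlineSpecimen] | tuple[list[OutlineSpecimen], list[ModificationParams]]:
    """Generate a seeded cohort of synthetic vault outlines.

    Deterministic: identical (spec, total_points) yields identical
    coordinates.  Deformations are applied to a dense outline, which is
    then re-sampled to ``total_points`` semi-landmarks with fixed segment
    proportions, so anchors are homologous across every draw.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dense = baseline_vault(total_points=801)
    counts = _segment_counts(total_points)
    cohort, all_params = [], []
    for k in range(spec.n):
        params = _draw_params(spec.param_distributions, rng)
        deformed = apply_modification(
            OutlineSpecimen(
                points=dense.points,
                landmarks=dense.landmarks,
                group=spec.group,
                id=f"{spec.group.upper()}-{k:03d}",
            ),
            params,
            rng=rng,
        )
        cohort.append(_resample_standard(deformed, counts))
        all_params.append(params)
    return (cohort, all_params) if return_params else cohort


def cohort_to_tps(
    cohort: list[OutlineSpecimen],
    path: str | Path,
    config_path: str | Path | None = None,
) -> Path:
    """Write a cohort as a TPS file plus a sidecar metadata config.

    The sidecar (YAML) records each specimen's group and the shared anchor
    indices, so ``read_tps`` + ``attach_metadata`` round-trips the cohort.
    Returns the sidecar path.
    """
    path = Path(path)
    records = [TpsRecord(points=list(s.points), id=s.id) for s in cohort]
    write_tps(records, path)
    config = {
        "landmarks": {"default": list(cohort[0].landmarks)},
        "groups": {"by_id": {s.id: s.group for s in cohort}},
    }
    config_path = Path(config_path) if config_path else path.with_suffix(".meta.yaml")
    config_path.write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
    return config_path
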