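"""Phi-function representation and eigenshape decomposition.

An open curve of P points is encoded as its Zahn-Roskies phi-function: the
cumulative signed turning angle between successive chords, one value per
interior vertex (P - 2 values), in radians.  Together with the step lengths
and the start pose (first point and first chord direction) this encodes the
curve exactly and invertibly, while the phi values themselves are invariant
to translation and rotation of the input.

The eigenshape decomposition is the singular value decomposition of the
mean-centered specimen-by-phi matrix: eigenvectors ("eigenshapes" ES1, ES2,
...) are hierarchical modes of outline shape variation, eigenvalues are the
covariance-matrix eigenvalues (divisor n - 1), and each specimen's
coordinates on the eigenshapes are its eigenscores.  Signs are pinned so
that each eigenshape's largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhiFunction",
    "EigenshapeModel",
    "phi_transform",
    "inverse_phi",
    "concat_segments",
    "segment_layout",
    "eigenshape_decompose",
    "project",
    "shape_model",
    "segment_submodel",
    "ternary_coordinates",
]


@dataclass
class PhiFunction:
    """Cumulative tangent-angle representation of one curve."""

    values: np.ndarray       # (P - 2,) cumulative turning angles, radians
    step_lengths: np.ndarray  # (P - 1,) chord lengths
    start_point: tuple[float, float]
    start_angle: float
    open: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        if len(self.step_lengths) != len(self.values) + 1:
            raise ValueError(
                "step_lengths must have exactly one more entry than values"
            )


def phi_transform(points: np.ndarray, open: bool = True) -> PhiFunction:
    """Convert an ordered point sequence to its phi-function.

    The turning angle at each interior vertex is the signed angle between
    the incoming and outgoing chords (atan2-based, in (-pi, pi]); values are
    the running sums of these turnings starting at the second vertex.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("phi_transform needs at least 3 (x, y) points")
    chords = np.diff(pts, axis=0)
    lengths = np.linalg.norm(chords, axis=1)
    bad = np.nonzero(lengths <= 1e-12 * max(lengths.sum(), 1e-300))[0]
    if bad.size:
        raise ValueError(f"coincident consecutive points at index {int(bad[0])}")
    angles = np.arctan2(chords[:, 1], chords[:, 0])
    turnings = np.diff(angles)
    turnings = (turnings + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    return PhiFunction(
        values=np.cumsum(turnings),
        step_lengths=lengths,
        start_point=(float(pts[0, 0]), float(pts[0, 1])),
        start_angle=float(angles[0]),
        open=open,
    )


def inverse_phi(phi: PhiFunction) -> np.ndarray:
    """Reconstruct the (x, y) point sequence from a phi-function.

    Exact inverse of :func:`phi_transform` under the stored pose.
    """
    angles = phi.start_angle + np.concatenate([[0.0], phi.values])
    if len(angles) != len(phi.step_lengths):
        raise ValueError("inconsistent lengths of values and step_lengths")
    steps = phi.step_lengths[:, None] * np.column_stack(
        [np.cos(angles), np.sin(angles)]
    )
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts + np.asarray(phi.start_point)


def tangent_angles(points: np.ndarray) -> np.ndarray:
    """Tangent-angle function of a curve: one absolute chord angle per step.

    Equals ``start_angle + [0, cumulative turnings]`` of the phi-function,
    i.e. the unwrapped chord direction as a function of arc position.  For
    curves that have already been Procrustes-aligned to a common frame this
    is the natural decomposition variable: a specimen's overall rotation
    enters each coordinate once instead of offsetting the whole cumulative
    vector through the first chord.
    """
    phi = phi_transform(points)
    return phi.start_angle + np.concatenate([[0.0], phi.values])


def outline_from_angles(
    theta: np.ndarray,
    step_lengths: np.ndarray,
    start_point: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rebuild the point sequence from a tangent-angle function and steps."""
    theta = np.asarray(theta, float)
    step_lengths = np.asarray(step_lengths, float)
    if len(theta) != len(step_lengths):
        raise ValueError("theta and step_lengths must have equal length")
    steps = step_lengths[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts + np.asarray(start_point)


def concat_segments(segments: list[np.ndarray]) -> np.ndarray:
    """Concatenate open segments sharing joint points, dropping duplicates."""
    parts = [np.asarray(segments[0], float)]
    for seg in segments[1:]:
        seg = np.asarray(seg, float)
        parts.append(seg[1:])
    return np.vstack(parts)


def segment_layout(counts: dict[str, int], order: tuple[str, ...]) -> dict[str, tuple[int, int]]:
    """Index ranges of each segment within the composite tangent-angle vector.

    The composite curve concatenates segments in ``order`` with joint
    vertices deduplicated; coordinate ``i`` of the tangent-angle function
    belongs to chord ``i`` (points ``i`` to ``i + 1``).  A segment of ``m``
    points contributes ``m - 1`` chords, so the ranges partition the vector
    contiguously.
    """
    boundaries = [0]
    for name in order:
        boundaries.append(boundaries[-1] + counts[name] - 1)
    return {
        name: (boundaries[k], boundaries[k + 1]) for k, name in enumerate(order)
    }


@dataclass
class EigenshapeModel:
    mean_phi: np.ndarray            # (p,)
    eigenshapes: np.ndarray         # (k, p) orthonormal rows ES1..ESk
    eigenvalues: np.ndarray         # (k,) descending, >= 0
    variance_fractions: np.ndarray  # normalized over total variance
    scores: np.ndarray              # (n, k) per-specimen eigenscores
    segment_layout: dict[str, tuple[int, int]] = field(default_factory=dict)
    ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_phi": self.mean_phi.tolist(),
            "eigenshapes": self.eigenshapes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "scores": self.scores.tolist(),
            "segment_layout": {k: list(v) for k, v in self.segment_layout.items()},
            "ids": list(self.ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EigenshapeModel":
        return cls(
            mean_phi=np.asarray(d["mean_phi"], float),
            eigenshapes=np.asarray(d["eigenshapes"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            variance_fractions=np.asarray(d["variance_fractions"], float),
            scores=np.asarray(d["scores"], float),
            segment_layout={k: tuple(v) for k, v in d.get("segment_layout", {}).items()},
            ids=list(d.get("ids", [])),
        )


def eigenshape_decompose(
    phis: np.ndarray,
    layout: dict[str, tuple[int, int]] | None = None,
    ids: list[str] | None = None,
) -> EigenshapeModel:
    """Eigenshape decomposition of a specimen-by-phi matrix.

    SVD of the mean-centered matrix; retains at most min(n - 1, p) axes.
    Zero-variance (constant) data yields a model with all eigenvalues zero
    and uniform variance fractions of zero, flagged by ``eigenvalues.size``.
    """
    X = np.asarray(phis, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a (n >= 3) x p matrix of phi vectors")
    n, p = X.shape
    mean = X.mean(axis=0)
    centered = X - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n - 1, p)
    u, s, vt = u[:, :k], s[:k], vt[:k]

    # pin SVD sign ambiguity: largest-|loading| entry of each axis positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]

    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    scores = u * s
    return EigenshapeModel(
        mean_phi=mean,
        eigenshapes=vt,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        scores=scores,
        segment_layout=dict(layout or {}),
        ids=list(ids or []),
    )


def project(model: EigenshapeModel, phi: np.ndarray | PhiFunction) -> np.ndarray:
    """Eigenscores of a phi vector: inner products with the eigenshapes."""
    vec = phi.values if isinstance(phi, PhiFunction) else np.asarray(phi, float)
    if vec.shape != model.mean_phi.shape:
        raise ValueError(
            f"phi length {vec.shape} does not match model {model.mean_phi.shape}"
        )
    return model.eigenshapes @ (vec - model.mean_phi)


def shape_model(
    model: EigenshapeModel,
    axis: int,
    score: float,
    step_lengths: np.ndarray,
    start_point: tuple[float, float] = (0.0, 0.0),
    start_angle: float = 0.0,
) -> np.ndarray:
    """Reconstruct the outline at a given position along one eigenshape.

    Inverts ``mean_phi + score * ES_axis`` under the supplied pose; score 0
    gives the mean shape.  Used to draw morphospace end-members.  Accepts
    models built either on cumulative-turning vectors (one value per
    interior vertex) or on tangent-angle functions (one value per chord);
    the vector length relative to ``step_lengths`` disambiguates.
    """
    if not 0 <= axis < len(model.eigenshapes):
        raise ValueError(f"axis {axis} out of range [0, {len(model.eigenshapes)})")
    step_lengths = np.asarray(step_lengths, float)
    vec = model.mean_phi + score * model.eigenshapes[axis]
    if len(vec) == len(step_lengths):  # tangent-angle function
        return outline_from_angles(vec, step_lengths, start_point)
    phi = PhiFunction(
        values=vec,
        step_lengths=step_lengths,
        start_point=start_point,
        start_angle=start_angle,
    )
    return inverse_phi(phi)


def segment_submodel(
    phis: np.ndarray,
    layout: dict[str, tuple[int, int]],
    segment: str,
    ids: list[str] | None = None,
) -> EigenshapeModel:
    """Eigenshape decomposition restricted to one segment's phi coordinates."""
    if segment not in layout:
        raise ValueError(f"unknown segment {segment!r}; layout has {sorted(layout)}")
    lo, hi = layout[segment]
    sub = np.asarray(phis, float)[:, lo:hi]
    return eigenshape_decompose(sub, layout={segment: (0, hi - lo)}, ids=ids)


def ternary_coordinates(scores: np.ndarray) -> np.ndarray:
    """Proportions of squared scores on the first three eigenshapes.

    An interpretation of a three-axis ternary plot: each specimen's signed
    ES1-ES3 scores are squared and normalized to sum to one, giving
    barycentric coordinates of relative loading on the three axes.
    """
    s2 = np.asarray(scores, float)[:, :3] ** 2
    tot = s2.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return s2 / tot
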