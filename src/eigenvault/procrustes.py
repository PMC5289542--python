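"""Generalized least-squares Procrustes superimposition.

Removes location (centering), scale (exact normalization to unit centroid
size) and orientation (reflection-free optimal rotation to an iteratively
updated consensus).  Reflections are excluded because all specimens are
digitized in the same left-lateral view.  The rotational gauge freedom of
the aligned set is pinned by orienting the consensus to the first
configuration, which makes results reproducible and order-insensitive up
to a global rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Configuration",
    "AlignedSet",
    "centroid_size",
    "align_pair",
    "gpa",
]


@dataclass
class Configuration:
    """An ordered semi-landmark configuration for one specimen."""

    points: np.ndarray  # (p, 2)
    id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"configuration {self.id!r}: points must be (p, 2)")


@dataclass
class AlignedSet:
    configs: list[Configuration]
    consensus: Configuration
    centroid_sizes: np.ndarray  # original sizes, one per specimen
    iterations: int = 0
    final_change: float = 0.0


def centroid_size(config: Configuration | np.ndarray) -> float:
    """Square root of summed squared distances of points from their centroid."""
    pts = config.points if isinstance(config, Configuration) else np.asarray(config, float)
    if len(pts) < 2:
        raise ValueError("centroid size needs at least 2 points")
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 0:
        raise ValueError("all points coincident: centroid size is zero")
    return size


def _center_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / size, size


def _optimal_rotation(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||target - source @ R.T||."""
    u, _, vt = np.linalg.svd(target.T @ source)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, d])
    return u @ flip @ vt


def align_pair(a: Configuration, b: Configuration) -> tuple[Configuration, float]:
    """Superimpose ``b`` on ``a`` by translation, scaling and rotation.

    Both configurations are centered and scaled to unit centroid size, then
    ``b`` is rotated (reflections excluded) to minimize the summed squared
    distance to ``a``.  Returns the aligned copy of ``b`` and the root-sum-
    square residual in unit-size shape space.
    """
    if a.points.shape != b.points.shape:
        raise ValueError("configurations must have equal point counts")
    a_n, _ = _center_scale(a.points)
    b_n, _ = _center_scale(b.points)
    rot = _optimal_rotation(a_n, b_n)
    aligned = b_n @ rot.T
    residual = float(np.sqrt(((a_n - aligned) ** 2).sum()))
    return Configuration(aligned, b.id), residual


def gpa(
    configs: list[Configuration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSet:
    """Generalized Procrustes analysis of two or more configurations.

    Each configuration is centered and scaled to unit centroid size exactly,
    then iteratively rotated to the running consensus (the arithmetic mean
    of the aligned set) until the consensus root-mean-square change drops
    below ``tol``.  Raises on non-convergence within ``max_iter``.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    shapes = {c.points.shape for c in configs}
    if len(shapes) > 1:
        raise ValueError(f"unequal point counts: {sorted(shapes)}")

    normalized, sizes = [], []
    for c in configs:
        pts, size = _center_scale(c.points)
        normalized.append(pts)
        sizes.append(size)
    stack = np.array(normalized)

    first_norm = stack[0].copy()
    consensus = stack[0].copy()
    change = np.inf
    for iteration in range(1, max_iter + 1):
        for k in range(len(stack)):
            rot = _optimal_rotation(consensus, stack[k])
            stack[k] = stack[k] @ rot.T
        new_consensus = stack.mean(axis=0)
        change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )

    # pin the rotational gauge: orient everything so the consensus matches
    # the first specimen's input pose (deterministic given the inputs)
    rot = _optimal_rotation(first_norm, consensus)
    consensus = consensus @ rot.T
    stack = stack @ rot.T
    consensus = stack.mean(axis=0)

    aligned = [Configuration(stack[k], configs[k].id) for k in range(len(stack))]
    return AlignedSet(
        configs=aligned,
        consensus=Configuration(consensus, "consensus"),
        centroid_sizes=np.array(sizes),
        iterations=iteration,
        final_change=change,
    )
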