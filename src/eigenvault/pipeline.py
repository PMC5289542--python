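"""End-to-end outline analysis: whole-vault and per-segment reports.

The whole-outline analysis chains segmentation, semi-landmark
harmonization, generalized Procrustes alignment, phi-function conversion,
eigenshape decomposition, stepwise discriminant selection, classification
with leave-one-out cross-validation, and pairwise Mahalanobis distances.
The per-segment analysis slices the composite phi vectors by segment and
repeats the decomposition and discriminant steps for each of the frontal,
parietal and occipital curves independently (by default on the two
modified groups, using all well-conditioned eigenshapes rather than a
stepwise subset).

All reports are plain nested dicts of JSON-serializable values, so a
report can be persisted, diffed and rendered to CSV without touching the
fitted objects.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .discriminant import (
    fit_classifier,
    loo_crossvalidate,
    mahalanobis_pairwise,
    stepwise_select,
)
from .eigenshape import (
    EigenshapeModel,
    concat_segments,
    eigenshape_decompose,
    segment_layout,
    segment_submodel,
    tangent_angles,
)
from .outline_geometry import SEGMENT_NAMES, harmonize_counts, split_segments
from .procrustes import Configuration, gpa
from .tps_io import OutlineSpecimen

__all__ = ["AnalysisConfig", "run_whole_outline", "run_segments", "report_to_csv"]


@dataclass
class AnalysisConfig:
    """Thresholds and policies of the analysis, with study defaults."""

    harmonize_policy: str = "max"
    p_enter: float = 0.01
    p_remove: float = 0.10
    max_vars: int = 6
    priors: str = "equal"            # or "proportional"
    segment_selection: str = "all"   # or "stepwise"
    segment_groups: tuple[str, ...] | None = None  # default: the two modified groups
    mahalanobis_alpha: float = 0.05
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["segment_groups"] is not None:
            d["segment_groups"] = list(d["segment_groups"])
        return d


def _priors_vector(config: AnalysisConfig, groups: np.ndarray) -> np.ndarray | None:
    if config.priors == "equal":
        return None
    labels = sorted(np.unique(groups).tolist())
    return np.array([(groups == lbl).sum() for lbl in labels], dtype=float)


def _prepare(specimens: list[OutlineSpecimen], config: AnalysisConfig):
    """Segmentation, harmonization, GPA and phi conversion, shared by both runs."""
    if not specimens:
        raise ValueError("no specimens")
    segmented = []
    for s in specimens:
        occ, par, fro = split_segments(s)
        segmented.append((s.id, s.group, occ, par, fro))
    harmonized = harmonize_counts(segmented, policy=config.harmonize_policy)

    configs = []
    for sid, _, occ, par, fro in harmonized.specimens:
        composite = concat_segments([occ.points, par.points, fro.points])
        configs.append(Configuration(composite, sid))
    aligned = gpa(configs, tol=config.gpa_tol, max_iter=config.gpa_max_iter)

    # decompose the tangent-angle function in the GPA-aligned frame: one
    # absolute chord angle per step, so a specimen's residual rotation is a
    # per-coordinate effect rather than a whole-vector offset
    phis = np.array([tangent_angles(c.points) for c in aligned.configs])
    layout = segment_layout(harmonized.counts, SEGMENT_NAMES)
    ids = [sid for sid, *_ in harmonized.specimens]
    groups = np.array([grp for _, grp, *_ in harmonized.specimens])
    return harmonized, aligned, phis, layout, ids, groups


def _well_conditioned_axes(model: EigenshapeModel, groups: np.ndarray) -> list[int]:
    """Axes usable with a nonsingular pooled covariance, incl. under LOO."""
    n = len(groups)
    g = len(np.unique(groups))
    k_max = max(1, n - g - 1)
    lam = model.eigenvalues
    keep = [j for j in range(len(lam)) if lam[j] > 1e-10 * lam[0]]
    return keep[:k_max]


def _discriminant_section(
    scores: np.ndarray,
    groups: np.ndarray,
    config: AnalysisConfig,
    selection_mode: str,
) -> dict:
    priors = _priors_vector(config, groups)
    if selection_mode == "stepwise":
        selected = stepwise_select(
            scores, groups, config.p_enter, config.p_remove, config.max_vars
        )
        if not selected:
            selected = [0]
    else:
        selected = list(range(scores.shape[1]))
    model = fit_classifier(scores, groups, selected, priors)
    cv_table, cv_acc = loo_crossvalidate(scores, groups, selected, priors)
    model.confusion_cv = cv_table
    maha = mahalanobis_pairwise(scores, groups, selected)
    return {
        "selected": [int(j) for j in selected],
        "selected_eigenshapes": [f"ES{j + 1}" for j in selected],
        "wilks_trace": [float(v) for v in model.wilks_trace],
        "labels": model.labels,
        "priors": model.priors.tolist(),
        "resubstitution": {
            "table": model.confusion.tolist(),
            "accuracy_pct": model.accuracies(cv=False),
        },
        "cross_validation": {
            "table": cv_table.tolist(),
            "accuracy_pct": cv_acc,
        },
        "mahalanobis": [
            {
                "pair": list(pair),
                "D2": v["D2"],
                "F": v["F"],
                "p": v["p"],
                "significant": bool(v["p"] < config.mahalanobis_alpha),
            }
            for pair, v in maha.items()
        ],
    }


def _variance_table(model: EigenshapeModel, top: int = 10) -> list[dict]:
    return [
        {
            "axis": f"ES{j + 1}",
            "eigenvalue": float(model.eigenvalues[j]),
            "variance_fraction": float(model.variance_fractions[j]),
        }
        for j in range(min(top, len(model.eigenvalues)))
    ]


def run_whole_outline(
    specimens: list[OutlineSpecimen],
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Whole-vault analysis producing the main report section."""
    config = config or AnalysisConfig()
    groups_present = {s.group for s in specimens}
    for grp in groups_present:
        if sum(s.group == grp for s in specimens) < 3:
            raise ValueError(f"group {grp!r} has fewer than 3 specimens")
    harmonized, aligned, phis, layout, ids, groups = _prepare(specimens, config)
    model = eigenshape_decompose(phis, layout=layout, ids=ids)
    usable = _well_conditioned_axes(model, groups)
    scores = model.scores[:, : max(usable) + 1]
    disc = _discriminant_section(scores, groups, config, "stepwise")
    return {
        "n_specimens": len(ids),
        "group_counts": {g: int((groups == g).sum()) for g in sorted(groups_present)},
        "harmonized_counts": {k: int(v) for k, v in harmonized.counts.items()},
        "gpa": {
            "iterations": aligned.iterations,
            "final_change": aligned.final_change,
        },
        "variance_table": _variance_table(model),
        "scores_table": [
            {"id": sid, "group": grp, "scores": model.scores[i, :6].tolist()}
            for i, (sid, grp) in enumerate(zip(ids, groups))
        ],
        "classification": disc,
        "provenance": {
            "config": config.to_dict(),
            "seed": seed,
            "version": __version__,
        },
    }


def run_segments(
    specimens: list[OutlineSpecimen],
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Per-segment analyses (frontal, parietal, occipital).

    Each segment gets its own eigenshape submodel and discriminant run,
    restricted by default to the two modified groups with all
    well-conditioned eigenshapes as variables.
    """
    config = config or AnalysisConfig()
    if config.segment_groups is not None:
        wanted = set(config.segment_groups)
    else:
        wanted = {s.group for s in specimens} - {"modern"}
    subset = [s for s in specimens if s.group in wanted]
    if len({s.group for s in subset}) < 2:
        raise ValueError("segment analysis needs at least two groups")
    _, _, phis, layout, ids, groups = _prepare(subset, config)

    sections = {}
    for name in ("frontal", "parietal", "occipital"):
        sub = segment_submodel(phis, layout, name, ids=ids)
        usable = _well_conditioned_axes(sub, groups)
        scores = sub.scores[:, : max(usable) + 1]
        disc = _discriminant_section(
            scores, groups, config, config.segment_selection
        )
        sections[name] = {
            "variance_table": _variance_table(sub),
            "classification": disc,
        }
    return {
        "groups": sorted(wanted),
        "n_specimens": len(ids),
        "segments": sections,
        "provenance": {
            "config": config.to_dict(),
            "seed": seed,
            "version": __version__,
        },
    }


def report_to_csv(report: dict, out_dir) -> list[str]:
    """Render a report's tables to CSV files; returns the paths written."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def dump(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(str(path))

    def classification_frames(prefix: str, section: dict) -> None:
        labels = section["labels"]
        for block in ("resubstitution", "cross_validation"):
            tab = pd.DataFrame(section[block]["table"], index=labels, columns=labels)
            tab.insert(0, "group", labels)
            tab["accuracy_pct"] = [
                section[block]["accuracy_pct"][lbl] for lbl in labels
            ]
            dump(f"{prefix}_{block}", tab)
        dump(f"{prefix}_mahalanobis", pd.DataFrame(section["mahalanobis"]))

    if "variance_table" in report:
        dump("variance", pd.DataFrame(report["variance_table"]))
        scores = pd.DataFrame(
            [
                {"id": r["id"], "group": r["group"]}
                | {f"ES{j + 1}": v for j, v in enumerate(r["scores"])}
                for r in report["scores_table"]
            ]
        )
        dump("scores", scores)
        classification_frames("whole", report["classification"])
    if "segments" in report:
        for name, section in report["segments"].items():
            dump(f"{name}_variance", pd.DataFrame(section["variance_table"]))
            classification_frames(name, section["classification"])
    return written
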