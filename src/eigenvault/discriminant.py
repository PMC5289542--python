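"""Stepwise Wilks'-lambda discriminant analysis of eigenscores.

Variables (eigenshape scores) enter a linear discriminant model one at a
time: at each step the candidate minimizing Wilks' lambda enters if the
partial F of its entry is significant at ``p_enter``; after each entry any
included variable whose partial F of removal exceeds ``p_remove`` leaves
again.  Selection stops when no candidate qualifies or when ``max_vars``
variables are in the model.  Classification uses the linear discriminant
rule with the pooled within-group covariance; group separation is
quantified by pairwise Mahalanobis distances with Hotelling-style F tests,
and generalization is assessed by leave-one-out cross-validation.

Wilks' lambda for a variable subset is det(W)/det(T), the ratio of the
within-group to the total scatter determinant; the overall significance of
a fitted subset uses Rao's F approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "DiscriminantModel",
    "wilks_lambda",
    "stepwise_select",
    "fit_classifier",
    "loo_crossvalidate",
    "mahalanobis_pairwise",
]


def _scatter_matrices(
    X: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Within-group (W) and total (T) scatter, plus per-group summaries."""
    labels = np.unique(groups)
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    info = {}
    for g in labels:
        Xg = X[groups == g]
        mg = Xg.mean(axis=0)
        W += (Xg - mg).T @ (Xg - mg)
        info[g] = {"n": len(Xg), "mean": mg}
    return W, T, info


def wilks_lambda(
    data: np.ndarray,
    groups: np.ndarray,
    subset: list[int] | None = None,
) -> tuple[float, float, float]:
    """Wilks' lambda with Rao's F approximation on a variable subset.

    Returns (lambda, F, p).  Lambda = det(W)/det(T) on the subset; small
    values indicate strong group separation.
    """
    X = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("subset must be non-empty")
        X = X[:, list(subset)]
    n, p = X.shape
    labels = np.unique(groups)
    g = len(labels)
    if g < 2 or any((groups == lbl).sum() < 2 for lbl in labels):
        raise ValueError("need >= 2 groups with >= 2 specimens each")
    W, T, _ = _scatter_matrices(X, groups)
    det_w = np.linalg.det(W)
    det_t = np.linalg.det(T)
    if det_t <= 0 or not np.isfinite(det_w / det_t):
        raise np.linalg.LinAlgError(
            "singular scatter matrix: reduce the number of variables"
        )
    lam = float(det_w / det_t)
    if det_w <= 0:
        lam = 0.0

    # Rao's F approximation
    t_ = n - 1 - (p + g) / 2
    df1 = p * (g - 1)
    denom = p**2 + (g - 1) ** 2 - 5
    s_ = np.sqrt((p**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    df2 = t_ * s_ - df1 / 2 + 1
    if df2 <= 0:
        raise ValueError("too few specimens for this many variables")
    lam_s = lam ** (1 / s_)
    F = (1 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else np.inf
    p_val = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return lam, float(F), p_val


def _partial_f(
    X: np.ndarray,
    groups: np.ndarray,
    lam_without: float,
    lam_with: float,
    p_in_model: int,
) -> tuple[float, float]:
    """Partial F for adding one variable to a model of ``p_in_model`` vars."""
    n = len(X)
    g = len(np.unique(groups))
    df2 = n - g - p_in_model
    if df2 <= 0 or lam_with <= 0:
        return np.inf, 0.0
    F = (lam_without / lam_with - 1) * df2 / (g - 1)
    return float(F), float(stats.f.sf(F, g - 1, df2))


def stepwise_select(
    data: np.ndarray,
    groups: np.ndarray,
    p_enter: float = 0.01,
    p_remove: float = 0.10,
    max_vars: int = 6,
) -> list[int]:
    """Stepwise Wilks'-lambda variable selection.

    Iteratively enters the candidate that minimizes lambda, provided the
    partial F of its entry is significant at ``p_enter``; after each entry,
    removes any included variable whose partial F of removal has
    p > ``p_remove``.  Deterministic: lambda ties break toward the lower
    variable index.  Returns the ordered selection (possibly empty).
    """
    X = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    n_vars = X.shape[1]
    selected: list[int] = []
    lam_current = 1.0

    while len(selected) < max_vars:
        best: tuple[float, int] | None = None
        for j in range(n_vars):
            if j in selected:
                continue
            try:
                lam_j, _, _ = wilks_lambda(X, groups, selected + [j])
            except (np.linalg.LinAlgError, ValueError):
                continue
            if best is None or lam_j < best[0] - 1e-15:
                best = (lam_j, j)
        if best is None:
            break
        lam_new, j_best = best
        F, p_val = _partial_f(X, groups, lam_current, lam_new, len(selected))
        if p_val >= p_enter:
            break
        selected.append(j_best)
        lam_current = lam_new

        # backward pass: drop variables that no longer earn their place
        removed = True
        while removed and len(selected) > 1:
            removed = False
            for j in list(selected):
                rest = [v for v in selected if v != j]
                lam_rest, _, _ = wilks_lambda(X, groups, rest)
                F_rm, p_rm = _partial_f(
                    X, groups, lam_rest, lam_current, len(rest)
                )
                if p_rm > p_remove and j != selected[-1]:
                    selected.remove(j)
                    lam_current = lam_rest
                    removed = True
                    break
    return selected


@dataclass
class DiscriminantModel:
    selected: list[int]
    labels: list[str]
    group_means: np.ndarray          # (g, k) on selected variables
    pooled_covariance: np.ndarray    # (k, k), divisor n - g
    priors: np.ndarray               # (g,)
    wilks_trace: list[float] = field(default_factory=list)
    confusion: np.ndarray | None = None          # resubstitution (g, g)
    confusion_cv: np.ndarray | None = None       # leave-one-out (g, g)
    mahalanobis: dict | None = None

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Assign each row to the group maximizing the linear discriminant score."""
        Xs = np.asarray(X, float)[:, self.selected]
        Sinv = np.linalg.inv(self.pooled_covariance)
        scores = np.empty((len(Xs), len(self.labels)))
        for k, mu in enumerate(self.group_means):
            a = Sinv @ mu
            scores[:, k] = Xs @ a - 0.5 * mu @ a + np.log(self.priors[k])
        return np.array([self.labels[i] for i in scores.argmax(axis=1)])

    def accuracies(self, cv: bool = False) -> dict[str, float]:
        """Per-group percentage accuracy, rounded to one decimal."""
        table = self.confusion_cv if cv else self.confusion
        if table is None:
            raise ValueError("confusion table not computed")
        return {
            lbl: float(round(100.0 * table[i, i] / table[i].sum(), 1))
            for i, lbl in enumerate(self.labels)
        }


def _fit_lda(
    X: np.ndarray, groups: np.ndarray, selected: list[int], priors: np.ndarray | None
) -> DiscriminantModel:
    Xs = X[:, selected]
    labels = sorted(np.unique(groups).tolist())
    g = len(labels)
    n, k = Xs.shape
    if n - g < k:
        raise np.linalg.LinAlgError("too few specimens for pooled covariance")
    means = np.array([Xs[groups == lbl].mean(axis=0) for lbl in labels])
    W = np.zeros((k, k))
    for lbl, mu in zip(labels, means):
        d = Xs[groups == lbl] - mu
        W += d.T @ d
    pooled = W / (n - g)
    if np.linalg.matrix_rank(pooled) < k:
        raise np.linalg.LinAlgError("singular pooled covariance")
    if priors is None:
        pr = np.full(g, 1.0 / g)
    else:
        pr = np.asarray(priors, float)
        pr = pr / pr.sum()
    return DiscriminantModel(
        selected=list(selected),
        labels=labels,
        group_means=means,
        pooled_covariance=pooled,
        priors=pr,
    )


def fit_classifier(
    data: np.ndarray,
    groups: np.ndarray,
    selection: list[int],
    priors: np.ndarray | None = None,
) -> DiscriminantModel:
    """Fit the linear discriminant rule and its resubstitution table.

    Equal priors by default.  Confusion rows follow the sorted group
    labels; row sums equal group sizes.
    """
    if not selection:
        raise ValueError("selection must be non-empty")
    X = np.asarray(data, float)
    groups = np.asarray(groups)
    model = _fit_lda(X, groups, selection, priors)

    lam_trace = []
    for m in range(1, len(selection) + 1):
        lam, _, _ = wilks_lambda(X, groups, selection[:m])
        lam_trace.append(lam)
    model.wilks_trace = lam_trace

    pred = model.classify(X)
    g = len(model.labels)
    table = np.zeros((g, g), dtype=int)
    idx = {lbl: i for i, lbl in enumerate(model.labels)}
    for true, hat in zip(groups, pred):
        table[idx[true], idx[hat]] += 1
    model.confusion = table
    return model


def loo_crossvalidate(
    data: np.ndarray,
    groups: np.ndarray,
    selection: list[int] | None = None,
    priors: np.ndarray | None = None,
    reselect: bool = False,
    p_enter: float = 0.01,
    p_remove: float = 0.10,
    max_vars: int = 6,
) -> tuple[np.ndarray, dict[str, float]]:
    """Leave-one-out cross-validated confusion table and accuracies.

    By default the variable selection made on the full data is reused in
    every fold (the common presentation of stepwise-DFA cross-validation
    tables); ``reselect=True`` redoes stepwise selection within each fold.
    """
    X = np.asarray(data, float)
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())
    if any((groups == lbl).sum() < 3 for lbl in labels):
        raise ValueError("every group needs >= 3 specimens for leave-one-out")
    if selection is None:
        selection = stepwise_select(X, groups, p_enter, p_remove, max_vars)
    g = len(labels)
    table = np.zeros((g, g), dtype=int)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        sel = (
            stepwise_select(X[mask], groups[mask], p_enter, p_remove, max_vars)
            if reselect
            else selection
        )
        if not sel:
            sel = selection or [0]
        model = _fit_lda(X[mask], groups[mask], sel, priors)
        pred = model.classify(X[i : i + 1])[0]
        table[idx[groups[i]], idx[pred]] += 1
    accuracies = {
        lbl: float(round(100.0 * table[k, k] / table[k].sum(), 1))
        for k, lbl in enumerate(labels)
    }
    return table, accuracies


def mahalanobis_pairwise(
    data: np.ndarray,
    groups: np.ndarray,
    selection: list[int],
) -> dict[tuple[str, str], dict[str, float]]:
    """Pairwise Mahalanobis D-squared between group means with F tests.

    D2 uses the pooled within-group covariance over *all* groups
    (divisor n - g); the F statistic is the Hotelling-style
    F = D2 * (n - g - k + 1) * n1 * n2 / (k * (n - g) * (n1 + n2))
    with (k, n - g - k + 1) degrees of freedom.
    """
    X = np.asarray(data, float)[:, selection]
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())
    n, k = X.shape
    g = len(labels)
    W = np.zeros((k, k))
    means = {}
    for lbl in labels:
        Xg = X[groups == lbl]
        means[lbl] = Xg.mean(axis=0)
        d = Xg - means[lbl]
        W += d.T @ d
    pooled = W / (n - g)
    Sinv = np.linalg.inv(pooled)
    out = {}
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        d2 = float(diff @ Sinv @ diff)
        n1 = int((groups == a).sum())
        n2 = int((groups == b).sum())
        df2 = n - g - k + 1
        F = d2 * df2 * n1 * n2 / (k * (n - g) * (n1 + n2)) if df2 > 0 else np.nan
        p = float(stats.f.sf(F, k, df2)) if df2 > 0 else np.nan
        out[(a, b)] = {"D2": d2, "F": float(F), "p": p, "df1": k, "df2": df2}
    return out
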