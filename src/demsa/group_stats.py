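"""One-way ANOVA, LSD compact-letter displays, and PCA summaries.

These are the generic statistical companions of the pipeline: every
treatment-level table carries a fixed-effects one-way ANOVA and an
unprotected Fisher LSD compact-letter display (the agricolae-style default:
letters are assigned whether or not the omnibus F test is significant), and
ordinations of profile or segment matrices are plain centered PCAs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = ["AnovaResult", "PcaSummary", "one_way_anova", "lsd_letters", "pca_summary"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    mse: float  # pooled within-group mean square, reused by the LSD test


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA from per-group value lists.

    Returns the full between/within decomposition (not just F and p) because
    the LSD letters need the pooled mean squared error and its degrees of
    freedom.  Degenerate inputs follow the usual conventions: if both sums
    of squares vanish (all values identical) F = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    mse = ssw / df_w
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w, 0.0)
        return AnovaResult(float("inf"), 0.0, df_b, df_w, 0.0)
    F = (ssb / df_b) / mse
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, float(mse))


def _lsd_nonsignificant(groups: Mapping[str, Sequence[float]], alpha: float) -> tuple[
    list[str], dict[str, float], set[frozenset[str]]
]:
    """Group labels ordered by descending mean, means, and the set of
    non-significant pairs under the pooled-MSE LSD t test."""
    labels = list(groups)
    anova = one_way_anova([groups[g] for g in labels])
    means = {g: float(np.mean(groups[g])) for g in labels}
    ns: set[frozenset[str]] = set()
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(groups[a]), len(groups[b])
        if anova.mse == 0.0:
            significant = means[a] != means[b]
        else:
            t = abs(means[a] - means[b]) / np.sqrt(anova.mse * (1 / na + 1 / nb))
            significant = 2 * stats.t.sf(t, anova.df_within) < alpha
        if not significant:
            ns.add(frozenset((a, b)))
    ordered = sorted(labels, key=lambda g: -means[g])
    return ordered, means, ns


def lsd_letters(groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
                gate: bool = False) -> dict[str, str]:
    """Fisher LSD compact-letter display.

    Pairwise t tests use the pooled ANOVA mean square and its within-group
    degrees of freedom.  Letter classes are the maximal cliques of the
    non-significance graph, ordered by the highest group mean they contain,
    so two groups share a letter exactly when their pairwise LSD test is
    non-significant at ``alpha``.  With ``gate=True`` the display is
    protected: a non-significant omnibus F collapses everything to "a".
    """
    labels = list(groups)
    if gate:
        omnibus = one_way_anova([groups[g] for g in labels])
        if omnibus.p >= alpha:
            return {g: "a" for g in labels}
    ordered, means, ns = _lsd_nonsignificant(groups, alpha)

    def compatible(subset: tuple[str, ...]) -> bool:
        return all(frozenset(p) in ns for p in itertools.combinations(subset, 2))

    # Maximal cliques by exhaustive search; group counts are tiny (<= ~10).
    cliques: list[tuple[str, ...]] = []
    for size in range(len(ordered), 0, -1):
        for subset in itertools.combinations(ordered, size):
            if compatible(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in labels}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in labels}


@dataclass(frozen=True)
class PcaSummary:
    variance_pct: np.ndarray  # per-axis explained variance, percent
    scores: pd.DataFrame      # samples x axes
    loadings: pd.DataFrame    # variables x axes


def pca_summary(matrix: pd.DataFrame, scale: str = "none",
                n_axes: int | None = None) -> PcaSummary:
    """Centered (optionally unit-variance scaled) PCA of a samples x variables
    matrix, with a deterministic sign convention: on each axis the
    largest-magnitude loading is positive.

    Constant columns carry no variance and are dropped with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if scale not in ("none", "unit-variance"):
        raise ValueError(f"unknown scale {scale!r}")
    X = matrix.astype(float)
    constant = X.columns[X.std(axis=0, ddof=0) == 0.0]
    if len(constant):
        warnings.warn(f"dropping constant columns: {list(constant)}", stacklevel=2)
        X = X.drop(columns=constant)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 non-constant variables")
    values = X.to_numpy()
    values = values - values.mean(axis=0)
    if scale == "unit-variance":
        values = values / values.std(axis=0, ddof=1)
    n_comp = min(values.shape[0] - 1, values.shape[1])
    if n_axes is not None:
        n_comp = min(n_comp, n_axes)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(values)
    loadings = pca.components_.T  # variables x axes
    for j in range(n_comp):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    axes = [f"PC{j + 1}" for j in range(n_comp)]
    return PcaSummary(
        variance_pct=100.0 * pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=matrix.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=axes),
    )
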