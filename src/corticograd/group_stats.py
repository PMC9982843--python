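"""ROI-wise and seed-distance group comparisons with BH-FDR, community
composition of altered connections, and Spearman clinical associations.

Group contrasts are Welch two-sample t-tests (unpaired; a Student mode is
available) or paired t-tests on per-ROI gradient values, corrected by
Benjamini-Hochberg across the N ROIs of one gradient dimension — each
dimension and contrast is its own FDR family. Seed-distance profiles test
the gradient distance from one seed ROI to every other ROI (family of N-1
targets per seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Atlas
from .gradient import GradientEmbedding, gradient_distance


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_matrix(group, dim: int) -> np.ndarray:
    """Stack one gradient dimension across subjects -> (n_subjects, N)."""
    if isinstance(group, np.ndarray):
        return group
    rows = []
    for e in group:
        if not isinstance(e, GradientEmbedding):
            raise TypeError("group must contain GradientEmbedding objects or be an array")
        if not e.aligned:
            raise ValueError("group comparisons require template-aligned embeddings")
        rows.append(e.component(dim))
    return np.vstack(rows)


def _ttests(a: np.ndarray, b: np.ndarray, paired: bool, welch: bool
            ) -> tuple[np.ndarray, np.ndarray]:
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test requires equal group sizes (matched order)")
        res = stats.ttest_rel(a, b, axis=0)
    else:
        res = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance ties (identical samples) give nan: no evidence of difference
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


def roi_group_test(group_a, group_b, dim: int = 1, *, paired: bool = False,
                   alpha: float = 0.05, welch: bool = True,
                   atlas: Atlas | None = None) -> pd.DataFrame:
    """Per-ROI group comparison of one gradient dimension.

    Parameters
    ----------
    group_a, group_b
        Lists of aligned :class:`GradientEmbedding` (or pre-stacked
        (n_subjects, N) arrays of gradient values).
    dim
        1-based gradient component tested.
    paired
        Paired t-test (matched subject order) instead of Welch/Student.

    Returns a DataFrame with one row per ROI: roi_id, dim, t, p, q,
    significant — q being BH-FDR across the N ROIs of this dimension.
    """
    a = _group_matrix(group_a, dim)
    b = _group_matrix(group_b, dim)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different ROI counts")
    t, p = _ttests(a, b, paired, welch)
    q = bh_fdr(p)
    roi_ids = atlas.roi_ids if atlas is not None else np.arange(1, a.shape[1] + 1)
    return pd.DataFrame({
        "roi_id": roi_ids,
        "dim": dim,
        "t": t,
        "p": p,
        "q": q,
        "significant": q < alpha,
    })


@dataclass(frozen=True)
class SeedDistanceProfile:
    """Seed-to-target gradient-distance alteration profile."""

    seed_roi: int
    table: pd.DataFrame  # one row per target: roi_id, t, p, q, significant
    altered_count: int
    community_composition: dict[str, float] = field(default_factory=dict)


def _distance_rows(group, seed_idx: int, dims: tuple[int, int]) -> np.ndarray:
    """Per-subject distances from seed to every ROI -> (n_subjects, N)."""
    if isinstance(group, np.ndarray):
        return group
    rows = []
    for e in group:
        d = gradient_distance(e, dims)
        rows.append(d[seed_idx])
    return np.vstack(rows)


def seed_distance_test(seed_roi: int, group_a, group_b, atlas: Atlas, *,
                       dims: tuple[int, int] = (1, 2), paired: bool = False,
                       alpha: float = 0.05, welch: bool = True) -> SeedDistanceProfile:
    """Test the gradient distance from one seed ROI to every other ROI.

    BH-FDR is applied across the N-1 targets of this seed. The community
    composition reports, over the significantly altered targets, the
    fraction belonging to each functional community (fractions sum to 1
    when any target is altered).
    """
    seed_idx = atlas.index_of(seed_roi)
    a = _distance_rows(group_a, seed_idx, dims)
    b = _distance_rows(group_b, seed_idx, dims)
    targets = np.delete(np.arange(atlas.n_roi), seed_idx)
    t, p = _ttests(a[:, targets], b[:, targets], paired, welch)
    q = bh_fdr(p)
    sig = q < alpha
    table = pd.DataFrame({
        "roi_id": atlas.roi_ids[targets],
        "t": t,
        "p": p,
        "q": q,
        "significant": sig,
    })
    altered = int(sig.sum())
    comp: dict[str, float] = {}
    if altered:
        comms = atlas.communities[targets][sig]
        labels, counts = np.unique(comms, return_counts=True)
        comp = {str(l): float(c) / altered for l, c in zip(labels, counts)}
    return SeedDistanceProfile(seed_roi, table, altered, comp)


def spearman_assoc(feature, measure) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties, two-sided t-approx p).

    Used to relate a per-case gradient feature (e.g., the target ROI's
    Gradient-2 value or a seed-target gradient distance) to a clinical
    measure (THI score/level, VAS rating).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(measure, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and measure must be equal-length 1-D")
    if x.size < 5:
        raise ValueError("need at least 5 cases for a Spearman correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
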