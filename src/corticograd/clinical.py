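"""Clinical tinnitus instruments and cohort contingency statistics.

The Tinnitus Handicap Inventory (THI) is a 25-item questionnaire; each
item is answered no/sometimes/yes and scored 0/2/4, so the global score is
an even integer between 0 and 100 that is binned into severity levels
(very mild … catastrophic). The visual analog scale (VAS) rates loudness
on a continuous 0-10 faint-to-loud axis. Cohort characteristics are
compared between tinnitus groups with two-sided Fisher's exact tests on
2×2 tables.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

THI_N_ITEMS = 25
THI_ITEM_VALUES = (0, 2, 4)

#: THI severity bins (level, low, high) on the even 0..100 score scale.
#: Level 0 ("no handicap", score 0) is an extension below the published
#: 1-16 / 18-36 / 38-56 / 58-76 / 78-100 grading so that fully resolved
#: tinnitus remains representable.
THI_LEVELS = (
    (0, 0, 0),
    (1, 2, 16),
    (2, 18, 36),
    (3, 38, 56),
    (4, 58, 76),
    (5, 78, 100),
)


def thi_score(items) -> int:
    """Global THI score: the sum of the 25 item scores (0/2/4 each)."""
    arr = list(items)
    if len(arr) != THI_N_ITEMS:
        raise ValueError(f"THI requires exactly {THI_N_ITEMS} items, got {len(arr)}")
    bad = [v for v in arr if v not in THI_ITEM_VALUES]
    if bad:
        raise ValueError(f"THI item values must be in {THI_ITEM_VALUES}, got {bad[0]!r}")
    return int(sum(arr))


def thi_level(score: int) -> int:
    """Severity level 0-5 of a THI global score.

    0 = no handicap, 1 = very mild (2-16), 2 = mild (18-36),
    3 = moderate (38-56), 4 = severe (58-76), 5 = catastrophic (78-100).
    Odd scores are rejected: 25 items scored 0/2/4 can only sum to an even
    number (the published bin gaps at 17/37/57/77 reflect this).
    """
    if not isinstance(score, (int, np.integer)):
        raise ValueError(f"THI score must be an integer, got {score!r}")
    if score % 2 != 0 or not 0 <= score <= 100:
        raise ValueError(f"THI score must be an even integer in 0..100, got {score}")
    for level, lo, hi in THI_LEVELS:
        if lo <= score <= hi:
            return level
    raise AssertionError("unreachable: levels partition the even 0..100 scores")


class TinnitusChange(str, enum.Enum):
    RESOLVED = "resolved"
    IMPROVED = "improved"
    UNCHANGED = "unchanged"
    WORSE = "worse"
    NEW_ONSET = "new_onset"
    NEVER = "never"


def classify_change(pre: int | None, post: int | None) -> TinnitusChange:
    """Classify pre→post tinnitus status change from THI scores.

    ``None`` means tinnitus absent at that session. Change is determined
    by the direction of the THI score: "resolved" is reserved for cases
    whose post score is 0 or whose tinnitus is reported absent.
    """
    if pre is None and post is None:
        return TinnitusChange.NEVER
    if pre is None:
        return TinnitusChange.NEW_ONSET
    if post is None or post == 0:
        return TinnitusChange.RESOLVED
    if post < pre:
        return TinnitusChange.IMPROVED
    if post > pre:
        return TinnitusChange.WORSE
    return TinnitusChange.UNCHANGED


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 count table.

    Sum of hypergeometric point probabilities not exceeding the observed
    table's probability (with a 1+1e-7 tolerance factor), margins fixed —
    the convention that reproduces the printed cohort p-values.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"need a 2×2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = t.astype(int)
    if t.sum() < 1:
        raise ValueError("table total must be >= 1")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class Characteristic:
    """A dichotomous cohort characteristic for a summary table row.

    ``column`` is the cohort-table column; ``levels`` gives the two level
    labels in display order (rows of the resulting 2×2 table).
    """

    name: str
    column: str
    levels: tuple[str, str]


def cohort_summary(records: pd.DataFrame, group_column: str,
                   group_levels: tuple[str, str],
                   characteristics: list[Characteristic]) -> pd.DataFrame:
    """Counts, percentages and Fisher p per characteristic by group.

    One output row per characteristic level; percentages are within-group
    to 2 decimals and the two-sided Fisher p (to 3 decimals) is attached
    to the characteristic's first row. A characteristic with an empty
    level in either group gets no p (with a warning), mirroring cohort
    tables that leave such entries blank.
    """
    rows = []
    g0 = records[records[group_column] == group_levels[0]]
    g1 = records[records[group_column] == group_levels[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError(f"empty group level in column {group_column!r}")
    for ch in characteristics:
        counts = np.array([
            [int((g[ch.column] == lvl).sum()) for g in (g0, g1)]
            for lvl in ch.levels
        ])
        if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
            warnings.warn(f"characteristic {ch.name!r} has an empty level; p omitted")
            p = np.nan
        else:
            p = round(fisher_exact(counts), 3)
        for j, lvl in enumerate(ch.levels):
            rows.append({
                "characteristic": ch.name,
                "level": lvl,
                f"n_{group_levels[0]}": counts[j, 0],
                f"pct_{group_levels[0]}": round(100.0 * counts[j, 0] / len(g0), 2),
                f"n_{group_levels[1]}": counts[j, 1],
                f"pct_{group_levels[1]}": round(100.0 * counts[j, 1] / len(g1), 2),
                "p": p if j == 0 else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference VS cohort contingency tables (published surgical cohort, n = 32
# patients; n = 22 with tinnitus at either session for the change analysis).
# Each entry is ((a, b), (c, d)): rows = characteristic levels, columns =
# groups. Table 1 columns: with tinnitus (n=18) / without (n=14), preoperative
# grouping. Table 2 columns: resolved+improved (n=6) / unchanged+worse (n=16).
# ---------------------------------------------------------------------------

VS_COHORT_TABLE1: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "gender_male_female": ((6, 6), (12, 8)),
    "age_ge50_lt50": ((8, 8), (10, 6)),
    "side_left_right": ((9, 7), (9, 7)),
    "preop_hearing_serviceable_unserviceable": ((9, 8), (9, 6)),
    "tumor_size_gt3_le3": ((3, 5), (15, 9)),
    "cochlear_nerve_preserved_cut": ((3, 1), (15, 13)),
    "resection_total_subtotal": ((15, 8), (3, 6)),
    "tumor_nature_solid_nonsolid": ((12, 7), (6, 7)),
}

VS_COHORT_TABLE2: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "gender_male_female": ((4, 4), (2, 12)),
    "age_ge50_lt50": ((3, 6), (3, 10)),
    "preop_hearing_serviceable_unserviceable": ((2, 11), (4, 5)),
    "tumor_size_le3_gt3": ((5, 14), (1, 2)),
    "iac_occupation_le1_gt1": ((6, 10), (0, 6)),
    "tumor_nature_solid_nonsolid": ((4, 12), (2, 4)),
    "brainstem_extrusion_pos_neg": ((2, 11), (4, 5)),
    "cochlear_nerve_preserved_cut": ((0, 4), (6, 12)),
    "resection_total_subtotal": ((5, 13), (1, 3)),
}

#: Tinnitus prevalence in the reference cohort: 18/32 preoperative (56.25%),
#: 21/32 postoperative (65.63%).
VS_COHORT_N = 32
VS_COHORT_TINNITUS_PRE = 18
VS_COHORT_TINNITUS_POST = 21


def reference_fisher_pvalues() -> dict[str, float]:
    """Two-sided Fisher p for every reference-cohort characteristic."""
    out = {}
    for name, tab in VS_COHORT_TABLE1.items():
        out[f"table1_{name}"] = fisher_exact(tab)
    for name, tab in VS_COHORT_TABLE2.items():
        out[f"table2_{name}"] = fisher_exact(tab)
    return out
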