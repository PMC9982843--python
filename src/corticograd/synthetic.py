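"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator is a two-factor latent model: every ROI time series is a
loading-weighted mixture of two independent unit-variance latent signals
plus white noise,

    X(t, i) = u_i f1(t) + v_i f2(t) + eps(t, i),

with the per-ROI loadings (u, v) laid out on a ring so the two leading
connectome gradients are analytically known — they span the (u, v) plane.
A group-specific effect is planted by shifting the target ROI's second
loading downward for affected (tinnitus) scans; tinnitus severity is
coupled to the size of that shift, so clinical scores correlate
negatively with the target ROI's Gradient-2 value downstream. Gene
expression carries a planted component spatially aligned with a supplied
group-difference map.

All randomness flows through one integer seed; each stage draws from its
own fixed-offset substream so regenerating any one artifact is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Atlas, COMMUNITIES

#: The seven cortical functional communities used for synthetic atlases.
DEFAULT_COMMUNITIES = ("Vis", "SM", "DA", "VA", "Lim", "FP", "DMN")

# fixed substream offsets (one per generation stage)
_STREAM_ATLAS = 11
_STREAM_TIMESERIES = 23
_STREAM_COHORT = 37
_STREAM_EXPRESSION = 53


@dataclass
class Scenario:
    """Study-condition parameters of a synthetic cohort.

    Defaults emulate the reference surgical cohort: 16 subjects per group
    arm at desk scale, 175 retained volumes per scan, tinnitus prevalence
    18/32 preoperative and 21/32 postoperative, a loading-scale planted
    effect of 0.8 at one target ROI, and unit-variance residual noise.
    """

    n_roi: int = 100
    n_subjects_per_group: int = 16
    n_reference_subjects: int = 32
    n_timepoints: int = 175
    effect_size_delta: float = 0.8
    effect_sd: float = 0.35
    noise_sd: float = 1.0
    target_roi: int | None = None          # defaults to the middle ROI
    coupling: float = 1.0                  # severity per unit of planted shift
    severity_noise_sd: float = 0.25
    prevalence_pre: float = 18 / 32
    prevalence_post: float = 21 / 32
    thi_thresholds: tuple[float, float] = (0.8, 1.8)
    thi_item_sd: float = 0.6
    vas_scale: float = 3.5
    vas_offset: float = 1.5
    vas_noise_sd: float = 1.0
    n_genes: int = 500
    n_signal_genes: int = 50
    expression_noise_sd: float = 1.0
    seed: int = 0
    latent_u: np.ndarray | None = field(default=None, repr=False)
    latent_v: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        if self.n_timepoints <= 2:
            raise ValueError("n_timepoints must exceed the number of latent factors")
        if not 0 <= self.prevalence_pre <= 1 or not 0 <= self.prevalence_post <= 1:
            raise ValueError("prevalences must be in [0, 1]")

    def resolve_target(self, atlas: Atlas) -> int:
        t = self.target_roi if self.target_roi is not None else (atlas.n_roi + 1) // 2
        if t not in atlas.roi_ids:
            raise ValueError(f"target_roi {t} not in atlas")
        return t

    def loadings(self, atlas: Atlas) -> tuple[np.ndarray, np.ndarray]:
        """Per-ROI loadings (u, v): by default the ring harmonics
        u = cos(theta_i), v = 0.95 sin(theta_i).

        The harmonic pair makes the expected connectivity kernel a function
        of ring distance only, so the leading two affinity components span
        the planted (u, v) plane exactly; the slight amplitude asymmetry
        orders the components (Gradient-1 tracks u, Gradient-2 tracks v)
        without breaking that symmetry appreciably."""
        n = atlas.n_roi
        if self.latent_u is not None and self.latent_v is not None:
            u = np.asarray(self.latent_u, dtype=float)
            v = np.asarray(self.latent_v, dtype=float)
            if u.shape != (n,) or v.shape != (n,):
                raise ValueError("latent loadings must have length n_roi")
            return u, v
        theta = 2 * np.pi * np.arange(n) / n
        return np.cos(theta), 0.95 * np.sin(theta)


def _rng(seed: int, offset: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset), int(extra)])


def generate_atlas(n_roi: int, communities=DEFAULT_COMMUNITIES, seed: int = 0) -> Atlas:
    """Synthetic annotation table: contiguous community blocks on a ring.

    ROIs are assigned to the communities in contiguous, near-equal blocks;
    coordinates lie on a ring of 60 mm radius so inter-ROI "community
    distance" is geometrically meaningful. Deterministic given the seed.
    """
    communities = tuple(communities)
    unknown = [c for c in communities if c not in COMMUNITIES]
    if unknown:
        raise ValueError(f"unknown community labels: {unknown}")
    if n_roi < len(communities):
        raise ValueError(f"n_roi={n_roi} is fewer than {len(communities)} communities")
    sizes = np.full(len(communities), n_roi // len(communities))
    sizes[: n_roi % len(communities)] += 1
    labels = np.repeat(list(communities), sizes)
    theta = 2 * np.pi * np.arange(n_roi) / n_roi
    within = np.concatenate([np.arange(1, s + 1) for s in sizes])
    table = pd.DataFrame({
        "roi_id": np.arange(1, n_roi + 1),
        "roi_name": [f"{c}_{k}" for c, k in zip(labels, within)],
        "community": labels,
        "hemisphere": np.where(np.arange(n_roi) < n_roi / 2, "L", "R"),
        "x": np.round(60 * np.cos(theta), 3),
        "y": np.round(60 * np.sin(theta), 3),
        "z": 0.0,
    })
    return Atlas(table)


def generate_timeseries(atlas: Atlas, scenario: Scenario, *, affected: bool = False,
                        shift: float | None = None, seed: int | None = None,
                        stream: int = 0) -> np.ndarray:
    """One scan: T×N two-factor latent time series.

    ``affected`` subtracts the planted shift (``shift`` or the scenario's
    ``effect_size_delta``) from the target ROI's second-factor loading.
    """
    u, v = scenario.loadings(atlas)
    if np.all(u == 0) and np.all(v == 0):
        raise ValueError("degenerate scenario: all latent loadings are zero")
    v = v.copy()
    if affected:
        v[atlas.index_of(scenario.resolve_target(atlas))] -= (
            scenario.effect_size_delta if shift is None else shift
        )
    rng = _rng(scenario.seed if seed is None else seed, _STREAM_TIMESERIES, stream)
    t = scenario.n_timepoints
    f1 = rng.standard_normal(t)
    f2 = rng.standard_normal(t)
    eps = rng.standard_normal((t, atlas.n_roi)) * scenario.noise_sd
    return np.outer(f1, u) + np.outer(f2, v) + eps


THI_ITEM_COLUMNS = [f"thi_item_{i:02d}" for i in range(1, 26)]

#: ``planted_shift`` is generator ground truth (the target-ROI loading shift
#: applied to that scan; 0 for unaffected scans), kept in the records for
#: parameter-recovery validation.
COHORT_COLUMNS = ["subject_id", "session", "group", "age", "sex",
                  "tinnitus", "vas", "planted_shift", *THI_ITEM_COLUMNS]


def _thi_items(severity: float, rng: np.random.Generator,
               thresholds: tuple[float, float], item_sd: float) -> np.ndarray:
    """Ordered-threshold item model: a noisy copy of the latent severity is
    cut at two thresholds into the 0/2/4 item responses."""
    latent = severity + rng.standard_normal(25) * item_sd
    return np.where(latent > thresholds[1], 4, np.where(latent > thresholds[0], 2, 0))


def generate_cohort(atlas: Atlas, scenario: Scenario, seed: int | None = None
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Full synthetic study: records plus per-scan time series.

    Produces ``n_subjects_per_group`` healthy controls (one ``hc`` session
    each) and the same number of VS patients with ``pre`` and ``post``
    sessions. Tinnitus counts match the configured prevalences exactly
    (rounded); a tinnitus scan's target-ROI loading is shifted by a
    subject-specific amount around ``effect_size_delta``, its THI latent
    severity is ``coupling`` times that shift plus noise (mapped to the 25
    items by ordered thresholds), and VAS is a rescaled noisy severity
    clipped to [0, 10]. Healthy controls never have tinnitus.

    Returns
    -------
    (records, timeseries) where records has one row per scan and
    timeseries maps (subject_id, session) to a T×N array.
    """
    seed = scenario.seed if seed is None else seed
    rng = _rng(seed, _STREAM_COHORT)
    n = scenario.n_subjects_per_group
    # half-up rounding so prevalence counts are deterministic and exact
    n_pre = int(np.floor(scenario.prevalence_pre * n + 0.5))
    n_post = int(np.floor(scenario.prevalence_post * n + 0.5))

    # subject-level tinnitus propensity; exact prevalence via rank cutoffs
    propensity = rng.standard_normal(n)
    pre_tin = np.zeros(n, bool)
    pre_tin[np.argsort(-propensity)[:n_pre]] = True
    post_rank = propensity + 0.5 * rng.standard_normal(n)
    post_tin = np.zeros(n, bool)
    post_tin[np.argsort(-post_rank)[:n_post]] = True

    shifts = np.maximum(
        scenario.effect_size_delta + scenario.effect_sd * rng.standard_normal(n), 0.0
    )

    records: list[dict] = []
    timeseries: dict[tuple[str, str], np.ndarray] = {}
    stream = 0

    def add_scan(subject_id, session, group, age, sex, tinnitus, shift):
        nonlocal stream
        ts = generate_timeseries(atlas, scenario, affected=tinnitus, shift=shift,
                                 seed=seed, stream=stream)
        stream += 1
        timeseries[(subject_id, session)] = ts
        row = {"subject_id": subject_id, "session": session, "group": group,
               "age": age, "sex": sex, "tinnitus": bool(tinnitus),
               "planted_shift": float(shift) if tinnitus else 0.0}
        if tinnitus:
            severity = (scenario.coupling * shift
                        + scenario.severity_noise_sd * rng.standard_normal())
            items = _thi_items(severity, rng, scenario.thi_thresholds,
                               scenario.thi_item_sd)
            vas = float(np.clip(scenario.vas_scale * severity + scenario.vas_offset
                                + scenario.vas_noise_sd * rng.standard_normal(), 0, 10))
        else:
            items = np.full(25, -1)    # stored as -1 = not administered
            vas = np.nan
        row["vas"] = vas
        row.update({c: int(x) for c, x in zip(THI_ITEM_COLUMNS, items)})
        records.append(row)

    ages = np.clip(np.round(rng.normal(46.4, 12.1, 2 * n)), 18, 80).astype(int)
    sexes = rng.permuted(["M"] * (3 * n // 4) + ["F"] * (2 * n - 3 * n // 4))
    for j in range(n):
        add_scan(f"hc{j + 1:03d}", "hc", "HC", ages[j], sexes[j], False, 0.0)
    for j in range(n):
        sid = f"vs{j + 1:03d}"
        age, sex = ages[n + j], sexes[n + j]
        add_scan(sid, "pre", "VS", age, sex, pre_tin[j], shifts[j])
        add_scan(sid, "post", "VS", age, sex, post_tin[j], shifts[j])
    df = pd.DataFrame.from_records(records, columns=COHORT_COLUMNS)
    return df, timeseries


def generate_reference_timeseries(atlas: Atlas, scenario: Scenario,
                                  n_subjects: int | None = None,
                                  seed: int | None = None) -> list[np.ndarray]:
    """Unaffected healthy scans for the gradient template (held out from
    every analysis group by construction: distinct substream, no records)."""
    seed = scenario.seed if seed is None else seed
    n = scenario.n_reference_subjects if n_subjects is None else n_subjects
    return [
        generate_timeseries(atlas, scenario, affected=False, seed=seed,
                            stream=10_000 + j)
        for j in range(n)
    ]


def expected_distance_alteration(atlas: Atlas, scenario: Scenario) -> np.ndarray:
    """Design-implied gradient-distance alteration profile of the target ROI.

    The planted shift moves the target by ``effect_size_delta`` along the
    second latent axis; the expected change of the target-to-ROI distance
    in the planted (u, v) plane is a smooth function of each ROI's
    position — the spatially distributed map on which the synthetic
    expression component is planted (a single-ROI spike has no spatial
    signature for imaging-transcriptomics to recover).
    """
    u, v = scenario.loadings(atlas)
    ti = atlas.index_of(scenario.resolve_target(atlas))
    d0 = np.hypot(u - u[ti], v - v[ti])
    d1 = np.hypot(u - u[ti], v - (v[ti] - scenario.effect_size_delta))
    delta = d1 - d0
    delta[ti] = 0.0
    return delta


def generate_expression(atlas: Atlas, difference_map, *, n_genes: int = 500,
                        n_signal_genes: int = 50, noise_sd: float = 1.0,
                        seed: int = 0) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Genes × ROI expression with a planted spatial component.

    Signal genes follow ``beta_g * t_i + noise`` with positive gene-specific
    amplitude ``beta_g ~ U(0.5, 1.5)`` on the standardized difference map;
    background genes are pure noise. Returns the matrix together with the
    planted gene set in GMT-ready form.
    """
    t = np.asarray(difference_map, dtype=float)
    if t.shape != (atlas.n_roi,):
        raise ValueError(f"difference map length {t.shape} != atlas N={atlas.n_roi}")
    if n_signal_genes > n_genes:
        raise ValueError("n_signal_genes must be <= n_genes")
    rng = _rng(seed, _STREAM_EXPRESSION)
    t_std = (t - t.mean()) / t.std() if t.std() > 0 else t - t.mean()
    symbols = [f"GENE{k:04d}" for k in range(1, n_genes + 1)]
    order = rng.permutation(n_genes)
    signal_rows = set(order[:n_signal_genes].tolist())
    expr = rng.standard_normal((n_genes, atlas.n_roi)) * noise_sd
    betas = rng.uniform(0.5, 1.5, n_signal_genes)
    for b, row in zip(betas, sorted(signal_rows)):
        expr[row] += b * t_std
    df = pd.DataFrame(expr, index=pd.Index(symbols, name="symbol"),
                      columns=atlas.roi_ids)
    planted = {"planted_signal": [symbols[r] for r in sorted(signal_rows)]}
    return df, planted


# ---------------------------------------------------------------------------
# Reference VS cohort fixture: per-patient records whose cross-tabulations
# equal the published contingency-table cell counts (n = 32 surgical
# patients; n = 22 with tinnitus at either session). Characteristics are
# assigned independently within each column group — any joint assignment
# with the printed margins yields the same 2×2 tables.
# ---------------------------------------------------------------------------

def _assign(n_group: dict[str, int], counts: dict[str, tuple[int, int]],
            group_col: str, group_levels: tuple[str, str],
            level_names: dict[str, tuple[str, str]]) -> pd.DataFrame:
    total = sum(n_group.values())
    df = pd.DataFrame({group_col: np.repeat(list(n_group), list(n_group.values()))})
    for char, (a, b) in counts.items():
        lvl1, lvl2 = level_names[char]
        col = []
        for g, ng in n_group.items():
            k = a if g == group_levels[0] else b
            col.extend([lvl1] * k + [lvl2] * (ng - k))
        df[char] = col
    assert len(df) == total
    return df


def reference_cohort_table1() -> pd.DataFrame:
    """Per-patient records reproducing the preoperative-tinnitus cohort
    table (n=32: 18 with tinnitus / 14 without)."""
    from .clinical import VS_COHORT_TABLE1
    counts = {name: (tab[0][0], tab[0][1]) for name, tab in VS_COHORT_TABLE1.items()}
    level_names = {
        name: tuple(name.rsplit("_", 2)[-2:]) for name in VS_COHORT_TABLE1
    }
    return _assign({"tinnitus": 18, "no_tinnitus": 14}, counts, "tinnitus_group",
                   ("tinnitus", "no_tinnitus"), level_names)


def reference_cohort_table2() -> pd.DataFrame:
    """Per-patient records reproducing the tinnitus-change cohort table
    (n=22: 6 resolved+improved / 16 unchanged+worse)."""
    from .clinical import VS_COHORT_TABLE2
    counts = {name: (tab[0][0], tab[0][1]) for name, tab in VS_COHORT_TABLE2.items()}
    level_names = {
        name: tuple(name.rsplit("_", 2)[-2:]) for name in VS_COHORT_TABLE2
    }
    return _assign({"resolved_improved": 6, "unchanged_worse": 16}, counts,
                   "change_group", ("resolved_improved", "unchanged_worse"),
                   level_names)
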