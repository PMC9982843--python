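"""Functional connectome construction.

The chain that turns an ROI time-series matrix into the affinity matrix
feeding the gradient embedding:

    Pearson FC  →  Fisher z  →  row-wise top-fraction threshold  →  cosine affinity

Thresholding is row-wise (each ROI keeps its top fraction of connections),
the convention of the gradient-mapping literature; a global mode is
available behind a flag. Cosine similarity is computed on the weighted
(z-valued) thresholded profiles, zeros included, so both edge weights and
the sparsity pattern shape the affinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: correlations are clipped to ±(1 - R_CLIP_EPS) before arctanh so that
#: duplicate-column degeneracies cannot produce infinities.
R_CLIP_EPS = 1e-7

STAGES = ("raw_r", "z", "thresholded", "affinity")


@dataclass(frozen=True)
class Connectome:
    """An N×N connectivity matrix tagged with its processing stage."""

    values: np.ndarray
    stage: str
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectome must be square, got shape {v.shape}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    def _require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"expected a {stage!r}-stage connectome, got {self.stage!r}")


def compute_fc(ts: np.ndarray) -> Connectome:
    """Pairwise Pearson correlation of ROI time series.

    Parameters
    ----------
    ts : (T, N) array
        One column per ROI, T >= 3 time points, every column nonconstant.

    Returns
    -------
    Connectome at stage ``raw_r``: symmetric, unit diagonal, entries in [-1, 1].
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D T×N array")
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 time points, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant time series for ROI index {const[0] + 1} (1-based)")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return Connectome(r, "raw_r")


def to_z(c: Connectome) -> Connectome:
    """Fisher z-transform (arctanh) with clipping; diagonal set to 0.

    The diagonal is excluded from all downstream steps, so it is zeroed
    here rather than carrying arctanh(1) = inf.
    """
    c._require_stage("raw_r")
    r = np.clip(c.values, -(1 - R_CLIP_EPS), 1 - R_CLIP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return Connectome(z, "z")


def threshold_top_fraction(c: Connectome, fraction: float, *,
                           mode: str = "row") -> Connectome:
    """Keep the strongest ``fraction`` of connections, zero the rest.

    Row-wise mode (default): each row keeps its ``ceil(fraction*(N-1))``
    largest off-diagonal entries; ties broken by larger value first, then
    lower column index. The result need not be symmetric. Global mode
    keeps the top fraction of all off-diagonal entries instead.
    """
    c._require_stage("z")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    z = c.values
    n = z.shape[0]
    keep = int(np.ceil(fraction * (n - 1)))
    out = np.zeros_like(z)
    if mode == "row":
        for i in range(n):
            row = z[i].copy()
            cols = np.delete(np.arange(n), i)
            vals = row[cols]
            # stable order: descending value, ascending column index
            order = np.lexsort((cols, -vals))
            kept = cols[order[:keep]]
            out[i, kept] = row[kept]
    elif mode == "global":
        iu = np.triu_indices(n, k=1)
        vals = z[iu]
        m = int(np.ceil(fraction * vals.size))
        order = np.argsort(-vals, kind="stable")
        sel = order[:m]
        mask = np.zeros((n, n), dtype=bool)
        mask[iu[0][sel], iu[1][sel]] = True
        mask |= mask.T
        out[mask] = z[mask]
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    np.fill_diagonal(out, 0.0)
    return Connectome(out, "thresholded", threshold_fraction=fraction)


def cosine_affinity(c: Connectome) -> Connectome:
    """Cosine similarity between thresholded connectivity profiles.

    a_ij = row_i · row_j / (‖row_i‖ ‖row_j‖) over the full N-length rows
    (zeros included); diagonal set to 1. An all-zero row — possible when a
    row retains only zero-valued entries — is an error naming the ROI.
    """
    c._require_stage("thresholded")
    rows = c.values
    norms = np.linalg.norm(rows, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"ROI index {zero[0] + 1} (1-based) has an all-zero connectivity profile"
        )
    a = (rows @ rows.T) / np.outer(norms, norms)
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return Connectome(a, "affinity", threshold_fraction=c.threshold_fraction)


def affinity_from_timeseries(ts: np.ndarray, fraction: float = 0.10, *,
                             mode: str = "row") -> Connectome:
    """Convenience: run the full FC → z → threshold → affinity chain."""
    return cosine_affinity(threshold_top_fraction(to_z(compute_fc(ts)), fraction, mode=mode))


def affinity_from_fc(c: Connectome, fraction: float = 0.10, *,
                     mode: str = "row") -> Connectome:
    """Affinity chain starting from an existing raw_r connectome."""
    return cosine_affinity(threshold_top_fraction(to_z(c), fraction, mode=mode))


def mean_fc(connectomes: list[Connectome]) -> Connectome:
    """Element-wise mean of raw_r connectomes (for group templates)."""
    if len(connectomes) < 2:
        raise ValueError("need at least 2 connectomes to average")
    shapes = {c.values.shape for c in connectomes}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous connectome sizes: {sorted(shapes)}")
    for c in connectomes:
        c._require_stage("raw_r")
    m = np.mean([c.values for c in connectomes], axis=0)
    np.fill_diagonal(m, 1.0)
    return Connectome(m, "raw_r")
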