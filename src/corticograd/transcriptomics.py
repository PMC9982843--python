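"""Imaging-transcriptomics: PLS regression of a regional alteration map on
gene expression, permutation significance, gene ranking, and gene-set
enrichment.

The regional alteration map (per-ROI t-values of a gradient contrast) is
the response, the gene × ROI expression matrix the predictors (ROIs are
observations). PLS1 — the first partial-least-squares component — is the
expression pattern most strongly covarying with the alteration map; its
per-gene weights define a transcriptomic signature whose ranked list is
scored against gene sets by a weighted running-sum enrichment statistic
with a gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_stats import bh_fdr

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


def _standardize_genes(expr: np.ndarray) -> np.ndarray:
    """Z-score each gene across ROIs; constant genes become all-zero."""
    mu = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (expr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


@dataclass
class PlsResult:
    """First-component PLS summary of map ~ expression."""

    pls1_roi_scores: np.ndarray     # per-ROI component-1 score
    gene_weights: np.ndarray        # per-gene PLS1 weight (standardized X)
    gene_symbols: list[str]
    var_explained_pls1: float       # response-variance share of component 1
    perm_p: float | None = None
    n_perm: int | None = None


def _pls1_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """One PLS component by the iterative latent-variable (NIPALS) scheme.

    ``x`` (N×G) is pre-standardized, ``y`` (N,) pre-centred. The start is
    deterministic — the response-covariance direction — and with a single
    response the iteration converges in one pass; the loop is kept as the
    general algorithm with tolerance 1e-10.

    Returns (weights, scores, response-variance fraction explained).
    """
    yv = y[:, None]
    w = x.T @ yv
    nw = np.linalg.norm(w)
    if nw == 0:
        return np.zeros(x.shape[1]), np.zeros(x.shape[0]), 0.0
    w /= nw
    for _ in range(_NIPALS_MAX_ITER):
        t = x @ w
        q = float((yv.T @ t).item()) / float((t.T @ t).item())
        w_new = x.T @ (yv * q)
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            break
        w = w_new
    t = (x @ w).ravel()
    denom = float(t @ t)
    coef = float(t @ y) / denom if denom > 0 else 0.0
    resid = y - coef * t
    ss_tot = float(y @ y)
    var_explained = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return w.ravel(), t, max(var_explained, 0.0)


def plsr_spatial(alteration_map, expr: pd.DataFrame, n_components: int = 1) -> PlsResult:
    """PLS of a per-ROI alteration map on a gene × ROI expression matrix.

    Genes are standardized (mean 0, SD 1 across ROIs) and the map centred
    inside this operation, so the result is invariant to affine rescaling
    of any single gene. Only component 1 is summarised (the signature of
    interest); ``n_components`` > 1 merely runs further deflation steps.
    """
    y = np.asarray(alteration_map, dtype=float)
    if y.ndim != 1:
        raise ValueError("alteration map must be 1-D (one value per ROI)")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 ROIs, got {n}")
    if expr.shape[1] != n:
        raise ValueError(f"expression has {expr.shape[1]} ROI columns, map has {n}")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if np.ptp(y) == 0:
        raise ValueError("alteration map is constant")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = _standardize_genes(expr.to_numpy(dtype=float)).T   # N × G
    yc = y - y.mean()
    w1, t1, ve1 = _pls1_fit(x, yc)
    # sign convention: component positively correlated with the map
    if float(t1 @ yc) < 0:
        w1, t1 = -w1, -t1
    return PlsResult(
        pls1_roi_scores=t1,
        gene_weights=w1,
        gene_symbols=[str(g) for g in expr.index],
        var_explained_pls1=ve1,
    )


def permutation_test_pls(alteration_map, expr: pd.DataFrame, n_perm: int = 1000,
                         seed: int = 0) -> tuple[float, PlsResult]:
    """Permutation p for the PLS1 response-variance share.

    The ROI order of the map is permuted uniformly ``n_perm`` times and the
    component-1 variance share recomputed; p = (1 + #{perm >= observed}) /
    (1 + n_perm), so p is never below the plus-one bound 1/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    res = plsr_spatial(alteration_map, expr)
    y = np.asarray(alteration_map, dtype=float)
    x = _standardize_genes(expr.to_numpy(dtype=float)).T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        _, _, ve = _pls1_fit(x, yc)
        if ve >= res.var_explained_pls1:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    res.perm_p = p
    res.n_perm = n_perm
    return p, res


def rank_genes(pls: PlsResult) -> pd.DataFrame:
    """Genes sorted by PLS1 weight, descending; ties broken by symbol."""
    df = pd.DataFrame({"symbol": pls.gene_symbols, "score": pls.gene_weights})
    df = df.sort_values(["score", "symbol"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Gene-set enrichment on the ranked signature
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-set enrichment: running-sum ES, sign-matched NES, permutation p,
    BH-FDR q, leading-edge genes."""

    table: pd.DataFrame
    skipped: list[str] = field(default_factory=list)
    n_perm: int = 0


def _running_sum_es(positions: np.ndarray, weights: np.ndarray, n: int
                    ) -> tuple[float, int]:
    """Enrichment score of a hit-position set on a ranked list of length n.

    ``positions`` are sorted 0-based ranks of the set's genes, ``weights``
    the corresponding |score|^exponent values. Returns (ES, peak index in
    the hit array; negative peaks refer to the step *before* the hit).
    The degenerate set covering the whole list has no complement to walk
    through; its ES is defined as 0.
    """
    h = positions.size
    if h == 0 or h == n:
        return 0.0, 0
    wsum = float(weights.sum())
    if wsum == 0:
        # all-zero scores in the set: fall back to unweighted steps
        weights = np.ones(h)
        wsum = float(h)
    cum = np.cumsum(weights) / wsum
    k = np.arange(1, h + 1)
    miss_denom = n - h
    dev_after = cum - (positions + 1 - k) / miss_denom
    dev_before = np.concatenate([[0.0], cum[:-1]]) - (positions - (k - 1)) / miss_denom
    ia = int(np.argmax(np.abs(dev_after)))
    ib = int(np.argmax(np.abs(dev_before)))
    if abs(dev_after[ia]) >= abs(dev_before[ib]):
        return float(dev_after[ia]), ia
    return float(dev_before[ib]), -(ib + 1)


def gsea(ranked: pd.DataFrame, sets: dict[str, list[str]], *, n_perm: int = 999,
         seed: int = 0, min_size: int = 5, max_size: int = 500,
         weight_exponent: float = 1.0) -> EnrichmentResult:
    """Gene-set enrichment of a ranked, scored gene list.

    For each set the classic weighted Kolmogorov-Smirnov running sum is
    walked down the ranking: hits advance by |score|^exponent (normalised),
    misses retreat by 1/(N - N_hit); ES is the extremum. The null is
    ``n_perm`` random same-size gene-label draws; NES = ES / mean(|ES_null|
    of matching sign) and p is one-sided on the matching sign with the
    plus-one rule. BH-FDR is applied across the retained sets.
    """
    if not {"symbol", "score"}.issubset(ranked.columns):
        raise ValueError("ranked list needs 'symbol' and 'score' columns")
    symbols = ranked["symbol"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(symbols)
    weights_full = np.abs(scores) ** weight_exponent
    pos_of = {s: i for i, s in enumerate(symbols)}
    rng = np.random.default_rng(seed)

    rows = []
    skipped = []
    for name, genes in sets.items():
        positions = np.array(sorted({pos_of[g] for g in genes if g in pos_of}), dtype=int)
        h = positions.size
        if h == 0:
            skipped.append(name)
            continue
        if not (min_size <= h <= max_size):
            skipped.append(name)
            continue
        es, peak = _running_sum_es(positions, weights_full[positions], n)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_pos = np.sort(rng.choice(n, size=h, replace=False))
            null[b], _ = _running_sum_es(perm_pos, weights_full[perm_pos], n)
        same_sign = null[null > 0] if es > 0 else null[null < 0] if es < 0 else null
        if es == 0 or same_sign.size == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / float(np.mean(np.abs(same_sign)))
            p = (1.0 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1.0 + same_sign.size)
        if es >= 0:
            cut = positions[peak] if peak >= 0 else positions[-peak - 1] - 1
            leading = [s for s in symbols[positions[positions <= cut]]]
        else:
            cut = positions[peak] if peak >= 0 else positions[-peak - 1]
            leading = [s for s in symbols[positions[positions >= cut]]]
        rows.append({
            "set": name, "size": h, "es": es, "nes": nes, "p": p,
            "leading_edge": ",".join(leading),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table, skipped=skipped, n_perm=n_perm)
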