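"""Leave-one-out stepwise prediction of tinnitus measures.

For each left-out case an ordinary-least-squares model of the clinical
measure (VAS rating, THI score or THI level) is built from candidate
gradient features by bidirectional stepwise selection — age, sex and an
intercept always included, features entering when their partial-test p
falls below ``alpha_enter`` and leaving when it exceeds ``alpha_remove`` —
and the held-out case is predicted from the converged model. A candidate
is a *reliable* predictor when it is entered and significant in at least
98% of the leave-one-out iterations; the pooled predictions are scored by
mean absolute error and their Pearson correlation with the observed
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RELIABILITY_THRESHOLD = 0.98
CONDITION_NUMBER_BOUND = 1e10


def _ols_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit returning (coefficients, two-sided coefficient p-values).

    Plain QR-based least squares with t-tests on the coefficients; the
    stepwise loop calls this thousands of times, so it stays lean.
    """
    n, k = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    if dof <= 0:
        return beta, np.ones(k)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, p


def _stepwise(base: np.ndarray, feats: np.ndarray, y: np.ndarray,
              alpha_enter: float, alpha_remove: float,
              max_iter: int) -> list[int]:
    """Bidirectional stepwise selection; returns selected feature indices.

    ``base`` (intercept + covariates) is always in the model. Forward
    ties are broken by candidate order in the feature manifest.
    """
    n_feat = feats.shape[1]
    selected: list[int] = []
    n_base = base.shape[1]
    for _ in range(max_iter):
        changed = False
        # forward: candidate with smallest partial p, if below alpha_enter
        best_j, best_p = -1, np.inf
        for j in range(n_feat):
            if j in selected:
                continue
            x = np.column_stack([base, feats[:, selected], feats[:, [j]]])
            _, p = _ols_pvalues(x, y)
            pj = p[-1]
            if pj < best_p - 1e-15:
                best_j, best_p = j, pj
        if best_j >= 0 and best_p < alpha_enter:
            selected.append(best_j)
            changed = True
        # backward: selected feature with largest p, if above alpha_remove
        if selected:
            x = np.column_stack([base, feats[:, selected]])
            _, p = _ols_pvalues(x, y)
            feat_p = p[n_base:]
            worst = int(np.argmax(feat_p))
            if feat_p[worst] > alpha_remove:
                selected.pop(worst)
                changed = True
        if not changed:
            return selected
    raise RuntimeError("stepwise selection did not converge")


@dataclass
class StepwiseReport:
    """Aggregate of a leave-one-out stepwise regression run."""

    feature_names: list[str]
    selected_sets: list[tuple[str, ...]]          # per LOO iteration
    reliability: dict[str, float]                  # entered-and-significant fraction
    predictions: np.ndarray                        # per-case predicted measure
    observed: np.ndarray
    mae: float
    mae_sd: float                                  # SD of per-case absolute errors
    r: float
    p_r: float
    reliable_features: list[str] = field(default_factory=list)
    significant: bool = False                      # p_r < 0.05
    config: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.observed)


def looswr(features: pd.DataFrame | np.ndarray, covariates: pd.DataFrame | np.ndarray,
           target, *, alpha_enter: float = 0.05, alpha_remove: float = 0.05,
           sig_alpha: float = 0.05, max_iter: int = 200) -> StepwiseReport:
    """Leave-one-out cross-validated stepwise linear regression.

    Parameters
    ----------
    features
        Case × candidate-feature matrix (gradient features of the most
        altered regions). Column names become feature names.
    covariates
        Case × covariate matrix (age in years, sex coded 0/1); always in
        the model together with the intercept.
    target
        Per-case clinical measure; must be nonconstant.
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        feats = features.to_numpy(dtype=float)
    else:
        feats = np.asarray(features, dtype=float)
        names = [f"feature_{j + 1}" for j in range(feats.shape[1])]
    cov = (covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame)
           else np.asarray(covariates, dtype=float))
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 cases, got {n}")
    if feats.shape[0] != n or cov.shape[0] != n:
        raise ValueError("features, covariates and target must have equal case counts")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; nothing to predict")
    if np.isnan(feats).any() or np.isnan(cov).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")

    base_full = np.column_stack([np.ones(n), cov])
    for j, name in enumerate(names):
        design = np.column_stack([base_full, feats[:, [j]]])
        if np.linalg.cond(design) > CONDITION_NUMBER_BOUND:
            raise ValueError(f"feature {name!r} is collinear with the covariates/intercept")

    preds = np.empty(n)
    selected_sets: list[tuple[str, ...]] = []
    hits = np.zeros(len(names))
    for i in range(n):
        keep = np.arange(n) != i
        base = base_full[keep]
        fi = feats[keep]
        yi = y[keep]
        sel = _stepwise(base, fi, yi, alpha_enter, alpha_remove, max_iter)
        x = np.column_stack([base, fi[:, sel]])
        beta, p = _ols_pvalues(x, yi)
        x_new = np.concatenate([base_full[i], feats[i, sel]])
        preds[i] = float(x_new @ beta)
        selected_sets.append(tuple(names[j] for j in sel))
        feat_p = p[base.shape[1]:]
        for rank, j in enumerate(sel):
            if feat_p[rank] < sig_alpha:
                hits[j] += 1

    reliability = {name: float(h) / n for name, h in zip(names, hits)}
    abs_err = np.abs(preds - y)
    if np.ptp(preds) == 0:
        r, p_r = 0.0, 1.0
    else:
        rr = stats.pearsonr(preds, y)
        r, p_r = float(rr.statistic), float(rr.pvalue)
    reliable = [nm for nm in names if reliability[nm] >= RELIABILITY_THRESHOLD]
    return StepwiseReport(
        feature_names=names,
        selected_sets=selected_sets,
        reliability=reliability,
        predictions=preds,
        observed=y,
        mae=float(abs_err.mean()),
        mae_sd=float(abs_err.std(ddof=1)) if n > 1 else 0.0,
        r=r,
        p_r=p_r,
        reliable_features=reliable,
        significant=p_r < sig_alpha,
        config={
            "alpha_enter": alpha_enter,
            "alpha_remove": alpha_remove,
            "sig_alpha": sig_alpha,
            "n_cases": n,
            "reliability_threshold": RELIABILITY_THRESHOLD,
        },
    )
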