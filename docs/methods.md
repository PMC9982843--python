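# Methods

## Analysis model

The pipeline treats each scan's ROI × ROI Pearson correlation matrix as
an estimate of the subject's functional connectome and asks how each
ROI's *connectivity profile* — its row of the connectome — is situated
relative to every other ROI's. The profile-similarity (cosine affinity)
matrix is embedded by PCA; the leading components ("gradients") are
continuous axes along which connectivity profiles vary, and a subject's
functional hierarchy is summarised by each ROI's coordinates on the
first two gradients. Statistical comparability across subjects rests on
two assumptions: (i) the affinity chain is applied identically to every
scan (same threshold fraction, same component count), and (ii) every
embedding is rotated onto a common template estimated from a reference
cohort that is disjoint from the analysis groups. Orthogonal Procrustes
alignment (rotation/reflection, no scaling) preserves all inter-ROI
distances within a subject, which is what makes the gradient-distance
comparisons meaningful.

Processing chain per scan, in order:

1. `compute_fc` — Pearson r for every ROI pair; hard error on a
   constant time series.
2. `to_z` — Fisher z = arctanh(r) after clipping |r| at 1 − 1e-7; the
   diagonal is set to 0 and never participates downstream.
3. `threshold_top_fraction` — row-wise: each ROI keeps its
   ceil(f·(N−1)) strongest connections. Row-wise (not global)
   thresholding is the convention of the gradient-mapping literature;
   a `mode="global"` flag provides the alternative. Negative z-values
   survive thresholding when a row has fewer positive entries than the
   keep count; they are retained as genuine (weak) profile information.
4. `cosine_affinity` — on the full thresholded rows including zeros, so
   both edge weights and sparsity pattern contribute. The result is
   symmetric with unit diagonal by construction.
5. `pca_embedding` — SVD of the column-centred affinity; variance
   fractions are σ_k²/Σσ² over all N−1 nonzero components. Component
   signs follow a largest-|loading|-positive convention so unaligned
   outputs are reproducible.
6. `procrustes_align` — the orthogonal Q minimising ‖E·Q − T‖_F.

Group inference: Welch t-tests by default (Student behind a flag),
paired t for pre/post contrasts, BH-FDR with the family defined as the
N ROIs of one gradient dimension within one contrast (per-dimension
families follow from reporting each gradient separately). Seed-distance
profiles use the N−1 targets of one seed as the family. Pooled
tinnitus analyses treat pre- and post-operative scans of the same
patient as independent cases; this mirrors the source study design and
is a known simplification (a subject-level mixed model is out of
scope).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `threshold_fraction` | 0.10 | proportion of connections kept per row; robustness range 0.10–0.20 |
| `n_components` | 10 | gradients computed and aligned; analyses use components 1–2 |
| `fdr_alpha` | 0.05 | BH-FDR level for every regional family |
| `alpha_enter`, `alpha_remove` | 0.05 / 0.05 | stepwise entry/removal partial-test thresholds; symmetric because no separate values are established |
| `n_permutations` | 1000 | PLS and enrichment nulls (999 cap for GSEA inside the pipeline) |
| `random_seed` | 0 | all randomness flows from this value |

Prediction: sex is coded 0/1 and age in years, unstandardised —
coefficients are never interpreted, only predictions. The reliability
threshold (0.98 of leave-one-out folds) is part of the method
definition. Significance of a prediction is judged on the pooled
leave-one-out predictions (two-sided Pearson p < 0.05).

## Synthetic cohort: what it emulates

Each scan is a two-factor latent model X(t,i) = u_i f1(t) + v_i f2(t) +
ε(t,i) with unit-variance latent signals and iid Gaussian noise
(`noise_sd` = 1). The default loadings are ring harmonics u = cos θ_i,
v = 0.95 sin θ_i over the ROI index. This choice is deliberate: with a
harmonic pair the expected connectivity kernel depends only on ring
distance, so the top two affinity components span the planted (u, v)
plane *exactly* — the structural bias that any other smooth loading
shape incurs through the z→threshold→cosine chain (canonical
correlations plateauing near 0.94 in our exploration) vanishes by
symmetry. The 0.95 amplitude asymmetry orders the axes so Gradient-1
identifies with u; with exactly equal amplitudes the in-plane rotation
of the leading pair is undetermined and per-scan "Gradient-1" would be
an arbitrary mixture. Axis identification is assessed after template
alignment, which is also how the analysis itself uses gradients.

Planted structure, per the default scenario (16 subjects per analysis
arm, 32 reference subjects for the template, 175 time points, 100
ROIs):

- **Group effect** — tinnitus-affected scans have the target ROI's
  second loading shifted by a subject-specific amount ~ N(0.8, 0.35²)
  (floored at 0). The shift is local: only the target ROI's loading
  changes.
- **Clinical coupling** — latent severity = coupling × shift + N(0,
  0.25²); the 25 THI items are an ordered-threshold discretisation of
  severity (thresholds 0.8 / 1.8, item noise SD 0.6, giving cohort THI
  scores in the reported ~20 ± 18 range), VAS = 3.5 × severity + 1.5 +
  N(0,1) clipped to [0, 10]. Tinnitus status is assigned by severity
  rank with exact prevalence counts (18/32 pre, 21/32 post at the
  study size; half-up rounding elsewhere).
- **Expression** — signal genes are β_g × (standardised map) + noise
  with β_g ~ U(0.5, 1.5); the map is the *expected gradient-distance
  alteration profile* of the target ROI, i.e. the change of
  target-to-ROI distance in the (u, v) plane induced by the shift.
  This profile is spatially distributed and smooth. A single-ROI spike
  map is deliberately not used: the PLS1 variance-explained statistic
  saturates under the rank-1 overfit when genes greatly outnumber ROIs,
  so a map with one informative coordinate has no permutation-testable
  spatial signature (a limitation that applies equally to real
  analyses with very focal alteration maps).

What the generator does **not** emulate: BOLD temporal autocorrelation,
scanner drift and motion artifacts, spatial autocorrelation of
neighbouring ROIs beyond the planted axes, hemispheric asymmetries,
tumor mass effects, and gene–gene co-expression structure. Passing
tests therefore demonstrate that the *statistical machinery* recovers
planted effects under clean conditions, not that the pipeline is robust
to fMRI artifact structure.

## Numerical choices

- r is clipped at ±(1 − 1e-7) before arctanh so duplicate columns
  cannot produce infinities.
- Thresholding ties break by larger value, then lower column index —
  fully deterministic.
- PLS1 uses the iterative latent-variable scheme with the
  response-covariance start and tolerance 1e-10 (with a single response
  it converges in one pass); genes with zero variance standardise to
  zero rather than NaN. The component is oriented to correlate
  positively with the map.
- Permutation p-values use the plus-one rule, (1 + #{null ≥ obs}) /
  (1 + n_perm), bounded away from zero.
- GSEA: hit steps weighted by |score|^1 normalised over the set, miss
  steps 1/(N − N_hit); ES is the running-sum extremum; NES divides by
  the mean |ES| of same-sign permutation nulls; the degenerate set
  containing every ranked gene has no complement to traverse and its ES
  is defined as 0. Permutation is gene-label (set-membership) sampling:
  with one observed map there is no phenotype axis to permute.
- Two-sided Fisher p sums hypergeometric point probabilities ≤ the
  observed probability × (1 + 1e-7); this is the convention that
  reproduces the reference cohort's printed values.
- Identical-group t-tests produce 0/1 rather than NaN (no evidence of
  difference).
- The THI score-0 case maps to severity level 0 ("no handicap"): the
  published bins start at level 1 (score ≥ 2), but resolved tinnitus
  must be representable. Odd THI scores are rejected — 25 items scored
  0/2/4 can only produce even sums.
- `classify_change` reserves "resolved" for post-THI of 0 or tinnitus
  reported absent; any smaller-but-nonzero post score is "improved" (no
  established minimal-change threshold exists).

## Design choices made where the design was open

- **PCA, not diffusion embedding**, as the reproducible choice for
  gradient extraction; the affinity chain is unchanged either way.
- **Procrustes without isotropic scaling** ("rotation" read strictly);
  a scaling variant exists but is off.
- **The alignment template is built from reference subjects only**, and
  its construction order is mean-connectome → affinity → PCA (not a
  mean of per-subject embeddings).
- **Uniform ROI shuffles** for the PLS null. Spatial-autocorrelation-
  preserving nulls (spin tests and variogram matching) are standard in
  imaging-transcriptomics but require geometry we do not model; results
  carry a note that autocorrelation is not preserved.
- **Pipeline feature orientation**: embedding-axis signs are
  statistically arbitrary, so the clinical gradient feature is oriented
  by the direction of the group contrast at the selected ROI before
  computing severity correlations; the reported negative correlations
  are therefore sign-deterministic.

## Known limitations

- Pooled tinnitus contrasts ignore within-subject correlation between
  pre- and post-operative scans.
- The variance share of the two leading gradients in the default
  scenario (~0.5 of total) is a property of the planted
  signal-to-noise ratio, not a calibration target; real cohorts report
  higher shares.
- The rank-1 PLS statistic is only permutation-testable for spatially
  distributed alteration maps (see above).
- The stepwise-regression reliability criterion inherits the usual
  caveats of stepwise selection; it is part of the method definition,
  not an endorsement over regularised alternatives.
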