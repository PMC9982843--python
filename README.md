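# corticograd

Functional-connectome **gradient analysis** for studying how cortical
hierarchy reorganises in disease — built around the question of why
tinnitus persists in patients with vestibular schwannoma (VS) after the
tumor is resected. The package takes per-subject ROI time series (plus a
cohort table and, optionally, a gene-expression matrix) and runs the full
chain: connectome construction, gradient embedding, group statistics,
clinical instruments, symptom prediction, and imaging-transcriptomics.
A synthetic-cohort generator with known ground truth makes every stage
testable without access to clinical imaging data.

## The method

For each scan with ROI time series, the pipeline computes

1. **Connectome** — Pearson correlation r_ij between all ROI pairs,
   Fisher z-transformed; each row keeps its top 10% strongest connections
   (the rest set to 0).
2. **Affinity** — cosine similarity between thresholded connectivity
   profiles: a_ij = z_i · z_j / (‖z_i‖‖z_j‖).
3. **Gradients** — PCA of the column-centred affinity matrix. The scores
   G_k(i) order ROIs along continuous axes of connectivity variation;
   σ_k²/Σσ² is the variance each gradient explains.
4. **Alignment** — orthogonal Procrustes rotation of each subject's
   k = 10 components onto a group template built from a held-out healthy
   reference set, so gradient values are comparable across subjects.
5. **Gradient distance** — d_ij = √((G1_i−G1_j)² + (G2_i−G2_j)²), the
   separation of two ROIs in the primary gradient plane.

Group contrasts use Welch (or paired) t-tests per ROI with
Benjamini–Hochberg FDR per gradient dimension; seed-distance profiles
test d(seed, ·) against all other ROIs. Tinnitus burden is measured by
the 25-item Tinnitus Handicap Inventory (items scored 0/2/4, global
score 0–100, severity levels 1–5) and a 0–10 visual analog scale, and
related to gradient features by Spearman correlation. Symptom
prediction uses leave-one-out stepwise linear regression (age, sex and
intercept always included; predictors enter/leave at p = 0.05; a feature
is *reliable* if selected and significant in ≥ 98% of folds), scored by
MAE and the Pearson r between predicted and observed values. The
transcriptomic stage regresses a regional alteration map on a gene × ROI
expression matrix by partial least squares: PLS1 is the expression
pattern most covarying with the map, its significance assessed by ROI
permutation, and its ranked gene list scored against GMT gene sets with
a weighted running-sum enrichment statistic (gene-label permutation
null, sign-matched NES, BH-FDR).

## Worked example

```python
from corticograd import AnalysisConfig, Scenario, simulate_study, run_pipeline

manifest = simulate_study(Scenario(seed=7), "scratch/example")
config = AnalysisConfig(random_seed=7, n_permutations=499)
summary = run_pipeline(config, manifest, "scratch/example/results")

s = summary["stages"]
print("variance explained (G1+G2):", s["gradients"]["mean_variance_explained_g1_g2"])
print("top tinnitus-contrast ROI:", s["group_stats"]["tinnitus_vs_hc_g2"]["top_roi"])
print("THI ~ target Gradient-2 rho:", s["clinical"]["spearman_target_g2"]["thi_score"]["rho"])
print("PLS1 variance explained:", s["transcriptomics"]["var_explained_pls1"],
      "permutation p =", s["transcriptomics"]["perm_p"])
```

prints

```
variance explained (G1+G2): 0.507024
top tinnitus-contrast ROI: 50
THI ~ target Gradient-2 rho: -0.5409
PLS1 variance explained: 0.921531 permutation p = 0.002
```

The synthetic scenario plants a gradient decrease at ROI 50 in
tinnitus-affected scans, couples tinnitus severity to the size of that
shift, and embeds a 50-gene expression component aligned with the
resulting distance-alteration map. The run recovers exactly that: the
two leading gradients carry ~51% of the connectome variance, the
tinnitus-vs-control contrast flags ROI 50, THI scores correlate
negatively with the target ROI's Gradient-2 value, and the PLS1
signature is significant against the permutation null with the planted
gene set top-enriched (NES 2.25, q = 0.012).

The same pipeline is scriptable from the shell:

```sh
corticograd run-all --seed 7 --out-dir scratch/example
corticograd simulate --out-dir inputs --seed 1        # individual stages
corticograd gradients --atlas inputs/atlas.tsv --timeseries inputs/timeseries/vs001_pre.tsv --out emb.tsv
```

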