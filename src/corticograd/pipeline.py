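"""End-to-end study pipeline: simulate → gradients → statistics → clinical
→ prediction → transcriptomics, with all results written as TSV + JSON.

The pipeline consumes a plain-text input manifest (atlas, per-scan time
series, cohort table, optional expression matrix and gene sets) and
writes per-scan aligned embeddings, group-statistic tables, the clinical
summary, the stepwise-prediction report and the PLS/enrichment report
into an output directory. A run summary JSON records the seed and config
hash; rerunning with the same seed and config reproduces it byte for
byte (stage timings go to the log file, which is not part of the
reproducible surface).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, group_stats, prediction, synthetic, transcriptomics
from .connectome import affinity_from_timeseries, compute_fc
from .gradient import build_template, gradient_distance, pca_embedding, procrustes_align
from .io import (AnalysisConfig, Atlas, read_atlas, read_expression, read_gmt,
                 read_timeseries, write_atlas, write_gmt, write_timeseries)

log = logging.getLogger("corticograd")


@dataclass
class InputManifest:
    """Paths to the pipeline's inputs (all plain text)."""

    atlas: Path
    cohort: Path
    timeseries_dir: Path       # one TSV per scan: <subject>_<session>.tsv
    reference_dir: Path        # template scans: ref_<k>.tsv
    expression: Path | None = None
    gene_sets: Path | None = None

    def validate(self) -> None:
        for name in ("atlas", "cohort", "timeseries_dir", "reference_dir"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest input {name!r} missing: {p}")
        for name in ("expression", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"manifest input {name!r} missing: {p}")


def simulate_study(scenario: synthetic.Scenario, out_dir: str | Path) -> InputManifest:
    """Generate a full synthetic study on disk and return its manifest.

    The expression matrix is planted on the *design* difference map (the
    target-ROI indicator) so that downstream transcriptomics has a
    recoverable signal regardless of the imaging-side estimate.
    """
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ref_dir = out / "reference"
    ts_dir.mkdir(parents=True, exist_ok=True)
    ref_dir.mkdir(parents=True, exist_ok=True)

    atlas = synthetic.generate_atlas(scenario.n_roi, seed=scenario.seed)
    write_atlas(atlas, out / "atlas.tsv")
    records, timeseries = synthetic.generate_cohort(atlas, scenario)
    records.to_csv(out / "cohort.tsv", sep="\t", index=False)
    for (sid, session), ts in timeseries.items():
        write_timeseries(ts, ts_dir / f"{sid}_{session}.tsv")
    for k, ts in enumerate(synthetic.generate_reference_timeseries(atlas, scenario)):
        write_timeseries(ts, ref_dir / f"ref_{k + 1:03d}.tsv")

    # planted expression signal on the design-implied distance-alteration map
    diff_map = synthetic.expected_distance_alteration(atlas, scenario)
    expr, planted = synthetic.generate_expression(
        atlas, diff_map, n_genes=scenario.n_genes,
        n_signal_genes=scenario.n_signal_genes,
        noise_sd=scenario.expression_noise_sd, seed=scenario.seed)
    expr.to_csv(out / "expression.tsv", sep="\t")
    rng = np.random.default_rng([scenario.seed, 97])
    sets = dict(planted)
    symbols = list(expr.index)
    for k in range(5):   # background sets for enrichment calibration
        sets[f"random_set_{k + 1}"] = sorted(
            rng.choice(symbols, size=30, replace=False).tolist())
    write_gmt(sets, out / "gene_sets.gmt")
    return InputManifest(
        atlas=out / "atlas.tsv", cohort=out / "cohort.tsv",
        timeseries_dir=ts_dir, reference_dir=ref_dir,
        expression=out / "expression.tsv", gene_sets=out / "gene_sets.gmt")


def _embed_scan(ts: np.ndarray, template, config: AnalysisConfig):
    aff = affinity_from_timeseries(ts, config.threshold_fraction)
    emb = pca_embedding(aff, k=config.n_components)
    aligned, _ = procrustes_align(emb, template)
    return aligned


def run_pipeline(config: AnalysisConfig, manifest: InputManifest,
                 out_dir: str | Path) -> dict:
    """Run every analysis stage; returns the summary dict written to
    ``summary.json``. Any stage failure aborts with the stage name; a
    sentinel file flags partially written output directories."""
    manifest.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sentinel = out / "_INCOMPLETE"
    sentinel.write_text("pipeline in progress; outputs are partial\n")
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.random_seed,
        "stages": {},
    }
    stage = "setup"
    t_start = time.perf_counter()
    try:
        log.info("seed=%s config_hash=%s", config.random_seed, config.config_hash())
        atlas = read_atlas(manifest.atlas)
        records = pd.read_csv(manifest.cohort, sep="\t")

        stage = "template"
        t0 = time.perf_counter()
        ref_ts = [read_timeseries(p, atlas)
                  for p in sorted(Path(manifest.reference_dir).glob("*.tsv"))]
        template = build_template(
            [compute_fc(ts) for ts in ref_ts],
            threshold_fraction=config.threshold_fraction,
            k=config.n_components, reference_id="reference_template")
        log.info("stage=template elapsed=%.2fs", time.perf_counter() - t0)

        stage = "gradients"
        t0 = time.perf_counter()
        emb_dir = out / "embeddings"
        emb_dir.mkdir(exist_ok=True)
        embeddings: dict[tuple[str, str], object] = {}
        for _, row in records.iterrows():
            key = (row["subject_id"], row["session"])
            ts = read_timeseries(
                Path(manifest.timeseries_dir) / f"{key[0]}_{key[1]}.tsv", atlas)
            emb = _embed_scan(ts, template, config)
            embeddings[key] = emb
            df = pd.DataFrame(emb.scores, columns=[f"G{j+1}" for j in range(emb.k)])
            df.insert(0, "roi_id", atlas.roi_ids)
            df["config_hash"] = config.config_hash()
            df.to_csv(emb_dir / f"{key[0]}_{key[1]}_embedding.tsv", sep="\t",
                      index=False, float_format="%.10g")
        var12 = float(np.mean([
            e.variance_explained[:2].sum() for e in embeddings.values()]))
        summary["stages"]["gradients"] = {
            "n_scans": len(embeddings),
            "mean_variance_explained_g1_g2": round(var12, 6),
        }
        log.info("stage=gradients elapsed=%.2fs", time.perf_counter() - t0)

        stage = "group_stats"
        t0 = time.perf_counter()
        def scans(mask):
            sel = records.loc[mask]
            return [embeddings[(r["subject_id"], r["session"])]
                    for _, r in sel.iterrows()]
        hc = scans(records["session"] == "hc")
        vs_pre = scans(records["session"] == "pre")
        vs_post = scans(records["session"] == "post")
        vs_tin = scans((records["group"] == "VS") & records["tinnitus"])
        vs_notin = scans((records["group"] == "VS") & ~records["tinnitus"])
        contrasts = {
            "pre_vs_hc": (vs_pre, hc, False),
            "pre_vs_post": (vs_pre, vs_post, True),
            "tinnitus_vs_hc": (vs_tin, hc, False),
            "tinnitus_vs_no_tinnitus": (vs_tin, vs_notin, False),
        }
        hits: dict[str, dict] = {}
        for name, (ga, gb, paired) in contrasts.items():
            for dim in config.primary_dims:
                res = group_stats.roi_group_test(
                    ga, gb, dim=dim, paired=paired, alpha=config.fdr_alpha,
                    atlas=atlas)
                res["config_hash"] = config.config_hash()
                res.to_csv(out / f"roi_test_{name}_g{dim}.tsv", sep="\t",
                           index=False, float_format="%.10g")
                top = res.loc[res["q"].idxmin()]
                hits[f"{name}_g{dim}"] = {
                    "top_roi": int(top["roi_id"]),
                    "top_t": float(top["t"]),
                    "top_q": float(top["q"]),
                    "n_significant": int(res["significant"].sum()),
                }
        summary["stages"]["group_stats"] = hits
        # seed-distance profile from the most altered tinnitus-contrast ROI
        g2 = config.primary_dims[1]
        target_roi = hits[f"tinnitus_vs_hc_g{g2}"]["top_roi"]
        profile = group_stats.seed_distance_test(
            target_roi, vs_tin, hc, atlas, dims=config.primary_dims,
            alpha=config.fdr_alpha)
        profile.table.to_csv(out / "seed_distance_tinnitus_vs_hc.tsv", sep="\t",
                             index=False, float_format="%.10g")
        summary["stages"]["seed_distance"] = {
            "seed_roi": target_roi,
            "altered_count": profile.altered_count,
            "community_composition": {k: round(v, 4) for k, v in
                                      sorted(profile.community_composition.items())},
        }
        log.info("stage=group_stats elapsed=%.2fs", time.perf_counter() - t0)

        stage = "clinical"
        t0 = time.perf_counter()
        tin_scans = records.loc[(records["group"] == "VS") & records["tinnitus"]].copy()
        thi_scores = [clinical.thi_score(row[synthetic.THI_ITEM_COLUMNS].tolist())
                      for _, row in tin_scans.iterrows()]
        tin_scans["thi_score"] = thi_scores
        tin_scans["thi_level"] = [clinical.thi_level(s) for s in thi_scores]
        tin_scans.to_csv(out / "tinnitus_scans.tsv", sep="\t", index=False)
        target_idx = atlas.index_of(target_roi)
        # orient the feature along the group-shift direction: embedding axis
        # signs are arbitrary, the contrast direction is not. With the shift
        # pointing "down", higher severity means a lower feature value, so
        # the clinical correlations come out negative.
        t_target = float(hits[f"tinnitus_vs_hc_g{g2}"]["top_t"])
        orient = -np.sign(t_target) if t_target != 0 else 1.0
        feature = orient * np.array([
            embeddings[(r["subject_id"], r["session"])].component(g2)[target_idx]
            for _, r in tin_scans.iterrows()])
        assoc = {}
        for measure in ("thi_score", "thi_level", "vas"):
            rho, p = group_stats.spearman_assoc(feature, tin_scans[measure])
            assoc[measure] = {"rho": round(rho, 4), "p": round(p, 6)}
        def _pct(mask):   # half-up to 2 decimals (65.625 -> 65.63)
            x = 100.0 * records.loc[mask, "tinnitus"].mean()
            return float(np.floor(x * 100 + 0.5) / 100)
        prevalence = {
            "pre": _pct(records["session"] == "pre"),
            "post": _pct(records["session"] == "post"),
        }
        summary["stages"]["clinical"] = {
            "tinnitus_prevalence_pct": prevalence,
            "spearman_target_g2": assoc,
        }
        log.info("stage=clinical elapsed=%.2fs", time.perf_counter() - t0)

        stage = "prediction"
        t0 = time.perf_counter()
        feats = pd.DataFrame({f"roi{target_roi}_g{g2}": feature})
        cov = pd.DataFrame({
            "age": tin_scans["age"].to_numpy(dtype=float),
            "sex": (tin_scans["sex"] == "M").to_numpy(dtype=float),
        })
        pred_summary = {}
        for measure in ("vas", "thi_score", "thi_level"):
            rep = prediction.looswr(
                feats, cov, tin_scans[measure].to_numpy(dtype=float),
                alpha_enter=config.alpha_enter, alpha_remove=config.alpha_remove)
            pd.DataFrame({"observed": rep.observed,
                          "predicted": rep.predictions}).to_csv(
                out / f"prediction_{measure}.tsv", sep="\t", index=False,
                float_format="%.10g")
            pred_summary[measure] = {
                "mae": round(rep.mae, 4), "mae_sd": round(rep.mae_sd, 4),
                "r": round(rep.r, 4), "p_r": round(rep.p_r, 6),
                "significant": bool(rep.significant),
                "reliable_features": rep.reliable_features,
            }
        summary["stages"]["prediction"] = pred_summary
        log.info("stage=prediction elapsed=%.2fs", time.perf_counter() - t0)

        if manifest.expression is not None:
            stage = "transcriptomics"
            t0 = time.perf_counter()
            expr = read_expression(manifest.expression, atlas)
            # alteration map = seed-distance t-profile of the target ROI:
            # spatially distributed (a geometric consequence of the shift)
            # and free of embedding-axis sign ambiguity, unlike the
            # single-ROI spike of the ROI-wise t-map
            dist_t = profile.table.set_index("roi_id")["t"]
            tmap = np.array([
                dist_t.get(rid, 0.0) for rid in atlas.roi_ids])
            perm_p, pls = transcriptomics.permutation_test_pls(
                tmap, expr, n_perm=config.n_permutations,
                seed=config.random_seed)
            ranked = transcriptomics.rank_genes(pls)
            ranked["config_hash"] = config.config_hash()
            ranked.to_csv(out / "pls1_gene_ranking.tsv", sep="\t", index=False,
                          float_format="%.10g")
            summary["stages"]["transcriptomics"] = {
                "var_explained_pls1": round(pls.var_explained_pls1, 6),
                "perm_p": round(perm_p, 6),
                "n_perm": config.n_permutations,
                "note": ("permutation null uses uniform ROI shuffles; spatial "
                         "autocorrelation is not preserved"),
            }
            if manifest.gene_sets is not None:
                sets = read_gmt(manifest.gene_sets)
                enr = transcriptomics.gsea(
                    ranked, sets, n_perm=min(config.n_permutations, 999),
                    seed=config.random_seed)
                enr.table.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                                 float_format="%.10g")
                if len(enr.table):
                    top = enr.table.iloc[0]
                    summary["stages"]["transcriptomics"]["top_set"] = {
                        "set": str(top["set"]), "nes": round(float(top["nes"]), 4),
                        "q": round(float(top["q"]), 6),
                    }
            log.info("stage=transcriptomics elapsed=%.2fs", time.perf_counter() - t0)

        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        sentinel.unlink()
        log.info("pipeline complete elapsed=%.2fs", time.perf_counter() - t_start)
        return summary
    except Exception as exc:
        log.error("stage=%s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
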