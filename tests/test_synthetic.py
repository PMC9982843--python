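"""The synthetic-cohort generator: planted structure must be recoverable
by the analysis chain, effects local, coupling monotone, output
deterministic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corticograd import (Scenario, affinity_from_timeseries, generate_atlas,
                         generate_cohort, generate_expression,
                         generate_timeseries, pca_embedding, procrustes_align,
                         roi_group_test)
from corticograd.clinical import thi_score
from corticograd.synthetic import (THI_ITEM_COLUMNS, expected_distance_alteration,
                                   DEFAULT_COMMUNITIES)


class TestGenerateAtlas:
    def test_one_roi_per_community(self):
        atlas = generate_atlas(7)
        assert sorted(atlas.communities) == sorted(DEFAULT_COMMUNITIES)

    def test_deterministic(self):
        a1 = generate_atlas(100, seed=1)
        a2 = generate_atlas(100, seed=1)
        pd.testing.assert_frame_equal(a1.table, a2.table)

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError, match="7"):
            generate_atlas(5)

    def test_contiguous_blocks(self):
        atlas = generate_atlas(100)
        comms = atlas.communities
        changes = sum(comms[i] != comms[i + 1] for i in range(99))
        assert changes == len(DEFAULT_COMMUNITIES) - 1


class TestGenerateTimeseries:
    def test_noiseless_equal_loadings_correlate_perfectly(self, atlas100):
        u = np.ones(100)
        v = np.zeros(100)
        sc = Scenario(seed=0, noise_sd=0.0, latent_u=u, latent_v=v)
        ts = generate_timeseries(atlas100, sc)
        r = np.corrcoef(ts[:, 0], ts[:, 1])[0, 1]
        assert r == pytest.approx(1.0)

    def test_degenerate_loadings_rejected(self, atlas100):
        sc = Scenario(seed=0, latent_u=np.zeros(100), latent_v=np.zeros(100))
        with pytest.raises(ValueError, match="zero"):
            generate_timeseries(atlas100, sc)

    def test_gradient1_recovery_after_alignment(self, atlas100,
                                                default_scenario, template32):
        """Aligned Gradient-1 of every scan tracks the planted first axis."""
        u, _ = default_scenario.loadings(atlas100)
        for j in range(8):
            ts = generate_timeseries(atlas100, default_scenario, stream=j)
            emb = pca_embedding(affinity_from_timeseries(ts), k=10)
            aligned, _ = procrustes_align(emb, template32)
            rho = stats.spearmanr(aligned.component(1), u).statistic
            assert abs(rho) > 0.9

    def test_planted_group_difference_detected(self, atlas100,
                                               default_scenario, template32):
        """Affected vs unaffected groups separate at the target ROI's
        Gradient-2 (two-sample t, p<0.05) in >=80% of repetitions."""
        tgt = atlas100.index_of(default_scenario.resolve_target(atlas100))
        hits = 0
        reps = 10
        for rep in range(reps):
            ga, gb = [], []
            for j in range(16):
                tsa = generate_timeseries(atlas100, default_scenario,
                                          affected=True, seed=50 + rep, stream=j)
                tsb = generate_timeseries(atlas100, default_scenario,
                                          affected=False, seed=50 + rep,
                                          stream=100 + j)
                ea, _ = procrustes_align(
                    pca_embedding(affinity_from_timeseries(tsa), k=10), template32)
                eb, _ = procrustes_align(
                    pca_embedding(affinity_from_timeseries(tsb), k=10), template32)
                ga.append(ea.component(2)[tgt])
                gb.append(eb.component(2)[tgt])
            if stats.ttest_ind(ga, gb, equal_var=False).pvalue < 0.05:
                hits += 1
        assert hits >= 0.8 * reps

    def test_effect_is_local(self, atlas100, default_scenario, template32):
        """Non-target ROIs show no group difference beyond FDR-controlled
        false positives."""
        tgt_roi = default_scenario.resolve_target(atlas100)
        ga, gb = [], []
        for j in range(16):
            tsa = generate_timeseries(atlas100, default_scenario, affected=True,
                                      seed=9, stream=j)
            tsb = generate_timeseries(atlas100, default_scenario, affected=False,
                                      seed=9, stream=100 + j)
            ga.append(procrustes_align(
                pca_embedding(affinity_from_timeseries(tsa), k=10), template32)[0])
            gb.append(procrustes_align(
                pca_embedding(affinity_from_timeseries(tsb), k=10), template32)[0])
        res = roi_group_test(ga, gb, dim=2, atlas=atlas100)
        off_target = res[res["roi_id"] != tgt_roi]
        assert off_target["significant"].sum() <= np.ceil(0.05 * 100)


class TestGenerateCohort:
    def test_prevalence_counts_exact_at_study_size(self, atlas100):
        sc = Scenario(seed=0, n_subjects_per_group=32, n_timepoints=20)
        records, _ = generate_cohort(atlas100, sc)
        pre = records[records["session"] == "pre"]
        post = records[records["session"] == "post"]
        assert pre["tinnitus"].sum() == 18      # 56.25% of 32
        assert post["tinnitus"].sum() == 21     # 65.63% of 32

    def test_same_seed_identical_records(self, atlas100):
        sc = Scenario(seed=5, n_subjects_per_group=4, n_timepoints=20)
        r1, ts1 = generate_cohort(atlas100, sc)
        r2, ts2 = generate_cohort(atlas100, sc)
        pd.testing.assert_frame_equal(r1, r2)
        for key in ts1:
            assert np.array_equal(ts1[key], ts2[key])

    def test_hc_never_has_tinnitus_and_vas_iff_tinnitus(self, atlas100):
        sc = Scenario(seed=2, n_subjects_per_group=8, n_timepoints=20)
        records, _ = generate_cohort(atlas100, sc)
        hc = records[records["group"] == "HC"]
        assert not hc["tinnitus"].any()
        assert records.loc[records["tinnitus"], "vas"].notna().all()
        assert records.loc[~records["tinnitus"], "vas"].isna().all()

    def test_thi_items_valid_for_tinnitus_scans(self, atlas100):
        sc = Scenario(seed=3, n_subjects_per_group=8, n_timepoints=20)
        records, _ = generate_cohort(atlas100, sc)
        for _, row in records[records["tinnitus"]].iterrows():
            items = [int(row[c]) for c in THI_ITEM_COLUMNS]
            score = thi_score(items)   # validates the 0/2/4 item set
            assert 0 <= score <= 100

    def test_null_coupling_breaks_clinical_association(self, atlas100):
        """coupling=0 severs severity from the planted shift, so the THI
        score is independent of the gradient-relevant ground truth."""
        assert _shift_association(atlas100, coupling=0.0) < 0.2

    def test_coupling_monotone(self, atlas100):
        """Stronger coupling yields a stronger (absolute) THI-shift
        association on average."""
        r0 = _shift_association(atlas100, coupling=0.0)
        r1 = _shift_association(atlas100, coupling=0.7)
        r2 = _shift_association(atlas100, coupling=2.0)
        assert r0 < r1 < r2


def _shift_association(atlas, coupling, seeds=range(4)) -> float:
    """Mean |Spearman| between THI score and the planted target-ROI shift
    (generator ground truth). severity_noise_sd is widened so THI scores
    retain variation even when the coupling is switched off."""
    vals = []
    for seed in seeds:
        sc = Scenario(seed=seed, coupling=coupling, n_subjects_per_group=48,
                      n_timepoints=20, severity_noise_sd=0.5)
        records, _ = generate_cohort(atlas, sc)
        tin = records[records["tinnitus"] & (records["session"] == "pre")]
        scores = np.array([thi_score([int(r[c]) for c in THI_ITEM_COLUMNS])
                           for _, r in tin.iterrows()])
        shift = tin["planted_shift"].to_numpy()
        if np.ptp(scores) == 0 or np.ptp(shift) == 0:
            continue
        vals.append(abs(stats.spearmanr(scores, shift).statistic))
    return float(np.mean(vals))


class TestGenerateExpression:
    def test_deterministic(self, atlas100):
        dmap = np.zeros(100)
        dmap[49] = -1
        e1, s1 = generate_expression(atlas100, dmap, seed=4)
        e2, s2 = generate_expression(atlas100, dmap, seed=4)
        pd.testing.assert_frame_equal(e1, e2)
        assert s1 == s2

    def test_planted_set_and_shapes(self, atlas100):
        dmap = np.sin(np.linspace(0, 2 * np.pi, 100))
        expr, sets = generate_expression(atlas100, dmap, n_genes=200,
                                         n_signal_genes=20, seed=0)
        assert expr.shape == (200, 100)
        assert len(sets["planted_signal"]) == 20

    def test_signal_genes_track_map(self, atlas100):
        dmap = np.sin(np.linspace(0, 2 * np.pi, 100))
        expr, sets = generate_expression(atlas100, dmap, n_genes=100,
                                         n_signal_genes=10, noise_sd=0.1, seed=1)
        for g in sets["planted_signal"]:
            r = np.corrcoef(expr.loc[g], dmap)[0, 1]
            assert r > 0.9

    def test_map_length_validated(self, atlas100):
        with pytest.raises(ValueError, match="length"):
            generate_expression(atlas100, np.zeros(99), seed=0)


def test_expected_distance_alteration_is_distributed(atlas100, default_scenario):
    """The design-implied distance-alteration map is smooth and nonzero for
    most ROIs (it is the geometric footprint of the target shift)."""
    dmap = expected_distance_alteration(atlas100, default_scenario)
    tgt = atlas100.index_of(default_scenario.resolve_target(atlas100))
    assert dmap[tgt] == 0.0
    assert (np.abs(np.delete(dmap, tgt)) > 1e-6).mean() > 0.9
    assert np.abs(np.diff(np.delete(dmap, tgt))).max() < 0.2  # smooth


def test_distance_alteration_geometry(atlas100, default_scenario):
    """A downward shift of the target along the second axis increases the
    distance to ROIs on the opposite side of that axis and decreases it on
    the same side: the sign of the alteration tracks the ROI's position in
    the planted plane."""
    dmap = expected_distance_alteration(atlas100, default_scenario)
    _, v = default_scenario.loadings(atlas100)
    tgt = atlas100.index_of(default_scenario.resolve_target(atlas100))
    keep = np.arange(100) != tgt
    rel = v[keep] - v[tgt]
    assert np.corrcoef(dmap[keep], rel)[0, 1] > 0.9


def test_planted_gene_set_recovered_across_seeds(atlas100, default_scenario):
    """The planted expression component is flagged at FDR q < 0.05 in at
    least 90% of seeds when the measured map is a noisy version of the
    design alteration profile."""
    from corticograd.transcriptomics import gsea, plsr_spatial, rank_genes
    base = expected_distance_alteration(atlas100, default_scenario)
    hits = 0
    seeds = range(10)
    for seed in seeds:
        rng_ = np.random.default_rng(seed)
        tmap = 6 * base + rng_.normal(0, 1, 100)   # t-map scale noise
        expr, planted = generate_expression(atlas100, base, n_genes=300,
                                            n_signal_genes=30, seed=seed)
        ranked = rank_genes(plsr_spatial(tmap, expr))
        sets = dict(planted)
        for k in range(5):
            sets[f"bg{k}"] = list(rng_.choice(expr.index, 30, replace=False))
        res = gsea(ranked, sets, n_perm=199, seed=seed)
        row = res.table.set_index("set").loc["planted_signal"]
        if row["q"] < 0.05:
            hits += 1
    assert hits >= 0.9 * len(seeds)
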