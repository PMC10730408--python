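"""Generative model: determinism, closed-form recovery, trajectory fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larvascreen.metrics import metrics_from_trajectories
from larvascreen.synth import (
    BehaviorParams,
    CohortConfig,
    GENOTYPES,
    _poisson_binomial_pmf,
    default_behavior_params,
    expected_metric_means,
    recover_parameters,
    simulate_cohort,
    simulate_latent,
    simulate_metric_matrix,
)


def _uniform_params(**overrides):
    bp = default_behavior_params(**overrides)
    return {g: bp for g in GENOTYPES}


class TestValidation:
    def test_probabilities_checked(self):
        with pytest.raises(ValueError):
            BehaviorParams(ppi_strength=1.5)

    def test_latency_ordering_checked(self):
        with pytest.raises(ValueError):
            BehaviorParams(latency_params={
                "slc": (30.0, 2.0, 4.0, 60.0), "llc": (25.0, 12.0, 22.0, 150.0),
                "obend": (60.0, 15.0, 22.0, 600.0),
                "react": (50.0, 15.0, 22.0, 350.0)})

    def test_seed_required(self):
        with pytest.raises(ValueError):
            CohortConfig(n_larvae=5).rng()

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(genotype_proportions={"wt": 0.5, "mut": 0.2})


class TestDeterminism:
    def test_latent_tables_identical_for_same_seed(self, protocol):
        a = simulate_latent(CohortConfig(n_larvae=8, seed=42), protocol)
        b = simulate_latent(CohortConfig(n_larvae=8, seed=42), protocol)
        pd.testing.assert_frame_equal(a.stimulus_table, b.stimulus_table)
        pd.testing.assert_frame_equal(a.bout_table, b.bout_table)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_trajectories_bitwise_identical_for_same_seed(self, protocol):
        segs_a, _, _ = simulate_cohort(CohortConfig(n_larvae=1, seed=9), protocol)
        segs_b, _, _ = simulate_cohort(CohortConfig(n_larvae=1, seed=9), protocol)
        assert len(segs_a) == len(segs_b)
        for sa, sb in zip(segs_a, segs_b):
            assert sa.segment_id == sb.segment_id
            np.testing.assert_array_equal(sa.xy, sb.xy)
            if sa.tail is not None:
                np.testing.assert_array_equal(sa.tail, sb.tail)

    def test_metric_matrix_identical_for_same_seed(self, protocol):
        m1, _, _ = simulate_metric_matrix(CohortConfig(n_larvae=6, seed=3), protocol)
        m2, _, _ = simulate_metric_matrix(CohortConfig(n_larvae=6, seed=3), protocol)
        pd.testing.assert_frame_equal(m1, m2)


class TestDegenerateConditions:
    def test_certain_responder_never_misses(self, protocol):
        params = _uniform_params(
            p_respond={"dark_flash": 1.0, "light_flash": 1.0},
            sensitivity_curve={"low": 1.0, "medium": 1.0, "high": 1.0},
            habituation_rate=0.0, ppi_strength=0.0,
            p_obend_given_response=1.0, p_slc_given_response=1.0)
        cfg = CohortConfig(n_larvae=5, seed=7, params=params)
        m, _, gt = simulate_metric_matrix(cfg, protocol)
        assert gt.stimulus_table["responded"].all()
        assert (m["df_freq_obend"] == 1.0).all()
        assert (m["asr_freq_slc"] == 1.0).all()
        assert (m["lf_freq_react"] == 1.0).all()
        assert (m["asr_habituation_slc"] == 0.0).all()
        assert (m["asr_ppi"] == 0.0).all()

    def test_zero_habituation_centers_index_near_zero(self, protocol):
        # with no decay the index centers on the small negative ratio-estimator
        # bias (E[1/B] > 1/E[B]); check both the enumeration and the proximity
        # of the observed mean to it
        bp = default_behavior_params(habituation_rate=0.0, ppi_strength=0.0)
        params = {g: bp for g in GENOTYPES}
        cfg = CohortConfig(n_larvae=120, seed=5, params=params)
        m, _, _ = simulate_metric_matrix(cfg, protocol)
        expected = expected_metric_means(bp, protocol)["asr_habituation_slc"]
        assert abs(expected) < 0.05
        assert m["asr_habituation_slc"].mean() == pytest.approx(expected, abs=0.05)


class TestClosedFormRecovery:
    def test_per_stimulus_habituation_decay(self, protocol):
        # 500 larvae, geometric decay h=0.5 across the DF train: empirical
        # per-stimulus response frequency matches p (1-h)^(k-1)
        h, p = 0.5, 0.95
        params = _uniform_params(habituation_rate=h)
        gt = simulate_latent(CohortConfig(n_larvae=500, seed=13, params=params),
                             protocol)
        df = gt.stimulus_table[gt.stimulus_table["assay"] == "DF"]
        freq = df.groupby("stim_index")["responded"].mean()
        order = np.argsort(freq.index.to_numpy())
        for rank, k in enumerate(freq.index.to_numpy()[order][:14], start=1):
            expect = p * (1 - h) ** (rank - 1)
            se = np.sqrt(max(expect * (1 - expect), 1e-4) / 500)
            assert abs(freq[k] - expect) < 4 * se + 0.005

    def test_ppi_estimator_expectation(self, protocol):
        # baseline response certainty makes E[PPI metric] = ppi_strength
        params = _uniform_params(
            sensitivity_curve={"low": 0.1, "medium": 0.5, "high": 1.0},
            p_slc_given_response=1.0, habituation_rate=0.0, ppi_strength=0.6)
        cfg = CohortConfig(n_larvae=400, seed=21, params=params)
        m, _, _ = simulate_metric_matrix(cfg, protocol)
        se = np.sqrt(0.6 * 0.4 / 10 / 400)
        assert m["asr_ppi"].mean() == pytest.approx(0.6, abs=4 * se + 0.01)

    def test_bout_count_poisson_expectation(self, protocol):
        gt = simulate_latent(CohortConfig(n_larvae=200, seed=2), protocol)
        counts = gt.bout_table.groupby(["larva_id", "phase"]).size().unstack()
        bp = default_behavior_params()
        for phase in ("light", "dark"):
            expect = bp.bout_rate_per_min[phase] * 8.0
            se = np.sqrt(expect / 200)
            assert abs(counts[phase].mean() - expect) < 4 * se

    def test_recover_parameters_report(self, protocol):
        cfg = CohortConfig(n_larvae=150, seed=31)
        m, _, gt = simulate_metric_matrix(cfg, protocol)
        rep = recover_parameters(m, gt, "het")
        assert {"estimate", "expected", "bias", "se", "n"} <= set(rep.columns)
        # stochastic but tight at this n: all recovery targets within 4 SE
        assert (rep["bias"].abs() <= (4 * rep["se"]).clip(lower=0.02)).all()


class TestLatentClassSeparation:
    def test_classification_recovers_latent_class(self, protocol):
        gt = simulate_latent(CohortConfig(n_larvae=100, seed=17), protocol)
        from larvascreen.synth import _events_for_larva
        from larvascreen.kinematics import KinematicThresholds
        hits = total = 0
        recorded = {
            assay: {i for i, e in enumerate(protocol.block(assay).events)
                    if e.recorded}
            for assay in ("LF", "DF", "ASR")}
        for lid, sub in gt.stimulus_table.groupby("larva_id"):
            events = _events_for_larva(sub, protocol, KinematicThresholds())
            for assay in events:
                block_rows = sub[(sub["assay"] == assay)
                                 & sub["stim_index"].isin(recorded[assay])]
                for ev, row in zip(events[assay], block_rows.itertuples()):
                    assert ev.stimulus is protocol.block(assay).events[row.stim_index]
                    if row.responded:
                        total += 1
                        hits += ev.label == row.resp_class
        assert total > 5000
        assert hits / total > 0.99

    def test_slc_llc_latency_separation(self, protocol):
        gt = simulate_latent(CohortConfig(n_larvae=50, seed=23), protocol)
        st_tab = gt.stimulus_table
        slc = st_tab.loc[st_tab["resp_class"] == "slc", "latency_ms"]
        llc = st_tab.loc[st_tab["resp_class"] == "llc", "latency_ms"]
        assert slc.max() < 20.0
        assert llc.min() > 20.0


class TestGenotypeDraws:
    def test_proportions_converge(self):
        # chi-square goodness of fit not rejected at alpha=0.01, 20 seeds;
        # a stimulus-free protocol and zero bout rates isolate genotype draws
        from larvascreen.protocol import AssayBlock, Protocol

        skinny = Protocol(blocks=[
            AssayBlock(a, 500.0, 200.0, events=[])
            for a in ("LF", "DF", "ASR")])
        quiet = _uniform_params(bout_rate_per_min={"light": 0.0, "dark": 0.0})
        rejections = 0
        for seed in range(20):
            gt = simulate_latent(
                CohortConfig(n_larvae=2000, seed=100 + seed, params=quiet),
                skinny)
            obs = gt.genotypes["genotype"].value_counts()
            exp = pd.Series({"wt": 500.0, "het": 1000.0, "mut": 500.0})
            chi2 = float((((obs - exp) ** 2) / exp).sum())
            if stats.chi2.sf(chi2, df=2) < 0.01:
                rejections += 1
        assert rejections <= 2

    def test_mendelian_default(self):
        cfg = CohortConfig(seed=1)
        assert cfg.genotype_proportions == {"wt": 0.25, "het": 0.5, "mut": 0.25}


class TestPoissonBinomial:
    def test_matches_binomial_for_equal_probabilities(self):
        pmf = _poisson_binomial_pmf(np.full(10, 0.3))
        expect = stats.binom.pmf(np.arange(11), 10, 0.3)
        np.testing.assert_allclose(pmf, expect, atol=1e-12)

    def test_heterogeneous_probabilities_against_enumeration(self, rng):
        ps = rng.uniform(0, 1, 6)
        pmf = _poisson_binomial_pmf(ps)
        brute = np.zeros(7)
        for bits in range(64):
            prob = 1.0
            k = 0
            for i in range(6):
                if bits >> i & 1:
                    prob *= ps[i]
                    k += 1
                else:
                    prob *= 1 - ps[i]
            brute[k] += prob
        np.testing.assert_allclose(pmf, brute, atol=1e-12)


class TestEndToEndTrajectories:
    def test_trajectory_pipeline_matches_latent_ground_truth(self, protocol):
        cfg = CohortConfig(n_larvae=2, seed=11)
        segs, geno, gt = simulate_cohort(cfg, protocol)
        by_larva = {}
        for s in segs:
            by_larva.setdefault(s.larva_id, {})[s.segment_id] = s
        st_tab = gt.stimulus_table
        for lid, seg_map in by_larva.items():
            vec = metrics_from_trajectories(seg_map, protocol)
            sub = st_tab[st_tab["larva_id"] == lid]
            recorded_df = sub[(sub["assay"] == "DF") & sub["block_id"].isin(
                ["df_block1", "df_block3", "df_block5"])]
            expect_obend = ((recorded_df["responded"])
                            & (recorded_df["resp_class"] == "obend")).mean()
            assert vec["df_freq_obend"] == pytest.approx(expect_obend)
            n_dark = ((gt.bout_table["larva_id"] == lid)
                      & (gt.bout_table["phase"] == "dark")).sum()
            assert vec["vmr_light_off_full_n_bouts"] == pytest.approx(n_dark, abs=1)
            assert len(vec) == 94

    def test_peak_curvature_recovered_exactly_from_poses(self, protocol):
        cfg = CohortConfig(n_larvae=1, seed=19)
        segs, _, gt = simulate_cohort(cfg, protocol)
        st_tab = gt.stimulus_table
        checked = 0
        for s in segs:
            if ":" not in s.segment_id:
                continue
            assay, idx = s.segment_id.split(":")
            row = st_tab[(st_tab["larva_id"] == s.larva_id)
                         & (st_tab["assay"] == assay)
                         & (st_tab["stim_index"] == int(idx))]
            if len(row) and row["responded"].iloc[0]:
                from larvascreen.tracking import compute_curvature
                peak = max(compute_curvature(np.vstack([s.xy[i], s.tail[i]]))
                           for i in range(s.n_frames))
                assert peak == pytest.approx(
                    row["peak_curvature_rad"].iloc[0], abs=1e-9)
                checked += 1
        assert checked > 20
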