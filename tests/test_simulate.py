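import numpy as np
import pytest

import sfcoupling as sfc
from sfcoupling import (
    Scenario,
    SimConfig,
    calibrate_copula,
    make_base_topology,
    simulate_cohort,
    simulate_fc_given_sc,
    simulate_sc,
    target_coupling,
)
from sfcoupling.coupling import regional_coupling


class TestSimulateCohort:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_adhd=10, n_control=10, n_nodes=8, seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimConfig(n_adhd=10, n_control=10, n_nodes=8, seed=5))
        assert a == b
        c = simulate_cohort(SimConfig(n_adhd=10, n_control=10, n_nodes=8, seed=6))
        assert a != c

    def test_full_retention_gives_all_waves(self):
        cfg = SimConfig(retention=1.0, n_nodes=8, seed=1)
        recs = simulate_cohort(cfg)
        assert len(recs) == 175 * 3

    def test_replicate_mean_matches_truncated_binomial_expectation(self):
        # attendance ~ Binomial(3, r) conditioned on >= 1:
        # E[scans] = n * 3r / (1 - (1-r)^3)
        cfg0 = SimConfig(n_nodes=8, seed=0)
        r, n_subj, w = cfg0.retention, 175, 3
        expect = n_subj * w * r / (1.0 - (1.0 - r) ** w)
        totals = [
            len(simulate_cohort(SimConfig(n_nodes=8, seed=s)))
            for s in range(200)
        ]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expect) < 3 * se

    def test_default_expected_size_near_study_sample(self):
        cfg = SimConfig(n_nodes=8, seed=0)
        expect = 175 * 3 * cfg.retention / (1 - (1 - cfg.retention) ** 3)
        assert abs(expect - 278) < 5

    def test_scanner_upgrade_at_wave3_only(self):
        recs = simulate_cohort(SimConfig(n_nodes=8, seed=2))
        for r in recs:
            assert (r.scanner == "post_upgrade") == (r.wave == 3)

    def test_controls_never_medicated(self):
        recs = simulate_cohort(SimConfig(n_nodes=8, seed=3))
        assert not any(r.medicated for r in recs if r.group == "control")

    def test_ages_increase_across_waves(self):
        recs = simulate_cohort(SimConfig(n_nodes=8, seed=4))
        by_subj = {}
        for r in recs:
            by_subj.setdefault(r.subject_id, []).append((r.wave, r.age))
        for waves in by_subj.values():
            waves.sort()
            ages = [a for _, a in waves]
            assert all(b > a for a, b in zip(ages, ages[1:]))


class TestBaseTopology:
    def test_density_matches_request(self, rng):
        base = make_base_topology(360, density=0.25, seed=9)
        iu = np.triu_indices(360, 1)
        frac = (base.weights[iu] > 0).mean()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_seeded_determinism(self):
        a = make_base_topology(60, 0.3, seed=4)
        b = make_base_topology(60, 0.3, seed=4)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_valid_structural_connectome(self):
        base = make_base_topology(60, 0.3, seed=4)
        base.validate()
        assert np.all(base.weights >= 0)

    def test_connected(self):
        from scipy.sparse.csgraph import connected_components
        base = make_base_topology(80, 0.1, seed=7)
        n_comp, _ = connected_components((base.weights > 0).astype(np.int8),
                                         directed=False)
        assert n_comp == 1


class TestSimulateSc:
    def test_degenerate_noise_reproduces_base(self):
        base = make_base_topology(40, 0.3, seed=3)
        out = simulate_sc(base, subject_sigma=0.0, dropout=0.0, rng=1)
        np.testing.assert_array_equal(out.weights, base.weights)

    def test_dropout_fraction_binomial(self):
        base = make_base_topology(80, 0.35, seed=3)
        iu = np.triu_indices(80, 1)
        n_edges = int((base.weights[iu] > 0).sum())
        out = simulate_sc(base, 0.0, dropout=0.1, rng=2)
        zeroed = n_edges - int((out.weights[iu] > 0).sum())
        sd = np.sqrt(n_edges * 0.1 * 0.9)
        assert abs(zeroed - 0.1 * n_edges) < 4 * sd

    def test_edge_cv_increases_with_subject_sigma(self):
        from sfcoupling import edge_cv
        base = make_base_topology(30, 0.4, seed=5)
        iu = np.triu_indices(30, 1)
        present = base.weights[iu] > 0
        med_cv = []
        for sigma in (0.1, 0.3, 0.6):
            rng = np.random.default_rng(11)
            scans = [simulate_sc(base, sigma, 0.0, rng) for _ in range(50)]
            cv = edge_cv(scans)[iu][present]
            med_cv.append(np.median(cv))
        assert med_cv[0] < med_cv[1] < med_cv[2]


class TestTargetCoupling:
    def test_null_constant(self):
        s = Scenario(kind="null", base_rho=0.3)
        assert target_coupling(s, "adhd", 13.0) == 0.3

    def test_increasing_linear(self):
        s = Scenario(kind="increasing", base_rho=0.2, slope_control=0.04)
        assert target_coupling(s, "control", 14.0) == pytest.approx(0.40)

    def test_plateau_flat_after_knee(self):
        s = Scenario(kind="increase_then_plateau", plateau_age=12.0)
        assert target_coupling(s, "control", 13.0) == target_coupling(
            s, "control", 12.0)

    def test_group_offset_and_interaction(self):
        off = Scenario(kind="group_offset", base_rho=0.3, offset_adhd=-0.1)
        assert target_coupling(off, "adhd", 10.0) == pytest.approx(0.2)
        assert target_coupling(off, "control", 10.0) == pytest.approx(0.3)
        gxa = Scenario(kind="group_by_age", base_rho=0.2, slope_adhd=0.05)
        assert target_coupling(gxa, "control", 14.0) == pytest.approx(0.2)
        assert target_coupling(gxa, "adhd", 14.0) == pytest.approx(0.45)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            Scenario(kind="exploding")


class TestCalibrateCopula:
    def test_zero_maps_to_zero(self):
        assert calibrate_copula(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert calibrate_copula(0.5) == pytest.approx(2 * np.sin(np.pi / 12))

    def test_limit_toward_one(self):
        assert calibrate_copula(1 - 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calibrate_copula(1.0)

    def test_gaussian_copula_relation_monte_carlo(self, rng):
        # bivariate normal with r = calibrate(0.5) has Spearman rho ~ 0.5
        from scipy.stats import spearmanr
        r = calibrate_copula(0.5)
        z1 = rng.standard_normal(200_000)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(200_000)
        assert spearmanr(z1, z2).statistic == pytest.approx(0.5, abs=0.01)


class TestSimulateFcGivenSc:
    def test_near_unit_targets_give_strong_coupling(self):
        base = make_base_topology(60, 0.4, seed=8)
        sc = simulate_sc(base, 0.3, 0.02, rng=3)
        fc = simulate_fc_given_sc(sc, np.full(60, 0.98), rng=4)
        rho = regional_coupling(sc, fc).rho
        assert np.nanmean(rho) > 0.8
        assert np.nanmin(rho) > 0.5

    def test_null_targets_centred_on_zero(self):
        base = make_base_topology(360, 0.35, seed=8)
        sc = simulate_sc(base, 0.3, 0.02, rng=5)
        fc = simulate_fc_given_sc(sc, np.zeros(360), rng=6)
        rho = regional_coupling(sc, fc).rho
        assert abs(np.nanmean(rho)) < 0.05

    def test_monotone_fidelity(self):
        # expected measured coupling strictly increases with the planted target
        base = make_base_topology(40, 0.4, seed=12)
        means = []
        rng = np.random.default_rng(13)
        for t in (0.1, 0.3, 0.6):
            vals = []
            for _ in range(100):
                sc = simulate_sc(base, 0.3, 0.02, rng)
                fc = simulate_fc_given_sc(sc, np.full(40, t), rng)
                vals.append(np.nanmean(regional_coupling(sc, fc).rho))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_valid_functional_connectome(self):
        base = make_base_topology(30, 0.4, seed=2)
        sc = simulate_sc(base, 0.3, 0.05, rng=1)
        fc = simulate_fc_given_sc(sc, np.full(30, 0.4), rng=2)
        fc.validate()

    def test_targets_out_of_range_rejected(self):
        base = make_base_topology(10, 0.5, seed=2)
        with pytest.raises(ValueError):
            simulate_fc_given_sc(base, np.ones(10), rng=0)


class TestScenarioSeparability:
    def test_wave3_minus_wave1_coupling_by_scenario(self, small_study):
        import pandas as pd
        kinds = small_study.scenario_kinds()
        rows = []
        for k, (rec, sc, fc) in enumerate(small_study.scans):
            rho = regional_coupling(sc, fc).rho
            for i in range(small_study.config.n_nodes):
                rows.append((rec.wave, kinds[i], rho[i]))
        df = pd.DataFrame(rows, columns=["wave", "kind", "rho"]).dropna()
        byw = df.groupby(["kind", "wave"])["rho"].mean().unstack()
        assert byw.loc["increasing", 3] - byw.loc["increasing", 1] > 0.05
        assert abs(byw.loc["null", 3] - byw.loc["null", 1]) < 0.04


class TestSimulatedStudy:
    def test_dataset_determinism(self):
        cfg = dict(n_adhd=4, n_control=4, n_nodes=16, seed=9)
        a = sfc.simulate_dataset(SimConfig(**cfg))
        b = sfc.simulate_dataset(SimConfig(**cfg))
        assert len(a.scans) == len(b.scans)
        for (r1, s1, f1), (r2, s2, f2) in zip(a.scans, b.scans):
            assert r1 == r2
            np.testing.assert_array_equal(s1.weights, s2.weights)
            np.testing.assert_array_equal(f1.weights, f2.weights)
        np.testing.assert_array_equal(a.planted, b.planted)

    def test_ground_truth_serializable(self, small_study):
        import json
        gt = small_study.ground_truth()
        payload = json.loads(json.dumps(gt))
        assert set(payload) == {"scenario_map", "planted_targets"}
        assert len(payload["scenario_map"]) == small_study.config.n_nodes
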