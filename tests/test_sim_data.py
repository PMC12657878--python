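import numpy as np
import pytest

from knockoffml.sim_data import (
    CovarianceSpec,
    SimulationScenario,
    build_covariance,
    choose_risk_features,
    default_covariance,
    draw_design,
    read_dataset,
    scenario_from_yaml,
    scenario_to_yaml,
    simulate_dataset,
    simulate_outcome,
    with_seed,
    write_dataset,
)


class TestBuildCovariance:
    def test_identity_when_no_correlation(self):
        sigma = build_covariance(CovarianceSpec(p=3, background_rho=0.0))
        assert np.array_equal(sigma, np.eye(3))

    def test_single_group_eigenvalues(self):
        # equicorrelated 3x3 with rho=0.5: eigenvalues {2, 0.5, 0.5}
        spec = CovarianceSpec(
            p=3, groups=((0, 1, 2),), within_group_rho=0.5, background_rho=0.0
        )
        sigma = build_covariance(spec)
        off = sigma[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.5)
        assert np.min(np.linalg.eigvalsh(sigma)) == pytest.approx(0.5)

    def test_singular_parameters_rejected(self):
        with pytest.raises(ValueError, match="background_rho"):
            build_covariance(CovarianceSpec(p=2, background_rho=1.0))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CovarianceSpec(p=6, groups=((0, 1, 2), (2, 3, 4)))


class TestDrawDesign:
    def test_binary_column_balanced(self, small_cov, rng):
        X = draw_design(small_cov, 4000, rng)
        # symmetric Gaussian cut at zero: mean 0.5 within 3 binomial SEs
        se = 0.5 / np.sqrt(4000)
        for col in sorted(X.binary):
            assert abs(X.frame[col].mean() - 0.5) < 3 * se
            assert set(X.frame[col].unique()) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, small_cov):
        a = draw_design(small_cov, 50, np.random.default_rng(3))
        b = draw_design(small_cov, 50, np.random.default_rng(3))
        assert a.frame.equals(b.frame)

    def test_default_study_shape(self):
        X = draw_design(default_covariance(), 10_000, np.random.default_rng(0))
        assert X.frame.shape == (10_000, 88)
        assert len(X.binary) == 20
        assert len(X.groups) == 20

    def test_large_sample_covariance_converges(self):
        spec = CovarianceSpec(
            p=9,
            groups=((0, 1, 2),),
            within_group_rho=0.5,
            background_rho=0.1,
        )
        X = draw_design(spec, 50_000, np.random.default_rng(5))
        emp = np.cov(X.values, rowvar=False)
        assert np.max(np.abs(emp - build_covariance(spec))) < 0.05


class TestChooseRiskFeatures:
    def test_group_membership_expands(self, small_cov):
        for seed in range(12):
            risk = choose_risk_features(
                small_cov, 2, np.random.default_rng(seed)
            )
            for g in small_cov.groups:
                drawn = set(g) & set(risk)
                assert drawn in (set(), set(g))

    def test_singletons_only(self):
        spec = CovarianceSpec(p=8)
        risk = choose_risk_features(spec, 4, np.random.default_rng(0))
        assert len(risk) == 4

    def test_deterministic(self, small_cov):
        a = choose_risk_features(small_cov, 2, np.random.default_rng(9))
        b = choose_risk_features(small_cov, 2, np.random.default_rng(9))
        assert a == b

    def test_binary_columns_excluded_by_default(self, small_cov):
        for seed in range(10):
            risk = choose_risk_features(
                small_cov, 4, np.random.default_rng(seed)
            )
            assert not set(risk) & set(small_cov.binary_columns)

    def test_too_many_groups_rejected(self, small_cov):
        # 2 groups + 4 continuous singletons are selectable
        with pytest.raises(ValueError, match="exceeds"):
            choose_risk_features(small_cov, 7, np.random.default_rng(0))


class TestSimulateOutcome:
    def test_null_effects_hit_baseline_rate(self, small_cov):
        scen = SimulationScenario(
            trait="dichotomous",
            n=50_000,
            cov=small_cov,
            beta_first=0.0,
            beta_rest=0.0,
            calibration_n=100_000,
            seed=1,
        )
        ds = simulate_dataset(scen)
        se = np.sqrt(0.162 * 0.838 / 50_000)
        assert abs(ds.y.mean() - 0.162) < 4 * se

    def test_marginal_calibration_with_effects(self, small_cov):
        scen = SimulationScenario(
            trait="dichotomous",
            n=50_000,
            cov=small_cov,
            n_risk_groups=2,
            calibration_n=1_000_000,
            seed=2,
        )
        ds = simulate_dataset(scen)
        assert abs(ds.y.mean() - 0.162) < 0.01

    def test_linear_quantitative_variance_decomposition(self):
        # four uncorrelated standardized risk features, beta = +-1.5:
        # var(signal) = 4 * 2.25 = 9, so R^2 = 9/10
        spec = CovarianceSpec(p=6, background_rho=0.0)
        scen = SimulationScenario(
            trait="quantitative", link="linear", n=60_000, cov=spec, seed=3
        )
        ds = simulate_dataset(scen)
        assert len(ds.risk_set) == 4
        S = ds.X.values[:, np.array(ds.risk_set)]
        beta = np.array([-1.5, 1.5, 1.5, 1.5])
        signal = S @ beta
        r2 = np.var(signal) / np.var(ds.y)
        assert r2 == pytest.approx(0.9, abs=0.02)

    def test_noiseless_limit(self, small_cov):
        scen = SimulationScenario(
            trait="quantitative",
            link="quadratic",
            n=200,
            cov=small_cov,
            n_risk_groups=1,
            noise_sd=1e-10,
            seed=4,
        )
        ds = simulate_dataset(scen)
        S = ds.X.values[:, np.array(ds.risk_set)]
        beta = np.full(len(ds.risk_set), 1.5)
        beta[0] = -1.5
        np.testing.assert_allclose(ds.y, (S**2) @ beta, atol=1e-8)

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError, match="link"):
            SimulationScenario(link="cubic")

    def test_replicates_bit_identical(self, small_scenario):
        a = simulate_dataset(small_scenario)
        b = simulate_dataset(with_seed(small_scenario, small_scenario.seed))
        assert a.X.frame.equals(b.X.frame)
        assert np.array_equal(a.y, b.y)
        assert a.risk_set == b.risk_set


class TestSerialization:
    def test_scenario_yaml_roundtrip(self, small_scenario, tmp_path):
        path = tmp_path / "scenario.yaml"
        scenario_to_yaml(small_scenario, path)
        assert scenario_from_yaml(path) == small_scenario

    def test_dataset_csv_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "data.csv"
        write_dataset(small_dataset, path)
        back = read_dataset(path)
        assert back.risk_set == small_dataset.risk_set
        assert back.X.binary == small_dataset.X.binary
        np.testing.assert_allclose(back.y, small_dataset.y)
        np.testing.assert_allclose(
            back.X.values, small_dataset.X.values, atol=1e-12
        )
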