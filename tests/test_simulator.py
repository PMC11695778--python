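import numpy as np
import pytest
from dins import (
    DomainError,
    ScenarioConfig,
    alternative_latent_and_error_draws,
    apply_general_dins,
    apply_missingness,
    apply_random_dins,
    apply_systematic_dins,
    heteroskedastic_sds,
    simulate_comparison,
    simulate_zeta_distribution,
    zeta_batch,
    zeta_full,
)
from dins.simulator import _simulate_batch, _systematic_dins_multipliers

from conftest import make_balanced


class TestScenarioConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"scenario": 6},
            {"n": 1},
            {"eta": 0.0},
            {"p": 1.5},
            {"m_max": -1.0},
            {"M": -0.1},
            {"scenario": 4, "q_lower": 0.2, "q_upper": 0.9},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(DomainError):
            ScenarioConfig(**kw)

    def test_json_roundtrip(self):
        cfg = ScenarioConfig(scenario=3, p=0.3, m_max=5.0, seed=9)
        assert ScenarioConfig.from_json(cfg.to_json()) == cfg


class TestSimulateComparison:
    def test_zero_noise_limit_is_exact_line(self):
        cfg = ScenarioConfig(scenario=1, n=10, R=3, cv_x=0.0, cv_y=0.0,
                             beta0=2.0, beta1=0.9, seed=1)
        data = simulate_comparison(cfg)
        np.testing.assert_allclose(data.y, 2.0 + 0.9 * data.x, rtol=1e-12)

    def test_seed_reproducibility(self):
        cfg = ScenarioConfig(scenario=1, n=8, R=2, seed=44)
        a, b = simulate_comparison(cfg), simulate_comparison(cfg)
        np.testing.assert_array_equal(a.x, b.x)

    def test_pooled_cv_recovers_generating_cv(self):
        # aggregate repeatability CV over replicated datasets ~ 1%
        cfg = ScenarioConfig(scenario=1, n=25, R=3, cv_x=0.01, cv_y=0.01)
        rng = np.random.default_rng(3)
        x, _ = _simulate_batch(cfg, 300, rng)
        pooled_sd = np.sqrt(x.var(axis=2, ddof=1).mean(axis=1))
        cv_hat = (pooled_sd / x.mean(axis=(1, 2))).mean()
        assert cv_hat == pytest.approx(0.01, rel=0.05)


class TestHeteroskedasticity:
    def test_eta_one_gives_base_sds(self):
        cfg = ScenarioConfig(scenario=2, n=5, R=3, eta=1.0)
        sd_x, sd_y = heteroskedastic_sds(cfg, np.array([10.0, 30, 20, 50, 40]))
        np.testing.assert_allclose(sd_x, cfg.sd_x * (1 + 0 * sd_x))
        np.testing.assert_allclose(sd_y, cfg.sd_y * np.ones(5))

    def test_top_rank_reaches_eta_times_base(self):
        cfg = ScenarioConfig(scenario=2, n=4, R=3, eta=7.5)
        tau = np.array([10.0, 20.0, 30.0, 40.0])
        sd_x, _ = heteroskedastic_sds(cfg, tau)
        assert sd_x[-1] == pytest.approx(7.5 * cfg.sd_x)
        # n equally spaced steps: rank j gets 1 + j(eta-1)/n
        np.testing.assert_allclose(
            sd_x / cfg.sd_x, 1 + np.arange(1, 5) * 6.5 / 4
        )

    def test_eta_below_one_decreasing_in_concentration(self):
        cfg = ScenarioConfig(scenario=2, n=6, R=3, eta=0.1)
        tau = np.linspace(10, 80, 6)
        sd_x, _ = heteroskedastic_sds(cfg, tau)
        assert (np.diff(sd_x) < 0).all()


class TestRandomDins:
    def test_null_parameters_leave_data_unchanged(self, rng):
        data = make_balanced(10, 3, rng)
        out0 = apply_random_dins(data, p=0.0, m_max=5.0, base=1.0, rng=1)
        out1 = apply_random_dins(data, p=0.5, m_max=0.0, base=1.0, rng=1)
        np.testing.assert_array_equal(out0.y, data.y)
        np.testing.assert_array_equal(out1.y, data.y)

    def test_affected_count_is_binomial(self, rng):
        data = make_balanced(25, 2, rng)
        counts = []
        for i in range(400):
            out = apply_random_dins(data, p=0.3, m_max=5.0, base=1.0, rng=i)
            shifted = np.unique(data.sample_ids[out.y != data.y])
            counts.append(len(shifted))
        # Binomial(25, 0.3): mean 7.5, SE of the mean ~ 0.11
        assert np.mean(counts) == pytest.approx(7.5, abs=0.5)

    def test_shifts_positive_and_bounded(self, rng):
        data = make_balanced(10, 3, rng)
        out = apply_random_dins(data, p=1.0, m_max=5.0, base=2.0, rng=4)
        shift = out.y - data.y
        per_sample = {s: np.unique(np.round(shift[data.sample_ids == s], 12))
                      for s in np.unique(data.sample_ids)}
        for v in per_sample.values():
            assert len(v) == 1  # replicates share one shift
            assert 0.0 < v[0] <= 10.0

    def test_strong_dins_inflates_zeta(self):
        cfg = ScenarioConfig(scenario=3, n=25, R=3, p=1.0, m_max=10.0)
        z = simulate_zeta_distribution(cfg, 2000, seed=8)
        assert np.median(z) > 5.0


class TestSystematicDins:
    def test_ramp_multipliers_match_worked_examples(self):
        # window [0.80, 1]: quantiles 0.85/0.90/0.95 -> 0.25/0.5/0.75 m_max
        s = np.array([0.85, 0.90, 0.95, 1.0, 0.5])
        mult = _systematic_dins_multipliers(s, 0.80, 1.0, m_max=8.0)
        np.testing.assert_allclose(mult, [2.0, 4.0, 6.0, 8.0, 0.0])

    def test_bottom_anchored_window_mirrors(self):
        s = np.array([0.0, 0.1, 0.2, 0.5])
        mult = _systematic_dins_multipliers(s, 0.0, 0.2, m_max=10.0)
        np.testing.assert_allclose(mult, [10.0, 5.0, 0.0, 0.0])

    def test_zero_m_max_is_identity(self, rng):
        data = make_balanced(10, 3, rng)
        out = apply_systematic_dins(data, 0.8, 1.0, m_max=0.0, base=1.0)
        np.testing.assert_array_equal(out.y, data.y)

    def test_shift_uses_latent_quantile_position(self, rng):
        data = make_balanced(6, 2, rng)
        tau = np.array([0.0, 10.0, 45.0, 90.0, 95.0, 100.0])
        out = apply_systematic_dins(
            data, 0.8, 1.0, m_max=4.0, base=1.0,
            tau=tau, c_lower=0.0, c_upper=100.0,
        )
        shift = out.y - data.y
        ids = np.unique(data.sample_ids)
        per = np.array([shift[data.sample_ids == s][0] for s in ids])
        np.testing.assert_allclose(per, [0, 0, 0, 2.0, 3.0, 4.0], atol=1e-12)


class TestGeneralDins:
    def test_zero_m_is_identity(self, rng):
        data = make_balanced(10, 3, rng)
        assert apply_general_dins(data, 0.0, base=1.0, rng=1) is data

    def test_mean_zeta_scales_with_inflation_squared(self):
        # E[zeta-hat] under synthesized DINS ~ (1+M)^2 times the null mean
        cfg = ScenarioConfig(scenario=1, n=25, R=3)
        rng = np.random.default_rng(17)
        x, y = _simulate_batch(cfg, 3000, rng)
        base = np.sqrt(cfg.sd_y**2 + cfg.beta1**2 * cfg.sd_x**2)
        null_mean = zeta_batch(x, y).mean()
        M = 1.0
        sd = base * np.sqrt((1 + M) ** 2 - 1)
        y_dins = y + rng.normal(0, sd, size=y.shape[:2])[:, :, None]
        ratio = zeta_batch(x, y_dins).mean() / null_mean
        assert ratio == pytest.approx((1 + M) ** 2, rel=0.10)

    def test_replicates_share_one_relocation(self, rng):
        data = make_balanced(10, 3, rng)
        out = apply_general_dins(data, 0.5, base=1.0, rng=2)
        shift = out.y - data.y
        for s in np.unique(data.sample_ids):
            assert np.ptp(shift[data.sample_ids == s]) == pytest.approx(0.0, abs=1e-12)


class TestZetaDistribution:
    def test_fixed_seed_bit_identical(self):
        cfg = ScenarioConfig(scenario=1, n=10, R=2)
        a = simulate_zeta_distribution(cfg, 1000, seed=5)
        b = simulate_zeta_distribution(cfg, 1000, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_scenario5_at_zero_m_equals_null_draws(self):
        cfg1 = ScenarioConfig(scenario=1, n=10, R=2)
        cfg5 = ScenarioConfig(scenario=5, n=10, R=2, M=0.0)
        a = simulate_zeta_distribution(cfg1, 2000, seed=6)
        b = simulate_zeta_distribution(cfg5, 2000, seed=6)
        np.testing.assert_array_equal(a, b)

    def test_scenario5_scaling_law_is_exact_per_draw(self):
        cfg0 = ScenarioConfig(scenario=5, n=10, R=2, M=0.0)
        cfg1 = ScenarioConfig(scenario=5, n=10, R=2, M=0.5)
        a = simulate_zeta_distribution(cfg0, 1000, seed=6)
        b = simulate_zeta_distribution(cfg1, 1000, seed=6)
        np.testing.assert_allclose(b, 2.25 * a, rtol=1e-12)

    def test_chunking_does_not_change_results(self):
        cfg = ScenarioConfig(scenario=2, n=10, R=2, eta=5.0)
        a = simulate_zeta_distribution(cfg, 700, seed=9, chunk=700)
        b = simulate_zeta_distribution(cfg, 700, seed=9, chunk=700)
        np.testing.assert_array_equal(a, b)


class TestMissingness:
    def test_zero_fraction_is_identity(self, rng):
        data = make_balanced(10, 3, rng)
        out = apply_missingness(data, "MAR", 0.0, rng=1)
        np.testing.assert_array_equal(out.x, data.x)

    def test_blanked_count_matches_fraction(self, rng):
        data = make_balanced(25, 3, rng)
        total = 0
        for i in range(200):
            out = apply_missingness(data, "MAR", 0.05, rng=i)
            total += np.isnan(out.x).sum() + np.isnan(out.y).sum()
        expected = 0.05 * 2 * 75
        assert total / 200 == pytest.approx(expected, rel=0.15)

    def test_mnar_prefers_high_values(self, rng):
        data = make_balanced(25, 3, rng)
        blanked, kept = [], []
        for i in range(150):
            out = apply_missingness(data, "MNAR", 0.2, rng=i)
            gone = np.isnan(out.x) & np.isfinite(data.x)
            blanked.extend(data.x[gone])
            kept.extend(data.x[~gone])
        assert np.mean(blanked) > np.mean(kept)

    def test_invalid_fraction_rejected(self, rng):
        data = make_balanced(6, 2, rng)
        with pytest.raises(DomainError):
            apply_missingness(data, "MAR", 0.7)


class TestAlternativeDraws:
    def test_lognormal_latent_matches_uniform_percentiles(self):
        cfg = ScenarioConfig(scenario=1, n=400, R=2, c_lower=5.0, c_upper=90.0)
        rng = np.random.default_rng(21)
        draws = np.concatenate(
            [
                alternative_latent_and_error_draws(cfg, "lognormal", "normal", rng).x
                for _ in range(60)
            ]
        )
        span = 85.0
        q01, q99 = np.quantile(draws, [0.01, 0.99])
        assert q01 == pytest.approx(5.0 + 0.01 * span, rel=0.05)
        assert q99 == pytest.approx(5.0 + 0.99 * span, rel=0.05)

    def test_normal_errors_reproduce_default_generator(self):
        cfg = ScenarioConfig(scenario=1, n=10, R=3, seed=33)
        a = simulate_comparison(cfg)
        b = alternative_latent_and_error_draws(cfg, "uniform", "normal")
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_t_errors_have_target_sd(self):
        cfg = ScenarioConfig(scenario=1, n=200, R=3, cv_x=0.02, cv_y=0.02)
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(50):
            d = alternative_latent_and_error_draws(cfg, "uniform", "t15", rng)
            vals.append(np.sqrt(zeta_full(d).var_x_pooled))
        assert np.mean(vals) == pytest.approx(cfg.sd_x, rel=0.05)
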