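"""Survival-bias simulation: construction checks and null faithfulness."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrpd.frailty import (
    AnalysisSubset,
    FrailtyConfig,
    estimate_replicate,
    gompertz_makeham_death_prob,
    run_frailty_study,
    sample_case_control,
    simulate_bmi,
    simulate_cohort,
    simulate_genotypes,
    table1_snp_panel,
    _per_snp_logistic,
)

PANEL3 = [("s1", 0.3, 0.05), ("s2", 0.5, 0.03), ("s3", 0.8, 0.02)]


def small_config(**kw):
    defaults = dict(
        n_individuals=20_000, n_cases=300, n_controls=2_000,
        n_replicates=2, seed=123,
    )
    defaults.update(kw)
    return FrailtyConfig(**defaults)


class TestGenotypes:
    def test_shape_and_dosage_range(self):
        rng = np.random.default_rng(0)
        g = simulate_genotypes(PANEL3, 500, rng)
        assert g.shape == (500, 3)
        assert g.min() >= 0 and g.max() <= 2

    def test_mean_dosage_converges_to_twice_eaf(self):
        rng = np.random.default_rng(1)
        g = simulate_genotypes([("s", 0.5, 0.0)], 100_000, rng)
        assert g.mean() == pytest.approx(1.0, abs=0.01)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError, match="eaf"):
            simulate_genotypes([("s", 1.0, 0.1)], 10, np.random.default_rng(0))


class TestBMI:
    def test_population_variance_near_one_with_fixture_panel(self):
        rng = np.random.default_rng(2)
        panel = table1_snp_panel()
        g = simulate_genotypes(panel, 100_000, rng)
        bmi = simulate_bmi(g, panel, rng)
        assert np.var(bmi) == pytest.approx(1.0, rel=0.02)
        assert np.mean(bmi) == pytest.approx(0.0, abs=0.02)

    def test_zero_effects_give_pure_unit_noise(self):
        rng = np.random.default_rng(3)
        panel = [("s", 0.5, 0.0)]
        g = simulate_genotypes(panel, 50_000, rng)
        bmi = simulate_bmi(g, panel, rng)
        assert np.var(bmi) == pytest.approx(1.0, rel=0.03)

    def test_regression_on_dosage_recovers_per_allele_effect(self):
        rng = np.random.default_rng(4)
        panel = [("s1", 0.4, 0.2), ("s2", 0.6, 0.1)]
        g = simulate_genotypes(panel, 50_000, rng)
        bmi = simulate_bmi(g, panel, rng)
        fit = stats.linregress(g[:, 0], bmi)
        assert abs(fit.slope - 0.2) < 3 * fit.stderr

    def test_excessive_genetic_variance_rejected(self):
        panel = [("s", 0.5, 2.0)]
        g = simulate_genotypes(panel, 100, np.random.default_rng(0))
        with pytest.raises(ValueError, match="variance"):
            simulate_bmi(g, panel, np.random.default_rng(0))


class TestMortality:
    def test_no_hazard_means_no_death(self):
        cfg = small_config(makeham_lambda=0.0, gompertz_alpha=0.0)
        assert gompertz_makeham_death_prob(80.0, 0.0, cfg) == 0.0

    def test_makeham_only_closed_form(self):
        cfg = small_config(makeham_lambda=0.01, gompertz_alpha=0.0,
                           bmi_log_hr_per_sd=0.0)
        p = gompertz_makeham_death_prob(70.0, 0.0, cfg)
        assert p == pytest.approx(1 - np.exp(-0.7), abs=1e-12)

    def test_zero_gompertz_slope_uses_analytic_limit(self):
        cfg = small_config(gompertz_beta=0.0, gompertz_alpha=0.002,
                           makeham_lambda=0.001, bmi_log_hr_per_sd=0.0)
        p = gompertz_makeham_death_prob(50.0, 0.0, cfg)
        assert p == pytest.approx(1 - np.exp(-0.003 * 50), abs=1e-12)

    def test_monotone_in_age_and_bmi(self):
        cfg = small_config()  # positive BMI hazard ratio by default
        ages = np.array([50.0, 60.0, 70.0, 80.0])
        p = gompertz_makeham_death_prob(ages, 0.0, cfg)
        assert np.all(np.diff(p) > 0)
        p_bmi = gompertz_makeham_death_prob(70.0, np.array([-2.0, 0.0, 2.0]), cfg)
        assert np.all(np.diff(p_bmi) > 0)

    def test_default_alpha_calibrated_to_20pct_mortality_by_70(self):
        cfg = small_config(bmi_log_hr_per_sd=0.0)
        assert gompertz_makeham_death_prob(70.0, 0.0, cfg) == pytest.approx(0.2)


class TestCohort:
    def test_pd_prevalence_matches_rate_table_within_binomial_error(self):
        cfg = small_config(n_individuals=100_000)
        cohort = simulate_cohort(cfg, np.random.default_rng(5))
        for low, high, rate in cfg.pd_rate_table[:4]:
            mask = (cohort.age >= low) & (cohort.age < high)
            n = mask.sum()
            observed = cohort.pd[mask].mean()
            assert abs(observed - rate) < 4 * np.sqrt(rate * (1 - rate) / n)

    def test_pd_independent_of_bmi_within_age_bins(self):
        cfg = small_config(n_individuals=100_000)
        cohort = simulate_cohort(cfg, np.random.default_rng(6))
        mask = (cohort.age >= 70) & (cohort.age < 75)
        r, p = stats.pointbiserialr(cohort.pd[mask], cohort.bmi[mask])
        assert p > 0.01 or abs(r) < 0.02

    def test_no_bmi_hazard_leaves_survivor_bmi_distribution_unshifted(self):
        cfg = small_config(n_individuals=100_000, bmi_log_hr_per_sd=0.0)
        cohort = simulate_cohort(cfg, np.random.default_rng(7))
        t, p = stats.ttest_ind(cohort.bmi[cohort.alive], cohort.bmi)
        assert p > 0.01 or abs(t) < 3

    def test_positive_bmi_hazard_depletes_high_bmi_among_old_survivors(self):
        cfg = small_config(n_individuals=100_000, bmi_log_hr_per_sd=np.log(2.0))
        cohort = simulate_cohort(cfg, np.random.default_rng(8))
        old = cohort.age >= 80
        assert cohort.bmi[old & cohort.alive].mean() < cohort.bmi[old].mean() - 0.05

    def test_survivorship_accounting(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, np.random.default_rng(9))
        assert cohort.alive.sum() + (~cohort.alive).sum() == cfg.n_individuals

    def test_rate_table_must_cover_age_support(self):
        cfg = small_config()
        cfg.age_distribution = [(20.0, 30.0, 1.0)]  # outside rate table
        with pytest.raises(ValueError, match="cover"):
            simulate_cohort(cfg, np.random.default_rng(10))

    def test_all_zero_pd_rates_fail_loudly_at_sampling(self):
        cfg = small_config()
        cfg.pd_rate_table = [(low, high, 0.0) for low, high, _ in cfg.pd_rate_table]
        cohort = simulate_cohort(cfg, np.random.default_rng(11))
        assert cohort.pd.sum() == 0
        with pytest.raises(ValueError, match="cases"):
            sample_case_control(cohort, cfg, np.random.default_rng(11))


class TestCaseControlSampling:
    def test_exact_counts_and_all_alive(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, np.random.default_rng(12))
        sub = sample_case_control(cohort, cfg, np.random.default_rng(12))
        assert sub.pd.sum() == cfg.n_cases
        assert (~sub.pd).sum() == cfg.n_controls

    def test_stratified_case_ages_match_target(self):
        bins = [(60.0, 70.0, 0.5), (70.0, 80.0, 0.5)]
        cfg = small_config(n_individuals=100_000, n_cases=600,
                           case_age_distribution=bins)
        cohort = simulate_cohort(cfg, np.random.default_rng(13))
        sub = sample_case_control(cohort, cfg, np.random.default_rng(13))
        case_ages = sub.age[sub.pd]
        observed = np.array([(case_ages < 70).sum(), (case_ages >= 70).sum()])
        chi2, p = stats.chisquare(observed, [300, 300])
        assert p > 0.001  # exact apportionment -> counts are deterministic

    def test_exhausted_stratum_reports_the_bin(self):
        bins = [(40.0, 45.0, 1.0)]  # few PD cases that young
        cfg = small_config(n_cases=5000, case_age_distribution=bins)
        cohort = simulate_cohort(cfg, np.random.default_rng(14))
        with pytest.raises(ValueError, match=r"\[40.0, 45.0\)"):
            sample_case_control(cohort, cfg, np.random.default_rng(14))


class TestEstimation:
    def test_per_snp_logistic_matches_statsmodels(self):
        rng = np.random.default_rng(15)
        g = rng.binomial(2, [0.3, 0.6], size=(3000, 2)).astype(np.int8)
        logit = -1.5 + 0.3 * g[:, 0] - 0.2 * g[:, 1]
        y = rng.random(3000) < 1 / (1 + np.exp(-logit))
        beta, se = _per_snp_logistic(g, y)
        for j in range(2):
            ref = sm.Logit(y, sm.add_constant(g[:, j].astype(float))).fit(disp=0)
            assert beta[j] == pytest.approx(ref.params[1], abs=1e-6)
            assert se[j] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_monomorphic_snp_dropped_with_warning(self):
        rng = np.random.default_rng(16)
        n = 2000
        g = np.column_stack([
            rng.binomial(2, 0.4, n), np.zeros(n, dtype=int), rng.binomial(2, 0.5, n),
            rng.binomial(2, 0.3, n),
        ]).astype(np.int8)
        sub = AnalysisSubset(
            genotypes=g,
            bmi=rng.normal(size=n),
            age=rng.uniform(50, 80, n),
            pd=rng.random(n) < 0.2,
        )
        panel = [("a", 0.4, 0.05), ("mono", 0.4, 0.05), ("b", 0.5, 0.03), ("c", 0.3, 0.04)]
        with pytest.warns(UserWarning, match="mono"):
            res = estimate_replicate(sub, panel, small_config())
        assert res.ivw_or_per_5kgm2 > 0

    def test_subset_with_single_class_rejected(self):
        rng = np.random.default_rng(17)
        sub = AnalysisSubset(
            genotypes=rng.binomial(2, 0.5, size=(50, 1)).astype(np.int8),
            bmi=rng.normal(size=50), age=rng.uniform(50, 80, 50),
            pd=np.zeros(50, dtype=bool),
        )
        with pytest.raises(ValueError):
            estimate_replicate(sub, [("a", 0.5, 0.05)], small_config())


class TestStudy:
    def test_seeded_determinism_end_to_end(self, tmp_path):
        cfg = small_config(n_replicates=2)
        s1 = run_frailty_study(cfg, out_dir=tmp_path / "a")
        s2 = run_frailty_study(cfg, out_dir=tmp_path / "b")
        assert s1.to_dict() == s2.to_dict()
        assert (tmp_path / "a" / "replicates.tsv").read_text() == (
            tmp_path / "b" / "replicates.tsv"
        ).read_text()

    def test_summary_files_written(self, tmp_path):
        cfg = small_config(n_replicates=2)
        run_frailty_study(cfg, out_dir=tmp_path)
        assert (tmp_path / "summary.json").exists()
        lines = (tmp_path / "replicates.tsv").read_text().strip().split("\n")
        assert len(lines) == 3

    def test_case_control_counts_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError):
            FrailtyConfig(n_individuals=100, n_cases=90, n_controls=20)
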