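"""Association statistics: batched logistic scan vs independent oracles,
trimmed-mean inflation factor, PC regressions and scan comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import stratpca as sp
from stratpca.assoc import (
    expected_trimmed_mean_chi2,
    inflation_factor,
    logistic_snp_scan,
    pc_regression,
    pvalue_correlation,
    site_associated_pcs,
    top_hits_comparison,
)

from conftest import small_config, toy_genotypes


# ---------------------------------------------------------------------------
# logistic scan
# ---------------------------------------------------------------------------

def test_null_scan_type_one_error_calibrated():
    g = toy_genotypes(2000, 2000, seed=13)
    y = np.random.default_rng(14).binomial(1, 0.5, 2000)
    scan = logistic_snp_scan(g, status=y)
    frac = (scan.tested["p"] < 0.05).mean()
    assert 0.03 < frac < 0.07


def test_two_by_three_table_matches_bruteforce_mle():
    # genotype-by-status counts: controls (30, 40, 30), cases (15, 35, 50)
    counts = {(0, 0): 30, (1, 0): 40, (2, 0): 30, (0, 1): 15, (1, 1): 35, (2, 1): 50}
    dosage = np.concatenate([[d] * n for (d, _), n in counts.items()])
    y = np.concatenate([[s] * n for (_, s), n in counts.items()])
    g = toy_genotypes(len(y), 1)
    g.dosages = dosage[:, None].astype(np.int8)
    scan = logistic_snp_scan(g, status=y)
    beta_hat = scan.table["beta"][0]

    def negloglik(params):
        a, b = params
        eta = a + b * dosage
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    res = optimize.minimize(negloglik, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10000})
    assert abs(beta_hat - res.x[1]) < 1e-6


def test_scan_matches_statsmodels_with_covariates():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    g = toy_genotypes(400, 20, seed=5)
    cov = rng.normal(size=(400, 2))
    y = rng.binomial(1, stats.norm.cdf(0.3 * cov[:, 0]))
    scan = logistic_snp_scan(g, status=y, covariates=cov)
    for j in (0, 7, 19):
        design = sm.add_constant(np.column_stack([g.dosages[:, j].astype(float), cov]))
        fit = sm.Logit(y, design).fit(disp=0)
        assert abs(scan.table["beta"][j] - fit.params[1]) < 1e-6
        assert abs(scan.table["se"][j] - fit.bse[1]) < 1e-6


def test_causal_log_odds_recovered():
    est = []
    for seed in range(10):
        rng = np.random.default_rng(700 + seed)
        g = toy_genotypes(2000, 5, seed=800 + seed)
        eta = -0.5 + 0.5 * g.dosages[:, 2].astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        scan = logistic_snp_scan(g, status=y)
        est.append(scan.table["beta"][2])
    assert abs(np.mean(est) - 0.5) < 0.15


def test_constant_and_separated_snps_flagged():
    g = toy_genotypes(100, 3, seed=2)
    g.dosages[:, 0] = 1  # constant
    y = np.zeros(100, dtype=int)
    y[:50] = 1
    g.dosages[:, 2] = np.where(y == 1, 2, 0).astype(np.int8)  # perfect separation
    scan = logistic_snp_scan(g, status=y)
    flags = scan.table["flag"]
    assert flags[0] == "constant"
    assert flags[1] == "ok"
    assert flags[2] in ("separated", "not_converged")
    assert np.isnan(scan.table["p"][2])


def test_p_consistent_with_chisq_and_invariances(small_cohort):
    genotypes, _ = small_cohort
    sub = genotypes.subset_snps(np.arange(200))
    scan = logistic_snp_scan(sub)
    ok = scan.tested
    np.testing.assert_allclose(ok["p"], stats.chi2.sf(ok["chisq"], 1), atol=1e-12)
    # sample order invariance
    perm = np.random.default_rng(3).permutation(sub.n_samples)
    scan_p = logistic_snp_scan(sub.subset_samples(perm))
    np.testing.assert_allclose(scan_p.table["chisq"], scan.table["chisq"], atol=1e-6)
    # covariate scaling invariance of the dosage test
    cov = np.random.default_rng(4).normal(size=(sub.n_samples, 2))
    s1 = logistic_snp_scan(sub, covariates=cov)
    s2 = logistic_snp_scan(sub, covariates=cov * 100.0)
    np.testing.assert_allclose(s1.table["p"], s2.table["p"], atol=1e-6)


def test_lrt_close_to_wald_on_null_data():
    g = toy_genotypes(500, 100, seed=21)
    y = np.random.default_rng(22).binomial(1, 0.5, 500)
    wald = logistic_snp_scan(g, status=y)
    lrt = logistic_snp_scan(g, status=y, test="lrt")
    assert np.nanmax(np.abs(wald.table["chisq"] - lrt.table["chisq"])) < 0.2


# ---------------------------------------------------------------------------
# trimmed-mean inflation factor
# ---------------------------------------------------------------------------

class TestExpectedTrimmedMean:
    def test_no_trim_is_unit_mean(self):
        assert expected_trimmed_mean_chi2(0.0) == 1.0

    def test_quadrature_matches_closed_form(self):
        # E[X | X < q] for chi2(1) has closed form cdf(q; df=3)/(1 - t)
        for t in (0.05, 0.1, 0.2):
            q = stats.chi2.ppf(1 - t, 1)
            closed = stats.chi2.cdf(q, 3) / (1 - t)
            assert abs(expected_trimmed_mean_chi2(t) - closed) < 1e-8

    def test_monte_carlo_agreement(self):
        t = 0.1
        draws = stats.chi2.rvs(1, size=10**6, random_state=9)
        q = np.quantile(draws, 1 - t)
        kept = draws[draws <= q]
        mc, se = kept.mean(), kept.std(ddof=1) / np.sqrt(len(kept))
        assert abs(expected_trimmed_mean_chi2(t) - mc) < 3 * se

    def test_strictly_decreasing_in_trim(self):
        vals = [expected_trimmed_mean_chi2(t) for t in (0.0, 0.05, 0.1, 0.2)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_trimmed_mean_chi2(0.5)


class TestInflationFactor:
    def test_null_chi2_lambda_near_one(self):
        draws = stats.chi2.rvs(1, size=10**5, random_state=17)
        assert 0.98 < inflation_factor(draws).lam < 1.02

    def test_scale_equivariance(self):
        draws = stats.chi2.rvs(1, size=10**5, random_state=18)
        lam = inflation_factor(1.7 * draws).lam
        assert 1.66 < lam < 1.74

    def test_constant_stats_no_trim(self):
        assert inflation_factor(np.full(200, 2.5), trim_fraction=0.0).lam == pytest.approx(2.5)

    def test_too_few_statistics_rejected(self):
        with pytest.raises(ValueError, match="100"):
            inflation_factor(np.ones(50))

    def test_two_sided_mode_also_calibrated(self):
        draws = stats.chi2.rvs(1, size=10**5, random_state=19)
        lam = inflation_factor(draws, two_sided=True).lam
        assert 0.97 < lam < 1.03


# ---------------------------------------------------------------------------
# PC ~ site + disease regression
# ---------------------------------------------------------------------------

class TestPCRegression:
    def _frame(self, scores):
        return pd.DataFrame({"sample_id": np.arange(len(scores)), "PC1": scores})

    def test_site_effect_recovered(self):
        rng = np.random.default_rng(31)
        site = np.repeat(["A", "B"], 500)
        status = rng.choice(["case", "control"], 1000)
        scores = 1.0 * (site == "B") + rng.normal(scale=0.1, size=1000)
        table = pc_regression(self._frame(scores), site, status)
        est = table[(table.term == "B")]["estimate"].iloc[0]
        assert abs(est - 1.0) < 0.05

    def test_duplicated_rows_same_estimates_smaller_p(self):
        rng = np.random.default_rng(32)
        site = np.repeat(["A", "B", "C"], 100)
        status = rng.choice(["case", "control"], 300)
        scores = 0.2 * (site == "C") + rng.normal(size=300)
        t1 = pc_regression(self._frame(scores), site, status)
        t2 = pc_regression(
            self._frame(np.tile(scores, 2)), np.tile(site, 2), np.tile(status, 2)
        )
        np.testing.assert_allclose(t1["estimate"], t2["estimate"], atol=1e-10)
        nontrivial = t1["p_value"] > 1e-12
        assert (t2["p_value"][nontrivial] < t1["p_value"][nontrivial]).all()

    def test_reference_site_absorbed_in_intercept(self):
        rng = np.random.default_rng(33)
        site = np.repeat(["MAYO", "NCO", "TBO"], 50)
        status = rng.choice(["case", "control"], 150)
        scores = rng.normal(size=150)
        table = pc_regression(self._frame(scores), site, status, reference_site="TBO")
        assert set(table.term) == {"Intercept", "MAYO", "NCO", "Disease"}

    def test_single_site_omits_site_terms(self):
        rng = np.random.default_rng(34)
        status = rng.choice(["case", "control"], 80)
        table = pc_regression(self._frame(rng.normal(size=80)), np.full(80, "X"), status)
        assert set(table.term) == {"Intercept", "Disease"}


def test_site_associated_pcs_separates_structure_from_noise(small_cohort, small_model):
    genotypes, truth = small_cohort
    hits = site_associated_pcs(
        small_model.scores_frame(),
        genotypes.samples["site"].to_numpy(),
        genotypes.samples["status"].to_numpy(),
    )
    corrs = [abs(np.corrcoef(small_model.scores[:, j], truth.ancestry)[0, 1])
             for j in range(small_model.k)]
    assert (int(np.argmax(corrs)) + 1) in hits  # the cline PC is site-associated
    # a pure-noise PC (weakest ancestry correlation among 5..10) is not
    noise_pc = 5 + int(np.argmin(corrs[4:]))
    assert noise_pc not in hits


# ---------------------------------------------------------------------------
# scan comparisons
# ---------------------------------------------------------------------------

def _null_scan(seed, n=400, p=2000):
    g = toy_genotypes(n, p, seed=seed)
    y = np.random.default_rng(seed + 1).binomial(1, 0.5, n)
    return logistic_snp_scan(g, status=y)


def test_pvalue_correlation_extremes():
    scan = _null_scan(41, p=500)
    assert pvalue_correlation(scan, scan) == pytest.approx(1.0)
    other = _null_scan(43, p=500)
    assert abs(pvalue_correlation(scan, other)) < 0.1


def test_corrections_agree_more_with_each_other_than_with_uncorrected(small_cohort):
    genotypes, _ = small_cohort
    model = sp.fit_pca(genotypes, k=10)
    controls = genotypes.subset_samples(genotypes.status_vector() == 0)
    proj = sp.project(genotypes, sp.fit_pca(controls, k=10))
    uncorr = logistic_snp_scan(genotypes)
    corr_a = logistic_snp_scan(genotypes, covariates=model.scores[:, :4])
    corr_b = logistic_snp_scan(
        genotypes, covariates=proj[[f"PC{i}" for i in range(1, 5)]].to_numpy()
    )
    r_ab = pvalue_correlation(corr_a, corr_b)
    r_ua = pvalue_correlation(uncorr, corr_a)
    assert r_ab > r_ua


class TestTopHits:
    def test_identical_scans_full_retention(self):
        scan = _null_scan(47, p=300)
        table = top_hits_comparison(scan, scan, n_top=10)
        np.testing.assert_allclose(table["neglog10_p_a"], table["neglog10_p_b"])
        assert table["retained"].all()

    def test_single_perturbed_snp_is_the_mover(self):
        scan_a = _null_scan(48, p=300)
        table_b = scan_a.table.copy()
        top = table_b.nsmallest(10, "p").index
        moved = top[3]
        table_b.loc[moved, "p"] = min(1.0, table_b.loc[moved, "p"] * 50)
        scan_b = sp.AssociationScan(table=table_b, covariates="x", n_samples=scan_a.n_samples)
        table = top_hits_comparison(scan_a, scan_b, n_top=10)
        movers = table[table["mover"]]
        assert list(movers["snp_id"]) == [scan_a.table.loc[moved, "snp_id"]]

    def test_n_top_beyond_shared_rejected(self):
        scan = _null_scan(49, p=50)
        with pytest.raises(ValueError, match="n_top"):
            top_hits_comparison(scan, scan, n_top=51)
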