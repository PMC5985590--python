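"""Tests of BLUP genetic values, the three scan methods, q-values,
PVE, consensus and fine-mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aspenscan.core import GenotypeMatrix
from aspenscan.scan import (blup_genetic_values, consensus_candidates,
                            finemap_causal, latent_factor_scan, lmm_gwas,
                            pca_outlier_scan, pve, storey_qvalues)
from aspenscan.structure import centered_kinship, genotype_pca
from tests.conftest import make_genotypes


def _toy_records(rng, n_clones=6, sigma_c=2.0, sigma_e=1.0):
    gv = rng.normal(0, sigma_c, n_clones)
    rows = []
    for c in range(n_clones):
        for site in ("A", "B"):
            for block in ("1", "2"):
                for year in (2005, 2006):
                    mu = 50 + (3 if site == "A" else 0) + 0.5 * int(block)
                    rows.append((site, block, year, f"c{c}",
                                 mu + gv[c] + rng.normal(0, sigma_e)))
    return pd.DataFrame(rows, columns=["site", "block", "year", "clone",
                                       "value"]), gv


def _henderson_blup(df, sigma_c2, sigma_e2):
    """Direct solve of Henderson's mixed-model equations."""
    clones = pd.unique(df["clone"])
    Z = pd.get_dummies(df["clone"], dtype=float)[clones].to_numpy()
    X = pd.get_dummies(
        df["site"].astype(str) + "/" + df["block"].astype(str),
        dtype=float).to_numpy()
    X = np.column_stack([np.ones(len(df)), X[:, 1:]])
    Xy = pd.get_dummies(
        df["site"].astype(str) + "/" + df["year"].astype(str),
        dtype=float).to_numpy()[:, 1:]
    # drop year columns collinear with blocks-in-site design
    X = np.column_stack([X, Xy])
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    rank = (np.abs(np.diag(R)) > np.abs(R[0, 0]) * 1e-10).sum()
    X = X[:, np.sort(piv[:rank])]
    y = df["value"].to_numpy(float)
    lam = sigma_e2 / sigma_c2
    top = np.hstack([X.T @ X, X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * np.eye(Z.shape[1])])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return pd.Series(sol[X.shape[1]:], index=clones)


class TestBlup:
    def test_matches_henderson_equations(self):
        """BLUPs agree with a direct mixed-model-equation solve at the
        REML variance components."""
        rng = np.random.default_rng(0)
        df, _ = _toy_records(rng)
        blups = blup_genetic_values(df)
        # recover the REML components the model used
        import statsmodels.regression.mixed_linear_model as mlm
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mlm.MixedLM.from_formula(
                "value ~ C(site) + C(site):C(block) + C(site):C(year)",
                data=df, groups=df["clone"]).fit(reml=True)
        oracle = _henderson_blup(df, float(m.cov_re.iloc[0, 0]),
                                 float(m.scale))
        assert np.allclose(blups.to_numpy(),
                           oracle[blups.index].to_numpy(), atol=1e-4)

    def test_negligible_shrinkage_when_residual_tiny(self):
        rng = np.random.default_rng(1)
        df, gv = _toy_records(rng, sigma_c=5.0, sigma_e=1e-4)
        blups = blup_genetic_values(df)
        assert np.corrcoef(blups.to_numpy(), gv)[0, 1] > 0.999

    def test_identical_clones_give_zero(self):
        rng = np.random.default_rng(2)
        df, _ = _toy_records(rng, sigma_c=0.0, sigma_e=0.0)
        assert np.allclose(blup_genetic_values(df).to_numpy(), 0.0)

    def test_exclusion_list(self):
        rng = np.random.default_rng(3)
        df, _ = _toy_records(rng)
        out = blup_genetic_values(df, exclude=[("A", 2006)])
        assert len(out) == df["clone"].nunique()

    def test_single_clone_fails(self):
        rng = np.random.default_rng(4)
        df, _ = _toy_records(rng, n_clones=1)
        with pytest.raises(ValueError):
            blup_genetic_values(df)


class TestPcaOutlier:
    def test_null_calibration_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(0)
        G = make_genotypes(rng.binomial(
            2, rng.uniform(0.1, 0.9, 500), (60, 500)))
        res = genotype_pca(G, K=2)
        p = pca_outlier_scan(G, res)
        assert kstest(p[np.isfinite(p)], "uniform").pvalue > 0.01

    def test_uncorrelated_snp_p_near_one(self):
        rng = np.random.default_rng(1)
        lab = np.repeat([0, 1], 30)
        p_mat = np.where(lab[:, None] == 0, 0.2, 0.8) * np.ones((60, 200))
        d = rng.binomial(2, p_mat)
        # one SNP constructed orthogonal to the cluster axis
        d[:, 0] = np.tile([0, 1, 2, 1], 15)
        G = make_genotypes(d)
        res = genotype_pca(G, K=2)
        pvals = pca_outlier_scan(G, res)
        assert pvals[0] > 0.5

    def test_planted_clinal_snp_is_outlier(self, default_cohort):
        """The causal SNP ranks among the smallest PCA-outlier p."""
        G, _, meta, truth = default_cohort
        res = genotype_pca(G, K=2)
        p = pca_outlier_scan(G, res)
        ci = truth["causal_index"]
        assert p[ci] <= np.nanquantile(p, 0.01)


class TestLatentFactor:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        rates = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            G = make_genotypes(r.binomial(
                2, r.uniform(0.2, 0.8, 400), (50, 400)))
            env = r.normal(0, 1, 50)
            res = latent_factor_scan(G, env, K=2)
            rates.append((res["p"] < 0.05).mean())
        assert 0.02 <= np.mean(rates) <= 0.08

    def test_nesting_k0_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        G = make_genotypes(rng.binomial(2, 0.4, (40, 25)))
        env = rng.normal(0, 1, 40)
        res = latent_factor_scan(G, env, K=0)
        for j in range(25):
            fit = sm.OLS(G.dosages[:, j].astype(float),
                         sm.add_constant(env)).fit()
            assert res["z"][j] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_power_on_planted_association(self):
        """An env-correlated SNP (1 SD effect) is found at q < 0.05."""
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n, m = 80, 300
            env = rng.normal(0, 1, n)
            d = rng.binomial(2, rng.uniform(0.2, 0.8, m), (n, m)).astype(float)
            liability = env + rng.normal(0, 1, n)
            d[:, 0] = (liability > np.quantile(liability, 0.67)).astype(int) \
                + (liability > np.quantile(liability, 0.33)).astype(int)
            G = make_genotypes(d.astype(np.int8))
            res = latent_factor_scan(G, env, K=2)
            q, _ = storey_qvalues(res["p"].to_numpy())
            hits += q[0] < 0.05
        assert hits >= 0.8 * n_seeds

    def test_k_too_large(self):
        G = make_genotypes(np.zeros((5, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            latent_factor_scan(G, np.zeros(5), K=5)


class TestLmmGwas:
    def test_identity_kinship_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        G = make_genotypes(rng.binomial(2, 0.4, (40, 15)))
        y = 0.5 * G.dosages[:, 2] + rng.normal(0, 1, 40)
        res = lmm_gwas(G, y, np.eye(40))
        for j in range(15):
            fit = sm.OLS(y, sm.add_constant(
                G.dosages[:, j].astype(float))).fit()
            assert res.beta[j] == pytest.approx(fit.params[1], abs=1e-6)
            assert res.se[j] == pytest.approx(fit.bse[1], rel=1e-5)
            assert res.p[j] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_exact_fit_recovers_effect(self):
        rng = np.random.default_rng(1)
        G = make_genotypes(rng.binomial(2, 0.5, (30, 5)))
        y = 2.0 * G.dosages[:, 3].astype(float)
        res = lmm_gwas(G, y, np.eye(30))
        assert res.beta[3] == pytest.approx(2.0, abs=1e-6)
        assert res.p[3] < 1e-30

    def test_reml_optimum_matches_grid_search(self):
        """1-D REML profile vs a dense grid over the variance ratio."""
        from aspenscan.scan import _reml_neg_loglik

        rng = np.random.default_rng(2)
        n = 30
        G = make_genotypes(rng.binomial(2, 0.5, (n, 400)))
        K = centered_kinship(G)
        u = np.linalg.cholesky(K + 1e-6 * np.eye(n)) @ rng.normal(0, 1, n)
        y = u + rng.normal(0, 0.5, n)
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        yt = U.T @ y
        x = rng.binomial(2, 0.5, n).astype(float)
        Xt = np.column_stack([U.T @ np.ones(n), U.T @ x])
        grid = np.linspace(-5, 5, 1000)
        grid_vals = [_reml_neg_loglik(g, w, yt, Xt) for g in grid]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(_reml_neg_loglik, bounds=(-5, 5),
                              args=(w, yt, Xt), method="bounded",
                              options={"xatol": 1e-6})
        assert res.fun <= min(grid_vals) + 1e-4

    def test_non_psd_kinship_rejected(self):
        G = make_genotypes(np.random.default_rng(0).binomial(2, 0.5, (5, 3)))
        K = -np.eye(5)
        with pytest.raises(ValueError, match="eigenvalue"):
            lmm_gwas(G, np.zeros(5), K)


class TestPve:
    def test_closed_form_cases(self):
        assert pve(0.5, 0.1, 0.2, 94) == pytest.approx(0.2101, abs=2e-4)
        assert pve(0.0, 0.1, 0.3, 94) == 0.0
        assert pve(1.2, 0.0, 0.5, 94) == 1.0

    def test_invalid_maf(self):
        with pytest.raises(ValueError):
            pve(0.5, 0.1, 0.0, 94)
        with pytest.raises(ValueError):
            pve(0.5, 0.1, 0.7, 94)


class TestStoreyQvalues:
    def test_all_ones(self):
        q, pi0 = storey_qvalues(np.ones(100))
        assert np.all(q == 1.0)

    def test_null_pi0_near_one(self):
        rng = np.random.default_rng(0)
        _, pi0 = storey_qvalues(rng.uniform(0, 1, 10_000))
        assert 0.9 <= pi0 <= 1.1

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 500)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_fdr_control_on_mixture(self):
        """Realized FDR at q < 0.05 stays below 0.10 (mixture sim)."""
        rng = np.random.default_rng(2)
        fdrs = []
        for _ in range(20):
            m0, m1 = 1800, 200
            z = np.concatenate([rng.normal(0, 1, m0),
                                rng.normal(3.5, 1, m1)])
            p = stats.norm.sf(z)
            truth = np.concatenate([np.zeros(m0), np.ones(m1)])
            q, _ = storey_qvalues(p)
            sel = q < 0.05
            if sel.sum():
                fdrs.append((truth[sel] == 0).mean())
        assert np.mean(fdrs) <= 0.10

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.2]))


class TestConsensus:
    def test_two_of_three_rule(self):
        sites = pd.DataFrame({"chrom": "c", "pos": [10, 20, 30]})
        flags = {
            "a": np.array([True, True, True]),
            "b": np.array([False, True, True]),
            "c": np.array([False, False, True]),
        }
        cand, regions = consensus_candidates(sites, flags)
        assert list(cand) == [1, 2]
        assert regions.iloc[0]["n_candidates"] == 2

    def test_empty_flags(self):
        sites = pd.DataFrame({"chrom": "c", "pos": [10]})
        flags = {"a": np.array([False]), "b": np.array([False]),
                 "c": np.array([False])}
        cand, regions = consensus_candidates(sites, flags)
        assert cand.size == 0
        assert len(regions) == 0

    def test_region_clustering_gap(self):
        sites = pd.DataFrame({
            "chrom": "c", "pos": [1000, 2000, 200_000, 201_000]})
        t = np.array([True] * 4)
        cand, regions = consensus_candidates(
            sites, {"a": t, "b": t}, gap=50_000)
        assert len(regions) == 2


def _finemap_oracle(z, R, max_causal, prior, ncp_sd, ridge):
    """Independent enumeration with scipy's dense MVN density."""
    m = z.size
    Rr = R + ridge * np.eye(m)
    post = {}
    for k in range(max_causal + 1):
        for C in itertools.combinations(range(m), k):
            cov = Rr.copy()
            if C:
                cov = Rr + ncp_sd**2 * Rr[:, list(C)] @ Rr[list(C), :]
            lp = stats.multivariate_normal.logpdf(z, mean=np.zeros(m),
                                                  cov=cov)
            post[C] = lp + k * np.log(prior) + (m - k) * np.log(1 - prior)
    mx = max(post.values())
    tot = sum(np.exp(v - mx) for v in post.values())
    incl = np.zeros(m)
    for C, v in post.items():
        for j in C:
            incl[j] += np.exp(v - mx) / tot
    return incl


class TestFinemap:
    def test_single_clear_causal(self):
        z = np.zeros(6)
        z[2] = 10.0
        res = finemap_causal(z, np.eye(6))
        assert res.causal_set == [2]
        assert res.inclusion_posterior[2] > 0.99

    def test_perfect_ld_symmetry(self):
        z = np.array([6.0, 6.0])
        res = finemap_causal(z, np.ones((2, 2)))
        assert set(res.causal_set) == {0, 1}
        a, b = res.inclusion_posterior
        assert a == pytest.approx(b, abs=1e-6)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        m = 8
        A = rng.normal(size=(m, m))
        R = A @ A.T
        dd = np.sqrt(np.diag(R))
        R = R / np.outer(dd, dd)
        z = rng.normal(0, 2, m)
        z[3] += 5
        res = finemap_causal(z, R, max_causal=2, prior=0.01)
        oracle = _finemap_oracle(z, R, 2, 0.01, 5.2, 1e-4)
        assert np.allclose(res.inclusion_posterior, oracle, atol=1e-8)

    def test_configuration_mass_sums_to_one(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 5)
        res = finemap_causal(z, np.eye(5))
        assert sum(res.config_posterior.values()) == pytest.approx(
            1.0, abs=1e-10)

    def test_enumeration_budget(self):
        with pytest.raises(ValueError, match="pre-filter"):
            finemap_causal(np.zeros(2000), np.eye(2000), max_causal=2,
                           max_configs=1000)
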