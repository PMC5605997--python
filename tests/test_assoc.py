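"""GWAS regression against closed-form and statsmodels oracles; PCs; lambda."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from neurogwas import (
    SimulationConfig,
    ValidationError,
    compute_pcs,
    genomic_inflation,
    gwas_linear,
    simulate_genotypes,
)
from .conftest import make_geno, make_pheno


class TestComputePcs:
    def _two_pop_geno(self, rng, n_per=100, m=60):
        f = np.where(rng.random(m) < 0.5, 0.1, 0.2)
        g1 = rng.binomial(2, f, size=(n_per, m)).astype(float)
        g2 = rng.binomial(2, np.clip(f + 0.6, 0, 1), size=(n_per, m)).astype(float)
        return make_geno(np.vstack([g1, g2]))

    def test_pc1_separates_differentiated_subpopulations(self, rng):
        g = self._two_pop_geno(rng)
        pcs = compute_pcs(g, k=2)
        pc1 = pcs.scores[:, 0]
        a, b = pc1[:100], pc1[100:]
        within = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) > 5 * within

    def test_k_zero_gives_empty_matrix(self, rng):
        g = self._two_pop_geno(rng)
        assert compute_pcs(g, k=0).scores.shape == (200, 0)

    def test_components_are_orthogonal(self, rng):
        g = self._two_pop_geno(rng)
        pcs = compute_pcs(g, k=3)
        gram = pcs.scores.T @ pcs.scores
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-8 * np.abs(np.diag(gram)).max())

    def test_permuting_samples_permutes_scores(self, rng):
        g = self._two_pop_geno(rng, n_per=30, m=40)
        perm = rng.permutation(60)
        pcs1 = compute_pcs(g, k=2)
        pcs2 = compute_pcs(g.subset_samples(list(perm)), k=2)
        assert np.allclose(pcs1.scores[perm], pcs2.scores, atol=1e-8)

    def test_k_above_rank_rejected(self, rng):
        base = rng.binomial(2, 0.4, size=(5, 3)).astype(float)
        dup = np.hstack([base, base, base, base])  # column rank <= 3
        g = make_geno(dup)
        with pytest.raises(ValidationError, match="rank"):
            compute_pcs(g, k=5)
        with pytest.raises(ValidationError, match="exceeds"):
            compute_pcs(make_geno(base), k=4)


WORKED_D = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
WORKED_Y = np.array([0.2, -0.1, 0.5, 0.4, 1.1, 0.9])


def closed_form_ols(d, y):
    """Textbook simple-regression oracle (normal equations by hand)."""
    n = len(d)
    dc, yc = d - d.mean(), y - y.mean()
    beta = (dc @ yc) / (dc @ dc)
    resid = yc - beta * dc
    s2 = (resid @ resid) / (n - 2)
    se = np.sqrt(s2 / (dc @ dc))
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta, se, t, p


class TestGwasLinear:
    def test_six_sample_worked_example(self):
        g = make_geno(WORKED_D[:, None])
        pheno = make_pheno(WORKED_Y)
        res = gwas_linear(g, pheno, [])
        beta, se, t, p = closed_form_ols(WORKED_D, WORKED_Y)
        assert res.loc[0, "beta"] == pytest.approx(beta, abs=1e-12)
        assert res.loc[0, "beta"] == pytest.approx(0.475)
        assert res.loc[0, "se"] == pytest.approx(se, abs=1e-12)
        assert res.loc[0, "t_stat"] == pytest.approx(t, abs=1e-10)
        assert res.loc[0, "p"] == pytest.approx(p, abs=1e-12)

    def test_matches_statsmodels_with_covariates(self, rng):
        n, m = 120, 8
        g = make_geno(rng.binomial(2, 0.3, size=(n, m)).astype(float))
        group = rng.integers(0, 2, n)
        age = rng.normal(40, 10, n)
        y = 0.3 * g.dosage[:, 2] - 0.4 * group + rng.normal(size=n)
        pheno = make_pheno(y, group=group)
        pheno["age"] = age
        res = gwas_linear(g, pheno, ["group", "age"])
        res = res.set_index("marker")
        for j in range(m):
            X = sm.add_constant(
                np.column_stack([g.dosage[:, j], group, age])
            )
            fit = sm.OLS(y, X).fit()
            row = res.loc[f"mk{j}"]
            assert row["beta"] == pytest.approx(fit.params[1], rel=1e-9)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-9)
            assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_monomorphic_marker_flagged(self):
        d = np.column_stack([np.full(10, 1.0), np.arange(10) % 3])
        g = make_geno(d.astype(float))
        res = gwas_linear(g, make_pheno(np.arange(10, dtype=float)), [])
        mono = res.set_index("marker").loc["mk0"]
        assert bool(mono["monomorphic"]) and mono["p"] == 1.0
        assert np.isnan(mono["beta"])

    def test_null_pvalues_are_uniform(self, rng):
        n, m = 300, 2000
        g = make_geno(rng.binomial(2, 0.3, size=(n, m)).astype(float))
        pheno = make_pheno(rng.normal(size=n))
        res = gwas_linear(g, pheno, [])
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        n = 100
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * d + rng.normal(size=n)
        z = rng.normal(size=n)
        # project z off span{1, d, y} so it is exactly orthogonal to all
        basis = np.column_stack([np.ones(n), d, y])
        q, _ = np.linalg.qr(basis)
        z = z - q @ (q.T @ z)
        g = make_geno(d[:, None])
        pheno = make_pheno(y)
        pheno["z"] = z
        b0 = gwas_linear(g, pheno, []).loc[0, "beta"]
        b1 = gwas_linear(g, pheno, ["z"]).loc[0, "beta"]
        assert abs(b0 - b1) < 1e-8

    def test_collinear_covariates_rejected_by_name(self, rng):
        n = 50
        g = make_geno(rng.binomial(2, 0.4, (n, 2)).astype(float))
        pheno = make_pheno(rng.normal(size=n))
        pheno["c1"] = np.arange(n, dtype=float)
        pheno["c2"] = 2.0 * pheno["c1"]
        with pytest.raises(ValidationError, match="c2"):
            gwas_linear(g, pheno, ["c1", "c2"])

    def test_missing_dosages_mean_imputed(self, rng):
        n = 200
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.6 * d + rng.normal(size=n)
        d_missing = d.copy()
        d_missing[rng.choice(n, 20, replace=False)] = np.nan
        g = make_geno(d_missing[:, None])
        res = gwas_linear(g, make_pheno(y), [])
        assert res.loc[0, "n_used"] == n
        assert res.loc[0, "beta"] == pytest.approx(0.6, abs=0.25)

    def test_power_increases_with_sample_size(self):
        power = []
        for n in (200, 500, 1000):
            hits = 0
            for seed in range(3):
                cfg = SimulationConfig(
                    n_samples=n,
                    n_markers=10,
                    maf_range=(0.3, 0.3),
                    causal_markers=[(0, 0.4)],
                    seed=100 + seed,
                )
                g = simulate_genotypes(cfg)
                from neurogwas import simulate_phenotype

                pheno = simulate_phenotype(g, cfg)
                res = gwas_linear(g, pheno, [])
                hits += res.set_index("marker").loc["m000000", "p"] < 5e-8
            power.append(hits / 3)
        assert power[0] <= power[1] <= power[2]
        assert power[2] > power[0]


class TestGenomicInflation:
    def test_null_uniform_lambda_near_one(self, rng):
        lam = genomic_inflation(rng.uniform(size=10_000))
        assert 0.95 < lam < 1.05

    def test_constant_half_is_exactly_one(self):
        # median chi-square of p=0.5 equals the null median by definition
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValidationError):
            genomic_inflation([])
        with pytest.raises(ValidationError):
            genomic_inflation([0.5, 0.0])
        with pytest.raises(ValidationError):
            genomic_inflation([0.5, 1.2])


def test_qq_table_is_monotone_and_matches_quantiles(rng):
    from neurogwas import qq_table

    p = rng.uniform(size=500)
    qq = qq_table(p)
    assert len(qq) == 500
    assert (np.diff(qq["observed_neglog10"]) <= 1e-12).all()
    assert qq["observed_neglog10"].iloc[0] == pytest.approx(
        -np.log10(np.sort(p)[0])
    )
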