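"""Association testing and clumping: oracles, calibration, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from oa_phenopower import assoc
from oa_phenopower.simulate.genotypes import GenotypePanel, PanelConfig, simulate_genotypes


def panel_from_dosages(dosages, pos=None, chrom=None):
    m = dosages.shape[1]
    vm = pd.DataFrame(
        {
            "CHR": np.ones(m, dtype=int) if chrom is None else chrom,
            "SNP": [f"snp{i:06d}" for i in range(m)],
            "BP": np.arange(1, m + 1) * 1000 if pos is None else pos,
            "MAF": np.full(m, 0.3),
            "BLOCK": np.zeros(m, dtype=int),
        }
    )
    return GenotypePanel(dosages=np.asarray(dosages, dtype=np.int8), variant_map=vm)


class TestLinearAssoc:
    def test_self_regression_has_unit_beta_and_floor_p(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(200, 3))
        panel = panel_from_dosages(g)
        y = g[:, 1].astype(float) - g[:, 1].mean()
        res = assoc.linear_assoc(panel, y)
        row = res.table.set_index("SNP").loc["snp000001"]
        assert row["BETA"] == pytest.approx(1.0, abs=1e-10)
        assert row["P"] == assoc.P_FLOOR

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        n = 300
        g = rng.integers(0, 3, size=(n, 1))
        covars = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        res = assoc.linear_assoc(panel_from_dosages(g), y, covariates=covars)
        X = np.column_stack([np.ones(n), covars, g[:, 0]])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
        assert res.table["BETA"].iloc[0] == pytest.approx(beta_hat[-1], abs=1e-8)
        assert res.table["SE"].iloc[0] == pytest.approx(se, abs=1e-8)

    def test_type_one_error_calibrated(self, independent_panel):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(independent_panel.n_subjects)
        res = assoc.linear_assoc(independent_panel, y)
        rate = (res.p < 0.05).mean()
        m = len(res.table)
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / m)

    def test_chi2_equals_squared_wald_z(self, independent_panel):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(independent_panel.n_subjects)
        res = assoc.linear_assoc(independent_panel, y)
        np.testing.assert_allclose(
            res.chi2, (res.table["BETA"] / res.table["SE"]) ** 2, atol=1e-6)

    def test_rank_deficient_covariates_rejected(self, independent_panel):
        n = independent_panel.n_subjects
        c = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            assoc.linear_assoc(independent_panel, np.zeros(n), covariates=c)


def logistic_loglik(beta, X, y):
    eta = X @ beta
    return -(y @ eta - np.logaddexp(0, eta).sum())


class TestLogisticAssoc:
    def test_single_snp_matches_generic_ml_oracle(self):
        rng = np.random.default_rng(5)
        n = 400
        g = rng.integers(0, 3, size=(n, 1))
        covar = rng.standard_normal((n, 1))
        logit = -0.5 + 0.4 * g[:, 0] + 0.3 * covar[:, 0]
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = assoc.logistic_assoc(panel_from_dosages(g), y, covariates=covar)
        X = np.column_stack([np.ones(n), covar, g[:, 0]])
        opt = optimize.minimize(logistic_loglik, np.zeros(3), args=(X, y.astype(float)),
                                method="BFGS")
        assert res.table["BETA"].iloc[0] == pytest.approx(opt.x[-1], abs=1e-6)

    def test_null_lambda_near_one(self):
        panel = simulate_genotypes(
            PanelConfig(n_subjects=1000, n_snps=5000, rho=0.0), seed=6)
        rng = np.random.default_rng(7)
        y = rng.random(1000) < 0.5
        res = assoc.logistic_assoc(panel, y)
        assert abs(assoc.lambda_gc(res) - 1.0) < 0.05

    def test_monomorphic_snp_excluded(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, size=(100, 3))
        g[:, 1] = 2
        panel = panel_from_dosages(g)
        y = rng.random(100) < 0.4
        res = assoc.logistic_assoc(panel, y)
        assert "snp000001" not in set(res.table["SNP"])

    def test_one_class_rejected(self):
        g = np.random.default_rng(9).integers(0, 3, size=(50, 2))
        with pytest.raises(ValueError, match="classes"):
            assoc.logistic_assoc(panel_from_dosages(g), np.zeros(50, dtype=bool))


class TestLambdaGC:
    def test_definition_on_constants(self):
        assert assoc.lambda_gc(np.full(11, assoc.CHI2_1DF_MEDIAN)) == pytest.approx(1.0)

    def test_small_sample_median_oracle(self):
        lam = assoc.lambda_gc(np.array([1.0, 2.0, 3.0]))
        assert lam == pytest.approx(2.0 / stats.chi2.ppf(0.5, 1), abs=1e-9)
        assert lam == pytest.approx(4.396, abs=5e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assoc.lambda_gc(np.array([]))


def reference_clump(table, r2_of, params):
    """Direct transcription of the clumping post-condition.

    ``table`` has SNP/CHR/BP/P; ``r2_of(a, b)`` returns the dosage r^2.
    """
    cands = table[table["P"] <= params.p1]
    order = cands.sort_values(["P", "BP", "SNP"]).index
    assigned = set()
    loci = []
    for i in order:
        if table.loc[i, "SNP"] in assigned:
            continue
        index_snp = table.loc[i, "SNP"]
        assigned.add(index_snp)
        members = []
        for j in table.index:
            s = table.loc[j, "SNP"]
            if s in assigned or table.loc[j, "P"] > params.p2:
                continue
            if table.loc[j, "CHR"] != table.loc[i, "CHR"]:
                continue
            if abs(table.loc[j, "BP"] - table.loc[i, "BP"]) > params.window_kb * 1000:
                continue
            if r2_of(index_snp, s) >= params.r2_max:
                assigned.add(s)
                members.append(s)
        loci.append((index_snp, tuple(sorted(members))))
    return loci


class TestGreedyClump:
    def make_result(self, panel, pvals):
        vm = panel.variant_map
        tab = pd.DataFrame(
            {
                "SNP": vm["SNP"],
                "CHR": vm["CHR"],
                "BP": vm["BP"],
                "BETA": 0.1,
                "SE": 0.05,
                "P": pvals,
                "CHI2": 4.0,
            }
        )
        return assoc.AssocResult(table=tab, n_used=panel.n_subjects)

    def test_single_significant_snp_is_one_locus(self, small_panel):
        p = np.ones(small_panel.n_snps)
        p[37] = 1e-10
        loci = assoc.greedy_clump(self.make_result(small_panel, p), small_panel)
        assert loci.count == 1 and loci.loci[0].index_snp == "snp000037"

    def test_hand_executed_three_snp_example(self):
        """A at 100 kb absorbs B (r2 0.5 at 200 kb); C at 600 kb stands alone."""
        rng = np.random.default_rng(10)
        n = 2000
        a = rng.integers(0, 3, size=n)
        flip = rng.random(n) < 0.25
        b = np.where(flip, rng.integers(0, 3, size=n), a)
        c = rng.integers(0, 3, size=n)
        panel = panel_from_dosages(
            np.column_stack([a, b, c]), pos=[100_000, 200_000, 600_000])
        gc = np.column_stack([a, b, c]).astype(float)
        gc -= gc.mean(0)
        r2_ab = (np.corrcoef(gc[:, 0], gc[:, 1])[0, 1]) ** 2
        assert r2_ab > 0.3  # construction sanity
        res = self.make_result(panel, np.array([1e-10, 1e-9, 4e-8]))
        loci = assoc.greedy_clump(res, panel)
        assert loci.count == 2
        assert loci.loci[0].index_snp == "snp000000"
        assert loci.loci[0].members == ["snp000001"]
        assert loci.loci[1].index_snp == "snp000002"

    def test_no_candidate_gives_zero_loci(self, small_panel):
        loci = assoc.greedy_clump(
            self.make_result(small_panel, np.full(small_panel.n_snps, 1e-3)), small_panel)
        assert loci.count == 0

    def random_instance(self, seed):
        panel = simulate_genotypes(
            PanelConfig(n_subjects=500, n_snps=200, block_size=10,
                        block_spacing_bp=np.random.default_rng(seed).choice(
                            [100_000, 300_000, 2_000_000])),
            seed=seed,
        )
        rng = np.random.default_rng(seed + 1)
        p = 10.0 ** (-12 * rng.random(200))
        return panel, self.make_result(panel, p)

    @pytest.mark.parametrize("seed", range(10))
    def test_identical_to_reference_transcription(self, seed):
        panel, res = self.random_instance(seed)
        params = assoc.ClumpParams()
        gc = panel.dosage_float()
        gc -= gc.mean(0)

        def r2_of(sa, sb):
            ja = int(sa[3:])
            jb = int(sb[3:])
            return np.corrcoef(gc[:, ja], gc[:, jb])[0, 1] ** 2

        expected = reference_clump(res.table, r2_of, params)
        got = assoc.greedy_clump(res, panel, params)
        assert [(l.index_snp, tuple(sorted(l.members))) for l in got.loci] == expected

    def test_monotone_in_p1_and_r2(self, small_panel):
        rng = np.random.default_rng(11)
        p = 10.0 ** (-10 * rng.random(small_panel.n_snps))
        res = self.make_result(small_panel, p)
        base = assoc.greedy_clump(res, small_panel, assoc.ClumpParams(p1=5e-8)).count
        looser_p1 = assoc.greedy_clump(res, small_panel, assoc.ClumpParams(p1=1e-4)).count
        assert looser_p1 >= base
        lower_r2 = assoc.greedy_clump(
            res, small_panel, assoc.ClumpParams(p1=5e-8, r2_max=0.01)).count
        assert lower_r2 <= base
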