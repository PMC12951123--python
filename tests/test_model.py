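import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from phylodecline.model import (
    PhyloProbitMM,
    association_test,
    ess,
)
from phylodecline.synthetic import gen_tree
from phylodecline.trees import vcv


def _simulate_binary(n, beta, sigma2_p, seed, tree=None):
    rng = np.random.default_rng(seed)
    p = len(beta) - 1
    x = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    if tree is not None and sigma2_p > 0:
        a = vcv(tree).correlation().matrix
        u = np.sqrt(sigma2_p) * (
            np.linalg.cholesky(a + 1e-10 * np.eye(n))
            @ rng.standard_normal(n)
        )
    else:
        a = np.eye(n)
        u = np.zeros(n)
    y = (x @ np.asarray(beta) + u + rng.standard_normal(n) > 0).astype(float)
    return y, x, a


class TestEss:
    def test_iid_draws(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert 800 <= ess(x) <= 1200

    def test_ar1_matches_theory(self):
        rng = np.random.default_rng(1)
        rho, n = 0.5, 2000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.standard_normal() * np.sqrt(1 - rho**2)
        theory = n * (1 - rho) / (1 + rho)
        assert abs(ess(x) - theory) / theory < 0.25

    def test_constant_sequence(self):
        with pytest.warns(UserWarning):
            assert ess(np.ones(50)) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestFit:
    def test_probit_limit_star_tree(self):
        # no phylogenetic effect: posterior mean of the intercept must sit at
        # the probit quantile of the event fraction
        rng = np.random.default_rng(2)
        n = 600
        y = np.zeros(n)
        y[: int(0.3 * n)] = 1.0
        y = rng.permutation(y)
        m = PhyloProbitMM(y, np.ones((n, 1)), np.eye(n), fix_sigma2_p=0.0)
        res = m.fit(iterations=20_000, burnin=4_000, thin=8, seed=3)
        mcse = res.draws_beta[:, 0].std(ddof=1) / np.sqrt(
            ess(res.draws_beta[:, 0])
        )
        assert abs(res.params.iloc[0] - ndtri(0.3)) < 3 * max(mcse, 1e-3)

    def test_draw_count_contract(self):
        y, x, a = _simulate_binary(50, [0.0, 1.0], 0.0, seed=4)
        res = PhyloProbitMM(y, x, a).fit(
            iterations=2_000, burnin=500, thin=5, seed=4
        )
        assert res.n_draws == (2_000 - 500) // 5
        assert res.draws_u.shape == (res.n_draws, 50)

    def test_fixed_seed_bit_identical(self):
        tree = gen_tree(60, seed=5)
        y, x, a = _simulate_binary(60, [0.0, 1.0], 1.0, seed=5, tree=tree)
        r1 = PhyloProbitMM(y, x, a).fit(iterations=3_000, burnin=500,
                                        thin=5, seed=6)
        r2 = PhyloProbitMM(y, x, a).fit(iterations=3_000, burnin=500,
                                        thin=5, seed=6)
        np.testing.assert_array_equal(r1.draws_beta, r2.draws_beta)
        np.testing.assert_array_equal(r1.draws_sigma2_p, r2.draws_sigma2_p)

    def test_rank_deficiency_names_columns(self):
        n = 40
        x = np.column_stack([np.ones(n), np.arange(n), 2 * np.arange(n)])
        y = (np.arange(n) > 20).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            PhyloProbitMM(y, x, np.eye(n), exog_names=["c0", "c1", "c1x2"])

    def test_all_zero_response_completes(self):
        n = 40
        with pytest.warns(UserWarning, match="separation"):
            m = PhyloProbitMM(
                np.zeros(n), np.ones((n, 1)), np.eye(n), fix_sigma2_p=0.0
            )
        res = m.fit(iterations=4_000, burnin=1_000, thin=3, seed=7)
        assert res.params.iloc[0] < -1.0

    def test_credible_interval_brackets_mean(self):
        y, x, a = _simulate_binary(80, [0.2, 0.8], 0.0, seed=8)
        res = PhyloProbitMM(y, x, a).fit(
            iterations=4_000, burnin=1_000, thin=4, seed=8
        )
        ci = res.conf_int()
        assert (ci["ci_low"] <= res.params).all()
        assert (res.params <= ci["ci_high"]).all()

    def test_summary_table_shape(self):
        y, x, a = _simulate_binary(50, [0.0, 0.5], 0.0, seed=9)
        res = PhyloProbitMM(
            y, x, a, exog_names=["intercept", "slope"]
        ).fit(iterations=2_000, burnin=500, thin=5, seed=9)
        s = res.summary()
        assert list(s.index) == ["intercept", "slope", "sigma2_p"]
        assert {"post_mean", "ci_low", "ci_high", "ess", "significant"} <= set(
            s.columns
        )


class TestDic:
    def test_degenerate_chain_has_zero_pd(self):
        y, x, a = _simulate_binary(40, [0.0, 1.0], 0.0, seed=10)
        res = PhyloProbitMM(y, x, a).fit(
            iterations=2_000, burnin=500, thin=5, seed=10
        )
        res.draws_beta = np.repeat(res.draws_beta[:1], 50, axis=0)
        res.draws_u = np.repeat(res.draws_u[:1] * 0, 50, axis=0)
        dbar, p_d, dic = res.dic()
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(dbar, abs=1e-8)

    def test_true_predictor_lowers_dic(self):
        rng = np.random.default_rng(11)
        n = 200
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (x @ np.array([0.0, 1.5]) + rng.standard_normal(n) > 0).astype(float)
        full = PhyloProbitMM(y, x, np.eye(n), fix_sigma2_p=0.0).fit(
            iterations=6_000, burnin=1_000, thin=5, seed=11
        )
        null = PhyloProbitMM(y, x[:, :1], np.eye(n), fix_sigma2_p=0.0).fit(
            iterations=6_000, burnin=1_000, thin=5, seed=11
        )
        assert null.dic()[2] - full.dic()[2] > 10

    def test_too_few_draws_rejected(self):
        y, x, a = _simulate_binary(40, [0.0, 1.0], 0.0, seed=12)
        res = PhyloProbitMM(y, x, a).fit(
            iterations=2_000, burnin=500, thin=5, seed=12
        )
        res.draws_beta = res.draws_beta[:5]
        res.draws_u = res.draws_u[:5]
        with pytest.raises(ValueError):
            res.dic()


class TestExchangeability:
    def test_permuted_species_order_same_answer(self):
        tree = gen_tree(60, seed=13)
        y, x, a = _simulate_binary(60, [0.0, 1.0], 1.0, seed=13, tree=tree)
        perm = np.random.default_rng(13).permutation(60)
        r1 = PhyloProbitMM(y, x, a).fit(
            iterations=20_000, burnin=4_000, thin=8, seed=14
        )
        r2 = PhyloProbitMM(y[perm], x[perm], a[np.ix_(perm, perm)]).fit(
            iterations=20_000, burnin=4_000, thin=8, seed=14
        )
        sd = r1.draws_beta[:, 1].std(ddof=1)
        assert abs(r1.params.iloc[1] - r2.params.iloc[1]) < 4 * sd / np.sqrt(
            min(ess(r1.draws_beta[:, 1]), ess(r2.draws_beta[:, 1]))
        ) + 0.05


class TestAssociationTest:
    @staticmethod
    def _category_table(n, seed):
        """Stability probability rises monotonically from CR to LC."""
        rng = np.random.default_rng(seed)
        cats = ["CR", "EN", "VU", "NT", "LC"]
        p_stable = {"CR": 0.05, "EN": 0.2, "VU": 0.4, "NT": 0.6, "LC": 0.85}
        rows = []
        for i in range(n):
            c = cats[i % len(cats)]
            stable = rng.random() < p_stable[c]
            rows.append(
                {"trend": "stable" if stable else "decreasing",
                 "threat_category": c}
            )
        return pd.DataFrame(rows, index=[f"t{i}" for i in range(n)])

    def test_monotone_stability_gives_positive_lc_contrast(self):
        n = 400
        table = self._category_table(n, seed=15)
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        from phylodecline.trees import parse_newick

        tree = parse_newick(newick)
        res = association_test(
            table, tree, iterations=8_000, burnin=2_000, thin=5, seed=15,
            fix_sigma2_p=0.0,
        )
        summ = res.summary()
        assert summ.loc["cat_LC", "post_mean"] > 0
        assert summ.loc["cat_LC", "ci_low"] > 0  # CI excludes zero

    def test_single_category_rejected(self):
        table = pd.DataFrame(
            {
                "trend": ["stable", "decreasing"] * 10,
                "threat_category": ["LC"] * 20,
            },
            index=[f"t{i}" for i in range(20)],
        )
        from phylodecline.trees import parse_newick

        tree = parse_newick(
            "(" + ",".join(f"t{i}:1" for i in range(20)) + ");"
        )
        with pytest.raises(ValueError):
            association_test(table, tree)
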