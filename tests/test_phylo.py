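import shutil
import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plumage import phylo
from plumage.errors import RankError, TreeError
from plumage.synth import SyntheticConfig, gen_tree

STAR4 = "(a:1.0,b:1.0,c:1.0,d:1.0);"
CHERRY = "((a:0.4,b:0.4):0.6,(c:0.4,d:0.4):0.6);"


def star_tree(n):
    tips = ",".join(f"t{i}:1.0" for i in range(n))
    return phylo.read_tree(f"({tips});")


class TestBrownianCov:
    def test_star_tree_identity(self):
        C = phylo.brownian_cov(phylo.read_tree(STAR4)).to_numpy()
        np.testing.assert_allclose(C, np.eye(4), atol=1e-12)

    def test_two_tip_and_cherry_hand_computation(self):
        C2 = phylo.brownian_cov(phylo.read_tree("(a:1.0,b:1.0);")).to_numpy()
        np.testing.assert_allclose(C2, np.eye(2), atol=1e-12)
        C = phylo.brownian_cov(phylo.read_tree(CHERRY))
        assert C.loc["a", "b"] == pytest.approx(0.6)
        assert C.loc["a", "c"] == pytest.approx(0.0)
        assert C.loc["a", "a"] == pytest.approx(1.0)

    def test_lambda_zero_is_diagonal(self):
        C = phylo.brownian_cov(phylo.read_tree(CHERRY), lam=0.0).to_numpy()
        np.testing.assert_allclose(C, np.diag(np.diag(C)))

    def test_negative_branch_rejected(self):
        with pytest.raises(TreeError):
            phylo.read_tree("(a:1.0,b:-0.5);")

    def test_tip_permutation_invariance(self, tree):
        labels = phylo.tip_labels(tree)
        perm = labels[::-1]
        C1 = phylo.brownian_cov(tree, labels=labels)
        C2 = phylo.brownian_cov(tree, labels=perm)
        np.testing.assert_allclose(C1.loc[perm, perm].to_numpy(), C2.to_numpy())


class TestPhyloPairedTTest:
    def test_equal_conditions_give_null(self, tree):
        labels = phylo.tip_labels(tree)
        x = pd.Series(np.linspace(1, 2, len(labels)), index=labels)
        res = phylo.phylo_paired_ttest(x, x, tree, fix_lambda=1.0)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_star_tree_matches_ordinary_paired_t(self):
        tr = star_tree(8)
        labels = phylo.tip_labels(tr)
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(10, 2, 8), index=labels)
        y = pd.Series(x + rng.normal(1, 1, 8), index=labels)
        ours = phylo.phylo_paired_ttest(x, y, tr, fix_lambda=0.0)
        ref = stats.ttest_rel(x, y)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.mean_difference == pytest.approx(float(np.mean(x - y)), rel=1e-12)

    def test_lambda_in_unit_interval_and_profile_optimal(self, tree):
        labels = phylo.tip_labels(tree)
        rng = np.random.default_rng(9)
        x = pd.Series(rng.normal(50, 5, len(labels)), index=labels)
        y = pd.Series(x - 20 + rng.normal(0, 3, len(labels)), index=labels)
        res = phylo.phylo_paired_ttest(x, y, tree)
        assert 0.0 <= res.lam <= 1.0
        # the profiled ML lambda beats both boundary values
        for lam in (0.0, 1.0):
            fixed = phylo.phylo_paired_ttest(x, y, tree, fix_lambda=lam)
            assert res.sigma2 <= fixed.sigma2 * (1 + 1e-6) or res.lam in (0.0, 1.0)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        tr = star_tree(12)
        labels = phylo.tip_labels(tr)
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.normal(0, 1, 12)}, index=labels)
        y = pd.Series(2.0 + 3.0 * X.x1 + rng.normal(0, 0.5, 12), index=labels)
        ours = phylo.pgls(y, X, tr)
        lr = stats.linregress(X.x1.to_numpy(), y.to_numpy())
        assert ours["coefficients"]["x1"] == pytest.approx(lr.slope, rel=1e-10)
        assert ours["coefficients"]["intercept"] == pytest.approx(lr.intercept, rel=1e-10)
        assert ours["se"]["x1"] == pytest.approx(lr.stderr, rel=1e-9)

    def test_perfect_fit_coefficient_one(self, tree):
        labels = phylo.tip_labels(tree)
        x = pd.Series(np.linspace(0, 1, len(labels)), index=labels)
        res = phylo.pgls(x, pd.DataFrame({"x": x}), tree)
        assert res["coefficients"]["x"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res["residuals"], 0, atol=1e-9)

    def test_rank_deficiency_rejected(self, tree):
        labels = phylo.tip_labels(tree)
        x = pd.Series(np.ones(len(labels)), index=labels)
        with pytest.raises(RankError):
            phylo.pgls(x, pd.DataFrame({"x": x}), tree)  # duplicates intercept

    def test_ou_model_runs_and_matches_bm_direction(self, tree):
        labels = phylo.tip_labels(tree)
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(0, 1, len(labels))}, index=labels)
        y = pd.Series(1 + 2 * X.x + rng.normal(0, 0.3, len(labels)), index=labels)
        bm = phylo.pgls(y, X, tree, model="BM")
        ou = phylo.pgls(y, X, tree, model="OU")
        assert np.sign(bm["coefficients"]["x"]) == np.sign(ou["coefficients"]["x"])
        assert ou["coefficients"]["x"] == pytest.approx(2.0, abs=0.5)


class TestPCA:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (12, 2))
        return pd.DataFrame({
            "a": 10 ** (base[:, 0]),
            "b": 10 ** (0.8 * base[:, 0] + 0.3 * rng.normal(size=12)),
            "c": 10 ** (base[:, 1]),
        })

    def test_variance_fractions_sum_to_one(self, table):
        res = phylo.pca(table, log=True)
        assert res["variance_fraction"].sum() == pytest.approx(1.0)

    def test_single_varying_column_dominates(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": 1.0, "c": 2.0})
        res = phylo.pca(t, scale=False)
        assert res["variance_fraction"]["PC1"] == pytest.approx(1.0)

    def test_constant_column_with_scaling_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": 5.0})
        with pytest.raises(RankError) as exc:
            phylo.pca(t, scale=True)
        assert "b" in str(exc.value)

    def test_reconstruction_identity(self, table):
        res = phylo.pca(table, log=True)
        approx = res["scores"].to_numpy() @ res["loadings"].to_numpy().T
        np.testing.assert_allclose(approx, res["transformed"].to_numpy(), atol=1e-10)

    def test_listwise_deletion_reported(self, table):
        t = table.copy()
        t.loc[3, "a"] = np.nan
        res = phylo.pca(t, log=True)
        assert res["dropped"] == [3]


class TestPhyloPCA:
    def test_star_tree_lambda_zero_matches_standard_pca(self):
        tr = star_tree(10)
        labels = phylo.tip_labels(tr)
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(0, 1, (10, 3)), index=labels,
                         columns=["a", "b", "c"])
        std = phylo.pca(X, center=True, scale=False)
        ph = phylo.phylo_pca(X, tr, method="BM")  # star tree: C = I = any lambda
        np.testing.assert_allclose(
            np.abs(ph["scores"].to_numpy()),
            np.abs(std["scores"].loc[labels].to_numpy()), atol=1e-8)

    def test_constant_trait_contributes_nothing(self, tree):
        labels = phylo.tip_labels(tree)
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.normal(0, 1, len(labels)),
                          "b": 3.0}, index=labels)
        res = phylo.phylo_pca(X, tree)
        assert res["eigenvalues"]["PC2"] == pytest.approx(0.0, abs=1e-10)

    def test_imbalanced_tree_differs_from_standard(self, tree):
        labels = phylo.tip_labels(tree)
        C = phylo.brownian_cov(tree, 1.0, labels).to_numpy()
        rng = np.random.default_rng(12)
        # traits simulated under BM on the (imbalanced) tree
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(labels)))
        X = pd.DataFrame(L @ rng.normal(0, 1, (len(labels), 3)), index=labels,
                         columns=["a", "b", "c"])
        std = phylo.pca(X, scale=False)
        ph = phylo.phylo_pca(X, tree, method="BM")
        diff = np.abs(np.abs(ph["scores"].to_numpy())
                      - np.abs(std["scores"].loc[labels].to_numpy())).max()
        assert diff > 1e-3


class TestAncestralStates:
    def test_constant_trait_everywhere(self, tree):
        labels = phylo.tip_labels(tree)
        rec = phylo.ancestral_states(tree, pd.Series(4.2, index=labels))
        vals = np.array(list(rec["node_states"].values()))
        np.testing.assert_allclose(vals, 4.2, atol=1e-9)

    def test_two_tip_closed_form_root(self):
        tr = phylo.read_tree("(a:0.5,b:2.0);")
        rec = phylo.ancestral_states(tr, pd.Series({"a": 1.0, "b": 4.0}))
        v1, v2, x1, x2 = 0.5, 2.0, 1.0, 4.0
        expected = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        assert rec["root_state"] == pytest.approx(expected, rel=1e-9)

    def test_recovers_simulated_bm_states(self):
        cfg = SyntheticConfig(seed=21, n_species=50)
        tr = gen_tree(cfg)
        rng = np.random.default_rng(21)
        true = {tr.seed_node: 0.0}
        for nd in tr.preorder_node_iter():
            if nd.parent_node is not None:
                v = nd.edge.length or 0.0
                true[nd] = true[nd.parent_node] + rng.normal(0, np.sqrt(max(v, 1e-12)))
        tips = pd.Series({leaf.taxon.label: true[leaf]
                          for leaf in tr.leaf_node_iter()})
        rec = phylo.ancestral_states(tr, tips)
        internal = [nd for nd in tr.preorder_node_iter() if not nd.is_leaf()]
        est = np.array([rec["node_states"][nd] for nd in internal])
        tru = np.array([true[nd] for nd in internal])
        assert np.corrcoef(est, tru)[0, 1] > 0.8

    def test_interpolation_linear_along_branch(self):
        tr = phylo.read_tree("(a:1.0,b:1.0);")
        rec = phylo.ancestral_states(tr, pd.Series({"a": 0.0, "b": 2.0}))
        mid = rec["interpolate"]("a", 0.5)
        assert mid == pytest.approx((rec["root_state"] + 0.0) / 2)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestRCrossChecks:
    """Independent oracles from the R comparative-methods ecosystem."""

    def test_pgls_matches_nlme_gls(self, tmp_path):
        newick = "((a:0.3,b:0.3):0.7,(c:0.5,d:0.5):0.5);"
        y = {"a": 1.0, "b": 1.4, "c": 2.4, "d": 2.0}
        x = {"a": 0.1, "b": 0.3, "c": 0.9, "d": 0.7}
        script = textwrap.dedent(f"""
            suppressMessages({{library(ape); library(nlme)}})
            tr <- read.tree(text="{newick}")
            d <- data.frame(y=c(1.0,1.4,2.4,2.0), x=c(0.1,0.3,0.9,0.7),
                            species=c("a","b","c","d"))
            d <- d[match(tr$tip.label, d$species), ]
            fit <- gls(y ~ x, data=d,
                       correlation=corBrownian(1, tr, form=~species))
            cat(coef(fit), sep="\\n")
        """)
        path = tmp_path / "pgls.R"
        path.write_text(script)
        out = subprocess.run(["Rscript", "--vanilla", str(path)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_int, r_slope = (float(v) for v in out.stdout.split())
        tr = phylo.read_tree(newick)
        res = phylo.pgls(pd.Series(y), pd.DataFrame({"x": pd.Series(x)}), tr)
        assert res["coefficients"]["intercept"] == pytest.approx(r_int, rel=1e-6)
        assert res["coefficients"]["x"] == pytest.approx(r_slope, rel=1e-6)

    def test_ancestral_root_matches_ape_ace(self, tmp_path):
        newick = "((a:0.3,b:0.3):0.7,(c:0.5,d:0.5):0.5);"
        script = textwrap.dedent(f"""
            suppressMessages(library(ape))
            tr <- read.tree(text="{newick}")
            x <- c(a=1.0, b=3.0, c=5.0, d=4.0)
            fit <- ace(x, tr, method="REML")
            cat(fit$ace[1], sep="\\n")
        """)
        path = tmp_path / "anc.R"
        path.write_text(script)
        out = subprocess.run(["Rscript", "--vanilla", str(path)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_root = float(out.stdout.strip().splitlines()[-1])
        rec = phylo.ancestral_states(
            phylo.read_tree(newick),
            pd.Series({"a": 1.0, "b": 3.0, "c": 5.0, "d": 4.0}))
        assert rec["root_state"] == pytest.approx(r_root, rel=1e-4)
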