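import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from gutcompass import GutcompassError, marginal_partition, permanova, rda, stepwise_rda
from gutcompass.enterotypes import DistanceMatrix, euclidean_distance
from gutcompass.variance import build_design, ezekiel_adjust


class TestRda:
    def test_point_biserial_equivalence(self, rng):
        y = rng.normal(size=40)
        x = rng.integers(0, 2, 40).astype(float)
        res = rda(pd.DataFrame({"y": y}), pd.DataFrame({"x": x}))
        r = stats.pointbiserialr(x, y).correlation
        assert res.r2 == pytest.approx(r ** 2, abs=1e-10)

    def test_orthogonal_design_gives_zero(self):
        y = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0]})
        x = pd.DataFrame({"x": [1.0, 1.0, -1.0, -1.0]})
        assert rda(y, x).r2 == pytest.approx(0.0, abs=1e-12)

    def test_ezekiel_formula(self):
        assert ezekiel_adjust(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9)

    def test_identity_response(self, rng):
        x = pd.DataFrame({"x": rng.normal(size=20)})
        assert rda(x.copy(), x).r2 == pytest.approx(1.0, abs=1e-9)

    def test_global_r2_bounds_marginals(self, rng):
        y = pd.DataFrame(rng.normal(size=(50, 8)))
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        res = marginal_partition(y, X)
        assert (res.marginal["r2"] <= res.r2 + 1e-12).all()
        assert res.adj_r2 <= res.r2

    def test_constant_variable_dropped(self, rng, caplog):
        import logging
        y = pd.DataFrame(rng.normal(size=(20, 4)))
        X = pd.DataFrame({"c": np.ones(20), "x": rng.normal(size=20)})
        with caplog.at_level(logging.WARNING, logger="gutcompass"):
            res = marginal_partition(y, X)
        row = res.marginal[res.marginal["variable"] == "c"]
        assert np.isnan(row["adj_r2"].iloc[0])

    def test_matches_vegan_rda(self, rng, tmp_path):
        y = rng.normal(size=(25, 6))
        X = pd.DataFrame({"a": rng.normal(size=25),
                          "b": rng.integers(0, 2, 25).astype(float)})
        res = rda(pd.DataFrame(y), X)
        ypath, xpath = tmp_path / "y.csv", tmp_path / "x.csv"
        pd.DataFrame(y).to_csv(ypath, index=False)
        X.to_csv(xpath, index=False)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("{ypath}")); X <- read.csv("{xpath}")
            m <- rda(Y ~ a + b, data=X)
            r <- RsquareAdj(m)
            cat(sprintf("%.12f %.12f", r$r.squared, r$adj.r.squared))
        """)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=120)
        r2_ref, adj_ref = map(float, out.stdout.split())
        assert res.r2 == pytest.approx(r2_ref, abs=1e-9)
        assert res.adj_r2 == pytest.approx(adj_ref, abs=1e-9)


class TestDesign:
    def test_categorical_dummy_coding(self):
        X = pd.DataFrame({"g": ["a", "b", "c", "a"]})
        mat, names, dropped = build_design(X)
        assert mat.shape == (4, 2)
        assert not dropped

    def test_aliased_column_dropped(self, rng):
        x = rng.normal(size=10)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        mat, names, dropped = build_design(X)
        assert dropped == ["x2"]


class TestStepwise:
    def test_single_strong_candidate_selected(self, rng):
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        y = np.outer(x, rng.normal(size=5)) + 0.3 * rng.normal(size=(n, 5))
        res = stepwise_rda(pd.DataFrame(y), pd.DataFrame({"x": x}),
                           n_perm=199, seed=0)
        assert list(res.stepwise["variable"]) == ["x"]
        assert res.stepwise["p"].iloc[0] < 0.05

    def test_trace_adjr2_nondecreasing(self, rng):
        n = 80
        X = pd.DataFrame({f"x{i}": rng.integers(0, 2, n).astype(float)
                          for i in range(4)})
        y = (np.outer(X["x0"], rng.normal(size=10))
             + np.outer(X["x1"], rng.normal(size=10))
             + 0.8 * rng.normal(size=(n, 10)))
        res = stepwise_rda(pd.DataFrame(y), X, n_perm=99, seed=0)
        adj = res.stepwise["adj_r2"].to_numpy()
        assert (np.diff(adj) >= -1e-12).all()

    def test_matches_vegan_ordir2step_selection(self, rng, tmp_path):
        n = 60
        X = pd.DataFrame({f"x{i}": rng.integers(0, 2, n).astype(float)
                          for i in range(5)})
        y = (np.outer(X["x0"], rng.normal(size=8)) * 1.5
             + 0.8 * rng.normal(size=(n, 8)))
        res = stepwise_rda(pd.DataFrame(y), X, n_perm=199, seed=0)
        ypath, xpath = tmp_path / "y.csv", tmp_path / "x.csv"
        pd.DataFrame(y).to_csv(ypath, index=False)
        X.to_csv(xpath, index=False)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("{ypath}")); X <- read.csv("{xpath}")
            m0 <- rda(Y ~ 1, data=X); m1 <- rda(Y ~ ., data=X)
            set.seed(1)
            sel <- ordiR2step(m0, scope=formula(m1), trace=FALSE,
                              permutations=how(nperm=199))
            cat(attr(terms(sel), "term.labels"))
        """)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=180)
        vegan_sel = out.stdout.split()
        assert list(res.stepwise["variable"]) == vegan_sel


class TestPermanova:
    def test_exhaustive_enumeration_small_instance(self, rng):
        pts = rng.standard_normal((6, 3))
        D = euclidean_distance(pd.DataFrame(pts))
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = permanova(D, g, n_perm=9999, seed=0)
        from itertools import combinations
        fs = []
        for combo in combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            fs.append(permanova(D, lab, n_perm=99, seed=0).pseudo_f)
        exact = np.mean([f >= res.pseudo_f - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_separated_clusters_give_minimal_p(self, rng):
        # n large enough that no random permutation reproduces the grouping
        pts = np.vstack([rng.standard_normal((15, 2)),
                         rng.standard_normal((15, 2)) + 50])
        D = euclidean_distance(pd.DataFrame(pts))
        g = np.repeat(["a", "b"], 15)
        res = permanova(D, g, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_pseudo_f_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.standard_normal((18, 4))
        D = euclidean_distance(pd.DataFrame(pts))
        g = np.repeat(["a", "b", "c"], 6)
        res = permanova(D, g, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.values), g, permutations=99)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_pseudo_f_matches_vegan_adonis(self, rng, tmp_path):
        pts = rng.standard_normal((15, 3))
        g = np.repeat(["a", "b", "c"], 5)
        D = euclidean_distance(pd.DataFrame(pts))
        res = permanova(D, g, n_perm=99, seed=0)
        path = tmp_path / "pts.csv"
        pd.DataFrame(pts).to_csv(path, index=False)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            P <- as.matrix(read.csv("{path}"))
            g <- factor(rep(c("a","b","c"), each=5))
            a <- adonis2(dist(P) ~ g, permutations=99)
            cat(sprintf("%.12f %.12f", a$F[1], a$R2[1]))
        """)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=120)
        f_ref, r2_ref = map(float, out.stdout.split())
        assert res.pseudo_f == pytest.approx(f_ref, rel=1e-9)
        assert res.partial_r2 == pytest.approx(r2_ref, rel=1e-9)

    def test_identical_seed_identical_p(self, rng):
        pts = rng.standard_normal((12, 2))
        D = euclidean_distance(pd.DataFrame(pts))
        g = np.repeat(["a", "b"], 6)
        p1 = permanova(D, g, n_perm=199, seed=5).p_value
        p2 = permanova(D, g, n_perm=199, seed=5).p_value
        assert p1 == p2

    def test_single_group_rejected(self, rng):
        D = euclidean_distance(pd.DataFrame(rng.standard_normal((6, 2))))
        with pytest.raises(GutcompassError):
            permanova(D, ["a"] * 6, n_perm=99, seed=0)

    def test_euclidean_f_equals_rda_f(self, rng):
        # PERMANOVA on Euclidean distances reproduces the classical RDA F
        n = 20
        y = rng.standard_normal((n, 4))
        x = rng.integers(0, 2, n).astype(float)
        D = euclidean_distance(pd.DataFrame(y))
        perm = permanova(D, pd.DataFrame({"x": x}), n_perm=99, seed=0)
        res = rda(pd.DataFrame(y), pd.DataFrame({"x": x}))
        f_rda = (res.r2 / 1) / ((1 - res.r2) / (n - 2))
        assert perm.pseudo_f == pytest.approx(f_rda, rel=1e-9)
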