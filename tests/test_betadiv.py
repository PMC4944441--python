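"""Weighted UniFrac and sequential-SS PERMANOVA."""

import io as _io
import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import TreeNode

from dysbiome.betadiv import (
    DistanceMatrix,
    distance_matrix,
    permanova,
    weighted_unifrac,
)
from dysbiome.containers import TaxonTable, ValidationError, stage_rng


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def _star(k: int) -> TreeNode:
    leaves = ",".join(f"T{j}:1" for j in range(k))
    return _tree(f"({leaves});")


class TestWeightedUnifrac:
    def test_identical_compositions_zero(self):
        tree = _star(4)
        taxa = [f"T{j}" for j in range(4)]
        v = np.array([5.0, 1.0, 3.0, 1.0])
        assert weighted_unifrac(v, 2 * v, tree, taxa) == pytest.approx(0.0)

    def test_star_tree_is_l1_distance(self):
        rng = np.random.default_rng(0)
        tree = _star(6)
        taxa = [f"T{j}" for j in range(6)]
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            expected = np.abs(p - q).sum()
            assert weighted_unifrac(p, q, tree, taxa) == pytest.approx(
                expected, abs=1e-12)

    def test_three_leaf_hand_walked_example(self):
        # ((A:1,B:1):1,C:2); p on A only, q on C only:
        # |1-0|*1 + |0-0|*1 + |1-0|*1 + |0-1|*2 = 4
        tree = _tree("((A:1,B:1):1,C:2);")
        d = weighted_unifrac(np.array([1.0, 0, 0]), np.array([0, 0, 1.0]),
                             tree, ["A", "B", "C"])
        assert d == pytest.approx(4.0, abs=1e-12)

    def test_matches_scikit_bio(self):
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(42)
        tree = _tree("((A:0.5,B:1.2):0.7,((C:0.3,D:0.9):1.1,E:2.0):0.4);")
        taxa = list("ABCDE")
        counts = rng.integers(0, 50, size=(4, 5)) + 1
        tbl = TaxonTable(pd.DataFrame(counts, index=list("wxyz"),
                                      columns=taxa), "counts")
        for normalized in (False, True):
            mine = distance_matrix(tbl, tree, normalized=normalized).values
            ref = beta_diversity("weighted_unifrac", counts,
                                 ids=list("wxyz"), taxa=taxa, tree=tree,
                                 normalized=normalized).data
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_taxon_missing_from_tree_rejected(self):
        tree = _star(2)
        with pytest.raises(ValidationError, match="absent"):
            weighted_unifrac(np.array([1.0, 1.0, 1.0]),
                             np.array([1.0, 1.0, 1.0]), tree,
                             ["T0", "T1", "MISSING"])


class TestDistanceMatrix:
    def test_duplicate_samples_have_zero_distance(self):
        tree = _star(3)
        taxa = [f"T{j}" for j in range(3)]
        data = pd.DataFrame([[3.0, 2, 5], [3.0, 2, 5], [1.0, 8, 1]],
                            index=["a", "b", "c"], columns=taxa)
        dm = distance_matrix(TaxonTable(data, "counts"), tree)
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] > 0

    def test_triangle_inequality_raw_form(self):
        rng = np.random.default_rng(1)
        tree = _tree("((A:0.5,B:1.2):0.7,((C:0.3,D:0.9):1.1,E:2.0):0.4);")
        taxa = list("ABCDE")
        comps = rng.dirichlet(np.ones(5) * 0.5, size=50)
        data = pd.DataFrame(comps, index=[f"s{i}" for i in range(50)],
                            columns=taxa)
        dm = distance_matrix(TaxonTable(data, "frequencies"), tree).values
        for i, j, k in itertools.combinations(range(12), 3):
            assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-10

    def test_sample_permutation_consistency(self):
        rng = np.random.default_rng(2)
        tree = _star(4)
        taxa = [f"T{j}" for j in range(4)]
        counts = rng.integers(1, 30, size=(5, 4)).astype(float)
        ids = [f"s{i}" for i in range(5)]
        tbl = TaxonTable(pd.DataFrame(counts, index=ids, columns=taxa),
                         "counts")
        perm = rng.permutation(5)
        tbl_p = TaxonTable(pd.DataFrame(counts[perm],
                                        index=[ids[i] for i in perm],
                                        columns=taxa), "counts")
        a = distance_matrix(tbl, tree).values
        b = distance_matrix(tbl_p, tree).values
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, atol=1e-12)


def _random_distance(rng, n, dim=3):
    pts = rng.normal(size=(n, dim))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix([f"s{i}" for i in range(n)], D)


def permanova_f_oracle(D, labels):
    """Single-factor pseudo-F computed straight from the group-wise
    squared-distance identity SS_within = sum_g (1/n_g) sum_{i<j in g}
    d_ij^2 (independent of the projection-based implementation)."""
    n = len(labels)
    D2 = D ** 2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = np.unique(labels).size - 1
    df_w = n - df_b - 1
    return ss_between, ss_within, (ss_between / df_b) / (ss_within / df_w)


class TestPermanova:
    def test_constant_factor_rejected(self):
        dm = _random_distance(np.random.default_rng(0), 6)
        with pytest.raises(ValidationError, match="constant"):
            permanova(dm, {"f": np.array(["a"] * 6)}, n_permutations=0)

    def test_equal_distance_closed_form(self):
        # all off-diagonal distances equal -> F = 1 and
        # R^2 = df_between / (n - 1) exactly
        n = 8
        D = np.full((n, n), 2.5)
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], D)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = permanova(dm, {"g": labels}, n_permutations=0)
        assert res.pseudo_f[0] == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared[0] == pytest.approx(1.0 / (n - 1), abs=1e-9)

    def test_r_squared_sums_to_one_with_residual(self):
        rng = np.random.default_rng(3)
        dm = _random_distance(rng, 10)
        res = permanova(dm, {
            "f1": np.array(list("aabbab" + "abab")),
            "f2": np.array(list("xyxyxy" + "xyxy")),
        }, n_permutations=0)
        total = res.r_squared.sum() + res.ss_residual / res.ss_total
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_groupwise_identity_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(6, 14))
            dm = _random_distance(rng, n)
            labels = rng.choice(["a", "b", "c"], size=n)
            if np.unique(labels).size < 2:
                continue
            ss_b, ss_w, f = permanova_f_oracle(dm.values, labels)
            res = permanova(dm, {"g": labels}, n_permutations=0)
            assert res.sums_of_squares[0] == pytest.approx(ss_b, rel=1e-9)
            assert res.ss_residual == pytest.approx(ss_w, rel=1e-9)
            assert res.pseudo_f[0] == pytest.approx(f, rel=1e-9)

    def test_mc_p_matches_exhaustive_enumeration(self):
        # n=6, two groups of 3: only 20 distinct assignments; the MC
        # engine must agree with full enumeration
        rng = np.random.default_rng(5)
        dm = _random_distance(rng, 6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        f_obs = permanova(dm, {"g": labels}, n_permutations=0).pseudo_f[0]
        f_all = []
        for pos in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6, dtype=object)
            for i in pos:
                lab[i] = "a"
            f_all.append(
                permanova(dm, {"g": lab}, n_permutations=0).pseudo_f[0])
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])
        res = permanova(dm, {"g": labels}, n_permutations=4999,
                        rng=stage_rng(0, "perm"))
        assert res.p_values[0] == pytest.approx(p_exact, abs=0.02)

    def test_relabeling_samples_changes_nothing(self):
        rng = np.random.default_rng(6)
        dm = _random_distance(rng, 9)
        labels = rng.choice(["a", "b"], size=9)
        while np.unique(labels).size < 2:
            labels = rng.choice(["a", "b"], size=9)
        r1 = permanova(dm, {"g": labels}, 99, stage_rng(1, "x"))
        dm2 = DistanceMatrix([f"q{i}" for i in range(9)], dm.values)
        r2 = permanova(dm2, {"g": labels}, 99, stage_rng(1, "x"))
        np.testing.assert_allclose(r1.r_squared, r2.r_squared)
        np.testing.assert_allclose(r1.p_values, r2.p_values)

    def test_term_order_changes_split_but_not_total(self):
        rng = np.random.default_rng(7)
        dm = _random_distance(rng, 12)
        f1 = rng.choice(["a", "b"], size=12)
        f2 = rng.choice(["x", "y"], size=12)
        while np.unique(f1).size < 2 or np.unique(f2).size < 2:
            f1 = rng.choice(["a", "b"], size=12)
            f2 = rng.choice(["x", "y"], size=12)
        r12 = permanova(dm, {"f1": f1, "f2": f2}, n_permutations=0)
        r21 = permanova(dm, {"f2": f2, "f1": f1}, n_permutations=0)
        assert r12.ss_total == pytest.approx(r21.ss_total, rel=1e-12)
        assert (r12.sums_of_squares.sum() + r12.ss_residual
                == pytest.approx(r21.sums_of_squares.sum()
                                 + r21.ss_residual, rel=1e-9))

    def test_null_p_values_uniform(self):
        # labels independent of distances -> p ~ U(0,1); KS across 500
        # simulated datasets must not reject at 0.01
        rng = np.random.default_rng(8)
        pvals = []
        for i in range(500):
            dm = _random_distance(rng, 12)
            labels = np.array(["a"] * 6 + ["b"] * 6)
            res = permanova(dm, {"g": labels}, n_permutations=199,
                            rng=stage_rng(i, "null-p"))
            pvals.append(res.p_values[0])
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_matches_vegan_adonis2(self, tmp_path):
        # independent R oracle on a small fixture
        rng = np.random.default_rng(42)
        n = 10
        dm = _random_distance(rng, n)
        f1 = np.array(["a", "a", "a", "b", "b", "b", "a", "b", "a", "b"])
        f2 = np.array(["x", "y"] * 5)
        res = permanova(dm, {"f1": f1, "f2": f2}, n_permutations=0)
        np.savetxt(tmp_path / "D.tsv", dm.values, delimiter="\t")
        with open(tmp_path / "f.tsv", "w") as fh:
            fh.write("f1\tf2\n")
            for a, b in zip(f1, f2):
                fh.write(f"{a}\t{b}\n")
        script = f'''
suppressMessages(library(vegan))
D <- as.dist(as.matrix(read.table("{tmp_path}/D.tsv")))
f <- read.table("{tmp_path}/f.tsv", header=TRUE)
a <- adonis2(D ~ f1 + f2, data=f, permutations=0, by="terms")
cat(a$SumOfSqs[1], a$SumOfSqs[2], a$R2[1], a$R2[2], a$F[1], a$F[2], "\\n")
'''
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        np.testing.assert_allclose(res.sums_of_squares, vals[0:2], rtol=1e-6)
        np.testing.assert_allclose(res.r_squared, vals[2:4], rtol=1e-6)
        np.testing.assert_allclose(res.pseudo_f, vals[4:6], rtol=1e-6)
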