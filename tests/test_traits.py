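"""SCBD, group tests, cophenetic distances, loss proportions, turnover, GLM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleoloss import synthdata, traits
from paleoloss.timeslice import TaxonOccupancy, TimeSliceGrid


def scbd_bruteforce(mat: np.ndarray) -> np.ndarray:
    """Element-by-element sum-of-squares decomposition (independent oracle)."""
    n_slices, n_taxa = mat.shape[1], mat.shape[0]
    Y = np.zeros((n_slices, n_taxa))
    for s in range(n_slices):
        tot = sum(mat[j, s] for j in range(n_taxa))
        for j in range(n_taxa):
            Y[s, j] = (mat[j, s] / tot) ** 0.5 if tot > 0 else 0.0
    ss = np.zeros(n_taxa)
    for j in range(n_taxa):
        m = sum(Y[s, j] for s in range(n_slices)) / n_slices
        ss[j] = sum((Y[s, j] - m) ** 2 for s in range(n_slices))
    return ss / ss.sum()


class TestSCBD:
    def test_single_taxon_is_one(self):
        ab = pd.DataFrame([[5, 2, 9]], index=["only"])
        assert traits.scbd(ab)["only"] == 1.0

    def test_identical_profiles_split_evenly(self):
        ab = pd.DataFrame([[5, 2, 9], [5, 2, 9]], index=["a", "b"])
        s = traits.scbd(ab)
        assert s["a"] == pytest.approx(0.5, abs=1e-12)

    def test_three_by_three_matches_bruteforce(self):
        mat = np.array([[5.0, 2.0, 0.0], [1.0, 1.0, 1.0], [0.0, 3.0, 4.0]])
        ab = pd.DataFrame(mat, index=["a", "b", "c"])
        got = traits.scbd(ab).to_numpy()
        expected = scbd_bruteforce(mat)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_sums_to_one_exactly(self):
        rng = np.random.default_rng(4)
        ab = pd.DataFrame(rng.random((40, 14)) * (rng.random((40, 14)) > 0.3))
        assert traits.scbd(ab).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            traits.scbd(pd.DataFrame(np.zeros((3, 4))))


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        x = np.arange(20.0)
        assert traits.group_compare(x, x.copy()).pvalue == 1.0

    def test_separated_groups_significant(self):
        res = traits.group_compare(np.arange(20.0), np.arange(100.0, 120.0))
        assert res.pvalue < 0.001

    def test_permutation_oracle_agrees_with_asymptotic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 1.0, 25)
        y = rng.normal(0.8, 1.0, 25)
        asym = traits.group_compare(x, y).pvalue

        # permutation distribution of the rank-sum statistic, two-sided
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        expected_sum = ranks.sum() * len(x) / len(pooled)
        obs_dev = abs(ranks[: len(x)].sum() - expected_sum)
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(ranks)
            count += abs(ranks[: len(x)].sum() - expected_sum) >= obs_dev
        perm_p = count / n_perm
        assert perm_p == pytest.approx(asym, abs=0.02)

    def test_welch_t_and_bonferroni(self):
        x, y = np.arange(10.0), np.arange(10.0) + 0.1
        res = traits.group_compare(x, y, test="t", n_comparisons=6)
        assert res.test == "t"
        assert res.pvalue == 1.0  # corrected and capped
        with pytest.raises(ValueError):
            traits.group_compare([1.0], [2.0, 3.0], test="t")


class TestCophenetic:
    NWK = "((A:1.0,B:1.0):2.0,(C:1.5,D:1.5):1.5);"

    def test_cherry_distance(self):
        M = traits.cophenetic_matrix("(A:1.0,B:1.0);")
        assert M.loc["A", "B"] == pytest.approx(2.0)

    def test_hand_computed_matrix(self):
        M = traits.cophenetic_matrix(self.NWK)
        assert M.loc["A", "B"] == pytest.approx(2.0)
        assert M.loc["C", "D"] == pytest.approx(3.0)
        assert M.loc["A", "C"] == pytest.approx(1 + 2 + 1.5 + 1.5)
        assert (np.diag(M) == 0).all()
        assert np.allclose(M, M.T)

    def test_ultrametric_tips_equidistant_across_root(self):
        nwk = synthdata.generate_tree([f"t{i}" for i in range(6)], seed=2)
        M = traits.cophenetic_matrix(nwk)
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        root_children = tree.seed_node.child_nodes()
        sides = []
        for ch in root_children:
            sides.append({l.taxon.label for l in ch.leaf_iter()})
        if len(sides) == 2 and all(sides):
            cross = [M.loc[a, b] for a in sides[0] for b in sides[1]]
            assert np.ptp(cross) < 1e-6 * max(cross)

    def test_random_tree_matches_path_walk_oracle(self):
        import dendropy

        nwk = synthdata.generate_tree([f"t{i}" for i in range(6)], seed=5)
        M = traits.cophenetic_matrix(nwk)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.is_rooted = True
        # brute-force: distance = depth(a) + depth(b) - 2 * depth(mrca)
        tips = {l.taxon.label: l for l in tree.leaf_node_iter()}
        for a, b in itertools.combinations(sorted(tips), 2):
            pdm_expected = (
                tips[a].distance_from_root()
                + tips[b].distance_from_root()
                - 2 * dendropy.Tree.mrca(tree, taxa=[tips[a].taxon, tips[b].taxon]).distance_from_root()
            )
            assert M.loc[a, b] == pytest.approx(pdm_expected, rel=1e-9)

    def test_missing_tip_raises_with_names(self):
        with pytest.raises(ValueError, match="ghost"):
            traits.cophenetic_compare(self.NWK, ["A", "ghost"], ["B"])

    def test_compare_groups(self):
        out = traits.cophenetic_compare(self.NWK, ["A", "B"], ["C", "D"])
        assert out["mean_within_lost"] == pytest.approx(2.0)
        assert out["mean_lost_to_other"] == pytest.approx(6.0)


def make_occ(pres: np.ndarray, db, grid=None) -> TaxonOccupancy:
    grid = grid or TimeSliceGrid(n_slices=pres.shape[2], width_yr=2000)
    return TaxonOccupancy(
        pres, pd.Index([f"T{i}" for i in range(pres.shape[1])]), np.asarray(db), grid
    )


class TestTypeAndFamilyLoss:
    def _setup(self):
        # 10 forbs (4 lost non-db), 5 trees (0 lost); families: Boraginaceae
        # has 5 non-db (threshold met), Pinaceae only 1 non-db (excluded)
        n_taxa = 15
        pres = np.ones((3, n_taxa, 14), dtype=bool)
        db = np.array([False] * 6 + [True] * 4 + [False] * 1 + [True] * 4)
        lost = [0, 1, 2, 3]  # non-db forbs lost in every iteration
        for t in lost:
            pres[:, t, 13] = False
        traits_df = pd.DataFrame(
            {
                "functional_type": ["forb"] * 10 + ["tree"] * 5,
                "family": ["Boraginaceae"] * 6 + ["Rosaceae"] * 4 + ["Pinaceae"] * 5,
            },
            index=[f"T{i}" for i in range(n_taxa)],
        )
        return make_occ(pres, db), traits_df

    def test_counting(self):
        occ, tr = self._setup()
        out = traits.type_and_family_loss(occ, tr)
        assert out["type_summary"].loc["forb", "median_pct"] == pytest.approx(40.0)
        assert out["type_summary"].loc["tree", "median_pct"] == 0.0

    def test_family_threshold_excludes_small_families(self):
        occ, tr = self._setup()
        out = traits.type_and_family_loss(occ, tr, min_family_nondb=5)
        assert "Boraginaceae" in out["family_summary"].index
        assert "Pinaceae" not in out["family_summary"].index
        assert "Rosaceae" not in out["family_summary"].index  # 0 non-db


class TestTurnover:
    def test_identical_assemblages_zero(self):
        assert traits.replacement_component(5, 0, 0) == 0.0

    def test_formula_arithmetic(self):
        # A={a,b,c}, B={a,d}: a=1, b=2, c=1 -> 1/(1+1) = 0.5
        assert traits.replacement_component(1, 2, 1) == 0.5

    def test_disjoint_equal_assemblages_one(self):
        assert traits.replacement_component(0, 3, 3) == 1.0

    def test_podani_variant(self):
        assert traits.replacement_component(1, 2, 1, family="podani") == pytest.approx(0.5)
        assert traits.replacement_component(0, 3, 3, family="podani") == 1.0

    def test_series_on_occupancy(self):
        pres = np.ones((2, 4, 3), dtype=bool)
        pres[:, :, 1] = [False, False, True, True]
        pres[:, 2:, 0] = False  # slice0 {0,1}; slice1 {2,3}: full replacement
        occ = make_occ(pres, [True] * 4)
        out = traits.turnover(occ)
        assert out.loc[0, "median"] == 1.0
        assert out.loc[1, "median"] == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_symmetric_and_bounded(self, a, b, c):
        v = traits.replacement_component(a, b, c)
        w = traits.replacement_component(a, c, b)
        if not np.isnan(v):
            assert v == w and 0 <= v <= 1


class TestDriverGLM:
    def test_independent_covariate_not_significant(self):
        rng = np.random.default_rng(12)
        n = 200
        resp = (rng.random(n) < 0.4).astype(float)
        cov = pd.DataFrame({"noise": rng.normal(size=n)})
        fit = traits.driver_glm(resp, cov)
        assert fit.table.loc["noise", "chi2"] < 3.84 or fit.table.loc["noise", "pvalue"] > 0.05

    def test_logistic_signal_recovered(self):
        rng = np.random.default_rng(13)
        n = 200
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 1.5 * x)))
        resp = (rng.random(n) < p).astype(float)
        fit = traits.driver_glm(resp, pd.DataFrame({"x": x}))
        assert fit.table.loc["x", "coef"] > 0
        assert fit.table.loc["x", "pvalue"] < 0.01

    def test_constant_covariate_zero_improvement(self):
        resp = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        fit = traits.driver_glm(resp, pd.DataFrame({"c": np.ones(6)}))
        assert fit.table.loc["c", "chi2"] == 0.0
        assert fit.table.loc["c", "pvalue"] == 1.0

    def test_separation_flagged_and_rescued(self):
        x = np.linspace(-2, 2, 40)
        resp = (x > 0).astype(float)
        fit = traits.driver_glm(resp, pd.DataFrame({"x": x}))
        row = fit.table.loc["x"]
        assert row["flagged"]
        assert row["coef"] > 0 and np.isfinite(row["chi2"])

    def test_lag_alignment(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        lagged = traits.lag_series(s, 1)
        assert np.isnan(lagged[0]) and (lagged[1:] == s[:-1]).all()
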