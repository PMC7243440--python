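import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ecoassembly import CommunityMatrix, ValidationError
from ecoassembly.community_stats import (
    DEFAULT_ENV_GROUPS,
    alpha_diversity,
    bray_curtis,
    correlate_alpha_env,
    env_group_mantel,
    era_genus_sharing,
    mantel_test,
    nmds,
    permanova,
)
from ecoassembly.containers import PairwiseMatrix


def _pm(n, mat, name="bray_curtis"):
    return PairwiseMatrix([f"s{i}" for i in range(n)], mat, name)


class TestBrayCurtis:
    def test_endpoints(self):
        m = CommunityMatrix(
            pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 5]],
                         index=["a", "b", "c"], columns=["x", "y", "z"])
        )
        bc = bray_curtis(m)
        assert bc.matrix[0, 1] == pytest.approx(0.0)
        assert bc.matrix[0, 2] == pytest.approx(1.0)

    def test_worked_example(self):
        m = CommunityMatrix(
            pd.DataFrame([[1, 2, 0], [0, 2, 4]], index=["j", "k"],
                         columns=["x", "y", "z"])
        )
        assert bray_curtis(m).matrix[0, 1] == pytest.approx(5 / 9)

    def test_symmetry(self, selection_dataset):
        bc = bray_curtis(selection_dataset.community)
        np.testing.assert_allclose(bc.matrix, bc.matrix.T)


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_richness(self):
        m = CommunityMatrix(
            pd.DataFrame([[10, 10, 10, 10]], index=["s"], columns=list("abcd"))
        )
        out = alpha_diversity(m)
        assert out.loc["s", "shannon"] == pytest.approx(np.log(4))

    def test_chao1_formula(self):
        # S_obs=10, F1=3 singletons, F2=1 doubleton -> 10 + 9/2 = 14.5
        counts = [1, 1, 1, 2, 5, 5, 5, 5, 5, 5]
        m = CommunityMatrix(
            pd.DataFrame([counts], index=["s"],
                         columns=[f"t{i}" for i in range(10)])
        )
        out = alpha_diversity(m)
        assert out.loc["s", "chao1"] == pytest.approx(14.5)
        assert (out["chao1"] >= out["observed_otus"]).all()

    def test_full_sample_faith_pd_is_total_branch_length(self, tiny_tree):
        m = CommunityMatrix(
            pd.DataFrame([[1, 1, 1]], index=["s"], columns=["A", "B", "C"])
        )
        out = alpha_diversity(m, tiny_tree)
        total = sum(n.length for n in tiny_tree.traverse(include_self=False))
        assert out.loc["s", "faith_pd"] == pytest.approx(total)


class TestNMDS:
    def test_embeddable_square_low_stress(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = _pm(4, squareform(pdist(pts)))
        res = nmds(d, k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_stress_nonincreasing_in_k(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 5))
        d = _pm(9, squareform(pdist(pts)))
        s2 = nmds(d, k=2, n_restarts=6, seed=0).stress
        s8 = nmds(d, k=8, n_restarts=6, seed=0).stress
        assert s8 <= s2 + 1e-9

    def test_duplicated_sample_coincident(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 2))
        pts = np.vstack([pts, pts[0]])
        d = _pm(8, squareform(pdist(pts)))
        res = nmds(d, k=2, n_restarts=8, seed=0)
        gap = np.linalg.norm(res.coordinates.iloc[0] - res.coordinates.iloc[7])
        assert gap < 0.05
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)


class TestPermanova:
    def test_planted_separation_min_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (10, 4))
        b = rng.normal(8, 1, (10, 4))
        d = _pm(20, squareform(pdist(np.vstack([a, b]))))
        res = permanova(d, ["A"] * 10 + ["B"] * 10, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        d = squareform(pdist(pts))
        groups = ["A"] * 6 + ["B"] * 6
        perm = rng.permutation(12)
        r1 = permanova(_pm(12, d), groups, n_perm=99, seed=0)
        d2 = d[np.ix_(perm, perm)]
        g2 = [groups[i] for i in perm]
        pm2 = PairwiseMatrix([f"s{i}" for i in perm], d2, "bray_curtis")
        r2 = permanova(pm2, g2, n_perm=99, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)

    def test_singleton_group_rejected(self):
        d = _pm(3, squareform(pdist(np.eye(3))))
        with pytest.raises(ValidationError):
            permanova(d, ["A", "A", "B"])


class TestMantel:
    def test_identity_r_one(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.normal(size=(10, 3))))
        res = mantel_test(_pm(10, d), _pm(10, d, "env_distance"), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_r_equals_lower_triangle_correlation(self):
        rng = np.random.default_rng(4)
        d1 = squareform(pdist(rng.normal(size=(9, 3))))
        d2 = squareform(pdist(rng.normal(size=(9, 3))))
        res = mantel_test(_pm(9, d1), _pm(9, d2, "env_distance"), n_perm=99, seed=0)
        iu = np.triu_indices(9, 1)
        expected = np.corrcoef(d1[iu], d2[iu])[0, 1]
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_constant_matrix_rejected(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValidationError, match="constant"):
            mantel_test(_pm(5, d), _pm(5, d * 0 + (1 - np.eye(5)), "env_distance"))


class TestEnvGroupMantel:
    def test_redox_group_membership(self):
        assert set(DEFAULT_ENV_GROUPS["redox"]) == {"Fe", "Mn"}
        assert set(DEFAULT_ENV_GROUPS["soil_fertility"]) == {
            "TN", "TP", "Na", "Ca", "Cu", "K", "Mg", "Zn", "SOC"
        }

    def test_constructed_association_near_one(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(12, 1))
        turnover = _pm(12, squareform(pdist(pos)))
        env = pd.DataFrame(
            {"SOC": pos[:, 0], "TN": rng.normal(size=12)},
            index=[f"s{i}" for i in range(12)],
        )
        out = env_group_mantel(turnover, env, {"soc_only": ("SOC",)},
                               n_perm=199, seed=0)
        assert out.loc[0, "mantel_r"] > 0.95

    def test_result_per_group(self, selection_dataset):
        from ecoassembly.community_stats import bray_curtis

        m = selection_dataset.community.select_samples(
            selection_dataset.community.sample_ids[:12]
        )
        bc = bray_curtis(m)
        out = env_group_mantel(bc, selection_dataset.env, n_perm=99, seed=0)
        assert list(out["group"]) == list(DEFAULT_ENV_GROUPS)


class TestCorrelateAlphaEnv:
    def test_proportional_r_one_and_sign_flip(self):
        alpha = pd.DataFrame({"observed_otus": [1.0, 2, 3, 4, 5]},
                             index=[f"s{i}" for i in range(5)])
        env = pd.DataFrame({"SOC": [2.0, 4, 6, 8, 10]}, index=alpha.index)
        out = correlate_alpha_env(alpha, env)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        out2 = correlate_alpha_env(alpha, -env)
        assert out2.loc[0, "r"] == pytest.approx(-1.0)

    def test_matches_hand_pearson(self):
        alpha = pd.DataFrame({"shannon": [1.0, 3, 2, 5, 4]},
                             index=[f"s{i}" for i in range(5)])
        env = pd.DataFrame({"pH": [6.0, 6.5, 6.2, 7.1, 6.8]}, index=alpha.index)
        out = correlate_alpha_env(alpha, env)
        a, e = alpha["shannon"], env["pH"]
        r = ((a - a.mean()) * (e - e.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((e - e.mean()) ** 2).sum()
        )
        assert out.loc[0, "r"] == pytest.approx(r, abs=1e-12)


class TestEraGenusSharing:
    def test_toy_occupancy_buckets(self):
        # 6 genera with known era occupancy over 3 eras
        data = pd.DataFrame(
            {
                "g1": [1, 1, 1],  # all 3 eras
                "g2": [1, 1, 0],
                "g3": [2, 0, 1],
                "g4": [1, 0, 0],
                "g5": [0, 3, 0],
                "g6": [0, 0, 4],
            },
            index=["a", "b", "c"],
        )
        m = CommunityMatrix(data)
        sf = pd.DataFrame(
            {"era": ["modern", "150-50", "300-150"], "age_years": [10, 100, 200]},
            index=["a", "b", "c"],
        )
        out = era_genus_sharing(m, sf).set_index("eras_present")
        assert out.loc[3, "n_genera"] == 1
        assert out.loc[2, "n_genera"] == 2
        assert out.loc[1, "n_genera"] == 3
        assert out["pct_genera"].sum() == pytest.approx(100.0)

    def test_genus_in_every_era_top_bucket(self, selection_dataset):
        from ecoassembly.data_io import collapse_rank

        genus = collapse_rank(selection_dataset.community, "genus")
        out = era_genus_sharing(genus, selection_dataset.samples)
        n_eras = selection_dataset.samples["era"].nunique()
        assert out["eras_present"].max() == n_eras
        assert out["pct_genera"].sum() == pytest.approx(100.0)
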