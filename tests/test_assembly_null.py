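import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoassembly import CommunityMatrix, NullEnsembleConfig, ValidationError
from ecoassembly.assembly_null import (
    beta_mntd,
    beta_nti,
    classify_pair,
    partition_processes,
    raup_crick_bray,
    stochasticity_trend,
    subset_by_timescale,
)
from ecoassembly.containers import PairwiseMatrix
from ecoassembly.phylo_signal import cophenetic_matrix
from ecoassembly.synthetic_data import ScenarioConfig, simulate_chronosequence

from conftest import random_community_and_tree


def beta_mntd_oracle(m, d):
    """Independent double-loop βMNTD implementation (written first)."""
    f = m.values() / m.values().sum(axis=1, keepdims=True)
    n, s = f.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            total = 0.0
            for side, (a, b) in enumerate(((j, k), (k, j))):
                for i in range(s):
                    if f[a, i] <= 0:
                        continue
                    best = min(d[i, i2] for i2 in range(s) if f[b, i2] > 0)
                    total += f[a, i] * best
            out[j, k] = 0.5 * total
    return out


class TestBetaMNTD:
    def test_two_singleton_samples(self):
        from ecoassembly.data_io import read_newick

        tree = read_newick("(A:0.2,B:0.2);")
        m = CommunityMatrix(
            pd.DataFrame([[1, 0], [0, 1]], index=["j", "k"], columns=["A", "B"])
        )
        bm = beta_mntd(m, cophenetic_matrix(tree))
        assert bm.matrix[0, 1] == pytest.approx(0.4)

    def test_self_distance_zero(self, selection_dataset):
        m = selection_dataset.community.select_samples(
            selection_dataset.community.sample_ids[:3]
        )
        bm = beta_mntd(m, cophenetic_matrix(selection_dataset.tree))
        assert np.all(np.diag(bm.matrix) == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, tree = random_community_and_tree(rng)
        d = cophenetic_matrix(tree).filter([str(t) for t in m.taxon_ids]).data
        bm = beta_mntd(m, d)
        np.testing.assert_allclose(bm.matrix, beta_mntd_oracle(m, d), atol=1e-12)

    def test_symmetric_nonnegative(self, selection_dataset):
        m = selection_dataset.community.select_samples(
            selection_dataset.community.sample_ids[:6]
        )
        bm = beta_mntd(m, cophenetic_matrix(selection_dataset.tree))
        assert (bm.matrix >= 0).all()
        np.testing.assert_allclose(bm.matrix, bm.matrix.T)


class TestBetaNTI:
    def test_zero_when_obs_equals_null_mean(self):
        # directly exercise the standardization on a synthetic null stream
        obs, nulls = 1.0, np.array([0.5, 1.5, 1.0, 0.8, 1.2])
        z = (obs - nulls.mean()) / nulls.std(ddof=1)
        assert z == pytest.approx(0.0)

    def test_deterministic_and_order_independent(self):
        rng = np.random.default_rng(3)
        m, tree = random_community_and_tree(rng, n_samples=5, n_taxa=15)
        d = cophenetic_matrix(tree)
        cfg = NullEnsembleConfig(99, 99, seed=11)
        a = beta_nti(m, d, cfg).matrix
        b = beta_nti(m, d, cfg).matrix
        np.testing.assert_array_equal(a, b)
        # a sample-subset recomputation reproduces the same pair indices'
        # streams only when pair positions match; here we check determinism
        # plus symmetry
        np.testing.assert_allclose(a, a.T, equal_nan=True)

    def test_saturated_pair_is_nan(self):
        """Samples containing every pool taxon have βMNTD 0 under any
        relabeling: the null collapses and βNTI is undefined."""
        from ecoassembly.data_io import read_newick

        tree = read_newick("((A:1,B:1):1,C:2);")
        m = CommunityMatrix(
            pd.DataFrame([[1, 1, 1], [2, 2, 2]], index=["j", "k"],
                         columns=["A", "B", "C"])
        )
        out = beta_nti(m, cophenetic_matrix(tree), NullEnsembleConfig(99, 99, 0))
        assert np.isnan(out.matrix[0, 1])


class TestRaupCrick:
    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        m, _ = random_community_and_tree(rng, n_samples=6, n_taxa=20)
        rc = raup_crick_bray(m, NullEnsembleConfig(99, 199, seed=1))
        v = rc.condensed()
        assert (v >= -1).all() and (v <= 1).all()
        np.testing.assert_allclose(rc.matrix, rc.matrix.T, equal_nan=True)

    def test_formula_endpoints(self):
        # RC = -1 when every null exceeds obs; 0 at the exact midpoint
        n_null = 200
        assert 2 * 0.0 / n_null - 1 == -1.0
        assert 2 * (n_null / 2) / n_null - 1 == 0.0

    def test_requires_counts(self, tiny_community):
        rel = tiny_community.relative()
        with pytest.raises(ValidationError, match="counts"):
            raup_crick_bray(rel, NullEnsembleConfig(99, 99, 0))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m, _ = random_community_and_tree(rng, n_samples=4, n_taxa=15)
        cfg = NullEnsembleConfig(99, 99, seed=2)
        np.testing.assert_array_equal(
            raup_crick_bray(m, cfg).matrix, raup_crick_bray(m, cfg).matrix
        )


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (3.1, 0.2, "variable_selection"),
            (-2.4, 0.99, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (1.0, -0.96, "homogenizing_dispersal"),
            (1.0, 0.3, "undominated"),
            (2.0, 0.0, "undominated"),  # strict boundary convention
            (0.0, 0.95, "undominated"),
            (-0.5, -0.95, "undominated"),
        ],
    )
    def test_truth_table(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_inclusive_boundary_flag(self):
        assert classify_pair(2.0, 0.0, inclusive=True) == "variable_selection"
        assert classify_pair(0.0, 0.95, inclusive=True) == "dispersal_limitation"

    @given(
        bnti=st.floats(-10, 10, allow_nan=False),
        rc=st.floats(-1, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_and_exclusive(self, bnti, rc):
        from ecoassembly.assembly_null import PROCESS_CLASSES

        assert classify_pair(bnti, rc) in PROCESS_CLASSES

    def test_nan_bnti_rejected(self):
        with pytest.raises(ValidationError):
            classify_pair(float("nan"), 0.0)


class TestPartition:
    def _pm(self, ids, mat, name):
        return PairwiseMatrix(ids, mat, name)

    def test_single_pair_one_hot(self):
        ids = ["a", "b"]
        bnti = self._pm(ids, np.array([[np.nan, 3.0], [3.0, np.nan]]), "beta_nti")
        rc = self._pm(ids, np.array([[np.nan, 0.1], [0.1, np.nan]]), "rc_bray")
        frac = partition_processes(bnti, rc)
        assert frac.fractions["variable_selection"] == 1.0
        assert frac.n_pairs == 1

    def test_fractions_sum_to_one_and_aggregates(self):
        rng = np.random.default_rng(0)
        n = 12
        ids = [f"s{i}" for i in range(n)]
        b = rng.normal(0, 2, (n, n))
        b = (b + b.T) / 2
        r = np.clip(rng.normal(0, 0.7, (n, n)), -1, 1)
        r = np.clip((r + r.T) / 2, -1, 1)
        np.fill_diagonal(b, np.nan)
        np.fill_diagonal(r, np.nan)
        frac = partition_processes(
            self._pm(ids, b, "beta_nti"), self._pm(ids, r, "rc_bray")
        )
        assert sum(frac.fractions.values()) == pytest.approx(1.0)
        assert frac.deterministic + frac.stochastic + frac.undominated == pytest.approx(1.0)

    def test_nan_pairs_excluded(self, caplog):
        ids = ["a", "b", "c"]
        b = np.array([[np.nan, np.nan, 3.0], [np.nan, np.nan, 0.0],
                      [3.0, 0.0, np.nan]])
        r = np.zeros((3, 3))
        frac = partition_processes(
            self._pm(ids, b, "beta_nti"), self._pm(ids, r, "rc_bray")
        )
        assert frac.n_pairs == 2 and frac.n_excluded == 1


@pytest.fixture(scope="module")
def study_shape():
    cfg = ScenarioConfig(name="shape", n_taxa=40, n_layers=23,
                         n_replicates=3, reads_per_sample=500, seed=4)
    sim = simulate_chronosequence(cfg)
    return sim.community, sim.samples


class TestSubsetByTimescale:
    def test_modern_era_five_layers_triplicate(self, study_shape):
        m, sf = study_shape
        sub, ssf, mask = subset_by_timescale(m, sf, "within_era", era="modern")
        assert sub.shape[0] == 15  # 5 layers × 3 replicates (1-9 cm)
        assert mask.shape == (15, 15)

    def test_single_era_span_errors(self, study_shape):
        m, sf = study_shape
        with pytest.raises(ValidationError, match="2 eras"):
            subset_by_timescale(m, sf, "across_eras",
                                oldest_age=630, youngest_age=560)

    def test_nested_spans_monotone_sample_counts(self, study_shape):
        m, sf = study_shape
        counts = []
        for youngest in (300, 150, 50, 0):
            sub, _, _ = subset_by_timescale(
                m, sf, "across_eras", oldest_age=630, youngest_age=youngest
            )
            counts.append(sub.shape[0])
        assert counts == sorted(counts)
        assert counts[-1] == 69

    def test_cross_pairs_only_mask(self, study_shape):
        m, sf = study_shape
        sub, ssf, mask = subset_by_timescale(
            m, sf, "across_eras", oldest_age=630, youngest_age=300,
            cross_pairs_only=True,
        )
        eras = ssf["era"].to_numpy()
        assert not mask[0, 1]  # same-era pair masked out
        assert mask[(eras[:, None] != eras[None, :])].all()


class TestStochasticityTrend:
    def test_exact_line(self):
        pts = [(x, 0.001 * x + 0.2) for x in (300, 480, 580, 630)]
        fit = stochasticity_trend(pts)
        assert fit.slope == pytest.approx(0.001)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_fraction_zero_slope(self):
        fit = stochasticity_trend([(300, 0.4), (480, 0.4), (630, 0.4)])
        assert fit.slope == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(100, 700, 8)
        y = rng.uniform(0, 1, 8)
        fit = stochasticity_trend(list(zip(x, y)))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            stochasticity_trend([(300, 0.4), (480, 0.5)])
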