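"""Network-based statistic: mask, residualization, t-stats, components."""

import numpy as np
import pytest
from scipy import stats

from ctrlnet.connectivity import ConnectivityMatrix
from ctrlnet.nbs import (Component, NbsConfig, NbsError, cohort_edge_table,
                         component_mean_strength, components_from_edges,
                         edge_inclusion_mask, edgewise_tstats, nbs_test,
                         residualize_edges, supra_components)


def mat(w):
    return ConnectivityMatrix(weights=np.asarray(w, float), rectified=True)


def uniform_cohort(n_subjects, n=6, value=0.2):
    w = value * (1 - np.eye(n))
    return [mat(w) for _ in range(n_subjects)]


class TestEdgeInclusionMask:
    def test_everywhere_positive_includes_all(self):
        mask = edge_inclusion_mask(uniform_cohort(10))
        assert mask.sum() == 6 * 5  # symmetric count

    def test_just_below_prevalence_excluded(self):
        # edge positive in 49 of 100 subjects -> excluded at 50%
        cohort = []
        for k in range(100):
            w = np.zeros((3, 3))
            w[1, 2] = w[2, 1] = 0.5
            if k < 49:
                w[0, 1] = w[1, 0] = 0.4
            cohort.append(mat(w))
        mask = edge_inclusion_mask(cohort)
        assert not mask[0, 1]
        assert mask[1, 2]

    def test_empty_cohort_rejected(self):
        with pytest.raises(NbsError):
            edge_inclusion_mask([])


class TestResidualize:
    def test_orthogonal_covariates_leave_tstats_alone(self):
        rng = np.random.default_rng(0)
        n = 200
        groups = np.array(["control"] * 100 + ["patient"] * 100)
        w = rng.standard_normal((n, 20))
        w[groups == "patient"] -= 0.5
        cov = rng.standard_normal((n, 3))  # noise, independent of group
        t_raw = edgewise_tstats(w, groups)
        t_res = edgewise_tstats(residualize_edges(w, cov), groups)
        assert np.allclose(t_raw, t_res, atol=0.25)

    def test_group_coded_covariate_absorbs_effect(self):
        rng = np.random.default_rng(1)
        groups = np.array(["control"] * 30 + ["patient"] * 30)
        w = rng.standard_normal((60, 10))
        w[groups == "patient"] += 1.0
        cov = (groups == "patient").astype(float)[:, None]
        t = edgewise_tstats(residualize_edges(w, cov), groups)
        assert np.max(np.abs(t)) < 1e-8

    def test_constant_extra_column_rejected(self):
        w = np.random.default_rng(2).standard_normal((20, 5))
        with pytest.raises(NbsError, match="rank"):
            residualize_edges(w, np.ones((20, 1)))


class TestEdgewiseT:
    def test_identical_groups_zero(self):
        block = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        w = np.vstack([block, block])  # patients mirror controls exactly
        groups = np.array(["control"] * 3 + ["patient"] * 3)
        assert np.allclose(edgewise_tstats(w, groups), 0.0)

    def test_zero_variance_edge_warns_and_zeroes(self):
        w = np.column_stack([np.full(6, 1.0), np.arange(6.0)])
        groups = np.array(["control"] * 3 + ["patient"] * 3)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t = edgewise_tstats(w, groups)
        assert t[0] == 0.0

    def test_hand_computed_3v3(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        w = np.concatenate([a, b])[:, None]
        groups = np.array(["control"] * 3 + ["patient"] * 3)
        t = edgewise_tstats(w, groups)[0]
        expected, _ = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(expected, abs=1e-12)

    def test_sign_is_controls_minus_patients(self):
        w = np.array([[2.0], [2.1], [1.9], [1.0], [1.2], [0.8]])
        groups = np.array(["control"] * 3 + ["patient"] * 3)
        assert edgewise_tstats(w, groups)[0] > 0


class TestSupraComponents:
    def test_no_supra_edges_empty(self):
        t = np.zeros((5, 5))
        assert supra_components(t, df=20) == []

    def test_reference_component_single_30_edge_set(self, component_edges):
        # feed the published edge set as a strongly supra-threshold graph
        t = np.zeros((34, 34))
        for i, j in component_edges:
            t[i, j] = t[j, i] = 10.0
        comps = supra_components(t, df=75, primary_p=0.05)
        assert len(comps) == 1
        assert comps[0].size == 30
        assert comps[0].n_nodes == 26

    def test_matches_union_find_oracle_on_random_graphs(self):
        import networkx as nx
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            t = np.zeros((n, n))
            iu, ju = np.triu_indices(n, k=1)
            hot = rng.random(len(iu)) < 0.3
            t[iu[hot], ju[hot]] = 10.0
            t += t.T
            comps = supra_components(t, df=30)
            g = nx.Graph(list(zip(iu[hot], ju[hot])))
            expected = sorted((len(c.edges), len(c.nodes))
                              for c in [g.subgraph(s) for s in
                                        nx.connected_components(g)])
            got = sorted((c.size, c.n_nodes) for c in comps)
            assert got == expected

    def test_lower_primary_p_never_grows_components(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal((20, 20))
        t = np.triu(t, 1) + np.triu(t, 1).T
        sizes = []
        for p in (0.1, 0.05, 0.01):
            comps = supra_components(t, df=40, primary_p=p)
            sizes.append(sum(c.size for c in comps))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestNbsTest:
    @pytest.fixture(scope="class")
    def toy_cohort(self):
        rng = np.random.default_rng(8)
        n_sub, n = 24, 10
        groups = np.array(["control"] * 12 + ["patient"] * 12)
        cohort = []
        for s in range(n_sub):
            w = np.abs(rng.normal(0.3, 0.1, (n, n)))
            w = np.triu(w, 1)
            if groups[s] == "patient":
                w[0, 1] -= 0.2
                w[1, 2] -= 0.2
                w[2, 3] -= 0.2
            w = np.clip(w, 0, 1)
            w = w + w.T
            cohort.append(mat(w))
        return cohort, groups

    def test_detects_planted_chain(self, toy_cohort):
        cohort, groups = toy_cohort
        res = nbs_test(cohort, None, groups,
                       NbsConfig(n_perm=500, seed=0))
        assert res.components
        top = res.components[0]
        assert {(0, 1), (1, 2), (2, 3)} <= set(top.edges)
        assert top.corrected_p_valid < 0.05

    def test_deterministic_given_seed(self, toy_cohort):
        cohort, groups = toy_cohort
        r1 = nbs_test(cohort, None, groups, NbsConfig(n_perm=300, seed=9))
        r2 = nbs_test(cohort, None, groups, NbsConfig(n_perm=300, seed=9))
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert [c.corrected_p for c in r1.components] == \
               [c.corrected_p for c in r2.components]

    def test_two_sided_tail_invariant_to_group_relabeling(self, toy_cohort):
        cohort, groups = toy_cohort
        flipped = np.where(groups == "control", "patient", "control")
        cfg = dict(n_perm=400, seed=2, tail="two_sided")
        r1 = nbs_test(cohort, None, groups, NbsConfig(**cfg))
        r2 = nbs_test(cohort, None, flipped, NbsConfig(**cfg))
        assert [c.corrected_p for c in r1.components] == \
               [c.corrected_p for c in r2.components]

    def test_exhaustive_enumeration_when_few_subjects(self):
        rng = np.random.default_rng(5)
        cohort = []
        for _ in range(8):
            w = np.abs(rng.normal(0.3, 0.1, (5, 5)))
            w = np.triu(w, 1)
            cohort.append(mat(w + w.T))
        groups = np.array(["control"] * 4 + ["patient"] * 4)
        with pytest.warns(UserWarning, match="exhaustive"):
            res = nbs_test(cohort, None, groups,
                           NbsConfig(n_perm=100, seed=0))
        assert len(res.null_max_sizes) == 70  # C(8,4)

    def test_small_group_rejected(self):
        cohort = uniform_cohort(3)
        groups = np.array(["control", "patient", "patient"])
        with pytest.raises(NbsError):
            nbs_test(cohort, None, groups, NbsConfig(n_perm=100))


class TestComponentMeanStrength:
    def test_constant_matrix_gives_constant(self, component_edges):
        w = 0.2 * (1 - np.eye(34))
        assert component_mean_strength(mat(w), component_edges) == \
            pytest.approx(0.200)

    def test_hand_averaged_three_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.1
        w[1, 2] = w[2, 1] = 0.2
        w[2, 3] = w[3, 2] = 0.6
        got = component_mean_strength(mat(w), [(0, 1), (1, 2), (2, 3)])
        assert got == pytest.approx(0.3)

    def test_empty_component_rejected(self):
        with pytest.raises(NbsError):
            component_mean_strength(mat(np.zeros((3, 3))), [])
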