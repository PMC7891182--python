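"""Network-based statistic: edge tests, components, permutation null."""

import numpy as np
import pytest

import _oracles as oracle
from wmnet import (
    CohortConfig,
    NBSParams,
    edge_statistics,
    generate_cohort,
    nbs_test,
    suprathreshold_components,
)


def stack_with_edge_values(values_per_subject, n=4, i=0, j=1):
    """A subject stack whose (i, j) edge carries the given values; a second
    constant edge keeps the presence mask non-degenerate."""
    stack = np.zeros((len(values_per_subject), n, n))
    for s, v in enumerate(values_per_subject):
        stack[s, i, j] = stack[s, j, i] = v
        stack[s, 2, 3] = stack[s, 3, 2] = 0.5 + 0.01 * ((-1) ** s) * (s + 1)
    return stack


class TestEdgeStatistics:
    def test_two_sample_t_hand_example(self):
        """Groups (1,2,3) vs (4,5,6): pooled t = -3.6742, p = 0.0214."""
        stack = stack_with_edge_values([1, 2, 3, 4, 5, 6])
        labels = np.array(["A"] * 3 + ["B"] * 3)
        t, p, mask = edge_statistics(stack, labels, contrast=("A", "B"))
        assert t[0, 1] == pytest.approx(-3.6742, abs=1e-4)
        assert p[0, 1] == pytest.approx(0.0214, abs=1e-4)
        assert t[0, 1] == pytest.approx(
            oracle.two_sample_t([1, 2, 3], [4, 5, 6]), abs=1e-12
        )

    def test_equal_means_give_zero_t(self):
        stack = stack_with_edge_values([0.3, 0.5, 0.2, 0.6])
        labels = np.array(["A", "A", "B", "B"])  # both means 0.4
        t, _, _ = edge_statistics(stack, labels, contrast=("A", "B"))
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_three_equal_group_means_give_zero_f(self):
        stack = stack_with_edge_values([1, 3, 2, 2, 0.5, 3.5])
        labels = np.array(["A", "A", "B", "B", "C", "C"])  # all means 2
        f, _, _ = edge_statistics(stack, labels, contrast="omnibus")
        assert f[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_omnibus_matches_anova_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=9).tolist()
        stack = stack_with_edge_values(vals)
        labels = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        f, _, _ = edge_statistics(stack, labels)
        expected = oracle.anova_f([vals[:3], vals[3:6], vals[6:]])
        assert f[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_edge_marked_missing(self):
        stack = stack_with_edge_values([1.0, 1.0, 1.0, 1.0])
        labels = np.array(["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="zero within-group variance"):
            t, p, _ = edge_statistics(stack, labels, contrast=("A", "B"))
        assert np.isnan(t[0, 1]) and np.isnan(p[0, 1])

    def test_presence_mask_excludes_rare_edges(self):
        stack = np.zeros((4, 4, 4))
        stack[0, 0, 1] = stack[0, 1, 0] = 0.5  # present in 1/4 subjects
        stack[:, 2, 3] = stack[:, 3, 2] = 0.5  # present in all
        labels = np.array(["A", "A", "B", "B"])
        _, _, mask = edge_statistics(stack, labels, contrast=("A", "B"))
        assert not mask[0, 1]
        assert mask[2, 3]

    def test_too_few_subjects_rejected(self):
        stack = stack_with_edge_values([1, 2, 3])
        with pytest.raises(ValueError):
            edge_statistics(stack, np.array(["A", "A", "B"]), contrast=("A", "B"))


class TestSuprathresholdComponents:
    def test_components_split_by_shared_nodes(self):
        p = np.ones((6, 6))
        for i, j in [(1, 2), (2, 3), (4, 5)]:
            p[i, j] = p[j, i] = 0.001
        comps = suprathreshold_components(p, 0.01)
        sizes = sorted(len(c) for c in comps)
        assert sizes == [1, 2]

    def test_no_suprathreshold_edges_gives_empty_list(self):
        p = np.full((5, 5), 0.5)
        assert suprathreshold_components(p, 0.01) == []

    def test_ring_is_one_component(self):
        p = np.ones((5, 5))
        for i in range(5):
            j = (i + 1) % 5
            p[i, j] = p[j, i] = 0.001
        comps = suprathreshold_components(p, 0.01)
        assert len(comps) == 1 and len(comps[0]) == 5

    def test_threshold_is_strict(self):
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = 0.01  # exactly the threshold: excluded
        assert suprathreshold_components(p, 0.01) == []

    def test_agrees_with_union_find_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 21))
            p = np.ones((n, n))
            iu, ju = np.triu_indices(n, k=1)
            hits = rng.random(iu.size) < 0.15
            p[iu[hits], ju[hits]] = 0.001
            p[ju[hits], iu[hits]] = 0.001
            comps = suprathreshold_components(p, 0.01)
            edges = [(int(i), int(j)) for i, j in zip(iu[hits], ju[hits])]
            expected = oracle.union_find_components(edges)
            assert sorted(len(c) for c in comps) == sorted(
                len(c) for c in expected
            )
            assert {frozenset(map(tuple, c)) for c in comps} == {
                frozenset(c) for c in expected
            }


class TestNBSTest:
    def test_corrected_p_formula_single_permutation(self):
        """With n_perm=1 and the permuted max below M, p = (1+0)/(1+1)."""
        c = generate_cohort(
            CohortConfig(n_per_group=10, n_regions=30, seed=4,
                         eglob_effect=1.0, planted_delta=0.3)
        )
        with pytest.warns(UserWarning, match="coarse"):
            res = nbs_test(
                c.stack, c.groups,
                NBSParams(n_perm=1, seed=0), contrast=("HC", "MCI"),
            )
        assert res.components
        top = res.components[0]
        assert top.p_corrected in (0.5, 1.0)
        if res.null_max_sizes[0] < top.size:
            assert top.p_corrected == 0.5

    def test_p_bounds_and_monotonicity(self):
        c = generate_cohort(
            CohortConfig(n_per_group=10, n_regions=30, seed=8,
                         eglob_effect=1.0, planted_delta=0.25)
        )
        res = nbs_test(
            c.stack, c.groups, NBSParams(n_perm=200, seed=1),
            contrast=("HC", "MCI"),
        )
        sizes = [comp.size for comp in res.components]
        ps = [comp.p_corrected for comp in res.components]
        for p in ps:
            assert 1 / 201 <= p <= 1.0
        # larger components never get larger corrected p
        for (s1, p1), (s2, p2) in zip(
            zip(sizes, ps), zip(sizes[1:], ps[1:])
        ):
            assert s1 >= s2 and p1 <= p2

    def test_deterministic_under_seed(self):
        c = generate_cohort(
            CohortConfig(n_per_group=8, n_regions=25, seed=2,
                         eglob_effect=1.0, planted_delta=0.25)
        )
        params = NBSParams(n_perm=150, seed=9)
        a = nbs_test(c.stack, c.groups, params, contrast=("HC", "MCI"))
        b = nbs_test(c.stack, c.groups, params, contrast=("HC", "MCI"))
        np.testing.assert_array_equal(a.null_max_sizes, b.null_max_sizes)
        assert [c1.p_corrected for c1 in a.components] == [
            c2.p_corrected for c2 in b.components
        ]

    def test_strict_greater_flag_matches_unsmoothed_proportion(self):
        c = generate_cohort(
            CohortConfig(n_per_group=8, n_regions=25, seed=2,
                         eglob_effect=1.0, planted_delta=0.25)
        )
        res = nbs_test(
            c.stack, c.groups,
            NBSParams(n_perm=150, seed=9, strict_greater=True),
            contrast=("HC", "MCI"),
        )
        for comp in res.components:
            expected = (res.null_max_sizes > comp.size).sum() / 150
            assert comp.p_corrected == pytest.approx(expected)

    def test_planted_component_recovered(self):
        """A strong focal deficit is found and overlaps the planted edges."""
        c = generate_cohort(
            CohortConfig(seed=1, eglob_effect=1.0, planted_delta=0.2)
        )
        res = nbs_test(
            c.stack, c.groups, NBSParams(n_perm=300, seed=1),
            contrast=("HC", "MCI"),
        )
        sig = res.significant
        assert sig
        planted = {tuple(e) for e in map(tuple, c.ground_truth["planted_edges"])}
        comp = set(sig[0].edges)
        jaccard = len(comp & planted) / len(comp | planted)
        assert jaccard >= 0.5
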