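import numpy as np
import pytest
from scipy import stats as sps

import connectokit as ck
from connectokit.errors import CohortError, ConnectokitError

from conftest import random_fa_matrix


def cohort_from_stack(stack, is_patient):
    subs = []
    for k, (w, pat) in enumerate(zip(stack, is_patient)):
        grp = "patient" if pat else "control"
        sid = f"s{k:02d}"
        subs.append(ck.Subject(sid, grp, ck.ConnectivityMatrix(w, subject_id=sid)))
    return ck.Cohort(subs)


def noisy_cohort(n_nodes, n_pat, n_ctrl, rng, density=0.9, effect=None):
    """Dense random cohort; `effect` = (edges, delta) lowers patient FA."""
    base = random_fa_matrix(n_nodes, density, rng)
    stack, labels = [], []
    for k in range(n_pat + n_ctrl):
        w = base.copy()
        iu = np.triu_indices(n_nodes, 1)
        noise = rng.normal(0, 0.03, len(iu[0]))
        w[iu] = np.where(w[iu] > 0, np.clip(w[iu] + noise, 0.05, 0.95), 0)
        w = np.triu(w, 1) + np.triu(w, 1).T
        pat = k < n_pat
        if pat and effect is not None:
            edges, delta = effect
            for i, j in edges:
                if w[i, j] > 0:
                    w[i, j] = w[j, i] = max(w[i, j] - delta, 0.05)
        stack.append(w)
        labels.append(pat)
    return cohort_from_stack(stack, labels)


class TestEdgeStatistic:
    def test_matches_scipy_pooled_t(self, rng):
        cohort = noisy_cohort(8, 5, 5, rng)
        stat, mask, _ = ck.edge_statistic(cohort, ck.NBSConfig(edge_mask_rule=1.0))
        stack = cohort.stack()
        pat = cohort.is_patient_mask()
        i, j = np.argwhere(mask)[0]
        expected = sps.ttest_ind(stack[~pat, i, j], stack[pat, i, j],
                                 equal_var=True).statistic
        assert stat[i, j] == pytest.approx(expected, abs=1e-10)

    def test_identical_groups_give_zero(self, rng):
        base = random_fa_matrix(6, 1.0, rng)
        cohort = cohort_from_stack([base] * 6, [True] * 3 + [False] * 3)
        stat, mask, zero_var = ck.edge_statistic(cohort, ck.NBSConfig())
        assert np.all(stat[mask] == 0)
        assert len(zero_var) == mask.sum() // 2

    def test_mask_rule_excludes_inconsistent_edges(self, rng):
        base = random_fa_matrix(6, 1.0, rng)
        missing = base.copy()
        missing[0, 1] = missing[1, 0] = 0.0
        cohort = cohort_from_stack([base] * 5 + [missing],
                                   [True] * 3 + [False] * 3)
        _, mask, _ = ck.edge_statistic(cohort, ck.NBSConfig(edge_mask_rule=1.0))
        assert not mask[0, 1]
        _, mask_relaxed, _ = ck.edge_statistic(
            cohort, ck.NBSConfig(edge_mask_rule=0.8))
        assert mask_relaxed[0, 1]


class TestSupraThresholdComponents:
    def test_no_edge_above_threshold(self):
        stat = np.zeros((4, 4))
        assert ck.supra_threshold_components(stat, 3.0) == []

    def test_hand_connectivity(self):
        stat = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            stat[i, j] = stat[j, i] = 4.0
        comps = ck.supra_threshold_components(stat, 3.0)
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].nodes == (0, 1, 2)

    def test_star_component_shape(self):
        stat = np.zeros((12, 12))
        for j in range(1, 11):
            stat[0, j] = stat[j, 0] = 5.0
        comps = ck.supra_threshold_components(stat, 3.0)
        assert len(comps) == 1
        assert len(comps[0].nodes) == 11 and comps[0].extent == 10

    def test_two_sided_alternative_uses_magnitude(self):
        stat = np.zeros((3, 3))
        stat[0, 1] = stat[1, 0] = -4.0
        assert ck.supra_threshold_components(stat, 3.0, "greater") == []
        assert len(ck.supra_threshold_components(stat, 3.0, "two-sided")) == 1


class TestFaSum:
    def test_single_edge(self, rng):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.45
        m = ck.ConnectivityMatrix(w)
        assert ck.nbs_fa_sum(m, [(0, 1)]) == pytest.approx(0.45)

    def test_absent_edges_contribute_zero(self, rng):
        w = random_fa_matrix(6, 1.0, rng)
        w[0, 1] = w[1, 0] = 0.0
        m = ck.ConnectivityMatrix(w)
        edges = [(0, 1), (2, 3), (4, 5)]
        assert ck.nbs_fa_sum(m, edges) == pytest.approx(w[2, 3] + w[4, 5])

    def test_empty_edge_set_errors(self, rng):
        m = ck.ConnectivityMatrix(np.zeros((3, 3)))
        with pytest.raises(ConnectokitError):
            ck.nbs_fa_sum(m, [])


class TestPermutationInference:
    def make_planted(self, rng, delta=0.25):
        edges = [(0, 1), (0, 2), (0, 3)]
        return noisy_cohort(10, 5, 5, rng, effect=(edges, delta)), edges

    def test_p_values_valid_and_component_recovered(self, rng):
        cohort, edges = self.make_planted(rng)
        res = ck.nbs_test(cohort, ck.NBSConfig(n_permutations=200, seed=1,
                                               primary_threshold=3.0))
        assert all(0 < p <= 1 for p in res.p_fwer)
        sig = res.significant_components()
        assert sig and set(edges) <= set(sig[0].edges)

    def test_fixed_seed_bit_reproducible(self, rng):
        cohort, _ = self.make_planted(rng)
        cfg = ck.NBSConfig(n_permutations=150, seed=9)
        r1 = ck.nbs_test(cohort, cfg)
        r2 = ck.nbs_test(cohort, cfg)
        assert np.array_equal(r1.null_max_extent, r2.null_max_extent)
        assert r1.p_fwer == r2.p_fwer

    def test_invariant_to_subject_ordering(self, rng):
        cohort, _ = self.make_planted(rng)
        shuffled = ck.Cohort(list(reversed(cohort.subjects)))
        cfg = ck.NBSConfig(n_permutations=150, seed=9)
        assert ck.nbs_test(cohort, cfg).p_fwer == \
            ck.nbs_test(shuffled, cfg).p_fwer

    def test_max_extent_monotone_in_threshold(self, rng):
        cohort, _ = self.make_planted(rng)
        stat, _, _ = ck.edge_statistic(cohort, ck.NBSConfig())
        extents = []
        for thr in (1.0, 2.0, 3.0, 4.0, 6.0):
            comps = ck.supra_threshold_components(stat, thr)
            extents.append(max((c.extent for c in comps), default=0))
        assert extents == sorted(extents, reverse=True)

    def test_threshold_above_everything_gives_no_components(self, rng):
        cohort, _ = self.make_planted(rng)
        res = ck.nbs_test(cohort, ck.NBSConfig(n_permutations=120, seed=2,
                                               primary_threshold=500.0))
        assert res.components == [] and res.p_fwer == []

    def test_monte_carlo_close_to_exact_enumeration(self, rng):
        cohort, _ = self.make_planted(rng, delta=0.12)
        cfg = ck.NBSConfig(n_permutations=200, seed=3, primary_threshold=2.5)
        exact = ck.NetworkBasedStatistic(cohort, cfg).fit(exact=True)
        mc = ck.NetworkBasedStatistic(cohort, cfg).fit()
        for pe, pm in zip(exact.p_fwer, mc.p_fwer):
            se = np.sqrt(pe * (1 - pe) / 200)
            assert abs(pm - pe) <= max(2 * se + 1 / 201, 0.02)

    def test_too_few_distinct_labelings_advises_exact(self, rng):
        cohort = noisy_cohort(6, 2, 3, rng)
        with pytest.raises(CohortError, match="exact"):
            ck.nbs_test(cohort, ck.NBSConfig(n_permutations=500, seed=0))

    def test_fa_sums_lower_in_patients_for_planted_cohort(self, rng):
        cohort, _ = self.make_planted(rng)
        res = ck.nbs_test(cohort, ck.NBSConfig(n_permutations=200, seed=4))
        assert res.fa_sums is not None
        df = res.fa_sums[res.fa_sums["component"] == 0]
        assert (df[df.group == "patient"]["nbs_fa_sum"].mean()
                < df[df.group == "control"]["nbs_fa_sum"].mean())

    def test_rank_statistic_variant_runs(self, rng):
        cohort, edges = self.make_planted(rng)
        res = ck.nbs_test(cohort, ck.NBSConfig(edge_stat="rank",
                                               primary_threshold=2.0,
                                               n_permutations=150, seed=5))
        assert all(0 < p <= 1 for p in res.p_fwer)
        big = max(res.components, key=lambda c: c.extent)
        assert set(edges) <= set(big.edges)
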