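"""Exact nonparametric tests against brute-force enumeration oracles, and
the cross-task validation battery."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import apakit as ak


class TestDescriptives:
    def test_cohort_updrs_column(self):
        d = ak.descriptives([32, 28, 41, 23, 45, 35, 28, 26])
        assert d.mean == pytest.approx(32.25)
        assert d.sd == pytest.approx(7.63, abs=0.005)

    def test_cohort_age_column(self):
        d = ak.descriptives([67, 76, 73, 65, 66, 63, 63, 67])
        assert d.mean == pytest.approx(67.50)
        assert d.sd == pytest.approx(4.66, abs=0.005)

    def test_single_observation_rejected(self):
        with pytest.raises(ak.ValidationError, match="single"):
            ak.descriptives([3.0])

    def test_empty_rejected(self):
        with pytest.raises(ak.ValidationError, match="empty"):
            ak.descriptives([])


def _wilcoxon_brute_force(diffs):
    """Two-sided exact p over all 2^m sign assignments (independent path:
    explicit iteration, no convolution)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(np.array(signs) * ranks)
          for signs in product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    p_lo = np.mean(ws <= w_obs + 1e-9)
    p_hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestWilcoxonExact:
    def test_all_positive_n5_one_sided(self):
        res = ak.wilcoxon_exact([1.0, 2.0, 0.5, 3.0, 1.5])
        assert res.w == 15.0
        assert res.p_exact_greater == pytest.approx(1 / 32)
        assert res.p_exact == pytest.approx(2 / 32)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.2, 1.0, 10), 2)
        res = ak.wilcoxon_exact(d)
        assert res.p_exact == pytest.approx(_wilcoxon_brute_force(d))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, 9)   # continuous: no ties, no zeros
        res = ak.wilcoxon_exact(d)
        ref = sps.wilcoxon(d, mode="exact")
        assert res.p_exact == pytest.approx(ref.pvalue)

    def test_antisymmetric_differences_centered(self):
        # perfectly antisymmetric: W+ sits at the distribution center
        res = ak.wilcoxon_exact([-2.0, -1.0, 1.0, 2.0])
        assert res.p_exact == 1.0
        assert res.z == pytest.approx(0.0)

    def test_all_zero_degenerate(self):
        res = ak.wilcoxon_exact([0.0, 0.0, 0.0])
        assert res.p_exact == 1.0
        assert res.n_used == 0

    def test_zeros_dropped(self):
        res = ak.wilcoxon_exact([0.0, 1.0, 2.0, -0.5])
        assert res.n_used == 3 and res.n_dropped == 1

    def test_paired_form(self):
        a, b = [3.0, 4.0, 5.0, 7.0, 9.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0, 1.0]
        assert ak.wilcoxon_exact(a, b).p_exact == \
            ak.wilcoxon_exact(np.subtract(a, b)).p_exact


def _mannwhitney_brute_force(a, b):
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array([sum(ranks[list(idx)]) - na * (na + 1) / 2
                   for idx in combinations(range(len(pooled)), na)])
    p_lo = np.mean(us <= u_obs + 1e-9)
    p_hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestMannWhitneyExact:
    def test_fully_separated_groups(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]
        res = ak.mannwhitney_exact(a, b)
        assert res.u == 0.0
        assert res.p_exact_less == pytest.approx(1 / 70)  # C(8,4) = 70

    def test_identical_groups_p_near_one(self):
        res = ak.mannwhitney_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_exact == 1.0
        assert res.u_a == pytest.approx(res.u_b)

    @pytest.mark.parametrize("na,nb,seed", [(10, 8, 0), (6, 6, 1), (5, 9, 2)])
    def test_matches_full_permutation_oracle(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0, 1, na), 1)   # rounding induces ties
        b = np.round(rng.normal(0.5, 1, nb), 1)
        res = ak.mannwhitney_exact(a, b)
        assert res.method == "enumeration"
        assert res.p_exact == pytest.approx(_mannwhitney_brute_force(a, b))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_exact_untied(self, seed):
        rng = np.random.default_rng(50 + seed)
        a, b = rng.normal(0, 1, 7), rng.normal(0.8, 1, 6)
        res = ak.mannwhitney_exact(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact")
        assert res.p_exact == pytest.approx(ref.pvalue)

    def test_permutation_fallback_seeded(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 14), rng.normal(0.7, 1, 14)
        r1 = ak.mannwhitney_exact(a, b, max_enumeration=100, seed=4)
        r2 = ak.mannwhitney_exact(a, b, max_enumeration=100, seed=4)
        assert r1.method == "permutation"
        assert r1.p_exact == r2.p_exact

    def test_empty_group_rejected(self):
        with pytest.raises(ak.ValidationError, match="empty"):
            ak.mannwhitney_exact([], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_unity(self, rng):
        x = rng.normal(0, 1, 12)
        res = ak.spearman(x, np.exp(x))     # strictly monotone transform
        assert res.r_s == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(8.0)
        res = ak.spearman(x, x[::-1])
        assert res.r_s == pytest.approx(-1.0)

    def test_exact_p_matches_sampled_permutation_oracle(self, rng):
        x = rng.normal(0, 1, 8)
        y = x + rng.normal(0, 1.5, 8)
        res = ak.spearman(x, y, method="exact")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        r_obs = np.corrcoef(rx, ry)[0, 1]
        n_mc = 100_000
        hits = 0
        for _ in range(n_mc):
            r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
            hits += abs(r) >= abs(r_obs) - 1e-9
        p_mc = hits / n_mc
        se = np.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(res.p - p_mc) < 4 * se + 1e-4

    def test_t_approximation_used_for_larger_n(self, rng):
        x = rng.normal(0, 1, 15)
        y = x + rng.normal(0, 1, 15)
        res = ak.spearman(x, y)
        assert res.method == "t"
        ref = sps.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ak.ValidationError, match="constant"):
            ak.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_invariance_under_monotone_transform_of_either(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        base = ak.spearman(x, y)
        assert ak.spearman(np.exp(x), y).r_s == pytest.approx(base.r_s)
        assert ak.spearman(x, y ** 3).r_s == pytest.approx(base.r_s)


class TestValidationAnalysis:
    def _frames(self, step_sup, step_unsup, scan_sup, scan_unsup):
        subjects = [f"s{i}" for i in range(len(step_sup))]
        step = pd.DataFrame({"subject": subjects, "supported": step_sup,
                             "unsupported": step_unsup})
        scan = pd.DataFrame({"subject": subjects, "supported": scan_sup,
                             "unsupported": scan_unsup})
        return step, scan

    def test_perfect_monotone_linkage(self, rng):
        amp = np.sort(rng.uniform(0.5, 1.0, 10))
        step, scan = self._frames(amp * 0.5, amp, 2 * amp * 0.5 + 1,
                                  2 * amp + 1)
        report = ak.validation_analysis(step, scan)
        assert report.cross_task.r_s == pytest.approx(1.0)
        assert report.step_wilcoxon.p_exact < 0.05

    def test_independent_tasks_centered_on_zero(self):
        rs = []
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 1, 10)
            step, scan = self._frames(np.zeros(10), a, np.zeros(10), b)
            rs.append(ak.validation_analysis(step, scan).cross_task.r_s)
        assert abs(np.mean(rs)) < 0.08
        assert np.mean(np.array(rs) > 0) == pytest.approx(0.5, abs=0.1)

    def test_power_at_observed_effect_size(self):
        """A noisy monotone cross-task linkage at n = 10 recovers
        r_s > 0.7 in >= 80% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            amp = rng.uniform(0.4, 1.0, 10)
            scan = 10 * amp + rng.normal(0, 0.8, 10)   # noisy monotone map
            step, scan_f = self._frames(np.zeros(10), amp, np.zeros(10), scan)
            r = ak.validation_analysis(step, scan_f).cross_task.r_s
            hits += r > 0.7
        assert hits / n_rep >= 0.80

    def test_clinical_correlations_reported(self, rng):
        amp = rng.uniform(0.4, 1.0, 8)
        step, scan = self._frames(amp * 0.5, amp, amp + 1, 2 * amp + 1)
        clinical = pd.DataFrame({"subject": [f"s{i}" for i in range(8)],
                                 "updrs_motor": 50 - 30 * amp})
        report = ak.validation_analysis(step, scan, clinical)
        assert report.updrs_vs_step.r_s == pytest.approx(-1.0)
        assert "UPDRS" in report.format_text()

    def test_subject_mismatch_rejected(self, rng):
        step, scan = self._frames(*(rng.uniform(0, 1, 5) for _ in range(4)))
        scan = scan.assign(subject=[f"x{i}" for i in range(5)])
        with pytest.raises(ak.ValidationError, match="subject"):
            ak.validation_analysis(step, scan)
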