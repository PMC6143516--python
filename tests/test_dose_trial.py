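"""Nonparametric group statistics and the dose-escalation decision rules."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tracereval as te
from tracereval.dose_trial import (
    group_summaries,
    kruskal_wallis_dunn,
    mann_whitney,
    plateau_optimal_dose,
    select_expansion_groups,
    spearman,
)


def kw_h_oracle(groups):
    """Tie-free rank-based H from first principles."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    rank_sums = {}
    for rank, (_, gi) in enumerate(pooled, start=1):
        rank_sums[gi] = rank_sums.get(gi, 0) + rank
    h = 12.0 / (n * (n + 1)) * sum(rank_sums[gi] ** 2 / len(groups[gi])
                                   for gi in rank_sums) - 3 * (n + 1)
    return h


class TestKruskalWallisDunn:
    def test_all_identical(self):
        h, p, _ = kruskal_wallis_dunn([[5, 5], [5, 5], [5]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_h(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p, _ = kruskal_wallis_dunn(groups)
        assert h == pytest.approx(7.2)
        assert h == pytest.approx(kw_h_oracle(groups))

    def test_dunn_z_hand_value(self):
        """Separated groups {1..3},{4..6},{7..9}: mean ranks 2/5/8, pooled
        variance 7.5, so z12 = -3/sqrt(5)."""
        _, _, pw = kruskal_wallis_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert pw[(0, 1)]["z"] == pytest.approx(-3 / math.sqrt(5))
        assert pw[(0, 2)]["z"] == pytest.approx(-6 / math.sqrt(5))

    def test_bonferroni_never_exceeds_one(self):
        _, _, pw = kruskal_wallis_dunn([[1, 2], [1.5, 2.5], [2, 3]])
        assert all(0 <= v["p_adjusted"] <= 1 for v in pw.values())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1, 2], []])

    def test_asymptotic_p_tracks_exact_permutation_p(self):
        """For total n <= 8 the chi-square p tracks the exact permutation
        distribution over all relabelings.  The permutation p is taken at
        the mid-p convention (half the probability atom at H_obs), the
        point the continuous approximation targets; the deviation stays
        below 0.05 in the median over datasets and below 0.1 always."""
        devs = []
        rng = np.random.default_rng(3)
        for _ in range(6):
            pooled = rng.normal(size=8)
            groups = [pooled[:3], pooled[3:6], pooled[6:]]
            h_obs, p_asym, _ = kruskal_wallis_dunn([g.tolist() for g in groups])
            strict = equal = total = 0
            idx = list(range(8))
            for c1 in itertools.combinations(idx, 3):
                rest = [i for i in idx if i not in c1]
                for c2 in itertools.combinations(rest, 3):
                    c3 = [i for i in rest if i not in c2]
                    perm = [pooled[list(c1)], pooled[list(c2)], pooled[c3]]
                    h, _, _ = kruskal_wallis_dunn([g.tolist() for g in perm])
                    total += 1
                    if h > h_obs + 1e-9:
                        strict += 1
                    elif h >= h_obs - 1e-9:
                        equal += 1
            devs.append(abs(p_asym - (strict + 0.5 * equal) / total))
        assert float(np.median(devs)) <= 0.05
        assert max(devs) <= 0.1

    def test_rank_invariance_under_monotone_transform(self):
        groups = [[1.0, 4.0, 2.5], [3.0, 8.0], [0.5, 9.0, 6.0]]
        h1, p1, pw1 = kruskal_wallis_dunn(groups)
        tg = [[math.exp(v) for v in g] for g in groups]
        h2, p2, pw2 = kruskal_wallis_dunn(tg)
        assert h1 == pytest.approx(h2)
        assert pw1[(0, 1)]["z"] == pytest.approx(pw2[(0, 1)]["z"])


class TestMannWhitney:
    def test_identical_samples_exact_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_fully_separated_enumeration(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_shift_invariance(self):
        u1, p1 = mann_whitney([1, 5, 3], [2, 8, 9, 4])
        u2, p2 = mann_whitney([101, 105, 103], [102, 108, 109, 104])
        assert (u1, p1) == (u2, p2)

    def test_exact_matches_scipy_without_ties(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            u, p = mann_whitney(x, y)
            u_ref, p_ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                              method="exact")
            assert u == pytest.approx(float(u_ref))
            assert p == pytest.approx(float(p_ref))

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 20).astype(float)
        y = rng.integers(1, 6, 25).astype(float)
        from scipy import stats
        u, p = mann_whitney(x, y)
        u_ref, p_ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic")
        assert (u, p) == (float(u_ref), float(p_ref))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1])


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 40, 80])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_rank_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho, _ = spearman(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        ref = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


class TestEscalationRules:
    def test_trial_medians_select_25_and_10(self):
        best, companion, flags = select_expansion_groups(
            {4.5: 1.2, 10: 1.79, 25: 3.07, 50: 3.0})
        assert (best, companion) == (25, 10)
        assert flags == []

    def test_tie_goes_to_lower_dose(self):
        best, companion, _ = select_expansion_groups({10: 2.0, 25: 2.0})
        assert best == 10

    def test_best_at_lowest_dose_flagged(self):
        best, companion, flags = select_expansion_groups({10: 3.0, 25: 2.0, 50: 1.0})
        assert (best, companion) == (10, 25)
        assert "best_at_lowest_dose" in flags

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            select_expansion_groups({25: 3.0})

    def test_plateau_found_at_25(self):
        """The step from 3.07 to 3.10 gains < 10%, so 25 mg is optimal."""
        dose, found = plateau_optimal_dose({4.5: 1.5, 10: 1.79, 25: 3.07, 50: 3.10})
        assert (dose, found) == (25, True)

    def test_doubling_sequence_no_plateau(self):
        dose, found = plateau_optimal_dose({4.5: 1, 10: 2, 25: 4, 50: 8})
        assert (dose, found) == (50, False)

    def test_flat_sequence_plateaus_at_lowest(self):
        dose, found = plateau_optimal_dose({4.5: 2.0, 10: 2.0, 25: 2.0})
        assert (dose, found) == (4.5, True)

    def test_nonpositive_tbr_rejected(self):
        with pytest.raises(ValueError):
            plateau_optimal_dose({10: 0.0, 25: 1.0})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(tbrs=st.lists(st.floats(0.1, 10.0), min_size=2, max_size=6),
           t1=st.floats(0.0, 0.5), t2=st.floats(0.0, 0.5))
    def test_plateau_monotone_in_threshold(self, tbrs, t1, t2):
        """Raising the relative threshold never yields a higher optimal dose."""
        doses = {float(i + 1): v for i, v in enumerate(tbrs)}
        lo, hi = sorted((t1, t2))
        d_lo, _ = plateau_optimal_dose(doses, rel_threshold=lo)
        d_hi, _ = plateau_optimal_dose(doses, rel_threshold=hi)
        assert d_hi <= d_lo


class TestGroupSummaries:
    def _records(self, cohort, rng):
        recs = []
        for p in cohort:
            rec = te.QuantRecord(patient_id=p.patient_id, level="fresh_slice")
            t = 100 * p.dose_mg * p.uptake_multiplier * rng.uniform(0.9, 1.1)
            b = 500.0 * rng.uniform(0.9, 1.1)
            rec.mfi_by_class = {1: t, "background": b}
            rec.tbr = t / b
            recs.append(rec)
        return recs

    def test_summaries_and_tests_emitted(self):
        cfg = te.CohortConfig(seed=9)
        cohort = te.make_cohort(cfg)
        recs = self._records(cohort, np.random.default_rng(0))
        out = group_summaries(recs, cohort)
        assert len(out["groups"]) == 4
        assert all(g.n == n for g, n in zip(out["groups"], (3, 10, 10, 3)))
        assert "kw_tumor_mfi" in out["tests"]
        g25 = next(g for g in out["groups"] if g.dose_mg == 25.0)
        bp = g25.boxplot["tbr"]
        assert bp["q25"] <= bp["median"] <= bp["q75"]
        assert bp["min"] <= bp["q25"] and bp["q75"] <= bp["max"]

    def test_single_patient_group_flagged(self):
        cfg = te.CohortConfig(dose_groups_mg=(10.0, 25.0), n_per_group=(1, 3), seed=2)
        cohort = te.make_cohort(cfg)
        recs = self._records(cohort, np.random.default_rng(1))
        out = group_summaries(recs, cohort)
        g10 = next(g for g in out["groups"] if g.dose_mg == 10.0)
        assert "underpowered" in g10.flags
        assert g10.medians["tbr"] == pytest.approx(recs[0].tbr)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            group_summaries([], [])
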