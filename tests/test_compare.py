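"""Rank tests, Dunn post hoc, and the repeated reference experiment."""

import numpy as np
import pytest
from scipy import stats

from somatoref.compare import (
    DegenerateDataError,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney_u,
    repeated_reference_comparison,
    wilcoxon_signed_rank,
)
from somatoref.simulate import draw_reference_sample, gamma_from_moments


class TestMannWhitney:
    def test_fully_separated_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_identical_samples(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(1000):
            ps.append(mann_whitney_u(rng.normal(size=25), rng.normal(size=25))[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_exact_approx_agree_at_cutoff(self, rng):
        worst = 0.0
        for _ in range(200):
            x, y = rng.normal(size=10), rng.normal(0.4, size=10)
            pe = mann_whitney_u(x, y)[1]  # tie-free, combined n = 20 -> exact
            pa = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            worst = max(worst, abs(pe - pa))
        assert worst < 0.01


class TestWilcoxon:
    def test_all_positive_differences(self):
        _, p = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert p == pytest.approx(0.25)  # 2/8 sign patterns

    def test_symmetric_differences(self):
        w, p = wilcoxon_signed_rank([0, 0, 0, 0], [-2, -1, 1, 2])
        assert p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        _, p_with = wilcoxon_signed_rank([5, 5, 0, 0, 0], [5, 5, 1, 2, 3])
        _, p_without = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert p_with == pytest.approx(p_without)

    def test_degenerate_all_zero(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(1000):
            d = rng.normal(size=30)
            ps.append(wilcoxon_signed_rank(np.zeros(30), d)[1])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_exact_approx_agree_at_cutoff(self, rng):
        # The corrected normal approximation at 15 tie-free pairs stays
        # within ~0.01 of enumeration (worst case slightly above).
        worst = 0.0
        for _ in range(200):
            d = rng.normal(0.3, size=15)
            pe = wilcoxon_signed_rank(np.zeros(15), d)[1]
            pa = stats.wilcoxon(d, method="approx", correction=True).pvalue
            worst = max(worst, abs(pe - pa))
        assert worst < 0.012


class TestKruskalDunn:
    def test_identical_constant_groups(self):
        h, p = kruskal_wallis([3, 3, 3], [3, 3, 3], [3, 3, 3])
        assert h == 0.0 and p == 1.0
        table = dunn_posthoc([[3, 3, 3], [3, 3, 3], [3, 3, 3]])
        assert np.all(table["p"] > 0.99)

    def test_two_group_concordance_with_mann_whitney(self, rng):
        agree = 0
        trials = 200
        for _ in range(trials):
            x = rng.normal(size=12)
            y = rng.normal(0.5, size=12)
            _, p_kw = kruskal_wallis(x, y)
            _, p_mw = mann_whitney_u(x, y)
            agree += (p_kw < 0.05) == (p_mw < 0.05)
        assert agree >= 0.95 * trials

    def test_power_monotone_in_shift(self, rng):
        shifts = [0.0, 0.5, 1.0, 2.0]
        mean_p = []
        for s in shifts:
            ps = [
                kruskal_wallis(
                    rng.normal(size=20), rng.normal(s, size=20), rng.normal(-s, size=20)
                )[1]
                for _ in range(100)
            ]
            mean_p.append(np.mean(ps))
        assert all(a >= b for a, b in zip(mean_p, mean_p[1:]))

    def test_extreme_pair_smallest_p(self, rng):
        lo = rng.normal(0, 1, size=30)
        mid = rng.normal(2, 1, size=30)
        hi = rng.normal(4, 1, size=30)
        table = dunn_posthoc([lo, mid, hi], labels=["lo", "mid", "hi"])
        idx = table.set_index(["group_i", "group_j"])["p"]
        assert idx[("lo", "hi")] == idx.min()

    def test_dunn_z_against_hand_computation(self):
        """3 groups x 4 tie-free observations, pooled-rank hand oracle."""
        a, b, c = [1, 5, 9, 12], [2, 6, 10, 11], [3, 4, 7, 8]
        table = dunn_posthoc([a, b, c], labels=["a", "b", "c"])
        pooled = np.array(a + b + c, dtype=float)
        ranks = stats.rankdata(pooled)
        rbar = [ranks[0:4].mean(), ranks[4:8].mean(), ranks[8:12].mean()]
        n_tot = 12
        se = np.sqrt(n_tot * (n_tot + 1) / 12.0 * (1 / 4 + 1 / 4))
        expected = {
            ("a", "b"): (rbar[0] - rbar[1]) / se,
            ("a", "c"): (rbar[0] - rbar[2]) / se,
            ("b", "c"): (rbar[1] - rbar[2]) / se,
        }
        for _, row in table.iterrows():
            assert row["z"] == pytest.approx(
                expected[(row["group_i"], row["group_j"])], abs=1e-10
            )

    def test_adjustment_flags(self):
        g = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        raw = dunn_posthoc(g)
        bonf = dunn_posthoc(g, adjust="bonferroni")
        assert np.all(bonf["p_adjusted"] >= raw["p"] - 1e-12)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])


class TestRepeatedComparison:
    def test_extreme_separation(self):
        params = gamma_from_moments(34.0, 17.0)
        patient = draw_reference_sample(params, 45, seed=1) + 5 * 17.0
        exp = repeated_reference_comparison(patient, params, reps=50, seed=2)
        assert exp.pct_significant == 100.0

    def test_null_type_one_rate(self, rng):
        """Pooled over fresh null patient samples, the flag rate is ~5%."""
        params = gamma_from_moments(92.6, 40.4)
        hits, total = 0, 400
        for i in range(total):
            patient = draw_reference_sample(params, 45, rng)
            exp = repeated_reference_comparison(patient, params, reps=1, seed=i)
            hits += exp.p_values[0] < 0.05
        # 4 binomial SEs around 5%
        assert abs(hits / total - 0.05) < 4 * np.sqrt(0.05 * 0.95 / total)

    def test_invariant_to_patient_order(self, rng):
        params = gamma_from_moments(61.5, 27.9)
        patient = draw_reference_sample(params, 30, seed=4)
        a = repeated_reference_comparison(patient, params, reps=20, seed=9)
        b = repeated_reference_comparison(patient[::-1], params, reps=20, seed=9)
        assert a.pct_significant == b.pct_significant

    def test_bookkeeping(self):
        params = gamma_from_moments(34.0, 17.0)
        patient = draw_reference_sample(params, 20, seed=0)
        exp = repeated_reference_comparison(
            patient, params, reps=40, seed=3, measure="TOJ", timepoint="initial"
        )
        assert len(exp.p_values) == 40
        assert all(0 <= p <= 1 for p in exp.p_values)
        expected_pct = 100.0 * sum(p < 0.05 for p in exp.p_values) / 40
        assert exp.pct_significant == expected_pct
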