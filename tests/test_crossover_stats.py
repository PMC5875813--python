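"""Paired tests, repeated-measures ANOVA, Bonferroni and reliability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergo import crossover_stats as cs


class TestPairedT:
    def test_identical_vectors_null(self):
        r = cs.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_computed_statistic(self):
        # differences {1,2,3,4}: t = 2.5 / (1.29099/2) = 3.873, df = 3
        a = np.zeros(4)
        b = np.array([1.0, 2.0, 3.0, 4.0])
        r = cs.paired_t(a, b)
        assert r.t == pytest.approx(3.872983, abs=1e-5)
        assert r.df == 3
        assert r.mean_diff == pytest.approx(2.5)

    def test_single_pair_is_error(self):
        with pytest.raises(ValueError):
            cs.paired_t([1.0], [2.0])

    def test_constant_nonzero_difference_is_degenerate(self):
        r = cs.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.degenerate and np.isinf(r.t) and r.p == 0.0

    def test_paired_sample_objects_accepted(self):
        samples = [cs.PairedSample(f"S{i}", float(i), float(i) + i * 0.5) for i in range(1, 5)]
        r = cs.paired_t(samples)
        assert r.mean_diff == pytest.approx(np.mean([0.5, 1.0, 1.5, 2.0]))

    def test_type_one_error_rate_under_null(self):
        # n = 12 per replicate, 1000 replicates of pure noise
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            if cs.paired_t(a, b).p <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


def bruteforce_rm_anova(data):
    """Independent loop-based sums-of-squares decomposition."""
    n, a, b = data.shape
    grand = sum(data[s, i, j] for s in range(n) for i in range(a) for j in range(b)) / (n * a * b)
    ms = [np.mean([data[s, i, j] for i in range(a) for j in range(b)]) for s in range(n)]
    ma = [np.mean([data[s, i, j] for s in range(n) for j in range(b)]) for i in range(a)]
    mb = [np.mean([data[s, i, j] for s in range(n) for i in range(a)]) for j in range(b)]
    ss_a = n * b * sum((x - grand) ** 2 for x in ma)
    ss_b = n * a * sum((x - grand) ** 2 for x in mb)
    ss_as = b * sum(
        (np.mean(data[s, i, :]) - ms[s] - ma[i] + grand) ** 2
        for s in range(n) for i in range(a)
    )
    ss_bs = a * sum(
        (np.mean(data[s, :, j]) - ms[s] - mb[j] + grand) ** 2
        for s in range(n) for j in range(b)
    )
    ss_ab = n * sum(
        (np.mean(data[:, i, j]) - ma[i] - mb[j] + grand) ** 2
        for i in range(a) for j in range(b)
    )
    ss_s = a * b * sum((x - grand) ** 2 for x in ms)
    ss_tot = sum(
        (data[s, i, j] - grand) ** 2 for s in range(n) for i in range(a) for j in range(b)
    )
    ss_abs = ss_tot - ss_s - ss_a - ss_b - ss_as - ss_bs - ss_ab
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab, ss_tot


class TestRmAnova:
    toy = np.array(
        [
            [[3.0, 5.0, 4.0], [6.0, 8.0, 9.0]],
            [[2.0, 4.0, 5.0], [5.0, 9.0, 7.0]],
            [[4.0, 6.0, 5.0], [8.0, 10.0, 9.0]],
        ]
    )  # 3 subjects × 2 conditions × 3 times, unequal per-subject effects

    def test_matches_bruteforce_decomposition(self):
        f_a, f_b, f_ab, ss_tot = bruteforce_rm_anova(self.toy)
        res = cs.rm_anova(self.toy)
        assert res["condition"].F == pytest.approx(f_a, abs=1e-10)
        assert res["time"].F == pytest.approx(f_b, abs=1e-10)
        assert res["interaction"].F == pytest.approx(f_ab, abs=1e-10)
        assert res.ss_total == pytest.approx(ss_tot, abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        n, a, b = self.toy.shape
        rows = [
            {"subject": s, "condition": i, "time": j, "y": self.toy[s, i, j]}
            for s in range(n) for i in range(a) for j in range(b)
        ]
        df = pd.DataFrame(rows)
        table = pg.rm_anova(
            data=df, dv="y", within=["condition", "time"], subject="subject", detailed=True
        )
        res = cs.rm_anova(self.toy)
        by_name = {r.Source: r.F for r in table.itertuples()}
        assert res["condition"].F == pytest.approx(by_name["condition"], rel=1e-8)
        assert res["time"].F == pytest.approx(by_name["time"], rel=1e-8)
        assert res["interaction"].F == pytest.approx(by_name["condition * time"], rel=1e-8)

    def test_degrees_of_freedom(self):
        res = cs.rm_anova(self.toy)
        assert (res["condition"].df_num, res["condition"].df_den) == (1, 2)
        assert (res["time"].df_num, res["time"].df_den) == (2, 4)
        assert (res["interaction"].df_num, res["interaction"].df_den) == (2, 4)

    def test_zero_condition_difference_gives_zero_f(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(4, 1, 3))
        data = np.concatenate([half, half], axis=1)
        assert cs.rm_anova(data)["condition"].F == pytest.approx(0.0, abs=1e-20)

    def test_constant_condition_shift_increases_f(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            data = rng.normal(size=(6, 2, 4))
            shifted = data.copy()
            shifted[:, 1, :] += 5.0  # shift well beyond any chance imbalance
            assert (
                cs.rm_anova(shifted)["condition"].F
                > cs.rm_anova(data)["condition"].F
            )

    def test_ss_conservation_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            data = rng.normal(size=(5, 2, 6))
            res = cs.rm_anova(data)
            assert sum(res.ss_components.values()) == pytest.approx(res.ss_total, rel=1e-10)

    def test_missing_cells_rejected(self):
        data = self.toy.copy()
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cs.rm_anova(data)


class TestBonferroni:
    def test_definition_and_cap(self):
        assert cs.bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert cs.bonferroni([0.5], m=4)[0] == 1.0
        assert cs.bonferroni([0.2], m=1)[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_never_below_raw(self, ps):
        adj = cs.bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestTypicalError:
    def test_perfect_reliability(self):
        r = cs.typical_error_cv([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["te"] == 0.0 and r["cv_percent"] == 0.0

    def test_formula_on_enumerated_differences(self):
        test = np.array([1.0, 1.2, 0.9, 1.1])
        retest = np.array([1.1, 1.0, 1.0, 1.3])
        d = retest - test
        r = cs.typical_error_cv(test, retest)
        assert r["te"] == pytest.approx(np.std(d, ddof=1) / np.sqrt(2))
        assert r["cv_percent"] == pytest.approx(
            100 * r["te"] / np.mean(np.concatenate([test, retest]))
        )

    def test_zero_grand_mean_is_error(self):
        with pytest.raises(ZeroDivisionError):
            cs.typical_error_cv([-1.0, 1.0], [1.0, -1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cs.typical_error_cv([1.0, 2.0], [1.0])


def test_posthoc_by_time_adjusts_over_timepoints():
    rng = np.random.default_rng(5)
    data = rng.normal(size=(8, 2, 4))
    data[:, 1, 2] += 2.0  # effect only at time index 2
    out = cs.posthoc_by_time(data)
    assert len(out) == 4
    for row in out:
        assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 4))
    assert out[2]["p_adj"] < 0.05
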