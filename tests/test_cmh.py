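"""CMH statistic, dual-mapper merge, and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from poolsim.cmh import (
    CmhResult,
    ContingencyStack,
    adjust_table,
    bh_adjust,
    build_stack,
    cmh_test,
    count_significant,
    merge_dual_mappers,
    cmh_test_calls,
)
from poolsim.snp_calling import SnpCall


def reference_cmh(tables, continuity_correction):
    """Independent closed-form evaluation of the CMH chi-square (test oracle)."""
    num = 0.0
    den = 0.0
    any_informative = False
    for t in np.asarray(tables, dtype=float):
        a = t[0, 0]
        r1, r2 = t[0].sum(), t[1].sum()
        c1, c2 = t[:, 0].sum(), t[:, 1].sum()
        n = t.sum()
        if n <= 1 or 0 in (r1, r2, c1, c2):
            continue
        any_informative = True
        num += a - r1 * c1 / n
        den += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if not any_informative or den == 0:
        return 0.0, 1.0, True
    cc = 0.5 if continuity_correction else 0.0
    stat = max(abs(num) - cc, 0.0) ** 2 / den
    return stat, float(stats.chi2.sf(stat, df=1)), False


class TestBuildStack:
    def test_direct_arrangement(self):
        call = SnpCall(
            "2L", 1, "A", "G", ((50, 10), (40, 20), (45, 15), (30, 30))
        )
        stack = build_stack(call, [(0, 2), (1, 3)])
        assert stack.tables.tolist() == [
            [[50, 10], [45, 15]],
            [[40, 20], [30, 30]],
        ]

    def test_single_pair(self):
        call = SnpCall("2L", 1, "A", "G", ((50, 10), (45, 15)))
        assert build_stack(call, [(0, 1)]).k == 1

    def test_out_of_range_pair(self):
        call = SnpCall("2L", 1, "A", "G", ((50, 10), (45, 15)))
        with pytest.raises(IndexError):
            build_stack(call, [(0, 5)])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ContingencyStack(tables=np.array([[[1, -1], [2, 3]]]))


class TestCmhTest:
    def test_identical_proportions_give_zero(self):
        stack = ContingencyStack(
            tables=np.array([[[30, 30], [30, 30]], [[30, 30], [30, 30]]])
        )
        res = cmh_test(stack, continuity_correction=False)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("correction", [True, False])
    def test_matches_independent_oracle(self, rng, correction):
        for _ in range(50):
            tables = rng.integers(0, 201, size=(2, 2, 2))
            res = cmh_test(ContingencyStack(tables=tables), correction)
            stat, p, deg = reference_cmh(tables, correction)
            assert res.statistic == pytest.approx(stat, rel=1e-12, abs=1e-12)
            assert res.p_value == pytest.approx(p, rel=1e-12, abs=1e-12)
            assert res.degenerate == deg

    @pytest.mark.parametrize("correction", [True, False])
    def test_matches_statsmodels(self, rng, correction):
        """statsmodels agrees wherever the corrected numerator is not floored
        (statsmodels squares |sum dev| - 1/2 even when it is negative)."""
        checked = 0
        while checked < 25:
            tables = rng.integers(1, 201, size=(2, 2, 2))
            dev = sum(
                t[0, 0] - t[0].sum() * t[:, 0].sum() / t.sum() for t in tables
            )
            if correction and abs(dev) < 0.5:
                continue
            res = cmh_test(ContingencyStack(tables=tables), correction)
            sm = StratifiedTable(np.dstack([tables[0], tables[1]]))
            ref = sm.test_null_odds(correction=correction)
            assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-10)
            # statsmodels computes 1 - cdf, which underflows to 0 in the far
            # tail where sf keeps precision; only compare where it resolves
            if float(ref.pvalue) > 1e-15:
                assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)
            else:
                assert res.p_value < 1e-15
            checked += 1

    def test_floored_numerator_where_statsmodels_is_not(self):
        """When |sum dev| < 1/2 the corrected statistic is exactly 0 (the
        numerator base is floored), never a spurious positive value."""
        tables = np.array([[[109, 124], [7, 36]], [[79, 61], [191, 89]]])
        res = cmh_test(ContingencyStack(tables=tables), continuity_correction=True)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_k1_uncorrected_equals_chi_square_score_test(self, rng):
        """With one stratum and no correction the CMH reduces to
        (n-1)/n times the Pearson chi-square of the 2x2 table."""
        for _ in range(20):
            t = rng.integers(1, 100, size=(1, 2, 2))
            res = cmh_test(ContingencyStack(tables=t), continuity_correction=False)
            pearson = stats.chi2_contingency(t[0], correction=False).statistic
            n = t.sum()
            assert res.statistic == pytest.approx(pearson * (n - 1) / n, rel=1e-12)

    def test_zero_margin_stratum_contributes_nothing(self):
        informative = np.array([[10, 20], [15, 5]])
        empty_row = np.array([[0, 0], [5, 5]])
        full = cmh_test(
            ContingencyStack(tables=np.stack([empty_row, informative]))
        )
        alone = cmh_test(ContingencyStack(tables=informative[None]))
        assert full.statistic == pytest.approx(alone.statistic)
        assert full.p_value == pytest.approx(alone.p_value)

    def test_all_uninformative_is_degenerate_p1(self):
        stack = ContingencyStack(
            tables=np.array([[[0, 0], [5, 5]], [[3, 4], [0, 0]]])
        )
        res = cmh_test(stack)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_row_swap_and_allele_relabel_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 50, size=(2, 2, 2))
            base = cmh_test(ContingencyStack(tables=t)).statistic
            swapped_rows = t[:, ::-1, :]
            swapped_cols = t[:, :, ::-1]
            assert cmh_test(
                ContingencyStack(tables=swapped_rows)
            ).statistic == pytest.approx(base)
            assert cmh_test(
                ContingencyStack(tables=swapped_cols)
            ).statistic == pytest.approx(base)

    @staticmethod
    def _null_ks(cov, seed):
        rng = np.random.default_rng(seed)
        n = 10_000
        f = rng.uniform(0.2, 0.8, n)
        calls = []
        maj = rng.binomial(cov, f[:, None] * np.ones((n, 4)))
        for i in range(n):
            calls.append(
                SnpCall(
                    "2L",
                    i + 1,
                    "A",
                    "G",
                    tuple((int(m), cov - int(m)) for m in maj[i]),
                )
            )
        table = cmh_test_calls(calls, [(0, 2), (1, 3)], continuity_correction=False)
        p = np.sort(table["p_value"].to_numpy())
        ecdf = np.arange(1, n + 1) / n
        return np.max(np.maximum(np.abs(ecdf - p), np.abs(ecdf - 1 / n - p)))

    def test_null_p_values_approximately_uniform(self):
        """Identical underlying frequencies + binomial noise: uncorrected
        p-values approach uniformity as coverage grows (KS < 0.03 at 500x,
        1e4 SNPs); at 30x discreteness leaves a visible but bounded
        departure (measured KS ~ 0.08)."""
        assert self._null_ks(500, seed=99) < 0.03
        assert self._null_ks(30, seed=99) < 0.10

    def test_batch_agrees_with_scalar_path(self, rng):
        calls = []
        for i in range(50):
            counts = tuple(
                (int(rng.integers(0, 100)), int(rng.integers(0, 100)))
                for _ in range(4)
            )
            calls.append(SnpCall("2L", i + 1, "A", "G", counts))
        pairs = [(0, 2), (1, 3)]
        table = cmh_test_calls(calls, pairs)
        for row, call in zip(table.itertuples(), calls):
            res = cmh_test(build_stack(call, pairs))
            assert row.statistic == pytest.approx(res.statistic, abs=1e-12)
            assert row.p_value == pytest.approx(res.p_value, abs=1e-12)


class TestMergeDualMappers:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "statistic", "p_value", "degenerate"]
        )

    def test_keeps_maximal_p_on_intersection(self):
        a = self._frame([("2L", 1, 6.0, 0.01, False)])
        b = self._frame([("2L", 1, 3.8, 0.05, False)])
        out = merge_dual_mappers(a, b)
        assert len(out) == 1
        assert out.loc[0, "p_value"] == 0.05
        assert out.loc[0, "statistic"] == 3.8

    def test_snp_in_one_mapper_only_is_dropped(self):
        a = self._frame([("2L", 1, 6.0, 0.01, False), ("2L", 2, 1.0, 0.3, False)])
        b = self._frame([("2L", 2, 2.0, 0.2, False)])
        out = merge_dual_mappers(a, b)
        assert out["pos"].tolist() == [2]
        assert out.loc[0, "p_value"] == 0.3

    def test_both_empty(self):
        assert len(merge_dual_mappers(self._frame([]), self._frame([]))) == 0

    def test_accepts_cmh_result_iterables(self):
        a = [CmhResult("2L", 1, 6.0, 0.01, False)]
        b = [CmhResult("2L", 1, 3.8, 0.05, False)]
        assert merge_dual_mappers(a, b).loc[0, "p_value"] == 0.05

    def test_never_grows_set_never_shrinks_p(self, rng):
        mk = lambda n, seed: self._frame(
            [
                ("2L", i, 1.0, p, False)
                for i, p in enumerate(np.random.default_rng(seed).random(n))
            ]
        )
        a, b = mk(50, 1), mk(40, 2)
        out = merge_dual_mappers(a, b)
        assert len(out) <= min(len(a), len(b))
        pa = a.set_index("pos")["p_value"]
        for row in out.itertuples():
            assert row.p_value >= pa[row.pos]


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels_on_uniforms(self):
        p = np.random.default_rng(4).random(1000)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(bh_adjust(p) - ref)) < 1e-12

    def test_monotone_q_at_least_p_and_capped(self):
        p = np.random.default_rng(8).random(500)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_readjustment_never_decreases_q(self):
        # BH is not idempotent (e.g. (0.1, 0.5) -> (0.2, 0.5) -> (0.4, 0.5)),
        # but re-adjusting can only move q-values up, never down
        p = np.random.default_rng(9).random(100)
        q = bh_adjust(p)
        assert np.all(bh_adjust(q) >= q - 1e-15)
        flat = np.full(10, 0.3)
        assert bh_adjust(flat) == pytest.approx(flat)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestCountSignificant:
    def _table(self, qs):
        return pd.DataFrame(
            {
                "chrom": ["2L"] * len(qs),
                "pos": range(1, len(qs) + 1),
                "p_value": qs,
                "q_value": qs,
            }
        )

    def test_all_q_one_gives_zero(self):
        assert count_significant(self._table([1.0, 1.0]), 0.01)[0] == 0

    def test_strict_inequality(self):
        n, hits = count_significant(self._table([0.005, 0.02, 0.01]), 0.01)
        assert n == 1
        assert hits["pos"].tolist() == [1]

    def test_requires_q_column(self):
        with pytest.raises(ValueError):
            count_significant(pd.DataFrame({"p_value": [0.5]}), 0.01)


def test_adjust_table_adds_bh_column():
    t = pd.DataFrame(
        {"chrom": ["2L"] * 3, "pos": [1, 2, 3], "p_value": [0.01, 0.02, 0.03]}
    )
    out = adjust_table(t)
    assert out["q_value"].tolist() == pytest.approx([0.03, 0.03, 0.03])
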