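"""Contingency construction, switch tests, BH adjustment, associations."""

import numpy as np
import pandas as pd
import pytest

from oracles import bf_bh, bf_chi2_independence, bf_fisher_2x2, bf_haldane_or, bf_pearson

from metaplast.pathways import PathwayDatabase, PathwayDefinition
from metaplast.scoring import (
    ActivityMatrix,
    DominanceMatrix,
    ExpressionMatrix,
    SampleMetadata,
    compute_activity,
    coverage_gate,
)
from metaplast.switches import (
    ContingencyTable,
    SwitchResult,
    adjust_pvalues,
    build_contingency,
    pair_covariate_association,
    significant_switches,
    single_mp_group_test,
)
from metaplast.switches import test_switch as run_switch_test


def _dom(calls, samples=None):
    samples = samples or [f"S{i}" for i in range(len(calls))]
    df = pd.DataFrame([calls], index=pd.Index(["A|B"], name="pair_id"), columns=samples)
    pairs = pd.DataFrame({"pathway_a": ["A"], "pathway_b": ["B"]}, index=df.index)
    return DominanceMatrix(calls=df, pair_index=pairs)


def _meta(groups, samples=None):
    samples = samples or [f"S{i}" for i in range(len(groups))]
    return SampleMetadata(
        table=pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    )


def _table(rows, groups=("young", "old"), n_ties=0):
    return ContingencyTable(
        pair_id="A|B",
        counts=pd.DataFrame(rows, index=list(groups), columns=["first_dominant", "second_dominant"]),
        n_ties_excluded=n_ties,
        degenerate=bool((np.array(rows).sum(axis=1) == 0).any()),
    )


class TestBuildContingency:
    def test_direct_tally(self):
        dom = _dom([1, 1, -1, -1, -1, 1])
        meta = _meta(["young"] * 3 + ["old"] * 3)
        t = build_contingency(dom, meta, "A|B")
        assert t.counts.to_numpy().tolist() == [[2, 1], [1, 2]]
        assert t.n_ties_excluded == 0

    def test_ties_excluded_and_counted(self):
        t = build_contingency(_dom([1, 0, -1, 0]), _meta(["young", "young", "old", "old"]), "A|B")
        assert t.counts.to_numpy().tolist() == [[1, 0], [0, 1]]
        assert t.n_ties_excluded == 2

    def test_three_group_shape(self):
        dom = _dom([1, -1, 1, -1, 1, -1])
        meta = _meta(["young", "young", "middle", "middle", "old", "old"])
        t = build_contingency(dom, meta, "A|B", groups=("young", "middle", "old"))
        assert t.counts.shape == (3, 2)

    def test_middle_samples_ignored_in_two_group_contrast(self):
        dom = _dom([1, 1, -1, -1])
        meta = _meta(["young", "middle", "middle", "old"])
        t = build_contingency(dom, meta, "A|B")
        assert t.counts.to_numpy().sum() == 2

    def test_empty_group_flagged_degenerate(self):
        t = build_contingency(_dom([1, -1]), _meta(["young", "young"]), "A|B")
        assert t.degenerate


class TestTestSwitch:
    def test_perfect_independence(self):
        r = run_switch_test(_table([[25, 25], [25, 25]]))
        assert r.test_used == "chi_square"
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.direction == "none"

    def test_odds_ratio_cross_product(self):
        # old group enriched for first-dominance: OR = (30/10)/(10/30) = 9
        r = run_switch_test(_table([[10, 30], [30, 10]]))
        assert r.odds_ratio == pytest.approx(9.0)
        assert r.direction == "toward_first"
        # mirrored table: odds of first-dominance fall with age
        r2 = run_switch_test(_table([[30, 10], [10, 30]]))
        assert r2.odds_ratio == pytest.approx(1 / 9)
        assert r2.direction == "toward_second"

    def test_small_table_fisher_with_haldane_correction(self):
        r = run_switch_test(_table([[3, 0], [0, 3]]))
        assert r.test_used == "fisher_exact"
        # +0.5 on every cell: cross-product magnitude 3.5^2 / 0.5^2 = 49
        assert r.odds_ratio == pytest.approx(1 / 49)
        r_swapped = run_switch_test(_table([[0, 3], [3, 0]]))
        assert r_swapped.odds_ratio == pytest.approx(49.0)

    def test_row_swap_inverts_or_and_preserves_p(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rows = rng.integers(0, 40, size=(2, 2)) + 1
            fwd = run_switch_test(_table(rows.tolist()))
            rev = run_switch_test(_table(rows[::-1].tolist()))
            assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
            assert fwd.odds_ratio == pytest.approx(1 / rev.odds_ratio)
            if fwd.direction != "none":
                assert fwd.direction != rev.direction

    def test_degenerate_zero_row(self):
        r = run_switch_test(_table([[0, 0], [10, 10]]))
        assert r.degenerate and r.p_value == 1.0 and r.direction == "none"

    def test_rx2_small_counts_permutation_is_seeded(self):
        table = _table([[3, 1], [1, 3], [0, 4]], groups=("young", "middle", "old"))
        r1 = run_switch_test(table, seed=11, n_permutations=2000)
        r2 = run_switch_test(table, seed=11, n_permutations=2000)
        assert r1.test_used == "permutation"
        assert r1.p_value == r2.p_value
        with pytest.raises(ValueError, match="seed"):
            run_switch_test(table)

    def test_permutation_p_close_to_chi2_on_moderate_table(self):
        table = _table([[36, 18], [18, 36], [27, 27]], groups=("young", "middle", "old"))
        r_perm = run_switch_test(table, min_expected=100, seed=3, n_permutations=20000)
        assert r_perm.test_used == "permutation"
        _, p_chi2 = bf_chi2_independence(table.counts.to_numpy())
        assert r_perm.p_value == pytest.approx(p_chi2, abs=0.01)

    def test_fisher_and_chi2_agree_on_large_cells(self):
        """With all cells >= 50 the two tests give close p-values in the tail
        that matters for screening (two-sided Fisher is lumpy near p = 1)."""
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 30:
            rows = rng.integers(50, 120, size=(2, 2))
            r = run_switch_test(_table(rows.tolist()))
            assert r.test_used == "chi_square"
            if r.p_value >= 0.1:
                continue
            checked += 1
            assert r.p_value == pytest.approx(bf_fisher_2x2(rows), abs=0.03)


class TestStatisticsOracles:
    """Implementation vs independent brute-force on random small instances."""

    def test_chi2_matches_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            rows = rng.integers(5, 60, size=(2, 2)) + 5
            r = run_switch_test(_table(rows.tolist()), min_expected=0.0)
            stat, p = bf_chi2_independence(rows)
            assert r.statistic == pytest.approx(stat, abs=1e-9)
            assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            rows = rng.integers(0, 10, size=(2, 2))
            if rows.sum(axis=1).min() == 0 or rows.sum(axis=0).min() == 0:
                continue
            r = run_switch_test(_table(rows.tolist()), min_expected=1e9)
            assert r.test_used == "fisher_exact"
            assert r.p_value == pytest.approx(bf_fisher_2x2(rows), abs=1e-9)

    def test_odds_ratio_matches_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            rows = rng.integers(0, 15, size=(2, 2))
            if rows.sum(axis=1).min() == 0 or rows.sum(axis=0).min() == 0:
                continue
            r = run_switch_test(_table(rows.tolist()))
            assert r.odds_ratio == pytest.approx(
                bf_haldane_or(rows[0], rows[1]), abs=1e-12
            )


class TestAdjustPvalues:
    def _results(self, pvals):
        return [
            SwitchResult(
                pair_id=f"P|{i}", test_used="chi_square", statistic=0.0, p_value=p,
                odds_ratio=1.0, direction="none",
                table=_table([[10, 10], [10, 10]]),
            )
            for i, p in enumerate(pvals)
        ]

    @pytest.mark.parametrize(
        "pvals,expected",
        [((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)), ((0.04,), (0.04,)), ((1.0, 1.0), (1.0, 1.0))],
    )
    def test_worked_examples(self, pvals, expected):
        adj = [r.adjusted_p for r in adjust_pvalues(self._results(pvals))]
        assert adj == pytest.approx(list(expected))

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            pvals = rng.uniform(0, 1, size=rng.integers(1, 40))
            adj = [r.adjusted_p for r in adjust_pvalues(self._results(pvals))]
            assert adj == pytest.approx(bf_bh(pvals).tolist(), abs=1e-12)

    def test_empty_input(self):
        assert adjust_pvalues([]) == []


class TestSignificantSwitches:
    def _with_q(self, qvals):
        from dataclasses import replace

        base = run_switch_test(_table([[10, 10], [10, 10]]))
        return [replace(base, pair_id=f"P{i}", adjusted_p=q) for i, q in enumerate(qvals)]

    def test_strict_threshold(self):
        res = significant_switches(self._with_q([0.049, 0.05, 0.2]))
        assert [r.pair_id for r in res] == ["P0"]

    def test_deterministic_order(self):
        res = significant_switches(self._with_q([0.01, 0.001, 0.01]))
        assert [r.pair_id for r in res] == ["P1", "P0", "P2"]

    def test_empty(self):
        assert significant_switches([]) == []


def _activity_for_signal(signal_a, signal_b):
    n = len(signal_a)
    samples = [f"S{i}" for i in range(n)]
    db = PathwayDatabase(
        (PathwayDefinition("A", "x", ("A1", "A2")), PathwayDefinition("B", "x", ("B1", "B2")))
    )
    vals = np.vstack([signal_a, signal_a, signal_b, signal_b]).astype(float)
    expr = ExpressionMatrix(
        values=pd.DataFrame(vals, index=["A1", "A2", "B1", "B2"], columns=samples),
        scale_tag="log",
    )
    return compute_activity(db, expr, coverage_gate(db, expr))


class TestPairCovariateAssociation:
    def _meta_with_cov(self, cov, samples):
        return SampleMetadata(
            table=pd.DataFrame({"cov": cov}, index=pd.Index(samples, name="sample_id"))
        )

    def test_perfect_anticorrelation(self):
        act = _activity_for_signal([2, 3, 4, 5], [1, 1, 1, 1])
        meta = self._meta_with_cov([4, 3, 2, 1], act.scores.columns)
        r = pair_covariate_association(act, "A|B", meta, "cov")
        assert r.pearson_r == pytest.approx(-1.0)

    def test_linear_in_covariate(self):
        act = _activity_for_signal([1, 2, 3, 4, 5], [0.5] * 5)
        meta = self._meta_with_cov([10, 20, 30, 40, 50], act.scores.columns)
        r = pair_covariate_association(act, "A|B", meta, "cov")
        assert r.pearson_r == pytest.approx(1.0)

    def test_constant_covariate_flagged(self):
        act = _activity_for_signal([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5])
        meta = self._meta_with_cov([5, 5, 5, 5], act.scores.columns)
        r = pair_covariate_association(act, "A|B", meta, "cov")
        assert r.degenerate and r.p_value == 1.0 and np.isnan(r.pearson_r)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            sig = rng.normal(size=n)
            cov = rng.normal(size=n)
            act = _activity_for_signal(sig, np.full(n, 0.5))
            meta = self._meta_with_cov(cov, act.scores.columns)
            res = pair_covariate_association(act, "A|B", meta, "cov")
            r_bf, p_bf = bf_pearson(sig, cov)
            assert res.pearson_r == pytest.approx(r_bf, abs=1e-12)
            assert res.p_value == pytest.approx(p_bf, abs=1e-12)

    def test_too_few_samples(self):
        act = _activity_for_signal([1, 2], [0.5, 0.5])
        meta = self._meta_with_cov([1, 2], act.scores.columns)
        with pytest.raises(ValueError, match=">= 3"):
            pair_covariate_association(act, "A|B", meta, "cov")


class TestSingleMpGroupTest:
    def _run(self, young_scores, old_scores):
        act = _activity_for_signal(
            list(young_scores) + list(old_scores), [0.5] * (len(young_scores) + len(old_scores))
        )
        groups = ["young"] * len(young_scores) + ["old"] * len(old_scores)
        meta = SampleMetadata(
            table=pd.DataFrame(
                {"group": groups}, index=pd.Index(act.scores.columns, name="sample_id")
            )
        )
        return single_mp_group_test(act, meta)

    def test_identical_groups_null(self):
        out = self._run([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.loc["A", "mean_difference"] == pytest.approx(0.0)
        assert out.loc["A", "p_value"] == pytest.approx(1.0)

    def test_constant_shift_recovered(self):
        out = self._run([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert out.loc["A", "mean_difference"] == pytest.approx(10.0)

    def test_group_below_two_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            self._run([1.0], [2.0, 3.0])
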