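"""Group-wise metabolic-switch statistics.

A metabolic switch is a pathway pair whose within-sample dominance
relationship differs between age groups. Each pair's dominance calls are
tabulated into a group-by-dominance contingency table (ties excluded), tested
with a chi-square test of independence — falling back to Fisher's exact test
(2x2) or a seeded Monte-Carlo permutation test (r x 2) when expected counts
are small — and summarized by an odds ratio giving the switch direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import expected_freq
from statsmodels.stats.multitest import multipletests

from .scoring import ActivityMatrix, DominanceMatrix, SampleMetadata

__all__ = [
    "ContingencyTable",
    "SwitchResult",
    "AssociationResult",
    "build_contingency",
    "test_switch",
    "adjust_pvalues",
    "significant_switches",
    "pair_covariate_association",
    "single_mp_group_test",
    "results_table",
]

DOMINANCE_COLUMNS = ("first_dominant", "second_dominant")


@dataclass(frozen=True)
class ContingencyTable:
    """Group-by-dominance counts for one pathway pair, ties excluded."""

    pair_id: str
    counts: pd.DataFrame  # groups (young -> old) x (first_dominant, second_dominant)
    n_ties_excluded: int
    degenerate: bool = False

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative contingency counts")
        if list(self.counts.columns) != list(DOMINANCE_COLUMNS):
            raise ValueError(f"columns must be {DOMINANCE_COLUMNS}")


@dataclass(frozen=True)
class SwitchResult:
    """Outcome of one pair's switch test.

    ``odds_ratio`` is the odds of first-pathway dominance in the oldest group
    over those odds in the youngest group (Haldane–Anscombe +0.5 applied to
    every cell when any cell is zero); direction is toward_first when the old
    group is enriched for first-pathway dominance (OR > 1).
    """

    pair_id: str
    test_used: str  # chi_square | fisher_exact | permutation | degenerate
    statistic: float
    p_value: float
    odds_ratio: float
    direction: str  # toward_first | toward_second | none
    table: ContingencyTable
    adjusted_p: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class AssociationResult:
    """Pearson correlation of a pair's dominance signal with a covariate."""

    pair_id: str
    covariate_name: str
    pearson_r: float
    p_value: float
    n_used: int
    degenerate: bool = False


def build_contingency(
    dom: DominanceMatrix,
    meta: SampleMetadata,
    pair_id: str,
    groups: tuple[str, ...] = ("young", "old"),
) -> ContingencyTable:
    """Tabulate one pair's dominance calls by age group.

    Rows follow the order of ``groups`` (young first); tie calls are excluded
    and counted in ``n_ties_excluded``. Samples whose group label is not in
    ``groups`` (e.g. the middle group in the default two-group contrast) are
    ignored. A table with an all-zero row is returned flagged degenerate.
    """
    calls = dom.calls.loc[pair_id]
    labels = meta.groups.reindex(calls.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"samples without group label: {missing}")
    counts = np.zeros((len(groups), 2), dtype=int)
    n_ties = 0
    for g_idx, g in enumerate(groups):
        sub = calls[labels == g]
        counts[g_idx, 0] = int((sub == 1).sum())
        counts[g_idx, 1] = int((sub == -1).sum())
        n_ties += int((sub == 0).sum())
    df = pd.DataFrame(counts, index=pd.Index(groups, name="group"), columns=list(DOMINANCE_COLUMNS))
    degenerate = bool((counts.sum(axis=1) == 0).any())
    return ContingencyTable(
        pair_id=pair_id, counts=df, n_ties_excluded=n_ties, degenerate=degenerate
    )


def _haldane_odds_ratio(young_row: np.ndarray, old_row: np.ndarray) -> float:
    a, b = float(old_row[0]), float(old_row[1])  # old: first-, second-dominant
    c, d = float(young_row[0]), float(young_row[1])  # young: first-, second-dominant
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def test_switch(
    table: ContingencyTable,
    min_expected: float = 5.0,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> SwitchResult:
    """Test one contingency table for group-dependent dominance.

    Chi-square test of independence (no continuity correction) when every
    expected count is >= ``min_expected``; otherwise Fisher's exact test for
    2x2 tables or a seeded Monte-Carlo permutation test (chi-square statistic
    under fixed margins) for r x 2 tables with r > 2. Degenerate tables (an
    empty row or column) return p = 1 with direction none.
    """
    counts = table.counts.to_numpy(dtype=float)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    odds_ratio = _haldane_odds_ratio(counts[0], counts[-1])

    if table.degenerate or (row_tot == 0).any() or (col_tot == 0).any():
        return SwitchResult(
            pair_id=table.pair_id,
            test_used="degenerate",
            statistic=0.0,
            p_value=1.0,
            odds_ratio=odds_ratio,
            direction="none",
            table=table,
            degenerate=True,
        )

    expected = expected_freq(counts)
    if (expected >= min_expected).all():
        stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
        test_used = "chi_square"
    elif counts.shape[0] == 2:
        _, p = stats.fisher_exact(counts, alternative="two-sided")
        stat = odds_ratio
        test_used = "fisher_exact"
    else:
        if seed is None:
            raise ValueError("permutation test requires a seed")
        rng = np.random.default_rng(seed)
        stat, _, _, _ = stats.chi2_contingency(counts, correction=False)
        sampler = stats.random_table(row_tot.astype(int), col_tot.astype(int))
        sims = sampler.rvs(n_permutations, random_state=rng)
        exp = expected_freq(counts)
        sim_stats = ((sims - exp) ** 2 / exp).sum(axis=(1, 2))
        p = (1 + int((sim_stats >= stat - 1e-12).sum())) / (1 + n_permutations)
        test_used = "permutation"

    if odds_ratio > 1:
        direction = "toward_first"
    elif odds_ratio < 1:
        direction = "toward_second"
    else:
        direction = "none"
    return SwitchResult(
        pair_id=table.pair_id,
        test_used=test_used,
        statistic=float(stat),
        p_value=float(p),
        odds_ratio=float(odds_ratio),
        direction=direction,
        table=table,
    )


def adjust_pvalues(results: list[SwitchResult], method: str = "BH") -> list[SwitchResult]:
    """Benjamini–Hochberg step-up adjustment across all tested pairs of one cohort."""
    if method != "BH":
        raise ValueError(f"unsupported adjustment method {method!r}")
    if not results:
        return []
    pvals = np.array([r.p_value for r in results])
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [replace(r, adjusted_p=float(q)) for r, q in zip(results, adj)]


def significant_switches(results: list[SwitchResult], alpha: float = 0.05) -> list[SwitchResult]:
    """Pairs with adjusted p strictly below alpha, sorted by (adjusted_p, pair_id)."""
    kept = [r for r in results if r.adjusted_p < alpha]
    return sorted(kept, key=lambda r: (r.adjusted_p, r.pair_id))


def pair_covariate_association(
    act: ActivityMatrix,
    pair_id: str,
    meta: SampleMetadata,
    covariate_name: str,
) -> AssociationResult:
    """Pearson correlation of the pair's activity difference with a covariate.

    The per-sample signal is score(A) - score(B); samples with a missing
    covariate are dropped. A zero-variance signal or covariate yields a
    degenerate result with undefined r and p = 1.
    """
    from .pathways import split_pair_id

    a, b = split_pair_id(pair_id)
    signal = act.pair_signal(a, b)
    cov = meta.covariate(covariate_name).reindex(signal.index)
    mask = cov.notna()
    x = signal[mask].to_numpy(dtype=float)
    y = cov[mask].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(
            f"covariate {covariate_name!r} present for {len(x)} samples; need >= 3"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            pair_id=pair_id,
            covariate_name=covariate_name,
            pearson_r=float("nan"),
            p_value=1.0,
            n_used=len(x),
            degenerate=True,
        )
    r, p = stats.pearsonr(x, y)
    return AssociationResult(
        pair_id=pair_id,
        covariate_name=covariate_name,
        pearson_r=float(r),
        p_value=float(p),
        n_used=len(x),
    )


def single_mp_group_test(
    act: ActivityMatrix,
    meta: SampleMetadata,
    group_young: str = "young",
    group_old: str = "old",
) -> pd.DataFrame:
    """Per-pathway two-group comparison of activity scores.

    Welch t-test (old vs young) on each scored pathway, BH-adjusted across
    pathways; the effect is the old-minus-young mean difference. Both groups
    need at least 2 samples.
    """
    groups = meta.groups.reindex(act.scores.columns)
    young_ids = groups.index[groups == group_young]
    old_ids = groups.index[groups == group_old]
    if len(young_ids) < 2 or len(old_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(young_ids)} {group_young} / "
            f"{len(old_ids)} {group_old}"
        )
    young = act.scores[young_ids].to_numpy(dtype=float)
    old = act.scores[old_ids].to_numpy(dtype=float)
    diff = old.mean(axis=1) - young.mean(axis=1)
    stat, p = stats.ttest_ind(old, young, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "mean_difference": diff,
            "t_statistic": stat,
            "p_value": p,
            "adjusted_p": adj,
        },
        index=act.scores.index.copy(),
    )


def results_table(results: list[SwitchResult]) -> pd.DataFrame:
    """Flatten switch results to one row per pair (TSV-ready)."""
    rows = []
    for r in results:
        counts = r.table.counts
        rec = {
            "pair_id": r.pair_id,
            "test_used": r.test_used,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "adjusted_p": r.adjusted_p,
            "odds_ratio": r.odds_ratio,
            "direction": r.direction,
            "n_ties_excluded": r.table.n_ties_excluded,
            "degenerate": r.degenerate,
        }
        for g in counts.index:
            rec[f"{g}_first"] = counts.loc[g, "first_dominant"]
            rec[f"{g}_second"] = counts.loc[g, "second_dominant"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("pair_id") if rows else pd.DataFrame(
        columns=["test_used", "statistic", "p_value", "adjusted_p", "odds_ratio", "direction"]
    )
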