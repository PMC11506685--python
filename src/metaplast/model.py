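"""Model/Results facade over the metabolic-plasticity pipeline.

`MetabolicPlasticityModel` holds a cohort (expression + sample metadata +
pathway database) and scoring settings; `fit()` runs coverage gating,
PPI-weighted activity scoring, intra-sample pair dominance and the group-wise
switch tests, returning a `MetabolicPlasticityResults` with the per-pair odds
ratios, p-values and BH-adjusted q-values, a `summary()` table, and hooks for
the downstream network, association and plotting steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import network as net_mod
from . import switches as sw
from .pathways import PathwayDatabase, enumerate_pairs, pair_id
from .scoring import (
    ActivityMatrix,
    DominanceMatrix,
    ExpressionMatrix,
    SampleMetadata,
    compute_activity,
    coverage_gate,
    pairwise_dominance,
)

__all__ = ["MetabolicPlasticityModel", "MetabolicPlasticityResults"]


class MetabolicPlasticityModel:
    """Pathway-pair metabolic plasticity model for one cohort.

    Parameters
    ----------
    expr : ExpressionMatrix
        Gene-by-sample expression (linear values are log2(v+1)-transformed
        before scoring).
    meta : SampleMetadata
        Sample table with a ``group`` column (see
        :func:`metaplast.scoring.assign_age_groups`).
    pathways : PathwayDatabase
        Gene sets with per-gene weights (uniform, or PPI-derived via
        :func:`metaplast.pathways.attach_ppi_weights`).
    min_coverage : float
        Fraction of a pathway's genes that must be detected for the pathway
        to be scored (boundary inclusive).
    tie_tol : float
        Absolute activity-difference tolerance below which a dominance call
        is a tie.
    groups : tuple of str
        Ordered group labels contrasted by the switch tests (youngest
        first); samples in other groups are ignored by the tests.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        meta: SampleMetadata,
        pathways: PathwayDatabase,
        min_coverage: float = 0.30,
        min_samples: int = 1,
        tie_tol: float = 1e-9,
        groups: tuple[str, ...] = ("young", "old"),
    ):
        missing = [s for s in expr.sample_ids if s not in set(meta.sample_ids)]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        self.expr = expr
        self.meta = meta
        self.pathways = pathways
        self.min_coverage = min_coverage
        self.min_samples = min_samples
        self.tie_tol = tie_tol
        self.groups = tuple(groups)

    @classmethod
    def from_dataframes(
        cls,
        expr: pd.DataFrame,
        meta: pd.DataFrame,
        pathways: PathwayDatabase,
        scale_tag: str = "linear",
        **kwargs,
    ) -> "MetabolicPlasticityModel":
        """Build from plain gene-by-sample and sample-metadata DataFrames."""
        return cls(
            ExpressionMatrix(values=expr, scale_tag=scale_tag),
            SampleMetadata(table=meta),
            pathways,
            **kwargs,
        )

    def score(self) -> ActivityMatrix:
        """Coverage-gate and score all pathways (no switch testing)."""
        gate = coverage_gate(
            self.pathways, self.expr, min_fraction=self.min_coverage,
            min_samples=self.min_samples,
        )
        return compute_activity(self.pathways, self.expr, gate)

    def fit(
        self,
        alpha: float = 0.05,
        min_expected: float = 5.0,
        n_permutations: int = 10_000,
        seed: int | None = None,
    ) -> "MetabolicPlasticityResults":
        """Run the full pipeline and return results.

        ``seed`` is required only when a small r x 2 table forces the
        Monte-Carlo permutation path.
        """
        activity = self.score()
        scored = set(activity.scored_ids)
        pairs = [(a, b) for a, b in enumerate_pairs(self.pathways) if a in scored and b in scored]
        if not pairs:
            raise ValueError("no scorable pathway pairs after the coverage gate")
        dominance = pairwise_dominance(activity, pairs, tie_tol=self.tie_tol)
        results = []
        for a, b in pairs:
            table = sw.build_contingency(dominance, self.meta, pair_id(a, b), groups=self.groups)
            results.append(
                sw.test_switch(
                    table, min_expected=min_expected, n_permutations=n_permutations, seed=seed
                )
            )
        results = sw.adjust_pvalues(results)
        return MetabolicPlasticityResults(
            model=self, activity=activity, dominance=dominance,
            switch_results=results, alpha=alpha,
        )


@dataclass
class MetabolicPlasticityResults:
    """Fitted switch-test results for one cohort."""

    model: MetabolicPlasticityModel
    activity: ActivityMatrix
    dominance: DominanceMatrix
    switch_results: list[sw.SwitchResult]
    alpha: float = 0.05

    @property
    def frame(self) -> pd.DataFrame:
        """All tested pairs as a DataFrame (statistic, p, q, OR, direction)."""
        return sw.results_table(self.switch_results)

    def significant(self, alpha: float | None = None) -> list[sw.SwitchResult]:
        """Switches with adjusted p strictly below alpha."""
        return sw.significant_switches(self.switch_results, alpha=alpha or self.alpha)

    def top_events(self, k: int = 200) -> list[sw.SwitchResult]:
        """Top-k significant events by adjusted p (for network construction)."""
        return net_mod.select_top_events(self.significant(), k=k)

    def to_network(self, cohort_tag: str = "cohort", k: int = 200):
        """Single-cohort metabo-plastic network from the top-k events."""
        return net_mod.build_network({cohort_tag: self.top_events(k)})

    def associate(self, pair_id: str, covariate_name: str) -> sw.AssociationResult:
        """Pearson correlation of a pair's signal with a continuous covariate."""
        return sw.pair_covariate_association(
            self.activity, pair_id, self.model.meta, covariate_name
        )

    def single_pathway_tests(self) -> pd.DataFrame:
        """Per-pathway Welch t-test of activity between the two contrast groups."""
        g = self.model.groups
        return sw.single_mp_group_test(
            self.activity, self.model.meta, group_young=g[0], group_old=g[-1]
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top switches."""
        n_sig = len(self.significant())
        n_scored = len(self.activity.scored_ids)
        lines = [
            "Metabolic Plasticity Switch Results",
            "=" * 60,
            f"samples:            {len(self.model.expr.sample_ids)}",
            f"contrast groups:    {' vs '.join(self.model.groups)}",
            f"pathways scored:    {n_scored} / {len(self.model.pathways)}"
            f" (coverage gate {self.model.min_coverage:.0%})",
            f"pairs tested:       {len(self.switch_results)}",
            f"significant (q<{self.alpha:g}): {n_sig}",
            "-" * 60,
        ]
        if self.switch_results:
            cols = ["test_used", "p_value", "adjusted_p", "odds_ratio", "direction"]
            head = self.frame.sort_values(["adjusted_p", "p_value"]).head(top)[cols]
            lines.append(head.to_string(float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def plot_pair(self, pair_id: str, ax=None):
        """Scatter the two pathways' activity scores, colored by group."""
        import matplotlib.pyplot as plt

        from .pathways import split_pair_id

        a, b = split_pair_id(pair_id)
        if ax is None:
            _, ax = plt.subplots()
        groups = self.model.meta.groups.reindex(self.activity.scores.columns)
        for g in dict.fromkeys(groups):
            mask = groups == g
            ax.scatter(
                self.activity.scores.loc[a, mask],
                self.activity.scores.loc[b, mask],
                label=str(g), alpha=0.7,
            )
        lims = [
            min(ax.get_xlim()[0], ax.get_ylim()[0]),
            max(ax.get_xlim()[1], ax.get_ylim()[1]),
        ]
        ax.plot(lims, lims, ls="--", c="gray", lw=1)
        ax.set_xlabel(f"{a} activity")
        ax.set_ylabel(f"{b} activity")
        ax.legend(title="group")
        return ax
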