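"""Seeded synthetic cohorts with planted metabolic switches.

The bulk generator emits log-scale expression with pathway-level
group x dominance reversals of configurable effect size: for a planted switch
(A, B, delta), young samples gain +delta on all of A's genes and old samples
gain +delta on all of B's genes, so the A-vs-B dominance relationship
reverses between groups. Effects are planted at the gene level so the
coverage gate, PPI weighting and scoring path are all exercised. The
single-cell generator emits negative-binomial UMI tables with configurable
per-group cell-type composition and cells constructed to violate exactly one
named QC rule each.

All generators are pure functions of their config: the same seed reproduces
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .pathways import PathwayDatabase, PathwayDefinition, enumerate_pairs, pair_id
from .scoring import ActivityMatrix, ExpressionMatrix, SampleMetadata

__all__ = [
    "BulkSimConfig",
    "ScSimConfig",
    "simulate_bulk_cohort",
    "simulate_age_covariate",
    "simulate_sc_cohort",
]

# age blocks per group; fixed thresholds (50, 65) recover these labels exactly
AGE_BLOCKS = {"young": (35.0, 50.0), "middle": (50.0, 65.0), "old": (65.0, 80.0)}


@dataclass(frozen=True)
class BulkSimConfig:
    """Configuration for a bulk cohort with planted dominance reversals.

    ``planted_switches`` entries are (pathway_a, pathway_b, effect_delta) with
    pathway ids MP01, MP02, ... and the effect in log2 units. ``n_middle``
    samples (no group effect) can be added so that quartile-based age
    grouping recovers the planted labels exactly.
    """

    n_pathways: int = 50
    genes_per_pathway: int = 20
    n_young: int = 30
    n_old: int = 30
    n_middle: int = 0
    planted_switches: tuple[tuple[str, str, float], ...] = ()
    gene_noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_switches", tuple(
            (a, b, float(d)) for a, b, d in self.planted_switches
        ))
        if self.n_pathways < 2 or self.genes_per_pathway < 2:
            raise ValueError("need >= 2 pathways and >= 2 genes per pathway")
        if self.n_young < 1 or self.n_old < 1 or self.n_middle < 0:
            raise ValueError("invalid sample counts")
        if self.gene_noise_sd < 0:
            raise ValueError("gene_noise_sd must be nonnegative")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ValueError("baseline_mean_range must be increasing")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        ids = set(self.pathway_ids)
        for a, b, d in self.planted_switches:
            if a == b:
                raise ValueError(f"planted switch ({a}, {b}) must reference distinct pathways")
            if a not in ids or b not in ids:
                raise ValueError(f"planted switch ({a}, {b}) references unknown pathway")
            if not np.isfinite(d):
                raise ValueError("effect_delta must be finite")

    @property
    def pathway_ids(self) -> list[str]:
        width = max(2, len(str(self.n_pathways)))
        return [f"MP{i + 1:0{width}d}" for i in range(self.n_pathways)]


def _bulk_truth(cfg: BulkSimConfig, db: PathwayDatabase) -> pd.DataFrame:
    """Per-pair ground truth: planted pairs plus every truly switching pair.

    A pair truly switches when its two pathways receive unequal
    (young, old) effect profiles — this includes collateral pairs formed by
    one planted pathway and one untouched pathway.
    """
    young_eff = dict.fromkeys(cfg.pathway_ids, 0.0)
    old_eff = dict.fromkeys(cfg.pathway_ids, 0.0)
    planted = {}
    for a, b, d in cfg.planted_switches:
        young_eff[a] += d
        old_eff[b] += d
        planted[pair_id(a, b)] = d
    rows = []
    for a, b in enumerate_pairs(db):
        d_young = young_eff[a] - young_eff[b]
        d_old = old_eff[a] - old_eff[b]
        if d_old > d_young:
            direction = "toward_first"
        elif d_old < d_young:
            direction = "toward_second"
        else:
            direction = "none"
        pid = pair_id(a, b)
        rows.append(
            {
                "pair_id": pid,
                "pathway_a": a,
                "pathway_b": b,
                "planted": pid in planted,
                "effect_delta": planted.get(pid, 0.0),
                "true_switch": d_old != d_young,
                "expected_direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


def simulate_bulk_cohort(
    cfg: BulkSimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, PathwayDatabase, pd.DataFrame]:
    """Simulate a log-scale bulk cohort with planted dominance reversals.

    Gene log-expression = baseline + group effect + N(0, gene_noise_sd).
    Baselines are drawn per gene from ``baseline_mean_range`` and re-centred
    so every pathway has the same mean baseline; without this, random
    pathway-level baseline gaps would mask small planted reversals. Ages are
    drawn from disjoint per-group blocks ([35,50) / [50,65) / [65,80)), so
    fixed-mode thresholds (50, 65) always recover the labels; quartile mode
    recovers them exactly when n_young = n_old and n_middle = n_young + n_old
    (the interpolated quartiles then fall strictly inside the block gaps).
    Returns (expression, metadata, pathway database, truth table).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.baseline_mean_range
    m = cfg.genes_per_pathway
    pathways = []
    gene_ids = []
    for pid in cfg.pathway_ids:
        genes = tuple(f"{pid}_G{j + 1:03d}" for j in range(m))
        gene_ids.extend(genes)
        pathways.append(PathwayDefinition(pathway_id=pid, name=f"synthetic pathway {pid}", genes=genes))
    db = PathwayDatabase(pathways=tuple(pathways), source_tag=f"synthetic(seed={cfg.seed})")

    baseline = rng.uniform(lo, hi, size=len(gene_ids))
    center = 0.5 * (lo + hi)
    for p_idx in range(cfg.n_pathways):
        sl = slice(p_idx * m, (p_idx + 1) * m)
        baseline[sl] += center - baseline[sl].mean()

    groups = (
        ["young"] * cfg.n_young + ["middle"] * cfg.n_middle + ["old"] * cfg.n_old
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(len(groups))]
    ages = np.array([rng.uniform(*AGE_BLOCKS[g]) for g in groups])

    effect = np.zeros((len(gene_ids), len(groups)))
    p_index = {pid: i for i, pid in enumerate(cfg.pathway_ids)}
    grp = np.array(groups)
    for a, b, d in cfg.planted_switches:
        sl_a = slice(p_index[a] * m, (p_index[a] + 1) * m)
        sl_b = slice(p_index[b] * m, (p_index[b] + 1) * m)
        effect[sl_a, grp == "young"] += d
        effect[sl_b, grp == "old"] += d

    noise = rng.normal(0.0, cfg.gene_noise_sd, size=effect.shape)
    values = pd.DataFrame(
        baseline[:, None] + effect + noise, index=gene_ids, columns=sample_ids
    )
    expr = ExpressionMatrix(values=values, scale_tag="log")
    meta = SampleMetadata(
        table=pd.DataFrame(
            {"age": ages, "group": groups}, index=pd.Index(sample_ids, name="sample_id")
        )
    )
    return expr, meta, db, _bulk_truth(cfg, db)


def simulate_age_covariate(
    act: ActivityMatrix,
    pair,
    target_r: float,
    seed: int,
    tolerance: float = 0.1,
    max_tries: int = 10,
) -> pd.Series:
    """A continuous age-surrogate covariate correlated with a pair's signal.

    The covariate is an affine transform of the pair's per-sample activity
    difference plus Gaussian noise scaled so the realized Pearson r matches
    ``target_r``; for n >= 100 the draw is checked against +/- ``tolerance``
    and resampled up to ``max_tries`` times.
    """
    if abs(target_r) > 1:
        raise ValueError(f"|target_r| must be <= 1, got {target_r}")
    a, b = pair if isinstance(pair, tuple) else pair.split("|")
    signal = act.pair_signal(a, b).to_numpy(dtype=float)
    if np.ptp(signal) == 0:
        raise ValueError("pair signal has zero variance")
    n = len(signal)
    index = act.scores.columns
    z = (signal - signal.mean()) / signal.std()
    rng = np.random.default_rng(seed)
    if abs(target_r) == 1.0:
        return pd.Series(60.0 + 10.0 * np.sign(target_r) * z, index=index, name="covariate")
    sign = np.sign(target_r) if target_r != 0 else 0.0
    noise_sd = np.sqrt(1.0 / target_r**2 - 1.0) if target_r != 0 else 1.0
    for _ in range(max_tries):
        raw = sign * z + rng.normal(0.0, noise_sd, size=n)
        realized = stats.pearsonr(z, raw)[0]
        if n < 100 or abs(realized - target_r) <= tolerance:
            return pd.Series(60.0 + 10.0 * raw, index=index, name="covariate")
    raise RuntimeError(
        f"could not hit target r={target_r} within +/-{tolerance} in {max_tries} draws"
    )


# constructed one-rule QC violators: (umi, distinct genes, mito fraction)
_VIOLATOR_RECIPES = {
    "umi_low": (80, 60, 0.0),
    "umi_high": (28_000, 4_200, 0.0),
    "genes_high": (12_000, 6_000, 0.0),
    "mito_high": (2_000, 1_200, 0.25),
    "ratio_low": (5_000, 200, 0.0),
}


@dataclass(frozen=True)
class ScSimConfig:
    """Configuration for a synthetic single-cell UMI cohort.

    ``cell_type_frequencies`` maps cell type -> {group -> frequency}; the
    frequencies of each group must sum to 1 over cell types.
    ``qc_violation_fraction`` maps QC rule name -> fraction of cells rebuilt
    to violate exactly that rule.
    """

    cell_type_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"T_cell": {"young": 0.5, "old": 0.5},
                                 "macrophage": {"young": 0.5, "old": 0.5}}
    )
    cells_per_group: int = 1000
    nb_mean: dict[str, float] | float = 3000.0
    nb_dispersion: dict[str, float] | float = 0.3
    qc_violation_fraction: dict[str, float] = field(default_factory=dict)
    n_genes: int = 8000
    n_mito_genes: int = 10
    profile_size: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_group < 1:
            raise ValueError("cells_per_group must be positive")
        groups = self.groups
        if not groups:
            raise ValueError("no groups defined")
        for g in groups:
            tot = sum(freqs.get(g, 0.0) for freqs in self.cell_type_frequencies.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies for group {g!r} sum to {tot}, expected 1")
        for rule, frac in self.qc_violation_fraction.items():
            if rule not in _VIOLATOR_RECIPES:
                raise ValueError(f"unknown QC rule {rule!r}")
            if not 0 <= frac < 1:
                raise ValueError(f"violation fraction for {rule!r} out of [0, 1)")
        if sum(self.qc_violation_fraction.values()) > 0.5:
            raise ValueError("total violation fraction above 0.5")
        if self.qc_violation_fraction.get("genes_high", 0) > 0 and self.n_genes < 6500:
            raise ValueError("genes_high violators need n_genes >= 6500")
        if self.n_genes < self.profile_size:
            raise ValueError("n_genes must be >= profile_size")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for freqs in self.cell_type_frequencies.values():
            for g in freqs:
                seen.setdefault(g)
        return list(seen)

    def _per_type(self, value, cell_type: str) -> float:
        return value[cell_type] if isinstance(value, dict) else float(value)


def _build_violator(rng, rule: str, n_genes: int, n_mito: int) -> np.ndarray:
    """Counts for a cell breaking exactly one QC rule with a wide margin."""
    umi, n_distinct, mito_frac = _VIOLATOR_RECIPES[rule]
    counts = np.zeros(n_genes, dtype=np.int64)
    mito_umi = int(round(umi * mito_frac))
    body_umi = umi - mito_umi
    n_body = n_distinct - (n_mito if mito_umi else 0)
    body_genes = rng.choice(np.arange(n_mito, n_genes), size=n_body, replace=False)
    base, extra = divmod(body_umi, n_body)
    counts[body_genes] = base
    counts[body_genes[:extra]] += 1
    if mito_umi:
        per_mito, extra = divmod(mito_umi, n_mito)
        counts[:n_mito] = per_mito
        counts[:extra] += 1
    return counts


def simulate_sc_cohort(
    cfg: ScSimConfig,
) -> tuple[sparse.csr_matrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a sparse gene-by-cell UMI matrix with planted QC violators.

    Per-cell library sizes are negative-binomial (gamma-Poisson) per cell
    type, clipped to [300, 12000] so clean cells pass every QC rule; reads
    are spread over a type-specific expression profile (Dirichlet weights on
    a subset of genes, mitochondrial genes held near 2% of mass). Designated
    violator cells are rebuilt to break exactly one named rule each.
    Returns (counts, cell label table, truth table with violated_rule).
    """
    rng = np.random.default_rng(cfg.seed)
    n_mito = cfg.n_mito_genes
    gene_ids = [f"MT-{i + 1}" for i in range(n_mito)] + [
        f"G{i + 1:05d}" for i in range(cfg.n_genes - n_mito)
    ]

    profiles = {}
    for ct in cfg.cell_type_frequencies:
        body = rng.choice(
            np.arange(n_mito, cfg.n_genes), size=cfg.profile_size - n_mito, replace=False
        )
        weights = rng.gamma(2.0, 1.0, size=cfg.profile_size - n_mito)
        weights = 0.98 * weights / weights.sum()
        idx = np.concatenate([np.arange(n_mito), body])
        p = np.concatenate([np.full(n_mito, 0.02 / n_mito), weights])
        profiles[ct] = (idx, p / p.sum())

    cells = []  # (cell_id, type, group)
    for group in cfg.groups:
        alloc = {}
        types = list(cfg.cell_type_frequencies)
        for ct in types:
            alloc[ct] = int(round(cfg.cell_type_frequencies[ct].get(group, 0.0) * cfg.cells_per_group))
        # fix rounding drift on the most frequent type
        drift = cfg.cells_per_group - sum(alloc.values())
        alloc[max(alloc, key=alloc.get)] += drift
        for ct in types:
            for _ in range(alloc[ct]):
                cells.append((f"C{len(cells) + 1:06d}", ct, group))

    n_cells = len(cells)
    violator_rule = [None] * n_cells
    cursor = 0
    order = rng.permutation(n_cells)
    for rule in sorted(cfg.qc_violation_fraction):
        n_viol = int(round(cfg.qc_violation_fraction[rule] * n_cells))
        for k in range(n_viol):
            violator_rule[order[cursor + k]] = rule
        cursor += n_viol

    cols, rows, vals = [], [], []
    for j, (cell_id, ct, group) in enumerate(cells):
        if violator_rule[j] is not None:
            counts = _build_violator(rng, violator_rule[j], cfg.n_genes, n_mito)
        else:
            mean = cfg._per_type(cfg.nb_mean, ct)
            disp = cfg._per_type(cfg.nb_dispersion, ct)
            lam = rng.gamma(1.0 / disp, mean * disp)
            total = int(np.clip(rng.poisson(lam), 300, 12_000))
            idx, p = profiles[ct]
            counts = np.zeros(cfg.n_genes, dtype=np.int64)
            counts[idx] = rng.multinomial(total, p)
        nz = np.nonzero(counts)[0]
        rows.extend(nz.tolist())
        cols.extend([j] * len(nz))
        vals.extend(counts[nz].tolist())

    counts_mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(cfg.n_genes, n_cells), dtype=np.int64
    )
    labels = pd.DataFrame(
        {
            "cell_id": [c[0] for c in cells],
            "cell_type": [c[1] for c in cells],
            "group": [c[2] for c in cells],
        }
    ).set_index("cell_id")
    truth = labels.copy()
    truth["violated_rule"] = [r if r is not None else "" for r in violator_rule]
    truth.attrs["gene_ids"] = gene_ids
    return counts_mat, labels, truth
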