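"""Cohort enrichment and population-stratified allele-frequency statistics.

* :func:`fisher_exact` — exact carrier-proportion comparison between two
  cohorts (two-sided by the point-probability method by default);
* :func:`chi2_proportions` — Pearson chi-square (1 df) proportion
  comparison for large case/control tables, continuity correction off by
  default;
* :func:`mean_maf_by_population` — per-population mean MAF of rare,
  damaging missense variants, with one-way ANOVA across groups and
  Bonferroni-adjusted pairwise Welch comparisons;
* :func:`bonferroni` — multiple-testing correction, min(1, m*p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "EnrichmentResult",
    "PopulationComparison",
    "fisher_exact",
    "chi2_proportions",
    "mean_maf_by_population",
    "bonferroni",
]


@dataclass
class TwoByTwo:
    """Carrier counts for two cohorts: (k1 of n1) vs (k2 of n2)."""

    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self) -> None:
        for k, n, grp in ((self.k1, self.n1, "1"), (self.k2, self.n2, "2")):
            if not 0 <= k <= n:
                raise ValueError(f"group {grp}: require 0 <= k <= n, got {k}/{n}")

    def table(self) -> np.ndarray:
        return np.array(
            [[self.k1, self.n1 - self.k1], [self.k2, self.n2 - self.k2]], dtype=np.int64
        )


@dataclass
class EnrichmentResult:
    test: str
    inputs: dict
    statistic: Optional[float]
    p_value: float
    p_adjusted: Optional[float] = None
    correction: Optional[str] = None
    warnings: list = field(default_factory=list)


def fisher_exact(table: TwoByTwo, alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher's exact test on a carrier 2x2 table.

    Two-sided p-value by the point-probability method: the sum of
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one.
    """
    odds, p = stats.fisher_exact(table.table(), alternative=alternative)
    return EnrichmentResult(
        test="fisher_exact",
        inputs={"k1": table.k1, "n1": table.n1, "k2": table.k2, "n2": table.n2,
                "alternative": alternative},
        statistic=float(odds) if np.isfinite(odds) else None,
        p_value=float(p),
    )


def chi2_proportions(table: TwoByTwo, correction: bool = False) -> EnrichmentResult:
    """Pearson chi-square (1 df) comparison of two proportions.

    Continuity correction is off by default, making the statistic equal the
    squared pooled two-proportion z statistic.  A warning is attached when
    any expected cell count is < 5; a zero margin (no carriers at all, or
    all carriers) is an error because the statistic is undefined.
    """
    t = table.table()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(t, correction=correction)
    warnings = []
    if (res.expected_freq < 5).any():
        warnings.append("expected_count_below_5")
    return EnrichmentResult(
        test="chi2_proportions",
        inputs={"k1": table.k1, "n1": table.n1, "k2": table.k2, "n2": table.n2,
                "continuity_correction": correction},
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        warnings=warnings,
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p) elementwise.

    ``m`` defaults to the number of p-values and must not be smaller.
    """
    p = np.asarray(list(p_values), dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


@dataclass
class PopulationComparison:
    """Population-stratified mean-MAF comparison of rare damaging variants."""

    means: dict
    counts: dict
    anova: EnrichmentResult
    pairwise: pd.DataFrame
    excluded: list = field(default_factory=list)


def mean_maf_by_population(
    variants: pd.DataFrame,
    populations: Optional[Sequence[str]] = None,
    maf_threshold: float = 0.01,
    cadd_threshold: float = 12.0,
) -> PopulationComparison:
    """Compare mean MAFs of rare, damaging missense variants across populations.

    ``variants`` needs a ``maf_<POP>`` column per population plus ``cadd``
    and ``consequence`` columns.  Input filter: missense consequence, CADD
    strictly > 12, and rare in every population (max MAF < threshold).
    Populations contributing fewer than 2 variants are excluded with a
    warning entry.  Returns per-population means, one-way ANOVA across the
    retained groups, and all pairwise Welch two-sample comparisons with
    Bonferroni adjustment over the number of pairs.
    """
    if populations is None:
        populations = [c[4:] for c in variants.columns if c.startswith("maf_")]
    maf_cols = [f"maf_{p}" for p in populations]
    missing = [c for c in maf_cols if c not in variants.columns]
    if missing:
        raise KeyError(f"missing MAF columns: {missing}")
    mask = (
        (variants["consequence"] == "missense")
        & (variants["cadd"] > cadd_threshold)
        & (variants[maf_cols].max(axis=1) < maf_threshold)
    )
    kept = variants.loc[mask]
    groups, means, counts, excluded = {}, {}, {}, []
    for pop in populations:
        vals = kept[f"maf_{pop}"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            excluded.append(pop)
            continue
        groups[pop] = vals
        means[pop] = float(vals.mean())
        counts[pop] = int(vals.size)
    if len(groups) < 2:
        raise ValueError("need at least 2 populations with >= 2 variants each")
    f_stat, anova_p = stats.f_oneway(*groups.values())
    anova = EnrichmentResult(
        test="anova_oneway",
        inputs={"populations": list(groups), "n_variants": counts},
        statistic=float(f_stat),
        p_value=float(anova_p),
    )
    pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"pop_a": a, "pop_b": b, "t": float(t), "p_value": float(p)})
    pairwise = pd.DataFrame(rows, columns=["pop_a", "pop_b", "t", "p_value"])
    if len(pairwise):
        pairwise["p_adjusted"] = bonferroni(pairwise["p_value"], m=len(pairs))
    return PopulationComparison(
        means=means, counts=counts, anova=anova, pairwise=pairwise, excluded=excluded
    )
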