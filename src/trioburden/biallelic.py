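"""Closed-form probability of biallelic inheritance of rare variation.

Given the frequencies ``f_1 ... f_n`` of the rare (MAF < 0.01) variants of
a gene in one population, the model computes, under Hardy-Weinberg
equilibrium in an outbred population::

    A = (1 - f_1) * ... * (1 - f_n)    # no rare variant on one haplotype
    B = A * (1 - A)                    # carrier-haplotype term
    P = 0.25 * B**2                    # biallelic (in-trans) offspring

``A`` is evaluated in log space for numerical stability at large n.  The
formulas are applied exactly as written; note that ``B`` is *not* the
standard heterozygote-carrier probability ``2A(1-A)``.  A Monte-Carlo
simulation of the described mating scheme (two parents, each heterozygous
for at least one rare variant, both transmitting a carrier haplotype to one
offspring) is provided as an independent check, and any systematic
discrepancy between the two is surfaced as a diagnostic ratio rather than
reconciled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PopulationFrequencySet",
    "BiallelicProbabilityResult",
    "MonteCarloResult",
    "BinomialComparison",
    "biallelic_probability",
    "monte_carlo_mating",
    "expected_vs_observed",
]


@dataclass
class PopulationFrequencySet:
    """Rare-variant MAFs of one gene in one population group."""

    gene: str
    population: str
    frequencies: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.frequencies:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency outside [0, 1]: {f}")


@dataclass
class BiallelicProbabilityResult:
    """The symbols A, B, P of the inheritance model for one gene x population."""

    A: float
    B: float
    P: float
    n_variants: int


@dataclass
class MonteCarloResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_sim: int
    n_events: int


@dataclass
class BinomialComparison:
    """Observed k/n qualifying probands vs a model probability P."""

    k: int
    n: int
    P: float
    p_value: float
    alternative: str
    degenerate: bool = False


def _frequencies(freqs) -> np.ndarray:
    if isinstance(freqs, PopulationFrequencySet):
        freqs = freqs.frequencies
    arr = np.asarray(list(freqs), dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("all frequencies must lie in [0, 1]")
    return arr


def biallelic_probability(freqs) -> BiallelicProbabilityResult:
    """Evaluate A, B, P from a frequency list (or PopulationFrequencySet).

    An empty list gives (A=1, B=0, P=0): with no rare variants no biallelic
    genotype can be inherited.  Any frequency of exactly 1 collapses A to 0.
    """
    f = _frequencies(freqs)
    if f.size == 0:
        return BiallelicProbabilityResult(1.0, 0.0, 0.0, 0)
    if np.any(f >= 1.0):
        A, one_minus_A = 0.0, 1.0
    else:
        # expm1 keeps full relative precision in 1-A when A is close to 1
        log_A = float(np.log1p(-f).sum())
        A = math.exp(log_A)
        one_minus_A = -math.expm1(log_A)
    B = A * one_minus_A
    P = 0.25 * B * B
    return BiallelicProbabilityResult(A, B, P, int(f.size))


def monte_carlo_mating(
    freqs,
    n_sim: int,
    seed,
    carrier_mode: str = "exact_het",
    chunk_size: int = 250_000,
) -> MonteCarloResult:
    """Simulate the mating scheme behind the closed-form model.

    Per replicate, each of two parents receives two haplotypes; haplotype h
    carries variant i independently with probability ``f_i`` (HWE, outbred
    population, no linkage).  The counted event is: each parent is a
    heterozygous carrier AND the offspring, receiving one uniformly chosen
    haplotype per parent, receives a carrier haplotype from each.

    ``carrier_mode`` pins the reading of "heterozygous for at least one rare
    variant": ``"exact_het"`` (default, strictest) requires exactly one of
    the parent's two haplotypes to be a carrier haplotype; ``"any"`` only
    requires at least one carrier haplotype.

    Returns the point estimate with a Clopper-Pearson 95% CI; a fixed seed
    gives reproducible estimates.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if carrier_mode not in ("exact_het", "any"):
        raise ValueError(f"unknown carrier_mode: {carrier_mode!r}")
    f = _frequencies(freqs)
    if f.size == 0:
        return MonteCarloResult(0.0, 0.0, 0.0, n_sim, 0)
    rng = np.random.default_rng(seed)
    n_events = 0
    remaining = n_sim
    while remaining > 0:
        m = min(chunk_size, remaining)
        remaining -= m
        # haplotypes: (replicates, 4 parental haplotypes); carrier = >=1 variant
        carrier = np.zeros((m, 4), dtype=bool)
        for fi in f:
            carrier |= rng.random((m, 4)) < fi
        father, mother = carrier[:, :2], carrier[:, 2:]
        if carrier_mode == "exact_het":
            fa_ok = father.sum(axis=1) == 1
            mo_ok = mother.sum(axis=1) == 1
        else:
            fa_ok = father.any(axis=1)
            mo_ok = mother.any(axis=1)
        t_fa = rng.integers(0, 2, size=m)
        t_mo = rng.integers(0, 2, size=m)
        inherited = (
            father[np.arange(m), t_fa] & mother[np.arange(m), t_mo]
        )
        n_events += int((fa_ok & mo_ok & inherited).sum())
    estimate = n_events / n_sim
    lo, hi = _clopper_pearson(n_events, n_sim)
    return MonteCarloResult(estimate, lo, hi, n_sim, n_events)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def expected_vs_observed(
    k: int, n: int, P: float, alternative: str = "greater"
) -> BinomialComparison:
    """Exact binomial test of observed qualifying probands against model P.

    Default is the one-sided upper tail (enrichment direction: is the cohort
    proportion higher than the population expectation?); ``alternative`` may
    be any of scipy's ``greater``/``less``/``two-sided``.  Degenerate model
    probabilities (P=0 or P=1) are handled directly and flagged.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if P == 0.0:
        # any observed carrier is impossible under the model
        p = 1.0 if k == 0 else 0.0
        return BinomialComparison(k, n, P, p, alternative, degenerate=True)
    if P == 1.0:
        p = 1.0 if k == n else (0.0 if alternative != "greater" else 1.0)
        return BinomialComparison(k, n, P, p, alternative, degenerate=True)
    res = stats.binomtest(k, n, P, alternative=alternative)
    return BinomialComparison(k, n, P, float(res.pvalue), alternative)
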