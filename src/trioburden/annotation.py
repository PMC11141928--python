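"""Variant annotation, QC filtering, and pathogenicity-score aggregation.

Each missense/LoF variant carries calls from up to eight functional
predictors (SIFT, LRT, MutationTaster, MutationAssessor, Polyphen2, FATHMM,
Provean — categorical labels — plus a numeric CADD score) and up to four
conservation metrics (GERP, phyloP, SiPhy, phastCons).  Two summary scores
are computed per variant:

* **damage prediction proportion** — the fraction of available predictors
  calling the variant damaging (a qualifying categorical label, or
  CADD > 12);
* **conservation prediction proportion** — the fraction of available
  conservation metrics strictly above their strong-conservation thresholds
  (SiPhy > 12, GERP > 4.4, phyloP > 1.6, phastCons > 0.5).

A variant *qualifies* for the biallelic burden analysis when it is a rare
(max population MAF <= 0.01) missense or LoF change with damage proportion
>= 0.25 and conservation proportion >= 0.5, optionally restricted to a
protein-domain interval and/or a priority gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "PREDICTOR_NAMES",
    "CONSERVATION_NAMES",
    "DEFAULT_DAMAGE_LABELS",
    "AnnotatedVariant",
    "SampleCall",
    "VariantScores",
    "ScoringConfig",
    "QCResult",
    "qc_filter",
    "rarity_filter",
    "damage_proportion",
    "conservation_proportion",
    "score_variant",
    "qualifying_variant",
]

#: The seven categorical functional predictors; CADD (numeric) is the eighth.
PREDICTOR_NAMES = (
    "SIFT",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "Polyphen2",
    "FATHMM",
    "Provean",
)

CONSERVATION_NAMES = ("GERP", "phyloP", "SiPhy", "phastCons")

#: Categorical labels counted as a damaging call (compared after
#: normalisation, see :func:`_normalize_label`).
DEFAULT_DAMAGE_LABELS = frozenset(
    {
        "damaging",
        "possibly damaging",
        "probably damaging",
        "disease causing",
        "deleterious",
        "medium",
    }
)


def _normalize_label(label: str) -> str:
    """Lower-case, trim, and treat ``_``/``-`` as spaces.

    VCF INFO values cannot contain spaces, so labels such as
    ``probably_damaging`` are written with underscores; normalisation makes
    them compare equal to the conventional spelling.
    """
    return label.strip().lower().replace("_", " ").replace("-", " ")


@dataclass
class SampleCall:
    """One sample's genotype call at one site, with QC fields."""

    genotype: int  # 0=hom_ref, 1=het, 2=hom_alt, -1=missing
    depth: Optional[int] = None
    alt_depth: Optional[int] = None


@dataclass
class AnnotatedVariant:
    """A normalized (biallelic) variant with predictor annotations.

    ``predictor_calls`` maps predictor name to a categorical label (string)
    or, for ``CADD``, a numeric score.  Only predictors with a call appear;
    the proportion denominators count available calls.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str  # missense | lof | synonymous | other
    in_domain: bool = False
    predictor_calls: dict = field(default_factory=dict)
    conservation_scores: dict = field(default_factory=dict)
    maf_by_population: dict = field(default_factory=dict)
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for pop, maf in self.maf_by_population.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF for {pop} outside [0, 1]: {maf}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass
class VariantScores:
    """Damage and conservation prediction proportions for one variant.

    A proportion is ``None`` (variant flagged not scoreable) when no
    predictor/metric of that class has a call.
    """

    damage_proportion: Optional[float]
    conservation_proportion: Optional[float]
    n_predictors_available: int
    n_conservation_available: int

    @property
    def scoreable(self) -> bool:
        return (
            self.damage_proportion is not None
            and self.conservation_proportion is not None
        )


@dataclass
class ScoringConfig:
    """All numeric cut-offs of the QC / rarity / scoring stage.

    Defaults follow the analysis protocol: depth strictly > 10x, PASS
    filter, indels retained up to 15 bp, alt-allele fraction strictly
    > 4:10, rarity MAF <= 0.01, CADD damaging if strictly > 12,
    conservation thresholds strict, and qualifying-variant score cut-offs
    damage >= 0.25 and conservation >= 0.5 (non-strict).
    """

    maf_threshold: float = 0.01
    min_depth: int = 10  # strict: DP must exceed this
    min_allelic_ratio: float = 0.4  # strict: alt fraction must exceed this
    max_indel_len: int = 15  # inclusive: indels up to this size retained
    cadd_threshold: float = 12.0
    gerp_threshold: float = 4.4
    phylop_threshold: float = 1.6
    siphy_threshold: float = 12.0
    phastcons_threshold: float = 0.5
    damage_qualifying_labels: frozenset = DEFAULT_DAMAGE_LABELS
    min_damage_proportion: float = 0.25
    min_conservation_proportion: float = 0.5
    rarity_mode: str = "max"  # "max" over populations, or "global"
    global_population_label: str = "GEN"
    domain_filter: bool = True
    domain_interval: Optional[tuple] = None  # protein coords, informational
    priority_gene_list: Optional[frozenset] = None
    qualifying_consequences: frozenset = frozenset({"missense", "lof"})

    def __post_init__(self) -> None:
        if self.domain_interval is not None:
            start, end = self.domain_interval
            if start > end:
                raise ValueError("domain interval start must be <= end")
        if self.rarity_mode not in ("max", "global"):
            raise ValueError(f"unknown rarity_mode: {self.rarity_mode!r}")

    @property
    def _normalized_labels(self) -> frozenset:
        return frozenset(_normalize_label(x) for x in self.damage_qualifying_labels)


@dataclass
class QCResult:
    passed: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.passed


def qc_filter(
    variant: AnnotatedVariant, call: SampleCall, config: ScoringConfig
) -> QCResult:
    """Site/call-level QC: PASS filter, depth > 10x, indel size <= 15 bp,
    alt-allele fraction > 4:10.

    The reason string names the first failing rule; missing depth/AD fields
    fail conservatively with ``missing_qc_fields``.
    """
    if variant.filter_status not in ("PASS", ".", None, ""):
        return QCResult(False, "filter")
    if call.depth is None or call.alt_depth is None:
        return QCResult(False, "missing_qc_fields")
    if call.depth <= config.min_depth:
        return QCResult(False, "depth")
    if variant.is_indel and variant.indel_length > config.max_indel_len:
        return QCResult(False, "indel_size")
    # allelic ratio applies to calls actually carrying the alt allele
    if call.genotype in (1, 2):
        if call.alt_depth / call.depth <= config.min_allelic_ratio:
            return QCResult(False, "allelic_ratio")
    return QCResult(True)


def rarity_filter(variant: AnnotatedVariant, config: ScoringConfig) -> bool:
    """Rare iff MAF <= threshold; a variant with MAF exactly 0.01 is kept
    (only MAF > 0.01 is excluded).

    In ``max`` mode the maximum MAF over all annotated populations must be
    <= the threshold (conservative); in ``global`` mode only the global
    population entry is checked.
    """
    if not variant.maf_by_population:
        raise ValueError(f"{variant.variant_id}: no population MAFs annotated")
    if config.rarity_mode == "global":
        maf = variant.maf_by_population.get(config.global_population_label)
        if maf is None:
            raise KeyError(
                f"{variant.variant_id}: no MAF for global population "
                f"{config.global_population_label!r}"
            )
        return maf <= config.maf_threshold
    return max(variant.maf_by_population.values()) <= config.maf_threshold


def damage_proportion(
    variant: AnnotatedVariant, config: ScoringConfig
) -> tuple[Optional[float], int]:
    """(#predictors calling damaging) / (#predictors with a call).

    CADD qualifies iff its score is strictly > 12; categorical labels are
    compared case-insensitively after trimming.  Returns ``(None, 0)`` when
    no predictor has a call.
    """
    labels = config._normalized_labels
    available = 0
    qualifying = 0
    for name, value in variant.predictor_calls.items():
        if value is None:
            continue
        available += 1
        if name.upper() == "CADD":
            if float(value) > config.cadd_threshold:
                qualifying += 1
        elif _normalize_label(str(value)) in labels:
            qualifying += 1
    if available == 0:
        return None, 0
    return qualifying / available, available


_CONSERVATION_THRESHOLDS = {
    "GERP": "gerp_threshold",
    "PHYLOP": "phylop_threshold",
    "SIPHY": "siphy_threshold",
    "PHASTCONS": "phastcons_threshold",
}


def conservation_proportion(
    variant: AnnotatedVariant, config: ScoringConfig
) -> tuple[Optional[float], int]:
    """(#conservation scores strictly above their thresholds) / (#available)."""
    available = 0
    qualifying = 0
    for name, score in variant.conservation_scores.items():
        if score is None:
            continue
        attr = _CONSERVATION_THRESHOLDS.get(name.upper())
        if attr is None:
            raise KeyError(f"unknown conservation metric: {name!r}")
        available += 1
        if float(score) > getattr(config, attr):
            qualifying += 1
    if available == 0:
        return None, 0
    return qualifying / available, available


def score_variant(variant: AnnotatedVariant, config: ScoringConfig) -> VariantScores:
    """Compute both prediction proportions for one variant."""
    dmg, n_pred = damage_proportion(variant, config)
    cons, n_cons = conservation_proportion(variant, config)
    return VariantScores(dmg, cons, n_pred, n_cons)


def qualifying_variant(
    variant: AnnotatedVariant, scores: VariantScores, config: ScoringConfig
) -> bool:
    """True iff the variant enters the biallelic burden analysis.

    Requires: missense/LoF consequence, rarity, damage proportion >= 0.25
    and conservation proportion >= 0.5 (both non-strict), domain membership
    when domain filtering is enabled, and priority-list membership when a
    list is configured.  Unscoreable variants never qualify.
    """
    if not scores.scoreable:
        return False
    if variant.consequence not in config.qualifying_consequences:
        return False
    if not rarity_filter(variant, config):
        return False
    if scores.damage_proportion < config.min_damage_proportion:
        return False
    if scores.conservation_proportion < config.min_conservation_proportion:
        return False
    if config.domain_filter and not variant.in_domain:
        return False
    if (
        config.priority_gene_list is not None
        and variant.gene not in config.priority_gene_list
    ):
        return False
    return True
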