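"""Trio segregation: compound-het phasing, biallelic and de novo detection.

Genotype codes throughout: ``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1``
missing.  Phasing of a pair of proband-het variants is resolved by parental
origin: the rule asks which parental haplotype configurations are
consistent with all five genotypes.  If only opposite-parent transmission
explains the data the pair is *in trans* (compound heterozygous); if only
same-parent transmission does, *in cis*; if both remain possible, or a
parental genotype is missing, or no Mendelian-consistent configuration
exists, the phase is *ambiguous*.

Detection applies a full-penetrance autosomal-recessive model: an event is
suppressed if any genotyped unaffected relative carries the same biallelic
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "Member",
    "Family",
    "Relative",
    "TrioGenotypes",
    "BiallelicEvent",
    "phase_pair",
    "detect_biallelic",
    "detect_de_novo",
    "cohort_summary",
    "proportion_pct",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

IN_TRANS = "in_trans"
IN_CIS = "in_cis"
AMBIGUOUS = "ambiguous"


@dataclass
class Member:
    sample_id: str
    role: str  # proband | mother | father | sibling | other
    affected: bool


@dataclass
class Family:
    """A pedigree unit with exactly one proband and unique parent roles."""

    family_id: str
    members: list

    def __post_init__(self) -> None:
        roles = [m.role for m in self.members]
        if roles.count("proband") != 1:
            raise ValueError(
                f"family {self.family_id}: expected exactly one proband, "
                f"got {roles.count('proband')}"
            )
        for parent in ("mother", "father"):
            if roles.count(parent) > 1:
                raise ValueError(f"family {self.family_id}: duplicate {parent}")

    @property
    def proband(self) -> Member:
        return next(m for m in self.members if m.role == "proband")


@dataclass
class Relative:
    """A genotyped non-parent relative used for the full-penetrance check."""

    sample_id: str
    affected: bool
    genotypes: dict  # variant_id -> genotype code


@dataclass
class TrioGenotypes:
    """Genotype calls for one trio at a set of variants.

    ``mother``/``father`` are ``None`` when the parent was not sequenced;
    a sequenced parent with a no-call at one site carries ``MISSING`` there.
    """

    family_id: str
    proband: dict
    mother: Optional[dict] = None
    father: Optional[dict] = None
    relatives: list = field(default_factory=list)

    def _parent_gt(self, parent: Optional[dict], variant: str) -> int:
        if parent is None:
            return MISSING
        return parent.get(variant, MISSING)


@dataclass
class BiallelicEvent:
    """A qualifying biallelic (or de novo) genotype in one proband."""

    family_id: str
    gene: str
    variant_a: str
    variant_b: str
    phase: Optional[str]  # in_trans | in_cis | ambiguous | None (de novo)
    model: str  # compound_het | homozygous | de_novo

    def __post_init__(self) -> None:
        if self.model == "compound_het" and self.variant_a == self.variant_b:
            raise ValueError("compound_het requires two distinct variants")
        if self.model == "homozygous" and self.variant_a != self.variant_b:
            raise ValueError("homozygous event must reference one variant")


def _can_transmit_x_not_y(gx: int, gy: int) -> bool:
    """Can a parent with genotypes (gx, gy) transmit a haplotype carrying
    variant x but not y?  Requires at least one x allele and at most one y
    allele (a hom-alt y forces y onto every transmitted haplotype)."""
    return gx >= HET and gy <= HET


def phase_pair(trio: TrioGenotypes, variant_a: str, variant_b: str) -> str:
    """Classify a pair of proband-het variants as in_trans/in_cis/ambiguous.

    A configuration of parental haplotypes is *trans-consistent* when one
    parent can transmit a haplotype carrying only variant_a while the other
    transmits one carrying only variant_b, and *cis-consistent* when one
    parent can transmit both variants on one haplotype while the other
    transmits neither.  Exactly one kind of consistent configuration gives
    that phase; both kinds (origin unresolvable), none (the genotypes are
    not Mendelian-consistent, e.g. an apparent de novo), or a missing
    parental genotype give ambiguous.  A hom-alt parent forces transmission
    of its allele, which this rule accounts for; the classification agrees
    with exhaustive enumeration of parental haplotype assignments.

    Precondition: the proband is het at both variants (raises otherwise).
    Symmetric in its variant arguments.
    """
    for v in (variant_a, variant_b):
        if trio.proband.get(v, MISSING) != HET:
            raise ValueError(
                f"phase_pair precondition violated: proband of "
                f"{trio.family_id} is not het at {v}"
            )
    fa_a = trio._parent_gt(trio.father, variant_a)
    fa_b = trio._parent_gt(trio.father, variant_b)
    mo_a = trio._parent_gt(trio.mother, variant_a)
    mo_b = trio._parent_gt(trio.mother, variant_b)
    if MISSING in (fa_a, fa_b, mo_a, mo_b):
        return AMBIGUOUS
    trans = (
        _can_transmit_x_not_y(fa_a, fa_b) and _can_transmit_x_not_y(mo_b, mo_a)
    ) or (
        _can_transmit_x_not_y(fa_b, fa_a) and _can_transmit_x_not_y(mo_a, mo_b)
    )
    # "both": a haplotype carrying a and b; "neither": one carrying neither
    cis = (
        fa_a >= HET and fa_b >= HET and mo_a <= HET and mo_b <= HET
    ) or (
        mo_a >= HET and mo_b >= HET and fa_a <= HET and fa_b <= HET
    )
    if trans and not cis:
        return IN_TRANS
    if cis and not trans:
        return IN_CIS
    return AMBIGUOUS


def _relative_carries_pair(rel: Relative, variant_a: str, variant_b: str) -> Optional[bool]:
    """Does a relative carry both variants of an in-trans pair?

    For a sibling sharing the parents that determined the pair's origins,
    carrying both variants implies carrying them in trans.  Returns ``None``
    when either genotype is missing (check skipped for that relative).
    """
    ga = rel.genotypes.get(variant_a, MISSING)
    gb = rel.genotypes.get(variant_b, MISSING)
    if ga == MISSING or gb == MISSING:
        return None
    return ga in (HET, HOM_ALT) and gb in (HET, HOM_ALT)


def detect_biallelic(
    trio: TrioGenotypes,
    qualifying_by_gene: Mapping[str, Sequence[str]],
) -> list:
    """Emit biallelic events for one trio over pre-filtered qualifying variants.

    Per gene: every unordered pair of proband-het variants phased in trans
    (compound het), plus every proband hom-alt genotype with both parents
    het (AR homozygous).  Under full penetrance an event is suppressed when
    a genotyped unaffected relative carries the same combination; a relative
    with a missing genotype skips the check (logged).
    """
    events: list = []
    unaffected = [r for r in trio.relatives if not r.affected]
    for gene, variants in qualifying_by_gene.items():
        hets = [v for v in variants if trio.proband.get(v, MISSING) == HET]
        for va, vb in combinations(hets, 2):
            if phase_pair(trio, va, vb) != IN_TRANS:
                continue
            suppressed = False
            for rel in unaffected:
                carries = _relative_carries_pair(rel, va, vb)
                if carries is None:
                    logger.info(
                        "family %s: relative %s missing genotype at %s/%s; "
                        "penetrance check skipped",
                        trio.family_id, rel.sample_id, va, vb,
                    )
                elif carries:
                    suppressed = True
                    break
            if not suppressed:
                events.append(
                    BiallelicEvent(trio.family_id, gene, va, vb, IN_TRANS, "compound_het")
                )
        for v in variants:
            if trio.proband.get(v, MISSING) != HOM_ALT:
                continue
            if (
                trio._parent_gt(trio.father, v) != HET
                or trio._parent_gt(trio.mother, v) != HET
            ):
                continue
            suppressed = False
            for rel in unaffected:
                g = rel.genotypes.get(v, MISSING)
                if g == MISSING:
                    logger.info(
                        "family %s: relative %s missing genotype at %s; "
                        "penetrance check skipped",
                        trio.family_id, rel.sample_id, v,
                    )
                elif g == HOM_ALT:
                    suppressed = True
                    break
            if not suppressed:
                events.append(
                    BiallelicEvent(trio.family_id, gene, v, v, IN_TRANS, "homozygous")
                )
    return events


def detect_de_novo(
    trio: TrioGenotypes,
    qualifying_variants: Mapping[str, str],
) -> list:
    """De novo calls: proband het/hom-alt while both parents are hom-ref.

    ``qualifying_variants`` maps variant id -> gene.  A variant is ineligible
    when either parent is unsequenced or has a missing genotype there.
    """
    events = []
    for v, gene in qualifying_variants.items():
        if trio.proband.get(v, MISSING) not in (HET, HOM_ALT):
            continue
        if trio._parent_gt(trio.father, v) != HOM_REF:
            continue
        if trio._parent_gt(trio.mother, v) != HOM_REF:
            continue
        events.append(BiallelicEvent(trio.family_id, gene, v, v, None, "de_novo"))
    return events


def proportion_pct(k: int, n: int) -> float:
    """100*k/n rounded half-up to one decimal (as printed in cohort tables)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(
        (Decimal(100 * k) / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def cohort_summary(events: Iterable[BiallelicEvent], families: Sequence) -> pd.DataFrame:
    """Per-gene count of probands carrying a confirmed biallelic genotype.

    A proband counts once per gene if it has at least one in-trans compound
    het or AR-homozygous event there (de novo and unphased events are not
    counted).  Returns a frame with columns ``gene, k, n, pct`` where
    ``pct = 100*k/n`` rounded to one decimal, sorted by descending k.
    """
    n = len(families)
    if n == 0:
        raise ValueError("cohort has no families")
    carriers: dict = {}
    for ev in events:
        if ev.model not in ("compound_het", "homozygous"):
            continue
        if ev.phase != IN_TRANS:
            continue
        carriers.setdefault(ev.gene, set()).add(ev.family_id)
    rows = [
        {"gene": gene, "k": len(fams), "n": n, "pct": proportion_pct(len(fams), n)}
        for gene, fams in carriers.items()
    ]
    frame = pd.DataFrame(rows, columns=["gene", "k", "n", "pct"])
    return frame.sort_values(["k", "gene"], ascending=[False, True]).reset_index(drop=True)
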