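"""Segregation logic: phasing by parental origin, detection, summaries."""

from itertools import product

import pandas as pd
import pytest

from trioburden.segregation import (
    AMBIGUOUS,
    HET,
    HOM_ALT,
    HOM_REF,
    IN_CIS,
    IN_TRANS,
    MISSING,
    BiallelicEvent,
    Family,
    Member,
    Relative,
    TrioGenotypes,
    cohort_summary,
    detect_biallelic,
    detect_de_novo,
    phase_pair,
    proportion_pct,
)

VA, VB = "1:100:A:G", "1:200:C:T"


def trio(fa_a, fa_b, mo_a, mo_b, pb_a=HET, pb_b=HET, relatives=()):
    return TrioGenotypes(
        family_id="F1",
        proband={VA: pb_a, VB: pb_b},
        father={VA: fa_a, VB: fa_b},
        mother={VA: mo_a, VB: mo_b},
        relatives=list(relatives),
    )


def phase_oracle(fa_a, fa_b, mo_a, mo_b):
    """Brute force: enumerate parental haplotype pairs and transmissions.

    Collects the phase of every haplotype assignment consistent with all
    five genotypes (proband het at both); a unique outcome gives that
    phase, anything else (no or mixed outcomes, or a missing parental
    genotype) is ambiguous.
    """
    if MISSING in (fa_a, fa_b, mo_a, mo_b):
        return AMBIGUOUS

    def hap_pairs(g_a, g_b):
        pairs = []
        for x1, x2 in ((0, 0), (0, 1), (1, 0), (1, 1)):
            for y1, y2 in ((0, 0), (0, 1), (1, 0), (1, 1)):
                if x1 + x2 == g_a and y1 + y2 == g_b:
                    pairs.append(((x1, y1), (x2, y2)))
        return pairs

    outcomes = set()
    for father in hap_pairs(fa_a, fa_b):
        for mother in hap_pairs(mo_a, mo_b):
            for tf, tm in product(range(2), range(2)):
                hf, hm = father[tf], mother[tm]
                if hf[0] + hm[0] != 1 or hf[1] + hm[1] != 1:
                    continue  # inconsistent with proband het/het
                carries_both = hf[0] and hf[1] or hm[0] and hm[1]
                outcomes.add(IN_CIS if carries_both else IN_TRANS)
    if len(outcomes) == 1:
        return outcomes.pop()
    return AMBIGUOUS


class TestPhasePair:
    @pytest.mark.parametrize(
        "fa,mo,expected",
        [
            ((HET, HOM_REF), (HOM_REF, HET), IN_TRANS),  # classic comp-het
            ((HET, HET), (HOM_REF, HOM_REF), IN_CIS),  # both paternal
            ((HET, HOM_REF), (HET, HET), AMBIGUOUS),  # both parents carry va
            ((HOM_ALT, HOM_REF), (HOM_REF, HET), IN_TRANS),  # hom-alt parent
            ((HOM_REF, HOM_REF), (HOM_REF, HET), AMBIGUOUS),  # va de novo
            ((MISSING, HOM_REF), (HOM_REF, HET), AMBIGUOUS),  # missing parent
        ],
    )
    def test_examples(self, fa, mo, expected):
        assert phase_pair(trio(fa[0], fa[1], mo[0], mo[1]), VA, VB) == expected

    def test_matches_haplotype_enumeration_exhaustively(self):
        """Rule-based phase equals brute-force haplotype enumeration for all
        81 parental genotype combinations."""
        for fa_a, fa_b, mo_a, mo_b in product((0, 1, 2), repeat=4):
            got = phase_pair(trio(fa_a, fa_b, mo_a, mo_b), VA, VB)
            assert got == phase_oracle(fa_a, fa_b, mo_a, mo_b), (
                fa_a, fa_b, mo_a, mo_b,
            )

    def test_symmetric_in_variant_order(self):
        for fa_a, fa_b, mo_a, mo_b in product((0, 1, 2, MISSING), repeat=4):
            t = trio(fa_a, fa_b, mo_a, mo_b)
            assert phase_pair(t, VA, VB) == phase_pair(t, VB, VA)

    def test_precondition_proband_must_be_het(self):
        with pytest.raises(ValueError):
            phase_pair(trio(HET, HOM_REF, HOM_REF, HET, pb_a=HOM_REF), VA, VB)


QUAL = {"GENE1": [VA, VB]}


class TestDetectBiallelic:
    def test_planted_in_trans_pair_detected(self):
        events = detect_biallelic(trio(HET, HOM_REF, HOM_REF, HET), QUAL)
        assert len(events) == 1
        ev = events[0]
        assert (ev.model, ev.phase) == ("compound_het", IN_TRANS)
        assert {ev.variant_a, ev.variant_b} == {VA, VB}

    def test_cis_pair_not_reported(self):
        assert detect_biallelic(trio(HET, HET, HOM_REF, HOM_REF), QUAL) == []

    def test_full_penetrance_suppression_by_unaffected_sibling(self):
        sib = Relative("S1", affected=False, genotypes={VA: HET, VB: HET})
        t = trio(HET, HOM_REF, HOM_REF, HET, relatives=[sib])
        assert detect_biallelic(t, QUAL) == []

    def test_affected_sibling_does_not_suppress(self):
        sib = Relative("S1", affected=True, genotypes={VA: HET, VB: HET})
        t = trio(HET, HOM_REF, HOM_REF, HET, relatives=[sib])
        assert len(detect_biallelic(t, QUAL)) == 1

    def test_missing_sibling_genotype_skips_check(self):
        sib = Relative("S1", affected=False, genotypes={VA: HET, VB: MISSING})
        t = trio(HET, HOM_REF, HOM_REF, HET, relatives=[sib])
        assert len(detect_biallelic(t, QUAL)) == 1

    def test_homozygous_recessive_detected(self):
        t = trio(HET, HOM_REF, HET, HOM_REF, pb_a=HOM_ALT, pb_b=HOM_REF)
        events = detect_biallelic(t, QUAL)
        assert len(events) == 1
        assert events[0].model == "homozygous"
        assert events[0].variant_a == events[0].variant_b == VA

    def test_homozygous_suppressed_by_unaffected_hom_alt_relative(self):
        sib = Relative("S1", affected=False, genotypes={VA: HOM_ALT})
        t = trio(HET, HOM_REF, HET, HOM_REF, pb_a=HOM_ALT, pb_b=HOM_REF,
                 relatives=[sib])
        assert detect_biallelic(t, QUAL) == []


class TestDetectDeNovo:
    def test_de_novo_called_when_parents_hom_ref(self):
        t = trio(HOM_REF, HOM_REF, HOM_REF, HOM_REF, pb_a=HET, pb_b=HOM_REF)
        events = detect_de_novo(t, {VA: "GENE1"})
        assert len(events) == 1 and events[0].model == "de_novo"

    def test_missing_parent_makes_variant_ineligible(self):
        t = TrioGenotypes("F1", proband={VA: HET}, father=None,
                          mother={VA: HOM_REF})
        assert detect_de_novo(t, {VA: "GENE1"}) == []

    def test_carrier_parent_excludes_de_novo(self):
        t = trio(HOM_REF, HOM_REF, HET, HOM_REF, pb_a=HET, pb_b=HOM_REF)
        assert detect_de_novo(t, {VA: "GENE1"}) == []


def make_events(n, gene="GENE1"):
    return [
        BiallelicEvent(f"F{i}", gene, VA, VB, IN_TRANS, "compound_het")
        for i in range(n)
    ]


class TestCohortSummary:
    @pytest.mark.parametrize(
        "k,n,pct", [(3, 16, 18.8), (20, 1700, 1.2), (4, 19, 21.1), (0, 16, 0.0)]
    )
    def test_printed_proportions(self, k, n, pct):
        assert proportion_pct(k, n) == pct

    def test_counts_probands_once_per_gene(self):
        events = make_events(3)
        # second event in the same proband and gene must not double count
        events.append(BiallelicEvent("F0", "GENE1", VB, VA, IN_TRANS, "compound_het"))
        summary = cohort_summary(events, [f"F{i}" for i in range(16)])
        assert summary.loc[0, "k"] == 3
        assert summary.loc[0, "pct"] == 18.8

    def test_de_novo_events_not_counted(self):
        events = [BiallelicEvent("F0", "GENE1", VA, VA, None, "de_novo")]
        summary = cohort_summary(events, ["F0", "F1"])
        assert summary.empty

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            cohort_summary([], [])


class TestFamilyInvariants:
    def test_exactly_one_proband_required(self):
        with pytest.raises(ValueError):
            Family("F1", [Member("a", "mother", False)])

    def test_duplicate_parent_rejected(self):
        with pytest.raises(ValueError):
            Family(
                "F1",
                [
                    Member("p", "proband", True),
                    Member("m1", "mother", False),
                    Member("m2", "mother", False),
                ],
            )

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            BiallelicEvent("F1", "G", VA, VA, IN_TRANS, "compound_het")
        with pytest.raises(ValueError):
            BiallelicEvent("F1", "G", VA, VB, IN_TRANS, "homozygous")
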