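"""Unit and property tests for QC, rarity, and score aggregation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trioburden.annotation import (
    AnnotatedVariant,
    PREDICTOR_NAMES,
    SampleCall,
    ScoringConfig,
    conservation_proportion,
    damage_proportion,
    qc_filter,
    qualifying_variant,
    rarity_filter,
    score_variant,
)

CFG = ScoringConfig()


def make_variant(**kwargs):
    defaults = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        gene="GENE1",
        consequence="missense",
        in_domain=True,
        maf_by_population={"AFR": 0.001, "NFE": 0.001},
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


def full_predictors(n_damaging, cadd=25.0):
    """n_damaging of the 7 categorical predictors damaging, plus CADD."""
    calls = {}
    for i, name in enumerate(PREDICTOR_NAMES):
        calls[name] = "damaging" if i < n_damaging else "benign"
    calls["CADD"] = cadd
    return calls


class TestQCFilter:
    @pytest.mark.parametrize(
        "depth,alt_depth,filter_status,ref,alt,passed,reason",
        [
            (11, 6, "PASS", "A", "G", True, None),  # depth 11, alt frac ~0.55
            (10, 6, "PASS", "A", "G", False, "depth"),  # >10x read strictly
            (100, 40, "PASS", "A", "G", False, "allelic_ratio"),  # 0.40 fails
            (100, 41, "PASS", "A", "G", True, None),  # 0.41 passes
            (50, 25, "q10", "A", "G", False, "filter"),
            (50, 25, "PASS", "A" * 17, "A", False, "indel_size"),  # 16 bp del
            (50, 25, "PASS", "A" * 16, "A", True, None),  # 15 bp retained
        ],
    )
    def test_rules(self, depth, alt_depth, filter_status, ref, alt, passed, reason):
        v = make_variant(ref=ref, alt=alt, filter_status=filter_status)
        res = qc_filter(v, SampleCall(1, depth, alt_depth), CFG)
        assert res.passed is passed
        assert res.reason == reason

    def test_missing_fields_fail_conservatively(self):
        res = qc_filter(make_variant(), SampleCall(1, None, None), CFG)
        assert not res.passed and res.reason == "missing_qc_fields"

    def test_hom_ref_call_skips_allelic_ratio(self):
        res = qc_filter(make_variant(), SampleCall(0, 50, 0), CFG)
        assert res.passed


class TestRarityFilter:
    def test_typical_rare_variant_passes(self):
        v = make_variant(maf_by_population={"AFR": 0.0008, "NFE": 0.0008})
        assert rarity_filter(v, CFG)

    def test_any_population_above_threshold_fails(self):
        v = make_variant(maf_by_population={"AFR": 0.011, "NFE": 0.0001})
        assert not rarity_filter(v, CFG)

    def test_boundary_maf_exactly_threshold_passes(self):
        # only MAF strictly above 0.01 is excluded
        v = make_variant(maf_by_population={"AFR": 0.01, "NFE": 0.01})
        assert rarity_filter(v, CFG)

    def test_global_mode_ignores_subpopulations(self):
        cfg = ScoringConfig(rarity_mode="global")
        v = make_variant(maf_by_population={"GEN": 0.005, "AFR": 0.02})
        assert rarity_filter(v, cfg)

    def test_no_mafs_is_an_error(self):
        with pytest.raises(ValueError):
            rarity_filter(make_variant(maf_by_population={}), CFG)


class TestDamageProportion:
    @pytest.mark.parametrize(
        "n_damaging,cadd,expected",
        [
            (7, 25.0, 1.0),  # all 8 qualify
            (0, 5.0, 0.0),
            (4, 5.0, 0.5),  # 4 of 8 (CADD below threshold)
            (0, 12.0, 0.0),  # CADD exactly 12: strict > 12
        ],
    )
    def test_counts(self, n_damaging, cadd, expected):
        v = make_variant(predictor_calls=full_predictors(n_damaging, cadd))
        prop, n = damage_proportion(v, CFG)
        assert n == 8
        assert prop == pytest.approx(expected)

    def test_missing_predictor_shrinks_denominator(self):
        v = make_variant(predictor_calls={"SIFT": "damaging", "LRT": "benign"})
        prop, n = damage_proportion(v, CFG)
        assert (prop, n) == (0.5, 2)

    def test_label_normalisation(self):
        v = make_variant(
            predictor_calls={"SIFT": " Probably_Damaging ", "LRT": "Disease_causing"}
        )
        prop, _ = damage_proportion(v, CFG)
        assert prop == 1.0

    def test_no_predictors_flagged_unscoreable(self):
        v = make_variant(predictor_calls={})
        assert damage_proportion(v, CFG) == (None, 0)
        assert not score_variant(v, CFG).scoreable


class TestConservationProportion:
    def test_all_strongly_conserved(self):
        v = make_variant(
            conservation_scores={"GERP": 5.0, "phyloP": 2.0, "SiPhy": 13, "phastCons": 0.9}
        )
        assert conservation_proportion(v, CFG) == (1.0, 4)

    def test_thresholds_are_strict(self):
        v = make_variant(
            conservation_scores={"GERP": 4.4, "phyloP": 1.6, "SiPhy": 12, "phastCons": 0.5}
        )
        assert conservation_proportion(v, CFG) == (0.0, 4)

    def test_single_qualifying_metric(self):
        v = make_variant(
            conservation_scores={"GERP": 5.0, "phyloP": 0.0, "SiPhy": 2, "phastCons": 0.1}
        )
        assert conservation_proportion(v, CFG) == (0.25, 4)


class TestQualifyingVariant:
    def qualify(self, v, cfg=CFG):
        return qualifying_variant(v, score_variant(v, cfg), cfg)

    def base_variant(self, **kwargs):
        return make_variant(
            predictor_calls=full_predictors(4, 25.0),
            conservation_scores={"GERP": 5.0, "phyloP": 2.0, "SiPhy": 13, "phastCons": 0.9},
            **kwargs,
        )

    def test_rule_conjunction(self):
        assert self.qualify(self.base_variant())

    def test_score_cutoffs_are_inclusive(self):
        # damage exactly 0.25 (2/8) and conservation exactly 0.5 (2/4)
        v = make_variant(
            predictor_calls=full_predictors(2, 5.0),
            conservation_scores={"GERP": 5.0, "phyloP": 2.0, "SiPhy": 2, "phastCons": 0.1},
        )
        scores = score_variant(v, CFG)
        assert scores.damage_proportion == 0.25
        assert scores.conservation_proportion == 0.5
        assert qualifying_variant(v, scores, CFG)

    def test_synonymous_never_qualifies(self):
        assert not self.qualify(self.base_variant(consequence="synonymous"))

    def test_domain_filter(self):
        v = self.base_variant(in_domain=False)
        assert not self.qualify(v)
        assert self.qualify(v, ScoringConfig(domain_filter=False))

    def test_priority_gene_list(self):
        cfg = ScoringConfig(priority_gene_list=frozenset({"OTHER"}))
        assert not self.qualify(self.base_variant(), cfg)


@given(
    n_qual=st.integers(0, 7),
    n_avail=st.integers(1, 7),
    cadd_high=st.booleans(),
)
def test_damage_proportion_bounds_and_monotonicity(n_qual, n_avail, cadd_high):
    """Proportion stays in [0,1] and never decreases as calls qualify."""
    n_qual = min(n_qual, n_avail)
    calls = {
        name: ("damaging" if i < n_qual else "benign")
        for i, name in enumerate(PREDICTOR_NAMES[:n_avail])
    }
    calls["CADD"] = 30.0 if cadd_high else 1.0
    v = make_variant(predictor_calls=calls)
    prop, n = damage_proportion(v, CFG)
    assert 0.0 <= prop <= 1.0
    assert n == n_avail + 1
    if n_qual < n_avail:  # flip one benign call to damaging: monotone
        calls[PREDICTOR_NAMES[n_qual]] = "deleterious"
        prop2, _ = damage_proportion(make_variant(predictor_calls=calls), CFG)
        assert prop2 >= prop


def test_filter_order_independence(small_cohort, scoring_config):
    """qc/rarity/qualifying applied in any order keep the same variant set."""
    from trioburden.pipeline import annotated_variants

    variants = annotated_variants(small_cohort)

    def survivors(order):
        kept = list(variants)
        for name in order:
            if name == "rarity":
                kept = [v for v in kept if rarity_filter(v, scoring_config)]
            elif name == "qualifying":
                kept = [
                    v
                    for v in kept
                    if qualifying_variant(v, score_variant(v, scoring_config), scoring_config)
                ]
            elif name == "qc":
                kept = [
                    v
                    for v in kept
                    if qc_filter(v, SampleCall(1, 50, 25), scoring_config).passed
                ]
        return {v.variant_id for v in kept}

    orders = [
        ("qc", "rarity", "qualifying"),
        ("qualifying", "qc", "rarity"),
        ("rarity", "qualifying", "qc"),
    ]
    results = [survivors(o) for o in orders]
    assert results[0] == results[1] == results[2]
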