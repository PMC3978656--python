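"""The 14-rank evidence decision table, aggregation and partitioning."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from oracles import evidence_rank_oracle
from pgxkit.evidence import (
    aggregate_variant_score,
    assign_evidence_code,
    partition_variants,
    relevance_tier,
    resolve_consistency,
)
from pgxkit.model import (
    DrugTarget,
    EvidenceCode,
    EvidenceRecord,
    Finding,
    MutationType,
    RelevanceTier,
    StudyCategory,
)


def make_record(category, target, finding, qualifier=None, private=False, n=None):
    return EvidenceRecord(
        subject="v", drug="d", study_category=category, drug_target=target,
        finding=finding, qualifier=qualifier, is_private=private, sample_size=n,
    )


@pytest.mark.parametrize(
    "category, target, finding, qualifier, expected_rank",
    [
        # direct consistent evidence by study category
        (StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST, Finding.CONSISTENT_EFFECT, None, 1),
        (StudyCategory.PK_PD, DrugTarget.DRUG_OF_INTEREST, Finding.CONSISTENT_EFFECT, None, 2),
        (StudyCategory.MOLECULAR_CELLULAR, DrugTarget.DRUG_OF_INTEREST, Finding.CONSISTENT_EFFECT, None, 3),
        # probe drug with/without mutation-type analysis
        (StudyCategory.MOLECULAR_CELLULAR, DrugTarget.PROBE_DRUG, Finding.CONSISTENT_EFFECT, MutationType.N, 4),
        (StudyCategory.MOLECULAR_CELLULAR, DrugTarget.PROBE_DRUG, Finding.CONSISTENT_EFFECT, None, 8),
        # other drug with/without mutation-type analysis
        (StudyCategory.CLINICAL_OUTCOMES, DrugTarget.OTHER_DRUG, Finding.CONSISTENT_EFFECT, MutationType.AD, 5),
        (StudyCategory.PK_PD, DrugTarget.OTHER_DRUG, Finding.CONSISTENT_EFFECT, MutationType.DP, 6),
        (StudyCategory.MOLECULAR_CELLULAR, DrugTarget.OTHER_DRUG, Finding.CONSISTENT_EFFECT, MutationType.SE, 7),
        (StudyCategory.CLINICAL_OUTCOMES, DrugTarget.OTHER_DRUG, Finding.CONSISTENT_EFFECT, None, 9),
        # inconclusive rows
        (StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST, Finding.INCONSISTENT, None, 9),
        (StudyCategory.PK_PD, DrugTarget.OTHER_DRUG, Finding.EFFECT_ON_OTHER_ONLY, None, 10),
        # screening / absence of effect
        (StudyCategory.SCREENING, DrugTarget.OTHER_DRUG, Finding.INSUFFICIENT, None, 13),
        (StudyCategory.PK_PD, DrugTarget.DRUG_OF_INTEREST, Finding.NO_EFFECT, None, 14),
        (StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST, Finding.LD_ATTRIBUTED, None, 14),
    ],
)
def test_decision_table_rows(category, target, finding, qualifier, expected_rank):
    code = assign_evidence_code(make_record(category, target, finding, qualifier))
    assert code.rank == expected_rank
    if qualifier is not None and expected_rank in (4, 5, 6, 7):
        assert code.qualifiers == frozenset({qualifier})


def test_private_mutation_ranks_12_regardless_of_category():
    for category in (StudyCategory.CLINICAL_OUTCOMES, StudyCategory.PK_PD, StudyCategory.MOLECULAR_CELLULAR):
        code = assign_evidence_code(
            make_record(category, DrugTarget.DRUG_OF_INTEREST, Finding.CONSISTENT_EFFECT, private=True)
        )
        assert code.rank == 12


def test_decision_table_totality_against_oracle():
    """Every combination of the five input axes maps to exactly one rank,
    agreeing with an independent transcription of the grading grid, and the
    full cross-product realizes all 14 ranks."""
    seen_ranks = set()
    for category, target, finding, qualifier, private in itertools.product(
        StudyCategory, DrugTarget, Finding, (None, MutationType.N), (False, True)
    ):
        code = assign_evidence_code(make_record(category, target, finding, qualifier, private))
        expected = evidence_rank_oracle(
            category.value, target.value, finding.value, qualifier is not None, private
        )
        assert code.rank == expected, (category, target, finding, qualifier, private)
        seen_ranks.add(code.rank)
    assert seen_ranks == set(range(1, 15))


def test_aggregation_takes_minimum_rank():
    codes = [EvidenceCode(13), EvidenceCode(3), EvidenceCode(10)]
    assert aggregate_variant_score(codes).rank == 3
    assert aggregate_variant_score([EvidenceCode(14)]).rank == 14


def test_aggregation_merges_qualifiers_on_ties():
    codes = [
        EvidenceCode(5, frozenset({MutationType.AE})),
        EvidenceCode(5, frozenset({MutationType.DP})),
        EvidenceCode(9),
    ]
    # brute-force expectation over the 3-element set
    best = min(c.rank for c in codes)
    expected_quals = frozenset().union(*(c.qualifiers for c in codes if c.rank == best))
    agg = aggregate_variant_score(codes)
    assert agg.rank == 5 and agg.qualifiers == expected_quals == frozenset({MutationType.AE, MutationType.DP})


def test_aggregation_rejects_empty_input():
    with pytest.raises(ValueError, match="no evidence"):
        aggregate_variant_score([])


@settings(deadline=None, max_examples=200)
@given(
    ranks=st.lists(st.integers(1, 14), min_size=1, max_size=8),
    extra=st.integers(1, 14),
)
def test_aggregation_is_monotone_under_new_evidence(ranks, extra):
    """Adding a record never weakens (raises) the aggregated rank."""

    def code(r):
        return EvidenceCode(r, frozenset({MutationType.N}) if r in (4, 5, 6, 7) else frozenset())

    before = aggregate_variant_score([code(r) for r in ranks]).rank
    after = aggregate_variant_score([code(r) for r in ranks + [extra]]).rank
    assert after <= before


def test_relevance_tiers_are_total_and_monotone():
    expected = (
        [RelevanceTier.CLINICALLY_RELEVANT]
        + [RelevanceTier.POTENTIALLY_RELEVANT] * 6
        + [RelevanceTier.UNKNOWN] * 6
        + [RelevanceTier.UNSUPPORTED]
    )
    order = [
        RelevanceTier.CLINICALLY_RELEVANT,
        RelevanceTier.POTENTIALLY_RELEVANT,
        RelevanceTier.UNKNOWN,
        RelevanceTier.UNSUPPORTED,
    ]
    tiers = []
    for rank in range(1, 15):
        quals = frozenset({MutationType.DP}) if rank in (4, 5, 6, 7) else frozenset()
        tiers.append(relevance_tier(EvidenceCode(rank, quals)))
    assert tiers == expected
    assert [order.index(t) for t in tiers] == sorted(order.index(t) for t in tiers)


def test_weighted_consistency():
    unanimous = [make_record(StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST,
                             Finding.CONSISTENT_EFFECT, n=500)]
    v = resolve_consistency(unanimous)
    assert v.verdict == "consistent" and v.support_fraction == 1.0

    mixed = [
        make_record(StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST,
                    Finding.CONSISTENT_EFFECT, n=100),
        make_record(StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST,
                    Finding.INCONSISTENT, n=900),
    ]
    v = resolve_consistency(mixed)
    assert v.verdict == "inconsistent"
    assert v.support_fraction == pytest.approx(100 / 1000)

    assert resolve_consistency([]).verdict == "no_data"


def test_partition_flags_gaps_and_downgrades_inconsistent_direct_evidence():
    clinical = make_record(StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST,
                           Finding.CONSISTENT_EFFECT, n=200)
    screen = make_record(StudyCategory.SCREENING, DrugTarget.OTHER_DRUG, Finding.INSUFFICIENT)
    contra = make_record(StudyCategory.CLINICAL_OUTCOMES, DrugTarget.DRUG_OF_INTEREST,
                         Finding.INCONSISTENT, n=900)

    result = partition_variants({
        "strong": [clinical],
        "screen_only": [screen],
        "contested": [clinical, contra],
    })
    strong = result.per_variant["strong"]
    assert strong.code.rank == 1
    assert strong.tier is RelevanceTier.CLINICALLY_RELEVANT
    assert not strong.gap_flag

    screened = result.per_variant["screen_only"]
    assert screened.code.rank == 13 and screened.gap_flag

    # weighted verdict is inconsistent (200 vs 900), so the rank-1 code is
    # downgraded to the inconclusive clinical row before aggregation
    contested = result.per_variant["contested"]
    assert contested.code.rank == 9
    assert contested.tier is RelevanceTier.UNKNOWN and contested.gap_flag
    assert result.gaps() == ["contested", "screen_only"]
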