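"""Evidence grading for drug-gene variants on the 14-rank ordinal scale.

A published observation is graded by three axes: study category (clinical
outcomes > PK/PD > molecular/cellular > screening), whether the drug studied
is the drug under review, a probe substrate, or some other drug, and whether
the observed effect is consistent. Mutation-type qualifiers lift indirect
evidence into ranks 4-7 (the mutation type is assumed broad enough to
extrapolate across drugs); without a qualifier such evidence stays at 8-11.
Rank 12 marks private mutations, 13 insufficient (screening-only) data, and
14 demonstrated absence of effect (including effects attributed to linkage
disequilibrium with a functional variant).

Per variant, the final grade is the *best* (lowest-ranked) code over all its
records; grades <= 7 mark a defined effect on drug response, >= 8 flag a gap
in knowledge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    DrugTarget,
    EvidenceCode,
    EvidenceRecord,
    Finding,
    RelevanceTier,
    StudyCategory,
)

__all__ = [
    "assign_evidence_code",
    "aggregate_variant_score",
    "relevance_tier",
    "resolve_consistency",
    "partition_variants",
    "ConsistencyVerdict",
    "VariantAssessment",
    "PartitionResult",
    "DEFAULT_CONSISTENCY_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_CONSISTENCY_THRESHOLD = 0.75

#: Rank offsets by study category for the "direct consistent effect" rows
_DIRECT_RANK = {
    StudyCategory.CLINICAL_OUTCOMES: 1,
    StudyCategory.PK_PD: 2,
    StudyCategory.MOLECULAR_CELLULAR: 3,
}
#: ... for the "other drug with mutation-type analysis" rows
_QUALIFIED_OTHER_RANK = {
    StudyCategory.CLINICAL_OUTCOMES: 5,
    StudyCategory.PK_PD: 6,
    StudyCategory.MOLECULAR_CELLULAR: 7,
}
#: ... for the "inconclusive / other drug only" rows
_UNKNOWN_RANK = {
    StudyCategory.CLINICAL_OUTCOMES: 9,
    StudyCategory.PK_PD: 10,
    StudyCategory.MOLECULAR_CELLULAR: 11,
}


def assign_evidence_code(record: EvidenceRecord) -> EvidenceCode:
    """Grade one evidence record on the 1-14 scale.

    Precedence: demonstrated no-effect/LD attribution (14) > private
    mutation (12) > screening-only (13) > the consistent/inconsistent rows.
    A probe-drug observation outside molecular/cellular studies has no row of
    its own and is treated as an other-drug observation (logged).
    """
    if record.finding is None:  # pragma: no cover - dataclass requires it
        raise ValueError("evidence record without finding")
    if record.finding in (Finding.NO_EFFECT, Finding.LD_ATTRIBUTED):
        return EvidenceCode(14)
    if record.is_private:
        return EvidenceCode(12)
    if record.study_category is StudyCategory.SCREENING or record.finding is Finding.INSUFFICIENT:
        return EvidenceCode(13)

    category = record.study_category
    target = record.drug_target
    if target is DrugTarget.PROBE_DRUG and category is not StudyCategory.MOLECULAR_CELLULAR:
        logger.warning(
            "probe-drug record outside molecular/cellular studies (%s/%s); treating as other drug",
            record.subject,
            record.drug,
        )
        target = DrugTarget.OTHER_DRUG

    if record.finding in (Finding.INCONSISTENT, Finding.EFFECT_ON_OTHER_ONLY):
        return EvidenceCode(_UNKNOWN_RANK[category])

    # finding is consistent_effect from here on
    if target is DrugTarget.DRUG_OF_INTEREST:
        return EvidenceCode(_DIRECT_RANK[category])
    if target is DrugTarget.PROBE_DRUG:
        if record.qualifier is not None:
            return EvidenceCode(4, frozenset({record.qualifier}))
        return EvidenceCode(8)
    # other drug
    if record.qualifier is not None:
        return EvidenceCode(_QUALIFIED_OTHER_RANK[category], frozenset({record.qualifier}))
    return EvidenceCode(_UNKNOWN_RANK[category])


def aggregate_variant_score(codes: Sequence[EvidenceCode]) -> EvidenceCode:
    """Best-evidence aggregation: the code with the minimum rank; ties merge
    their qualifier sets."""
    if not codes:
        raise ValueError("no evidence: cannot aggregate an empty code list")
    best = min(code.rank for code in codes)
    qualifiers = frozenset().union(*(c.qualifiers for c in codes if c.rank == best))
    return EvidenceCode(best, qualifiers)


def relevance_tier(code: EvidenceCode) -> RelevanceTier:
    """Partition a rank into the four clinical-relevance tiers."""
    if code.rank == 1:
        return RelevanceTier.CLINICALLY_RELEVANT
    if 2 <= code.rank <= 7:
        return RelevanceTier.POTENTIALLY_RELEVANT
    if 8 <= code.rank <= 13:
        return RelevanceTier.UNKNOWN
    return RelevanceTier.UNSUPPORTED


@dataclass(frozen=True)
class ConsistencyVerdict:
    verdict: str  # "consistent" | "inconsistent" | "no_data"
    support_fraction: Optional[float] = None


def resolve_consistency(
    records: Iterable[EvidenceRecord],
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> ConsistencyVerdict:
    """Weighted consistency across studies of one subject and drug.

    Each directional record (consistent_effect, inconsistent, no_effect)
    is weighted by its sample size (1 when unreported); the verdict is
    ``consistent`` iff the weighted share of consistent_effect reaches
    ``threshold``. Records with no directional finding carry no weight.
    """
    support = 0.0
    total = 0.0
    for rec in records:
        if rec.finding not in (Finding.CONSISTENT_EFFECT, Finding.INCONSISTENT, Finding.NO_EFFECT):
            continue
        w = float(rec.sample_size or 1)
        total += w
        if rec.finding is Finding.CONSISTENT_EFFECT:
            support += w
    if total == 0:
        return ConsistencyVerdict("no_data")
    fraction = support / total
    return ConsistencyVerdict("consistent" if fraction >= threshold else "inconsistent", fraction)


@dataclass(frozen=True)
class VariantAssessment:
    code: EvidenceCode
    tier: RelevanceTier
    gap_flag: bool
    n_records: int


@dataclass
class PartitionResult:
    per_variant: dict[str, VariantAssessment] = field(default_factory=dict)

    def gaps(self) -> list[str]:
        return sorted(v for v, a in self.per_variant.items() if a.gap_flag)


def partition_variants(
    evidence: Mapping[str, Sequence[EvidenceRecord]],
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> PartitionResult:
    """Score and partition each variant's evidence.

    When the weighted verdict over a variant's drug-of-interest records is
    inconsistent, its direct-evidence codes (ranks 1-3) are downgraded to the
    corresponding inconclusive rows (9-11) before best-evidence aggregation.
    A gap flag marks aggregated ranks >= 8 (missing or insufficient data).
    """
    result = PartitionResult()
    for variant, records in evidence.items():
        if not records:
            raise ValueError(f"no evidence: variant {variant!r} has an empty record list")
        direct = [r for r in records if r.drug_target is DrugTarget.DRUG_OF_INTEREST]
        verdict = resolve_consistency(direct, threshold)
        codes = []
        for rec in records:
            code = assign_evidence_code(rec)
            if verdict.verdict == "inconsistent" and code.rank in (1, 2, 3):
                code = EvidenceCode(code.rank + 8)
            codes.append(code)
        agg = aggregate_variant_score(codes)
        result.per_variant[variant] = VariantAssessment(
            code=agg,
            tier=relevance_tier(agg),
            gap_flag=agg.rank >= 8,
            n_records=len(records),
        )
    return result
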