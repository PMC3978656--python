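"""Synthetic cohorts and fixtures: HWE sampling, genotype decomposition,
and an evidence-record set spanning the whole grading scale.

Cohorts are sampled by two independent allele draws per individual from a
specified allele-frequency set (random mating, no linkage disequilibrium or
admixture), which is exactly the model under which expected diplotype
frequencies are computed. Diplotypes are decomposed back into per-site
unphased genotypes so the caller can be exercised end to end without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    Diplotype,
    DrugTarget,
    EvidenceRecord,
    Finding,
    KnowledgeBase,
    MutationType,
    StudyCategory,
)
from .popfreq import AlleleFrequencySet

__all__ = [
    "CohortSpec",
    "sample_cohort",
    "decompose_to_genotypes",
    "genotype_rows",
    "evidence_fixture_set",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 42


@dataclass(frozen=True)
class CohortSpec:
    gene: str
    freqs: AlleleFrequencySet
    n: int
    seed: int = DEFAULT_SEED
    ancestry: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")


def sample_cohort(kb: KnowledgeBase, spec: CohortSpec) -> list[Diplotype]:
    """Draw ``n`` diplotypes, each from two independent allele draws."""
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.freqs.freqs)
    p = np.array([spec.freqs.freqs[a] for a in names])
    draws = rng.choice(len(names), size=(spec.n, 2), p=p / p.sum())
    return [
        kb.diplotype(spec.gene, names[int(a)], names[int(b)])
        for a, b in draws
    ]


def decompose_to_genotypes(kb: KnowledgeBase, diplotype: Diplotype) -> dict[str, tuple[str, str]]:
    """Per-site unphased genotype implied by a diplotype: the multiset union
    of the two haplotypes' states at every site in the gene's variant panel
    (reference where an allele has no requirement)."""
    gene = diplotype.gene
    panel = kb.variants.get(gene, {})
    out: dict[str, tuple[str, str]] = {}
    doses = diplotype.doses()
    for rsid, var in panel.items():
        states = []
        for name, _copies in doses:
            allele = kb.allele(gene, name)  # raises for undefined alleles
            states.append(allele.defining_variants.get(rsid, var.ref_state))
        if any(s is None for s in states):
            raise ValueError(f"{gene} {rsid}: reference state unparseable")
        out[rsid] = tuple(sorted(states))  # type: ignore[return-value]
    return out


def genotype_rows(kb: KnowledgeBase, diplotype: Diplotype, sample_id: str) -> list[dict]:
    """Genotype-table rows (one per panel site) for one sampled individual,
    including a whole-gene copy_number column for duplication diplotypes."""
    copies = sum(2 if c == "N" else int(c) for _, c in diplotype.doses())
    rows = []
    for rsid, (a, b) in decompose_to_genotypes(kb, diplotype).items():
        rows.append(
            {
                "sample_id": sample_id,
                "gene": diplotype.gene,
                "rsid": rsid,
                "genotype": f"{a}/{b}",
                "copy_number": copies if copies != 2 else "",
            }
        )
    return rows


def evidence_fixture_set(seed: int = DEFAULT_SEED) -> list[EvidenceRecord]:
    """Deterministic evidence records covering every rank 1-14 and every
    mutation-type qualifier for the qualified ranks 4-7 (24 qualified
    records). The seed only perturbs reported sample sizes."""
    rng = np.random.default_rng(seed)

    def n() -> int:
        return int(rng.integers(20, 2000))

    drug = "drugX"
    records: list[EvidenceRecord] = []
    # ranks 1-3: consistent direct evidence by study category
    for cat in (StudyCategory.CLINICAL_OUTCOMES, StudyCategory.PK_PD, StudyCategory.MOLECULAR_CELLULAR):
        records.append(
            EvidenceRecord(
                subject=f"v_direct_{cat.value}", drug=drug, study_category=cat,
                drug_target=DrugTarget.DRUG_OF_INTEREST, finding=Finding.CONSISTENT_EFFECT,
                sample_size=n(),
            )
        )
    # rank 4 (probe drug, molecular) and 5-7 (other drug) x 6 qualifiers
    for qual in MutationType:
        records.append(
            EvidenceRecord(
                subject=f"v_probe_{qual.value}", drug=drug,
                study_category=StudyCategory.MOLECULAR_CELLULAR,
                drug_target=DrugTarget.PROBE_DRUG, finding=Finding.CONSISTENT_EFFECT,
                qualifier=qual, sample_size=n(),
            )
        )
        for cat in (StudyCategory.CLINICAL_OUTCOMES, StudyCategory.PK_PD, StudyCategory.MOLECULAR_CELLULAR):
            records.append(
                EvidenceRecord(
                    subject=f"v_other_{cat.value}_{qual.value}", drug=drug, study_category=cat,
                    drug_target=DrugTarget.OTHER_DRUG, finding=Finding.CONSISTENT_EFFECT,
                    qualifier=qual, sample_size=n(),
                )
            )
    # rank 8: probe drug only, no mutation-type analysis
    records.append(
        EvidenceRecord(
            subject="v_probe_only", drug=drug, study_category=StudyCategory.MOLECULAR_CELLULAR,
            drug_target=DrugTarget.PROBE_DRUG, finding=Finding.CONSISTENT_EFFECT, sample_size=n(),
        )
    )
    # ranks 9-11: inconclusive by study category
    for cat in (StudyCategory.CLINICAL_OUTCOMES, StudyCategory.PK_PD, StudyCategory.MOLECULAR_CELLULAR):
        records.append(
            EvidenceRecord(
                subject=f"v_mixed_{cat.value}", drug=drug, study_category=cat,
                drug_target=DrugTarget.DRUG_OF_INTEREST, finding=Finding.INCONSISTENT,
                sample_size=n(),
            )
        )
    # rank 12: private mutation
    records.append(
        EvidenceRecord(
            subject="v_private", drug=drug, study_category=StudyCategory.CLINICAL_OUTCOMES,
            drug_target=DrugTarget.DRUG_OF_INTEREST, finding=Finding.CONSISTENT_EFFECT,
            is_private=True, sample_size=1,
        )
    )
    # rank 13: screening only
    records.append(
        EvidenceRecord(
            subject="v_screen", drug=drug, study_category=StudyCategory.SCREENING,
            drug_target=DrugTarget.OTHER_DRUG, finding=Finding.INSUFFICIENT,
        )
    )
    # rank 14: demonstrated no effect / LD attribution
    records.append(
        EvidenceRecord(
            subject="v_null", drug=drug, study_category=StudyCategory.CLINICAL_OUTCOMES,
            drug_target=DrugTarget.DRUG_OF_INTEREST, finding=Finding.NO_EFFECT, sample_size=n(),
        )
    )
    records.append(
        EvidenceRecord(
            subject="v_ld", drug=drug, study_category=StudyCategory.PK_PD,
            drug_target=DrugTarget.DRUG_OF_INTEREST, finding=Finding.LD_ATTRIBUTED, sample_size=n(),
        )
    )
    return records
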