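"""Drug-specific genotype-phenotype translation over Punnett squares.

Every unordered pair of a gene's functional alleles is a potential diplotype;
a drug's translation table assigns each one a PK/PD phenotype. Assignment is
resolved in a fixed order: (1) explicit membership in a published category;
(2) membership after substituting rare alleles by their similarity reference
(e.g. CYP2C19*6 interpreted as *2); (3) where the table opts in, the
highest-functioning-allele policy (increased > normal > reduced > none), used
for CYP2D6-style genes where a single functional allele determines the
metabolizer type; (4) unknown. The same diplotype may resolve differently per
drug — CYP2C19*1/*17 is an ultra-rapid metabolizer for clopidogrel but has
unknown metabolizer status for proton pump inhibitors.

An activity-score policy (summing per-allele activity values into binned
phenotypes) is also provided but not enabled for any packaged table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    Diplotype,
    FallbackPolicy,
    FUNCTION_ORDER,
    FunctionClass,
    KnowledgeBase,
    PkpdLabel,
    TranslationTable,
    resolve_similarity,
    split_dose,
)

__all__ = [
    "enumerate_diplotypes",
    "extrapolate_allele",
    "assign_phenotype",
    "build_full_punnett",
    "activity_score",
    "PhenotypeAssignment",
    "PunnettTable",
]


@dataclass(frozen=True)
class PhenotypeAssignment:
    """Resolved phenotype for one diplotype under one drug."""

    diplotype: Diplotype
    drug: str
    pkpd_label: PkpdLabel
    clinical_text: str
    category_id: Optional[str]
    provenance: str  # explicit_lookup | similarity_extrapolated | policy_derived | unknown
    fda_text: Optional[str] = None


@dataclass
class PunnettTable:
    gene: str
    drug: str
    cells: dict[str, PhenotypeAssignment] = field(default_factory=dict)

    def unknown_cells(self) -> list[str]:
        """Diplotypes with no resolvable phenotype — the gaps in knowledge."""
        return sorted(
            name for name, a in self.cells.items() if a.pkpd_label is PkpdLabel.UNKNOWN
        )


def enumerate_diplotypes(
    kb: KnowledgeBase, gene: str, alleles: Optional[Iterable[str]] = None
) -> list[Diplotype]:
    """All n(n+1)/2 unordered allele pairs (with repetition) for a gene."""
    names = sorted(alleles if alleles is not None else kb.gene_alleles(gene))
    if not names:
        raise ValueError(f"no alleles to enumerate for gene {gene!r}")
    seen: dict[str, Diplotype] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            d = kb.diplotype(gene, a, b)
            seen[d.canonical_name] = d
    return sorted(seen.values(), key=lambda d: d.canonical_name)


def extrapolate_allele(kb: KnowledgeBase, gene: str, name: str) -> str:
    """Effective allele name after following similarity links transitively."""
    base, copies = split_dose(name)
    resolved = resolve_similarity(kb, gene, base)
    return name if resolved == base else (resolved if copies == 1 else f"{resolved}x{copies}")


def _best_function(kb: KnowledgeBase, diplotype: Diplotype) -> Optional[FunctionClass]:
    """Highest function class present in the diplotype; whole-gene
    duplications of a functional allele count as increased function."""
    classes = []
    for name, copies in diplotype.doses():
        allele = kb.allele(diplotype.gene, name)
        fc = allele.function_class
        if copies != 1 and fc in (FunctionClass.NORMAL, FunctionClass.INCREASED):
            fc = FunctionClass.INCREASED
        classes.append(fc)
    if any(fc is FunctionClass.UNKNOWN for fc in classes):
        return None
    return min(classes, key=FUNCTION_ORDER.index)


def activity_score(
    kb: KnowledgeBase, diplotype: Diplotype
) -> Optional[float]:
    """Summed activity value over allele doses (duplication multiplies);
    None when any allele lacks an activity value."""
    total = 0.0
    for name, copies in diplotype.doses():
        allele = kb.allele(diplotype.gene, name)
        if allele.activity_value is None:
            return None
        mult = 2 if copies == "N" else int(copies)
        total += allele.activity_value * mult
    return total


def assign_phenotype(
    kb: KnowledgeBase, diplotype: Diplotype, drug: str
) -> PhenotypeAssignment:
    """Resolve the drug-specific phenotype of a diplotype.

    Raises ``KeyError`` when no translation table exists for (drug, gene).
    """
    gene = diplotype.gene
    table = kb.table(drug, gene)

    def from_category(cat, provenance: str) -> PhenotypeAssignment:
        # a category whose PK/PD label is unknown is reported with
        # provenance "unknown" even when explicitly listed
        if cat.pkpd_label is PkpdLabel.UNKNOWN:
            provenance = "unknown"
        return PhenotypeAssignment(
            diplotype=diplotype,
            drug=drug,
            pkpd_label=cat.pkpd_label,
            clinical_text=cat.clinical_text,
            category_id=cat.id,
            provenance=provenance,
            fda_text=cat.fda_text,
        )

    cat = table.category_for_member(diplotype.pair_key)
    if cat is not None:
        return from_category(cat, "explicit_lookup")

    substituted = kb.diplotype(
        gene,
        extrapolate_allele(kb, gene, diplotype.alleles[0]),
        extrapolate_allele(kb, gene, diplotype.alleles[1]),
    )
    if substituted.pair_key != diplotype.pair_key:
        cat = table.category_for_member(substituted.pair_key)
        if cat is not None:
            return from_category(cat, "similarity_extrapolated")

    if table.fallback_policy is FallbackPolicy.HIGHEST_FUNCTION_ALLELE:
        for candidate in (diplotype, substituted):
            fc = _best_function(kb, candidate)
            if fc is None:
                continue
            cat = table.category_for_function(fc)
            if cat is not None:
                return from_category(cat, "policy_derived")

    return PhenotypeAssignment(
        diplotype=diplotype,
        drug=drug,
        pkpd_label=PkpdLabel.UNKNOWN,
        clinical_text="Unknown effect on drug response",
        category_id=None,
        provenance="unknown",
    )


def build_full_punnett(
    kb: KnowledgeBase,
    drug: str,
    gene: str,
    alleles: Optional[Sequence[str]] = None,
) -> PunnettTable:
    """Assign a phenotype to every enumerated diplotype of the gene."""
    table = PunnettTable(gene=gene, drug=drug)
    for d in enumerate_diplotypes(kb, gene, alleles):
        table.cells[d.canonical_name] = assign_phenotype(kb, d, drug)
    return table
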