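"""Expected diplotype and phenotype-category frequencies per ancestry.

Under Hardy-Weinberg equilibrium, allele frequencies p_a imply diplotype
frequencies p_a^2 (homozygotes) and 2 p_a p_b (heterozygotes). Folding those
through a drug's translation table yields expected phenotype-category
percentages. The packaged tables carry the *printed* expected population
frequencies, which may derive from observed cohort counts rather than HWE;
computed-vs-printed comparisons are therefore reported as a reconciliation
table, not asserted equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .model import (
    Ancestry,
    FreqValue,
    KnowledgeBase,
    PkpdLabel,
    TranslationTable,
    freq_as_float,
)
from .translate import assign_phenotype, enumerate_diplotypes

__all__ = [
    "AlleleFrequencySet",
    "hwe_diplotype_frequencies",
    "category_frequencies",
    "lookup_category_frequency",
    "reconcile_with_printed",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Allele frequencies (fractions) for one gene in one ancestry group."""

    gene: str
    ancestry: Optional[Ancestry]
    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError(f"{self.gene}: negative allele frequency")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.gene}: allele frequencies sum to {total!r}, not 1")


def hwe_diplotype_frequencies(
    kb: KnowledgeBase, freqs: AlleleFrequencySet
) -> dict[str, float]:
    """Map canonical diplotype name -> expected fraction under HWE."""
    names = sorted(freqs.freqs)
    out: dict[str, float] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            d = kb.diplotype(freqs.gene, a, b)
            p = freqs.freqs[a] ** 2 if a == b else 2 * freqs.freqs[a] * freqs.freqs[b]
            out[d.canonical_name] = out.get(d.canonical_name, 0.0) + p
    total = sum(out.values())
    assert abs(total - 1.0) <= 1e-9, total
    return out


def category_frequencies(
    kb: KnowledgeBase,
    diplotype_freqs: Mapping[str, float],
    table: TranslationTable,
) -> dict[str, float]:
    """Fold diplotype fractions into per-category percents via phenotype
    assignment; diplotypes that resolve to no category land in an
    ``unknown`` bucket. Mass is conserved exactly."""
    out: dict[str, float] = {}
    for name, fraction in diplotype_freqs.items():
        pair = name.removeprefix(table.gene).strip()
        a, b = pair.split("/")
        assignment = assign_phenotype(kb, kb.diplotype(table.gene, a, b), table.drug)
        key = assignment.category_id if assignment.category_id is not None else "unknown"
        out[key] = out.get(key, 0.0) + 100.0 * fraction
    return out


def lookup_category_frequency(
    kb: KnowledgeBase,
    drug: str,
    gene: str,
    category: str,
    ancestry: Union[Ancestry, str],
) -> FreqValue:
    """Exact printed expected-population frequency (percent, or an upper
    bound for '<x' entries) for a category, addressed by category id or
    PK/PD label."""
    table = kb.table(drug, gene)
    cat = table.category_by_label(category)
    if cat is None:
        raise KeyError(f"{drug}/{gene}: no category {category!r}")
    anc = Ancestry(ancestry)
    if anc not in cat.expected_freqs:
        raise KeyError(f"{drug}/{gene} category {cat.id}: no frequency for {anc.value}")
    return cat.expected_freqs[anc]


def reconcile_with_printed(
    kb: KnowledgeBase,
    freqs: AlleleFrequencySet,
    drug: str,
) -> list[dict]:
    """Deviation table: computed HWE category percents vs the printed values
    (bounds compared as bounds)."""
    table = kb.table(drug, freqs.gene)
    computed = category_frequencies(kb, hwe_diplotype_frequencies(kb, freqs), table)
    rows = []
    for cat in table.categories:
        printed = cat.expected_freqs.get(freqs.ancestry) if freqs.ancestry else None
        got = computed.get(cat.id, 0.0)
        rows.append(
            {
                "category": cat.id,
                "computed_percent": round(got, 2),
                "printed": None if printed is None else str(printed),
                "deviation": None
                if printed is None
                else round(got - freq_as_float(printed, bound_value=getattr(printed, "limit", 0.0)), 2),
            }
        )
    if "unknown" in computed:
        rows.append(
            {"category": "unknown", "computed_percent": round(computed["unknown"], 2), "printed": None, "deviation": None}
        )
    return rows
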