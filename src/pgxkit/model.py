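"""Domain types for drug-centric pharmacogenomic interpretation.

The core vocabulary: a *variant* is a single DNA change (usually a SNP); a
*functional allele* is a named haplotype of a pharmacogene (star allele such
as CYP2C19*2, or a plain single-nucleotide allele such as VKORC1 "A") defined
by a minimal set of variants; a *diplotype* is the unordered pair of alleles
an individual carries; a *translation table* maps diplotypes of one gene to a
drug-specific PK/PD phenotype (metabolizer or transporter category) with
clinical interpretation text and expected population frequencies for three
ancestry groups.

Evidence about a variant/drug association is graded on a 14-point ordinal
scale (1 = strongest: consistent clinical-outcomes data for the drug under
review; 14 = published evidence of *no* effect). Ranks 4-7 additionally carry
a mutation-type qualifier from a fixed six-label set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union


class Ancestry(str, Enum):
    """The three ancestry groups for which population frequencies are reported."""

    CAUCASIAN = "Caucasian"
    AFRICAN = "African"
    EAST_ASIAN = "EastAsian"


class MutationType(str, Enum):
    """Six-label mutation-type qualifier attached to evidence ranks 4-7.

    The labels are treated as an opaque controlled vocabulary; descriptions
    are configurable via :data:`MUTATION_TYPE_DESCRIPTIONS`.
    """

    N = "n"
    SCD = "scd"
    SE = "se"
    AE = "ae"
    AD = "ad"
    DP = "dp"


#: Editable one-line descriptions of the six mutation-type labels.
MUTATION_TYPE_DESCRIPTIONS: dict[MutationType, str] = {
    MutationType.N: "null mutation abolishing protein function",
    MutationType.SCD: "splicing change or defect",
    MutationType.SE: "substitution affecting enzyme structure",
    MutationType.AE: "altered expression",
    MutationType.AD: "altered substrate/drug affinity",
    MutationType.DP: "duplication or copy-number change",
}


class FunctionClass(str, Enum):
    INCREASED = "increased"
    NORMAL = "normal"
    REDUCED = "reduced"
    NONE = "none"
    UNKNOWN = "unknown"


#: Ordering used by the highest-functioning-allele policy (best first).
FUNCTION_ORDER: tuple[FunctionClass, ...] = (
    FunctionClass.INCREASED,
    FunctionClass.NORMAL,
    FunctionClass.REDUCED,
    FunctionClass.NONE,
)


class StudyCategory(str, Enum):
    CLINICAL_OUTCOMES = "clinical_outcomes"
    PK_PD = "pk_pd"
    MOLECULAR_CELLULAR = "molecular_cellular"
    SCREENING = "screening"


class DrugTarget(str, Enum):
    DRUG_OF_INTEREST = "drug_of_interest"
    PROBE_DRUG = "probe_drug"
    OTHER_DRUG = "other_drug"


class Finding(str, Enum):
    CONSISTENT_EFFECT = "consistent_effect"
    INCONSISTENT = "inconsistent"
    EFFECT_ON_OTHER_ONLY = "effect_on_other_only"
    NO_EFFECT = "no_effect"
    LD_ATTRIBUTED = "ld_attributed"
    INSUFFICIENT = "insufficient"


class RelevanceTier(str, Enum):
    CLINICALLY_RELEVANT = "clinically_relevant"
    POTENTIALLY_RELEVANT = "potentially_relevant"
    UNKNOWN = "unknown"
    UNSUPPORTED = "unsupported"


class PkpdLabel(str, Enum):
    EM = "EM"
    IM = "IM"
    PM = "PM"
    UM = "UM"
    UNKNOWN = "unknown"
    NORMAL_TRANSPORT = "normal_transport"
    DECREASED_TRANSPORT = "decreased_transport"
    INCREASED_TRANSPORT = "increased_transport"
    CUSTOM = "custom"


class FallbackPolicy(str, Enum):
    LOOKUP_ONLY = "lookup_only"
    HIGHEST_FUNCTION_ALLELE = "highest_function_allele"
    UNKNOWN = "unknown"


class OutcomeStatus(str, Enum):
    APPROVED = "approved"
    DEFERRED = "deferred"
    REJECTED = "rejected"


class ModelError(ValueError):
    """Invariant violation in a domain object."""


_NUC_CHANGE_RE = re.compile(r"([ACGT])\s*>\s*([ACGT])\s*$")


@dataclass(frozen=True)
class Variant:
    """A single DNA change, keyed by (gene, rsid)."""

    gene: str
    rsid: Optional[str] = None
    nucleotide_change: Optional[str] = None
    mutation_type: Optional[MutationType] = None
    allele_freqs: Mapping[Ancestry, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rsid and not self.nucleotide_change:
            raise ModelError(f"variant in {self.gene}: rsid or nucleotide_change required")
        for anc, f in self.allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ModelError(f"variant {self.rsid}: frequency {f} for {anc} outside [0,1]")

    @property
    def ref_state(self) -> Optional[str]:
        m = _NUC_CHANGE_RE.search(self.nucleotide_change or "")
        return m.group(1) if m else None

    @property
    def alt_state(self) -> Optional[str]:
        m = _NUC_CHANGE_RE.search(self.nucleotide_change or "")
        return m.group(2) if m else None


@dataclass(frozen=True)
class FunctionalAllele:
    """A star allele (or plain single-SNP allele) of one pharmacogene.

    ``defining_variants`` maps rsid -> required nucleotide state; the
    reference allele (e.g. *1) has an empty mapping and absorbs all-reference
    genotypes. ``similarity_reference`` names another allele of the same gene
    whose interpretation rules this allele inherits (rare-allele
    extrapolation, e.g. CYP2C19*6 -> *2).
    """

    gene: str
    name: str
    function_class: FunctionClass = FunctionClass.UNKNOWN
    defining_variants: Mapping[str, str] = field(default_factory=dict)
    activity_value: Optional[float] = None
    similarity_reference: Optional[str] = None
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ModelError(f"allele {self.gene}{self.name}: copy_number must be >= 1")
        if self.activity_value is not None and self.activity_value < 0:
            raise ModelError(f"allele {self.gene}{self.name}: negative activity_value")


@dataclass(frozen=True)
class EvidenceRecord:
    """One published observation about a variant/allele in the context of a drug."""

    subject: str
    drug: str
    study_category: StudyCategory
    drug_target: DrugTarget
    finding: Finding
    gene: Optional[str] = None
    qualifier: Optional[MutationType] = None
    is_private: bool = False
    sample_size: Optional[int] = None
    effect_estimate: Optional[tuple[float, float, float]] = None  # (point, lo, hi)

    def __post_init__(self) -> None:
        if self.sample_size is not None and self.sample_size < 1:
            raise ModelError("sample_size must be positive")
        if self.effect_estimate is not None:
            point, lo, hi = self.effect_estimate
            if not lo <= point <= hi:
                raise ModelError(f"effect estimate CI {lo}..{hi} does not bracket point {point}")


_QUALIFIED_RANKS = frozenset({4, 5, 6, 7})


@dataclass(frozen=True)
class EvidenceCode:
    """A 1-14 evidence grade; ranks 4-7 carry mutation-type qualifiers."""

    rank: int
    qualifiers: frozenset[MutationType] = frozenset()

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= 14:
            raise ModelError(f"evidence rank {self.rank} outside 1..14")
        if (self.rank in _QUALIFIED_RANKS) != bool(self.qualifiers):
            raise ModelError(
                f"rank {self.rank}: qualifiers must be present exactly for ranks 4-7"
            )

    def __str__(self) -> str:
        if self.qualifiers:
            quals = ",".join(sorted(q.value for q in self.qualifiers))
            return f"{self.rank}{quals}"
        return str(self.rank)


# ---------------------------------------------------------------------------
# Diplotypes and canonical naming
# ---------------------------------------------------------------------------

_STAR_RE = re.compile(r"^\*(\d+)([A-Za-z0-9+]*)$")
_MULT_RE = re.compile(r"^(.*?)x(\d+|N)$")


def split_dose(part: str) -> tuple[str, Union[int, str]]:
    """Split an allele-name part like ``*1x2`` into (``*1``, 2).

    The symbolic multiplier ``N`` (as printed for duplication genotypes,
    ``*1xN``) is preserved as the string ``"N"``.
    """
    m = _MULT_RE.match(part)
    if m and (m.group(2) == "N" or int(m.group(2)) >= 2):
        mult: Union[int, str] = m.group(2) if m.group(2) == "N" else int(m.group(2))
        return m.group(1), mult
    return part, 1


def format_dose(name: str, copies: Union[int, str]) -> str:
    return name if copies == 1 else f"{name}x{copies}"


def allele_sort_key(part: str, reference: Optional[str] = None):
    """Deterministic allele ordering: reference first, then star alleles by
    numeric value ascending (suffix lexicographic), then plain names
    lexicographic; copy-number multiplier sorts last within an allele."""
    base, copies = split_dose(part)
    is_ref = 0 if (reference is not None and base == reference) else 1
    m = _STAR_RE.match(base)
    copies_key = 0 if copies == 1 else (10**6 if copies == "N" else int(copies))
    if m:
        return (is_ref, 0, int(m.group(1)), m.group(2), copies_key)
    return (is_ref, 1, 0, base, copies_key)


def normalize_multiplier(part: str) -> str:
    """Collapse any concrete duplication multiplier (x2, x3, ...) to ``xN``
    so calls can be matched against printed duplication genotypes."""
    base, copies = split_dose(part)
    return f"{base}xN" if copies != 1 else base


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of functional-allele doses at one gene.

    ``alleles`` holds two parts, each an allele name with an optional
    ``x<copies>`` suffix for whole-gene duplications; parts are stored in
    canonical sort order so construction from either ordering yields an
    identical object.
    """

    gene: str
    alleles: tuple[str, str]
    reference: Optional[str] = None

    @classmethod
    def of(cls, gene: str, a: str, b: str, reference: Optional[str] = None) -> "Diplotype":
        parts = sorted((a, b), key=lambda p: allele_sort_key(p, reference))
        return cls(gene=gene, alleles=(parts[0], parts[1]), reference=reference)

    @property
    def canonical_name(self) -> str:
        a, b = self.alleles
        sep = "" if a.startswith("*") and b.startswith("*") else " "
        return f"{self.gene}{sep}{a}/{b}"

    @property
    def pair_key(self) -> str:
        """Gene-less pair string used for translation-table membership,
        with duplication multipliers normalized to ``xN``."""
        return f"{normalize_multiplier(self.alleles[0])}/{normalize_multiplier(self.alleles[1])}"

    def base_alleles(self) -> tuple[str, str]:
        return (split_dose(self.alleles[0])[0], split_dose(self.alleles[1])[0])

    def doses(self) -> tuple[tuple[str, Union[int, str]], tuple[str, Union[int, str]]]:
        return (split_dose(self.alleles[0]), split_dose(self.alleles[1]))

    def __str__(self) -> str:
        return self.canonical_name


# ---------------------------------------------------------------------------
# Translation tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UpperBound:
    """A printed '<x' frequency entry, kept as a bound rather than a point."""

    limit: float

    def __str__(self) -> str:
        return f"<{self.limit:g}"


FreqValue = Union[float, UpperBound]


def freq_as_float(v: FreqValue, bound_value: float = 0.0) -> float:
    return bound_value if isinstance(v, UpperBound) else float(v)


@dataclass
class PhenotypeCategory:
    """One row of a drug-gene translation table: a named diplotype category
    with its PK/PD phenotype, interpretation text and printed expected
    population frequencies (percent)."""

    id: str
    pkpd_label: PkpdLabel
    clinical_text: str
    fda_text: Optional[str] = None
    member_diplotypes: list[str] = field(default_factory=list)
    expected_freqs: dict[Ancestry, FreqValue] = field(default_factory=dict)
    policy_function: Optional[FunctionClass] = None

    def __post_init__(self) -> None:
        for anc, v in self.expected_freqs.items():
            limit = v.limit if isinstance(v, UpperBound) else float(v)
            if not 0.0 <= limit <= 100.0:
                raise ModelError(f"category {self.id}: {anc} frequency {v} outside [0,100]")


@dataclass
class TranslationTable:
    """Per-drug mapping from diplotypes of one gene to phenotype categories."""

    drug: str
    gene: str
    categories: list[PhenotypeCategory]
    fallback_policy: FallbackPolicy = FallbackPolicy.LOOKUP_ONLY

    def __post_init__(self) -> None:
        self._member_index: dict[str, PhenotypeCategory] = {}
        for cat in self.categories:
            for member in cat.member_diplotypes:
                if member in self._member_index:
                    # duplicate membership is surfaced by validation, not here
                    continue
                self._member_index[member] = cat

    def category_for_member(self, pair_key: str) -> Optional[PhenotypeCategory]:
        return self._member_index.get(pair_key)

    def category_by_id(self, category_id: str) -> Optional[PhenotypeCategory]:
        for cat in self.categories:
            if cat.id == category_id:
                return cat
        return None

    def category_by_label(self, label: str) -> Optional[PhenotypeCategory]:
        for cat in self.categories:
            if cat.pkpd_label.value.lower() == label.lower() or cat.id.lower() == label.lower():
                return cat
        return None

    def category_for_function(self, fc: FunctionClass) -> Optional[PhenotypeCategory]:
        for cat in self.categories:
            if cat.policy_function == fc:
                return cat
        return None


@dataclass
class DrugGeneOutcome:
    """One advisory-group vote: a drug, its gene(s), approval status, and
    which genetic results are highly actionable."""

    drug: str
    genes: list[str]
    status: OutcomeStatus
    reason: str = ""
    highly_actionable: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status in (OutcomeStatus.DEFERRED, OutcomeStatus.REJECTED) and not self.reason:
            raise ModelError(f"{self.drug}: {self.status.value} outcome requires a reason")


@dataclass(frozen=True)
class GeneDef:
    name: str
    reference_allele: str


@dataclass
class KnowledgeBase:
    """Cross-linked container for the whole packaged knowledge base."""

    genes: dict[str, GeneDef] = field(default_factory=dict)
    variants: dict[str, dict[str, Variant]] = field(default_factory=dict)  # gene -> rsid -> Variant
    alleles: dict[str, dict[str, FunctionalAllele]] = field(default_factory=dict)
    evidence: list[EvidenceRecord] = field(default_factory=list)
    tables: dict[tuple[str, str], TranslationTable] = field(default_factory=dict)
    outcomes: list[DrugGeneOutcome] = field(default_factory=list)
    version: str = "1"

    # -- convenience accessors -------------------------------------------
    def gene_alleles(self, gene: str) -> dict[str, FunctionalAllele]:
        return self.alleles.get(gene, {})

    def allele(self, gene: str, name: str) -> FunctionalAllele:
        try:
            return self.alleles[gene][name]
        except KeyError:
            raise KeyError(f"allele {gene} {name!r} not in knowledge base") from None

    def table(self, drug: str, gene: str) -> TranslationTable:
        try:
            return self.tables[(drug, gene)]
        except KeyError:
            raise KeyError(f"no translation table for drug {drug!r} and gene {gene!r}") from None

    def tables_for_drug(self, drug: str) -> list[TranslationTable]:
        return [t for (d, g), t in sorted(self.tables.items()) if d == drug]

    def reference_allele(self, gene: str) -> str:
        return self.genes[gene].reference_allele

    def diplotype(self, gene: str, a: str, b: str) -> Diplotype:
        return Diplotype.of(gene, a, b, reference=self.genes[gene].reference_allele)

    def outcomes_for_drug(self, drug: str) -> list[DrugGeneOutcome]:
        return [o for o in self.outcomes if o.drug == drug]

    def approved_drugs(self) -> list[str]:
        return sorted({o.drug for o in self.outcomes if o.status is OutcomeStatus.APPROVED})

    def approved_drug_gene_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for o in self.outcomes:
            if o.status is OutcomeStatus.APPROVED:
                pairs.extend((o.drug, g) for g in o.genes)
        return sorted(pairs)


def resolve_similarity(kb: KnowledgeBase, gene: str, name: str, _max_depth: int = 32) -> str:
    """Follow ``similarity_reference`` links transitively to the effective
    allele name used for interpretation (acyclicity enforced at KB load)."""
    seen = []
    current = name
    for _ in range(_max_depth):
        allele = kb.allele(gene, current)
        if allele.similarity_reference is None:
            return current
        seen.append(current)
        current = allele.similarity_reference
        if current in seen:
            raise ModelError(f"cyclic similarity_reference at {gene} {current}")
    raise ModelError(f"similarity chain too deep at {gene} {name}")
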