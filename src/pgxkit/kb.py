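"""Loading, validation and serialization of the drug-gene knowledge base.

The knowledge base is a directory of UTF-8 tab-separated files:

* ``genes.tsv`` — gene symbol and reference allele name
* ``variants.tsv`` — defining DNA variants with optional ancestry frequencies
* ``alleles.tsv`` — functional alleles with function class / similarity links
* ``allele_variants.tsv`` — rsid + required state per allele
* ``evidence.tsv`` — one published observation per row
* ``outcomes.tsv`` — advisory-group votes per drug
* ``tables.tsv`` + ``translation/<drug>__<gene>.tsv`` — phenotype categories

A packaged knowledge base transcribed from published interpretation tables
for seven approved drugs/drug classes (clopidogrel, warfarin, PPIs, codeine,
thiopurines, simvastatin, celecoxib) and nine genes ships with the package.
Frequencies are stored as printed percents; ``<x`` entries are kept as upper
bounds. The defining-variant rsIDs of most packaged alleles are synthetic
stand-ins (``rsV2``, ``rsD4``, ...): the published per-allele SNP definitions
live in supplementary material that is not reproduced here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .model import (
    Ancestry,
    Diplotype,
    DrugGeneOutcome,
    EvidenceRecord,
    FallbackPolicy,
    Finding,
    FreqValue,
    FunctionClass,
    FunctionalAllele,
    GeneDef,
    KnowledgeBase,
    ModelError,
    MutationType,
    OutcomeStatus,
    PhenotypeCategory,
    PkpdLabel,
    StudyCategory,
    DrugTarget,
    TranslationTable,
    UpperBound,
    Variant,
    allele_sort_key,
    freq_as_float,
    split_dose,
)

__all__ = [
    "KBError",
    "Violation",
    "ValidationReport",
    "load_knowledge_base",
    "validate_knowledge_base",
    "write_knowledge_base",
    "kb_to_json",
    "packaged_kb_path",
    "load_packaged_kb",
]


class KBError(ValueError):
    """Raised for unloadable or structurally broken knowledge bases."""


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.violations.append(Violation(severity, message))

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    def __bool__(self) -> bool:  # truthy when clean
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


_ANCESTRY_COLS = {
    Ancestry.CAUCASIAN: "freq_caucasian",
    Ancestry.AFRICAN: "freq_african",
    Ancestry.EAST_ASIAN: "freq_eastasian",
}

_MANDATORY_FILES = (
    "genes.tsv",
    "variants.tsv",
    "alleles.tsv",
    "allele_variants.tsv",
    "evidence.tsv",
    "outcomes.tsv",
    "tables.tsv",
)


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise KBError(f"{path.name}: malformed table ({exc})") from exc
    return df.fillna("")


def _parse_freq(raw: str, where: str) -> Optional[FreqValue]:
    raw = raw.strip()
    if not raw:
        return None
    if raw.startswith("<"):
        try:
            return UpperBound(float(raw[1:]))
        except ValueError:
            raise KBError(f"{where}: bad frequency bound {raw!r}") from None
    try:
        return float(raw)
    except ValueError:
        raise KBError(f"{where}: bad frequency {raw!r}") from None


def canonical_pair_key(member: str, reference: Optional[str] = None) -> str:
    """Canonicalize a gene-less diplotype string like ``*17/*2`` -> ``*2/*17``."""
    parts = member.split("/")
    if len(parts) != 2:
        raise KBError(f"bad diplotype member {member!r} (expected 'a/b')")
    parts = sorted((p.strip() for p in parts), key=lambda p: allele_sort_key(p, reference))
    return f"{parts[0]}/{parts[1]}"


def load_knowledge_base(root_path: Union[str, Path]) -> KnowledgeBase:
    """Load and cross-link a knowledge-base directory.

    Raises :class:`KBError` for a missing mandatory file, a malformed row
    (with file and line context), or any dangling cross-reference; soft data
    problems (frequency sums, duplicate memberships) are left to
    :func:`validate_knowledge_base`.
    """
    root = Path(root_path)
    for fname in _MANDATORY_FILES:
        if not (root / fname).is_file():
            raise KBError(f"{fname.split('.')[0]} table missing: {root / fname}")

    kb = KnowledgeBase()

    genes = _read_tsv(root / "genes.tsv")
    for i, row in genes.iterrows():
        if not row["gene"] or not row["reference_allele"]:
            raise KBError(f"genes.tsv line {i + 2}: gene and reference_allele required")
        kb.genes[row["gene"]] = GeneDef(row["gene"], row["reference_allele"])

    variants = _read_tsv(root / "variants.tsv")
    for i, row in variants.iterrows():
        where = f"variants.tsv line {i + 2}"
        gene = row["gene"]
        if gene not in kb.genes:
            raise KBError(f"{where}: unknown gene {gene!r}")
        freqs = {}
        for anc, col in _ANCESTRY_COLS.items():
            v = _parse_freq(row.get(col, ""), where)
            if v is not None:
                freqs[anc] = freq_as_float(v)
        mt = MutationType(row["mutation_type"]) if row["mutation_type"] else None
        try:
            var = Variant(
                gene=gene,
                rsid=row["rsid"] or None,
                nucleotide_change=row["nucleotide_change"] or None,
                mutation_type=mt,
                allele_freqs=freqs,
            )
        except ModelError as exc:
            raise KBError(f"{where}: {exc}") from exc
        kb.variants.setdefault(gene, {})[var.rsid or var.nucleotide_change] = var

    # allele defining-variant links are gathered first, then attached
    links = _read_tsv(root / "allele_variants.tsv")
    defining: dict[tuple[str, str], dict[str, str]] = {}
    for i, row in links.iterrows():
        where = f"allele_variants.tsv line {i + 2}"
        if row["gene"] not in kb.genes:
            raise KBError(f"{where}: unknown gene {row['gene']!r}")
        if row["rsid"] not in kb.variants.get(row["gene"], {}):
            raise KBError(f"{where}: dangling variant reference {row['rsid']!r}")
        if not row["required_state"]:
            raise KBError(f"{where}: required_state missing")
        defining.setdefault((row["gene"], row["allele"]), {})[row["rsid"]] = row["required_state"]

    alleles = _read_tsv(root / "alleles.tsv")
    for i, row in alleles.iterrows():
        where = f"alleles.tsv line {i + 2}"
        gene = row["gene"]
        if gene not in kb.genes:
            raise KBError(f"{where}: unknown gene {gene!r}")
        try:
            allele = FunctionalAllele(
                gene=gene,
                name=row["name"],
                function_class=FunctionClass(row["function_class"] or "unknown"),
                defining_variants=defining.pop((gene, row["name"]), {}),
                activity_value=float(row["activity_value"]) if row.get("activity_value", "") else None,
                similarity_reference=row.get("similarity_reference", "") or None,
            )
        except (ModelError, ValueError) as exc:
            raise KBError(f"{where}: {exc}") from exc
        kb.alleles.setdefault(gene, {})[allele.name] = allele
    if defining:
        dangling = ", ".join(f"{g} {a}" for g, a in sorted(defining))
        raise KBError(f"allele_variants.tsv: dangling allele reference(s): {dangling}")

    evidence = _read_tsv(root / "evidence.tsv")
    for i, row in evidence.iterrows():
        where = f"evidence.tsv line {i + 2}"
        est = None
        if row.get("effect_point", ""):
            try:
                est = (
                    float(row["effect_point"]),
                    float(row.get("effect_lo", "") or row["effect_point"]),
                    float(row.get("effect_hi", "") or row["effect_point"]),
                )
                est = (est[0], est[1], est[2])
                est = (est[0], min(est), max(est))
            except ValueError as exc:
                raise KBError(f"{where}: bad effect estimate") from exc
        try:
            rec = EvidenceRecord(
                subject=row["subject"],
                gene=row.get("gene", "") or None,
                drug=row["drug"],
                study_category=StudyCategory(row["study_category"]),
                drug_target=DrugTarget(row["drug_target"]) if row["drug_target"] else DrugTarget.OTHER_DRUG,
                finding=Finding(row["finding"]),
                qualifier=MutationType(row["qualifier"]) if row["qualifier"] else None,
                is_private=row.get("is_private", "").lower() in ("true", "1", "yes"),
                sample_size=int(row["sample_size"]) if row.get("sample_size", "") else None,
                effect_estimate=est,
            )
        except (ModelError, ValueError) as exc:
            raise KBError(f"{where}: {exc}") from exc
        kb.evidence.append(rec)

    outcomes = _read_tsv(root / "outcomes.tsv")
    for i, row in outcomes.iterrows():
        where = f"outcomes.tsv line {i + 2}"
        try:
            out = DrugGeneOutcome(
                drug=row["drug"],
                genes=[g for g in row["genes"].split(";") if g],
                status=OutcomeStatus(row["status"]),
                reason=row.get("reason", ""),
                highly_actionable=[h for h in row.get("highly_actionable", "").split(";") if h],
            )
        except (ModelError, ValueError) as exc:
            raise KBError(f"{where}: {exc}") from exc
        kb.outcomes.append(out)

    tables_meta = _read_tsv(root / "tables.tsv")
    for i, row in tables_meta.iterrows():
        where = f"tables.tsv line {i + 2}"
        drug, gene = row["drug"], row["gene"]
        if gene not in kb.genes:
            raise KBError(f"{where}: unknown gene {gene!r}")
        tpath = root / "translation" / f"{drug}__{gene}.tsv"
        if not tpath.is_file():
            raise KBError(f"{where}: translation file missing: {tpath.name}")
        kb.tables[(drug, gene)] = _load_translation_table(
            tpath, drug, gene, FallbackPolicy(row["fallback_policy"] or "lookup_only"),
            reference=kb.genes[gene].reference_allele,
        )

    _check_cross_references(kb)
    return kb


def _load_translation_table(
    path: Path, drug: str, gene: str, policy: FallbackPolicy, reference: str
) -> TranslationTable:
    df = _read_tsv(path)
    cats: list[PhenotypeCategory] = []
    for i, row in df.iterrows():
        where = f"{path.name} line {i + 2}"
        freqs: dict[Ancestry, FreqValue] = {}
        for anc, col in _ANCESTRY_COLS.items():
            v = _parse_freq(row.get(col, ""), where)
            if v is not None:
                freqs[anc] = v
        members = [
            canonical_pair_key(m, reference)
            for m in row["member_diplotypes"].split(";")
            if m.strip()
        ]
        try:
            cats.append(
                PhenotypeCategory(
                    id=row["category_id"],
                    pkpd_label=PkpdLabel(row["pkpd_label"]),
                    clinical_text=row["clinical_text"],
                    fda_text=row.get("fda_text", "") or None,
                    member_diplotypes=members,
                    expected_freqs=freqs,
                    policy_function=FunctionClass(row["policy_function"]) if row.get("policy_function", "") else None,
                )
            )
        except (ModelError, ValueError) as exc:
            raise KBError(f"{where}: {exc}") from exc
    return TranslationTable(drug=drug, gene=gene, categories=cats, fallback_policy=policy)


def _check_cross_references(kb: KnowledgeBase) -> None:
    """Raise on dangling references: similarity links, table members,
    approved outcomes without translation tables."""
    problems: list[str] = []
    for gene, alleles in kb.alleles.items():
        for allele in alleles.values():
            ref = allele.similarity_reference
            if ref is not None and ref not in alleles:
                problems.append(f"{gene} {allele.name}: similarity_reference {ref!r} undefined")
    for (drug, gene), table in kb.tables.items():
        known = set(kb.alleles.get(gene, {}))
        for cat in table.categories:
            for member in cat.member_diplotypes:
                for part in member.split("/"):
                    base, _ = split_dose(part)
                    if base not in known:
                        problems.append(
                            f"table {drug}/{gene} category {cat.id}: allele {base!r} undefined"
                        )
    for out in kb.outcomes:
        if out.status is OutcomeStatus.APPROVED:
            for gene in out.genes:
                if (out.drug, gene) not in kb.tables:
                    problems.append(
                        f"outcome {out.drug}/{gene}: approved but no translation table"
                    )
    # cycles in similarity links
    for gene, alleles in kb.alleles.items():
        for name in alleles:
            seen = set()
            cur = name
            while alleles.get(cur) is not None and alleles[cur].similarity_reference:
                if cur in seen:
                    problems.append(f"{gene} {name}: cyclic similarity_reference")
                    break
                seen.add(cur)
                cur = alleles[cur].similarity_reference
    if problems:
        raise KBError("dangling references:\n  " + "\n  ".join(sorted(set(problems))))


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Check soft data invariants; violations are reported, not raised.

    Covered: per-ancestry frequency sums within [99, 101] (upper-bound
    entries counted as 0), diplotype membership disjointness across
    categories, reference alleles with defining variants, screening evidence
    without finding=insufficient, and variant frequencies outside [0, 1].
    """
    report = ValidationReport()
    for (drug, gene), table in kb.tables.items():
        seen: dict[str, str] = {}
        for cat in table.categories:
            for member in cat.member_diplotypes:
                if member in seen and seen[member] != cat.id:
                    report.add(
                        "warning",
                        f"{drug}/{gene}: diplotype {member} in categories {seen[member]} and {cat.id}",
                    )
                seen[member] = cat.id
        for anc in Ancestry:
            vals = [cat.expected_freqs.get(anc) for cat in table.categories]
            if all(v is None for v in vals):
                continue
            total = sum(freq_as_float(v) for v in vals if v is not None)
            if not 99.0 <= total <= 101.0:
                report.add(
                    "warning",
                    f"{drug}/{gene}: {anc.value} frequencies sum to {total:g}, outside [99, 101]",
                )
    for gene, gdef in kb.genes.items():
        ref = kb.alleles.get(gene, {}).get(gdef.reference_allele)
        if ref is not None and ref.defining_variants:
            report.add("warning", f"{gene}: reference allele {ref.name} has defining variants")
    for rec in kb.evidence:
        if rec.study_category is StudyCategory.SCREENING and rec.finding is not Finding.INSUFFICIENT:
            report.add(
                "warning",
                f"evidence {rec.gene or ''}{rec.subject}/{rec.drug}: screening study with finding {rec.finding.value}",
            )
    return report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _freq_str(v: Optional[FreqValue]) -> str:
    if v is None:
        return ""
    if isinstance(v, UpperBound):
        return f"<{v.limit:g}"
    return f"{v:g}"


def write_knowledge_base(kb: KnowledgeBase, root_path: Union[str, Path]) -> Path:
    """Write ``kb`` back out as a KB directory (TSVs + kb.json). Round-trips
    through :func:`load_knowledge_base`."""
    root = Path(root_path)
    (root / "translation").mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [{"gene": g.name, "reference_allele": g.reference_allele} for g in kb.genes.values()]
    ).to_csv(root / "genes.tsv", sep="\t", index=False)

    vrows = []
    for gene in kb.genes:
        for var in kb.variants.get(gene, {}).values():
            vrows.append(
                {
                    "gene": gene,
                    "rsid": var.rsid or "",
                    "nucleotide_change": var.nucleotide_change or "",
                    "mutation_type": var.mutation_type.value if var.mutation_type else "",
                    **{
                        col: (f"{var.allele_freqs[anc]:g}" if anc in var.allele_freqs else "")
                        for anc, col in _ANCESTRY_COLS.items()
                    },
                }
            )
    pd.DataFrame(vrows).to_csv(root / "variants.tsv", sep="\t", index=False)

    arows, lrows = [], []
    for gene in kb.genes:
        for allele in kb.alleles.get(gene, {}).values():
            arows.append(
                {
                    "gene": gene,
                    "name": allele.name,
                    "function_class": allele.function_class.value,
                    "activity_value": "" if allele.activity_value is None else f"{allele.activity_value:g}",
                    "similarity_reference": allele.similarity_reference or "",
                }
            )
            for rsid, state in allele.defining_variants.items():
                lrows.append({"gene": gene, "allele": allele.name, "rsid": rsid, "required_state": state})
    pd.DataFrame(arows).to_csv(root / "alleles.tsv", sep="\t", index=False)
    pd.DataFrame(lrows).to_csv(root / "allele_variants.tsv", sep="\t", index=False)

    erows = []
    for rec in kb.evidence:
        erows.append(
            {
                "subject": rec.subject,
                "gene": rec.gene or "",
                "drug": rec.drug,
                "study_category": rec.study_category.value,
                "drug_target": rec.drug_target.value,
                "finding": rec.finding.value,
                "qualifier": rec.qualifier.value if rec.qualifier else "",
                "is_private": "true" if rec.is_private else "false",
                "sample_size": "" if rec.sample_size is None else str(rec.sample_size),
                "effect_point": "" if rec.effect_estimate is None else f"{rec.effect_estimate[0]:g}",
                "effect_lo": "" if rec.effect_estimate is None else f"{rec.effect_estimate[1]:g}",
                "effect_hi": "" if rec.effect_estimate is None else f"{rec.effect_estimate[2]:g}",
            }
        )
    pd.DataFrame(erows).to_csv(root / "evidence.tsv", sep="\t", index=False)

    orows = [
        {
            "drug": o.drug,
            "genes": ";".join(o.genes),
            "status": o.status.value,
            "reason": o.reason,
            "highly_actionable": ";".join(o.highly_actionable),
        }
        for o in kb.outcomes
    ]
    pd.DataFrame(orows).to_csv(root / "outcomes.tsv", sep="\t", index=False)

    trows = [
        {"drug": d, "gene": g, "fallback_policy": t.fallback_policy.value}
        for (d, g), t in sorted(kb.tables.items())
    ]
    pd.DataFrame(trows).to_csv(root / "tables.tsv", sep="\t", index=False)
    for (drug, gene), table in kb.tables.items():
        crows = [
            {
                "category_id": c.id,
                "pkpd_label": c.pkpd_label.value,
                "policy_function": c.policy_function.value if c.policy_function else "",
                "clinical_text": c.clinical_text,
                "fda_text": c.fda_text or "",
                "member_diplotypes": ";".join(c.member_diplotypes),
                **{col: _freq_str(c.expected_freqs.get(anc)) for anc, col in _ANCESTRY_COLS.items()},
            }
            for c in table.categories
        ]
        pd.DataFrame(crows).to_csv(root / "translation" / f"{drug}__{gene}.tsv", sep="\t", index=False)

    (root / "kb.json").write_text(kb_to_json(kb), encoding="utf-8")
    return root


def kb_to_json(kb: KnowledgeBase) -> str:
    """JSON export of the whole knowledge base for programmatic consumers."""

    def default(obj):
        if isinstance(obj, UpperBound):
            return {"upper_bound": obj.limit}
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        raise TypeError(f"unserializable {type(obj)}")

    payload = {
        "version": kb.version,
        "genes": {g: dataclasses.asdict(d) for g, d in kb.genes.items()},
        "variants": {g: {k: dataclasses.asdict(v) for k, v in vs.items()} for g, vs in kb.variants.items()},
        "alleles": {g: {k: dataclasses.asdict(a) for k, a in als.items()} for g, als in kb.alleles.items()},
        "evidence": [dataclasses.asdict(r) for r in kb.evidence],
        "outcomes": [dataclasses.asdict(o) for o in kb.outcomes],
        "tables": {
            f"{d}__{g}": {
                "drug": d,
                "gene": g,
                "fallback_policy": t.fallback_policy.value,
                "categories": [dataclasses.asdict(c) for c in t.categories],
            }
            for (d, g), t in sorted(kb.tables.items())
        },
    }
    return json.dumps(payload, indent=2, default=default, sort_keys=True)


def packaged_kb_path() -> Path:
    """Filesystem path of the knowledge base shipped with the package."""
    return Path(resources.files("pgxkit") / "data" / "kb")


def load_packaged_kb() -> KnowledgeBase:
    return load_knowledge_base(packaged_kb_path())
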