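"""Participant-facing pharmacogenomic risk reports.

A report assembles, for one sample, drug and gene: the called diplotype (or
an explicit ambiguity statement), its drug-specific PK/PD phenotype and
clinical interpretation, any FDA guideline text, the expected frequency of
the phenotype category in the ancestry group most relevant to the
participant, and an actionability level. Two actionability levels exist:
``high`` for the genetic results the advisory outcome table singles out for
more urgent communication (e.g. clopidogrel poor metabolizers, codeine
ultra-rapid metabolizers), and ``standard`` for everything else. Reports are
only produced for drugs with an approved outcome; deferred or rejected drugs
yield a refusal carrying the recorded reason.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .caller import DiplotypeCall
from .model import (
    Ancestry,
    KnowledgeBase,
    OutcomeStatus,
    PkpdLabel,
)
from .popfreq import lookup_category_frequency

__all__ = [
    "ActionabilityLevel",
    "RiskReport",
    "ReportRefusal",
    "actionability_level",
    "build_report",
    "build_multi_gene_report",
    "render_report",
    "report_from_json",
]

DEFAULT_LIMITATIONS = (
    "This result is based on a fixed panel of tested variants; rare or "
    "untested alleles, unphased double-heterozygous genotypes, and "
    "copy-number events outside the assay's range may not be detected. "
    "Interpretations reflect published evidence available at the time the "
    "knowledge base was curated."
)


class ReportRefusal(RuntimeError):
    """Raised when a report is requested for a non-approved drug."""

    def __init__(self, drug: str, status: OutcomeStatus, reason: str):
        self.drug = drug
        self.status = status
        self.reason = reason
        super().__init__(
            f"no report for {drug}: outcome status is {status.value}"
            + (f" ({reason})" if reason else "")
        )


@dataclass(frozen=True)
class ActionabilityLevel:
    level: str  # "high" | "standard"


def actionability_level(
    kb: KnowledgeBase, drug: str, phenotype: str, gene: Optional[str] = None
) -> ActionabilityLevel:
    """``high`` iff the phenotype (category id, PK/PD label, or diplotype
    name) is listed among the drug's highly actionable genetic results.

    Gene-qualified entries ("CYP2C9:PM") match when the gene agrees or no
    gene is given.
    """
    outcomes = kb.outcomes_for_drug(drug)
    if not outcomes:
        raise KeyError(f"drug {drug!r} has no outcomes entry")
    query = phenotype.strip().lower()
    for out in outcomes:
        if out.status is not OutcomeStatus.APPROVED:
            continue
        for token in out.highly_actionable:
            tgene, _, label = token.rpartition(":")
            if tgene and gene is not None and tgene.lower() != gene.lower():
                continue
            if label.strip().lower() == query:
                return ActionabilityLevel("high")
    return ActionabilityLevel("standard")


@dataclass
class RiskReport:
    sample_id: str
    drug: str
    gene: str
    diplotype: str
    pkpd_phenotype: str
    interpretation: str
    fda_text: str
    ancestry: str
    category_frequency: str
    actionability: str
    limitations: str
    kb_version: str
    candidate_diplotypes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _approved_outcome(kb: KnowledgeBase, drug: str, gene: str):
    outcomes = kb.outcomes_for_drug(drug)
    if not outcomes:
        raise KeyError(f"drug {drug!r} has no outcomes entry")
    for o in outcomes:
        if o.status is OutcomeStatus.APPROVED and gene in o.genes:
            return o
    # refuse with the most specific non-approved entry
    entry = next((o for o in outcomes if gene in o.genes), outcomes[0])
    raise ReportRefusal(drug, entry.status, entry.reason)


def build_report(
    kb: KnowledgeBase,
    call: DiplotypeCall,
    drug: str,
    ancestry: Union[Ancestry, str],
    limitations: str = DEFAULT_LIMITATIONS,
) -> RiskReport:
    """Assemble a risk report from a diplotype call.

    Discordant (phase-ambiguous) calls are reported with an unknown effect
    on drug response and both candidate diplotypes listed.
    """
    anc = Ancestry(ancestry)
    _approved_outcome(kb, drug, call.gene)

    assignment = call.phenotype
    if call.status == "no_call" or assignment is None:
        diplotype_text = "no call"
        label = PkpdLabel.UNKNOWN
        interpretation = "Genotype incompatible with known alleles; no result"
        fda = ""
        category_id = None
    else:
        label = assignment.pkpd_label
        interpretation = assignment.clinical_text
        fda = assignment.fda_text or ""
        category_id = assignment.category_id
        if call.status == "ambiguous_discordant":
            names = " or ".join(d.canonical_name for d in call.candidates)
            diplotype_text = f"ambiguous: {names} (unphased genotype)"
        else:
            diplotype_text = call.resolved_diplotype.canonical_name  # type: ignore[union-attr]
            if call.status == "ambiguous_equivalent":
                diplotype_text += " (phenotype-equivalent candidates)"

    freq_text = "not reported"
    lookup_key = category_id or ("unknown" if label is PkpdLabel.UNKNOWN else None)
    if lookup_key is not None:
        try:
            freq_text = f"{lookup_category_frequency(kb, drug, call.gene, lookup_key, anc)}"
        except KeyError:
            freq_text = "not reported"

    queries = {label.value}
    if category_id:
        queries.add(category_id)
    if call.resolved_diplotype is not None:
        queries.add(call.resolved_diplotype.pair_key)
    act = ActionabilityLevel(
        "high"
        if any(actionability_level(kb, drug, q, gene=call.gene).level == "high" for q in queries)
        else "standard"
    )
    return RiskReport(
        sample_id=call.sample_id,
        drug=drug,
        gene=call.gene,
        diplotype=diplotype_text,
        pkpd_phenotype=label.value,
        interpretation=interpretation,
        fda_text=fda or "No specific FDA pharmacogenomic guideline for this category",
        ancestry=anc.value,
        category_frequency=freq_text,
        actionability=act.level,
        limitations=limitations,
        kb_version=kb.version,
        candidate_diplotypes=[d.canonical_name for d in call.candidates],
        warnings=list(call.warnings),
    )


def build_multi_gene_report(
    kb: KnowledgeBase,
    calls: Sequence[DiplotypeCall],
    drug: str,
    ancestry: Union[Ancestry, str],
) -> list[RiskReport]:
    """Per-gene reports for multi-gene drugs (e.g. warfarin with CYP2C9,
    VKORC1 and CYP4F2); interpretations are concatenated by the caller-facing
    renderer, not combined into a joint dose prediction."""
    return [build_report(kb, call, drug, ancestry) for call in calls]


_MARKDOWN_SECTIONS = (
    ("Genetic result", "diplotype"),
    ("Phenotype", "pkpd_phenotype"),
    ("Interpretation", "interpretation"),
    ("FDA guidance", "fda_text"),
    ("Expected frequency", None),
    ("Actionability", "actionability"),
    ("Limitations", "limitations"),
)


def render_report(report: RiskReport, format: str = "markdown") -> str:
    """Deterministic rendering; ``json`` round-trips losslessly."""
    if format == "json":
        return json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True)
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    lines = [
        f"# PGx risk report: {report.drug} / {report.gene}",
        "",
        f"Sample: {report.sample_id}  |  Knowledge base version: {report.kb_version}",
        "",
    ]
    for heading, attr in _MARKDOWN_SECTIONS:
        lines.append(f"## {heading}")
        if heading == "Expected frequency":
            lines.append(
                f"{report.category_frequency}% of individuals of {report.ancestry} "
                "ancestry are expected to share this phenotype category."
            )
        else:
            lines.append(getattr(report, attr) or "-")
        lines.append("")
    if report.warnings:
        lines.append("## Notes")
        lines.extend(f"- {w}" for w in report.warnings)
        lines.append("")
    return "\n".join(lines)


def report_from_json(text: str) -> RiskReport:
    return RiskReport(**json.loads(text))
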