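"""Star-allele diplotype calling from unphased per-sample genotypes.

Array-style genotyping yields independent biallelic calls per site without
phase; the caller searches *all* unordered allele pairs of a gene (including
whole-gene copy-number expansions when a gene copy number above 2 is
reported) and keeps every pair whose combined defining-variant states
reproduce the observed genotype at every assayed site. Phase ambiguity is
surfaced, never resolved statistically: when several candidate diplotypes
match, the call is ambiguous, and its downstream phenotype is reported as
unknown whenever the candidates disagree for the queried drug. The classic
case is a double heterozygote at the CYP2C19 *2- and *17-defining sites:
trans (*2/*17, an intermediate metabolizer for PPIs) cannot be distinguished
from *1 with *2+*17 in cis, for which the metabolizer type is unknown.

Sites that were not assayed are treated as reference-compatible, with an
"untyped sites" warning attached to the call.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

from .model import (
    Diplotype,
    FUNCTION_ORDER,
    FunctionClass,
    KnowledgeBase,
    PkpdLabel,
    format_dose,
)
from .translate import assign_phenotype, PhenotypeAssignment

__all__ = [
    "SampleGenotypes",
    "DiplotypeCall",
    "parse_genotype_table",
    "read_vcf_genotypes",
    "match_star_alleles",
    "call_diplotype",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleGenotypes:
    """Unphased rsID-keyed genotype calls for one sample."""

    sample_id: str
    calls: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    gene_copy_number: dict[str, int] = field(default_factory=dict)
    phased: bool = False

    def gene_calls(self, gene: str) -> dict[str, tuple[str, str]]:
        return {rsid: g for (g_, rsid), g in self.calls.items() if g_ == gene}


@dataclass
class DiplotypeCall:
    """Outcome of candidate matching for one sample and gene."""

    sample_id: str
    gene: str
    candidates: list[Diplotype]
    status: str  # resolved | ambiguous_equivalent | ambiguous_discordant | no_call
    resolved_diplotype: Optional[Diplotype] = None
    phenotype: Optional[PhenotypeAssignment] = None
    warnings: list[str] = field(default_factory=list)


class GenotypeParseError(ValueError):
    pass


def parse_genotype_table(source: Union[str, Path, TextIO]) -> list[SampleGenotypes]:
    """Read a genotype TSV: sample_id, gene, rsid, genotype ("X/Y"), and an
    optional copy_number column applying to the whole gene."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False).fillna("")
    required = {"sample_id", "gene", "rsid", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(f"genotype table missing column(s): {sorted(missing)}")
    samples: dict[str, SampleGenotypes] = {}
    for i, row in df.iterrows():
        line = i + 2
        sid = row["sample_id"]
        sample = samples.setdefault(sid, SampleGenotypes(sample_id=sid))
        gt = row["genotype"].strip()
        if gt:
            parts = gt.split("/")
            if len(parts) != 2 or not all(parts):
                raise GenotypeParseError(f"line {line}: malformed genotype {gt!r} (expected 'X/Y')")
            key = (row["gene"], row["rsid"])
            pair = tuple(sorted(parts))
            if key in sample.calls and sample.calls[key] != pair:
                raise GenotypeParseError(
                    f"line {line}: conflicting duplicate call for {sid} at {key[0]}:{key[1]}"
                )
            sample.calls[key] = pair  # type: ignore[assignment]
        cn = row.get("copy_number", "")
        if cn:
            try:
                sample.gene_copy_number[row["gene"]] = int(cn)
            except ValueError:
                raise GenotypeParseError(f"line {line}: bad copy_number {cn!r}") from None
    return list(samples.values())


def read_vcf_genotypes(path: Union[str, Path], kb: KnowledgeBase) -> list[SampleGenotypes]:
    """Read a minimal VCF (GT field; ID column carrying the rsID) into
    per-sample genotype sets, mapping rsIDs to genes via the KB."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rsid_to_gene = {
        rsid: gene for gene, variants in kb.variants.items() for rsid in variants
    }
    vcf = VCF(str(path))
    samples = [SampleGenotypes(sample_id=s) for s in vcf.samples]
    for record in vcf:
        rsid = record.ID
        if rsid is None:
            continue
        gene = rsid_to_gene.get(rsid)
        if gene is None:
            logger.warning("VCF record %s: rsID not in knowledge base; retained as unassigned", rsid)
            continue
        states = [record.REF] + list(record.ALT)
        for sample, gt in zip(samples, record.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:  # missing call
                continue
            pair = tuple(sorted((states[a], states[b])))
            sample.calls[(gene, rsid)] = pair  # type: ignore[assignment]
    return samples


def _haplotype_state(kb: KnowledgeBase, gene: str, allele: str, rsid: str) -> str:
    """State contributed by one haplotype at one site (reference unless the
    allele's definition requires otherwise)."""
    defn = kb.allele(gene, allele).defining_variants
    if rsid in defn:
        return defn[rsid]
    var = kb.variants[gene][rsid]
    if var.ref_state is None:
        raise ValueError(f"{gene} {rsid}: reference state unparseable from nucleotide change")
    return var.ref_state


def _pair_matches(
    kb: KnowledgeBase,
    gene: str,
    doses: Sequence[tuple[str, int]],
    observed: dict[str, tuple[str, str]],
) -> bool:
    """Does a multiset of allele doses reproduce the observed unphased
    genotype at every assayed site?

    For diploid configurations the comparison is an exact multiset match;
    with copy-number expansions (>2 haplotypes) the biallelic array call is
    compared as a set of observed states.
    """
    total_copies = sum(c for _, c in doses)
    for rsid, obs in observed.items():
        contributed: list[str] = []
        for name, copies in doses:
            contributed.extend([_haplotype_state(kb, gene, name, rsid)] * copies)
        if total_copies == 2:
            if Counter(contributed) != Counter(obs):
                return False
        else:
            if set(contributed) != set(obs):
                return False
    return True


def match_star_alleles(
    kb: KnowledgeBase, sample: SampleGenotypes, gene: str
) -> tuple[list[Diplotype], list[str]]:
    """Exhaustive candidate search over unordered allele pairs.

    Returns (candidates, warnings). With gene copy number n > 2, pairs are
    expanded over whole-gene duplications (copies summing to n); when several
    expansions of the same base pair match, the duplication of the
    higher-function allele is kept (with a warning).
    """
    alleles = kb.gene_alleles(gene)
    if not alleles:
        raise ValueError(f"gene {gene!r} has no allele definitions")
    observed = sample.gene_calls(gene)
    warnings: list[str] = []

    panel = set(kb.variants.get(gene, {}))
    unknown_sites = sorted(set(observed) - panel)
    if unknown_sites:
        warnings.append(f"unknown rsIDs ignored: {', '.join(unknown_sites)}")
        observed = {r: g for r, g in observed.items() if r in panel}
    untyped = sorted(panel - set(observed))
    if untyped:
        warnings.append(f"untyped sites treated as reference: {', '.join(untyped)}")

    cn = sample.gene_copy_number.get(gene, 2)
    names = sorted(alleles)
    candidates: dict[str, Diplotype] = {}
    matched_doses: dict[frozenset, list[tuple[tuple[str, int], tuple[str, int]]]] = {}
    for a, b in itertools.combinations_with_replacement(names, 2):
        if cn == 2:
            splits = [((a, 1), (b, 1))]
        else:
            splits = [
                ((a, i), (b, cn - i))
                for i in range(1, cn)
                if not (a == b and i > cn - i)  # symmetric duplicates
            ]
        for dose_a, dose_b in splits:
            if _pair_matches(kb, gene, (dose_a, dose_b), observed):
                matched_doses.setdefault(frozenset((a, b)), []).append((dose_a, dose_b))

    for base_pair, splits in matched_doses.items():
        if len(splits) > 1:
            # several copy-number splits of the same allele pair fit the
            # biallelic calls; prefer duplicating the higher-function allele
            def split_rank(split):
                dup_fcs = [
                    FUNCTION_ORDER.index(kb.allele(gene, name).function_class)
                    if kb.allele(gene, name).function_class in FUNCTION_ORDER
                    else len(FUNCTION_ORDER)
                    for name, copies in split
                    if copies > 1
                ]
                return min(dup_fcs) if dup_fcs else len(FUNCTION_ORDER) + 1

            best = min(splits, key=split_rank)
            warnings.append(
                f"copy-number split ambiguous for {'/'.join(sorted(base_pair))}; "
                "assigned duplication to the higher-function allele"
            )
            splits = [best]
        (na, ca), (nb, cb) = splits[0]
        d = kb.diplotype(gene, format_dose(na, ca), format_dose(nb, cb))
        candidates[d.canonical_name] = d

    if not candidates:
        sites = ", ".join(f"{rsid}={'/'.join(g)}" for rsid, g in sorted(observed.items()))
        warnings.append(f"no allele pair is compatible with the observed genotype ({sites})")
    n_het_sites = sum(1 for a, b in observed.values() if a != b)
    if len(candidates) > 1:
        warnings.append(
            "unphased multi-site heterozygote: several allele configurations fit; "
            "phase cannot be determined from array genotypes"
        )
    elif n_het_sites >= 2 and candidates:
        only = next(iter(candidates.values()))
        a, b = only.base_alleles()
        ref = kb.reference_allele(gene)
        if a != b and ref not in (a, b):
            warnings.append(
                "double heterozygote assumed in trans; an undescribed cis haplotype "
                "carrying both variants would change the call"
            )
    return sorted(candidates.values(), key=lambda d: d.canonical_name), warnings


def call_diplotype(
    kb: KnowledgeBase,
    sample: SampleGenotypes,
    gene: str,
    drug: str,
    candidates: Optional[Sequence[Diplotype]] = None,
    warnings: Optional[list[str]] = None,
) -> DiplotypeCall:
    """Turn matcher candidates into a call with phase-ambiguity status.

    One candidate resolves directly. Several candidates that share the same
    phenotype for the queried drug are equivalent (any representative is
    reported); candidates with differing phenotypes make the call discordant
    and its phenotype unknown — never a guess.
    """
    if candidates is None:
        candidates, warnings = match_star_alleles(kb, sample, gene)
    warnings = list(warnings or [])
    candidates = list(candidates)

    if not candidates:
        return DiplotypeCall(sample.sample_id, gene, [], "no_call", warnings=warnings)

    assignments = [assign_phenotype(kb, d, drug) for d in candidates]
    if len(candidates) == 1:
        return DiplotypeCall(
            sample.sample_id, gene, candidates, "resolved",
            resolved_diplotype=candidates[0], phenotype=assignments[0], warnings=warnings,
        )
    labels = {a.pkpd_label for a in assignments}
    if len(labels) == 1:
        return DiplotypeCall(
            sample.sample_id, gene, candidates, "ambiguous_equivalent",
            resolved_diplotype=candidates[0], phenotype=assignments[0], warnings=warnings,
        )
    unknown = PhenotypeAssignment(
        diplotype=candidates[0],
        drug=drug,
        pkpd_label=PkpdLabel.UNKNOWN,
        clinical_text="Unknown effect on drug response (phase-ambiguous genotype)",
        category_id=None,
        provenance="unknown",
    )
    return DiplotypeCall(
        sample.sample_id, gene, candidates, "ambiguous_discordant",
        phenotype=unknown, warnings=warnings,
    )
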