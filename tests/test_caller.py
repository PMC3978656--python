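"""Star-allele calling from unphased genotypes: candidate search, phase
ambiguity, copy number, and the decompose/match round trip."""

import io
import itertools

import pytest

from oracles import brute_force_candidates
from pgxkit.caller import (
    GenotypeParseError,
    SampleGenotypes,
    call_diplotype,
    match_star_alleles,
    parse_genotype_table,
)
from pgxkit.cohort import decompose_to_genotypes
from pgxkit.model import PkpdLabel, split_dose


def sample_for(kb, gene, diplotype, sample_id="S1"):
    s = SampleGenotypes(sample_id=sample_id)
    s.calls = {(gene, rsid): gt for rsid, gt in decompose_to_genotypes(kb, diplotype).items()}
    copies = sum(2 if c == "N" else int(c) for _, c in diplotype.doses())
    if copies != 2:
        s.gene_copy_number[gene] = copies
    return s


# -- parsing ---------------------------------------------------------------


def test_parse_simple_row():
    text = "sample_id\tgene\trsid\tgenotype\nS1\tCYP2C19\trsV2\tA/G\n"
    samples = parse_genotype_table(io.StringIO(text))
    assert len(samples) == 1
    assert samples[0].calls[("CYP2C19", "rsV2")] == ("A", "G")


def test_parse_header_only_yields_empty_list():
    assert parse_genotype_table(io.StringIO("sample_id\tgene\trsid\tgenotype\n")) == []


def test_parse_rejects_conflicting_duplicates():
    text = (
        "sample_id\tgene\trsid\tgenotype\n"
        "S1\tCYP2C19\trsV2\tA/G\n"
        "S1\tCYP2C19\trsV2\tG/G\n"
    )
    with pytest.raises(GenotypeParseError, match="line 3"):
        parse_genotype_table(io.StringIO(text))


def test_parse_rejects_malformed_genotype():
    text = "sample_id\tgene\trsid\tgenotype\nS1\tCYP2C19\trsV2\tAG\n"
    with pytest.raises(GenotypeParseError, match="line 2"):
        parse_genotype_table(io.StringIO(text))


def test_vcf_input_maps_rsids_through_the_kb(kb, tmp_path):
    from pgxkit.caller import read_vcf_genotypes

    vcf = tmp_path / "sample.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=10>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "10\t100\trsV2\tG\tA\t.\tPASS\t.\tGT\t0/1\n"
        "10\t200\trsV17\tC\tT\t.\tPASS\t.\tGT\t0/1\n"
    )
    samples = read_vcf_genotypes(vcf, kb)
    assert len(samples) == 1 and samples[0].sample_id == "S1"
    assert samples[0].calls[("CYP2C19", "rsV2")] == ("A", "G")
    call = call_diplotype(kb, samples[0], "CYP2C19", "PPIs")
    assert call.status == "resolved"
    assert call.resolved_diplotype.canonical_name == "CYP2C19*2/*17"


# -- candidate matching ----------------------------------------------------


def test_all_reference_matches_reference_homozygote(kb):
    s = sample_for(kb, "CYP2C19", kb.diplotype("CYP2C19", "*1", "*1"))
    candidates, _ = match_star_alleles(kb, s, "CYP2C19")
    assert [d.canonical_name for d in candidates] == ["CYP2C19*1/*1"]


def test_homozygous_alternate_matches_variant_homozygote(kb):
    s = sample_for(kb, "CYP2C19", kb.diplotype("CYP2C19", "*2", "*2"))
    candidates, _ = match_star_alleles(kb, s, "CYP2C19")
    assert [d.canonical_name for d in candidates] == ["CYP2C19*2/*2"]


def test_matcher_agrees_with_brute_force_oracle(kb):
    """For every diploid diplotype of a 5-allele gene, the matcher's
    candidate set equals an independent exhaustive search."""
    gene = "CYP2C19"
    names = sorted(kb.gene_alleles(gene))
    assert len(names) == 5
    for a, b in itertools.combinations_with_replacement(names, 2):
        d = kb.diplotype(gene, a, b)
        s = sample_for(kb, gene, d)
        observed = s.gene_calls(gene)
        candidates, _ = match_star_alleles(kb, s, gene)
        assert [c.canonical_name for c in candidates] == brute_force_candidates(kb, gene, observed)


def test_double_heterozygote_without_cis_allele_notes_trans_assumption(kb):
    s = sample_for(kb, "CYP2C19", kb.diplotype("CYP2C19", "*2", "*17"))
    candidates, warnings = match_star_alleles(kb, s, "CYP2C19")
    assert [d.canonical_name for d in candidates] == ["CYP2C19*2/*17"]
    assert any("trans" in w for w in warnings)


def test_double_heterozygote_with_cis_allele_is_ambiguous(kb_with_cis):
    kb = kb_with_cis
    s = sample_for(kb, "CYP2C19", kb.diplotype("CYP2C19", "*2", "*17"))
    candidates, _ = match_star_alleles(kb, s, "CYP2C19")
    assert {d.pair_key for d in candidates} == {"*2/*17", "*1/*2+*17"}


def test_discordant_candidates_yield_unknown_phenotype(kb_with_cis):
    kb = kb_with_cis
    s = sample_for(kb, "CYP2C19", kb.diplotype("CYP2C19", "*2", "*17"))
    call = call_diplotype(kb, s, "CYP2C19", "PPIs")
    # trans *2/*17 is an IM for PPIs; *1 with *2+*17 in cis is unknown
    assert call.status == "ambiguous_discordant"
    assert call.phenotype.pkpd_label is PkpdLabel.UNKNOWN
    assert call.resolved_diplotype is None


def test_equivalent_candidates_resolve_to_shared_phenotype(kb_with_cis):
    kb = kb_with_cis
    s = sample_for(kb, "CYP2C19", kb.diplotype("CYP2C19", "*2", "*17"))
    call = call_diplotype(kb, s, "CYP2C19", "clopidogrel")
    # both candidates carry an undetermined metabolizer status for clopidogrel
    assert call.status == "ambiguous_equivalent"
    assert call.phenotype.pkpd_label is PkpdLabel.UNKNOWN


def test_incompatible_genotype_gives_no_call_with_diagnostic(kb):
    s = SampleGenotypes("S1", calls={("CYP2C19", "rsV2"): ("A", "T")})
    call = call_diplotype(kb, s, "CYP2C19", "clopidogrel")
    assert call.status == "no_call"
    assert any("rsV2" in w for w in call.warnings)


def test_copy_number_three_reference_only_duplicates_reference(kb):
    s = sample_for(kb, "CYP2D6", kb.diplotype("CYP2D6", "*1", "*1"))
    s.gene_copy_number["CYP2D6"] = 3
    candidates, _ = match_star_alleles(kb, s, "CYP2D6")
    assert [d.canonical_name for d in candidates] == ["CYP2D6*1/*1x2"]
    call = call_diplotype(kb, s, "CYP2D6", "codeine")
    assert call.status == "resolved"
    assert call.phenotype.pkpd_label is PkpdLabel.UM


def test_copy_number_split_tie_prefers_higher_function_allele(kb):
    s = sample_for(kb, "CYP2D6", kb.diplotype("CYP2D6", "*1", "*4"))
    s.gene_copy_number["CYP2D6"] = 3
    candidates, warnings = match_star_alleles(kb, s, "CYP2D6")
    assert [d.canonical_name for d in candidates] == ["CYP2D6*1x2/*4"]
    assert any("higher-function" in w for w in warnings)


def test_resolved_single_candidate(kb):
    s = sample_for(kb, "TPMT", kb.diplotype("TPMT", "*1", "*3A"))
    call = call_diplotype(kb, s, "TPMT", "thiopurines")
    assert call.status == "resolved"
    assert call.resolved_diplotype.canonical_name == "TPMT*1/*3A"
    assert call.phenotype.pkpd_label is PkpdLabel.IM


def test_round_trip_for_all_packaged_explicit_diplotypes(kb):
    """Decompose -> match -> call recovers every explicitly listed diplotype
    whose two alleles have disjoint defining-variant sets (diploid and
    duplication members alike; duplication members are checked at the
    category level because total copy number alone cannot pin the split)."""
    checked = 0
    for (drug, gene), table in kb.tables.items():
        for cat in table.categories:
            for member in cat.member_diplotypes:
                a, b = member.split("/")
                a = a.replace("xN", "x2")
                b = b.replace("xN", "x2")
                va = kb.allele(gene, split_dose(a)[0]).defining_variants
                vb = kb.allele(gene, split_dose(b)[0]).defining_variants
                if split_dose(a)[0] != split_dose(b)[0] and set(va) & set(vb):
                    continue  # shared defining site: genuinely ambiguous
                d = kb.diplotype(gene, a, b)
                call = call_diplotype(kb, sample_for(kb, gene, d), gene, drug)
                assert call.status == "resolved", (drug, gene, member, call.status)
                if "x2" in a or "x2" in b:
                    assert call.phenotype.category_id == cat.id, (member, call)
                else:
                    assert call.resolved_diplotype.canonical_name == d.canonical_name
                checked += 1
    assert checked >= 30
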