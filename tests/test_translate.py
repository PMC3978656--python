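"""Punnett enumeration and drug-specific phenotype assignment."""

import itertools

import pytest

from pgxkit.model import PkpdLabel
from pgxkit.translate import (
    assign_phenotype,
    build_full_punnett,
    enumerate_diplotypes,
    extrapolate_allele,
)


@pytest.mark.parametrize(
    "alleles, expected_count",
    [(["*1", "*2", "*17"], 6), (["*1"], 1), (["*1", "*2", "*3", "*4", "*5"], 15)],
)
def test_enumeration_counts(kb, alleles, expected_count):
    gene = "CYP2D6" if len(alleles) == 5 else "CYP2C19"
    diplotypes = enumerate_diplotypes(kb, gene, alleles)
    assert len(diplotypes) == expected_count == len(alleles) * (len(alleles) + 1) // 2
    # brute-force double loop over ordered pairs folds to the same set
    brute = {
        kb.diplotype(gene, a, b).canonical_name
        for a in alleles
        for b in alleles
    }
    assert {d.canonical_name for d in diplotypes} == brute


def test_enumeration_rejects_empty_allele_set(kb):
    with pytest.raises(ValueError):
        enumerate_diplotypes(kb, "CYP2C19", [])


def test_extrapolation_follows_similarity_links(kb):
    assert extrapolate_allele(kb, "CYP2C19", "*6") == "*2"
    assert extrapolate_allele(kb, "CYP2C19", "*1") == "*1"


def test_extrapolation_is_transitive_over_chains(kb_dir_copy):
    from pgxkit import load_knowledge_base

    with open(kb_dir_copy / "alleles.tsv", "a") as fh:
        fh.write("CYP2C19\t*90\tnone\t\t*91\nCYP2C19\t*91\tnone\t\t*2\n")
    kb2 = load_knowledge_base(kb_dir_copy)
    assert extrapolate_allele(kb2, "CYP2C19", "*90") == "*2"


def test_poor_metabolizer_lookup_for_clopidogrel(kb):
    a = assign_phenotype(kb, kb.diplotype("CYP2C19", "*2", "*2"), "clopidogrel")
    assert a.pkpd_label is PkpdLabel.PM
    assert "greatly reduced or abolished enzymatic function" in a.clinical_text
    assert a.provenance == "explicit_lookup"


def test_same_diplotype_diverges_between_drugs(kb):
    d = kb.diplotype("CYP2C19", "*1", "*17")
    clop = assign_phenotype(kb, d, "clopidogrel")
    ppi = assign_phenotype(kb, d, "PPIs")
    assert clop.pkpd_label is PkpdLabel.UM
    assert ppi.pkpd_label is PkpdLabel.UNKNOWN


def test_rare_allele_resolves_by_similarity_substitution(kb):
    a = assign_phenotype(kb, kb.diplotype("CYP2C19", "*1", "*6"), "clopidogrel")
    assert a.pkpd_label is PkpdLabel.IM
    assert a.provenance == "similarity_extrapolated"
    # ... and matches the substituted diplotype's assignment exactly
    sub = assign_phenotype(kb, kb.diplotype("CYP2C19", "*1", "*2"), "clopidogrel")
    assert (a.pkpd_label, a.category_id, a.clinical_text) == (
        sub.pkpd_label, sub.category_id, sub.clinical_text,
    )


def test_highest_function_allele_policy_for_codeine(kb):
    explicit = assign_phenotype(kb, kb.diplotype("CYP2D6", "*1", "*4"), "codeine")
    assert explicit.pkpd_label is PkpdLabel.EM and explicit.provenance == "explicit_lookup"
    derived = assign_phenotype(kb, kb.diplotype("CYP2D6", "*1", "*41"), "codeine")
    assert derived.pkpd_label is PkpdLabel.EM and derived.provenance == "policy_derived"
    dup = assign_phenotype(kb, kb.diplotype("CYP2D6", "*1x2", "*41"), "codeine")
    assert dup.pkpd_label is PkpdLabel.UM  # duplication counts as increased function


def test_missing_table_raises_naming_the_pair(kb):
    with pytest.raises(KeyError, match="clopidogrel.*CYP2D6"):
        assign_phenotype(kb, kb.diplotype("CYP2D6", "*1", "*1"), "clopidogrel")


def test_full_punnett_covers_all_cells(kb):
    pt = build_full_punnett(kb, "clopidogrel", "CYP2C19", ["*1", "*2", "*17"])
    assert len(pt.cells) == 6
    assert pt.cells["CYP2C19*2/*17"].pkpd_label is PkpdLabel.UNKNOWN
    assert pt.unknown_cells() == ["CYP2C19*2/*17"]

    for drug, gene in [("clopidogrel", "CYP2C19"), ("codeine", "CYP2D6"), ("warfarin", "VKORC1")]:
        n = len(kb.gene_alleles(gene))
        pt = build_full_punnett(kb, drug, gene)
        assert len(pt.cells) == n * (n + 1) // 2
        assert all(a is not None for a in pt.cells.values())


def test_single_allele_gene_yields_reference_homozygote_cell(kb):
    pt = build_full_punnett(kb, "warfarin", "VKORC1", ["G"])
    assert list(pt.cells) == ["VKORC1 G/G"]
    assert pt.cells["VKORC1 G/G"].category_id == "GG"


def test_codeine_punnett_matches_published_memberships(kb):
    pt = build_full_punnett(kb, "codeine", "CYP2D6", ["*1", "*4", "*41"])
    got = {name: a.pkpd_label.value for name, a in pt.cells.items()}
    assert got == {
        "CYP2D6*1/*1": "EM",
        "CYP2D6*1/*4": "EM",
        "CYP2D6*1/*41": "EM",  # not printed; derived from the highest-function rule
        "CYP2D6*4/*4": "PM",
        "CYP2D6*4/*41": "IM",
        "CYP2D6*41/*41": "IM",
    }
    assert pt.cells["CYP2D6*1/*41"].provenance == "policy_derived"


def test_assignment_is_symmetric_in_allele_order(kb):
    alleles = list(kb.gene_alleles("CYP2C19"))
    for a, b in itertools.combinations(alleles, 2):
        ab = assign_phenotype(kb, kb.diplotype("CYP2C19", a, b), "PPIs")
        ba = assign_phenotype(kb, kb.diplotype("CYP2C19", b, a), "PPIs")
        assert ab == ba
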