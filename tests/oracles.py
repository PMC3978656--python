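"""Independent oracles used by the test suite.

These re-derive expected results by brute force or by a literal transcription
of the published grading grid, independently of the library code paths they
check.
"""

from collections import Counter
from itertools import combinations_with_replacement

# ---------------------------------------------------------------------------
# Evidence grading oracle: the 14-row grid as an ordered rule list
# (first matching rule wins). Axes: study category, drug target, finding,
# qualifier presence, privateness.
# ---------------------------------------------------------------------------

_ANY = object()

# (category, target, finding, qualified, private) -> rank; None matches anything
_RULES = [
    # absence of effect trumps everything
    ((_ANY, _ANY, "no_effect", _ANY, _ANY), 14),
    ((_ANY, _ANY, "ld_attributed", _ANY, _ANY), 14),
    # private mutations
    ((_ANY, _ANY, _ANY, _ANY, True), 12),
    # screening-only / insufficient data
    (("screening", _ANY, _ANY, _ANY, _ANY), 13),
    ((_ANY, _ANY, "insufficient", _ANY, _ANY), 13),
    # inconclusive rows by study category
    (("clinical_outcomes", _ANY, "inconsistent", _ANY, _ANY), 9),
    (("pk_pd", _ANY, "inconsistent", _ANY, _ANY), 10),
    (("molecular_cellular", _ANY, "inconsistent", _ANY, _ANY), 11),
    (("clinical_outcomes", _ANY, "effect_on_other_only", _ANY, _ANY), 9),
    (("pk_pd", _ANY, "effect_on_other_only", _ANY, _ANY), 10),
    (("molecular_cellular", _ANY, "effect_on_other_only", _ANY, _ANY), 11),
    # consistent direct evidence
    (("clinical_outcomes", "drug_of_interest", "consistent_effect", _ANY, _ANY), 1),
    (("pk_pd", "drug_of_interest", "consistent_effect", _ANY, _ANY), 2),
    (("molecular_cellular", "drug_of_interest", "consistent_effect", _ANY, _ANY), 3),
    # probe drug (only molecular/cellular has probe rows)
    (("molecular_cellular", "probe_drug", "consistent_effect", True, _ANY), 4),
    (("molecular_cellular", "probe_drug", "consistent_effect", False, _ANY), 8),
    # probe drug in other study types behaves like another drug
    (("clinical_outcomes", "probe_drug", "consistent_effect", True, _ANY), 5),
    (("pk_pd", "probe_drug", "consistent_effect", True, _ANY), 6),
    (("clinical_outcomes", "probe_drug", "consistent_effect", False, _ANY), 9),
    (("pk_pd", "probe_drug", "consistent_effect", False, _ANY), 10),
    # another drug with / without mutation-type analysis
    (("clinical_outcomes", "other_drug", "consistent_effect", True, _ANY), 5),
    (("pk_pd", "other_drug", "consistent_effect", True, _ANY), 6),
    (("molecular_cellular", "other_drug", "consistent_effect", True, _ANY), 7),
    (("clinical_outcomes", "other_drug", "consistent_effect", False, _ANY), 9),
    (("pk_pd", "other_drug", "consistent_effect", False, _ANY), 10),
    (("molecular_cellular", "other_drug", "consistent_effect", False, _ANY), 11),
]


def evidence_rank_oracle(category, target, finding, qualified, private):
    probe = (category, target, finding, qualified, private)
    for pattern, rank in _RULES:
        if all(p is _ANY or p == v for p, v in zip(pattern, probe)):
            return rank
    raise AssertionError(f"oracle has no rule for {probe}")


# ---------------------------------------------------------------------------
# Brute-force diploid candidate search (no copy-number expansion)
# ---------------------------------------------------------------------------


def brute_force_candidates(kb, gene, observed):
    """All unordered allele pairs whose combined states reproduce the
    observed genotype at every observed site (diploid only)."""
    names = sorted(kb.gene_alleles(gene))
    panel = kb.variants[gene]
    hits = []
    for a, b in combinations_with_replacement(names, 2):
        ok = True
        for rsid, obs in observed.items():
            expected = []
            for allele_name in (a, b):
                defn = kb.allele(gene, allele_name).defining_variants
                expected.append(defn.get(rsid, panel[rsid].ref_state))
            if Counter(expected) != Counter(obs):
                ok = False
                break
        if ok:
            hits.append(kb.diplotype(gene, a, b).canonical_name)
    return sorted(hits)
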