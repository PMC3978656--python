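# pgxkit

Drug-centric pharmacogenomic (PGx) interpretation: from published evidence
about a drug-gene variant to a participant-facing risk report.

Clinical adoption of PGx testing needs a reproducible path from the
literature to a diagnostic interpretation. `pgxkit` implements that path as
a reusable engine for the people who build and audit such pipelines —
PGx curators, clinical bioinformaticians, and researchers studying how
genotype-to-phenotype translation rules behave at cohort scale:

1. **Evidence grading.** Every published observation about a variant and a
   drug is graded on a 14-rank ordinal scale: rank 1 is consistent clinical
   outcomes data for the drug under review; ranks 2–3 are consistent PK/PD
   or in-vitro data for that drug; ranks 4–7 are indirect evidence (probe
   substrate or another drug) rescued by a mutation-type qualifier from a
   six-label vocabulary (n, scd, se, ae, ad, dp); ranks 8–13 are
   inconclusive; rank 14 is demonstrated absence of effect. A variant's
   grade is the minimum rank over its records; grades ≤ 7 mark a defined
   effect, ≥ 8 flag a gap in knowledge. Ranks map onto four relevance tiers
   (clinically relevant / potentially relevant / unknown / unsupported).
2. **Diplotype translation.** For each drug-gene pair, a Punnett square
   over the gene's star alleles assigns every unordered diplotype *a*/*b* a
   PK/PD phenotype (EM/IM/PM/UM for metabolizing enzymes, transport levels
   for transporters) by explicit table lookup, then similarity
   extrapolation for rare alleles (CYP2C19\*6 is interpreted like \*2),
   then — where a table opts in — the highest-functioning-allele rule. The
   same diplotype can differ by drug: CYP2C19\*1/\*17 is an ultra-rapid
   metabolizer for clopidogrel but has unknown status for proton pump
   inhibitors.
3. **Star-allele calling.** Unphased rsID-keyed genotypes (TSV or minimal
   VCF) are matched exhaustively against allele definitions; phase
   ambiguity (e.g. \*2 and \*17 heterozygous in trans vs a cis haplotype)
   and whole-gene copy number are surfaced explicitly, and discordant
   candidates always yield an *unknown* phenotype, never a guess.
4. **Population frequencies.** Under Hardy–Weinberg equilibrium, allele
   frequencies *p* imply diplotype frequencies *p²* and *2pq*; folding them
   through a translation table gives expected phenotype-category
   percentages per ancestry group (Caucasian, African, East Asian).
5. **Risk reports.** Per sample, drug and gene: the call, interpretation,
   FDA guideline text, ancestry-matched expected frequency, and a
   high/standard actionability level. Only drugs with an approved advisory
   outcome are reportable.

The package ships a machine-readable knowledge base (plain TSV + JSON
export) covering seven approved drugs/drug classes and nine pharmacogenes:
clopidogrel (CYP2C19), warfarin (CYP2C9, VKORC1, CYP4F2), proton pump
inhibitors (CYP2C19), codeine (CYP2D6), thiopurines (TPMT), simvastatin
(SLCO1B1) and celecoxib (CYP2C9), with each category's published expected
population frequencies stored at printed precision (`<x` entries are kept
as upper bounds). Most defining-variant rsIDs in the packaged KB are
synthetic stand-ins (`rsV2`, `rsD4`, …); see `docs/methods.md`.

## Worked example

Simulate a small cohort under HWE, call diplotypes, and build a report:

```sh
$ pgxkit --seed 5 simulate --gene CYP2C19 --n 3 --out geno.tsv
$ pgxkit interpret --genotypes geno.tsv --drug clopidogrel
sample_id  gene     status    diplotype       candidates      phenotype
S00001     CYP2C19  resolved  CYP2C19*17/*17  CYP2C19*17/*17  UM
S00002     CYP2C19  resolved  CYP2C19*1/*1    CYP2C19*1/*1    EM
S00003     CYP2C19  resolved  CYP2C19*1/*1    CYP2C19*1/*1    EM
```

Sample S00001 is homozygous for the gain-of-function \*17 allele, an
ultra-rapid metabolizer (UM) with respect to clopidogrel. Its report
(`pgxkit report --genotypes geno.tsv --drug clopidogrel --ancestry
Caucasian`) states the expected frequency of this category — 34.0% of
individuals of Caucasian ancestry share the UM category for clopidogrel —
and a *standard* actionability level (only poor metabolizers are highly
actionable for clopidogrel).

The full translation logic is visible in the Punnett square:

```sh
$ pgxkit punnett --drug clopidogrel --gene CYP2C19
diplotype      pkpd_label  category_id  provenance
CYP2C19*1/*1   EM          EM           explicit_lookup
CYP2C19*1/*17  UM          UM           explicit_lookup
CYP2C19*1/*2   IM          IM           explicit_lookup
CYP2C19*1/*6   IM          IM           similarity_extrapolated
CYP2C19*2/*17  unknown     UNK          unknown
...
```

`*1/*6` has no published row of its own; it resolves through the \*6 → \*2
similarity link to the intermediate-metabolizer category. `*2/*17` is a
published category whose metabolizer status is undetermined — a flagged gap
in knowledge.

Other subcommands: `validate-kb` (data invariants: per-ancestry frequency
sums within 100 ± 1, disjoint category memberships, acyclic similarity
links), `score-evidence`, `frequencies`, and `report`; `--kb DIR` swaps in
an external knowledge base with the same layout.

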