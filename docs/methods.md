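# Methods

This note documents the models and procedures implemented by `pgxkit`, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## The evidence decision table

A single published observation is characterized by five axes: study
category (clinical outcomes ≻ PK/PD ≻ molecular/cellular ≻ screening),
drug target (the drug under review, a probe substrate, or another drug),
finding (consistent effect, inconsistent, effect on another drug only, no
effect, LD-attributed, insufficient), presence of a mutation-type
qualifier, and whether the variant is private. `assign_evidence_code` maps
every combination to exactly one rank 1–14; totality is enforced by an
exhaustive cross-product test against an independently written rule table.

Ordering decisions the source material leaves open, fixed here for
determinism:

* **Precedence** among overriding findings: demonstrated no-effect or
  LD-attribution (rank 14) beats privateness (12), which beats
  screening-only/insufficient (13), which beats everything else.
* **Insufficient data outside screening studies** has no published row; it
  is mapped to rank 13 (insufficient data) so the table stays total.
* **Probe-drug observations outside molecular/cellular studies** have no
  row either; they are treated as other-drug observations with a logged
  warning.
* **Ranks 4–7 without a qualifier are unconstructible** (`EvidenceCode`
  enforces qualifiers exactly for those ranks); an unqualified probe or
  other-drug observation lands at 8–11 instead.
* The defined-effect boundary is **rank ≤ 7** (the source states the
  boundary inconsistently in places; the convention adopted is ≤ 7 defined
  effect, ≥ 8 gap flag).

Per-variant aggregation takes the minimum rank (monotone: more evidence
never weakens a grade), merging qualifier sets on ties. When the
sample-size-weighted share of consistent findings among a variant's
drug-of-interest records falls below a threshold (default 0.75,
configurable — the source says only that evidence "may be weighted in favor
of larger studies"), direct-evidence ranks 1–3 are downgraded to the
inconclusive rows 9–11 before aggregation.

The six mutation-type labels (n, scd, se, ae, ad, dp) are treated as an
opaque controlled vocabulary: their published definitions are not available
in the transcribed material, so `MUTATION_TYPE_DESCRIPTIONS` carries
editable one-line glosses and nothing in the engine depends on their
semantics.

## Diplotype translation

Resolution order: explicit category membership → membership after
transitive similarity substitution (acyclicity checked at KB load) →
highest-functioning-allele policy (only for tables that opt in) → unknown.
Lookup-first matters: for CYP2C19 the published \*1/\*2 → IM assignment
contradicts a highest-allele rule, so CYP2C19 tables are pure lookup, while
the codeine–CYP2D6 table opts into the policy with the function ordering
increased ≻ normal ≻ reduced ≻ none. Whole-gene duplications of a
normal-or-better allele count as increased function, which places
duplication genotypes in the UM category. An activity-score alternative
(summing per-allele activity values) is implemented (`activity_score`) but
not enabled for any packaged table. Whether CYP2D6 \*1/\*41 is EM or IM is
not printed; it resolves via the policy to EM and is flagged
`provenance=policy_derived`.

Canonical diplotype names sort the reference allele first, then star
alleles by numeric value (suffix lexicographic), then plain names, with
copy-number suffixes (`x2`) last; concrete multipliers normalize to `xN`
for matching against printed duplication categories. A category whose
PK/PD label is unknown is reported with `provenance="unknown"` even when
the diplotype is explicitly listed, so "unknown" always means exactly one
thing downstream.

## Star-allele calling

The matcher does an exhaustive search over unordered allele pairs; a pair
is a candidate iff the multiset union of its haplotype states reproduces
the observed unphased genotype at every assayed site. Numerical/degenerate
choices:

* Unassayed panel sites are reference-compatible (arrays type a fixed
  panel); each call carries an "untyped sites" warning listing them.
* Phase is never inferred statistically. A double heterozygote with a
  defined cis haplotype allele yields two candidates; with no cis allele
  defined, the single trans candidate carries an explicit trans-assumption
  note. Discordant candidates always produce an unknown phenotype.
* Copy number is whole-gene only. With n > 2 gene copies, allele doses
  summing to n are enumerated, and the biallelic array call is compared as
  a state *set* (dosage beyond two haplotype classes is not observable on
  the assumed platform). When several dose splits of the same allele pair
  fit, the duplication is assigned to the higher-function allele, with a
  warning — total copy number alone cannot distinguish, e.g., \*1x2/\*4
  from \*1/\*4x2.

## Population frequencies

Hardy–Weinberg equilibrium (random mating, no inbreeding or structure,
autosomal) is the frequency model: category percent = 100 × Σ member
diplotype fractions, conserving mass exactly. The packaged tables store
the *printed* expected population frequencies, whose derivation (HWE vs
observed cohort counts) is not stated in the source; computed-vs-printed
comparisons are therefore exposed as a reconciliation/deviation table
(`reconcile_with_printed`), not asserted equal. Printed `<x` entries are
stored as upper bounds and contribute 0 to sum checks (tolerance [99,
101]). Percents are reported at printed precision (one decimal, two where
the table prints 0.04).

## The packaged knowledge base

Genes, alleles, outcomes, and the nine drug-gene translation tables are
transcribed from the published interpretation tables at printed precision.
Two caveats:

* **Defining variants are synthetic stand-ins.** The published per-allele
  SNP definitions live in supplementary material not reproduced here, so
  the packaged `variants.tsv`/`allele_variants.tsv` use clearly synthetic
  rsIDs (`rsV2`, `rsD4`, `rsT460`, …) and simplified single-nucleotide
  changes (including for alleles that are really deletions, such as
  CYP2D6\*5). The only real rsID is rs9923231 (VKORC1 −1639G>A), which the
  main text prints. Calls against real genotype data require replacing
  these definitions; the engine itself is agnostic.
* **Illustrative evidence rows.** `evidence.tsv` ships a small set of
  records consistent with main-text statements (e.g. clinical evidence for
  CYP2C9\*3–celecoxib, case-report-level codeine UM data); the per-variant
  evidence tables are supplementary-only. Full 14-rank coverage for
  testing comes from `evidence_fixture_set`.
* The per-variant ancestry frequencies in `variants.tsv` are realistic
  defaults chosen once for simulation, not published values.

Table 2's cross-gene warfarin actionable result ("low warfarin dose
requirement") is attached to the CYP2C9 PM and VKORC1 AA categories
individually — an approximation, since the engine reports per-gene.
Per-status rows split multi-gene outcome lines so approved drugs (7) and
approved drug-gene slots (9) can be counted directly.

## Synthetic cohorts

`sample_cohort` draws two independent alleles per individual from a stated
frequency set — exactly the HWE model used analytically, with no linkage
disequilibrium, genotyping error, no-calls, or admixture. Passing
end-to-end tests therefore establishes internal consistency of
sample → decompose → match → call → translate (binomial 3-SE agreement at
n = 20 000, seed fixed at 42 by default), not robustness to real array
data. Problem sizes used in tests and the acceptance script (cohorts of
4 000–20 000; full enumeration of the 288-combination evidence input
space) are desk-scale and run in seconds.

## Known limitations

* No statistical phasing, novel-allele discovery, or structural-variant
  breakpoints; CNV is whole-gene.
* No combined multi-gene warfarin dose table (supplementary-only); warfarin
  reports concatenate per-gene interpretations.
* Ancestry is a report input, never inferred.
* X-linked/mitochondrial inheritance and population-structure corrections
  are out of scope for the HWE module.
* The knowledge base is a snapshot; there is no versioned migration
  machinery beyond the `version` field.
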