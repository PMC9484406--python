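# Methods

This note documents the models, rules and numerical choices behind
`eoadtriage`, and what the synthetic validation does and does not show.

## Cohort model

A patient carries an ID, sex, integer age at onset, a modified Goldman
family-history score, an APOE genotype and optionally a CSF biomarker
profile.

**Goldman score.** The modified scale grades familial aggregation of
dementia: S1 — at least three affected in two generations, one a
first-degree relative of the other two, with early onset; S1.5 — as S1
with late-onset disease; S2 — at least three affected relatives without a
clear autosomal-dominant pattern; S3 — a single affected first- or
second-degree relative with early onset; S3.5 — as S3 with late onset.
S1/S1.5 map to *strong* family history, S2/S3/S3.5 to *moderate*, no score
to *sporadic*. The raw score is stored and the strength always derived,
never stored, so the two cannot diverge.

**CSF profile.** The AD biomarker profile requires p-tau/Aβ42 > 0.108 and
Aβ42/Aβ40 < 0.68, both strict, so boundary values fail; a missing ratio
yields an *indeterminate* outcome distinct from a negative one. The
cutoffs are study-specific inclusion thresholds, kept as module constants.

**APOE.** ε alleles are haplotypes of rs429358/rs7412:
T-C → ε3, T-T → ε2, C-C → ε4, C-T → ε1. With unphased genotypes the
doubly heterozygous case cannot be resolved (ε2/ε4 vs ε1/ε3); the ε2/ε4
reading is returned — ε1 is vanishingly rare — with an explicit
`phase_ambiguous` flag, never silently. Genotypes are unordered pairs
(ε2/ε4 ≡ ε4/ε2). Cohort counting partitions patients into ε4/ε4, single-ε4,
other, and an explicit *unknown* bucket that is reported, not dropped.

**Onset bound.** The early-onset inclusion bound (< 65 years) is a
parameter of cohort validation, not a hard-coded invariant, since it is an
eligibility criterion rather than a property of the data model.

## Selection filters

Calls are kept when they pass, in this order: (1) inside a target region
expanded by `flank_bp` = 7; (2) depth ≥ `min_depth` = 10 reads; (3) for
heterozygous calls only, allelic balance alt/(ref+alt) within
[`ab_min`, `ab_max`] = [0.30, 0.70] — homozygous and hemizygous calls are
exempt; (4) reference-population allele frequency < `max_maf` = 1%, where
a variant absent from the reference counts as frequency 0 and passes.
The first failing criterion becomes the call's reason code, so reasons are
deterministic; calls with missing depth/AD fields are rejected as
`missing_quality` (configurable to keep). The balance bounds are
inclusive: printed one-decimal bounds are taken to include themselves, and
the tests pin behaviour at exactly 0.30 and 0.70.

Filtering is idempotent and order-independent (property-tested).
Internally coordinates are 0-based half-open; VCF stays 1-based and
conversion happens only at I/O boundaries. Region files use BED
convention, stated in their header line. Multi-allelic records are
decomposed per alt allele per carrier; allele pairs are parsimony-trimmed
(shared suffix then prefix). Full left-alignment against a reference
sequence is not performed: panel VCFs are caller-normalised upstream, and
the synthetic data use SNVs only.

Genotype-level FORMAT/DP is preferred, with site INFO/DP as fallback;
missing AD/DP stay missing rather than becoming zeros.

## Annotation

Knowledge tables are keyed by (gene, HGVS c.) because published variant
tables print HGVS, not coordinates; VCF-derived calls are bridged through
an explicit coordinate→HGVS mapping file. Gene panels are pairwise
disjoint and validated at load (the causative panel is exactly
{APP, PSEN1, PSEN2}). "Conflicting interpretations" is a first-class
ClinVar state carrying its vote multiset — the decision tree treats
conflicting-with-pathogenic-votes differently from plain VUS. A variant is
*novel* (never reported) iff absent from both ClinVar and HGMD. Reference
population counts are stored as printed ("alt/total"); a not-reported
population is propagated as missing and never imputed to zero at
annotation time — rarity imputation happens only inside the filter, and
testability handling only inside the statistics.

HGMD phenotype strings are interpreted structurally: a phenotype ending in
"?" is a questioned report; one containing "increased risk" is a risk
annotation rather than a disease-causing record; anything else is
disease-causing. Literature flags (`PTV`, `PRIOR_AD_REPORT`,
`QUESTIONABLE_PATHOGENICITY`) capture prior-publication evidence that the
database columns alone do not encode; they are part of the curated input,
not derived.

The GWAS susceptibility panel ships with the 17 genes in which rare
variants were tabulated plus 17 further canonical AD GWAS loci genes to
reach the 34 analysed; the remainder is marked user-overridable in
`panels.yaml`.

## Consensus prediction of never-reported variants

Missense variants are voted on by four tools (PolyPhen-2, M-CAP, CADD,
MutationTaster): likely pathogenic iff ≥ 3 call damage. Splice-region
variants use NetGene2/MaxEntScan/HSF and silent variants
MutationTaster/CADD/FATHMM-XF; for these three-tool classes the package
uses a simple majority (≥ 2 of 3) — only the four-tool threshold is fixed
by convention, so the three-tool threshold is a configurable design choice.
`NO_CALL` counts as not-damaging (conservative toward benignity;
configurable). Two positional rules precede voting: a never-reported APP
variant outside exons 16/17 (the Aβ-encoding region) is likely benign
regardless of votes, and a never-reported protein-truncating variant is
presumed damaging (configurable). The module consumes verdict labels, not
raw scores; score thresholding is the verdict provider's responsibility.
The classifier is deterministic, order-independent in its verdict list,
and monotone in damaging votes (property-tested over all 2⁴ patterns).

## Enrichment statistics

Each testable variant yields a 2×2 allele table: cohort alt count (HET and
HEMI carriers contribute 1 allele, HOM_ALT 2) over a denominator of
2 alleles per genotyped patient minus 1 per hemizygous carrier, against the
reference alt/total counts. Panel sequencing is assumed complete
(every patient genotyped at every site); per-site denominators can be
supplied to relax this.

The two-sided Fisher p-value follows the minimum-likelihood convention
(shared by R and SciPy): sum of hypergeometric point probabilities not
exceeding the observed one, with 1e-7 relative tolerance on the
comparison. Degenerate tables (no alt anywhere) return 1. The
implementation delegates to `scipy.stats.fisher_exact` and is verified
against an independent full-enumeration oracle on every table with row
margins ≤ 30.

BH adjustment (`statsmodels`, verified against a hand-coded step-up
oracle) is applied per *family*, defined as one results table — the five
fixture tables each form a family; in bundle mode each gene panel does.
Every result records its family size. Variants absent from the reference
are excluded from the family entirely rather than tested against 0/total:
testing against a zero count would manufacture significance from absence
of evidence.

The printed adjusted p-values of the source tables are not recoverable
from the printed counts under any standard 2×2 construction (the cohort
denominators and family sizes were not published); the statistics are
therefore validated against enumeration oracles, not against printed p
columns. Notably, the contributor-of-disease call that depends on
enrichment still reproduces with the package's own counts.

## Clinical decision tree

Rules fire in a fixed order; the first match wins and every decision
records its rule path:

1. **Diagnostic** — causative gene and: ClinVar pathogenic/likely
   pathogenic; or ClinVar-absent with an HGMD disease-causing record; or
   conflicting ClinVar submissions including ≥ 1 pathogenic vote
   (threshold configurable) together with an HGMD disease record.
2. **Diagnostic (novel)** — never-reported causative-gene variant with a
   likely-pathogenic consensus.
3. **Contributor / risk factor** — uncertain alleles in causative or
   AD-risk genes (ClinVar VUS; conflicting without pathogenic votes;
   questioned HGMD record without a ClinVar class; benign-classed variants
   carrying an increased-risk HGMD annotation or a prior-literature flag):
   *contributor of disease* when at least one carrier is familial **and**
   the BH-adjusted p < 0.05, else *risk factor*. Both conditions are
   required conjunctively. Novel AD-risk-gene variants with a
   likely-pathogenic consensus, or with a prior-AD-report flag, are risk
   factors.
4. **Weak risk** — pathogenic/likely pathogenic/uncertain alleles (known
   or by consensus) in genes causative for other dementias.
5. **Benign / likely benign** — ClinVar benign or likely benign without
   contrary evidence; novel variants with a benign consensus.
6. **Unclassified** — everything else (e.g. GWAS-panel variants without
   usable evidence).

The printed benign-vs-likely-benign wording in the source tables is not
internally consistent (ClinVar-"Benign" rows appear under both labels);
the tree derives the benign side deterministically from the ClinVar class
or consensus, and validation treats benign/likely-benign as one
equivalence class. All non-benign labels reproduce exactly.

**Patient explanation** unions four sources: a *causative* allele
(diagnostic or contributor in a causative gene), APOE ε4/ε4, a
*moderate-risk* allele (risk factor in APP/PSEN1/PSEN2/TREM2), and a
*weak-risk* allele in a non-AD dementia gene (whether weak risk alone
explains a case is configurable; default yes). Percentages are rounded to
two decimals half-up, matching clinical-report convention, and are always
recomputed from counts.

## Packaged fixtures

The five TSVs under `data/tables` transcribe the published variant tables
of a 102-patient EOAD panel study. Two inputs the tables do not print are
completed synthetically and deterministically, and say so in their
docstrings: (1) `fixture_cohort()` builds the 102 patients around the
printed carriers so the published marginals hold exactly (46 familial with
10 strong, APOE 8 ε4/ε4 + 30 ε3/ε4 + 2 ε2/ε4 with the homozygotes free of
causative variants, 49 males; filler onset ages below the bound);
(2) `fixture_verdicts()` synthesises per-tool verdict sets realising each
printed consensus call. Consequently cohort-level quantities that depend
on the *joint* distribution of unprinted per-patient fields (e.g. which
individual patients are APOE ε4/ε4) are reconstruction-dependent and are
not asserted; counts and percentages that depend only on printed data
reproduce exactly.

## Synthetic cohort generator

Defaults mirror the study cohort: n = 102, familial fraction 46/102 with
strong history in 10/46, onset 56.88 ± 5.84 years, category fractions
equal to the published per-category carrier fractions (diagnostic 9/102,
contributor 2/102, risk factor 8/102, weak risk 13/102, APOE ε4/ε4 8/102),
mean depth 80×, allele-balance noise SD 0.06, reference population of
129,100 alleles.

Each patient draws one latent category and receives evidence that
*deterministically* yields it: diagnostic — a unique ClinVar-pathogenic
PSEN1 variant; contributor — one shared PSEN2 VUS absent from the
reference sample (0/129,100), so even a single familial carrier tests
enriched (p ≈ 0.0016 in a causative-gene family of one testable variant);
risk factor — a unique TREM2 VUS at 100/129,100, whose single-carrier p
(≈ 0.15) can never clear 0.05 after adjustment; weak risk — a unique DCTN1
VUS; APOE ε4/ε4 — homozygous rs429358-C with no qualifying variant.
Contributor patients are forced familial (a sporadic-only scenario with a
nonzero contributor fraction is rejected as infeasible) and the familial
probability of the remaining patients is adjusted so the overall familial
fraction is preserved in expectation. Four decoy calls violate exactly one
filter criterion each (off-target, 9×, allelic balance drawn in
(0.05, 0.25), 5% reference frequency) and carry their expected rejection
reason in the truth file.

Ages are drawn from a normal truncated to [30, 65) whose *location* is
solved (Brent's method) so the truncated mean equals the configured mean —
naive truncation at the early-onset bound would bias the sample mean
downward by about a quarter of a year. Depths are Poisson with a floor at
the depth threshold for clean calls; heterozygous allele balances are
normal around 0.5, clipped into the filter window, with the rounded read
counts re-clamped so integer arithmetic cannot push a clean call outside
the window. One `numpy` Generator seeded from the single scenario seed
drives all randomness; the same seed yields a byte-identical bundle.

Because recovery is deterministic by construction, passing the end-to-end
tests shows that the pipeline implements its own rules exactly — it does
not show robustness to evidence configurations the generator never emits
(conflicting multi-variant carriers, hemizygous calls, genotyping dropout,
population stratification).

## Validation experiment sizes

The test suite enumerates all 2×2 tables with row margins ≤ 30 (one
representative per row-swap orbit) against the Fisher oracle, checks BH on
10,000 random p-vectors, runs 1,000 random decoy cohorts through the
filters, and verifies exact truth recovery plus a pooled binomial check of
recovered category fractions over 200 synthetic cohorts of 102 patients
(seeds 0–199; the six simultaneous category comparisons use a
Bonferroni-corrected family-wise 95% interval). These sizes keep the whole
suite within a few minutes on one CPU.

## Known limitations

- The decision tree covers the evidence patterns occurring in the packaged
  tables and generator; rarer combinations (e.g. ClinVar pathogenic with a
  contradicting HGMD entry) fall through to the closest rule rather than a
  bespoke one.
- Indel left-alignment requires caller-normalised input.
- CSF eligibility is modelled but not exercised by the fixtures (the
  published tables contain only already-eligible patients).
- The enrichment model assumes complete genotyping of the panel in every
  patient unless per-site denominators are supplied.
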