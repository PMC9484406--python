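"""Clinical classification of annotated variants and cohort aggregation.

The decision tree maps each annotated variant to one clinical category, in
a fixed rule order (first match wins):

1. *Diagnostic*: in an AD-causative gene (APP/PSEN1/PSEN2), a variant that
   is pathogenic or likely pathogenic in ClinVar, listed as disease-causing
   in HGMD, or with conflicting ClinVar submissions that include at least
   one pathogenic/likely-pathogenic vote alongside an HGMD disease record.
2. *Diagnostic* (novel): a never-reported causative-gene variant whose
   in-silico consensus is likely pathogenic.
3. Uncertain variants in causative or AD-risk genes (TREM2/ABCA7/SORL1) —
   ClinVar VUS, conflicting submissions without a pathogenic vote, a
   questioned HGMD record, or a benign-classed variant carrying a
   prior-AD-risk or questioned-pathogenicity literature flag: *contributor
   of disease* when at least one carrier is familial AND the variant is
   enriched versus the reference population (BH-adjusted p < 0.05),
   otherwise a *risk factor*.  Novel AD-risk-gene variants with a
   likely-pathogenic consensus are risk factors.
4. *Weak risk*: pathogenic / likely pathogenic / uncertain variants (known
   or by consensus) in genes causative for other dementias (ALS/FTD
   spectrum and related).
5. *Benign* / *likely benign*: ClinVar benign or likely benign without
   contrary evidence, and novel variants with a benign consensus.
6. Everything else (e.g. GWAS-panel variants with no usable evidence) is
   left unclassified.

Patient-level aggregation mirrors the explained-case summary: a patient is
explained by a causative allele (diagnostic or contributor in a causative
gene), APOE e4 homozygosity, a moderate-risk allele (risk factor in
APP/PSEN1/PSEN2/TREM2), or a weak-risk allele in a non-AD dementia gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Optional, Sequence

from .annotation import AnnotatedVariant, ClinvarClass, LiteratureFlag, PanelName
from .cohort import FamilyHistoryStrength, Patient
from .consensus import ConsensusLabel, ConsensusResult
from .stats import EnrichmentResult


class ClinicalCategory(Enum):
    DIAGNOSTIC = "diagnostic"
    CONTRIBUTOR = "contributor_of_disease"
    RISK_FACTOR = "risk_factor"
    WEAK_RISK = "weak_risk"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    UNCLASSIFIED = "unclassified"


#: categories on the benign side of the spectrum
BENIGN_SPECTRUM = frozenset({ClinicalCategory.BENIGN, ClinicalCategory.LIKELY_BENIGN})

#: genes whose not-strictly-pathogenic alleles count as moderate risk
MODERATE_RISK_GENES = frozenset({"APP", "PSEN1", "PSEN2", "TREM2"})


@dataclass(frozen=True)
class ClassificationConfig:
    #: BH-adjusted significance level for the contributor rule
    alpha: float = 0.05
    #: minimum pathogenic/likely-pathogenic ClinVar votes for a conflicting
    #: record to count as pathogenic when HGMD also lists disease
    conflicting_pathogenic_votes: int = 1
    #: whether a weak-risk allele alone can explain a patient
    weak_risk_explains: bool = True


@dataclass(frozen=True)
class ClassifiedVariant:
    annotated: AnnotatedVariant
    category: ClinicalCategory
    rationale: tuple[str, ...]
    consensus: Optional[ConsensusResult] = None
    enrichment: Optional[EnrichmentResult] = None

    @property
    def gene(self) -> str:
        return self.annotated.gene

    @property
    def key(self) -> tuple[str, str]:
        return self.annotated.key

    @property
    def carrier_ids(self) -> tuple[str, ...]:
        return self.annotated.carrier_ids


def _is_uncertainish(v: AnnotatedVariant) -> bool:
    """Variant with genuinely uncertain evidence, eligible for the
    risk-factor/contributor rule."""
    k = v.knowledge
    if k.clinvar_class is ClinvarClass.VUS:
        return True
    if k.clinvar_class is ClinvarClass.CONFLICTING and k.pathogenic_votes == 0:
        return True
    # a questioned HGMD disease report without a benign ClinVar consensus
    if (
        k.hgmd_questionable
        and k.clinvar_class is ClinvarClass.NOT_REPORTED
    ):
        return True
    # benign-classed but with prior literature casting doubt
    flags = {LiteratureFlag.PRIOR_AD_REPORT, LiteratureFlag.QUESTIONABLE_PATHOGENICITY}
    if k.literature_flags & flags:
        return True
    # ClinVar benign but HGMD annotates an increased-risk association
    if (
        k.clinvar_class in (ClinvarClass.BENIGN, ClinvarClass.LIKELY_BENIGN)
        and k.hgmd_risk_annotation
    ):
        return True
    return False


def classify_variant(
    annotated: AnnotatedVariant,
    consensus: Optional[ConsensusResult] = None,
    enrichment: Optional[EnrichmentResult] = None,
    carriers_fh: Optional[Sequence[FamilyHistoryStrength]] = None,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> ClassifiedVariant:
    """Apply the decision tree to one annotated variant.

    ``consensus`` is required for never-reported variants; ``enrichment``
    is the variant's test result or None when not testable; ``carriers_fh``
    gives the family-history strength of each carrier.
    """
    k = annotated.knowledge
    panel = annotated.panel
    rationale: list[str] = []

    if annotated.novel and consensus is None:
        raise ValueError(
            f"{k.gene} {k.hgvs_c}: never-reported variant requires a consensus result"
        )
    if carriers_fh is None:
        carriers_fh = []

    def out(category: ClinicalCategory) -> ClassifiedVariant:
        return ClassifiedVariant(
            annotated=annotated, category=category, rationale=tuple(rationale),
            consensus=consensus, enrichment=enrichment,
        )

    known_pathogenic = (
        k.clinvar_class in (ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC)
        or (k.clinvar_class is ClinvarClass.NOT_REPORTED and k.hgmd_disease_causing)
        or (
            k.clinvar_class is ClinvarClass.CONFLICTING
            and k.pathogenic_votes >= cfg.conflicting_pathogenic_votes
            and k.hgmd_disease_causing
        )
    )

    # (1)-(2): diagnostic alleles in causative genes
    if panel is PanelName.AD_CAUSATIVE:
        if known_pathogenic:
            rationale.append("causative_gene_known_pathogenic")
            return out(ClinicalCategory.DIAGNOSTIC)
        if annotated.novel and consensus.label is ConsensusLabel.LIKELY_PATHOGENIC:
            rationale.append("causative_gene_novel_consensus_pathogenic")
            return out(ClinicalCategory.DIAGNOSTIC)

    # (3): uncertain alleles in causative or AD-risk genes
    if panel in (PanelName.AD_CAUSATIVE, PanelName.AD_RISK):
        if not annotated.novel and _is_uncertainish(annotated):
            rationale.append("uncertain_in_ad_gene")
            familial = any(
                fh is not FamilyHistoryStrength.SPORADIC for fh in carriers_fh
            )
            if familial and enrichment is not None and enrichment.adj_p < cfg.alpha:
                rationale.append("familial_carrier_and_enriched")
                return out(ClinicalCategory.CONTRIBUTOR)
            rationale.append("not_enriched_or_sporadic")
            return out(ClinicalCategory.RISK_FACTOR)
        if annotated.novel:
            if LiteratureFlag.PRIOR_AD_REPORT in k.literature_flags:
                rationale.append("novel_with_prior_risk_report")
                return out(ClinicalCategory.RISK_FACTOR)
            if consensus.label is ConsensusLabel.LIKELY_PATHOGENIC:
                # only reachable for AD_RISK: causative novels returned above
                rationale.append("novel_consensus_pathogenic_in_risk_gene")
                return out(ClinicalCategory.RISK_FACTOR)
        if known_pathogenic and panel is PanelName.AD_RISK:
            rationale.append("known_pathogenic_in_risk_gene")
            return out(ClinicalCategory.RISK_FACTOR)

    # (4): weak risk in other-dementia genes
    if panel is PanelName.OTHER_DEMENTIA:
        uncertain_or_worse = (
            known_pathogenic
            or k.clinvar_class in (ClinvarClass.VUS, ClinvarClass.CONFLICTING)
            or (k.hgmd_phenotype is not None and k.clinvar_class is ClinvarClass.NOT_REPORTED)
            or (annotated.novel and consensus.label is ConsensusLabel.LIKELY_PATHOGENIC)
        )
        if uncertain_or_worse:
            rationale.append("pathogenic_or_uncertain_in_other_dementia_gene")
            return out(ClinicalCategory.WEAK_RISK)

    # (5): benign spectrum
    if k.clinvar_class is ClinvarClass.BENIGN:
        rationale.append("known_benign")
        return out(ClinicalCategory.BENIGN)
    if k.clinvar_class is ClinvarClass.LIKELY_BENIGN:
        rationale.append("known_likely_benign")
        return out(ClinicalCategory.LIKELY_BENIGN)
    if annotated.novel and consensus.label is ConsensusLabel.LIKELY_BENIGN:
        rationale.append("novel_consensus_benign")
        return out(ClinicalCategory.LIKELY_BENIGN)

    # (6)
    return out(ClinicalCategory.UNCLASSIFIED)


# --------------------------------------------------------------------------
# Patient-level explanation

class ExplanationSource(Enum):
    CAUSATIVE = "causative"
    APOE44 = "apoe_e4_homozygous"
    MODERATE_RISK = "moderate_risk"
    NON_AD_GENE = "non_ad_gene"


@dataclass(frozen=True)
class PatientExplanation:
    patient_id: str
    explained_by: frozenset[ExplanationSource]

    @property
    def explained(self) -> bool:
        return bool(self.explained_by)


def explain_patient(
    patient: Patient,
    variants: Sequence[ClassifiedVariant],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> PatientExplanation:
    """Explanation sources for one patient given the variants they carry."""
    sources: set[ExplanationSource] = set()
    for v in variants:
        if patient.patient_id not in v.carrier_ids:
            raise ValueError(
                f"{v.gene} {v.key[1]} not carried by {patient.patient_id}"
            )
        if (
            v.category in (ClinicalCategory.DIAGNOSTIC, ClinicalCategory.CONTRIBUTOR)
            and v.annotated.panel is PanelName.AD_CAUSATIVE
        ):
            sources.add(ExplanationSource.CAUSATIVE)
        if v.category is ClinicalCategory.RISK_FACTOR and v.gene in MODERATE_RISK_GENES:
            sources.add(ExplanationSource.MODERATE_RISK)
        if v.category is ClinicalCategory.WEAK_RISK and cfg.weak_risk_explains:
            sources.add(ExplanationSource.NON_AD_GENE)
    if patient.apoe is not None and patient.apoe.e4_count == 2:
        sources.add(ExplanationSource.APOE44)
    return PatientExplanation(patient.patient_id, frozenset(sources))


# --------------------------------------------------------------------------
# Cohort summary

def percent(count: int, total: int) -> float:
    """Percentage with 2-decimal half-up rounding (report convention)."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_familial: int
    n_sporadic: int
    n_strong: int
    explained_familial: int
    explained_sporadic: int
    by_source_familial: dict[ExplanationSource, int]
    by_source_sporadic: dict[ExplanationSource, int]

    @property
    def familial_percent(self) -> float:
        return percent(self.n_familial, self.n_patients)

    @property
    def strong_percent_of_familial(self) -> float:
        return percent(self.n_strong, self.n_familial)

    @property
    def explained_fraction_familial(self) -> float:
        return percent(self.explained_familial, self.n_familial)

    @property
    def explained_fraction_sporadic(self) -> float:
        return percent(self.explained_sporadic, self.n_sporadic)


def summarize_cohort(
    patients: Sequence[Patient],
    explanations: Sequence[PatientExplanation],
) -> CohortSummary:
    """Stratified explained-case summary (familial vs sporadic)."""
    expl = {e.patient_id: e for e in explanations}
    missing = [p.patient_id for p in patients if p.patient_id not in expl]
    if missing:
        raise ValueError(f"patients without explanation record: {missing}")
    n_familial = sum(p.familial for p in patients)
    n_strong = sum(
        p.family_history is FamilyHistoryStrength.STRONG for p in patients
    )
    by_f: dict[ExplanationSource, int] = {s: 0 for s in ExplanationSource}
    by_s: dict[ExplanationSource, int] = {s: 0 for s in ExplanationSource}
    explained_f = explained_s = 0
    for p in patients:
        e = expl[p.patient_id]
        bucket = by_f if p.familial else by_s
        for src in e.explained_by:
            bucket[src] += 1
        if e.explained:
            if p.familial:
                explained_f += 1
            else:
                explained_s += 1
    return CohortSummary(
        n_patients=len(patients),
        n_familial=n_familial,
        n_sporadic=len(patients) - n_familial,
        n_strong=n_strong,
        explained_familial=explained_f,
        explained_sporadic=explained_s,
        by_source_familial=by_f,
        by_source_sporadic=by_s,
    )


def count_category_patients(
    classified: Iterable[ClassifiedVariant],
    categories: set[ClinicalCategory],
    genes: Optional[set[str]] = None,
    cohort_size: Optional[int] = None,
) -> tuple[int, Optional[float]]:
    """Distinct patients carrying a variant in the given categories.

    A patient carrying several qualifying variants counts once.  Returns
    the count and, when ``cohort_size`` is given, the percentage of the
    cohort (2-decimal half-up).
    """
    carriers = {
        pid
        for v in classified
        if v.category in categories and (genes is None or v.gene in genes)
        for pid in v.carrier_ids
    }
    pct = percent(len(carriers), cohort_size) if cohort_size else None
    return len(carriers), pct
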