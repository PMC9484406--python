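"""End-to-end variant triage: annotation, consensus, enrichment,
classification and cohort aggregation.

Two entry points cover the two input shapes:

* :func:`run_fixture_pipeline` starts from already-filtered knowledge
  tables (the packaged published tables, or any table in the same dialect)
  whose carrier lists are part of the table.
* :func:`run_bundle` starts from a VCF plus metadata directory (as written
  by :mod:`eoadtriage.simulate`): calls are read from the VCF, passed
  through the selection filters, bridged to the knowledge table through an
  explicit coordinate->HGVS mapping file, and carriers are derived from the
  surviving calls.

Each knowledge table (fixture mode) or gene panel (bundle mode) forms one
multiple-testing family for the Benjamini-Hochberg adjustment, mirroring
per-table reporting of adjusted p-values.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .annotation import (
    AnnotatedVariant, Carrier, KnowledgeTable, PanelName, PanelSet, annotate,
)
from .classify import (
    ClassificationConfig, ClassifiedVariant, ClinicalCategory, CohortSummary,
    ExplanationSource, PatientExplanation, classify_variant, explain_patient,
    summarize_cohort,
)
from .cohort import FamilyHistoryStrength, Patient, load_patients_tsv
from .consensus import (
    ConsensusConfig, ConsensusResult, PredictorVerdict, consensus_classify,
    load_verdicts_tsv,
)
from .filtering import (
    FilterConfig, FilterResult, RegionSet, VariantCall, Zygosity,
    apply_filters, read_vcf,
)
from .stats import AlleleTable, enrich_family, enrich_variant


@dataclass
class PipelineResult:
    patients: list[Patient]
    classified: list[ClassifiedVariant]
    explanations: list[PatientExplanation]
    summary: CohortSummary
    filter_result: Optional[FilterResult] = None

    @property
    def by_patient(self) -> dict[str, list[ClassifiedVariant]]:
        out: dict[str, list[ClassifiedVariant]] = {p.patient_id: [] for p in self.patients}
        for v in self.classified:
            for pid in v.carrier_ids:
                out.setdefault(pid, []).append(v)
        return out

    def category_of(self, key: tuple[str, str]) -> ClinicalCategory:
        for v in self.classified:
            if v.key == key:
                return v.category
        raise KeyError(key)


def _classify_annotated(
    groups: Sequence[Sequence[AnnotatedVariant]],
    verdicts: dict[tuple[str, str], list[PredictorVerdict]],
    fh_by_patient: dict[str, FamilyHistoryStrength],
    n_genotyped: int,
    cls_cfg: ClassificationConfig,
    cons_cfg: ConsensusConfig,
) -> list[ClassifiedVariant]:
    """Classify annotated variants, one enrichment family per group."""
    classified: list[ClassifiedVariant] = []
    for group in groups:
        tables: dict[tuple[str, str], Optional[AlleleTable]] = {
            v.key: enrich_variant(
                [c.zygosity for c in v.carriers], n_genotyped, v.knowledge.population
            )
            for v in group
        }
        enrichment = enrich_family(tables)
        for v in group:
            consensus: Optional[ConsensusResult] = None
            if v.novel:
                consensus = consensus_classify(
                    v.knowledge.effect_class,
                    verdicts.get(v.key, []),
                    gene=v.gene,
                    app_exon=v.knowledge.app_exon,
                    cfg=cons_cfg,
                )
            carriers_fh = [
                fh_by_patient.get(pid, FamilyHistoryStrength.SPORADIC)
                for pid in v.carrier_ids
            ]
            classified.append(classify_variant(
                v, consensus=consensus, enrichment=enrichment[v.key],
                carriers_fh=carriers_fh, cfg=cls_cfg,
            ))
    return classified


def _aggregate(
    patients: list[Patient],
    classified: list[ClassifiedVariant],
    cls_cfg: ClassificationConfig,
    filter_result: Optional[FilterResult] = None,
) -> PipelineResult:
    carried: dict[str, list[ClassifiedVariant]] = {p.patient_id: [] for p in patients}
    for v in classified:
        for pid in v.carrier_ids:
            if pid in carried:
                carried[pid].append(v)
    explanations = [
        explain_patient(p, carried[p.patient_id], cfg=cls_cfg) for p in patients
    ]
    summary = summarize_cohort(patients, explanations)
    return PipelineResult(
        patients=patients, classified=classified,
        explanations=explanations, summary=summary,
        filter_result=filter_result,
    )


def run_fixture_pipeline(
    tables: dict[str, KnowledgeTable],
    patients: list[Patient],
    panels: PanelSet,
    verdicts: dict[tuple[str, str], list[PredictorVerdict]],
    cls_cfg: ClassificationConfig = ClassificationConfig(),
    cons_cfg: ConsensusConfig = ConsensusConfig(),
) -> PipelineResult:
    """Run annotation through aggregation on knowledge tables with carriers.

    Each table is one enrichment family.  The cohort allele denominator
    assumes every patient genotyped at every site (panel sequencing).
    """
    fh = {p.patient_id: p.family_history for p in patients}
    groups = [annotate(t, panels) for t in tables.values()]
    classified = _classify_annotated(
        groups, verdicts, fh, n_genotyped=len(patients),
        cls_cfg=cls_cfg, cons_cfg=cons_cfg,
    )
    return _aggregate(patients, classified, cls_cfg)


def run_published_fixtures(
    cls_cfg: ClassificationConfig = ClassificationConfig(),
) -> PipelineResult:
    """Convenience wrapper: run the pipeline on the packaged study tables."""
    from . import fixtures

    tables = fixtures.load_fixture_tables()
    return run_fixture_pipeline(
        tables=tables,
        patients=fixtures.fixture_cohort(tables),
        panels=fixtures.load_panels(),
        verdicts=fixtures.fixture_verdicts(tables),
        cls_cfg=cls_cfg,
    )


# --------------------------------------------------------------------------
# Bundle (VCF) mode

def load_variant_map(path: str | Path) -> dict[tuple[str, int, str, str], tuple[str, str]]:
    """Coordinate -> (gene, hgvs_c) adapter table."""
    out: dict[tuple[str, int, str, str], tuple[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = (
                row["gene"], row["hgvs_c"],
            )
    return out


def run_bundle(
    bundle_dir: str | Path,
    filter_cfg: FilterConfig = FilterConfig(),
    cls_cfg: ClassificationConfig = ClassificationConfig(),
    cons_cfg: ConsensusConfig = ConsensusConfig(),
) -> PipelineResult:
    """Run the full pipeline on a bundle directory (VCF + metadata).

    Expects cohort.vcf, patients.tsv, knowledge.tsv, verdicts.tsv,
    variant_map.tsv and regions.bed, as written by the synthetic-cohort
    generator.  One enrichment family per gene panel.
    """
    bundle = Path(bundle_dir)
    patients = load_patients_tsv(bundle / "patients.tsv")
    panels = PanelSet.from_yaml(bundle / "panels.yaml")
    knowledge = KnowledgeTable.from_tsv(bundle / "knowledge.tsv")
    verdicts = load_verdicts_tsv(bundle / "verdicts.tsv")
    variant_map = load_variant_map(bundle / "variant_map.tsv")
    regions = RegionSet.from_bed(bundle / "regions.bed")

    calls = read_vcf(bundle / "cohort.vcf")

    def ref_freq(call: VariantCall) -> Optional[float]:
        key = variant_map.get(call.key)
        if key is None:
            return None
        rec = knowledge.get(key)
        if rec is None or rec.population is None:
            return None
        return rec.population.frequency

    filt = apply_filters(calls, filter_cfg, regions=regions, ref_freq=ref_freq)

    # rebuild per-variant carrier lists from the surviving calls
    fh = {p.patient_id: p.family_history for p in patients}
    carriers_by_key: dict[tuple[str, str], list[Carrier]] = {}
    for call in filt.kept:
        key = variant_map.get(call.key)
        if key is None or key not in knowledge:
            continue  # call without knowledge record: not interpretable
        carriers_by_key.setdefault(key, []).append(Carrier(
            patient_id=call.patient_id,
            fh_score_label=".",
            zygosity=call.zygosity,
        ))

    by_panel: dict[PanelName, list[AnnotatedVariant]] = {}
    for key in sorted(carriers_by_key):
        rec = knowledge.records[key]
        av = AnnotatedVariant(
            knowledge=rec,
            carriers=tuple(sorted(carriers_by_key[key], key=lambda c: c.patient_id)),
            panel=panels.panel_of(rec.gene),
        )
        by_panel.setdefault(av.panel, []).append(av)

    classified = _classify_annotated(
        [by_panel[p] for p in sorted(by_panel, key=lambda p: p.value)],
        verdicts, fh, n_genotyped=len(patients),
        cls_cfg=cls_cfg, cons_cfg=cons_cfg,
    )
    return _aggregate(patients, classified, cls_cfg, filter_result=filt)


# --------------------------------------------------------------------------
# Report output

def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write classified variants, per-patient explanations and the cohort
    summary to a report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "classified_variants.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "hgvs_c", "hgvs_p", "panel", "category",
                    "carriers", "raw_p", "adj_p", "family_size", "rationale"])
        for v in result.classified:
            e = v.enrichment
            w.writerow([
                v.gene, v.key[1], v.annotated.knowledge.hgvs_p or ".",
                v.annotated.panel.value, v.category.value,
                ",".join(v.carrier_ids),
                f"{e.raw_p:.4g}" if e else "NA",
                f"{e.adj_p:.4g}" if e else "NA",
                e.test_family_size if e else "NA",
                ";".join(v.rationale) or ".",
            ])

    with open(out / "patient_explanations.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["patient_id", "explained", "sources"])
        for e in result.explanations:
            w.writerow([
                e.patient_id, int(e.explained),
                ",".join(sorted(s.value for s in e.explained_by)) or ".",
            ])

    s = result.summary
    summary = {
        "n_patients": s.n_patients,
        "n_familial": s.n_familial,
        "n_sporadic": s.n_sporadic,
        "n_strong": s.n_strong,
        "familial_percent": s.familial_percent,
        "strong_percent_of_familial": s.strong_percent_of_familial,
        "explained_familial": s.explained_familial,
        "explained_sporadic": s.explained_sporadic,
        "explained_fraction_familial": s.explained_fraction_familial,
        "explained_fraction_sporadic": s.explained_fraction_sporadic,
        "by_source_familial": {k.value: v for k, v in s.by_source_familial.items()},
        "by_source_sporadic": {k.value: v for k, v in s.by_source_sporadic.items()},
    }
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
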