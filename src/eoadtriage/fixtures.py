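"""Packaged study fixtures: the published variant tables and a cohort
reconstruction.

The five TSVs under ``data/tables`` transcribe the published per-variant
tables (causative genes, TREM2, other-dementia genes, ABCA7/SORL1, GWAS
susceptibility genes), one row per variant-carrier pair.  Only carriers
appear in print, so :func:`fixture_cohort` completes the 102-patient cohort
synthetically and deterministically: carrier IDs and family-history scores
are taken from the tables, and non-carrier patients are added so that the
published marginals hold exactly — 46 familial patients of whom 10 have a
strong family history, 8 APOE e4/e4 homozygotes (all without causative-gene
variants, 7 familial of whom 2 strong), 30 e3/e4 and 2 e2/e4 heterozygotes,
and 49 males.  Ages at onset of non-carriers are filler values below the
early-onset bound; per-patient ages are not printed and nothing downstream
consumes them.

Per-tool predictor verdicts are likewise not printed (only the consensus
call is); :func:`fixture_verdicts` synthesises a verdict set per novel
variant that realises the printed consensus under the voting rules.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

from .annotation import KnowledgeTable, PanelSet
from .cohort import APOEGenotype, ApoeAllele, GoldmanScore, Patient, Sex, parse_goldman
from .consensus import PredictorVerdict, synthesize_verdicts
from .filtering import EffectClass

#: fixture tables in reporting order; each is its own multiple-testing family
TABLE_FILES = (
    "causative_ad_genes.tsv",
    "trem2.tsv",
    "other_dementia_genes.tsv",
    "ad_risk_genes.tsv",
    "gwas_genes.tsv",
)

#: published cohort marginals realised by the reconstruction
COHORT_SIZE = 102
N_FAMILIAL = 46
N_STRONG = 10
N_APOE44 = 8
N_APOE44_FAMILIAL = 7
N_APOE44_STRONG = 2
N_E3E4 = 30
N_E2E4 = 2
N_MALE = 49


def _data_dir() -> Path:
    return Path(str(resources.files("eoadtriage").joinpath("data")))


def load_panels() -> PanelSet:
    return PanelSet.from_yaml(_data_dir() / "panels.yaml")


def load_fixture_tables() -> dict[str, KnowledgeTable]:
    """The five packaged variant tables, keyed by file stem."""
    tables_dir = _data_dir() / "tables"
    return {
        Path(name).stem: KnowledgeTable.from_tsv(tables_dir / name)
        for name in TABLE_FILES
    }


def fixture_verdicts(tables: dict[str, KnowledgeTable]) -> dict[tuple[str, str], list[PredictorVerdict]]:
    """Synthetic per-tool verdicts realising each printed consensus call.

    Protein-truncating variants are excluded: the voting rules presume them
    damaging without a tool battery.
    """
    verdicts: dict[tuple[str, str], list[PredictorVerdict]] = {}
    for table in tables.values():
        for key, pred in table.predictions.items():
            rec = table.records[key]
            if not rec.novel or rec.effect_class is EffectClass.PTV:
                continue
            verdicts[key] = synthesize_verdicts(
                rec.effect_class, damaging=pred == "likely_pathogenic"
            )
    return verdicts


def _collect_carriers(tables: dict[str, KnowledgeTable]) -> dict[str, str]:
    """patient_id -> family-history score label, checked for consistency."""
    carriers: dict[str, str] = {}
    for table in tables.values():
        for carrier_list in table.carriers.values():
            for c in carrier_list:
                prev = carriers.get(c.patient_id)
                if prev is not None and prev != c.fh_score_label:
                    raise ValueError(
                        f"inconsistent family-history score for {c.patient_id}: "
                        f"{prev} vs {c.fh_score_label}"
                    )
                carriers[c.patient_id] = c.fh_score_label
    return carriers


def fixture_cohort(tables: Optional[dict[str, KnowledgeTable]] = None) -> list[Patient]:
    """Reconstruct the 102-patient cohort around the printed carriers."""
    if tables is None:
        tables = load_fixture_tables()
    carriers = _collect_carriers(tables)

    all_ids = [f"AD#{i:03d}" for i in range(1, COHORT_SIZE + 1)]
    unused = [pid for pid in all_ids if pid not in carriers]

    patients: dict[str, Patient] = {}
    for pid, fh_label in carriers.items():
        patients[pid] = Patient(patient_id=pid, goldman_score=parse_goldman(fh_label))

    n_familial_carriers = sum(1 for p in patients.values() if p.familial)
    n_strong_carriers = sum(
        1 for p in patients.values()
        if p.goldman_score in (GoldmanScore.S1, GoldmanScore.S1_5)
    )

    # APOE e4 homozygotes: non-carriers, 7 familial (2 with strong history)
    apoe44_ids = unused[:N_APOE44]
    e44 = APOEGenotype(ApoeAllele.E4, ApoeAllele.E4)
    apoe44_scores = (
        [GoldmanScore.S1, GoldmanScore.S1_5]
        + [GoldmanScore.S3_5] * (N_APOE44_FAMILIAL - N_APOE44_STRONG)
        + [GoldmanScore.NONE] * (N_APOE44 - N_APOE44_FAMILIAL)
    )
    for pid, score in zip(apoe44_ids, apoe44_scores):
        patients[pid] = Patient(patient_id=pid, goldman_score=score, apoe=e44)

    # remaining familial / strong counts filled with non-carrier patients
    strong_fill = N_STRONG - n_strong_carriers - N_APOE44_STRONG
    familial_fill = N_FAMILIAL - n_familial_carriers - N_APOE44_FAMILIAL
    if strong_fill < 0 or familial_fill < strong_fill:
        raise ValueError("carrier family-history counts exceed published marginals")
    fill_ids = unused[N_APOE44:N_APOE44 + familial_fill]
    for i, pid in enumerate(fill_ids):
        score = GoldmanScore.S1 if i < strong_fill else GoldmanScore.S3
        patients[pid] = Patient(patient_id=pid, goldman_score=score)
    for pid in unused[N_APOE44 + familial_fill:]:
        patients[pid] = Patient(patient_id=pid, goldman_score=GoldmanScore.NONE)

    # APOE heterozygotes among the remaining patients, in ID order
    remaining = [pid for pid in all_ids if patients[pid].apoe is None]
    for pid in remaining[:N_E2E4]:
        patients[pid].apoe = APOEGenotype(ApoeAllele.E2, ApoeAllele.E4)
    for pid in remaining[N_E2E4:N_E2E4 + N_E3E4]:
        patients[pid].apoe = APOEGenotype(ApoeAllele.E3, ApoeAllele.E4)
    for pid in remaining[N_E2E4 + N_E3E4:]:
        patients[pid].apoe = APOEGenotype(ApoeAllele.E3, ApoeAllele.E3)

    # filler demographics matching the printed sex split and onset bound
    cohort = [patients[pid] for pid in all_ids]
    for i, p in enumerate(cohort):
        p.sex = Sex.M if i < N_MALE else Sex.F
        p.age_at_onset = 52 + (i % 11)
    return cohort
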