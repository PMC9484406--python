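"""Join filtered variants to packaged knowledge: gene panels, ClinVar/HGMD
classes, gnomAD non-Finnish European allele counts and literature flags.

Knowledge tables are keyed by (gene, HGVS c.) because published variant
tables print HGVS rather than genomic coordinates; VCF-derived calls are
bridged through an explicit coordinate->HGVS mapping file (see
:mod:`eoadtriage.pipeline`).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .filtering import EffectClass, Zygosity


class PanelName(Enum):
    AD_CAUSATIVE = "ad_causative"
    AD_RISK = "ad_risk"
    OTHER_DEMENTIA = "other_dementia"
    AD_GWAS = "ad_gwas"
    NONE = "none"


@dataclass(frozen=True)
class GenePanel:
    name: PanelName
    genes: frozenset[str]


#: gene-content requirements checked when panels are loaded
_PANEL_REQUIREMENTS: dict[PanelName, tuple[set[str], bool]] = {
    # (required genes, exact)
    PanelName.AD_CAUSATIVE: ({"APP", "PSEN1", "PSEN2"}, True),
    PanelName.AD_RISK: ({"TREM2", "ABCA7", "SORL1"}, False),
    PanelName.OTHER_DEMENTIA: ({
        "CCNF", "CHCHD10", "CSF1R", "DCTN1", "FIG4", "FUS",
        "MAPT", "NOTCH3", "OPTN", "SQSTM1", "TYROBP", "UBQLN2",
    }, False),
    PanelName.AD_GWAS: (set(), False),
}


class PanelSet:
    """Pairwise-disjoint gene panels with a gene -> panel lookup."""

    def __init__(self, panels: Sequence[GenePanel]):
        self.panels = {p.name: p for p in panels}
        self._gene_to_panel: dict[str, PanelName] = {}
        for p in panels:
            for g in p.genes:
                if g in self._gene_to_panel:
                    raise ValueError(
                        f"gene {g} in both {self._gene_to_panel[g].value} and {p.name.value}"
                    )
                self._gene_to_panel[g] = p.name
        for name, (required, exact) in _PANEL_REQUIREMENTS.items():
            if name not in self.panels:
                continue
            genes = self.panels[name].genes
            if exact and genes != frozenset(required):
                raise ValueError(f"panel {name.value} must be exactly {sorted(required)}")
            if not required <= genes:
                raise ValueError(
                    f"panel {name.value} missing required genes {sorted(required - genes)}"
                )

    def panel_of(self, gene: str) -> PanelName:
        return self._gene_to_panel.get(gene, PanelName.NONE)

    def genes(self, name: PanelName) -> frozenset[str]:
        return self.panels[name].genes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        panels = [
            GenePanel(PanelName(name), frozenset(genes))
            for name, genes in raw["panels"].items()
        ]
        return cls(panels)


# --------------------------------------------------------------------------
# Knowledge records

class ClinvarClass(Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    CONFLICTING = "conflicting"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    NOT_REPORTED = "NR"


#: short codes used in the conflicting-detail vote multiset
_VOTE_CODES = {
    "P": ClinvarClass.PATHOGENIC,
    "LP": ClinvarClass.LIKELY_PATHOGENIC,
    "VUS": ClinvarClass.VUS,
    "LB": ClinvarClass.LIKELY_BENIGN,
    "B": ClinvarClass.BENIGN,
}


@dataclass(frozen=True)
class PopulationCounts:
    """Reference-population allele counts, printed as "alt/total"."""

    ac_alt: int
    ac_total: int
    population_label: str = "gnomAD-NFE"

    def __post_init__(self) -> None:
        if not (0 <= self.ac_alt <= self.ac_total):
            raise ValueError(f"require 0 <= ac_alt <= ac_total, got {self}")

    @property
    def frequency(self) -> float:
        return self.ac_alt / self.ac_total if self.ac_total else 0.0

    def __str__(self) -> str:
        return f"{self.ac_alt}/{self.ac_total}"


def parse_population_counts(text: str, population_label: str = "gnomAD-NFE") -> Optional[PopulationCounts]:
    """Parse an "alt/total" allele-count string; "NR"/"NA"/"." mean not reported."""
    s = text.strip()
    if s.upper() in {"NR", "NA", "", "."}:
        return None
    m = re.fullmatch(r"(\d+)\s*/\s*(\d+)", s)
    if not m:
        raise ValueError(f"malformed allele-count string: {text!r}")
    return PopulationCounts(int(m.group(1)), int(m.group(2)), population_label)


class LiteratureFlag(Enum):
    #: protein-truncating variant
    PTV = "PTV"
    #: prior report associating the variant with AD risk
    PRIOR_AD_REPORT = "PRIOR_AD_REPORT"
    #: historically reported pathogenic, later reclassified/questioned
    QUESTIONABLE_PATHOGENICITY = "QUESTIONABLE_PATHOGENICITY"


@dataclass(frozen=True)
class KnowledgeRecord:
    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    clinvar_class: ClinvarClass = ClinvarClass.NOT_REPORTED
    conflicting_detail: Optional[Mapping[ClinvarClass, int]] = None
    hgmd_phenotype: Optional[str] = None  # None = not reported
    population: Optional[PopulationCounts] = None  # None = not reported
    literature_flags: frozenset[LiteratureFlag] = frozenset()
    effect_class: EffectClass = EffectClass.OTHER
    app_exon: Optional[int] = None

    def __post_init__(self) -> None:
        has_detail = bool(self.conflicting_detail)
        if has_detail != (self.clinvar_class is ClinvarClass.CONFLICTING):
            raise ValueError(
                f"{self.gene} {self.hgvs_c}: conflicting_detail present iff "
                "clinvar_class is CONFLICTING"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_c)

    @property
    def novel(self) -> bool:
        """Never reported: absent from both ClinVar and HGMD."""
        return (
            self.clinvar_class is ClinvarClass.NOT_REPORTED
            and self.hgmd_phenotype is None
        )

    @property
    def pathogenic_votes(self) -> int:
        if not self.conflicting_detail:
            return 0
        return sum(
            n for c, n in self.conflicting_detail.items()
            if c in (ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC)
        )

    @property
    def hgmd_questionable(self) -> bool:
        """HGMD phenotype recorded with a question mark (disputed report)."""
        return self.hgmd_phenotype is not None and self.hgmd_phenotype.rstrip().endswith("?")

    @property
    def hgmd_disease_causing(self) -> bool:
        """HGMD lists the variant as disease-causing: a phenotype without a
        question mark and not a mere "increased risk" annotation."""
        if self.hgmd_phenotype is None:
            return False
        pheno = self.hgmd_phenotype.lower()
        return not self.hgmd_questionable and "increased risk" not in pheno

    @property
    def hgmd_risk_annotation(self) -> bool:
        return (
            self.hgmd_phenotype is not None
            and "increased risk" in self.hgmd_phenotype.lower()
        )


@dataclass(frozen=True)
class Carrier:
    patient_id: str
    fh_score_label: str = "0"
    zygosity: Zygosity = Zygosity.HET


def infer_effect_class(hgvs_c: str, hgvs_p: str) -> EffectClass:
    """Coarse consequence class from the HGVS strings alone.

    Intronic offsets (c.123+4, c.456-3) mark splice-region variants;
    "p.X123=" marks silent; frameshift/stop-gain mark protein-truncating;
    in-frame del/dup/ins without frameshift are in-frame indels; a plain
    amino-acid substitution is missense.
    """
    if re.search(r"\d+[+-]\d+", hgvs_c):
        return EffectClass.SPLICE_REGION
    p = hgvs_p.strip()
    if not p:
        return EffectClass.OTHER
    if p.endswith("="):
        return EffectClass.SILENT
    if "fs" in p or "Ter" in p or p.endswith("*"):
        return EffectClass.PTV
    if any(tok in p for tok in ("del", "dup", "ins")):
        return EffectClass.INDEL_INFRAME
    return EffectClass.MISSENSE


# --------------------------------------------------------------------------
# Knowledge table loading

def _parse_conflicting_detail(text: str) -> dict[ClinvarClass, int]:
    detail: dict[ClinvarClass, int] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        code, _, n = part.partition(":")
        code = code.strip().upper()
        if code not in _VOTE_CODES:
            raise ValueError(f"unknown vote code {code!r} in {text!r}")
        detail[_VOTE_CODES[code]] = detail.get(_VOTE_CODES[code], 0) + int(n)
    if not detail:
        raise ValueError(f"empty conflicting_detail: {text!r}")
    return detail


_CLASS_LABELS = {
    "pathogenic": ClinvarClass.PATHOGENIC,
    "likely_pathogenic": ClinvarClass.LIKELY_PATHOGENIC,
    "vus": ClinvarClass.VUS,
    "uncertain_significance": ClinvarClass.VUS,
    "conflicting": ClinvarClass.CONFLICTING,
    "likely_benign": ClinvarClass.LIKELY_BENIGN,
    "benign": ClinvarClass.BENIGN,
    "nr": ClinvarClass.NOT_REPORTED,
}


class KnowledgeTable:
    """Lookup keyed by (gene, hgvs_c), with per-variant carrier lists.

    The TSV dialect has one row per (gene, hgvs_c, patient_id); knowledge
    columns must be identical across rows of the same variant, and the same
    carrier may not be listed twice for one variant.
    """

    #: columns beyond these are ignored, so tables may carry extra metadata
    REQUIRED = ["gene", "hgvs_c", "hgvs_p", "patient_id", "fh_score",
                "clinvar", "hgmd", "gnomad_nfe"]
    OPTIONAL = ["conflicting_detail", "zygosity", "prediction", "flags", "app_exon"]

    def __init__(self) -> None:
        self.records: dict[tuple[str, str], KnowledgeRecord] = {}
        self.carriers: dict[tuple[str, str], list[Carrier]] = {}
        self.predictions: dict[tuple[str, str], str] = {}

    def add(self, record: KnowledgeRecord, carrier: Carrier,
            prediction: Optional[str] = None) -> None:
        key = record.key
        if key in self.records:
            if self.records[key] != record:
                raise ValueError(f"conflicting duplicate knowledge rows for {key}")
            if any(c.patient_id == carrier.patient_id for c in self.carriers[key]):
                raise ValueError(f"duplicate carrier {carrier.patient_id} for {key}")
        else:
            self.records[key] = record
            self.carriers[key] = []
        self.carriers[key].append(carrier)
        if prediction:
            self.predictions[key] = prediction

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.records

    def get(self, key: tuple[str, str]) -> Optional[KnowledgeRecord]:
        return self.records.get(key)

    @classmethod
    def from_tsv(cls, *paths: str | Path) -> "KnowledgeTable":
        table = cls()
        for path in paths:
            with open(path, newline="") as fh:
                reader = csv.DictReader(fh, delimiter="\t")
                missing = set(cls.REQUIRED) - set(reader.fieldnames or [])
                if missing:
                    raise ValueError(f"{path}: missing columns {sorted(missing)}")
                last_key: Optional[tuple[str, str]] = None
                for ln, row in enumerate(reader, start=2):
                    try:
                        last_key = table._add_row(row, last_key)
                    except ValueError as exc:
                        raise ValueError(f"{path}, line {ln}: {exc}") from None
        return table

    def _add_row(self, row: Mapping[str, str],
                 last_key: Optional[tuple[str, str]]) -> tuple[str, str]:
        def get(col: str) -> str:
            return (row.get(col) or "").strip()

        gene, hgvs_c = get("gene"), get("hgvs_c")
        if not gene and not hgvs_c and last_key is not None:
            # continuation row: an additional carrier of the previous variant
            gene, hgvs_c = last_key
            rec = self.records[(gene, hgvs_c)]
        else:
            clinvar_label = get("clinvar").lower()
            if clinvar_label not in _CLASS_LABELS:
                raise ValueError(f"unknown ClinVar class label {clinvar_label!r}")
            clinvar = _CLASS_LABELS[clinvar_label]
            detail = (
                _parse_conflicting_detail(get("conflicting_detail"))
                if get("conflicting_detail") else None
            )
            hgmd = get("hgmd")
            hgvs_p = get("hgvs_p")
            flags = frozenset(
                LiteratureFlag(f.strip())
                for f in get("flags").split(",") if f.strip()
            )
            rec = KnowledgeRecord(
                gene=gene,
                hgvs_c=hgvs_c,
                hgvs_p="" if hgvs_p == "." else hgvs_p,
                clinvar_class=clinvar,
                conflicting_detail=detail,
                hgmd_phenotype=None if hgmd.upper() in {"NR", "", "."} else hgmd,
                population=parse_population_counts(get("gnomad_nfe")),
                literature_flags=flags,
                effect_class=infer_effect_class(hgvs_c, "" if hgvs_p == "." else hgvs_p),
                app_exon=int(get("app_exon")) if get("app_exon") not in {"", "."} else None,
            )
        zyg_label = get("zygosity").lower() or "het"
        carrier = Carrier(
            patient_id=get("patient_id"),
            fh_score_label=get("fh_score") or "0",
            zygosity=Zygosity(zyg_label),
        )
        pred = get("prediction")
        self.add(rec, carrier, None if pred in {"", "."} else pred)
        return (gene, hgvs_c)

    def to_tsv(self, path: str | Path) -> None:
        """Write the table back out (one row per variant-carrier pair)."""
        cols = self.REQUIRED + self.OPTIONAL
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(cols)
            for key in sorted(self.records):
                rec = self.records[key]
                for carrier in self.carriers[key]:
                    detail = ""
                    if rec.conflicting_detail:
                        inv = {v: k for k, v in _VOTE_CODES.items()}
                        detail = ";".join(
                            f"{inv[c]}:{n}" for c, n in sorted(
                                rec.conflicting_detail.items(), key=lambda x: x[0].value
                            )
                        )
                    w.writerow([
                        rec.gene, rec.hgvs_c, rec.hgvs_p or ".",
                        carrier.patient_id, carrier.fh_score_label,
                        rec.clinvar_class.value if rec.clinvar_class is not ClinvarClass.NOT_REPORTED else "NR",
                        rec.hgmd_phenotype or "NR",
                        str(rec.population) if rec.population else "NR",
                        detail,
                        carrier.zygosity.value,
                        self.predictions.get(key, "."),
                        ",".join(sorted(f.value for f in rec.literature_flags)),
                        rec.app_exon if rec.app_exon is not None else ".",
                    ])


# --------------------------------------------------------------------------
# Annotated variants

@dataclass(frozen=True)
class AnnotatedVariant:
    knowledge: KnowledgeRecord
    carriers: tuple[Carrier, ...]
    panel: PanelName

    @property
    def novel(self) -> bool:
        return self.knowledge.novel

    @property
    def gene(self) -> str:
        return self.knowledge.gene

    @property
    def key(self) -> tuple[str, str]:
        return self.knowledge.key

    @property
    def carrier_ids(self) -> tuple[str, ...]:
        return tuple(c.patient_id for c in self.carriers)


def annotate(table: KnowledgeTable, panels: PanelSet) -> list[AnnotatedVariant]:
    """Join every knowledge-table variant to its panel; a pure function of
    the inputs (annotating twice gives the same result)."""
    return [
        AnnotatedVariant(
            knowledge=table.records[key],
            carriers=tuple(table.carriers[key]),
            panel=panels.panel_of(key[0]),
        )
        for key in sorted(table.records)
    ]


def count_variants_and_genes(
    annotated: Iterable[AnnotatedVariant],
    panel: PanelName,
    genes: Optional[set[str]] = None,
) -> tuple[int, int, int]:
    """(distinct variants, distinct genes, distinct carriers) within a panel,
    optionally restricted to a gene subset."""
    selected = [
        v for v in annotated
        if v.panel is panel and (genes is None or v.gene in genes)
    ]
    n_variants = len({v.key for v in selected})
    n_genes = len({v.gene for v in selected})
    n_patients = len({pid for v in selected for pid in v.carrier_ids})
    return n_variants, n_genes, n_patients
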