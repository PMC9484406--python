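"""Domain model for an EOAD study cohort.

Patients carry demographic fields, a modified Goldman family-history score,
an APOE genotype and (optionally) a CSF biomarker profile.  The modified
Goldman scale grades aggregation of dementia in the family: S1 requires at
least three affected in two generations with early onset, S1.5 is the same
with late-onset disease, S2 is three affected relatives without a clear
dominant pattern, S3/S3.5 a single affected first- or second-degree relative
(early/late onset).  S1 and S1.5 count as *strong* family history, S2-S3.5
as *moderate*; absence of a score marks a sporadic case.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence


class Sex(Enum):
    M = "M"
    F = "F"


class GoldmanScore(Enum):
    """Modified Goldman family-history score; NONE means sporadic."""

    S1 = "S1"
    S1_5 = "S1.5"
    S2 = "S2"
    S3 = "S3"
    S3_5 = "S3.5"
    NONE = "none"


class FamilyHistoryStrength(Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    SPORADIC = "sporadic"


_GOLDMAN_STRENGTH = {
    GoldmanScore.S1: FamilyHistoryStrength.STRONG,
    GoldmanScore.S1_5: FamilyHistoryStrength.STRONG,
    GoldmanScore.S2: FamilyHistoryStrength.MODERATE,
    GoldmanScore.S3: FamilyHistoryStrength.MODERATE,
    GoldmanScore.S3_5: FamilyHistoryStrength.MODERATE,
    GoldmanScore.NONE: FamilyHistoryStrength.SPORADIC,
}

# Accepted spellings in metadata files ("0" is a common shorthand for no
# family history in clinical tables).
_GOLDMAN_LABELS = {
    "s1": GoldmanScore.S1,
    "1": GoldmanScore.S1,
    "s1.5": GoldmanScore.S1_5,
    "s1,5": GoldmanScore.S1_5,
    "1.5": GoldmanScore.S1_5,
    "1,5": GoldmanScore.S1_5,
    "s2": GoldmanScore.S2,
    "2": GoldmanScore.S2,
    "s3": GoldmanScore.S3,
    "3": GoldmanScore.S3,
    "s3.5": GoldmanScore.S3_5,
    "s3,5": GoldmanScore.S3_5,
    "3.5": GoldmanScore.S3_5,
    "3,5": GoldmanScore.S3_5,
    "0": GoldmanScore.NONE,
    "none": GoldmanScore.NONE,
    "": GoldmanScore.NONE,
    ".": GoldmanScore.NONE,
}


def parse_goldman(label: str) -> GoldmanScore:
    """Parse a Goldman score label as printed in clinical tables."""
    try:
        return _GOLDMAN_LABELS[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown Goldman score label: {label!r}") from None


def goldman_strength(score: GoldmanScore) -> FamilyHistoryStrength:
    """Map a Goldman score to strong/moderate/sporadic family history."""
    if not isinstance(score, GoldmanScore):
        raise ValueError(f"unknown Goldman score: {score!r}")
    return _GOLDMAN_STRENGTH[score]


# --------------------------------------------------------------------------
# CSF biomarker profile

#: In-house cutoffs defining an AD-like CSF biomarker profile.
PTAU_AB42_CUTOFF = 0.108
AB42_AB40_CUTOFF = 0.68


@dataclass(frozen=True)
class CSFProfile:
    """CSF biomarker ratios; either may be missing (None)."""

    ptau_ab42_ratio: Optional[float] = None
    ab42_ab40_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ptau_ab42_ratio", "ab42_ab40_ratio"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


def csf_ad_profile(csf: CSFProfile) -> Optional[bool]:
    """AD biomarker profile: p-tau/Abeta42 > 0.108 and Abeta42/Abeta40 < 0.68.

    Both inequalities are strict; boundary values do not qualify.  Returns
    None (indeterminate) when either ratio is missing, which is distinct
    from a definite ``False``.
    """
    if csf.ptau_ab42_ratio is None or csf.ab42_ab40_ratio is None:
        return None
    return (
        csf.ptau_ab42_ratio > PTAU_AB42_CUTOFF
        and csf.ab42_ab40_ratio < AB42_AB40_CUTOFF
    )


# --------------------------------------------------------------------------
# APOE

class ApoeAllele(Enum):
    E1 = "e1"
    E2 = "e2"
    E3 = "e3"
    E4 = "e4"


class ApoeSource(Enum):
    DECLARED = "declared"
    DERIVED_FROM_SNPS = "derived_from_snps"


# rs429358/rs7412 haplotype -> epsilon allele (both SNPs on the forward
# coding sense: reference T at rs429358, reference C at rs7412 is e3).
_HAPLOTYPE_TO_EPSILON = {
    ("T", "C"): ApoeAllele.E3,
    ("T", "T"): ApoeAllele.E2,
    ("C", "C"): ApoeAllele.E4,
    ("C", "T"): ApoeAllele.E1,
}

_ALLELE_ORDER = {a: i for i, a in enumerate(ApoeAllele)}


@dataclass(frozen=True)
class APOEGenotype:
    """Unordered pair of epsilon alleles (e2/e4 == e4/e2)."""

    allele1: ApoeAllele
    allele2: ApoeAllele
    source: ApoeSource = ApoeSource.DECLARED
    phase_ambiguous: bool = False

    def __post_init__(self) -> None:
        # normalise to a canonical order so equality is pair equality
        a, b = self.allele1, self.allele2
        if _ALLELE_ORDER[a] > _ALLELE_ORDER[b]:
            object.__setattr__(self, "allele1", b)
            object.__setattr__(self, "allele2", a)

    @property
    def alleles(self) -> tuple[ApoeAllele, ApoeAllele]:
        return (self.allele1, self.allele2)

    @property
    def e4_count(self) -> int:
        return sum(a is ApoeAllele.E4 for a in self.alleles)

    def label(self) -> str:
        return f"{self.allele1.value}/{self.allele2.value}"

    @classmethod
    def from_label(cls, label: str, **kw) -> "APOEGenotype":
        try:
            a, b = label.strip().lower().split("/")
            return cls(ApoeAllele(a), ApoeAllele(b), **kw)
        except Exception:
            raise ValueError(f"malformed APOE genotype label: {label!r}") from None


def _parse_base_pair(gt: str | Sequence[str], snp: str) -> tuple[str, str]:
    if isinstance(gt, str):
        pair = tuple(gt.strip().upper().replace("|", "/").split("/"))
    else:
        pair = tuple(str(x).upper() for x in gt)
    if len(pair) != 2 or any(b not in {"C", "T"} for b in pair):
        raise ValueError(f"{snp} genotype must be an unordered pair over {{C,T}}, got {gt!r}")
    return pair  # type: ignore[return-value]


def apoe_from_snps(rs429358_gt: str | Sequence[str], rs7412_gt: str | Sequence[str]) -> APOEGenotype:
    """Derive the epsilon genotype from rs429358 and rs7412 genotypes.

    Haplotypes map T/C -> e3, T/T -> e2, C/C -> e4, C/T -> e1.  When both
    SNPs are heterozygous the phase cannot be resolved from genotypes alone
    (e2/e4 versus e1/e3); the e2/e4 assignment is returned, as e1 is
    vanishingly rare, with ``phase_ambiguous`` set.
    """
    a429 = _parse_base_pair(rs429358_gt, "rs429358")
    a7412 = _parse_base_pair(rs7412_gt, "rs7412")
    het429 = a429[0] != a429[1]
    het7412 = a7412[0] != a7412[1]
    if het429 and het7412:
        return APOEGenotype(
            ApoeAllele.E2, ApoeAllele.E4,
            source=ApoeSource.DERIVED_FROM_SNPS, phase_ambiguous=True,
        )
    # at most one SNP is heterozygous, so hap pairing is phase-independent
    h1 = (a429[0], a7412[0])
    h2 = (a429[1], a7412[1])
    return APOEGenotype(
        _HAPLOTYPE_TO_EPSILON[h1], _HAPLOTYPE_TO_EPSILON[h2],
        source=ApoeSource.DERIVED_FROM_SNPS,
    )


# --------------------------------------------------------------------------
# Patient

@dataclass
class Patient:
    patient_id: str
    sex: Optional[Sex] = None
    age_at_onset: Optional[int] = None
    goldman_score: GoldmanScore = GoldmanScore.NONE
    apoe: Optional[APOEGenotype] = None
    csf: Optional[CSFProfile] = None

    @property
    def familial(self) -> bool:
        return self.goldman_score is not GoldmanScore.NONE

    @property
    def family_history(self) -> FamilyHistoryStrength:
        return goldman_strength(self.goldman_score)


def validate_cohort(patients: Sequence[Patient], max_onset: int = 65) -> None:
    """Check cohort invariants: unique IDs and early-onset inclusion bound.

    The onset bound (default 65 years, i.e. EOAD) is a parameter because it
    is an inclusion criterion, not a property of the model.
    """
    seen: set[str] = set()
    for p in patients:
        if p.patient_id in seen:
            raise ValueError(f"duplicate patient_id: {p.patient_id}")
        seen.add(p.patient_id)
        if p.age_at_onset is not None and p.age_at_onset >= max_onset:
            raise ValueError(
                f"{p.patient_id}: age at onset {p.age_at_onset} >= {max_onset}"
            )


def count_apoe_categories(patients: Iterable[Patient]) -> dict[str, int]:
    """Partition a cohort by APOE e4 carrier status.

    Returns counts for e4 homozygotes, e4 heterozygotes (exactly one e4
    allele), everything else, and a separate bucket for unresolved
    genotypes, which are never silently dropped.
    """
    counts = {"e4_homozygous": 0, "e4_heterozygous": 0, "other": 0, "unknown": 0}
    for p in patients:
        if p.apoe is None:
            counts["unknown"] += 1
        elif p.apoe.e4_count == 2:
            counts["e4_homozygous"] += 1
        elif p.apoe.e4_count == 1:
            counts["e4_heterozygous"] += 1
        else:
            counts["other"] += 1
    return counts


# --------------------------------------------------------------------------
# Metadata I/O

_MISSING = {"", "."}


def load_patients_tsv(path: str | Path) -> list[Patient]:
    """Read patient metadata from TSV.

    Required column: patient_id.  Optional: sex, age_at_onset,
    goldman_score, rs429358_gt + rs7412_gt or apoe_genotype,
    ptau_ab42_ratio, ab42_ab40_ratio.  "." marks a missing value.
    """
    patients = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing required header with patient_id column")
        for i, row in enumerate(reader, start=2):
            def get(col: str) -> Optional[str]:
                v = row.get(col)
                if v is None or v.strip() in _MISSING:
                    return None
                return v.strip()

            try:
                apoe: Optional[APOEGenotype] = None
                if get("apoe_genotype"):
                    apoe = APOEGenotype.from_label(get("apoe_genotype"))  # type: ignore[arg-type]
                elif get("rs429358_gt") and get("rs7412_gt"):
                    apoe = apoe_from_snps(get("rs429358_gt"), get("rs7412_gt"))  # type: ignore[arg-type]
                csf = None
                if get("ptau_ab42_ratio") or get("ab42_ab40_ratio"):
                    csf = CSFProfile(
                        float(get("ptau_ab42_ratio")) if get("ptau_ab42_ratio") else None,
                        float(get("ab42_ab40_ratio")) if get("ab42_ab40_ratio") else None,
                    )
                patients.append(Patient(
                    patient_id=row["patient_id"].strip(),
                    sex=Sex(get("sex")) if get("sex") else None,
                    age_at_onset=int(get("age_at_onset")) if get("age_at_onset") else None,
                    goldman_score=parse_goldman(get("goldman_score") or "none"),
                    apoe=apoe,
                    csf=csf,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from None
    validate_cohort(patients)
    return patients


def write_patients_tsv(patients: Sequence[Patient], path: str | Path) -> None:
    cols = ["patient_id", "sex", "age_at_onset", "goldman_score",
            "rs429358_gt", "rs7412_gt", "apoe_genotype"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for p in patients:
            w.writerow([
                p.patient_id,
                p.sex.value if p.sex else ".",
                p.age_at_onset if p.age_at_onset is not None else ".",
                p.goldman_score.value if p.familial else ".",
                ".", ".",
                p.apoe.label() if p.apoe else ".",
            ])
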