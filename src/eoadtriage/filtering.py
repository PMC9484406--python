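"""Variant selection filters for panel-sequencing calls.

Calls are kept when they (i) fall in the coding target regions or their
7 bp flanks, (ii) are covered by at least 10 reads, (iii) if heterozygous,
show an allelic balance between 0.30 and 0.70 inclusive, and (iv) have a
reference-population (gnomAD non-Finnish European) allele frequency below
1%.  A variant absent from the reference population counts as frequency 0
and passes the rarity filter.  Rejected calls carry the first failed
criterion, checked in the fixed order region -> depth -> allelic balance ->
frequency, so reason codes are deterministic.

Internally coordinates are 0-based half-open; VCF input/output stays
1-based.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence


class Zygosity(Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"


class EffectClass(Enum):
    MISSENSE = "missense"
    SILENT = "silent"
    SPLICE_REGION = "splice_region"
    INDEL_INFRAME = "indel_inframe"
    PTV = "ptv"
    OTHER = "other"


@dataclass(frozen=True)
class VariantCall:
    """One observed alt allele in one patient (post multi-allelic split)."""

    patient_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: Optional[str] = None
    depth: Optional[int] = None
    alt_depth: Optional[int] = None
    ref_depth: Optional[int] = None
    zygosity: Zygosity = Zygosity.HET
    effect_class: EffectClass = EffectClass.OTHER

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if (
            self.depth is not None
            and self.alt_depth is not None
            and self.ref_depth is not None
            and self.alt_depth + self.ref_depth > self.depth
        ):
            raise ValueError(
                f"AD sum {self.alt_depth + self.ref_depth} exceeds DP {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 10
    ab_min: float = 0.30
    ab_max: float = 0.70
    max_maf: float = 0.01
    flank_bp: int = 7
    #: reject calls whose depth/AD fields are missing (set False to keep them)
    drop_missing_quality: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.ab_min < self.ab_max <= 1):
            raise ValueError("require 0 <= ab_min < ab_max <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.max_maf <= 1):
            raise ValueError("max_maf must be in (0, 1]")


class RegionSet:
    """Merged per-chromosome intervals (0-based half-open) with gene labels."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, gene in intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, gene))
        self._starts: dict[str, list[int]] = {}
        self._merged: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int, str]] = []
            for s, e, g in ivs:
                if merged and s <= merged[-1][1] and g == merged[-1][2]:
                    ps, pe, pg = merged[-1]
                    merged[-1] = (ps, max(pe, e), pg)
                elif merged and s < merged[-1][1]:
                    raise ValueError(
                        f"overlapping intervals for different genes at {chrom}:{s}"
                    )
                else:
                    merged.append((s, e, g))
            self._merged[chrom] = merged
            self._starts[chrom] = [s for s, _, _ in merged]

    def lookup(self, chrom: str, pos: int, flank: int = 0) -> Optional[str]:
        """Gene whose (flank-expanded) interval covers 1-based ``pos``."""
        ivs = self._merged.get(chrom)
        if not ivs:
            return None
        p0 = pos - 1  # to 0-based
        i = bisect_right(self._starts[chrom], p0 + flank)
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e, g = ivs[j]
                if s - flank <= p0 < e + flank:
                    return g
        return None

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return self.lookup(chrom, pos) is not None

    @property
    def intervals(self) -> list[tuple[str, int, int, str]]:
        return [
            (c, s, e, g)
            for c in sorted(self._merged)
            for s, e, g in self._merged[c]
        ]

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        """Read a BED-like TSV: chrom, start, end, gene (0-based half-open)."""
        intervals = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("track"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}, line {ln}: expected 4 columns")
                intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
        return cls(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# coordinates: 0-based half-open (BED convention)\n")
            for chrom, s, e, g in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{g}\n")


# --------------------------------------------------------------------------
# VCF reading

def _trim_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix of a ref/alt pair.

    Suffix- then prefix-trimming yields the parsimonious representation for
    already left-aligned input; full left-alignment against a reference
    sequence is out of scope (panel VCFs are caller-normalised upstream).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_vcf(
    path: str | Path,
    sample_map: Optional[Mapping[str, str]] = None,
) -> list[VariantCall]:
    """Read per-sample alt-carrying genotypes from a VCF (v4.x).

    Multi-allelic records are decomposed into one call per alt allele per
    carrier; genotype-level FORMAT/DP is used when present, falling back to
    site INFO/DP; missing AD/DP stay missing rather than becoming zeros.
    ``sample_map`` optionally renames VCF sample names to patient IDs and
    must cover every sample in the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_map is not None:
        missing = [s for s in samples if s not in sample_map]
        if missing:
            raise ValueError(f"samples absent from sample_map: {missing}")
        samples = [sample_map[s] for s in samples]

    calls: list[VariantCall] = []
    for rec in vcf:
        try:
            ad = rec.format("AD")
        except Exception:
            ad = None
        try:
            dp = rec.format("DP")
        except Exception:
            dp = None
        info_dp = rec.INFO.get("DP")
        gene = rec.INFO.get("GENE")
        for si, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            alt_idx = sorted({a for a in alleles if a > 0})
            if not alt_idx:
                continue  # ref-only or fully missing genotype
            for ai in alt_idx:
                alt = rec.ALT[ai - 1]
                if alt is None or alt in {".", "<NON_REF>", "*"}:
                    continue
                n_called = len(alleles)
                if n_called == 1:
                    zyg = Zygosity.HEMI
                elif all(a == ai for a in alleles):
                    zyg = Zygosity.HOM_ALT
                else:
                    zyg = Zygosity.HET
                depth = None
                if dp is not None and dp[si][0] >= 0:
                    depth = int(dp[si][0])
                elif info_dp is not None:
                    depth = int(info_dp)
                ref_d = alt_d = None
                if ad is not None and len(ad[si]) > ai:
                    if ad[si][0] >= 0:
                        ref_d = int(ad[si][0])
                    if ad[si][ai] >= 0:
                        alt_d = int(ad[si][ai])
                pos, ref, alt_t = _trim_allele_pair(rec.POS, rec.REF, alt)
                calls.append(VariantCall(
                    patient_id=samples[si],
                    chrom=rec.CHROM,
                    pos=pos,
                    ref=ref,
                    alt=alt_t,
                    gene=gene,
                    depth=depth,
                    alt_depth=alt_d,
                    ref_depth=ref_d,
                    zygosity=zyg,
                ))
    return calls


# --------------------------------------------------------------------------
# Filters

def allelic_balance(call: VariantCall) -> Optional[float]:
    """Fraction of reads supporting the alt allele; None when not computable."""
    if call.ref_depth is None or call.alt_depth is None:
        return None
    total = call.ref_depth + call.alt_depth
    if total <= 0:
        return None
    return call.alt_depth / total


#: rejection reason codes, in the order the criteria are applied
REASON_REGION = "region"
REASON_DEPTH = "depth"
REASON_AB = "allelic_balance"
REASON_MAF = "maf"
REASON_MISSING = "missing_quality"


@dataclass
class FilterResult:
    kept: list[VariantCall]
    rejected: list[tuple[VariantCall, str]]

    @property
    def reasons(self) -> dict[tuple[str, int, str, str, str], str]:
        return {(c.patient_id, *c.key): r for c, r in self.rejected}


RefFrequency = Callable[[VariantCall], Optional[float]]


def apply_filters(
    calls: Sequence[VariantCall],
    cfg: FilterConfig,
    regions: Optional[RegionSet] = None,
    ref_freq: Optional[RefFrequency] = None,
) -> FilterResult:
    """Partition calls into kept and rejected-with-reason.

    ``ref_freq`` returns the reference-population allele frequency for a
    call, or None when the variant is not reported there (treated as 0).
    ``regions`` may be omitted to skip the region criterion (e.g. when the
    calls were already target-restricted upstream); likewise ``ref_freq``.
    """
    kept: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    for call in calls:
        reason = _first_failure(call, cfg, regions, ref_freq)
        if reason is None:
            kept.append(call)
        else:
            rejected.append((call, reason))
    return FilterResult(kept=kept, rejected=rejected)


def _first_failure(
    call: VariantCall,
    cfg: FilterConfig,
    regions: Optional[RegionSet],
    ref_freq: Optional[RefFrequency],
) -> Optional[str]:
    if regions is not None:
        if regions.lookup(call.chrom, call.pos, flank=cfg.flank_bp) is None:
            return REASON_REGION
    if call.depth is None:
        if cfg.drop_missing_quality:
            return REASON_MISSING
    elif call.depth < cfg.min_depth:
        return REASON_DEPTH
    if call.zygosity is Zygosity.HET:
        ab = allelic_balance(call)
        if ab is None:
            if cfg.drop_missing_quality:
                return REASON_MISSING
        elif not (cfg.ab_min <= ab <= cfg.ab_max):
            return REASON_AB
    if ref_freq is not None:
        freq = ref_freq(call)
        if freq is not None and freq >= cfg.max_maf:
            return REASON_MAF
    return None


def count_distinct_variants(
    calls: Iterable[VariantCall],
    genes: Optional[set[str]] = None,
) -> int:
    """Number of distinct (chrom, pos, ref, alt) among the calls.

    Carriers of the same variant count once.  ``genes`` optionally restricts
    to calls annotated with one of the given gene symbols.
    """
    return len({
        c.key for c in calls if genes is None or c.gene in genes
    })


# --------------------------------------------------------------------------
# Output

def write_filter_tsv(result: FilterResult, path: str | Path) -> None:
    """Write kept and rejected calls with their FILTER status as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["patient_id", "chrom", "pos", "ref", "alt", "gene",
                    "depth", "ref_depth", "alt_depth", "zygosity", "filter"])
        for call, status in [(c, "PASS") for c in result.kept] + result.rejected:
            w.writerow([
                call.patient_id, call.chrom, call.pos, call.ref, call.alt,
                call.gene or ".",
                call.depth if call.depth is not None else ".",
                call.ref_depth if call.ref_depth is not None else ".",
                call.alt_depth if call.alt_depth is not None else ".",
                call.zygosity.value, status,
            ])
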