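"""Synthetic EOAD cohort generator with planted category structure.

The generator emulates the input side of a panel-sequencing study: a
multi-sample VCF on a toy contig ("chrS") with realistic depth and
allele-balance noise, patient metadata with Goldman family-history scores
and APOE SNP genotypes, a knowledge table with ClinVar/HGMD classes and
reference-population allele counts, predictor verdicts for never-reported
variants, and truth files recording every latent assignment.  Each patient
is drawn one latent category (diagnostic / contributor / risk factor /
weak risk / APOE e4-homozygous / unexplained) and receives a planted
variant (or APOE genotype) whose evidence deterministically yields that
category under the classification rules; decoy calls that must fail each
selection filter are planted alongside with their expected rejection
reasons.  The same seed always produces a byte-identical bundle.

Default parameters mirror the study cohort the pipeline was built around:
102 patients, 45.1% familial (strong history in 10/46 of those), age at
onset 56.88 +/- 5.84 years, and category fractions matching the published
per-category carrier counts.

What the generator does not emulate: linkage between variants (one
qualifying variant per patient), per-site genotyping dropout, sequencing
error profiles beyond depth/allele-balance noise, and population structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import optimize, stats as sp_stats

from .annotation import ClinvarClass, KnowledgeTable, KnowledgeRecord, Carrier, PopulationCounts
from .cohort import GoldmanScore
from .consensus import PredictorVerdict, synthesize_verdicts
from .filtering import (
    EffectClass, FilterConfig, RegionSet, VariantCall, Zygosity,
    REASON_AB, REASON_DEPTH, REASON_MAF, REASON_REGION,
)

CONTIG = "chrS"

#: latent patient categories (truth labels)
CATEGORIES = ("diagnostic", "contributor", "risk_factor", "weak_risk",
              "apoe44", "unexplained")


@dataclass(frozen=True)
class ScenarioConfig:
    n_patients: int = 102
    #: latent category probabilities; the remainder is "unexplained"
    diagnostic: float = 9 / 102
    contributor: float = 2 / 102
    risk_factor: float = 8 / 102
    weak_risk: float = 13 / 102
    apoe44: float = 8 / 102
    familial_fraction: float = 46 / 102
    strong_given_familial: float = 10 / 46
    aao_mean: float = 56.88
    aao_sd: float = 5.84
    aao_bounds: tuple[float, float] = (30.0, 65.0)
    depth_mean: float = 80.0
    ab_noise_sd: float = 0.06
    ref_population_size: int = 129100

    def __post_init__(self) -> None:
        fracs = [self.diagnostic, self.contributor, self.risk_factor,
                 self.weak_risk, self.apoe44]
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("category fractions must lie in [0,1] and sum to <= 1")
        for name in ("familial_fraction", "strong_given_familial"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.contributor > 0 and self.familial_fraction < self.contributor:
            raise ValueError(
                "contributor variants require familial carriers: "
                "familial_fraction must be >= the contributor fraction"
            )
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @property
    def unexplained(self) -> float:
        return 1.0 - (self.diagnostic + self.contributor + self.risk_factor
                      + self.weak_risk + self.apoe44)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "aao_bounds" in raw:
            raw["aao_bounds"] = tuple(raw["aao_bounds"])
        return cls(**raw)


# toy contig layout: one 2 kb coding interval per gene, 10 kb apart
_GENES = ("APP", "PSEN1", "PSEN2", "TREM2", "DCTN1", "CLU")
_GENE_START = {g: 10_000 + 10_000 * i for i, g in enumerate(_GENES)}
_GENE_LEN = 2_000

#: genes hosting each planted category
_CATEGORY_GENE = {
    "diagnostic": "PSEN1",
    "contributor": "PSEN2",
    "risk_factor": "TREM2",
    "weak_risk": "DCTN1",
    "benign": "CLU",
}

_BASES = ("A", "C", "G", "T")


def toy_regions() -> RegionSet:
    return RegionSet([
        (CONTIG, _GENE_START[g], _GENE_START[g] + _GENE_LEN, g) for g in _GENES
    ])


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs_c: str
    record: KnowledgeRecord
    carriers: list[tuple[str, Zygosity]]
    kind: str  # "planted" | "decoy"
    expected_category: Optional[str] = None
    expected_reason: Optional[str] = None
    #: decoy knobs consumed by the VCF emitter
    forced_depth: Optional[int] = None
    forced_ab: Optional[float] = None


@dataclass
class SyntheticBundle:
    config: ScenarioConfig
    seed: int
    patients: list[dict]        # metadata rows
    variants: list[PlantedVariant]
    truth_patients: list[dict]  # patient_id, category, familial, strong
    verdicts: dict[tuple[str, str], list[PredictorVerdict]]

    def write(self, out_dir: str | Path) -> Path:
        return _write_bundle(self, Path(out_dir))


def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter such that the (lo, hi)-truncated normal with scale
    ``sd`` has the requested mean."""
    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(sp_stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(optimize.brentq(
        lambda loc: trunc_mean(loc) - mean, mean - 3 * sd, mean + 3 * sd, xtol=1e-6,
    ))


def draw_ages(config: ScenarioConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ages at onset from a truncated normal whose truncated mean equals
    ``aao_mean`` (the truncation at the early-onset bound would otherwise
    bias the sample mean downward)."""
    lo, hi = config.aao_bounds
    loc = _truncnorm_loc(config.aao_mean, config.aao_sd, lo, hi)
    a, b = (lo - loc) / config.aao_sd, (hi - loc) / config.aao_sd
    return sp_stats.truncnorm.rvs(
        a, b, loc=loc, scale=config.aao_sd, size=n, random_state=rng,
    )


def _mutate(base_idx: int) -> tuple[str, str]:
    ref = _BASES[base_idx % 4]
    alt = _BASES[(base_idx + 1) % 4]
    return ref, alt


def _make_variant(
    gene: str,
    offset: int,
    record_kw: dict,
    carriers: list[tuple[str, Zygosity]],
    kind: str = "planted",
    **kw,
) -> PlantedVariant:
    pos = _GENE_START[gene] + offset + 1  # to 1-based
    ref, alt = _mutate(offset)
    hgvs_c = f"c.{offset + 1}{ref}>{alt}"
    rec = KnowledgeRecord(gene=gene, hgvs_c=hgvs_c, **record_kw)
    return PlantedVariant(
        chrom=CONTIG, pos=pos, ref=ref, alt=alt, gene=gene, hgvs_c=hgvs_c,
        record=rec, carriers=carriers, kind=kind, **kw,
    )


def plant_filter_decoys(patient_ids: list[str], ref_n: int) -> list[PlantedVariant]:
    """One decoy call per filter criterion, truth-labelled with the
    rejection reason it must trigger."""
    pid = patient_ids[0]
    benign = dict(clinvar_class=ClinvarClass.BENIGN,
                  effect_class=EffectClass.MISSENSE)
    decoys = [
        # outside every region interval and its flank
        PlantedVariant(
            chrom=CONTIG, pos=5_000, ref="A", alt="G", gene="",
            hgvs_c="decoy_region",
            record=KnowledgeRecord(gene="NOGENE", hgvs_c="decoy_region", **benign),
            carriers=[(pid, Zygosity.HET)], kind="decoy",
            expected_reason=REASON_REGION,
        ),
        _make_variant(
            "APP", 100, dict(population=PopulationCounts(1, ref_n), **benign),
            [(pid, Zygosity.HET)], kind="decoy",
            expected_reason=REASON_DEPTH, forced_depth=9,
        ),
        _make_variant(
            "APP", 200, dict(population=PopulationCounts(1, ref_n), **benign),
            [(pid, Zygosity.HET)], kind="decoy",
            expected_reason=REASON_AB, forced_ab=0.15,
        ),
        # common in the reference population (5%)
        _make_variant(
            "APP", 300,
            dict(population=PopulationCounts(ref_n // 20, ref_n), **benign),
            [(pid, Zygosity.HET)], kind="decoy",
            expected_reason=REASON_MAF,
        ),
    ]
    return decoys


def generate(config: ScenarioConfig, seed: int) -> SyntheticBundle:
    """Draw a cohort and plant variants guaranteeing each latent category."""
    rng = np.random.default_rng(seed)
    n = config.n_patients
    ids = [f"SYN#{i:03d}" for i in range(1, n + 1)]

    # latent categories; contributor carriers are forced familial, so the
    # familial probability of the remaining patients is adjusted to keep the
    # overall familial fraction at its configured value in expectation
    probs = np.array([config.diagnostic, config.contributor, config.risk_factor,
                      config.weak_risk, config.apoe44, config.unexplained])
    categories = [CATEGORIES[i] for i in rng.choice(6, size=n, p=probs)]
    if config.contributor < 1:
        q = (config.familial_fraction - config.contributor) / (1 - config.contributor)
    else:
        q = 1.0
    q = min(max(q, 0.0), 1.0)

    familial = np.empty(n, dtype=bool)
    strong = np.zeros(n, dtype=bool)
    for i, cat in enumerate(categories):
        familial[i] = True if cat == "contributor" else rng.random() < q
        if familial[i]:
            strong[i] = rng.random() < config.strong_given_familial

    ages = np.rint(draw_ages(config, n, rng)).astype(int)
    ages = np.clip(ages, int(config.aao_bounds[0]), int(config.aao_bounds[1]) - 1)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")

    # Goldman labels realising the familial/strong draw
    moderate_cycle = [GoldmanScore.S2, GoldmanScore.S3, GoldmanScore.S3_5]
    strong_cycle = [GoldmanScore.S1, GoldmanScore.S1_5]
    goldman: list[GoldmanScore] = []
    for i in range(n):
        if not familial[i]:
            goldman.append(GoldmanScore.NONE)
        elif strong[i]:
            goldman.append(strong_cycle[i % 2])
        else:
            goldman.append(moderate_cycle[i % 3])

    # APOE SNP genotypes: e4/e4 for the APOE44 category; the rest are e3/e3
    # or e3/e4 (never e4/e4), with a 30% heterozygote rate
    rs429358, rs7412 = [], []
    for i, cat in enumerate(categories):
        if cat == "apoe44":
            rs429358.append("C/C")
            rs7412.append("C/C")
        elif rng.random() < 0.30:
            rs429358.append("T/C")
            rs7412.append("C/C")
        else:
            rs429358.append("T/T")
            rs7412.append("C/C")

    patients = [
        {
            "patient_id": ids[i],
            "sex": str(sexes[i]),
            "age_at_onset": int(ages[i]),
            "goldman_score": goldman[i].value if goldman[i] is not GoldmanScore.NONE else ".",
            "rs429358_gt": rs429358[i],
            "rs7412_gt": rs7412[i],
        }
        for i in range(n)
    ]
    truth_patients = [
        {
            "patient_id": ids[i],
            "category": categories[i],
            "familial": int(familial[i]),
            "strong": int(strong[i]),
            "explained": int(categories[i] != "unexplained"),
        }
        for i in range(n)
    ]

    ref_n = config.ref_population_size
    variants: list[PlantedVariant] = []
    offset = {g: 400 for g in _GENES}  # offsets < 400 reserved for decoys

    def next_offset(gene: str) -> int:
        offset[gene] += 7
        return offset[gene]

    # one unique pathogenic PSEN1 variant per diagnostic patient
    for i, cat in enumerate(categories):
        if cat != "diagnostic":
            continue
        variants.append(_make_variant(
            "PSEN1", next_offset("PSEN1"),
            dict(
                hgvs_p="p.(Xaa1Xaa)", clinvar_class=ClinvarClass.PATHOGENIC,
                hgmd_phenotype="Alzheimer disease",
                effect_class=EffectClass.MISSENSE,
            ),
            [(ids[i], Zygosity.HET)],
            expected_category="diagnostic",
        ))

    # one shared PSEN2 VUS for every contributor patient; absent from the
    # reference population sample, so any cohort carrier is enriched
    contributors = [ids[i] for i, c in enumerate(categories) if c == "contributor"]
    if contributors:
        variants.append(_make_variant(
            "PSEN2", next_offset("PSEN2"),
            dict(
                hgvs_p="p.(Xaa2Xaa)", clinvar_class=ClinvarClass.VUS,
                hgmd_phenotype="Alzheimer disease?",
                population=PopulationCounts(0, ref_n),
                effect_class=EffectClass.MISSENSE,
            ),
            [(pid, Zygosity.HET) for pid in contributors],
            expected_category="contributor",
        ))

    # unique TREM2 VUS per risk-factor patient, too frequent in the
    # reference for a single carrier to reach enrichment
    for i, cat in enumerate(categories):
        if cat != "risk_factor":
            continue
        variants.append(_make_variant(
            "TREM2", next_offset("TREM2"),
            dict(
                hgvs_p="p.(Xaa3Xaa)", clinvar_class=ClinvarClass.VUS,
                hgmd_phenotype="Alzheimer disease?",
                population=PopulationCounts(100, ref_n),
                effect_class=EffectClass.MISSENSE,
            ),
            [(ids[i], Zygosity.HET)],
            expected_category="risk_factor",
        ))

    # unique DCTN1 VUS per weak-risk patient
    for i, cat in enumerate(categories):
        if cat != "weak_risk":
            continue
        variants.append(_make_variant(
            "DCTN1", next_offset("DCTN1"),
            dict(
                hgvs_p="p.(Xaa4Xaa)", clinvar_class=ClinvarClass.VUS,
                hgmd_phenotype="amyotrophic lateral sclerosis",
                population=PopulationCounts(5, ref_n),
                effect_class=EffectClass.MISSENSE,
            ),
            [(ids[i], Zygosity.HET)],
            expected_category="weak_risk",
        ))

    # rare benign CLU background variants for half the unexplained patients
    for i, cat in enumerate(categories):
        if cat != "unexplained" or i % 2:
            continue
        variants.append(_make_variant(
            "CLU", next_offset("CLU"),
            dict(
                hgvs_p="p.(Xaa5Xaa)", clinvar_class=ClinvarClass.BENIGN,
                population=PopulationCounts(min(1000, ref_n), ref_n),
                effect_class=EffectClass.MISSENSE,
            ),
            [(ids[i], Zygosity.HET)],
            expected_category="benign",
        ))

    variants.extend(plant_filter_decoys(ids, ref_n))
    return SyntheticBundle(
        config=config, seed=seed, patients=patients, variants=variants,
        truth_patients=truth_patients, verdicts={},
    )


# --------------------------------------------------------------------------
# Bundle serialisation

def _draw_call_depths(
    v: PlantedVariant,
    config: ScenarioConfig,
    rng: np.random.Generator,
    cfg: FilterConfig = FilterConfig(),
) -> dict[str, tuple[int, int, int]]:
    """(depth, ref_depth, alt_depth) per carrier, honouring decoy knobs and
    guaranteeing clean calls pass the depth and allele-balance criteria."""
    out: dict[str, tuple[int, int, int]] = {}
    for pid, zyg in v.carriers:
        if v.forced_depth is not None:
            depth = v.forced_depth
        else:
            depth = max(cfg.min_depth, int(rng.poisson(config.depth_mean)))
        if zyg is Zygosity.HOM_ALT:
            alt = depth
        else:
            if v.forced_ab is not None:
                ab = v.forced_ab
            else:
                ab = float(np.clip(
                    rng.normal(0.5, config.ab_noise_sd), cfg.ab_min, cfg.ab_max,
                ))
            alt = int(round(ab * depth))
            if v.forced_ab is None:
                # keep the realised balance inside the window after rounding
                alt = min(max(alt, math.ceil(cfg.ab_min * depth)),
                          math.floor(cfg.ab_max * depth))
        out[pid] = (depth, depth - alt, alt)
    return out


def _write_bundle(bundle: SyntheticBundle, out_dir: Path) -> Path:
    import csv
    from importlib import resources

    out_dir.mkdir(parents=True, exist_ok=True)
    config, seed = bundle.config, bundle.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    ids = [p["patient_id"] for p in bundle.patients]

    # patients.tsv
    with open(out_dir / "patients.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        cols = ["patient_id", "sex", "age_at_onset", "goldman_score",
                "rs429358_gt", "rs7412_gt"]
        w.writerow(cols)
        for p in bundle.patients:
            w.writerow([p[c] for c in cols])

    # regions + panels
    toy_regions().to_bed(out_dir / "regions.bed")
    panels_src = resources.files("eoadtriage").joinpath("data/panels.yaml")
    (out_dir / "panels.yaml").write_text(panels_src.read_text())

    # knowledge table + verdicts (planted variants only need verdicts when
    # never reported; none are in the default scenario, but decoys and
    # user-extended scenarios may add them)
    table = KnowledgeTable()
    for v in bundle.variants:
        for pid, zyg in v.carriers:
            table.add(v.record, Carrier(patient_id=pid, zygosity=zyg))
    table.to_tsv(out_dir / "knowledge.tsv")

    verdicts = dict(bundle.verdicts)
    for v in bundle.variants:
        if v.record.novel and v.record.effect_class is not EffectClass.PTV:
            verdicts.setdefault(
                (v.gene, v.hgvs_c),
                synthesize_verdicts(v.record.effect_class, damaging=False),
            )
    with open(out_dir / "verdicts.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "hgvs_c", "tool", "verdict"])
        for key in sorted(verdicts):
            for pv in verdicts[key]:
                w.writerow([key[0], key[1], pv.tool.value, pv.verdict.value])

    # variant map (coordinate -> HGVS adapter)
    with open(out_dir / "variant_map.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "gene", "hgvs_c"])
        for v in sorted(bundle.variants, key=lambda v: v.pos):
            w.writerow([v.chrom, v.pos, v.ref, v.alt, v.record.gene, v.hgvs_c])

    # truth files
    with open(out_dir / "truth.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["patient_id", "category", "familial", "strong", "explained"])
        for row in bundle.truth_patients:
            w.writerow([row["patient_id"], row["category"], row["familial"],
                        row["strong"], row["explained"]])
    with open(out_dir / "truth_variants.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "gene", "hgvs_c", "kind",
                    "carriers", "expected_category", "expected_reason"])
        for v in sorted(bundle.variants, key=lambda v: v.pos):
            w.writerow([
                v.chrom, v.pos, v.ref, v.alt, v.record.gene, v.hgvs_c, v.kind,
                ",".join(pid for pid, _ in v.carriers),
                v.expected_category or ".", v.expected_reason or ".",
            ])

    # VCF
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length=200000>",
        f"##source=eoadtriage-simulate(seed={seed})",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    for v in sorted(bundle.variants, key=lambda v: (v.pos, v.alt)):
        depths = _draw_call_depths(v, config, rng)
        carrier_zyg = dict(v.carriers)
        fields = []
        for pid in ids:
            if pid in carrier_zyg:
                depth, ref_d, alt_d = depths[pid]
                gt = "1/1" if carrier_zyg[pid] is Zygosity.HOM_ALT else "0/1"
                fields.append(f"{gt}:{ref_d},{alt_d}:{depth}")
            else:
                depth = max(10, int(rng.poisson(config.depth_mean)))
                fields.append(f"0/0:{depth},0:{depth}")
        info = f"GENE={v.record.gene}" if v.record.gene else "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT:AD:DP\t"
            + "\t".join(fields)
        )
    (out_dir / "cohort.vcf").write_text("\n".join(lines) + "\n")
    return out_dir


# --------------------------------------------------------------------------
# Truth-side helpers used by recovery experiments

def recovered_patient_category(
    explained_by: frozenset,
    variant_categories: list[str],
) -> str:
    """Collapse pipeline output for one patient back to a latent category."""
    from .classify import ClinicalCategory, ExplanationSource

    if ClinicalCategory.DIAGNOSTIC.value in variant_categories:
        return "diagnostic"
    if ClinicalCategory.CONTRIBUTOR.value in variant_categories:
        return "contributor"
    names = {s.value for s in explained_by}
    if ExplanationSource.MODERATE_RISK.value in names:
        return "risk_factor"
    if ExplanationSource.NON_AD_GENE.value in names:
        return "weak_risk"
    if ExplanationSource.APOE44.value in names:
        return "apoe44"
    return "unexplained"
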