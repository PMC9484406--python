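"""Cohort-versus-reference allele-count enrichment.

Each variant's cohort allele count is compared with its gnomAD non-Finnish
European count in a 2x2 table tested with the two-sided Fisher exact test
(minimum-likelihood convention: the p-value sums the probabilities of all
tables with the same margins whose point probability does not exceed the
observed one, with a 1e-7 relative tolerance on the comparison — the
convention shared by R and SciPy).  P-values are adjusted per reporting
family with the Benjamini-Hochberg step-up procedure; variants absent from
the reference population are not testable and are excluded from the family
rather than tested against a zero count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .annotation import PopulationCounts
from .filtering import Zygosity


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table: cohort alt/total vs reference alt/total."""

    cohort_alt: int
    cohort_total: int
    ref_alt: int
    ref_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.cohort_alt <= self.cohort_total):
            raise ValueError(f"invalid cohort counts in {self}")
        if not (0 <= self.ref_alt <= self.ref_total):
            raise ValueError(f"invalid reference counts in {self}")
        if self.cohort_total <= 0 or self.ref_total <= 0:
            raise ValueError("allele totals must be positive")

    @property
    def as_2x2(self) -> list[list[int]]:
        return [
            [self.cohort_alt, self.cohort_total - self.cohort_alt],
            [self.ref_alt, self.ref_total - self.ref_alt],
        ]


@dataclass(frozen=True)
class EnrichmentResult:
    raw_p: float
    adj_p: float
    table: AlleleTable
    test_family_size: int

    def __post_init__(self) -> None:
        if not (0 <= self.raw_p <= self.adj_p <= 1 + 1e-12):
            raise ValueError(f"require 0 <= raw_p <= adj_p <= 1, got {self}")

    @property
    def significant(self) -> bool:
        return self.adj_p < 0.05


def fisher_exact_two_sided(table: AlleleTable) -> float:
    """Two-sided Fisher exact p-value for an allele-count table.

    A degenerate table (an all-zero or all-full alt column) carries no
    evidence either way and returns 1 by convention.
    """
    k = table.cohort_alt + table.ref_alt
    n = table.cohort_total + table.ref_total
    if k == 0 or k == n:
        return 1.0
    return float(sp_stats.fisher_exact(table.as_2x2, alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_variant(
    carrier_zygosities: Sequence[Zygosity],
    n_genotyped: int,
    ref: Optional[PopulationCounts],
) -> Optional[AlleleTable]:
    """Build the cohort-vs-reference allele table for one variant.

    Alt alleles: HET and HEMI carriers contribute 1, HOM_ALT carriers 2.
    The cohort allele denominator is 2 per genotyped patient, less one per
    hemizygous carrier.  Returns None (not testable) when the variant has
    no reference-population record.
    """
    if n_genotyped < len(carrier_zygosities):
        raise ValueError("n_genotyped smaller than the number of carriers")
    if ref is None:
        return None
    alt = sum(2 if z is Zygosity.HOM_ALT else 1 for z in carrier_zygosities)
    n_hemi = sum(z is Zygosity.HEMI for z in carrier_zygosities)
    return AlleleTable(
        cohort_alt=alt,
        cohort_total=2 * n_genotyped - n_hemi,
        ref_alt=ref.ac_alt,
        ref_total=ref.ac_total,
    )


def enrich_family(
    tables: dict[tuple[str, str], Optional[AlleleTable]],
) -> dict[tuple[str, str], Optional[EnrichmentResult]]:
    """Test every testable variant of one reporting family and BH-adjust.

    The family is the set of testable variants passed in one call — one
    results table in report terms.  Non-testable entries (None) come back
    as None and do not enter the family size.
    """
    keys = sorted(k for k, t in tables.items() if t is not None)
    raw = [fisher_exact_two_sided(tables[k]) for k in keys]  # type: ignore[arg-type]
    adj = bh_adjust(raw)
    m = len(keys)
    out: dict[tuple[str, str], Optional[EnrichmentResult]] = {
        k: None for k in tables
    }
    for k, rp, ap in zip(keys, raw, adj):
        out[k] = EnrichmentResult(
            raw_p=rp, adj_p=min(float(ap), 1.0),
            table=tables[k], test_family_size=m,  # type: ignore[arg-type]
        )
    return out
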