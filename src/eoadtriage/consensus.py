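"""Consensus pathogenicity prediction for never-reported variants.

Missense variants are judged by four tools (PolyPhen-2, M-CAP, CADD,
MutationTaster) and called likely pathogenic when at least three of the
four predict a damaging effect.  Splice-region variants use three splice
predictors (NetGene2, MaxEntScan, Human Splicing Finder) and silent
variants three tools (MutationTaster, CADD, FATHMM-XF); for these
three-tool classes a simple majority (at least 2 of 3) is required — the
threshold is configurable since only the four-tool rule is fixed by
convention.  Two positional rules precede voting: a never-reported APP
variant outside exons 16/17 (the amyloid-beta region) is considered likely
benign regardless of tool output, and a never-reported protein-truncating
variant is presumed damaging.

The module consumes tool *verdicts* (damaging / tolerated / no call), not
raw scores; thresholding raw scores is the verdict provider's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import csv

from .annotation import AnnotatedVariant
from .filtering import EffectClass


class Tool(Enum):
    POLYPHEN2 = "polyphen2"
    MCAP = "mcap"
    CADD = "cadd"
    MUTATIONTASTER = "mutationtaster"
    NETGENE2 = "netgene2"
    MAXENTSCAN = "maxentscan"
    HSF = "hsf"
    FATHMM_XF = "fathmm_xf"


class Verdict(Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class PredictorVerdict:
    tool: Tool
    verdict: Verdict


#: tool battery per consequence class; in-frame indels are scored by the
#: missense battery (those tools accept small in-frame changes)
TOOLSETS: dict[EffectClass, frozenset[Tool]] = {
    EffectClass.MISSENSE: frozenset({
        Tool.POLYPHEN2, Tool.MCAP, Tool.CADD, Tool.MUTATIONTASTER,
    }),
    EffectClass.INDEL_INFRAME: frozenset({
        Tool.POLYPHEN2, Tool.MCAP, Tool.CADD, Tool.MUTATIONTASTER,
    }),
    EffectClass.SPLICE_REGION: frozenset({
        Tool.NETGENE2, Tool.MAXENTSCAN, Tool.HSF,
    }),
    EffectClass.SILENT: frozenset({
        Tool.MUTATIONTASTER, Tool.CADD, Tool.FATHMM_XF,
    }),
}

#: amyloid-beta-encoding APP exons; novel APP variants elsewhere are benign
APP_PATHOGENIC_EXONS = frozenset({16, 17})


class ConsensusLabel(Enum):
    LIKELY_PATHOGENIC = "likely_pathogenic"
    LIKELY_BENIGN = "likely_benign"


@dataclass(frozen=True)
class ConsensusResult:
    label: ConsensusLabel
    votes_damaging: int
    votes_total: int
    rule_applied: str

    def __post_init__(self) -> None:
        if self.votes_damaging > self.votes_total:
            raise ValueError("votes_damaging exceeds votes_total")


@dataclass(frozen=True)
class ConsensusConfig:
    #: damaging votes required out of the four missense tools
    missense_threshold: int = 3
    #: damaging votes required out of the three splice/silent tools
    three_tool_threshold: int = 2
    #: whether NO_CALL counts toward the damaging tally (default: it does
    #: not, conservative toward benignity)
    no_call_damaging: bool = False
    #: presume never-reported protein-truncating variants damaging
    ptv_presumed_damaging: bool = True


def consensus_classify(
    effect_class: EffectClass,
    verdicts: Sequence[PredictorVerdict],
    gene: str,
    app_exon: Optional[int] = None,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> ConsensusResult:
    """Classify a never-reported variant from predictor verdicts.

    The APP positional rule dominates: for gene APP the exon must be given,
    and outside exons 16/17 the variant is likely benign whatever the tools
    say.  Verdict order never matters; each tool may appear at most once
    and the tool set must match the consequence class.
    """
    if gene == "APP":
        if app_exon is None:
            raise ValueError("APP variant requires app_exon for the positional rule")
        if app_exon not in APP_PATHOGENIC_EXONS:
            return ConsensusResult(
                ConsensusLabel.LIKELY_BENIGN, 0, len(verdicts),
                rule_applied="app_outside_exon_16_17",
            )

    if effect_class is EffectClass.PTV and cfg.ptv_presumed_damaging:
        return ConsensusResult(
            ConsensusLabel.LIKELY_PATHOGENIC, 0, 0,
            rule_applied="ptv_presumed_damaging",
        )

    expected = TOOLSETS.get(effect_class)
    if expected is None:
        raise ValueError(f"no predictor battery defined for {effect_class}")
    tools = [v.tool for v in verdicts]
    if len(set(tools)) != len(tools):
        raise ValueError("duplicate tool verdicts")
    if set(tools) != set(expected):
        raise ValueError(
            f"verdict tool set {sorted(t.value for t in tools)} does not match "
            f"the {effect_class.value} battery {sorted(t.value for t in expected)}"
        )

    damaging = sum(
        1 for v in verdicts
        if v.verdict is Verdict.DAMAGING
        or (cfg.no_call_damaging and v.verdict is Verdict.NO_CALL)
    )
    total = len(verdicts)
    if total == 4:
        threshold, rule = cfg.missense_threshold, f"ge_{cfg.missense_threshold}_of_4"
    else:
        threshold, rule = cfg.three_tool_threshold, f"ge_{cfg.three_tool_threshold}_of_3"
    label = (
        ConsensusLabel.LIKELY_PATHOGENIC if damaging >= threshold
        else ConsensusLabel.LIKELY_BENIGN
    )
    return ConsensusResult(label, damaging, total, rule_applied=rule)


def count_consensus_label(
    results: Iterable[tuple[AnnotatedVariant, ConsensusResult]],
    label: ConsensusLabel,
    restrict_genes: Optional[set[str]] = None,
) -> int:
    """Distinct variants whose consensus carries the given label."""
    return len({
        v.key for v, r in results
        if r.label is label and (restrict_genes is None or v.gene in restrict_genes)
    })


# --------------------------------------------------------------------------
# Verdict table I/O

def load_verdicts_tsv(path: str | Path) -> dict[tuple[str, str], list[PredictorVerdict]]:
    """Read a verdict TSV: gene, hgvs_c, tool, verdict (one row per tool)."""
    verdicts: dict[tuple[str, str], list[PredictorVerdict]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "hgvs_c", "tool", "verdict"}
        if not required <= set(reader.fieldnames or []):
            raise ValueError(f"{path}: verdict TSV requires columns {sorted(required)}")
        for ln, row in enumerate(reader, start=2):
            try:
                pv = PredictorVerdict(
                    Tool(row["tool"].strip().lower()),
                    Verdict(row["verdict"].strip().lower()),
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {ln}: {exc}") from None
            verdicts.setdefault((row["gene"].strip(), row["hgvs_c"].strip()), []).append(pv)
    return verdicts


def write_verdicts_tsv(
    verdicts: dict[tuple[str, str], list[PredictorVerdict]],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "hgvs_c", "tool", "verdict"])
        for (gene, hgvs_c) in sorted(verdicts):
            for pv in verdicts[(gene, hgvs_c)]:
                w.writerow([gene, hgvs_c, pv.tool.value, pv.verdict.value])


def synthesize_verdicts(
    effect_class: EffectClass,
    damaging: bool,
) -> list[PredictorVerdict]:
    """Build a verdict set for the class's tool battery that votes uniformly
    damaging or leaves a single damaging vote (below every threshold).

    This is a convenience for constructing predictor-output stand-ins when
    only a summary prediction label is available, e.g. when transcribing a
    published table that prints the consensus call but not per-tool scores.
    """
    tools = sorted(TOOLSETS[effect_class], key=lambda t: t.value)
    out = []
    for i, tool in enumerate(tools):
        if damaging:
            verdict = Verdict.DAMAGING
        else:
            # a single damaging vote stays below the 2-of-3 and 3-of-4 bars
            verdict = Verdict.DAMAGING if i == 0 else Verdict.TOLERATED
        out.append(PredictorVerdict(tool, verdict))
    return out
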