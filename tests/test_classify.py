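"""Clinical decision tree, patient explanations and cohort aggregation."""

import pytest

from eoadtriage.annotation import PanelName
from eoadtriage.classify import (
    BENIGN_SPECTRUM, ClinicalCategory, ExplanationSource, PatientExplanation,
    classify_variant, count_category_patients, explain_patient, percent,
    summarize_cohort,
)
from eoadtriage.cohort import (
    APOEGenotype, GoldmanScore, Patient, parse_goldman,
)

C = ClinicalCategory

#: printed clinical labels for the causative-gene table; the benign versus
#: likely-benign wording is not self-consistent in print (see the likewise
#: inconsistent p.Ser236= and p.Thr743= rows), so benign-spectrum rows are
#: compared as one equivalence class
TABLE2_LABELS = {
    ("APP", "c.1305C>T"): C.BENIGN,
    ("APP", "c.2137G>A"): C.DIAGNOSTIC,
    ("APP", "c.2229C>T"): C.BENIGN,
    ("PSEN1", "c.104G>A"): C.RISK_FACTOR,
    ("PSEN1", "c.253C>T"): C.DIAGNOSTIC,
    ("PSEN1", "c.275G>C"): C.DIAGNOSTIC,
    ("PSEN1", "c.497T>A"): C.DIAGNOSTIC,
    ("PSEN1", "c.617G>C"): C.DIAGNOSTIC,
    ("PSEN1", "c.791C>T"): C.DIAGNOSTIC,
    ("PSEN1", "c.1172T>C"): C.DIAGNOSTIC,
    ("PSEN1", "c.1315A>G"): C.DIAGNOSTIC,
    ("PSEN1", "c.185G>A"): C.BENIGN,
    ("PSEN2", "c.211C>T"): C.RISK_FACTOR,
    ("PSEN2", "c.520A>G"): C.CONTRIBUTOR,
    ("PSEN2", "c.668G>C"): C.DIAGNOSTIC,
    ("PSEN2", "c.708T>C"): C.LIKELY_BENIGN,
    ("PSEN2", "c.1186C>T"): C.DIAGNOSTIC,
}

TABLE3_LABELS = {
    ("TREM2", "c.140G>A"): C.RISK_FACTOR,
    ("TREM2", "c.287C>A"): C.RISK_FACTOR,
    ("TREM2", "c.632T>C"): C.RISK_FACTOR,
    ("TREM2", "c.407G>A"): C.RISK_FACTOR,
    ("TREM2", "c.668C>T"): C.RISK_FACTOR,
}

TABLE5_LABELS = {
    ("ABCA7", "c.2126_2132delAGCAGGG"): C.RISK_FACTOR,
    ("ABCA7", "c.2476G>A"): C.RISK_FACTOR,
    ("ABCA7", "c.2629G>A"): C.LIKELY_BENIGN,
    ("ABCA7", "c.3412A>C"): C.RISK_FACTOR,
    ("ABCA7", "c.3472+5G>C"): C.RISK_FACTOR,
    ("ABCA7", "c.4343G>A"): C.LIKELY_BENIGN,
    ("ABCA7", "c.4795G>A"): C.LIKELY_BENIGN,
    ("ABCA7", "c.5570+5G>C"): C.RISK_FACTOR,
    ("SORL1", "c.133G>T"): C.RISK_FACTOR,
    ("SORL1", "c.1805C>T"): C.RISK_FACTOR,
    ("SORL1", "c.3346A>G"): C.LIKELY_BENIGN,
    ("SORL1", "c.4077C>T"): C.RISK_FACTOR,
    ("SORL1", "c.5448T>C"): C.LIKELY_BENIGN,
    ("SORL1", "c.6150A>G"): C.LIKELY_BENIGN,
}


def _same_label(got: ClinicalCategory, expected: ClinicalCategory) -> bool:
    if expected in BENIGN_SPECTRUM:
        return got in BENIGN_SPECTRUM
    return got is expected


class TestPublishedLabelReproduction:
    @pytest.mark.parametrize("labels", [TABLE2_LABELS, TABLE3_LABELS, TABLE5_LABELS],
                             ids=["causative", "trem2", "abca7_sorl1"])
    def test_printed_labels_reproduced(self, published, labels):
        got = {v.key: v.category for v in published.classified}
        for key, expected in labels.items():
            assert _same_label(got[key], expected), (key, got[key], expected)

    def test_every_published_variant_classified(self, published):
        assert len(published.classified) == 17 + 5 + 33 + 14 + 26
        for v in published.classified:
            if v.category is not C.UNCLASSIFIED:
                assert v.rationale

    def test_contributor_requires_both_conditions(self, published):
        """The contributor call rests on a familial carrier AND enrichment."""
        v = next(v for v in published.classified if v.key == ("PSEN2", "c.520A>G"))
        assert v.category is C.CONTRIBUTOR
        assert v.enrichment is not None and v.enrichment.adj_p < 0.05
        # same evidence class, sporadic carriers only -> risk factor
        v2 = next(v for v in published.classified if v.key == ("PSEN2", "c.211C>T"))
        assert v2.category is C.RISK_FACTOR

    def test_novel_consensus_drives_causative_diagnostic(self, published):
        v = next(v for v in published.classified if v.key == ("PSEN1", "c.253C>T"))
        assert v.annotated.novel and v.category is C.DIAGNOSTIC

    def test_missing_consensus_for_novel_rejected(self, published):
        v = next(v for v in published.classified if v.key == ("PSEN1", "c.253C>T"))
        with pytest.raises(ValueError, match="consensus"):
            classify_variant(v.annotated, consensus=None)


class TestPatientCounts:
    CAUSATIVE = {"APP", "PSEN1", "PSEN2"}

    def test_nine_diagnostic_carriers(self, published):
        n, pct = count_category_patients(
            published.classified, {C.DIAGNOSTIC}, genes=self.CAUSATIVE,
            cohort_size=102)
        assert (n, pct) == (9, 8.82)

    def test_diagnostic_or_contributor_carriers(self, published):
        n, pct = count_category_patients(
            published.classified, {C.DIAGNOSTIC, C.CONTRIBUTOR},
            genes=self.CAUSATIVE, cohort_size=102)
        assert (n, pct) == (11, 10.78)

    def test_moderate_risk_carriers(self, published):
        n, pct = count_category_patients(
            published.classified, {C.RISK_FACTOR},
            genes={"PSEN1", "PSEN2", "TREM2"}, cohort_size=102)
        assert (n, pct) == (8, 7.84)

    def test_double_carrier_counted_once(self, published):
        """One patient carries two diagnostic variants (APP + PSEN1) and
        must appear once in the carrier count."""
        diag = [v for v in published.classified
                if v.category is C.DIAGNOSTIC and v.gene in self.CAUSATIVE]
        all_carriers = [pid for v in diag for pid in v.carrier_ids]
        assert len(all_carriers) == 10 and len(set(all_carriers)) == 9


class TestExplainPatient:
    def test_causative_from_diagnostic_variant(self, published):
        by_patient = published.by_patient
        expl = explain_patient(
            next(p for p in published.patients if p.patient_id == "AD#055"),
            by_patient["AD#055"])
        assert ExplanationSource.CAUSATIVE in expl.explained_by

    def test_apoe44_without_variants(self):
        p = Patient("X", apoe=APOEGenotype.from_label("e4/e4"))
        expl = explain_patient(p, [])
        assert expl.explained_by == {ExplanationSource.APOE44}

    def test_benign_only_is_unexplained(self, published):
        p = next(p for p in published.patients if p.patient_id == "AD#022")
        expl = explain_patient(p, published.by_patient["AD#022"])
        # AD#022 carries the benign PSEN1 p.Arg62His and an unclassified
        # GWAS-gene variant: neither explains the disease
        assert not expl.explained

    def test_foreign_variant_rejected(self, published):
        p = Patient("ZZZ")
        with pytest.raises(ValueError):
            explain_patient(p, published.by_patient["AD#055"])


class TestSummaries:
    def test_published_family_history_marginals(self, published):
        s = published.summary
        assert (s.n_patients, s.n_familial, s.n_strong) == (102, 46, 10)
        assert s.familial_percent == 45.10
        assert s.strong_percent_of_familial == 21.74

    def test_percent_rounding_half_up(self):
        assert percent(46, 102) == 45.10
        assert percent(10, 46) == 21.74
        assert percent(1, 800) == 0.13  # 0.125 rounds up, not to even
        assert percent(0, 0) == 0.0

    def test_empty_cohort_summary(self):
        s = summarize_cohort([], [])
        assert s.n_patients == 0 and s.explained_fraction_familial == 0.0

    def test_missing_explanation_rejected(self):
        with pytest.raises(ValueError, match="X"):
            summarize_cohort([Patient("X")], [])

    def test_percentages_recompute_from_counts(self, published):
        s = published.summary
        assert s.explained_fraction_familial == percent(s.explained_familial, s.n_familial)
        assert s.explained_fraction_sporadic == percent(s.explained_sporadic, s.n_sporadic)


class TestRuleDeterminism:
    def test_carrier_order_never_changes_category(self, published):
        for v in published.classified:
            if len(v.annotated.carriers) < 2:
                continue
            reversed_ann = type(v.annotated)(
                knowledge=v.annotated.knowledge,
                carriers=tuple(reversed(v.annotated.carriers)),
                panel=v.annotated.panel,
            )
            carriers_fh = [
                Patient("t", goldman_score=parse_goldman(c.fh_score_label)).family_history
                for c in reversed_ann.carriers
            ]
            redone = classify_variant(
                reversed_ann, consensus=v.consensus, enrichment=v.enrichment,
                carriers_fh=carriers_fh,
            )
            assert redone.category is v.category
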