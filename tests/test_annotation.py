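"""Knowledge tables, gene panels and the annotation join."""

import pytest

from eoadtriage.annotation import (
    AnnotatedVariant, Carrier, ClinvarClass, GenePanel, KnowledgeRecord,
    KnowledgeTable, LiteratureFlag, PanelName, PanelSet, PopulationCounts,
    annotate, count_variants_and_genes, infer_effect_class,
    parse_population_counts,
)
from eoadtriage.filtering import EffectClass


class TestPopulationCounts:
    def test_parse_printed_format(self):
        pc = parse_population_counts("506/129030")
        assert (pc.ac_alt, pc.ac_total) == (506, 129030)
        assert pc.frequency == pytest.approx(506 / 129030)

    @pytest.mark.parametrize("text", ["NR", "NA", ".", ""])
    def test_not_reported(self, text):
        assert parse_population_counts(text) is None

    @pytest.mark.parametrize("text", ["506", "a/b", "5/-1", "1/2/3"])
    def test_malformed_rejected(self, text):
        with pytest.raises(ValueError):
            parse_population_counts(text)

    def test_alt_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            PopulationCounts(10, 5)


class TestEffectClass:
    @pytest.mark.parametrize("hgvs_c,hgvs_p,expected", [
        ("c.617G>C", "p.Gly206Ala", EffectClass.MISSENSE),
        ("c.1305C>T", "p.Phe435=", EffectClass.SILENT),
        ("c.3472+5G>C", "", EffectClass.SPLICE_REGION),
        ("c.1462-3C>T", "", EffectClass.SPLICE_REGION),
        ("c.2467C>T", "p.Gln823Ter", EffectClass.PTV),
        ("c.556dupC", "p.Gln186ProfsTer19", EffectClass.PTV),
        ("c.430_447del", "p.Gly144_Tyr149del", EffectClass.INDEL_INFRAME),
        ("c.100A>G", "", EffectClass.OTHER),
    ])
    def test_inference(self, hgvs_c, hgvs_p, expected):
        assert infer_effect_class(hgvs_c, hgvs_p) is expected


class TestPanels:
    def test_packaged_panels_disjoint_and_complete(self, panels):
        assert panels.genes(PanelName.AD_CAUSATIVE) == {"APP", "PSEN1", "PSEN2"}
        assert {"TREM2", "ABCA7", "SORL1"} <= panels.genes(PanelName.AD_RISK)
        assert len(panels.genes(PanelName.OTHER_DEMENTIA)) == 12
        assert len(panels.genes(PanelName.AD_GWAS)) == 34
        assert panels.panel_of("PSEN1") is PanelName.AD_CAUSATIVE
        assert panels.panel_of("UNKNOWN_GENE") is PanelName.NONE

    def test_overlapping_panels_rejected(self):
        with pytest.raises(ValueError, match="TREM2"):
            PanelSet([
                GenePanel(PanelName.AD_CAUSATIVE, frozenset({"APP", "PSEN1", "PSEN2"})),
                GenePanel(PanelName.AD_RISK, frozenset({"TREM2"})),
                GenePanel(PanelName.OTHER_DEMENTIA, frozenset({"TREM2", "MAPT"})),
            ])

    def test_causative_panel_content_enforced(self):
        with pytest.raises(ValueError, match="ad_causative"):
            PanelSet([GenePanel(PanelName.AD_CAUSATIVE, frozenset({"APP"}))])


def _record(**kw):
    defaults = dict(gene="PSEN1", hgvs_c="c.1A>G", hgvs_p="p.Met1Val",
                    clinvar_class=ClinvarClass.VUS)
    defaults.update(kw)
    return KnowledgeRecord(**defaults)


class TestKnowledgeTable:
    def test_conflicting_detail_iff_conflicting(self):
        with pytest.raises(ValueError):
            _record(conflicting_detail={ClinvarClass.VUS: 2})
        with pytest.raises(ValueError):
            _record(clinvar_class=ClinvarClass.CONFLICTING)

    def test_novel_iff_absent_from_both(self):
        assert _record(clinvar_class=ClinvarClass.NOT_REPORTED).novel
        assert not _record(clinvar_class=ClinvarClass.NOT_REPORTED,
                           hgmd_phenotype="Alzheimer disease").novel
        assert not _record().novel

    def test_conflicting_duplicate_rows_rejected(self):
        table = KnowledgeTable()
        table.add(_record(), Carrier("P1"))
        table.add(_record(), Carrier("P2"))  # extra carrier: fine
        with pytest.raises(ValueError, match="duplicate carrier"):
            table.add(_record(), Carrier("P1"))
        with pytest.raises(ValueError, match="conflicting duplicate"):
            table.add(_record(clinvar_class=ClinvarClass.BENIGN), Carrier("P3"))

    def test_tsv_roundtrip(self, tables, tmp_path):
        for name, table in tables.items():
            out = tmp_path / f"{name}.tsv"
            table.to_tsv(out)
            back = KnowledgeTable.from_tsv(out)
            assert back.records == table.records
            assert back.carriers == table.carriers

    def test_unknown_class_label_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene\thgvs_c\thgvs_p\tpatient_id\tfh_score\tclinvar\thgmd\tgnomad_nfe\n"
            "APP\tc.1A>G\t.\tP1\t0\tbogus\tNR\tNR\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            KnowledgeTable.from_tsv(path)


class TestAnnotate:
    def test_known_pathogenic_in_causative_panel(self, tables, panels):
        ann = annotate(tables["causative_ad_genes"], panels)
        by_key = {v.key: v for v in ann}
        v = by_key[("PSEN1", "c.275G>C")]
        assert v.knowledge.clinvar_class is ClinvarClass.PATHOGENIC
        assert v.panel is PanelName.AD_CAUSATIVE and not v.novel

    def test_risk_gene_with_hgmd_risk_annotation(self, tables, panels):
        ann = annotate(tables["trem2"], panels)
        v = {x.key: x for x in ann}[("TREM2", "c.140G>A")]
        assert v.knowledge.clinvar_class is ClinvarClass.LIKELY_BENIGN
        assert v.knowledge.hgmd_risk_annotation
        assert v.panel is PanelName.AD_RISK

    def test_novel_variant_flagged(self, tables, panels):
        ann = annotate(tables["causative_ad_genes"], panels)
        assert {x.key: x for x in ann}[("PSEN1", "c.253C>T")].novel

    def test_annotate_is_pure_join(self, tables, panels):
        once = annotate(tables["trem2"], panels)
        twice = annotate(tables["trem2"], panels)
        assert once == twice

    def test_population_not_imputed(self, tables, panels):
        ann = annotate(tables["causative_ad_genes"], panels)
        v = {x.key: x for x in ann}[("PSEN1", "c.253C>T")]
        assert v.knowledge.population is None  # NR propagates, never 0


class TestPublishedTableCounts:
    def test_other_dementia_33_variants_12_genes(self, tables, panels):
        ann = annotate(tables["other_dementia_genes"], panels)
        n_var, n_gene, _ = count_variants_and_genes(ann, PanelName.OTHER_DEMENTIA)
        assert (n_var, n_gene) == (33, 12)

    def test_trem2_five_singletons_in_four_patients(self, tables, panels):
        ann = annotate(tables["trem2"], panels)
        assert count_variants_and_genes(ann, PanelName.AD_RISK, genes={"TREM2"}) \
            == (5, 1, 4)

    def test_empty_panel(self, tables, panels):
        ann = annotate(tables["trem2"], panels)
        assert count_variants_and_genes(ann, PanelName.AD_GWAS) == (0, 0, 0)

    def test_all_fixture_rows_are_rare(self, tables):
        """Reference frequencies below 1% throughout — the tables contain
        only rare variants; a violation flags a transcription error."""
        for table in tables.values():
            for rec in table.records.values():
                if rec.population is not None:
                    assert rec.population.frequency < 0.01, rec.key
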