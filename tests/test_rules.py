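"""Keyword heuristics, cross-source checks and the full rule stage."""

import pytest

from srameta import schema
from srameta.context import build_context
from srameta.rules import (
    LIBRARY_SELECTION_KEYWORDS,
    cross_source_check,
    heuristic_biopsy_type,
    heuristic_library_selection,
    heuristic_sequencing_source,
    run_rule_stage,
)
from srameta.sra_io import RunRecord, parse_biosample_xml, parse_run_xml
from srameta.synthetic import generate_pool, render_fixture_xml

# one context per printed keyword, built from the keyword groups themselves
_KEYWORD_CASES = [
    ("polyA", "PolyA"), ("polyA", "poly.A"), ("polyA", "oligo.dT"),
    ("polyA", "oligodT"), ("polyA", "truseq.mrna"),
    ("polyA", "truseq.stranded.mrna"), ("polyA", "truseq.standard.mrna"),
    ("polyA", "smarter.mRNA"), ("polyA", "stranded.mRNA"),
    ("inverse rRNA", "ribominus"), ("inverse rRNA", "ribodep"),
    ("inverse rRNA", "ribozero"), ("inverse rRNA", "ribo.zero"),
    ("inverse rRNA", "riboerase"), ("inverse rRNA", "ribogone"),
    ("inverse rRNA", "ribocop"), ("inverse rRNA", "ribo-dep"),
    ("inverse rRNA", "ribo-mi"), ("inverse rRNA", "ribo minus"),
    ("inverse rRNA", "depleted ribosomal RNA"),
    ("inverse rRNA", "remove ribosomal transcripts"),
    ("inverse rRNA", "TruSeq.Stranded.Total"), ("inverse rRNA", "TruSeq.Total"),
    ("inverse rRNA", "SMARTer.Stranded.Total"), ("inverse rRNA", "SMARTer.Total"),
    ("hybrid selection", "Hybrid.Selection"), ("hybrid selection", "Exon.capture"),
    ("hybrid selection", "Exome.capture"), ("hybrid selection", "RNA.Exome"),
    ("hybrid selection", "geoMX"),
    ("small RNA", "TruSeq.Small"), ("small RNA", "size.fractionated"),
]


class TestLibrarySelectionHeuristic:
    @pytest.mark.parametrize("expected, keyword", _KEYWORD_CASES)
    def test_every_printed_keyword_is_classified(self, expected, keyword):
        text = f"Libraries were prepared using {keyword} during processing."
        assert heuristic_library_selection(text) == expected

    @pytest.mark.parametrize(
        "text, expected",
        [
            ("libraries prepared with oligo-dT beads", "polyA"),
            ("Ribo-Zero depletion was performed", "inverse rRNA"),
            ("TruSeq Small RNA kit", "small RNA"),
            ("standard protocol", None),
        ],
    )
    def test_representative_phrasings(self, text, expected):
        assert heuristic_library_selection(text) == expected

    def test_precedence_polya_first(self):
        text = "polyA selection followed by ribozero depletion"
        assert heuristic_library_selection(text) == "polyA"

    def test_labels_stay_in_allowed_set(self, registry):
        allowed = set(registry.get("library_selection").allowed_values)
        for label, _ in LIBRARY_SELECTION_KEYWORDS:
            assert label in allowed


class TestSequencingSourceHeuristic:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("scRNA-seq of tumor cells", "single cell"),
            ("Visium spatial transcriptomics", "spatial"),
            ("10x Chromium droplet capture", "single cell"),
            ("bulk RNA extraction", "bulk"),
            ("RNA-seq of tissue homogenate", None),
        ],
    )
    def test_keyword_groups(self, text, expected):
        assert heuristic_sequencing_source(text) == expected


class TestBiopsyTypeHeuristic:
    def test_metastasis_needs_cancer_and_keyword(self):
        assert heuristic_biopsy_type("melanoma liver metastasis") == "metastasis"
        assert heuristic_biopsy_type("liver metastasis", is_cancer_hint=True) == "metastasis"

    def test_blood_without_metastasis(self):
        assert heuristic_biopsy_type(
            "peripheral blood mononuclear cells from donors") == "blood"

    def test_cancer_without_keywords_is_primary(self):
        assert heuristic_biopsy_type("resected lung carcinoma tissue") == "primary"
        assert heuristic_biopsy_type("tissue sample", is_cancer_hint=True) == "primary"

    def test_no_cancer_context_abstains(self):
        assert heuristic_biopsy_type("healthy tissue biopsy") is None


class TestCrossSourceCheck:
    def test_agreement_collapses_case_insensitively(self):
        values, flags = cross_source_check([("lung", "sra_xml"), ("Lung", "biosample")])
        assert values == ["lung"]
        assert flags == []

    def test_disagreement_flags_and_retains_all(self):
        values, flags = cross_source_check([("lung", "sra_xml"), ("liver", "biosample")])
        assert set(values) == {"lung", "liver"}
        assert len(flags) == 1 and "liver" in flags[0]

    def test_single_source_accepted(self):
        values, flags = cross_source_check([("lung", "biosample")])
        assert values == ["lung"] and flags == []


def _record(biosample=None, sample=None, api=None):
    return RunRecord(
        run_accession="SRR1",
        sample_fields=sample or {},
        biosample_attributes=biosample or {},
        api_fields=api or {},
    )


class TestRunRuleStage:
    def test_alias_extraction_validates_and_tags(self, lexicons):
        record = _record(biosample={"sex": "female", "age": "fibroblast"})
        row = run_rule_stage(record, build_context(record), lexicons)
        assert row.fields["sex"].values == ["female"]
        assert row.fields["sex"].source == "rule"
        assert row.fields["sex"].status == "validated"
        assert row.fields["age"].values == []           # nonsense age rejected

    def test_api_direct_classes_filled_from_api(self, lexicons):
        record = _record(api={"study_accession": "SRP1", "instrument_platform": "ILLUMINA",
                              "number_of_base_pairs": "123", "library_strategy": "RNA-Seq"})
        row = run_rule_stage(record, build_context(record), lexicons)
        for name in ("study_accession", "instrument_platform",
                     "number_of_base_pairs", "library_strategy"):
            assert row.fields[name].source == "api"
            assert row.fields[name].values

    def test_cell_line_hit_propagates_attributes(self, lexicons):
        record = _record(sample={"description": "cultured HeLa cells were profiled"})
        row = run_rule_stage(record, build_context(record), lexicons)
        assert row.fields["cell_line"].values == ["HeLa"]
        assert row.fields["organ"].values == ["uterine cervix"]
        assert row.fields["organ"].source == "lexicon_propagation"
        assert row.fields["organ"].term_id == "ANAT:0013"

    def test_conflict_is_flagged_with_ambiguity_note(self, lexicons):
        record = _record(sample={"organ": "lung"}, biosample={"organ": "liver"})
        bundle = build_context(record)
        row = run_rule_stage(record, bundle, lexicons)
        assert row.fields["organ"].status == "flagged"
        assert any(note.startswith("organ:") for note in bundle.ambiguity_notes)

    def test_disease_synonym_normalized_with_id(self, lexicons):
        record = _record(biosample={"disease": "TB"})
        row = run_rule_stage(record, build_context(record), lexicons)
        assert row.fields["disease"].values == ["tuberculosis"]
        assert row.fields["disease"].term_id == "DIS:0001"

    def test_deterministic(self, lexicons):
        record = _record(biosample={"sex": "F", "disease": "melanoma"},
                         sample={"description": "bulk RNA from A549 cells"})
        rows = [run_rule_stage(record, build_context(record), lexicons) for _ in range(2)]
        assert rows[0] == rows[1]

    def test_full_recall_on_explicit_plants_and_silence_without(self, lexicons, registry):
        planted = generate_pool(
            6, seed=21,
            config={"mode_props": {"explicit": 1.0, "paraphrase": 0.0}})
        for sample in planted:
            run_xml, biosample_xml, _ = render_fixture_xml(sample)
            record = parse_run_xml(run_xml)
            record.biosample_attributes = parse_biosample_xml(biosample_xml)
            row = run_rule_stage(record, build_context(record), lexicons)
            for name, mode in sample.mode.items():
                if mode != "explicit":
                    continue
                got = {v.casefold() for v in row.fields[name].values}
                want = {v.casefold() for v in sample.truth[name]}
                cls = registry.get(name)
                if cls.name in ("disease", "organ", "biopsy_site"):
                    assert row.fields[name].values  # normalized form may differ
                else:
                    assert want <= got, (name, row.fields[name])

    def test_no_false_positives_on_plant_free_record(self, lexicons):
        record = _record(sample={"title": "archived specimen twelve"})
        row = run_rule_stage(record, build_context(record), lexicons)
        for cls in schema.registry().llm_routed:
            assert row.fields[cls.name].values == [], cls.name
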