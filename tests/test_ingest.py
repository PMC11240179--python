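"""Tests for record parsing, filtering, labeling and author utilities."""

import numpy as np
import pytest

from litatlas.ingest import (
    COVID_SUBTOPIC_TERMS,
    COVID_TERMS,
    JOURNAL_LABEL_TERMS,
    CleanRecord,
    PaperRecord,
    assign_covid_topics,
    assign_journal_labels,
    clean_abstract,
    extract_forename,
    filter_records,
    infer_gender,
    passes_filters,
    read_medline_xml,
    read_records_tsv,
    select_subcorpus,
    write_medline_xml,
    write_records_tsv,
)
from litatlas.names import NameGenderTable, builtin_name_table


def rec(pmid="1", text="x", **kw):
    kw.setdefault("abstract_sections", [("", text)])
    return PaperRecord(pmid=pmid, **kw)


VALID = "This is a valid abstract. " * 12  # ~312 chars, ends with '.'


class TestCleanAbstract:
    @pytest.mark.parametrize("sections,expected", [
        ([("", "Text body. (ABSTRACT TRUNCATED AT 250 WORDS)")], "Text body."),
        ([("METHODS", "We did X."), ("RESULTS", "We found Y.")], "We did X. We found Y."),
        ([("", "One paragraph.")], "One paragraph."),
        ([("", "  Spaced\n out.  ")], "Spaced out."),
        ([("BACKGROUND", ""), ("", "Only this.")], "Only this."),
    ])
    def test_examples(self, sections, expected):
        assert clean_abstract(sections) == expected

    def test_all_empty_sections_signal(self):
        assert clean_abstract([("A", ""), ("", "   ")]) == ""

    def test_truncation_phrase_mid_text(self):
        out = clean_abstract([("", "Start. (ABSTRACT TRUNCATED AT 400 WORDS) End.")])
        assert out == "Start. End."


class TestFilters:
    @pytest.mark.parametrize("record,reason", [
        (rec(text="a" * 248 + "."), "too_short"),           # 249 chars
        (rec(text="a" * 4001 + "."), "too_long"),
        (rec(text="a" * 300 + " expression increased"), "unfinished"),
        (rec(text=VALID, language="fre"), "non_english"),
        (rec(abstract_sections=[("", "")]), "empty_abstract"),
    ])
    def test_rejection_reasons(self, record, reason):
        clean, got = passes_filters(record)
        assert clean is None and got == reason

    def test_inclusive_boundaries(self):
        ok250, _ = passes_filters(rec(text="a" * 249 + "."))
        assert ok250 is not None and len(ok250.abstract) == 250
        ok4000, _ = passes_filters(rec(text="a" * 3999 + "."))
        assert ok4000 is not None and len(ok4000.abstract) == 4000

    @pytest.mark.parametrize("ending", [".", "?", "!"])
    def test_accepted_sentence_endings(self, ending):
        clean, reason = passes_filters(rec(text="a" * 300 + ending))
        assert reason is None

    def test_unfinished_checked_after_truncation_removal(self):
        text = "a" * 300 + ". (ABSTRACT TRUNCATED AT 250 WORDS)"
        clean, reason = passes_filters(rec(text=text))
        assert reason is None and clean.abstract.endswith(".")

    def test_duplicate_pmid_first_occurrence_kept(self):
        records = [rec(pmid="7", text=VALID), rec(pmid="7", text=VALID)]
        kept, reasons = filter_records(records)
        assert len(kept) == 1 and reasons == {"duplicate_pmid": 1}
        kept2, reasons2 = filter_records(records, dedupe=False)
        assert len(kept2) == 2 and reasons2 == {}

    def test_rejections_sum_to_input_minus_kept(self):
        records = [rec(pmid=str(i), text=VALID) for i in range(5)]
        records += [rec(pmid="r1", text="short."), rec(pmid="r2", text=VALID, language="ger")]
        kept, reasons = filter_records(records)
        assert sum(reasons.values()) == len(records) - len(kept)

    def test_filter_is_idempotent(self):
        records = [rec(pmid=str(i), text=VALID) for i in range(4)]
        records.append(rec(pmid="bad", text="too short."))
        kept, _ = filter_records(records)
        refiltered = [PaperRecord(pmid=c.pmid, abstract_sections=[("", c.abstract)],
                                  journal=c.journal, year=c.year) for c in kept]
        kept2, reasons2 = filter_records(refiltered)
        assert len(kept2) == len(kept) and reasons2 == {}


class TestJournalLabels:
    def make(self, journal):
        return CleanRecord(pmid="1", title="", abstract=VALID, journal=journal, year=2000)

    def test_single_keyword(self):
        out = assign_journal_labels([self.make("Annals of Surgery")])
        assert out[0].label == "surgery"

    def test_case_insensitive(self):
        out = assign_journal_labels([self.make("VIROLOGY TODAY")])
        assert out[0].label == "virology"

    def test_no_keyword_unlabeled(self):
        out = assign_journal_labels([self.make("Nature")])
        assert out[0].label is None

    def test_multi_match_seeded_and_stable(self):
        recs = [self.make("Neuroscience and Pharmacology Reports")]
        a = assign_journal_labels(recs, seed=42)[0].label
        b = assign_journal_labels(recs, seed=42)[0].label
        assert a == b and a in {"neuroscience", "pharmacology"}
        labels = {assign_journal_labels(recs, seed=s)[0].label for s in range(30)}
        assert labels == {"neuroscience", "pharmacology"}

    def test_without_ties_seed_independent(self):
        recs = [self.make("Journal of Genetics"), self.make("Cancer Research")]
        for seed in (0, 1, 99):
            labels = [r.label for r in assign_journal_labels(recs, seed=seed)]
            assert labels == ["genetics", "cancer"]

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError):
            assign_journal_labels([self.make("Nature")], keywords=[])

    def test_default_list_has_38_terms(self):
        assert len(JOURNAL_LABEL_TERMS) == 38 and "virology" in JOURNAL_LABEL_TERMS


class TestSubcorpora:
    def make(self, abstract, retracted=False, label=None):
        return CleanRecord(pmid="1", title="", abstract=abstract, journal="",
                           year=2020, label=label, retracted=retracted)

    def test_covid_exact_case_variants(self):
        records = [self.make("We study SARS-CoV-2 replication."),
                   self.make("We study sars-cov-2 replication."),  # wrong case
                   self.make("Nothing viral here.")]
        mask = select_subcorpus(records, "covid").mask
        assert mask.tolist() == [True, False, False]
        assert len(COVID_TERMS) == 8

    def test_hiv_aids_any_case(self):
        records = [self.make("A study of hiv prevalence."),
                   self.make("AIDS-related outcomes."), self.make("Influenza only.")]
        assert select_subcorpus(records, "hiv_aids").mask.tolist() == [True, True, False]

    def test_retracted_intact_excludes_modified_abstracts(self):
        records = [self.make("Original text here.", retracted=True),
                   self.make("This retraction notice replaces it.", retracted=True),
                   self.make("Original text here.", retracted=False)]
        assert select_subcorpus(records, "retracted_intact").mask.tolist() == [True, False, False]

    def test_journal_label_selector(self):
        records = [self.make("x", label="virology"), self.make("x", label="surgery")]
        assert select_subcorpus(records, "journal_label:virology").mask.tolist() == [True, False]

    def test_empty_term_list_all_false(self):
        records = [self.make("anything")]
        assert select_subcorpus(records, "custom", terms=[]).mask.tolist() == [False]

    def test_unknown_selector(self):
        with pytest.raises(ValueError):
            select_subcorpus([self.make("x")], "nope")

    def test_masks_are_pure_functions_of_text(self):
        records = [self.make(t) for t in
                   ("HIV study one.", "Plain paper.", "An AIDS cohort.", "Another.")]
        mask = select_subcorpus(records, "hiv_aids").mask
        perm = [2, 0, 3, 1]
        permuted = select_subcorpus([records[i] for i in perm], "hiv_aids").mask
        assert permuted.tolist() == [mask[i] for i in perm]


class TestCovidTopics:
    def test_known_term(self):
        assert assign_covid_topics(["COVID-19 mortality trends"])[0] == "mortality"

    def test_multi_match_seeded(self):
        title = "Vaccine hesitancy during the outbreak"
        got = assign_covid_topics([title], seed=5)
        assert got[0] in {"vaccine", "outbreak"}
        assert got == assign_covid_topics([title], seed=5)

    def test_no_match(self):
        assert assign_covid_topics(["A title about nothing relevant"])[0] is None

    def test_term_list_has_27_terms(self):
        assert len(COVID_SUBTOPIC_TERMS) == 27


class TestAuthors:
    @pytest.mark.parametrize("field,expected", [
        ("Eva-Maria", "Eva"), ("Jose Maria", "Jose"), ("J", None),
        ("Maria", "Maria"), ("", None), (None, None), ("J-P", None),
    ])
    def test_extract_forename(self, field, expected):
        assert extract_forename(field) == expected

    def test_infer_gender_clamps_year(self):
        table = builtin_name_table()
        late = infer_gender("Leslie", 2015, table)
        assert late == infer_gender("Leslie", table.year_range[1], table)
        assert late[0] == "female"

    def test_infer_gender_missing_name(self):
        assert infer_gender("Xqzk", 2000, builtin_name_table()) == ("unknown", None)

    def test_infer_gender_threshold(self):
        table = NameGenderTable.from_rows([("Alex", 2000, 0.7)])
        assert infer_gender("Alex", 2000, table) == ("female", 0.7)
        assert infer_gender("Alex", 2000, table, threshold=0.8)[0] == "male"


class TestIO:
    def _records(self):
        return [PaperRecord(
            pmid="10", title="A title.",
            abstract_sections=[("METHODS", "We did X."), ("", "Then Y.")],
            journal="Nature Neuroscience", year=2001, language="eng",
            authors=[("Eva-Maria", "Smith"), ("John", "Doe")], retracted=True,
        ), PaperRecord(pmid="11", title="B.", abstract_sections=[("", VALID)],
                       journal="Cancer Cell", year=2015)]

    def test_xml_round_trip(self, tmp_path):
        path = tmp_path / "corpus.xml"
        write_medline_xml(self._records(), path)
        back = read_medline_xml(path)
        assert back == self._records()

    def test_tsv_round_trip_flattens_sections(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        write_records_tsv(self._records(), path)
        back = read_records_tsv(path)
        assert back[0].abstract_sections == [("", "We did X. Then Y.")]
        assert back[0].authors == self._records()[0].authors
        assert back[1].year == 2015 and back[0].retracted
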