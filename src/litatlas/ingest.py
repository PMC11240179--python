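"""Parse bibliographic records, filter and clean abstracts, assign labels.

The cleaning pipeline mirrors the preprocessing used to build large literature
atlases from MEDLINE-style records: abstract subsections are flattened to a
single paragraph, truncation notices are stripped, and records are dropped if
they are non-English, have empty/too short/too long abstracts (250–4,000
characters, inclusive), or end mid-sentence ("unfinished" abstracts, which
otherwise form artifact clusters in learned representations). Discipline
labels are assigned from journal-title keywords; topical sub-corpora (COVID,
HIV/AIDS, influenza, ...) are selected by abstract term matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from lxml import etree

from .names import NameGenderTable

__all__ = [
    "PaperRecord",
    "CleanRecord",
    "SubcorpusMask",
    "JOURNAL_LABEL_TERMS",
    "COVID_TERMS",
    "COVID_SUBTOPIC_TERMS",
    "RETRACTION_WORDS",
    "clean_abstract",
    "passes_filters",
    "filter_records",
    "assign_journal_labels",
    "select_subcorpus",
    "assign_covid_topics",
    "extract_forename",
    "infer_gender",
    "read_medline_xml",
    "write_medline_xml",
    "read_records_tsv",
    "write_records_tsv",
    "write_clean_tsv",
    "read_clean_tsv",
]

#: The 38 journal-title keywords used for discipline labels.
JOURNAL_LABEL_TERMS: tuple[str, ...] = (
    "anesthesiology", "biochemistry", "bioinformatics", "cancer", "cardiology",
    "chemistry", "computation", "dermatology", "ecology", "education",
    "engineering", "environment", "ethics", "genetics", "gynecology",
    "healthcare", "immunology", "infectious", "material", "microbiology",
    "neurology", "neuroscience", "nursing", "nutrition", "ophthalmology",
    "optics", "pathology", "pediatric", "pharmacology", "physics",
    "physiology", "psychiatry", "psychology", "radiology", "rehabilitation",
    "surgery", "veterinary", "virology",
)

#: Exact-case variants marking a COVID-related abstract.
COVID_TERMS: tuple[str, ...] = (
    "covid-19", "COVID-19", "Covid-19", "CoViD-19", "2019-nCoV", "SARS-CoV-2",
    "coronavirus disease 2019", "Coronavirus disease 2019",
)

#: The 27 frequent title terms used to partition the COVID sub-corpus.
COVID_SUBTOPIC_TERMS: tuple[str, ...] = (
    "antibody", "anxiety", "cancer", "children", "clinical", "epidemic",
    "healthcare", "immune", "implications", "mental", "mortality", "outbreak",
    "pediatric", "pneumonia", "population", "psychological", "respiratory",
    "social", "strategies", "students", "surgery", "symptoms", "therapy",
    "transmission", "treatment", "vaccine", "workers",
)

#: Words whose presence marks a post-retraction modified abstract.
RETRACTION_WORDS: tuple[str, ...] = ("retracted", "retraction", "withdrawn", "withdrawal")

_TRUNC_RE = re.compile(r"\(ABSTRACT TRUNCATED AT \d+ WORDS\)")
_WS_RE = re.compile(r"\s+")


@dataclass
class PaperRecord:
    """One raw bibliographic entry.

    ``abstract_sections`` is an ordered list of (optional section label, text)
    pairs; unlabeled single-paragraph abstracts use one pair with an empty
    label. ``authors`` holds (forename field, last name) pairs in byline order.
    """

    pmid: str
    title: str = ""
    abstract_sections: list[tuple[str, str]] = field(default_factory=list)
    journal: str = ""
    year: int = 0
    language: str = "eng"
    authors: list[tuple[str, str]] = field(default_factory=list)
    retracted: bool = False


@dataclass
class CleanRecord:
    """A filtered record: single-paragraph abstract plus derived fields."""

    pmid: str
    title: str
    abstract: str
    journal: str
    year: int
    label: str | None = None
    first_author_forename: str | None = None
    last_author_forename: str | None = None
    first_author_gender: str | None = None
    last_author_gender: str | None = None
    retracted: bool = False


@dataclass
class SubcorpusMask:
    """Boolean membership of each record in a named sub-corpus."""

    name: str
    mask: np.ndarray
    terms: tuple[str, ...] = ()

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


def clean_abstract(sections: list[tuple[str, str]]) -> str:
    """Flatten labeled sections into one paragraph.

    Section labels are dropped, texts joined with single spaces, any
    "(ABSTRACT TRUNCATED AT <n> WORDS)" phrase removed, and whitespace
    normalized. Returns "" when every section is empty.
    """
    parts = [text.strip() for _label, text in sections if text and text.strip()]
    text = " ".join(parts)
    text = _TRUNC_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def passes_filters(
    record: PaperRecord,
    *,
    min_chars: int = 250,
    max_chars: int = 4000,
    language: str = "eng",
    seen_pmids: set[str] | None = None,
) -> tuple[CleanRecord | None, str | None]:
    """Apply the cleaning filters to one record.

    Returns ``(CleanRecord, None)`` when kept, else ``(None, reason)`` with
    reason in {non_english, empty_abstract, too_short, too_long, unfinished,
    duplicate_pmid}. Length bounds are inclusive and measured on the cleaned
    single-paragraph text; the unfinished check runs after truncation-phrase
    removal. Duplicates are only detected when ``seen_pmids`` is supplied
    (first kept occurrence wins).
    """
    if record.language != language:
        return None, "non_english"
    abstract = clean_abstract(record.abstract_sections)
    if not abstract:
        return None, "empty_abstract"
    if len(abstract) < min_chars:
        return None, "too_short"
    if len(abstract) > max_chars:
        return None, "too_long"
    if abstract[-1] not in ".?!":
        return None, "unfinished"
    if seen_pmids is not None and record.pmid in seen_pmids:
        return None, "duplicate_pmid"

    first = extract_forename(record.authors[0][0]) if record.authors else None
    last = extract_forename(record.authors[-1][0]) if record.authors else None
    clean = CleanRecord(
        pmid=record.pmid,
        title=record.title,
        abstract=abstract,
        journal=record.journal,
        year=record.year,
        first_author_forename=first,
        last_author_forename=last,
        retracted=record.retracted,
    )
    return clean, None


def filter_records(
    records,
    *,
    min_chars: int = 250,
    max_chars: int = 4000,
    language: str = "eng",
    dedupe: bool = True,
) -> tuple[list[CleanRecord], dict[str, int]]:
    """Filter a corpus; returns kept records and per-reason rejection counts.

    Rejection counts always sum to ``len(records) - len(kept)``.
    """
    kept: list[CleanRecord] = []
    reasons: dict[str, int] = {}
    seen: set[str] | None = set() if dedupe else None
    for rec in records:
        clean, reason = passes_filters(
            rec, min_chars=min_chars, max_chars=max_chars,
            language=language, seen_pmids=seen,
        )
        if clean is None:
            reasons[reason] = reasons.get(reason, 0) + 1
        else:
            if seen is not None:
                seen.add(rec.pmid)
            kept.append(clean)
    return kept, reasons


def _term_matches(text: str, term: str, case_mode: str) -> bool:
    if case_mode == "insensitive":
        return term.lower() in text.lower()
    if case_mode == "first_letter":  # term as printed, or Capitalized
        return term in text or term.capitalize() in text
    if case_mode == "exact":
        return term in text
    raise ValueError(f"unknown case_mode: {case_mode!r}")


def _assign_keyword(texts, keywords, seed, case_mode) -> list[str | None]:
    rng = np.random.default_rng(seed)
    out: list[str | None] = []
    for text in texts:
        matches = [kw for kw in keywords if _term_matches(text, kw, case_mode)]
        if not matches:
            out.append(None)
        elif len(matches) == 1:
            out.append(matches[0])
        else:
            out.append(matches[int(rng.integers(len(matches)))])
    return out


def assign_journal_labels(
    records: list[CleanRecord],
    keywords=JOURNAL_LABEL_TERMS,
    seed: int = 0,
    case_mode: str = "insensitive",
) -> list[CleanRecord]:
    """Label each record by the keyword contained in its journal title.

    A record is labeled iff the journal title contains a keyword as a
    substring ("either capitalized or not" — by default full case-insensitive
    matching; ``case_mode='first_letter'`` restricts to term/Term). Multiple
    matches are resolved by a seeded uniform draw; records matching nothing
    stay unlabeled. Returns new records (input untouched).
    """
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    labels = _assign_keyword((r.journal for r in records), keywords, seed, case_mode)
    return [replace(r, label=lab) for r, lab in zip(records, labels)]


def assign_covid_topics(
    titles, seed: int = 0, terms=COVID_SUBTOPIC_TERMS, case_mode: str = "insensitive"
) -> list[str | None]:
    """Assign one of the 27 subtopic keywords to each title, or None."""
    return _assign_keyword(titles, terms, seed, case_mode)


def select_subcorpus(records: list[CleanRecord], selector, terms=None) -> SubcorpusMask:
    """Boolean mask of records belonging to a named topical sub-corpus.

    Built-in selectors (matching against the cleaned abstract):

    - ``covid``: any of the 8 exact-case COVID term variants;
    - ``hiv_aids``: "HIV" or "AIDS", any case;
    - ``influenza``; ``meta_analysis``; ``ml_mention`` ("machine learning") —
      case-insensitive;
    - ``journal_label:<keyword>``: records carrying that journal-based label;
    - ``retracted_intact``: retraction flag set AND the abstract lacks the
      four retraction-notice words;
    - ``custom``: pass ``terms`` explicitly (case-insensitive substrings).
    """
    abstracts = [r.abstract for r in records]

    def any_term(term_list, case_mode):
        return np.array(
            [any(_term_matches(a, t, case_mode) for t in term_list) for a in abstracts],
            dtype=bool,
        )

    if selector == "covid":
        return SubcorpusMask("covid", any_term(COVID_TERMS, "exact"), COVID_TERMS)
    if selector == "hiv_aids":
        return SubcorpusMask("hiv_aids", any_term(("hiv", "aids"), "insensitive"), ("HIV", "AIDS"))
    if selector == "influenza":
        return SubcorpusMask("influenza", any_term(("influenza",), "insensitive"), ("influenza",))
    if selector == "meta_analysis":
        return SubcorpusMask("meta_analysis", any_term(("meta-analysis",), "insensitive"), ("meta-analysis",))
    if selector == "ml_mention":
        return SubcorpusMask("ml_mention", any_term(("machine learning",), "insensitive"), ("machine learning",))
    if isinstance(selector, str) and selector.startswith("journal_label:"):
        kw = selector.split(":", 1)[1]
        mask = np.array([r.label == kw for r in records], dtype=bool)
        return SubcorpusMask(selector, mask, (kw,))
    if selector == "retracted_intact":
        flagged = np.array([r.retracted for r in records], dtype=bool)
        modified = any_term(RETRACTION_WORDS, "insensitive")
        return SubcorpusMask("retracted_intact", flagged & ~modified, RETRACTION_WORDS)
    if selector == "custom":
        if terms is None:
            raise ValueError("custom selector requires a term list")
        return SubcorpusMask("custom", any_term(tuple(terms), "insensitive"), tuple(terms))
    raise ValueError(f"unknown selector: {selector!r}")


def extract_forename(forename_field: str | None) -> str | None:
    """First word of the forename field, hyphens treated as spaces.

    "Eva-Maria" -> "Eva"; single-letter results (initials) are discarded.
    """
    if not forename_field:
        return None
    words = forename_field.replace("-", " ").split()
    if not words or len(words[0]) < 2:
        return None
    return words[0]


def infer_gender(
    name: str | None,
    year: int,
    table: NameGenderTable,
    threshold: float = 0.5,
) -> tuple[str, float | None]:
    """Majority gender of ``name`` bearers around ``year``.

    The year is clamped to the table's covered range. Returns
    ``("female", p)`` when the proportion female p >= threshold,
    ``("male", p)`` otherwise, and ``("unknown", None)`` for names absent
    from the table.
    """
    if name is None:
        return "unknown", None
    p = table.prop_female(name, year)
    if p is None:
        return "unknown", None
    return ("female" if p >= threshold else "male"), p


def infer_record_genders(
    records: list[CleanRecord], table: NameGenderTable, threshold: float = 0.5
) -> list[CleanRecord]:
    """Fill first/last-author gender fields from a name–gender table."""
    out = []
    for rec in records:
        first, _ = infer_gender(rec.first_author_forename, rec.year, table, threshold)
        last, _ = infer_gender(rec.last_author_forename, rec.year, table, threshold)
        out.append(replace(rec, first_author_gender=first, last_author_gender=last))
    return out


# ---------------------------------------------------------------------------
# IO: MEDLINE-style XML dialect and delimited text
# ---------------------------------------------------------------------------

def read_medline_xml(path) -> list[PaperRecord]:
    """Read records from the MEDLINE-style XML dialect.

    Understands PubmedArticle/MedlineCitation with PMID, ArticleTitle,
    Abstract/AbstractText[@Label], Journal/Title, PubDate/Year, Language,
    AuthorList/Author/ForeName+LastName, and a PublicationType of
    "Retracted Publication" for the retraction flag.
    """
    tree = etree.parse(str(path))
    records = []
    for art in tree.iter("PubmedArticle"):
        cit = art.find("MedlineCitation")
        if cit is None:
            continue
        pmid = cit.findtext("PMID", default="")
        article = cit.find("Article")
        title = article.findtext("ArticleTitle", default="") if article is not None else ""
        sections = []
        if article is not None:
            for ab in article.findall("Abstract/AbstractText"):
                sections.append((ab.get("Label", ""), ab.text or ""))
        journal = article.findtext("Journal/Title", default="") if article is not None else ""
        year_text = (
            article.findtext("Journal/JournalIssue/PubDate/Year", default="0")
            if article is not None else "0"
        )
        language = article.findtext("Language", default="eng") if article is not None else "eng"
        authors = []
        if article is not None:
            for au in article.findall("AuthorList/Author"):
                authors.append((au.findtext("ForeName", default=""),
                                au.findtext("LastName", default="")))
        retracted = False
        if article is not None:
            for pt in article.findall("PublicationTypeList/PublicationType"):
                if (pt.text or "").strip() == "Retracted Publication":
                    retracted = True
        records.append(PaperRecord(
            pmid=pmid, title=title, abstract_sections=sections, journal=journal,
            year=int(year_text or 0), language=language, authors=authors,
            retracted=retracted,
        ))
    return records


def write_medline_xml(records: list[PaperRecord], path) -> None:
    """Write records in the MEDLINE-style XML dialect read by read_medline_xml."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        etree.SubElement(journal, "Title").text = rec.journal
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        etree.SubElement(pubdate, "Year").text = str(rec.year)
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract_sections:
            ab = etree.SubElement(article, "Abstract")
            for label, text in rec.abstract_sections:
                el = etree.SubElement(ab, "AbstractText")
                if label:
                    el.set("Label", label)
                el.text = text
        etree.SubElement(article, "Language").text = rec.language
        if rec.authors:
            alist = etree.SubElement(article, "AuthorList")
            for fore, lastname in rec.authors:
                au = etree.SubElement(alist, "Author")
                etree.SubElement(au, "LastName").text = lastname
                etree.SubElement(au, "ForeName").text = fore
        if rec.retracted:
            ptl = etree.SubElement(article, "PublicationTypeList")
            etree.SubElement(ptl, "PublicationType").text = "Retracted Publication"
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


_TSV_COLUMNS = ("pmid", "title", "abstract", "journal", "year", "language",
                "authors", "retracted")


def _fmt_authors(authors) -> str:
    return ";".join(f"{fore}:{last}" for fore, last in authors)


def _parse_authors(text: str):
    if not text:
        return []
    return [tuple(part.split(":", 1)) if ":" in part else (part, "")
            for part in text.split(";")]


def write_records_tsv(records: list[PaperRecord], path) -> None:
    """Write raw records as one TSV row per paper (sections flattened)."""
    import pandas as pd

    rows = [{
        "pmid": r.pmid, "title": r.title,
        "abstract": clean_abstract(r.abstract_sections) if r.abstract_sections else "",
        "journal": r.journal, "year": r.year, "language": r.language,
        "authors": _fmt_authors(r.authors), "retracted": int(r.retracted),
    } for r in records]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list[PaperRecord]:
    """Read raw records from TSV (abstract becomes one unlabeled section)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"pmid": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        sections = [("", row.abstract)] if row.abstract else []
        records.append(PaperRecord(
            pmid=str(row.pmid), title=row.title, abstract_sections=sections,
            journal=row.journal, year=int(row.year), language=row.language,
            authors=_parse_authors(row.authors), retracted=bool(int(row.retracted)),
        ))
    return records


def write_clean_tsv(records: list[CleanRecord], path) -> None:
    import pandas as pd

    rows = [{
        "pmid": r.pmid, "title": r.title, "abstract": r.abstract,
        "journal": r.journal, "year": r.year, "label": r.label or "",
        "first_author_forename": r.first_author_forename or "",
        "last_author_forename": r.last_author_forename or "",
        "first_author_gender": r.first_author_gender or "",
        "last_author_gender": r.last_author_gender or "",
        "retracted": int(r.retracted),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clean_tsv(path) -> list[CleanRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"pmid": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(CleanRecord(
            pmid=str(row.pmid), title=row.title, abstract=row.abstract,
            journal=row.journal, year=int(row.year), label=row.label or None,
            first_author_forename=row.first_author_forename or None,
            last_author_forename=row.last_author_forename or None,
            first_author_gender=row.first_author_gender or None,
            last_author_gender=row.last_author_gender or None,
            retracted=bool(int(row.retracted)),
        ))
    return out
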