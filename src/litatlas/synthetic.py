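"""Synthetic corpora with the statistical structure the atlas analyses assume.

Two generators are provided. ``generate_records`` emits bibliographic records
whose abstracts are bags of words drawn from topic-specific vocabularies (plus
shared stop-words), whose journal titles carry the topic's label keyword,
whose publication years follow per-topic Gaussian drift, whose author
forenames reflect a time-varying female proportion, and whose retraction flags
are enriched in chosen topics. ``generate_vector_mixture`` skips the text and
draws labeled spherical-Gaussian vectors directly, with cluster centers a
configurable number of within-cluster standard deviations apart — the standard
benchmark for neighbor-embedding and kNN-metric code.

Everything is driven by one global seed: each stage draws from its own child
seed so components are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .ingest import PaperRecord
from .names import NameGenderTable, builtin_name_table
from .vectorize import VectorSet

__all__ = [
    "TopicSpec",
    "SyntheticConfig",
    "generate_records",
    "generate_vector_mixture",
    "builtin_name_table",
    "DEFAULT_STOPWORDS",
]

#: Shared function words mixed into every topic's abstracts.
DEFAULT_STOPWORDS: tuple[str, ...] = (
    "the", "of", "and", "in", "to", "with", "for", "was", "were", "that",
    "these", "results", "study", "analysis", "using", "between", "observed",
    "significant", "increased", "patients", "method", "data", "effect",
)


@dataclass
class TopicSpec:
    """One synthetic topic: vocabulary, journal keyword, year drift, rates.

    ``female_prop`` may be a constant in [0,1] or a list of (year, proportion)
    anchors interpolated linearly — it sets the probability that a generated
    author forename is drawn from the majority-female name pool in that year.
    """

    name: str
    vocabulary: dict[str, float]
    journal_keyword: str = ""
    year_center: float = 2005.0
    year_sd: float = 6.0
    female_prop: float | list[tuple[float, float]] = 0.4
    retraction_rate: float = 0.0
    weight: float = 1.0

    def female_prop_at(self, year: float) -> float:
        if isinstance(self.female_prop, (int, float)):
            return float(self.female_prop)
        anchors = sorted(self.female_prop)
        ys = np.array([a[0] for a in anchors], dtype=float)
        ps = np.array([a[1] for a in anchors], dtype=float)
        return float(np.interp(year, ys, ps))

    def validate(self) -> None:
        if not 0.0 <= self.retraction_rate <= 1.0:
            raise ValueError(f"retraction_rate out of [0,1]: {self.retraction_rate}")
        props = ([self.female_prop] if isinstance(self.female_prop, (int, float))
                 else [p for _, p in self.female_prop])
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("female proportions must lie in [0,1]")
        if self.year_sd < 0:
            raise ValueError("year_sd must be nonnegative")


@dataclass
class SyntheticConfig:
    """Full description of a synthetic corpus / vector mixture."""

    n_papers: int
    topics: list[TopicSpec]
    cluster_separation: float = 6.0
    dim: int = 50
    seed: int = 0
    year_range: tuple[int, int] = (1975, 2021)
    abstract_words: int = 90
    min_chars: int = 250
    stopwords: tuple[str, ...] = DEFAULT_STOPWORDS
    stopword_frac: float = 0.4
    n_authors: tuple[int, int] = (1, 5)

    def validate(self) -> None:
        if self.n_papers < 0:
            raise ValueError("n_papers must be nonnegative")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be nonnegative")
        for t in self.topics:
            t.validate()

    def topic_probs(self) -> np.ndarray:
        w = np.array([t.weight for t in self.topics], dtype=float)
        return w / w.sum()

    # -- structured text (YAML) round trip --------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_papers": self.n_papers,
            "cluster_separation": self.cluster_separation,
            "dim": self.dim,
            "seed": self.seed,
            "year_range": list(self.year_range),
            "abstract_words": self.abstract_words,
            "min_chars": self.min_chars,
            "stopword_frac": self.stopword_frac,
            "topics": [{
                "name": t.name,
                "vocabulary": t.vocabulary,
                "journal_keyword": t.journal_keyword,
                "year_center": t.year_center,
                "year_sd": t.year_sd,
                "female_prop": (t.female_prop if isinstance(t.female_prop, (int, float))
                                else [list(a) for a in t.female_prop]),
                "retraction_rate": t.retraction_rate,
                "weight": t.weight,
            } for t in self.topics],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        topics = []
        for t in doc.pop("topics"):
            fp = t.get("female_prop", 0.4)
            if isinstance(fp, list):
                t["female_prop"] = [tuple(a) for a in fp]
            topics.append(TopicSpec(**t))
        doc["year_range"] = tuple(doc.get("year_range", (1975, 2021)))
        return cls(topics=topics, **doc)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_year(rng, topic: TopicSpec, year_range) -> int:
    y = int(round(rng.normal(topic.year_center, topic.year_sd)))
    return int(min(max(y, year_range[0]), year_range[1]))


def _sample_abstract(rng, topic: TopicSpec, cfg: SyntheticConfig) -> str:
    vocab = sorted(topic.vocabulary)
    weights = np.array([topic.vocabulary[w] for w in vocab], dtype=float)
    weights = weights / weights.sum()
    words: list[str] = []
    while True:
        n_more = max(cfg.abstract_words - len(words), 20)
        from_stop = rng.random(n_more) < cfg.stopword_frac
        topic_words = rng.choice(vocab, size=n_more, p=weights)
        stop_words = rng.choice(cfg.stopwords, size=n_more)
        words.extend(np.where(from_stop, stop_words, topic_words).tolist())
        text = " ".join(words)
        if len(text) + 1 >= cfg.min_chars and len(words) >= cfg.abstract_words:
            break
    return text[0].upper() + text[1:] + "."


def _sample_authors(rng, topic, year, table: NameGenderTable, n_authors) -> list[tuple[str, str]]:
    lastnames = ("Smith", "Garcia", "Chen", "Mueller", "Okafor", "Tanaka",
                 "Rossi", "Novak", "Silva", "Kim")
    female_pool = table.names(year, female=True)
    male_pool = table.names(year, female=False)
    k = int(rng.integers(n_authors[0], n_authors[1] + 1))
    p_female = topic.female_prop_at(year)
    authors = []
    for _ in range(k):
        pool = female_pool if rng.random() < p_female else male_pool
        fore = str(rng.choice(pool))
        last = str(rng.choice(lastnames))
        authors.append((fore, last))
    return authors


def generate_records(
    config: SyntheticConfig, name_table: NameGenderTable | None = None
) -> list[PaperRecord]:
    """Generate a synthetic bibliographic corpus.

    Each record's abstract is drawn from its topic vocabulary (>= ``min_chars``
    characters, ending with a period), the journal title contains the topic's
    label keyword, the year follows the topic's drift distribution truncated
    to ``year_range``, author forenames are drawn from the name table with the
    topic's female proportion at that year, and the retraction flag is
    Bernoulli with the topic rate. Identical config + seed gives identical
    output.
    """
    config.validate()
    if not config.topics:
        raise ValueError("at least one topic is required")
    table = name_table or builtin_name_table()
    rng_topic, rng_year, rng_text, rng_auth, rng_flag = _child_rngs(config.seed, 5)

    n = config.n_papers
    topic_idx = rng_topic.choice(len(config.topics), size=n, p=config.topic_probs())
    records: list[PaperRecord] = []
    for i in range(n):
        topic = config.topics[int(topic_idx[i])]
        year = _sample_year(rng_year, topic, config.year_range)
        abstract = _sample_abstract(rng_text, topic, config)
        authors = _sample_authors(rng_auth, topic, year, table, config.n_authors)
        kw = topic.journal_keyword or topic.name
        journal = f"Journal of {kw.capitalize()} Research"
        title_words = abstract.split()[: 8]
        records.append(PaperRecord(
            pmid=f"{100000 + i}",
            title=" ".join(title_words).rstrip(".") + ".",
            abstract_sections=[("", abstract)],
            journal=journal,
            year=year,
            language="eng",
            authors=authors,
            retracted=bool(rng_flag.random() < topic.retraction_rate),
        ))
    return records


def _cluster_centers(n_topics: int, dim: int, separation: float, rng) -> np.ndarray:
    """Centers pairwise ``separation`` apart (unit within-cluster sd).

    With dim >= n_topics a regular simplex gives exactly equal pairwise
    distances; in lower dimensions centers are placed on a sphere of radius
    separation/sqrt(2), which matches the simplex distance only approximately.
    """
    if separation == 0 or n_topics == 1:
        return np.zeros((n_topics, dim))
    if dim >= n_topics:
        centers = np.zeros((n_topics, dim))
        centers[:, :n_topics] = np.eye(n_topics)
        centers -= centers.mean(axis=0)
        return centers * (separation / np.sqrt(2.0))
    dirs = rng.standard_normal((n_topics, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * (separation / np.sqrt(2.0))


def generate_vector_mixture(config: SyntheticConfig) -> tuple[VectorSet, np.ndarray]:
    """Draw labeled vectors from a spherical Gaussian mixture.

    Rows are unit-variance spherical Gaussians around cluster centers that are
    pairwise ``cluster_separation`` apart in within-cluster standard-deviation
    units. Returns the vectors and a per-row topic-label array.
    """
    config.validate()
    if config.dim < 1:
        raise ValueError("dim must be >= 1")
    if not config.topics:
        raise ValueError("at least one topic is required")
    rng_assign, rng_centers, rng_noise = _child_rngs(config.seed, 3)
    n, t = config.n_papers, len(config.topics)
    idx = rng_assign.choice(t, size=n, p=config.topic_probs())
    centers = _cluster_centers(t, config.dim, config.cluster_separation, rng_centers)
    X = centers[idx] + rng_noise.standard_normal((n, config.dim))
    labels = np.array([config.topics[i].name for i in idx])
    ids = np.array([f"{100000 + i}" for i in range(n)])
    vs = VectorSet(ids=ids, X=X, metric="euclidean", provenance="synthetic")
    return vs, labels
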