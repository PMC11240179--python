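"""The packaged synthetic literature study, end to end.

This module fixes the conditions of the package's own worked analysis: a
synthetic corpus whose statistical structure emulates a large bibliographic
database — topic-clustered abstracts with topic-specific vocabularies,
journal titles carrying discipline keywords, per-topic publication-year
drift (including a recent, strongly clustered pandemic-style topic),
time-varying female authorship, and retraction flags enriched in one
"paper-mill-prone" topic. Each stage of the corpus-to-atlas pipeline is a
function here so the numbered analysis drivers, the tests and the acceptance
script all run the same computation.
"""

from __future__ import annotations

import numpy as np

from .embed import Embedding2D, OptimizerSchedule, build_knn_graph, tsne_embed, uniform_affinities
from .ingest import (
    CleanRecord,
    assign_journal_labels,
    filter_records,
    infer_record_genders,
    select_subcorpus,
)
from .metrics import (
    chance_level_accuracy,
    isolatedness,
    knn_label_accuracy,
    knn_overlap_series,
    knn_recall,
    knn_year_rmse,
    region_flag_fraction,
)
from .names import builtin_name_table
from .synthetic import SyntheticConfig, TopicSpec, generate_records
from .trends import fit_trend, yearly_fraction
from .vectorize import VectorSet, reduce_svd, tfidf_matrix, tokenize_and_vocab

__all__ = [
    "study_topics",
    "study_config",
    "build_clean_corpus",
    "vectorize_corpus",
    "embed_corpus",
    "corpus_statistics",
    "trend_statistics",
    "run_study",
]

# word pools for the topic vocabularies; each topic mixes its own pool with
# the shared stop-words. Adjacent disciplines share a few bridge terms
# (virology/covid, neuroscience/genetics, surgery/cancer) so cross-topic
# neighbors exist, as they do between related fields in real corpora.
_VOCAB = {
    "virology": ("virus viral infection influenza replication strain antigen "
                 "vaccine titer host pathogen serum antibody epitope outbreak"),
    "covid": ("SARS-CoV-2 covid-19 pandemic lockdown quarantine respiratory "
              "coronavirus transmission vaccination mask ventilation spike "
              "pneumonia outbreak severity antibody virus"),
    "neuroscience": ("neuron cortex synapse spike plasticity hippocampus axon "
                     "dendrite cognition stimulus receptor circuit behavior "
                     "imaging electrophysiology expression gene"),
    "genetics": ("gene genome allele mutation expression transcription locus "
                 "variant sequencing heritability chromosome methylation "
                 "polymorphism phenotype annotation receptor imaging"),
    "surgery": ("surgical resection patient outcome laparoscopic anastomosis "
                "postoperative incision suture morbidity operative graft "
                "complication hospital recovery"),
    "cancer": ("tumor oncology carcinoma metastasis biomarker apoptosis "
               "proliferation chemotherapy malignant microRNA osteosarcoma "
               "targeting pathway prognosis survival patient resection"),
}


def _vocab(words: str, extra: dict | None = None) -> dict[str, float]:
    out = {w: 1.0 for w in words.split()}
    if extra:
        out.update(extra)
    return out


def study_topics() -> list[TopicSpec]:
    """The six-topic structure of the packaged study.

    The covid-like topic is recent and tightly clustered in time; the cancer
    topic carries an enriched retraction rate (paper-mill-style region); the
    genetics topic mentions machine learning; female authorship rises over
    the covered years at field-specific levels.
    """
    rising = [(1975.0, 0.15), (2021.0, 0.55)]
    return [
        TopicSpec(name="virology", vocabulary=_vocab(_VOCAB["virology"]),
                  journal_keyword="virology", year_center=2003.0, year_sd=9.0,
                  female_prop=rising, retraction_rate=0.005, weight=1.0),
        TopicSpec(name="covid", vocabulary=_vocab(_VOCAB["covid"]),
                  journal_keyword="infectious", year_center=2020.5, year_sd=0.8,
                  female_prop=[(1975.0, 0.25), (2021.0, 0.5)],
                  retraction_rate=0.005, weight=0.7),
        TopicSpec(name="neuroscience", vocabulary=_vocab(_VOCAB["neuroscience"]),
                  journal_keyword="neuroscience", year_center=2008.0, year_sd=8.0,
                  female_prop=rising, retraction_rate=0.005, weight=1.0),
        TopicSpec(name="genetics",
                  vocabulary=_vocab(_VOCAB["genetics"], {"machine learning": 0.6}),
                  journal_keyword="genetics", year_center=2010.0, year_sd=7.0,
                  female_prop=rising, retraction_rate=0.005, weight=1.0),
        TopicSpec(name="surgery", vocabulary=_vocab(_VOCAB["surgery"]),
                  journal_keyword="surgery", year_center=2000.0, year_sd=10.0,
                  female_prop=[(1975.0, 0.05), (2021.0, 0.35)],
                  retraction_rate=0.005, weight=1.0),
        TopicSpec(name="cancer", vocabulary=_vocab(_VOCAB["cancer"]),
                  journal_keyword="cancer", year_center=2013.0, year_sd=6.0,
                  female_prop=rising, retraction_rate=0.08, weight=1.0),
    ]


def study_config(n_papers: int = 6000, seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(
        n_papers=n_papers, topics=study_topics(), cluster_separation=6.0,
        dim=50, seed=seed, year_range=(1975, 2021),
    )


def build_clean_corpus(config: SyntheticConfig, seed: int = 0):
    """Generate, filter, label and gender-annotate the study corpus."""
    records = generate_records(config)
    kept, rejections = filter_records(records)
    kept = assign_journal_labels(kept, seed=seed)
    kept = infer_record_genders(kept, builtin_name_table())
    return kept, rejections


def vectorize_corpus(records: list[CleanRecord], d: int = 50,
                     row_normalize: bool = False):
    """TF-IDF on the cleaned abstracts, reduced with truncated SVD."""
    counts = tokenize_and_vocab([r.abstract for r in records])
    tfidf = tfidf_matrix(counts, ids=[r.pmid for r in records])
    d = min(d, min(tfidf.X.shape) - 1)
    return counts, tfidf, reduce_svd(tfidf, d, row_normalize=row_normalize)


def embed_corpus(vectors: VectorSet, k: int = 10, seed: int = 0,
                 n_iter: int = 2250, n_exaggeration: int = 250) -> Embedding2D:
    """Uniform-affinity t-SNE of the reduced vectors."""
    knn = build_knn_graph(vectors, k, mode="exact")
    P = uniform_affinities(knn)
    schedule = OptimizerSchedule(n_iter=n_iter, n_exaggeration=n_exaggeration,
                                 seed=seed)
    return tsne_embed(P, vectors, schedule)


def _cluster_box(embedding: Embedding2D, member_mask: np.ndarray,
                 q: float = 5.0) -> tuple[float, float, float, float]:
    """Axis-aligned box spanning the central mass of a point subset."""
    pts = embedding.Y[member_mask]
    x_lo, x_hi = np.percentile(pts[:, 0], [q, 100 - q])
    y_lo, y_hi = np.percentile(pts[:, 1], [q, 100 - q])
    return float(x_lo), float(x_hi), float(y_lo), float(y_hi)


def corpus_statistics(records, vectors: VectorSet, embedding: Embedding2D,
                      k: int = 10, test_size: int = 1000, seed: int = 0) -> dict:
    """The kNN statistics of the study corpus, high-dimensional and 2-D."""
    labels = np.array([r.label for r in records], dtype=object)
    years = np.array([r.year for r in records], dtype=float)
    n = len(records)

    acc_high = knn_label_accuracy(vectors, labels, k=k, test_size=test_size, seed=seed)
    acc_2d = knn_label_accuracy(embedding.Y, labels, k=k, test_size=test_size, seed=seed)
    chance = chance_level_accuracy(labels, test_size=test_size, seed=seed)
    rmse = knn_year_rmse(vectors, years, k=k, test_size=test_size, seed=seed)
    rmse_chance = knn_year_rmse(vectors, years, k=k, test_size=test_size,
                                seed=seed, mode="chance")
    recall = knn_recall(vectors, embedding, k=k, subset_size=test_size, seed=seed)

    covid = select_subcorpus(records, "covid")
    iso_covid = isolatedness(vectors, covid, k=k, subset_size=1000, seed=seed)
    virology = select_subcorpus(records, "journal_label:virology")
    iso_virology = isolatedness(vectors, virology, k=k, subset_size=1000, seed=seed)

    retracted = select_subcorpus(records, "retracted_intact")
    enriched = np.array([r.label == "cancer" for r in records])
    box = _cluster_box(embedding, enriched)
    flagged, total, fraction = region_flag_fraction(embedding, retracted.mask, box)

    return {
        "n_corpus": n,
        "knn_accuracy_highdim_pct": acc_high,
        "knn_accuracy_2d_pct": acc_2d,
        "chance_accuracy_pct": chance,
        "year_rmse_knn": rmse,
        "year_rmse_chance": rmse_chance,
        "knn_recall_2d_pct": recall,
        "isolatedness_covid_pct": iso_covid,
        "isolatedness_virology_pct": iso_virology,
        "retracted_region": {"flagged": flagged, "total": total,
                             "fraction": fraction},
        "final_kl": embedding.final_kl,
    }


def trend_statistics(records, vectors: VectorSet, k: int = 10, seed: int = 0) -> dict:
    """Trend analyses: ML mentions, female first authorship, kNN overlap."""
    ml = select_subcorpus(records, "ml_mention")

    def female_first(rec):
        if rec.first_author_gender in (None, "unknown"):
            return None
        return rec.first_author_gender == "female"

    female_series = yearly_fraction(records, female_first, exclude_terminal=True)
    rows = np.repeat(female_series.years,
                     female_series.denominators).astype(float)
    resp = np.concatenate([
        np.concatenate([np.ones(nm), np.zeros(dn - nm)])
        for nm, dn in zip(female_series.numerators, female_series.denominators)
    ])
    female_fit = fit_trend(rows, resp, family="binomial-logit")

    labels = np.array([r.label for r in records], dtype=object)
    years = np.array([r.year for r in records])
    neuro = labels == "neuroscience"
    genetics_target = labels == "genetics"
    overlap = knn_overlap_series(vectors, neuro, genetics_target, years,
                                 k=k, per_year_cap=500, seed=seed)

    return {
        "ml_mention_pct": 100.0 * float(ml.mask.mean()),
        "female_first_series": female_series,
        "female_first_fit": female_fit,
        "female_first_fitted_first_year": float(female_fit.mean[0]),
        "female_first_fitted_last_year": float(female_fit.mean[-1]),
        "neuro_genetics_overlap_mean_pct": 100.0 * float(overlap["overlap"].mean()),
        "overlap_series": overlap,
    }


def run_study(seed: int = 0, n_papers: int = 6000, svd_dim: int = 50,
              n_iter: int = 2250) -> dict:
    """Run the whole pipeline and return every computed statistic."""
    config = study_config(n_papers=n_papers, seed=seed)
    records, rejections = build_clean_corpus(config, seed=seed)
    counts, tfidf, svd = vectorize_corpus(records, d=svd_dim)
    embedding = embed_corpus(svd, k=10, seed=seed, n_iter=n_iter)
    stats = corpus_statistics(records, svd, embedding, seed=seed)
    trends = trend_statistics(records, svd, seed=seed)
    return {
        "config": config, "records": records, "rejections": rejections,
        "counts": counts, "tfidf": tfidf, "vectors": svd,
        "embedding": embedding, "stats": stats, "trends": trends,
    }
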