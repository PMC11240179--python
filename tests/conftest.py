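import numpy as np
import pytest

from litatlas.synthetic import SyntheticConfig, TopicSpec, generate_records, generate_vector_mixture


def make_topics(n=3, keywords=("surgery", "genetics", "virology", "cardiology"),
                retraction_rates=None, **kw):
    rates = retraction_rates or [0.0] * n
    return [
        TopicSpec(
            name=f"topic{i}",
            vocabulary={f"term{i}{j}": 1.0 + (j % 3) for j in range(40)},
            journal_keyword=keywords[i % len(keywords)],
            year_center=1995.0 + 8 * i,
            year_sd=5.0,
            retraction_rate=rates[i],
            **kw,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def mixture200():
    """200 points, 3 well-separated Gaussian clusters in 10-D, with years."""
    cfg = SyntheticConfig(n_papers=200, topics=make_topics(3),
                          cluster_separation=6.0, dim=10, seed=11)
    vs, labels = generate_vector_mixture(cfg)
    rng = np.random.default_rng(12)
    years = rng.integers(1980, 2021, 200).astype(float)
    return vs, labels, years


@pytest.fixture(scope="session")
def small_corpus():
    """A ~300-record synthetic corpus with three journal-labeled topics."""
    cfg = SyntheticConfig(n_papers=300, topics=make_topics(3, retraction_rates=[0.2, 0.0, 0.0]),
                          seed=21)
    return generate_records(cfg), cfg
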