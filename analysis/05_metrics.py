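#!/usr/bin/env python
"""Quantify the atlas: kNN accuracy, year RMSE, recall, isolatedness, regions.

Reads the cleaned corpus, the reduced vectors and the 2-D embedding, and
computes the full metric suite: label accuracy in the high-dimensional and
2-D spaces with chance level, publication-year RMSE with chance level, kNN
recall of the embedding, isolatedness of topical sub-corpora, and the
fraction of retracted papers inside the retraction-enriched 2-D region.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from litatlas.embed import read_embedding
from litatlas.ingest import read_clean_tsv
from litatlas.study import corpus_statistics
from litatlas.vectorize import load_vectors


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--test-size", type=int, default=1000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_clean_tsv(args.results / "corpus_clean.tsv")
    vectors = load_vectors(str(args.results / "vectors_svd"))
    embedding = read_embedding(str(args.results / "embedding"))

    stats = corpus_statistics(records, vectors, embedding,
                              test_size=args.test_size, seed=args.seed)
    out = {}
    for key, val in stats.items():
        if hasattr(val, "value"):
            out[key] = {"value": round(float(val.value), 4), "k": val.k,
                        "n_test": val.n_test, "seed": val.seed}
            print(f"{key}: {val.value:.2f}")
        elif isinstance(val, dict):
            out[key] = val
            print(f"{key}: {val}")
        else:
            out[key] = float(val) if isinstance(val, np.floating) else val
            print(f"{key}: {out[key]}")
    with open(args.results / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {args.results}/metrics.json")


if __name__ == "__main__":
    main()
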