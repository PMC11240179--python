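#!/usr/bin/env python
"""Vectorize the cleaned abstracts: log-scaled TF-IDF reduced with SVD.

Tokenizes (lowercase, >=2 word characters), applies the TF-IDF weighting
X_ij = (1 + ln C_ij)(1 + ln((1+n)/(1+df_j))) with unit-l2 rows, and projects
onto the top singular subspace. Writes the reduced vectors with a JSON
sidecar.
"""

import argparse
from pathlib import Path

from litatlas.ingest import read_clean_tsv
from litatlas.study import vectorize_corpus
from litatlas.vectorize import save_vectors


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--svd-dim", type=int, default=50)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_clean_tsv(args.results / "corpus_clean.tsv")
    counts, tfidf, svd = vectorize_corpus(records, d=args.svd_dim)

    save_vectors(svd, str(args.results / "vectors_svd"))
    nnz = tfidf.X.nnz
    n, v = tfidf.X.shape
    print(f"TF-IDF matrix: {n} x {v} with {nnz} nonzeros "
          f"({100 * nnz / (n * v):.2f}% dense)")
    print(f"SVD scores: {svd.X.shape[0]} x {svd.X.shape[1]}")
    print(f"wrote {args.results}/vectors_svd.tsv (+ .json sidecar)")


if __name__ == "__main__":
    main()
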