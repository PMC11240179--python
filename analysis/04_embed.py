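#!/usr/bin/env python
"""Embed the reduced vectors in 2-D with uniform-affinity t-SNE.

Builds the exact k=10 nearest-neighbor graph, places uniform affinities on
it, and optimizes for 2,250 iterations (250 of linearly annealed early
exaggeration, then 2,000 plain) from a PCA initialization with learning rate
n/12. Writes coordinates plus the KL-divergence trace.
"""

import argparse
from pathlib import Path

from litatlas.embed import write_embedding
from litatlas.study import embed_corpus
from litatlas.vectorize import load_vectors


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--k", type=int, default=10)
    ap.add_argument("--n-iter", type=int, default=2250)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    vectors = load_vectors(str(args.results / "vectors_svd"))
    embedding = embed_corpus(vectors, k=args.k, seed=args.seed,
                             n_iter=args.n_iter)
    write_embedding(embedding, str(args.results / "embedding"))

    first_iter, first_kl = embedding.kl_trace[0]
    print(f"embedded {embedding.n} points in 2-D")
    print(f"KL divergence: {first_kl:.4f} (iteration {first_iter}) -> "
          f"{embedding.final_kl:.4f} (final)")
    print(f"wrote {args.results}/embedding.tsv (+ .json sidecar)")


if __name__ == "__main__":
    main()
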