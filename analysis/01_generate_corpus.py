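#!/usr/bin/env python
"""Generate the synthetic study corpus and write it to results/.

Emulates the statistical structure of a large bibliographic database with six
topics (virology, a recent tightly-clustered covid-like topic, neuroscience,
genetics, surgery, cancer), journal titles carrying discipline keywords,
per-topic year drift, time-varying female authorship and a retraction-
enriched topic. Writes the raw records as TSV, a small XML sample in the
MEDLINE-style dialect, and the generating configuration.
"""

import argparse
from pathlib import Path

from litatlas.ingest import write_medline_xml, write_records_tsv
from litatlas.study import study_config
from litatlas.synthetic import generate_records


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-papers", type=int, default=6000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    config = study_config(n_papers=args.n_papers, seed=args.seed)
    records = generate_records(config)

    config.to_yaml(args.results / "corpus_config.yaml")
    write_records_tsv(records, args.results / "corpus_raw.tsv")
    write_medline_xml(records[:50], args.results / "corpus_sample.xml")

    by_topic = {}
    for r in records:
        by_topic[r.journal] = by_topic.get(r.journal, 0) + 1
    print(f"generated {len(records)} records across {len(by_topic)} journals:")
    for journal, count in sorted(by_topic.items()):
        print(f"  {journal}: {count}")
    print(f"retracted: {sum(r.retracted for r in records)}")
    print(f"wrote {args.results}/corpus_raw.tsv, corpus_sample.xml, corpus_config.yaml")


if __name__ == "__main__":
    main()
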