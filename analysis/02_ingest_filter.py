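#!/usr/bin/env python
"""Filter, label and gender-annotate the raw corpus.

Applies the cleaning rules (English only, non-empty abstract of 250-4,000
characters ending in sentence punctuation, truncation phrases removed,
duplicates dropped), assigns journal-keyword discipline labels, and infers
author genders from forenames and publication years. Writes the cleaned
corpus and a per-reason rejection log.
"""

import argparse
from pathlib import Path

import pandas as pd

from litatlas.ingest import (
    assign_journal_labels,
    filter_records,
    infer_record_genders,
    read_records_tsv,
    write_clean_tsv,
)
from litatlas.names import builtin_name_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_records_tsv(args.results / "corpus_raw.tsv")
    kept, rejections = filter_records(records)
    kept = assign_journal_labels(kept, seed=args.seed)
    kept = infer_record_genders(kept, builtin_name_table())

    write_clean_tsv(kept, args.results / "corpus_clean.tsv")
    pd.DataFrame(sorted(rejections.items()),
                 columns=["reason", "count"]).to_csv(
        args.results / "rejections.tsv", sep="\t", index=False)

    labeled = sum(r.label is not None for r in kept)
    resolved = sum(r.first_author_gender not in (None, "unknown") for r in kept)
    print(f"kept {len(kept)}/{len(records)} records "
          f"({len(records) - len(kept)} rejected: {rejections or 'none'})")
    print(f"labeled: {labeled} ({100 * labeled / len(kept):.1f}%)")
    print(f"first-author gender resolved: {resolved} "
          f"({100 * resolved / len(kept):.1f}%)")
    print(f"wrote {args.results}/corpus_clean.tsv, rejections.tsv")


if __name__ == "__main__":
    main()
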