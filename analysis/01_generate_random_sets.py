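#!/usr/bin/env python
"""Generate the GC-stratified random test sets used by the study.

Builds the all-negative sets at the study geometries: length 62 and
length 100 without a consensus, and length 70 with the acceptor AG
dinucleotide fixed at positions 49-50.  Because distinct GC batches can
collide on the same integer mark and every occupied mark is pruned to
exactly 50 sequences, the totals come out below 50 x 101: 3150, 5050 and
3450 respectively.  Writes each set as FASTA plus a TSV manifest and a
summary table.
"""

import argparse
from pathlib import Path

import pandas as pd

from nullbench import ConsensusSpec, generate_gc_stratified
from nullbench.io import write_dataset_fasta, write_dataset_manifest

SETS = {
    "len62": dict(length=62, consensus=None),
    "len100_raw_score": dict(length=100, consensus=None),
    "len70_acceptor": dict(length=70, consensus=ConsensusSpec(49, "AG")),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=50, help="sequences per GC mark")
    ap.add_argument("--out", type=Path, default=Path("results/random_sets"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, spec in SETS.items():
        data = generate_gc_stratified(
            args.n, spec["length"], seed=args.seed, consensus=spec["consensus"]
        )
        write_dataset_fasta(data, args.out / f"{name}.fasta")
        write_dataset_manifest(data, args.out / f"{name}.tsv")
        rows.append(
            {
                "set": name,
                "length": spec["length"],
                "consensus": spec["consensus"].motif if spec["consensus"] else "-",
                "n_per_mark": args.n,
                "occupied_marks": data.occupied_marks.size,
                "total_sequences": len(data),
            }
        )
        print(
            f"{name}: {len(data)} sequences over {data.occupied_marks.size} marks"
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "summary.tsv", sep="\t", index=False)
    print(f"\nwritten to {args.out}")


if __name__ == "__main__":
    main()
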