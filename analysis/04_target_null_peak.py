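#!/usr/bin/env python
"""Where does the target-null log-odds curve peak?

With an i.i.d. family model of GC fraction g scored against the
per-sequence target null, the log-odds of a sequence is -L times the
KL divergence from its own base frequencies to the family distribution,
so it is maximal exactly when the sequence's composition matches the
family's.  Over the stratified negatives the per-mark mean log-odds
should therefore peak at mark round(100 g) — the "centering" property
that lets the target null cancel the compositional bias a family model
carries.

This driver measures the empirical peak for g in {5%, 25%, 50%, 75%,
95%}.  The argmax of a per-mark mean is a noisy statistic (within-mark
A/T and G/C split entropy has a spread of ~1.4 bits against a ~0.03-bit
signal between adjacent marks), so it uses a large per-mark sample
(default 30000) rather than the study default of 50.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nullbench import generate_gc_stratified, make_fixed_gc
from nullbench.null_models import raw_score_counts, target_raw_score_counts

GCS = (0.05, 0.25, 0.5, 0.75, 0.95)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=30000, help="sequences per GC mark")
    ap.add_argument("--length", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/target_null_peak.tsv"))
    args = ap.parse_args()

    data = generate_gc_stratified(args.n, args.length, seed=args.seed)
    counts = data.counts()
    target_bits = target_raw_score_counts(counts)
    marks = data.marks
    uniq = np.unique(marks)

    rows = []
    for g in GCS:
        s = raw_score_counts(counts, make_fixed_gc(g)) - target_bits
        means = np.array([s[marks == m].mean() for m in uniq])
        peak = int(uniq[np.argmax(means)])
        rows.append({"family_gc": g, "expected_peak": round(100 * g),
                     "observed_peak": peak, "peak_mean_bits": means.max()})
        print(f"family GC {g:.2f}: per-mark mean log-odds peaks at mark {peak} "
              f"(expected {round(100 * g)}), peak mean {means.max():+.3f} bits")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)
    print(f"\n-> {args.out}")


if __name__ == "__main__":
    main()
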