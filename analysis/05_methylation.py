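#!/usr/bin/env python
"""Per-CpG methylation of assigned bisulfite consensi.

Reads the methylated-site-count histogram written by
02_run_experiment.py and prints, per allele group, the distribution
over the 35 CpG sites summed across selection conditions — the check
that in vitro methylation persists on the methylated allele while
unmethylated and wild-type sequences stay unmethylated.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()

    hist = pd.read_csv(args.results / "methylation_histogram.tsv", sep="\t")
    summed = hist.groupby(["group", "n_methylated"])["count"].sum().reset_index()
    print("Methylated-site counts per group role (summed across arms):")
    for group, sub in summed.groupby("group"):
        total = sub["count"].sum()
        if total == 0:
            continue
        mean = (sub.n_methylated * sub["count"]).sum() / total
        top = sub[sub["count"] > 0].sort_values("count", ascending=False).head(3)
        modes = ", ".join(f"{int(r.n_methylated)} ({int(r['count'])})" for _, r in top.iterrows())
        print(f"  {group:>9}: n={total}, mean {mean:.1f} of 35; top bins: {modes}")


if __name__ == "__main__":
    main()
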