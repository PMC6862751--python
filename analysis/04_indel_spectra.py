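#!/usr/bin/env python
"""Junction indel spectra and rate comparisons.

Reads the junction size distributions, the 6-TG positional indel
profile, and the Fisher tests from 02_run_experiment.py and prints the
repair-outcome comparisons: methylated vs unmethylated, exogenous vs
endogenous inserts, forward vs inverted wild type.
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()

    sizes = pd.read_csv(args.results / "junction_sizes.tsv", sep="\t")
    stats = json.loads((args.results / "stats.json").read_text())

    print("Junction indel size spectra (max-1 scaled, non-6-TG samples):")
    for name, sub in sizes.groupby("comparison"):
        top = sub.sort_values("count", ascending=False).head(4)
        desc = ", ".join(f"{int(r['size']):+d}:{r.scaled:.2f}" for _, r in top.iterrows())
        print(f"  {name:>14}: {desc}")

    print("\nJunction indel rates (Fisher's exact, non-6-TG samples):")
    for name, f in stats.get("fisher_indel_rates", {}).items():
        print(
            f"  {name}: {100 * f['rate_a']:.1f}% ({f['k_a']}/{f['n_a']}) vs "
            f"{100 * f['rate_b']:.1f}% ({f['k_b']}/{f['n_b']}), p = {f['p']:.3g}"
        )

    profile_path = args.results / "indel_profile_6tg.tsv"
    if profile_path.exists():
        prof = pd.read_csv(profile_path, sep="\t")
        peak = prof.sort_values("fraction", ascending=False).head(4)
        print("\n6-TG indel profile peaks (position, fraction of reads):")
        for _, r in peak.iterrows():
            print(f"  {int(r.position)}: {r.fraction:.2f}")


if __name__ == "__main__":
    main()
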