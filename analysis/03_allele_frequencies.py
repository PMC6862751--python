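#!/usr/bin/env python
"""Summarise allele and orientation frequencies across selection arms.

Reads the frequency tables written by 02_run_experiment.py and prints
the selection story: methylated/unmethylated insert shares per arm
under the exact-match convention, the orientation summary, and the
fold-change comparison with its paired test.
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()

    freq = pd.read_csv(args.results / "frequencies.tsv", sep="\t")
    stats = json.loads((args.results / "stats.json").read_text())

    strict = freq[freq.policy == "strict_matched"].copy()
    strict["arm"] = pd.Categorical(strict["arm"], ["pre", "mock", "6tg"])
    strict["meth_allele"] = strict.sample_id.str.split("_").str[0]
    strict["role"] = "wildtype"
    strict.loc[strict.group == strict.meth_allele, "role"] = "methylated"
    strict.loc[
        (strict.group != strict.meth_allele) & (strict.group != "wildtype"), "role"
    ] = "unmethylated"
    print("Long-read exact-match forward shares (%), mean over samples:")
    print(
        strict.pivot_table(values="pct", index="role", columns="arm", observed=True)
        .round(2)
        .to_string()
    )

    orient = freq[(freq.policy == "orientation") & (freq.orientation == "inverted")]
    print("\nInverted fraction among oriented exact-match calls (%):")
    print(orient.groupby(orient.sample_id.str.split("_rep").str[-1].str.split("_").str[-1])
          ["pct"].mean().round(2).to_string())

    print("\nShort-read fold changes (6-TG over mock):")
    print(json.dumps(stats.get("illumina_fold_change", {}), indent=1))
    print("\nLong-read 6-TG shares, methylated vs unmethylated:")
    print(json.dumps(stats.get("pacbio_6tg_pct", {}), indent=1))


if __name__ == "__main__":
    main()
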