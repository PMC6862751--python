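#!/usr/bin/env python
"""Build the surrogate locus model and write the reference set.

Writes forward and inverted reference FASTA plus a JSON sidecar of all
windows and offsets under results/reference/, and prints the
structural facts the downstream callers rely on.
"""

import argparse
from pathlib import Path

from islandswap.reference_model import build_model, find_cpgs, write_reference


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/reference"))
    args = ap.parse_args()

    model = build_model(args.seed)
    model.validate()
    fasta, sidecar = write_reference(model, args.out)

    print(f"locus: {len(model.locus_seq)} bp "
          f"({model.flank_up} + {model.insert_len} + {model.flank_down})")
    print(f"cut sites (0-based inter-base): {model.cut_left}, {model.cut_right}")
    print("SNVs (insert offset, ref>alt, allele):")
    for s in model.snvs:
        print(f"  {s.offset}: {s.ref_base}>{s.alt_base} ({s.allele_id})")
    print("PAM mutations:", ", ".join(
        f"{p.offset}: {p.ref_base}>{p.alt_base}" for p in model.pams))
    print(f"windows (1-based, insert-relative): illumina {model.illumina_window}, "
          f"pacbio {model.pacbio_window}, bisulfite {model.bisulfite_window}")
    n_cpg = len(find_cpgs(model.insert_seq, model.bisulfite_window))
    print(f"CpG dinucleotides in bisulfite window: {n_cpg}")
    print(f"wrote {fasta} and {sidecar}")


if __name__ == "__main__":
    main()
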