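"""Locus model for the HPRT1 CpG-island replacement experiment.

The experiment excises a 1120-bp CpG-island segment with two flanking
Cas9 cuts and replaces it with a transfected copy that carries two
synonymous allele-defining SNVs (per allele) and two PAM mutations at
the sixth base from each insert end.  The real hg19 sequence is not
bundled; instead a seeded surrogate sequence with CpG-island-like GC
content (60%) is generated under the printed structural constraints:

* insert span chrX:133593819-133594938 (1120 bp), flanked by ~700 bp
  upstream and ~165 bp downstream of amplified context,
* SNVs at insert-relative offsets 532 (C>T, allele 1), 535 (C>G,
  allele 2), 538 (C>T, allele 2) and 541 (T>A, allele 1),
* PAM mutations at offsets 6 (G>C) and 1115 (C>G),
* a 44-bp short-read exact-match window (offsets 502-545), a 250-bp
  long-read window (306-555) and a 283-bp bisulfite window (478-760)
  containing exactly 35 CpG dinucleotides,
* no CpG dinucleotide overlapping an SNV offset, in either the
  wild-type or the variant sequence, so that allele assignment of
  bisulfite-converted reads stays well defined.

All user-facing coordinates are 1-based inclusive (genomic convention);
internal string indexing is 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: genomic anchor of the cut-out segment (1-based inclusive, GRCh37)
INSERT_CHROM = "chrX"
INSERT_GENOMIC_START = 133593819
INSERT_GENOMIC_END = 133594938
INSERT_LEN = INSERT_GENOMIC_END - INSERT_GENOMIC_START + 1  # 1120

#: allele-defining synonymous SNVs: (genomic position, ref, alt, allele)
_SNV_TABLE = (
    (133594350, "C", "T", "allele1"),
    (133594353, "C", "G", "allele2"),
    (133594356, "C", "T", "allele2"),
    (133594359, "T", "A", "allele1"),
)

#: PAM-destroying mutations at the sixth base from each insert end
_PAM_TABLE = (
    (133593824, "G", "C", "left"),
    (133594933, "C", "G", "right"),
)

#: exact-match / analysis windows (genomic, 1-based inclusive)
_ILLUMINA_WINDOW_GENOMIC = (133594320, 133594363)   # 44 bp, exon 1 CDS
_PACBIO_WINDOW_GENOMIC = (133594124, 133594373)     # 250 bp promoter/exon/splice donor
_BISULFITE_WINDOW_GENOMIC = (133594296, 133594578)  # 283 bp, 35 CpGs

N_CPG = 35


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeWindow:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnvSpec:
    """Allele-defining SNV at a 1-based offset within the insert."""

    offset: int
    ref_base: str
    alt_base: str
    allele_id: str


@dataclass(frozen=True)
class PamMutationSpec:
    """PAM-destroying edit at the sixth base from one insert end."""

    offset: int
    ref_base: str
    alt_base: str
    side: str


def _rel(genomic_pos: int) -> int:
    """Genomic position -> 1-based offset within the insert."""
    return genomic_pos - INSERT_GENOMIC_START + 1


SNVS = tuple(
    SnvSpec(_rel(pos), ref, alt, allele) for pos, ref, alt, allele in _SNV_TABLE
)
PAMS = tuple(
    PamMutationSpec(_rel(pos), ref, alt, side) for pos, ref, alt, side in _PAM_TABLE
)
ILLUMINA_WINDOW = (_rel(_ILLUMINA_WINDOW_GENOMIC[0]), _rel(_ILLUMINA_WINDOW_GENOMIC[1]))
PACBIO_WINDOW = (_rel(_PACBIO_WINDOW_GENOMIC[0]), _rel(_PACBIO_WINDOW_GENOMIC[1]))
BISULFITE_WINDOW = (_rel(_BISULFITE_WINDOW_GENOMIC[0]), _rel(_BISULFITE_WINDOW_GENOMIC[1]))

ALLELE_IDS = ("wildtype", "allele1", "allele2")


@dataclass(frozen=True)
class AmpliconModel:
    """Sequenced locus: upstream flank + 1120-bp insert + downstream flank.

    ``cut_left``/``cut_right`` are 0-based inter-base positions within
    ``locus_seq`` (blunt Cas9 cuts, three bases 5' of each PAM, which
    places them exactly at the insert boundaries).  Windows, SNV and CpG
    offsets are 1-based inclusive relative to the insert.
    """

    locus_seq: str
    flank_up: int
    flank_down: int
    snvs: tuple[SnvSpec, ...] = SNVS
    pams: tuple[PamMutationSpec, ...] = PAMS
    illumina_window: tuple[int, int] = ILLUMINA_WINDOW
    pacbio_window: tuple[int, int] = PACBIO_WINDOW
    bisulfite_window: tuple[int, int] = BISULFITE_WINDOW
    cpg_offsets: tuple[int, ...] = ()
    genomic_anchor: GenomeWindow = field(
        default_factory=lambda: GenomeWindow(
            INSERT_CHROM, INSERT_GENOMIC_START, INSERT_GENOMIC_END
        )
    )

    # -- coordinate helpers -------------------------------------------------

    @property
    def insert_len(self) -> int:
        return len(self.locus_seq) - self.flank_up - self.flank_down

    @property
    def cut_left(self) -> int:
        return self.flank_up

    @property
    def cut_right(self) -> int:
        return self.flank_up + self.insert_len

    @property
    def insert_seq(self) -> str:
        """Wild-type cut-to-cut segment."""
        return self.locus_seq[self.cut_left : self.cut_right]

    @property
    def flank_up_seq(self) -> str:
        return self.locus_seq[: self.cut_left]

    @property
    def flank_down_seq(self) -> str:
        return self.locus_seq[self.cut_right :]

    def insert_to_locus(self, offset: int) -> int:
        """1-based insert offset -> 0-based index into ``locus_seq``."""
        if not 1 <= offset <= self.insert_len:
            raise ValueError(f"offset {offset} outside insert 1..{self.insert_len}")
        return self.flank_up + offset - 1

    def to_genomic(self, offset: int) -> GenomeWindow:
        """1-based insert offset -> single-base genomic window."""
        if not 1 <= offset <= self.insert_len:
            raise ValueError(f"offset {offset} outside insert 1..{self.insert_len}")
        pos = self.genomic_anchor.start + offset - 1
        return GenomeWindow(self.genomic_anchor.chrom, pos, pos)

    def from_genomic(self, coord: int) -> int:
        """Genomic coordinate -> 1-based insert offset."""
        if not self.genomic_anchor.start <= coord <= self.genomic_anchor.end:
            raise ValueError(f"coordinate {coord} outside modeled span")
        return coord - self.genomic_anchor.start + 1

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Assert every structural invariant of the model."""
        if self.insert_len != INSERT_LEN:
            raise ValueError(f"insert length {self.insert_len} != {INSERT_LEN}")
        if self.flank_up < 100 or self.flank_down < 100:
            raise ValueError("flanks must be >= 100 bp")
        if self.illumina_window[1] - self.illumina_window[0] + 1 != 44:
            raise ValueError("illumina window must span 44 bp")
        if self.pacbio_window[1] - self.pacbio_window[0] + 1 != 250:
            raise ValueError("pacbio window must span 250 bp")
        ins = self.insert_seq
        for snv in self.snvs:
            if ins[snv.offset - 1] != snv.ref_base:
                raise ValueError(f"wild-type base at SNV offset {snv.offset} is not {snv.ref_base}")
            for win in (self.illumina_window, self.pacbio_window, self.bisulfite_window):
                if not win[0] <= snv.offset <= win[1]:
                    raise ValueError(f"SNV offset {snv.offset} outside window {win}")
            # no CpG may overlap an SNV offset, for wild-type or variant base
            for base in (snv.ref_base, snv.alt_base):
                s = ins[: snv.offset - 1] + base + ins[snv.offset :]
                i = snv.offset - 1
                if (i > 0 and s[i - 1 : i + 1] == "CG") or s[i : i + 2] == "CG":
                    raise ValueError(f"CpG overlaps SNV offset {snv.offset} (base {base})")
        for pam in self.pams:
            if ins[pam.offset - 1] != pam.ref_base:
                raise ValueError(f"wild-type base at PAM offset {pam.offset} is not {pam.ref_base}")
        expected_right = self.insert_len - 6 + 1
        offs = sorted(p.offset for p in self.pams)
        if offs != [6, expected_right]:
            raise ValueError(f"PAM offsets {offs} != [6, {expected_right}]")
        if len(self.cpg_offsets) != N_CPG:
            raise ValueError(f"{len(self.cpg_offsets)} CpGs recorded, expected {N_CPG}")
        if tuple(find_cpgs(ins, self.bisulfite_window)) != self.cpg_offsets:
            raise ValueError("cpg_offsets inconsistent with sequence")


def find_cpgs(insert_seq: str, window: tuple[int, int]) -> list[int]:
    """1-based insert offsets of the C of each CG dinucleotide fully inside window."""
    lo, hi = window
    return [
        p
        for p in range(lo, hi)  # C at p, G at p+1, both <= hi
        if insert_seq[p - 1 : p + 1] == "CG"
    ]


def _draw_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random DNA at 60% GC as a character array."""
    return rng.choice(np.array(list("ACGT")), size=n, p=[0.2, 0.3, 0.3, 0.2])


def _attempt_insert(rng: np.random.Generator) -> str | None:
    """One attempt at a constraint-satisfying surrogate insert sequence."""
    arr = _draw_sequence(rng, INSERT_LEN)
    # fixed reference bases at SNV and PAM offsets
    for spec in (*SNVS, *PAMS):
        arr[spec.offset - 1] = spec.ref_base
    # keep SNV offsets out of CpG context for every variant base:
    # 532 C/T and 538 C/T forbid a following G; 535 C/G forbids a
    # preceding C and a following G; 541 T/A can never form a CpG.
    for off in (532, 535, 538):
        if arr[off] == "G":  # 0-based off = offset+1-1
            arr[off] = rng.choice(np.array(list("ACT")))
    if arr[533] == "C":  # base before offset 535
        arr[533] = rng.choice(np.array(list("AGT")))

    seq = list(arr)
    lo, hi = BISULFITE_WINDOW
    protected = set()
    for snv in SNVS:
        protected.update(range(snv.offset - 2, snv.offset + 2))

    def cpg_starts() -> list[int]:
        return [p for p in range(lo, hi) if seq[p - 1] == "C" and seq[p] == "G"]

    # repair the CpG count inside the bisulfite window to exactly 35
    for _ in range(4000):
        starts = cpg_starts()
        if len(starts) == N_CPG:
            break
        if len(starts) > N_CPG:
            candidates = [p for p in starts if p not in protected and p + 1 not in protected]
            if not candidates:
                return None
            p = candidates[rng.integers(len(candidates))]
            seq[p] = "A"  # destroy the G of the pair; A never seeds a new CpG
        else:
            p = int(rng.integers(lo, hi))
            if p in protected or p + 1 in protected:
                continue
            seq[p - 1] = "C"
            seq[p] = "G"
    else:
        return None
    # no CpG may straddle the window's right edge: its C would sit inside
    # the window and differ between converted reference variants without
    # being one of the 35 counted sites
    if seq[hi - 1] == "C" and seq[hi] == "G":
        seq[hi] = "A"
    return "".join(seq)


def build_model(
    seed: int, flank_up: int = 700, flank_down: int = 165, max_attempts: int = 50
) -> AmpliconModel:
    """Construct the surrogate locus model for a given seed.

    Deterministic for a given ``(seed, flank_up, flank_down)``.  The
    default flanks match the long-read amplicon design (primers ~700 bp
    upstream of one cut and ~165 bp downstream of the other).

    Raises ``RuntimeError`` if the structural constraints cannot be
    satisfied within ``max_attempts`` independent draws.
    """
    if flank_up < 100 or flank_down < 100:
        raise ValueError("flank_up and flank_down must be >= 100")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1512AD]))
    for _ in range(max_attempts):
        insert = _attempt_insert(rng)
        if insert is None:
            continue
        up = "".join(_draw_sequence(rng, flank_up))
        down = "".join(_draw_sequence(rng, flank_down))
        model = AmpliconModel(
            locus_seq=up + insert + down,
            flank_up=flank_up,
            flank_down=flank_down,
            cpg_offsets=tuple(find_cpgs(insert, BISULFITE_WINDOW)),
        )
        try:
            model.validate()
        except ValueError:
            continue
        return model
    raise RuntimeError(f"no constraint-satisfying sequence in {max_attempts} attempts")


def derive_allele(model: AmpliconModel, allele_id: str, pam_mutated: bool) -> str:
    """Insert sequence for one allele, optionally with both PAM mutations.

    The result differs from the wild-type insert at exactly the allele's
    SNV offsets (none for ``wildtype``) plus, if ``pam_mutated``, the two
    PAM offsets.
    """
    if allele_id not in ALLELE_IDS:
        raise ValueError(f"unknown allele_id {allele_id!r}")
    seq = list(model.insert_seq)
    for snv in model.snvs:
        if snv.allele_id == allele_id:
            seq[snv.offset - 1] = snv.alt_base
    if pam_mutated:
        for pam in model.pams:
            seq[pam.offset - 1] = pam.alt_base
    return "".join(seq)


def invert_between_cuts(model: AmpliconModel, insert_seq: str) -> str:
    """Full locus with the cut-to-cut segment reverse-complemented.

    Models re-ligation of the excised segment in inverted orientation:
    flanks are kept unaltered, the insert is reverse-complemented.
    """
    if len(insert_seq) != model.insert_len:
        raise ValueError(
            f"insert length {len(insert_seq)} != {model.insert_len}"
        )
    return model.flank_up_seq + revcomp(insert_seq) + model.flank_down_seq


def locus_with_insert(model: AmpliconModel, insert_seq: str) -> str:
    """Full locus with the given segment in forward orientation."""
    if len(insert_seq) != model.insert_len:
        raise ValueError(
            f"insert length {len(insert_seq)} != {model.insert_len}"
        )
    return model.flank_up_seq + insert_seq + model.flank_down_seq


def reference_loci(model: AmpliconModel) -> dict[str, str]:
    """Named forward and inverted reference loci.

    Transfected alleles carry the PAM mutations; the wild-type segment
    does not.  ``*_inv`` references invert the segment between the cuts
    while keeping the flanks unaltered.
    """
    refs: dict[str, str] = {}
    for allele in ALLELE_IDS:
        ins = derive_allele(model, allele, pam_mutated=(allele != "wildtype"))
        name = "wt" if allele == "wildtype" else allele
        refs[f"locus_{name}_fwd"] = locus_with_insert(model, ins)
        refs[f"locus_{name}_inv"] = invert_between_cuts(model, ins)
    return refs


def write_reference(model: AmpliconModel, outdir: str | Path) -> tuple[Path, Path]:
    """Write reference FASTA plus a JSON sidecar of windows and offsets."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "references.fasta"
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference_loci(model).items()
    ]
    SeqIO.write(records, fasta, "fasta")
    sidecar = outdir / "references.json"
    sidecar.write_text(
        json.dumps(
            {
                "genomic_anchor": {
                    "chrom": model.genomic_anchor.chrom,
                    "start": model.genomic_anchor.start,
                    "end": model.genomic_anchor.end,
                },
                "flank_up": model.flank_up,
                "flank_down": model.flank_down,
                "insert_len": model.insert_len,
                "cut_left": model.cut_left,
                "cut_right": model.cut_right,
                "snvs": [vars(s) for s in model.snvs],
                "pams": [vars(p) for p in model.pams],
                "illumina_window": list(model.illumina_window),
                "pacbio_window": list(model.pacbio_window),
                "bisulfite_window": list(model.bisulfite_window),
                "cpg_offsets": list(model.cpg_offsets),
            },
            indent=1,
        )
    )
    return fasta, sidecar
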