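"""Truth-labeled read simulation for the three sequencing branches.

Each simulated cell is haploid and carries exactly one editing outcome
at the locus:

``deletion``
    the cut-to-cut segment is lost and the flanks religate;
``wt_fwd`` / ``wt_inv``
    the excised wild-type segment is re-inserted, forward or inverted;
``meth_fwd`` / ``meth_inv`` and ``unmeth_fwd`` / ``unmeth_inv``
    a transfected, PAM-mutated allele is inserted forward or inverted.
    Which physical allele (1 or 2) is the methylated one is an arm-level
    design choice (the reciprocal-plate design), so outcome classes are
    expressed in methylation terms and mapped to alleles per arm.

Every junction formed by re-ligation may carry a small NHEJ indel:
deletions chew symmetrically into the two sides of the junction,
insertions add random bases at it.  6-thioguanine selection resamples
the population: cells that still express the gene (forward wild-type or
forward unmethylated insert, with no junction deletion reaching the
functional promoter/exon window) survive only at a small rate
``epsilon``; silenced cells (methylated forward insert, any inversion,
any wholesale deletion, or a functional-window-disrupting indel)
survive freely.

Reads are emitted post-merge/post-CCS (the upstream demultiplex, read
merging and circular-consensus steps are outside the model): constant
quality, substitution errors only, one UMI per original molecule (= per
cell and branch).  The short-read branch only amplifies forward-
oriented, non-deletion templates (nested design anchored outside the 5'
cut); the long-read branch covers the full locus but excludes wholesale
deletions by default (the ~2-kb band gel extraction); the bisulfite
branch amplifies within the segment, so orientation does not matter,
and applies one bisulfite conversion per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_model import AmpliconModel, derive_allele, revcomp

OUTCOME_CLASSES = (
    "deletion",
    "wt_fwd",
    "wt_inv",
    "meth_fwd",
    "meth_inv",
    "unmeth_fwd",
    "unmeth_inv",
)
#: classes whose cells still express the gene (killed by 6-TG)
EXPRESSING_CLASSES = frozenset({"wt_fwd", "unmeth_fwd"})

BRANCHES = ("illumina", "pacbio", "bisulfite")

_BASES = np.array(list("ACGT"))

#: default editing-outcome proportions of the pre-selection cell pool.
#: Anchored to the printed pre-selection read shares: methylated insert
#: 0.65% and unmethylated 2.37% (both orientations, halved per
#: orientation), 63.4% forward among oriented sequences, and a
#: substantial wholesale-deletion fraction (not quantified upstream;
#: 0.25 chosen); wild-type classes absorb the remainder.
DEFAULT_CLASS_PROPORTIONS = {
    "deletion": 0.25,
    "wt_fwd": 0.4602,
    "wt_inv": 0.2596,
    "meth_fwd": 0.0033,
    "meth_inv": 0.0032,
    "unmeth_fwd": 0.0120,
    "unmeth_inv": 0.0117,
}


@dataclass(frozen=True)
class IndelModel:
    """Junction indel model: geometric sizes, mostly deletions."""

    prob_indel: float = 0.3  # per junction
    p_insertion: float = 0.2
    mean_size: float = 3.0
    max_size: int = 50

    def draw(self, rng: np.random.Generator) -> int:
        """Signed indel size for one junction (0 = none)."""
        if rng.random() >= self.prob_indel:
            return 0
        size = min(int(rng.geometric(1.0 / self.mean_size)), self.max_size)
        return size if rng.random() < self.p_insertion else -size


@dataclass(frozen=True)
class SimConfig:
    """Per-sample simulation parameters (one transfection arm)."""

    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_cells: int = 2000
    reads_per_cell: int = 1
    umi_length: int = 12
    methylated_allele: str = "allele1"  # reciprocal arm: which allele is methylated
    error_rates: dict[str, float] = field(
        default_factory=lambda: {"illumina": 0.001, "pacbio": 0.006, "bisulfite": 0.001}
    )
    maintenance_rate: float = 0.95
    conversion_failure_rate: float = 0.005
    background_methylation: float = 0.01
    epsilon: float = 0.001  # 6-TG survival of expressing, indel-free cells
    indel_model: IndelModel = field(default_factory=IndelModel)
    keep_deletions: bool = False

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, not 1")
        if set(self.class_proportions) - set(OUTCOME_CLASSES):
            raise ValueError("unknown outcome class in proportions")
        for v in (
            self.maintenance_rate,
            self.conversion_failure_rate,
            self.background_methylation,
            self.epsilon,
            *self.error_rates.values(),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.methylated_allele not in ("allele1", "allele2"):
            raise ValueError("methylated_allele must be allele1 or allele2")


@dataclass
class Cell:
    """One simulated haploid cell and its truth labels."""

    cell_id: str
    outcome: str
    allele: str  # wildtype / allele1 / allele2 / "" for deletion
    locus: str
    left_indel: int  # signed junction indel (0 = none)
    right_indel: int
    left_del_into_insert: int  # deletion depth past the junction into the insert
    right_del_into_insert: int
    meth_states: np.ndarray | None  # bool per window CpG, None for deletion

    @property
    def meth_vector(self) -> str:
        if self.meth_states is None:
            return ""
        return "".join("M" if m else "U" for m in self.meth_states)


@dataclass
class SimRead:
    read_id: str
    seq: str
    cell: Cell
    umi: str
    branch: str


def truth_group_orientation(outcome: str, methylated_allele: str) -> tuple[str, str]:
    """Expected (caller group, orientation) for a truth outcome class."""
    if outcome == "deletion":
        return "deletion", "n/a"
    allele = class_to_allele(outcome, methylated_allele)
    return allele, "inverted" if outcome.endswith("_inv") else "forward"


def class_to_allele(outcome: str, methylated_allele: str) -> str:
    """Map an outcome class to the physical allele it carries."""
    if outcome == "deletion":
        return ""
    if outcome.startswith("wt"):
        return "wildtype"
    other = "allele2" if methylated_allele == "allele1" else "allele1"
    return methylated_allele if outcome.startswith("meth") else other


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _apply_junction(
    left: str, right: str, indel: int, rng: np.random.Generator
) -> tuple[str, str, str]:
    """Chew or pad the two sides of one junction.

    Deletions (negative) remove ``|size|//2`` bases before the junction
    and the remainder after it; insertions add random bases between.
    Returns (new_left, inserted_bases, new_right).
    """
    if indel == 0:
        return left, "", right
    if indel > 0:
        return left, _random_bases(rng, indel), right
    size = -indel
    a = size // 2
    b = size - a
    return left[: len(left) - a] if a else left, "", right[b:]


def simulate_cell(
    model: AmpliconModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    cell_id: str = "c0",
) -> Cell:
    """Draw one cell: outcome class, junction indels, methylation truth."""
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes])
    outcome = classes[rng.choice(len(classes), p=probs)]
    allele = class_to_allele(outcome, cfg.methylated_allele)

    fu, fd = model.flank_up_seq, model.flank_down_seq
    if outcome == "deletion":
        indel = cfg.indel_model.draw(rng)
        left, ins, right = _apply_junction(fu, fd, indel, rng)
        return Cell(cell_id, outcome, allele, left + ins + right,
                    indel, 0, 0, 0, None)

    insert = derive_allele(model, allele, pam_mutated=(allele != "wildtype"))
    oriented = revcomp(insert) if outcome.endswith("_inv") else insert
    li = cfg.indel_model.draw(rng)
    ri = cfg.indel_model.draw(rng)
    # right junction first so left-side coordinates are unaffected
    mid, ins_r, right = _apply_junction(oriented, fd, ri, rng)
    left, ins_l, mid = _apply_junction(fu, mid, li, rng)
    locus = left + ins_l + mid + ins_r + right

    n_cpg = len(model.cpg_offsets)
    p_meth = cfg.maintenance_rate if outcome.startswith("meth") else cfg.background_methylation
    meth = rng.random(n_cpg) < p_meth

    return Cell(
        cell_id, outcome, allele, locus, li, ri,
        left_del_into_insert=(-li) - ((-li) // 2) if li < 0 else 0,
        right_del_into_insert=(-ri) - ((-ri) // 2) if ri < 0 else 0,
        meth_states=meth,
    )


def simulate_cells(
    model: AmpliconModel, cfg: SimConfig, rng: np.random.Generator, prefix: str = "c"
) -> list[Cell]:
    return [
        simulate_cell(model, cfg, rng, cell_id=f"{prefix}{i:05d}")
        for i in range(cfg.n_cells)
    ]


def functional_window_hit(cell: Cell, model: AmpliconModel) -> bool:
    """True if a junction deletion reaches the promoter/exon window.

    The functional window is the long-read exact-match region (promoter,
    exon 1, splice donor).  A left-junction deletion covers insert
    offsets ``1..d``; a right-junction deletion covers the last ``d``
    offsets.
    """
    lo, hi = model.pacbio_window
    n = model.insert_len
    return (cell.left_del_into_insert >= lo) or (
        cell.right_del_into_insert >= n - hi + 1
    )


def apply_selection(
    cells: list[Cell],
    cfg: SimConfig,
    arm: str,
    model: AmpliconModel,
    rng: np.random.Generator,
    n_out: int | None = None,
) -> list[Cell]:
    """Selection step: ``pre`` is identity, ``mock`` resamples uniformly,
    ``6tg`` resamples with survival weights (expressing, indel-free
    cells survive only at ``epsilon``)."""
    if arm not in ("pre", "mock", "6tg"):
        raise ValueError(f"unknown arm {arm!r}")
    if arm == "pre":
        return list(cells)
    n_out = len(cells) if n_out is None else n_out
    if arm == "mock":
        idx = rng.integers(0, len(cells), size=n_out)
    else:
        weights = np.array(
            [
                cfg.epsilon
                if (c.outcome in EXPRESSING_CLASSES and not functional_window_hit(c, model))
                else 1.0
                for c in cells
            ]
        )
        total = weights.sum()
        if total <= 0:
            raise ValueError("empty surviving pool under 6-TG selection")
        idx = rng.choice(len(cells), size=n_out, replace=True, p=weights / total)
    return [
        replace(cells[i], cell_id=f"{cells[i].cell_id}.{arm}{k}")
        for k, i in enumerate(idx)
    ]


# -- branch templates -------------------------------------------------------

#: margin of template context kept on each side of a branch window (bp)
AMPLICON_MARGIN = 20


def _illumina_template(cell: Cell, model: AmpliconModel, cfg: SimConfig) -> str | None:
    """Short amplicon around the 44-bp exon window, forward classes only.

    The nested design anchors one primer upstream of the 5' cut and one
    inside the segment, so deletions, inversions and (in real data)
    random integrations never amplify; a junction deletion that removes
    the inner primer site also kills the template.
    """
    if cell.outcome not in ("wt_fwd", "meth_fwd", "unmeth_fwd"):
        return None
    lo, hi = model.illumina_window
    if cell.left_del_into_insert >= lo - AMPLICON_MARGIN:
        return None
    insert = derive_allele(model, cell.allele, pam_mutated=(cell.allele != "wildtype"))
    return insert[lo - 1 - AMPLICON_MARGIN : hi + AMPLICON_MARGIN]


def _pacbio_template(cell: Cell, model: AmpliconModel, cfg: SimConfig) -> str | None:
    if cell.outcome == "deletion" and not cfg.keep_deletions:
        return None
    return cell.locus


def _convert_bisulfite(
    template: str,
    start_offset: int,
    window_cpg_states: dict[int, bool],
    cfg: SimConfig,
    is_meth_class: bool,
    rng: np.random.Generator,
) -> str:
    """Top-strand bisulfite conversion of one molecule.

    ``start_offset`` is the 1-based insert offset of ``template[0]``.
    CpG cytosines keep C when methylated; everything else converts C->T
    except for rare conversion failures.
    """
    out = list(template)
    n = len(template)
    for i, base in enumerate(template):
        if base != "C":
            continue
        offset = start_offset + i
        is_cpg = i + 1 < n and template[i + 1] == "G"
        if is_cpg:
            if offset in window_cpg_states:
                methylated = window_cpg_states[offset]
            else:
                p = cfg.maintenance_rate if is_meth_class else cfg.background_methylation
                methylated = rng.random() < p
            if methylated:
                continue
        if rng.random() < cfg.conversion_failure_rate:
            continue  # conversion failure reads as C
        out[i] = "T"
    return "".join(out)


def _bisulfite_template(
    cell: Cell, model: AmpliconModel, cfg: SimConfig, rng: np.random.Generator
) -> str | None:
    """Converted amplicon over the bisulfite window, any orientation.

    Both primers sit inside the segment, so the amplified sequence is
    identical for forward and inverted insertions; wholesale deletions
    have no template.
    """
    if cell.outcome == "deletion":
        return None
    lo, hi = model.bisulfite_window
    start = lo - AMPLICON_MARGIN
    insert = derive_allele(model, cell.allele, pam_mutated=(cell.allele != "wildtype"))
    template = insert[start - 1 : hi + AMPLICON_MARGIN]
    states = {
        off: bool(st) for off, st in zip(model.cpg_offsets, cell.meth_states)
    }
    return _convert_bisulfite(
        template, start, states, cfg, cell.outcome.startswith("meth"), rng
    )


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def emit_reads(
    branch: str,
    cells: list[Cell],
    model: AmpliconModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    read_prefix: str = "",
) -> list[SimRead]:
    """Emit truth-labeled reads for one branch.

    Each cell contributes one original molecule carrying one UMI and
    ``reads_per_cell`` sequenced copies with independent substitution
    errors.  Long reads are strand-flipped at random (circular consensus
    reads come in either sense); the two short-read branches are
    directional.
    """
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}")
    rate = cfg.error_rates[branch]
    reads: list[SimRead] = []
    for cell in cells:
        if branch == "illumina":
            template = _illumina_template(cell, model, cfg)
        elif branch == "pacbio":
            template = _pacbio_template(cell, model, cfg)
        else:
            template = _bisulfite_template(cell, model, cfg, rng)
        if template is None:
            continue
        umi = _random_bases(rng, cfg.umi_length)
        molecule = umi + template
        for k in range(cfg.reads_per_cell):
            seq = _add_errors(molecule, rate, rng)
            if branch == "pacbio" and rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"{read_prefix}{branch}_{cell.cell_id}_{k}"
            reads.append(SimRead(rid, seq, cell, umi, branch))
    return reads


def truth_table(reads: list[SimRead]) -> pd.DataFrame:
    """Truth TSV: one row per emitted read."""
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "cell_id": [r.cell.cell_id for r in reads],
            "class": [r.cell.outcome for r in reads],
            "allele": [r.cell.allele for r in reads],
            "left_indel": [r.cell.left_indel for r in reads],
            "right_indel": [r.cell.right_indel for r in reads],
            "umi": [r.umi for r in reads],
            "meth_vector": [r.cell.meth_vector for r in reads],
        }
    )


def write_fastq(reads: list[SimRead], path: str | Path) -> Path:
    """4-line FASTQ, constant quality I (Q40)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return path
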