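"""End-to-end orchestration: simulate -> align -> consensus -> call ->
profile -> stats, as one configured, seeded, reproducible run.

The run mirrors the experimental design: two reciprocal transfections
(allele 1 methylated / allele 2 methylated), each in ``n_replicates``
replicates, each sampled pre-selection, after mock selection and after
6-TG selection.  Every stage draws from its own counter-derived random
stream so a stage can be re-run in isolation, and re-running the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .align_core import AlignmentResult, global_align, choose_orientation
from .allele_caller import (
    CallingFrame,
    call_illumina,
    call_pacbio,
    calls_frame,
    illumina_frame,
    pacbio_frames,
    tabulate,
)
from .bisulfite_caller import (
    align_bisulfite,
    build_bisulfite_refs,
    call_methylation,
    methylation_frame,
    methylation_histogram,
)
from .indel_profiler import indel_rate, positional_profile, sizes_from_calls
from .reference_model import build_model
from .stats_compare import fisher_exact, fold_change, paired_t
from .synthetic_reads import (
    SimConfig,
    apply_selection,
    emit_reads,
    simulate_cells,
    truth_table,
)
from .umi_consensus import cluster_by_umi, consensus, extract_umi

ARMS = ("pre", "mock", "6tg")
RECIPROCALS = ("allele1", "allele2")  # which allele is the methylated one


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    n_replicates: int = 3  # per reciprocal design (total samples = 2n x 3 arms)
    sim: SimConfig = field(default_factory=SimConfig)
    branches: tuple[str, ...] = ("illumina", "pacbio", "bisulfite")
    flank_up: int = 700
    flank_down: int = 165

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(seed: int = 1) -> RunConfig:
    """The default demonstration run: 3 replicates x 2 reciprocal arms
    x 3 selection conditions, 2000 cells per sample."""
    return RunConfig(seed=seed)


@dataclass
class SampleResult:
    sample_id: str
    replicate: int
    methylated_allele: str
    arm: str
    pacbio_calls: pd.DataFrame | None = None
    pacbio_alignments: dict[str, AlignmentResult] = field(default_factory=dict)
    illumina_calls: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_umi_dropped: dict[str, int] = field(default_factory=dict)


@dataclass
class RunResult:
    config: RunConfig
    model: object
    samples: list[SampleResult]
    tables: dict[str, pd.DataFrame]
    stats: dict


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *key]))


def _collapse(
    reads,
    align_one,
    realign_one,
    umi_window: tuple[int, int],
):
    """Shared align -> UMI -> consensus -> realign path for one branch.

    Returns (consensus alignments, cluster sizes, umi drop count).
    A single-member consensus reconstructs its member read exactly, so
    its realignment is the member's alignment and is reused as is.
    """
    alignments = [align_one(r) for r in reads]
    kept, umis = [], []
    dropped = 0
    for a in alignments:
        u = extract_umi(a, umi_window)
        if u is None:
            dropped += 1
        else:
            kept.append(a)
            umis.append(u)
    clusters = cluster_by_umi(kept, umis)
    out = []
    sizes = []
    for cl in clusters:
        cid = f"u{cl.umi}"
        if cl.size == 1:
            final = cl.members[0]
        else:
            cseq = consensus(cl)
            final = realign_one(cseq, cid)
        out.append((cid, final, cl.size))
        sizes.append(cl.size)
    return out, sizes, dropped


def process_pacbio(reads, frames: dict[str, CallingFrame], scoring=None):
    """PacBio branch: orientation-resolved consensus calls."""
    refs = [f.ref for f in frames.values()]
    umi_w = next(iter(frames.values())).umi_window

    def align_one(r):
        return choose_orientation(r.seq, refs, query_id=r.read_id)

    def realign_one(seq, cid):
        return choose_orientation(seq, refs, query_id=cid)

    collapsed, _sizes, dropped = _collapse(reads, align_one, realign_one, umi_w)
    calls = [call_pacbio(a, frames, consensus_id=cid, n_reads=n) for cid, a, n in collapsed]
    aln = {cid: a for cid, a, _ in collapsed}
    return calls_frame(calls), aln, dropped


def process_illumina(reads, frame: CallingFrame):
    def align_one(r):
        return global_align(
            r.seq, frame.ref.seq, query_id=r.read_id,
            ref_id=frame.ref.ref_id, orientation_class="forward",
        )

    def realign_one(seq, cid):
        return global_align(
            seq, frame.ref.seq, query_id=cid,
            ref_id=frame.ref.ref_id, orientation_class="forward",
        )

    collapsed, _sizes, dropped = _collapse(reads, align_one, realign_one, frame.umi_window)
    calls = [call_illumina(a, frame, consensus_id=cid, n_reads=n) for cid, a, n in collapsed]
    return calls_frame(calls), dropped


def process_bisulfite(reads, refset):
    def align_one(r):
        return align_bisulfite(r.seq, refset, query_id=r.read_id)

    def realign_one(seq, cid):
        return align_bisulfite(seq, refset, query_id=cid)

    collapsed, _sizes, dropped = _collapse(reads, align_one, realign_one, refset.umi_window)
    calls = [call_methylation(a, refset, consensus_id=cid, n_reads=n) for cid, a, n in collapsed]
    return methylation_frame(calls), dropped


def _pct(table: pd.DataFrame, group: str, orientation: str = "forward") -> float:
    sel = table[(table.group == group) & (table.orientation == orientation)]
    return float(sel["pct"].iloc[0]) if len(sel) else float("nan")


def run_end_to_end(config: RunConfig) -> RunResult:
    """Execute the full simulated experiment and all summaries."""
    seed = config.seed
    try:
        model = build_model(seed, config.flank_up, config.flank_down)
        frames = pacbio_frames(model, config.sim.umi_length)
        ill_frame = illumina_frame(model, config.sim.umi_length)
        bis_refs = build_bisulfite_refs(model, config.sim.umi_length)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError(f"model: {e}") from e

    samples: list[SampleResult] = []
    freq_rows: list[pd.DataFrame] = []
    arm_i = {a: i for i, a in enumerate(ARMS)}
    for ri, meth_allele in enumerate(RECIPROCALS):
        for rep in range(config.n_replicates):
            cfg = replace(config.sim, methylated_allele=meth_allele)
            try:
                cells_pre = simulate_cells(
                    model, cfg, _rng(seed, 1, ri, rep), prefix=f"r{ri}{rep}c"
                )
            except Exception as e:
                raise StageError(f"simulate: {e}") from e
            for arm in ARMS:
                sid = f"{meth_allele}_meth_rep{rep + 1}_{arm}"
                res = SampleResult(sid, rep + 1, meth_allele, arm)
                try:
                    cells = apply_selection(
                        cells_pre, cfg, arm, model, _rng(seed, 2, ri, rep, arm_i[arm])
                    )
                except Exception as e:
                    raise StageError(f"selection: {e}") from e
                for bi, branch in enumerate(config.branches):
                    try:
                        reads = emit_reads(
                            branch, cells, model, cfg,
                            _rng(seed, 3, ri, rep, arm_i[arm], bi),
                            read_prefix=f"{sid}:",
                        )
                        res.truth[branch] = truth_table(reads)
                        if branch == "pacbio":
                            calls, aln, dropped = process_pacbio(reads, frames)
                            res.pacbio_calls = calls
                            res.pacbio_alignments = aln
                        elif branch == "illumina":
                            calls, dropped = process_illumina(reads, ill_frame)
                            res.illumina_calls = calls
                        else:
                            calls, dropped = process_bisulfite(reads, bis_refs)
                            res.methylation = calls
                        res.n_umi_dropped[branch] = dropped
                    except Exception as e:
                        raise StageError(f"{branch}: {e}") from e
                samples.append(res)
                if res.pacbio_calls is not None:
                    for policy in ("strict_matched", "orientation",
                                   "all_aligned_minus_deletions"):
                        freq_rows.append(
                            tabulate(res.pacbio_calls, policy, sid, arm)
                        )
                if res.illumina_calls is not None:
                    t = tabulate(res.illumina_calls, "strict_matched", sid, arm)
                    t["policy"] = "illumina_strict"
                    freq_rows.append(t)

    tables: dict[str, pd.DataFrame] = {}
    tables["frequencies"] = (
        pd.concat(freq_rows, ignore_index=True) if freq_rows else pd.DataFrame()
    )
    try:
        stats = compute_stats(config, samples, tables["frequencies"])
        tables["methylation_histogram"] = _methylation_histogram(samples)
        tables["junction_sizes"] = _junction_tables(samples)
    except Exception as e:
        raise StageError(f"stats: {e}") from e
    stats["config_hash"] = config.hash()
    stats["seed"] = seed
    return RunResult(config, model, samples, tables, stats)


def _sample_table(freq: pd.DataFrame, sid: str, policy: str) -> pd.DataFrame:
    return freq[(freq.sample_id == sid) & (freq.policy == policy)]


def _methylation_histogram(samples: list[SampleResult]) -> pd.DataFrame:
    """Histogram by *role* (methylated / unmethylated / wild type):
    which physical allele carries the methylated insert alternates
    between the reciprocal designs, so pooling must follow the role."""
    frames = []
    for s in samples:
        if s.methylation is None or s.methylation.empty:
            continue
        df = s.methylation.copy()
        df["arm"] = s.arm
        role = {
            s.methylated_allele: "methylated",
            ("allele2" if s.methylated_allele == "allele1" else "allele1"): "unmethylated",
            "wildtype": "wildtype",
            "unassigned": "unassigned",
        }
        df["group"] = df["group"].map(role)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    merged = pd.concat(frames, ignore_index=True)
    return methylation_histogram(merged, by=["arm"])


def _junction_tables(samples: list[SampleResult]) -> pd.DataFrame:
    """Max-1-scaled junction size distributions for the printed
    comparisons (non-6-TG samples, assigned long-read calls)."""
    rows = []
    comparisons = {
        "methylated": lambda s, c: c.group == s.methylated_allele,
        "unmethylated": lambda s, c: c.group
        == ("allele2" if s.methylated_allele == "allele1" else "allele1"),
        "exogenous": lambda s, c: c.group.isin(("allele1", "allele2")),
        "endogenous": lambda s, c: c.group == "wildtype",
        "wt_forward": lambda s, c: (c.group == "wildtype") & (c.orientation == "forward"),
        "wt_inverted": lambda s, c: (c.group == "wildtype") & (c.orientation == "inverted"),
    }
    for name, selector in comparisons.items():
        parts = []
        for s in samples:
            if s.arm == "6tg" or s.pacbio_calls is None:
                continue
            c = s.pacbio_calls
            parts.append(c[selector(s, c)])
        if not parts:
            continue
        pooled = pd.concat(parts, ignore_index=True)
        if pooled.empty:
            continue
        dist = sizes_from_calls(pooled).to_frame()
        dist["comparison"] = name
        rows.append(dist)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def compute_stats(
    config: RunConfig, samples: list[SampleResult], freq: pd.DataFrame
) -> dict:
    """Headline comparisons across replicates.

    * short-read fold changes (6-TG over mock) of methylated vs
      unmethylated allele percentages, paired per replicate, log
      transform;
    * long-read 6-TG percentages of methylated vs unmethylated alleles
      (exact-match convention), arcsine-square-root transform;
    * orientation summary per arm;
    * Fisher tests of junction indel rates (non-6-TG samples):
      methylated vs unmethylated, exogenous vs endogenous inserts, and
      forward vs inverted wild type.
    """
    stats: dict = {}
    by_key = {(s.methylated_allele, s.replicate, s.arm): s for s in samples}
    n_rep = config.n_replicates

    fold_meth, fold_unmeth = [], []
    pb_meth, pb_unmeth = [], []
    for ma in RECIPROCALS:
        ua = "allele2" if ma == "allele1" else "allele1"
        for rep in range(1, n_rep + 1):
            s6 = by_key.get((ma, rep, "6tg"))
            sm = by_key.get((ma, rep, "mock"))
            if s6 is None or sm is None:
                continue
            if s6.illumina_calls is not None:
                t6 = _sample_table(freq, s6.sample_id, "illumina_strict")
                tm = _sample_table(freq, sm.sample_id, "illumina_strict")
                fold_meth.append(fold_change(_pct(t6, ma), _pct(tm, ma)))
                fold_unmeth.append(fold_change(_pct(t6, ua), _pct(tm, ua)))
            if s6.pacbio_calls is not None:
                t6 = _sample_table(freq, s6.sample_id, "strict_matched")
                pb_meth.append(_pct(t6, ma))
                pb_unmeth.append(_pct(t6, ua))

    def _finite_mean(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    if fold_meth:
        pairs = [
            (m, u)
            for m, u in zip(fold_meth, fold_unmeth)
            if np.isfinite(m) and np.isfinite(u) and m > 0 and u > 0
        ]
        stats["illumina_fold_change"] = {
            "mean_methylated": _finite_mean(fold_meth),
            "mean_unmethylated": _finite_mean(fold_unmeth),
            "n_pairs": len(pairs),
        }
        if len(pairs) >= 2:
            r = paired_t([p[0] for p in pairs], [p[1] for p in pairs], "log")
            stats["illumina_fold_change"].update(t=r.t, p=r.p, transform=r.transform)
    if pb_meth:
        pb_pairs = [
            (m, u)
            for m, u in zip(pb_meth, pb_unmeth)
            if np.isfinite(m) and np.isfinite(u)
        ]
        stats["pacbio_6tg_pct"] = {
            "mean_methylated": _finite_mean(pb_meth),
            "mean_unmethylated": _finite_mean(pb_unmeth),
            "n_pairs": len(pb_pairs),
        }
        if len(pb_pairs) >= 2:
            r = paired_t(
                [m / 100 for m, _ in pb_pairs],
                [u / 100 for _, u in pb_pairs],
                "arcsine_sqrt",
            )
            stats["pacbio_6tg_pct"].update(t=r.t, p=r.p, transform=r.transform)

    orient = {}
    osub = freq[freq.policy == "orientation"]
    for arm in ARMS:
        vals = []
        for s in samples:
            if s.arm != arm or s.pacbio_calls is None:
                continue
            t = _sample_table(osub, s.sample_id, "orientation")
            vals.append(_pct(t, "any", "inverted"))
        if vals:
            orient[arm] = {"mean_pct_inverted": float(np.nanmean(vals)), "n": len(vals)}
    stats["orientation_summary"] = orient

    def pooled_calls(selector):
        parts = []
        for s in samples:
            if s.arm == "6tg" or s.pacbio_calls is None:
                continue
            c = s.pacbio_calls
            parts.append(c[selector(s, c)])
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    fishers = {}
    contrasts = {
        "methylated_vs_unmethylated": (
            lambda s, c: c.group == s.methylated_allele,
            lambda s, c: c.group
            == ("allele2" if s.methylated_allele == "allele1" else "allele1"),
        ),
        "exogenous_vs_endogenous": (
            lambda s, c: c.group.isin(("allele1", "allele2")),
            lambda s, c: c.group == "wildtype",
        ),
        "wt_forward_vs_inverted": (
            lambda s, c: (c.group == "wildtype") & (c.orientation == "forward"),
            lambda s, c: (c.group == "wildtype") & (c.orientation == "inverted"),
        ),
    }
    for name, (sel_a, sel_b) in contrasts.items():
        ca, cb = pooled_calls(sel_a), pooled_calls(sel_b)
        if len(ca) == 0 or len(cb) == 0:
            continue
        pa, ka, na = indel_rate(ca)
        pb, kb, nb = indel_rate(cb)
        fishers[name] = {
            "rate_a": pa,
            "rate_b": pb,
            "k_a": ka,
            "n_a": na,
            "k_b": kb,
            "n_b": nb,
            "p": fisher_exact([[ka, na - ka], [kb, nb - kb]]),
        }
    stats["fisher_indel_rates"] = fishers
    return stats


def positional_profile_6tg(run: RunResult) -> pd.DataFrame:
    """Indel occupancy along the locus for the short-read-comparable
    6-TG subset: methylated and unmethylated alleles with a perfect
    match at the SNVs and surrounding exon window, forward orientation."""
    alns = []
    for s in run.samples:
        if s.arm != "6tg" or s.pacbio_calls is None:
            continue
        calls = s.pacbio_calls
        wanted = calls[
            calls.group.isin(("allele1", "allele2")) & (calls.orientation == "forward")
        ]
        for cid in wanted.consensus_id:
            a = s.pacbio_alignments.get(cid)
            if a is not None:
                alns.append(a)
    if not alns:
        return pd.DataFrame()
    return positional_profile(alns).to_frame()


def write_outputs(run: RunResult, outdir: str | Path) -> Path:
    """Write TSV/JSON artifacts; the directory is removed on failure."""
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        meta = {"seed": run.config.seed, "config_hash": run.config.hash()}
        for name, df in run.tables.items():
            if df is None or len(df) == 0:
                continue
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        for s in run.samples:
            if s.pacbio_calls is not None:
                s.pacbio_calls.to_csv(
                    outdir / f"calls_pacbio_{s.sample_id}.tsv", sep="\t", index=False
                )
            if s.methylation is not None:
                s.methylation.to_csv(
                    outdir / f"methylation_{s.sample_id}.tsv", sep="\t", index=False
                )
        profile = positional_profile_6tg(run)
        if len(profile):
            profile.to_csv(outdir / "indel_profile_6tg.tsv", sep="\t", index=False)
        (outdir / "stats.json").write_text(
            json.dumps({**meta, **run.stats}, indent=1, default=float)
        )
    except Exception as e:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise StageError(f"write: {e}") from e
    return outdir
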