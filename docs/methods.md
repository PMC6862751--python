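# Methods

## The system being modeled

A haploid human cell line carries a single copy of a housekeeping gene
whose promoter-associated CpG island (1120 bp) is excised by two
flanking Cas9 cuts.  Non-homologous end joining (NHEJ) then re-ligates
the break with one of a small set of outcomes per cell: wholesale
deletion of the island, re-insertion of the excised wild-type segment,
or insertion of a co-transfected exogenous copy — either in vitro
methylated or unmethylated — in forward or inverted orientation.  The
exogenous copies carry two synonymous allele-defining SNVs each (so
sequencing can tell them apart from the native sequence and from each
other without bisulfite conversion) and PAM-destroying mutations at the
sixth base from each segment end (so Cas9 does not re-cut a successful
insertion).  Because loss of the gene's expression confers resistance
to a selective drug (6-thioguanine), selection enriches cells in which
the island was deleted, inverted, or replaced by a methylated
(silencing) copy.

The package reconstructs the sequencing analysis of that experiment as
a tested pipeline over synthetic reads with known truth: a generative
outcome model, three amplicon branches (short-read exon window,
full-locus long reads, bisulfite), orientation-resolved global
alignment, UMI consensus, strict allele/orientation calling, junction
indel profiling, methylation calling, and the comparison statistics.

## Surrogate locus

The real genomic sequence is not bundled.  `build_model(seed)`
generates a surrogate locus (700 bp upstream flank + 1120 bp insert +
165 bp downstream flank, matching the long-read amplicon design) with
CpG-island-like base composition (60% GC) under the printed structural
constraints:

* SNVs at insert offsets 532 (C>T, allele 1), 535 (C>G, allele 2),
  538 (C>T, allele 2), 541 (T>A, allele 1) — derived from the
  experiment's genomic coordinates relative to the insert start — with
  the wild-type bases forced at those offsets;
* PAM mutations G>C at offset 6 and C>G at offset 1115 (sixth base
  from each end); cuts are modeled as blunt at the insert boundaries,
  consistent with the PAM positions;
* exact-match windows: 44 bp (offsets 502–545, short-read), 250 bp
  (306–555, long-read promoter/exon/splice-donor), 283 bp (478–760,
  bisulfite);
* exactly 35 CpG dinucleotides inside the bisulfite window, placed or
  removed by a seeded repair loop; no CpG may overlap an SNV offset in
  either the wild-type or variant sequence, and no CpG may straddle
  the bisulfite window's right edge.  The first constraint keeps
  bisulfite allele assignment well defined (see below); the second
  keeps "positions differing between converted reference variants
  inside the window" identical to the 35 counted sites.

Coordinates are 1-based inclusive at every user-facing surface
(matching genomic convention) and 0-based half-open internally;
conversion happens only at interfaces.

## Outcome and read simulation

Each simulated cell draws one outcome class.  Default pre-selection
proportions are anchored to the printed pre-selection read shares:
methylated insert 0.65% and unmethylated insert 2.37% (split roughly
evenly between orientations), 63.4% forward among oriented sequences,
and a wholesale-deletion share of 0.25 (not quantified upstream; a
substantial value was chosen since the deletion band dominated gels).
Wild-type re-insertion absorbs the remainder:

    deletion .25, wt_fwd .4602, wt_inv .2596,
    meth_fwd .0033, meth_inv .0032, unmeth_fwd .0120, unmeth_inv .0117

These read shares are used directly as cell-outcome proportions — PCR
and size biases that separate the two in real data are deliberately
not modeled.

Junction indels: each junction independently carries an indel with
probability 0.3; 80% are deletions; sizes are geometric with mean 3,
capped at 50.  Deletions chew symmetrically into the two sides of the
junction; insertions add random bases.  The size law is a modeling
choice (no distribution is published); it populates both the ≤5 bp
assignable regime and the >5 bp regime that fails the PAM-match rule.

Selection: `pre` returns the pool unchanged; `mock` resamples it
uniformly; `6tg` resamples with survival weight 1 for silenced cells
(deletion, any inversion, methylated forward insert, or any expressing
cell whose junction deletion reaches the functional promoter/exon
window) and weight ε = 0.001 for expressing cells (the experiment's
selection was "nearly complete"; ε is a knob, not a claim).  Under the
default indel model (cap 50), junction deletions can never reach the
functional window, so the indel-rescue channel that enriched
unmethylated inserts in the real data is absent from default runs:
the unmethylated allele's post-selection share is ~0 and its
fold change degenerates to 0/undefined.  The package therefore asserts
the two directional headline properties (methylated allele enriched
among forward exact-match calls after selection; inversion dominant
after selection) rather than the printed magnitudes.  Configuring a
long-tailed indel model restores the rescue channel, and the
selection logic for it is unit-tested that way.

Reads are emitted post-merge/post-CCS (demultiplexing, pair merging
and circular consensus calling are out of scope): constant quality
(Q40), substitution errors only — long reads at 0.006 (matching a
99.4% consensus accuracy), short branches at 0.001.  One UMI
(uniform over ACGT^12; the tag length is a choice) per molecule = per
cell and branch; `reads_per_cell` copies.  Branch rules: the
short-read branch amplifies only forward, non-deletion templates (the
nested design's outer primer sits upstream of the 5' cut); the
long-read branch covers the full locus but drops wholesale deletions
by default (the ~2 kb gel band; `keep_deletions` retains them); the
bisulfite branch amplifies within the segment, so inverted insertions
yield the same amplicon as forward ones, and conversion is applied
once per molecule (maintenance rate 0.95 on methylated-class CpGs,
conversion failure 0.005, background methylation 0.01).

## Alignment

A banded affine-gap (Gotoh) global aligner with EMBOSS-needle-style
defaults (match +5, mismatch −4, gap open 10, gap extend 0.5; a gap of
length L costs open + L·extend — the named upstream tool's parameters
are not published, so its defaults are adopted).  Ties resolve
deterministically: diagonal beats gap, deletion precedes insertion in
reading order, gaps are placed leftmost.  `N` in a read mismatches
everything (so it can never satisfy a perfect-match window); `N` in a
reference is a wildcard used only for the 12-base UMI slot, letting
the random tag align as a match run and be extracted by reference
coordinates.

The band starts at half-width 64 plus the length difference and is
re-widened whenever the traced path touches a band edge, so results
equal the unbanded program; an exhaustive small-pair oracle and
banded-vs-full comparisons cover this.  Orientation and reference
choice pre-screens all (reference × read-orientation) combinations
with edlib edit distance and scores only those within 60 edits of the
minimum exactly; reads identical to a reference skip the dynamic
program entirely.  An exact all-combinations mode exists and is tested
to agree.  Score ties across orientation classes are flagged ambiguous
rather than broken (a wholesale deletion aligns identically to the
forward and inverted references, which share flanks — the deletion
call precedes the ambiguity check for exactly this reason).

### Junction-anchored gap normalization

In repetitive sequence a junction deletion admits several
score-equivalent placements.  Two artifacts follow: a placement
shifted toward the flank can let a flank base spuriously occupy the
PAM slot, and alignment against the wild-type reference can let the
gap swallow a genuinely mutated PAM base (hiding a mismatch inside the
deletion, which is cheaper than showing it).  The caller therefore
(i) normalizes deletion runs near a cut to abut the cut on the
segment side (shifts are taken only across equal reference bases, so
the score is unchanged), and (ii) when a read with a junction indel
fails the perfect-match rules, re-anchors it against each
allele-matched reference before declaring it unassigned.  Both steps
implement the experiment's actual matching semantics — expectations
are allele-specific — and are what makes the PAM-window property
exact: junction deletions of ≤5 bp into the segment remain assignable,
≥6 bp remove the sixth-base PAM and never are.

## Consensus

Reads are grouped by exact UMI string (no edit-distance merging: the
4^12 tag space makes collisions negligible, and the minimal rule is
reproducible; minimum cluster size 1).  The consensus is per-column
plurality over {A, C, G, T, gap} in the winning reference frame (read
Ns abstain); ties yield N — which can never pass a perfect-match
window — and a gap wins only as unique plurality.  Insertions are
voted as whole strings per inter-base position, ties resolving to no
insertion.  Members aligned to a different reference than the cluster
majority are excluded and counted.  Consensi are realigned before
calling; a single-member consensus reconstructs its read exactly, so
its member's alignment is reused unchanged.

## Calling rules

Short-read: perfect match over the 44-bp exon window (SNV offsets
exempted from the mismatch condition but not from gaps) and an SNV
4-tuple equal to exactly one of the three patterns; orientation is
always forward by construction.  Long-read: wholesale deletion first
(an alignment deletion ≥ insert length − 50 spanning the segment — an
alignment-level replacement for the experiment's amplicon-size
criterion); then window, SNV tuple and both PAM bases must match
perfectly on the winning orientation's frame, with allele-appropriate
PAM expectations (original bases for wild type, mutated for the
transfected alleles).  Chimeric SNV patterns are never partially
called.  Junction indel sizes within ±5 bp of each cut are recorded on
every call; indels abutting a window boundary from outside do not
violate exactness.

Frequency tables support the two denominator conventions used for the
printed figures: `strict_matched` (assigned forward calls only, wild
type included), `orientation` (forward vs inverted among assigned
calls, deletions excluded), and `all_aligned_minus_deletions` (every
non-deletion consensus, assigned or not — the insertion-rate
convention).

## Bisulfite calling

Each allele gets three reference variants — converted assuming no CpG
methylated, converted assuming all CpGs methylated, and unconverted —
sharing coordinates.  A read anchors on its best-scoring variant;
assignment requires a perfect match at conversion-invariant window
positions (bases that are not cytosines) plus the post-conversion SNV
tuple.  The C>T SNVs convert to the same base as their wild-type
cytosine, but each allele retains one conversion-immune distinguishing
base (allele 1's T>A, allele 2's C>G), so the three post-conversion
patterns stay mutually distinct; the no-CpG-at-SNV constraint of the
locus model is what guarantees the C>T SNVs convert deterministically.
The modeled strand is the top strand throughout.  Methylation is read
per site, not inferred from the winning variant: C at a window CpG
means methylated, T unmethylated, gap/other uncallable (excluded from
the count denominator).  Histograms of methylated-site counts (0–35)
are grouped by role — methylated, unmethylated, wild type — because
the physical allele carrying methylation alternates between the two
reciprocal transfection designs.

## Statistics

Natural-log-transformed paired t-tests for fold changes and
arcsine-square-root-transformed paired t-tests for proportions, paired
within transfection replicate (three replicates of each reciprocal
design, six pairs; the experiment does not state its pairing n, six is
the default).  Zero-variance differences: all-zero gives t=0, p=1;
constant non-zero is flagged degenerate.  Fisher's exact test
(two-sided, hypergeometric summation) on 2×2 junction-indel-rate
tables, excluding 6-TG samples from rate comparisons; degenerate
margins give p=1.  Clopper–Pearson intervals back the recovery checks.
Zero mock frequencies give undefined (NaN) fold changes with no
automatic pseudo-count.  No multiple-testing correction is applied.

## Problem sizes and determinism

The demonstration run is 2 reciprocal designs × 3 replicates × 3
selection arms at 2000 cells per sample, one consensus molecule per
cell; acceptance-level checks use the same scale (the zero-error
completeness check covers 6 samples × 2000 cells).  One global seed
expands into per-stage counter-derived streams, so any stage can be
re-run in isolation and a repeated run is byte-identical; every output
carries the configuration hash and seed.

## What passing tests do and do not show

The simulator emulates outcome mixtures, junction indels, orientation,
UMIs, substitution errors, bisulfite conversion and selection — not
PCR chimeras or duplicate family-size structure, not size-biased
amplification (its consequence, the deletion exclusion, is modeled as
a hard rule), not indel or error processes beyond the stated
distributions, and not multi-copy concatemer insertions.  Recovery
results on synthetic data therefore validate the analysis logic —
classification, counting, normalization, statistics — under the stated
generative model, not the upstream chemistry.  Known limitations: the
long-indel rescue channel is absent under default indel sizes (see
above); wholesale-deletion quantification is deliberately avoided
except as an exclusion rule; near-identical UMI merging is not
implemented.
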