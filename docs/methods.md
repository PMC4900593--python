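# Methods

This note records the models, algorithms, parameter choices and known
limitations behind each module, in the order data flows through the
pipeline.

## Synthetic data (`mitopool.simulate`)

**Substitution model.** Sequences evolve site-independently down a rooted
tree with branch lengths in expected substitutions per site. Per branch the
4×4 transition matrix is `expm(Q·t)` with an HKY-type rate matrix Q
(transition/transversion ratio `kappa`, default 4 — a typical mitochondrial
value) normalised to one expected substitution per site per unit branch
length at its own stationary composition. Base composition heterogeneity is
produced by *lineage-specific target frequencies*: a lineage listed in
`lineage_freqs` (and its descendants, unless overridden) substitutes toward
its own composition, which makes the overall process non-stationary. This
is deliberately the simplest mechanism that induces the two phenomena the
distance module must handle — a significant composition χ² and bias in
stationarity-assuming corrections — and is not meant as a mechanistic model
of mutational drift.

**Indels and the true alignment.** Indel events arrive as a Poisson process
(`indel_rate` events per site per unit branch length, default 0) with
geometric lengths (mean ≈ 1.4). Every alignment column carries a sortable
key; insertions derive keys from their anchor column, so the true multiple
alignment is assembled by a key sort with no aligner. Deleted positions stay
deleted in descendants.

**Reads.** Read lengths are normal (clipped at 30 bp) around the platform
mean; starts are uniform on the circle and reads spanning the origin are
emitted as contiguous strings from the doubled genome, their labels keeping
the wrapped interval. Default platform means follow the observed
per-platform values of the reference study (MiSeq 448, HiSeq 95, 454 523,
Ion Torrent 98 bp). Error rates are free parameters — the study does not
report chemistry-level rates — with defaults encoding the qualitative
ranking: substitutions 0.2 % (Illumina) to 0.5 % (454/Ion Torrent), and
homopolymer indels 0 (Illumina), 0.5 % (454), 1 % (Ion Torrent) per
homopolymer run of length ≥ 3 (one base added or dropped, the flow-space
miscall behind phantom nucleotides). Quality strings are constant Q40;
quality realism is out of scope. Paired profiles emit mates as `/1`–`/2`
reads that downstream stages treat independently (the source protocol
pooled mates per sample before assembly).

**Pools.** A pooled set draws each taxon's reads from its non-failed
amplicons (two overlapping circular intervals per taxon by convention,
~6.4 kb + ~10.7 kb in the reference design), splits the taxon's yield
across amplicons by length, strips all taxon information from read ids and
keeps truth labels separately. A scheme that does not cover a genome warns
rather than errors — a failed long-range PCR is a real outcome that leaves
a fraction of the genome unsequenced, not a caller bug.

**Tree samples.** Target clade frequencies are realised by solving
`M p = f` over the exhaustively enumerated rooted topologies (M marking
which topology contains which clade) as a nonnegative least squares problem
with a light ridge toward the uniform distribution: hard constraints are
enforced to 1e-6 and under-determined targets spread mass evenly, so an
empty constraint set yields the uniform distribution over all topologies.
Unrealisable targets are rejected with a diagnostic. Trees are then drawn
i.i.d. multinomially.

**What the generator does not emulate:** real gene content/order,
quality-score structure, coverage biases (GC, amplicon edge effects),
chimeric reads, or contamination. Passing tests demonstrate correctness of
the algorithms under these idealised conditions, not performance on real
libraries.

## Windowed reduction (`mitopool.reduction`)

p-distances use pairwise deletion of gap/N columns (the standard
convention). The sliding profile is computed from cumulative sums over
doubled columns so circular wrap costs nothing. Partitioning is a greedy
change-point pass: a block closes when the within-block range of the
profile exceeds `homogeneity_tol` (default 0.05) and the block has reached
`min_block` columns; boundaries are then widened so consecutive windows
(including last→first) overlap by ≥ `min_overlap` (default 50 columns).
This satisfies the same constraints as the published 16-window scheme — the
scheme itself was drawn by eye, so the algorithm aims at the validator
(coverage + overlap + homogeneity), not at reproducing those exact
boundaries.

The retention threshold is the window's maximum pairwise divergence plus an
**additive** 10-percentage-point allowance (0.22 → 0.32), capped at 1. A
multiplicative reading (0.22 → 0.242) is available via
`mode="multiplicative"`; the additive reading is the default because the
allowance exists to guarantee that all target reads are pulled, and a
multiplicative margin barely moves the threshold.

**Read scoring.** Retention decisions separate substitutions from indels,
as read mappers do: a fast edit-distance gate (edlib, bounded at
`(threshold + max_gap_frac)·read_length`, both strands) discards hopeless
reads and locates the candidate region; survivors are re-aligned locally
under affine gap penalties (match 2 / mismatch −3 / open −8 / extend −3)
and retained iff the alignment covers ≥ 50 % of the read, the substitution
fraction over aligned columns is ≤ threshold, total gap bases ≤ 15 % of the
read, and no gap run exceeds `max_gap_size`. A unit-cost edit path is *not*
used for the decision because it shreds divergent sequence into many short
gaps, understating the substitution fraction. Whether the original
pipeline's "mismatch threshold per read" counted indels is unknown; this
package counts substitutions only and constrains gaps separately.

Window consensus is per-column majority; ties become IUPAC ambiguity codes,
and columns whose majority symbol is a gap are dropped so the consensus is
a valid gap-free mapping reference.

## Assembly (`mitopool.assembly`)

The assembler is a transparent reimplementation of the baiting / iterative
mapping idea, not of any existing assembler's internals: k-mer seeding
(word length 14 by default) proposes diagonals, edlib aligns the placed
slice, constraints (mismatch fraction, gap fraction, gap run, ambiguity
count) filter placements, equally good placements are resolved by a seeded
RNG ("multiple best matches mapped randomly", reproducibly), and the
reference is replaced by the per-column majority consensus each iteration.
Consensus ties produce IUPAC codes; a strict deletion majority drops the
column; an insertion supported by more than half the local coverage is
spliced in.

Two regimes:

* **Mapping regime** (`extend_ends=False`, the default of all presets):
  the whole read must fit inside the reference frame. On a circular target
  with a linear reference this *causes* the edge artifact — coverage decays
  linearly to zero over the last read-length of each end because
  junction-spanning reads are unplaceable — which is exactly the
  terminal-loss behaviour the rotation protocol exists to repair. Uncovered
  terminal positions are trimmed (internal ones become N), and such a run
  reports `complete=False`.
* **Baiting regime** (`extend_ends=True`): reads anchored at the current
  ends may overhang; the per-offset majority of overhangs (≥ 2 supporting
  reads) extends the assembly, capped at half the mean read length per end
  per iteration to prevent chimeric runaway. Growth past the circular
  origin is detected by the self-overlap property of a wrapped assembly
  (its suffix equals its prefix): prefix k-mers anchor candidate overlaps,
  verified at ≥ 98 % identity, and the duplicated suffix is trimmed. A
  genuine ≥ 50 bp terminal repeat in the genome would defeat this check;
  that is a documented limitation, not handled.

**Rotation protocol.** `assemble_with_rotation` runs the assembler against
the seed and against the seed rotated by `rotate_k` (default 1000 bp),
derotates the second run by locating each run's head inside the other, and
lays both onto the inferred circle (length = sum of the two head offsets).
Conflicting bases take the higher-coverage call; equal support yields an
IUPAC ambiguity; coverage is the per-base maximum of the two runs. How the
original protocol trimmed the two runs before merging is not documented
anywhere; the rule here (anchor-by-overlap, higher coverage wins) is this
package's own choice. If the runs share too little sequence to anchor
(fewer than `2·rotate_k` bases, or a failed run), the longer run is
returned with a warning instead.

Preset registry: `multiplex_initial` (3 % mismatches, gap ≤ 15, ambiguity
1, 100 iterations, random multi-best), `multiplex_rescue` (1 % mismatches,
ambiguity 2 — the stricter conspecific-reference pass), `hiseq_extract`
(15 % gaps, gap ≤ 50, word length 14, ambiguity 4).

## Platform concordance (`mitopool.concordance`)

Reconstructions of one specimen are derotated to a common origin (probe
search in the doubled sequence) and aligned by anchoring every sequence to
the first via global pairwise alignment, merging the pairwise gaps into a
shared column set — the standard shortcut for near-identical sequences;
inputs under 50 % identity (edit-distance identity) are rejected as a
likely specimen mix-up.

A **phantom single nucleotide** is operationalised as an insertion-type
disagreement: a column where the focal platform has a base (or N) and a
strict majority of the other platforms have a gap. Counts are kept per
focal base, with N tallied separately; a phantom whose base nonetheless
wins the all-platforms consensus (support ≥ gaps) is tallied as
"insertions added" instead, and the phantom *rate* — 100 × (A+C+G+T+N
counts) / reconstructed length, half-up to 2 decimals — excludes the
accepted insertions. These two conventions are interpretations (the N and
insertions-added rows of the published error table are not defined in
text); they are adopted because they reproduce the published rates (0.28 %,
0.43 %, 0.05 %) exactly from the published counts. Adjacent phantoms in one
homopolymer run count per inserted base; alignment may coalesce an
insertion that extends an existing run, which is why the injection
invariant is tested at non-homopolymer positions. GC% is computed over
unambiguous bases only, half-up to 1 decimal.

## Distances (`mitopool.distances`)

LogDet/paralinear uses the 4-state −¼ scaling (rescale when comparing to
software with another constant) and pairwise deletion. A singular
site-pattern matrix (e.g. a base absent from one sequence, or a saturated
pair whose determinant crosses zero by sampling noise) raises a dedicated
error; matrix builders record such pairs as undefined entries, bootstrap
replicates containing them are redrawn (count reported), and tree building
refuses matrices with undefined entries, naming the pairs.

The composition test is the χ² independence statistic on the taxa × base
count table (non-gap, non-N sites; all-zero base columns dropped with df
adjusted). How other implementations treat ambiguity codes here varies;
this one excludes all non-ACGT symbols.

Minimum evolution is realised as canonical neighbor joining — the standard
heuristic — rather than an exhaustive ME search; on additive matrices NJ
reproduces the generating tree exactly (asserted against an independent
implementation). Q-criterion ties break by seeded RNG when a seed is given.
Negative branch-length estimates are clamped to zero.

## Tree-set support (`mitopool.treesupport`)

Trees are reduced to cluster sets (the leaf set below each node of the
rooted tree); all support computation is set algebra on those clusters. A
partial split {clade} on subset S is displayed by a tree iff some cluster C
satisfies C ∩ S = clade — the cluster-restriction identity for pruned
rooted trees — so partial support needs no explicit pruning (the test suite
cross-checks against literal prune-and-check). Polytomies neither support
nor conflict: a clade counts only as an exact cluster, and denominators
stay at the full sample size.

`reduce_taxa` treats input trees as unrooted split sets, roots on the
designated outgroup (which is then dropped from the leaf set, yielding the
ingroup-clade frame), and collapses each named taxon set to one leaf. Each
set must be a clade in at least `1 − tol` of the trees (default `tol=0`);
offending trees are dropped, and exceeding the tolerance rejects with the
observed fraction. Canonical topology strings sort children by smallest
leaf label; enumeration of all (2n−3)!! rooted topologies (guarded at
n ≤ 9) and all 2ⁿ−n−2 possible clades is exact, and topology indices in
output follow this canonical order — not the layout order of any published
figure. Burn-in and thinning of posterior samples are the caller's
responsibility; `TreeSample.subsample` draws m trees uniformly with a seed.

## Problem sizes and numerical conventions

Synthetic studies in the tests and acceptance script use 2–16 kb genomes,
20× error-free coverage for assembly ground truth, 8 kb × 12 replicates for
LogDet calibration, and 10,000–20,000-tree samples for frequency
round-trips; these sizes put binomial/SE tolerances (3 SDs) well below the
effect sizes being asserted while keeping the full suite fast. Rounding of
published-style percentages is decimal half-up at the printed precision.
Degenerate inputs follow the conventions stated per module: empty read sets
return the seed unchanged (`complete=False`), zero-yield profiles are
valid, all-gap consensus columns are dropped, and zero-support table cells
render as "-".

## Known limitations

* The assembler is deliberately simple: no quality awareness, no paired-end
  constraint, no repeat resolution; terminal repeats ≥ 50 bp can be
  mistaken for circular closure.
* The windowing heuristic optimises the validator's constraints, not
  boundary-for-boundary agreement with any hand-drawn scheme.
* LogDet entries for saturated pairs are undefined by design rather than
  imputed.
* The phantom-calling conventions for the N and insertions-added rows are
  interpretations, as documented above.
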