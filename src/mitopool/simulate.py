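"""Synthetic data with ground truth: genomes, reads, pools, tree samples.

This module generates every input the pipeline consumes, under the study
conditions it targets — a small radiation of ~16 kb circular mitogenomes
with pairwise divergences up to ~35%, platform read sets with the observed
mean read lengths (MiSeq 448 bp, HiSeq 95 bp, 454 523 bp, Ion Torrent
98 bp), homopolymer-prone indel errors on the pyro/semiconductor platforms,
non-indexed pooled amplicon mixtures, and samples of trees with controlled
clade frequencies.  Every read carries a truth label (source taxon and
circular source interval) so extraction and assembly can be scored exactly.

Sequence evolution runs site-independently down a rooted tree: per branch a
4x4 transition matrix is obtained by matrix exponential of a scaled HKY-type
rate matrix; lineage-specific target base compositions (an F81-style pull
toward per-lineage frequencies) make the process non-stationary, which is
what LogDet distances are for.  Indel events maintain the true multiple
alignment, so downstream windowing needs no aligner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import nnls

from .reduction import ReferenceAlignment, p_distance
from .treesupport import TreeSample, enumerate_rooted_trees_with_clusters

__all__ = [
    "CircularGenome",
    "EvolutionSpec",
    "PlatformProfile",
    "TruthLabel",
    "Read",
    "ReadSet",
    "Amplicon",
    "PLATFORM_PROFILES",
    "simulate_genomes",
    "simulate_reads",
    "simulate_pool",
    "simulate_treeset",
]

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CircularGenome:
    """A circular nucleotide sequence; coordinate 0 is an arbitrary but fixed
    origin (for real mitogenomes conventionally the start of a tRNA gene)."""

    id: str
    seq: str
    origin_note: str = ""

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty genome")
        bad = set(self.seq) - set(_BASES)
        if bad:
            raise ValueError(f"genome contains non-ACGT symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, length: int) -> str:
        """Substring of given length starting at ``start`` with wrap."""
        if length > self.length:
            raise ValueError("fetch longer than the genome")
        doubled = self.seq + self.seq
        start %= self.length
        return doubled[start:start + length]


@dataclass
class EvolutionSpec:
    """Tree plus substitution/indel model for genome simulation.

    ``tree`` is a newick string with branch lengths in expected
    substitutions per site.  ``kappa`` is the transition/transversion rate
    ratio; ``base_freqs`` the root composition; ``lineage_freqs`` optionally
    maps leaf (or internal-label) names to target compositions toward which
    that lineage's substitution process is biased — compositional
    heterogeneity strong enough to mislead stationarity-assuming distances.
    """

    tree: str
    kappa: float = 4.0
    base_freqs: Sequence[float] = (0.31, 0.26, 0.14, 0.29)
    lineage_freqs: Mapping[str, Sequence[float]] | None = None
    indel_rate: float = 0.0
    indel_extend: float = 0.3
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.base_freqs, dtype=float)
        if not np.isclose(f.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if (f < 0).any():
            raise ValueError("base frequencies must be nonnegative")


@dataclass
class PlatformProfile:
    """Read-generation parameters for one sequencing platform."""

    name: str
    mean_read_len: int
    read_len_sd: float = 0.0
    paired: bool = False
    insert_mean: int = 0
    insert_sd: float = 0.0
    sub_error_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    yield_reads: int = 0

    def __post_init__(self):
        if self.mean_read_len <= 0:
            raise ValueError("mean_read_len must be positive")
        for r in (self.sub_error_rate, self.homopolymer_indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if self.yield_reads < 0:
            raise ValueError("yield_reads must be >= 0")


#: Default platform profiles.  Mean read lengths are the observed per-platform
#: means of the study system; error rates are free parameters (the platform
#: vendors' chemistry-level rates are not part of the data) with defaults
#: reflecting the qualitative ranking: Illumina substitution-dominated,
#: 454 / Ion Torrent homopolymer-indel-prone.
PLATFORM_PROFILES: dict[str, PlatformProfile] = {
    "miseq": PlatformProfile(
        name="miseq", mean_read_len=448, read_len_sd=45.0,
        sub_error_rate=0.002, homopolymer_indel_rate=0.0,
    ),
    "hiseq": PlatformProfile(
        name="hiseq", mean_read_len=95, read_len_sd=5.0,
        sub_error_rate=0.002, homopolymer_indel_rate=0.0,
    ),
    "r454": PlatformProfile(
        name="r454", mean_read_len=523, read_len_sd=80.0,
        sub_error_rate=0.005, homopolymer_indel_rate=0.005,
    ),
    "iontorrent": PlatformProfile(
        name="iontorrent", mean_read_len=98, read_len_sd=15.0,
        sub_error_rate=0.005, homopolymer_indel_rate=0.01,
    ),
}


@dataclass(frozen=True)
class TruthLabel:
    """Provenance of one simulated read."""

    read_id: str
    source_taxon: str
    start: int      # circular interval on the source genome, half-open,
    end: int        # start > end means the read spans the origin
    strand: int = 1


@dataclass
class Read:
    id: str
    seq: str
    qual: str = ""

    def __post_init__(self):
        if not self.qual:
            self.qual = "I" * len(self.seq)


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    labels: dict[str, TruthLabel] = field(default_factory=dict)
    platform: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    def total_bases(self) -> int:
        return sum(len(r.seq) for r in self.reads)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")

    @classmethod
    def from_fastq(cls, path, platform: str = "") -> "ReadSet":
        reads = []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                reads.append(Read(id=header[1:].strip().split()[0],
                                  seq=seq, qual=qual))
        return cls(reads=reads, platform=platform)

    def write_labels_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource_taxon\tstart\tend\tstrand\n")
            for lab in self.labels.values():
                fh.write(f"{lab.read_id}\t{lab.source_taxon}\t{lab.start}\t"
                         f"{lab.end}\t{lab.strand}\n")


@dataclass(frozen=True)
class Amplicon:
    """A circular interval amplified from one genome; may have failed."""

    start: int
    end: int
    failed: bool = False


# ---------------------------------------------------------------------------
# substitution machinery


def _rate_matrix(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """HKY rate matrix normalised to one expected substitution per unit
    branch length at the given stationary frequencies."""
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.dot(freqs, np.diag(q))
    if rate > 0:
        q /= rate
    return q


def transition_matrix(t: float, freqs: Sequence[float],
                      kappa: float = 4.0) -> np.ndarray:
    """P(t) = exp(Q t) for the HKY process at the given composition."""
    return expm(_rate_matrix(np.asarray(freqs, float), kappa) * t)


# ---------------------------------------------------------------------------
# genome simulation with a true alignment
#
# Alignment bookkeeping: every column has a sortable key.  Root columns are
# (i,); an insertion of m bases after the column with key K on the branch
# with unique id b gets keys K + (b, 1) ... K + (b, m).  Lexicographic tuple
# order is consistent across lineages, so leaf alignments assemble by key
# sort.  Deletions blank the character but keep the key in descendants.


def _evolve_branch(seq_keys, seq_chars, t, pmat, indel_rate, indel_extend,
                   branch_id, rng):
    chars = np.array(seq_chars)  # int codes; -1 = deleted
    alive = chars >= 0
    n_alive = int(alive.sum())
    if t > 0 and n_alive:
        cum = pmat.cumsum(axis=1)
        draws = rng.random(n_alive)
        old = chars[alive]
        new = (draws[:, None] > cum[old]).sum(axis=1)
        chars[alive] = new
    keys = list(seq_keys)
    chars = chars.tolist()
    if indel_rate > 0 and t > 0 and n_alive:
        n_events = rng.poisson(indel_rate * t * n_alive)
        for ev in range(n_events):
            alive_idx = [i for i, c in enumerate(chars) if c >= 0]
            if len(alive_idx) < 10:
                break
            pos = alive_idx[rng.integers(len(alive_idx))]
            length = 1 + rng.geometric(1.0 - indel_extend) - 1
            if rng.random() < 0.5:  # deletion
                k = 0
                i = pos
                while i < len(chars) and k < length:
                    if chars[i] >= 0:
                        chars[i] = -1
                        k += 1
                    i += 1
            else:  # insertion after pos
                anchor = keys[pos]
                new_keys = [anchor + (branch_id, ev + 1, j + 1)
                            for j in range(length)]
                new_chars = rng.integers(0, 4, size=length).tolist()
                keys[pos + 1:pos + 1] = new_keys
                chars[pos + 1:pos + 1] = new_chars
    return keys, chars


def simulate_genomes(
    spec: EvolutionSpec, root_genome_length: int = 16000
) -> tuple[dict[str, CircularGenome], ReferenceAlignment]:
    """Evolve circular genomes down ``spec.tree``.

    Returns one genome per leaf plus the true multiple alignment (gaps mark
    indel history).  With all branch lengths zero every leaf equals the
    root and the alignment is gap-free.
    """
    if root_genome_length <= 0:
        raise ValueError("root genome length must be positive")
    tree = dendropy.Tree.get(data=spec.tree, schema="newick",
                             rooting="force-rooted")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.base_freqs, float)
    root_chars = rng.choice(4, size=root_genome_length, p=freqs).tolist()
    root_keys = [(i,) for i in range(root_genome_length)]

    lineage_freqs = {
        k: np.asarray(v, float)
        for k, v in (spec.lineage_freqs or {}).items()
    }

    results: dict[str, tuple[list, list]] = {}
    branch_counter = itertools.count(1)

    def label_of(node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def freqs_for(node) -> np.ndarray:
        # a lineage's target composition applies to the branch leading to it
        # and is inherited by its descendants unless overridden
        lab = label_of(node)
        if lab is not None and lab in lineage_freqs:
            return lineage_freqs[lab]
        if node.parent_node is not None:
            return freqs_for(node.parent_node)
        return freqs

    def descend(node, keys, chars):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            target = freqs_for(child)
            pmat = transition_matrix(t, target, spec.kappa) if t > 0 else None
            bid = next(branch_counter)
            k2, c2 = _evolve_branch(
                keys, chars, t,
                pmat if pmat is not None else np.eye(4),
                spec.indel_rate, spec.indel_extend, bid, rng,
            )
            if child.is_leaf():
                results[child.taxon.label] = (k2, c2)
            else:
                descend(child, k2, c2)

    descend(tree.seed_node, root_keys, root_chars)

    genomes = {}
    for name in leaves:
        keys, chars = results[name]
        seq = "".join(_BASES[c] for c in chars if c >= 0)
        genomes[name] = CircularGenome(id=name, seq=seq,
                                       origin_note="simulation origin 0")

    # assemble the true alignment over the union of live columns
    all_keys = sorted(
        {k for name in leaves
         for k, c in zip(*results[name]) if c >= 0}
    )
    key_pos = {k: i for i, k in enumerate(all_keys)}
    rows = []
    for name in leaves:
        row = ["-"] * len(all_keys)
        for k, c in zip(*results[name]):
            if c >= 0 and k in key_pos:
                row[key_pos[k]] = _BASES[c]
        rows.append("".join(row))
    aln = ReferenceAlignment(taxa=leaves, rows=rows, circular=True)
    return genomes, aln


def max_pairwise_p_distance(aln: ReferenceAlignment) -> float:
    """Achieved maximum pairwise p-distance of a simulated alignment."""
    best = 0.0
    for i in range(len(aln.rows)):
        for j in range(i + 1, len(aln.rows)):
            best = max(best, p_distance(aln.rows[i], aln.rows[j]))
    return best


# ---------------------------------------------------------------------------
# read simulation

_ERR_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


def _apply_substitutions(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _ERR_OTHER[arr[i]][rng.integers(3)]
    return "".join(arr)


def _homopolymer_runs(seq: str, min_len: int = 3):
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _apply_homopolymer_indels(seq: str, rate: float, rng) -> str:
    """Per homopolymer run (length >= 3), add or drop one base with
    probability ``rate`` — the flow-space miscall that produces phantom
    single nucleotides."""
    if rate <= 0:
        return seq
    out = []
    cursor = 0
    for i, j in _homopolymer_runs(seq):
        out.append(seq[cursor:i])
        run = seq[i:j]
        if rng.random() < rate:
            run = run + run[0] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        cursor = j
    out.append(seq[cursor:])
    return "".join(out)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_reads(
    genome: CircularGenome,
    profile: PlatformProfile,
    seed: int = 0,
    id_prefix: str | None = None,
    circular: bool = True,
    coord_offset: int = 0,
    label_taxon: str | None = None,
) -> ReadSet:
    """Draw reads from circular coordinates (reads may span the origin),
    apply per-profile errors, and label every read with its source interval.

    Paired profiles emit mates as two reads sharing an id stem with ``/1``
    and ``/2`` suffixes; downstream stages treat mates independently.
    ``coord_offset``/``label_taxon`` let amplicon sub-sequences report truth
    in the parent genome's coordinate frame.
    """
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else f"{genome.id}_{profile.name}"
    taxon = label_taxon or genome.id
    L = genome.length
    reads: list[Read] = []
    labels: dict[str, TruthLabel] = {}

    def draw_len(mean: float, sd: float) -> int:
        n = int(round(rng.normal(mean, sd))) if sd > 0 else int(mean)
        return max(30, min(n, L))

    def emit(rid: str, start: int, length: int, strand: int) -> None:
        truth = genome.fetch(start, length) if circular else \
            genome.seq[start:start + length]
        seq = truth if strand == 1 else _revcomp(truth)
        seq = _apply_homopolymer_indels(seq, profile.homopolymer_indel_rate, rng)
        seq = _apply_substitutions(seq, profile.sub_error_rate, rng)
        g_start = (start + coord_offset) % (L if circular else 10 ** 12)
        g_end = (start + length + coord_offset) % L if circular \
            else start + length + coord_offset
        reads.append(Read(id=rid, seq=seq))
        labels[rid] = TruthLabel(read_id=rid, source_taxon=taxon,
                                 start=g_start, end=g_end, strand=strand)

    n = profile.yield_reads
    i = 0
    while i < n:
        if profile.paired:
            insert_mean = profile.insert_mean or 3 * profile.mean_read_len
            insert = draw_len(insert_mean, profile.insert_sd or
                              0.1 * insert_mean)
            rl1 = min(draw_len(profile.mean_read_len, profile.read_len_sd),
                      insert)
            rl2 = min(draw_len(profile.mean_read_len, profile.read_len_sd),
                      insert)
            start = int(rng.integers(L)) if circular else \
                int(rng.integers(max(1, L - insert + 1)))
            stem = f"{prefix}_{i:06d}"
            emit(f"{stem}/1", start, rl1, 1)
            emit(f"{stem}/2", (start + insert - rl2) % L if circular
                 else start + insert - rl2, rl2, -1)
            i += 2
        else:
            rl = draw_len(profile.mean_read_len, profile.read_len_sd)
            start = int(rng.integers(L)) if circular else \
                int(rng.integers(max(1, L - rl + 1)))
            strand = 1 if rng.random() < 0.5 else -1
            emit(f"{prefix}_{i:06d}", start, rl, strand)
            i += 1
    return ReadSet(reads=reads, labels=labels, platform=profile.name)


def simulate_pool(
    genomes: Mapping[str, CircularGenome],
    per_taxon_profiles: Mapping[str, PlatformProfile],
    amplicon_scheme: Mapping[str, Sequence[Amplicon]],
    seed: int = 0,
) -> ReadSet:
    """A non-indexed pooled read set from per-taxon amplicons.

    Each taxon contributes reads only from its non-failed amplicons (a
    failed long-range PCR removes roughly a whole genome fragment, the way
    one study sample retained only about a third of its mitogenome).  Read
    ids carry no taxon information; truth labels are kept separately.
    Emits a warning (in the returned set's ``platform`` field staying
    unchanged) rather than an error when a scheme does not cover a genome.
    """
    import warnings

    rng = np.random.default_rng(seed)
    all_reads: list[Read] = []
    all_labels: dict[str, TruthLabel] = {}
    counter = 0
    for taxon in sorted(genomes):
        genome = genomes[taxon]
        profile = per_taxon_profiles[taxon]
        amps = amplicon_scheme.get(taxon, ())
        live = [a for a in amps if not a.failed]
        covered = sum((a.end - a.start) % genome.length or genome.length
                      for a in live)
        if covered < genome.length:
            warnings.warn(
                f"amplicon scheme covers only ~{covered} of "
                f"{genome.length} bp for {taxon}", stacklevel=2,
            )
        if not live:
            continue
        # split the taxon's yield across live amplicons by length
        sizes = np.array(
            [(a.end - a.start) % genome.length or genome.length for a in live],
            dtype=float,
        )
        yields = np.floor(profile.yield_reads * sizes / sizes.sum()).astype(int)
        yields[0] += profile.yield_reads - int(yields.sum())
        for amp, n_amp in zip(live, yields):
            size = (amp.end - amp.start) % genome.length or genome.length
            fragment = CircularGenome(
                id=f"{taxon}_amp", seq=genome.fetch(amp.start, size)
            )
            sub = replace(profile, yield_reads=int(n_amp))
            rs = simulate_reads(
                fragment, sub, seed=int(rng.integers(2 ** 31)),
                id_prefix="pool", circular=False,
                coord_offset=amp.start, label_taxon=taxon,
            )
            # renumber ids so the pool is anonymous and collision-free
            for r in rs.reads:
                old = r.id
                r.id = f"pool_{counter:07d}" + \
                    ("/" + old.rsplit("/", 1)[1] if "/" in old else "")
                lab = rs.labels.pop(old)
                rs.labels[r.id] = TruthLabel(
                    read_id=r.id, source_taxon=lab.source_taxon,
                    start=lab.start % genome.length,
                    end=lab.end % genome.length, strand=lab.strand,
                )
                counter += 1
            all_reads.extend(rs.reads)
            all_labels.update(rs.labels)
    return ReadSet(reads=all_reads, labels=all_labels, platform="pool")


# ---------------------------------------------------------------------------
# tree-set simulation


def simulate_treeset(
    leaves: Sequence[str],
    target_clade_frequencies: Mapping[Iterable[str], float],
    n_trees: int,
    seed: int = 0,
    source: str = "simulated",
) -> TreeSample:
    """Sample rooted trees whose empirical clade frequencies converge to the
    requested targets.

    A probability distribution over the enumerated rooted topologies is
    found by solving ``M p = f`` (with ``p`` a distribution and ``M``
    marking which topologies contain which clade) as a nonnegative least
    squares problem regularised toward the uniform distribution, so
    under-determined targets spread mass evenly (no constraints at all
    gives the uniform distribution over all topologies); targets no
    distribution can realise are rejected with a diagnostic.  Topologies
    are then drawn i.i.d. from that distribution.
    """
    leaves = sorted(set(leaves))
    topo = enumerate_rooted_trees_with_clusters(leaves)
    targets = {frozenset(k): float(v)
               for k, v in target_clade_frequencies.items()}
    for clade, f in targets.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"target frequency for {sorted(clade)} not in [0,1]")
        if not clade < frozenset(leaves):
            raise ValueError(f"clade {sorted(clade)} not a proper subset of leaves")

    m = len(topo)
    a_eq = [[1.0] * m]
    b_eq = [1.0]
    for clade, f in targets.items():
        a_eq.append([1.0 if clade in clusters else 0.0 for _, clusters in topo])
        b_eq.append(f)
    a_eq = np.asarray(a_eq)
    b_eq = np.asarray(b_eq)
    # hard constraints heavily weighted; a light ridge pulls the solution
    # toward uniform so under-determined targets spread mass evenly
    weight, ridge = 1e4, 1.0
    a_full = np.vstack([weight * a_eq, ridge * np.eye(m)])
    b_full = np.concatenate([weight * b_eq, ridge * np.full(m, 1.0 / m)])
    p, _ = nnls(a_full, b_full)
    if np.abs(a_eq @ p - b_eq).max() > 1e-6:
        raise ValueError(
            "no distribution over rooted topologies realises the requested "
            f"clade frequencies {{{', '.join(str(sorted(c)) + ': ' + str(f) for c, f in targets.items())}}}"
        )
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_trees, p)
    trees = []
    for (nwk, _), k in zip(topo, counts):
        trees.extend([nwk] * int(k))
    order = rng.permutation(len(trees))
    return TreeSample(trees=[trees[i] for i in order], source=source)
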