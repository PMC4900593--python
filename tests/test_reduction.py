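"""Windowing, divergence profiles, thresholds and read extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopool.published import HISEQ_ALIGNMENT_LENGTH, load_hiseq_windows
from mitopool.reduction import (
    ReferenceAlignment,
    Window,
    annotate_windows,
    compute_threshold,
    extract_reads,
    p_distance,
    partition_by_divergence,
    sliding_pdistance_profile,
    validate_windows,
    window_consensus,
)
from mitopool.simulate import (
    CircularGenome,
    EvolutionSpec,
    PlatformProfile,
    ReadSet,
    simulate_genomes,
    simulate_reads,
)

BASES = "ACGT"


def brute_force_profile(aln, window_len):
    """Independent recomputation: per start, max pairwise p-distance."""
    L = aln.length
    out = []
    for s in range(L):
        cols = [(s + k) % L for k in range(window_len)]
        best = 0.0
        for i in range(len(aln.rows)):
            for j in range(i + 1, len(aln.rows)):
                num = den = 0
                for c in cols:
                    a, b = aln.rows[i][c], aln.rows[j][c]
                    if a in BASES and b in BASES:
                        den += 1
                        num += a != b
                if den:
                    best = max(best, num / den)
        out.append(best)
    return np.array(out)


class TestPdistanceProfile:
    def test_identical_rows_give_zero_profile(self):
        aln = ReferenceAlignment(taxa=["a", "b"], rows=["ACGT" * 20] * 2)
        _, prof = sliding_pdistance_profile(aln, 10)
        assert np.all(prof == 0.0)

    def test_single_mismatch_in_ten(self):
        aln = ReferenceAlignment(
            taxa=["a", "b"], rows=["AAAAAAAAAA", "AAAATAAAAA"],
            circular=False,
        )
        _, prof = sliding_pdistance_profile(aln, 10)
        assert prof[0] == pytest.approx(0.10)

    def test_matches_brute_force_on_random_toy(self):
        rng = np.random.default_rng(42)
        rows = ["".join(rng.choice(list("ACGT-"), 60, p=[0.23] * 4 + [0.08]))
                for _ in range(4)]
        aln = ReferenceAlignment(taxa=list("abcd"), rows=rows)
        starts, prof = sliding_pdistance_profile(aln, 5, step=1)
        expected = brute_force_profile(aln, 5)
        np.testing.assert_allclose(prof, expected)

    def test_rejects_oversized_window_on_linear_alignment(self):
        aln = ReferenceAlignment(taxa=["a", "b"], rows=["ACGT", "ACGA"],
                                 circular=False)
        with pytest.raises(ValueError):
            sliding_pdistance_profile(aln, 10)

    def test_pdistance_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list(BASES), 200))
        b = "".join(rng.choice(list(BASES), 200))
        assert p_distance(a, b) == p_distance(b, a)
        assert 0.0 <= p_distance(a, b) <= 1.0
        assert p_distance(a, a) == 0.0


class TestPartition:
    def test_flat_profile_gives_single_window(self):
        starts = np.arange(1000)
        prof = np.full(1000, 0.2)
        windows = partition_by_divergence(starts, prof, 1000, min_block=100)
        assert len(windows) == 1
        rep = validate_windows(windows, 0, 1000)
        assert rep["covers_alignment"]

    def test_step_profile_boundary_near_change_point(self):
        L = 2000
        starts = np.arange(L)
        prof = np.where(starts < 1000, 0.05, 0.30)
        windows = partition_by_divergence(starts, prof, L, min_block=200,
                                          min_overlap=50)
        assert len(windows) == 2
        boundary = sorted(w.start for w in windows if w.start != 0
                          and w.start < 1900)
        # the widened start sits min_overlap before the detected change
        assert any(abs((b + 50) - 1000) <= 2 for b in boundary)
        rep = validate_windows(windows, 50, L)
        assert rep["ok"]

    def test_printed_window_scheme_validates_at_50bp(self):
        windows = load_hiseq_windows()
        assert len(windows) == 16
        rep = validate_windows(windows, 50, HISEQ_ALIGNMENT_LENGTH)
        assert rep["covers_alignment"]
        assert rep["min_consecutive_overlap"] == 50


class TestValidateWindows:
    def test_two_window_overlap_arithmetic(self):
        ws = [Window(0, 100), Window(90, 200)]
        rep = validate_windows(ws, 10, 200)
        assert rep["min_consecutive_overlap"] == 10
        assert rep["covers_alignment"]

    def test_single_whole_circle_window(self):
        rep = validate_windows([Window(0, 0)], 50, 500)
        assert rep["covers_alignment"]
        assert rep["min_consecutive_overlap"] is None

    def test_wrap_window_overlap(self):
        ws = [Window(0, 300), Window(250, 80)]  # second wraps the origin
        rep = validate_windows(ws, 50, 400)
        assert rep["covers_alignment"]
        assert rep["min_consecutive_overlap"] == 50 + 80


class TestConsensus:
    def test_identical_rows_consensus_strips_gaps(self):
        aln = ReferenceAlignment(taxa=["a", "b"], rows=["AC-GT", "AC-GT"])
        assert window_consensus(aln, Window(0, 0)) == "ACGT"

    def test_tie_yields_iupac_code(self):
        aln = ReferenceAlignment(taxa=list("abcd"),
                                 rows=["A", "A", "T", "T"])
        assert window_consensus(aln, Window(0, 0)) == "W"

    def test_matches_per_column_tally_and_row_order_invariance(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list("ACGT-"), 40)) for _ in range(4)]
        aln = ReferenceAlignment(taxa=list("abcd"), rows=rows)
        cons = window_consensus(aln, Window(0, 0))
        # independent tally
        expected = []
        for c in range(40):
            col = [r[c] for r in rows]
            counts = {b: col.count(b) for b in BASES if col.count(b)}
            gaps = col.count("-")
            if not counts or gaps > max(counts.values()):
                continue
            top = max(counts.values())
            tied = sorted(b for b, n in counts.items() if n == top)
            iupac = {"A": "A", "C": "C", "G": "G", "T": "T",
                     "AG": "R", "CT": "Y", "CG": "S", "AT": "W",
                     "GT": "K", "AC": "M", "CGT": "B", "AGT": "D",
                     "ACT": "H", "ACG": "V", "ACGT": "N"}
            expected.append(iupac["".join(tied)])
        assert cons == "".join(expected)
        shuffled = ReferenceAlignment(taxa=list("dcba"), rows=rows[::-1])
        assert window_consensus(shuffled, Window(0, 0)) == cons


class TestThreshold:
    @pytest.mark.parametrize("d,a,expected", [
        (0.22, 0.10, 0.32),
        (0.35, 0.10, 0.45),
        (0.95, 0.10, 1.0),
    ])
    def test_additive_rule_and_cap(self, d, a, expected):
        assert compute_threshold(d, a) == pytest.approx(expected)

    def test_multiplicative_mode(self):
        assert compute_threshold(0.22, 0.10, mode="multiplicative") == \
            pytest.approx(0.242)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_threshold_within_unit_interval_and_monotone(self, d, a):
        t = compute_threshold(d, a)
        assert 0.0 <= t <= 1.0
        assert t >= compute_threshold(d, 0.0) or t == 1.0


@pytest.fixture(scope="module")
def separated_pool():
    """Targets ~6% from the consensus, decoys random (~75%)."""
    spec = EvolutionSpec(tree="((T1:0.03,T2:0.03):0.01,O:0.04);", seed=11)
    genomes, aln = simulate_genomes(spec, 2000)
    rng = np.random.default_rng(3)
    decoy = CircularGenome(id="D",
                           seq="".join(rng.choice(list(BASES), 2000)))
    prof = PlatformProfile(name="hiseq", mean_read_len=95,
                           read_len_sd=5, yield_reads=120)
    reads, labels = [], {}
    for g in [genomes["T1"], genomes["T2"], decoy]:
        rs = simulate_reads(g, prof, seed=17 + len(reads))
        reads += rs.reads
        labels.update(rs.labels)
    pool = ReadSet(reads=reads, labels=labels)
    consensus = window_consensus(aln, Window(0, 0))
    return pool, consensus


class TestExtractReads:
    def test_exact_substring_retained(self):
        consensus = "ACGTTGCA" * 30
        read = ReadSet(reads=[])
        from mitopool.simulate import Read

        read.reads.append(Read(id="r1", seq=consensus[40:120]))
        kept = extract_reads(read, consensus, threshold=0.0)
        assert [r.id for r in kept.reads] == ["r1"]

    def test_divergent_read_discarded(self):
        rng = np.random.default_rng(5)
        consensus = "".join(rng.choice(list(BASES), 300))
        from mitopool.simulate import Read

        noisy = list(consensus[50:150])
        flip = rng.choice(100, size=40, replace=False)
        for i in flip:
            noisy[i] = BASES[(BASES.index(noisy[i]) + 1) % 4]
        pool = ReadSet(reads=[Read(id="bad", seq="".join(noisy))])
        kept = extract_reads(pool, consensus, threshold=0.32)
        assert len(kept) == 0

    def test_perfect_recall_and_precision_with_separation(self, separated_pool):
        pool, consensus = separated_pool
        kept = extract_reads(pool, consensus, threshold=0.32, circular=True)
        tp = sum(1 for r in kept.reads
                 if pool.labels[r.id].source_taxon != "D")
        n_target = sum(1 for lab in pool.labels.values()
                       if lab.source_taxon != "D")
        assert tp / n_target == 1.0          # recall
        assert tp / len(kept) == 1.0         # precision

    def test_raising_threshold_never_drops_reads(self, separated_pool):
        pool, consensus = separated_pool
        previous = set()
        for t in (0.05, 0.20, 0.35, 0.60):
            kept = {r.id for r in
                    extract_reads(pool, consensus, t, circular=True).reads}
            assert previous <= kept
            previous = kept


class TestRotationInvariance:
    def test_rotating_alignment_rotates_windows_but_not_contents(self):
        spec = EvolutionSpec(tree="((A:0.05,B:0.05):0.03,C:0.09);", seed=13)
        _, aln = simulate_genomes(spec, 1500)
        k = 400
        rotated = aln.rotated(k)
        starts, prof = sliding_pdistance_profile(aln, 200)
        starts_r, prof_r = sliding_pdistance_profile(rotated, 200)
        np.testing.assert_allclose(np.roll(prof, k), prof_r)
        # window contents (consensus, divergence) unchanged after rotation
        w = Window(100, 600)
        w_rot = Window((100 + k) % aln.length, (600 + k) % aln.length)
        assert window_consensus(aln, w) == window_consensus(rotated, w_rot)
        a = annotate_windows(aln, [w])[0]
        b = annotate_windows(rotated, [w_rot])[0]
        assert a.max_p_distance == pytest.approx(b.max_p_distance)
        assert a.threshold == pytest.approx(b.threshold)
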