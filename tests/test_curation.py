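"""Seed finding, read harvesting, PWM consensus and seed extension.

Alignment scores are cross-checked against an independent quadratic
Smith-Waterman (Gotoh) dynamic program, read harvesting against a naive
substring scan, and PWM depths against an interval-stabbing count.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from fibroin_arch import (
    AlignParams,
    AnchoredRead,
    CurationConfig,
    InputError,
    ParameterError,
    PwmColumn,
    Read,
    ReadSimParams,
    Termination,
    build_pwm,
    call_consensus,
    extend_seed,
    find_terminal_seeds,
    harvest_matching_reads,
    simulate_reads,
)


def sw_gotoh(a: str, b: str, match=2.0, mismatch=-3.0, open_=-5.0, ext=-2.0) -> float:
    """Independent affine-gap local alignment score (quadratic DP)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _rc(s: str) -> str:
    return str(Seq(s).reverse_complement())


class TestFindTerminalSeeds:
    def test_perfect_match_scores_twice_length(self):
        terminus = "ACGTACGTGGCCATAT" * 4
        seeds = find_terminal_seeds(
            [("c1", terminus)], [("t", terminus)], AlignParams(min_score=10)
        )
        assert len(seeds) == 1
        assert seeds[0].alignment_score == 2 * len(terminus)
        assert seeds[0].strand == "+"

    def test_reverse_complement_contig_same_score_minus_strand(self):
        terminus = "ACGTACGTGGCCATATTTGACC" * 3
        seeds = find_terminal_seeds(
            [("c1", _rc(terminus))], [("t", terminus)], AlignParams(min_score=10)
        )
        assert len(seeds) == 1
        assert seeds[0].strand == "-"
        assert seeds[0].alignment_score == 2 * len(terminus)
        assert seeds[0].sequence == terminus  # strand-normalised

    def test_planted_terminus_among_random_contigs(self):
        rng = np.random.default_rng(13)
        contigs = [
            (f"rand_{i}", "".join(rng.choice(list("ACGT"), 120)))
            for i in range(10)
        ]
        terminus = "".join(rng.choice(list("ACGT"), 80))
        contigs.append(("planted", terminus))
        seeds = find_terminal_seeds(
            contigs, [("t", terminus)], AlignParams(min_score=60)
        )
        assert [s.source_contig for s in seeds] == ["planted"]
        # cross-check: no random contig reaches the threshold per the DP oracle
        for cid, cseq in contigs[:-1]:
            assert max(sw_gotoh(cseq, terminus), sw_gotoh(_rc(cseq), terminus)) < 60

    def test_scores_match_dp_oracle(self):
        rng = np.random.default_rng(21)
        terminus = "".join(rng.choice(list("ACGT"), 30))
        for i in range(5):
            contig = "".join(rng.choice(list("ACGT"), 50))
            seeds = find_terminal_seeds(
                [("c", contig)], [("t", terminus)], AlignParams(min_score=0.5)
            )
            expected = max(sw_gotoh(contig, terminus), sw_gotoh(_rc(contig), terminus))
            assert seeds[0].alignment_score == pytest.approx(expected)

    def test_translated_mode_finds_protein_homology(self):
        protein = "MSKLDNPEQRWYFHCTTGVM" * 3
        from fibroin_arch import reverse_translate

        contig = reverse_translate(protein, "uniform_random", rng_seed=3)
        seeds = find_terminal_seeds(
            [("c", _rc(contig))],
            [("t", protein)],
            AlignParams(min_score=100, mode="translated"),
        )
        assert len(seeds) == 1 and seeds[0].strand == "-"

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            find_terminal_seeds([], [("t", "ACGT")])


class TestHarvest:
    def test_zero_error_anchored_reads_agree_with_template(self, gene5, gene5_reads):
        growing = gene5.cds[:100]
        anchors = harvest_matching_reads(growing, gene5_reads, k=75)
        assert anchors
        for a in anchors:
            for i, base in enumerate(a.sequence):
                coord = a.offset + i
                if 0 <= coord < len(gene5.cds):
                    assert base == gene5.cds[coord]

    def test_vacuous_match_yields_empty(self):
        reads = [Read("r0", "A" * 150, "I" * 150)]
        assert harvest_matching_reads("C" * 150, reads, k=150) == []

    def test_matches_naive_substring_oracle(self, random_template):
        reads = simulate_reads(
            random_template, ReadSimParams(coverage=15, rng_seed=3)
        )[:200]
        growing = random_template[:500]
        k = 31
        kmer = growing[-k:]
        expected = set()
        for read in reads:
            for seq in (read.sequence, _rc(read.sequence)):
                p = seq.find(kmer)
                while p != -1:
                    expected.add((read.read_id, seq, (len(growing) - k) - p))
                    p = seq.find(kmer, p + 1)
        got = {
            (a.read_id, a.sequence, a.offset)
            for a in harvest_matching_reads(growing, reads, k=k)
        }
        assert got == expected

    def test_k_exceeding_read_length_rejected(self):
        reads = [Read("r0", "ACGT" * 10, "I" * 40)]
        with pytest.raises(ParameterError):
            harvest_matching_reads("A" * 100, reads, k=60)


class TestPwm:
    def test_unanimous_column(self):
        anchors = [AnchoredRead(f"r{i}", "C" * 75 + "A", 25) for i in range(5)]
        cols = build_pwm(anchors, growing_len=100)
        assert cols[0].counts == {"A": 5, "C": 0, "G": 0, "T": 0}
        assert cols[0].depth == 5

    def test_dominant_fraction(self):
        anchors = [AnchoredRead(f"r{i}", "C" * 75 + "G", 25) for i in range(4)]
        anchors.append(AnchoredRead("r4", "C" * 75 + "T", 25))
        cols = build_pwm(anchors, growing_len=100)
        assert cols[0].depth == 5
        assert cols[0].dominant_frac == pytest.approx(0.8)

    def test_depth_matches_interval_stabbing_oracle(self):
        rng = np.random.default_rng(5)
        anchors = []
        for i in range(50):
            length = int(rng.integers(30, 120))
            offset = int(rng.integers(-50, 80))
            seq = "".join(rng.choice(list("ACGT"), length))
            anchors.append(AnchoredRead(f"r{i}", seq, offset))
        growing_len = 100
        cols = build_pwm(anchors, growing_len)
        for j, col in enumerate(cols):
            coord = growing_len + j
            expected = sum(
                1
                for a in anchors
                if a.offset <= coord < a.offset + len(a.sequence)
            )
            assert col.depth == expected
        # first uncovered coordinate truncates the matrix
        if cols:
            coord = growing_len + len(cols)
            assert (
                sum(
                    1
                    for a in anchors
                    if a.offset <= coord < a.offset + len(a.sequence)
                )
                == 0
            )

    def test_empty_anchor_list(self):
        assert build_pwm([], 100) == []


class TestCallConsensus:
    CONFIG = CurationConfig(min_depth=3, min_dominant_frac=0.9)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 9, "C": 0, "G": 1, "T": 0}, "A"),  # 0.9 inclusive
            ({"A": 5, "C": 0, "G": 5, "T": 0}, Termination.AMBIGUOUS),
            ({"A": 2, "C": 0, "G": 0, "T": 0}, Termination.LOW_DEPTH),
            ({"A": 8, "C": 2, "G": 0, "T": 0}, Termination.AMBIGUOUS),
        ],
    )
    def test_threshold_semantics(self, counts, expected):
        col = PwmColumn(counts, sum(counts.values()), 0)
        assert call_consensus(col, self.CONFIG) == expected


class TestExtendSeed:
    def test_starved_read_set_stops_immediately(self, random_template):
        seed = random_template[:200]
        # reads drawn only from the seed region: nothing extends past it
        reads = simulate_reads(seed, ReadSimParams(coverage=20, rng_seed=1))
        result = extend_seed(seed, reads, CurationConfig())
        assert result.termination in (Termination.NO_READS, Termination.LOW_DEPTH)
        assert result.appended <= 5

    def test_deterministic(self, gene5, gene5_reads):
        a = extend_seed(gene5.cds[:360], gene5_reads, CurationConfig())
        b = extend_seed(gene5.cds[:360], gene5_reads, CurationConfig())
        assert a == b

    def test_seed_shorter_than_k_rejected(self, gene5_reads):
        with pytest.raises(InputError):
            extend_seed("ACGT", gene5_reads, CurationConfig(k=75))

    def test_no_false_calls_on_error_free_reads(self, gene5, gene5_reads):
        """Every appended base equals the template base at any coverage."""
        for cov_seed in (5, 6):
            reads = simulate_reads(
                gene5.cds, ReadSimParams(coverage=15, rng_seed=cov_seed)
            )
            result = extend_seed(gene5.cds[:360], reads, CurationConfig())
            assert result.sequence == gene5.cds[: len(result.sequence)]
            assert len(result.support) == result.appended
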