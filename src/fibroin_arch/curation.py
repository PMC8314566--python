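"""Seed-extension curation of repetitive fibroin genes from short reads.

Highly repetitive silk genes collapse in de Bruijn graph assemblies, so the
repetitive domain is reconstructed here by a seed-and-extend procedure:
contigs homologous to a fibroin N/C-terminal domain are located by local
alignment and used as seeds; short reads containing an exact copy of the
seed's terminal large k-mer are anchored at that match; the bases the
anchored reads contribute past the current 3' end are tallied into a
position weight matrix (PWM); and the consensus base is appended only when
the column passes a strict depth and dominance threshold.  Extension stops
when the growing 3' end re-enters sequence it has produced before — the
operational signature of having reached the tandem repeat array — or when
read support runs out.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import InputError, ParameterError
from .simulate import Read


class Termination(enum.Enum):
    """Why an extension stopped."""

    NO_READS = "NO_READS"
    LOW_DEPTH = "LOW_DEPTH"
    AMBIGUOUS = "AMBIGUOUS"
    REPEAT_DETECTED = "REPEAT_DETECTED"
    MAX_LENGTH = "MAX_LENGTH"


@dataclass(frozen=True)
class CurationConfig:
    """Extension thresholds.

    k
        Anchor k-mer length; 75 (half a 150-bp read) balances anchor
        specificity against depth.
    min_depth / min_dominant_frac
        A PWM column is called only if at least ``min_depth`` reads vote
        and the modal base holds at least ``min_dominant_frac`` of the
        votes; both comparisons are inclusive.
    repeat_window
        k-mer length used for repeat-entry detection.  Kept well below
        ``k`` (default 25): the recurrence of a short terminal word flags
        entry into the tandem array while the long anchor k-mer still
        overlaps unique sequence — with ``repeat_window == k`` the anchor
        itself goes multi-mapping (AMBIGUOUS) before the repeat is ever
        detected.  A window of w fires inside a nucleotide-period-p tract
        of length >= w + p, so 25 catches even the shortest default
        repeat tract (the 33-nt poly-A run, period 3 under first-codon
        back-translation) deterministically.
    """

    k: int = 75
    min_depth: int = 3
    min_dominant_frac: float = 0.9
    max_extension: int = 100_000
    repeat_window: int | None = 25

    def validate(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if not (0.5 < self.min_dominant_frac <= 1.0):
            raise ParameterError("min_dominant_frac must be in (0.5, 1]")
        if self.min_depth < 1:
            raise ParameterError("min_depth must be >= 1")
        if self.max_extension < 1:
            raise ParameterError("max_extension must be >= 1")

    @property
    def effective_repeat_window(self) -> int:
        return self.repeat_window if self.repeat_window is not None else self.k


@dataclass(frozen=True)
class AlignParams:
    """Local-alignment settings for seed finding.

    Nucleotide mode scores +2/-3 with affine gaps -5/-2; translated mode
    scores protein-vs-protein with BLOSUM62 and -11/-1 gaps over three
    frames per strand.
    """

    min_score: float = 60.0
    mode: str = "nucleotide"  # or "translated"
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class Seed:
    """A contig fragment homologous to a fibroin terminus.

    ``sequence`` is strand-normalised so that extension proceeds 3'-ward.
    """

    seed_id: str
    sequence: str
    source_contig: str
    strand: str
    alignment_score: float


@dataclass
class AnchoredRead:
    """A read anchored by an exact terminal k-mer match.

    ``offset`` is the (signed) coordinate of the read's first base in the
    growing sequence's coordinate system.
    """

    read_id: str
    sequence: str
    offset: int


@dataclass
class PwmColumn:
    """Base votes at one coordinate past the current 3' end."""

    counts: dict[str, int]
    depth: int
    position: int

    def modal(self) -> tuple[str, int, bool]:
        """(modal base, modal count, tied?)"""
        top = max(self.counts.values())
        winners = [b for b, c in self.counts.items() if c == top]
        return winners[0], top, len(winners) > 1

    @property
    def dominant_frac(self) -> float:
        if self.depth == 0:
            return 0.0
        return self.modal()[1] / self.depth


@dataclass
class ExtensionResult:
    sequence: str
    support: list[tuple[int, float]]  # per appended base: (depth, dominant_frac)
    termination: Termination
    rounds: int
    seed_length: int = 0

    @property
    def appended(self) -> int:
        return len(self.support)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if params.mode == "nucleotide":
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
        aligner.open_gap_score = params.gap_open
        aligner.extend_gap_score = params.gap_extend
    elif params.mode == "translated":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        raise ParameterError(f"unknown alignment mode {params.mode!r}")
    return aligner


def _frames(nt: str) -> list[str]:
    out = []
    for f in range(3):
        trimmed = nt[f : f + 3 * ((len(nt) - f) // 3)]
        out.append(str(Seq(trimmed).translate()) if trimmed else "")
    return out


def _best_score(
    aligner: Align.PairwiseAligner,
    contig: str,
    terminus: str,
    mode: str,
) -> float:
    if mode == "nucleotide":
        return float(aligner.score(contig, terminus))
    return max(
        (float(aligner.score(frame, terminus)) for frame in _frames(contig) if frame),
        default=float("-inf"),
    )


def find_terminal_seeds(
    contigs: Sequence[tuple[str, str]],
    reference_termini: Sequence[tuple[str, str]],
    align_params: AlignParams | None = None,
) -> list[Seed]:
    """Locate contigs homologous to a fibroin terminal domain.

    Smith–Waterman local alignment of every contig (both strands; three
    frames per strand in translated mode) against every reference
    terminus.  Contigs reaching ``min_score`` are returned as seeds,
    strand-normalised, sorted by score descending with ties broken by
    contig id.
    """
    if not contigs or not reference_termini:
        raise InputError("contigs and reference termini must be non-empty")
    params = align_params or AlignParams()
    aligner = _make_aligner(params)
    seeds: list[Seed] = []
    for contig_id, contig_seq in contigs:
        contig_seq = contig_seq.upper()
        rc = _revcomp(contig_seq)
        fwd = max(
            _best_score(aligner, contig_seq, t.upper(), params.mode)
            for _, t in reference_termini
        )
        rev = max(
            _best_score(aligner, rc, t.upper(), params.mode)
            for _, t in reference_termini
        )
        score = max(fwd, rev)
        if score >= params.min_score:
            strand = "+" if fwd >= rev else "-"
            seeds.append(
                Seed(
                    seed_id=f"{contig_id}|{strand}",
                    sequence=contig_seq if strand == "+" else rc,
                    source_contig=contig_id,
                    strand=strand,
                    alignment_score=score,
                )
            )
    seeds.sort(key=lambda s: (-s.alignment_score, s.source_contig))
    return seeds


def harvest_matching_reads(
    growing: str,
    reads: Sequence[Read],
    k: int,
    both_strands: bool = True,
) -> list[AnchoredRead]:
    """Every read containing the terminal k-mer of ``growing`` exactly.

    Each occurrence in each orientation yields one anchor; reads whose
    anchored extent ends before the growing 3' end are still returned
    (they simply contribute no PWM votes).
    """
    if len(growing) < k:
        raise InputError("growing sequence shorter than k")
    kmer = growing[-k:]
    kmer_start = len(growing) - k
    anchors: list[AnchoredRead] = []
    for read in reads:
        if len(read.sequence) < k:
            raise ParameterError("k exceeds read length")
        orientations = [read.sequence]
        if both_strands:
            orientations.append(_revcomp(read.sequence))
        for seq in orientations:
            p = seq.find(kmer)
            while p != -1:
                anchors.append(AnchoredRead(read.read_id, seq, kmer_start - p))
                p = seq.find(kmer, p + 1)
    return anchors


def build_pwm(anchored: Sequence[AnchoredRead], growing_len: int) -> list[PwmColumn]:
    """Tally anchored reads into PWM columns past the current 3' end.

    Column j (coordinate ``growing_len + j``) counts the base of every
    anchored read covering that coordinate; columns are emitted until the
    first zero-depth coordinate.
    """
    if not anchored:
        return []
    max_end = max(a.offset + len(a.sequence) for a in anchored)
    columns: list[PwmColumn] = []
    for coord in range(growing_len, max_end):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        depth = 0
        for a in anchored:
            i = coord - a.offset
            if 0 <= i < len(a.sequence):
                base = a.sequence[i]
                if base in counts:
                    counts[base] += 1
                    depth += 1
        if depth == 0:
            break
        columns.append(PwmColumn(counts, depth, coord))
    return columns


def call_consensus(
    column: PwmColumn, config: CurationConfig
) -> str | Termination:
    """Modal base of a column, or the verdict explaining why there is none."""
    if column.depth < config.min_depth:
        return Termination.LOW_DEPTH
    base, top, tied = column.modal()
    if tied or top / column.depth < config.min_dominant_frac:
        return Termination.AMBIGUOUS
    return base


class _KmerIndex:
    """Exact k-mer index over a read set (both orientations)."""

    def __init__(self, reads: Sequence[Read], k: int, both_strands: bool = True):
        self.k = k
        self.table: dict[str, list[tuple[str, str, int]]] = {}
        for read in reads:
            if len(read.sequence) < k:
                raise ParameterError("k exceeds read length")
            orientations = [read.sequence]
            if both_strands:
                orientations.append(_revcomp(read.sequence))
            for seq in orientations:
                for p in range(len(seq) - k + 1):
                    self.table.setdefault(seq[p : p + k], []).append(
                        (read.read_id, seq, p)
                    )

    def anchors(self, growing: str) -> list[AnchoredRead]:
        kmer = growing[-self.k :]
        kmer_start = len(growing) - self.k
        return [
            AnchoredRead(rid, seq, kmer_start - p)
            for rid, seq, p in self.table.get(kmer, ())
        ]


def extend_seed(
    seed: Seed | str,
    reads: Sequence[Read],
    config: CurationConfig | None = None,
) -> ExtensionResult:
    """Extend a seed 3'-ward through PWM consensus until a stop condition.

    Per round: harvest reads anchored at the terminal k-mer, tally the
    first PWM column, call it, and append the consensus base.  Stops with
    NO_READS when no anchored read votes past the 3' end, LOW_DEPTH or
    AMBIGUOUS when the call fails, REPEAT_DETECTED when the new terminal
    ``repeat_window``-mer already occurs earlier in the curated sequence,
    or MAX_LENGTH at the extension cap.  Reads are re-harvested after
    every appended base, so each column is voted on by the fullest anchor
    set available.

    To curate the C-terminal side, reverse-complement seed and reads and
    extend again.
    """
    cfg = config or CurationConfig()
    cfg.validate()
    sequence = seed.sequence if isinstance(seed, Seed) else seed
    sequence = sequence.upper()
    if len(sequence) < cfg.k:
        raise InputError("seed shorter than k")
    index = _KmerIndex(reads, cfg.k)
    rw = cfg.effective_repeat_window
    growing = sequence
    support: list[tuple[int, float]] = []
    rounds = 0
    termination: Termination
    while True:
        rounds += 1
        anchors = index.anchors(growing)
        column = _first_column(anchors, len(growing))
        if column is None:
            termination = Termination.NO_READS
            break
        verdict = call_consensus(column, cfg)
        if isinstance(verdict, Termination):
            termination = verdict
            break
        growing += verdict
        support.append((column.depth, column.dominant_frac))
        if len(support) >= cfg.max_extension:
            termination = Termination.MAX_LENGTH
            break
        if len(growing) > rw:
            window = growing[-rw:]
            if growing.find(window) < len(growing) - rw:
                termination = Termination.REPEAT_DETECTED
                break
    return ExtensionResult(
        sequence=growing,
        support=support,
        termination=termination,
        rounds=rounds,
        seed_length=len(sequence),
    )


def _first_column(
    anchors: Sequence[AnchoredRead], growing_len: int
) -> PwmColumn | None:
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    depth = 0
    for a in anchors:
        i = growing_len - a.offset
        if 0 <= i < len(a.sequence):
            base = a.sequence[i]
            if base in counts:
                counts[base] += 1
                depth += 1
    if depth == 0:
        return None
    return PwmColumn(counts, depth, growing_len)


def identity_to_template(curated: str, template: str) -> float:
    """Fraction of curated bases matching the template prefix positionally."""
    n = min(len(curated), len(template))
    if n == 0:
        return 0.0
    matches = sum(1 for a, b in zip(curated[:n], template[:n]) if a == b)
    return matches / len(curated)
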