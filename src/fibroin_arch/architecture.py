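"""Motif architecture of silk H-fibroin repetitive domains.

Bagworm H-fibroin carries a long central repetitive domain built from tandem
repeat units.  Each unit is an ordered succession of four motif regions:

* ``POLY_A_E``  — a polyalanine run, typically interrupted by a single central
  glutamic acid (``(A)nE(A)n``);
* ``GA_PURE``   — alternating glycine–alanine with no serine;
* ``LINKER_IV`` — a short isoleucine/valine stretch;
* ``GA_SER``    — alternating glycine–alanine containing serine.

The poly-A and pure-GA regions form beta-sheet crystallites in the spun
fibre; the linker and serine-containing GA region stay amorphous.  This
module translates curated CDS, segments proteins into those regions,
decomposes the repetitive domain into repeat units, and computes
motif-length distributions, amino-acid composition and the predicted
crystalline fraction.

All coordinates are 0-based half-open intervals in protein space.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import InputError, ParameterError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

Interval = tuple[int, int]


class MotifType(enum.Enum):
    """Region types a segmented residue can carry."""

    POLY_A_E = "POLY_A_E"
    GA_PURE = "GA_PURE"
    LINKER_IV = "LINKER_IV"
    GA_SER = "GA_SER"
    TERMINAL = "TERMINAL"
    UNASSIGNED = "UNASSIGNED"


#: The four motif types that make up a repeat unit, in canonical order.
CANONICAL_ORDER = (
    MotifType.POLY_A_E,
    MotifType.GA_PURE,
    MotifType.LINKER_IV,
    MotifType.GA_SER,
)

#: Region types counted as crystalline (beta-sheet forming) in spun fibre.
CRYSTALLINE_TYPES = frozenset({MotifType.POLY_A_E, MotifType.GA_PURE})


@dataclass(frozen=True)
class SegConfig:
    """Tolerances for motif-region segmentation.

    min_polyA_run
        Minimum consecutive alanines needed to open a poly-A anchor.  The
        default of 4 guarantees that the isolated alanines of a GA
        alternation can never seed an anchor.
    min_linker_run
        Minimum consecutive I/V residues for a linker anchor.
    max_impurity_frac
        Fraction of residues outside {G, A, S} tolerated inside a GA region
        before the gap is left UNASSIGNED.
    require_ser
        If true, the post-linker GA region must contain at least one serine
        to be typed GA_SER; otherwise it is UNASSIGNED.
    """

    min_polyA_run: int = 4
    min_linker_run: int = 2
    max_impurity_frac: float = 0.1
    require_ser: bool = True

    def validate(self) -> None:
        if self.min_polyA_run < 1:
            raise ParameterError("min_polyA_run must be >= 1")
        if self.min_linker_run < 1:
            raise ParameterError("min_linker_run must be >= 1")
        if not (0.0 <= self.max_impurity_frac < 0.5):
            raise ParameterError("max_impurity_frac must be in [0, 0.5)")


@dataclass
class Segmentation:
    """Ordered, non-overlapping typed intervals over one protein."""

    protein_id: str
    regions: list[tuple[MotifType, Interval]]
    repeat_domain_span: Interval | None

    def typed_regions(self) -> list[tuple[MotifType, Interval]]:
        """Regions belonging to the four canonical motif types."""
        return [r for r in self.regions if r[0] in CANONICAL_ORDER]

    def total_length(self) -> int:
        return sum(e - s for _, (s, e) in self.regions)


@dataclass
class RepeatUnit:
    """One repeat unit: up to four typed spans tiling ``unit_span``."""

    unit_index: int
    spans: list[tuple[MotifType, Interval]]
    unit_span: Interval

    def span_of(self, motif: MotifType) -> Interval | None:
        for m, iv in self.spans:
            if m is motif:
                return iv
        return None


@dataclass
class ArchitectureStats:
    """Per-species motif-length, composition and crystallinity summaries."""

    lengths: pd.DataFrame  # long format: species, motif, length
    summary: pd.DataFrame  # species x motif: n, mean, median, q1, q3
    aa_freq: dict[str, np.ndarray] = field(default_factory=dict)
    crystalline: pd.DataFrame | None = None


def translate_longest_orf(cds: str, min_codons: int = 10) -> str:
    """Translate a sense-stranded CDS, returning its best open reading frame.

    Scans the three forward frames, preferring the longest stop-free ORF that
    begins with ATG; if no frame contains a start codon, falls back to the
    longest stop-free frame fragment.  Ties go to the lowest frame index,
    then the leftmost start.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise InputError("CDS must be at least one codon long")
    best_orf: tuple[int, int, str] | None = None  # (-len, frame, protein)
    best_frag: tuple[int, int, str] | None = None
    for frame in range(3):
        trimmed = cds[frame : frame + 3 * ((len(cds) - frame) // 3)]
        if not trimmed:
            continue
        protein = str(Seq(trimmed).translate())
        pos = 0
        for fragment in protein.split("*"):
            if fragment:
                if best_frag is None or len(fragment) > -best_frag[0]:
                    best_frag = (-len(fragment), frame, fragment)
                m = fragment.find("M")
                if m != -1:
                    orf = fragment[m:]
                    if best_orf is None or len(orf) > -best_orf[0]:
                        best_orf = (-len(orf), frame, orf)
            pos += len(fragment) + 1
    chosen = best_orf if best_orf is not None else best_frag
    if chosen is None or len(chosen[2]) < min_codons:
        raise InputError(
            f"no reading frame yields at least {min_codons} codons"
        )
    return chosen[2]


def _polya_anchors(protein: str, min_run: int) -> list[Interval]:
    """Maximal A-runs >= min_run, optionally spanning one central E.

    The glutamic acid sits at the centre of the block, so when the A-run
    left of the E outruns the right one the excess leading alanines are
    trimmed off the anchor — they are the tail of the preceding GA
    alternation (which always ends in A) rather than part of the poly-A
    block.
    """
    pattern = re.compile(
        rf"A{{{min_run},}}(?:EA{{{min_run},}})?"
    )
    spans = []
    for m in pattern.finditer(protein):
        start, end = m.span()
        block = m.group()
        e_pos = block.find("E")
        if e_pos != -1:
            left, right = e_pos, len(block) - e_pos - 1
            if left > right:
                start += left - right
        spans.append((start, end))
    return spans


def _linker_anchors(protein: str, min_run: int) -> list[Interval]:
    pattern = re.compile(rf"[IV]{{{min_run},}}")
    return [m.span() for m in pattern.finditer(protein)]


def _ga_pure_enough(segment: str, max_impurity: float) -> bool:
    if not segment:
        return False
    impurity = sum(1 for c in segment if c not in "GAS") / len(segment)
    return impurity <= max_impurity


def segment_repetitive_domain(
    protein: str,
    config: SegConfig | None = None,
    protein_id: str = "query",
) -> Segmentation:
    """Segment a fibroin protein into its four motif regions.

    Anchor pass: poly-A(-E) runs and I/V linker runs are located first; the
    gaps between successive anchors are then typed positionally — a gap from
    a poly-A anchor to the next linker is the pure GA region, a gap from a
    linker to the next poly-A anchor is the serine-containing GA region —
    with composition used only for validation (impurity and serine checks).
    The stretch of {G, A, S} residues directly after the last linker anchor
    closes the final unit's GA_SER region.  Residues outside the repetitive
    domain are typed TERMINAL; gaps failing validation are UNASSIGNED.

    A protein with no anchors yields a single all-TERMINAL segmentation.
    """
    if not protein:
        raise InputError("protein must be non-empty")
    protein = protein.upper()
    cfg = config or SegConfig()
    cfg.validate()

    anchors: list[tuple[MotifType, Interval]] = [
        (MotifType.POLY_A_E, iv)
        for iv in _polya_anchors(protein, cfg.min_polyA_run)
    ] + [
        (MotifType.LINKER_IV, iv)
        for iv in _linker_anchors(protein, cfg.min_linker_run)
    ]
    anchors.sort(key=lambda r: r[1])

    if not anchors:
        return Segmentation(
            protein_id, [(MotifType.TERMINAL, (0, len(protein)))], None
        )

    regions: list[tuple[MotifType, Interval]] = []
    for (left_t, (ls, le)), (right_t, (rs, _)) in zip(anchors, anchors[1:]):
        regions.append((left_t, (ls, le)))
        if le == rs:
            continue
        gap = protein[le:rs]
        gap_iv = (le, rs)
        if left_t is MotifType.POLY_A_E and right_t is MotifType.LINKER_IV:
            ok = _ga_pure_enough(gap, cfg.max_impurity_frac)
            regions.append((MotifType.GA_PURE if ok else MotifType.UNASSIGNED, gap_iv))
        elif left_t is MotifType.LINKER_IV and right_t is MotifType.POLY_A_E:
            ok = _ga_pure_enough(gap, cfg.max_impurity_frac) and (
                "S" in gap or not cfg.require_ser
            )
            regions.append((MotifType.GA_SER if ok else MotifType.UNASSIGNED, gap_iv))
        else:
            regions.append((MotifType.UNASSIGNED, gap_iv))
    regions.append(anchors[-1])

    # Close the final unit: {G,A,S} run directly after a trailing linker.
    tail_start = anchors[-1][1][1]
    if anchors[-1][0] is MotifType.LINKER_IV and tail_start < len(protein):
        run_end = tail_start
        while run_end < len(protein) and protein[run_end] in "GAS":
            run_end += 1
        if run_end > tail_start:
            tail = protein[tail_start:run_end]
            ok = "S" in tail or not cfg.require_ser
            regions.append(
                (
                    MotifType.GA_SER if ok else MotifType.UNASSIGNED,
                    (tail_start, run_end),
                )
            )

    domain_start = regions[0][1][0]
    domain_end = regions[-1][1][1]
    out: list[tuple[MotifType, Interval]] = []
    if domain_start > 0:
        out.append((MotifType.TERMINAL, (0, domain_start)))
    out.extend(regions)
    if domain_end < len(protein):
        out.append((MotifType.TERMINAL, (domain_end, len(protein))))
    return Segmentation(protein_id, out, (domain_start, domain_end))


def split_repeat_units(seg: Segmentation) -> list[RepeatUnit]:
    """Decompose a segmentation into repeat units.

    A unit opens at each POLY_A_E region and closes before the next one; the
    trailing partial unit is kept with whatever types it contains.
    """
    units: list[RepeatUnit] = []
    current: list[tuple[MotifType, Interval]] = []
    for motif, iv in seg.regions:
        if motif is MotifType.POLY_A_E:
            if current:
                units.append(_close_unit(len(units), current))
            current = [(motif, iv)]
        elif motif in CANONICAL_ORDER and current:
            current.append((motif, iv))
    if current:
        units.append(_close_unit(len(units), current))
    return units


def _close_unit(index: int, spans: list[tuple[MotifType, Interval]]) -> RepeatUnit:
    return RepeatUnit(index, spans, (spans[0][1][0], spans[-1][1][1]))


def motif_length_stats(
    segmentations: Mapping[str, Sequence[Segmentation]],
) -> ArchitectureStats:
    """Per-species, per-motif length distributions.

    Returns a long-format length table and a summary with n, mean, median
    and quartiles, ordered by species then motif name (both alphabetical).
    Species/motif combinations with no regions appear with n=0 and NaN
    statistics.
    """
    if not segmentations:
        raise InputError("at least one species is required")
    rows = []
    for species in sorted(segmentations):
        segs = segmentations[species]
        if not segs:
            raise InputError(f"species {species!r} has no segmentations")
        for seg in segs:
            for motif, (s, e) in seg.typed_regions():
                rows.append((species, motif.value, e - s))
    lengths = pd.DataFrame(rows, columns=["species", "motif", "length"])
    motifs = sorted(m.value for m in CANONICAL_ORDER)
    summary_rows = []
    for species in sorted(segmentations):
        for motif in motifs:
            vals = lengths.query(
                "species == @species and motif == @motif"
            )["length"].to_numpy(dtype=float)
            if vals.size:
                summary_rows.append(
                    (
                        species,
                        motif,
                        vals.size,
                        float(np.mean(vals)),
                        float(np.median(vals)),
                        float(np.percentile(vals, 25)),
                        float(np.percentile(vals, 75)),
                    )
                )
            else:
                summary_rows.append(
                    (species, motif, 0, np.nan, np.nan, np.nan, np.nan)
                )
    summary = pd.DataFrame(
        summary_rows,
        columns=["species", "motif", "n", "mean", "median", "q1", "q3"],
    )
    return ArchitectureStats(lengths=lengths, summary=summary)


def aa_frequency(protein_region: str) -> np.ndarray:
    """Amino-acid frequency vector over the 20 standard residues.

    Components are ordered alphabetically (ACDEFGHIKLMNPQRSTVWY) and sum
    to 1.  Residues outside the standard alphabet are rejected.
    """
    if not protein_region:
        raise InputError("region must be non-empty")
    counts = np.zeros(20, dtype=float)
    for aa in protein_region.upper():
        idx = _AA_INDEX.get(aa)
        if idx is None:
            raise InputError(f"non-standard residue {aa!r}")
        counts[idx] += 1
    return counts / counts.sum()


def repetitive_domain_sequence(protein: str, seg: Segmentation) -> str:
    """Concatenated canonical-motif residues of a segmented protein."""
    return "".join(protein[s:e] for _, (s, e) in seg.typed_regions())


def crystalline_fraction(unit: RepeatUnit) -> float:
    """Predicted crystalline (beta-sheet) fraction of one repeat unit.

    The poly-A-E and pure-GA spans count as crystalline; the linker and
    serine-containing GA spans as amorphous.
    """
    span = unit.unit_span
    total = span[1] - span[0]
    if total <= 0:
        raise InputError("zero-length unit")
    if unit.span_of(MotifType.POLY_A_E) is None or unit.span_of(
        MotifType.GA_PURE
    ) is None:
        raise InputError("unit must contain POLY_A_E and GA_PURE spans")
    crystalline = sum(
        e - s for m, (s, e) in unit.spans if m in CRYSTALLINE_TYPES
    )
    return crystalline / total


def protein_crystalline_fraction(units: Iterable[RepeatUnit]) -> float:
    """Length-weighted mean crystalline fraction over a protein's units."""
    units = list(units)
    if not units:
        raise InputError("no repeat units")
    weights = np.array([u.unit_span[1] - u.unit_span[0] for u in units], float)
    fracs = np.array([crystalline_fraction(u) for u in units])
    return float(np.average(fracs, weights=weights))


def segmentation_to_table(seg: Segmentation) -> pd.DataFrame:
    """BED-like table (id, start, end, motif_type) for one segmentation."""
    return pd.DataFrame(
        [
            (seg.protein_id, s, e, m.value)
            for m, (s, e) in seg.regions
        ],
        columns=["protein_id", "start", "end", "motif_type"],
    )
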