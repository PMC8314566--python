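"""Synthetic fibroin genes, short reads and mechanics tables.

The generator emulates the architecture of a bagworm H-fibroin: unique
N- and C-terminal domains flanking a tandem array of repeat units, each
unit ordered poly-A-with-central-E -> pure GA -> I/V linker -> serine-
containing GA.  Reads are uniform-coverage substitution-error 150-mers,
and the mechanics tables carry per-fibre tensile measurements whose
species means follow a configurable (by default negative) line in the
crystalline fraction.  Everything is bit-reproducible under a seed, so
curation, segmentation and statistics can all be tested against known
ground truth without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .architecture import Interval, MotifType
from .errors import InputError, ParameterError

# aa -> codons, alphabetical within each residue
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ArchitectureParams:
    """Repeat-unit geometry of a simulated H-fibroin.

    Defaults follow the bagworm consensus architecture: a 23-residue
    (A)11-E-(A)11 block, a 40-residue pure GA region, a 6-residue I/V
    linker and a 90-residue serine-containing GA region per unit.  Jitter
    is a per-unit multiplicative half-width applied to the GA and linker
    lengths only; the poly-A-E block is held at its fixed length, matching
    its conserved 23-residue size across species.
    """

    n_units: int = 5
    polyA_half_len: int = 11
    ga_pure_len: int = 40
    linker_len: int = 6
    ga_ser_len: int = 90
    ser_rate: float = 0.2
    jitter: float = 0.1
    n_term_len: int = 120
    c_term_len: int = 120

    def validate(self) -> None:
        if self.n_units < 1:
            raise ParameterError("n_units must be >= 1")
        if self.polyA_half_len < 1:
            raise ParameterError("polyA_half_len must be >= 1")
        if self.ga_pure_len < 2 or self.ga_pure_len % 2:
            raise ParameterError("ga_pure_len must be an even integer >= 2")
        if self.linker_len < 2:
            raise ParameterError("linker_len must be >= 2")
        if self.ga_ser_len < 2 or self.ga_ser_len % 2:
            raise ParameterError("ga_ser_len must be an even integer >= 2")
        if not (0.0 < self.ser_rate <= 0.5):
            raise ParameterError("ser_rate must be in (0, 0.5]")
        if not (0.0 <= self.jitter < 0.5):
            raise ParameterError("jitter must be in [0, 0.5)")
        if self.n_term_len < 0 or self.c_term_len < 0:
            raise ParameterError("n_term_len/c_term_len must be >= 0")

    @property
    def polyA_total_len(self) -> int:
        """Full (A)nE(A)n block length, central E included."""
        return 2 * self.polyA_half_len + 1


@dataclass
class SimulatedFibroinGene:
    """A simulated gene together with its ground-truth annotation."""

    gene_id: str
    protein: str
    cds: str | None
    n_term_span: Interval
    c_term_span: Interval
    unit_spans: list[Interval]
    region_truth: list[list[tuple[MotifType, Interval]]]

    def flat_truth(self) -> list[tuple[MotifType, Interval]]:
        return [r for unit in self.region_truth for r in unit]


@dataclass(frozen=True)
class ReadSimParams:
    """Uniform-coverage substitution-only short-read simulation settings."""

    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.0
    rng_seed: int = 0
    both_strands: bool = True

    def validate(self) -> None:
        if self.read_length < 1:
            raise ParameterError("read_length must be >= 1")
        if self.coverage <= 0:
            raise ParameterError("coverage must be > 0")
        if not (0.0 <= self.error_rate < 0.1):
            raise ParameterError("error_rate must be in [0, 0.1)")


@dataclass
class Read:
    """One simulated read, FASTQ-writable."""

    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class MechRecord:
    """One tensile measurement of one fibre of one species."""

    species: str
    tensile_strength: float  # MPa
    youngs_modulus: float  # GPa
    extensibility: float  # %
    toughness: float  # MJ/m^3


@dataclass(frozen=True)
class CrystallinityRecord:
    species: str
    crystalline_fraction: float  # dimensionless, [0, 1]


@dataclass(frozen=True)
class MechSimSpec:
    """Study design for the synthetic mechanics tables.

    Species-mean tensile strength follows
    ``strength_intercept + strength_slope * crystalline_fraction`` and the
    default slope is negative: fibres from species with a larger predicted
    crystalline fraction break at lower stress.  Per-fibre values are drawn
    from normals around the species means, truncated at zero.
    """

    crystalline_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "species_A": 0.25,
            "species_B": 0.35,
            "species_C": 0.45,
            "species_D": 0.55,
            "species_E": 0.65,
        }
    )
    n_fibres: int = 8
    strength_intercept: float = 1800.0  # MPa at zero crystallinity
    strength_slope: float = -2000.0  # MPa per unit crystalline fraction
    strength_sd: float = 50.0
    modulus_mean: float = 8.0  # GPa
    modulus_sd: float = 1.0
    extensibility_mean: float = 25.0  # %
    extensibility_sd: float = 3.0
    toughness_mean: float = 120.0  # MJ/m^3
    toughness_sd: float = 15.0

    def validate(self) -> None:
        for name in (
            "strength_sd",
            "modulus_sd",
            "extensibility_sd",
            "toughness_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_fibres < 1:
            raise ParameterError("n_fibres must be >= 1")
        for sp, f in self.crystalline_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ParameterError(
                    f"crystalline_fractions[{sp!r}] must be in [0, 1]"
                )


def _ga_pure(length: int) -> str:
    return "GA" * (length // 2)


def _linker(length: int) -> str:
    return ("IV" * ((length + 1) // 2))[:length]


def _ga_ser(length: int, ser_rate: float) -> str:
    """GA alternation with serines substituted at evenly spaced positions.

    The alternation restarts with G after each serine, so the region is a
    tandem of G-led GA blocks punctuated by S (e.g. length 10, rate 0.4
    gives ``GASGAGASGA``).
    """
    n_ser = max(1, round(ser_rate * (length // 2)))
    ser_at = {int((i + 0.5) * length / n_ser) for i in range(n_ser)}
    out: list[str] = []
    toggle = "G"
    for pos in range(length):
        if pos in ser_at:
            out.append("S")
            toggle = "G"
        else:
            out.append(toggle)
            toggle = "A" if toggle == "G" else "G"
    return "".join(out)


def _poly_a_e(half_len: int) -> str:
    return "A" * half_len + "E" + "A" * half_len


_TERMINAL_AA = "CDEFGHIKLMNPQRSTWY"  # A, I, V handled via constraints


def _random_terminal(
    length: int,
    rng: np.random.Generator,
    forbid_last_a: bool = False,
    first_not_gas: bool = False,
) -> str:
    """Random low-alanine terminal domain.

    Alanine frequency is capped well below 5% and consecutive A or
    consecutive I/V pairs are forbidden, so terminal domains can never
    satisfy the poly-A or linker anchor detectors.  Optional boundary
    guards keep the junctions with the repetitive domain unambiguous.
    """
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    weights = np.ones(20)
    weights[alphabet.index("A")] = 0.3  # ~1.6% alanine
    weights /= weights.sum()
    out: list[str] = []
    while len(out) < length:
        aa = alphabet[int(rng.choice(20, p=weights))]
        prev = out[-1] if out else ""
        if aa == "A" and prev == "A":
            continue
        if aa in "IV" and prev in "IV":
            continue
        if not out and first_not_gas and aa in "GAS":
            continue
        out.append(aa)
    if forbid_last_a and out and out[-1] == "A":
        out[-1] = "Q"
    return "".join(out)


def _jittered(nominal: int, jitter: float, rng: np.random.Generator, even: bool) -> int:
    if jitter == 0:
        return nominal
    raw = nominal * rng.uniform(1.0 - jitter, 1.0 + jitter)
    if even:
        return max(2, 2 * round(raw / 2))
    return max(2, round(raw))


def generate_fibroin_protein(
    params: ArchitectureParams, rng_seed: int = 0, gene_id: str = "synth_fibroin"
) -> SimulatedFibroinGene:
    """Generate a fibroin protein with exact ground-truth region spans.

    Each unit is ``A^h E A^h`` + ``(GA)^(g/2)`` + an I/V alternation +
    a serine-substituted GA alternation; jitter perturbs the GA and linker
    lengths per unit while the poly-A-E block stays fixed.  Terminal
    domains (if enabled) are seeded random low-alanine sequences.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    n_term = (
        _random_terminal(params.n_term_len, rng, forbid_last_a=True)
        if params.n_term_len
        else ""
    )
    parts = [n_term]
    pos = len(n_term)
    unit_spans: list[Interval] = []
    region_truth: list[list[tuple[MotifType, Interval]]] = []
    for _ in range(params.n_units):
        ga_pure = _jittered(params.ga_pure_len, params.jitter, rng, even=True)
        linker = _jittered(params.linker_len, params.jitter, rng, even=False)
        ga_ser = _jittered(params.ga_ser_len, params.jitter, rng, even=True)
        segments = [
            (MotifType.POLY_A_E, _poly_a_e(params.polyA_half_len)),
            (MotifType.GA_PURE, _ga_pure(ga_pure)),
            (MotifType.LINKER_IV, _linker(linker)),
            (MotifType.GA_SER, _ga_ser(ga_ser, params.ser_rate)),
        ]
        unit_start = pos
        truth: list[tuple[MotifType, Interval]] = []
        for motif, seq in segments:
            truth.append((motif, (pos, pos + len(seq))))
            parts.append(seq)
            pos += len(seq)
        unit_spans.append((unit_start, pos))
        region_truth.append(truth)
    c_term = (
        _random_terminal(params.c_term_len, rng, first_not_gas=True)
        if params.c_term_len
        else ""
    )
    parts.append(c_term)
    protein = "".join(parts)
    return SimulatedFibroinGene(
        gene_id=gene_id,
        protein=protein,
        cds=None,
        n_term_span=(0, len(n_term)),
        c_term_span=(pos, pos + len(c_term)),
        unit_spans=unit_spans,
        region_truth=region_truth,
    )


def reverse_translate(
    protein: str,
    codon_policy: str = "first_codon",
    rng_seed: int = 0,
) -> str:
    """Back-translate a protein under the standard genetic code.

    ``first_codon`` deterministically picks the alphabetically first codon
    of each residue (this makes protein-level tandem repeats exact
    nucleotide repeats, which the curation repeat detector relies on);
    ``uniform_random`` draws codons uniformly and reproducibly under
    ``rng_seed``.
    """
    if codon_policy not in ("first_codon", "uniform_random"):
        raise ParameterError(f"unknown codon_policy {codon_policy!r}")
    protein = protein.upper()
    rng = np.random.default_rng(rng_seed)
    codons: list[str] = []
    for aa in protein:
        options = _CODONS.get(aa)
        if options is None:
            raise InputError(f"non-standard residue {aa!r}")
        if codon_policy == "first_codon":
            codons.append(options[0])
        else:
            codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def generate_fibroin_gene(
    params: ArchitectureParams,
    rng_seed: int = 0,
    codon_policy: str = "first_codon",
    gene_id: str = "synth_fibroin",
) -> SimulatedFibroinGene:
    """Protein + CDS in one call; translate(cds) == protein by construction."""
    gene = generate_fibroin_protein(params, rng_seed, gene_id)
    gene.cds = reverse_translate(gene.protein, codon_policy, rng_seed)
    assert str(Seq(gene.cds).translate()) == gene.protein
    return gene


def simulate_reads(template: str, params: ReadSimParams) -> list[Read]:
    """Uniform-coverage substitution-error reads from one template.

    Read count is ``round(coverage * len(template) / read_length)``; start
    positions are uniform, each read is reverse-complemented with
    probability 1/2 when ``both_strands`` is set, and substitutions are
    i.i.d. at ``error_rate`` to a uniformly chosen different base.
    Qualities are constant 'I' (Q40) — the pipeline never consumes them,
    but the FASTQ must be well-formed.
    """
    params.validate()
    template = template.upper()
    if len(template) < params.read_length:
        raise InputError("template shorter than read_length")
    rng = np.random.default_rng(params.rng_seed)
    n_reads = round(params.coverage * len(template) / params.read_length)
    starts = rng.integers(0, len(template) - params.read_length + 1, n_reads)
    qual = "I" * params.read_length
    reads: list[Read] = []
    for i, start in enumerate(starts):
        seq = template[start : start + params.read_length]
        strand = "+"
        if params.both_strands and rng.random() < 0.5:
            seq = str(Seq(seq).reverse_complement())
            strand = "-"
        if params.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(params.read_length) < params.error_rate)
            for j in hits:
                choices = _BASES[_BASES != arr[j]]
                arr[j] = choices[int(rng.integers(3))]
            seq = arr.tobytes().decode()
        reads.append(Read(f"read_{i}:{start}:{strand}", seq, qual))
    return reads


def generate_mech_dataset(
    spec: MechSimSpec | None = None, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic per-fibre mechanics table plus crystallinity table.

    Returns ``(mech, cryst)`` data frames; ``mech`` has one row per fibre
    with the four tensile properties, ``cryst`` one row per species.
    """
    spec = spec or MechSimSpec()
    spec.validate()
    rng = np.random.default_rng(rng_seed)
    mech_rows = []
    cryst_rows = []
    for species in sorted(spec.crystalline_fractions):
        frac = spec.crystalline_fractions[species]
        cryst_rows.append((species, frac))
        mean_strength = spec.strength_intercept + spec.strength_slope * frac

        def draw(mean: float, sd: float) -> np.ndarray:
            if sd == 0:
                return np.full(spec.n_fibres, max(mean, 0.0))
            return np.clip(rng.normal(mean, sd, spec.n_fibres), 0, None)

        strengths = draw(mean_strength, spec.strength_sd)
        moduli = draw(spec.modulus_mean, spec.modulus_sd)
        exts = draw(spec.extensibility_mean, spec.extensibility_sd)
        toughs = draw(spec.toughness_mean, spec.toughness_sd)
        for s, m, e, t in zip(strengths, moduli, exts, toughs):
            mech_rows.append((species, float(s), float(m), float(e), float(t)))
    mech = pd.DataFrame(
        mech_rows,
        columns=[
            "species",
            "tensile_strength",
            "youngs_modulus",
            "extensibility",
            "toughness",
        ],
    )
    cryst = pd.DataFrame(cryst_rows, columns=["species", "crystalline_fraction"])
    return mech, cryst


def truth_table(gene: SimulatedFibroinGene) -> pd.DataFrame:
    """Ground-truth segmentation as a BED-like table."""
    return pd.DataFrame(
        [
            (gene.gene_id, s, e, m.value)
            for m, (s, e) in gene.flat_truth()
        ],
        columns=["gene_id", "start", "end", "motif_type"],
    )


def two_species_params(
    base: ArchitectureParams | None = None,
) -> dict[str, ArchitectureParams]:
    """The default two-species contrast: GA regions of full vs half length.

    Mirrors the bagworm comparison in which one species' GA motifs are
    about half the length of the others' while the poly-A-E block is
    conserved.
    """
    base = base or ArchitectureParams()
    return {
        "species_long_GA": base,
        "species_short_GA": replace(
            base,
            ga_pure_len=base.ga_pure_len // 2,
            ga_ser_len=base.ga_ser_len // 2,
        ),
    }
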