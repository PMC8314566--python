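# Methods

## The model

A bagworm-type H-fibroin is modelled as

    N-terminal domain · (repeat unit)^n · C-terminal domain

with each repeat unit the ordered concatenation of four motif regions:

1. **poly-A-E** — `A^h E A^h`, a polyalanine run with a single central
   glutamic acid (default h = 11, total 23 residues);
2. **pure GA** — an even-length glycine–alanine alternation starting with
   G (default 40 residues);
3. **I/V linker** — an isoleucine/valine alternation (default 6 residues);
4. **GA-S** — an even-length GA alternation carrying serines at evenly
   spaced positions, with the alternation restarting at G after each S
   (default 90 residues; `ser_rate` = 0.2 of the region's A slots).

The poly-A-E and pure-GA regions are counted as crystalline (β-sheet
forming in spun fibre), the linker and GA-S regions as amorphous. The
crystalline fraction of a unit is the crystalline length over the unit
length; a protein's value is the length-weighted mean over its units.

Terminal domains are seeded random sequences with alanine frequency
kept below 5% and with no AA or I/V–I/V dinucleotide-style pairs, so they
can never satisfy the repeat-region detectors; the residues flanking the
repetitive domain are additionally constrained (no trailing A on the
N-terminal side, no leading G/A/S on the C-terminal side) so the
junctions stay unambiguous.

### Length jitter

`jitter` is a per-unit multiplicative half-width applied to the GA and
linker lengths only (uniform on `[1-j, 1+j]`, GA lengths re-rounded to
even). The poly-A-E block is held fixed, mirroring its conserved
23-residue size across species while the GA regions vary. The default
jitter of 0.1 is a design choice (no per-unit variance is published);
it is surfaced in the configuration and set to 0 for exact-recovery
tests.

## Read simulation

Reads are single 150-mers at uniform random start positions,
reverse-complemented with probability 1/2, with i.i.d. substitutions at
`error_rate` to a uniformly chosen different base; no indels, no
quality model (constant Q40), no paired-end structure — the curation
algorithm consumes reads individually. Read count is
`round(coverage · template_length / read_length)`. Note that under
uniform starts the expected depth decays linearly over the final
`read_length` bases of the template (the last base is covered only by
reads starting at the single last valid position); zero-error
full-template reconstruction checks therefore run with `min_depth = 1`.

## Segmentation

An anchor pass locates all poly-A(-E) runs (maximal A-runs ≥ 4,
optionally spanning exactly one E with runs ≥ 4 on both sides) and all
I/V runs (≥ 2). Gaps between successive anchors are then typed by
position — poly-A→linker gaps are pure GA, linker→poly-A gaps are GA-S —
with composition used only for validation: a gap must be ≥ 90% from
{G, A, S}, and a GA-S gap must contain a serine (`require_ser`); failing
gaps are UNASSIGNED. Residues outside the repetitive domain are
TERMINAL.

Two boundary rules close genuinely ambiguous cases:

* the GA-S region ends in `…GA`, so its final alanine abuts the next
  unit's poly-A run; because the glutamic acid sits at the centre of the
  poly-A block, an anchor whose left A-run outruns its right one has the
  excess leading alanines returned to the preceding gap;
* the final unit's GA-S region has no following poly-A anchor; the
  maximal {G, A, S} run directly after the last linker anchor closes it.

With these rules, segmentation of generator output reproduces the
ground-truth annotation exactly at any jitter, which the test suite
asserts.

`min_polyA_run = 4` guarantees the isolated alanines of a GA alternation
can never seed a poly-A anchor; `min_linker_run = 2` accepts the
shortest valid linker.

## Seed-extension curation

Seeds are contigs reaching a Smith–Waterman local-alignment score
threshold against a reference terminal domain (+2/−3, gaps −5/−2 in
nucleotide mode; BLOSUM62 with −11/−1 over three frames per strand in
translated mode), strand-normalised so extension runs 3′-ward. The
C-terminal side is curated by reverse-complementing the inputs.

Extension is base by base: all reads containing the current terminal
k-mer (k = 75, half a read) are anchored at the exact match, their votes
one position past the 3′ end form a PWM column, and the modal base is
appended iff depth ≥ `min_depth` (3) and the modal fraction ≥
`min_dominant_frac` (0.9), both inclusive; a tied mode is AMBIGUOUS,
never an arbitrary pick. Reads are re-harvested after every appended
base, so each column sees the fullest anchor set. Because anchoring
requires an exact 75-mer, reads with any error inside the anchor window
are excluded from voting, which is what keeps miscall rates negligible
at realistic error rates; raising either threshold can only shorten the
extension (monotonicity, asserted in tests).

Termination is NO_READS (no votes past the 3′ end), LOW_DEPTH or
AMBIGUOUS (threshold failure), MAX_LENGTH (cap, default 100 kb), or
REPEAT_DETECTED: the terminal `repeat_window`-mer already occurs earlier
in the curated sequence. A window of length w recurs inside a tract of
nucleotide period p once w + p bases of the tract have been curated, so
the stop lands just inside the first repeat tract. The default window
(25 nt) is deliberately much smaller than k: it fires inside the
shortest default tract (the 33-nt poly-A run, period 3 under first-codon
back-translation), while the 75-nt anchor still overlaps unique
sequence. Setting `repeat_window = k` instead ends extension with an
AMBIGUOUS verdict slightly past the repeat entry — the anchor itself
goes multi-mapping first — which is why the smaller window is the
default.

Back-translation policy matters here: `first_codon` (alphabetically
first codon per residue) makes protein-level repeats exact nucleotide
repeats, the regime the repeat detector is built for; `uniform_random`
produces nucleotide-diverse repeats and is available for composition
work.

## Statistics

* Amino-acid frequency vectors are 20-component, alphabetically ordered,
  summing to 1; between-species comparison uses the Pearson
  product-moment correlation with a two-sided t-transform p-value.
* Group comparisons of tensile properties use Welch's unequal-variance
  t-test (two-sided, Welch–Satterthwaite df): fibre groups have unequal
  n and variance, so the pooled-variance form is not assumed.
* The crystallinity trend joins the mechanics and crystallinity tables
  on species, averages each property per species (one point per
  species), and reports Pearson r, the least-squares slope, and whether
  the species ranking by crystalline fraction is strictly decreasing in
  the property.
* No multiple-testing correction is applied; p-values are reported raw,
  and outputs say so.

The synthetic mechanics generator draws per-fibre values from normals
around species means (clipped at zero), with species-mean strength on
the configured line `intercept + slope · crystalline_fraction`
(defaults: 1800 MPa, −2000 MPa per unit fraction, SD 50 MPa, 8 fibres
per species across 5 species with fractions 0.25–0.65, moduli ~8 GPa,
extensibility ~25%, toughness ~120 MJ/m³).

## Reproducibility and problem sizes

Every stochastic step takes an explicit integer seed; the pipeline
derives stage seeds from one global seed and repeated runs are
byte-identical (the run report's timestamp is omitted unless requested).
The test suite and acceptance script work at desk scale: 3-kb genes
(five 159-residue units plus 120-residue terminals), 30–50× read sets,
20 seeded curation replicates for the noise-robustness check, and 100
replicate mechanics tables for the trend-recovery check.

## What the synthetic data does not show

The generator emulates motif order, length variation, substitution
noise and a linear strength–crystallinity relationship. It does not
model indels, coverage bias, chimeric or paired reads, codon usage of
real species, inter-unit sequence divergence (units are identical up to
length jitter, the hardest case for assembly but the easiest for exact
repeat detection), or any mechanistic link between architecture and
mechanics beyond the configured line. Passing tests therefore
demonstrate algorithmic correctness under the stated model, not
biological validity of the crystallinity–strength relationship, which
in the source material rests on X-ray scattering and tensile data.
Wet-lab quantities (absolute strengths, moduli) are inputs here, never
predictions.
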