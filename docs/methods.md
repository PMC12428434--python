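# Methods

This note documents the models and procedures implemented in `mitocr`, the
parameter choices that matter, the numerical conventions, and the limits of
what the synthetic-data tests demonstrate.

## Coordinates, feature tables, partition totals

All external coordinates are 1-based and inclusive, matching published
mitogenome feature tables. The `Size` and `Intergenics` columns of a feature
table are treated as advisory: published tables are not always internally
consistent (adjacent-gene overlaps are sometimes printed with a different
sign convention than simple coordinate arithmetic gives), so coordinates are
authoritative and disagreements raise warnings rather than errors. The
intergenic gap between consecutive features is `next.start − prev.end − 1`;
negative values are overlaps. Genome length without a sequence is the
maximum end coordinate. Per-class totals count overlapping features
per-feature, without deduplication — this matches how per-class totals are
conventionally tallied from table columns (e.g. ATP8/ATP6 and ND4L/ND4
overlaps are counted twice in the protein-coding total).

Incomplete terminal codons (`T--`, `TA-`, `AG-`) count as one codon; this is
the only reading under which the per-gene sizes of a typical 13-gene
vertebrate set sum to the conventional total codon count.

## Composition and codon usage

Skews are AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C). N bases
are excluded from all denominators and reported separately; a skew whose
denominator is zero is `None`, never coerced to 0. The vertebrate
mitochondrial code (NCBI translation table 2, via Biopython) is the only
built-in code; the genes analysed are all mitochondrial. RSCU excludes stop
codons by default (they are not synonymous alternatives of an amino acid);
an `include_stops` flag adds the four-codon stop family for studies that
report raw stop-codon usage. Within a family with nonzero total, RSCU values
average to 1 exactly; codons of entirely unused families are `None` (0/0
carries no preference information).

## Control-region landmarks

The motif engine matches ordered element lists: literal k-mers, alternations
of literals, and bounded wildcard gaps. Defaults (spec-string form):

```
TAS     = ATG N(8,9) CAT|TAT
CSB-D   = TTC|TTA N(11,11) TTC|CTC
CSB-I   = ATA N(15,15) ATA
CSB-II  = AAACCCC N(4,4) CCCCC
CSB-III = AAACCCCC
OL-motif = GCGGG
```

In the CSB-D query the alternation binds to the single adjacent base
(`TT(C|A)`, `(T|C)TC`); this is the consistent reading given that the TAS
alternation spans a full 3-mer, and both readings can be expressed through
the pattern-spec strings if a user disagrees. N in the *scanned* sequence
matches only gaps, never literals. All overlapping hits are reported (no
greedy masking — multiple TAS sites are biologically expected); at a fixed
start, a variable-gap pattern collapses to its shortest expansion. Scanning
is single-strand by default (CRs are conventionally reported on one strand);
`both_strands=True` is available. The T-homopolymer is any maximal run of
≥ 6 T. VR3 is delimited as everything after the last CSB-III hit; VR1/VR2
have no operational definition in the literature precise enough to compute,
so they are deliberately not reported.

## Tandem-repeat arrays and heteroplasmy patterns

Detection is deterministic seed-and-extend. Candidate periods are distances
d ∈ [`min_unit`, `max_unit`] between **consecutive** occurrences of an exact
10-mer (non-consecutive pairs only add harmonics). From each seed, the array
grows unit-by-unit in both directions while every added unit keeps
per-unit identity ≥ `min_identity` (default 0.85) to the running majority
consensus (column ties keep the earliest unit's base). Two refinements deal
with the self-similarity of tandem arrays:

- *Period reduction*: an array grown at a multiple of a smaller admissible
  period is re-grown at that smaller period from its cleanest sub-unit.
  Harmonic periods otherwise absorb edge noise, since most of their
  positions match by construction.
- *Seed skipping*: a seed inside an already-built array at the same period
  and phase (or at a multiple of the built period) is skipped — re-growing
  it reproduces the built array or a harmonic of it.

Overlapping arrays are resolved by longest span, then smallest unit, then
**fewest total mismatches to the array consensus**, then leftmost start.
The mismatch criterion is load-bearing: a decomposition phase-shifted into
the flank has the same span and unit length as the true one, and leftmost
alone would systematically prefer the shifted variant whenever the flank
base adjacent to the array happens to extend a unit. Where two decompositions
are *genuinely* equally good (identical length, unit and mismatch count —
e.g. a perfect terminal partial copy, which makes the unit phase rotationally
ambiguous), leftmost decides, deterministically.

A flanking segment matching a unit prefix (3' side) or suffix (5' side) at
≥ 0.90 identity over ≥ 20 bp is attached as an imperfect partial copy; it
never counts toward the copy number (copy numbers are complete-unit counts;
a flag includes it for studies that count otherwise). The matched length is
the longest window above the identity floor, which can overshoot a perfect
partial copy by a few bases when similar flank sequence follows it; in the
synthetic cohort the partial copy ends the molecule, so recovery is exact.

Unit typing is by exact sequence identity — no clustering threshold — since
the types of interest differ at one to three fixed sites. T1 is the modal
unit across the cohort (overridable via `reference_unit`); remaining labels
rank by descending frequency, ties by first occurrence. Array phases are
aligned by best circular rotation against the modal unit before typing.

Pattern labels (P1, P2, …) attach to distinct run-length encodings in order
of first occurrence. Mechanism calls: pure patterns are
*slippage-consistent*; a heterogeneous pattern is *recombination-supported*
iff every constituent type also occurs as a pure pattern in ≥ 1 other
individual (both donor haplotypes demonstrably exist in the population);
remaining heterogeneous patterns are *slippage-or-unknown*.

## Gene order

The canonical vertebrate order is the 39-token circle
F 12S V 16S L1 ND1 I Q M ND2 W A N OL C Y COX1 S2 D COX2 K ATP8 ATP6 COX3 G
ND3 R ND4L ND4 H S1 L2 ND5 ND6 E CYTB T P CR, with Q, A, N, OL, C, Y, S2,
ND6, E and P on the light strand. Signatures rotate to tRNA-Phe (else 12S);
noncoding segments ≥ 30 bp participate as NC tokens, smaller spacers are
ignored. Event classification runs in a fixed greedy order — copy-number
differences (duplication/loss), strand switches (inversion), then the
residual permutation gene-by-gene via a longest-common-subsequence frame:
displacement ≤ 3 positions (circular) is reshuffling, more is translocation.
The 3-position window matches the scale of the documented tRNA-cluster swaps
(IQM→QIM, His-Ser-Leu→Ser-Leu-His) versus genuine cross-genome moves, and is
a configurable knob. The decomposition is deterministic; it does not claim
event-count minimality (no breakpoint/DCJ optimisation).

## Evolutionary statistics

**K2P.** Transitions are A↔G and C↔T. Sites with non-ACGT in either
sequence are excluded (pairwise deletion — the usual default when the
alternative is unstated). `d = −½ ln((1 − 2P − Q)√(1 − 2Q))`; a non-positive
log argument is reported as a flagged undefined result, never a silent NaN.

**NJ.** Saitou–Nei agglomeration with criterion
`Q_ij = (n−2)d_ij − r_i − r_j`, ties broken by the smallest index pair, the
final three-taxon join in closed form, and a single-edge tree for two taxa
as a convenience. Negative branch lengths are retained and flagged
(traceability over aesthetics); `clamp=True` sets them to 0. On additive
matrices the generating topology and branch lengths are recovered exactly
(tested against 50 random trees and cross-checked against scikit-bio's NJ).

**Ka/Ks.** The estimator is the classic unweighted pathway-counting method
under the vertebrate mitochondrial code. Site counting excludes mutations to
stop codons from each position's denominator, so S + N = 3 × codons holds
identically. Codon pairs with non-ACGT bases or aligned stops are excluded
and counted. Multi-difference codons average over the substitution orderings
that avoid stops; if every ordering passes through a stop, all orderings are
used. Both proportions receive the Jukes–Cantor correction; p ≥ 0.75 is
flagged undefined. Ka/Ks with Ks = 0 is `None` by default (configurable).
The concatenated-gene profile row pools site and difference counts across
genes — it is not the mean of per-gene ratios. Exact reproduction of any
particular published Ka/Ks table is not claimed: pairwise Ka/Ks methods
differ in site weighting (transition bias, unequal codon frequencies), and
the estimator here is the transparent, well-specified baseline. With a
transition bias (κ > 1) it carries the known mild downward bias on ω.

## Synthetic data: what it emulates and what it does not

All generators are driven by `numpy.random.default_rng(seed)` and are
byte-reproducible from (seed, parameters).

*Control regions* use i.i.d. background at CR-like composition (A 37.7 %,
C 19.3 %, G 14.2 %, T 28.8 %; A+T ≈ 66.5 %) with non-overlapping planted
instances; default spec: 3 TAS, 1 CSB-II, 1 CSB-III, 1 T-homopolymer and no
CSB-D, mirroring a teleost CR in which CSB-D is not identifiable. Background
positions inside any unplanted motif hit are re-drawn until only the planted
instances remain (capped; an infeasible spec errors out) — negative controls
are guaranteed, not probable.

*Repeat cohorts* default to the study conditions: 19 individuals, 107 bp
units (52 bp upstream + 55 bp downstream part), 8 types — T1 plus five
1-substitution, one 2-substitution (T6) and one 3-substitution (T4)
variants — 10 patterns (5 pure, 5 two-type heterogeneous), copy numbers
3×1 / 4×12 / 5×5 / 6×1, a 256 bp pre-repeat flank, and a 3'-terminal
imperfect copy consisting of the complete upstream part plus the first five
downstream bases (57 bp). The heterogeneous patterns mixing T1 and T3 are
the recombination-supported ones; the other three mix a type never seen
pure. Two identifiability constraints are built in deliberately: variant
sites are planted in the central window of the unit (clear of the leading
partial-copy-length and the trailing identity-slack bases), because an edge
difference can be rotated out of the array by an equally consistent
phase-shifted decomposition — the planted phase would then not be a
well-defined truth; and the flank is re-drawn until it shares no 10-mer with
the repeat region, its final base differs from the unit's final base, and it
contains no internal 10-mer duplication at a seedable distance. These
constraints make "exact recovery" a meaningful target. Real flanks are not
guaranteed any of this; on real data, array *boundaries* may be off by a few
bases where flank sequence happens to extend the periodicity, while type
census and pattern structure are robust to it.

*Gene orders* apply named single events (cluster swap, long-range move, tRNA
duplication, strand flip, OL loss) to the canonical order; the default
10-genome fixture yields 7 distinct arrangements.

*Codon evolution* draws a uniform sense-codon ancestor and applies
single-base proposals (transition weight κ, default 2) with stops rejected,
synonymous changes always accepted and nonsynonymous accepted with
probability ω, until accepted synonymous substitutions reach
`target_ks × S_sites(ancestor)` (default 0.3; a guard rejects saturating
targets). This is a star-pair simulation: no rate variation among sites, no
codon-frequency bias, no phylogenetic structure. It suffices for recovery
checks (planted ω = 0.2 is recovered within ±50 % at 5,000 codons; smaller ω
remains correctly ordered) but does not exercise the biases real data
present (unequal codon usage, site-specific constraint).

## Problem sizes

The shipped acceptance checks use 200 random sequences (0.1–2 kb) for the
scanner oracle, 100 cohort seeds (19 × ~0.6–0.9 kb each), 200 planted
gene-order edits, 50 random 5–8-taxon trees, and 5,000-codon pairs for ω
recovery; the full suite and the acceptance script each run in well under a
minute on one CPU.

## Known limitations

- The repeat detector is exact-k-mer seeded: arrays whose every unit pair
  differs within each 10-mer window of a period would not be seeded; with
  unit divergence of 1–3 sites per 107 bp this is not a practical concern.
- Array boundary identification at the identity floor is fuzzy by ±(1 −
  identity)·unit-length bases on flanks that resemble the unit; see above.
- The gene-order event decomposition is deterministic, not minimal; complex
  multi-event histories may classify differently than a parsimony analysis.
- Ka/Ks ignores transition/transversion bias and codon-frequency bias in
  site counting (the classic estimator's known behaviour).
- Validation against the real deposited accessions (genome composition,
  CR landmark census, VR3 cohort purity) requires downloading those records;
  the machinery (`seq_stats.composition_table`, `cr_annotation.annotate_cr`,
  `repeat_analysis.analyze_cohort`) is the same code exercised here on
  synthetic inputs.
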