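# Methods

This note documents the models, conventions and numerical choices behind
`twinmito`, in the order the pipeline runs them. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Genome model and statistics

An `AnnotatedGenome` is a DNA string (the *sequenced* portion only) plus
ordered `GeneFeature`s with 1-based inclusive segment coordinates; a segment
with `start > end` wraps the origin and is legal only on circular genomes.
Physically circular molecules deposited with one unsequenced gap are stored
as `linear_gapped`: every downstream statistic (GC, coding fraction,
spacers) uses the sequenced length as its denominator, which is the
convention under which such genomes are tabulated.

Conventions that shape the numbers:

* **Coding coverage** is a position-set union over protein, rRNA, tRNA and
  annotated-ORF loci, so overlapping genes count once. Intron features count
  as part of their host gene's locus: intronic nucleotides are
  coding-covered but excluded from spliced gene lengths. The alternative
  (introns as non-coding) is one flag away, but the locus convention
  reproduces both the gene-length and the coding-percentage styles of
  published organellar tables most consistently.
* **GC content** excludes IUPAC ambiguity codes from numerator and
  denominator, so partially ambiguous assemblies do not bias composition.
* **Spacers** are measured between consecutive gene loci along the genome
  (cyclically on circles, open across the gap otherwise); pairs at negative
  distance are reported as overlaps and excluded from the spacer mean.
  This yields the accounting identity — union coverage + spacer bp +
  overlap-corrected bp = sequenced length — which the tests assert on every
  simulated genome.
* **Codon statistics** run over complete protein-coding genes only (fused
  genes once, annotated ORFs excluded by default as potentially spurious);
  the third-position statistic is (#A + #T at codon position 3) / #codons.

Translation supports the universal code (table 1) and the table-4 variant
(TGA→Trp) used by some centric diatom mitochondria, plus an `open_frame`
mode for dinoflagellate host genes, which lack canonical start and stop
codons: translate from base 1, trim a trailing partial codon, map stops to
`*` without complaint.

## Inversion distance

Gene orders are compared as signed permutations: the reference order
defines identity numbering and the `+` orientation; genes missing from
either genome are dropped, as are duplicated names (the unique-marker
requirement of the classical theory — with duplicated markers the problem
is different and harder). Fewer than three shared markers is an error.

The distance is the exact Hannenhalli–Pevzner formula
`d = (n + 1) − c + h + f` on the extended, doubled representation
(`+x → (2x−1, 2x)`, `−x → (2x, 2x−1)`, framed by `0` and `2n+1`):

* `c` — breakpoint-graph cycles (black edges join position pairs, gray
  edges value pairs).
* A gray edge is *oriented* when its endpoints sit at equal-parity
  positions. Cycles sharing interleaving gray edges form components; a
  component with no oriented edge is unoriented.
* `h` — hurdles: on the circle obtained by joining the two ends, an
  unoriented component one of whose two arcs contains no other unoriented
  component (i.e. minimal spans, plus a span containing all others).
* `f = 1` exactly when the hurdle count is odd, at least 3, and every
  hurdle is a superhurdle (deleting it does not lower the hurdle count
  because a protecting component takes its place).

Hurdle/superhurdle detection is O(n²), fine at the ~60-marker scale of
organellar genomes. Circular gene orders are anchored: rotate (and reflect
if needed — a circular molecule has no intrinsic reading direction) so the
anchor marker reads `+` first, drop it, renumber, and solve the linear
problem. Both circular and linear modes are exposed; circular is the
default for circular genomes.

**Verification.** An independent oracle does breadth-first search over
reversal moves and shares nothing with the theory above. For n ≤ 7 it
sweeps the whole signed-permutation group once per n (byte-packed states,
vectorised frontier expansion, sorted-array dedup; the n = 7 group has
645 120 states) and caches distance levels; for n = 8–9 it grows complete
distance balls from both ends and takes the minimum d₁+d₂ over their
intersection, which is exact because both balls store true distances. The
test suite checks implementation ≡ oracle exhaustively for all signed
permutations with n ≤ 4 (there are 384 + … states) and on hundreds of
seeded random permutations up to n = 8. The n = 8 group itself (10.3M
states) is deliberately not table-swept — the per-query ball search is the
better memory/time trade-off at that size.

Synteny blocks are maximal runs of shared genes whose orientation-aware
adjacencies (an adjacency equals its mirror image: `(a,b) ≡ (−b,−a)`) are
present in every genome; whole-block strand flips therefore do not break a
block. Blocks are reported in the first genome's frame.

## Structural-event detectors

All detectors share one alignment configuration (recorded in report
headers): protein Smith–Waterman/Needleman–Wunsch with BLOSUM62, gap open
11 / extend 1; nucleotide match +2 / mismatch −3, gap open 5 / extend 2.
Identity is always matches / aligned columns with terminal gaps excluded.

* **Fission** — each candidate protein is locally aligned to the intact
  parent; an event requires exactly two candidates each covering ≥ 25 % of
  the parent, jointly ≥ 80 %, with span overlap ≤ 10 aa (thresholds
  config-exposed; chosen so that a clean two-domain split is unambiguous
  while unrelated or redundant candidates fail). The breakpoint is the aa
  interval between the two spans.
* **Fusion** — for every protein pair adjacent in the split genome, a
  single protein of the other genome qualifies when the upstream protein
  maps to its N-terminal and the downstream protein to its C-terminal
  region, in order; the pair is rejected if the downstream gene also exists
  on its own. Evidence flags record the two hallmarks of a fresh fusion:
  no stop codon between the gene-derived regions, and a methionine at the
  position where the downstream part begins.
* **In-frame insertion** — the first in-group protein serves as alignment
  reference; each outgroup is globally aligned to it (free terminal gaps)
  and the insert is the longest reference region gapped in *all* outgroups
  (≥ 10 aa). Boundaries are mapped onto the other in-group members through
  pairwise alignments, so members may legitimately report different insert
  lengths. Composing pairwise alignments against a fixed reference stands
  in for a full MSA; for a presence/absence region this loses nothing and
  keeps the package dependency-free. Without an outgroup the polarity
  (insertion vs deletion) is undecidable and the function refuses to guess.
  Identities inside vs outside the insert are reported, not enforced.
  Because coordinates are codon-level, the nt length is 3× the aa length
  and in-frame by construction; both first/last-aa-of-insert boundary
  conventions can be read off the reported interval.
* **Intron interruption** — the cDNA is decomposed into a maximal colinear
  chain of exact matches on the locus (k-mer seeded, k = 16, maximally
  extended, heaviest-chain dynamic program). Chain gaps where the locus
  side is ≥ 20 nt longer than the cDNA side are introns; the precise splice
  point within a gap minimises exon mismatches. A chain covering < 90 % of
  the cDNA is an error, not a silent partial answer. With 2 % exon
  divergence, planted introns are recovered within ±3 nt (asserted).
* **Trans-splice junction** — the maximal transcript prefix is matched
  ungapped against the 3′ end of part 1 and the maximal suffix against the
  5′ start of part 2, scoring +1 match / −1 mismatch so substitutional
  editing (which concentrates upstream of real junctions) shifts nothing;
  the residues between the two claims are the junction insert. If the
  claims overlap, the overlap is reported as an ambiguity interval rather
  than silently resolved.

## RNA editing

Editing here is substitutional by definition: the transcript is anchored on
the gene by its best ungapped placement, and edlib's unrestricted edit
distance serves as an indel screen — if the best ungapped placement needs
more changes than the edit distance, the pair truly differs by an indel and
the call is refused with a position. Every mismatch then becomes a site
with codon index, codon position ((pos−1) mod 3 + 1), and amino-acid
consequence; the site count equals the Hamming distance over the compared
span by construction. RNA bases are mapped to the DNA alphabet (mRNA U
reported as T), and edits read genomic → transcript, so "A-to-G editing"
means A in DNA, G in cDNA. Partial fragments are handled by the anchor
plus a `frame_offset` giving the gene fragment's phase in the full CDS.

Cross-species site conservation goes through a codon-level homolog map
built from a global alignment of the two translations; two sites match
when their codons align, the within-codon position agrees, and the
substitution type is identical. The non-synonymous fraction is reported
per dataset, never assumed.

## Pseudogene mapping

Fragments are aligned locally against every reference gene on both strands;
within one fragment, several non-overlapping matches are found by best-hit
recursion on the unmatched remainder, so a contig can carry remnants of two
genes. Matches need ≥ 50 nt and ≥ 40 % identity — below the most degenerate
published cases, to avoid truncating the observed range. Overlapping claims
on the fragment are resolved by score, then longer gene interval, then gene
name. Conservation classes: conserved ≥ 90 %, degenerate < 60 %,
intermediate between (config-exposed).

**Boundary convention.** A reported match starts and ends on a run of 10
consecutive identities. Without this, the Smith–Waterman optimum routinely
absorbs a few coincidentally matching flank bases (match +2 beats
mismatch −3 whenever slightly more than half of an extension matches), and
a short gap jump can even reach a chance match run in the flank; requiring
a clean terminal run makes the probability of either negligible
(0.25¹⁰ ≈ 10⁻⁶ per position). The flip side is documented: for strongly
degenerate matches the reported span is the conserved core, not the full
homologous stretch.

**Coverage uniformity.** The "no hot spots" question is formalised as a
chi-square of binned match depth (10 bins) against the uniform expectation.
Depth at neighbouring positions is correlated — one fragment covers a
contiguous run — so the asymptotic chi-square null is wrong
(anticonservative) for fragment data. The statistic is kept but its p-value
is calibrated by seeded Monte Carlo: fragments of the observed lengths are
re-placed uniformly at random 999 times and the statistic recomputed. A
constructed hot spot (all fragments stacked on one bin) is rejected at
α = 0.01; uniformly placed fragments are not rejected in ≥ 95 % of seeded
replicates (both asserted).

## Synthetic data

The generator emulates the statistical structure of a compact diatom-type
mitochondrial genome: default 58 genes with a protein/rRNA/tRNA mix near
33/2/23, mean protein gene ≈ 790 nt (SD 240, codon-rounded), two rRNAs
near 2.85/1.48 kb, tRNAs 71–89 nt, exponential spacers with mean 58 nt,
GC 31 %, third-codon-position A+T 79 %, random strands, circular topology —
the regime the analysis is designed for. Editing pairs default to the
dinoflagellate spectrum (A→G 0.70, T→C 0.15, C→T 0.10, G→C 0.05; codon
positions weighted 0.45/0.45/0.10) with exactly `n_sites` distinct planted
substitutions and no indels. Pseudogene sets draw spans uniformly along the
gene (100–400 nt), identities from a configurable level set, random
orientations, and random flanks of 50–150 nt whose base adjacent to the
core is forced to mismatch the gene continuation, so the planted span is
the true maximal match and span-recovery is well defined. Structural-event
specs plant fission (random internal breakpoint, second part relocated to
the opposite strand), fusion (upstream loses its stop, downstream keeps its
initiator; a `colocate` step first makes the partners adjacent, the
precondition of a fusion scenario), in-frame insertions, whole-genome CDS
divergence, and trans-spliced transcripts with a junction insert (default
penta-A) and upstream edits.

Determinism: one integer seed drives a named stream per generator stage
(`default_rng([seed, crc32(stage)])`), so adding a stage never perturbs
another stage's draws, and equal seeds give byte-identical output
(asserted down to GenBank bytes).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error and assembly artefacts, codon
usage beyond base composition (no amino-acid realism), repeat families in
flanks and spacers, tRNA/rRNA secondary structure, selection-shaped
divergence (mutations are i.i.d. substitutions), and duplicated gene
copies beyond name-level duplicates.

## Problem sizes and verification scope

The shipped test and acceptance runs use: BFS-oracle equivalence on 500
seeded random permutations (n ≤ 8; the n ≤ 7 portion answered from cached
whole-group sweeps, n = 8 by per-query ball search), 100 seeded editing
pairs, structural-event recovery at 0 % and 2 % CDS divergence, 20–40
pseudogene fragments per replicate, and 5-seed genome batches for the
accounting identity — sizes at which every stage's planted truth is checked
exhaustively while the whole suite stays comfortably within a single CPU's
patience. The accession-based suite recomputes published genome-level
numbers from deposited GenBank records and therefore needs those records
on disk (`data/accessions/`) or fetchable.

## Known limitations

* Rearrangement distances assume unique markers; duplicated gene names are
  dropped rather than modelled (no duplicated-marker or DCJ variants).
* The fission/fusion detectors are protein-level and threshold-based; they
  are designed for the clean two-part events seen in organellar genomes,
  not for promiscuous domain shuffling.
* The intron detector requires exact 16-mers shared between exon and cDNA;
  beyond ~6 % divergence the chain can fragment.
* The editing caller works on consensus sequences; there is no per-read
  error model or editing-level quantification.
* Trans-splice junction ambiguity (overlapping prefix/suffix claims) is
  reported but not resolved by codon-usage or homology heuristics.
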