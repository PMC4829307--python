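# Methods

## Model of the data

The pipeline's substrate is a steady-state nuclear pre-mRNA pool of one long
gene, sequenced as 2×100 nt paired-end reads from 250–650 nt fragments with
an expected insert around 400 nt. Each fragment is a window on one molecule
at one moment of its maturation, so three signals carry kinetic information:

1. the splicing **phase** of a read pair (pre / intermediate / post /
   exon-only), driven by which features its ends touch;
2. per-intron **coverage**: an intron that is removed slowly spends longer in
   the pool, so its normalized depth is higher;
3. paired **junction/intron reads**, which witness the relative order of
   removal of neighboring introns directly.

Gapped alignments whose skip does not match an annotated junction witness a
fourth signal: intermediates of multi-step intron removal (recursive,
intermezzo, nested).

## Coordinates and the gene model

All coordinates are 1-based, fully closed, genomic (the SAM/GFF convention);
BED input is converted on read. Exon/intron indices follow transcript
(5′→3′) order so "intron *n* between exons *n* and *n*+1" holds on both
strands; on the minus strand the donor site of an intron is its genomically
highest base. Only a single transcript isoform is modeled; annotations with
several isoforms for the requested gene are rejected rather than merged,
because every downstream index (junction *n*, intron *n*+1) presumes one
linear exon order. Masks (promoters, UTRs, embedded RNAs, probe gaps) are
user-supplied BED intervals; they remove positions from coverage statistics
only and never affect read classification.

## Phase decision table

The table is total and symmetric in end order. An end is a *junction* end
only when its skip exactly matches one annotated intron; a skip anywhere
else deliberately does **not** make the pair post-splicing — such reads are
the input of the multi-step module. "Large" pairs are those whose outermost
span exceeds expected_insert + 3·SD (defaults 400 ± 100 nt; both
configurable, since the library only pins the insert approximately). Large
spans reroute intronic~intronic pairs to the intermediate class (an
unspliced molecule cannot place two reads 40 kb apart within one fragment);
pairs in different exons stay post regardless of span, following the
feature-based definition.

## Coverage and speed classes

Per-feature median depth includes zero-coverage positions and skips masked
ones. Normalization multiplies each sample's medians by
reference_depth / (that sample's mean exon coverage); the reference defaults
to the grand mean exon coverage across samples, keeping values in depth
units so the fast/slow cutoffs 90 and 130 remain interpretable. Pinning
`reference_depth` makes normalized values exactly independent of any one
sample's sequencing depth (with the default, rescaling one sample moves all
values by a single common factor and no ratio changes). Speed classes use
the global cutoffs; the sliding units (5 introns, step 3, final partial unit
allowed — 26 units for 78 introns) report only the relative ranking within
each unit. Introns whose masked profile still contains a >5× local spike
(95th percentile / median) are flagged outliers and dropped from the GC and
positional regressions, which are ordinary least squares with two-sided
p-values; fewer than 3 points or a constant predictor is reported
"degenerate" rather than fitted.

## Splice-ratio and exon blocks

S(n) counts pairs (junction ex(n)–ex(n+1) ~ mate fully inside intron n+1);
NS(n) counts pairs (mate fully inside intron n ~ junction ex(n+1)–ex(n+2)).
Junction ends must match the annotation exactly and the mate must be gapless
within the named intron. One pair may tally one S and one NS of different
introns (the two tallies concern different questions). The ratio S/(S+NS) is
classified sequential (> 0.5), non-sequential (< 0.5) or intermediate
(within ε = 0.05 of 0.5 — the class exists because ratios hugging 0.5 are
not decidable); below min_support = 5 informative pairs the call is
"insufficient". Both S and NS are undefined for the final intron (they
require an intron or junction beyond the gene), so it is always reported
insufficient. Counts pool over libraries; pooling invariance (ratio of sums
= count-weighted mean) is a tested identity.

Exon blocks are maximal runs of ≥2 consecutive early-removed introns (fast
and/or sequential) flanked on both sides by slow or non-sequential introns;
gene ends count as flanks, and an intermediate intron breaks a run without
serving as a flank. A run of k introns joins k+1 ≥ 3 exons.

## Multi-step events

Every mate is treated as a single-end read; each skip ≥ min_gap (50 nt, the
floor that separates candidate splicing from indels and NAGNAG wobble)
yields one candidate. Boundary refinement first computes the
alignment-equivalent slide range of the gap from the reference sequence,
then picks the placement maximizing matches of the terminal dinucleotides to
GT…AG (ties → leftmost); it can neither leave the ambiguity range nor lower
the motif score. Filters then discard gaps not contained in a single intron,
gaps whose two sites are both annotated (ordinary junctions), and gaps whose
non-annotated site lies within 50 nt of either exon–intron boundary — the
published filter names the first 50 intronic nucleotides; applying it at
both ends is this package's choice, because acceptor-proximal artifacts are
equally suspect. Counts are summed within each cell line and an event is
kept only if present in every cell line (guarding against PCR-duplicate
artifacts private to one library). Classification: annotated donor + internal
acceptor → 5′RS; internal donor + annotated acceptor → 3′RS; both internal →
nested. A 5′RS and a 3′RS of one intron whose internal sites bracket a
positive retained segment are re-labeled an intermezzo pair (retained length
d₂ − a₁ − 1 in transcript direction); only paired members leave the RS
tallies, co-occurring intermezzi are reported independently and never
merged. An intron with ≥1 surviving event is "multi-step", otherwise
"single-step"; the length contrast between modes uses the Mann–Whitney
rank-sum test (the natural unpaired location test for two intron-length
groups). Annotated-site matching is exact (0 nt tolerance) after refinement.

## Motifs

Each event contributes a 4-nt donor context (2 bases upstream + first 2
skipped bases) and a 4-nt acceptor context (last 2 skipped bases + 2
downstream), reverse-complemented to the transcribed strand for minus-strand
genes. Position-frequency matrices are exact (no pseudocounts); N bases are
excluded from canonical fractions and from the column denominators at their
position. The dinucleotide pair table covers the canonical pair and the
common non-canonical pairs plus CT-AC and "other". Sequence-logo rendering
is not included; the PFM is the contract.

## Synthetic generator

The generator emulates the steady-state nuclear harvest: initiation times
uniform over a window equal to the full transcription time plus 10 min,
elongation at 2,400 nt/min, and per-intron exponential removal clocks that
start once one base past the 3′ splice site is transcribed. Planted
multi-step paths traverse ordered steps (e.g. 5′RS: fast removal of
[donor, internal acceptor] at 2/min, then slow completion at 0.05/min —
fast first steps and slow completion keep intermediates visible in the
snapshot). Internal exons are 32–275 nt; intron lengths are log-uniform in a
configurable range; annotated and planted sites are canonical GT/AG unless a
planted event opts out. Fragments start uniformly along each molecule
(molecules weighted by retained length) and alignments are emitted exactly,
with a skip at every removed segment, so the aligner is bypassed; an
identical seed yields byte-identical SAM and truth. Not simulated: capture
probe affinity, GC bias, PCR duplication, sequencing error and alignment
error — so passing tests demonstrate the correctness of the inference given
faithful alignments, not robustness to those artifacts.

Problem sizes of the shipped studies: order recovery uses 20 introns
(600–2,000 nt, ten introns planted non-sequential at 10× slower removal than
their downstream neighbor), 3,000 molecules, 300× depth; the event study
uses 10 introns (2,000–4,000 nt), three cell lines, 1,500 molecules and 150×
depth each — sizes chosen so every planted event is supported by well over
10 reads per cell line while a full run stays in seconds. The two-intron
race check compares the sampled removal order of 10,000 molecule pairs with
the closed form P = 1 − e^(−k₁δ)·k₂/(k₁+k₂), where δ is the eligibility lag
of the downstream intron.

## Known limitations

* Single-isoform gene models only; alternative promoters/isoforms of real
  genes must be reduced to one transcript upstream.
* The splice-ratio is undefined for the final intron and blind to removal
  order of non-adjacent intron pairs.
* Event discovery requires the intermediate state to be populated at harvest;
  very fast completion steps make true multi-step introns look single-step
  (the single-step class is therefore an absence-of-evidence call).
* Coverage-based speed classes inherit any unmasked capture-probe or
  expression artifacts; masking is the only correction applied, and the
  cutoffs 90/130 presume depths in the regime the normalization reference
  establishes.
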