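# splicestep

Order and multi-step structure of co-transcriptional intron removal, inferred
from targeted paired-end sequencing of nuclear pre-mRNA.

Long human genes such as dystrophin (*DMD*, 79 exons, 2.09 Mb of primary
transcript, introns from 107 bp to 360 kb) are transcribed over many hours at
~2.4 kb/min and spliced while transcription is still running. Capture-based
sequencing of nuclear pre-mRNA takes a snapshot of that process: every read
pair carries a piece of a molecule frozen somewhere between "no intron
removed" and "fully spliced". `splicestep` turns coordinate-sorted alignments
of such data, a single-transcript gene model and the genome sequence into:

* **Splicing-phase classification** of read pairs. A pair is *post*-splicing
  if both ends sit in exons or span exon–exon junctions, *intermediate* if an
  intronic or boundary end is paired with a junction end (or both ends are
  intronic but separated by far more than the ~400 nt library insert), *pre*
  if it touches intronic sequence with no junction evidence, and *exon-only*
  if confined to one exon.
* **Intron splicing-speed classes** from coverage. Per-intron median depth
  (zeros included, masked regions excluded) is normalized by each sample's
  mean exon coverage so values stay in read-depth units; introns below 90 are
  *fast*, above 130 *slow*, in between *intermediate*. Diagnostics include
  replicate correlation (log-scale Pearson), GC and 5′→3′ positional
  regressions, and a local-spike outlier flag.
* **Relative removal order** from paired junction/intron reads. For intron
  *n*,

      splice-ratio(n) = S / (S + NS)

  where S counts pairs with one end on the exon(n)–exon(n+1) junction and the
  mate inside intron n+1, and NS counts pairs with one end inside intron n
  and the mate on the exon(n+1)–exon(n+2) junction. Ratios above 0.5 call the
  intron *sequential*, below 0.5 *non-sequential*, within ±0.05 of 0.5
  *intermediate*. Runs of early-removed introns flanked by slow/non-sequential
  introns are reported as **exon blocks** (≥3 exons already joined while
  their flanking introns persist).
* **Multi-step splicing events** from gapped alignments whose skip does not
  match an annotated junction: boundary refinement toward the canonical
  GT…AG motif within the alignment-ambiguity range, removal of
  junction-proximal artifacts (<50 nt from an exon–intron boundary), per
  cell-line summation and presence-in-every-cell-line intersection, then
  classification as 5′-recursive (annotated donor reused), 3′-recursive
  (annotated acceptor reused), *nested* (both sites internal), with 5′RS/3′RS
  pairs that bracket a retained internal cassette re-labeled *intermezzo*.
* **Splice-site motif summaries**: 4-nt donor/acceptor contexts, exact
  position-frequency matrices, canonical GT/AG fractions and a
  donor–acceptor dinucleotide pair table (GT-AG, GC-AG, GT-TG, GA-AG, GT-AC,
  AT-AG, CT-AC, other).

A kinetic **synthetic-data generator** makes the whole pipeline testable
offline: constant-rate transcription initiation, elongation at 2.4 kb/min,
per-intron exponential removal clocks that start when the 3′ splice site is
transcribed, planted multi-step paths, and exact 2×100 nt paired-end SAM
emission with a full truth table.

## Worked example

Simulate three "cell lines" from one synthetic 8-intron gene in which intron
2 is slow and carries a planted 5′-recursive step, intron 5 carries a planted
nested step, and run the full pipeline:

```python
import numpy as np
from splicestep.synthetic import (SimulationConfig, PlantedEvent, simulate_gene,
                                  simulate_sample, write_fasta, write_gff3)
from splicestep.pipeline import PipelineConfig, SampleSpec, run_pipeline

plan = (PlantedEvent(2, "5RS", (600,)), PlantedEvent(5, "nested", (400, 900)))
cfg = SimulationConfig(n_introns=8, intron_length_range=(1500, 3500),
                       removal_rates=[0.6, 0.05, 0.6, 0.6, 0.3, 0.6, 0.6, 0.6],
                       planted_events=plan, depth=120, n_molecules=1200, seed=42)
model, seq = simulate_gene(cfg, np.random.default_rng(cfg.seed))
write_fasta("genome.fa", cfg.chrom, seq); write_gff3("gene.gff3", model)
samples = []
for i, line in enumerate(("A", "B", "C")):
    sam, _ = simulate_sample(model, cfg, f"lib{i}", line, seed=1000 + i)
    open(f"{line}.sam", "w").write(sam)
    samples.append(SampleSpec(f"lib{i}", line, f"{line}.sam"))
summary = run_pipeline(PipelineConfig(samples=samples, gene_id="SYNGENE",
                                      annotation="gene.gff3", genome="genome.fa",
                                      out_dir="out", min_mapped_reads=1000))
```

Selected output (see `out/summary.json` for the full report):

```
samples.lib0.phase_fractions   pre 0.842, intermediate 0.100, post 0.057
coverage.speed_counts          fast 6, intermediate 0, slow 2
order.class_counts             sequential 5, non-sequential 2, insufficient 1
order.exon_blocks              exons 3-5 and exons 6-9
order.coverage_vs_ratio        r = -0.97, p = 2.4e-4
events.class_counts            5RS 1, nested 1
motifs.canonical fractions     donor 1.0, acceptor 1.0 (pair table GT-AG 1.0)
```

Reading it: most pairs are pre-splicing, as expected for nuclear pre-mRNA.
The two slow introns (2 and 5) are called non-sequential, so their
neighboring fast introns join exons around them into two exon blocks, and
coverage anti-correlates with the splice-ratio (slow removal ⇒ high coverage
⇒ low ratio). Both planted multi-step events are recovered in all three cell
lines with their planted classes and canonical GT/AG sites.

The same run is available from a shell via `splicestep run-all --manifest
manifest.tsv --gene-id SYNGENE --annotation gene.gff3 --genome genome.fa`;
per-stage subcommands (`classify`, `coverage`, `order`, `events`, `motifs`,
`simulate`, `validate`, `model`) expose the individual stages.

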