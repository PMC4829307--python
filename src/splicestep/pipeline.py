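"""End-to-end orchestration: classification -> coverage -> order -> events
-> motifs, with deterministic report files.

Every stage output is a pure function of (inputs, config), so re-running a
configuration reproduces byte-identical reports.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import pysam

from . import coverage as cov
from . import motif as mot
from . import multistep as ms
from . import splice_order as so
from .gene_model import apply_masks, load_gene_model
from .read_classify import iter_read_pairs, tally_categories

__all__ = ["SampleSpec", "PipelineConfig", "validate_inputs", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    cell_line: str
    bam: str


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    gene_id: str
    annotation: str
    genome: str | None = None  # FASTA path; motif/refinement stages need it
    masks: str | None = None  # BED path
    out_dir: str = "splicestep_out"
    speed_cutoffs: tuple[float, float] = (90.0, 130.0)
    window: int = 5
    step: int = 3
    epsilon: float = 0.05
    min_support: int = 5
    boundary_margin: int = 50
    min_gap: int = 50
    expected_insert: int = 400
    insert_sd: int = 100
    insert_sd_mult: float = 3.0
    min_mapped_reads: int = 500_000
    max_mismatches: int = 5
    seed: int = 0


def _log(msg: str) -> None:
    print(f"[splicestep] {msg}", file=sys.stderr)


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Existence, contig-name agreement and sort-order checks.

    Returns non-fatal diagnostics; raises PipelineError on fatal problems.
    """
    if not config.samples:
        raise PipelineError("empty sample manifest")
    diags: list[str] = []
    for path in [config.annotation, config.genome, config.masks] + [s.bam for s in config.samples]:
        if path is not None and not os.path.exists(path):
            raise PipelineError(f"input not found: {path}")
    model = load_gene_model(config.annotation, config.gene_id)
    if config.genome is not None:
        from pyfaidx import Fasta

        contigs = set(Fasta(config.genome).keys())
        if model.chrom not in contigs:
            raise PipelineError(
                f"contig mismatch: annotation names {model.chrom!r}, genome has "
                f"{sorted(contigs)}; rename contigs to agree"
            )
    for s in config.samples:
        with pysam.AlignmentFile(s.bam, check_sq=False) as fh:
            header = fh.header.to_dict()
            sq = {r["SN"] for r in header.get("SQ", [])}
            if sq and model.chrom not in sq:
                raise PipelineError(
                    f"contig mismatch in {s.bam}: annotation names {model.chrom!r}, "
                    f"alignment has {sorted(sq)}"
                )
            if header.get("HD", {}).get("SO") != "coordinate":
                raise PipelineError(f"coordinate-sorted input required: {s.bam}")
    return diags


def _load_genome(config: PipelineConfig):
    if config.genome is None:
        return None
    from pyfaidx import Fasta

    return Fasta(config.genome)


ALL_STAGES = ("classify", "coverage", "order", "events", "motifs")

# each stage needs its prerequisites to have run
_STAGE_DEPS = {"order": {"coverage"}, "motifs": {"events"}}


def _expand_stages(stages) -> set[str]:
    want = set(stages)
    unknown = want - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    changed = True
    while changed:
        changed = False
        for st in list(want):
            extra = _STAGE_DEPS.get(st, set()) - want
            if extra:
                want |= extra
                changed = True
    want.add("classify")  # QC gate always runs
    return want


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages (prerequisites added automatically); write
    per-stage TSVs plus summary.json into ``config.out_dir`` and return the
    summary dict."""
    stages = _expand_stages(stages)
    validate_inputs(config)
    os.makedirs(config.out_dir, exist_ok=True)
    model = load_gene_model(config.annotation, config.gene_id)
    if config.masks:
        model = apply_masks(model, config.masks, warn=_log)
    genome = _load_genome(config)

    summary: dict = {
        "gene_id": config.gene_id,
        "n_exons": len(model.exons),
        "n_introns": len(model.introns),
        # out_dir is where the report lives, not an analysis parameter; keeping
        # it out makes reruns byte-identical wherever they are written
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("samples", "out_dir")
        },
        "samples": {},
    }

    # --- stage 1: phase classification + sample QC ------------------------
    kept_samples: list[SampleSpec] = []
    for s in config.samples:
        counts = tally_categories(
            iter_read_pairs(s.bam, s.sample_id, config.max_mismatches),
            model,
            config.expected_insert,
            config.insert_sd,
            config.insert_sd_mult,
            sample_id=s.sample_id,
            warn=_log,
        )
        mapped_reads = 2 * counts.total
        if mapped_reads < config.min_mapped_reads:
            _log(
                f"sample {s.sample_id} excluded: {mapped_reads} gene-mapped reads "
                f"below the {config.min_mapped_reads} floor (low sequencing yield)"
            )
            summary["samples"][s.sample_id] = {"excluded_low_yield": True}
            continue
        kept_samples.append(s)
        summary["samples"][s.sample_id] = {
            "cell_line": s.cell_line,
            "mapped_reads": mapped_reads,
            "phase_counts": dict(counts.counts),
            "phase_fractions": {k: round(v, 6) for k, v in counts.fractions.items()},
            "exonic_base_fraction": round(counts.exonic_base_fraction, 6),
            "unassignable_pairs": counts.unassignable,
        }
    if not kept_samples:
        raise PipelineError("no samples pass the mapped-read floor")

    # defaults so later stages / outputs work under a stage subset
    intron_norm = pd.Series(dtype=float)
    speed: dict[int, str] = {}
    calls: dict = {}
    order_counts: dict = {}
    blocks: list = []
    events: list = []
    steps_table = pd.DataFrame(columns=["intron", "length", "n_events", "mode"])

    # --- stage 2: coverage ------------------------------------------------
    if "coverage" in stages:
        tables = {}
        outliers: dict[str, list[int]] = {}
        for s in kept_samples:
            depth = cov.depth_from_alignments(s.bam, model, config.max_mismatches)
            tables[s.sample_id] = cov.feature_median_table(depth, model)
            outliers[s.sample_id] = cov.detect_coverage_outliers(depth, model)
        norm = cov.normalize_coverage(tables)
        intron_norm = (
            norm[norm.feature == "intron"]
            .drop_duplicates(["index"])
            .set_index("index")
            .cross_sample_mean
        )
        outlier_set = sorted({i for ids in outliers.values() for i in ids})
        speed = dict(
            zip(intron_norm.index,
                cov.classify_intron_speed(intron_norm.values, config.speed_cutoffs))
        )
        regress_idx = [i for i in intron_norm.index if i not in outlier_set]
        pos_reg = cov.positional_bias_regression(intron_norm.loc[regress_idx].values)
        summary["coverage"] = {
            "speed_counts": {
                c: int(sum(v == c for v in speed.values())) for c in cov.SPEED_CLASSES
            },
            "outlier_introns": outlier_set,
            "positional_bias": {
                "slope": None if np.isnan(pos_reg.slope) else pos_reg.slope,
                "p_value": None if np.isnan(pos_reg.p_value) else pos_reg.p_value,
                "degenerate": pos_reg.degenerate,
            },
            "n_windows": len(cov.window_reports(intron_norm.values, config.window,
                                                config.step)),
        }
        if genome is not None:
            gc = [
                cov.gc_fraction(ms.get_seq(genome, model.chrom, i.start, i.end))
                for i in model.introns
                if i.index in regress_idx
            ]
            gc_reg = cov.gc_bias_regression(
                np.array(gc), intron_norm.loc[regress_idx].values
            )
            if not gc_reg.degenerate and gc_reg.p_value < 0.05:
                _log("warning: significant GC-coverage association; proceeding uncorrected")
            summary["coverage"]["gc_bias"] = {
                "slope": None if np.isnan(gc_reg.slope) else gc_reg.slope,
                "p_value": None if np.isnan(gc_reg.p_value) else gc_reg.p_value,
                "degenerate": gc_reg.degenerate,
            }

    # --- stage 3: splicing order ------------------------------------------
    if "order" in stages:
        def all_pairs():
            for s in kept_samples:
                for pair in iter_read_pairs(s.bam, s.sample_id, config.max_mismatches):
                    yield pair

        order_counts = so.count_order_pairs(all_pairs(), model)
        calls = so.call_all_introns(order_counts, model, config.epsilon, config.min_support)
        order_classes = {n: c.order_class for n, c in calls.items()}
        ratios = {n: c.splice_ratio for n, c in calls.items()}
        blocks = so.derive_exon_blocks(order_classes, speed)
        summary["order"] = {
            "class_counts": {
                c: int(sum(v == c for v in order_classes.values()))
                for c in ("sequential", "non-sequential", "intermediate", "insufficient")
            },
            "exon_blocks": [
                {"first_exon": b.first_exon, "last_exon": b.last_exon} for b in blocks
            ],
        }
        try:
            r, p = so.order_vs_coverage_correlation(ratios, intron_norm.to_dict())
            summary["order"]["coverage_vs_ratio"] = {"r": r, "p_value": p}
        except ValueError as exc:
            summary["order"]["coverage_vs_ratio"] = {"error": str(exc)}

    # --- stage 4: multi-step events ---------------------------------------
    if "events" in stages:
        splits = []
        for s in kept_samples:
            sp = ms.extract_split_reads(
                s.bam, model, s.sample_id, s.cell_line, config.min_gap,
                config.max_mismatches
            )
            if genome is not None:
                sp = [
                    ms.refine_gap_boundaries(
                        ms.compute_shift_range(x, genome, model.chrom), genome,
                        model.chrom, model.strand,
                    )
                    for x in sp
                ]
            splits.extend(sp)
        splits = ms.filter_split_events(splits, model, config.boundary_margin)
        matrices = ms.build_event_matrix(splits, model.strand)
        events = ms.intersect_samples(matrices, model) if matrices else []
        ms.detect_intermezzo(events, model)
        steps_table = ms.classify_intron_steps(events, model)
        summary["events"] = {
            "n_intersected": len(events),
            "class_counts": {
                c: int(sum(ev.event_class == c for ev in events))
                for c in ("5RS", "3RS", "nested", "intermezzo")
            },
            "step_modes": ms.step_mode_summary(steps_table),
        }

    # --- stage 5: motifs ---------------------------------------------------
    if "motifs" in stages and genome is not None and events:
        contexts = mot.extract_contexts(events, genome, model, warn=_log)
        msum = mot.summarize_motifs(contexts)
        recursive = [c for c in contexts if c.event_class in ("5RS", "3RS")]
        rsum = mot.summarize_motifs(recursive)
        summary["motifs"] = {
            "canonical_donor_fraction": msum.canonical_donor_fraction,
            "canonical_acceptor_fraction": msum.canonical_acceptor_fraction,
            "recursive_canonical_donor_fraction": rsum.canonical_donor_fraction
            if not rsum.empty else None,
            "recursive_canonical_acceptor_fraction": rsum.canonical_acceptor_fraction
            if not rsum.empty else None,
            "pair_table": {k: round(v, 6) for k, v in msum.pair_table.items()},
        }

    _write_outputs(config, model, calls, order_counts, speed, intron_norm, blocks,
                   events, steps_table, summary)
    return summary


def _write_outputs(config, model, calls, order_counts, speed, intron_norm, blocks,
                   events, steps_table, summary) -> None:
    od = config.out_dir
    rows = []
    for n in sorted(calls):
        c = calls[n]
        oc = order_counts[n]
        rows.append(
            {
                "intron": n,
                "S": oc.S,
                "NS": oc.NS,
                "splice_ratio": "" if c.splice_ratio is None else f"{c.splice_ratio:.4f}",
                "order_class": c.order_class,
                "speed_class": speed.get(n, ""),
                "normalized_coverage": f"{intron_norm.get(n, float('nan')):.3f}",
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(od, "introns.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "block": i + 1,
                "first_exon": b.first_exon,
                "last_exon": b.last_exon,
                "left_flank_intron": b.left_flank_intron,
                "right_flank_intron": b.right_flank_intron,
            }
            for i, b in enumerate(blocks)
        ]
    ).to_csv(os.path.join(od, "exon_blocks.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "intron": ev.intron,
                "donor_pos": ev.donor_pos,
                "acceptor_pos": ev.acceptor_pos,
                "class": ev.event_class,
                "span": ev.span,
                "intermezzo_partner": "" if ev.intermezzo_partner is None
                else f"{ev.intermezzo_partner[0]}-{ev.intermezzo_partner[1]}",
                **{f"support_{k}": v for k, v in sorted(ev.support.items())},
            }
            for ev in events
        ]
    ).to_csv(os.path.join(od, "events.tsv"), sep="\t", index=False)
    steps_table.to_csv(os.path.join(od, "intron_step_modes.tsv"), sep="\t", index=False)
    with open(os.path.join(od, "gene_model.tsv"), "w") as fh:
        fh.write(model.to_tsv())
    with open(os.path.join(od, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
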