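"""Synthetic co-transcriptional splicing data with full ground truth.

The generator emulates steady-state nuclear capture sequencing of one long
multi-intron gene: transcription initiates at a constant rate, the polymerase
elongates at ~2.4 kb/min, each intron becomes splicing-eligible once its 3'
splice site is transcribed and is removed after an exponential waiting time.
Planted multi-step paths (5'RS / 3'RS / nested / intermezzo) traverse their
intermediate states in order, so sampled molecules expose the intermediates
as gapped reads.  Fragments of 250-650 nt are drawn uniformly along each
molecule and sequenced as 2x100 nt read pairs written as SAM records against
the synthetic reference; every pair carries a truth phase label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import ExonInterval, GeneModel

__all__ = [
    "PlantedEvent",
    "SimulationConfig",
    "Molecule",
    "TruthTable",
    "simulate_gene",
    "simulate_transcripts",
    "emit_read_pairs",
    "simulate_sample",
    "analytic_race_probability",
    "sample_race",
    "order_truth",
    "dmd_like_config",
    "write_fasta",
    "write_gff3",
]


@dataclass(frozen=True)
class PlantedEvent:
    """A multi-step splicing path planted in one intron.

    ``offsets`` are 1-based positions inside the intron (from its 5' end):
    5RS -> (internal_acceptor,), 3RS -> (internal_donor,),
    nested -> (internal_donor, internal_acceptor),
    intermezzo -> (acceptor_of_5'_part, donor_of_3'_part).
    """

    intron: int
    kind: str  # 5RS | 3RS | nested | intermezzo
    offsets: tuple[int, ...]
    step_rate: float = 2.0  # 1/min, early steps (fast, so intermediates exist)
    final_rate: float = 0.05  # 1/min, completion (slow -> long-lived intermediates)
    canonical: bool = True
    cell_lines: tuple[str, ...] | None = None  # None -> planted in every sample


@dataclass
class SimulationConfig:
    n_introns: int = 20
    exon_length_range: tuple[int, int] = (32, 275)  # internal exon sizes
    intron_length_range: tuple[int, int] = (600, 2000)
    intron_length_log_uniform: bool = True
    elongation_rate: float = 2400.0  # nt/min
    removal_rates: float | list[float] = 0.5  # 1/min once eligible
    planted_events: tuple[PlantedEvent, ...] = ()
    fragment_size_range: tuple[int, int] = (250, 650)
    read_length: int = 100
    expected_insert: int = 400
    depth: float = 100.0  # target fold-coverage over the gene span
    n_molecules: int = 2000
    extra_time: float = 10.0  # min of initiation window past full transcription
    flank: int = 300  # reference bases on each side of the gene
    chrom: str = "chrS"
    gene_id: str = "SYNGENE"
    seed: int = 0

    def rate(self, intron_index: int) -> float:
        if isinstance(self.removal_rates, (int, float)):
            return float(self.removal_rates)
        return float(self.removal_rates[intron_index - 1])


@dataclass
class Molecule:
    t0: float  # initiation time (snapshot is t = 0)
    pol_pos: int  # last transcribed genomic position
    removed: list[tuple[int, int]]  # removed genomic segments, sorted, disjoint

    def retained(self, span_start: int) -> list[tuple[int, int]]:
        out = []
        cur = span_start
        for lo, hi in self.removed:
            if lo > self.pol_pos:
                break
            if lo > cur:
                out.append((cur, min(lo - 1, self.pol_pos)))
            cur = hi + 1
        if cur <= self.pol_pos:
            out.append((cur, self.pol_pos))
        return out


@dataclass
class TruthTable:
    introns: pd.DataFrame  # index, length, rate, order_truth
    events: pd.DataFrame  # intron, kind, donor_pos, acceptor_pos, cell_lines
    pairs: pd.DataFrame  # pair_id, phase, size_label (per emitted sample)


# ---- gene + genome --------------------------------------------------------


def _draw_intron_lengths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.intron_length_range
    if cfg.intron_length_log_uniform:
        return np.exp(rng.uniform(math.log(lo), math.log(hi), cfg.n_introns)).astype(int)
    return rng.integers(lo, hi + 1, cfg.n_introns)


def simulate_gene(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Build a plus-strand GeneModel and its reference sequence.

    Annotated donors start with GT and acceptors end with AG; planted event
    sites are canonical GT/AG too unless the event says otherwise."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    exon_lens = rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1,
                             cfg.n_introns + 1)
    intron_lens = _draw_intron_lengths(cfg, rng)

    exons = []
    pos = cfg.flank + 1
    for i, el in enumerate(exon_lens, start=1):
        exons.append(ExonInterval(i, pos, pos + int(el) - 1))
        pos += int(el)
        if i <= cfg.n_introns:
            pos += int(intron_lens[i - 1])
    model = GeneModel(gene_id=cfg.gene_id, chrom=cfg.chrom, strand="+", exons=exons)

    total = exons[-1].end + cfg.flank
    seq = rng.choice(list("ACGT"), size=total)

    def put(p: int, s: str) -> None:
        seq[p - 1 : p - 1 + len(s)] = list(s)

    for intr in model.introns:
        put(intr.start, "GT")
        put(intr.end - 1, "AG")
        # forbid gap sliding at annotated boundaries
        if seq[intr.start - 2] == "G":
            seq[intr.start - 2] = "C"
        if seq[intr.end] == "G":
            seq[intr.end] = "C"

    for ev in cfg.planted_events:
        intr = model.intron(ev.intron)
        for off in ev.offsets:
            if off < 50 or intr.length - off < 50:
                raise ValueError("planted site must be >=50 nt from intron boundaries")
        donor_motif = "GT" if ev.canonical else "CC"
        acceptor_motif = "AG" if ev.canonical else "CC"
        if ev.kind == "5RS":
            a = intr.start + ev.offsets[0] - 1
            put(a - 1, acceptor_motif)
            put(a + 1, "GT")  # donor of the completion step
        elif ev.kind == "3RS":
            d = intr.start + ev.offsets[0] - 1
            put(d, donor_motif)
            put(d - 2, "AG")  # acceptor of the completion step
        elif ev.kind == "nested":
            d = intr.start + ev.offsets[0] - 1
            a = intr.start + ev.offsets[1] - 1
            put(d, donor_motif)
            put(a - 1, acceptor_motif)
        elif ev.kind == "intermezzo":
            a1 = intr.start + ev.offsets[0] - 1
            d2 = intr.start + ev.offsets[1] - 1
            put(a1 - 1, acceptor_motif)
            put(d2, donor_motif)
        else:
            raise ValueError(f"unknown planted kind {ev.kind}")
    return model, "".join(seq)


# ---- kinetics -------------------------------------------------------------


def analytic_race_probability(k1: float, k2: float, delta: float) -> float:
    """P(intron 1 removed before intron 2) for exponential removal at rates
    k1, k2 when intron 1 becomes eligible ``delta`` minutes earlier."""
    return 1.0 - math.exp(-k1 * delta) * (k2 / (k1 + k2))


def sample_race(
    k1: float, k2: float, delta: float, n: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of the same race from sampled waiting times."""
    t1 = rng.exponential(1.0 / k1, n)
    t2 = delta + rng.exponential(1.0 / k2, n)
    return float(np.mean(t1 < t2))


def order_truth(model: GeneModel, cfg: SimulationConfig) -> dict[int, str]:
    """Planted order class per intron from the analytic race against its
    downstream neighbor (sequential iff P(removed first) > 0.5)."""
    out = {}
    v = cfg.elongation_rate
    for intr in model.introns[:-1]:
        nxt = model.intron(intr.index + 1)
        delta = (nxt.acceptor_site - intr.acceptor_site) / v
        p = analytic_race_probability(cfg.rate(intr.index), cfg.rate(intr.index + 1), delta)
        out[intr.index] = "sequential" if p > 0.5 else "non-sequential"
    return out


def _event_steps(ev: PlantedEvent, intron) -> list[dict]:
    """Ordered removal steps: each is {'segments': [(lo,hi),...], 'rate',
    'after': indices of prerequisite steps, 'elig_pos': genomic position that
    must be transcribed}."""
    s, e = intron.start, intron.end
    o = [s + off - 1 for off in ev.offsets]
    if ev.kind == "5RS":
        return [
            {"segments": [(s, o[0])], "rate": ev.step_rate, "after": [], "elig_pos": o[0] + 1},
            {"segments": [(o[0] + 1, e)], "rate": ev.final_rate, "after": [0], "elig_pos": e + 1},
        ]
    if ev.kind == "3RS":
        return [
            {"segments": [(o[0], e)], "rate": ev.step_rate, "after": [], "elig_pos": e + 1},
            {"segments": [(s, o[0] - 1)], "rate": ev.final_rate, "after": [0], "elig_pos": e + 1},
        ]
    if ev.kind == "nested":
        d, a = o
        return [
            {"segments": [(d, a)], "rate": ev.step_rate, "after": [], "elig_pos": a + 1},
            {"segments": [(s, d - 1), (a + 1, e)], "rate": ev.final_rate, "after": [0],
             "elig_pos": e + 1},
        ]
    a1, d2 = o
    return [  # intermezzo
        {"segments": [(s, a1)], "rate": ev.step_rate, "after": [], "elig_pos": a1 + 1},
        {"segments": [(d2, e)], "rate": ev.step_rate, "after": [], "elig_pos": e + 1},
        {"segments": [(a1 + 1, d2 - 1)], "rate": ev.final_rate, "after": [0, 1],
         "elig_pos": e + 1},
    ]


def simulate_transcripts(
    model: GeneModel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    planted: tuple[PlantedEvent, ...] | None = None,
) -> list[Molecule]:
    """Snapshot (t = 0) of a steady-state population under constant-rate
    initiation.  Introns with a planted event follow the multi-step path;
    all others are removed in a single step."""
    if planted is None:
        planted = cfg.planted_events
    by_intron = {ev.intron: ev for ev in planted}
    span_start, _ = model.span
    v = cfg.elongation_rate
    window = model.span_length / v + cfg.extra_time
    molecules = []
    for _ in range(cfg.n_molecules):
        t0 = -float(rng.uniform(0.0, window))
        pol = span_start + min(model.span_length - 1, int(v * (0.0 - t0)))
        removed: list[tuple[int, int]] = []
        for intr in model.introns:
            ev = by_intron.get(intr.index)
            if ev is None:
                if intr.end + 1 > pol:
                    continue
                elig = t0 + (intr.end + 1 - span_start + 1) / v
                if elig + rng.exponential(1.0 / cfg.rate(intr.index)) <= 0.0:
                    removed.append((intr.start, intr.end))
                continue
            steps = _event_steps(ev, intr)
            done_at: list[float | None] = []
            for st in steps:
                if st["elig_pos"] > pol:
                    done_at.append(None)
                    continue
                elig = t0 + (st["elig_pos"] - span_start + 1) / v
                for pre in st["after"]:
                    if done_at[pre] is None:
                        elig = None
                        break
                    elig = max(elig, done_at[pre])
                if elig is None:
                    done_at.append(None)
                    continue
                done_at.append(elig + rng.exponential(1.0 / st["rate"]))
            for st, t_done in zip(steps, done_at):
                if t_done is not None and t_done <= 0.0:
                    removed.extend(st["segments"])
        removed.sort()
        molecules.append(Molecule(t0=t0, pol_pos=pol, removed=removed))
    return molecules


# ---- read emission --------------------------------------------------------


def _truth_phase(
    blocks1, blocks2, model: GeneModel, expected_insert: int, insert_sd: int, sd_mult: float
) -> tuple[str, str]:
    """Phase label from the true fragment geometry (same decision table,
    computed directly from the molecule's block structure)."""

    def cat(blocks):
        has_junction = False
        for (a_lo, a_hi), (b_lo, b_hi) in zip(blocks, blocks[1:]):
            if model.junction_for_gap(a_hi + 1, b_lo - 1) is not None:
                has_junction = True
        if has_junction:
            return "junction", None
        kinds = set()
        exon_ids = set()
        for lo, hi in blocks:
            f1, f2 = model.feature_at(lo), model.feature_at(hi)
            if f1 != f2 or f1 is None:
                return "boundary", None
            kinds.add(f1[0])
            if f1[0] == "exon":
                exon_ids.add(f1[1])
        if kinds == {"exon"}:
            return "exon", (exon_ids.pop() if len(exon_ids) == 1 else None)
        if kinds == {"intron"}:
            return "intron", None
        return "boundary", None

    c1, e1 = cat(blocks1)
    c2, e2 = cat(blocks2)
    span = max(b[1] for b in blocks1 + blocks2) - min(b[0] for b in blocks1 + blocks2) + 1
    large = span > expected_insert + sd_mult * insert_sd
    size = "large" if large else "normal"
    cats = {c1, c2}
    if cats <= {"exon", "junction"}:
        if cats == {"exon"} and e1 is not None and e1 == e2:
            return "exon-only", size
        return "post", size
    if "junction" in cats:
        return "intermediate", size
    if c1 == c2 == "intron" and large:
        return "intermediate", "large"
    return "pre", size


def _frag_blocks(retained, cum, frag_lo: int, frag_hi: int) -> list[tuple[int, int]]:
    """Genomic blocks of molecule-coordinate interval [frag_lo, frag_hi)."""
    blocks = []
    for (g_lo, g_hi), offset in zip(retained, cum):
        seg_len = g_hi - g_lo + 1
        lo = max(frag_lo, offset)
        hi = min(frag_hi, offset + seg_len)
        if hi > lo:
            blocks.append((g_lo + lo - offset, g_lo + hi - 1 - offset))
    return blocks


def _cigar(blocks) -> str:
    parts = []
    for i, (lo, hi) in enumerate(blocks):
        if i:
            parts.append(f"{lo - blocks[i - 1][1] - 1}N")
        parts.append(f"{hi - lo + 1}M")
    return "".join(parts)


def emit_read_pairs(
    molecules: list[Molecule],
    model: GeneModel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "S1",
):
    """Draw paired 2x100 nt reads and return (sam_text, pairs_truth_frame).

    Fragments start uniformly along each molecule (molecule chosen with
    probability proportional to its retained length) with lengths uniform in
    the configured range; molecules shorter than the fragment are skipped.
    Alignments are exact by construction: a skip gap is emitted at every
    removed segment the fragment crosses.
    """
    span_start, _ = model.span
    rl = cfg.read_length
    f_lo, f_hi = cfg.fragment_size_range
    retained = [m.retained(span_start) for m in molecules]
    cums = []
    lengths = np.zeros(len(molecules))
    for i, segs in enumerate(retained):
        offs = np.concatenate([[0], np.cumsum([b - a + 1 for a, b in segs])])
        cums.append(offs[:-1])
        lengths[i] = offs[-1]
    weights = lengths / lengths.sum()
    n_pairs = int(round(cfg.depth * model.span_length / (2 * rl)))

    header = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{model.chrom}\tLN:{model.span[1] + cfg.flank}",
        f"@RG\tID:{sample_id}\tSM:{sample_id}",
    ]
    records = []
    truth_rows = []
    mol_idx = rng.choice(len(molecules), size=n_pairs, p=weights)
    frag_lens = rng.integers(f_lo, f_hi + 1, size=n_pairs)
    u_starts = rng.random(n_pairs)
    for k in range(n_pairs):
        i = int(mol_idx[k])
        L = int(frag_lens[k])
        if lengths[i] < max(L, rl):
            continue
        L = min(L, int(lengths[i]))
        start = int(u_starts[k] * (lengths[i] - L + 1))
        b1 = _frag_blocks(retained[i], cums[i], start, start + rl)
        b2 = _frag_blocks(retained[i], cums[i], start + L - rl, start + L)
        if not b1 or not b2:
            continue
        qname = f"{sample_id}:pair{k:07d}"
        phase, size = _truth_phase(b1, b2, model, cfg.expected_insert, 100, 3.0)
        truth_rows.append({"pair_id": qname, "phase": phase, "size_label": size,
                           "molecule": i})
        tlen = b2[-1][1] - b1[0][0] + 1
        records.append(
            (b1[0][0],
             f"{qname}\t99\t{model.chrom}\t{b1[0][0]}\t60\t{_cigar(b1)}\t=\t{b2[0][0]}\t{tlen}\t*\t*")
        )
        records.append(
            (b2[0][0],
             f"{qname}\t147\t{model.chrom}\t{b2[0][0]}\t60\t{_cigar(b2)}\t=\t{b1[0][0]}\t{-tlen}\t*\t*")
        )
    records.sort(key=lambda r: r[0])
    sam = "\n".join(header + [r[1] for r in records]) + "\n"
    return sam, pd.DataFrame(truth_rows)


def simulate_sample(
    model: GeneModel,
    cfg: SimulationConfig,
    sample_id: str,
    cell_line: str,
    seed: int,
):
    """Molecules + reads for one library, honoring per-event cell-line
    restrictions."""
    rng = np.random.default_rng(seed)
    planted = tuple(
        ev for ev in cfg.planted_events
        if ev.cell_lines is None or cell_line in ev.cell_lines
    )
    molecules = simulate_transcripts(model, cfg, rng, planted=planted)
    sam, truth = emit_read_pairs(molecules, model, cfg, rng, sample_id=sample_id)
    return sam, truth


# ---- presets and writers --------------------------------------------------


def dmd_like_config(seed: int = 0) -> SimulationConfig:
    """Dystrophin-like preset: 79 exons, 78 introns with log-uniform lengths
    between 107 nt and 360 kb, elongation 2.4 kb/min."""
    return SimulationConfig(
        n_introns=78,
        intron_length_range=(107, 360_000),
        intron_length_log_uniform=True,
        seed=seed,
    )


def write_fasta(path: str, chrom: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_gff3(path: str, model: GeneModel) -> None:
    s, e = model.span
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{model.chrom}\tsynthetic\tgene\t{s}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={model.gene_id};gene_id={model.gene_id}\n"
        )
        fh.write(
            f"{model.chrom}\tsynthetic\tmRNA\t{s}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={model.gene_id}.t1;Parent={model.gene_id};gene_id={model.gene_id};"
            f"transcript_id={model.gene_id}.t1\n"
        )
        for ex in sorted(model.exons, key=lambda x: x.start):
            fh.write(
                f"{model.chrom}\tsynthetic\texon\t{ex.start}\t{ex.end}\t.\t{model.strand}\t.\t"
                f"Parent={model.gene_id}.t1;gene_id={model.gene_id};"
                f"transcript_id={model.gene_id}.t1\n"
            )
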