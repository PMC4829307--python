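"""Splice-site motif summaries for multi-step splicing events.

Each event contributes two 4-nt contexts on the transcribed strand: the
donor side (2 bases immediately upstream of the donor + the first 2 donor
bases, canonically ..GT) and the acceptor side (the last 2 acceptor bases,
canonically AG, + 2 bases immediately downstream).  Contexts are summarized
as exact position-frequency matrices, canonical-dinucleotide fractions, and
a donor-acceptor dinucleotide pair table over the common canonical and
non-canonical pairs (GT-AG, GC-AG, GT-TG, GA-AG, GT-AC, AT-AG, CT-AC, other).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import GeneModel
from .multistep import SpliceEvent, get_seq, revcomp

__all__ = ["SiteContext", "MotifSummary", "extract_contexts", "summarize_motifs", "PAIR_CLASSES"]

BASES = ("A", "C", "G", "T")
PAIR_CLASSES = ("GT-AG", "GC-AG", "GT-TG", "GA-AG", "GT-AC", "AT-AG", "CT-AC", "other")


@dataclass(frozen=True)
class SiteContext:
    event_key: tuple[int, int]
    event_class: str
    side: str  # donor | acceptor
    sequence: str  # exactly 4 uppercase bases, transcribed strand


@dataclass
class MotifSummary:
    n_events: int
    pfm_donor: pd.DataFrame  # 4 positions x 4 bases, columns sum to 1
    pfm_acceptor: pd.DataFrame
    canonical_donor_fraction: float  # donor dinucleotide == GT
    canonical_acceptor_fraction: float  # acceptor dinucleotide == AG
    pair_table: dict[str, float]  # fractions over PAIR_CLASSES, sums to 1
    pair_counts: dict[str, int]
    empty: bool = False


def _context(genome, chrom: str, strand: str, pos: int, side: str) -> str:
    """4-nt transcribed-strand context for a site at genomic ``pos``.

    ``pos`` is the transcript-sense first skipped base (donor) or last
    skipped base (acceptor)."""
    if strand == "+":
        if side == "donor":
            seq = get_seq(genome, chrom, pos - 2, pos + 1)
        else:
            seq = get_seq(genome, chrom, pos - 1, pos + 2)
        return seq
    if side == "donor":
        seq = get_seq(genome, chrom, pos - 1, pos + 2)
    else:
        seq = get_seq(genome, chrom, pos - 2, pos + 1)
    return revcomp(seq)


def extract_contexts(
    events: list[SpliceEvent], genome, model: GeneModel, warn=None
) -> list[SiteContext]:
    """Donor and acceptor contexts for every event, strand-corrected so a
    canonical donor context always ends in GT and a canonical acceptor
    context starts with AG.  Sites too close to a contig edge are skipped."""
    out = []
    for ev in events:
        for side, pos in (("donor", ev.donor_pos), ("acceptor", ev.acceptor_pos)):
            try:
                seq = _context(genome, model.chrom, model.strand, pos, side)
            except (IndexError, KeyError):
                seq = ""
            if len(seq) != 4:
                if warn is not None:
                    warn(f"context at {pos} within 2 nt of contig edge; skipped")
                continue
            out.append(SiteContext((ev.donor_pos, ev.acceptor_pos), ev.event_class or "", side, seq))
    return out


def _pfm(seqs: list[str]) -> pd.DataFrame:
    mat = np.zeros((4, 4))
    valid = np.zeros(4)
    for s in seqs:
        for i, b in enumerate(s):
            if b in BASES:
                mat[i, BASES.index(b)] += 1
                valid[i] += 1
    with np.errstate(invalid="ignore"):
        mat = mat / valid[:, None]
    return pd.DataFrame(mat, index=[f"pos{i+1}" for i in range(4)], columns=list(BASES))


def _pair_class(donor_di: str, acceptor_di: str) -> str:
    pair = f"{donor_di}-{acceptor_di}"
    return pair if pair in PAIR_CLASSES else "other"


def summarize_motifs(
    contexts: list[SiteContext], event_class: str | None = None, warn=None
) -> MotifSummary:
    """PFMs, canonical fractions and the dinucleotide pair table, optionally
    restricted to one event class ('5RS', '3RS', 'nested', 'intermezzo').

    Fractions are exact (no pseudocounts); contexts containing N are counted
    in the PFM denominator only at unambiguous positions and excluded from
    the canonical fractions."""
    if event_class is not None:
        contexts = [c for c in contexts if c.event_class == event_class]
    donors = {c.event_key: c.sequence for c in contexts if c.side == "donor"}
    acceptors = {c.event_key: c.sequence for c in contexts if c.side == "acceptor"}
    keys = sorted(set(donors) | set(acceptors))
    if not keys:
        if warn is not None:
            warn("empty motif class")
        empty_pfm = _pfm([])
        return MotifSummary(0, empty_pfm, empty_pfm, float("nan"), float("nan"), {}, {}, empty=True)

    donor_dis = [donors[k][2:4] for k in keys if k in donors]
    acceptor_dis = [acceptors[k][0:2] for k in keys if k in acceptors]

    def canon_frac(dis: list[str], target: str) -> float:
        unambig = [d for d in dis if "N" not in d]
        if not unambig:
            return float("nan")
        return sum(d == target for d in unambig) / len(unambig)

    pair_counts: Counter = Counter()
    for k in keys:
        if k in donors and k in acceptors:
            pair_counts[_pair_class(donors[k][2:4], acceptors[k][0:2])] += 1
    total_pairs = sum(pair_counts.values())
    pair_table = {
        cls: (pair_counts.get(cls, 0) / total_pairs if total_pairs else 0.0)
        for cls in PAIR_CLASSES
    }
    return MotifSummary(
        n_events=len(keys),
        pfm_donor=_pfm([donors[k] for k in keys if k in donors]),
        pfm_acceptor=_pfm([acceptors[k] for k in keys if k in acceptors]),
        canonical_donor_fraction=canon_frac(donor_dis, "GT"),
        canonical_acceptor_fraction=canon_frac(acceptor_dis, "AG"),
        pair_table=pair_table,
        pair_counts={cls: pair_counts.get(cls, 0) for cls in PAIR_CLASSES},
    )
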