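"""Classify aligned read pairs into pre-, intermediate- and post-splicing phases.

A paired fragment from a nascent transcript carries a snapshot of its splicing
state: ends confined to exons or spanning exon-exon junctions indicate
completed splicing (post), an intronic or boundary end paired with a junction
end indicates splicing in progress (intermediate), and intronic ends with a
normal insert indicate unspliced pre-mRNA (pre).  Pairs mapping wholly inside
one exon are uninformative and kept in their own bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .gene_model import GeneModel

__all__ = [
    "AlignedEnd",
    "ReadPairRecord",
    "SpliceCategory",
    "CategoryCounts",
    "classify_read_pair",
    "end_category",
    "tally_categories",
    "iter_read_pairs",
]

PHASES = ("pre", "intermediate", "post", "exon-only")


@dataclass(frozen=True)
class AlignedEnd:
    """One aligned mate: matched blocks (1-based closed) on the genome.

    Gaps between consecutive blocks are the skipped ('N') segments of the
    gapped alignment.
    """

    start: int
    blocks: tuple[tuple[int, int], ...]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Skipped intervals (first skipped base, last skipped base)."""
        return tuple(
            (a[1] + 1, b[0] - 1) for a, b in zip(self.blocks, self.blocks[1:])
        )


@dataclass(frozen=True)
class ReadPairRecord:
    pair_id: str
    sample_id: str
    end1: AlignedEnd
    end2: AlignedEnd

    @property
    def inferred_span(self) -> int:
        lo = min(self.end1.start, self.end2.start)
        hi = max(self.end1.end, self.end2.end)
        return hi - lo + 1


@dataclass(frozen=True)
class SpliceCategory:
    phase: str  # pre | intermediate | post | exon-only
    size_label: str  # normal | large


@dataclass
class CategoryCounts:
    sample_id: str = ""
    counts: dict = field(default_factory=lambda: {p: 0 for p in PHASES})
    unassignable: int = 0
    exonic_bases: int = 0
    intronic_bases: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict:
        t = self.total
        return {p: (c / t if t else 0.0) for p, c in self.counts.items()}

    @property
    def exonic_base_fraction(self) -> float:
        t = self.exonic_bases + self.intronic_bases
        return self.exonic_bases / t if t else 0.0


def end_category(end: AlignedEnd, model: GeneModel) -> str:
    """'junction' | 'boundary' | 'intron' | 'exon' | 'outside'.

    A gap that exactly removes one annotated intron makes the end a junction
    end; gaps elsewhere do not (those reads are handled by the multi-step
    event module) and the end is categorised from its matched blocks.
    """
    for lo, hi in end.gaps:
        if model.junction_for_gap(lo, hi) is not None:
            return "junction"
    kinds = set()
    for bs, be in end.blocks:
        f1 = model.feature_at(bs)
        f2 = model.feature_at(be)
        if f1 is None or f2 is None:
            return "outside"
        kinds.add(f1)
        kinds.add(f2)
        if f1 != f2:
            kinds.add("boundary")
    if "boundary" in kinds:
        return "boundary"
    tags = {k[0] for k in kinds}
    if tags == {"exon"}:
        return "exon"
    if tags == {"intron"}:
        return "intron"
    return "boundary"  # blocks in different feature kinds without shared position


def _sole_exon(end: AlignedEnd, model: GeneModel) -> int | None:
    idx = {model.feature_at(p)[1] for bs, be in end.blocks for p in (bs, be)}
    return idx.pop() if len(idx) == 1 else None


def classify_read_pair(
    pair: ReadPairRecord,
    model: GeneModel,
    expected_insert: int = 400,
    insert_sd: int = 100,
    sd_mult: float = 3.0,
) -> SpliceCategory:
    """Assign exactly one splicing phase to a pair overlapping the gene.

    The decision table is total and symmetric in end order:

    * post: ex~ex (two different exons), ex~(ex-ex), (ex-ex)~(ex-ex)
    * exon-only: both ends inside the same single exon
    * intermediate: junction end paired with an intronic or boundary end,
      or both ends intronic with a 'large' span (> insert + sd_mult * sd)
    * pre: everything else touching intronic sequence without a junction end
    """
    c1 = end_category(pair.end1, model)
    c2 = end_category(pair.end2, model)
    if "outside" in (c1, c2):
        raise ValueError("unassignable: end outside gene span")
    large = pair.inferred_span > expected_insert + sd_mult * insert_sd
    size = "large" if large else "normal"
    cats = {c1, c2}
    if cats <= {"exon", "junction"}:
        if cats == {"exon"}:
            e1 = _sole_exon(pair.end1, model)
            e2 = _sole_exon(pair.end2, model)
            if e1 is not None and e1 == e2:
                return SpliceCategory("exon-only", size)
        return SpliceCategory("post", size)
    if "junction" in cats:  # mate is intron or boundary
        return SpliceCategory("intermediate", size)
    if c1 == c2 == "intron" and large:
        return SpliceCategory("intermediate", "large")
    return SpliceCategory("pre", size)


def tally_categories(
    pairs,
    model: GeneModel,
    expected_insert: int = 400,
    insert_sd: int = 100,
    sd_mult: float = 3.0,
    sample_id: str = "",
    warn=None,
) -> CategoryCounts:
    out = CategoryCounts(sample_id=sample_id)
    for pair in pairs:
        try:
            cat = classify_read_pair(pair, model, expected_insert, insert_sd, sd_mult)
        except ValueError:
            out.unassignable += 1
            continue
        out.counts[cat.phase] += 1
        for end in (pair.end1, pair.end2):
            for bs, be in end.blocks:
                # count bases by feature, walking feature boundaries
                p = bs
                while p <= be:
                    kind, idx = model.feature_at(p)
                    feat = model.exon(idx) if kind == "exon" else model.intron(idx)
                    q = min(be, feat.end)
                    n = q - p + 1
                    if kind == "exon":
                        out.exonic_bases += n
                    else:
                        out.intronic_bases += n
                    p = q + 1
    if out.total == 0 and warn is not None:
        warn("no classifiable pairs")
    return out


# ---- SAM/BAM ingestion ----------------------------------------------------


def _aligned_end(seg: pysam.AlignedSegment) -> AlignedEnd:
    blocks: list[tuple[int, int]] = []
    pos = seg.reference_start + 1  # to 1-based
    for op, ln in seg.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            if blocks and blocks[-1][1] == pos - 1:
                blocks[-1] = (blocks[-1][0], pos + ln - 1)
            else:
                blocks.append((pos, pos + ln - 1))
            pos += ln
        elif op in (2, 3):  # D/N consume reference; only N (3) opens a gap
            if op == 2 and blocks:
                blocks[-1] = (blocks[-1][0], blocks[-1][1] + ln)
            pos += ln
        # I/S/H/P consume no reference
    return AlignedEnd(start=blocks[0][0], blocks=tuple(blocks))


def _passes_filters(seg: pysam.AlignedSegment, max_mismatches: int) -> bool:
    if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
        return False
    if seg.has_tag("NH") and seg.get_tag("NH") > 1:
        return False
    if seg.has_tag("NM") and seg.get_tag("NM") > max_mismatches:
        return False
    return True


def iter_read_pairs(path: str, sample_id: str = "", max_mismatches: int = 5):
    """Yield ReadPairRecord from a SAM/BAM file (uniquely mapped, <=5 mismatches
    per end, primary alignments only).  Duplicate-flagged pairs are skipped."""
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if not seg.is_paired or seg.is_duplicate:
                continue
            if not _passes_filters(seg, max_mismatches):
                pending.pop(seg.query_name, None)
                continue
            mate = pending.pop(seg.query_name, None)
            if mate is None:
                pending[seg.query_name] = seg
                continue
            first, second = (mate, seg) if mate.is_read1 else (seg, mate)
            yield ReadPairRecord(
                pair_id=seg.query_name,
                sample_id=sample_id,
                end1=_aligned_end(first),
                end2=_aligned_end(second),
            )
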