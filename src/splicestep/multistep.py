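"""Discovery and classification of multi-step intron-removal events.

Split (gapped) single-end alignments whose skip does not match an annotated
junction are candidate intermediates of multi-step splicing.  After motif-
guided boundary refinement, boundary filters and a presence-in-every-cell-line
intersection, each event is classified by which of its two sites reuses an
annotated splice site:

* 5'RS  - annotated donor + internal acceptor (5' recursive / ratchet step)
* 3'RS  - internal donor + annotated acceptor
* nested - both sites internal

A 5'RS and a 3'RS event in one intron whose internal sites leave a positive
internal segment form an intermezzo pair: the retained cassette is
transiently joined to the flanking exons and removed in a final step.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam
from scipy import stats

from .gene_model import GeneModel
from .read_classify import _aligned_end, _passes_filters

__all__ = [
    "SplitAlignment",
    "SpliceEvent",
    "extract_split_reads",
    "compute_shift_range",
    "refine_gap_boundaries",
    "filter_split_events",
    "build_event_matrix",
    "intersect_samples",
    "classify_event",
    "detect_intermezzo",
    "classify_intron_steps",
    "reanalyze_event_table",
    "get_seq",
]

EVENT_CLASSES = ("5RS", "3RS", "nested")


@dataclass(frozen=True)
class SplitAlignment:
    read_id: str
    sample_id: str
    cell_line: str
    gap_start: int  # first skipped base (genomic, 1-based)
    gap_end: int  # last skipped base
    shift_left: int = 0  # how far the gap can slide (alignment-equivalent)
    shift_right: int = 0

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start + 1


@dataclass
class SpliceEvent:
    donor_pos: int  # transcript-sense 5' site: first skipped base
    acceptor_pos: int  # transcript-sense 3' site: last skipped base
    intron: int
    support: dict[str, int] = field(default_factory=dict)  # cell line -> reads
    event_class: str | None = None
    intermezzo_partner: tuple[int, int] | None = None  # partner (donor, acceptor)

    @property
    def span(self) -> int:
        return abs(self.acceptor_pos - self.donor_pos) + 1

    def key(self) -> tuple[int, int]:
        return (self.donor_pos, self.acceptor_pos)


# ---- sequence access ------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def get_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end] 1-based closed from a dict, str or pyfaidx-like."""
    if start < 1:
        raise IndexError(f"position {start} before contig start")
    if isinstance(genome, str):
        return genome[start - 1 : end].upper()
    if isinstance(genome, dict):
        return genome[chrom][start - 1 : end].upper()
    return str(genome[chrom][start - 1 : end]).upper()  # pyfaidx.Fasta


# ---- extraction -----------------------------------------------------------


def extract_split_reads(
    path: str,
    model: GeneModel,
    sample_id: str = "",
    cell_line: str = "",
    min_gap: int = 50,
    max_mismatches: int = 5,
) -> list[SplitAlignment]:
    """One SplitAlignment per qualifying skip gap; each mate of a pair is
    treated as an independent single-end read, and a read with several gaps
    yields several records."""
    s, e = model.span
    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if not _passes_filters(seg, max_mismatches):
                continue
            end = _aligned_end(seg)
            for lo, hi in end.gaps:
                if hi - lo + 1 < min_gap:
                    continue
                if lo < s or hi > e:
                    continue
                out.append(
                    SplitAlignment(
                        read_id=seg.query_name,
                        sample_id=sample_id,
                        cell_line=cell_line,
                        gap_start=lo,
                        gap_end=hi,
                    )
                )
    return out


# ---- boundary refinement --------------------------------------------------


def compute_shift_range(split: SplitAlignment, genome, chrom: str, max_shift: int = 10) -> SplitAlignment:
    """Alignment-equivalent slide range of the gap.

    The gap [s, e] can shift right by k when seq[s+j-1] == seq[e+j] for
    j = 1..k (the bases entering the gap on the left match those leaving on
    the right), and symmetrically for left shifts.
    """
    s, e = split.gap_start, split.gap_end

    def base(pos: int) -> str:
        try:
            b = get_seq(genome, chrom, pos, pos)
        except (IndexError, KeyError):
            return ""
        return b

    right = 0
    while right < max_shift and base(s + right) != "" and base(s + right) == base(e + right + 1):
        right += 1
    left = 0
    while left < max_shift and base(s - left - 1) != "" and base(s - left - 1) == base(e - left):
        left += 1
    return replace(split, shift_left=left, shift_right=right)


def _motif_score(genome, chrom: str, strand: str, lo: int, hi: int) -> int:
    """Matches of the transcript-sense terminal dinucleotides against GT..AG
    (0-4)."""
    if strand == "+":
        donor = get_seq(genome, chrom, lo, lo + 1)
        acceptor = get_seq(genome, chrom, hi - 1, hi)
    else:
        donor = revcomp(get_seq(genome, chrom, hi - 1, hi))
        acceptor = revcomp(get_seq(genome, chrom, lo, lo + 1))
    score = 0
    score += int(donor[0] == "G") + int(len(donor) > 1 and donor[1] == "T")
    score += int(acceptor[0] == "A") + int(len(acceptor) > 1 and acceptor[1] == "G")
    return score


def refine_gap_boundaries(
    split: SplitAlignment, genome, chrom: str, strand: str = "+"
) -> SplitAlignment:
    """Among all alignment-equivalent gap placements pick the one whose
    terminal dinucleotides best match the canonical GT..AG splice motif;
    ties resolve to the genomically leftmost placement.  Never moves outside
    the ambiguity range and never decreases the motif score."""
    best = None
    for k in range(-split.shift_left, split.shift_right + 1):
        lo, hi = split.gap_start + k, split.gap_end + k
        score = _motif_score(genome, chrom, strand, lo, hi)
        cand = (score, -lo)
        if best is None or cand > best[0]:
            best = (cand, k)
    k = best[1]
    return replace(
        split,
        gap_start=split.gap_start + k,
        gap_end=split.gap_end + k,
        shift_left=split.shift_left + k,
        shift_right=split.shift_right - k,
    )


# ---- filtering ------------------------------------------------------------


def _sites(split: SplitAlignment, strand: str) -> tuple[int, int]:
    """(donor_pos, acceptor_pos) in transcript sense."""
    if strand == "+":
        return split.gap_start, split.gap_end
    return split.gap_end, split.gap_start


def filter_split_events(
    splits: list[SplitAlignment], model: GeneModel, boundary_margin: int = 50
) -> list[SplitAlignment]:
    """Keep splits representing a within-one-intron event with at least one
    non-annotated site.

    Discards: gaps not contained in a single intron; gaps whose two sites are
    both annotated splice sites (ordinary junctions); gaps whose
    non-annotated site lies within ``boundary_margin`` nt of either
    exon-intron boundary (NAGNAG-style junction wobble)."""
    donors = model.annotated_donors
    acceptors = model.annotated_acceptors
    kept = []
    for sp in splits:
        f1 = model.feature_at(sp.gap_start)
        f2 = model.feature_at(sp.gap_end)
        if f1 is None or f2 is None or f1[0] != "intron" or f1 != f2:
            continue
        intron = model.intron(f1[1])
        donor, acceptor = _sites(sp, model.strand)
        donor_annot = donors.get(donor) == intron.index
        acceptor_annot = acceptors.get(acceptor) == intron.index
        if donor_annot and acceptor_annot:
            continue
        ok = True
        for pos, annot in ((donor, donor_annot), (acceptor, acceptor_annot)):
            if annot:
                continue
            if min(pos - intron.start, intron.end - pos) < boundary_margin:
                ok = False
                break
        if ok:
            kept.append(sp)
    return kept


# ---- matrices and intersection -------------------------------------------


def build_event_matrix(splits: list[SplitAlignment], strand: str = "+") -> dict[str, Counter]:
    """Per cell line, (donor_pos, acceptor_pos) -> split-read count, with
    libraries of the same cell line summed."""
    matrices: dict[str, Counter] = defaultdict(Counter)
    for sp in splits:
        matrices[sp.cell_line][_sites(sp, strand)] += 1
    return dict(matrices)


def intersect_samples(matrices: dict[str, Counter], model: GeneModel) -> list[SpliceEvent]:
    """Events with >=1 supporting read in every cell line (guards against
    PCR-duplicate artifacts private to one library)."""
    if not matrices:
        raise ValueError("no samples")
    lines = sorted(matrices)
    common = set(matrices[lines[0]])
    for ln in lines[1:]:
        common &= set(matrices[ln])
    events = []
    for donor, acceptor in sorted(common):
        pos_lo, pos_hi = min(donor, acceptor), max(donor, acceptor)
        feat = model.feature_at(pos_lo)
        intron = feat[1] if feat and feat[0] == "intron" else 0
        ev = SpliceEvent(
            donor_pos=donor,
            acceptor_pos=acceptor,
            intron=intron,
            support={ln: matrices[ln][(donor, acceptor)] for ln in lines},
        )
        ev.event_class = classify_event(ev, model)
        events.append(ev)
    return events


def classify_event(event: SpliceEvent, model: GeneModel) -> str:
    if event.intron < 1:
        return "unlocalized"
    intron = model.intron(event.intron)
    donor_annot = event.donor_pos == intron.donor_site
    acceptor_annot = event.acceptor_pos == intron.acceptor_site
    if donor_annot and not acceptor_annot:
        return "5RS"
    if acceptor_annot and not donor_annot:
        return "3RS"
    return "nested"


def detect_intermezzo(events: list[SpliceEvent], model: GeneModel) -> list[SpliceEvent]:
    """Pair 5'RS and 3'RS events of one intron whose internal sites bracket a
    positive retained segment (the intermezzo cassette).

    In transcript direction a 5'RS with internal acceptor a1 and a 3'RS with
    internal donor d2 strictly downstream of a1 retain d2 - a1 - 1 nt between
    them.  Both members are re-labeled; overlapping candidates stay unpaired.
    Multiple non-overlapping intermezzi per intron are allowed and reported
    independently (never merged)."""
    sign = 1 if model.strand == "+" else -1
    by_intron: dict[int, list[SpliceEvent]] = defaultdict(list)
    for ev in events:
        by_intron[ev.intron].append(ev)
    for intron, evs in by_intron.items():
        five = sorted(
            (e for e in evs if e.event_class == "5RS"),
            key=lambda e: sign * e.acceptor_pos,
        )
        three = sorted(
            (e for e in evs if e.event_class == "3RS"),
            key=lambda e: sign * e.donor_pos,
        )
        used = set()
        for f in five:
            for t in three:
                if id(t) in used:
                    continue
                retained = sign * (t.donor_pos - f.acceptor_pos) - 1
                if retained > 0:
                    f.intermezzo_partner = t.key()
                    t.intermezzo_partner = f.key()
                    f.event_class = "intermezzo"
                    t.event_class = "intermezzo"
                    used.add(id(t))
                    break
    return events


def intermezzo_retained_length(five: SpliceEvent, three: SpliceEvent, strand: str = "+") -> int:
    sign = 1 if strand == "+" else -1
    return sign * (three.donor_pos - five.acceptor_pos) - 1


# ---- per-intron summary ---------------------------------------------------


def classify_intron_steps(events: list[SpliceEvent], model: GeneModel) -> pd.DataFrame:
    """Per intron: multi-step iff at least one intersected event survived the
    filters, else single-step."""
    with_events = {ev.intron for ev in events}
    rows = []
    for intr in model.introns:
        rows.append(
            {
                "intron": intr.index,
                "length": intr.length,
                "n_events": sum(ev.intron == intr.index for ev in events),
                "mode": "multi-step" if intr.index in with_events else "single-step",
            }
        )
    return pd.DataFrame(rows)


def step_mode_summary(table: pd.DataFrame) -> dict:
    """Mean intron length per mode plus a rank-sum location test."""
    single = table.loc[table["mode"] == "single-step", "length"].to_numpy()
    multi = table.loc[table["mode"] == "multi-step", "length"].to_numpy()
    out = {
        "n_single": int(single.size),
        "n_multi": int(multi.size),
        "mean_length_single": float(single.mean()) if single.size else float("nan"),
        "mean_length_multi": float(multi.mean()) if multi.size else float("nan"),
    }
    if single.size and multi.size:
        out["ranksum_p"] = float(stats.mannwhitneyu(single, multi, alternative="two-sided").pvalue)
    return out


def reanalyze_event_table(table: pd.DataFrame, model: GeneModel) -> dict:
    """Re-derive event classes and summary fractions from a plain table of
    donor/acceptor coordinates (one row per intersected event).

    Expected columns: donor_pos, acceptor_pos (transcript-sense genomic
    coordinates); optional per-sample support columns are ignored here."""
    events = []
    for _, row in table.iterrows():
        lo = min(int(row.donor_pos), int(row.acceptor_pos))
        feat = model.feature_at(lo)
        intron = feat[1] if feat and feat[0] == "intron" else 0
        ev = SpliceEvent(int(row.donor_pos), int(row.acceptor_pos), intron)
        ev.event_class = classify_event(ev, model)
        events.append(ev)
    detect_intermezzo(events, model)
    n = len(events)
    by_class = Counter(ev.event_class for ev in events)
    steps = classify_intron_steps(events, model)
    return {
        "n_events": n,
        "counts": dict(by_class),
        "fractions": {k: v / n for k, v in by_class.items()} if n else {},
        "n_single_step_introns": int((steps["mode"] == "single-step").sum()),
        "n_multi_step_introns": int((steps["mode"] == "multi-step").sum()),
        "events": events,
    }
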