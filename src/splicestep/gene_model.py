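"""Transcript gene model: exons, derived introns, masks, coordinate authority.

All internal coordinates are 1-based, fully closed, on the genome (SAM/GFF
convention).  BED input is converted on read.  Exon and intron indices follow
transcript (5'->3') order, not genomic order, so "intron n sits between exons
n and n+1" holds on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gffutils
import numpy as np

__all__ = [
    "GeneModelError",
    "ExonInterval",
    "IntronInterval",
    "GeneModel",
    "load_gene_model",
    "load_bed12",
    "apply_masks",
]


class GeneModelError(ValueError):
    """Malformed or missing annotation."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon, transcript-order ``index`` starting at 1."""

    index: int
    start: int  # genomic, 1-based closed, start <= end
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IntronInterval:
    """Intron ``index`` lies between exons ``index`` and ``index + 1``.

    ``donor_site`` is the first intronic base at the 5' splice site and
    ``acceptor_site`` the last intronic base at the 3' splice site, so on the
    minus strand donor_site > acceptor_site genomically.
    """

    index: int
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def donor_site(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_site(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneModel:
    """Ordered exon/intron model of a single transcript plus coverage masks."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval]
    introns: list[IntronInterval] = field(default_factory=list)
    masks: list[tuple[int, int]] = field(default_factory=list)  # 1-based closed, merged

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"invalid strand {self.strand!r}")
        if len(self.exons) < 2:
            raise GeneModelError("malformed annotation: fewer than 2 exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:
                raise GeneModelError("malformed annotation: overlapping exons")
        if not self.introns:
            self.introns = self._derive_introns()
        # fast lookup arrays (genomic order)
        self._exon_starts = np.array([e.start for e in genomic])
        self._exon_ends = np.array([e.end for e in genomic])
        self._exon_index = np.array([e.index for e in genomic])

    def _derive_introns(self) -> list[IntronInterval]:
        introns = []
        for n, (a, b) in enumerate(zip(self.exons, self.exons[1:]), start=1):
            lo, hi = (a.end + 1, b.start - 1) if self.strand == "+" else (b.end + 1, a.start - 1)
            if hi < lo:
                raise GeneModelError("malformed annotation: adjacent exons leave no intron")
            introns.append(IntronInterval(n, lo, hi, self.strand))
        return introns

    # ---- span and lookup -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return int(self._exon_starts[0]), int(self._exon_ends[-1])

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s + 1

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def feature_at(self, pos: int) -> tuple[str, int] | None:
        """('exon', i) / ('intron', n) for a genomic position, None outside."""
        if not self.contains(pos):
            return None
        i = int(np.searchsorted(self._exon_starts, pos, side="right")) - 1
        if i >= 0 and pos <= self._exon_ends[i]:
            return ("exon", int(self._exon_index[i]))
        # between genomic exon i and i+1: transcript intron index
        left = int(self._exon_index[i])
        right = int(self._exon_index[i + 1])
        return ("intron", min(left, right))

    def exon(self, index: int) -> ExonInterval:
        return self.exons[index - 1]

    def intron(self, index: int) -> IntronInterval:
        return self.introns[index - 1]

    def junction_for_gap(self, gap_lo: int, gap_hi: int) -> int | None:
        """Junction index n if the skipped interval equals intron n exactly."""
        if not hasattr(self, "_gap_map"):
            self._gap_map = {(i.start, i.end): i.index for i in self.introns}
        return self._gap_map.get((gap_lo, gap_hi))

    @property
    def annotated_donors(self) -> dict[int, int]:
        return {i.donor_site: i.index for i in self.introns}

    @property
    def annotated_acceptors(self) -> dict[int, int]:
        return {i.acceptor_site: i.index for i in self.introns}

    # ---- masks -----------------------------------------------------------

    def masked_positions(self, start: int, end: int) -> int:
        """Number of masked bases inside [start, end]."""
        n = 0
        for ms, me in self.masks:
            lo, hi = max(start, ms), min(end, me)
            if hi >= lo:
                n += hi - lo + 1
        return n

    def effective_length(self, feature: ExonInterval | IntronInterval) -> int:
        return feature.length - self.masked_positions(feature.start, feature.end)

    def is_fully_masked(self, feature: ExonInterval | IntronInterval) -> bool:
        return self.effective_length(feature) == 0

    def unmasked_bool(self, start: int, end: int) -> np.ndarray:
        """Boolean array over [start, end], True where NOT masked."""
        keep = np.ones(end - start + 1, dtype=bool)
        for ms, me in self.masks:
            lo, hi = max(start, ms), min(end, me)
            if hi >= lo:
                keep[lo - start : hi - start + 1] = False
        return keep

    # ---- round trips -----------------------------------------------------

    def to_bed12(self) -> str:
        genomic = sorted(self.exons, key=lambda e: e.start)
        s, e = self.span
        sizes = ",".join(str(x.length) for x in genomic)
        starts = ",".join(str(x.start - s) for x in genomic)
        return "\t".join(
            map(
                str,
                [self.chrom, s - 1, e, self.gene_id, 0, self.strand, s - 1, e, 0,
                 len(genomic), sizes + ",", starts + ","],
            )
        )

    def to_tsv(self) -> str:
        lines = ["feature\tindex\tstart\tend\tlength\teffective_length"]
        for ex in self.exons:
            lines.append(f"exon\t{ex.index}\t{ex.start}\t{ex.end}\t{ex.length}\t{self.effective_length(ex)}")
        for intr in self.introns:
            lines.append(
                f"intron\t{intr.index}\t{intr.start}\t{intr.end}\t{intr.length}\t{self.effective_length(intr)}"
            )
        return "\n".join(lines) + "\n"


# ---- loaders -------------------------------------------------------------


def _model_from_genomic_exons(
    gene_id: str, chrom: str, strand: str, exons_genomic: list[tuple[int, int]]
) -> GeneModel:
    exons_genomic = sorted(exons_genomic)
    ordered = exons_genomic if strand == "+" else exons_genomic[::-1]
    exons = [ExonInterval(i, s, e) for i, (s, e) in enumerate(ordered, start=1)]
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)


def load_gene_model(annotation: str, gene_id: str, fmt: str | None = None) -> GeneModel:
    """Load the single-transcript model for ``gene_id``.

    ``annotation`` is a path or the literal GFF3/GTF/BED12 content.  Exactly
    one transcript must carry the gene id; alternative isoforms are rejected.
    """
    import os

    text = annotation
    if "\n" not in annotation and os.path.exists(annotation):
        with open(annotation) as fh:
            text = fh.read()
    if fmt is None:
        first = next((l for l in text.splitlines() if l.strip() and not l.startswith("#")), "")
        fmt = "bed12" if len(first.split("\t")) == 12 else "gff"
    if fmt == "bed12":
        return load_bed12(text, gene_id)

    db = gffutils.create_db(
        text, ":memory:", from_string=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_parent: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for ex in db.features_of_type("exon"):
        attrs = ex.attributes
        gid = (attrs.get("gene_id") or attrs.get("gene") or [None])[0]
        tid = (attrs.get("transcript_id") or attrs.get("Parent") or [gid])[0]
        if gid != gene_id and tid != gene_id:
            continue
        by_parent.setdefault(tid, []).append(ex)
        meta[tid] = (ex.seqid, ex.strand)
    if not by_parent:
        raise GeneModelError(f"gene not found: {gene_id}")
    if len(by_parent) > 1:
        raise GeneModelError(
            f"gene {gene_id} has {len(by_parent)} isoforms; a single transcript is required"
        )
    (tid, exs), = by_parent.items()
    chrom, strand = meta[tid]
    return _model_from_genomic_exons(gene_id, chrom, strand, [(e.start, e.end) for e in exs])


def load_bed12(text: str, gene_id: str | None = None) -> GeneModel:
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise GeneModelError("malformed annotation: BED12 requires 12 fields")
        if gene_id is not None and f[3] != gene_id:
            continue
        chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [
            (chrom_start + st + 1, chrom_start + st + sz) for st, sz in zip(starts, sizes)
        ]
        return _model_from_genomic_exons(name, chrom, strand, exons)
    raise GeneModelError(f"gene not found: {gene_id}")


def apply_masks(model: GeneModel, bed: str, warn=None) -> GeneModel:
    """Return a copy of ``model`` with mask intervals from BED content/path.

    BED is 0-based half-open; converted to the internal 1-based closed
    convention.  Intervals outside the gene span are ignored with a warning.
    """
    import os

    text = bed
    if bed and "\n" not in bed and os.path.exists(bed):
        with open(bed) as fh:
            text = fh.read()
    s, e = model.span
    raw: list[tuple[int, int]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if f[0] != model.chrom:
            continue
        lo, hi = int(f[1]) + 1, int(f[2])
        if hi < s or lo > e:
            if warn is not None:
                warn(f"mask {lo}-{hi} outside gene span; ignored")
            continue
        raw.append((max(lo, s), min(hi, e)))
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(raw):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    out = replace(model)
    out.masks = merged
    return out
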