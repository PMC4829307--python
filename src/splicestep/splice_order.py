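"""Splice-ratio analysis: relative order of removal of neighboring introns.

For intron n, a pair with one end spanning the exon(n)-exon(n+1) junction and
its mate inside intron n+1 shows intron n was removed while n+1 was still
present (sequential support, S).  A pair with one end inside intron n and its
mate spanning the exon(n+1)-exon(n+2) junction shows the downstream neighbor
went first (non-sequential support, NS).  splice_ratio = S / (S + NS);
ratios above 0.5 call the intron sequentially spliced, below 0.5
non-sequentially, with a small epsilon band around 0.5 called intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gene_model import GeneModel
from .read_classify import AlignedEnd

__all__ = [
    "OrderCounts",
    "OrderCall",
    "ExonBlock",
    "count_order_pairs",
    "splice_ratio",
    "call_all_introns",
    "derive_exon_blocks",
    "order_vs_coverage_correlation",
]


@dataclass
class OrderCounts:
    intron: int
    S: int = 0
    NS: int = 0

    @property
    def support(self) -> int:
        return self.S + self.NS


@dataclass(frozen=True)
class OrderCall:
    intron: int
    splice_ratio: float | None
    order_class: str  # sequential | non-sequential | intermediate | insufficient


@dataclass(frozen=True)
class ExonBlock:
    first_exon: int
    last_exon: int
    left_flank_intron: int | None  # None at a gene end
    right_flank_intron: int | None


def _junctions(end: AlignedEnd, model: GeneModel) -> set[int]:
    out = set()
    for lo, hi in end.gaps:
        j = model.junction_for_gap(lo, hi)
        if j is not None:
            out.add(j)
    return out


def _sole_intron(end: AlignedEnd, model: GeneModel) -> int | None:
    """Intron index if the end maps fully inside one intron, else None."""
    if end.gaps:
        return None
    idx = set()
    for bs, be in end.blocks:
        f1, f2 = model.feature_at(bs), model.feature_at(be)
        if f1 is None or f2 is None or f1[0] != "intron" or f1 != f2:
            return None
        idx.add(f1[1])
    return idx.pop() if len(idx) == 1 else None


def count_order_pairs(pairs, model: GeneModel) -> dict[int, OrderCounts]:
    """Tally S and NS per intron from intermediate-phase read pairs.

    A junction end counts only when its skip exactly matches an annotated
    intron, and the mate must lie fully inside the named intron.  Each pair
    increments at most one S and at most one NS tally (necessarily of
    different introns).
    """
    counts = {i.index: OrderCounts(i.index) for i in model.introns}
    n_introns = len(model.introns)
    for pair in pairs:
        s_hit = ns_hit = None
        for end, mate in ((pair.end1, pair.end2), (pair.end2, pair.end1)):
            juncs = _junctions(end, model)
            if not juncs:
                continue
            mate_intron = _sole_intron(mate, model)
            if mate_intron is None:
                continue
            for n in juncs:
                # S(n): junction ex(n)-ex(n+1) with mate in intron n+1
                if s_hit is None and mate_intron == n + 1 and n + 1 <= n_introns:
                    s_hit = n
                # NS(m): mate in intron m with junction ex(m+1)-ex(m+2), m = n-1
                if ns_hit is None and mate_intron == n - 1 and n - 1 >= 1:
                    ns_hit = n - 1
        if s_hit is not None:
            counts[s_hit].S += 1
        if ns_hit is not None:
            counts[ns_hit].NS += 1
    return counts


def splice_ratio(
    counts: OrderCounts, epsilon: float = 0.05, min_support: int = 5
) -> OrderCall:
    if counts.support < min_support or counts.support == 0:
        return OrderCall(counts.intron, None, "insufficient")
    ratio = counts.S / counts.support
    if abs(ratio - 0.5) <= epsilon:
        cls = "intermediate"
    elif ratio > 0.5:
        cls = "sequential"
    else:
        cls = "non-sequential"
    return OrderCall(counts.intron, ratio, cls)


def call_all_introns(
    counts: dict[int, OrderCounts],
    model: GeneModel,
    epsilon: float = 0.05,
    min_support: int = 5,
) -> dict[int, OrderCall]:
    """Per-intron order calls.  Both S and NS are undefined for the final
    intron (no further intron / junction downstream), so it is always
    reported as insufficient."""
    last = len(model.introns)
    out = {}
    for n, c in counts.items():
        if n == last:
            out[n] = OrderCall(n, None, "insufficient")
        else:
            out[n] = splice_ratio(c, epsilon, min_support)
    return out


def derive_exon_blocks(
    order_classes: dict[int, str],
    speed_classes: dict[int, str],
) -> list[ExonBlock]:
    """Maximal runs of >=2 consecutive early-removed introns (fast and/or
    sequential) flanked on both sides by slow or non-sequential introns;
    gene ends count as flanks.  A run of k introns joins k+1 exons, so a
    block always contains >=3 exons."""
    introns = sorted(set(order_classes) | set(speed_classes))
    first, last = introns[0], introns[-1]

    def is_flank(n: int) -> bool:
        return speed_classes.get(n) == "slow" or order_classes.get(n) == "non-sequential"

    def is_member(n: int) -> bool:
        if is_flank(n):
            return False
        return speed_classes.get(n) == "fast" or order_classes.get(n) == "sequential"

    blocks: list[ExonBlock] = []
    run: list[int] = []
    for n in introns + [None]:
        if n is not None and is_member(n):
            run.append(n)
            continue
        if len(run) >= 2:
            left = run[0] - 1 if run[0] > first else None
            right = n if (n is not None and is_flank(n)) else (None if run[-1] == last else -1)
            left_ok = left is None or is_flank(left)
            right_ok = right is None or (right != -1 and is_flank(right))
            if left_ok and right_ok:
                blocks.append(ExonBlock(run[0], run[-1] + 1, left, right if right != -1 else None))
        run = []
    return blocks


def order_vs_coverage_correlation(
    ratios: dict[int, float | None], normalized_coverage: dict[int, float]
) -> tuple[float, float]:
    """Pearson r (and p) between normalized intron coverage and splice-ratio
    over introns where both are defined.  Expected negative: low coverage
    (fast removal) goes with high splice-ratio (sequential)."""
    common = [n for n in ratios if ratios[n] is not None and np.isfinite(normalized_coverage.get(n, np.nan))]
    if len(common) < 3:
        raise ValueError("need >=3 introns with defined ratios")
    x = np.array([normalized_coverage[n] for n in common], dtype=float)
    y = np.array([ratios[n] for n in common], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate: constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
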