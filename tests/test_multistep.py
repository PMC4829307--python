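"""Split-read event discovery: extraction, refinement, filtering,
intersection, classification, intermezzo pairing."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from splicestep import multistep as ms
from splicestep.gene_model import ExonInterval, GeneModel


@pytest.fixture(scope="module")
def model2i():
    """2 introns: 101-1100 (1 kb) and 1301-4600 (3.3 kb)."""
    return GeneModel(
        "M", "c", "+",
        [ExonInterval(1, 1, 100), ExonInterval(2, 1101, 1300), ExonInterval(3, 4601, 4700)],
    )


def sam_text(model, rows):
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{model.chrom}\tLN:10000",
    ]
    for name, pos, cig in rows:
        lines.append(f"{name}\t0\t{model.chrom}\t{pos}\t60\t{cig}\t*\t0\t0\t*\t*")
    return "\n".join(lines) + "\n"


def split(lo, hi, line="A", sample="s1", read="r"):
    return ms.SplitAlignment(read, sample, line, lo, hi)


def test_extract_split_reads_per_gap(model2i, tmp_path):
    rows = [
        ("gapped", 1400, "40M3095N60M"),  # one qualifying gap inside intron 2
        ("plain", 200, "100M"),  # ungapped -> nothing
        ("twogaps", 150, "30M100N30M200N40M"),  # two records
        ("short", 300, "50M10N50M"),  # below min_gap -> nothing
    ]
    p = tmp_path / "x.sam"
    p.write_text(sam_text(model2i, rows))
    out = ms.extract_split_reads(str(p), model2i, "s1", "A")
    by_read = Counter(s.read_id for s in out)
    assert by_read == {"gapped": 1, "twogaps": 2}
    g = next(s for s in out if s.read_id == "gapped")
    assert g.gap_length == 3095


def test_shift_range_and_refinement_pick_canonical_placement():
    #            1         2         3
    #   123456789012345678901234567890123456
    seq = "AAAACCGTTTTTTTTTTAGGCCCCAAAACCCC"
    # true gap 7..19 is GT.......AG; the equal flanking G makes it slideable
    sp = split(8, 20)  # misplaced by +1: starts at T, ends past the AG
    sp = ms.compute_shift_range(sp, seq, "c")
    assert sp.shift_left >= 1
    ref = ms.refine_gap_boundaries(sp, seq, "c", "+")
    assert (ref.gap_start, ref.gap_end) == (7, 19)
    assert seq[ref.gap_start - 1 : ref.gap_start + 1] == "GT"
    assert seq[ref.gap_end - 2 : ref.gap_end] == "AG"


def test_refinement_identity_when_shift_range_is_zero():
    seq = "ACGTACGTACGTACGTACGTACGTACGT"
    sp = split(5, 20)  # shift range left at 0: placement must not move
    ref = ms.refine_gap_boundaries(sp, seq, "c", "+")
    assert (ref.gap_start, ref.gap_end) == (5, 20)


def test_refinement_tie_breaks_leftmost():
    # two placements with identical (zero-canonical) score: stay leftmost
    seq = "AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
    sp = ms.compute_shift_range(split(10, 19), seq, "c", max_shift=3)
    ref = ms.refine_gap_boundaries(sp, seq, "c", "+")
    assert ref.gap_start == 10 - sp.shift_left


def test_refinement_never_decreases_motif_score():
    rng = np.random.default_rng(13)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), 400))
        lo = int(rng.integers(50, 200))
        hi = lo + int(rng.integers(60, 150))
        sp = ms.compute_shift_range(split(lo, hi), seq, "c")
        ref = ms.refine_gap_boundaries(sp, seq, "c", "+")
        assert -sp.shift_left <= ref.gap_start - lo <= sp.shift_right
        assert ms._motif_score(seq, "c", "+", ref.gap_start, ref.gap_end) >= ms._motif_score(
            seq, "c", "+", lo, hi
        )


def test_filters(model2i):
    i2 = model2i.intron(2)  # 1301..4300
    # both sites annotated (ordinary junction) -> discarded
    annotated = split(i2.start, i2.end)
    # non-annotated acceptor 30 nt from the 3' boundary -> discarded
    near_edge = split(i2.start, i2.end - 30)
    # annotated donor + mid-intron acceptor (>50 in) -> retained (5'RS shape)
    good = split(i2.start, i2.start + 999)
    # gap spanning two introns -> discarded
    multi = split(model2i.intron(1).start + 60, i2.start + 500)
    kept = ms.filter_split_events([annotated, near_edge, good, multi], model2i)
    assert kept == [good]


def test_event_matrix_sums_libraries_within_cell_line(model2i):
    i2 = model2i.intron(2)
    d, a = i2.start, i2.start + 999
    splits = [split(d, a, "A", "lib1")] * 2 + [split(d, a, "A", "lib2")] * 3
    mats = ms.build_event_matrix(splits, "+")
    assert mats["A"][(d, a)] == 5


def test_intersection_keeps_3_of_3_only(model2i):
    i2 = model2i.intron(2)
    everywhere = (i2.start, i2.start + 999)
    partial = (i2.start + 200, i2.start + 1400)
    mats = {
        "A": Counter({everywhere: 2, partial: 4}),
        "B": Counter({everywhere: 1, partial: 2}),
        "C": Counter({everywhere: 3}),
    }
    events = ms.intersect_samples(mats, model2i)
    assert [ev.key() for ev in events] == [everywhere]
    assert events[0].support == {"A": 2, "B": 1, "C": 3}
    with pytest.raises(ValueError, match="no samples"):
        ms.intersect_samples({}, model2i)


def test_event_classification(model2i):
    i2 = model2i.intron(2)
    five = ms.SpliceEvent(i2.donor_site, i2.start + 3094, 2)
    three = ms.SpliceEvent(i2.end - 1802, i2.acceptor_site, 2)
    nested = ms.SpliceEvent(i2.start + 400, i2.start + 900, 2)
    assert ms.classify_event(five, model2i) == "5RS"
    assert ms.classify_event(three, model2i) == "3RS"
    assert ms.classify_event(nested, model2i) == "nested"


def test_intermezzo_pairing_and_retained_length(model2i):
    i2 = model2i.intron(2)
    # 5' part ends at a1; 3' part starts at d2 = a1 + 159 -> retained 158 nt
    a1 = i2.start + 799
    d2 = a1 + 159
    five = ms.SpliceEvent(i2.donor_site, a1, 2, event_class="5RS")
    three = ms.SpliceEvent(d2, i2.acceptor_site, 2, event_class="3RS")
    lone = ms.SpliceEvent(i2.donor_site, i2.start + 2000, 2, event_class="5RS")
    ms.detect_intermezzo([five, three, lone], model2i)
    assert five.event_class == three.event_class == "intermezzo"
    assert five.intermezzo_partner == three.key()
    assert ms.intermezzo_retained_length(five, three, "+") == 158
    assert lone.event_class == "5RS" and lone.intermezzo_partner is None


def test_intermezzo_overlapping_pair_not_paired(model2i):
    i2 = model2i.intron(2)
    five = ms.SpliceEvent(i2.donor_site, i2.start + 1500, 2, event_class="5RS")
    three = ms.SpliceEvent(i2.start + 1000, i2.acceptor_site, 2, event_class="3RS")
    ms.detect_intermezzo([five, three], model2i)
    assert five.event_class == "5RS" and three.event_class == "3RS"


def test_step_mode_summary_and_ranksum(model2i):
    i2 = model2i.intron(2)
    events = [ms.SpliceEvent(i2.start + 400, i2.start + 900, 2, event_class="nested")]
    table = ms.classify_intron_steps(events, model2i)
    assert table.set_index("intron")["mode"].to_dict() == {1: "single-step", 2: "multi-step"}
    summary = ms.step_mode_summary(table)
    assert summary["n_single"] == 1 and summary["n_multi"] == 1
    assert summary["mean_length_multi"] == 3300.0


def test_reanalyze_event_table(model2i):
    i2 = model2i.intron(2)
    table = pd.DataFrame(
        {
            "donor_pos": [i2.donor_site, i2.start + 400, i2.end - 500],
            "acceptor_pos": [i2.start + 999, i2.start + 900, i2.acceptor_site],
        }
    )
    out = ms.reanalyze_event_table(table, model2i)
    assert out["n_events"] == 3
    # the 5'RS + 3'RS pair brackets a positive retained segment -> intermezzo
    assert out["counts"] == {"intermezzo": 2, "nested": 1}
    assert out["n_single_step_introns"] == 1
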