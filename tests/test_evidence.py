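"""Fragment QC and classification."""

import math

import pytest

from fusionscope.errors import CrossContigPairError, FusionScopeError
from fusionscope.evidence import (
    AlignedRead,
    FragmentClass,
    QCThresholds,
    classify_fragment,
    collect_breakpoints,
    end_clipping,
    percent_identity,
    sequence_entropy,
)


def _read(contig, start, cigar, seq, nm=0, reverse=False, qname="f1"):
    return AlignedRead(
        qname=qname,
        contig=contig,
        start=start,
        cigar=cigar,
        edit_distance=nm,
        sequence=seq,
        is_reverse=reverse,
    )


class TestSequenceEntropy:
    def test_single_symbol(self):
        assert sequence_entropy("AAAAAAAAAA") == 0.0

    def test_uniform_four_symbols(self):
        assert sequence_entropy("ACGTACGTACGT") == pytest.approx(2.0)

    def test_hand_computed_two_symbol(self):
        # 6 A, 4 C: -(0.6 log2 0.6 + 0.4 log2 0.4) = 0.970951
        assert sequence_entropy("AAACCAAACC") == pytest.approx(0.9710, abs=1e-4)

    def test_n_excluded(self):
        assert sequence_entropy("AANNAA") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(FusionScopeError):
            sequence_entropy("")


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "aligned,nm,expected",
        [(100, 2, 0.98), (100, 3, 0.97), (50, 0, 1.0)],
    )
    def test_examples(self, aligned, nm, expected):
        read = _read("c", 0, [("M", aligned)], "A" * aligned, nm=nm)
        assert percent_identity(read) == pytest.approx(expected)

    def test_no_aligned_bases_rejected(self):
        read = _read("c", 0, [("S", 10)], "A" * 10)
        with pytest.raises(FusionScopeError):
            percent_identity(read)


class TestEndClipping:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ([("S", 10), ("M", 90)], (10, 0)),
            ([("S", 11), ("M", 89)], (11, 0)),
            ([("M", 90), ("H", 10)], (0, 10)),
            ([("M", 100)], (0, 0)),
        ],
    )
    def test_examples(self, cigar, expected):
        n = sum(l for op, l in cigar if op in "MIS=X")
        assert end_clipping(_read("c", 0, cigar, "A" * n)) == expected


@pytest.fixture(scope="module")
def contig(toy_contig):
    return toy_contig


def _split_pair(contig, left_break, right_break, a=40, b=60, nm=0, qname="sp1"):
    gap = right_break - left_break - 1
    start = left_break + 1 - a
    seq = (
        contig.sequence[start : left_break + 1]
        + contig.sequence[right_break : right_break + b]
    )
    r1 = _read(contig.name, start, [("M", a), ("N", gap), ("M", b)], seq, nm=nm, qname=qname)
    m_start = right_break + b + 20
    r2 = _read(
        contig.name,
        m_start,
        [("M", 100)],
        contig.sequence[m_start : m_start + 100],
        reverse=True,
        qname=qname,
    )
    return (r1, r2)


class TestClassifyFragment:
    def test_clean_split_read(self, contig):
        lb = contig.geneB_offset - 50
        rb = contig.geneB_offset + 80
        ev = classify_fragment(_split_pair(contig, lb, rb), contig)
        assert ev.fclass is FragmentClass.SPLIT
        assert ev.breakpoint == (lb, rb)
        assert (ev.anchor_left, ev.anchor_right) == (40, 60)

    def test_split_with_short_anchor_discarded(self, contig):
        lb = contig.geneB_offset - 50
        rb = contig.geneB_offset + 80
        ev = classify_fragment(_split_pair(contig, lb, rb, a=9, b=60), contig)
        assert ev.fclass is FragmentClass.DISCARD

    def test_split_low_identity_discarded(self, contig):
        lb = contig.geneB_offset - 50
        rb = contig.geneB_offset + 80
        ev = classify_fragment(_split_pair(contig, lb, rb, nm=3), contig)
        assert ev.fclass is FragmentClass.DISCARD

    def test_split_low_entropy_anchor_discarded(self, contig):
        lb = contig.geneB_offset - 50
        rb = contig.geneB_offset + 80
        pair = _split_pair(contig, lb, rb)
        r1 = pair[0]
        poly_a = "A" * 40 + r1.sequence[40:]
        r1 = _read(contig.name, r1.start, r1.cigar, poly_a, qname=r1.qname)
        ev = classify_fragment((r1, pair[1]), contig)
        assert ev.fclass is FragmentClass.DISCARD

    def test_spanning_pair(self, contig):
        off = contig.geneB_offset
        r1 = _read(contig.name, 100, [("M", 100)], contig.sequence[100:200])
        r2 = _read(
            contig.name,
            off + 150,
            [("M", 100)],
            contig.sequence[off + 150 : off + 250],
            reverse=True,
        )
        ev = classify_fragment((r1, r2), contig)
        assert ev.fclass is FragmentClass.SPANNING

    def test_discordant_orientation_not_spanning(self, contig):
        off = contig.geneB_offset
        r1 = _read(contig.name, 100, [("M", 100)], contig.sequence[100:200], reverse=True)
        r2 = _read(
            contig.name,
            off + 150,
            [("M", 100)],
            contig.sequence[off + 150 : off + 250],
            reverse=True,
        )
        ev = classify_fragment((r1, r2), contig)
        assert ev.fclass is FragmentClass.BACKGROUND

    def test_counter_5p_requires_breakpoints(self, contig):
        lb = contig.geneB_offset - 200
        rb = contig.geneB_offset + 80
        start = lb - 30
        r = _read(contig.name, start, [("M", 100)], contig.sequence[start : start + 100])
        assert classify_fragment((r,), contig).fclass is FragmentClass.BACKGROUND
        ev = classify_fragment((r,), contig, breakpoints=[(lb, rb)])
        assert ev.fclass is FragmentClass.COUNTER_5P

    def test_counter_3p(self, contig):
        lb = contig.geneB_offset - 200
        rb = contig.geneB_offset + 300
        start = rb - 40
        r = _read(contig.name, start, [("M", 100)], contig.sequence[start : start + 100])
        ev = classify_fragment((r,), contig, breakpoints=[(lb, rb)])
        assert ev.fclass is FragmentClass.COUNTER_3P

    def test_counter_needs_overlap_both_sides(self, contig):
        lb = contig.geneB_offset - 200
        rb = contig.geneB_offset + 80
        start = lb - 5  # only 6 bases left of the breakpoint
        r = _read(contig.name, start, [("M", 100)], contig.sequence[start : start + 100])
        ev = classify_fragment((r,), contig, breakpoints=[(lb, rb)])
        assert ev.fclass is FragmentClass.BACKGROUND

    def test_cross_contig_pair_rejected(self, contig):
        r1 = _read("other", 0, [("M", 100)], "A" * 100)
        r2 = _read(contig.name, 0, [("M", 100)], "A" * 100, reverse=True)
        with pytest.raises(CrossContigPairError):
            classify_fragment((r1, r2), contig)

    def test_classification_is_partition(self, contig):
        """Every fragment receives exactly one class."""
        off = contig.geneB_offset
        lb, rb = off - 50, off + 80
        pairs = [
            _split_pair(contig, lb, rb, qname="a"),
            (
                _read(contig.name, 100, [("M", 100)], contig.sequence[100:200], qname="b"),
                _read(contig.name, off + 10, [("M", 100)],
                      contig.sequence[off + 10 : off + 110], reverse=True, qname="b"),
            ),
            (_read(contig.name, 5, [("M", 50)], contig.sequence[5:55], qname="c"),),
        ]
        for pair in pairs:
            ev = classify_fragment(pair, contig, breakpoints=[(lb, rb)])
            assert isinstance(ev.fclass, FragmentClass)

    def test_monotonic_under_tightening(self, contig):
        off = contig.geneB_offset
        lb, rb = off - 50, off + 80
        pairs = [
            _split_pair(contig, lb, rb, a=12, b=60, qname="s1"),
            _split_pair(contig, lb, rb, a=40, b=40, qname="s2"),
            (
                _read(contig.name, 100, [("M", 100)], contig.sequence[100:200], qname="p"),
                _read(contig.name, off + 10, [("M", 100)],
                      contig.sequence[off + 10 : off + 110], reverse=True, qname="p"),
            ),
        ]
        loose = QCThresholds()
        tight = QCThresholds(min_anchor=20, min_identity=0.99, min_entropy=1.5)

        def support(thr):
            classes = [classify_fragment(p, contig, thr).fclass for p in pairs]
            return sum(
                c in (FragmentClass.SPLIT, FragmentClass.SPANNING) for c in classes
            )

        assert support(tight) <= support(loose)


class TestCollectBreakpoints:
    def test_two_breakpoints_disjoint_split_sets(self, contig):
        off = contig.geneB_offset
        bp1 = (off - 300, off + 50)
        bp2 = (off - 100, off + 200)
        frags = [
            classify_fragment(_split_pair(contig, *bp1, qname=f"x{i}"), contig)
            for i in range(3)
        ] + [
            classify_fragment(_split_pair(contig, *bp2, qname=f"y{i}"), contig)
            for i in range(2)
        ]
        cands = collect_breakpoints(frags, contig)
        assert [c.key for c in cands] == [bp1, bp2]
        assert cands[0].split_read_ids == {"x0", "x1", "x2"}
        assert cands[1].split_read_ids == {"y0", "y1"}
        assert not (cands[0].split_read_ids & cands[1].split_read_ids)

    def test_spanning_bracketing_both_breakpoints(self, contig):
        off = contig.geneB_offset
        bp1 = (off - 300, off + 50)
        bp2 = (off - 100, off + 200)
        frags = [
            classify_fragment(_split_pair(contig, *bp1, qname="x"), contig),
            classify_fragment(_split_pair(contig, *bp2, qname="y"), contig),
        ]
        r1 = _read(contig.name, off - 500, [("M", 100)],
                   contig.sequence[off - 500 : off - 400], qname="sp")
        r2 = _read(contig.name, off + 250, [("M", 100)],
                   contig.sequence[off + 250 : off + 350], reverse=True, qname="sp")
        frags.append(classify_fragment((r1, r2), contig))
        cands = collect_breakpoints(frags, contig)
        assert all("sp" in c.spanning_compatible_ids for c in cands)

    def test_spanning_only_creates_no_candidate(self, contig):
        off = contig.geneB_offset
        r1 = _read(contig.name, 100, [("M", 100)], contig.sequence[100:200], qname="sp")
        r2 = _read(contig.name, off + 10, [("M", 100)],
                   contig.sequence[off + 10 : off + 110], reverse=True, qname="sp")
        frags = [classify_fragment((r1, r2), contig)]
        assert collect_breakpoints(frags, contig) == []

    def test_counter_counts_tallied(self, contig):
        off = contig.geneB_offset
        bp = (off - 200, off + 300)
        frags = [classify_fragment(_split_pair(contig, *bp, qname="s"), contig)]
        for i, pos in enumerate((bp[0] - 30, bp[0] - 45)):
            r = _read(contig.name, pos, [("M", 100)],
                      contig.sequence[pos : pos + 100], qname=f"c{i}")
            frags.append(classify_fragment((r,), contig, breakpoints=[bp]))
        r3 = _read(contig.name, bp[1] - 50, [("M", 100)],
                   contig.sequence[bp[1] - 50 : bp[1] + 50], qname="c3")
        frags.append(classify_fragment((r3,), contig, breakpoints=[bp]))
        cands = collect_breakpoints(frags, contig)
        assert cands[0].counter_5p_count == 2
        assert cands[0].counter_3p_count == 1
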