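"""Fragment classification against fusion contigs.

Each aligned fragment becomes exactly one of: breakpoint-defining SPLIT
read, SPANNING pair, COUNTER evidence for an unfused partner, BACKGROUND,
or DISCARD when it would be evidence but fails per-read QC (identity,
end clipping, anchor length, anchor entropy).
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pysam

from .contig import FusionContig
from .errors import CrossContigPairError, FusionScopeError

logger = logging.getLogger(__name__)

_CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")
_ALIGN_OPS = set("M=X")


class FragmentClass(str, Enum):
    SPLIT = "SPLIT"
    SPANNING = "SPANNING"
    COUNTER_5P = "COUNTER_5P"
    COUNTER_3P = "COUNTER_3P"
    BACKGROUND = "BACKGROUND"
    DISCARD = "DISCARD"


@dataclass
class QCThresholds:
    """Per-read evidence requirements (defaults follow the method)."""

    min_anchor: int = 10
    min_entropy: float = 1.2
    min_identity: float = 0.98
    max_end_clip: int = 10
    counter_overlap: int = 10


@dataclass
class AlignedRead:
    """One alignment record, pre-digested from SAM/BAM."""

    qname: str
    contig: str
    start: int
    cigar: list[tuple[str, int]]
    edit_distance: int
    sequence: str
    is_reverse: bool = False
    is_read1: bool = True

    @property
    def aligned_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _ALIGN_OPS)

    @property
    def ref_end(self) -> int:
        """One past the last reference base consumed."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    def end_clipping(self) -> tuple[int, int]:
        """Terminal soft+hard clip lengths, (left, right)."""
        left = right = 0
        i = 0
        while i < len(self.cigar) and self.cigar[i][0] in "SH":
            left += self.cigar[i][1]
            i += 1
        j = len(self.cigar) - 1
        while j > i and self.cigar[j][0] in "SH":
            right += self.cigar[j][1]
            j -= 1
        return left, right

    def ref_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by aligned (M/=/X) bases."""
        blocks = []
        ref = self.start
        for op, n in self.cigar:
            if op in _ALIGN_OPS:
                blocks.append((ref, ref + n))
            if op in _REF_CONSUMING:
                ref += n
        return blocks

    def junction_gaps(self) -> list[dict]:
        """N-gap junctions with flanking aligned-base tallies and query
        subsequences on each side of the gap."""
        gaps = []
        ref = self.start
        query = 0
        events: list[tuple[str, int, int, int]] = []  # (op, n, ref_at, query_at)
        for op, n in self.cigar:
            events.append((op, n, ref, query))
            if op in _REF_CONSUMING:
                ref += n
            if op in _QUERY_CONSUMING:
                query += n
        for idx, (op, n, ref_at, _) in enumerate(events):
            if op != "N":
                continue
            left_ref = sum(
                m for o, m, _, _ in events[:idx] if o in _ALIGN_OPS
            )
            right_ref = sum(
                m for o, m, _, _ in events[idx + 1 :] if o in _ALIGN_OPS
            )
            left_q = "".join(
                self.sequence[q : q + m]
                for o, m, _, q in events[:idx]
                if o in _ALIGN_OPS
            )
            right_q = "".join(
                self.sequence[q : q + m]
                for o, m, _, q in events[idx + 1 :]
                if o in _ALIGN_OPS
            )
            gaps.append(
                {
                    "gap_start": ref_at,
                    "gap_end": ref_at + n,
                    "anchor_left": left_ref,
                    "anchor_right": right_ref,
                    "left_seq": left_q,
                    "right_seq": right_q,
                }
            )
        return gaps

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedRead":
        cigar = [(_CIGAR_OPS[op], n) for op, n in (aln.cigartuples or [])]
        return cls(
            qname=aln.query_name,
            contig=aln.reference_name,
            start=aln.reference_start,
            cigar=cigar,
            edit_distance=_edit_distance(aln),
            sequence=(aln.query_sequence or "").upper(),
            is_reverse=aln.is_reverse,
            is_read1=not aln.is_read2,
        )


_warned_no_nm = False


def _edit_distance(aln: pysam.AlignedSegment) -> int:
    global _warned_no_nm
    if aln.has_tag("NM"):
        return int(aln.get_tag("NM"))
    if aln.has_tag("MD"):
        md = str(aln.get_tag("MD"))
        mismatches = len(re.findall(r"[ACGTN]", re.sub(r"\^[ACGTN]+", "", md)))
        indels = sum(n for op, n in (aln.cigartuples or []) if op in (1, 2))
        return mismatches + indels
    if not _warned_no_nm:
        logger.warning("no NM or MD tag found; assuming edit distance 0")
        _warned_no_nm = True
    return 0


def sequence_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the A/C/G/T composition; N excluded."""
    if not seq:
        raise FusionScopeError("entropy of empty sequence")
    counts = Counter(b for b in seq.upper() if b in "ACGT")
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def percent_identity(read: AlignedRead) -> float:
    """(aligned length - edit distance) / aligned length."""
    alen = read.aligned_length
    if alen == 0:
        raise FusionScopeError(f"read {read.qname}: no aligned bases")
    return (alen - read.edit_distance) / alen


def end_clipping(read: AlignedRead) -> tuple[int, int]:
    return read.end_clipping()


@dataclass
class FragmentEvidence:
    """Classification outcome for one fragment (read pair or orphan)."""

    fragment_id: str
    fclass: FragmentClass
    breakpoint: tuple[int, int] | None = None
    anchor_left: int = 0
    anchor_right: int = 0
    qc: dict = field(default_factory=dict)
    # per-mate alignment geometry, kept for breakpoint bookkeeping
    mate_spans: list[tuple[int, int]] = field(default_factory=list)
    mate_blocks: list[list[tuple[int, int]]] = field(default_factory=list)


@dataclass
class BreakpointCandidate:
    """A distinct (left_break, right_break) with its evidence sets.

    ``left_break`` is the contig coordinate of the last base of the 5'
    segment; ``right_break`` the first base of the 3' segment.
    """

    contig: str
    left_break: int
    right_break: int
    split_read_ids: set[str] = field(default_factory=set)
    spanning_compatible_ids: set[str] = field(default_factory=set)
    counter_5p_count: int = 0
    counter_3p_count: int = 0

    @property
    def key(self) -> tuple[int, int]:
        return (self.left_break, self.right_break)


def _passes_basic(read: AlignedRead, thr: QCThresholds) -> bool:
    left, right = read.end_clipping()
    if left > thr.max_end_clip or right > thr.max_end_clip:
        return False
    return percent_identity(read) >= thr.min_identity


def _junction_crossing(read: AlignedRead, offset: int) -> dict | None:
    """The junction gap whose removed interval spans geneB_offset."""
    for gap in read.junction_gaps():
        if gap["gap_start"] <= offset <= gap["gap_end"]:
            return gap
    return None


def _coverage(blocks, start, end) -> int:
    """Aligned bases falling inside [start, end)."""
    return sum(max(0, min(e, end) - max(s, start)) for s, e in blocks)


def _counter_hits(
    read: AlignedRead, contig: FusionContig, breakpoints, ov: int
) -> list[tuple[tuple[int, int], str]]:
    hits = []
    blocks = read.ref_blocks()
    span = (read.start, read.ref_end)
    for bp in breakpoints:
        left_break, right_break = bp if isinstance(bp, tuple) else bp.key
        if span[1] <= contig.geneB_offset:  # wholly within geneA
            before = _coverage(blocks, 0, left_break + 1)
            after = _coverage(blocks, left_break + 1, contig.geneB_offset)
            if before >= ov and after >= ov:
                hits.append(((left_break, right_break), "5P"))
        elif span[0] >= contig.geneB_offset:  # wholly within geneB
            before = _coverage(blocks, contig.geneB_offset, right_break)
            after = _coverage(blocks, right_break, len(contig))
            if before >= ov and after >= ov:
                hits.append(((left_break, right_break), "3P"))
    return hits


def classify_fragment(
    pair: tuple[AlignedRead, ...],
    contig: FusionContig,
    thresholds: QCThresholds | None = None,
    breakpoints: list | None = None,
) -> FragmentEvidence:
    """Classify one fragment (1 or 2 mates) against a fusion contig.

    COUNTER calls require candidate ``breakpoints``; without them a
    would-be counter fragment is BACKGROUND (the pipeline reclassifies
    after split-read breakpoints are known).
    """
    thr = thresholds or QCThresholds()
    reads = [r for r in pair if r is not None]
    if not reads:
        raise FusionScopeError("empty fragment")
    if len({r.contig for r in reads}) > 1:
        raise CrossContigPairError(
            f"fragment {reads[0].qname}: mates on different contigs"
        )
    fid = reads[0].qname
    offset = contig.geneB_offset
    spans = [(r.start, r.ref_end) for r in reads]
    blocks = [r.ref_blocks() for r in reads]

    def _result(fclass, **kw):
        return FragmentEvidence(
            fragment_id=fid,
            fclass=fclass,
            mate_spans=spans,
            mate_blocks=blocks,
            **kw,
        )

    # SPLIT: some mate's alignment crosses geneB_offset via a junction
    # gap; if several mates cross, a QC-passing one wins
    crossing = []
    for read in reads:
        gap = _junction_crossing(read, offset)
        if gap is None:
            continue
        ent_l = sequence_entropy(gap["left_seq"]) if gap["left_seq"] else 0.0
        ent_r = sequence_entropy(gap["right_seq"]) if gap["right_seq"] else 0.0
        qc = {
            "identity": percent_identity(read),
            "entropy_left": ent_l,
            "entropy_right": ent_r,
            "clip": read.end_clipping(),
        }
        ok = (
            _passes_basic(read, thr)
            and gap["anchor_left"] >= thr.min_anchor
            and gap["anchor_right"] >= thr.min_anchor
            and ent_l >= thr.min_entropy
            and ent_r >= thr.min_entropy
        )
        crossing.append((ok, gap, qc))
    if crossing:
        for ok, gap, qc in crossing:
            if ok:
                return _result(
                    FragmentClass.SPLIT,
                    breakpoint=(gap["gap_start"] - 1, gap["gap_end"]),
                    anchor_left=gap["anchor_left"],
                    anchor_right=gap["anchor_right"],
                    qc=qc,
                )
        return _result(FragmentClass.DISCARD, qc=crossing[0][2])

    # SPANNING: mates concordantly on opposite sides of the junction
    if len(reads) == 2:
        (s0, e0), (s1, e1) = spans
        left_idx = None
        if e0 <= offset and s1 >= offset:
            left_idx = 0
        elif e1 <= offset and s0 >= offset:
            left_idx = 1
        if left_idx is not None:
            left, right = reads[left_idx], reads[1 - left_idx]
            if not left.is_reverse and right.is_reverse:  # FR orientation
                qc = {
                    "identity": min(percent_identity(r) for r in reads),
                    "entropy": min(sequence_entropy(r.sequence) for r in reads),
                }
                ok = all(_passes_basic(r, thr) for r in reads) and all(
                    sequence_entropy(r.sequence) >= thr.min_entropy for r in reads
                )
                if ok:
                    return _result(FragmentClass.SPANNING, qc=qc)
                return _result(FragmentClass.DISCARD, qc=qc)

    # COUNTER: wholly within one gene, straddling a candidate breakpoint
    if breakpoints:
        hits = []
        for read in reads:
            hits.extend(_counter_hits(read, contig, breakpoints, thr.counter_overlap))
        if hits:
            qc = {
                "identity": min(percent_identity(r) for r in reads),
                "entropy": min(sequence_entropy(r.sequence) for r in reads),
            }
            ok = all(_passes_basic(r, thr) for r in reads) and all(
                sequence_entropy(r.sequence) >= thr.min_entropy for r in reads
            )
            if not ok:
                return _result(FragmentClass.DISCARD, qc=qc)
            side = "5P" if any(h[1] == "5P" for h in hits) else "3P"
            cls = (
                FragmentClass.COUNTER_5P if side == "5P" else FragmentClass.COUNTER_3P
            )
            return _result(cls, qc=qc)

    return _result(FragmentClass.BACKGROUND)


def collect_breakpoints(
    fragments: list[FragmentEvidence],
    contig: FusionContig,
    counter_overlap: int = 10,
) -> list[BreakpointCandidate]:
    """Aggregate fragment evidence into breakpoint candidates.

    Candidates exist only where split reads define a junction.  Each
    spanning fragment joins the compatible set of every candidate its
    mates bracket without crossing; counter fragments are tallied per
    side at every candidate they straddle.
    """
    candidates: dict[tuple[int, int], BreakpointCandidate] = {}
    for frag in fragments:
        if frag.fclass is FragmentClass.SPLIT:
            key = frag.breakpoint
            cand = candidates.setdefault(
                key,
                BreakpointCandidate(
                    contig=contig.name, left_break=key[0], right_break=key[1]
                ),
            )
            cand.split_read_ids.add(frag.fragment_id)

    for frag in fragments:
        if frag.fclass is FragmentClass.SPANNING:
            left_span = min(frag.mate_spans)
            right_span = max(frag.mate_spans)
            for cand in candidates.values():
                if (
                    left_span[1] - 1 <= cand.left_break
                    and right_span[0] >= cand.right_break
                ):
                    cand.spanning_compatible_ids.add(frag.fragment_id)
        elif frag.fclass in (FragmentClass.COUNTER_5P, FragmentClass.COUNTER_3P):
            for cand in candidates.values():
                seen = set()
                for blocks, span in zip(frag.mate_blocks, frag.mate_spans):
                    read = _SpanView(span, blocks)
                    for _, side in _counter_hits(
                        read, contig, [cand.key], counter_overlap
                    ):
                        seen.add(side)
                if "5P" in seen:
                    cand.counter_5p_count += 1
                if "3P" in seen:
                    cand.counter_3p_count += 1

    return sorted(candidates.values(), key=lambda c: c.key)


class _SpanView:
    """Minimal read-like view over stored spans/blocks for counter tallies."""

    def __init__(self, span, blocks):
        self.start, self._end = span
        self._blocks = blocks

    @property
    def ref_end(self):
        return self._end

    def ref_blocks(self):
        return self._blocks


def read_alignments(
    sam_path: str | Path,
) -> tuple[dict[str, dict[str, list[AlignedRead]]], int]:
    """Group primary alignments by contig and fragment name.

    Returns (contig -> qname -> mates, total distinct fragments in the
    file including unmapped records).  Fragments whose mates map to
    different contigs are dropped with a warning.
    """
    by_contig: dict[str, dict[str, list[AlignedRead]]] = defaultdict(dict)
    qnames: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for aln in sam:
            if aln.query_name:
                qnames.add(aln.query_name)
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            read = AlignedRead.from_pysam(aln)
            by_contig[read.contig].setdefault(read.qname, []).append(read)

    placed: dict[str, str] = {}
    dropped: set[str] = set()
    for ctg, groups in by_contig.items():
        for qname in groups:
            if qname in placed and placed[qname] != ctg:
                dropped.add(qname)
            placed[qname] = ctg
    if dropped:
        logger.warning("dropping %d cross-contig fragments", len(dropped))
        for ctg in by_contig:
            for qname in dropped:
                by_contig[ctg].pop(qname, None)
    return dict(by_contig), len(qnames)
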