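"""Breakpoint sequence features.

Splice dinucleotides, agreement with reference exon boundaries,
exact-k-mer microhomology mapping between the partner gene segments, and
assembly of the fixed 9-attribute vector used for clustering.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum

from .contig import FusionContig
from .errors import EdgeBreakpointError, FusionScopeError
from .evidence import BreakpointCandidate
from .quantify import ExpressionSummary

DEFAULT_CONSENSUS = frozenset({("GT", "AG")})
EXTENDED_CONSENSUS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})


class SpliceType(str, Enum):
    ONLY_REF_SPLICE = "ONLY_REF_SPLICE"
    INCL_NON_REF_SPLICE = "INCL_NON_REF_SPLICE"
    NON_CANONICAL = "NON_CANONICAL"


@dataclass
class MicrohomologyMap:
    """Exact shared k-mers between the two gene segments of a contig.

    ``matches`` holds (posA, posB) contig start coordinates with the
    k-mer wholly inside the respective segment.
    """

    k: int
    matches: list[tuple[int, int]]
    gene_a_length: int
    gene_b_length: int

    def __len__(self) -> int:
        return len(self.matches)


@dataclass
class BreakpointFeatures:
    donor_dinuc: str
    acceptor_dinuc: str
    consensus: bool
    left_ref_agree: bool
    right_ref_agree: bool
    splice_type: SpliceType
    n_microhomologies: int
    microhomology_distance: float


FEATURE_NAMES = (
    "ffpm",
    "far_5p",
    "far_3p",
    "counter_ffpm_5p",
    "counter_ffpm_3p",
    "consensus_indicator",
    "ref_agree_indicator",
    "n_microhomologies",
    "microhomology_distance",
)


@dataclass
class FeatureVector:
    """The 9 numeric attributes, in fixed order (see FEATURE_NAMES)."""

    ffpm: float
    far_5p: float
    far_3p: float
    counter_ffpm_5p: float
    counter_ffpm_3p: float
    consensus_indicator: int
    ref_agree_indicator: int
    n_microhomologies: int
    microhomology_distance: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(float(getattr(self, name)) for name in FEATURE_NAMES)


def find_microhomologies(contig: FusionContig, k: int = 10) -> MicrohomologyMap:
    """All exact k-mer matches between the geneA and geneB segments.

    Matches are enumerated as every (posA, posB) start pair; k-mers
    containing N are excluded.
    """
    if k < 4:
        raise FusionScopeError(f"microhomology k must be >= 4, got {k}")
    seq = contig.sequence.upper()
    offset = contig.geneB_offset
    index: dict[str, list[int]] = defaultdict(list)
    for pos in range(0, offset - k + 1):
        kmer = seq[pos : pos + k]
        if "N" not in kmer:
            index[kmer].append(pos)
    matches: list[tuple[int, int]] = []
    for pos in range(offset, len(seq) - k + 1):
        kmer = seq[pos : pos + k]
        if "N" in kmer:
            continue
        for pos_a in index.get(kmer, ()):
            matches.append((pos_a, pos))
    matches.sort()
    return MicrohomologyMap(
        k=k,
        matches=matches,
        gene_a_length=contig.gene_a_length,
        gene_b_length=contig.gene_b_length,
    )


def breakpoint_dinucleotides(
    contig: FusionContig,
    bp: BreakpointCandidate,
    consensus_set: frozenset = DEFAULT_CONSENSUS,
) -> tuple[str, str, bool]:
    """Donor/acceptor dinucleotides flanking a breakpoint.

    Donor = 2 bases immediately after the last 5'-segment base; acceptor
    = 2 bases immediately before the first 3'-segment base.
    """
    seq = contig.sequence
    if (
        bp.left_break < 2
        or bp.left_break + 3 > len(seq)
        or bp.right_break - 2 < 0
        or bp.right_break > len(seq) - 2
    ):
        raise EdgeBreakpointError(
            f"breakpoint ({bp.left_break}, {bp.right_break}) at contig edge"
        )
    donor = seq[bp.left_break + 1 : bp.left_break + 3].upper()
    acceptor = seq[bp.right_break - 2 : bp.right_break].upper()
    if len(donor) < 2 or len(acceptor) < 2:
        raise EdgeBreakpointError(
            f"breakpoint ({bp.left_break}, {bp.right_break}) at contig edge"
        )
    return donor, acceptor, (donor, acceptor) in consensus_set


def reference_agreement(
    bp: BreakpointCandidate,
    contig: FusionContig,
    consensus: bool,
) -> tuple[bool, bool, SpliceType]:
    """Does the breakpoint coincide with annotated exon boundaries?

    Left agrees when left_break is an annotated geneA exon 3' end;
    right agrees when right_break is an annotated geneB exon 5' start
    (both in transcribed orientation, union over transcripts).
    """
    left_agree = bp.left_break in contig.donor_sites()
    right_agree = bp.right_break in contig.acceptor_sites()
    if not consensus:
        splice = SpliceType.NON_CANONICAL
    elif left_agree and right_agree:
        splice = SpliceType.ONLY_REF_SPLICE
    else:
        splice = SpliceType.INCL_NON_REF_SPLICE
    return left_agree, right_agree, splice


def microhomology_distance(
    bp: BreakpointCandidate, mh: MicrohomologyMap
) -> float:
    """Euclidean contig-space distance to the nearest microhomology.

    With no matches, returns the contig diagonal sqrt(lenA^2 + lenB^2) —
    the maximal possible distance — keeping the feature finite.
    """
    if not mh.matches:
        return math.hypot(mh.gene_a_length, mh.gene_b_length)
    return min(
        math.hypot(bp.left_break - pa, bp.right_break - pb)
        for pa, pb in mh.matches
    )


def compute_breakpoint_features(
    contig: FusionContig,
    bp: BreakpointCandidate,
    mh: MicrohomologyMap,
    consensus_set: frozenset = DEFAULT_CONSENSUS,
) -> BreakpointFeatures:
    donor, acceptor, consensus = breakpoint_dinucleotides(contig, bp, consensus_set)
    left_agree, right_agree, splice = reference_agreement(bp, contig, consensus)
    return BreakpointFeatures(
        donor_dinuc=donor,
        acceptor_dinuc=acceptor,
        consensus=consensus,
        left_ref_agree=left_agree,
        right_ref_agree=right_agree,
        splice_type=splice,
        n_microhomologies=len(mh),
        microhomology_distance=microhomology_distance(bp, mh),
    )


def assemble_feature_vector(
    expression: ExpressionSummary,
    features: BreakpointFeatures,
) -> FeatureVector:
    """Bundle expression + breakpoint features into the fixed 9-vector."""
    if expression is None or features is None:
        raise FusionScopeError("missing attributes for feature vector")
    return FeatureVector(
        ffpm=expression.ffpm,
        far_5p=expression.far_5p,
        far_3p=expression.far_3p,
        counter_ffpm_5p=expression.counter_ffpm_5p,
        counter_ffpm_3p=expression.counter_ffpm_3p,
        consensus_indicator=1 if features.consensus else 0,
        ref_agree_indicator=1 if (features.left_ref_agree and features.right_ref_agree) else 0,
        n_microhomologies=features.n_microhomologies,
        microhomology_distance=features.microhomology_distance,
    )


def write_microhomology_tsv(mh: MicrohomologyMap, contig_name: str, path) -> None:
    """Dump the match map as a 3-column TSV for external plotting."""
    with open(path, "w") as out:
        out.write("contig\tposA\tposB\n")
        for pa, pb in mh.matches:
            out.write(f"{contig_name}\t{pa}\t{pb}\n")
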