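"""Minimum-evidence, long-double-anchor, promiscuity and paralog filters."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import FusionScopeError
from .evidence import BreakpointCandidate, FragmentClass, FragmentEvidence
from .features import BreakpointFeatures


class FilterRule(str, Enum):
    MIN_SPLIT = "MIN_SPLIT"
    NON_CONSENSUS_SPLIT = "NON_CONSENSUS_SPLIT"
    LDAS = "LDAS"
    PROMISCUITY = "PROMISCUITY"
    PARALOG = "PARALOG"


@dataclass
class FilterDecision:
    variant_id: object
    failed_rules: list[FilterRule] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def min_evidence_filter(
    bp: BreakpointCandidate,
    features: BreakpointFeatures,
    min_split: int = 1,
    min_split_non_consensus: int = 3,
) -> FilterDecision:
    """At least one split read; three when the splice is non-consensus."""
    failed = []
    n_split = len(bp.split_read_ids)
    if n_split < min_split:
        failed.append(FilterRule.MIN_SPLIT)
    if not features.consensus and n_split < min_split_non_consensus:
        failed.append(FilterRule.NON_CONSENSUS_SPLIT)
    return FilterDecision(variant_id=(bp.contig, *bp.key), failed_rules=failed)


def ldas_filter(
    bp: BreakpointCandidate,
    split_evidence: list[FragmentEvidence],
    min_anchor: int = 25,
    aggregate: bool = False,
) -> FilterDecision:
    """Long double anchor support: >=25 aligned bases on both sides.

    Default reading: a single split read must satisfy both anchors.  The
    ``aggregate`` mode passes when the per-side maxima (over different
    reads) each reach the threshold.
    """
    splits = [
        f
        for f in split_evidence
        if f.fclass is FragmentClass.SPLIT and f.breakpoint == bp.key
    ]
    if aggregate:
        ok = (
            splits
            and max(f.anchor_left for f in splits) >= min_anchor
            and max(f.anchor_right for f in splits) >= min_anchor
        )
    else:
        ok = any(
            f.anchor_left >= min_anchor and f.anchor_right >= min_anchor
            for f in splits
        )
    failed = [] if ok else [FilterRule.LDAS]
    return FilterDecision(variant_id=(bp.contig, *bp.key), failed_rules=failed)


def promiscuity_filter(
    fusions: list[tuple[str, str, float]],
    max_partners: int = 10,
) -> list[FilterDecision]:
    """Fail every fusion of a gene with more than ``max_partners``
    distinct partner genes in the sample."""
    partners: dict[str, set[str]] = defaultdict(set)
    for gene_a, gene_b, _ in fusions:
        partners[gene_a].add(gene_b)
        partners[gene_b].add(gene_a)
    promiscuous = {g for g, ps in partners.items() if len(ps) > max_partners}
    decisions = []
    for gene_a, gene_b, _ in fusions:
        failed = (
            [FilterRule.PROMISCUITY]
            if gene_a in promiscuous or gene_b in promiscuous
            else []
        )
        decisions.append(
            FilterDecision(variant_id=(gene_a, gene_b), failed_rules=failed)
        )
    return decisions


def paralog_filter(
    fusions: list[tuple[str, str, float]],
    paralog_pairs: set[frozenset],
) -> list[FilterDecision]:
    """Fail fusions shadowed by a strictly better-supported fusion whose
    partners are pairwise the same gene or a listed paralog."""

    def related(x: str, y: str) -> bool:
        return x == y or frozenset((x, y)) in paralog_pairs

    decisions = []
    for i, (a_i, b_i, s_i) in enumerate(fusions):
        shadowed = any(
            s_j > s_i and related(a_j, a_i) and related(b_j, b_i)
            for j, (a_j, b_j, s_j) in enumerate(fusions)
            if j != i
        )
        failed = [FilterRule.PARALOG] if shadowed else []
        decisions.append(
            FilterDecision(variant_id=(a_i, b_i), failed_rules=failed)
        )
    return decisions


def load_paralog_pairs(path: str | Path) -> set[frozenset]:
    """Two-column TSV of gene ids -> set of unordered pairs."""
    pairs: set[frozenset] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0] or not cols[1]:
                raise FusionScopeError(
                    f"{path}: malformed paralog line {lineno}: {line!r}"
                )
            pairs.add(frozenset(cols))
    return pairs


def write_filter_report(decisions: list[FilterDecision], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("variant\tpassed\tfailed_rules\n")
        for d in decisions:
            rules = ",".join(r.value for r in d.failed_rules)
            out.write(f"{d.variant_id}\t{str(d.passed)}\t{rules}\n")
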