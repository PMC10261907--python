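"""Fusion contig construction.

Loads gene models from GTF/FASTA, shrinks long introns (keeping the two
flanking halves so splice-adjacent sequence survives), and concatenates a
5' and a 3' partner gene into a single contig in collinear transcribed
orientation.  Every retained base carries an invertible genome<->contig
coordinate mapping.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pyfaidx

from .errors import (
    AmbiguousLocusError,
    FusionScopeError,
    SelfFusionError,
    UnknownGeneError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MAX_INTRON = 1000


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _merge_intervals(intervals):
    """Merge overlapping or book-ended half-open intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """A gene: merged exon union plus per-transcript exon lists.

    Exons are 0-based half-open genome intervals, stored in ascending
    genome order regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]]
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FusionScopeError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.transcripts:
            raise FusionScopeError(f"gene {self.gene_id}: no transcripts")
        all_exons = [iv for ivs in self.transcripts.values() for iv in ivs]
        for s, e in all_exons:
            if e <= s:
                raise FusionScopeError(
                    f"gene {self.gene_id}: empty or negative exon interval ({s}, {e})"
                )
        self.transcripts = {
            tid: sorted(ivs) for tid, ivs in sorted(self.transcripts.items())
        }
        if not self.exons:
            self.exons = _merge_intervals(all_exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genome interval from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s


@dataclass
class CoordinateMap:
    """Piecewise-linear, invertible mapping between genome and contig.

    ``segments`` is a sorted list of ``(genome_start, genome_end,
    local_start)`` triples over the retained bases; ``local`` coordinates
    run 5'->3' along the *plus* genome strand.  For minus-strand genes the
    mapping flips locals so that contig coordinates run in transcribed
    orientation.  ``contig_offset`` places the gene segment within the
    full fusion contig.
    """

    segments: list[tuple[int, int, int]]
    length: int
    strand: str
    contig_offset: int = 0

    def __post_init__(self) -> None:
        self._g_starts = [s for s, _, _ in self.segments]
        locs = sorted((ls, ge - gs) for gs, ge, ls in self.segments)
        self._l_starts = [ls for ls, _ in locs]
        self._l_segments = sorted(
            ((ls, gs, ge) for gs, ge, ls in self.segments)
        )

    def _local_of_genome(self, gpos: int) -> int | None:
        i = bisect.bisect_right(self._g_starts, gpos) - 1
        if i < 0:
            return None
        gs, ge, ls = self.segments[i]
        if not (gs <= gpos < ge):
            return None
        return ls + (gpos - gs)

    def _genome_of_local(self, local: int) -> int | None:
        i = bisect.bisect_right(self._l_starts, local) - 1
        if i < 0:
            return None
        ls, gs, ge = self._l_segments[i]
        if not (ls <= local < ls + (ge - gs)):
            return None
        return gs + (local - ls)

    def genome_to_contig(self, gpos: int) -> int | None:
        """Contig coordinate of a genome position, or None if removed."""
        local = self._local_of_genome(gpos)
        if local is None:
            return None
        if self.strand == "-":
            local = self.length - 1 - local
        return self.contig_offset + local

    def contig_to_genome(self, cpos: int) -> int | None:
        """Genome coordinate of a contig position, or None if outside."""
        local = cpos - self.contig_offset
        if not (0 <= local < self.length):
            return None
        if self.strand == "-":
            local = self.length - 1 - local
        return self._genome_of_local(local)


@dataclass(frozen=True)
class ContigExon:
    """An exon remapped onto a fusion contig (0-based half-open)."""

    gene_id: str
    transcript_id: str
    start: int
    end: int
    chrom: str
    genome_start: int
    genome_end: int
    genome_strand: str


@dataclass
class FusionContig:
    """Concatenated, intron-shrunk two-gene sequence.

    Both gene segments read 5'->3' in transcribed orientation left to
    right; geneA occupies ``[0, geneB_offset)`` and geneB the rest.
    """

    name: str
    sequence: str
    geneB_offset: int
    gene_a_id: str
    gene_b_id: str
    maps: dict[str, CoordinateMap]
    annotations: list[ContigExon]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gene_a_length(self) -> int:
        return self.geneB_offset

    @property
    def gene_b_length(self) -> int:
        return len(self.sequence) - self.geneB_offset

    def exons_of(self, gene_id: str) -> list[ContigExon]:
        return [e for e in self.annotations if e.gene_id == gene_id]

    def donor_sites(self) -> set[int]:
        """Contig coordinates of geneA exon 3' last bases (union view)."""
        return {e.end - 1 for e in self.exons_of(self.gene_a_id)}

    def acceptor_sites(self) -> set[int]:
        """Contig coordinates of geneB exon 5' first bases (union view)."""
        return {e.start for e in self.exons_of(self.gene_b_id)}

    def map_for_position(self, cpos: int) -> tuple[str, CoordinateMap]:
        gid = self.gene_a_id if cpos < self.geneB_offset else self.gene_b_id
        return gid, self.maps[gid]

    def genome_position(self, cpos: int) -> tuple[str, int, str]:
        """(chrom, 1-based genome position, strand) of a contig position."""
        gid, cmap = self.map_for_position(cpos)
        gpos = cmap.contig_to_genome(cpos)
        if gpos is None:
            raise FusionScopeError(
                f"contig {self.name}: position {cpos} has no genome mapping"
            )
        exon = next(e for e in self.annotations if e.gene_id == gid)
        return exon.chrom, gpos + 1, cmap.strand


def _attr_first(feature, key):
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def load_gene_models(
    gtf_path: str | Path,
    fasta_path: str | Path,
    gene_ids: set[str],
    missing: str = "error",
) -> dict[str, GeneModel]:
    """Load the requested genes from a GTF, validating against the FASTA.

    GTF coordinates (1-based inclusive) are converted to internal 0-based
    half-open intervals.  Raises :class:`UnknownGeneError` when a
    requested id is absent (unless ``missing="skip"``) and
    :class:`AmbiguousLocusError` when a gene has exons on more than one
    chromosome or strand.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    wanted = set(gene_ids)
    found: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = _attr_first(feat, "gene_id")
        if gid not in wanted:
            continue
        tid = _attr_first(feat, "transcript_id") or f"{gid}.t1"
        rec = found.setdefault(
            gid, {"chroms": set(), "strands": set(), "transcripts": {}}
        )
        rec["chroms"].add(feat.seqid)
        rec["strands"].add(feat.strand)
        rec["transcripts"].setdefault(tid, []).append((feat.start - 1, feat.end))

    absent = sorted(wanted - set(found))
    if absent and missing != "skip":
        raise UnknownGeneError(f"unknown gene(s): {', '.join(absent)}")

    fasta = pyfaidx.Fasta(str(fasta_path))
    models: dict[str, GeneModel] = {}
    for gid in sorted(found):
        rec = found[gid]
        if len(rec["chroms"]) > 1 or len(rec["strands"]) > 1:
            raise AmbiguousLocusError(
                f"gene {gid}: exons on multiple chromosomes/strands"
            )
        chrom = next(iter(rec["chroms"]))
        if chrom not in fasta:
            raise UnknownGeneError(f"gene {gid}: chromosome {chrom} not in FASTA")
        models[gid] = GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=next(iter(rec["strands"])),
            transcripts=rec["transcripts"],
        )
    return models


def shrink_introns(
    gene: GeneModel, seq: str, max_intron: int = DEFAULT_MAX_INTRON
) -> tuple[str, CoordinateMap]:
    """Shrink introns longer than ``max_intron`` to their flanking halves.

    ``seq`` is the plus-strand genomic sequence of the gene span.  An
    intron of length L > max_intron keeps its first ceil(max_intron/2)
    and last floor(max_intron/2) bases; exon bases are untouched.  The
    returned sequence is plus-strand (orientation is applied at contig
    assembly); the map is invertible on every retained base.
    """
    if max_intron < 2:
        raise FusionScopeError(f"max_intron must be >= 2, got {max_intron}")
    span_start, span_end = gene.span
    if len(seq) != span_end - span_start:
        raise FusionScopeError(
            f"gene {gene.gene_id}: sequence length {len(seq)} != span "
            f"{span_end - span_start}"
        )
    keep_head = (max_intron + 1) // 2
    keep_tail = max_intron // 2

    retained: list[tuple[int, int]] = []
    prev_end = None
    for s, e in gene.exons:
        if prev_end is not None and s > prev_end:
            gap = s - prev_end
            if gap <= max_intron:
                retained.append((prev_end, s))
            else:
                retained.append((prev_end, prev_end + keep_head))
                retained.append((s - keep_tail, s))
        retained.append((s, e))
        prev_end = e
    retained = _merge_intervals(retained)

    segments: list[tuple[int, int, int]] = []
    pieces: list[str] = []
    local = 0
    for gs, ge in retained:
        segments.append((gs, ge, local))
        pieces.append(seq[gs - span_start : ge - span_start])
        local += ge - gs
    cmap = CoordinateMap(segments=segments, length=local, strand=gene.strand)
    return "".join(pieces), cmap


def _fetch_span(genome, gene: GeneModel) -> str:
    s, e = gene.span
    region = genome[gene.chrom][s:e]
    return str(region).upper()


def build_fusion_contig(
    geneA: GeneModel,
    geneB: GeneModel,
    genome,
    max_intron: int = DEFAULT_MAX_INTRON,
) -> FusionContig:
    """Concatenate geneA (5') and geneB (3') into one fusion contig.

    Minus-strand genes are reverse-complemented so both segments read
    5'->3' left to right.  ``genome`` is any mapping of chromosome name
    to a sliceable sequence (``pyfaidx.Fasta`` or a plain dict of str).
    """
    if geneA.gene_id == geneB.gene_id:
        raise SelfFusionError(f"self-fusion unsupported: {geneA.gene_id}")

    parts: list[str] = []
    maps: dict[str, CoordinateMap] = {}
    annotations: list[ContigExon] = []
    offset = 0
    for gene in (geneA, geneB):
        shrunk, cmap = shrink_introns(gene, _fetch_span(genome, gene), max_intron)
        if gene.strand == "-":
            shrunk = revcomp(shrunk)
        cmap.contig_offset = offset
        maps[gene.gene_id] = cmap
        for tid, exons in gene.transcripts.items():
            for gs, ge in exons:
                c1 = cmap.genome_to_contig(gs)
                c2 = cmap.genome_to_contig(ge - 1)
                if c1 is None or c2 is None:  # exon bases always retained
                    raise FusionScopeError(
                        f"gene {gene.gene_id}: exon ({gs},{ge}) lost in shrinking"
                    )
                annotations.append(
                    ContigExon(
                        gene_id=gene.gene_id,
                        transcript_id=tid,
                        start=min(c1, c2),
                        end=max(c1, c2) + 1,
                        chrom=gene.chrom,
                        genome_start=gs,
                        genome_end=ge,
                        genome_strand=gene.strand,
                    )
                )
        parts.append(shrunk)
        offset += len(shrunk)

    annotations.sort(key=lambda e: (e.gene_id != geneA.gene_id, e.transcript_id, e.start))
    return FusionContig(
        name=f"{geneA.gene_id}--{geneB.gene_id}",
        sequence="".join(parts),
        geneB_offset=len(parts[0]),
        gene_a_id=geneA.gene_id,
        gene_b_id=geneB.gene_id,
        maps=maps,
        annotations=annotations,
    )


def write_contigs(
    contigs: list[FusionContig],
    out_fasta: str | Path,
    out_gtf: str | Path,
    line_width: int = 60,
) -> None:
    """Write contig sequences (FASTA) and remapped exons (GTF, 1-based)."""
    if not contigs:
        raise FusionScopeError("no contigs to write")
    names = [c.name for c in contigs]
    if len(set(names)) != len(names):
        raise FusionScopeError("duplicate contig names")

    with open(out_fasta, "w") as fa:
        for contig in contigs:
            fa.write(f">{contig.name}\n")
            for i in range(0, len(contig.sequence), line_width):
                fa.write(contig.sequence[i : i + line_width] + "\n")

    with open(out_gtf, "w") as gtf:
        for contig in contigs:
            for exon in contig.annotations:
                attrs = (
                    f'gene_id "{exon.gene_id}"; '
                    f'transcript_id "{exon.transcript_id}";'
                )
                gtf.write(
                    "\t".join(
                        [
                            contig.name,
                            "fusionscope",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            "+",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
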