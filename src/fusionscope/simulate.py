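"""Synthetic data generation.

Produces random multi-exon genes on both strands (GT-AG introns by
construction), plants fusion breakpoints of several archetypes on fusion
contigs, and emits reads with ground-truth SAM alignments plus a truth
table, so the whole pipeline is testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pysam

from .contig import FusionContig, GeneModel, build_fusion_contig
from .errors import FusionScopeError

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class FusionMode(str, Enum):
    REF_SPLICE = "REF_SPLICE"
    NON_REF_CONSENSUS = "NON_REF_CONSENSUS"
    NON_CANONICAL = "NON_CANONICAL"
    MICROHOMOLOGY_ARTIFACT = "MICROHOMOLOGY_ARTIFACT"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 4
    exon_count: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (200, 1600)
    gene_gap: tuple[int, int] = (300, 800)
    read_length: int = 100
    frag_mean: int = 300
    frag_sd: int = 30
    error_rate: float = 0.0
    microhomology_k: int = 10

    def __post_init__(self) -> None:
        if self.frag_mean < self.read_length:
            raise FusionScopeError("fragment length must be >= read length")
        if self.read_length < 40:
            raise FusionScopeError("read_length must be >= 40")


@dataclass
class Depths:
    """Requested fragment counts for one planted breakpoint."""

    n_split: int = 8
    n_spanning: int = 10
    n_counter_5p: int = 0
    n_counter_3p: int = 0


@dataclass
class PlantedBreakpoint:
    mode: FusionMode
    left_break: int
    right_break: int
    depths: Depths = field(default_factory=Depths)


@dataclass
class PlantedFusion:
    name: str
    gene_a: str
    gene_b: str
    contig: FusionContig
    breakpoints: list[PlantedBreakpoint]
    n_background: int = 0


@dataclass
class TruthRecord:
    fragment_id: str
    contig: str
    fclass: str
    left_break: int = -1
    right_break: int = -1


@dataclass
class SamRead:
    qname: str
    flag: int
    contig: str
    pos: int
    cigar: str
    seq: str
    nm: int
    mate_pos: int
    tlen: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_genome_and_genes(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Random chromosome with interleaved plus/minus multi-exon genes.

    Every intron reads GT...AG on the transcribed strand by construction.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    parts: list[str] = []
    pos = 0
    genes: dict[str, GeneModel] = {}
    for i in range(cfg.n_genes):
        gap = int(rng.integers(cfg.gene_gap[0], cfg.gene_gap[1] + 1))
        parts.append(_random_seq(rng, gap))
        pos += gap
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(cfg.exon_count[0], cfg.exon_count[1] + 1))
        exons: list[tuple[int, int]] = []
        for j in range(n_exons):
            if j > 0:
                ilen = int(
                    rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)
                )
                intron = list(_random_seq(rng, ilen))
                if strand == "+":
                    intron[0:2] = "GT"
                    intron[-2:] = "AG"
                else:  # transcribed strand is the reverse complement
                    intron[0:2] = "CT"
                    intron[-2:] = "AC"
                parts.append("".join(intron))
                pos += ilen
            elen = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            parts.append(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
        gid = f"G{i + 1}"
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom="chr1",
            strand=strand,
            transcripts={f"{gid}.t1": exons},
        )
    parts.append(_random_seq(rng, 200))
    return {"chr1": "".join(parts)}, genes


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for chrom in sorted(genome):
            out.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_genes_gtf(genes: dict[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        for gid in sorted(genes):
            gene = genes[gid]
            for tid, exons in gene.transcripts.items():
                for s, e in exons:
                    attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                    out.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "sim",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def _edit_contig_bases(
    contig: FusionContig, genome: dict[str, str], cpos: int, bases: str
) -> None:
    """Write transcribed-strand ``bases`` at contig positions, applied as
    the corresponding (possibly complemented) genome edits in place."""
    for i, base in enumerate(bases):
        gid, cmap = contig.map_for_position(cpos + i)
        gpos = cmap.contig_to_genome(cpos + i)
        if gpos is None:
            raise FusionScopeError(f"contig position {cpos + i} not mapped")
        exon = next(e for e in contig.annotations if e.gene_id == gid)
        chrom = exon.chrom
        out_base = base if cmap.strand == "+" else _COMP[base]
        seq = genome[chrom]
        genome[chrom] = seq[:gpos] + out_base + seq[gpos + 1 :]


def _contig_exons(contig: FusionContig, gene_id: str) -> list[tuple[int, int]]:
    ivs = sorted({(e.start, e.end) for e in contig.exons_of(gene_id)})
    return ivs


def plant_fusion(
    geneA: GeneModel,
    geneB: GeneModel,
    genome: dict[str, str],
    mode: FusionMode,
    rng: np.random.Generator,
    k: int = 10,
    donor_exon: int | None = None,
    acceptor_exon: int | None = None,
    depths: Depths | None = None,
) -> tuple[dict[str, str], PlantedFusion]:
    """Plant one fusion breakpoint, editing the genome where the mode
    demands specific flanking sequence.

    REF_SPLICE joins annotated exon boundaries (GT-AG by gene
    construction); NON_REF_CONSENSUS joins mid-exon positions edited to
    GT-AG; NON_CANONICAL joins mid-exon positions with non-GT-AG flanks;
    MICROHOMOLOGY_ARTIFACT first writes a shared k-mer into both genes
    and places the junction at its start coordinates.
    """
    genome = dict(genome)
    margin = 30
    contig = build_fusion_contig(geneA, geneB, genome)
    exons_a = _contig_exons(contig, geneA.gene_id)
    exons_b = _contig_exons(contig, geneB.gene_id)

    def mid_position(exons, room, lo_abs, hi_abs):
        # mid-exon position leaving space for read placement on both sides
        order = rng.permutation(len(exons))
        for idx in order:
            s, e = exons[int(idx)]
            lo = max(s + margin, lo_abs)
            hi = min(e - margin - room, hi_abs)
            if hi > lo:
                return int(rng.integers(lo, hi))
        raise FusionScopeError(f"mode {mode}: no exon can host a breakpoint")

    if mode is FusionMode.REF_SPLICE:
        if len(exons_a) < 2 or len(exons_b) < 2:
            raise FusionScopeError("REF_SPLICE needs multi-exon genes")
        d_idx = donor_exon if donor_exon is not None else len(exons_a) - 2
        a_idx = acceptor_exon if acceptor_exon is not None else 1
        if not (0 <= d_idx < len(exons_a) - 1) or not (1 <= a_idx < len(exons_b)):
            raise FusionScopeError("REF_SPLICE exon choice incompatible")
        left_break = exons_a[d_idx][1] - 1
        right_break = exons_b[a_idx][0]
    elif mode in (FusionMode.NON_REF_CONSENSUS, FusionMode.NON_CANONICAL):
        offset = contig.geneB_offset
        left_break = mid_position(exons_a, 3, 250, offset - 250)
        right_break = mid_position(exons_b, 3, offset + 150, len(contig) - 400)
        if mode is FusionMode.NON_REF_CONSENSUS:
            _edit_contig_bases(contig, genome, left_break + 1, "GT")
            _edit_contig_bases(contig, genome, right_break - 2, "AG")
        else:
            _edit_contig_bases(contig, genome, left_break + 1, "CC")
            _edit_contig_bases(contig, genome, right_break - 2, "TT")
    elif mode is FusionMode.MICROHOMOLOGY_ARTIFACT:
        offset = contig.geneB_offset
        pos_a = mid_position(exons_a, k, 250, offset - 250)
        pos_b = mid_position(exons_b, k, offset + 150, len(contig) - 400)
        kmer = list(_random_seq(rng, k))
        kmer[1] = "C"  # donor dinucleotide can never read GT
        kmer = "".join(kmer)
        _edit_contig_bases(contig, genome, pos_a, kmer)
        _edit_contig_bases(contig, genome, pos_b, kmer)
        _edit_contig_bases(contig, genome, pos_b - 2, "CC")  # non-AG acceptor
        left_break, right_break = pos_a, pos_b
    else:  # pragma: no cover
        raise FusionScopeError(f"unknown mode {mode}")

    contig = build_fusion_contig(geneA, geneB, genome)
    planted = PlantedFusion(
        name=contig.name,
        gene_a=geneA.gene_id,
        gene_b=geneB.gene_id,
        contig=contig,
        breakpoints=[
            PlantedBreakpoint(
                mode=mode,
                left_break=left_break,
                right_break=right_break,
                depths=depths or Depths(),
            )
        ],
    )
    return genome, planted


def _apply_errors(
    seq: str, rng: np.random.Generator, error_rate: float
) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        old = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != old]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode(), len(hits)


class _FusedAxis:
    """Coordinates along the fused transcript: contig[0..left_break] then
    contig[right_break..]; maps reads back to contig CIGARs."""

    def __init__(self, contig: FusionContig, left_break: int, right_break: int):
        self.contig = contig
        self.left_break = left_break
        self.right_break = right_break
        self.junction = left_break + 1
        self.length = self.junction + (len(contig) - right_break)
        self.gap = right_break - left_break - 1

    def read(self, t_start: int, length: int) -> tuple[int, str, str]:
        """(contig start, CIGAR, sequence) of a read on the fused axis."""
        seq = self.contig.sequence
        t_end = t_start + length
        if t_end <= self.junction:
            return t_start, f"{length}M", seq[t_start:t_end]
        if t_start >= self.junction:
            start = self.right_break + (t_start - self.junction)
            return start, f"{length}M", seq[start : start + length]
        a = self.junction - t_start
        b = length - a
        cigar = f"{a}M{self.gap}N{b}M"
        pieces = seq[t_start : self.junction] + seq[self.right_break : self.right_break + b]
        return t_start, cigar, pieces


class _PlainAxis:
    """Reads drawn directly from a contig interval (no junction)."""

    def __init__(self, contig: FusionContig, lo: int, hi: int):
        self.contig = contig
        self.lo = lo
        self.length = hi - lo

    def read(self, t_start: int, length: int) -> tuple[int, str, str]:
        start = self.lo + t_start
        return start, f"{length}M", self.contig.sequence[start : start + length]


def _make_pair(
    axis, f_start: int, f_len: int, read_len: int, qname: str,
    contig_name: str, rng: np.random.Generator, error_rate: float,
) -> list[SamRead]:
    p1, c1, s1 = axis.read(f_start, read_len)
    p2, c2, s2 = axis.read(f_start + f_len - read_len, read_len)
    s1, nm1 = _apply_errors(s1, rng, error_rate)
    s2, nm2 = _apply_errors(s2, rng, error_rate)
    tlen = (p2 + read_len) - p1
    return [
        SamRead(qname, 99, contig_name, p1, c1, s1, nm1, p2, tlen),
        SamRead(qname, 147, contig_name, p2, c2, s2, nm2, p1, -tlen),
    ]


def simulate_reads(
    planted: PlantedFusion,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[SamRead], list[TruthRecord]]:
    """Emit split / spanning / counter / background fragments for one
    fusion contig with truth records, as ground-truth SAM alignments."""
    contig = planted.contig
    L = cfg.read_length
    offset = contig.geneB_offset
    sam: list[SamRead] = []
    truth: list[TruthRecord] = []
    counter = 0

    def frag_len(minimum: int, maximum: int) -> int:
        f = int(round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
        return max(minimum, min(f, maximum))

    for bp_i, planted_bp in enumerate(planted.breakpoints):
        axis = _FusedAxis(contig, planted_bp.left_break, planted_bp.right_break)
        d = planted_bp.depths

        if axis.junction < L:
            raise FusionScopeError("breakpoint too close to contig start for reads")
        for _ in range(d.n_split):
            counter += 1
            anchor = int(rng.integers(30, L - 29))
            t_start = axis.junction - anchor
            f = frag_len(L + 10, axis.length - t_start - 1)
            qname = f"{contig.name}|bp{bp_i}|SPLIT|{counter}"
            sam.extend(
                _make_pair(axis, t_start, f, L, qname, contig.name, rng, cfg.error_rate)
            )
            truth.append(
                TruthRecord(
                    qname,
                    contig.name,
                    "SPLIT",
                    planted_bp.left_break,
                    planted_bp.right_break,
                )
            )

        for _ in range(d.n_spanning):
            counter += 1
            f = frag_len(2 * L + 4, min(axis.length, 2 * L + 4 + 200))
            slack = f - 2 * L
            u_max = min(slack, axis.junction - L)
            u = int(rng.integers(0, u_max)) if u_max > 0 else 0
            t_start = axis.junction - L - u
            qname = f"{contig.name}|bp{bp_i}|SPANNING|{counter}"
            sam.extend(
                _make_pair(axis, t_start, f, L, qname, contig.name, rng, cfg.error_rate)
            )
            truth.append(
                TruthRecord(
                    qname,
                    contig.name,
                    "SPANNING",
                    planted_bp.left_break,
                    planted_bp.right_break,
                )
            )

        ov = 10
        for side, n in (("5P", d.n_counter_5p), ("3P", d.n_counter_3p)):
            brk = planted_bp.left_break if side == "5P" else planted_bp.right_break
            lo = 0 if side == "5P" else offset
            hi = offset if side == "5P" else len(contig)
            for _ in range(n):
                counter += 1
                shift = int(rng.integers(ov + 5, L - ov - 5))
                r_start = brk - shift
                f = frag_len(L + 10, hi - r_start - 1)
                if r_start < lo or r_start + f > hi:
                    raise FusionScopeError("counter fragment does not fit segment")
                axis_c = _PlainAxis(contig, r_start, hi)
                qname = f"{contig.name}|bp{bp_i}|COUNTER_{side}|{counter}"
                sam.extend(
                    _make_pair(axis_c, 0, f, L, qname, contig.name, rng, cfg.error_rate)
                )
                truth.append(
                    TruthRecord(
                        qname,
                        contig.name,
                        f"COUNTER_{side}",
                        planted_bp.left_break,
                        planted_bp.right_break,
                    )
                )

    # background: fragments clear of every planted breakpoint
    if planted.n_background:
        ov = 10
        left_min = min((b.left_break for b in planted.breakpoints), default=offset)
        right_max = max((b.right_break for b in planted.breakpoints), default=offset)
        windows = []
        if left_min - ov - 5 > cfg.frag_mean + 20:
            windows.append((0, left_min - ov - 5))
        if len(contig) - (right_max + ov + 5) > cfg.frag_mean + 20:
            windows.append((right_max + ov + 5, len(contig)))
        if not windows:
            raise FusionScopeError("no room for background fragments")
        for b in range(planted.n_background):
            counter += 1
            lo, hi = windows[b % len(windows)]
            f = frag_len(2 * L + 4, hi - lo - 1)
            start = int(rng.integers(lo, hi - f))
            axis_b = _PlainAxis(contig, start, hi)
            qname = f"{contig.name}|bg|BACKGROUND|{counter}"
            sam.extend(
                _make_pair(axis_b, 0, f, L, qname, contig.name, rng, cfg.error_rate)
            )
            truth.append(TruthRecord(qname, contig.name, "BACKGROUND"))

    return sam, truth


def write_sam(
    reads_by_contig: dict[str, list[SamRead]],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write truth alignments as SAM text with NM tags."""
    names = sorted(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": contig_lengths[n]} for n in names],
    }
    ref_id = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name in names:
            for read in reads_by_contig.get(name, []):
                a = pysam.AlignedSegment(out.header)
                a.query_name = read.qname
                a.flag = read.flag
                a.reference_id = ref_id[read.contig]
                a.reference_start = read.pos
                a.mapping_quality = 60
                a.cigarstring = read.cigar
                a.query_sequence = read.seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
                a.next_reference_id = ref_id[read.contig]
                a.next_reference_start = read.mate_pos
                a.template_length = read.tlen
                a.set_tag("NM", read.nm)
                out.write(a)


def write_fastq(
    reads_by_contig: dict[str, list[SamRead]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Paired FASTQ; reverse-strand mates are written as sequenced."""

    def rc(seq: str) -> str:
        return "".join(_COMP[b] for b in reversed(seq))

    with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
        for name in sorted(reads_by_contig):
            for read in reads_by_contig[name]:
                out = r1 if read.flag & 64 else r2
                seq = rc(read.seq) if read.flag & 16 else read.seq
                out.write(f"@{read.qname}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("fragment_id\tcontig\tclass\tleft_break\tright_break\n")
        for rec in truth:
            out.write(
                f"{rec.fragment_id}\t{rec.contig}\t{rec.fclass}\t"
                f"{rec.left_break}\t{rec.right_break}\n"
            )


@dataclass
class Scenario:
    """A fully materialized simulation: files on disk plus truth."""

    out_dir: Path
    genome_fasta: Path
    genes_gtf: Path
    fusions_file: Path
    sam_file: Path
    truth_file: Path
    planted: list[PlantedFusion]
    truth: list[TruthRecord]
    genes: dict[str, GeneModel]
    total_fragments: int


def simulate_scenario(
    out_dir: str | Path,
    cfg: SimulationConfig,
    fusion_specs: list[dict],
    extra_candidates: list[tuple[str, str]] | None = None,
    write_fastqs: bool = False,
) -> Scenario:
    """Generate a genome, plant the requested fusions, emit reads.

    Each fusion spec is a dict with keys ``gene_a``, ``gene_b``,
    ``mode`` and optionally ``depths`` (Depths), ``n_background``,
    ``donor_exon``, ``acceptor_exon``, ``extra_breakpoints`` (list of
    dicts with mode/donor_exon/acceptor_exon/depths for additional
    variants on the same contig).  ``extra_candidates`` lists fusion
    pairs written to the candidate file without any planted reads.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 10_000)
    genome, genes = simulate_genome_and_genes(cfg)

    planted_list: list[PlantedFusion] = []
    for spec in fusion_specs:
        gene_a = genes[spec["gene_a"]]
        gene_b = genes[spec["gene_b"]]
        mode = FusionMode(spec["mode"])
        genome, planted = plant_fusion(
            gene_a,
            gene_b,
            genome,
            mode,
            rng,
            k=cfg.microhomology_k,
            donor_exon=spec.get("donor_exon"),
            acceptor_exon=spec.get("acceptor_exon"),
            depths=spec.get("depths"),
        )
        planted.n_background = spec.get("n_background", 0)
        for extra in spec.get("extra_breakpoints", []):
            e_mode = FusionMode(extra.get("mode", mode))
            genome, more = plant_fusion(
                gene_a,
                gene_b,
                genome,
                e_mode,
                rng,
                k=cfg.microhomology_k,
                donor_exon=extra.get("donor_exon"),
                acceptor_exon=extra.get("acceptor_exon"),
                depths=extra.get("depths"),
            )
            planted.breakpoints.extend(more.breakpoints)
        planted_list.append(planted)

    # rebuild all contigs against the final edited genome
    for planted in planted_list:
        planted.contig = build_fusion_contig(
            genes[planted.gene_a], genes[planted.gene_b], genome
        )

    reads_by_contig: dict[str, list[SamRead]] = {}
    truth: list[TruthRecord] = []
    contig_lengths: dict[str, int] = {}
    for planted in planted_list:
        reads, recs = simulate_reads(planted, cfg, rng)
        reads_by_contig[planted.contig.name] = reads
        contig_lengths[planted.contig.name] = len(planted.contig)
        truth.extend(recs)

    genome_fasta = out_dir / "genome.fa"
    genes_gtf = out_dir / "genes.gtf"
    fusions_file = out_dir / "fusions.txt"
    sam_file = out_dir / "reads.sam"
    truth_file = out_dir / "truth.tsv"

    write_genome_fasta(genome, genome_fasta)
    write_genes_gtf(genes, genes_gtf)
    write_sam(reads_by_contig, contig_lengths, sam_file)
    write_truth_table(truth, truth_file)

    candidates = [(p.gene_a, p.gene_b) for p in planted_list]
    candidates += list(extra_candidates or [])
    with open(fusions_file, "w") as out:
        for a, b in candidates:
            out.write(f"{a}::{b}\n")

    if write_fastqs:
        write_fastq(reads_by_contig, out_dir / "reads_1.fastq", out_dir / "reads_2.fastq")

    total_fragments = len({r.fragment_id for r in truth})
    manifest = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "fusions": [p.name for p in planted_list],
        "total_fragments": total_fragments,
        "files": {
            "genome": genome_fasta.name,
            "gtf": genes_gtf.name,
            "fusions": fusions_file.name,
            "sam": sam_file.name,
            "truth": truth_file.name,
        },
    }
    with open(out_dir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)

    return Scenario(
        out_dir=out_dir,
        genome_fasta=genome_fasta,
        genes_gtf=genes_gtf,
        fusions_file=fusions_file,
        sam_file=sam_file,
        truth_file=truth_file,
        planted=planted_list,
        truth=truth,
        genes=genes,
        total_fragments=total_fragments,
    )


def standard_scenarios(seed: int = 0) -> list[dict]:
    """Eight canonical zero-error scenarios exercising every archetype.

    Each entry has ``name``, ``cfg``, ``fusion_specs``,
    ``extra_candidates`` suitable for :func:`simulate_scenario`.
    """

    def cfg(extra_seed: int, **kw) -> SimulationConfig:
        return SimulationConfig(seed=seed * 1_000 + extra_seed, **kw)

    return [
        {
            "name": "ref_splice_basic",
            "cfg": cfg(1),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "REF_SPLICE",
                    "depths": Depths(8, 10, 5, 3),
                    "n_background": 20,
                }
            ],
            "extra_candidates": [],
        },
        {
            "name": "two_fusions",
            "cfg": cfg(2),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "REF_SPLICE",
                    "depths": Depths(6, 8, 4, 2),
                    "n_background": 10,
                },
                {
                    "gene_a": "G3",
                    "gene_b": "G4",
                    "mode": "NON_REF_CONSENSUS",
                    "depths": Depths(5, 7, 0, 0),
                    "n_background": 10,
                },
            ],
            "extra_candidates": [],
        },
        {
            "name": "two_variants",
            "cfg": cfg(3),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "REF_SPLICE",
                    "donor_exon": 0,
                    "acceptor_exon": 1,
                    "depths": Depths(8, 6, 0, 0),
                    "extra_breakpoints": [
                        {
                            "mode": "REF_SPLICE",
                            "donor_exon": 1,
                            "acceptor_exon": 2,
                            "depths": Depths(2, 4, 0, 0),
                        }
                    ],
                }
            ],
            "extra_candidates": [],
        },
        {
            "name": "non_canonical_pass",
            "cfg": cfg(4),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "NON_CANONICAL",
                    "depths": Depths(4, 6, 0, 0),
                }
            ],
            "extra_candidates": [],
        },
        {
            "name": "non_canonical_filtered",
            "cfg": cfg(5),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "NON_CANONICAL",
                    "depths": Depths(2, 6, 0, 0),
                }
            ],
            "extra_candidates": [],
        },
        {
            "name": "microhomology_artifact",
            "cfg": cfg(6),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "MICROHOMOLOGY_ARTIFACT",
                    "depths": Depths(5, 6, 0, 0),
                }
            ],
            "extra_candidates": [],
        },
        {
            "name": "minus_strand_pair",
            "cfg": cfg(7),
            "fusion_specs": [
                {
                    "gene_a": "G2",
                    "gene_b": "G3",
                    "mode": "REF_SPLICE",
                    "depths": Depths(7, 9, 3, 3),
                }
            ],
            "extra_candidates": [],
        },
        {
            "name": "background_only",
            "cfg": cfg(8),
            "fusion_specs": [
                {
                    "gene_a": "G1",
                    "gene_b": "G2",
                    "mode": "REF_SPLICE",
                    "depths": Depths(0, 0, 0, 0),
                    "n_background": 30,
                }
            ],
            "extra_candidates": [("G3", "G4")],
        },
    ]


def archetype_feature_table(
    n_per_class: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Raw 9-attribute vectors drawn from three fusion archetypes.

    Class 0 mimics known-driver-like fusions (high expression, high
    3'-allelic ratio, consensus ref-agreeing splice, microhomology
    poor); class 1 mimics microhomology-proximal non-consensus
    artifacts; class 2 mimics fusions drowned in unfused-partner
    counter-evidence.  Returns (X, labels, archetype names).
    """
    rng = np.random.default_rng(seed)
    n = n_per_class

    def block(ffpm, far5, far3, c5, c3, cons, agree, nmh, dist):
        return np.column_stack(
            [
                np.clip(rng.normal(*ffpm, size=n), 0.001, None),
                np.clip(rng.normal(*far5, size=n), 0.05, None),
                np.clip(rng.normal(*far3, size=n), 0.05, None),
                np.clip(rng.normal(*c5, size=n), 0.0, None),
                np.clip(rng.normal(*c3, size=n), 0.0, None),
                np.full(n, cons, dtype=float),
                np.full(n, agree, dtype=float),
                rng.poisson(nmh, size=n).astype(float),
                np.clip(rng.normal(*dist, size=n), 0.0, None),
            ]
        )

    cosmic_like = block(
        (5.0, 1.0), (3.0, 0.5), (30.0, 5.0), (0.1, 0.05), (0.1, 0.05),
        1.0, 1.0, 2.0, (3000.0, 500.0),
    )
    artifact_like = block(
        (1.0, 0.3), (2.0, 0.5), (2.0, 0.5), (0.5, 0.2), (0.5, 0.2),
        0.0, 0.0, 30.0, (30.0, 20.0),
    )
    high_counter = block(
        (0.3, 0.1), (1.05, 0.1), (1.05, 0.1), (40.0, 8.0), (40.0, 8.0),
        1.0, 0.0, 2.0, (2500.0, 500.0),
    )
    X = np.vstack([cosmic_like, artifact_like, high_counter])
    y = np.repeat(np.arange(3), n)
    return X, y, ["COSMIC-like", "artifact-like", "high-counter"]
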