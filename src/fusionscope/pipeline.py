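"""End-to-end orchestration and reporting.

Contig building -> fragment classification -> EM quantification ->
breakpoint features -> filtering, with a per-variant TSV report, a
filtered-variant companion report, and a machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import classify as _classify
from .contig import build_fusion_contig, load_gene_models
from .errors import FusionScopeError, SelfFusionError
from .evidence import (
    FragmentClass,
    QCThresholds,
    classify_fragment,
    collect_breakpoints,
    read_alignments,
)
from .features import (
    DEFAULT_CONSENSUS,
    assemble_feature_vector,
    compute_breakpoint_features,
    find_microhomologies,
)
from .filters import (
    FilterRule,
    ldas_filter,
    load_paralog_pairs,
    min_evidence_filter,
    paralog_filter,
    promiscuity_filter,
)
from .quantify import em_assign, summarize_expression

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "fusion",
    "contig",
    "left_break",
    "right_break",
    "left_chrom",
    "left_genome_pos",
    "left_strand",
    "right_chrom",
    "right_genome_pos",
    "right_strand",
    "junction_reads",
    "spanning_fragments",
    "est_spanning",
    "est_total",
    "splice_type",
    "ffpm",
    "far_5p",
    "far_3p",
    "counter_ffpm_5p",
    "counter_ffpm_3p",
    "n_microhomologies",
    "microhomology_distance",
    "filter_status",
    "failed_rules",
    "cluster",
    "category",
]


@dataclass
class RunConfig:
    """Inputs and thresholds for one inspection run.

    Defaults reproduce the published settings: anchors 10, identity
    0.98, end clip 10, entropy 1.2, LDAS 25, microhomology k 10.
    """

    fusions_path: str
    fasta_path: str
    gtf_path: str
    sam_path: str
    out_dir: str
    total_fragments: int | None = None
    max_intron: int = 1000
    min_anchor: int = 10
    min_identity: float = 0.98
    max_end_clip: int = 10
    min_entropy: float = 1.2
    counter_overlap: int = 10
    ldas_min: int = 25
    ldas_aggregate: bool = False
    min_split: int = 1
    min_split_non_consensus: int = 3
    microhomology_k: int = 10
    max_partners: int = 10
    use_em_counts: bool = True
    consensus_set: frozenset = DEFAULT_CONSENSUS
    paralogs_path: str | None = None
    cosmic_path: str | None = None
    seed: int = 0

    def thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_anchor=self.min_anchor,
            min_entropy=self.min_entropy,
            min_identity=self.min_identity,
            max_end_clip=self.max_end_clip,
            counter_overlap=self.counter_overlap,
        )


def parse_fusion_list(path: str | Path) -> list[tuple[str, str]]:
    """Candidate fusions, one "geneA::geneB" (or "geneA--geneB") per line."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            for sep in ("::", "--"):
                if sep in line:
                    a, _, b = line.partition(sep)
                    break
            else:
                raise FusionScopeError(
                    f"{path}: line {lineno}: cannot parse fusion {line!r} "
                    "(expected geneA::geneB)"
                )
            if not a or not b:
                raise FusionScopeError(
                    f"{path}: line {lineno}: cannot parse fusion {line!r}"
                )
            pairs.append((a, b))
    return pairs


def _load_name_set(path: str | Path | None) -> set[str]:
    if path is None:
        return set()
    names: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(line)
    return names


@dataclass
class RunResult:
    rows: list[dict]
    filtered_rows: list[dict]
    summary: dict
    report_path: Path | None = None


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def run_inspect(cfg: RunConfig, model=None) -> RunResult:
    """Run the full evaluation; deterministic for fixed inputs and seed."""
    logger.info("effective thresholds: %s", {
        k: v for k, v in asdict(cfg).items() if not k.endswith("path")
    })
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    candidates = parse_fusion_list(cfg.fusions_path)
    gene_ids = {g for pair in candidates for g in pair}
    models = load_gene_models(cfg.gtf_path, cfg.fasta_path, gene_ids, missing="skip")

    import pyfaidx

    genome = pyfaidx.Fasta(str(cfg.fasta_path))
    by_contig, counted_fragments = read_alignments(cfg.sam_path)
    total_fragments = cfg.total_fragments or counted_fragments
    if cfg.total_fragments:
        logger.info("FFPM denominator from config: %d", total_fragments)
    else:
        logger.info("FFPM denominator counted from SAM: %d", total_fragments)
    if total_fragments <= 0:
        raise FusionScopeError("no fragments available for normalization")

    thresholds = cfg.thresholds()
    statuses: dict[str, str] = {}
    rows: list[dict] = []
    filtered_rows: list[dict] = []
    fusion_variant_rows: dict[str, list[dict]] = {}

    for gene_a, gene_b in sorted(set(candidates)):
        display = f"{gene_a}::{gene_b}"
        if gene_a not in models or gene_b not in models:
            statuses[display] = "unresolvable"
            continue
        try:
            contig = build_fusion_contig(
                models[gene_a], models[gene_b], genome, max_intron=cfg.max_intron
            )
        except SelfFusionError:
            statuses[display] = "unresolvable"
            continue

        groups = by_contig.get(contig.name, {})
        frags = []
        for qname in sorted(groups):
            frags.append(
                classify_fragment(tuple(groups[qname]), contig, thresholds)
            )
        bps = collect_breakpoints(frags, contig, cfg.counter_overlap)
        if bps:
            refined = []
            for frag in frags:
                if frag.fclass is FragmentClass.BACKGROUND:
                    qname = frag.fragment_id
                    refined.append(
                        classify_fragment(
                            tuple(groups[qname]), contig, thresholds, bps
                        )
                    )
                else:
                    refined.append(frag)
            frags = refined
            bps = collect_breakpoints(frags, contig, cfg.counter_overlap)

        if not bps:
            statuses[display] = "no_evidence"
            continue

        abundances = em_assign(bps)
        mh = find_microhomologies(contig, cfg.microhomology_k)
        split_evidence = [f for f in frags if f.fclass is FragmentClass.SPLIT]

        variant_rows = []
        for bp, ab in zip(bps, abundances):
            expr = summarize_expression(
                ab, bp, total_fragments, use_em=cfg.use_em_counts
            )
            feats = compute_breakpoint_features(contig, bp, mh, cfg.consensus_set)
            vector = assemble_feature_vector(expr, feats)
            failed: list[FilterRule] = []
            failed += min_evidence_filter(
                bp, feats, cfg.min_split, cfg.min_split_non_consensus
            ).failed_rules
            failed += ldas_filter(
                bp, split_evidence, cfg.ldas_min, cfg.ldas_aggregate
            ).failed_rules

            l_chrom, l_pos, l_strand = contig.genome_position(bp.left_break)
            r_chrom, r_pos, r_strand = contig.genome_position(bp.right_break)
            variant_rows.append(
                {
                    "fusion": display,
                    "contig": contig.name,
                    "left_break": bp.left_break,
                    "right_break": bp.right_break,
                    "left_chrom": l_chrom,
                    "left_genome_pos": l_pos,
                    "left_strand": l_strand,
                    "right_chrom": r_chrom,
                    "right_genome_pos": r_pos,
                    "right_strand": r_strand,
                    "junction_reads": len(bp.split_read_ids),
                    "spanning_fragments": len(bp.spanning_compatible_ids),
                    "est_spanning": ab.est_spanning,
                    "est_total": ab.est_total_fragments,
                    "splice_type": feats.splice_type.value,
                    "ffpm": expr.ffpm,
                    "far_5p": expr.far_5p,
                    "far_3p": expr.far_3p,
                    "counter_ffpm_5p": expr.counter_ffpm_5p,
                    "counter_ffpm_3p": expr.counter_ffpm_3p,
                    "n_microhomologies": feats.n_microhomologies,
                    "microhomology_distance": feats.microhomology_distance,
                    "_failed": failed,
                    "_gene_a": gene_a,
                    "_gene_b": gene_b,
                    "_vector": vector,
                }
            )
        fusion_variant_rows[display] = variant_rows

    # fusion-level screens over variants passing the per-variant rules
    surviving = [
        (rs[0]["_gene_a"], rs[0]["_gene_b"], sum(r["est_total"] for r in rs))
        for rs in fusion_variant_rows.values()
        if any(not r["_failed"] for r in rs)
    ]
    fusion_failures: dict[tuple[str, str], list[FilterRule]] = {}
    if surviving:
        for dec in promiscuity_filter(surviving, cfg.max_partners):
            if not dec.passed:
                fusion_failures.setdefault(dec.variant_id, []).extend(
                    dec.failed_rules
                )
        paralog_pairs = (
            load_paralog_pairs(cfg.paralogs_path) if cfg.paralogs_path else set()
        )
        for dec in paralog_filter(surviving, paralog_pairs):
            if not dec.passed:
                fusion_failures.setdefault(dec.variant_id, []).extend(
                    dec.failed_rules
                )

    for display, variant_rows in sorted(fusion_variant_rows.items()):
        any_pass = False
        all_failed_rules: set[str] = set()
        for row in variant_rows:
            failed = list(row.pop("_failed"))
            failed += fusion_failures.get((row["_gene_a"], row["_gene_b"]), [])
            row.pop("_gene_a"), row.pop("_gene_b")
            vector = row.pop("_vector")
            if model is not None:
                label, category = _classify.predict_category(
                    model, [vector.as_tuple()]
                )[0]
                row["cluster"], row["category"] = label, category
            else:
                row["cluster"], row["category"] = "NA", "NA"
            if failed:
                row["filter_status"] = "filtered"
                row["failed_rules"] = ",".join(
                    sorted({r.value for r in failed})
                )
                all_failed_rules.update(r.value for r in failed)
                filtered_rows.append(row)
            else:
                row["filter_status"] = "pass"
                row["failed_rules"] = ""
                rows.append(row)
                any_pass = True
        if any_pass:
            statuses[display] = "validated"
        else:
            statuses[display] = "filtered:" + ",".join(sorted(all_failed_rules))

    summary = {
        "fusions": statuses,
        "total_fragments": total_fragments,
        "n_variants_reported": len(rows),
        "n_variants_filtered": len(filtered_rows),
        "seed": cfg.seed,
        "thresholds": {
            "min_anchor": cfg.min_anchor,
            "min_identity": cfg.min_identity,
            "max_end_clip": cfg.max_end_clip,
            "min_entropy": cfg.min_entropy,
            "ldas_min": cfg.ldas_min,
            "microhomology_k": cfg.microhomology_k,
            "max_partners": cfg.max_partners,
        },
    }

    report_path = out_dir / "report.tsv"
    _write_rows(rows, report_path)
    _write_rows(filtered_rows, out_dir / "filtered.tsv")
    with open(out_dir / "summary.json", "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True)
        out.write("\n")
    return RunResult(
        rows=rows,
        filtered_rows=filtered_rows,
        summary=summary,
        report_path=report_path,
    )


def _write_rows(rows: list[dict], path: Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in sorted(
            rows, key=lambda r: (r["fusion"], r["left_break"], r["right_break"])
        ):
            out.write("\t".join(_fmt(row[c]) for c in REPORT_COLUMNS) + "\n")


def annotate_report(
    rows: list[dict], tag_lists: dict[str, set[str]]
) -> list[dict]:
    """Add one boolean tag column per named gene/fusion set.

    A tag applies when the set contains the fusion display name or
    either partner gene.  Rows are never removed.
    """
    annotated = []
    for row in rows:
        new = dict(row)
        gene_a, _, gene_b = row["fusion"].partition("::")
        for tag, names in sorted(tag_lists.items()):
            hit = (
                row["fusion"] in names
                or row["fusion"].replace("::", "--") in names
                or gene_a in names
                or gene_b in names
            )
            new[tag] = bool(hit)
        annotated.append(new)
    return annotated
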