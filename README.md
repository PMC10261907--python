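# fusionscope

Supervised in-silico evaluation of candidate fusion transcripts from
RNA-seq alignments. Given a genome FASTA, gene-structure GTF, a list of
candidate fusions (`geneA::geneB`) and read alignments to fusion
contigs, fusionscope:

1. **Builds fusion contigs** — concatenates both genes in collinear
   transcribed orientation with long introns shrunk to 1 kb (keeping the
   two flanking halves), with invertible genome↔contig coordinate maps
   (`fusionscope.contig`).
2. **Classifies fragments** — breakpoint-defining split reads, spanning
   pairs, unfused-partner counter-evidence, or background, under
   per-read QC (identity ≥ 0.98, end clipping ≤ 10, anchors ≥ 10,
   anchor entropy ≥ 1.2) (`fusionscope.evidence`).
3. **Quantifies variants** — EM-based fractional assignment of
   ambiguous spanning fragments (kallisto-style equivalence classes),
   FFPM normalization and fusion allelic ratios (`fusionscope.quantify`).
4. **Computes breakpoint features** — splice dinucleotides, reference
   exon-boundary agreement, exact k-mer (k=10) microhomology map and
   breakpoint-to-microhomology distance; assembles the 9-attribute
   feature vector (`fusionscope.features`).
5. **Filters** — minimum split support (1, or 3 for non-consensus
   splices), long double anchor support (≥ 25/25 from a single read),
   promiscuous-partner and paralog screens (`fusionscope.filters`).
6. **Clusters and classifies** — Z-score/truncate/rescale feature
   scaling to [-2, 2], kNN (k=50) Leiden clustering, per-cluster
   one-sided Fisher enrichment with BH correction, and a random-forest
   cluster predictor (max 300/cluster, 2/3–1/3 split) mapping clusters
   to categories such as "COSMIC-like" (`fusionscope.classify`).
7. **Simulates** — a first-class synthetic-data module generating
   genomes, multi-exon genes (GT-AG introns by construction), planted
   fusion archetypes (reference splice / non-reference consensus /
   non-canonical / microhomology artifact), and reads with ground-truth
   SAM + truth tables (`fusionscope.simulate`).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: evidence-recovery
oracles on zero-error simulations, EM closed-form agreement, brute-force
microhomology oracles, filter truth tables, scaling contracts, Fisher
vs. hypergeometric-tail oracle, classifier recovery on synthetic
archetypes, and byte-level determinism.

## CLI

```bash
# generate a synthetic scenario
fusionscope simulate --config scenario.yaml -O sim_out

# evaluate candidates against alignments
fusionscope inspect --fusions sim_out/fusions.txt --fasta sim_out/genome.fa \
    --gtf sim_out/genes.gtf --sam sim_out/reads.sam -O results --seed 0

# cluster a feature table and train the category predictor
fusionscope classify --features features.tsv -O model_out --seed 0
```

`inspect` writes `report.tsv` (passing variants), `filtered.tsv`
(variants with their failed rules) and `summary.json` (per-candidate
status: `validated` / `filtered:<rules>` / `no_evidence` /
`unresolvable`). Runs are deterministic for a fixed config and seed.

Example simulate YAML:

```yaml
seed: 1
n_genes: 4
fusions:
  - gene_a: G1
    gene_b: G2
    mode: REF_SPLICE        # or NON_REF_CONSENSUS / NON_CANONICAL /
                            # MICROHOMOLOGY_ARTIFACT
    depths: {n_split: 8, n_spanning: 10, n_counter_5p: 5, n_counter_3p: 3}
    n_background: 20
extra_candidates: [[G3, G4]]
```

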