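# tfnet

Analysis toolkit for characterizing transcription-factor (TF) families in an
allopolyploid plant genome and their abiotic-stress responsiveness. It
implements, as a reusable and tested pipeline:

- **Rule-based TF family/subfamily classification** from domain-hit tables
  (AP2/EREBP, bZIP, MYB, NAC, WRKY; WRKY calls require both a WRKY domain —
  canonical or accepted degenerate core — and a zinc-finger motif), plus
  chromosome-distribution chi-squared homogeneity tests and count-vector
  clustering (`tfnet.inventory`).
- **Cis-element consensus scanning** of fixed-length promoters with
  IUPAC-degenerate motifs on both strands, and per-family / per-chromosome /
  per-subfamily distributions (`tfnet.cis`).
- **Synteny-set gene categorization** into novel / conserved / multi-copy /
  lost, with sub-genome and per-family preference summaries
  (`tfnet.synteny`).
- **Differential expression**: relative expression (log2FC vs control), a
  simplified noise-dominance DE probability (a documented analogue of
  noise-distribution methods, not a NOIseq re-implementation), DEG filtering
  with threshold sweeps, Venn/set summaries, GO-keyword crucial-DEG
  selection, 2^-dCt, and expression clustering (`tfnet.deg`).
- **Grey correlation coefficient (GCC) co-expression networks**: asymmetric
  grey relational matrix (resolution ratio rho, default 0.5), OR-rule
  thresholding at tau (default 0.94) with max-weight edges, density ratios
  and degree/expression correlations (`tfnet.gcc`).
- **Process–gene projection networks** from GO BP annotations (edge weight =
  shared-term count) with hypergeometric + Bonferroni enrichment
  (`tfnet.gonet`).
- **Directed regulatory-network analysis**: homolog DEG-label transfer,
  focal subnetworks, triangle-motif counting with orientation classes,
  cross-network edge intersection (`tfnet.regnet`).
- **Synthetic data generation** for every input format with machine-readable
  ground truth (planted co-expression clusters, DE effects, cis-element
  positions, synteny categories, GO bias, triangle motifs), enabling
  parameter-recovery tests without any downloads (`tfnet.synth`).

## CLI

The `tfnet` entry point chains the stages; all interchange formats are
plain TSV / FASTA / JSON:

```bash
tfnet synth --seed 1 --outdir work             # full synthetic input bundle
tfnet classify --hits work/domain_hits.tsv --outdir work
tfnet cis-scan --promoters work/promoters.fasta --records work/records.tsv --outdir work
tfnet synteny --sets work/homolog_sets.tsv --records work/records.tsv \
      --ancestor-records work/ancestor_records.tsv --outdir work
tfnet deg --expression work/expression.tsv --samples work/samples.tsv \
      --go work/go.tsv --records work/records.tsv --outdir work
tfnet gcc-net --rel work/relative_expression.tsv --records work/records.tsv \
      --rho 0.5 --tau 0.94 --outdir work
tfnet go-net --go work/go.tsv --records work/records.tsv --outdir work
tfnet reg-net --edges work/regulatory_edges.tsv --homology work/homology_map.tsv \
      --degs work/deg_calls.tsv --outdir work
tfnet report --outdir work                      # aggregate stage JSONs
```

`tfnet synth` accepts `--config cfg.yaml` with any `SynthConfig` field;
a fixed seed makes every output byte-identical.

## Layout

```
src/tfnet/
  config.py     pipeline + synthetic-data configuration
  graphs.py     shared graph metrics (degree, components, hubs)
  inventory.py  family classification rules, chromosome statistics
  cis.py        IUPAC consensus promoter scanning
  synteny.py    homologous-set gene categorization
  deg.py        relative expression, DE probability, DEG summaries
  gcc.py        grey correlation matrix + co-expression network
  gonet.py      GO bipartite projection + enrichment
  regnet.py     directed regulatory-network analysis
  synth.py      synthetic-data generator with ground truth
  io.py         TSV/FASTA/JSON readers and writers
  cli.py        click-based CLI
tests/          unit, property and acceptance suites
scripts/acceptance.py
```
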