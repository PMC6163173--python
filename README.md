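# coexnet

Signed weighted gene co-expression network analysis as a tested, reusable
pipeline: network construction (Pearson correlation → signed power adjacency →
topological overlap), module detection (average-linkage clustering + a dynamic
tree cut variant), module eigengenes, connectivity-stability resampling,
module expression-variation (RSD) profiling, a higher-order eigengene
meta-network, and log-space hypergeometric enrichment/overlap statistics —
exercised end-to-end on synthetic expression data with planted modules.

## Layout

| module               | contents |
| -------------------- | -------- |
| `coexnet.synthetic`  | planted-module expression generator (latent-factor block model), matched gene sets (GMT) and gene positions (BED) |
| `coexnet.network`    | correlation, signed adjacency `((1+r)/2)^β`, scale-free soft-threshold selection, TOM, connectivity |
| `coexnet.detect`     | UPGMA dendrogram, dynamic tree cut (static cut → recursive splitting → height-jump chain stripping), module eigengenes via SVD |
| `coexnet.stats`      | within-module connectivity and hub genes, half-sample stability resampling, gene/module RSD, module–condition association |
| `coexnet.meta`       | eigengene meta-network and meta-modules, global module connectivity, top edges, Welch group test |
| `coexnet.enrich`     | log-space hypergeometric tail, Benjamini–Hochberg adjustment, gene-set and positional (sliding-window) enrichment, set-overlap comparison, packaged 48-module annotation table |
| `coexnet.io`         | TSV/GMT/BED readers and writers, pipeline config (YAML), end-to-end runner with manifest |
| `coexnet.plots`      | optional stability bar chart and RSD radar chart (needs matplotlib) |

## CLI

Every stage is a subcommand; `run` chains them all from one YAML config:

```bash
coexnet simulate --config examples/demo.yaml        # synthetic data + truth
coexnet run --config examples/demo.yaml             # full pipeline
coexnet modules --expression expr.tsv --beta 6 --out out/
coexnet meta --eigengenes out/eigengenes.tsv --out out/
coexnet enrich --partition out/partition.tsv --gmt sets.gmt --bed positions.bed
```

`coexnet run` writes the partition, eigengenes, power-selection table,
connectivity, hub genes, stability report, RSD tables, meta-network tables,
enrichment tables and a `manifest.json` with a config snapshot, stage timings
and sha256 checksums of every output. Reruns with the same seed are
byte-identical.

Key defaults: log2 transform before correlation, candidate powers include 14,
stability = 1000 half-sample draws, meta-network power 3 with minimum module
size 2, positional enrichment threshold 7e-7. All of them are config fields.

## Notes

- Expression input is a genes-in-rows TSV (first column gene ids, header row
  sample ids); values must be positive (RSD is defined on the raw scale).
- p-values far below double-precision underflow are handled in log10 space
  (`enrich.hypergeom_log_tail`); the convention is the inclusive upper tail
  P(X ≥ k).
- `grey` is the reserved label for unassigned genes and never participates in
  per-module statistics.
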