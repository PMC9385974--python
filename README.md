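# cernakit

A tested, reusable pipeline for programmed-cell-death (PCD) ceRNA-network
analysis: two-dataset differential-expression screening with an
empirical-Bayes moderated t, PCD gene-set intersection, multi-source
consensus voting over interaction predictions, tripartite
lncRNA–miRNA–mRNA network assembly, seven-algorithm hub-node consensus,
and regulatory-axis extraction. All inputs can be generated synthetically
with known ground truth, so every stage is verifiable offline.

## Modules

| Module | Purpose |
|---|---|
| `cernakit.gene_sets` | Read/normalise/merge/deduplicate gene lists (plain text, GMT) |
| `cernakit.diffexpr` | Moderated-t differential expression, DEG calling, cross-dataset intersection, membership tables |
| `cernakit.enrichment` | Hypergeometric over-representation analysis with BH adjustment |
| `cernakit.cerna` | Consensus voting over prediction sources; tripartite network assembly; SIF/GraphML export |
| `cernakit.hubs` | From-scratch MCC, Degree, EPC, EcCentricity, Closeness, Radiality, Betweenness; consensus hubs; axes |
| `cernakit.synthetic` | Expression/interaction simulators with planted ground truth; packaged worked-example fixtures |
| `cernakit.pipeline` / `cernakit.cli` | End-to-end orchestration from one YAML config; `cernakit` CLI |

## CLI

```sh
# write a complete synthetic scenario (expression, gene lists, noisy
# prediction sources, ground truth, ready-made config)
cernakit simulate --out scenario --seed 1 --n-genes 1000

# run the full pipeline
cernakit run --config scenario/config.yaml

# single stages
cernakit de --expression expr.tsv --groups groups.tsv --platform count --out de.tsv
cernakit membership --de-table ds1 de1.tsv --de-table ds2 de2.tsv \
    --gene-list apoptosis args.txt --out membership.tsv
cernakit enrich --genes query.txt --gmt collection.gmt --out ora.tsv
cernakit cerna --membership membership.tsv --category DEARG \
    --mirna-evidence db1.tsv --mirna-evidence db2.tsv \
    --mirna-evidence db3.tsv --mirna-evidence db4.tsv \
    --lncrna-evidence la.tsv --lncrna-evidence lb.tsv --out netdir
cernakit hubs --network netdir/DEARG.graphml --out hubdir

# worked-example tables (membership fixture, axis list)
cernakit fixtures --out fixtures/
```

The pipeline report (`report.json`) is timestamp-free; re-running with the
same config and seed reproduces it byte for byte.

## Method notes

- DEG calling uses a raw p-value cutoff (p < 0.05) combined with
  |log2FC| > 1, both strict, with no multiple-testing adjustment; the
  two-dataset intersection stands in for formal FDR control. This mirrors
  the screening design the pipeline reproduces and is a known statistical
  caveat.
- Cross-dataset intersection deliberately ignores direction concordance
  (genes often flip sign between platforms).
- Consensus thresholds default to 3-of-4 sources for miRNA→mRNA and
  2-of-2 for lncRNA→miRNA; both are configurable.
- The "lncRNA–mRNA interactions sharing the same miRNAs" assembly rule is
  implemented as: keep lncRNA–miRNA pairs whose miRNA targets a retained
  mRNA. Whether miRNAs lacking an upstream lncRNA partner are kept is
  controlled by `require_lncrna_partner` (default: kept).
- EPC needs an edge-retention probability on unweighted graphs; it is
  fixed at 0.5 with 1000 seeded Monte-Carlo realizations by default.
- Top-k ranking at ties defaults to extending the list to all nodes tied
  with the k-th score (`tie_policy="include_ties"`); truncation is
  available.
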