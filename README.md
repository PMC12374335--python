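# methinherit

Analysis pipeline for bisulfite methylomes across generations: per-cytosine
methylation summarisation, window-based DMR calling with a two-sided Fisher
exact test, promoter/gene-body annotation of DMR-associated genes (DMGs),
and cross-generation / cross-omics integration producing shared-gene sets
and direction-concordance tables. A bundled synthetic-data module generates
complete, statistically realistic inputs (reference genome, gene models,
paired methylomes with planted DMRs and configurable inheritance, coupled
DEG/DEP tables) with emitted ground truth, so the whole pipeline is testable
offline.

## Layout

| module | role |
| --- | --- |
| `methinherit.io_formats` | all on-disk formats (cytosine reports, GFF3/BED gene models, DMR BED6+, DMG tables); every coordinate-convention change lives here |
| `methinherit.methylome` | per-site/global methylation arithmetic: context classification, CpG strand merging, per-context summaries, bisulfite conversion rate |
| `methinherit.dmr` | context-stratified windows, >= 5-sites-per-sample filter, pooled two-group Fisher exact test, two-fold change rule, hyper/hypo direction, optional BH adjustment |
| `methinherit.annotate` | DMR -> gene-body / promoter (1 kb at the TSS, upstream by default) assignment, DMG strata |
| `methinherit.integrate` | DEG filter (fold change >= 2, Q <= 0.001), DEP filter (fold change >= 1.3, FDR <= 0.05; 1.5 variant available), sperm/embryo Venn sets, direction-concordance table |
| `methinherit.synthetic_data` | beta-binomial methylome simulator with planted DMRs, inheritance, coupled expression; deterministic per seed |
| `methinherit.cli` | `methinherit` command: `simulate`, `summarize`, `call-dmrs`, `annotate`, `integrate`, `run-all` |

Internal coordinates are 0-based half-open. Cytosine reports follow the
Bismark-style CX dialect (1-based positions); DMR output is BED6+.

## Quick start

Full synthetic demo (simulate -> summaries -> DMRs for sperm and embryo ->
DMG tables -> Venn + concordance), about half a minute:

```sh
methinherit run-all --outdir demo --seed 1
```

Individual stages on your own data:

```sh
methinherit summarize --report sample.cx.tsv --out summary.tsv --control-chroms lambda
methinherit call-dmrs --report-a fresh.cx.tsv --report-b stored.cx.tsv \
    --out-bed dmrs.bed --window-size 1000 --min-sites 5 --fold-change 2 --alpha 0.05
methinherit annotate --dmrs dmrs.bed --genes genes.gff3 --out dmgs.tsv \
    --promoter-size 1000 --promoter-mode upstream
methinherit integrate --sperm-dmgs sperm_dmgs.tsv --embryo-dmgs embryo_dmgs.tsv \
    --degs degs.tsv --deps deps.tsv --map protein_map.tsv --outdir integration
```

`simulate` accepts a YAML config mirroring
`methinherit.synthetic_data.SimulationConfig`; every run writes a
provenance JSON (parameters, version, input checksums).

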