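# genicmark

Genic marker discovery from transcriptome assemblies: microsatellite (SSR)
mining and localization, multi-species SNV classification, and a
genotyping-suitability filter cascade — with a synthetic-data generator that
plants ground truth so every stage can be verified closed-loop.

## What it does

* **SSR mining** (`ssr_miner`) — detects maximal perfect di-/tri-/tetranucleotide
  repeat tracts (default thresholds: ≥9 / ≥6 / ≥4 complete copies), with
  motifs canonicalized into strand/rotation families (e.g. `AG/CT`), and
  emits per-class/per-family summary tables.
* **SSR localization** (`ssr_locator`) — assigns each tract to 5′UTR, ORF,
  3′UTR or Other using a per-transcript principal-ORF annotation (BED) and
  strand; boundary-straddling tracts go to Other.
* **SNV classification** (`variant_classify`) — splits variants into SNPs vs
  INDELs and tags each site as intraspecific (heterozygous within a species)
  and/or interspecific (each member species homozygous, ≥2 distinct alleles)
  for every 2–4 species combination, from a multi-sample VCF plus a
  sample→species panel.
* **Suitability filters** (`marker_filters`) — the CS60 (another SNV closer
  than 60 nt), CL60 (closer than 60 nt to a transcript edge), HV (more than
  5 SNVs in a 100-nt window) and CEF (CAPS: a catalogued restriction enzyme
  cuts the two allelic contexts differently) cascade; a marker is kept when
  it clears the first three and passes CEF. A catalogue of 20 common
  6-cutter enzymes is packaged (`--enzymes` accepts a custom TSV, IUPAC
  degenerate sites supported).
* **Summaries** (`summary_report`) — most-expressed-isoform unigene
  selection, splice-variant fraction, length histograms, and shared
  one-decimal percentage formatting (banker's rounding, truncation optional).
* **Synthetic data** (`synthetic_data`) — generates transcripts, ORFs,
  planted SSRs and a 4-species VCF with a truth table: planted tracts are
  the only SSRs (rejection sampling), genotype patterns encode intended
  classifications, and configurable fractions of variants violate each
  filter (close pairs, edge-proximal sites, dense clusters, sites with and
  without a differential restriction site).

All internal coordinates are 0-based half-open; VCF positions are converted
at the I/O boundary only.

## CLI

```bash
genicmark simulate --out-dir sim --seed 1 --n-transcripts 50
genicmark mine-ssr --fasta sim/transcripts.fasta --out hits.tsv --summary motifs.tsv
genicmark locate-ssr --hits hits.tsv --orfs sim/orfs.bed --out localized.tsv
genicmark classify-snv --vcf sim/variants.vcf --panel sim/panel.tsv \
    --out tagged.tsv --summary snv_summary.tsv --annotated-vcf annotated.vcf
genicmark filter-markers --vcf sim/variants.vcf --panel sim/panel.tsv \
    --fasta sim/transcripts.fasta --out markers.tsv --summary marker_summary.tsv
genicmark report --transcripts sim/transcripts.fasta --localized localized.tsv --out-dir report
genicmark run-all --out-dir run --seed 1 --n-transcripts 50   # whole pipeline
```

Every threshold is a flag (`--min-di/--min-tri/--min-tetra`, `--cs`, `--cl`,
`--hv-window`, `--hv-max`, `--flank`); the defaults encode the standard
settings. `simulate` also accepts a `key=value` config file via `--config`.

## Layout

```
src/genicmark/        io_formats, ssr_miner, ssr_locator, variant_classify,
                      marker_filters, summary_report, synthetic_data, cli
src/genicmark/data/   packaged restriction-enzyme catalogue (TSV)
tests/                unit + property tests, brute-force oracles
                      (tests/oracles.py), acceptance criteria
scripts/acceptance.py acceptance report generator
```
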