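# mirevo

A desk-scale toolkit for comparative analysis of clustered miRNA families:
seed-match target prediction over 3'UTRs, transposon-origin screening of
miRNA loci, differential-expression target (DET) selection and pooling
across knockout lines, cross-species target-sharing statistics, per-base
conservation contrasts, population allele-frequency summaries, and
sperm-competition goodness-of-fit statistics.  A synthetic-data module
emulates every input with known ground truth so the whole pipeline can be
exercised and validated without external datasets.

## Modules

| module | what it does |
| --- | --- |
| `mirevo.simulate` | synthetic inputs + truth ledger: TE-descended miRNA family, orthologous UTR sets with implanted seed sites, negative-binomial KO count matrices, conservation tracks, allele tables, binomial competition assays |
| `mirevo.scan` | seed (nt 2–7) extraction, 6mer/7mer-A1/7mer-m8/8mer site scanning with optional G:U wobble, multi-tier target prediction with union semantics |
| `mirevo.de` | median-of-ratios + Welch-on-log2 differential expression, Benjamini–Hochberg FDR, DEG selection (\|FC\| ≥ 2, FDR < 0.05), per-line DET intersection and ≥2-line pooling |
| `mirevo.cross_species` | ortholog-mapped target sharing (Venn/pairwise), targets-per-miRNA and sites-per-transcript comparisons, TE-overlapping 3'UTR join |
| `mirevo.conservation` | per-base score mapping into UTR coordinates, paired site vs non-site contrast, feature-class Kruskal–Wallis + Dunn/Holm, `mnd = 2·daf·(1−daf)` |
| `mirevo.te_origin` | exact Smith–Waterman local alignment (affine gaps), identity-threshold TE screening on both strands, Nussinov-based hairpin-capability heuristic, directional substitution spectra |
| `mirevo.competition` | chi-squared paternity goodness-of-fit, Wilson intervals, count reconstruction from printed percentages, litter-size trend OLS, paired rate comparison |
| `mirevo.io`, `mirevo.pipeline`, `mirevo.cli` | FASTA/BED/bedGraph/VCF/TSV readers and writers, coordinate lifting, stage orchestration with manifests and a hashed report |

## CLI

```sh
# end-to-end synthetic run (deterministic under a fixed seed)
mirevo --seed 1 --outdir out run-all

# individual stages on files
mirevo scan --mirnas mirnas.fa --utrs utrs.fa --out sites.tsv
mirevo de --counts counts.tsv --ko-line ko1 --out de_ko1.tsv
mirevo det --de-table de_all.tsv --targets sites.tsv --out pooled.tsv
mirevo cross-species --targets targets_sp1.tsv --targets targets_sp2.tsv \
    --orthologs orthologs.tsv --reference ref_genes.txt \
    --reference-species sp1 --out shared.tsv
mirevo conserve --scores scores.bedgraph --sites sites.bed --out contrast.tsv
mirevo popgen --alleles alleles.tsv --out classes.tsv
mirevo teorigin --te library.fa --loci loci.fa --out hits.tsv
mirevo compete --assays assays.tsv --out stats.tsv
```

Counts TSVs use gene rows and `LINE_rN` sample columns; all intervals are
0-based half-open (1-based conversion happens only at the VCF boundary).
Every pipeline stage writes a `manifest.json` with parameters and output
hashes, and `run-all` emits a report whose hash is stable across runs with
the same configuration.

## Conventions and caveats

- Sequences are normalized to the RNA alphabet on ingestion (T→U);
  ambiguity codes never pair.
- Scanning tiers emulate external predictors of differing stringency; the
  defaults (strict ≥7mer Watson–Crick; relaxed 6mer + 1 wobble) are this
  package's choices, flagged as such in output metadata.
- The built-in DE test is a lightweight stand-in, not a DESeq2
  reimplementation; external DE tables can be ingested instead.
- Hairpin capability is judged by base-pair maximization plus a
  dominant-stem test, not thermodynamic folding; thresholds are package
  defaults.
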