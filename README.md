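# rtscan

Analysis toolkit for readthrough transcripts (RTs) — polycistronic mRNAs
arising when transcription fails to terminate at a gene's polyadenylation
site — called from full-length long-read transcript models against a gene
annotation. The pipeline:

1. **RT detection** (`rtscan.rt_detection`): transcripts whose exons overlap
   the CDS of ≥2 distinct tandem same-strand protein-coding genes are called
   RTs, grouped into loci by their ordered gene tuple, and tallied per sample
   (reads, distinct splice structures, loci, proportion of the library).
2. **Intergenic splicing** (`rtscan.intergenic_splicing`): introns joining the
   first gene's 3′ region to the second gene's 5′ region (IS introns) are
   detected, merged across reads, and flagged major/minor; each locus is
   classified by whether first-gene monocistronic polyadenylation falls
   inside an IS intron.
3. **PolyA signals** (`rtscan.polya_signals`): strand-aware windows running
   up to 150 nt upstream of first-gene polyA sites (bounded by the IS donor)
   are scanned for polyadenylation-signal-like (NUE) and cleavage-element-like
   (CE) hexamers from user-supplied dictionaries.
4. **Expression support** (`rtscan.expression_support`): CAGE TSS support of
   second genes (strict TPM > threshold), translation efficiency
   (footprints/RNA reads per ORF) with Tukey HSD contrasts on log TE, and
   upper-tail hypergeometric enrichment of organelle-localized first genes.
5. **Synthetic data** (`rtscan.synthetic_data`): a seeded generator emitting
   genome FASTA, GFF3 annotation, BED12 transcripts, CAGE/ORF/localization
   TSVs with planted ground truth for every stage, plus recovery scoring.

## CLI

```bash
# generate a synthetic bundle with planted truth
rtscan simulate --seed 7 --n-gene-pairs 10 --outdir sim/

# full pipeline from a YAML config (see PipelineConfig fields)
rtscan all --config config.yaml

# individual stages
rtscan call --annotation ann.gff3 -t wt=wt.bed -t upf1=upf1.bed
rtscan is-classify --annotation ann.gff3 -t s=reads.bed --genome genome.fa
rtscan polya-scan --annotation ann.gff3 -t s=reads.bed --genome genome.fa \
    --nue-hexamers nue.txt --ce-hexamers ce.txt
rtscan tss --annotation ann.gff3 -t s=reads.bed --cage cage.tsv
rtscan te --orf-counts orf_counts.tsv
rtscan enrich --population-size 27000 --population-successes 4000 \
    --sample-size 271 --sample-successes 89
```

All thresholds (CDS-overlap bp, polyA cluster radius, scan-window length,
TPM threshold, TSS window) are configurable flags/config keys and are logged
in the run manifest (`manifest.json`) together with input checksums.
Outputs are plain TSVs: a per-sample summary table, a locus master table,
IS-intron and termination-class tables, hexamer-scan results, TE group and
pairwise tables, and the enrichment p-value.

Coordinates are 0-based half-open internally; GFF3 is converted at the
parsing boundary, BED12 is native, and TSV positions are 1-based in files.

## Notes

- Hexamer dictionaries ship only as *literature-style defaults*
  (`HexamerDictionary.literature_defaults()`); real analyses should supply
  explicit one-hexamer-per-line files.
- Library normalization for TE is simple per-million scaling, not a
  variance-stabilizing method; disable with `normalize=False` (default).
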