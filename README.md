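# lncfocal

Detection of **focal somatic copy-number alterations (SCNAs) that hit long
non-coding RNA (lncRNA) exons while sparing the flanking protein-coding
genes**, from targeted array-CGH probe log-ratios.

Most recurrent amplifications and deletions in cancer genomes have been
mapped onto protein-coding genes; lncRNA loci are poorly covered by
commercial copy-number platforms and are routinely skipped in analysis. A
focal event that removes or amplifies *only* the exons of an intergenic
lncRNA — leaving its nearest protein-coding neighbours copy-number
unchanged — is strong evidence that the lncRNA itself, not a passenger
region, is the target of selection. `lncfocal` implements the full
strategy for finding such events as a tested, reusable pipeline:

1. **annotation** — build a non-redundant exon catalogue from lncRNA and
   protein-coding transcript annotation, keep intergenic lncRNAs, and assign
   each its nearest upstream/downstream protein-coding neighbour.
2. **probedesign** — emulate tiered targeted probe selection: two probes per
   exon with 100/300/500 bp boundary-extension fallbacks, fill-up to ≥ 10
   probes for transcripts with few exons, and two probes on each of the two
   nearest flanking protein-coding exons.
3. **segmentation** — circular binary segmentation (CBS) of per-sample probe
   log₂ ratios: recursively maximise the two-sample *t*-statistic over
   circular arc boundaries and accept splits by permutation test; plus a
   1 Mb-binned cross-profile Pearson correlation for quality control.
4. **focalfilter** — the focal-call cascade. A segment becomes a call for a
   lncRNA iff it (1) overlaps a lncRNA exon, (2) is not contained in a
   segmental duplication, (3) overlaps ≤ 3 known germline CNVs, (4) has
   |mean log-ratio| ≥ 1.5, (5) for gains covers the entire transcript,
   (6) overlaps no flanking protein-coding exon, and (7) exceeds each
   flank segment's |mean log-ratio| by ≥ 0.5. Calls whose flanks are
   copy-number neutral (|log-ratio| < 0.35) form the *stringent* subset;
   the rest capture superimposed events (e.g. a homozygous deletion inside
   a larger heterozygous one).
5. **qpcr** — flank-normalised ΔΔCq validation:
   `rq = 2^-[(Cq_ab − Cq_flank)_sample − (Cq_ab − Cq_flank)_control]`,
   with verdicts (confirmed focal / one side / not confirmed /
   indeterminate) and a cohort screen that maps rq to copy states
   (homozygous del / het del / neutral / gain).
6. **textmine** — term-document matrix over two abstract corpora,
   comparison-cloud deviation scores, and per-word Fisher's exact
   enrichment computed from the hypergeometric mass.
7. **simdata** — a synthetic-data generator that plants a known truth
   (genes, copy-number events, probe noise, Cq tables, enriched words) so
   every stage is testable end-to-end without external data.

## Worked example

Simulate a 5-sample panel (5 chromosomes × 10 Mb, 100 protein-coding + 50
lncRNA genes, 10 planted focal CN-0 deletions and 10 focal CN-8
amplifications, probe noise σ = 0.25) and run the pipeline on it:

```bash
lncfocal simulate --seed 1 --out fixture --sigma 0.25 --samples 5
# wrote fixture to fixture: 150 transcripts, 624 probes, 20 planted events

lncfocal run --annotation fixture/annotation.gff3 --signals fixture/signals \
    --segdups fixture/segdups.bed --variants fixture/known_variants.bed \
    --out results --seed 1
# pipeline complete: 19 focal calls (report: results/run_report.json)

head -4 results/calls.tsv | cut -f1-10
```

```
sample  lnc_gene_id  chrom  start    end      n_probes  mean_lr    direction  high_confidence  stringency
S01     LNC0014      chr2   4429395  4434147  10        -4.296015  loss       True             stringent
S01     LNC0024      chr3   4816806  4823057  10        -4.375995  loss       True             stringent
S01     LNC0037      chr4   5523052  5525996  10         1.960908  gain       False            stringent
```

The first call says: in sample S01, the segment spanning the 10 probes of
lncRNA gene LNC0014 has mean log₂ ratio ≈ −4.3 (a homozygous deletion; the
simulator floors CN 0 at log₂ 0.05 ≈ −4.32), both flanking protein-coding
segments are copy-number neutral, so the call is high-confidence
(|log-ratio| > 2.5) and stringent. 19 of the 20 planted events are
recovered at this noise level with no false calls; the run report records
per-rule attrition, e.g. for S01 the 52 (segment, lncRNA) candidate pairs
split into 3 retained, 26 discarded for sub-threshold amplitude, 20 for
excess known-variant overlap and 3 partial amplifications.

The same stages are available as library functions
(`lncfocal.recovery_experiment` runs the whole chain in memory and scores
it against the planted truth) and as further subcommands (`annotate`,
`design`, `segment`, `qc-correlate`, `filter`, `qpcr`, `textmine`).

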