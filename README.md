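# medipseq

Comparative methylome analysis for MeDIP-seq: from mapped reads of
methylated-DNA immunoprecipitation (MeDIP) and input libraries to
differential methylation calls between cell populations — e.g. breast
cancer cell lines against normal mammary epithelial cells, or an
EMT-induced sample against its control.

DNA methylation in mammals occurs at CpG dinucleotides, which are
depleted genome-wide except in CpG islands (CGIs). Cancer methylomes
show two opposed signatures: massive loss of methylation in CpG-poor
background (concentrated in large partially methylated domains) and
focal gain at CpG-rich, gene-related regions. MeDIP-seq reads sample
fragments in proportion to their methylated-CpG content, so comparative
methylation analysis reduces to careful counting. The package provides:

* **Fragment inference** — a singleton read becomes a 250 bp block
  extended from its 5' mapping position along its strand; a read pair
  becomes its outer span; duplicates (identical outer coordinates /
  5' anchors) are removed; reads with mapping quality < 10 are dropped.
* **Segment analysis** — 100 kb windows, counts normalized to reads per
  10 million, MeDIP/input ratios, masking of amplified segments
  (input > 3× median), and per-segment classification against a
  reference: *hyper* iff sample/reference ≥ 2, *hypo* iff
  reference/sample ≥ 2, else *nd*; plus average-linkage clustering of
  samples on 1 − Pearson correlation of log2 profiles.
* **CpG-level analysis** — qualitative calls (hyper: covered by all test
  samples but not the reference; hypo: the converse), the neighbor-CpG
  count and the observed/expected CpG ratio
  CpG_o/e = (N_CpG · L)/(N_C · N_G) over centered 500 bp windows, and the
  CpG-rich/poor split at o/e > 0.6.
* **Feature attribution** — one label per CpG with priority
  repeat > promoter (10 kb strand-upstream of the TSS) > exon > intron >
  intergenic, signed TSS distances, and distance profiles normalized by
  CpG density.
* **Expression correlation** — normalized counts in 1 kb bins over
  ±10 kb of each TSS, correlated with expression across samples
  (Pearson on log2 scales, labels at |r| ≥ 0.5), summarized by distance.
* **EMT switching** — epithelial/mesenchymal-specific CpGs by the
  all/none coverage rule, per-site and per-CGI transitions between an
  EMT-treated sample and its control, and alteration fractions of
  specific vs background regions.
* **A ground-truthed simulator** — a toy genome with CpG-depleted
  background, islands, shores, satellite repeats and gene clusters;
  per-cell-type region-level methylation (normal baseline, cancer
  hypo/hyper program, EMT switching at exact planted rates); MeDIP
  fragments sampled proportional to methylated-CpG content × copy
  number; input fragments with planted amplifications; expression
  coupled to the planted methylome. Every analysis stage is validated by
  recovering what the simulator planted.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic data (2 × 5 Mb genome, 11 MeDIP and 7 input libraries
of 80k fragments each). For example:

```bash
python analysis/03_segment_methylome.py --seed 1
python analysis/06_emt_switching.py --seed 1
```

prints, among other tables:

```
  sample  hyper  hypo  nd  amplified
    MCF7      5    33  62         10
    T47D      8    34  58          0
   ...
hypomethylated segments outnumber hypermethylated in every line (mean ratio 4.4x),
driven by the planted partially-methylated domains.
```

— per cancer line, the number of 100 kb segments called hyper- and
hypomethylated against the reference; MCF7's 10 amplified segments are
its planted 1 Mb 5× copy-number gain, masked from classification — and:

```
region-level alteration fractions:
           group  n_regions  fraction_altered
 a_specific_hypo         29          0.379310
b_specific_hyper         29          0.413793
 background_hypo         48          0.104167
background_hyper         86          0.104651
```

— after EMT induction, ~38% of epithelial-specific methylated CGIs lost
methylation and ~41% of mesenchymal-specific CGIs gained it, against a
~10% background alteration rate: the simulator planted exactly 40% and
10%, so the pipeline recovers the cell-type-specific switching it was
designed to detect.

The same pipeline runs from files via a YAML config (genome FASTA,
BED12 genes, BED tracks, read TSV/SAM, expression TSV):

```bash
medipseq run --config study.yaml --outdir out/
medipseq report --outdir out/
```

Subcommands `simulate`, `process`, `segment`, `cpg`, `features`,
`correlate` and `emt` run individual stages; every parameter above
(extension length, window, folds, pseudocount, o/e threshold, promoter
span, bin sizes, mapq cutoff) is a named config key with the defaults
stated here. See `docs/methods.md` for the full model description and
design rationale.

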