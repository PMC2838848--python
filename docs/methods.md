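# Methods

`medipseq` implements a comparative MeDIP-seq methylome analysis: from
mapped reads of methylated-DNA immunoprecipitation (MeDIP) and input
libraries to differential methylation calls at three resolutions, genomic
context attribution, expression coupling, and cell-type-specific
methylation switching. This note records the models, the parameters that
matter, the synthetic data the package is validated on, and the places
where a design choice was genuinely open.

## Fragment inference

MeDIP enriches sonicated fragments of 200–600 bp containing
5-methylcytosine; a 36 bp sequenced read marks one end of such a
fragment. The pipeline represents each fragment by a *block*:

* singleton read → a fixed-length extension from the read's 5' mapping
  position along its strand (`ext_length`, default 250 bp — the center of
  the enriched-fragment size range). On the − strand the block anchors at
  the read's rightmost coordinate and extends leftward; blocks are
  clipped, not dropped, at chromosome ends.
* read pair → the outer span of the two mates. Inter-chromosomal pairs
  are skipped and counted.

Duplicates are artifacts of PCR over whole-genome-amplified libraries:
pairs with identical outer coordinates, and singletons with identical
(chromosome, 5' anchor, strand), are collapsed to one block. Singleton
deduplication is on by default but switchable (`dedup`), since the
diagnostic signal for PCR bias comes from paired ends while the mechanism
applies to both read types. Reads with mapping quality < 10 (`min_mapq`)
are removed before any analysis.

## Segment-level comparison

The genome is tiled into `window` = 100 kb half-open segments (the last
segment of a chromosome may be short). Blocks are counted per segment by
their midpoint — the default because it conserves counts exactly, making
the per-10-million normalization `norm = raw × 10⁷ / total_blocks` sum
exactly to 10⁷ per sample; an `overlap` mode is available for comparison.
Each segment's MeDIP signal is divided by the matched input library,

    ratio = (medip_norm + c) / (input_norm + c),      c = pseudocount = 1,

which corrects for copy number and mappability; the pseudocount keeps the
ratio defined on empty segments and vanishes at realistic depths (~10⁵
normalized reads per 100 kb segment). Samples without an input library
are compared on normalized MeDIP counts against the reference's
normalized MeDIP counts — the comparison must be like-for-like on both
sides — and are flagged `no_input` in the output.

Copy-number gains inflate MeDIP counts irrespective of methylation, so
segments whose input coverage exceeds `amp_fold` = 3 × the genome-wide
median input are flagged amplified and excluded from classification (the
rule is strictly `>`; a segment exactly at 3× is kept). The
median-fold detector is this package's choice; at input depths of a few
hundred blocks per segment it flags a planted 5× gain essentially always.

A test sample is classified per segment against the reference:

    hyper  iff  sample / reference ≥ fold        (fold = 2, inclusive)
    hypo   iff  reference / sample ≥ fold
    nd     otherwise, and always on masked segments.

The rule is antisymmetric under swapping sample and reference and
monotone in the sample's signal. Sample relationships are summarized by
average-linkage hierarchical clustering on 1 − Pearson correlation of
log2(norm + 1) segment profiles, with columns ordered lexicographically
before linkage so the tree is reproducible; the tree is written as
Newick.

## CpG-level qualitative comparison

Ratios are undefined wherever a sample has no reads, so single-CpG
comparisons are presence/absence: a site (the C of a CG dinucleotide on
the + strand; the − strand CpG is the same site) is *covered* when at
least `min_depth` = 1 deduplicated blocks overlap its two bases. Then

* hyper: covered in **every** test-group sample and **not** in the
  reference;
* hypo: covered in the reference and in **no** test sample.

This all/none rule is deliberately strict: it trades sensitivity for a
call set shared by the whole group. It is informative only in a sparse
coverage regime (roughly ≤ a few × per sample in unenriched background);
in deep data it saturates — see the simulator section.

Sequence context per site is scored over a centered 500 bp window
(`context_window`): the number of other CpGs in the window, and the
classical observed/expected CpG ratio

    CpG_o/e = (N_CpG × L) / (N_C × N_G)

with L the clipped window length, N_CpG counting CG dinucleotides fully
inside the window (a CG straddling the edge is excluded), and 0 returned
when N_C or N_G is 0. `N` bases never form CpGs but count toward L — the
simplest deterministic rule at assembly gaps. Sites split into CpG-rich
(o/e strictly > 0.6, the classical CpG-island criterion) and CpG-poor.

## Feature attribution and TSS distance

Each CpG gets exactly one label with priority

    repeat > promoter > exon > intron > intergenic.

Repeats are excluded first; a promoter is the 10 kb strand-upstream flank
of a TSS (`promoter_span`) — on the − strand, [tss+1, tss+10001). The
priority resolves overlaps between genes (e.g. a CpG in one gene's intron
and another's promoter is `promoter`). TSS distance is signed along gene
orientation (negative = upstream), to the nearest TSS within `max_dist`
= 10 kb, ties broken toward the lexicographically smaller gene id.
Distance profiles report, per 500 bp bin, the subset count, total CpG
count and their ratio — the subset's frequency corrected for the strong
CpG density peak at the TSS.

## Expression correlation

The ±10 kb around each TSS is divided into 1 kb bins oriented along the
gene (−10…−1 upstream, +1…+10 downstream; flipped for − strand genes;
bins beyond a chromosome end are missing). Per-10M normalized block
counts per bin are correlated with expression across the samples present
in both tables (≥ 4 required): Pearson r between log2(count + 1) and
log2(expression + 1) by default, Spearman available. Genes are labeled
positive (r ≥ 0.5) or negative (r ≤ −0.5); rows with zero variance get an
undefined r and label `none`. The statistic, log transform and |r| ≥ 0.5
threshold are this package's choices, exposed as `corr_method` and
`corr_threshold` — at n = 6 samples any correlation label is coarse, and
results are reported as method-parameterized rather than canonical.

## Cell-type specificity and EMT switching

Cell lines are grouped by phenotype (epithelial vs mesenchymal). A CpG is
group-specific when covered in all members of one group and none of the
other (the same strict all/none logic as the hyper/hypo rule; the groups
must be disjoint). Comparing the EMT-treated sample with its control
classifies each site as `emt_hyper` (gained coverage), `emt_hypo` (lost),
or unchanged.

Alteration fractions — P(lost | epithelial-specific), P(gained |
mesenchymal-specific), and background rates over non-specific sites
(conditioned on control coverage, since only covered sites can lose it) —
are computed over CpGs in the **interior** of annotated CpG islands, at
least one block length (250 bp) from the island boundary. The margin is
the method's spatial resolution: coverage at island borders is produced
by fragments anchored in the flanking sequence, so border sites flip
between two independent libraries regardless of any methylation change,
and including them inflates background rates. Because methylation
patterns switch as regions, the headline estimate is region-level: a CGI
counts as specific if it contains any specific interior CpG and as
altered if the majority of those sites changed. The site-level fractions
are reported alongside, overall and per feature category.

At CpG-island resolution, per-CGI block counts (one count per overlapping
block) are normalized per 10M and classified against the reference with
the same two-fold rule (pseudocount added to both sides); the
control→treated status change defines transitions ("hyper lost", "hypo
gained", …), and the fraction of each library's blocks overlapping any
CGI is reported.

## The synthetic study

The simulator generates everything the pipeline consumes, with complete
ground truth, at a default scale of 2 chromosomes × 5 Mb, 200 genes and
~118k CpGs — the whole study runs in well under a minute on one CPU.

**Genome.** Background sequence is drawn i.i.d. at 41% GC and then
CpG-depleted: each background CG survives with probability 0.22, giving
o/e ≈ 0.22, matching the depletion of vertebrate bulk genome. CpG islands
(800–1600 bp, GC 0.64, no depletion, o/e ≈ 1.0) are placed at 70% of gene
promoters (always at gene-cluster promoters) plus 30 intergenic islands
per chromosome; 2 kb satellite-like repeat arrays share the island
composition (a CpG-rich repeat family), and ordinary repeats are
background-composition intervals. Genes have three 200 bp exons and two
2–5 kb introns; three gene-dense 100 kb cluster loci per chromosome model
the clustered hypermethylation targets of cancer genomes.

**Methylation.** Region-level Bernoulli probabilities per CpG: background
0.8, island shores (±500 bp) 0.1, unmethylated islands 0.0, methylated
islands 0.9, satellites 0.9. Cell types:

* normal/epithelial reference: baseline, plus *epithelial-signature*
  islands (an exact 15% of islands) methylated;
* *mesenchymal-signature* islands (another 15%) methylated only in
  mesenchymal lines;
* cancer: background × 0.85 (mild global loss) with an exact 35% of
  non-cluster 100 kb domains at × 0.1 — shared partially methylated
  domains (PMDs) — plus 5% private domains per line; all cluster islands
  methylated (shared gene-related hypermethylation); satellites
  demethylated to 0.05;
* EMT treated = control with an **exact** 40% of each signature island
  class switched to the other phenotype's state and an exact 10% of
  non-signature islands toggled (the background alteration rate).

Exact-count (permutation) planting rather than per-island coin flips
makes the planted rates recoverable quantities instead of random
variables. The realized methylome is one Bernoulli draw per CpG per
sample.

**Reads.** MeDIP sampling picks a methylated CpG with probability
proportional to its copy-number fold, then places a uniform 200–600 bp
fragment uniformly among positions covering it — equivalent to sampling
fragments proportionally to their methylated-CpG content × copy number,
the simplest linear model of antibody enrichment (no saturation or
density bias, which the analysis also does not correct for). Fragments
are emitted as 36 bp mapped reads, paired with probability 0.1 (inputs:
singletons only), with 2% of reads given mapping quality < 10 to exercise
the quality filter. Input fragments are uniform × copy fold; one 1 Mb 5×
amplification is planted in MCF7. Expression for six lines is generated
as log2 expr = base − 4 × promoter-island methylation + 3 × mean
gene-body background methylation + N(0, 0.3), encoding promoter
repression and positive gene-body coupling (the cross-sample variance
comes from signature islands and private PMDs).

**Depth.** 80,000 fragments per library ≈ 2× block coverage of the toy
genome background. This is the deliberate operating point of the
qualitative coverage rule: enrichment concentrates island coverage to
~30–40× while leaving the CpG-poor background sparse enough that
presence/absence is informative, mirroring the ~1× per-sample effective
coverage of genome-scale MeDIP studies. At several-fold higher depth the
all/none rule saturates (everything covered everywhere) and CpG-level
calls degenerate — a property of the method, not of the implementation.

**Scenarios.** The default scenario carries all cancer/EMT effects. A
`segment_recovery` scenario plants *only* an exact 4-fold methylation
reduction in 10% of 100 kb segments (one tumor vs the reference, no other
effects), isolating the segment classifier: with per-10M renormalization
a planted 4-fold reduction appears as a ratio of ≈ 0.25/0.925 ≈ 0.27, and
unchanged segments at ≈ 1.08, so the two-fold rule recovers planted
segments without false calls.

**What the simulator does not model** — and therefore what passing tests
do not show about real data: mappability and alignment artifacts,
sequencing error, fragment-size and GC biases of library preparation,
antibody saturation, per-molecule epiallele structure (methylation is an
independent Bernoulli per CpG, not haplotype-correlated), replicate
variability, and real genome annotation complexity (isoforms, overlapping
genes, repeat families with homology). Recovery rates here measure
algorithmic correctness under the stated generative model, not expected
performance on sequencing data.

## Numerical and degenerate-input conventions

* All internal coordinates are 0-based half-open (BED); 1-based inclusive
  appears only in human-readable rendering.
* Fold thresholds are inclusive (≥); the o/e split and the amplification
  rule are strict (>).
* Classification with a zero on one side: a positive sample over a zero
  reference is hyper (and symmetrically); 0/0 is nd. With the default
  pseudocount these cases cannot arise.
* Empty inputs: empty read files load as empty frames with a warning;
  all-zero input libraries produce no amplification flags (with a
  warning) rather than flagging everything.
* Determinism: a single integer seed drives the whole simulation; reruns
  are byte-identical. The pipeline records parameters, seed and input
  checksums in `manifest.json`.

## Known limitations

* The qualitative CpG rule has no statistical calibration — no
  significance or FDR is attached to hyper/hypo calls, matching the
  fold/coverage design it implements.
* The amplification detector is a marginal median-fold rule; it will
  fragment broad low-level gains and cannot separate ploidy shifts from
  focal amplification.
* Expression correlation at n = 6 samples has low power; labels are
  descriptive.
* SAM ingestion reads mandatory fields and MAPQ only; mate spans are
  approximated by the read length (alignment is upstream of this
  package).
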