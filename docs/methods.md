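# Methods

This note documents the models, conventions, defaults and limitations of
`cernaforge`, in the order data flows through the package.

## Coordinates, strands and sequences

All genomic intervals are 0-based half-open internally; BED output is
native, GTF output converts to 1-based inclusive. A back-splice junction is
stored as `(chrom, start, end, strand)` with `start` the genomic-leftmost
coordinate and `end` the rightmost, matching BED-style circRNA conventions;
on the "+" strand `start` is the acceptor and `end` the donor, mirrored on
"−". Spliced sequences are always given in transcription (5′→3′)
orientation. U and T are interchangeable everywhere; sequences are
normalized to the DNA alphabet at module boundaries.

## Synthetic-data generator (`simulate`)

The generator emulates a three-group left-ventricle cohort — non-ischemic
controls (n = 12), ischemic heart disease (n = 12), and ischemic heart
disease with type-2 diabetes (n = 11) — with 100-nt reads. Defaults are
chosen so a full study runs in seconds on one CPU: 300 genes, 50 circular
isoforms, 30 miRNAs, depth 1e5 counts per sample, negative-binomial
dispersion 0.1, 300-nt 3′UTRs.

- **Genome/models.** One chromosome of i.i.d. A/C/G/T; each gene has 2–5
  non-overlapping exons of 120–300 nt. Exon sizes keep even two-exon
  circles longer than typical reads so junction crossing is a minority
  event per circle, as in real libraries.
- **Circular isoforms.** Each circle is a contiguous exon run (the
  "exons i..j" pattern of annotated circRNAs) on a distinct host gene.
- **Counts.** Gamma–Poisson (negative binomial) with per-feature lognormal
  abundance weights and lognormal library-size jitter (σ = 0.15).
  Dispersion 0 degenerates to Poisson. The count distribution is a
  community-standard choice; nothing in the modeled study constrains it.
- **Segment alignments.** Reads start uniformly along each transcript.
  Reads from circular transcripts are drawn NB around `circ_reads_mean`
  (default 150) scaled by the planted fold change, so the *detected*
  junction support carries the planted effects into DE. A read crossing
  the back-splice is emitted as segments whose genomic order is inverted
  in read order; a read longer than the circle wraps more than once and
  contributes one crossing per wrap. Sequencing error, quality scores and
  UMI chemistry are not modeled.
- **Planted circuits.** Five sponging circuits by default: circRNA
  |log2FC| ≥ 1.5 in the diabetic-ischemic contrast, the miRNA planted with
  the opposite sign and the mRNA targets with the same sign (the ceRNA
  expectation); 8mer/7mer seed sites, with guard bases forcing the exact
  site class; junction-spanning MREs are written across circular position
  0 by editing the genome inside the flanking exons, so every downstream
  sequence reconstruction stays consistent. mRNA target sites are planted
  into standalone UTR sequences with collision-avoiding placement
  (bounded retries).
- **Determinism.** One sequential numpy PCG64 stream from the config seed;
  a fixed seed gives byte-identical outputs, which the suite checks at the
  file level.

Because sequences are i.i.d., chance seed matches occur at the analytic
rate (per specific 7-mer, L·(1/4)⁷ per target of length L). Passing tests
therefore demonstrate correct recovery *relative to that background*, not
performance on real transcriptomes, where site context, conservation and
expression structure differ.

## Detection (`circdetect`)

Junctions are called from inverted consecutive segment pairs and
aggregated per sample; the minimum reported support is one read, with the
presence filter as the downstream gatekeeper. Annotation requires exact
coincidence of both junction boundaries with annotated exon boundaries of
one gene (no fuzz window; exactness keeps behavior crisp and testable).
Junctions matching no gene are kept and flagged `unannotated`; junctions
matching several genes produce one flagged row per candidate. The presence
rule is: expressed in group *g* iff nonzero in ≥ ⌈0.5·n_g⌉ samples of *g*;
kept overall iff expressed in ≥ 1 group. FPM is count/library·1e6 with
library size defaulting to the column sum (in the pipeline: total aligned
reads of the sample). The junction sequence is the last `flank` nt of the
spliced circle followed by its first `flank` nt (default flank 100 →
200 nt); circles shorter than 2·flank wrap, since the circle is periodic.

## Differential expression (`diffexp`)

TMM factors follow the published trimmed-mean-of-M-values recipe:
reference = sample whose 75th percentile of count/library is closest to
the mean; pairwise M and A over features nonzero in both samples; double
trim (30 % of M from each tail, 5 % of A); inverse-asymptotic-variance
weighted mean of the surviving M values; factors renormalized to geometric
mean 1. Weights are computed on the fraction scale (the binomial variance
evaluated at a common nominal depth) — the common depth cancels in the
weighted mean, which makes the factors exactly invariant to rescaling a
single library while preserving the precision ordering across features.

The DE statistic is a moderated t: pooled two-group variance shrunk toward
the feature-wide mean variance with prior df d₀ (default 4), p-values from
t with d_g + d₀ df. This preserves the variance-moderation idea of
empirical-Bayes DE without reproducing a specific package's machinery;
`prior_df=0` gives the ordinary pooled t and `stat="welch"` the
unequal-variance t. Under a Gaussian equal-variance null the default
statistic's type-I rate is nominal to within Monte-Carlo error (checked in
the suite at 50 × 1000 features, n = 12 vs 12). Volcano classes use
|log2FC| ≥ 0.58 (boundary inclusive) and P < 0.05 (strict); network
admission uses the `both` class, i.e. raw P rather than FDR, consistent
with an inclusive, exploratory screen — FDR is reported alongside.
Features tested are those passing the presence filter in ≥ 1 group.
Multi-factor designs and covariates are out of scope.

## Interaction prediction (`interact`)

Canonical seed matching, perfect Watson–Crick, no G:U wobble: 6mer
(match to miRNA 2–7), 7mer-A1 (6mer + target A), 7mer-m8 (match to 2–8),
8mer (7mer-m8 + A); each occurrence gets its most specific class. The
"binding probability" is a transparent class→score surrogate
{8mer 0.99, 7mer-m8 0.97, 7mer-A1 0.96, 6mer 0.90}, calibrated so the
conventional > 0.95 cutoff retains 7mer/8mer sites and drops 6mers; it is
swappable via the `scores` argument. Circular targets are scanned on the
full spliced sequence extended by its first 7 nt, so a junction-spanning
site is found exactly once; positions are reported modulo circle length.
Only the best site decides edge retention; `n_sites` distinguishes
single-MRE from multi-MRE sponges. One prediction set is emitted (no
multi-database union/intersection); thermodynamic folding, conservation
and CLIP weighting are out of scope.

## Network (`network`)

Nodes are DE features (the `both` volcano class in the chosen contrast)
incident to ≥ 1 retained edge whose other endpoint is also DE; isolated
nodes are dropped; the graph is bipartite-by-layer (sponge: circ→miR,
target: miR→mRNA). miRNA admission requires significance, matching the
all-layers-DE construction; expression-direction consistency is *not*
enforced as a filter (observed networks mix directions). Cell-type
expression filtering removes nodes absent from a layer's expressed set and
re-drops the newly isolated; it commutes exactly with construction, and
the suite asserts node-for-node, edge-for-edge equality on random
instances. Serialization orders nodes and edges canonically, so GraphML
and SIF output is byte-stable.

## Enrichment (`enrich`)

One-sided upper-tail hypergeometric over-representation, BH-adjusted,
significance at FDR < 0.05. The universe defaults (in the pipeline) to all
mRNAs passing the presence filter. Only mRNAs enter the test; miRNAs map
to a pathway iff a network target maps, circRNAs iff a sponged miRNA maps.
Pathway selection (e.g. angiogenesis, VEGF signaling) is a user-provided
list of set names, not hardcoded biology.

## Quantification (`quant`)

Pure Livak arithmetic with amplification efficiency fixed at 2. Ct > 35 in
either channel marks a row undetectable; such rows are excluded *before*
averaging and surfaced explicitly (status `below_detection`), never
silently zeroed. Replicates aggregate by the geometric mean of folds
(arithmetic mean of ΔΔCt), so the calibrator's mean fold is exactly 1.
Pulldown enrichment is ΔΔCt against the control probe; the biotin-miRNA
pulldown statistic is X/Y with X the pulldown ratio and Y the input ratio;
RNase-R resistance is ΔΔCt against the undigested aliquot; spike-in
normalization substitutes the spike Ct for the reference term.
Efficiency-corrected variants and absolute quantification are out of
scope.

## Pipeline and problem sizes

`pipeline.run_pipeline` composes the stages on a simulated study and
scores recovery: planted-path recovery, edge precision/recall against the
planted circuits, junction false-call and support-exactness rates and
annotation accuracy. The default study (35 samples, 300 genes, 50 circles,
30 miRNAs) runs in a few seconds; the calibration experiments in the test
suite and acceptance script use 1000-feature, 24-sample matrices over tens
of Monte-Carlo replicates — sizes chosen to make Monte-Carlo error small
relative to the effects being checked while keeping the whole suite quick
on a single CPU.

## Known limitations

- The score surrogate makes edge retention a step function of site class;
  it cannot rank two 8mer sites.
- Exact-boundary annotation misses circles whose boundaries are off by
  even 1 nt from the gene model (a deliberate policy; a fuzz window would
  be a small extension).
- The generator's i.i.d. sequences and independent features understate the
  correlation structure of real transcriptomes; calibration results
  transfer only to the extent the moderated-t assumptions hold.
- Network edge "precision against truth" counts chance seed matches
  between truly-DE features as false, so it is conservative by the
  analytic background-match rate.
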