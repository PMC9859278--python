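# Methods

## The inference problem

The ceRNA hypothesis states that transcripts sharing miRNA binding sites
compete for a limited miRNA pool: when a sponge (lncRNA or circRNA) is
highly expressed it absorbs the miRNA and de-represses the miRNA's mRNA
targets. The observable signature in expression data over grouped samples
is (i) the sponge and the mRNA share a larger set of predicted binding
miRNAs than chance allows, (ii) each shared miRNA is negatively correlated
with both, and (iii) sponge and mRNA are positively correlated with each
other. cerna-forge operationalizes exactly this triple criterion, together
with the upstream stages that produce its inputs (circRNA calling/typing,
lncRNA gating/typing, DE screening, association, enrichment).

## Statistical core

**Shared-miRNA test.** For a pair (a, b) with K miRNAs targeting a, n
targeting b, k shared, and a universe of N miRNAs, the evidence of shared
targeting is the upper-tail hypergeometric probability
P(X ≥ k), X ~ Hypergeometric(N, K, n). The universe N defaults to every
miRNA with at least one target in the consensus map — the smallest
well-defined universe; it can be widened to all profiled miRNAs. The same
kernel, same code path, drives the over-representation analysis, so
enrichment and sponge p-values are bit-identical on shared (N, K, n, k).

**Correlation.** Pearson r on the 9 samples, with the two-tailed p from
t = r·√((n−2)/(1−r²)) on n−2 df. Zero-variance vectors raise and the pair
is excluded upstream with a warning. Thresholds as used in the screens:
trans-association |r| > 0.999 (an extreme cut that effectively demands
collinearity); sponge screen r < −0.65 per shared miRNA with both
partners, positive partner–partner r; key tier r < −0.9 (strict
inequality, so r = −0.9 is not key), significant tier r < −0.63 with
p < 0.05 — the two tiers are flags, never silent filters. The significant
tier uses raw p. Network edges require r < −0.95 with BH-adjusted
correlation p < 0.05.

**Two-group count test.** The default is an exact conditional binomial:
conditional on the pooled total t = s₁ + s₂ of a feature's group sums,
s₁ ~ Binomial(t, L₁/(L₁+L₂)) under the null, with L_g the summed library
sizes; two-sided p by the minimum-likelihood method. This is the
dispersion-zero limit of the negative-binomial exact test used by
count-based DE packages; a NB variant with a method-of-moments common
dispersion is provided as a plug-in (`nb_exact_test`), and the test is an
injection point in `de_screen`. Bit-identity with any external DE package
is not promised. log2FC = log2((m₂+c)/(m₁+c)) on depth-equalized counts
with pseudocount c = 1 raw count at the common depth, so zero means never
produce infinite fold changes. Swapping the group order negates log2FC and
leaves p unchanged.

**Multiple testing.** BH step-up FDR, recomputed over the feature family
of each comparison (DE), over each category's term family (enrichment),
and over the edge-candidate family (networks).

## Screening conventions

- circRNA filter: the seven conditions are a conjunction, both `n_uniq`
  conditions applied (`> 2` and `> ⌊samples/2⌋`); the quality condition is
  the disjunction exactly as stated (`best_qual_A > 35 or best_qual_B > 35`);
  circRNA length is the genomic span end − start + 1 (pre-splicing), with
  the span strictly below 100 kb.
- Coordinates: files are 1-based inclusive (GTF convention); all internal
  interval arithmetic is half-open 0-based; the shift happens only in the
  readers/writers.
- circRNA type precedence (the six labels are not defined relative to each
  other anywhere authoritative, so the package fixes a deterministic
  order): same-strand protein-coding overlap first — annot_exons (both
  back-splice ends on exon boundaries, ±0 nt tolerance, ≥ 2 exons spanned)
  > one_exon (contained in one exon) > exon_intron (overlaps exon and
  intron) > intronic (contained in one intron) — then antisense
  (opposite-strand overlap), then intergenic. A same-strand overlap that
  matches no structural rule (e.g. a span running off the gene end from an
  intron) is reported exon_intron as the conservative structural label.
  host_gene is empty exactly for intergenic.
- lncRNA class precedence: same-strand exonic overlap → sense_overlapping;
  same-strand fully-intronic → intronic; opposite-strand exonic overlap →
  antisense; no overlap with a TSS within 1 kb of an opposite-strand
  coding TSS → bidirectional; no overlap → intergenic; anything else
  (e.g. opposite-strand intron-only overlap) → other. The 1 kb divergent-
  promoter window is a convention, configurable; no authoritative distance
  exists for it.
- The lncRNA gate is the intersection rule: both assessors non-coding AND
  no protein hit AND length > 200 nt (strict).
- "Medium/high expression" (FPKM ≥ 50) is an annotation
  (`expression_tier`), not a DE prerequisite; a caller can subset on it.
- cis distance is the nucleotide gap between nearest feature boundaries
  (0 when overlapping); stream (UPSTREAM/DOWNSTREAM) is relative to the
  gene's strand. The anchor choice is a convention — no published
  definition fixes it.
- Trans association emits pairs only above the positive threshold by
  default; a separate negative tail (`neg_r`, e.g. −0.96) can be switched
  on explicitly, because a single |r| cut and the reported
  strong-negative pairs cannot be reconciled under one rule.
- Antisense association uses opposite-strand exonic overlap as the
  deterministic core of the antisense relation; thermodynamic duplex
  prediction is out of scope, but an externally computed MFE table can be
  passed to restrict pairs (`mfe_table`).
- Enrichment significance defaults to FDR ≤ 0.05 and can be switched to
  raw p < 0.05 per analysis; terms with K < 2 after background
  intersection are untestable and skipped. The background defaults to all
  genes in the expression matrix.
- Immune-circRNA screening takes a user-supplied term→class map (no live
  pathway database): circRNAs whose host genes sit in significantly
  enriched immune-classed terms, ranked by mean expression, top 10, ties
  at the boundary broken by circ_id lexicographic order.

## The synthetic generator

`generate_dataset` emulates the 3-group × 3-replicate design (sample
labels A1-L … C5-L). What it models:

- **Counts**: negative binomial with var = μ + φμ², common dispersion
  φ = 0.02 by default, per-feature base means log-uniform on [20, 500]
  (mRNA/lncRNA/miRNA) and [5, 50] (circRNA). Library sizes and dispersions
  are free parameters of the config — the source study reports neither.
- **Planted DE**: the second group of the assigned comparison has its mean
  scaled by 2^3 (|log2 ratio| = 3), cycling over the three comparisons.
- **Planted ceRNA triplets**: each triplet shares one per-sample latent
  trend z (a monotone age trend with small jitter — planted RNAs decline
  with age); sponge and mRNA means follow base·(1 + a·z), every shared
  miRNA follows base·(1 − a·z), with amplitude a = 0.8 and a high base
  mean (300) so NB noise attenuates the correlation only mildly. The
  linear (not exponential) modulation keeps the population correlation at
  −1 before noise and avoids degenerate collinearity after it. A
  Monte-Carlo over 200 replicate generations at these frozen defaults gave
  empirical r(miRNA, mRNA) mean −0.93, below −0.63 in 100 % of replicates;
  4 shared miRNAs per triplet out of a ~38-miRNA universe put the
  hypergeometric p well below 0.05.
- **Annotation**: one synthetic chromosome per 50 genes, non-overlapping
  9-kb three-exon gene bodies every 40 kb, overlap only where a planted
  class requires it — classification truth is unambiguous by construction.
- **Target maps**: three predictor tables = a consensus random layer
  (rate 0.02, present in all three) + per-predictor noise (rate 0.05) +
  the planted pairs, so the intersection contains realistic null sharing.
- **Null model**: `generate_null_targets` draws every miRNA–target link
  i.i.d. (defaults: 2000 miRNAs, rate 0.3). Conditional on the set sizes
  the shared-count is exactly hypergeometric, so the screen's null firing
  rate can be measured; dense sets keep the discrete p-value support fine
  near 0.05 (observed rate ≈ 0.04–0.055 over seeds — slightly conservative,
  as a discrete exact test must be).

What it does **not** model, hence what passing tests do not show about
real data: read-level artifacts (no FASTQ, no alignment), sequence-level
miRNA seed matching (target tables are drawn, not predicted), isoform
complexity (one transcript per gene), batch effects, library-size
imbalance beyond sampling noise, and the correlated gene–gene background
of real transcriptomes. Recovery rates on this generator are a correctness
check of the screening logic, not a sensitivity claim for real tissues.

## Problem sizes and determinism

The reference scenario is 60 genes, 20 lncRNAs, 18 circRNAs, 40 miRNAs,
3 triplets, 9 planted DE features — large enough that every class and
condition occurs, small enough that the whole suite and the acceptance
script run in seconds. Stochastic summaries (triplet recovery, FDP, DE
detection) are measured over 50 and 20 generator seeds respectively; the
null calibration uses 1000 candidate pairs at a fixed seed. All randomness
flows from `numpy.random.default_rng(seed)`; regenerating with the same
seed is byte-identical on disk, and re-running the pipeline on identical
inputs reproduces identical output hashes (sorted writes, full-precision
floats).

## Known limitations

- The hypergeometric screen treats target predictions as ground truth;
  prediction noise propagates directly into K, n, k.
- With 9 samples, correlation thresholds like −0.9 sit in the far tail of
  the null but estimates are high-variance; the key/significant tiers are
  flags so the caller can see the evidence rather than lose it.
- The conditional binomial default is anti-conservative under strong
  overdispersion; use the NB plug-in with an estimated common dispersion
  when group variability is large.
- The six circRNA types and five lncRNA classes depend on the annotation's
  completeness; unannotated exons shift labels toward intergenic/other.
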