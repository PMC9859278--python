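# cerna-forge

A tested, reusable pipeline for inferring **ceRNA (competing endogenous
RNA) networks** from multi-layer bulk RNA-seq of a small grouped design —
the setting of developmental-stage transcriptome studies in livestock,
where lncRNA, circRNA, miRNA and mRNA expression over 3 groups × 3
replicates is mined for miRNA-sponge regulation.

It is written for bioinformaticians who have the standard upstream outputs
in hand (a genome annotation, count matrices, back-splice candidate tables
from a find_circ-style caller, per-predictor miRNA target tables,
coding-potential calls) and want the downstream screening stages as a
library with explicit, overridable thresholds:

1. **circRNA detection** — filter back-splice junction candidates with seven
   conjunctive quality conditions (`breakpoints = 1`, `anchor_overlap ≤ 2`,
   `edit ≤ 2`, `n_uniq > 2`, `best_qual_A > 35 or best_qual_B > 35`,
   `n_uniq > ⌊samples/2⌋`, span < 100 kb), quantify in back-spliced reads
   per million (RPM), and assign each circRNA one of six positional types
   (annot_exons, one_exon, exon_intron, intronic, antisense, intergenic).
2. **lncRNA annotation** — gate novel lncRNAs (both coding-potential
   assessors non-coding ∧ no protein hit ∧ length > 200 nt) and classify
   into intergenic / bidirectional / antisense / sense-overlapping /
   intronic (plus an unresolved bucket).
3. **differential expression** — FPKM/RPM/CPM normalization, an exact
   conditional binomial two-group test (the dispersion-zero limit of the
   negative-binomial exact test, with an NB plug-in), BH-FDR, screening at
   FDR < 0.05 (lncRNA/mRNA) or p < 0.05 (circRNA) with |log2FC| > 1,
   Z-scoring, and 2^−ΔΔCT relative quantification.
4. **association** — lncRNA–mRNA candidates in three modes: antisense
   (opposite-strand exonic overlap), cis (within 30 kb up/downstream), and
   trans (|Pearson r| > 0.999 across samples).
5. **enrichment** — generic over-representation analysis of gene sets
   against user-supplied GO-like/pathway-like term maps (hypergeometric
   upper tail + BH-FDR per category).
6. **ceRNA network** — the core screen. For a sponge candidate pair
   (ncRNA *a*, mRNA *b*) sharing k miRNAs, with K miRNAs targeting *a*,
   n targeting *b*, in a universe of N:

       P = Σ_{i=k}^{min(K,n)} C(K,i) · C(N−K, n−i) / C(N,n)

   A pair is reported when P < 0.05, every shared miRNA correlates below
   r < −0.65 with both partners, and the partners correlate positively;
   key sponges carry the stricter r < −0.9 tier. Networks export as
   Cytoscape SIF with an edge-attribute table (miRNA–target edges at
   r < −0.95, FDR < 0.05).

A first-class **synthetic-data generator** produces every input with planted
ground truth (ceRNA triplets, DE features, positional classes), so all
stages are tested against constructed truth rather than fixtures.

## Worked example

```python
from cerna_forge import generate_dataset
from cerna_forge.cerna import candidate_pairs, intersect_targets, screen_cerna

ds = generate_dataset(seed=1)
final = intersect_targets(ds.target_maps)          # consensus of 3 predictors
nc = [t.transcript_id for t in ds.lnc_transcripts] + list(ds.circ_expr.feature_ids)
mrna = [f for f in ds.gene_expr.feature_ids if f.startswith("gene_")]
cands = candidate_pairs(final, nc, mrna)
kept = screen_cerna(cands, ds.mirna_expr, ds.gene_expr, ds.circ_expr)
print(kept[["ce_a", "ce_b", "k", "K", "n", "N", "hyper_p", "r_ab"]])
```

prints

```
    ce_a      ce_b  k  K  n  N  hyper_p     r_ab
lnc_0001 gene_0058  4  5  4 38 0.000068 0.931491
lnc_0002 gene_0060  4  5  5 38 0.000331 0.907199
```

— two retained sponge pairs: `lnc_0001` shares 4 of the 38-miRNA universe
with `gene_0058` (hypergeometric P = 6.8 × 10⁻⁵, far below chance), the two
are strongly co-expressed (r = 0.93), and each shared miRNA is
anti-correlated with both partners. Both are planted triplets the
generator buried in the data; across 50 seeds the screen recovers ≥ 98 %
of planted triplets with a false-discovery proportion near zero.

The `examples/` directory has one short narrative script per capability
(simulation, circRNA filtering, lncRNA classification, DE, association,
ceRNA screening, the full file-based pipeline), and `cerna-forge --help`
exposes the same stages as CLI verbs (`init`, `simulate`, `circ`, `lnc`,
`de`, `enrich`, `cerna`, `run`).

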