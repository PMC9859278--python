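"""Synthetic study generator with planted ground truth.

Emulates the 3-age-group x 3-replicate submandibular-gland design: a genome
annotation, negative-binomial count matrices for mRNA/lncRNA, circRNA
back-splice candidates, miRNA expression, three per-predictor miRNA target
tables, and coding-potential flags — all with planted structure (ceRNA
triplets, differential features, positional classes) recorded as truth so
every downstream stage can be scored.

Counts are negative binomial (mean per group, common dispersion), matching
the overdispersion an exact-test analysis assumes. Planted anti-correlation
uses a shared per-sample latent trend with opposite signs on the miRNA side
versus the sponge/mRNA side, plus independent NB noise, giving a tunable
Pearson r without degenerate collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, Exon, Gene, Transcript
from .circrna import CANDIDATE_COLUMNS
from .enrichment import TermMap
from .matrix import ExpressionMatrix, SampleDesign
from .cerna import TargetMap

__all__ = ["GeneratorConfig", "PlantedTruth", "SyntheticDataset",
           "generate_dataset", "generate_circ_candidates"]

# gene body template: 3 exons of 1 kb at offsets 0, 4k, 8k (introns 1k-4k, 5k-8k)
_EXON_OFFSETS = ((0, 1000), (4000, 5000), (8000, 9000))
_GENE_SPAN = 9000
_GENE_SPACING = 40_000
_LNC_CLASS_CYCLE = ("intergenic", "bidirectional", "antisense",
                    "sense_overlapping", "intronic")
_CIRC_TYPE_CYCLE = ("annot_exons", "one_exon", "exon_intron", "intronic",
                    "antisense", "intergenic")


@dataclass
class GeneratorConfig:
    """Frozen study conditions; defaults are the tested reference scenario."""

    n_genes: int = 60
    n_lncrnas: int = 20
    n_circs: int = 18
    n_mirnas: int = 40
    n_triplets: int = 3
    n_shared_mirnas: int = 4        # shared binding miRNAs planted per triplet
    n_de: int = 9                   # planted DE features (mRNA genes)
    de_log2_effect: float = 3.0     # |log2 group-mean ratio| of planted DE
    corr_amplitude: float = 0.8     # latent-trend amplitude for planted triplets
    dispersion: float = 0.02        # common NB dispersion (var = mu + phi mu^2)
    background_target_rate: float = 0.05   # per-predictor random miRNA-target rate
    consensus_target_rate: float = 0.02    # random pairs planted in all 3 predictors
    base_mean_range: tuple[float, float] = (20.0, 500.0)
    circ_mean_range: tuple[float, float] = (5.0, 50.0)
    planted_base_mean: float = 300.0
    genes_per_chrom: int = 50
    n_decoy_transcripts: int = 4    # novel transcripts that must fail the lncRNA gate

    def validate(self) -> None:
        n_lnc_sponges = (self.n_triplets + 1) // 2
        n_circ_sponges = self.n_triplets // 2
        if self.n_triplets * self.n_shared_mirnas > self.n_mirnas:
            raise ValueError(
                f"{self.n_triplets} triplets x {self.n_shared_mirnas} shared miRNAs "
                f"exceed the {self.n_mirnas} miRNAs available")
        if self.n_triplets + self.n_de > self.n_genes:
            raise ValueError(
                f"planted mRNAs ({self.n_triplets} triplet + {self.n_de} DE) "
                f"exceed the {self.n_genes} genes available")
        if n_lnc_sponges > self.n_lncrnas:
            raise ValueError("more lncRNA sponges requested than lncRNAs generated")
        if n_circ_sponges > self.n_circs:
            raise ValueError("more circRNA sponges requested than circRNAs generated")
        if self.n_lncrnas + self.n_circs > self.n_genes:
            raise ValueError("need at least one anchor gene per planted lncRNA/circRNA")


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure; ids refer to generated tables."""

    cerna_triplets: list[tuple[str, str, str]]      # (anchor miRNA, sponge, mRNA)
    triplet_shared: list[list[str]]                 # all shared miRNAs per triplet
    de_features: dict[str, str]                     # feature_id -> comparison
    true_classes: dict[str, str]                    # lncRNA class / circRNA type

    def to_json_dict(self) -> dict:
        return {
            "cerna_triplets": [list(t) for t in self.cerna_triplets],
            "triplet_shared": self.triplet_shared,
            "de_features": self.de_features,
            "true_classes": self.true_classes,
        }


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the truth."""

    design: SampleDesign
    annotation: AnnotationSet
    transcripts: pd.DataFrame            # transcript_id, length (gate input)
    lnc_transcripts: list[Transcript]
    gene_expr: ExpressionMatrix          # mRNA + lncRNA raw counts
    circ_expr: ExpressionMatrix          # back-spliced read counts
    mirna_expr: ExpressionMatrix
    circ_candidates: pd.DataFrame
    target_maps: list[TargetMap]
    coding_flags: pd.DataFrame
    terms: list[TermMap] = field(default_factory=list)
    pathway_classes: dict[str, str] = field(default_factory=dict)
    truth: PlantedTruth | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with var = mu + phi mu^2; Poisson in the phi -> 0 limit."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-9, None)
    if phi <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mean))


def _build_annotation(cfg: GeneratorConfig) -> tuple[list[Gene], list[str]]:
    genes: list[Gene] = []
    gene_ids: list[str] = []
    for i in range(cfg.n_genes):
        chrom = f"chrS{i // cfg.genes_per_chrom + 1}"
        local = i % cfg.genes_per_chrom
        start = 50_000 + local * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        gid = f"gene_{i + 1:04d}"
        tx = Transcript(f"{gid}.t1", gid, chrom, start, start + _GENE_SPAN, strand,
                        exons=[Exon(start + a, start + b) for a, b in _EXON_OFFSETS])
        genes.append(Gene(gid, chrom, start, start + _GENE_SPAN, strand,
                          transcripts=[tx], biotype="protein_coding"))
        gene_ids.append(gid)
    return genes, gene_ids


def _plant_lncrnas(cfg: GeneratorConfig, genes: list[Gene],
                   rng: np.random.Generator) -> tuple[list[Transcript], dict[str, str]]:
    lncs: list[Transcript] = []
    classes: dict[str, str] = {}
    for j in range(cfg.n_lncrnas):
        g = genes[j]  # one anchor gene per lncRNA, disjoint from circ anchors
        cls = _LNC_CLASS_CYCLE[j % len(_LNC_CLASS_CYCLE)]
        lid = f"lnc_{j + 1:04d}"
        span = int(rng.integers(400, 1200))
        if cls == "intergenic":
            s = g.end + 15_000
            strand = g.strand
        elif cls == "bidirectional":
            strand = "-" if g.strand == "+" else "+"
            if g.strand == "+":
                s, span = g.start - 400 - span, span  # TSS (end side) near gene TSS
            else:
                s = g.end + 400
        elif cls == "antisense":
            strand = "-" if g.strand == "+" else "+"
            s, span = g.start + 4100, 800            # covers exon 2
        elif cls == "sense_overlapping":
            strand = g.strand
            s, span = g.start + 4100, 800
        else:  # intronic: fully inside intron 1
            strand = g.strand
            s, span = g.start + 1400, min(span, 2400)
        tx = Transcript(lid, f"{lid}_locus", g.chrom, s, s + span, strand,
                        exons=[Exon(s, s + span)], biotype="lncRNA")
        lncs.append(tx)
        classes[lid] = cls
    return lncs, classes


def _plant_circs(cfg: GeneratorConfig, genes: list[Gene]
                 ) -> tuple[list[dict], dict[str, str]]:
    """Back-splice spans with known types; coordinates 1-based inclusive."""
    rows: list[dict] = []
    classes: dict[str, str] = {}
    offset = cfg.n_lncrnas  # anchor genes after the lncRNA anchors
    for j in range(cfg.n_circs):
        g = genes[offset + j]
        ctype = _CIRC_TYPE_CYCLE[j % len(_CIRC_TYPE_CYCLE)]
        if ctype == "annot_exons":
            s0, e0, strand = g.start, g.start + 5000, g.strand
        elif ctype == "one_exon":
            s0, e0, strand = g.start + 100, g.start + 800, g.strand
        elif ctype == "exon_intron":
            s0, e0, strand = g.start + 500, g.start + 2000, g.strand
        elif ctype == "intronic":
            s0, e0, strand = g.start + 1500, g.start + 2500, g.strand
        elif ctype == "antisense":
            s0, e0 = g.start + 200, g.start + 1200
            strand = "-" if g.strand == "+" else "+"
        else:  # intergenic: mid-gap, away from planted lncRNAs of other genes
            s0, e0, strand = g.end + 11_000, g.end + 11_400, g.strand
        cid = f"novel_circ_{j + 1:06d}"
        rows.append({"circ_id": cid, "chrom": g.chrom, "start": s0 + 1, "end": e0,
                     "strand": strand,
                     "host_gene": g.gene_id if ctype != "intergenic" else ""})
        classes[cid] = ctype
    return rows, classes


def _quality_fields(rng: np.random.Generator) -> dict:
    """Junction quality fields that pass all seven filter conditions."""
    return {
        "breakpoints": 1,
        "anchor_overlap": int(rng.integers(0, 3)),
        "edit": int(rng.integers(0, 3)),
        "n_uniq": int(rng.integers(5, 21)),
        "best_qual_A": int(rng.integers(36, 41)),
        "best_qual_B": int(rng.integers(0, 41)),
    }


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0
                     ) -> SyntheticDataset:
    """Generate the full synthetic study. Deterministic for a fixed seed."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    design = SampleDesign.default()
    samples = design.sample_ids
    n_s = len(samples)

    genes, gene_ids = _build_annotation(cfg)
    lncs, lnc_classes = _plant_lncrnas(cfg, genes, rng)
    circ_rows, circ_classes = _plant_circs(cfg, genes)

    ann_genes = list(genes)
    for t in lncs:  # lncRNA loci enter the annotation as non-coding genes
        ann_genes.append(Gene(t.gene_id, t.chrom, t.start, t.end, t.strand,
                              transcripts=[t], biotype="lncRNA"))
    annotation = AnnotationSet(sorted(ann_genes, key=lambda g: (g.chrom, g.start, g.gene_id)))

    mirna_ids = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    lnc_ids = [t.transcript_id for t in lncs]
    circ_ids = [r["circ_id"] for r in circ_rows]

    # ------------------------------------------------------------- planting plan
    sponges: list[str] = []
    for t in range(cfg.n_triplets):  # alternate lncRNA / circRNA sponges
        sponges.append(lnc_ids[t // 2] if t % 2 == 0 else circ_ids[t // 2])
    triplet_mrnas = gene_ids[-cfg.n_triplets:] if cfg.n_triplets else []
    shared_sets = [mirna_ids[t * cfg.n_shared_mirnas:(t + 1) * cfg.n_shared_mirnas]
                   for t in range(cfg.n_triplets)]
    triplets = [(shared_sets[t][0], sponges[t], triplet_mrnas[t])
                for t in range(cfg.n_triplets)]

    de_pool = [g for g in gene_ids if g not in set(triplet_mrnas)]
    de_ids = de_pool[:cfg.n_de]
    comparisons = ["A_vs_B", "A_vs_C", "B_vs_C"]
    de_features = {fid: comparisons[i % 3] for i, fid in enumerate(de_ids)}

    # per-sample latent trend shared within each triplet (age trend + jitter)
    trend = np.linspace(1.0, -1.0, n_s)  # planted RNAs decline with age
    latents = [trend + rng.normal(0.0, 0.05, n_s) for _ in range(cfg.n_triplets)]

    group_idx = {g: [samples.index(s) for s in design.samples_in(g)]
                 for g in design.groups}

    def _mean_matrix(feature_ids, mean_range) -> pd.DataFrame:
        base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                                  len(feature_ids)))
        return pd.DataFrame(np.tile(base[:, None], (1, n_s)),
                            index=feature_ids, columns=samples)

    gene_feature_ids = gene_ids + lnc_ids
    mu_gene = _mean_matrix(gene_feature_ids, cfg.base_mean_range)
    mu_circ = _mean_matrix(circ_ids, cfg.circ_mean_range)
    mu_mirna = _mean_matrix(mirna_ids, cfg.base_mean_range)

    # planted DE: scale the second group of the comparison by 2^effect
    for fid, comp in de_features.items():
        g2 = comp.split("_vs_")[1]
        mu_gene.loc[fid, design.samples_in(g2)] *= 2.0 ** cfg.de_log2_effect

    # planted triplets: opposite-sign linear modulation around a high base mean
    a = cfg.corr_amplitude
    for t, (z, shared) in enumerate(zip(latents, shared_sets)):
        up = np.clip(cfg.planted_base_mean * (1.0 + a * z), 1.0, None)
        down = np.clip(cfg.planted_base_mean * (1.0 - a * z), 1.0, None)
        sponge, mrna = sponges[t], triplet_mrnas[t]
        mu_gene.loc[mrna] = up
        if sponge in mu_gene.index:
            mu_gene.loc[sponge] = up
        else:
            mu_circ.loc[sponge] = up
        for m in shared:
            mu_mirna.loc[m] = down

    phi = cfg.dispersion
    gene_counts = pd.DataFrame(_nb_draw(rng, mu_gene.to_numpy(), phi),
                               index=gene_feature_ids, columns=samples)
    circ_counts = pd.DataFrame(_nb_draw(rng, mu_circ.to_numpy(), phi),
                               index=circ_ids, columns=samples)
    mirna_counts = pd.DataFrame(_nb_draw(rng, mu_mirna.to_numpy(), phi),
                                index=mirna_ids, columns=samples)

    # ----------------------------------------------------------- circ candidates
    cand_rows = []
    for r, cid in zip(circ_rows, circ_ids):
        row = {k: r[k] for k in ("chrom", "start", "end", "strand")}
        row.update(_quality_fields(rng))
        for s in samples:
            row[s] = int(circ_counts.loc[cid, s])
        cand_rows.append(row)
    circ_candidates = pd.DataFrame(cand_rows,
                                   columns=list(CANDIDATE_COLUMNS) + samples)

    # ------------------------------------------------------------- target maps
    predictors = ["predictorA", "predictorB", "predictorC"]
    all_targets = lnc_ids + circ_ids + gene_ids
    consensus: set[tuple[str, str]] = set()
    for m in mirna_ids:
        for t in all_targets:
            if rng.random() < cfg.consensus_target_rate:
                consensus.add((m, t))
    for shared, sponge, mrna in zip(shared_sets, sponges, triplet_mrnas):
        for m in shared:
            consensus.add((m, sponge))
            consensus.add((m, mrna))
    maps = []
    for name in predictors:
        pairs = set(consensus)
        for m in mirna_ids:
            for t in all_targets:
                if rng.random() < cfg.background_target_rate:
                    pairs.add((m, t))
        maps.append(TargetMap(name, pairs))

    # ------------------------------------------------------------- coding flags
    flag_rows = [{"transcript_id": lid, "assessor1_noncoding": True,
                  "assessor2_noncoding": True, "protein_hit": False}
                 for lid in lnc_ids]
    tx_rows = [{"transcript_id": t.transcript_id, "length": t.length}
               for t in lncs]
    decoy_modes = [("decoy_cod1", False, True, False, 600),
                   ("decoy_cod2", True, False, False, 600),
                   ("decoy_prot", True, True, True, 600),
                   ("decoy_short", True, True, False, 150)]
    for i in range(cfg.n_decoy_transcripts):
        did, a1, a2, hit, length = decoy_modes[i % len(decoy_modes)]
        did = f"{did}_{i + 1:02d}"
        flag_rows.append({"transcript_id": did, "assessor1_noncoding": a1,
                          "assessor2_noncoding": a2, "protein_hit": hit})
        tx_rows.append({"transcript_id": did, "length": length})
    coding_flags = pd.DataFrame(flag_rows)
    transcripts = pd.DataFrame(tx_rows)

    # ---------------------------------------------------------------- term maps
    terms, pathway_classes = _make_terms(cfg, gene_ids, circ_rows, triplet_mrnas, rng)

    truth = PlantedTruth(
        cerna_triplets=triplets,
        triplet_shared=shared_sets,
        de_features=de_features,
        true_classes={**lnc_classes, **circ_classes},
    )
    return SyntheticDataset(
        design=design, annotation=annotation, transcripts=transcripts,
        lnc_transcripts=lncs,
        gene_expr=ExpressionMatrix(gene_counts, "counts", "mRNA+lncRNA"),
        circ_expr=ExpressionMatrix(circ_counts, "counts", "circRNA"),
        mirna_expr=ExpressionMatrix(mirna_counts, "counts", "miRNA"),
        circ_candidates=circ_candidates, target_maps=maps,
        coding_flags=coding_flags, terms=terms, pathway_classes=pathway_classes,
        truth=truth,
    )


def _make_terms(cfg: GeneratorConfig, gene_ids, circ_rows, triplet_mrnas,
                rng: np.random.Generator):
    """Synthetic GO-like and pathway-like term maps over the generated genes.

    One immune pathway collects the circRNA host genes and triplet mRNAs so
    the immune-circRNA screen has a live target; the rest are random sets.
    """
    host_genes = sorted({r["host_gene"] for r in circ_rows if r["host_gene"]})
    immune = TermMap("path_0001", "Immune cell signaling", "pathway",
                     set(host_genes[:12]) | set(triplet_mrnas))
    terms = [immune]
    classes = {"path_0001": "Immune system"}
    for i in range(2, 7):
        size = int(rng.integers(5, 15))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        tid = f"path_{i:04d}"
        terms.append(TermMap(tid, f"Pathway {i}", "pathway", members))
        classes[tid] = "Metabolism"
    for i in range(1, 9):
        size = int(rng.integers(5, 20))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        terms.append(TermMap(f"GO:{i:07d}", f"process {i}", "BP", members))
    return terms, classes


def generate_null_targets(n_mirnas: int = 2000, n_nc: int = 25, n_mrna: int = 40,
                          target_rate: float = 0.3, seed: int = 0) -> TargetMap:
    """Target map with NO planted structure: every miRNA-target link i.i.d.

    Under this null, conditional on the per-feature targeting-set sizes, the
    shared-miRNA overlap of any (ncRNA, mRNA) pair is exactly hypergeometric,
    so the sponge screen's p-values can be checked for calibration. The
    default sizes give dense enough target sets that the discrete p-value
    support is fine near 0.05.
    """
    rng = np.random.default_rng(seed)
    mirnas = [f"miR-{i + 1:05d}" for i in range(n_mirnas)]
    targets = [f"nc_{i + 1:04d}" for i in range(n_nc)] + \
              [f"gene_{i + 1:04d}" for i in range(n_mrna)]
    pairs = set()
    for t in targets:
        hit = rng.random(n_mirnas) < target_rate
        for m, h in zip(mirnas, hit):
            if h:
                pairs.add((m, t))
    return TargetMap("null", pairs)


def generate_circ_candidates(n_pass: int, n_fail: int, seed: int = 0,
                             n_samples: int = 9) -> pd.DataFrame:
    """Standalone candidate table with constructed pass/fail truth.

    Exactly ``n_pass`` rows satisfy all seven filter conditions; ``n_fail``
    rows each violate one targeted condition (cycling through all seven, so
    every condition is covered once n_fail >= 7). Columns ``planted_pass``
    and ``violated`` carry the constructed truth; ``violated`` names the
    first condition violated in the filter's reporting order.
    """
    if n_pass < 0 or n_fail < 0:
        raise ValueError("n_pass and n_fail must be >= 0")
    rng = np.random.default_rng(seed)
    samples = list(SampleDesign.default().sample_ids)[:n_samples] or [
        f"S{i + 1}" for i in range(n_samples)]
    if len(samples) < n_samples:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    rows = []

    def _base_row(i: int) -> dict:
        start = 10_000 + 50_000 * i
        row = {"chrom": "chrS1", "start": start,
               "end": start + int(rng.integers(300, 5000)), "strand": "+"}
        row.update(_quality_fields(rng))
        for s in samples:
            row[s] = int(rng.integers(0, 50))
        return row

    for i in range(n_pass):
        row = _base_row(i)
        row["planted_pass"] = True
        row["violated"] = ""
        rows.append(row)
    half = n_samples // 2
    fail_makers = [
        ("breakpoints", lambda r: r.update(breakpoints=2)),
        ("anchor_overlap", lambda r: r.update(anchor_overlap=3)),
        ("edit", lambda r: r.update(edit=3)),
        ("n_uniq>2", lambda r: r.update(n_uniq=2)),
        ("best_qual", lambda r: r.update(best_qual_A=35, best_qual_B=35)),
        ("n_uniq>samples/2", lambda r: r.update(n_uniq=max(3, half))),
        ("length", lambda r: r.update(end=r["start"] + 100_000 - 1)),
    ]
    for j in range(n_fail):
        name, breaker = fail_makers[j % len(fail_makers)]
        if name == "n_uniq>samples/2" and half < 3:
            # condition 6 cannot be violated alone when floor(n/2) < 3
            name, breaker = fail_makers[3]
        row = _base_row(n_pass + j)
        breaker(row)
        row["planted_pass"] = False
        row["violated"] = name
        rows.append(row)
    cols = list(CANDIDATE_COLUMNS) + samples + ["planted_pass", "violated"]
    return pd.DataFrame(rows, columns=cols)
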