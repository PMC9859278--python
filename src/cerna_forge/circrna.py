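"""Back-splice junction filtering, RPM quantification, and circRNA type classification.

A circRNA candidate is one back-splice junction with the quality fields a
find_circ-style caller emits. Filtering applies seven conjunctive conditions;
classification assigns exactly one of six positional types against the
annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, Gene

__all__ = [
    "CANDIDATE_COLUMNS", "FILTER_CONDITIONS", "CIRC_TYPES",
    "evaluate_conditions", "filter_candidates", "rpm_normalize",
    "classify_circ", "classify_all", "CircRecord",
]

log = logging.getLogger(__name__)

#: required columns of a candidate table (per-sample count columns are extra)
CANDIDATE_COLUMNS = (
    "chrom", "start", "end", "strand", "breakpoints", "anchor_overlap",
    "edit", "n_uniq", "best_qual_A", "best_qual_B",
)

#: the six positional types, in classification precedence order
CIRC_TYPES = ("annot_exons", "one_exon", "exon_intron", "intronic",
              "antisense", "intergenic")

#: condition name -> human-readable rule, in the order violations are reported
FILTER_CONDITIONS = {
    "breakpoints": "breakpoints == 1",
    "anchor_overlap": "anchor_overlap <= 2",
    "edit": "edit <= 2",
    "n_uniq>2": "n_uniq > 2",
    "best_qual": "best_qual_A > 35 or best_qual_B > 35",
    "n_uniq>samples/2": "n_uniq > int(samples/2)",
    "length": "genomic span < 100000 nt",
}

MAX_SPAN_NT = 100_000


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"candidate table missing required column(s): {missing}")


def evaluate_conditions(candidates: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Boolean pass/fail per condition for every candidate row.

    Returns a frame indexed like ``candidates`` with one boolean column per
    condition in :data:`FILTER_CONDITIONS`, plus ``pass_all`` and a
    ``fail_reason`` column naming the first violated condition ('' if none).
    """
    _require_columns(candidates, CANDIDATE_COLUMNS)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    c = candidates
    span = c["end"].astype(int) - c["start"].astype(int) + 1  # 1-based inclusive
    checks = pd.DataFrame(
        {
            "breakpoints": c["breakpoints"].astype(int) == 1,
            "anchor_overlap": c["anchor_overlap"].astype(int) <= 2,
            "edit": c["edit"].astype(int) <= 2,
            "n_uniq>2": c["n_uniq"].astype(int) > 2,
            "best_qual": (c["best_qual_A"].astype(int) > 35)
                         | (c["best_qual_B"].astype(int) > 35),
            "n_uniq>samples/2": c["n_uniq"].astype(int) > n_samples // 2,
            "length": span < MAX_SPAN_NT,
        },
        index=c.index,
    )
    checks["pass_all"] = checks.all(axis=1)
    reasons = []
    failed = ~checks[list(FILTER_CONDITIONS)]
    for i in checks.index:
        row = failed.loc[i]
        reasons.append(next((name for name in FILTER_CONDITIONS if row[name]), ""))
    checks["fail_reason"] = reasons
    return checks


def filter_candidates(candidates: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Retain candidates satisfying all seven junction-quality conditions.

    Conditions (conjunction): breakpoints == 1; anchor_overlap <= 2;
    edit <= 2; n_uniq > 2; best_qual_A > 35 or best_qual_B > 35;
    n_uniq > floor(n_samples/2); genomic span (end-start+1) < 100 kb.
    Input row order is preserved.
    """
    checks = evaluate_conditions(candidates, n_samples)
    return candidates.loc[checks["pass_all"]].copy()


def rpm_normalize(counts: pd.DataFrame, library_totals: pd.Series) -> pd.DataFrame:
    """Back-spliced reads per million mapped reads: count * 1e6 / library_total.

    ``library_totals`` must cover every sample column and be strictly positive.
    """
    totals = library_totals.reindex(counts.columns)
    bad = totals.index[totals.isna() | (totals <= 0)].tolist()
    if bad:
        raise ValueError(f"non-positive or missing library total for sample(s): {bad}")
    return counts.astype(float).mul(1e6).div(totals, axis=1)


@dataclass
class CircRecord:
    circ_id: str
    chrom: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    circ_type: str
    host_gene: str | None

    def __post_init__(self):
        if self.circ_type not in CIRC_TYPES:
            raise ValueError(f"unknown circ_type {self.circ_type!r}")
        if (self.host_gene is None) != (self.circ_type == "intergenic"):
            raise ValueError("host_gene must be None exactly for intergenic circRNAs")


def _classify_against_gene(start: int, end: int, gene: Gene) -> str | None:
    """Type within one same-strand gene, or None if no rule matches."""
    exons = [(e.start, e.end) for e in gene.exons()]
    if not exons:
        return None
    # annot_exons: both back-splice ends coincide with exon boundaries, >= 2 exons spanned
    left_ok = any(start == s for s, _ in exons)
    right_ok = any(end == e for _, e in exons)
    spanned = [x for x in exons if x[0] < end and x[1] > start]
    if left_ok and right_ok and len(spanned) >= 2:
        return "annot_exons"
    if any(s <= start and end <= e for s, e in exons):
        return "one_exon"
    overlaps_exon = bool(spanned)
    introns = gene.introns()
    if any(s <= start and end <= e for s, e in introns):
        return "intronic"
    overlaps_intron = any(x[0] < end and x[1] > start for x in introns)
    if overlaps_exon and overlaps_intron:
        return "exon_intron"
    return None


def classify_circ(chrom: str, start: int, end: int, strand: str,
                  annotation: AnnotationSet) -> tuple[str, str | None]:
    """Assign one of the six positional types to a back-splice span.

    Coordinates are internal (0-based half-open). Precedence: same-strand
    gene overlap (annot_exons > one_exon > exon_intron > intronic), then
    opposite-strand overlap (antisense), then intergenic. Returns
    ``(circ_type, host_gene)``; host_gene is None only for intergenic.
    """
    if chrom not in annotation.chromosomes:
        log.warning("chromosome %s absent from annotation; classifying intergenic", chrom)
        return "intergenic", None
    same = [g for g in annotation.genes_overlapping(chrom, start, end, strand=strand)
            if g.biotype == "protein_coding"]
    best: tuple[int, str, str] | None = None
    for gene in same:
        t = _classify_against_gene(start, end, gene)
        if t is not None:
            rank = CIRC_TYPES.index(t)
            if best is None or rank < best[0]:
                best = (rank, t, gene.gene_id)
    if best is not None:
        return best[1], best[2]
    opposite_strand = "-" if strand == "+" else "+"
    anti = [g for g in annotation.genes_overlapping(chrom, start, end, strand=opposite_strand)
            if g.biotype == "protein_coding"]
    if anti:
        return "antisense", anti[0].gene_id
    if same:  # same-strand overlap that matched no structural rule: treat as exon_intron edge
        return "exon_intron", same[0].gene_id
    return "intergenic", None


def classify_all(candidates: pd.DataFrame, annotation: AnnotationSet,
                 id_prefix: str = "novel_circ") -> pd.DataFrame:
    """Classify every candidate row; returns a table with circ_id/type/host_gene.

    Input coordinates follow the external convention (1-based inclusive);
    the 0-based shift happens here, at the file boundary.
    """
    _require_columns(candidates, ("chrom", "start", "end", "strand"))
    rows = []
    for i, (_, r) in enumerate(candidates.iterrows(), start=1):
        start0, end0 = int(r["start"]) - 1, int(r["end"])
        ctype, host = classify_circ(str(r["chrom"]), start0, end0, str(r["strand"]),
                                    annotation)
        rows.append({
            "circ_id": f"{id_prefix}_{i:06d}",
            "chrom": r["chrom"], "start": r["start"], "end": r["end"],
            "strand": r["strand"], "circ_type": ctype,
            "host_gene": host if host is not None else "",
        })
    return pd.DataFrame(rows, columns=["circ_id", "chrom", "start", "end", "strand",
                                       "circ_type", "host_gene"])
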