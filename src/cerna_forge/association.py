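"""Three-mode lncRNA-mRNA association: antisense, cis (30 kb window), trans.

Antisense: opposite-strand exonic overlap (the deterministic core of the
antisense relation; an externally computed minimum-free-energy duplex table
can be supplied instead through ``mfe_table``). Cis: genomic proximity
within a window of a protein-coding gene. Trans: near-perfect expression
correlation across the 9 samples.
"""

from __future__ import annotations

import pandas as pd

from .annotation import AnnotationSet, Transcript
from .matrix import ExpressionMatrix
from .stats import ZeroVarianceError, pearson

__all__ = ["find_cis", "find_trans", "find_antisense", "ASSOC_COLUMNS"]

ASSOC_COLUMNS = ("lncrna_id", "target_id", "mode", "stream", "distance", "r", "p", "sign")


def _assoc_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(ASSOC_COLUMNS))


def _gap(a_start, a_end, b_start, b_end) -> int:
    """Nucleotide gap between two half-open intervals; 0 when overlapping."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if a_end <= b_start else a_start - b_end


def _corr_or_none(expr_a, expr_b, fid_a, fid_b):
    try:
        return pearson(expr_a.row(fid_a), expr_b.row(fid_b))
    except (KeyError, ZeroVarianceError):
        return None


def find_cis(lncrnas: list[Transcript], annotation: AnnotationSet,
             window: int = 30_000,
             lnc_expr: ExpressionMatrix | None = None,
             gene_expr: ExpressionMatrix | None = None) -> pd.DataFrame:
    """lncRNA-gene pairs within ``window`` nt up- or downstream of a coding gene.

    Distance is the gap between the nearest transcript/gene boundaries
    (0 if overlapping, stream OVERLAP). Stream is relative to the gene's
    strand: a lncRNA on the promoter side of the gene is UPSTREAM. When
    expression matrices are supplied, Pearson r/p are attached per pair.
    """
    rows = []
    for lnc in lncrnas:
        for gene in annotation.coding_genes():
            if gene.chrom != lnc.chrom:
                continue
            d = _gap(lnc.start, lnc.end, gene.start, gene.end)
            if d > window:
                continue
            if d == 0:
                stream = "OVERLAP"
            else:
                lnc_before = lnc.end <= gene.start
                if gene.strand == "+":
                    stream = "UPSTREAM" if lnc_before else "DOWNSTREAM"
                else:
                    stream = "DOWNSTREAM" if lnc_before else "UPSTREAM"
            r = p = float("nan")
            sign = ""
            if lnc_expr is not None and gene_expr is not None:
                rp = _corr_or_none(lnc_expr, gene_expr, lnc.transcript_id, gene.gene_id)
                if rp is not None:
                    r, p = rp
                    sign = "pos" if r > 0 else "neg"
            rows.append({"lncrna_id": lnc.transcript_id, "target_id": gene.gene_id,
                         "mode": "cis", "stream": stream, "distance": d,
                         "r": r, "p": p, "sign": sign})
    return _assoc_frame(rows)


def find_trans(lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
               r_threshold: float = 0.999,
               neg_r: float | None = None) -> pd.DataFrame:
    """Co-expression (trans) pairs: |r| > r_threshold across matched samples.

    ``neg_r`` optionally adds a separate negative tail: pairs with
    r < neg_r are also emitted (off by default). Constant rows are skipped
    with a warning upstream of the correlation.
    """
    if list(lnc_expr.sample_ids) != list(mrna_expr.sample_ids):
        raise ValueError("lncRNA and mRNA matrices must share the same sample columns")
    rows = []
    for lid in lnc_expr.feature_ids:
        x = lnc_expr.row(lid)
        for mid in mrna_expr.feature_ids:
            if mid == lid:
                continue
            try:
                r, p = pearson(x, mrna_expr.row(mid))
            except ZeroVarianceError:
                continue
            keep = abs(r) > r_threshold or (neg_r is not None and r < neg_r)
            if keep:
                rows.append({"lncrna_id": lid, "target_id": mid, "mode": "trans",
                             "stream": "", "distance": -1, "r": r, "p": p,
                             "sign": "pos" if r > 0 else "neg"})
    return _assoc_frame(rows)


def find_antisense(lncrnas: list[Transcript], annotation: AnnotationSet,
                   lnc_expr: ExpressionMatrix | None = None,
                   gene_expr: ExpressionMatrix | None = None,
                   mfe_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """lncRNA-gene pairs with opposite-strand exonic overlap.

    The overlap length (nt, over merged gene exons) is reported in the
    distance column with stream OVERLAP; many lncRNAs may target one gene.
    ``mfe_table`` (columns lncrna_id, target_id, mfe) restricts pairs to an
    externally computed duplex set when given.
    """
    allowed = None
    if mfe_table is not None:
        allowed = set(zip(mfe_table["lncrna_id"], mfe_table["target_id"]))
    rows = []
    for lnc in lncrnas:
        lnc_exons = [(e.start, e.end) for e in lnc.exons] or [(lnc.start, lnc.end)]
        opposite = "-" if lnc.strand == "+" else "+"
        for gene in annotation.genes_overlapping(lnc.chrom, lnc.start, lnc.end,
                                                 strand=opposite):
            if gene.biotype != "protein_coding":
                continue
            gx = [(e.start, e.end) for e in gene.exons()] or [(gene.start, gene.end)]
            overlap = 0
            for ls, le in lnc_exons:
                for gs, ge in gx:
                    overlap += max(0, min(le, ge) - max(ls, gs))
            if overlap == 0:
                continue
            if allowed is not None and (lnc.transcript_id, gene.gene_id) not in allowed:
                continue
            r = p = float("nan")
            sign = ""
            if lnc_expr is not None and gene_expr is not None:
                rp = _corr_or_none(lnc_expr, gene_expr, lnc.transcript_id, gene.gene_id)
                if rp is not None:
                    r, p = rp
                    sign = "pos" if r > 0 else "neg"
            rows.append({"lncrna_id": lnc.transcript_id, "target_id": gene.gene_id,
                         "mode": "antisense", "stream": "OVERLAP", "distance": overlap,
                         "r": r, "p": p, "sign": sign})
    return _assoc_frame(rows)
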