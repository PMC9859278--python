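"""Generic over-representation analysis against user-supplied term maps.

Terms are GO-like (BP/MF/CC) or pathway-like gene sets; the test is the
upper-tail hypergeometric (identical kernel to the sponge screen), with
BH-FDR computed within each category's test family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .stats import bh_adjust, hypergeom_upper_tail

__all__ = ["TermMap", "ora", "read_gmt", "write_gmt"]

log = logging.getLogger(__name__)

CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass
class TermMap:
    """One gene-set term: id, display name, category, member genes."""

    term_id: str
    term_name: str
    category: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")


def ora(study_genes, background_genes, terms: list[TermMap],
        sig_field: str = "fdr", alpha: float = 0.05,
        min_term_size: int = 2) -> pd.DataFrame:
    """Over-representation of the study set in each term.

    Per term: k = study genes in term, K = background genes in term,
    n = |study|, N = |background|; p is the upper-tail hypergeometric;
    FDR is BH within each category. Terms with K < ``min_term_size`` after
    background intersection are untestable and skipped (logged). The
    ``significant`` flag applies ``sig_field`` (fdr or p) at ``alpha``
    (<=, matching the FDR <= 0.05 convention).
    """
    study = set(study_genes)
    background = set(background_genes)
    stray = sorted(study - background)
    if stray:
        raise ValueError(f"study genes absent from background: {stray[:10]}")
    if sig_field not in {"fdr", "p"}:
        raise ValueError("sig_field must be 'fdr' or 'p'")
    N, n = len(background), len(study)
    rows = []
    for t in sorted(terms, key=lambda t: t.term_id):
        genes = t.genes & background
        if len(genes) < min_term_size:
            log.info("skipping untestable term %s (K=%d)", t.term_id, len(genes))
            continue
        K = len(genes)
        k = len(genes & study)
        rows.append({"term_id": t.term_id, "term_name": t.term_name,
                     "category": t.category, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_upper_tail(k, K, n, N)})
    res = pd.DataFrame(rows, columns=["term_id", "term_name", "category",
                                      "k", "K", "n", "N", "p"])
    if len(res) == 0:
        res["fdr"] = []
        res["significant"] = []
        return res
    res["fdr"] = 1.0
    for cat, idx in res.groupby("category").groups.items():
        res.loc[idx, "fdr"] = bh_adjust(res.loc[idx, "p"].to_numpy())
    res["significant"] = res[sig_field] <= alpha
    return res.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def read_gmt(path: str, category: str = "pathway") -> list[TermMap]:
    """GMT reader: term_id <TAB> description <TAB> gene1 <TAB> gene2 ...

    A description field of the form 'category=BP' overrides ``category``.
    """
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            tid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            cat = category
            name = desc
            if desc.startswith("category="):
                cat = desc.split("=", 1)[1]
                name = tid
            terms.append(TermMap(tid, name, cat, set(genes)))
    return terms


def write_gmt(terms: list[TermMap], path: str) -> None:
    with open(path, "w") as fh:
        for t in sorted(terms, key=lambda t: t.term_id):
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\tcategory={t.category}\t{genes}\n")
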