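"""ceRNA (miRNA-sponge) screening and network export.

A candidate ceRNA pair is a non-coding RNA (lncRNA or circRNA) and an mRNA
that share predicted miRNA binding partners. Evidence combines (a) an
upper-tail hypergeometric test on the shared-miRNA overlap against the
miRNA universe, (b) negative correlation of every shared miRNA with both
partners, and (c) positive correlation between the partners themselves.
Key sponges are flagged by a stricter negative-correlation tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import ZeroVarianceError, bh_adjust, hypergeom_upper_tail, pearson

__all__ = [
    "TargetMap", "intersect_targets", "hypergeom_shared", "candidate_pairs",
    "screen_cerna", "select_key", "screen_immune_circ", "build_edges",
    "write_sif",
]


@dataclass
class TargetMap:
    """miRNA -> target pairs from one predictor (or their intersection)."""

    predictor_name: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, predictor_name: str = "") -> "TargetMap":
        return cls(predictor_name, set(zip(df["miRNA_id"], df["target_id"])))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["miRNA_id", "target_id"])

    def mirnas_of(self, target_id: str) -> set[str]:
        return {m for m, t in self.pairs if t == target_id}

    def targets_of(self, mirna_id: str) -> set[str]:
        return {t for m, t in self.pairs if m == mirna_id}

    @property
    def mirna_universe(self) -> set[str]:
        return {m for m, _ in self.pairs}


def intersect_targets(maps: list[TargetMap]) -> TargetMap:
    """Pairs present in every predictor's table (the consensus prediction)."""
    if not maps:
        raise ValueError("need at least one target map")
    if len(maps) < 2:
        raise ValueError("intersection needs >= 2 predictor maps")
    pairs = set.intersection(*(m.pairs for m in maps))
    name = "&".join(m.predictor_name or "?" for m in maps)
    return TargetMap(name, pairs)


def hypergeom_shared(K: int, n: int, k: int, N: int) -> float:
    """Upper-tail hypergeometric p for a shared-miRNA overlap.

    N: miRNA universe size, K: miRNAs targeting partner a, n: miRNAs
    targeting partner b, k: shared. Same kernel as the enrichment test.
    """
    return hypergeom_upper_tail(k, K, n, N)


def candidate_pairs(targets: TargetMap, nc_ids, mrna_ids,
                    universe: set[str] | None = None) -> pd.DataFrame:
    """All (ncRNA, mRNA) pairs sharing >= 1 miRNA, with hypergeometric evidence.

    The default universe N is every miRNA with at least one target in
    ``targets``; pass ``universe`` to widen it (e.g. all profiled miRNAs).
    Columns: ce_a, ce_b, shared_mirnas (comma-joined), k, K, n, N, hyper_p.
    """
    uni = universe if universe is not None else targets.mirna_universe
    N = len(uni)
    by_target: dict[str, set[str]] = {}
    for m, t in targets.pairs:
        if m in uni:
            by_target.setdefault(t, set()).add(m)
    rows = []
    for a in sorted(nc_ids):
        ma = by_target.get(a, set())
        if not ma:
            continue
        for b in sorted(mrna_ids):
            if b == a:
                continue
            mb = by_target.get(b, set())
            shared = ma & mb
            if not shared:
                continue
            p = hypergeom_shared(len(ma), len(mb), len(shared), N)
            rows.append({"ce_a": a, "ce_b": b,
                         "shared_mirnas": ",".join(sorted(shared)),
                         "k": len(shared), "K": len(ma), "n": len(mb),
                         "N": N, "hyper_p": p})
    return pd.DataFrame(rows, columns=["ce_a", "ce_b", "shared_mirnas",
                                       "k", "K", "n", "N", "hyper_p"])


def _row_lookup(feature_id: str, *matrices: ExpressionMatrix) -> np.ndarray | None:
    for m in matrices:
        if feature_id in m.values.index:
            return m.row(feature_id)
    return None


def screen_cerna(pairs: pd.DataFrame, mirna_expr: ExpressionMatrix,
                 *ce_exprs: ExpressionMatrix,
                 alpha: float = 0.05, neg_r: float = -0.65,
                 pos_r: float = 0.0) -> pd.DataFrame:
    """Apply the full sponge screen to candidate pairs.

    A pair is retained iff hyper_p < alpha AND r(ce_a, ce_b) > pos_r AND
    every shared miRNA correlates below ``neg_r`` with both partners.
    Pairs with missing expression are skipped with a warning column rather
    than an exception. Adds r_ab, min/max shared-miRNA correlations and the
    ``retained`` flag; returns retained rows only, sorted by (ce_a, ce_b).
    """
    import logging
    log = logging.getLogger(__name__)
    out = []
    for _, row in pairs.iterrows():
        xa = _row_lookup(row["ce_a"], *ce_exprs)
        xb = _row_lookup(row["ce_b"], *ce_exprs)
        if xa is None or xb is None:
            log.warning("missing expression for pair (%s, %s); skipped",
                        row["ce_a"], row["ce_b"])
            continue
        try:
            r_ab, p_ab = pearson(xa, xb)
        except ZeroVarianceError:
            continue
        shared = [s for s in str(row["shared_mirnas"]).split(",") if s]
        worst_a = worst_b = -1.0  # max (least negative) correlation seen
        ok = True
        for m in shared:
            xm = _row_lookup(m, mirna_expr)
            if xm is None:
                ok = False
                break
            try:
                r_ma, _ = pearson(xm, xa)
                r_mb, _ = pearson(xm, xb)
            except ZeroVarianceError:
                ok = False
                break
            worst_a = max(worst_a, r_ma)
            worst_b = max(worst_b, r_mb)
            if not (r_ma < neg_r and r_mb < neg_r):
                ok = False
        if not ok:
            continue
        if row["hyper_p"] < alpha and r_ab > pos_r:
            rec = dict(row)
            rec.update({"r_ab": r_ab, "p_ab": p_ab,
                        "max_mirna_r_a": worst_a, "max_mirna_r_b": worst_b})
            out.append(rec)
    cols = list(pairs.columns) + ["r_ab", "p_ab", "max_mirna_r_a", "max_mirna_r_b"]
    res = pd.DataFrame(out, columns=cols)
    return res.sort_values(["ce_a", "ce_b"]).reset_index(drop=True)


def select_key(records: pd.DataFrame, r_cut: float = -0.9,
               significant_r: float = -0.63, alpha: float = 0.05) -> pd.DataFrame:
    """Tier miRNA-correlated sponges: 'key' (r < r_cut, strict) vs 'significant'.

    ``records`` carries per-sponge r and p against a named miRNA. Adds
    boolean ``is_key`` (r strictly below r_cut) and ``is_significant``
    (r < significant_r and p < alpha, the weaker tier). Both are flags,
    not silent filters.
    """
    out = records.copy()
    out["is_key"] = out["r"] < r_cut
    out["is_significant"] = (out["r"] < significant_r) & (out["p"] < alpha)
    return out


def screen_immune_circ(circ_records: pd.DataFrame, enrichment_results: pd.DataFrame,
                       pathway_class_map: dict[str, str],
                       circ_expr: ExpressionMatrix, term_genes: dict[str, set],
                       top_n: int = 10, sig_col: str = "significant") -> pd.DataFrame:
    """Top-N immune circRNAs: host gene in a significant immune pathway, by expression.

    ``pathway_class_map`` labels term_ids with a class; terms whose class
    contains 'immune' qualify. Ranking is by mean expression (descending),
    ties at the boundary broken by circ_id lexicographic order.
    """
    sig_terms = set(enrichment_results.loc[enrichment_results[sig_col], "term_id"])
    immune_terms = {t for t in sig_terms
                    if "immune" in pathway_class_map.get(t, "").lower()}
    immune_genes: set[str] = set()
    for t in immune_terms:
        immune_genes |= set(term_genes.get(t, set()))
    hits = circ_records.loc[circ_records["host_gene"].isin(immune_genes)].copy()
    if len(hits) == 0:
        return hits
    mean_expr = circ_expr.values.mean(axis=1)
    hits["mean_expr"] = hits["circ_id"].map(mean_expr).fillna(0.0)
    hits = hits.sort_values(["mean_expr", "circ_id"],
                            ascending=[False, True], kind="mergesort")
    return hits.head(top_n).reset_index(drop=True)


def build_edges(cerna_pairs: pd.DataFrame, targets: TargetMap,
                mirna_expr: ExpressionMatrix, *ce_exprs: ExpressionMatrix,
                r_cut: float = -0.95, sig_cut: float = 0.05) -> pd.DataFrame:
    """Network edge list for export.

    miRNA-target edges: targeting relation exists, r < r_cut, and BH-adjusted
    correlation p < sig_cut. ceRNA edges connect the retained sponge pairs.
    Self-loops are never emitted; output is deterministically sorted.
    Columns: source, target, edge_type, r, p, fdr.
    """
    cand = []
    for m, t in sorted(targets.pairs):
        if m == t:
            continue
        xm = _row_lookup(m, mirna_expr)
        xt = _row_lookup(t, *ce_exprs)
        if xm is None or xt is None:
            continue
        try:
            r, p = pearson(xm, xt)
        except ZeroVarianceError:
            continue
        cand.append({"source": m, "target": t, "edge_type": "miRNA-target",
                     "r": r, "p": p})
    edges = pd.DataFrame(cand, columns=["source", "target", "edge_type", "r", "p"])
    if len(edges):
        edges["fdr"] = bh_adjust(edges["p"].to_numpy())
        edges = edges.loc[(edges["r"] < r_cut) & (edges["fdr"] < sig_cut)]
    else:
        edges["fdr"] = []
    ce = [{"source": row["ce_a"], "target": row["ce_b"], "edge_type": "ceRNA",
           "r": row.get("r_ab", float("nan")), "p": row.get("hyper_p", float("nan")),
           "fdr": float("nan")}
          for _, row in cerna_pairs.iterrows() if row["ce_a"] != row["ce_b"]]
    ce_frame = pd.DataFrame(ce, columns=edges.columns)
    parts = [p for p in (edges, ce_frame) if len(p)]
    out = pd.concat(parts, ignore_index=True) if parts else edges
    return out.sort_values(["edge_type", "source", "target"],
                           kind="mergesort").reset_index(drop=True)


def write_sif(edges: pd.DataFrame, path: str) -> None:
    """Cytoscape SIF export: source <TAB> interaction <TAB> target, sorted."""
    with open(path, "w") as fh:
        for _, e in edges.iterrows():
            fh.write(f"{e['source']}\t{e['edge_type']}\t{e['target']}\n")
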