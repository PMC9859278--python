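"""End-to-end driver: chain every stage on a config, write a manifest.

The pipeline is deterministic for fixed inputs and seed; the manifest
records input hashes, thresholds, and per-stage in/out counts so two runs
can be diffed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import read_gtf
from .association import find_antisense, find_cis, find_trans
from .cerna import (TargetMap, build_edges, candidate_pairs, intersect_targets,
                    screen_cerna, screen_immune_circ, write_sif)
from .circrna import classify_all, filter_candidates, rpm_normalize
from .de import DEThresholds, de_screen, summarize_de, zscore_rows
from .enrichment import ora, read_gmt
from .io import expr_from_frame, file_sha256, read_design, read_tsv, write_tsv
from .lncrna import classify_table, gate_novel_lncrnas, length_bins
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

STAGES = ("circrna_detection", "lncrna_annotation", "expression_de",
          "association", "enrichment", "cerna_network")


@dataclass
class PipelineThresholds:
    """Every screening threshold, visible and overridable in one place."""

    de_alpha: float = 0.05
    de_min_lfc: float = 1.0
    de_lnc_sig_field: str = "fdr"   # lncRNA screen uses FDR
    de_circ_sig_field: str = "p"    # circRNA screen uses raw p
    cis_window: int = 30_000
    trans_r: float = 0.999
    enrich_alpha: float = 0.05
    enrich_sig_field: str = "fdr"
    cerna_alpha: float = 0.05
    cerna_neg_r: float = -0.65
    cerna_pos_r: float = 0.0
    cerna_key_r: float = -0.9
    edges_r: float = -0.95
    edges_sig: float = 0.05

    def validate(self) -> None:
        for name in ("de_alpha", "enrich_alpha", "cerna_alpha", "edges_sig"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.cis_window < 0:
            raise ValueError("cis_window must be >= 0")
        for name in ("cerna_neg_r", "cerna_key_r", "edges_r"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")


@dataclass
class PipelineConfig:
    """Input paths + thresholds + seed; unknown YAML keys are rejected."""

    input_dir: str
    output_dir: str
    seed: int = 0
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"input_dir", "output_dir", "seed", "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        thr = raw.pop("thresholds", {}) or {}
        valid_thr = {f for f in PipelineThresholds.__dataclass_fields__}
        bad = set(thr) - valid_thr
        if bad:
            raise ValueError(f"unknown threshold key(s): {sorted(bad)}")
        cfg = cls(input_dir=raw["input_dir"], output_dir=raw["output_dir"],
                  seed=int(raw.get("seed", 0)),
                  thresholds=PipelineThresholds(**thr))
        cfg.thresholds.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"input_dir": self.input_dir, "output_dir": self.output_dir,
                            "seed": self.seed, "thresholds": asdict(self.thresholds)},
                           fh, sort_keys=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all six stages; returns the run directory.

    Re-running on identical inputs reproduces identical outputs (sorted,
    full-precision writes; the only randomness is the seed recorded in the
    manifest).
    """
    thr = config.thresholds
    thr.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "thresholds": asdict(thr), "inputs": {}, "stages": []}
    for p in sorted(indir.iterdir()):
        if p.is_file():
            manifest["inputs"][p.name] = file_sha256(p)

    def stage(name):
        def deco(fn):
            def wrapped():
                try:
                    counts = fn()
                except StageError:
                    raise
                except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                    raise StageError(name, type(exc).__name__, str(exc)) from exc
                manifest["stages"].append({"stage": name, **(counts or {})})
                log.info("stage %s: %s", name, counts)
            return wrapped
        return deco

    # shared inputs
    try:
        annotation = read_gtf(indir / "annotation.gtf")
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotation", "ParseError", str(exc)) from exc
    design = read_design(indir / "design.tsv")
    gene_expr = expr_from_frame(read_tsv(indir / "gene_counts.tsv"), "counts")
    circ_counts = expr_from_frame(read_tsv(indir / "circ_counts.tsv"), "counts")
    mirna_expr = expr_from_frame(read_tsv(indir / "mirna_counts.tsv"), "counts")
    state: dict = {}

    @stage("circrna_detection")
    def s_circ():
        cand = read_tsv(indir / "circ_candidates.tsv")
        kept = filter_candidates(cand, n_samples=len(design.sample_ids))
        classified = classify_all(kept, annotation)
        rpm = rpm_normalize(circ_counts.values, circ_counts.values.sum(axis=0))
        state["circ_records"] = classified
        state["circ_rpm"] = ExpressionMatrix(rpm, "RPM", "circRNA")
        write_tsv(classified, outdir / "circ_records.tsv")
        return {"candidates_in": len(cand), "retained": len(kept)}

    @stage("lncrna_annotation")
    def s_lnc():
        flags = read_tsv(indir / "coding_flags.tsv")
        txs = read_tsv(indir / "transcripts.tsv")
        for col in ("assessor1_noncoding", "assessor2_noncoding", "protein_hit"):
            flags[col] = flags[col].astype(bool)
        gated = gate_novel_lncrnas(txs, flags)
        lnc_txs = [annotation.transcripts[t] for t in gated["transcript_id"]
                   if t in annotation.transcripts]
        classes = classify_table(lnc_txs, annotation)
        state["lnc_records"] = classes
        state["lnc_transcripts"] = lnc_txs
        write_tsv(classes, outdir / "lnc_records.tsv")
        write_tsv(length_bins(classes), outdir / "lnc_length_bins.tsv")
        return {"transcripts_in": len(txs), "novel_lncrnas": len(gated)}

    @stage("expression_de")
    def s_de():
        results = []
        for comp in [("A", "B"), ("A", "C"), ("B", "C")]:
            lnc_thr = DEThresholds(thr.de_lnc_sig_field, thr.de_alpha, thr.de_min_lfc)
            circ_thr = DEThresholds(thr.de_circ_sig_field, thr.de_alpha, thr.de_min_lfc)
            results.append(de_screen(gene_expr, design, comp, lnc_thr))
            circ_res = de_screen(circ_counts, design, comp, circ_thr)
            circ_res["feature_kind"] = "circRNA"
            results.append(circ_res)
        de_all = pd.concat(results, ignore_index=True)
        state["de_results"] = de_all
        write_tsv(de_all, outdir / "de_results.tsv")
        write_tsv(summarize_de(de_all), outdir / "de_summary.tsv")
        z = zscore_rows(gene_expr)
        zf = z.values.copy()
        zf.insert(0, "feature_id", zf.index)
        write_tsv(zf.reset_index(drop=True), outdir / "zscores.tsv")
        n_de = int((de_all["direction"] != "ns").sum())
        return {"features_tested": len(de_all), "differential": n_de}

    @stage("association")
    def s_assoc():
        lnc_txs = state["lnc_transcripts"]
        parts = [
            find_antisense(lnc_txs, annotation, gene_expr, gene_expr),
            find_cis(lnc_txs, annotation, thr.cis_window, gene_expr, gene_expr),
            find_trans(gene_expr.subset([t.transcript_id for t in lnc_txs
                                         if t.transcript_id in gene_expr.values.index]),
                       gene_expr, thr.trans_r),
        ]
        nonempty = [p for p in parts if len(p)] or parts[:1]
        assoc = pd.concat(nonempty, ignore_index=True)
        state["assoc"] = assoc
        write_tsv(assoc, outdir / "associations.tsv")
        return {"records": len(assoc)}

    @stage("enrichment")
    def s_enrich():
        terms = read_gmt(indir / "terms.gmt")
        background = [f for f in gene_expr.feature_ids if f.startswith("gene_")]
        hosts = sorted({h for h in state["circ_records"]["host_gene"]
                        if h and h in set(background)})
        res = ora(hosts, background, terms,
                  sig_field=thr.enrich_sig_field, alpha=thr.enrich_alpha)
        state["enrichment"] = res
        state["terms"] = terms
        write_tsv(res, outdir / "enrichment.tsv")
        return {"terms_tested": len(res),
                "significant": int(res["significant"].sum()) if len(res) else 0}

    @stage("cerna_network")
    def s_cerna():
        tmaps = [TargetMap.from_frame(read_tsv(p), p.stem.replace("targets_", ""))
                 for p in sorted(indir.glob("targets_*.tsv"))]
        final = intersect_targets(tmaps)
        nc_ids = (list(state["lnc_records"]["transcript_id"])
                  + list(state["circ_records"]["circ_id"]))
        mrna_ids = [f for f in gene_expr.feature_ids if f.startswith("gene_")]
        cands = candidate_pairs(final, nc_ids, mrna_ids)
        kept = screen_cerna(cands, mirna_expr, gene_expr, state["circ_rpm"],
                            alpha=thr.cerna_alpha, neg_r=thr.cerna_neg_r,
                            pos_r=thr.cerna_pos_r)
        write_tsv(kept, outdir / "cerna_pairs.tsv")
        classes_path = indir / "pathway_classes.tsv"
        if classes_path.exists() and "enrichment" in state:
            cls = dict(read_tsv(classes_path).itertuples(index=False, name=None))
            term_genes = {t.term_id: t.genes for t in state["terms"]}
            immune = screen_immune_circ(state["circ_records"], state["enrichment"],
                                        cls, state["circ_rpm"], term_genes)
            write_tsv(immune, outdir / "immune_circrnas.tsv")
        edges = build_edges(kept, final, mirna_expr, gene_expr, state["circ_rpm"],
                            r_cut=thr.edges_r, sig_cut=thr.edges_sig)
        write_tsv(edges, outdir / "edges.tsv")
        write_sif(edges, outdir / "network.sif")
        return {"candidate_pairs": len(cands), "cerna_pairs": len(kept),
                "edges": len(edges)}

    for fn in (s_circ, s_lnc, s_de, s_assoc, s_enrich, s_cerna):
        fn()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
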