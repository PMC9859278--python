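"""Shared readers/writers for the pipeline's plain-text formats.

Every table is TSV with a ``# columns:`` header comment declaring its schema,
so a written file can be re-read losslessly and audited by eye. Annotation
is GTF; term sets are GMT; networks are SIF; truth and manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .annotation import write_gtf
from .matrix import ExpressionMatrix, SampleDesign

__all__ = ["write_tsv", "read_tsv", "write_dataset", "file_sha256"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with a '# columns:' schema comment; floats at full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       keep_default_na=False, na_values=[""])


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _expr_to_frame(expr: ExpressionMatrix) -> pd.DataFrame:
    out = expr.values.copy()
    out.insert(0, "feature_id", out.index)
    return out.reset_index(drop=True)


def expr_from_frame(df: pd.DataFrame, unit: str = "counts",
                    feature_kind: str = "") -> ExpressionMatrix:
    vals = df.set_index("feature_id")
    return ExpressionMatrix(vals, unit=unit, feature_kind=feature_kind)


def write_dataset(dataset, outdir: str | Path) -> dict[str, str]:
    """Write every generated input to ``outdir``; returns name -> path map.

    Layout: annotation.gtf, design.tsv, gene_counts.tsv, circ_counts.tsv,
    mirna_counts.tsv, circ_candidates.tsv, targets_<predictor>.tsv x3,
    coding_flags.tsv, transcripts.tsv, terms.gmt, pathway_classes.tsv,
    truth.json.
    """
    from .enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _emit(name: str, fn) -> None:
        p = outdir / name
        fn(p)
        paths[name] = str(p)

    _emit("annotation.gtf", lambda p: write_gtf(dataset.annotation, p))
    _emit("design.tsv", lambda p: write_tsv(dataset.design.to_frame(), p))
    _emit("gene_counts.tsv", lambda p: write_tsv(_expr_to_frame(dataset.gene_expr), p))
    _emit("circ_counts.tsv", lambda p: write_tsv(_expr_to_frame(dataset.circ_expr), p))
    _emit("mirna_counts.tsv", lambda p: write_tsv(_expr_to_frame(dataset.mirna_expr), p))
    _emit("circ_candidates.tsv", lambda p: write_tsv(dataset.circ_candidates, p))
    for tm in dataset.target_maps:
        _emit(f"targets_{tm.predictor_name}.tsv",
              lambda p, tm=tm: write_tsv(tm.to_frame(), p))
    _emit("coding_flags.tsv", lambda p: write_tsv(dataset.coding_flags, p))
    _emit("transcripts.tsv", lambda p: write_tsv(dataset.transcripts, p))
    if dataset.terms:
        _emit("terms.gmt", lambda p: write_gmt(dataset.terms, p))
        classes = pd.DataFrame(sorted(dataset.pathway_classes.items()),
                               columns=["term_id", "term_class"])
        _emit("pathway_classes.tsv", lambda p: write_tsv(classes, p))
    if dataset.truth is not None:
        def _truth(p):
            with open(p, "w") as fh:
                json.dump(dataset.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        _emit("truth.json", _truth)
    return paths


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign.from_frame(read_tsv(path))
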