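"""Novel-lncRNA gating and positional classification.

A transcript is accepted as a novel lncRNA only when both coding-potential
assessors call it non-coding, no protein annotation hit exists, and it is
longer than 200 nt (the defining length of a lncRNA). Accepted transcripts
are then classified by position relative to protein-coding genes.
"""

from __future__ import annotations

import pandas as pd

from .annotation import AnnotationSet, Transcript

__all__ = [
    "LNC_CLASSES", "MIN_LNC_LENGTH", "gate_novel_lncrnas",
    "classify_lncrna", "length_bins",
]

#: the five positional classes plus the unresolved bucket
LNC_CLASSES = ("intergenic", "bidirectional", "antisense",
               "sense_overlapping", "intronic", "other")

MIN_LNC_LENGTH = 200  # nt; strict lower bound

FLAG_COLUMNS = ("transcript_id", "assessor1_noncoding", "assessor2_noncoding", "protein_hit")


def gate_novel_lncrnas(transcripts: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Intersection gate for novel lncRNAs.

    ``transcripts`` needs columns transcript_id and length (nt); ``flags``
    needs the two assessor calls and the protein-annotation hit flag.
    A transcript passes iff both assessors call non-coding AND there is no
    protein hit AND length > 200 nt. Returns the passing subset of
    ``transcripts`` with an ``is_novel_lncrna`` column (all True), original
    row order preserved.
    """
    missing_cols = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing_cols:
        raise KeyError(f"flags table missing column(s): {missing_cols}")
    fl = flags.set_index("transcript_id")
    missing = [t for t in transcripts["transcript_id"] if t not in fl.index]
    if missing:
        raise ValueError(f"transcripts without coding-potential flags: {missing}")
    f = fl.loc[transcripts["transcript_id"]]
    keep = (
        f["assessor1_noncoding"].to_numpy(dtype=bool)
        & f["assessor2_noncoding"].to_numpy(dtype=bool)
        & ~f["protein_hit"].to_numpy(dtype=bool)
        & (transcripts["length"].to_numpy() > MIN_LNC_LENGTH)
    )
    out = transcripts.loc[keep].copy()
    out["is_novel_lncrna"] = True
    return out


def classify_lncrna(transcript: Transcript, annotation: AnnotationSet,
                    bidirectional_window: int = 1000) -> str:
    """One of the five positional classes (or 'other') for a lncRNA transcript.

    Precedence against protein-coding genes:
      1. same-strand exonic overlap            -> sense_overlapping
      2. same-strand, fully inside one intron  -> intronic
      3. opposite-strand exonic overlap        -> antisense
      4. no overlap, TSS within
         ``bidirectional_window`` nt of an
         opposite-strand gene TSS              -> bidirectional
      5. no overlap at all                     -> intergenic
      6. anything unresolved                   -> other

    The bidirectional window is a convention (divergent promoters), default
    1 kb, configurable.
    """
    chrom, start, end, strand = (transcript.chrom, transcript.start,
                                 transcript.end, transcript.strand)
    coding = [g for g in annotation.genes_overlapping(chrom, start, end)
              if g.biotype == "protein_coding"]
    same = [g for g in coding if g.strand == strand]
    opposite = [g for g in coding if g.strand != strand]

    lnc_exons = [(e.start, e.end) for e in transcript.exons] or [(start, end)]

    def exonic_overlap(gene) -> bool:
        gx = [(e.start, e.end) for e in gene.exons()] or [(gene.start, gene.end)]
        return any(ls < ge and le > gs for ls, le in lnc_exons for gs, ge in gx)

    if any(exonic_overlap(g) for g in same):
        return "sense_overlapping"
    for g in same:
        if any(s <= start and end <= e for s, e in g.introns()):
            return "intronic"
    if any(exonic_overlap(g) for g in opposite):
        return "antisense"
    if not coding:
        tss = transcript.tss
        for g in annotation.coding_genes():
            if g.chrom == chrom and g.strand != strand \
                    and abs(g.tss - tss) <= bidirectional_window:
                return "bidirectional"
        return "intergenic"
    return "other"


def classify_table(transcripts, annotation: AnnotationSet,
                   bidirectional_window: int = 1000) -> pd.DataFrame:
    """Classify a list of Transcript objects; returns transcript_id/length/lnc_class."""
    rows = [{"transcript_id": t.transcript_id, "length": t.length,
             "lnc_class": classify_lncrna(t, annotation, bidirectional_window)}
            for t in transcripts]
    return pd.DataFrame(rows, columns=["transcript_id", "length", "lnc_class"])


def length_bins(records: pd.DataFrame, bin_width: int = 100) -> pd.DataFrame:
    """Length histogram with left-open right-closed bins labelled '201-300', ...

    Bin b covers lengths in (b*w, (b+1)*w]; counts sum to the number of
    records. Empty input gives an empty frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(records) == 0:
        return pd.DataFrame(columns=["bin", "count"])
    lengths = records["length"].astype(int)
    # (b*w, (b+1)*w] => index via ceil(length/w) - 1
    idx = (lengths + bin_width - 1) // bin_width - 1
    counts = idx.value_counts().sort_index()
    out = pd.DataFrame({
        "bin": [f"{b * bin_width + 1}-{(b + 1) * bin_width}" for b in counts.index],
        "count": counts.to_numpy(),
    })
    return out
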