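"""Genomic annotation container used by every positional classifier.

External files are GTF (1-based, inclusive). Internally every interval is
half-open 0-based; :func:`_to_internal` / :func:`_to_gtf` are the only places
the shift happens, so interval arithmetic never mixes conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

__all__ = ["Exon", "Transcript", "Gene", "AnnotationSet", "read_gtf", "write_gtf"]


def _to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_inclusive


def _to_gtf(start0: int, end0: int) -> tuple[int, int]:
    return start0 + 1, end0


@dataclass(frozen=True)
class Exon:
    start: int  # 0-based half-open
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty exon [{self.start}, {self.end})")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Exon] = field(default_factory=list)
    biotype: str = ""

    @property
    def length(self) -> int:
        """Spliced length (sum of exon lengths); genomic span if exon-less."""
        if self.exons:
            return sum(e.end - e.start for e in self.exons)
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start, strand-aware, 0-based position."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def exons(self) -> list[Exon]:
        out: list[Exon] = []
        for t in self.transcripts:
            out.extend(t.exons)
        return sorted(set(out), key=lambda e: (e.start, e.end))

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between the merged exon set of all transcripts."""
        merged = _merge([(e.start, e.end) for e in self.exons()])
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(merged, merged[1:])]


def _merge(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class AnnotationSet:
    """Gene/transcript/exon intervals with per-chromosome interval trees."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            for t in g.transcripts:
                self.transcripts[t.transcript_id] = t
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end, g.gene_id)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def genes_overlapping(self, chrom: str, start: int, end: int,
                          strand: str | None = None) -> list[Gene]:
        """Genes whose body overlaps [start, end), optionally strand-restricted."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def coding_genes(self) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]


def _validate_gtf_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(
                f"GTF parse error at line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}")
        if not (fields[3].isdigit() and fields[4].isdigit()):
            raise ValueError(
                f"GTF parse error at line {lineno}: non-integer coordinates "
                f"{fields[3]!r}/{fields[4]!r}")


def read_gtf(path: str) -> AnnotationSet:
    """Load a GTF into an AnnotationSet (gene/transcript/exon features)."""
    with open(path) as fh:
        _validate_gtf_lines(fh.read())
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    return _from_db(db)


def read_gtf_string(text: str) -> AnnotationSet:
    """Parse GTF from an in-memory string (used in tests and docs)."""
    db = gffutils.create_db(
        text, ":memory:", from_string=True, force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    return _from_db(db)


def _from_db(db) -> AnnotationSet:
    genes: dict[str, Gene] = {}
    for f in db.features_of_type("gene"):
        s0, e0 = _to_internal(f.start, f.end)
        biotype = (f.attributes.get("gene_biotype") or ["protein_coding"])[0]
        gid = f.attributes["gene_id"][0]
        genes[gid] = Gene(gid, f.seqid, s0, e0, f.strand, biotype=biotype)
    for f in db.features_of_type("transcript"):
        s0, e0 = _to_internal(f.start, f.end)
        gid = f.attributes["gene_id"][0]
        tid = f.attributes["transcript_id"][0]
        biotype = (f.attributes.get("transcript_biotype") or [""])[0]
        tx = Transcript(tid, gid, f.seqid, s0, e0, f.strand, biotype=biotype)
        if gid not in genes:  # transcript without explicit gene record
            genes[gid] = Gene(gid, f.seqid, s0, e0, f.strand, biotype="protein_coding")
        genes[gid].transcripts.append(tx)
    txs = {t.transcript_id: t for g in genes.values() for t in g.transcripts}
    for f in db.features_of_type("exon"):
        s0, e0 = _to_internal(f.start, f.end)
        tid = f.attributes["transcript_id"][0]
        if tid in txs:
            txs[tid].exons.append(Exon(s0, e0))
    for t in txs.values():
        t.exons.sort(key=lambda e: e.start)
    return AnnotationSet(sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)))


def write_gtf(annotation: AnnotationSet, path: str) -> None:
    """Write gene/transcript/exon records as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            s, e = _to_gtf(g.start, g.end)
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\tcerna_forge\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                ts, te = _to_gtf(t.start, t.end)
                tattrs = (f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                          + (f' transcript_biotype "{t.biotype}";' if t.biotype else ""))
                fh.write(f"{t.chrom}\tcerna_forge\ttranscript\t{ts}\t{te}\t.\t{t.strand}\t.\t{tattrs}\n")
                for ex in t.exons:
                    xs, xe = _to_gtf(ex.start, ex.end)
                    fh.write(f"{t.chrom}\tcerna_forge\texon\t{xs}\t{xe}\t.\t{t.strand}\t.\t{tattrs}\n")
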