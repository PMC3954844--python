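"""Gene annotation model and the two 3' tag counting (3TC) transformations.

3TC suppresses degradation-driven false positives in differential expression
by editing the annotation used for counting, in two steps:

1. *Isoform filtering* — keep a single representative isoform per gene
   (the most highly expressed one, or alternatively the isoform(s) whose
   3' end is the most downstream), so overlapping isoforms cannot
   contaminate gene-level counts.
2. *3' length restriction* — truncate each retained isoform to its
   3'-terminal ``N`` nucleotides, discarding all exonic bases further 5'.
   Because polyA-selected libraries lose 5' coverage as RNA degrades while
   3' coverage is preserved, counting only the 3' tag equalizes the
   countable region between intact and degraded samples.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based inclusive convention.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "Interval",
    "TranscriptModel",
    "GeneModel",
    "Annotation",
    "parse_gtf",
    "write_gtf",
    "read_abundance_table",
    "filter_major_isoform",
    "filter_threeprime_isoform",
    "restrict_threeprime",
]


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered chain of disjoint exons on a single strand.

    Exons are stored sorted by ascending genomic start regardless of strand;
    transcript (5'→3') order is derived from the strand when needed.
    """

    transcript_id: str
    gene_id: str
    biotype: str | None
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons span chromosomes {chroms}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if any(e.strand != self.strand for e in exons):
            raise ValueError(f"{self.transcript_id}: exon strand mismatch")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3'-most base boundary (end on +, start on -)."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    def exons_5to3(self) -> tuple[Interval, ...]:
        """Exons in transcript orientation (5'→3')."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    biotype: str | None
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs >= 1 transcript")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.gene_id}: duplicate transcript ids")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"{self.gene_id}: transcript gene_id mismatch")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.gene_id}: transcripts disagree on chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


class Annotation:
    """An ordered collection of genes (insertion order preserved)."""

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self._genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def transcripts(self) -> Iterable[TranscriptModel]:
        for g in self:
            yield from g.transcripts

    def map_transcripts(self, fn) -> "Annotation":
        """New Annotation with ``fn`` applied to every transcript (None drops it)."""
        out = Annotation()
        for g in self:
            txs = tuple(t2 for t in g.transcripts if (t2 := fn(t)) is not None)
            if txs:
                out.add(GeneModel(g.gene_id, g.biotype, txs))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self._genes == other._genes


# ---------------------------------------------------------------------------
# GTF I/O


def _as_text_stream(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "rt")


def parse_gtf(source, protein_coding_only: bool = False) -> Annotation:
    """Parse an Ensembl-dialect GTF into an :class:`Annotation`.

    Only ``exon`` features are modeled (counting is exon-based); CDS/UTR and
    gene/transcript container lines are ignored.  1-based inclusive GTF
    coordinates are converted to 0-based half-open.

    Parameters
    ----------
    source
        Path or open text stream of GTF lines.
    protein_coding_only
        If True, retain only genes whose ``gene_biotype`` attribute is
        ``protein_coding`` (genes lacking the attribute are dropped).
    """
    stream = _as_text_stream(source)
    close = stream is not source
    # (gene_id) -> {"biotype": ..., "tx": {transcript_id: [Interval, ...]}}
    genes: dict[str, dict] = {}
    tx_biotype: dict[str, str | None] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises various types
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: exon missing {exc} attribute")
            start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
            if end <= start:
                raise GtfParseError(f"line {lineno}: end < start")
            if feat.strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: missing strand")
            biotypes = feat.attributes.get("gene_biotype")
            biotype = biotypes[0] if biotypes else None
            rec = genes.setdefault(gene_id, {"biotype": biotype, "tx": {}})
            if rec["biotype"] is None:
                rec["biotype"] = biotype
            tx_biotype.setdefault(transcript_id, biotype)
            rec["tx"].setdefault(transcript_id, []).append(
                Interval(feat.seqid, start, end, feat.strand)
            )
    finally:
        if close:
            stream.close()

    ann = Annotation()
    for gene_id, rec in genes.items():
        if protein_coding_only and rec["biotype"] != "protein_coding":
            continue
        txs = tuple(
            TranscriptModel(tid, gene_id, rec["biotype"], exons[0].strand, tuple(exons))
            for tid, exons in rec["tx"].items()
        )
        ann.add(GeneModel(gene_id, rec["biotype"], txs))
    return ann


def write_gtf(ann: Annotation, dest=None, source: str = "threetc") -> str | None:
    """Write exon features in 1-based inclusive GTF, deterministically ordered
    by (gene_id, transcript_id, start).  Returns the text when ``dest`` is None."""
    buf = dest if hasattr(dest, "write") else io.StringIO()
    for gene in sorted(ann, key=lambda g: g.gene_id):
        for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            for exon in tx.exons:  # already ascending-start
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                if gene.biotype is not None:
                    attrs += f' gene_biotype "{gene.biotype}";'
                buf.write(
                    f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{exon.strand}\t.\t{attrs}\n"
                )
    if hasattr(dest, "write"):
        return None
    text = buf.getvalue()
    if dest is not None:
        with open(dest, "wt") as fh:
            fh.write(text)
        return None
    return text


def read_abundance_table(source) -> dict[str, float]:
    """Read a ``transcript_id<TAB>abundance`` TSV (FPKM-like values)."""
    df = pd.read_csv(source, sep="\t")
    if not {"transcript_id", "abundance"} <= set(df.columns):
        raise ValueError("abundance table needs columns transcript_id, abundance")
    if (df["abundance"] < 0).any():
        raise ValueError("abundances must be non-negative")
    return dict(zip(df["transcript_id"], df["abundance"].astype(float)))


# ---------------------------------------------------------------------------
# 3TC step 1: isoform filtering


def filter_major_isoform(
    ann: Annotation, abundance: Mapping[str, float]
) -> Annotation:
    """Keep, per gene, the isoform with the highest abundance.

    Transcripts absent from ``abundance`` are treated as abundance 0.  Ties
    (including all-zero genes) are broken by lexicographically smallest
    transcript_id, so the result is deterministic and every gene keeps
    exactly one isoform; silent genes are removed later by the expression
    filter, not here.
    """
    out = Annotation()
    for gene in ann:
        best = min(
            gene.transcripts,
            key=lambda t: (-float(abundance.get(t.transcript_id, 0.0)), t.transcript_id),
        )
        out.add(GeneModel(gene.gene_id, gene.biotype, (best,)))
    return out


def filter_threeprime_isoform(ann: Annotation) -> Annotation:
    """Keep, per gene, the isoform(s) whose 3' end is the most downstream.

    Annotation-only alternative to expression-based filtering, for when no
    high-quality sample is available to quantify isoforms.  On the + strand
    "most downstream" is the maximum end coordinate; on the - strand the
    minimum start.  All tied isoforms are retained.
    """
    out = Annotation()
    for gene in ann:
        ends = [t.three_prime_end for t in gene.transcripts]
        extreme = max(ends) if gene.strand == "+" else min(ends)
        keep = tuple(
            t for t in gene.transcripts if t.three_prime_end == extreme
        )
        out.add(GeneModel(gene.gene_id, gene.biotype, keep))
    return out


# ---------------------------------------------------------------------------
# 3TC step 2: 3' length restriction


def _restrict_transcript(tx: TranscriptModel, n: float) -> TranscriptModel:
    keep = min(n, tx.transcript_length)
    if keep >= tx.transcript_length:
        return tx
    keep = int(keep)
    new_exons: list[Interval] = []
    remaining = keep
    # walk exons from the 3' end, keeping whole exons until the boundary exon
    for exon in reversed(tx.exons_5to3()):
        take = min(remaining, len(exon))
        if tx.strand == "+":
            new_exons.append(Interval(exon.chrom, exon.end - take, exon.end, "+"))
        else:
            new_exons.append(Interval(exon.chrom, exon.start, exon.start + take, "-"))
        remaining -= take
        if remaining == 0:
            break
    return TranscriptModel(
        tx.transcript_id, tx.gene_id, tx.biotype, tx.strand, tuple(new_exons)
    )


def restrict_threeprime(ann: Annotation, n: float) -> Annotation:
    """Truncate every transcript to its 3'-terminal ``min(n, length)`` bases.

    ``n`` may be ``math.inf`` (no restriction; identity).  Exons wholly
    outside the retained window are dropped and the boundary exon is
    trimmed; exon order and disjointness are preserved.
    """
    if math.isinf(n) and n > 0:
        return ann.map_transcripts(lambda t: t)
    if n <= 0 or n != int(n):
        raise ValueError(f"length restriction must be a positive integer or inf, got {n}")
    return ann.map_transcripts(lambda t: _restrict_transcript(t, n))
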