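"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by per-base enumeration,
never by calling the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from threetc.annotation import Annotation, GeneModel, Interval, TranscriptModel


def make_tx(tid, gid, strand, exons, chrom="chr1", biotype="protein_coding"):
    return TranscriptModel(
        tid, gid, biotype, strand,
        tuple(Interval(chrom, s, e, strand) for s, e in exons),
    )


def make_gene(gid, strand, exons_per_tx, chrom="chr1"):
    """exons_per_tx: dict transcript_id -> [(start, end), ...]."""
    txs = tuple(
        make_tx(tid, gid, strand, exons, chrom=chrom)
        for tid, exons in exons_per_tx.items()
    )
    return GeneModel(gid, "protein_coding", txs)


def transcript_bases_5to3(tx) -> list[int]:
    """Oracle helper: every genomic base of a transcript in 5'->3' order."""
    bases: list[int] = []
    for e in tx.exons_5to3():
        coords = range(e.start, e.end)
        bases.extend(coords if tx.strand == "+" else reversed(coords))
    return bases


def random_transcript(rng: np.random.Generator, tid="t1", gid="g1",
                      chrom="chr1", lo=0, hi=100_000):
    """A random multi-exon transcript on either strand."""
    n_exons = int(rng.integers(1, 11))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(lo, lo + 500))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(1, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(1, 300))
        if pos >= hi:
            break
    return make_tx(tid, gid, strand, exons, chrom=chrom)


def strict_count_oracle(fragments, ann: Annotation):
    """Per-base brute-force intersection-strict classification.

    Returns (counts dict, no_feature, ambiguous).  For every fragment the
    set of genes covering each aligned base is intersected literally.
    """
    cover: dict[str, dict[int, set[str]]] = {}
    for gene in ann:
        for tx in gene.transcripts:
            for e in tx.exons:
                chrom_map = cover.setdefault(e.chrom, {})
                for b in range(e.start, e.end):
                    chrom_map.setdefault(b, set()).add(gene.gene_id)
    counts = {g: 0 for g in ann.gene_ids}
    no_feature = ambiguous = 0
    for frag in fragments:
        chrom_map = cover.get(frag.chrom, {})
        gene_sets = [
            chrom_map.get(b, set())
            for s, e in frag.blocks
            for b in range(s, e)
        ]
        inter = set.intersection(*gene_sets) if gene_sets else set()
        if len(inter) == 0:
            no_feature += 1
        elif len(inter) == 1:
            counts[next(iter(inter))] += 1
        else:
            ambiguous += 1
    return counts, no_feature, ambiguous


def bh_step_up_oracle(p: np.ndarray) -> np.ndarray:
    """Direct BH step-up: sort, p_(i) * m / i, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
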