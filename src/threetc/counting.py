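"""Gene-level fragment counting with htseq-style intersection-strict semantics.

A fragment (a single read, or a merged mate pair) is assigned to the set of
genes whose exons cover *every* aligned base of the fragment:

* set empty (some base uncovered, or no gene covers all bases) -> ``no_feature``
* exactly one gene -> counted for that gene
* more than one gene -> ``ambiguous``

Counting is unstranded by default (TruSeq-style libraries), fragment-level
(mates of a pair are merged and counted at most once), uses primary
alignments only and retains duplicates.

The classifier is vectorized: the annotation is flattened into a partition
of each chromosome into segments between exon boundaries, each segment
labelled with the set of genes whose (per-gene merged) exons cover it.  A
fragment's gene set is then the intersection of the segment labels its
blocks touch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import Annotation

__all__ = [
    "AlignedFragment",
    "FragmentSet",
    "GeneIndex",
    "CountColumn",
    "CountMatrix",
    "count_sample",
    "build_matrix",
    "downsample",
]

NO_FEATURE = -1
AMBIGUOUS = -2


@dataclass(frozen=True)
class AlignedFragment:
    """One sequenced fragment: the union of aligned blocks of its read(s)."""

    name: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]


def merge_blocks(blocks: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of intervals: sort and merge overlapping/adjacent blocks."""
    srt = sorted(blocks)
    out: list[list[int]] = []
    for s, e in srt:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


class FragmentSet:
    """Column-oriented store of aligned fragments (one chromosome name space).

    Fragments are held as flat numpy arrays (CSR layout over blocks) so the
    intersection-strict classifier can run vectorized.  Construct from an
    iterable of :class:`AlignedFragment` or from a SAM/BAM file; write back
    to SAM for interoperability.
    """

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_lengths: Sequence[int],
        frag_chrom: np.ndarray,
        block_offsets: np.ndarray,
        block_starts: np.ndarray,
        block_ends: np.ndarray,
        names: list[str] | None = None,
    ) -> None:
        self.chrom_names = list(chrom_names)
        self.chrom_lengths = list(chrom_lengths)
        self.frag_chrom = np.asarray(frag_chrom, dtype=np.int32)
        self.block_offsets = np.asarray(block_offsets, dtype=np.int64)
        self.block_starts = np.asarray(block_starts, dtype=np.int64)
        self.block_ends = np.asarray(block_ends, dtype=np.int64)
        self.names = names
        if self.block_offsets[0] != 0 or self.block_offsets[-1] != len(self.block_starts):
            raise ValueError("inconsistent block offsets")

    def __len__(self) -> int:
        return len(self.frag_chrom)

    @classmethod
    def from_fragments(
        cls,
        fragments: Iterable[AlignedFragment],
        chrom_lengths: dict[str, int] | None = None,
    ) -> "FragmentSet":
        chrom_idx: dict[str, int] = {}
        names: list[str] = []
        fchrom: list[int] = []
        offs: list[int] = [0]
        bs: list[int] = []
        be: list[int] = []
        for f in fragments:
            ci = chrom_idx.setdefault(f.chrom, len(chrom_idx))
            names.append(f.name)
            fchrom.append(ci)
            for s, e in f.blocks:
                bs.append(s)
                be.append(e)
            offs.append(len(bs))
        cnames = list(chrom_idx)
        if chrom_lengths is None:
            # infer: max block end per chromosome plus margin
            lengths = [1000] * len(cnames)
            be_arr = np.array(be, dtype=np.int64) if be else np.zeros(0, dtype=np.int64)
            if len(be_arr):
                block_chrom = np.repeat(
                    np.array(fchrom, dtype=np.int64), np.diff(np.array(offs))
                )
                for i in range(len(cnames)):
                    mask = block_chrom == i
                    if mask.any():
                        lengths[i] = int(be_arr[mask].max()) + 1000
        else:
            lengths = [chrom_lengths.get(c, 0) for c in cnames]
        return cls(
            cnames,
            lengths,
            np.array(fchrom, dtype=np.int32),
            np.array(offs, dtype=np.int64),
            np.array(bs, dtype=np.int64),
            np.array(be, dtype=np.int64),
            names=names,
        )

    @classmethod
    def from_sam(cls, path) -> "FragmentSet":
        """Read primary alignments from SAM/BAM, merging mate pairs into fragments.

        Non-primary (secondary/supplementary) records are skipped; duplicates
        are retained.  Orphan mates count as single-end fragments.  Mates
        mapped to different chromosomes yield a fragment on a synthetic "*"
        chromosome (classified as no_feature downstream).
        """
        pending: dict[str, tuple[str, list[tuple[int, int]]]] = {}
        fragments: list[AlignedFragment] = []
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            chrom_lengths = dict(zip(sam.references, sam.lengths))
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                blocks = rec.get_blocks()
                if not blocks:
                    continue
                if rec.is_paired and not rec.mate_is_unmapped:
                    key = rec.query_name
                    if key in pending:
                        chrom0, blocks0 = pending.pop(key)
                        if chrom0 == rec.reference_name:
                            fragments.append(
                                AlignedFragment(
                                    key, chrom0, merge_blocks(blocks0 + list(blocks))
                                )
                            )
                        else:  # inter-chromosomal pair: never exon-contained
                            fragments.append(AlignedFragment(key, "*", ((0, 1),)))
                    else:
                        pending[key] = (rec.reference_name, list(blocks))
                else:
                    fragments.append(
                        AlignedFragment(
                            rec.query_name, rec.reference_name, merge_blocks(blocks)
                        )
                    )
        # orphaned pending mates: count as single-end fragments
        for name, (chrom, blocks) in pending.items():
            fragments.append(AlignedFragment(name, chrom, merge_blocks(blocks)))
        chrom_lengths["*"] = 1000
        return cls.from_fragments(fragments, chrom_lengths)

    def iter_fragments(self) -> Iterable[AlignedFragment]:
        for i in range(len(self)):
            lo, hi = self.block_offsets[i], self.block_offsets[i + 1]
            name = self.names[i] if self.names else f"frag{i:08d}"
            yield AlignedFragment(
                name,
                self.chrom_names[self.frag_chrom[i]],
                tuple(
                    (int(s), int(e))
                    for s, e in zip(self.block_starts[lo:hi], self.block_ends[lo:hi])
                ),
            )

    def subset(self, indices: np.ndarray) -> "FragmentSet":
        indices = np.asarray(indices, dtype=np.int64)
        nblocks = np.diff(self.block_offsets)[indices]
        new_offs = np.concatenate([[0], np.cumsum(nblocks)])
        block_idx = np.repeat(self.block_offsets[indices], nblocks) + (
            np.arange(new_offs[-1]) - np.repeat(new_offs[:-1], nblocks)
        )
        return FragmentSet(
            self.chrom_names,
            self.chrom_lengths,
            self.frag_chrom[indices],
            new_offs,
            self.block_starts[block_idx],
            self.block_ends[block_idx],
            names=[self.names[i] for i in indices] if self.names else None,
        )

    def to_sam(self, path, read_length: int | None = None) -> None:
        """Write fragments as single-end SAM records with spliced CIGARs.

        Each fragment becomes one forward-strand record whose CIGAR encodes
        its blocks as M segments separated by N skips; sequence and quality
        are omitted ('*') since no downstream step consumes them.
        """
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": int(l)}
                for c, l in zip(self.chrom_names, self.chrom_lengths)
                if c != "*"
            ],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, frag in enumerate(self.iter_fragments()):
                if frag.chrom == "*":
                    continue
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = frag.name
                rec.reference_name = frag.chrom
                rec.reference_start = frag.blocks[0][0]
                rec.mapping_quality = 50
                rec.flag = 0
                cigar = []
                prev_end = None
                for s, e in frag.blocks:
                    if prev_end is not None:
                        cigar.append((3, s - prev_end))  # N skip
                    cigar.append((0, e - s))  # M
                    prev_end = e
                rec.cigartuples = cigar
                out.write(rec)


class GeneIndex:
    """Segment-partition index over an annotation for fast strict classification.

    For every chromosome the union of each gene's exons is computed, all
    boundary coordinates are pooled, and the resulting segments are labelled
    with the set of genes covering them (most segments: zero or one gene).
    """

    def __init__(self, ann: Annotation) -> None:
        self.gene_ids = ann.gene_ids
        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for gene in ann:
            gi = gene_pos[gene.gene_id]
            for s, e in merge_blocks(
                (ex.start, ex.end) for tx in gene.transcripts for ex in tx.exons
            ):
                per_chrom.setdefault(gene.chrom, []).append((s, e, gi))
        # chrom -> (breaks, ngenes, gene1, setid, sets)
        self._chrom: dict[str, tuple] = {}
        for chrom, ivals in per_chrom.items():
            breaks = np.unique(
                np.concatenate([[s for s, _, _ in ivals], [e for _, e, _ in ivals]])
            )
            nseg = len(breaks) - 1
            events: list[tuple[int, int, int]] = []
            for s, e, gi in ivals:
                events.append((s, 0, gi))
                events.append((e, 1, gi))
            events.sort()
            ngenes = np.zeros(nseg, dtype=np.int32)
            gene1 = np.full(nseg, -1, dtype=np.int64)
            setid = np.full(nseg, -1, dtype=np.int64)
            sets: list[frozenset[int]] = []
            active: set[int] = set()
            ei = 0
            for si in range(nseg):
                pos = breaks[si]
                while ei < len(events) and events[ei][0] == pos:
                    _, kind, gi = events[ei]
                    (active.discard if kind else active.add)(gi)
                    ei += 1
                ngenes[si] = len(active)
                if len(active) == 1:
                    gene1[si] = next(iter(active))
                elif len(active) > 1:
                    sets.append(frozenset(active))
                    setid[si] = len(sets) - 1
            self._chrom[chrom] = (breaks, ngenes, gene1, setid, sets)

    def classify(self, frags: FragmentSet) -> np.ndarray:
        """Per-fragment gene index, or NO_FEATURE / AMBIGUOUS codes."""
        n = len(frags)
        result = np.full(n, NO_FEATURE, dtype=np.int64)
        nblocks = np.diff(frags.block_offsets)
        block_frag = np.repeat(np.arange(n), nblocks)
        for ci, chrom in enumerate(frags.chrom_names):
            entry = self._chrom.get(chrom)
            fmask = frags.frag_chrom == ci
            if not fmask.any():
                continue
            if entry is None:
                continue  # chromosome absent from annotation -> no_feature
            breaks, ngenes, gene1, setid, sets = entry
            nseg = len(breaks) - 1
            bmask = fmask[block_frag]
            bs = frags.block_starts[bmask]
            be = frags.block_ends[bmask]
            bfrag = block_frag[bmask]
            i0 = np.searchsorted(breaks, bs, side="right") - 1
            i1 = np.searchsorted(breaks, be - 1, side="right") - 1
            valid = (i0 >= 0) & (i1 >= 0) & (i0 < nseg) & (i1 < nseg) & (i0 <= i1)
            bad_frags = np.unique(bfrag[~valid])
            # expand each valid block into the segment range it spans
            i0v, i1v, fv = i0[valid], i1[valid], bfrag[valid]
            counts = i1v - i0v + 1
            tot = int(counts.sum())
            if tot:
                offs = np.concatenate([[0], np.cumsum(counts)])
                segs = np.repeat(i0v, counts) + (
                    np.arange(tot) - np.repeat(offs[:-1], counts)
                )
                seg_frag = np.repeat(fv, counts)
                seg_n = ngenes[segs]
                uncovered = np.unique(seg_frag[seg_n == 0])
                multi = np.unique(seg_frag[seg_n > 1])
                # common path: all touched segments are single-gene
                g = np.where(seg_n == 1, gene1[segs], -3)
                order = np.argsort(seg_frag, kind="stable")
                sf, gs = seg_frag[order], g[order]
                uniq, starts = np.unique(sf, return_index=True)
                gmin = np.minimum.reduceat(gs, starts)
                gmax = np.maximum.reduceat(gs, starts)
                ok = gmin == gmax
                result[uniq[ok]] = gmin[ok]
                result[uniq[~ok]] = NO_FEATURE
                # fragments touching multi-gene segments need set intersection
                slow = np.setdiff1d(multi, np.concatenate([uncovered, bad_frags]))
                for fi in slow:
                    lo, hi = frags.block_offsets[fi], frags.block_offsets[fi + 1]
                    inter: frozenset[int] | None = None
                    dead = False
                    for s, e in zip(frags.block_starts[lo:hi], frags.block_ends[lo:hi]):
                        j0 = int(np.searchsorted(breaks, s, side="right")) - 1
                        j1 = int(np.searchsorted(breaks, e - 1, side="right")) - 1
                        for j in range(j0, j1 + 1):
                            if ngenes[j] == 0:
                                dead = True
                                break
                            cur = (
                                frozenset([int(gene1[j])])
                                if ngenes[j] == 1
                                else sets[setid[j]]
                            )
                            inter = cur if inter is None else inter & cur
                            if not inter:
                                dead = True
                                break
                        if dead:
                            break
                    if dead or not inter:
                        result[fi] = NO_FEATURE
                    elif len(inter) == 1:
                        result[fi] = next(iter(inter))
                    else:
                        result[fi] = AMBIGUOUS
                result[uncovered] = NO_FEATURE
            result[bad_frags] = NO_FEATURE
        return result


@dataclass
class CountColumn:
    """Per-sample gene counts plus the htseq-style special tallies."""

    sample: str
    counts: pd.Series  # index: gene_id, values: int
    no_feature: int
    ambiguous: int
    total_fragments: int

    def __post_init__(self) -> None:
        assigned = int(self.counts.sum()) + self.no_feature + self.ambiguous
        if assigned > self.total_fragments:
            raise ValueError("counts exceed total fragments")


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with group labels."""

    counts: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label
    no_feature: pd.Series | None = None
    ambiguous: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if list(self.counts.columns) != list(self.groups.index):
            raise ValueError("sample order mismatch between counts and groups")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        if self.no_feature is not None:
            df.loc["__no_feature"] = self.no_feature
        if self.ambiguous is not None:
            df.loc["__ambiguous"] = self.ambiguous
        df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, groups: pd.Series) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        special = [r for r in ("__no_feature", "__ambiguous") if r in df.index]
        nf = df.loc["__no_feature"] if "__no_feature" in df.index else None
        amb = df.loc["__ambiguous"] if "__ambiguous" in df.index else None
        df = df.drop(index=special)
        return cls(df.astype(int), groups.loc[df.columns], nf, amb)


def count_sample(
    alignments,
    ann: Annotation,
    sample: str = "sample",
    index: GeneIndex | None = None,
) -> CountColumn:
    """Count fragments per gene under intersection-strict rules.

    ``alignments`` may be a SAM/BAM path, a :class:`FragmentSet`, or an
    iterable of :class:`AlignedFragment`.
    """
    if isinstance(alignments, FragmentSet):
        frags = alignments
    elif isinstance(alignments, (str,)) or hasattr(alignments, "__fspath__"):
        frags = FragmentSet.from_sam(alignments)
    else:
        frags = FragmentSet.from_fragments(alignments)
    idx = index if index is not None else GeneIndex(ann)
    codes = idx.classify(frags)
    counts = np.zeros(len(idx.gene_ids), dtype=np.int64)
    hit = codes >= 0
    if hit.any():
        np.add.at(counts, codes[hit], 1)
    return CountColumn(
        sample=sample,
        counts=pd.Series(counts, index=pd.Index(idx.gene_ids, name="gene_id")),
        no_feature=int((codes == NO_FEATURE).sum()),
        ambiguous=int((codes == AMBIGUOUS).sum()),
        total_fragments=len(frags),
    )


def build_matrix(columns: Sequence[CountColumn], sample_sheet: pd.DataFrame) -> CountMatrix:
    """Assemble per-sample columns into a CountMatrix, ordered per the sample sheet.

    ``sample_sheet`` needs columns ``sample`` and ``group``; every listed
    sample must appear exactly once among ``columns`` and all columns must
    share one gene universe.
    """
    if sample_sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample id in sample sheet")
    by_sample = {}
    for col in columns:
        if col.sample in by_sample:
            raise ValueError(f"duplicate column for sample {col.sample}")
        by_sample[col.sample] = col
    missing = set(sample_sheet["sample"]) - set(by_sample)
    if missing:
        raise ValueError(f"no counts for samples: {sorted(missing)}")
    ref_genes = list(by_sample[sample_sheet["sample"].iloc[0]].counts.index)
    data = {}
    nf, amb = {}, {}
    for s in sample_sheet["sample"]:
        col = by_sample[s]
        if list(col.counts.index) != ref_genes:
            raise ValueError(f"gene universe mismatch in sample {s}")
        data[s] = col.counts.values
        nf[s], amb[s] = col.no_feature, col.ambiguous
    counts = pd.DataFrame(data, index=pd.Index(ref_genes, name="gene_id"))
    groups = pd.Series(
        sample_sheet["group"].values, index=pd.Index(sample_sheet["sample"], name="sample")
    )
    return CountMatrix(counts, groups, pd.Series(nf), pd.Series(amb))


def downsample(alignments, n_fragments: int, seed: int):
    """Uniform fragment-level subsample without replacement, mates kept together.

    Accepts and returns a :class:`FragmentSet`, or filters a SAM file when
    given ``(in_path, out_path)`` via :func:`downsample_sam`.
    """
    if not isinstance(alignments, FragmentSet):
        alignments = FragmentSet.from_sam(alignments)
    total = len(alignments)
    if n_fragments > total:
        raise ValueError(f"requested {n_fragments} fragments, only {total} available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=n_fragments, replace=False))
    return alignments.subset(keep)


def downsample_sam(in_path, out_path, n_fragments: int, seed: int) -> None:
    """Downsample a SAM/BAM to ``n_fragments`` fragments, preserving records.

    Selection is by query name so both mates of a pair survive together;
    the same seed always selects the same fragment set.
    """
    names: list[str] = []
    seen: set[str] = set()
    with pysam.AlignmentFile(str(in_path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name not in seen:
                seen.add(rec.query_name)
                names.append(rec.query_name)
    if n_fragments > len(names):
        raise ValueError(f"requested {n_fragments} fragments, only {len(names)} available")
    rng = np.random.default_rng(seed)
    chosen = set(np.array(names, dtype=object)[
        np.sort(rng.choice(len(names), size=n_fragments, replace=False))
    ])
    with pysam.AlignmentFile(str(in_path), check_sq=False) as sam:
        with pysam.AlignmentFile(str(out_path), "w", template=sam) as out:
            for rec in sam:
                if rec.query_name in chosen:
                    out.write(rec)
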