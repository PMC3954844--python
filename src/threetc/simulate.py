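"""Synthetic degraded-RNA experiment generator.

Emulates polyA-selected RNA-seq from partially degraded transcripts so the
whole 3TC pipeline can be exercised offline with a known truth table.

Degradation model
-----------------
Random in-vivo/in-vitro breakage is memoryless along the molecule, and polyA
selection recovers only the fragment that carries the 3' end.  The retained
part of a transcript of length ``L`` is therefore 3'-anchored with length

    D = min(L, Exponential(rate = lambda))

where ``lambda`` (per nucleotide) is an abstract degradation level: 0 means
intact (D = L), larger values mean more degraded.  Sequenced fragments start
uniformly within the retained segment, which produces the characteristic 3'
coverage bias of degraded polyA libraries.

Because library preparation samples fragments in proportion to the retained
molecule mass, the expected fragment yield of a gene is proportional to
``expression x E[min(L, Exp(lambda))]`` and the per-sample composition is
renormalized to the library size; a sequenced fragment's parent molecule
accordingly has a *length-biased* retained length.  Long transcripts thus
lose a larger share of their fragments under degradation than short ones —
the mechanism that creates spurious, length-correlated differential
expression between samples of unequal quality — while the expected yield
inside a 3'-terminal window of size N scales with E[min(N, D)], which is
equal across genes once N is below typical retained lengths: exactly the
equalization 3TC exploits.

Counts are negative-binomial across replicates (dispersion ``alpha``), a
configurable fraction of genes carries a planted fold change in group B, and
all randomness is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, GeneModel, Interval, TranscriptModel, write_gtf
from .counting import FragmentSet

__all__ = ["SimConfig", "SimBundle", "simulate_annotation", "simulate_reads",
           "simulate_experiment", "expected_retained_length",
           "sample_retained_lengths"]

_MIN_EXON = 30


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a two-group degraded-vs-intact experiment.

    Defaults describe a bulk comparison in the spirit of the RIN-graded
    libraries the method targets: ~2000 protein-coding genes, three
    replicates per group, one million fragments per library of 100 nt
    reads, lognormal baseline expression, NB dispersion 0.05, 10% of genes
    truly differential at 4-fold, and group B degraded at lambda = 5e-4
    (mean break spacing 2 kb) versus an intact group A.
    """

    n_genes: int = 2000
    isoforms_per_gene: tuple[int, int] = (1, 3)
    length_range: tuple[int, int] = (200, 15000)
    exon_count_range: tuple[int, int] = (1, 10)
    intron_range: tuple[int, int] = (60, 2000)
    group_lambda: tuple[float, float] = (0.0, 5e-4)
    n_replicates: tuple[int, int] = (3, 3)
    library_size: int = 1_000_000
    read_length: int = 100
    paired: bool = False
    fragment_length: int = 250
    expr_meanlog: float = 1.5
    expr_sdlog: float = 1.0
    de_fraction: float = 0.1
    fold_change: float = 4.0
    dispersion: float = 0.05
    groups: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must be in [0, 1]")
        if any(l < 0 for l in self.group_lambda) or self.dispersion < 0:
            raise ValueError("rates must be non-negative")
        if self.library_size < 0 or self.n_genes <= 0:
            raise ValueError("sizes must be positive")


def expected_retained_length(length: float, lam: float) -> float:
    """Closed form E[min(L, Exp(lambda))] = (1 - exp(-lambda*L)) / lambda."""
    if lam == 0:
        return float(length)
    return (1.0 - math.exp(-lam * length)) / lam


def sample_retained_lengths(
    lengths, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw 3'-anchored retained-segment lengths D = min(L, Exp(lambda))."""
    L = np.asarray(lengths, dtype=np.int64)
    if lam == 0:
        return L.copy()
    D = np.minimum(L, np.ceil(rng.exponential(1.0 / lam, size=L.shape)).astype(np.int64))
    return np.maximum(D, 1)


def _sample_retained_length_biased(
    L: np.ndarray, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Retained length of the molecule a *sequenced fragment* came from.

    Library preparation samples fragments proportionally to retained
    molecule mass, so the parent molecule's D is length-biased:
    P_frag(D) ∝ D·P(D).  Sampled by rejection (accept D with probability
    D/L), which keeps the per-molecule law exactly min(L, Exp(lambda)).
    """
    if lam == 0:
        return L.copy()
    D = np.empty(L.shape, dtype=np.int64)
    todo = np.arange(L.size)
    while todo.size:
        cand = sample_retained_lengths(L[todo], lam, rng)
        acc = rng.random(todo.size) * L[todo] < cand
        D[todo[acc]] = cand[acc]
        todo = todo[~acc]
    return D


# ---------------------------------------------------------------------------
# annotation generation


def _split_lengths(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into ``parts`` pieces of at least _MIN_EXON each."""
    parts = max(1, min(parts, total // _MIN_EXON))
    props = rng.dirichlet(np.ones(parts))
    lens = np.maximum(_MIN_EXON, np.floor(props * total).astype(int))
    # repair the sum on the last piece, keeping it >= _MIN_EXON
    lens[-1] = total - lens[:-1].sum()
    while lens[-1] < _MIN_EXON and parts > 1:
        lens = lens[:-1]
        parts -= 1
        lens[-1] = total - lens[:-1].sum()
    return lens


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate a toy chromosome of non-overlapping multi-isoform genes.

    Returns ``(annotation, truth, abundance)`` where ``truth`` is a
    DataFrame (gene_id, major_transcript, length, baseline, fold_change,
    is_de) and ``abundance`` maps transcript_id -> simulated FPKM-like
    abundance with the designated major isoform the per-gene argmax.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    chrom = "chrS"
    cursor = 1000
    genes: list[GeneModel] = []
    truth_rows = []
    abundance: dict[str, float] = {}
    is_de = rng.random(cfg.n_genes) < cfg.de_fraction
    baselines = rng.lognormal(cfg.expr_meanlog, cfg.expr_sdlog, cfg.n_genes)
    directions = rng.random(cfg.n_genes) < 0.5
    lmin, lmax = cfg.length_range
    for gi in range(cfg.n_genes):
        gene_id = f"G{gi:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(np.exp(rng.uniform(np.log(lmin), np.log(lmax))))
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = _split_lengths(length, n_exons, rng)
        introns = rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1,
                               size=max(0, len(exon_lens) - 1))
        # genomic layout, ascending
        starts, pos = [], cursor
        for i, el in enumerate(exon_lens):
            starts.append(pos)
            pos += int(el)
            if i < len(introns):
                pos += int(introns[i])
        exons = tuple(
            Interval(chrom, s, s + int(el), strand)
            for s, el in zip(starts, exon_lens)
        )
        major_id = f"T{gi:05d}.1"
        major = TranscriptModel(major_id, gene_id, "protein_coding", strand, exons)
        txs = [major]
        base = float(baselines[gi])
        abundance[major_id] = base
        n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
        for j in range(2, n_iso + 1):
            alt = _alternative_isoform(major, f"T{gi:05d}.{j}", rng)
            if alt is not None:
                txs.append(alt)
                abundance[alt.transcript_id] = base * float(rng.uniform(0.05, 0.6))
        genes.append(GeneModel(gene_id, "protein_coding", tuple(txs)))
        fc = 1.0
        if is_de[gi]:
            fc = cfg.fold_change if directions[gi] else 1.0 / cfg.fold_change
        truth_rows.append(
            dict(gene_id=gene_id, major_transcript=major_id,
                 length=major.transcript_length, baseline=base,
                 fold_change=fc, is_de=bool(is_de[gi]))
        )
        cursor = pos + int(rng.integers(500, 2000))
    ann = Annotation(genes)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return ann, truth, abundance


def _alternative_isoform(major: TranscriptModel, tid: str,
                         rng: np.random.Generator) -> TranscriptModel | None:
    """A minor isoform: usually 5'-shortened (same 3' end), sometimes with
    its 3'-terminal exon removed (distinct 3' end)."""
    ex53 = list(major.exons_5to3())
    if len(ex53) > 1 and rng.random() < 0.3:
        kept = ex53[:-1]  # drop 3'-most exon
    elif len(ex53) > 1:
        drop = int(rng.integers(1, len(ex53)))
        kept = ex53[drop:]
    else:
        e = ex53[0]
        frac = rng.uniform(0.3, 0.9)
        take = max(_MIN_EXON, int(len(e) * frac))
        if take >= len(e):
            return None
        if major.strand == "+":
            kept = [Interval(e.chrom, e.end - take, e.end, "+")]
        else:
            kept = [Interval(e.chrom, e.start, e.start + take, "-")]
    return TranscriptModel(tid, major.gene_id, major.biotype, major.strand, tuple(kept))


# ---------------------------------------------------------------------------
# read generation


class _TranscriptMaps:
    """Flat arrays mapping transcript coordinates to the genome for a set of
    (major) transcripts, enabling vectorized fragment placement."""

    def __init__(self, transcripts: list[TranscriptModel]) -> None:
        self.lengths = np.array([t.transcript_length for t in transcripts], dtype=np.int64)
        self.strands = np.array([1 if t.strand == "+" else -1 for t in transcripts])
        gene_base = np.concatenate([[0], np.cumsum(self.lengths)])
        self.gene_base = gene_base
        cum, gs, ge = [], [], []
        for ti, t in enumerate(transcripts):
            off = 0
            for e in t.exons_5to3():
                cum.append(gene_base[ti] + off)
                gs.append(e.start)
                ge.append(e.end)
                off += len(e)
        self.ex_cum = np.array(cum, dtype=np.int64)  # global tx coord of exon 5' base
        self.ex_gs = np.array(gs, dtype=np.int64)
        self.ex_ge = np.array(ge, dtype=np.int64)

    def map_interval(self, tx_idx: np.ndarray, t0: np.ndarray, t1: np.ndarray):
        """Map transcript intervals [t0, t1) to genomic blocks.

        Returns ``(starts, ends, offsets)`` in CSR form per input interval,
        blocks sorted by ascending genomic start.
        """
        g0 = self.gene_base[tx_idx] + t0
        g1end = self.gene_base[tx_idx] + t1 - 1
        e0 = np.searchsorted(self.ex_cum, g0, side="right") - 1
        e1 = np.searchsorted(self.ex_cum, g1end, side="right") - 1
        span = e1 - e0 + 1
        strand = self.strands[tx_idx]
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        nblocks = span.copy()
        single = span == 1
        o = g0 - self.ex_cum[e0]
        ln = t1 - t0
        s_plus = self.ex_gs[e0] + o
        s_minus = self.ex_ge[e0] - o - ln
        bstart = np.where(strand > 0, s_plus, s_minus)
        # assemble: vector path for single-exon fragments, loop for spliced
        out_starts = np.empty(int(span.sum()), dtype=np.int64)
        out_ends = np.empty_like(out_starts)
        offs = np.concatenate([[0], np.cumsum(span)])
        out_starts[offs[:-1][single]] = bstart[single]
        out_ends[offs[:-1][single]] = bstart[single] + ln[single]
        for i in np.nonzero(~single)[0]:
            blocks = []
            remaining = int(ln[i])
            tpos = int(g0[i])
            for e in range(int(e0[i]), int(e1[i]) + 1):
                exon_len = int(self.ex_ge[e] - self.ex_gs[e])
                off_in = tpos - int(self.ex_cum[e])
                take = min(remaining, exon_len - off_in)
                if strand[i] > 0:
                    blocks.append((int(self.ex_gs[e]) + off_in,
                                   int(self.ex_gs[e]) + off_in + take))
                else:
                    blocks.append((int(self.ex_ge[e]) - off_in - take,
                                   int(self.ex_ge[e]) - off_in))
                tpos += take
                remaining -= take
            blocks.sort()
            lo = offs[i]
            for k, (bs, be) in enumerate(blocks):
                out_starts[lo + k] = bs
                out_ends[lo + k] = be
        return out_starts, out_ends, offs


def simulate_reads(
    cfg: SimConfig,
    ann: Annotation,
    truth: pd.DataFrame,
    group: str,
    sample_seed: int,
    sample: str = "sample",
) -> FragmentSet:
    """Generate one library: aligned fragments from degraded molecules.

    ``group`` must be one of ``cfg.groups``; the planted fold change applies
    to the second group.  Fragment yield per gene is NB-distributed around
    the library-size-normalized expected value (expression x retained mass).
    """
    rng = np.random.default_rng(sample_seed)
    gi = list(cfg.groups).index(group)
    lam = cfg.group_lambda[gi]
    majors = [
        next(t for t in ann[g].transcripts if t.transcript_id == truth.loc[g, "major_transcript"])
        for g in truth.index
    ]
    maps = _TranscriptMaps(majors)
    L = maps.lengths.astype(float)
    w = truth["baseline"].values.astype(float)
    if gi == 1:
        w = w * truth["fold_change"].values
    if lam > 0:
        retained_mass = (1.0 - np.exp(-lam * L)) / lam
    else:
        retained_mass = L
    expected = cfg.library_size * (w * retained_mass) / np.sum(w * retained_mass)
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        n_mol = rng.negative_binomial(r, r / (r + np.maximum(expected, 1e-12)))
    else:
        n_mol = rng.poisson(expected)
    M = int(n_mol.sum())
    gidx = np.repeat(np.arange(len(majors)), n_mol)
    Lm = maps.lengths[gidx]
    D = _sample_retained_length_biased(Lm, lam, rng)
    flen = np.minimum(D, cfg.read_length if not cfg.paired else cfg.fragment_length)
    # fragment start, uniform over the retained 3'-anchored segment
    slack = D - flen
    s = (Lm - D) + (rng.random(M) * (slack + 1)).astype(np.int64)
    if cfg.paired:
        rl = np.minimum(cfg.read_length, flen)
        st1, en1, of1 = maps.map_interval(gidx, s, s + rl)
        st2, en2, of2 = maps.map_interval(gidx, s + flen - rl, s + flen)
        return _merge_paired(maps, st1, en1, of1, st2, en2, of2, ann)
    starts, ends, offs = maps.map_interval(gidx, s, s + flen)
    genome_len = max(
        (e.end for g in ann for t in g.transcripts for e in t.exons), default=0
    ) + 1000
    return FragmentSet(
        ["chrS"], [genome_len],
        np.zeros(M, dtype=np.int32), offs, starts, ends,
        names=None,
    )


def _merge_paired(maps, st1, en1, of1, st2, en2, of2, ann) -> FragmentSet:
    from .counting import merge_blocks

    n = len(of1) - 1
    fs: list[int] = []
    fe: list[int] = []
    offs = [0]
    for i in range(n):
        blocks = [(int(s), int(e)) for s, e in zip(st1[of1[i]:of1[i + 1]], en1[of1[i]:of1[i + 1]])]
        blocks += [(int(s), int(e)) for s, e in zip(st2[of2[i]:of2[i + 1]], en2[of2[i]:of2[i + 1]])]
        for s, e in merge_blocks(blocks):
            fs.append(s)
            fe.append(e)
        offs.append(len(fs))
    genome_len = max(
        (e.end for g in ann for t in g.transcripts for e in t.exons), default=0
    ) + 1000
    return FragmentSet(
        ["chrS"], [genome_len],
        np.zeros(n, dtype=np.int32),
        np.array(offs, dtype=np.int64),
        np.array(fs, dtype=np.int64),
        np.array(fe, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# full experiment


@dataclass
class SimBundle:
    """Everything the end-to-end pipeline needs, plus the ground truth."""

    config: SimConfig
    annotation: Annotation
    truth: pd.DataFrame
    abundance: dict[str, float]
    sample_sheet: pd.DataFrame  # columns: sample, group
    fragments: dict[str, FragmentSet]

    def write(self, outdir) -> dict[str, Path]:
        """Write GTF, per-sample SAM, abundance TSV, sample sheet and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"gtf": outdir / "annotation.gtf"}
        write_gtf(self.annotation, paths["gtf"])
        ab = pd.DataFrame(
            {"transcript_id": list(self.abundance), "abundance": list(self.abundance.values())}
        )
        paths["abundance"] = outdir / "abundance.tsv"
        ab.to_csv(paths["abundance"], sep="\t", index=False)
        sheet = self.sample_sheet.copy()
        sam_paths = []
        for s in sheet["sample"]:
            p = outdir / f"{s}.sam"
            self.fragments[s].to_sam(p)
            sam_paths.append(str(p))
        sheet["path"] = sam_paths
        paths["sample_sheet"] = outdir / "samples.tsv"
        sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t")
        return paths


def simulate_experiment(cfg: SimConfig) -> SimBundle:
    """Simulate a complete two-group experiment, reproducible from cfg.seed."""
    ss = np.random.SeedSequence(cfg.seed)
    ann_seed, *rest = ss.spawn(1 + sum(cfg.n_replicates))
    ann, truth, abundance = simulate_annotation(cfg, np.random.default_rng(ann_seed))
    rows = []
    fragments = {}
    k = 0
    for gi, group in enumerate(cfg.groups):
        for rep in range(cfg.n_replicates[gi]):
            name = f"{group}{rep + 1}"
            child = rest[k]
            k += 1
            sample_seed = int(child.generate_state(1)[0] % (2**31))
            fragments[name] = simulate_reads(cfg, ann, truth, group, sample_seed, name)
            rows.append(dict(sample=name, group=group))
    sheet = pd.DataFrame(rows)
    return SimBundle(cfg, ann, truth, abundance, sheet, fragments)
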