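"""Intersection-strict counting, matrix assembly and downsampling."""

import numpy as np
import pandas as pd
import pysam
import pytest

from threetc.annotation import Annotation, GeneModel
from threetc.counting import (
    AlignedFragment,
    CountMatrix,
    FragmentSet,
    GeneIndex,
    build_matrix,
    count_sample,
    downsample,
    downsample_sam,
)
from threetc.annotation import restrict_threeprime

from conftest import make_gene, random_transcript, strict_count_oracle


def frag(name, blocks, chrom="chr1"):
    return AlignedFragment(name, chrom, tuple(blocks))


@pytest.fixture
def two_gene_ann():
    return Annotation([
        make_gene("g1", "+", {"t1": [(100, 200), (300, 400)]}),
        make_gene("g2", "-", {"t2": [(1000, 1200)]}),
    ])


class TestStrictClassification:
    def test_read_inside_single_exon_counts_for_that_gene(self, two_gene_ann):
        col = count_sample([frag("r1", [(120, 170)])], two_gene_ann)
        assert col.counts["g1"] == 1 and col.no_feature == 0

    def test_read_running_into_intron_is_no_feature(self, two_gene_ann):
        col = count_sample([frag("r1", [(180, 210)])], two_gene_ann)
        assert col.counts.sum() == 0 and col.no_feature == 1

    def test_read_in_two_overlapping_genes_is_ambiguous(self):
        ann = Annotation([
            make_gene("g1", "+", {"t1": [(0, 500)]}),
            make_gene("g2", "+", {"t2": [(100, 600)]}),
        ])
        col = count_sample([frag("r1", [(200, 300)])], ann)
        assert col.ambiguous == 1 and col.counts.sum() == 0

    def test_read_in_overlap_but_exiting_one_gene_counts_unique_cover(self):
        ann = Annotation([
            make_gene("g1", "+", {"t1": [(0, 500)]}),
            make_gene("g2", "+", {"t2": [(100, 300)]}),
        ])
        col = count_sample([frag("r1", [(250, 400)])], ann)  # leaves g2 at 300
        assert col.counts["g1"] == 1 and col.ambiguous == 0

    def test_spliced_read_matching_exon_chain(self, two_gene_ann):
        col = count_sample([frag("r1", [(150, 200), (300, 350)])], two_gene_ann)
        assert col.counts["g1"] == 1

    def test_unknown_chromosome_is_no_feature(self, two_gene_ann):
        col = count_sample([frag("r1", [(0, 50)], chrom="chrZ")], two_gene_ann)
        assert col.no_feature == 1

    def test_fragment_tallies_bound_by_total(self, two_gene_ann):
        frags = [frag(f"r{i}", [(120, 160)]) for i in range(5)]
        col = count_sample(frags, two_gene_ann)
        assert col.counts.sum() + col.no_feature + col.ambiguous == col.total_fragments

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        for case in range(60):
            genes, cursor = [], 0
            for gi in range(int(rng.integers(1, 8))):
                tx = random_transcript(rng, tid=f"t{gi}", gid=f"g{gi}",
                                       lo=cursor, hi=cursor + 4000)
                genes.append(GeneModel(f"g{gi}", "protein_coding", (tx,)))
                # sometimes overlap the next gene with this one
                cursor = tx.exons[-1].end - (
                    int(rng.integers(0, 500)) if rng.random() < 0.4 else -200
                )
                cursor = max(cursor, 0)
            ann = Annotation(genes)
            span = max(e.end for g in ann for t in g.transcripts for e in t.exons)
            frags = []
            for ri in range(int(rng.integers(5, 60))):
                nb = int(rng.integers(1, 4))
                pos = int(rng.integers(0, span))
                blocks = []
                for _ in range(nb):
                    ln = int(rng.integers(1, 120))
                    blocks.append((pos, pos + ln))
                    pos += ln + int(rng.integers(1, 400))
                frags.append(frag(f"r{ri}", blocks))
            col = count_sample(frags, ann)
            exp_counts, exp_nf, exp_amb = strict_count_oracle(frags, ann)
            assert col.counts.to_dict() == exp_counts, f"case {case}"
            assert (col.no_feature, col.ambiguous) == (exp_nf, exp_amb), f"case {case}"

    def test_invariant_to_fragment_order(self, two_gene_ann, rng):
        frags = [frag(f"r{i}", [(int(s), int(s) + 30)])
                 for i, s in enumerate(rng.integers(0, 1300, size=80))]
        a = count_sample(frags, two_gene_ann)
        b = count_sample(frags[::-1], two_gene_ann)
        assert a.counts.equals(b.counts)
        assert (a.no_feature, a.ambiguous) == (b.no_feature, b.ambiguous)

    def test_counts_monotone_in_restriction_length(self, rng, two_gene_ann):
        frags = [frag(f"r{i}", [(int(s), int(s) + 40)])
                 for i, s in enumerate(rng.integers(0, 1300, size=200))]
        c1 = count_sample(frags, restrict_threeprime(two_gene_ann, 80))
        c2 = count_sample(frags, restrict_threeprime(two_gene_ann, 160))
        assert (c1.counts <= c2.counts).all()


class TestSamInput:
    def write_sam(self, path, records):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in records:
                out.write(rec)

    def rec(self, header, name, start, cigar, flag=0, mate_start=None):
        r = pysam.AlignedSegment(header)
        r.query_name = name
        r.reference_id = 0
        r.reference_start = start
        r.cigarstring = cigar
        r.flag = flag
        r.mapping_quality = 50
        if mate_start is not None:
            r.next_reference_id = 0
            r.next_reference_start = mate_start
        return r

    def test_proper_pair_counted_once(self, tmp_path, two_gene_ann):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
        )
        r1 = self.rec(header, "p1", 110, "40M", flag=0x1 | 0x2 | 0x40, mate_start=150)
        r2 = self.rec(header, "p1", 150, "40M", flag=0x1 | 0x2 | 0x80, mate_start=110)
        sam = tmp_path / "pair.sam"
        self.write_sam(sam, [r1, r2])
        col = count_sample(str(sam), two_gene_ann)
        assert col.total_fragments == 1
        assert col.counts["g1"] == 1

    def test_secondary_and_supplementary_skipped(self, tmp_path, two_gene_ann):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
        )
        recs = [
            self.rec(header, "r1", 120, "30M"),
            self.rec(header, "r1", 1000, "30M", flag=0x100),
            self.rec(header, "r2", 1050, "30M", flag=0x800),
        ]
        sam = tmp_path / "sec.sam"
        self.write_sam(sam, recs)
        col = count_sample(str(sam), two_gene_ann)
        assert col.total_fragments == 1 and col.counts["g1"] == 1

    def test_spliced_cigar_blocks(self, tmp_path, two_gene_ann):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
        )
        sam = tmp_path / "spl.sam"
        self.write_sam(sam, [self.rec(header, "r1", 150, "50M100N50M")])
        col = count_sample(str(sam), two_gene_ann)
        assert col.counts["g1"] == 1

    def test_fragmentset_sam_round_trip_preserves_counts(self, tmp_path, two_gene_ann):
        frags = [frag("a", [(120, 160)]), frag("b", [(150, 200), (300, 360)]),
                 frag("c", [(1100, 1150)])]
        fs = FragmentSet.from_fragments(frags, {"chr1": 100000})
        sam = tmp_path / "rt.sam"
        fs.to_sam(sam)
        direct = count_sample(fs, two_gene_ann)
        loaded = count_sample(str(sam), two_gene_ann)
        assert direct.counts.equals(loaded.counts)


class TestBuildMatrix:
    def cols(self, two_gene_ann):
        f1 = [frag("a", [(120, 150)])]
        f2 = [frag("b", [(1020, 1060)]), frag("c", [(120, 150)])]
        return [
            count_sample(f1, two_gene_ann, sample="s1"),
            count_sample(f2, two_gene_ann, sample="s2"),
        ]

    def sheet(self):
        return pd.DataFrame({"sample": ["s1", "s2"], "group": ["A", "B"]})

    def test_matrix_shape_and_order(self, two_gene_ann):
        m = build_matrix(self.cols(two_gene_ann), self.sheet())
        assert m.counts.shape == (2, 2)
        assert m.samples == ["s1", "s2"]
        assert m.counts.loc["g2", "s2"] == 1

    def test_duplicate_sample_rejected(self, two_gene_ann):
        sheet = pd.DataFrame({"sample": ["s1", "s1"], "group": ["A", "B"]})
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(self.cols(two_gene_ann), sheet)

    def test_missing_gene_universe_mismatch_rejected(self, two_gene_ann):
        cols = self.cols(two_gene_ann)
        cols[1].counts = cols[1].counts.drop("g2")
        with pytest.raises(ValueError, match="mismatch"):
            build_matrix(cols, self.sheet())

    def test_tsv_round_trip(self, two_gene_ann, tmp_path):
        m = build_matrix(self.cols(two_gene_ann), self.sheet())
        p = tmp_path / "counts.tsv"
        m.to_tsv(p)
        text = p.read_text()
        assert "__no_feature" in text and "__ambiguous" in text
        m2 = CountMatrix.from_tsv(p, m.groups)
        assert m2.counts.equals(m.counts)


class TestDownsample:
    def fragset(self, n=50):
        return FragmentSet.from_fragments(
            [frag(f"r{i}", [(10 * i, 10 * i + 8)]) for i in range(n)],
            {"chr1": 10000},
        )

    def test_full_size_is_identity(self):
        fs = self.fragset()
        out = downsample(fs, len(fs), seed=3)
        assert np.array_equal(out.block_starts, fs.block_starts)

    def test_zero_gives_empty(self):
        out = downsample(self.fragset(), 0, seed=3)
        assert len(out) == 0

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(self.fragset(), 51, seed=3)

    def test_same_seed_same_selection(self):
        fs = self.fragset()
        a = downsample(fs, 20, seed=11)
        b = downsample(fs, 20, seed=11)
        assert np.array_equal(a.block_starts, b.block_starts)
        c = downsample(fs, 20, seed=12)
        assert not np.array_equal(a.block_starts, c.block_starts)

    def test_sam_downsample_keeps_mates_together(self, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
        )
        recs = []
        for i in range(30):
            for flag, start in ((0x1 | 0x40, 100 * i), (0x1 | 0x80, 100 * i + 50)):
                r = pysam.AlignedSegment(header)
                r.query_name = f"p{i}"
                r.reference_id = 0
                r.reference_start = start
                r.cigarstring = "30M"
                r.flag = flag
                r.next_reference_id = 0
                r.next_reference_start = 0
                recs.append(r)
        src = tmp_path / "in.sam"
        with pysam.AlignmentFile(str(src), "w", header=header) as out:
            for r in recs:
                out.write(r)
        dst = tmp_path / "out.sam"
        downsample_sam(src, dst, 10, seed=5)
        with pysam.AlignmentFile(str(dst)) as sam:
            names = [r.query_name for r in sam]
        assert len(names) == 20  # both mates of each chosen fragment
        assert all(names.count(n) == 2 for n in set(names))
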