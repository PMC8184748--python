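"""Fragment parsing, demultiplexing, segment coverage, downsampling, store."""

import numpy as np
import pytest

from pliertlc.genome import ChromosomeSet, Viewpoint, digest_reference
from pliertlc.tlc_io import (
    ReadSet,
    ViewpointDataset,
    demultiplex,
    downsample,
    load_store,
    parse_alignments,
    save_store,
    segment_coverage,
    write_sam,
)

CHROMS = ChromosomeSet(["chr1", "chr2"], [10_000, 10_000])


def make_readset(frags, n_reads=None, chroms=CHROMS):
    """frags: list of (read, chrom_code, start, end, mq, strand)."""
    a = np.asarray(frags, dtype=np.int64)
    return ReadSet(
        chroms,
        a[:, 0],
        a[:, 1].astype(np.int32),
        a[:, 2],
        a[:, 3],
        a[:, 4].astype(np.int16),
        a[:, 5].astype(np.int8),
        n_reads=n_reads if n_reads is not None else int(a[:, 0].max()) + 1,
    )


class TestSamParsing:
    def _write_sam(self, path, records):
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:chr2\tLN:10000\n")
            for r in records:
                fh.write(r + "\n")

    def test_mq_zero_excluded_and_split_parts_pooled(self, tmp_path):
        p = tmp_path / "t.sam"
        self._write_sam(
            p,
            [
                "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t*\t*",
                "r1\t2048\tchr2\t201\t60\t40M\t*\t0\t0\t*\t*",
                "r1\t2048\tchr2\t501\t0\t40M\t*\t0\t0\t*\t*",  # MQ 0 -> dropped
                "r2\t16\tchr1\t301\t30\t30M\t*\t0\t0\t*\t*",
                "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*",  # unmapped
            ],
        )
        rs = parse_alignments(p)
        assert rs.n_reads == 2
        r1 = rs.read_names.index("r1")
        assert (rs.read_index == r1).sum() == 2  # three records, one below MQ cut

    def test_three_split_parts_in_read_order(self, tmp_path):
        p = tmp_path / "t.sam"
        self._write_sam(
            p,
            [
                "r1\t0\tchr1\t1\t60\t10M\t*\t0\t0\t*\t*",
                "r1\t2048\tchr2\t101\t60\t10M\t*\t0\t0\t*\t*",
                "r1\t2048\tchr1\t201\t60\t10M\t*\t0\t0\t*\t*",
            ],
        )
        rs = parse_alignments(p)
        assert rs.n_fragments == 3
        assert list(rs.start) == [0, 100, 200]

    def test_empty_stream(self, tmp_path):
        p = tmp_path / "t.sam"
        self._write_sam(p, [])
        rs = parse_alignments(p)
        assert rs.n_reads == 0 and rs.n_fragments == 0

    def test_round_trip_via_sam(self, rearranged_library):
        _, rs, _ = rearranged_library
        # written-and-reparsed alignments give the same mapped fragments
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "x.sam")
            write_sam(rs, p)
            back = parse_alignments(p, chroms=rs.chroms)
        mapped = rs.mapped(0)
        assert back.n_fragments == mapped.n_fragments
        key_a = np.sort(back.chrom_code * 10**9 + back.start)
        key_b = np.sort(mapped.chrom_code * 10**9 + mapped.start)
        assert np.array_equal(key_a, key_b)


VPS = [
    Viewpoint(name="MYC", chrom="chr1", start=1_000, end=2_000),
    Viewpoint(name="BCL2", chrom="chr2", start=1_000, end=2_000),
]


class TestDemultiplex:
    def test_largest_summed_overlap_wins(self):
        rs = make_readset(
            [
                (0, 0, 1_900, 1_980, 60, 1),  # 80 bp on MYC
                (0, 1, 1_980, 2_500, 60, 1),  # 20 bp on BCL2
            ]
        )
        per, counters = demultiplex(rs, VPS)
        assert per["MYC"].n_reads == 1 and per["BCL2"].n_reads == 0

    def test_no_overlap_discarded(self):
        rs = make_readset([(0, 0, 5_000, 5_100, 60, 1)])
        per, counters = demultiplex(rs, VPS)
        assert counters["discarded"] == 1
        assert all(v.n_reads == 0 for v in per.values())

    def test_tie_goes_to_panel_order_and_counted(self):
        rs = make_readset(
            [
                (0, 0, 1_000, 1_100, 60, 1),  # 100 bp on MYC
                (0, 1, 1_000, 1_100, 60, 1),  # 100 bp on BCL2
            ]
        )
        per, counters = demultiplex(rs, VPS)
        assert per["MYC"].n_reads == 1
        assert counters["ties"] == 1

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        frags = []
        for r in range(200):
            for _ in range(rng.integers(1, 4)):
                c = int(rng.integers(0, 2))
                s = int(rng.integers(0, 9_000))
                frags.append((r, c, s, s + 100, 60, 1))
        rs = make_readset(frags, n_reads=200)
        per, counters = demultiplex(rs, VPS)
        assert sum(v.n_reads for v in per.values()) + counters["discarded"] == 200


class TestSegmentCoverage:
    SEQS = {"chr1": "A" * 10_000, "chr2": "A" * 10_000}

    def _segs(self):
        # plant motifs every 1000 bp
        s = ("A" * 996 + "CATG") * 10
        return digest_reference({"chr1": s, "chr2": s}, "CATG")

    def test_one_read_counts_once_per_segment(self):
        segs = self._segs()
        rs = make_readset(
            [
                (0, 0, 100, 200, 60, 1),
                (0, 0, 300, 400, 60, 1),  # same segment, same read
            ]
        )
        cov = segment_coverage(rs, segs)
        assert cov.support[segs.locate("chr1", 150)] == 1

    def test_two_reads_count_twice(self):
        segs = self._segs()
        rs = make_readset(
            [(0, 0, 100, 200, 60, 1), (1, 0, 300, 400, 60, 1)], n_reads=2
        )
        cov = segment_coverage(rs, segs)
        assert cov.support[segs.locate("chr1", 150)] == 2

    def test_straddling_fragment_covers_both_segments(self):
        segs = self._segs()
        rs = make_readset([(0, 0, 950, 1_050, 60, 1)])
        cov = segment_coverage(rs, segs)
        assert cov.support[segs.locate("chr1", 950)] == 1
        assert cov.support[segs.locate("chr1", 1_050)] == 1

    def test_empty_readset_uncovered(self):
        segs = self._segs()
        rs = make_readset([(0, 0, 1, 2, 60, 1)], n_reads=1).select_reads(np.array([], dtype=int))
        cov = segment_coverage(rs, segs)
        assert cov.support.sum() == 0

    def test_order_invariance_and_duplication_dedup(self):
        segs = self._segs()
        frags = [
            (0, 0, 100, 250, 60, 1),
            (0, 1, 5_000, 5_100, 60, 1),
            (1, 0, 2_100, 2_300, 60, -1),
        ]
        a = segment_coverage(make_readset(frags, n_reads=2), segs)
        b = segment_coverage(make_readset(frags[::-1], n_reads=2), segs)
        c = segment_coverage(make_readset(frags + frags, n_reads=2), segs)
        assert np.array_equal(a.support, b.support)
        assert np.array_equal(a.support, c.support)

    def test_out_of_bounds_fragment_rejected(self):
        segs = self._segs()
        rs = make_readset([(0, 0, 9_990, 10_050, 60, 1)])
        with pytest.raises(ValueError):
            segment_coverage(rs, segs)


class TestDownsample:
    def _rs(self, n=1_000):
        frags = [(r, 0, 100 * (r % 50), 100 * (r % 50) + 50, 60, 1) for r in range(n)]
        return make_readset(frags, n_reads=n)

    def test_identity_when_n_large(self):
        rs = self._rs()
        assert downsample(rs, 2_000, seed=1) is rs
        assert downsample(rs, 1_000, seed=1) is rs

    def test_deterministic_and_exact_size(self):
        rs = self._rs()
        a = downsample(rs, 100, seed=7)
        b = downsample(rs, 100, seed=7)
        assert a.n_reads == 100
        assert np.array_equal(a.start, b.start)

    def test_subset_and_coverage_domination(self, small_segments):
        rng = np.random.default_rng(3)
        frags = [
            (r, 0, int(p), int(p) + 80, 60, 1)
            for r in range(500)
            for p in rng.integers(0, 999_000, size=2)
        ]
        chroms = small_segments.chroms
        rs = ReadSet(
            chroms,
            np.asarray([f[0] for f in frags]),
            np.asarray([f[1] for f in frags], dtype=np.int32),
            np.asarray([f[2] for f in frags]),
            np.asarray([f[3] for f in frags]),
            np.full(len(frags), 60, dtype=np.int16),
            np.ones(len(frags), dtype=np.int8),
            n_reads=500,
        )
        sub = downsample(rs, 100, seed=1)
        full_cov = segment_coverage(rs, small_segments)
        sub_cov = segment_coverage(sub, small_segments)
        assert (sub_cov.support <= full_cov.support).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            downsample(self._rs(), -1, seed=0)


class TestStore:
    def test_round_trip_lossless(self, tmp_path, rearranged_library, small_segments):
        cfg, rs, _ = rearranged_library
        vp = cfg.viewpoints[0]
        ds = ViewpointDataset("s1", vp, rs).with_coverage(small_segments)
        p = tmp_path / "store.h5"
        save_store(p, [ds])
        back = load_store(p, segments=small_segments)[("s1", vp.name)]
        assert np.array_equal(back.reads.start, rs.start)
        assert np.array_equal(back.reads.mq, rs.mq)
        assert np.array_equal(back.coverage.support, ds.coverage.support)
        assert back.viewpoint == vp

    def test_version_mismatch_is_explicit(self, tmp_path):
        import h5py

        p = tmp_path / "bad.h5"
        with h5py.File(p, "w") as f:
            f.attrs["schema_version"] = "something-else"
        with pytest.raises(ValueError, match="schema"):
            load_store(p)

    def test_multiple_samples_and_viewpoints(self, tmp_path, rearranged_library):
        cfg, rs, _ = rearranged_library
        datasets = []
        for s in ("s1", "s2"):
            for v in ("A", "B", "C"):
                vp = Viewpoint(name=v, chrom="chr1", start=450_000, end=550_000)
                datasets.append(ViewpointDataset(s, vp, rs))
        p = tmp_path / "store.h5"
        save_store(p, datasets)
        assert len(load_store(p)) == 6
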