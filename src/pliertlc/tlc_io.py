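"""Ligated-fragment I/O: split-read parsing, demultiplexing, segment coverage.

A proximity-ligation read is a concatenate of restriction fragments; after
split-alignment each read yields several aligned fragments scattered over the
genome. This module parses those alignments (primary + supplementary records,
MQ > 0), pools both mates under one read id, assigns reads to viewpoints by
largest probe overlap, and reduces a read set to per-segment coverage — the
quantity the caller's statistics are built on.

Read sets are stored columnar (one row per fragment) for speed; a million
reads with ~2-3 fragments each is the normal working size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import ChromosomeSet, SegmentIndex, Viewpoint, validate_viewpoints

log = logging.getLogger(__name__)

STORE_SCHEMA_VERSION = "pliertlc-store-1"


class ReadSet:
    """Columnar table of aligned fragments grouped into reads.

    Fragment rows are ordered by (read, order-on-read). ``read_index`` maps
    each fragment to its read (0..n_reads-1, contiguous).
    """

    def __init__(
        self,
        chroms: ChromosomeSet,
        read_index: np.ndarray,
        chrom_code: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        mq: np.ndarray,
        strand: np.ndarray,
        n_reads: int,
        sample_id: str = "sample",
        viewpoint: Optional[str] = None,
        read_names: Optional[List[str]] = None,
    ):
        self.chroms = chroms
        self.read_index = np.asarray(read_index, dtype=np.int64)
        self.chrom_code = np.asarray(chrom_code, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.mq = np.asarray(mq, dtype=np.int16)
        self.strand = np.asarray(strand, dtype=np.int8)
        self.n_reads = int(n_reads)
        self.sample_id = sample_id
        self.viewpoint = viewpoint
        self.read_names = read_names
        if not (
            len(self.read_index)
            == len(self.chrom_code)
            == len(self.start)
            == len(self.end)
            == len(self.mq)
            == len(self.strand)
        ):
            raise ValueError("fragment columns differ in length")
        if len(self.start) and np.any(self.end <= self.start):
            raise ValueError("fragments must satisfy start < end")

    @property
    def n_fragments(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return self.n_reads

    def mapped(self, min_mq_exclusive: int = 0) -> "ReadSet":
        """Keep fragments with MQ strictly above threshold; drop empty reads."""
        keep = self.mq > min_mq_exclusive
        return self._subset_fragments(keep)

    def _subset_fragments(self, keep: np.ndarray) -> "ReadSet":
        ri = self.read_index[keep]
        uniq, new_ri = np.unique(ri, return_inverse=True)
        names = [self.read_names[i] for i in uniq] if self.read_names is not None else None
        return ReadSet(
            self.chroms,
            new_ri,
            self.chrom_code[keep],
            self.start[keep],
            self.end[keep],
            self.mq[keep],
            self.strand[keep],
            n_reads=len(uniq),
            sample_id=self.sample_id,
            viewpoint=self.viewpoint,
            read_names=names,
        )

    def select_reads(self, read_ids: np.ndarray, viewpoint: Optional[str] = None) -> "ReadSet":
        """Subset to the given read ids (renumbered contiguously, order kept)."""
        read_ids = np.asarray(read_ids, dtype=np.int64)
        lut = np.full(self.n_reads, -1, dtype=np.int64)
        lut[read_ids] = np.arange(len(read_ids))
        keep = lut[self.read_index] >= 0
        ri = lut[self.read_index[keep]]
        order = np.argsort(ri, kind="stable")
        names = None
        if self.read_names is not None:
            names = [self.read_names[i] for i in read_ids]
        return ReadSet(
            self.chroms,
            ri[order],
            self.chrom_code[keep][order],
            self.start[keep][order],
            self.end[keep][order],
            self.mq[keep][order],
            self.strand[keep][order],
            n_reads=len(read_ids),
            sample_id=self.sample_id,
            viewpoint=viewpoint if viewpoint is not None else self.viewpoint,
            read_names=names,
        )

    def concat(self, other: "ReadSet", sample_id: Optional[str] = None) -> "ReadSet":
        if self.chroms != other.chroms:
            raise ValueError("read sets come from different references")
        return ReadSet(
            self.chroms,
            np.concatenate([self.read_index, other.read_index + self.n_reads]),
            np.concatenate([self.chrom_code, other.chrom_code]),
            np.concatenate([self.start, other.start]),
            np.concatenate([self.end, other.end]),
            np.concatenate([self.mq, other.mq]),
            np.concatenate([self.strand, other.strand]),
            n_reads=self.n_reads + other.n_reads,
            sample_id=sample_id or self.sample_id,
            viewpoint=None,
        )


@dataclass
class SegmentCoverage:
    """Per-segment distinct-read support (global segment ids)."""

    segments: SegmentIndex
    support: np.ndarray  # int32, len == segments.n_segments
    n_reads: int

    @property
    def covered(self) -> np.ndarray:
        return self.support > 0


def parse_alignments(path: str, chroms: Optional[ChromosomeSet] = None, min_mq_exclusive: int = 0) -> ReadSet:
    """Parse a SAM/BAM of split-aligned proximity-ligation reads.

    Primary and supplementary records are pooled per query name (both mates
    share a name and are pooled into one read unit); secondary and unmapped
    records are dropped; fragments with MQ <= ``min_mq_exclusive`` are
    excluded. Malformed records are counted and skipped.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    counters = {"records": 0, "unmapped": 0, "secondary": 0, "low_mq": 0, "malformed": 0}
    per_read: Dict[str, List[Tuple[int, int, int, int, int]]] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if chroms is None:
            chroms = ChromosomeSet(list(fh.references), list(fh.lengths))
        for rec in fh:
            counters["records"] += 1
            try:
                if rec.is_unmapped:
                    counters["unmapped"] += 1
                    continue
                if rec.is_secondary:
                    counters["secondary"] += 1
                    continue
                if rec.mapping_quality <= min_mq_exclusive:
                    counters["low_mq"] += 1
                    continue
                code = chroms.index(rec.reference_name)
                s, e = rec.reference_start, rec.reference_end
                if e is None or e <= s:
                    raise ValueError("bad interval")
                per_read.setdefault(rec.query_name, []).append(
                    (code, s, e, rec.mapping_quality, -1 if rec.is_reverse else 1)
                )
            except (ValueError, KeyError):
                counters["malformed"] += 1
                continue
    names = list(per_read)
    cols: List[List[int]] = [[], [], [], [], [], []]
    for i, name in enumerate(names):
        for frag in per_read[name]:
            cols[0].append(i)
            cols[1].append(frag[0])
            cols[2].append(frag[1])
            cols[3].append(frag[2])
            cols[4].append(frag[3])
            cols[5].append(frag[4])
    log.info("parse_alignments counters: %s", json.dumps(counters))
    return ReadSet(
        chroms,
        np.asarray(cols[0], dtype=np.int64),
        np.asarray(cols[1], dtype=np.int32),
        np.asarray(cols[2], dtype=np.int64),
        np.asarray(cols[3], dtype=np.int64),
        np.asarray(cols[4], dtype=np.int16),
        np.asarray(cols[5], dtype=np.int8),
        n_reads=len(names),
        read_names=names,
    )


def write_sam(readset: ReadSet, path: str) -> None:
    """Emit a read set as SAM (first fragment primary, rest supplementary)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": n, "LN": int(L)}
            for n, L in zip(readset.chroms.names, readset.chroms.lengths)
        ],
    }
    first_of_read = np.ones(readset.n_fragments, dtype=bool)
    if readset.n_fragments:
        first_of_read[1:] = readset.read_index[1:] != readset.read_index[:-1]
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(readset.n_fragments):
            a = pysam.AlignedSegment(out.header)
            ri = int(readset.read_index[i])
            a.query_name = (
                readset.read_names[ri] if readset.read_names is not None else f"read_{ri}"
            )
            a.reference_id = int(readset.chrom_code[i])
            a.reference_start = int(readset.start[i])
            a.mapping_quality = int(readset.mq[i]) if readset.mq[i] > 0 else 0
            flag = 0
            if readset.strand[i] < 0:
                flag |= 0x10
            if not first_of_read[i]:
                flag |= 0x800
            a.flag = flag
            a.cigarstring = f"{int(readset.end[i] - readset.start[i])}M"
            out.write(a)


def demultiplex(
    readset: ReadSet, viewpoints: Sequence[Viewpoint]
) -> Tuple[Dict[str, ReadSet], Dict[str, int]]:
    """Assign each read to the viewpoint with the largest summed overlap.

    Overlap is summed in bp across all of a read's fragments against each
    viewpoint's probed envelope. Reads with zero overlap everywhere are
    discarded; exact ties go to the viewpoint appearing first in panel order
    (counted in the ``ties`` counter).
    """
    validate_viewpoints(viewpoints)
    n_vp = len(viewpoints)
    ov = np.zeros((readset.n_reads, n_vp), dtype=np.int64)
    for j, vp in enumerate(viewpoints):
        code = readset.chroms.index(vp.chrom)
        on = readset.chrom_code == code
        lo = np.maximum(readset.start[on], vp.start)
        hi = np.minimum(readset.end[on], vp.end)
        w = np.clip(hi - lo, 0, None)
        np.add.at(ov[:, j], readset.read_index[on], w)
    best = np.argmax(ov, axis=1)
    best_ov = ov[np.arange(readset.n_reads), best]
    assigned = best_ov > 0
    n_ties = int(np.sum((ov == best_ov[:, None]).sum(axis=1)[assigned] > 1))
    out: Dict[str, ReadSet] = {}
    for j, vp in enumerate(viewpoints):
        ids = np.flatnonzero(assigned & (best == j))
        out[vp.name] = readset.select_reads(ids, viewpoint=vp.name)
    counters = {
        "input_reads": readset.n_reads,
        "assigned": int(assigned.sum()),
        "discarded": int((~assigned).sum()),
        "ties": n_ties,
    }
    counters.update({f"assigned_{vp.name}": out[vp.name].n_reads for vp in viewpoints})
    log.info("demultiplex counters: %s", json.dumps(counters))
    return out, counters


def segment_coverage(readset: ReadSet, segments: SegmentIndex) -> SegmentCoverage:
    """Distinct-read support per restriction segment.

    A fragment overlaps a segment if they share >= 1 bp. Multiple fragments
    of one read on one segment count once (per-read dedup).
    """
    if readset.chroms != segments.chroms:
        raise ValueError("read set and segment index use different references")
    n_segs = segments.n_segments
    pair_read: List[np.ndarray] = []
    pair_seg: List[np.ndarray] = []
    for name in readset.chroms.names:
        code = readset.chroms.index(name)
        on = np.flatnonzero(readset.chrom_code == code)
        if len(on) == 0:
            continue
        L = readset.chroms.length(name)
        if np.any(readset.end[on] > L) or np.any(readset.start[on] < 0):
            raise ValueError(f"fragment beyond bounds of {name}")
        b = segments.boundaries[name]
        lo = np.searchsorted(b, readset.start[on], side="right") - 1
        hi = np.searchsorted(b, readset.end[on], side="left") - 1
        hi = np.maximum(hi, lo)
        counts = hi - lo + 1
        total = int(counts.sum())
        # expand [lo_i, hi_i] ranges into flat (read, segment) pairs
        rep_read = np.repeat(readset.read_index[on], counts)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        segs = np.repeat(lo, counts) + offs + segments.offsets[code]
        pair_read.append(rep_read)
        pair_seg.append(segs)
    if pair_read:
        key = np.concatenate(pair_read) * n_segs + np.concatenate(pair_seg)
        uniq = np.unique(key)
        support = np.bincount((uniq % n_segs).astype(np.int64), minlength=n_segs)
    else:
        support = np.zeros(n_segs, dtype=np.int64)
    return SegmentCoverage(segments, support.astype(np.int32), readset.n_reads)


def downsample(readset: ReadSet, n_reads: int, seed: int) -> ReadSet:
    """Uniform random subset of exactly ``n_reads`` reads (identity if >= size)."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads >= readset.n_reads:
        return readset
    rng = np.random.default_rng(seed)
    ids = np.sort(rng.choice(readset.n_reads, size=n_reads, replace=False))
    return readset.select_reads(ids)


@dataclass
class ViewpointDataset:
    """All reads of one (sample, viewpoint) pair plus derived coverage."""

    sample_id: str
    viewpoint: Viewpoint
    reads: ReadSet
    coverage: Optional[SegmentCoverage] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def with_coverage(self, segments: SegmentIndex, min_mq_exclusive: int = 0) -> "ViewpointDataset":
        cov = segment_coverage(self.reads.mapped(min_mq_exclusive), segments)
        return ViewpointDataset(self.sample_id, self.viewpoint, self.reads, cov, dict(self.meta))


# ---------------------------------------------------------------------------
# HDF5 dataset store


def save_store(path: str, datasets: Iterable[ViewpointDataset], segments: Optional[SegmentIndex] = None) -> None:
    """Persist (sample, viewpoint) datasets to one HDF5 store."""
    import h5py

    with h5py.File(str(path), "w") as f:
        f.attrs["schema_version"] = STORE_SCHEMA_VERSION
        for ds in datasets:
            g = f.create_group(f"{ds.sample_id}/{ds.viewpoint.name}")
            rs = ds.reads
            g.attrs["sample_id"] = ds.sample_id
            g.attrs["viewpoint"] = json.dumps(
                {
                    "name": ds.viewpoint.name,
                    "chrom": ds.viewpoint.chrom,
                    "start": ds.viewpoint.start,
                    "end": ds.viewpoint.end,
                    "probes": list(map(list, ds.viewpoint.probes)),
                }
            )
            g.attrs["meta"] = json.dumps(ds.meta, default=str)
            g.attrs["chrom_names"] = json.dumps(rs.chroms.names)
            g.create_dataset("chrom_lengths", data=rs.chroms.lengths)
            g.attrs["n_reads"] = rs.n_reads
            for col in ("read_index", "chrom_code", "start", "end", "mq", "strand"):
                g.create_dataset(col, data=getattr(rs, col), compression="gzip", compression_opts=1)
            if ds.coverage is not None:
                g.create_dataset("support", data=ds.coverage.support, compression="gzip", compression_opts=1)


def load_store(path: str, segments: Optional[SegmentIndex] = None) -> Dict[Tuple[str, str], ViewpointDataset]:
    import h5py

    out: Dict[Tuple[str, str], ViewpointDataset] = {}
    with h5py.File(str(path), "r") as f:
        version = f.attrs.get("schema_version")
        if version != STORE_SCHEMA_VERSION:
            raise ValueError(
                f"store schema mismatch: found {version!r}, expected {STORE_SCHEMA_VERSION!r}"
            )
        for sample in f:
            for vp_name in f[sample]:
                g = f[sample][vp_name]
                vp_info = json.loads(g.attrs["viewpoint"])
                vp = Viewpoint(
                    name=vp_info["name"],
                    chrom=vp_info["chrom"],
                    start=vp_info["start"],
                    end=vp_info["end"],
                    probes=tuple(map(tuple, vp_info["probes"])),
                )
                chroms = ChromosomeSet(json.loads(g.attrs["chrom_names"]), g["chrom_lengths"][:])
                rs = ReadSet(
                    chroms,
                    g["read_index"][:],
                    g["chrom_code"][:],
                    g["start"][:],
                    g["end"][:],
                    g["mq"][:],
                    g["strand"][:],
                    n_reads=int(g.attrs["n_reads"]),
                    sample_id=str(g.attrs["sample_id"]),
                    viewpoint=vp.name,
                )
                cov = None
                if "support" in g and segments is not None:
                    cov = SegmentCoverage(segments, g["support"][:], rs.n_reads)
                elif "support" in g:
                    cov = SegmentCoverage(None, g["support"][:], rs.n_reads)  # type: ignore[arg-type]
                out[(str(g.attrs["sample_id"]), vp.name)] = ViewpointDataset(
                    str(g.attrs["sample_id"]), vp, rs, cov, json.loads(g.attrs["meta"])
                )
    return out
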