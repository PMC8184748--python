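"""Reference geometry: restriction-segment digestion, interval grids, viewpoints.

The caller never works with raw base pairs directly: coverage is counted on
restriction *segments* (the units produced by the in situ digestion, NlaIII /
CATG by default) and statistics are computed on equal-width genomic interval
grids (e.g. 5 kb and 75 kb bins). Both coordinate systems are built here and
shared by every downstream stage.

All coordinates are 0-based half-open internally; BED output keeps that
convention, human-readable reports convert to 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

_VALID_MOTIF = re.compile(r"^[ACGTacgt]+$")


class ChromosomeSet:
    """Ordered set of named chromosomes with lengths.

    Hosts the shared name <-> integer-code mapping used by the columnar
    fragment tables.
    """

    def __init__(self, names: Sequence[str], lengths: Sequence[int]):
        names = list(names)
        lengths = [int(x) for x in lengths]
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(L < 1 for L in lengths):
            raise ValueError("chromosome lengths must be positive")
        self.names: List[str] = names
        self.lengths: np.ndarray = np.asarray(lengths, dtype=np.int64)
        self._index: Dict[str, int] = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ChromosomeSet)
            and self.names == other.names
            and bool(np.array_equal(self.lengths, other.lengths))
        )

    def index(self, name: str) -> int:
        return self._index[name]

    def length(self, name: str) -> int:
        return int(self.lengths[self._index[name]])

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "ChromosomeSet":
        return cls(list(sequences), [len(s) for s in sequences.values()])

    @classmethod
    def from_fasta(cls, path: str) -> "ChromosomeSet":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls([name for name in fa.keys()], [len(fa[name]) for name in fa.keys()])


class SegmentIndex:
    """Restriction segments per chromosome, as boundary arrays.

    ``boundaries[chrom]`` is a sorted int64 array ``[0, c1, ..., ck, L]``;
    segment ``i`` on that chromosome is ``[b[i], b[i+1])``. Interior
    boundaries sit at motif occurrence starts (the motif bases belong to the
    downstream segment), so the segments tile the chromosome exactly.

    Segments also carry a global id: chromosomes concatenated in
    ``chroms`` order.
    """

    def __init__(self, chroms: ChromosomeSet, boundaries: Mapping[str, np.ndarray], motif: str):
        self.chroms = chroms
        self.motif = motif.upper()
        self.boundaries: Dict[str, np.ndarray] = {}
        counts = []
        for name in chroms.names:
            b = np.asarray(boundaries[name], dtype=np.int64)
            L = chroms.length(name)
            if b[0] != 0 or b[-1] != L or np.any(np.diff(b) <= 0):
                raise ValueError(f"boundaries of {name} do not tile [0,{L})")
            self.boundaries[name] = b
            counts.append(len(b) - 1)
        self._counts = np.asarray(counts, dtype=np.int64)
        # global id of the first segment of each chromosome
        self.offsets = np.concatenate([[0], np.cumsum(self._counts)])

    @property
    def n_segments(self) -> int:
        return int(self.offsets[-1])

    def n_segments_of(self, chrom: str) -> int:
        return int(self._counts[self.chroms.index(chrom)])

    def segment_lengths(self) -> np.ndarray:
        return np.concatenate([np.diff(self.boundaries[c]) for c in self.chroms.names])

    def median_segment_length(self) -> float:
        return float(np.median(self.segment_lengths()))

    def starts(self, chrom: str) -> np.ndarray:
        return self.boundaries[chrom][:-1]

    def locate(self, chrom: str, pos: int) -> int:
        """Local segment id containing ``pos`` (0-based)."""
        L = self.chroms.length(chrom)
        if not (0 <= pos < L):
            raise ValueError(f"position {chrom}:{pos} out of bounds [0,{L})")
        b = self.boundaries[chrom]
        return int(np.searchsorted(b, pos, side="right") - 1)

    def global_id(self, chrom: str, local_id: int) -> int:
        return int(self.offsets[self.chroms.index(chrom)] + local_id)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for name in self.chroms.names:
                b = self.boundaries[name]
                off = self.offsets[self.chroms.index(name)]
                for i in range(len(b) - 1):
                    fh.write(f"{name}\t{b[i]}\t{b[i + 1]}\tseg_{off + i}\n")

    @classmethod
    def from_bed(cls, path: str, motif: str = "CATG") -> "SegmentIndex":
        per: Dict[str, List[int]] = {}
        ends: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e = line.split("\t")[:3]
                per.setdefault(chrom, []).append(int(s))
                ends[chrom] = max(ends.get(chrom, 0), int(e))
        chroms = ChromosomeSet(list(per), [ends[c] for c in per])
        bounds = {c: np.asarray(sorted(per[c]) + [ends[c]]) for c in per}
        return cls(chroms, bounds, motif)


def digest_reference(sequences: Mapping[str, str], motif: str = "CATG") -> SegmentIndex:
    """In silico digestion of a reference into restriction segments.

    A boundary is placed at the first base of every motif occurrence
    (case-insensitive; 'N' never matches). A chromosome with no occurrence
    yields a single segment ``[0, L)``.
    """
    if not sequences:
        raise ValueError("no sequences to digest")
    if not motif or not _VALID_MOTIF.match(motif):
        raise ValueError(f"motif {motif!r} must be non-empty plain ACGT (no ambiguity codes)")
    motif_u = motif.upper()
    pat = re.compile(re.escape(motif_u))
    boundaries: Dict[str, np.ndarray] = {}
    for name, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"empty sequence: {name}")
        s = str(seq).upper()
        hits = [m.start() for m in pat.finditer(s)]
        b = [0] + [h for h in hits if h > 0] + [len(s)]
        boundaries[name] = np.asarray(sorted(set(b)), dtype=np.int64)
    chroms = ChromosomeSet.from_sequences({n: sequences[n] for n in sequences})
    return SegmentIndex(chroms, boundaries, motif_u)


def digest_fasta(path: str, motif: str = "CATG") -> SegmentIndex:
    """Digest every sequence present in a FASTA file."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return digest_reference({name: str(fa[name][:]) for name in fa.keys()}, motif)


class IntervalGrid:
    """Equal-width bins per chromosome, anchored at coordinate 0.

    Bin ``i`` covers ``[i*width, min((i+1)*width, L))``; the last bin may be
    partial. Bins carry global ids (chromosomes concatenated in order).
    """

    def __init__(self, chroms: ChromosomeSet, width: int):
        width = int(width)
        if width < 1:
            raise ValueError("bin width must be >= 1")
        self.chroms = chroms
        self.width = width
        self.n_bins_per_chrom = np.asarray(
            [-(-int(L) // width) for L in chroms.lengths], dtype=np.int64
        )
        self.offsets = np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self.offsets[-1])

    def n_bins_of(self, chrom: str) -> int:
        return int(self.n_bins_per_chrom[self.chroms.index(chrom)])

    def chrom_slice(self, chrom: str) -> slice:
        i = self.chroms.index(chrom)
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def locate(self, chrom: str, pos: int) -> int:
        L = self.chroms.length(chrom)
        if not (0 <= pos < L):
            raise ValueError(f"position {chrom}:{pos} out of bounds [0,{L})")
        return pos // self.width

    def global_bin(self, chrom: str, pos: int) -> int:
        return int(self.offsets[self.chroms.index(chrom)] + self.locate(chrom, pos))

    def bin_bounds(self, chrom: str, local_bin: int) -> Tuple[int, int]:
        L = self.chroms.length(chrom)
        s = local_bin * self.width
        return s, min(s + self.width, L)


def build_grid(chroms: ChromosomeSet, width: int) -> IntervalGrid:
    return IntervalGrid(chroms, width)


@dataclass(frozen=True)
class Viewpoint:
    """A probe-targeted locus; its captured ligation products form one dataset."""

    name: str
    chrom: str
    start: int
    end: int
    probes: Tuple[Tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"viewpoint {self.name}: end <= start")
        for s, e in self.probes:
            if s < self.start or e > self.end:
                raise ValueError(f"viewpoint {self.name}: probe [{s},{e}) outside envelope")

    @property
    def envelope(self) -> Tuple[int, int]:
        return self.start, self.end


def validate_viewpoints(viewpoints: Sequence[Viewpoint]) -> None:
    names = [v.name for v in viewpoints]
    if len(set(names)) != len(names):
        raise ValueError("duplicate viewpoint names")
    by_chrom: Dict[str, List[Viewpoint]] = {}
    for v in viewpoints:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        vs = sorted(vs, key=lambda v: v.start)
        for a, b in zip(vs, vs[1:]):
            if b.start < a.end:
                raise ValueError(f"viewpoints {a.name} and {b.name} overlap on {chrom}")


def read_viewpoints_bed(path: str) -> List[Viewpoint]:
    """Read a 4+-column BED-like TSV (chrom, start, end, name)."""
    out: List[Viewpoint] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"viewpoint line needs >=4 columns: {line!r}")
            chrom, s, e, name = fields[:4]
            out.append(Viewpoint(name=name, chrom=chrom, start=int(s), end=int(e)))
    validate_viewpoints(out)
    return out


def write_viewpoints_bed(viewpoints: Iterable[Viewpoint], path: str) -> None:
    with open(path, "w") as fh:
        for v in viewpoints:
            fh.write(f"{v.chrom}\t{v.start}\t{v.end}\t{v.name}\n")
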