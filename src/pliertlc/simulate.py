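"""Synthetic FFPE-TLC-like libraries with planted rearrangements.

The generator emits pre-aligned split reads (no raw sequence realism) that
reproduce the statistical structure the caller assumes:

* every read is anchored at the probed viewpoint and carries a random number
  of ligated fragments;
* cis ligation partners follow a power-law contact decay ``(d + d0)^-gamma``
  of linear distance ``d`` on the cell's (possibly rearranged) derivative
  chromosome — so in rearranged cells the partner locus acquires cis-like
  decay across the breakpoint;
* trans partners are uniform background at a configurable rate;
* FFPE degradation is emulated by rendering a random subset of restriction
  segments unobservable (sparsity);
* the mini-genome is treated as a *window* of a full-size genome: ligations
  landing outside the window are generated but unobserved, which keeps
  per-bin background coverage at realistic levels despite the small
  reference.

Fragments that span a derivative-chromosome junction are split into two
aligned pieces, yielding genuine fusion reads at the planted breakpoint.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome import ChromosomeSet, SegmentIndex, Viewpoint, digest_reference
from .tlc_io import ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Rearrangement:
    """A planted event fusing the viewpoint's locus to a partner region."""

    viewpoint: str
    kind: str  # "reciprocal" | "one_sided" | "insertion"
    target_chrom: str
    target_breakpoint: int
    partner_chrom: str
    partner_breakpoint: int
    insert_size: int = 0  # insertion only: donor length taken from the partner

    def __post_init__(self):
        if self.kind not in ("reciprocal", "one_sided", "insertion"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.kind == "insertion" and self.insert_size <= 0:
            raise ValueError("insertion requires insert_size > 0")


@dataclass(frozen=True)
class SimulationConfig:
    chromosome_lengths: Tuple[Tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 7_500_000),
        ("chr4", 7_500_000),
        ("chr5", 7_500_000),
        ("chr6", 7_500_000),
    )
    target_median_segment: int = 141
    motif: str = "CATG"
    viewpoints: Tuple[Viewpoint, ...] = (
        Viewpoint(name="TARGET1", chrom="chr1", start=4_850_000, end=5_150_000),
    )
    rearrangements: Tuple[Rearrangement, ...] = ()
    rearranged_fraction: float = 0.0
    n_reads: int = 1_000_000
    ligations_per_read: float = 0.3  # Poisson mean of non-anchor fragments
    gamma: float = 2.0  # cis contact-decay exponent
    d0: int = 10_000  # decay offset, bp
    trans_rate: float = 0.4  # probability a ligation is trans background
    modeled_chrom_length: int = 125_000_000  # virtual full chromosome span
    modeled_genome_length: int = 1_000_000_000  # virtual genome for trans thinning
    sparsity: float = 0.5  # fraction of segments unobservable
    background_dispersion: float = 1.5  # lognormal sigma of the off-target field
    dispersion_block: int = 25_000  # block size of the off-target field, bp
    panel_seed: int = 77  # probe-panel identity: off-target field shared across samples
    fragment_len_mean: float = 150.0
    fragment_len_sd: float = 50.0
    fragment_len_min: int = 30
    fragment_len_max: int = 500
    mq0_fraction: float = 0.02
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rearranged_fraction <= 1.0):
            raise ValueError("rearranged_fraction must be in [0,1]")
        if not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must be in [0,1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (0.0 <= self.trans_rate <= 1.0):
            raise ValueError("trans_rate must be in [0,1]")
        for r in self.rearrangements:
            vp = self._viewpoint(r.viewpoint)
            if r.partner_chrom == vp.chrom:
                lo = min(r.partner_breakpoint, r.partner_breakpoint + r.insert_size)
                hi = max(r.partner_breakpoint, r.partner_breakpoint + r.insert_size)
                if lo < vp.end and hi > vp.start:
                    raise ValueError("partner region overlaps the viewpoint")

    def _viewpoint(self, name: str) -> Viewpoint:
        for v in self.viewpoints:
            if v.name == name:
                return v
        raise ValueError(f"unknown viewpoint {name!r}")

    def to_json(self) -> str:
        d = {
            "chromosome_lengths": list(map(list, self.chromosome_lengths)),
            "target_median_segment": self.target_median_segment,
            "motif": self.motif,
            "viewpoints": [
                {"name": v.name, "chrom": v.chrom, "start": v.start, "end": v.end}
                for v in self.viewpoints
            ],
            "rearrangements": [vars(r) | {} for r in self.rearrangements],
            "rearranged_fraction": self.rearranged_fraction,
            "n_reads": self.n_reads,
            "ligations_per_read": self.ligations_per_read,
            "gamma": self.gamma,
            "d0": self.d0,
            "trans_rate": self.trans_rate,
            "modeled_chrom_length": self.modeled_chrom_length,
            "modeled_genome_length": self.modeled_genome_length,
            "sparsity": self.sparsity,
            "seed": self.seed,
            "sample_id": self.sample_id,
        }
        return json.dumps(d, indent=2)


@dataclass
class TruthSet:
    """Ground truth emitted with every simulated library."""

    sample_id: str
    rearrangements: Tuple[Rearrangement, ...]
    rearranged_fraction: float
    seed: int
    read_from_rearranged_cell: np.ndarray  # bool per read in the ReadSet
    partner_window: int = 2_500_000  # half-width used to label true partners

    def partner_regions(self, viewpoint: str) -> List[Tuple[str, int, int]]:
        out = []
        for r in self.rearrangements:
            if r.viewpoint != viewpoint:
                continue
            w = self.partner_window
            lo = max(0, r.partner_breakpoint - w)
            out.append((r.partner_chrom, lo, r.partner_breakpoint + max(w, r.insert_size)))
        return out


def default_translocation(kind: str = "reciprocal") -> Rearrangement:
    """The standard planted event for the default config's geometry."""
    return Rearrangement(
        viewpoint="TARGET1",
        kind=kind,
        target_chrom="chr1",
        target_breakpoint=5_000_000,
        partner_chrom="chr2",
        partner_breakpoint=5_000_000,
    )


# ---------------------------------------------------------------------------
# reference construction


def make_reference(
    chromosome_lengths: Mapping[str, int] | Sequence[Tuple[str, int]],
    target_median_segment: Optional[int] = 141,
    motif: str = "CATG",
    seed: int = 0,
) -> Tuple[Dict[str, str], ChromosomeSet]:
    """Random reference whose in silico digest median matches a target.

    Recognition-site spacings are drawn from an exponential with median
    ``target_median_segment``; accidental motif occurrences in the random
    background are scrubbed first, so digestion boundaries land exactly on
    the planted sites. ``target_median_segment=None`` plants no sites at all
    (one segment per chromosome).
    """
    items = list(chromosome_lengths.items()) if isinstance(chromosome_lengths, Mapping) else list(chromosome_lengths)
    if any(L < 10_000 for _, L in items):
        raise ValueError("chromosome lengths must be >= 10 kb")
    if target_median_segment is not None and target_median_segment <= len(motif):
        raise ValueError("target median segment length must exceed the motif length")
    rng = np.random.default_rng(seed)
    motif_b = np.frombuffer(motif.upper().encode(), dtype=np.uint8)
    sequences: Dict[str, str] = {}
    for name, L in items:
        arr = _BASES[rng.integers(0, 4, size=int(L))].copy()
        _scrub_motif(arr, motif_b)
        if target_median_segment:
            scale = target_median_segment / math.log(2.0)
            n_gap = int(2.5 * L / target_median_segment) + 10
            gaps = np.maximum(len(motif) + 1, np.rint(rng.exponential(scale, size=n_gap))).astype(np.int64)
            pos = np.cumsum(gaps)
            pos = pos[pos < L - len(motif)]
            for p in pos:
                arr[p : p + len(motif)] = motif_b
        sequences[name] = arr.tobytes().decode()
    return sequences, ChromosomeSet.from_sequences(sequences)


def _scrub_motif(arr: np.ndarray, motif: np.ndarray) -> None:
    """Destroy accidental motif occurrences in place."""
    m = len(motif)
    for _ in range(8):
        win = np.lib.stride_tricks.sliding_window_view(arr, m)
        hits = np.flatnonzero((win == motif).all(axis=1))
        if len(hits) == 0:
            return
        # mutating the 2nd motif base to 'T' cannot create a new occurrence
        arr[hits + 1] = ord("T")
    raise RuntimeError("failed to scrub motif occurrences")


# ---------------------------------------------------------------------------
# derivative genomes


@dataclass
class _Derivative:
    """One derivative chromosome as a list of reference blocks (+ strand)."""

    name: str
    blocks: List[Tuple[int, int, int]]  # (chrom_code, ref_start, ref_end)

    def __post_init__(self):
        lens = np.asarray([e - s for _, s, e in self.blocks], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(lens)])
        self.length = int(self.cum[-1])


class GenomeView:
    """The (possibly rearranged) genome of one cell class."""

    def __init__(self, chroms: ChromosomeSet, derivatives: List[_Derivative]):
        self.chroms = chroms
        self.ders = derivatives

    @classmethod
    def reference(cls, chroms: ChromosomeSet) -> "GenomeView":
        ders = [
            _Derivative(name, [(chroms.index(name), 0, chroms.length(name))])
            for name in chroms.names
        ]
        return cls(chroms, ders)

    @classmethod
    def rearranged(cls, chroms: ChromosomeSet, events: Sequence[Rearrangement], viewpoints: Mapping[str, Viewpoint]) -> "GenomeView":
        used: set = set()
        ders: List[_Derivative] = []
        touched: set = set()
        for r in events:
            c1, c2 = chroms.index(r.target_chrom), chroms.index(r.partner_chrom)
            if c1 in used or (c2 in used and c2 != c1):
                raise ValueError("rearrangements may not share chromosomes")
            used |= {c1, c2}
            L1, L2 = chroms.length(r.target_chrom), chroms.length(r.partner_chrom)
            b1, b2 = r.target_breakpoint, r.partner_breakpoint
            if r.kind == "reciprocal":
                ders.append(_Derivative(f"der_{r.target_chrom}", [(c1, 0, b1), (c2, b2, L2)]))
                ders.append(_Derivative(f"der_{r.partner_chrom}", [(c2, 0, b2), (c1, b1, L1)]))
            elif r.kind == "one_sided":
                if c1 == c2:
                    # intra-chromosomal fusion: the span [b1, b2) is lost
                    lo, hi = min(b1, b2), max(b1, b2)
                    ders.append(_Derivative(f"der_{r.target_chrom}", [(c1, 0, lo), (c1, hi, L1)]))
                else:
                    ders.append(_Derivative(f"der_{r.target_chrom}", [(c1, 0, b1), (c2, b2, L2)]))
                    ders.append(_Derivative(f"rem_{r.target_chrom}", [(c1, b1, L1)]))
                    ders.append(_Derivative(f"rem_{r.partner_chrom}", [(c2, 0, b2)]))
            else:  # insertion (cut-and-paste of the donor interval)
                s, e = b2, b2 + r.insert_size
                ders.append(
                    _Derivative(
                        f"der_{r.target_chrom}", [(c1, 0, b1), (c2, s, e), (c1, b1, L1)]
                    )
                )
                ders.append(_Derivative(f"der_{r.partner_chrom}", [(c2, 0, s), (c2, e, L2)]))
        for name in chroms.names:
            if chroms.index(name) not in used:
                ders.append(_Derivative(name, [(chroms.index(name), 0, chroms.length(name))]))
        return cls(chroms, ders)

    def locate_ref(self, chrom_code: int, pos: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Map reference positions to (derivative index, derivative offset)."""
        der_id = np.full(len(pos), -1, dtype=np.int64)
        dpos = np.zeros(len(pos), dtype=np.int64)
        for di, der in enumerate(self.ders):
            for bi, (code, rs, re_) in enumerate(der.blocks):
                if code != chrom_code:
                    continue
                m = (pos >= rs) & (pos < re_) & (der_id < 0)
                der_id[m] = di
                dpos[m] = der.cum[bi] + (pos[m] - rs)
        if np.any(der_id < 0):
            raise ValueError("reference position not present in any derivative")
        return der_id, dpos

    def der_lengths(self) -> np.ndarray:
        return np.asarray([d.length for d in self.ders], dtype=np.int64)

    def map_intervals(self, der_id: np.ndarray, s: np.ndarray, e: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Map derivative intervals to reference pieces, splitting at junctions.

        Returns (origin_row, chrom_code, ref_start, ref_end); rows appear in
        derivative-coordinate order, so consecutive pieces of one interval
        represent consecutive parts of the (split) alignment.
        """
        rows: List[np.ndarray] = []
        codes: List[np.ndarray] = []
        starts: List[np.ndarray] = []
        ends: List[np.ndarray] = []
        order_key: List[np.ndarray] = []
        for di, der in enumerate(self.ders):
            on = np.flatnonzero(der_id == di)
            if len(on) == 0:
                continue
            for bi, (code, rs, re_) in enumerate(der.blocks):
                lo = np.maximum(s[on], der.cum[bi])
                hi = np.minimum(e[on], der.cum[bi + 1])
                m = hi > lo
                if not m.any():
                    continue
                rows.append(on[m])
                codes.append(np.full(int(m.sum()), code, dtype=np.int32))
                starts.append(rs + (lo[m] - der.cum[bi]))
                ends.append(rs + (hi[m] - der.cum[bi]))
                order_key.append(lo[m])
        if not rows:
            z = np.array([], dtype=np.int64)
            return z, z.astype(np.int32), z, z
        row = np.concatenate(rows)
        key = np.concatenate(order_key)
        o = np.lexsort((key, row))
        return (
            row[o],
            np.concatenate(codes)[o],
            np.concatenate(starts)[o],
            np.concatenate(ends)[o],
        )


# ---------------------------------------------------------------------------
# sampling helpers


def _sample_decay_distance(rng: np.random.Generator, n: int, gamma: float, d0: float, d_max: float) -> np.ndarray:
    """Distances from the truncated power-law density ``(d + d0)^-gamma``."""
    u = rng.random(n)
    if abs(gamma - 1.0) < 1e-12:
        hi = math.log((d_max + d0) / d0)
        return (d0 * np.expm1(u * hi)).astype(np.int64)
    a = 1.0 - gamma
    lo, hi = d0 ** a, (d_max + d0) ** a
    return ((lo + u * (hi - lo)) ** (1.0 / a) - d0).astype(np.int64)


_offtarget_cache: dict = {}


def _offtarget_blocks(
    config: SimulationConfig, chroms: ChromosomeSet, eligible: Tuple[int, ...]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Off-target capture field: lognormal weight per genomic block.

    Keyed by the panel seed (not the sample seed): the field models
    probe-driven off-target pulldown, identical for every library captured
    with one panel. Returns (chrom_code, block_start, block_len, cumulative
    weight) over the eligible chromosomes.
    """
    key = (config.panel_seed, config.background_dispersion, config.dispersion_block, tuple(chroms.names), eligible)
    if key in _offtarget_cache:
        return _offtarget_cache[key]
    prng = np.random.default_rng(np.random.SeedSequence(entropy=config.panel_seed, spawn_key=(23,)))
    codes: List[np.ndarray] = []
    starts: List[np.ndarray] = []
    lens: List[np.ndarray] = []
    weights: List[np.ndarray] = []
    bs = config.dispersion_block
    sig = config.background_dispersion
    # field drawn for every chromosome (deterministic layout), then subset
    for c in range(len(chroms)):
        L = int(chroms.lengths[c])
        n = -(-L // bs)
        st = np.arange(n, dtype=np.int64) * bs
        ln = np.minimum(st + bs, L) - st
        w = prng.lognormal(mean=-0.5 * sig * sig, sigma=sig, size=n) if sig > 0 else np.ones(n)
        if c in eligible:
            codes.append(np.full(n, c, dtype=np.int64))
            starts.append(st)
            lens.append(ln)
            weights.append(w * (ln / bs))
    out = (
        np.concatenate(codes),
        np.concatenate(starts),
        np.concatenate(lens),
        np.cumsum(np.concatenate(weights)),
    )
    _offtarget_cache[key] = out
    return out


def _fragment_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    l = rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd, size=n)
    return np.clip(np.rint(l), cfg.fragment_len_min, cfg.fragment_len_max).astype(np.int64)


# ---------------------------------------------------------------------------
# the sample simulator


def simulate_sample(
    config: SimulationConfig,
    sequences: Optional[Dict[str, str]] = None,
    segments: Optional[SegmentIndex] = None,
) -> Tuple[ReadSet, TruthSet]:
    """Generate one viewpoint-anchored library plus its ground truth.

    ``sequences``/``segments`` may be passed to reuse a reference across
    samples; otherwise they are built from the config (seeded).
    """
    if sequences is None:
        sequences, _ = make_reference(
            dict(config.chromosome_lengths), config.target_median_segment, config.motif, seed=config.seed
        )
    if segments is None:
        segments = digest_reference(sequences, config.motif)
    chroms = segments.chroms
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(11,)))

    if len(config.viewpoints) != 1:
        raise NotImplementedError("one viewpoint per simulated library")
    vp = config.viewpoints[0]
    vp_code = chroms.index(vp.chrom)
    views = {
        False: GenomeView.reference(chroms),
        True: GenomeView.rearranged(chroms, config.rearrangements, {v.name: v for v in config.viewpoints})
        if config.rearrangements
        else GenomeView.reference(chroms),
    }
    excluded_chroms = {
        False: {vp_code},
        True: {vp_code}
        | {chroms.index(r.partner_chrom) for r in config.rearrangements}
        | {chroms.index(r.target_chrom) for r in config.rearrangements},
    }

    n = config.n_reads
    from_rearranged = rng.random(n) < config.rearranged_fraction

    frag_read: List[np.ndarray] = []
    frag_code: List[np.ndarray] = []
    frag_start: List[np.ndarray] = []
    frag_end: List[np.ndarray] = []
    frag_anchor: List[np.ndarray] = []

    for label in (False, True):
        ridx = np.flatnonzero(from_rearranged == label)
        if len(ridx) == 0:
            continue
        view = views[label]
        nr = len(ridx)
        anchors_ref = rng.integers(vp.start, vp.end, size=nr)
        der_id, dpos = view.locate_ref(vp_code, anchors_ref)
        der_len = view.der_lengths()

        # anchor fragments (split at junctions if they span one)
        alen = _fragment_lengths(rng, nr, config)
        a_s = np.maximum(dpos - alen // 2, 0)
        a_e = np.minimum(a_s + alen, der_len[der_id])
        row, code, rs, re_ = view.map_intervals(der_id, a_s, a_e)
        frag_read.append(ridx[row])
        frag_code.append(code)
        frag_start.append(rs)
        frag_end.append(re_)
        frag_anchor.append(np.ones(len(row), dtype=bool))

        # ligated fragments
        k = rng.poisson(config.ligations_per_read, size=nr)
        lig_row = np.repeat(np.arange(nr), k)  # row into this class's reads
        m = len(lig_row)
        if m == 0:
            continue
        is_trans = rng.random(m) < config.trans_rate
        llen = _fragment_lengths(rng, m, config)

        # cis: decay distance on the derivative, either direction
        ci = np.flatnonzero(~is_trans)
        if len(ci):
            d = _sample_decay_distance(rng, len(ci), config.gamma, config.d0, config.modeled_chrom_length)
            sign = np.where(rng.random(len(ci)) < 0.5, 1, -1)
            pos = dpos[lig_row[ci]] + sign * d
            lim = der_len[der_id[lig_row[ci]]]
            vis = (pos >= 0) & (pos < lim)
            ci = ci[vis]
            if len(ci):
                pos = pos[vis]
                did = der_id[lig_row[ci]]
                s = np.maximum(pos - llen[ci] // 2, 0)
                e = np.minimum(s + llen[ci], der_len[did])
                e = np.maximum(e, s + 1)
                row, code, rs, re_ = view.map_intervals(did, s, e)
                frag_read.append(ridx[lig_row[ci][row]])
                frag_code.append(code)
                frag_start.append(rs)
                frag_end.append(re_)
                frag_anchor.append(np.zeros(len(row), dtype=bool))

        # trans: background over the virtual genome; only the modeled window
        # (minus the chromosomes involved in the anchor's derivative) lands.
        # Within the window, placement follows the panel's off-target field:
        # hybridization capture is not spatially uniform, and the lognormal
        # block weights reproduce the overdispersed, occasionally pile-like
        # background of real libraries (shared across samples of one panel).
        ti = np.flatnonzero(is_trans)
        if len(ti):
            eligible = [c for c in range(len(chroms)) if c not in excluded_chroms[label]]
            lens = np.asarray([chroms.lengths[c] for c in eligible], dtype=np.int64)
            window = int(lens.sum())
            vis = rng.random(len(ti)) < window / config.modeled_genome_length
            ti = ti[vis]
            if len(ti):
                b_code, b_start, b_len, b_cumw = _offtarget_blocks(config, chroms, tuple(eligible))
                r = rng.random(len(ti)) * b_cumw[-1]
                which = np.searchsorted(b_cumw, r, side="right") - 1
                code = b_code[which].astype(np.int32)
                pos = b_start[which] + (rng.random(len(ti)) * b_len[which]).astype(np.int64)
                L = np.asarray([chroms.lengths[c] for c in code], dtype=np.int64)
                s = np.maximum(pos - llen[ti] // 2, 0)
                e = np.minimum(s + llen[ti], L)
                e = np.maximum(e, s + 1)
                frag_read.append(ridx[lig_row[ti]])
                frag_code.append(code)
                frag_start.append(s)
                frag_end.append(e)
                frag_anchor.append(np.zeros(len(ti), dtype=bool))

    read = np.concatenate(frag_read)
    code = np.concatenate(frag_code)
    start = np.concatenate(frag_start)
    end = np.concatenate(frag_end)
    anchor = np.concatenate(frag_anchor)

    # FFPE sparsity: a random subset of segments is unobservable; ligated
    # fragments whose midpoint falls there are dropped (the captured anchor
    # is conditioned on, so on-target read counts stay interpretable).
    if config.sparsity > 0:
        drop_seg = rng.random(segments.n_segments) < config.sparsity
        mid = (start + end) // 2
        gid = np.empty(len(start), dtype=np.int64)
        for c_i, name in enumerate(chroms.names):
            m = code == c_i
            if m.any():
                b = segments.boundaries[name]
                gid[m] = segments.offsets[c_i] + np.searchsorted(b, mid[m], side="right") - 1
        keep = anchor | ~drop_seg[gid]
        read, code, start, end, anchor = read[keep], code[keep], start[keep], end[keep], anchor[keep]

    # assemble: sort by read, anchors first within a read
    o = np.lexsort((~anchor, read))
    read, code, start, end = read[o], code[o], start[o], end[o]
    kept_reads, new_idx = np.unique(read, return_inverse=True)

    m = len(read)
    mq = np.full(m, 60, dtype=np.int16)
    mq[rng.random(m) < config.mq0_fraction] = 0
    strand = np.where(rng.random(m) < 0.5, 1, -1).astype(np.int8)

    rs = ReadSet(
        chroms,
        new_idx,
        code,
        start,
        end,
        mq,
        strand,
        n_reads=len(kept_reads),
        sample_id=config.sample_id,
        viewpoint=vp.name,
    )
    truth = TruthSet(
        sample_id=config.sample_id,
        rearrangements=config.rearrangements,
        rearranged_fraction=config.rearranged_fraction,
        seed=config.seed,
        read_from_rearranged_cell=from_rearranged[kept_reads],
    )
    return rs, truth


# ---------------------------------------------------------------------------
# dilution / mixing


def mix(
    positive: ReadSet,
    control: ReadSet,
    fraction: float,
    n_reads: int,
    seed: int,
    positive_truth: Optional[TruthSet] = None,
) -> Tuple[ReadSet, np.ndarray]:
    """Dilute a positive library with control reads.

    Each emitted read is drawn from the positive set with probability
    ``fraction`` (else control), without replacement within each source.
    Returns the mixture and a per-read boolean array marking reads that
    originate from a rearranged cell of the positive sample (all False when
    ``positive_truth`` is omitted and for control reads).
    """
    if positive.chroms != control.chroms:
        raise ValueError("read sets come from different references")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    take_pos = rng.random(n_reads) < fraction
    n_pos = int(take_pos.sum())
    n_ctl = n_reads - n_pos
    if n_pos > positive.n_reads or n_ctl > control.n_reads:
        raise ValueError("source read sets too small for requested mixture")
    pos_ids = np.sort(rng.choice(positive.n_reads, size=n_pos, replace=False))
    ctl_ids = np.sort(rng.choice(control.n_reads, size=n_ctl, replace=False))
    mixed = positive.select_reads(pos_ids).concat(control.select_reads(ctl_ids))
    labels = np.zeros(n_reads, dtype=bool)
    if positive_truth is not None and n_pos:
        labels[:n_pos] = positive_truth.read_from_rearranged_cell[pos_ids]
    return mixed, labels


# ---------------------------------------------------------------------------
# detection evaluation


def _overlaps(call, region: Tuple[str, int, int]) -> bool:
    chrom, lo, hi = region
    return call.chrom == chrom and call.start < hi and call.end > lo


def label_calls(calls: Sequence, truth: TruthSet, viewpoint: str) -> np.ndarray:
    """True/false-positive labels: TP iff the footprint overlaps a planted
    partner region of the correct viewpoint."""
    regions = truth.partner_regions(viewpoint)
    return np.asarray([any(_overlaps(c, r) for r in regions) for c in calls], dtype=bool)


def evaluate_detection(calls: Sequence, truth: TruthSet, viewpoint: str) -> Dict[str, float]:
    """Precision/recall of significant calls and AUC-PR over the score sweep.

    Every planted rearrangement of the viewpoint counts as one positive; a
    call not overlapping any planted partner region is a false positive. The
    PR curve sweeps the enrichment score over *all* calls, so planted events
    that produced no call depress the attainable recall.
    """
    n_pos = len(truth.partner_regions(viewpoint))
    sig = [c for c in calls if getattr(c, "significant", True)]
    sig_labels = label_calls(sig, truth, viewpoint)
    tp_events = sum(
        any(_overlaps(c, r) for c in sig) for r in truth.partner_regions(viewpoint)
    )
    precision = float(sig_labels.mean()) if len(sig) else 1.0
    recall = tp_events / n_pos if n_pos else 1.0

    ranked = sorted(calls, key=lambda c: -c.enrichment)
    labels = label_calls(ranked, truth, viewpoint)
    auc = 0.0
    if n_pos:
        tp = fp = 0
        prev_recall = 0.0
        hit: set = set()
        for c, lab in zip(ranked, labels):
            if lab:
                tp += 1
                for i, r in enumerate(truth.partner_regions(viewpoint)):
                    if _overlaps(c, r):
                        hit.add(i)
            else:
                fp += 1
            r_now = len(hit) / n_pos
            p_now = tp / (tp + fp)
            auc += (r_now - prev_recall) * p_now
            prev_recall = r_now
    return {"precision": precision, "recall": recall, "auc_pr": auc, "n_calls": float(len(sig))}
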