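"""Call post-processing: amplification detection, blacklists, butterfly
contact matrices, breakpoint localization, fusion reads.

A significant enrichment call says *where* extra proximity-ligation products
cluster; these steps say *what* the cluster is. Overlapping calls from
several probe sets in one sample indicate amplification rather than a fusion
of any single target. The butterfly matrix — 2D contacts between the target
window and the partner window — distinguishes a reciprocal rearrangement
(complementary quadrant enrichment flipping at the breakpoint) from
one-sided events and bystanders, and fusion reads (split alignments whose
junction is not a restriction site) pin the breakpoint to base resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _importlib_resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import EnrichmentCall
from .genome import SegmentIndex, Viewpoint
from .tlc_io import ReadSet

Region = Tuple[str, int, int]


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and a_end > b_start


# ---------------------------------------------------------------------------
# amplification detection


@dataclass
class AmplificationEvent:
    sample: str
    chrom: str
    start: int
    end: int
    viewpoints: List[str]


def detect_amplifications(
    calls_by_viewpoint: Dict[str, Sequence[EnrichmentCall]],
    primary_viewpoints: Sequence[str],
    igh_region: Optional[Region] = None,
) -> List[AmplificationEvent]:
    """Overlapping significant calls from >= 2 primary probe sets -> one event.

    Calls overlapping the IGH region are exempt: a double-hit sample may
    legitimately fuse several targets to IGH, which is a rearrangement, not
    an amplification.
    """
    pool: List[Tuple[str, EnrichmentCall]] = []
    sample = "sample"
    for vp in primary_viewpoints:
        for c in calls_by_viewpoint.get(vp, []):
            if not c.significant:
                continue
            if igh_region is not None and c.chrom == igh_region[0] and _overlap(c.start, c.end, igh_region[1], igh_region[2]):
                continue
            pool.append((vp, c))
            sample = c.sample
    # union-find over >=1 bp overlaps on the same chromosome
    events: List[AmplificationEvent] = []
    pool.sort(key=lambda t: (t[1].chrom, t[1].start))
    cur: List[Tuple[str, EnrichmentCall]] = []
    cur_end = -1

    def _flush():
        vps = sorted({vp for vp, _ in cur})
        if len(vps) >= 2:
            events.append(
                AmplificationEvent(
                    sample=sample,
                    chrom=cur[0][1].chrom,
                    start=min(c.start for _, c in cur),
                    end=max(c.end for _, c in cur),
                    viewpoints=vps,
                )
            )

    for vp, c in pool:
        if cur and (c.chrom != cur[0][1].chrom or c.start >= cur_end):
            _flush()
            cur, cur_end = [], -1
        cur.append((vp, c))
        cur_end = max(cur_end, c.end)
    if cur:
        _flush()
    return events


# ---------------------------------------------------------------------------
# blacklist


def load_default_blacklist() -> Tuple[Dict[str, List[Region]], Region]:
    """Shipped hg19 per-viewpoint blacklist and IGH region."""
    import yaml

    text = (_importlib_resources.files("pliertlc") / "resources/hg19_blacklist.yaml").read_text()
    raw = yaml.safe_load(text)
    bl = {vp: [tuple(r) for r in regions] for vp, regions in raw["blacklist"].items()}
    igh = tuple(raw["igh_region"])
    return bl, igh  # type: ignore[return-value]


def apply_blacklist(
    calls: Sequence[EnrichmentCall], blacklist: Dict[str, Sequence[Region]]
) -> Tuple[List[EnrichmentCall], List[EnrichmentCall]]:
    """Remove calls overlapping a region blacklisted for their own viewpoint."""
    retained: List[EnrichmentCall] = []
    removed: List[EnrichmentCall] = []
    for c in calls:
        bad = any(
            c.chrom == chrom and _overlap(c.start, c.end, lo, hi)
            for chrom, lo, hi in blacklist.get(c.viewpoint, [])
        )
        (removed if bad else retained).append(c)
    return retained, removed


# ---------------------------------------------------------------------------
# butterfly contact matrices


@dataclass
class ButterflyMatrix:
    target_window: Region
    partner_window: Region
    bin_width: int
    counts: np.ndarray  # shape (target bins, partner bins)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# target\t{self.target_window[0]}\t{self.target_window[1]}\t{self.target_window[2]}\n")
            fh.write(f"# partner\t{self.partner_window[0]}\t{self.partner_window[1]}\t{self.partner_window[2]}\n")
            fh.write(f"# bin_width\t{self.bin_width}\n")
            np.savetxt(fh, self.counts, fmt="%d", delimiter="\t")

    def plot(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(np.log1p(self.counts), origin="lower", aspect="auto", cmap="viridis")
        ax.set_xlabel(f"{self.partner_window[0]}:{self.partner_window[1]}-{self.partner_window[2]}")
        ax.set_ylabel(f"{self.target_window[0]}:{self.target_window[1]}-{self.target_window[2]}")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def butterfly_matrix(
    readset: ReadSet, target_window: Region, partner_window: Region, bin_width: int = 20_000
) -> ButterflyMatrix:
    """2D contact counts between two windows.

    Every (target-side fragment, partner-side fragment) pair of a read with
    at least one fragment in each window increments one cell; fragments are
    binned by their midpoint.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    tc, ts, te = target_window
    pc, ps, pe = partner_window
    if te <= ts or pe <= ps:
        raise ValueError("zero-width window")
    if tc == pc and _overlap(ts, te, ps, pe):
        raise ValueError("windows must be disjoint")
    nt = -(-(te - ts) // bin_width)
    npb = -(-(pe - ps) // bin_width)
    mid = (readset.start + readset.end) // 2
    t_on = (readset.chrom_code == readset.chroms.index(tc)) & (mid >= ts) & (mid < te)
    p_on = (readset.chrom_code == readset.chroms.index(pc)) & (mid >= ps) & (mid < pe)
    counts = np.zeros((nt, npb), dtype=np.int64)
    t_reads = readset.read_index[t_on]
    p_reads = readset.read_index[p_on]
    t_bins = (mid[t_on] - ts) // bin_width
    p_bins = (mid[p_on] - ps) // bin_width
    common = np.intersect1d(t_reads, p_reads)
    if len(common):
        import pandas as pd

        dt = pd.DataFrame({"r": t_reads, "tb": t_bins})
        dp = pd.DataFrame({"r": p_reads, "pb": p_bins})
        pairs = dt.merge(dp, on="r")
        np.add.at(counts, (pairs["tb"].to_numpy(), pairs["pb"].to_numpy()), 1)
    return ButterflyMatrix(target_window, partner_window, bin_width, counts)


# ---------------------------------------------------------------------------
# breakpoint localization from a butterfly matrix


@dataclass
class BreakpointEstimate:
    pattern: str  # "reciprocal" | "one_sided" | "none"
    target_bp: Optional[int] = None
    partner_bp: Optional[int] = None
    contrast: float = 0.0
    note: str = ""


def localize_breakpoint(
    matrix: ButterflyMatrix,
    min_total: int = 50,
    contrast_threshold: float = 0.3,
    enrichment_ratio: float = 2.0,
) -> BreakpointEstimate:
    """Locate the breakpoint as the cut maximizing quadrant density contrast.

    For every cut (i, j) the matrix splits into four quadrants; a reciprocal
    rearrangement enriches one complementary (diagonal) pair and depletes the
    other. The returned coordinates are the bin edges of the best cut; the
    pattern class reflects how many of the dominant-diagonal quadrants are
    individually enriched over the anti-diagonal ones.
    """
    C = matrix.counts.astype(float)
    nt, npb = C.shape
    if matrix.total < min_total or nt < 2 or npb < 2:
        return BreakpointEstimate(pattern="none", note="sparse matrix")
    S = np.zeros((nt + 1, npb + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(C, axis=0), axis=1)
    total = S[-1, -1]
    best = None
    for i in range(1, nt):
        for j in range(1, npb):
            a = S[i, j]  # low-target x low-partner
            b = S[i, -1] - S[i, j]  # low-target x high-partner
            c = S[-1, j] - S[i, j]  # high-target x low-partner
            d = total - a - b - c
            # densities (counts per cell)
            da = a / (i * j)
            db = b / (i * (npb - j))
            dc = c / ((nt - i) * j)
            dd = d / ((nt - i) * (npb - j))
            contrast = abs((da + dd) - (db + dc)) / (da + db + dc + dd + 1e-12)
            if best is None or contrast > best[0]:
                best = (contrast, i, j, (da, db, dc, dd))
    contrast, i, j, (da, db, dc, dd) = best
    if contrast < contrast_threshold:
        return BreakpointEstimate(pattern="none", contrast=contrast)
    tgt_bp = matrix.target_window[1] + i * matrix.bin_width
    par_bp = matrix.partner_window[1] + j * matrix.bin_width
    if da + dd >= db + dc:
        hi_pair, lo_pair = (da, dd), (db, dc)
    else:
        hi_pair, lo_pair = (db, dc), (da, dd)
    lo_ref = max(lo_pair) + 1e-12
    n_enriched = sum(1 for q in hi_pair if q > enrichment_ratio * lo_ref)
    pattern = "reciprocal" if n_enriched == 2 else ("one_sided" if n_enriched == 1 else "none")
    return BreakpointEstimate(pattern=pattern, target_bp=tgt_bp, partner_bp=par_bp, contrast=contrast)


# ---------------------------------------------------------------------------
# fusion reads


@dataclass
class FusionRead:
    read_id: int
    target_chrom: str
    target_junction: int
    partner_chrom: str
    partner_junction: int
    orientation: Tuple[int, int]  # strand pair


def find_fusion_reads(
    readset: ReadSet,
    call: EnrichmentCall,
    viewpoint: Viewpoint,
    segments: SegmentIndex,
    tolerance_bp: int = 1,
) -> List[FusionRead]:
    """Split alignments spanning the target/partner junction.

    Consecutive fragment pairs on a read qualify if one side overlaps the
    viewpoint's probed envelope (or, for a cis call, lies on the viewpoint
    chromosome outside the call) and the other overlaps the call footprint.
    A junction within +- ``tolerance_bp`` of a restriction-segment boundary
    on either side is a ligation junction, not a fusion, and is discarded.
    """
    out: List[FusionRead] = []
    chroms = readset.chroms
    vp_code = chroms.index(viewpoint.chrom)
    call_code = chroms.index(call.chrom)
    n = readset.n_fragments
    if n < 2:
        return out
    same_read = readset.read_index[1:] == readset.read_index[:-1]
    call_ov = (
        (readset.chrom_code == call_code)
        & (readset.start < call.end)
        & (readset.end > call.start)
    )
    for i in np.flatnonzero(same_read & (call_ov[:-1] | call_ov[1:])):
        a, b = int(i), int(i) + 1
        for t_idx, p_idx in ((a, b), (b, a)):
            t_on = readset.chrom_code[t_idx] == vp_code and _overlap(
                readset.start[t_idx], readset.end[t_idx], viewpoint.start, viewpoint.end
            )
            p_on = readset.chrom_code[p_idx] == call_code and _overlap(
                readset.start[p_idx], readset.end[p_idx], call.start, call.end
            )
            if not (t_on and p_on):
                continue
            tj = int(readset.end[t_idx]) if readset.strand[t_idx] > 0 else int(readset.start[t_idx])
            pj = int(readset.start[p_idx]) if readset.strand[p_idx] > 0 else int(readset.end[p_idx])
            if _near_boundary(segments, viewpoint.chrom, tj, tolerance_bp) or _near_boundary(
                segments, call.chrom, pj, tolerance_bp
            ):
                continue
            out.append(
                FusionRead(
                    read_id=int(readset.read_index[t_idx]),
                    target_chrom=viewpoint.chrom,
                    target_junction=tj,
                    partner_chrom=call.chrom,
                    partner_junction=pj,
                    orientation=(int(readset.strand[t_idx]), int(readset.strand[p_idx])),
                )
            )
            break
    return out


def _near_boundary(segments: SegmentIndex, chrom: str, pos: int, tol: int) -> bool:
    b = segments.boundaries[chrom]
    i = np.searchsorted(b, pos)
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(b) and abs(int(b[j]) - pos) <= tol:
            return True
    return False


def write_fusion_bedpe(fusions: Sequence[FusionRead], path: str) -> None:
    with open(path, "w") as fh:
        for f in fusions:
            s1, s2 = ("+" if f.orientation[0] > 0 else "-"), ("+" if f.orientation[1] > 0 else "-")
            fh.write(
                f"{f.target_chrom}\t{f.target_junction}\t{f.target_junction + 1}\t"
                f"{f.partner_chrom}\t{f.partner_junction}\t{f.partner_junction + 1}\t"
                f"read_{f.read_id}\t.\t{s1}\t{s2}\n"
            )
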