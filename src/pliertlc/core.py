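"""The PLIER statistic: permutation z-scores on smoothed segment-coverage bins.

Per interval width (scale), every genomic bin gets a *proximity frequency* f
(number of restriction segments in the bin covered by >= 1 ligated fragment).
Gaussian smoothing of f along each chromosome gives the *proximity score* p.
Two permutation nulls estimate the expected p and its spread per bin:

* shuffle — f values permuted among all eligible bins genome-wide, then
  smoothed per chromosome;
* swap — only the nonzero f values are permuted among the positions that had
  nonzero f (zero bins stay zero), protecting sparse libraries where the
  shuffle null underestimates the expectation.

The final per-bin z is the minimum of the two null z-scores. On the
viewpoint's own chromosome the strong distance-decay around the probed locus
is first removed: the probed region +- 250 kb is masked, each flank is
smoothed and fitted by isotonic regression constrained non-increasing with
distance from the probed region, and the residual (smoothed - fit) replaces
the proximity score before the same permutation machinery runs.

Bins with z above the selection threshold are merged (< 1 Mb gaps) into
candidate regions whose integrated z is the 90th percentile of member z;
candidates are grouped across scales (< 10 Mb) and a group is emitted only if
every scale contributes. The largest scale's integrated z is the final
*enrichment score*; trans calls are significant at >= 8.0, cis calls at
> 16.0 and only outside +- 3 Mb of the viewpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import convolve1d

from .genome import IntervalGrid, Viewpoint, build_grid
from .tlc_io import SegmentCoverage

log = logging.getLogger(__name__)

DOMAIN_TRANS = 0
DOMAIN_CIS = 1
DOMAIN_MASKED = 2


@dataclass(frozen=True)
class PlierParams:
    """Caller parameters; defaults are the optimum found by parameter sweep."""

    scales: Tuple[int, ...] = (5_000, 75_000)
    sigma: float = 0.75  # Gaussian width, in bin units
    span: int = 31  # kernel footprint, bins (odd)
    n_perm: int = 1000
    z_select: float = 5.0
    merge_dist: int = 1_000_000
    group_dist: int = 10_000_000
    trans_sig: float = 8.0
    cis_sig: float = 16.0
    probed_flank_exclusion: int = 250_000
    cis_call_exclusion: int = 3_000_000
    sd_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.span % 2 != 1 or self.span < 1:
            raise ValueError("span must be odd and >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError("scales must be strictly ascending")
        for name in ("z_select", "trans_sig", "cis_sig", "sd_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# smoothing


def gaussian_kernel(sigma: float, span: int) -> np.ndarray:
    """Discrete Gaussian, truncated at ``span`` bins, renormalized to sum 1."""
    if span % 2 != 1 or span < 1:
        raise ValueError("span must be odd and >= 1")
    half = (span - 1) // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(values: np.ndarray, sigma: float, span: int) -> np.ndarray:
    """Edge-renormalized Gaussian smoothing of one per-chromosome track.

    At chromosome edges the truncated kernel is renormalized over the
    available support, so a constant track stays constant everywhere.
    Accepts a 1-D track or a (rows, bins) matrix smoothed along the last axis.
    """
    k = gaussian_kernel(sigma, span)
    return _smooth_with_kernel(np.asarray(values, dtype=float), k)


def _smooth_with_kernel(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(values)
    num = convolve1d(v, kernel, axis=-1, mode="constant", cval=0.0)
    den = convolve1d(np.ones(v.shape[-1]), kernel, mode="constant", cval=0.0)
    out = num / den
    return out[0] if values.ndim == 1 else out


# ---------------------------------------------------------------------------
# proximity frequency


def proximity_frequency(coverage: SegmentCoverage, grid: IntervalGrid) -> np.ndarray:
    """Covered-segment count per bin (segment assigned to its start's bin)."""
    if coverage.segments.chroms != grid.chroms:
        raise ValueError("coverage and grid use different references")
    f = np.zeros(grid.n_bins, dtype=np.int64)
    segs = coverage.segments
    for i, name in enumerate(grid.chroms.names):
        lo, hi = segs.offsets[i], segs.offsets[i + 1]
        cov = coverage.covered[lo:hi]
        starts = segs.starts(name)[cov]
        if len(starts):
            local = starts // grid.width
            f[grid.chrom_slice(name)] += np.bincount(local, minlength=grid.n_bins_of(name))
    return f


# ---------------------------------------------------------------------------
# permutation nulls


def _accumulate_null(
    values: np.ndarray,
    positions: np.ndarray,
    n_bins: int,
    n_perm: int,
    rng: np.random.Generator,
    statistic: Callable[[np.ndarray], np.ndarray],
    block: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """mu/sd of ``statistic`` over permutations of ``values`` among ``positions``.

    ``statistic`` maps a (rows, n_bins) matrix of permuted f tracks to the
    per-bin statistic (smoothed score, or cis residual). Permutations are
    drawn one at a time from ``rng`` so a naive loop oracle can reproduce the
    stream exactly.
    """
    # block-merged Welford accumulation: exact zero variance when every
    # permutation yields the same statistic (degenerate pools)
    mean = np.zeros(n_bins)
    m2 = np.zeros(n_bins)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        F = np.zeros((b, n_bins))
        for r in range(b):
            F[r, positions] = values[rng.permutation(len(values))]
        stat = statistic(F)
        bmean = stat.mean(axis=0)
        bm2 = ((stat - bmean) ** 2).sum(axis=0)
        delta = bmean - mean
        total = done + b
        mean += delta * (b / total)
        m2 += bm2 + delta * delta * (done * b / total)
        done += b
    return mean, np.sqrt(m2 / n_perm)


def null_shuffle(
    f: np.ndarray,
    pool: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    statistic: Callable[[np.ndarray], np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Shuffle null: all pool values permuted among pool positions."""
    pool = np.asarray(pool)
    if len(pool) == 0:
        raise ValueError("shuffle null needs a non-empty pool")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    return _accumulate_null(np.asarray(f, float)[pool], pool, len(f), n_perm, rng, statistic)


def null_swap(
    f: np.ndarray,
    pool: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    statistic: Callable[[np.ndarray], np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Swap null: only nonzero values permuted among nonzero positions."""
    pool = np.asarray(pool)
    if len(pool) == 0:
        raise ValueError("swap null needs a non-empty pool")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    f = np.asarray(f, float)
    nz = pool[f[pool] > 0]
    if len(nz) == 0:
        log.warning("swap null degenerate: no nonzero bins in pool")
        zeros = np.zeros(len(f))
        return zeros, zeros.copy()
    return _accumulate_null(f[nz], nz, len(f), n_perm, rng, statistic)


def compute_z(
    p: np.ndarray,
    shuffle: Tuple[np.ndarray, np.ndarray],
    swap: Tuple[np.ndarray, np.ndarray],
    sd_floor: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Final z = min of shuffle-z and swap-z; returns (z, floored flags)."""
    mu_sh, sd_sh = shuffle
    mu_sw, sd_sw = swap
    z_sh = (p - mu_sh) / np.maximum(sd_sh, sd_floor)
    z_sw = (p - mu_sw) / np.maximum(sd_sw, sd_floor)
    floored = (sd_sh < sd_floor) | (sd_sw < sd_floor)
    return np.minimum(z_sh, z_sw), floored


# ---------------------------------------------------------------------------
# isotonic background correction (cis)


def isotonic_fit(y: np.ndarray, increasing: bool) -> np.ndarray:
    """Monotone least-squares fit (pool-adjacent-violators)."""
    from sklearn.isotonic import isotonic_regression

    if len(y) == 0:
        return np.asarray(y, dtype=float)
    return isotonic_regression(np.asarray(y, dtype=float), increasing=increasing)


@dataclass
class CisLayout:
    """Bin-level layout of the viewpoint chromosome for cis scoring."""

    mask_lo: int  # first masked bin (probed envelope +- exclusion)
    mask_hi: int  # one past last masked bin
    call_lo: int  # first bin excluded from calling (+- 3 Mb)
    call_hi: int
    n_bins: int

    @property
    def left(self) -> slice:
        return slice(0, self.mask_lo)

    @property
    def right(self) -> slice:
        return slice(self.mask_hi, self.n_bins)

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[self.mask_lo : self.mask_hi] = False
        return np.flatnonzero(keep)

    def callable_mask(self) -> np.ndarray:
        ok = np.ones(self.n_bins, dtype=bool)
        ok[self.call_lo : self.call_hi] = False
        return ok


def cis_layout(viewpoint: Viewpoint, grid: IntervalGrid, params: PlierParams) -> CisLayout:
    L = grid.chroms.length(viewpoint.chrom)
    if viewpoint.end > L or viewpoint.start < 0:
        raise ValueError("viewpoint envelope outside chromosome")
    n = grid.n_bins_of(viewpoint.chrom)
    w = grid.width
    mlo = max(0, (viewpoint.start - params.probed_flank_exclusion) // w)
    mhi = min(n, -(-(viewpoint.end + params.probed_flank_exclusion) // w))
    clo = max(0, (viewpoint.start - params.cis_call_exclusion) // w)
    chi = min(n, -(-(viewpoint.end + params.cis_call_exclusion) // w))
    return CisLayout(int(mlo), int(mhi), int(clo), int(chi), n)


def cis_residual(F: np.ndarray, layout: CisLayout, sigma: float, span: int) -> np.ndarray:
    """Smoothed-minus-isotonic residual per flank; masked bins are zero.

    Each flank runs from the probed edge to its chromosome end; the isotonic
    fit is constrained non-increasing with distance from the probed region.
    Accepts a 1-D track or a (rows, bins) matrix.
    """
    single = F.ndim == 1
    F2 = np.atleast_2d(np.asarray(F, dtype=float))
    out = np.zeros_like(F2)
    kernel = gaussian_kernel(sigma, span)
    for sl, increasing in ((layout.left, True), (layout.right, False)):
        if sl.stop - (sl.start or 0) == 0:
            continue
        sm = _smooth_with_kernel(F2[:, sl], kernel)
        sm = np.atleast_2d(sm)
        for r in range(sm.shape[0]):
            out[r, sl] = sm[r] - isotonic_fit(sm[r], increasing=increasing)
    return out[0] if single else out


def cis_smoothed(F: np.ndarray, layout: CisLayout, sigma: float, span: int) -> np.ndarray:
    """Per-flank smoothing only (no isotonic subtraction); masked bins zero."""
    single = F.ndim == 1
    F2 = np.atleast_2d(np.asarray(F, dtype=float))
    out = np.zeros_like(F2)
    kernel = gaussian_kernel(sigma, span)
    for sl in (layout.left, layout.right):
        if sl.stop - (sl.start or 0) == 0:
            continue
        out[:, sl] = np.atleast_2d(_smooth_with_kernel(F2[:, sl], kernel))
    return out[0] if single else out


# ---------------------------------------------------------------------------
# score tracks


@dataclass
class ScoreTrack:
    """Per-scale arrays over all genome bins (global bin ids)."""

    scale: int
    grid: IntervalGrid
    f: np.ndarray
    p: np.ndarray
    mu_shuffle: np.ndarray
    sd_shuffle: np.ndarray
    mu_swap: np.ndarray
    sd_swap: np.ndarray
    z: np.ndarray
    domain: np.ndarray  # int8: 0 trans, 1 cis, 2 masked
    callable: np.ndarray  # bool: eligible for candidate selection
    floored: np.ndarray  # bool: z computed through the sd floor


@dataclass
class CandidateCall:
    chrom: str
    start: int
    end: int
    scale: int
    bins: List[int]  # selected local bins
    integrated_z: float
    floored: bool = False


@dataclass
class EnrichmentCall:
    sample: str
    viewpoint: str
    chrom: str
    start: int
    end: int
    z_by_scale: Dict[int, float]
    enrichment: float
    kind: str  # "trans" | "cis"
    significant: bool = False
    flags: List[str] = field(default_factory=list)


def _rng_stream(seed: int, scale_index: int, kind: str, cis: bool = False) -> np.random.Generator:
    # dedicated counter-based stream per (seed, scale, null type, domain)
    code = {"shuffle": 1, "swap": 2}[kind]
    ss = np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF, spawn_key=(scale_index, code, int(cis))
    )
    return np.random.Generator(np.random.Philox(ss))


def score_scale(
    coverage: SegmentCoverage,
    viewpoint: Viewpoint,
    scale: int,
    params: PlierParams,
    scale_index: int = 0,
) -> ScoreTrack:
    """Compute the full per-bin z track at one interval width."""
    chroms = coverage.segments.chroms
    grid = build_grid(chroms, scale)
    f = proximity_frequency(coverage, grid).astype(float)
    n = grid.n_bins
    p = np.full(n, np.nan)
    mu_sh = np.full(n, np.nan)
    sd_sh = np.full(n, np.nan)
    mu_sw = np.full(n, np.nan)
    sd_sw = np.full(n, np.nan)
    z = np.full(n, np.nan)
    domain = np.full(n, DOMAIN_TRANS, dtype=np.int8)
    callable_ = np.zeros(n, dtype=bool)
    floored = np.zeros(n, dtype=bool)

    vp_chrom = viewpoint.chrom
    trans_slices = [grid.chrom_slice(c) for c in chroms.names if c != vp_chrom]
    trans_idx = np.concatenate([np.arange(sl.start, sl.stop) for sl in trans_slices]) if trans_slices else np.array([], dtype=int)

    if len(trans_idx):
        kernel = gaussian_kernel(params.sigma, params.span)

        def trans_statistic(F: np.ndarray) -> np.ndarray:
            out = np.zeros_like(F)
            for sl in trans_slices:
                out[:, sl] = np.atleast_2d(_smooth_with_kernel(F[:, sl], kernel))
            return out

        for sl in trans_slices:
            p[sl] = _smooth_with_kernel(f[sl], kernel)
        sh = null_shuffle(f, trans_idx, params.n_perm, _rng_stream(params.seed, scale_index, "shuffle"), trans_statistic)
        sw = null_swap(f, trans_idx, params.n_perm, _rng_stream(params.seed, scale_index, "swap"), trans_statistic)
        zt, fl = compute_z(p, (sh[0], sh[1]), (sw[0], sw[1]), params.sd_floor)
        mu_sh[trans_idx], sd_sh[trans_idx] = sh[0][trans_idx], sh[1][trans_idx]
        mu_sw[trans_idx], sd_sw[trans_idx] = sw[0][trans_idx], sw[1][trans_idx]
        z[trans_idx] = zt[trans_idx]
        floored[trans_idx] = fl[trans_idx]
        callable_[trans_idx] = True

    # --- cis chromosome
    csl = grid.chrom_slice(vp_chrom)
    layout = cis_layout(viewpoint, grid, params)
    f_c = f[csl]
    n_c = layout.n_bins
    domain[csl] = DOMAIN_CIS
    dom_c = domain[csl]
    dom_c[layout.mask_lo : layout.mask_hi] = DOMAIN_MASKED
    unmasked = layout.unmasked()
    if len(unmasked):
        p_c = cis_residual(f_c, layout, params.sigma, params.span)

        def cis_statistic(F: np.ndarray) -> np.ndarray:
            return cis_residual(F, layout, params.sigma, params.span)

        # dedicated counter-based streams for the cis nulls
        rng_sh = _rng_stream(params.seed, scale_index, "shuffle", cis=True)
        rng_sw = _rng_stream(params.seed, scale_index, "swap", cis=True)
        sh = null_shuffle(f_c, unmasked, params.n_perm, rng_sh, cis_statistic)
        sw = null_swap(f_c, unmasked, params.n_perm, rng_sw, cis_statistic)
        zc, fl = compute_z(p_c, sh, sw, params.sd_floor)
        idx = csl.start + unmasked
        p[idx] = p_c[unmasked]
        mu_sh[idx], sd_sh[idx] = sh[0][unmasked], sh[1][unmasked]
        mu_sw[idx], sd_sw[idx] = sw[0][unmasked], sw[1][unmasked]
        z[idx] = zc[unmasked]
        floored[idx] = fl[unmasked]
        call_ok = layout.callable_mask()
        callable_[csl] = call_ok & (dom_c != DOMAIN_MASKED)

    return ScoreTrack(scale, grid, f, p, mu_sh, sd_sh, mu_sw, sd_sw, z, domain, callable_, floored)


# ---------------------------------------------------------------------------
# candidate selection, cross-scale grouping, significance


def integrated_z(values: Sequence[float]) -> float:
    """90th percentile with linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(values, dtype=float), 90, method="linear"))


def candidate_calls(track: ScoreTrack, params: PlierParams) -> List[CandidateCall]:
    """Select z > threshold bins, merge gaps < merge_dist, integrate z."""
    out: List[CandidateCall] = []
    grid = track.grid
    w = grid.width
    for name in grid.chroms.names:
        sl = grid.chrom_slice(name)
        zc = track.z[sl]
        ok = track.callable[sl] & np.isfinite(zc) & (zc > params.z_select)
        sel = np.flatnonzero(ok)
        if len(sel) == 0:
            continue
        # split where the bp gap between consecutive selected bins >= merge_dist
        gaps = (np.diff(sel) - 1) * w
        breaks = np.flatnonzero(gaps >= params.merge_dist)
        groups = np.split(sel, breaks + 1)
        L = grid.chroms.length(name)
        for g in groups:
            start = int(g[0]) * w
            end = min((int(g[-1]) + 1) * w, L)
            iz = integrated_z(zc[g])
            out.append(
                CandidateCall(
                    chrom=name,
                    start=start,
                    end=end,
                    scale=track.scale,
                    bins=[int(b) for b in g],
                    integrated_z=iz,
                    floored=bool(track.floored[sl][g].any()),
                )
            )
    return out


def combine_scales(
    candidates_by_scale: Dict[int, List[CandidateCall]],
    params: PlierParams,
    sample: str = "sample",
    viewpoint: Optional[Viewpoint] = None,
) -> List[EnrichmentCall]:
    """Group candidates across scales (< group_dist); require every scale.

    The enrichment score of a group is the largest scale's integrated z
    (maximum over that scale's members if several fall in one group, with the
    footprint as their union).
    """
    scales = sorted(params.scales)
    if set(candidates_by_scale) != set(scales):
        raise ValueError("candidates must be supplied for every configured scale")
    largest = scales[-1]
    allc: List[CandidateCall] = [c for cands in candidates_by_scale.values() for c in cands]
    out: List[EnrichmentCall] = []
    by_chrom: Dict[str, List[CandidateCall]] = {}
    for c in allc:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cands in by_chrom.items():
        cands = sorted(cands, key=lambda c: (c.start, c.end))
        groups: List[List[CandidateCall]] = []
        cur: List[CandidateCall] = []
        cur_end = -np.inf
        for c in cands:
            if cur and c.start - cur_end >= params.group_dist:
                groups.append(cur)
                cur = []
                cur_end = -np.inf
            cur.append(c)
            cur_end = max(cur_end, c.end)
        if cur:
            groups.append(cur)
        for g in groups:
            present = {c.scale for c in g}
            if present != set(scales):
                continue
            z_by_scale = {s: max(c.integrated_z for c in g if c.scale == s) for s in scales}
            big = [c for c in g if c.scale == largest]
            flags = []
            if len(big) > 1:
                flags.append("multiple_largest_scale_members")
            if any(c.floored for c in g):
                flags.append("sd_floor")
            out.append(
                EnrichmentCall(
                    sample=sample,
                    viewpoint=viewpoint.name if viewpoint else "",
                    chrom=chrom,
                    start=min(c.start for c in big),
                    end=max(c.end for c in big),
                    z_by_scale=z_by_scale,
                    enrichment=z_by_scale[largest],
                    kind="cis" if (viewpoint and chrom == viewpoint.chrom) else "trans",
                    flags=flags,
                )
            )
    return sorted(out, key=lambda c: (c.chrom, c.start))


def significant_calls(calls: List[EnrichmentCall], params: PlierParams) -> List[EnrichmentCall]:
    """Apply class-specific significance thresholds; returns all calls flagged."""
    out = []
    for c in calls:
        sig = c.enrichment >= params.trans_sig if c.kind == "trans" else c.enrichment > params.cis_sig
        out.append(replace(c, significant=bool(sig)))
    return out


@dataclass
class PlierResult:
    sample: str
    viewpoint: Viewpoint
    params: PlierParams
    tracks: Dict[int, ScoreTrack]
    candidates: Dict[int, List[CandidateCall]]
    calls: List[EnrichmentCall]

    @property
    def significant(self) -> List[EnrichmentCall]:
        return [c for c in self.calls if c.significant]


def call_rearrangements(
    coverage: SegmentCoverage,
    viewpoint: Viewpoint,
    params: Optional[PlierParams] = None,
    sample: str = "sample",
) -> PlierResult:
    """Run the full per-viewpoint caller on one coverage profile."""
    params = params or PlierParams()
    tracks: Dict[int, ScoreTrack] = {}
    cands: Dict[int, List[CandidateCall]] = {}
    for i, scale in enumerate(sorted(params.scales)):
        tr = score_scale(coverage, viewpoint, scale, params, scale_index=i)
        tracks[scale] = tr
        cands[scale] = candidate_calls(tr, params)
    calls = combine_scales(cands, params, sample=sample, viewpoint=viewpoint)
    calls = significant_calls(calls, params)
    return PlierResult(sample, viewpoint, params, tracks, cands, calls)
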