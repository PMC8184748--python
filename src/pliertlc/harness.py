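"""Re-enactments of the sensitivity/specificity experimental designs.

These harness functions reproduce, on synthetic libraries, the designs used
to characterize the caller on real material: dilution titrations of a
rearranged sample into control material, read-depth downsampling, negative
controls, and detection-power curves over rearranged-cell fractions. A
detection is counted only when the planted partner is called AND no
false-positive call appears anywhere in the genome — any extra call voids
the repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import PlierParams, PlierResult, call_rearrangements
from .genome import SegmentIndex, digest_reference
from .simulate import (
    SimulationConfig,
    TruthSet,
    default_translocation,
    make_reference,
    mix,
    simulate_sample,
)
from .tlc_io import ReadSet, downsample, segment_coverage


@dataclass
class Study:
    """A reference plus matched positive/control libraries, ready to mix."""

    config: SimulationConfig
    sequences: Dict[str, str]
    segments: SegmentIndex
    positive: ReadSet
    positive_truth: TruthSet
    control: ReadSet


def build_study(
    seed: int,
    library_reads: int = 1_300_000,
    positive_fraction: float = 0.5,
    config: Optional[SimulationConfig] = None,
) -> Study:
    """Simulate the titration source material.

    One positive library (reciprocal translocation present in
    ``positive_fraction`` of cells) and one matched control from the same
    reference and probe panel, each of ``library_reads`` on-target reads.
    """
    base = config or SimulationConfig()
    sequences, _ = make_reference(
        dict(base.chromosome_lengths), base.target_median_segment, base.motif, seed=seed
    )
    segments = digest_reference(sequences, base.motif)
    pos_cfg = replace(
        base,
        rearrangements=(default_translocation(),) if not base.rearrangements else base.rearrangements,
        rearranged_fraction=positive_fraction,
        n_reads=library_reads,
        sample_id="positive",
        seed=seed + 1,
    )
    ctl_cfg = replace(
        base, rearrangements=(), rearranged_fraction=0.0, n_reads=library_reads,
        sample_id="control", seed=seed + 2,
    )
    positive, truth = simulate_sample(pos_cfg, sequences=sequences, segments=segments)
    control, _ = simulate_sample(ctl_cfg, sequences=sequences, segments=segments)
    return Study(pos_cfg, sequences, segments, positive, truth, control)


def detect(
    readset: ReadSet, study: Study, params: PlierParams
) -> Tuple[bool, int, PlierResult]:
    """Run the caller; return (partner called, n extra significant calls, result)."""
    vp = study.config.viewpoints[0]
    cov = segment_coverage(readset.mapped(0), study.segments)
    result = call_rearrangements(cov, vp, params, sample=readset.sample_id)
    regions = study.positive_truth.partner_regions(vp.name)
    hit = False
    extra = 0
    for c in result.significant:
        if any(c.chrom == r[0] and c.start < r[2] and c.end > r[1] for r in regions):
            hit = True
        else:
            extra += 1
    return hit, extra, result


def titration(
    study: Study,
    params: PlierParams,
    fractions: Sequence[float] = (0.05, 0.01, 0.002),
    replicates: int = 3,
    n_reads: int = 1_000_000,
    seed: int = 0,
) -> List[dict]:
    """Dilute the positive library to the target rearranged-cell fractions.

    ``fractions`` are rearranged-cell fractions of the mixture; the share of
    positive-library reads is fraction / positive_fraction.
    """
    out = []
    pos_frac = study.positive_truth.rearranged_fraction
    for frac in fractions:
        for rep in range(replicates):
            mseed = (seed * 1000 + int(frac * 10_000) + rep) % (2**31)
            mixed, labels = mix(
                study.positive, study.control, frac / pos_frac, n_reads,
                seed=mseed, positive_truth=study.positive_truth,
            )
            hit, extra, _ = detect(mixed, study, params)
            out.append(
                {
                    "fraction": frac,
                    "replicate": rep,
                    "n_reads": n_reads,
                    "n_rearranged_reads": int(labels.sum()),
                    "partner_called": hit,
                    "extra_calls": extra,
                    "success": hit and extra == 0,
                }
            )
    return out


def lowest_detected_fraction(results: Sequence[dict]) -> Optional[float]:
    """Smallest titration fraction at which every replicate succeeded."""
    by_frac: Dict[float, List[bool]] = {}
    for r in results:
        by_frac.setdefault(r["fraction"], []).append(r["success"])
    ok = [f for f, succ in by_frac.items() if all(succ)]
    return min(ok) if ok else None


def downsampling(
    study: Study,
    params: PlierParams,
    readset: ReadSet,
    depth: int,
    repeats: int = 20,
    seed: int = 0,
) -> List[dict]:
    """Repeated random draws at a fixed depth; success as in the titration."""
    out = []
    for rep in range(repeats):
        sub = downsample(readset, depth, seed=(seed * 100 + rep) % (2**31))
        hit, extra, _ = detect(sub, study, params)
        out.append(
            {"depth": depth, "repeat": rep, "partner_called": hit,
             "extra_calls": extra, "success": hit and extra == 0}
        )
    return out


def specificity(
    params: PlierParams,
    n_samples: int = 20,
    n_reads: int = 400_000,
    sparsities: Sequence[float] = (0.3, 0.5, 0.7),
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> List[dict]:
    """Negative samples at varying FFPE sparsity; counts significant calls."""
    base = config or SimulationConfig()
    sequences, _ = make_reference(
        dict(base.chromosome_lengths), base.target_median_segment, base.motif, seed=seed
    )
    segments = digest_reference(sequences, base.motif)
    vp = base.viewpoints[0]
    out = []
    for i in range(n_samples):
        cfg = replace(
            base, rearrangements=(), rearranged_fraction=0.0, n_reads=n_reads,
            sparsity=sparsities[i % len(sparsities)], sample_id=f"neg{i}",
            seed=(seed * 1000 + 17 * i + 3) % (2**31),
        )
        rs, _ = simulate_sample(cfg, sequences=sequences, segments=segments)
        cov = segment_coverage(rs.mapped(0), segments)
        res = call_rearrangements(cov, vp, params, sample=cfg.sample_id)
        out.append(
            {"sample": cfg.sample_id, "sparsity": cfg.sparsity,
             "n_significant": len(res.significant)}
        )
    return out


def power_curve(
    params: PlierParams,
    fractions: Sequence[float] = (0.0, 0.002, 0.01, 0.05, 0.5),
    n_seeds: int = 10,
    n_reads: int = 300_000,
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> Dict[float, float]:
    """Detection probability per rearranged-cell fraction (simulated directly)."""
    base = config or SimulationConfig()
    sequences, _ = make_reference(
        dict(base.chromosome_lengths), base.target_median_segment, base.motif, seed=seed
    )
    segments = digest_reference(sequences, base.motif)
    vp = base.viewpoints[0]
    rear = (default_translocation(),)
    truth = TruthSet(
        sample_id="power", rearrangements=rear, rearranged_fraction=0.0, seed=seed,
        read_from_rearranged_cell=np.zeros(0, dtype=bool),
    )
    regions = truth.partner_regions(vp.name)
    out: Dict[float, float] = {}
    for frac in fractions:
        hits = 0
        for s in range(n_seeds):
            cfg = replace(
                base, rearrangements=rear if frac > 0 else (),
                rearranged_fraction=frac, n_reads=n_reads,
                seed=(seed * 10_000 + int(frac * 100_000) + s) % (2**31),
            )
            rs, _ = simulate_sample(cfg, sequences=sequences, segments=segments)
            cov = segment_coverage(rs.mapped(0), segments)
            res = call_rearrangements(cov, vp, params)
            hit = any(
                c.chrom == r[0] and c.start < r[2] and c.end > r[1]
                for c in res.significant
                for r in regions
            )
            extra = sum(
                1
                for c in res.significant
                if not any(c.chrom == r[0] and c.start < r[2] and c.end > r[1] for r in regions)
            )
            hits += int(hit and extra == 0)
        out[frac] = hits / n_seeds
    return out
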