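"""End-to-end orchestration: digest -> demultiplex -> call -> post-process -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .core import EnrichmentCall, PlierParams, PlierResult, call_rearrangements
from .genome import SegmentIndex, Viewpoint, digest_fasta, read_viewpoints_bed
from .postprocess import (
    AmplificationEvent,
    FusionRead,
    Region,
    apply_blacklist,
    detect_amplifications,
    find_fusion_reads,
    load_default_blacklist,
    write_fusion_bedpe,
)
from .tlc_io import ReadSet, demultiplex, parse_alignments, segment_coverage

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reference: str
    alignments: str
    viewpoints: str
    output_dir: str
    sample_id: str = "sample"
    motif: str = "CATG"
    params: PlierParams = field(default_factory=PlierParams)
    blacklist_path: Optional[str] = None
    use_default_blacklist: bool = False
    primary_viewpoints: Tuple[str, ...] = ()
    igh_region: Optional[Region] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        pr = raw.pop("params", {})
        if isinstance(pr, dict):
            if "scales" in pr:
                pr["scales"] = tuple(pr["scales"])
            raw["params"] = PlierParams(**pr)
        if raw.get("igh_region"):
            raw["igh_region"] = tuple(raw["igh_region"])
        if raw.get("primary_viewpoints"):
            raw["primary_viewpoints"] = tuple(raw["primary_viewpoints"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.reference, self.alignments, self.viewpoints):
            if not os.path.exists(p):
                raise FileNotFoundError(p)


@dataclass
class RearrangementReport:
    sample: str
    calls: List[EnrichmentCall]  # retained calls, significance flagged
    removed: List[EnrichmentCall]  # blacklisted
    amplifications: List[AmplificationEvent]
    fusion_reads: Dict[str, List[FusionRead]]  # keyed by call id string
    counters: Dict[str, object] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def significant(self) -> List[EnrichmentCall]:
        return [c for c in self.calls if c.significant]

    def to_dict(self) -> Dict[str, object]:
        def call_d(c: EnrichmentCall) -> Dict[str, object]:
            d = dataclasses.asdict(c)
            d["z_by_scale"] = {str(k): v for k, v in c.z_by_scale.items()}
            return d

        return {
            "sample": self.sample,
            "calls": [call_d(c) for c in self.calls],
            "removed": [call_d(c) for c in self.removed],
            "amplifications": [dataclasses.asdict(a) for a in self.amplifications],
            "fusion_reads": {
                k: [dataclasses.asdict(f) for f in v] for k, v in self.fusion_reads.items()
            },
            "counters": self.counters,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "RearrangementReport":
        def mk_call(cd: dict) -> EnrichmentCall:
            cd = dict(cd)
            cd["z_by_scale"] = {int(k): v for k, v in cd["z_by_scale"].items()}
            return EnrichmentCall(**cd)

        return cls(
            sample=d["sample"],
            calls=[mk_call(c) for c in d["calls"]],
            removed=[mk_call(c) for c in d["removed"]],
            amplifications=[AmplificationEvent(**a) for a in d["amplifications"]],
            fusion_reads={
                k: [FusionRead(**{**f, "orientation": tuple(f["orientation"])}) for f in v]
                for k, v in d["fusion_reads"].items()
            },
            counters=d.get("counters", {}),
            provenance=d.get("provenance", {}),
        )


def call_id(c: EnrichmentCall) -> str:
    return f"{c.viewpoint}:{c.chrom}:{c.start}-{c.end}"


def run_on_datasets(
    segments: SegmentIndex,
    readsets: Dict[str, Tuple[Viewpoint, ReadSet]],
    params: PlierParams,
    sample_id: str = "sample",
    blacklist: Optional[Dict[str, Sequence[Region]]] = None,
    primary_viewpoints: Sequence[str] = (),
    igh_region: Optional[Region] = None,
    counters: Optional[Dict[str, object]] = None,
) -> Tuple[RearrangementReport, Dict[str, PlierResult]]:
    """Caller + post-processing on already-demultiplexed in-memory read sets."""
    results: Dict[str, PlierResult] = {}
    all_calls: List[EnrichmentCall] = []
    for name, (vp, rs) in readsets.items():
        cov = segment_coverage(rs.mapped(0), segments)
        res = call_rearrangements(cov, vp, params, sample=sample_id)
        results[name] = res
        all_calls.extend(res.calls)
    if blacklist:
        retained, removed = apply_blacklist(all_calls, blacklist)
    else:
        retained, removed = list(all_calls), []
    by_vp: Dict[str, List[EnrichmentCall]] = {}
    for c in retained:
        by_vp.setdefault(c.viewpoint, []).append(c)
    amps = detect_amplifications(by_vp, primary_viewpoints or list(readsets), igh_region)
    fusions: Dict[str, List[FusionRead]] = {}
    for name, (vp, rs) in readsets.items():
        for c in by_vp.get(name, []):
            if c.significant:
                fusions[call_id(c)] = find_fusion_reads(rs.mapped(0), c, vp, segments)
    report = RearrangementReport(
        sample=sample_id,
        calls=sorted(retained, key=lambda c: (c.viewpoint, c.chrom, c.start)),
        removed=removed,
        amplifications=amps,
        fusion_reads=fusions,
        counters=counters or {},
        provenance={
            "version": __version__,
            "params": dataclasses.asdict(params),
            "sample": sample_id,
        },
    )
    return report, results


def run_pipeline(config: RunConfig) -> RearrangementReport:
    """Full file-based pipeline; writes the report into ``config.output_dir``."""
    config.validate_paths()
    os.makedirs(config.output_dir, exist_ok=True)
    log.info("stage=digest reference=%s", config.reference)
    segments = digest_fasta(config.reference, config.motif)
    viewpoints = read_viewpoints_bed(config.viewpoints)
    log.info("stage=parse alignments=%s", config.alignments)
    reads = parse_alignments(config.alignments, chroms=segments.chroms)
    log.info("stage=demultiplex n_reads=%d", reads.n_reads)
    per_vp, counters = demultiplex(reads, viewpoints)
    blacklist = None
    igh = config.igh_region
    if config.blacklist_path:
        import yaml

        with open(config.blacklist_path) as fh:
            raw = yaml.safe_load(fh)
        blacklist = {vp: [tuple(r) for r in regions] for vp, regions in raw["blacklist"].items()}
        if igh is None and raw.get("igh_region"):
            igh = tuple(raw["igh_region"])
    elif config.use_default_blacklist:
        blacklist, default_igh = load_default_blacklist()
        igh = igh or default_igh
    report, results = run_on_datasets(
        segments,
        {vp.name: (vp, per_vp[vp.name]) for vp in viewpoints},
        config.params,
        sample_id=config.sample_id,
        blacklist=blacklist,
        primary_viewpoints=config.primary_viewpoints,
        igh_region=igh,
        counters=counters,
    )
    report.provenance["config"] = {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    write_report(report, config.output_dir)
    return report


def write_report(report: RearrangementReport, outdir: str) -> List[str]:
    """TSV call table, BED footprints, BEDPE fusions, JSON provenance."""
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    written: List[str] = []

    rows = []
    for c in report.calls:
        row = {
            "sample": c.sample,
            "viewpoint": c.viewpoint,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "class": c.kind,
            "enrichment": c.enrichment,
            "significant": c.significant,
            "flags": ",".join(c.flags),
        }
        for s, z in sorted(c.z_by_scale.items()):
            row[f"z_{s}"] = z
        rows.append(row)
    cols = ["sample", "viewpoint", "chrom", "start", "end", "class", "enrichment", "significant", "flags"]
    table = pd.DataFrame(rows)
    if rows:
        extra = [c for c in table.columns if c not in cols]
        table = table[cols + sorted(extra)]
    else:
        table = pd.DataFrame(columns=cols)
    p = os.path.join(outdir, "calls.tsv")
    table.to_csv(p, sep="\t", index=False)
    written.append(p)

    p = os.path.join(outdir, "calls.bed")
    with open(p, "w") as fh:
        for c in report.significant:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.viewpoint}\t{c.enrichment:.2f}\n")
    written.append(p)

    p = os.path.join(outdir, "amplifications.bed")
    with open(p, "w") as fh:
        for a in report.amplifications:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{'+'.join(a.viewpoints)}\n")
    written.append(p)

    all_fusions = [f for v in report.fusion_reads.values() for f in v]
    p = os.path.join(outdir, "fusions.bedpe")
    write_fusion_bedpe(all_fusions, p)
    written.append(p)

    p = os.path.join(outdir, "report.json")
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default)
    written.append(p)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def write_bedgraph(track, chrom_names: Optional[Sequence[str]] = None, path: str = "track.bedgraph") -> None:
    """Export a per-scale z track as bedGraph."""
    grid = track.grid
    with open(path, "w") as fh:
        for name in chrom_names or grid.chroms.names:
            sl = grid.chrom_slice(name)
            z = track.z[sl]
            for i, v in enumerate(z):
                if np.isfinite(v):
                    s, e = grid.bin_bounds(name, i)
                    fh.write(f"{name}\t{s}\t{e}\t{v:.4f}\n")
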