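"""Depth profiling, low-coverage discovery, sample QC gate, cohort sharing."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align import AlignedRead
from .call import VariantSet
from .panel import GenomicInterval, Panel


@dataclass
class DepthProfile:
    """Per-base depth arrays over target intervals."""

    depths: dict[GenomicInterval, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for iv, arr in self.depths.items():
            if len(arr) != len(iv):
                raise ValueError(f"depth array length {len(arr)} != interval {iv}")
            if (np.asarray(arr) < 0).any():
                raise ValueError("negative depth")


@dataclass
class SampleStats:
    sample_id: str
    total_reads: int
    mean_base_quality: float
    uncovered_region_count: int


def depth_profile(reads: Iterable[AlignedRead], panel: Panel,
                  include_primers: bool = False) -> DepthProfile:
    """Depth of aligned (M or D) bases per target position."""
    targets = panel.target_intervals(include_primers=include_primers)
    arrays = {iv: np.zeros(len(iv), dtype=np.int64) for iv in targets}
    for read in reads:
        t = read.ref_start
        for op, n in read.ops:
            if op in ("M", "D"):
                for iv, arr in arrays.items():
                    if iv.chrom != read.chrom:
                        continue
                    lo = max(t, iv.start)
                    hi = min(t + n, iv.end)
                    if lo < hi:
                        arr[lo - iv.start : hi - iv.start] += 1
                t += n
    return DepthProfile(arrays)


def low_coverage_regions(profile: DepthProfile, threshold: int = 30) -> list[GenomicInterval]:
    """Maximal runs of consecutive target bases with depth strictly below
    the threshold, as half-open genomic intervals."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out: list[GenomicInterval] = []
    for iv in sorted(profile.depths):
        arr = np.asarray(profile.depths[iv])
        low = arr < threshold
        if not low.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(iv.chrom, iv.start + int(s), iv.start + int(e)))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def qc_gate(
    stats: list[SampleStats],
    quality_fraction: float = 0.30,
    reads_fraction: float = 0.10,
    reference_fraction: float = 0.20,
    interpretation: str = "literal",
) -> dict:
    """Apply the cohort sample-exclusion rule.

    The reference quality and read count are the means over the best
    ``ceil(reference_fraction * n)`` samples — those with the fewest
    uncovered regions (ties broken by sample id).  With the default
    ``literal`` interpretation a sample is excluded iff its mean base
    quality is below ``quality_fraction`` of the reference quality OR its
    read count is below ``reads_fraction`` of the reference count.  The
    alternative ``relative_drop`` interpretation excludes on a relative
    drop instead (value < (1 - fraction) * reference).
    """
    if not stats:
        raise ValueError("qc_gate requires at least one sample")
    if interpretation not in ("literal", "relative_drop"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    n_ref = math.ceil(reference_fraction * len(stats))
    best = sorted(stats, key=lambda s: (s.uncovered_region_count, s.sample_id))[:n_ref]
    ref_quality = float(np.mean([s.mean_base_quality for s in best]))
    ref_reads = float(np.mean([s.total_reads for s in best]))
    if interpretation == "literal":
        q_cut = quality_fraction * ref_quality
        r_cut = reads_fraction * ref_reads
    else:
        q_cut = (1 - quality_fraction) * ref_quality
        r_cut = (1 - reads_fraction) * ref_reads
    included, excluded = [], []
    for s in stats:
        reasons = []
        if s.mean_base_quality < q_cut:
            reasons.append("quality")
        if s.total_reads < r_cut:
            reasons.append("reads")
        if reasons:
            excluded.append((s, reasons))
        else:
            included.append(s)
    return {
        "included": included,
        "excluded": excluded,
        "reference_quality": ref_quality,
        "reference_reads": ref_reads,
    }


_BUCKETS = ("<50%", "50-80%", ">=80%")


def cohort_sharing(sets: Mapping[str, VariantSet]) -> dict:
    """Per-variant sharing fraction across samples, bucketed.

    Buckets: [0, 0.5) — unique/candidate variants; [0.5, 0.8); [0.8, 1]
    — likely systematic.  Fractions are sample counts over total samples.
    """
    if not sets:
        raise ValueError("cohort_sharing requires at least one sample")
    n = len(sets)
    counts: dict[tuple, int] = {}
    for vs in sets.values():
        for key in vs.keys():
            counts[key] = counts.get(key, 0) + 1
    fractions = {key: c / n for key, c in counts.items()}
    buckets = {b: [] for b in _BUCKETS}
    for key, frac in sorted(fractions.items()):
        if frac < 0.5:
            buckets["<50%"].append(key)
        elif frac < 0.8:
            buckets["50-80%"].append(key)
        else:
            buckets[">=80%"].append(key)
    return {"fractions": fractions, "buckets": buckets}


def sharing_report(sharing: dict) -> pd.DataFrame:
    rows = [
        (f"{chrom}:{pos + 1}:{ref}>{alt}", frac)
        for (chrom, pos, ref, alt), frac in sorted(sharing["fractions"].items())
    ]
    return pd.DataFrame(rows, columns=["variant", "sharing_fraction"])
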