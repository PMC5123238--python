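"""Two-step ADO-aware pipeline and single-round baselines.

Round 1 trims primers, aligns and calls variants.  Any round-1 variant whose
reference span intersects a primer footprint marks that amplicon as
ADO-suspect: all of its read pairs are removed and a second align/call round
runs on the remainder, recovering alleles hidden by drop-out-biased
amplicons.  The two call sets are merged with round-1 precedence.

The single-round entry point emulates simpler workflows: ``softclip``
(primer identification + soft-clipped alignment + one calling pass, the
MiSeq Custom Amplicon behaviour), ``trimmed`` (round 1 only), and
``untrimmed`` (raw reads aligned with primer bases feeding the pileup —
the naive approach that dilutes primer-footprint alleles below calling
thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .align import AlignedRead, AlignmentCache, AlignParams, align_pairs
from .call import (
    CallParams,
    VariantCall,
    VariantSet,
    build_pileup,
    call_variants,
    merge_variant_sets,
)
from .panel import GenomicInterval, Panel
from .trim import ReadPair, TrimmedReadPair, TrimStats, trim_pairs


@dataclass
class PipelineResult:
    step1_variants: VariantSet
    step2_variants: VariantSet
    merged: VariantSet
    affected_amplicons: set[str]
    removed_pairs: int
    stats: dict = field(default_factory=dict)


def _variant_span(call: VariantCall) -> GenomicInterval:
    if call.kind == "INS":
        return GenomicInterval(call.chrom, call.pos, call.pos + 1)  # anchor base
    return GenomicInterval(call.chrom, call.pos, call.pos + len(call.ref))


def variants_in_primer_regions(
    vs: VariantSet, panel: Panel
) -> dict[tuple, set[str]]:
    """Map each variant key to the amplicons whose primer footprint it hits.

    A variant affects an amplicon iff its reference span intersects the
    amplicon's ULSO or DLSO genomic footprint (half-open intersection).
    Only variants hitting at least one footprint appear in the result.
    """
    out: dict[tuple, set[str]] = {}
    for call in vs:
        span = _variant_span(call)
        hit = {
            amp.id
            for amp in panel.amplicons
            if span.overlaps(amp.ulso_footprint) or span.overlaps(amp.dlso_footprint)
        }
        if hit:
            out[call.key] = hit
    return out


def remove_affected_reads(
    pairs: Iterable[TrimmedReadPair], affected: set[str]
) -> tuple[list[TrimmedReadPair], int]:
    """Drop every pair assigned to an ADO-suspect amplicon."""
    pairs = list(pairs)
    kept = [p for p in pairs if p.amplicon_id not in affected]
    return kept, len(pairs) - len(kept)


def _mean_target_depth(reads: list[AlignedRead], panel: Panel) -> float:
    targets = panel.target_intervals(include_primers=False)
    total_bases = sum(len(iv) for iv in targets)
    if not total_bases:
        return 0.0
    covered = 0
    for read in reads:
        t = read.ref_start
        for op, n in read.ops:
            if op == "M":
                for iv in targets:
                    if iv.chrom == read.chrom:
                        covered += max(0, min(t + n, iv.end) - max(t, iv.start))
                t += n
            elif op == "D":
                t += n
    return covered / total_bases


def run_two_step(
    pairs: Iterable[ReadPair],
    panel: Panel,
    align_params: AlignParams | None = None,
    call_params: CallParams | None = None,
) -> PipelineResult:
    """Run the two-round trim → align → call → remove → re-call → merge pipeline.

    Exactly one removal round is executed; when round 1 finds no variant in
    any primer footprint, round 2 is skipped and ``merged == step1``.
    """
    align_params = align_params or AlignParams()
    call_params = call_params or CallParams()
    cache = AlignmentCache()

    trimmed, trim_stats = trim_pairs(pairs, panel)
    aligned1, unaligned1 = align_pairs(trimmed, panel, align_params, "trimmed", cache=cache)
    columns1 = build_pileup(aligned1, panel)
    step1 = call_variants(columns1, call_params, panel, step=1)

    footprint_hits = variants_in_primer_regions(step1, panel)
    affected: set[str] = set().union(*footprint_hits.values()) if footprint_hits else set()

    stats = {
        "trim": trim_stats,
        "unaligned_step1": unaligned1,
        "mean_depth_step1": _mean_target_depth(aligned1, panel),
        "footprint_variants": sorted(footprint_hits),
    }

    if affected:
        kept, removed = remove_affected_reads(trimmed, affected)
        # alignment is deterministic per (read, amplicon): reuse round-1 placements
        aligned2 = [r for r in aligned1 if r.amplicon_id not in affected]
        columns2 = build_pileup(aligned2, panel)
        step2 = call_variants(columns2, call_params, panel, step=2)
        merged = merge_variant_sets(step1, step2)
        stats["mean_depth_step2"] = _mean_target_depth(aligned2, panel)
        stats["uncovered_after_removal_bp"] = _uncovered_bases(columns1, columns2)
    else:
        removed = 0
        step2 = VariantSet()
        merged = merge_variant_sets(step1, step2)

    return PipelineResult(
        step1_variants=step1,
        step2_variants=step2,
        merged=merged,
        affected_amplicons=affected,
        removed_pairs=removed,
        stats=stats,
    )


def _uncovered_bases(columns1, columns2) -> int:
    """Target bases covered in round 1 that lost all coverage in round 2."""
    cov1 = {(c.chrom, c.pos) for c in columns1 if c.depth > 0}
    cov2 = {(c.chrom, c.pos) for c in columns2 if c.depth > 0}
    return len(cov1 - cov2)


def run_single_round(
    pairs: Iterable[ReadPair],
    panel: Panel,
    align_params: AlignParams | None = None,
    call_params: CallParams | None = None,
    mode: str = "softclip",
) -> VariantSet:
    """One primer-identification + alignment + calling pass.

    ``softclip`` keeps primer bases as soft-clips (excluded from pileup);
    ``trimmed`` removes them; ``untrimmed`` lets them feed the pileup.
    """
    if mode not in ("softclip", "trimmed", "untrimmed"):
        raise ValueError(f"unknown single-round mode {mode!r}")
    align_params = align_params or AlignParams()
    call_params = call_params or CallParams()
    pairs = list(pairs)
    trimmed, _ = trim_pairs(pairs, panel)
    originals = {p.id: p for p in pairs} if mode != "trimmed" else None
    aligned, _ = align_pairs(
        trimmed, panel, align_params,
        mode="trimmed" if mode == "trimmed" else mode,
        originals=originals,
        cache=AlignmentCache(),
    )
    columns = build_pileup(aligned, panel)
    return call_variants(columns, call_params, panel, step=1)
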