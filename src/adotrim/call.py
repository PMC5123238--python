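"""Pileup construction and allele-fraction variant calling.

The caller is deliberately simple and deterministic: a site is called when
its depth, alternate-allele count and alternate-allele fraction clear fixed
thresholds.  The default minimum fraction of 0.25 mirrors the allele
balance below which mainstream callers tend to drop heterozygous sites
(the false-homozygosity regime that allele drop-out produces), and the
depth floor of 30 matches the usual low-coverage cutoff for amplicon
panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .align import AlignedRead
from .errors import VcfParseError
from .panel import Panel

_KIND_ORDER = {"SNV": 0, "INS": 1, "DEL": 2}


@dataclass(frozen=True)
class CallParams:
    min_alt_fraction: float = 0.25
    hom_fraction: float = 0.75
    min_depth: int = 30
    min_alt_count: int = 5

    def __post_init__(self):
        if not (0 < self.min_alt_fraction <= self.hom_fraction <= 1):
            raise ValueError("require 0 < min_alt_fraction <= hom_fraction <= 1")


@dataclass
class PileupColumn:
    chrom: str
    pos: int                      # 0-based
    ref_base: str
    base_counts: dict[str, int] = field(default_factory=dict)
    ins_counts: dict[str, int] = field(default_factory=dict)   # anchored after pos
    del_counts: dict[int, int] = field(default_factory=dict)   # deletions spanning pos
    del_starts: dict[int, int] = field(default_factory=dict)   # deletions starting at pos

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + sum(self.del_counts.values())


@dataclass
class VariantCall:
    chrom: str
    pos: int                      # 0-based position of the first ref base
    ref: str
    alt: str
    kind: str                     # SNV | INS | DEL
    genotype: str                 # het | hom
    alt_fraction: float
    depth: int
    step: int = 1
    in_both: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """Collection of variant calls keyed by (chrom, pos, ref, alt)."""

    def __init__(self, calls: Iterable[VariantCall] = ()):
        self._calls: dict[tuple, VariantCall] = {}
        for c in calls:
            self.add(c)

    def add(self, call: VariantCall) -> None:
        if call.key in self._calls:
            raise ValueError(f"duplicate variant key {call.key}")
        self._calls[call.key] = call

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(sorted(self._calls.values(), key=lambda c: c.key))

    def __len__(self) -> int:
        return len(self._calls)

    def __contains__(self, key) -> bool:
        if isinstance(key, VariantCall):
            key = key.key
        return key in self._calls

    def get(self, key) -> VariantCall | None:
        return self._calls.get(key)

    def keys(self) -> set[tuple]:
        return set(self._calls)

    def __eq__(self, other) -> bool:
        return isinstance(other, VariantSet) and self.keys() == other.keys()


def build_pileup(
    reads: Iterable[AlignedRead],
    panel: Panel,
    include_primers: bool = True,
) -> list[PileupColumn]:
    """Tally bases and indels per target position from aligned reads.

    Soft-clipped bases contribute nothing.  Deleted reference bases count
    toward depth at every deleted column; inserted bases are anchored after
    the preceding reference base and do not add depth.
    """
    targets = panel.target_intervals(include_primers=include_primers)
    base_arrays: dict[str, np.ndarray] = {}
    for chrom, seq in panel.reference.items():
        base_arrays[chrom] = np.zeros((5, len(seq)), dtype=np.int64)
    code = {c: i for i, c in enumerate("ACGTN")}
    idx_chunks: dict[str, list[np.ndarray]] = {c: [] for c in base_arrays}
    code_chunks: dict[str, list[np.ndarray]] = {c: [] for c in base_arrays}
    ins_events: dict[tuple[str, int], dict[str, int]] = {}
    del_span: dict[tuple[str, int], dict[int, int]] = {}
    del_start: dict[tuple[str, int], dict[int, int]] = {}

    for read in reads:
        t = read.ref_start
        q = 0
        for op, n in read.ops:
            if op == "M":
                seg = np.frombuffer(read.seq[q : q + n].encode(), dtype=np.uint8)
                codes = np.empty(n, dtype=np.int64)
                for b, i in code.items():
                    codes[seg == ord(b)] = i
                idx_chunks[read.chrom].append(np.arange(t, t + n))
                code_chunks[read.chrom].append(codes)
                t += n
                q += n
            elif op == "S":
                q += n
            elif op == "I":
                anchor = t - 1
                d = ins_events.setdefault((read.chrom, anchor), {})
                ins = read.seq[q : q + n]
                d[ins] = d.get(ins, 0) + 1
                q += n
            elif op == "D":
                ds = del_start.setdefault((read.chrom, t), {})
                ds[n] = ds.get(n, 0) + 1
                for p in range(t, t + n):
                    dd = del_span.setdefault((read.chrom, p), {})
                    dd[n] = dd.get(n, 0) + 1
                t += n
            else:  # pragma: no cover
                raise ValueError(f"unexpected op {op!r}")

    for chrom in base_arrays:
        if idx_chunks[chrom]:
            np.add.at(
                base_arrays[chrom],
                (np.concatenate(code_chunks[chrom]), np.concatenate(idx_chunks[chrom])),
                1,
            )

    columns: list[PileupColumn] = []
    for iv in targets:
        arr = base_arrays[iv.chrom]
        ref = panel.reference[iv.chrom]
        for pos in range(iv.start, iv.end):
            counts = {b: int(arr[i, pos]) for b, i in code.items() if arr[i, pos]}
            ins = ins_events.get((iv.chrom, pos), {})
            spans = del_span.get((iv.chrom, pos), {})
            starts = del_start.get((iv.chrom, pos), {})
            if not counts and not spans and not ins:
                continue
            columns.append(
                PileupColumn(
                    chrom=iv.chrom,
                    pos=pos,
                    ref_base=ref[pos],
                    base_counts=counts,
                    ins_counts=dict(ins),
                    del_counts=dict(spans),
                    del_starts=dict(starts),
                )
            )
    return columns


def call_variants(
    columns: Iterable[PileupColumn],
    params: CallParams | None = None,
    panel: Panel | None = None,
    step: int = 1,
) -> VariantSet:
    """Call at most one alternate allele per site from pileup columns.

    A site yields a call iff depth >= min_depth and some non-reference
    allele (base, insertion or deletion) reaches min_alt_count reads and
    min_alt_fraction of depth.  Fractions at or above hom_fraction are
    classified homozygous.  ``panel`` supplies reference context for indel
    allele strings; it is only needed when indels can occur.
    """
    if params is None:
        params = CallParams()
    out = VariantSet()
    for col in columns:
        depth = col.depth
        if depth < params.min_depth:
            continue
        ref_seq = panel.reference[col.chrom] if panel is not None else None
        candidates: list[tuple[int, int, VariantCall]] = []
        for base, count in col.base_counts.items():
            if base == col.ref_base or base == "N":
                continue
            candidates.append(
                (count, _KIND_ORDER["SNV"],
                 VariantCall(col.chrom, col.pos, col.ref_base, base, "SNV",
                             "het", count / depth, depth, step))
            )
        for ins_seq, count in col.ins_counts.items():
            candidates.append(
                (count, _KIND_ORDER["INS"],
                 VariantCall(col.chrom, col.pos, col.ref_base,
                             col.ref_base + ins_seq, "INS",
                             "het", count / depth, depth, step))
            )
        for length, count in col.del_starts.items():
            if ref_seq is None or col.pos == 0:
                continue
            anchor = col.pos - 1
            ref_allele = ref_seq[anchor : col.pos + length]
            candidates.append(
                (count, _KIND_ORDER["DEL"],
                 VariantCall(col.chrom, anchor, ref_allele, ref_seq[anchor], "DEL",
                             "het", count / depth, depth, step))
            )
        if not candidates:
            continue
        # highest count wins; ties prefer SNV, then lexical allele
        candidates.sort(key=lambda t: (-t[0], t[1], t[2].alt))
        count, _, call = candidates[0]
        frac = count / depth
        if count < params.min_alt_count or frac < params.min_alt_fraction:
            continue
        call.genotype = "hom" if frac >= params.hom_fraction else "het"
        if call.key not in out:
            out.add(call)
    return out


def merge_variant_sets(step1: VariantSet, step2: VariantSet) -> VariantSet:
    """Key-union of two call sets; on collision the step-1 record is kept
    and flagged as seen in both steps.  Provenance (`step`) is retained."""
    merged = VariantSet()
    keys2 = step2.keys()
    for call in step1:
        if call.key in keys2:
            merged.add(replace(call, in_both=True))
        else:
            merged.add(replace(call))
    for call in step2:
        if call.key not in merged:
            merged.add(replace(call))
    return merged


def compare_variant_sets(trimming: VariantSet, baseline: VariantSet) -> dict:
    """Shared/unique breakdown and per-kind new-discovery rate.

    The new discovery rate for a kind is the percentage of trimming-pipeline
    variants of that kind not found by the baseline pipeline.
    """
    shared = [c for c in trimming if c.key in baseline]
    trimming_only = [c for c in trimming if c.key not in baseline]
    baseline_only = [c for c in baseline if c.key not in trimming]
    ndr: dict[str, float] = {}
    kinds = sorted({c.kind for c in trimming} | {"SNV", "INS", "DEL", "all"})
    for kind in kinds:
        if kind == "all":
            total = len(trimming)
            only = len(trimming_only)
        else:
            total = sum(1 for c in trimming if c.kind == kind)
            only = sum(1 for c in trimming_only if c.kind == kind)
        ndr[kind] = 100.0 * only / total if total else 0.0
    return {
        "shared": shared,
        "trimming_only": trimming_only,
        "baseline_only": baseline_only,
        "new_discovery_rate": ndr,
    }


_VCF_HEADER_LINES = [
    '##INFO=<ID=STEP,Number=1,Type=Integer,Description="Calling round (1 or 2)">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth at site">',
    '##INFO=<ID=GENO,Number=1,Type=String,Description="Genotype class (het or hom)">',
    '##INFO=<ID=BOTH,Number=0,Type=Flag,Description="Seen in both calling rounds">',
]


def write_vcf(vs: VariantSet, path: str | Path, panel: Panel | None = None) -> None:
    """Write a VariantSet as VCF 4.2 (positions converted to 1-based)."""
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    contigs = sorted(panel.reference) if panel is not None else sorted({c.chrom for c in vs})
    for chrom in contigs:
        length = len(panel.reference[chrom]) if panel is not None else None
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in vs:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                alleles=(call.ref, call.alt),
            )
            rec.info["STEP"] = call.step
            rec.info["AF"] = round(call.alt_fraction, 6)
            rec.info["DP"] = call.depth
            rec.info["GENO"] = call.genotype
            if call.in_both:
                rec.info["BOTH"] = True
            out.write(rec)


def _classify(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    return "DEL"


def read_vcf(path: str | Path) -> VariantSet:
    """Read a VCF written by :func:`write_vcf` back into a VariantSet."""
    out = VariantSet()
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if len(rec.alts or ()) != 1:
                    raise VcfParseError(
                        f"{path}: expected exactly one ALT at {rec.chrom}:{rec.pos}"
                    )
                alt = rec.alts[0]
                out.add(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        kind=_classify(rec.ref, alt),
                        genotype=str(rec.info.get("GENO", "het")),
                        alt_fraction=float(rec.info.get("AF", 0.0)),
                        depth=int(rec.info.get("DP", 0)),
                        step=int(rec.info.get("STEP", 1)),
                        in_both=bool(rec.info.get("BOTH", False)),
                    )
                )
    except (OSError, ValueError) as exc:
        if isinstance(exc, VcfParseError):
            raise
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    return out
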