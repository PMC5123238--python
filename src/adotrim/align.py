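"""Placement of amplicon reads on the reference via banded local alignment.

Reads are aligned only against their assigned amplicon's expected sequence
(insert only, or primers + insert for the soft-clip / untrimmed modes), not
genome-wide: amplicon assignment has already localized them.  Alignment is
local (Smith–Waterman) with affine gaps, restricted to a diagonal band wide
enough to express the permitted cumulative gap length — at most one third of
the read length.  Reads whose best alignment needs more gap than that, or
covers less than two thirds of the read, are reported unaligned.

Most amplicon reads contain no indel, so a gapless scan (all diagonals,
optimal terminal clipping) is tried first and the dynamic program is only
run when the gapless placement is not clearly optimal.  Alignment results
are memoized per (amplicon, mode, sequence): amplicon data is massively
duplicated and this makes throughput independent of read multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam
from Bio.Seq import reverse_complement

from .panel import AmpliconDef, Panel
from .trim import ReadPair, TrimmedReadPair

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class AlignParams:
    """Scoring and banding parameters for the per-amplicon aligner."""

    match: int = 2
    mismatch: int = 2      # penalty, applied as negative
    gap_open: int = 4      # cost of the first gap base
    gap_extend: int = 1    # cost of each further gap base
    max_gap_fraction: float = 1 / 3
    min_aligned_fraction: float = 2 / 3

    def max_gap(self, read_len: int) -> int:
        return int(self.max_gap_fraction * read_len)


@dataclass
class AlignedRead:
    """A read placed on the reference through its amplicon.

    ``ops`` is a CIGAR-like list of (op, length) with op in {M, I, D, S};
    M covers both match and mismatch.  ``seq``/``qual`` are stored in aligned
    (plus-strand) orientation; mate 2 is reverse-complemented on the way in.
    """

    read_id: str
    amplicon_id: str
    chrom: str
    ref_start: int
    ops: list[tuple[str, int]]
    seq: str
    qual: str
    mate: int
    strand: str = "+"

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")

    def check(self) -> None:
        consumed = sum(n for op, n in self.ops if op in "MIS")
        if consumed != len(self.seq):
            raise ValueError(
                f"{self.read_id}: ops consume {consumed} bases, read has {len(self.seq)}"
            )
        for i, (op, n) in enumerate(self.ops):
            if n <= 0:
                raise ValueError(f"{self.read_id}: non-positive op length")
            if op == "S" and i not in (0, len(self.ops) - 1):
                raise ValueError(f"{self.read_id}: internal soft-clip")
            if i and self.ops[i - 1][0] == op:
                raise ValueError(f"{self.read_id}: adjacent ops of same kind")


@dataclass(frozen=True)
class _CoreAlignment:
    """Mode-independent alignment of a query against a target string."""

    score: int
    target_start: int
    query_start: int
    query_end: int          # exclusive; [query_start, query_end) is aligned
    ops: tuple[tuple[str, int], ...]   # M/I/D runs only


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _gapless_scan(query: str, target: str, params: AlignParams):
    """Best gapless local alignment over all diagonals with terminal clipping.

    Returns (score, offset, seg_start, seg_end, n_mismatch) or None when the
    query is longer than the target.
    """
    lq, lt = len(query), len(target)
    if lq > lt or lq == 0:
        return None
    q = _encode(query)
    t = _encode(target)
    windows = np.lib.stride_tricks.sliding_window_view(t, lq)
    contrib = np.where(windows == q, params.match, -params.mismatch).astype(np.int32)
    cum = np.zeros((windows.shape[0], lq + 1), dtype=np.int32)
    np.cumsum(contrib, axis=1, out=cum[:, 1:])
    run_min = np.minimum.accumulate(cum[:, :-1], axis=1)
    gains = cum[:, 1:] - run_min            # best segment ending at each j
    per_offset = gains.max(axis=1)
    offset = int(per_offset.argmax())       # ties -> smallest offset
    row = gains[offset]
    best = int(per_offset[offset])
    if best <= 0:
        return None
    # latest end, then earliest start: longest segment among ties
    seg_end = int(np.flatnonzero(row == best)[-1]) + 1
    seg_start = int(cum[offset, :seg_end].argmin())
    n_mm = int((contrib[offset, seg_start:seg_end] < 0).sum())
    return best, offset, seg_start, seg_end, n_mm


def _banded_sw(query: str, target: str, params: AlignParams, center_diag: int,
               half_width: int) -> _CoreAlignment | None:
    """Affine-gap local DP restricted to diagonals center_diag ± half_width."""
    lq, lt = len(query), len(target)
    NEG = -(10 ** 9)
    m, x = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    H = {}
    E = {}
    F = {}
    best_score, best_cell = 0, None

    def h(i, j):
        if i < 0 or j < 0:
            return NEG
        if i == 0 or j == 0:
            return 0
        return H.get((i, j), NEG if abs(j - i - center_diag) > half_width else 0)

    for i in range(1, lq + 1):
        lo = max(1, i + center_diag - half_width)
        hi = min(lt, i + center_diag + half_width)
        qc = query[i - 1]
        for j in range(lo, hi + 1):
            e = max(h(i - 1, j) - go, E.get((i - 1, j), NEG) - ge)
            f = max(h(i, j - 1) - go, F.get((i, j - 1), NEG) - ge)
            sub = m if (qc == target[j - 1] and qc != "N") else -x
            val = max(0, h(i - 1, j - 1) + sub, e, f)
            H[(i, j)] = val
            E[(i, j)] = e
            F[(i, j)] = f
            if val > best_score:
                best_score, best_cell = val, (i, j)
    if best_cell is None:
        return None

    ops: list[tuple[str, int]] = []
    i, j = best_cell
    state = "H"
    while True:
        if state == "H":
            val = H.get((i, j), 0)
            if val == 0 or i == 0 or j == 0:
                break
            qc = query[i - 1]
            sub = m if (qc == target[j - 1] and qc != "N") else -x
            if val == h(i - 1, j - 1) + sub:
                ops.append(("M", 1))
                i, j = i - 1, j - 1
            elif val == E.get((i, j), NEG):
                state = "E"
            elif val == F.get((i, j), NEG):
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            ops.append(("I", 1))
            if E.get((i, j), NEG) == E.get((i - 1, j), NEG) - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # F
            ops.append(("D", 1))
            if F.get((i, j), NEG) == F.get((i, j - 1), NEG) - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
    ops.reverse()
    merged = _merge_ops(ops)
    if not merged:
        return None
    q_start, t_start = i, j
    q_end = q_start + sum(n for op, n in merged if op in "MI")
    return _CoreAlignment(best_score, t_start, q_start, q_end, tuple(merged))


def align_query(query: str, target: str, params: AlignParams) -> _CoreAlignment | None:
    """Banded local alignment of a query against a target sequence.

    Returns None for an unalignable read: no positive-scoring placement,
    cumulative gaps above the one-third cap, or aligned coverage below
    ``min_aligned_fraction`` of the read.
    """
    if not query or not target:
        return None
    max_gap = params.max_gap(len(query))
    scan = _gapless_scan(query, target, params)
    core: _CoreAlignment | None = None
    if scan is not None:
        score, offset, s, e, n_mm = scan
        if n_mm <= 2 and (e - s) >= len(query) - 4:
            # a gapped alignment cannot beat a near-perfect gapless one
            core = _CoreAlignment(score, offset + s, s, e, (("M", e - s),))
    if core is None:
        center = scan[1] if scan is not None else (len(target) - len(query)) // 2
        # band twice the gap cap: optima that overspend the cap are still
        # found (and then rejected) instead of being replaced by junk paths
        core = _banded_sw(query, target, params, center, max(2 * max_gap, 16))
    if core is None:
        return None
    gap_len = sum(n for op, n in core.ops if op in "ID")
    if gap_len > max_gap:
        return None
    aligned = core.query_end - core.query_start
    if aligned < params.min_aligned_fraction * len(query):
        return None
    return core


class AlignmentCache(dict):
    """Memo table keyed by (amplicon id, mode, mate, sequence)."""


def _assemble(
    core: _CoreAlignment | None,
    seq: str,
    qual: str,
    genomic_offset: int,
    read_id: str,
    amp: AmpliconDef,
    mate: int,
) -> AlignedRead | None:
    if core is None:
        return None
    ops = list(core.ops)
    lead = core.query_start
    trail = len(seq) - core.query_end
    if lead:
        ops.insert(0, ("S", lead))
    if trail:
        ops.append(("S", trail))
    ar = AlignedRead(
        read_id=read_id,
        amplicon_id=amp.id,
        chrom=amp.chrom,
        ref_start=genomic_offset + core.target_start,
        ops=ops,
        seq=seq,
        qual=qual,
        mate=mate,
        strand="+" if mate == 1 else "-",
    )
    ar.check()
    return ar


def align_to_amplicon(
    pair: TrimmedReadPair,
    panel: Panel,
    params: AlignParams | None = None,
    mode: str = "trimmed",
    original: ReadPair | None = None,
    cache: AlignmentCache | None = None,
) -> list[AlignedRead]:
    """Align both mates of an assigned pair; returns the mates that placed.

    Modes:

    ``trimmed``
        target is the expected insert sequence; primer bases are gone.
    ``softclip``
        the trimmed portion is aligned as in ``trimmed`` mode but the primer
        bases of the original read are kept in the record as soft-clips, so
        they are excluded from pileup (MiSeq-workflow emulation).  Requires
        ``original``.
    ``untrimmed``
        the raw read is aligned against ULSO + insert + DLSO and primer bases
        contribute to pileup as ordinary matches.  Requires ``original``.
    """
    if params is None:
        params = AlignParams()
    if mode not in ("trimmed", "softclip", "untrimmed"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if mode in ("softclip", "untrimmed") and original is None:
        raise ValueError(f"mode {mode!r} requires the original (untrimmed) pair")
    try:
        amp = panel[pair.amplicon_id]
    except KeyError:
        raise KeyError(f"unknown amplicon id {pair.amplicon_id!r}") from None

    if mode == "untrimmed":
        target = amp.ulso + amp.insert_seq + reverse_complement(amp.dlso)
        offset = amp.insert_start - len(amp.ulso)
    else:
        target = amp.insert_seq
        offset = amp.insert_start

    out: list[AlignedRead] = []
    for mate in (1, 2):
        if mode == "untrimmed":
            raw_seq = original.seq1 if mate == 1 else original.seq2
            raw_qual = original.qual1 if mate == 1 else original.qual2
            query = raw_seq if mate == 1 else reverse_complement(raw_seq)
            qual = raw_qual if mate == 1 else raw_qual[::-1]
        else:
            t_seq = pair.seq1 if mate == 1 else pair.seq2
            t_qual = pair.qual1 if mate == 1 else pair.qual2
            query = t_seq if mate == 1 else reverse_complement(t_seq)
            qual = t_qual if mate == 1 else t_qual[::-1]
        key = (amp.id, mode, mate, query)
        if cache is not None and key in cache:
            core = cache[key]
        else:
            core = align_query(query, target, params)
            if cache is not None:
                cache[key] = core
        if mode == "softclip":
            # re-attach the primer bases of the raw read as soft-clips
            primer_len = len(amp.ulso) if mate == 1 else len(amp.dlso)
            raw_seq = original.seq1 if mate == 1 else original.seq2
            raw_qual = original.qual1 if mate == 1 else original.qual2
            full = raw_seq if mate == 1 else reverse_complement(raw_seq)
            full_qual = raw_qual if mate == 1 else raw_qual[::-1]
            if core is not None:
                if mate == 1:
                    shifted = _CoreAlignment(
                        core.score, core.target_start,
                        core.query_start + primer_len, core.query_end + primer_len,
                        core.ops,
                    )
                else:
                    shifted = core  # primer is at the 3' end after revcomp
                ar = _assemble(shifted, full, full_qual, offset, pair.id, amp, mate)
            else:
                ar = None
        else:
            ar = _assemble(core, query, qual, offset, pair.id, amp, mate)
        if ar is not None:
            out.append(ar)
    return out


def align_pairs(
    pairs: Iterable[TrimmedReadPair],
    panel: Panel,
    params: AlignParams | None = None,
    mode: str = "trimmed",
    originals: dict[str, ReadPair] | None = None,
    cache: AlignmentCache | None = None,
) -> tuple[list[AlignedRead], int]:
    """Align a stream of assigned pairs; returns (aligned reads, unaligned count)."""
    if cache is None:
        cache = AlignmentCache()
    aligned: list[AlignedRead] = []
    unaligned = 0
    for pair in pairs:
        original = originals.get(pair.id) if originals else None
        reads = align_to_amplicon(pair, panel, params, mode, original, cache)
        aligned.extend(reads)
        unaligned += 2 - len(reads)
    return aligned, unaligned


def read_alignments(path: str | Path) -> list[AlignedRead]:
    """Read a SAM file written by :func:`write_alignments` back into memory."""
    code_op = {0: "M", 1: "I", 2: "D", 4: "S"}
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    amplicon_id=rec.get_tag("XA") if rec.has_tag("XA") else "",
                    chrom=rec.reference_name,
                    ref_start=rec.reference_start,
                    ops=[(code_op[c], n) for c, n in rec.cigartuples],
                    seq=rec.query_sequence,
                    qual=pysam.qualities_to_qualitystring(rec.query_qualities),
                    mate=2 if rec.is_read2 else 1,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out


def write_alignments(reads: Iterable[AlignedRead], panel: Panel, path: str | Path) -> None:
    """Write aligned reads as a minimal SAM file (M/I/D/S CIGAR ops only)."""
    chroms = sorted(panel.reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(panel.reference[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    op_code = {"M": 0, "I": 1, "D": 2, "S": 4}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.query_sequence = read.seq
            a.query_qualities = pysam.qualitystring_to_array(read.qual)
            a.reference_id = tid[read.chrom]
            a.reference_start = read.ref_start
            a.mapping_quality = 60
            a.cigartuples = [(op_code[op], n) for op, n in read.ops]
            flag = 0x1 | (0x40 if read.mate == 1 else 0x80)
            if read.strand == "-":
                flag |= 0x10
            a.flag = flag
            a.set_tag("XA", read.amplicon_id)
            out.write(a)
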