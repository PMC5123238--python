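"""Primer identification and trimming of paired amplicon reads.

Each read pair is assigned to the amplicon whose ULSO matches the start of
read 1 and whose DLSO matches the start of read 2, allowing at most one
mismatch per read and no gaps.  Matching primers are cut off sequence and
quality; pairs matching no primer pair are discarded.  N bases (in primer or
read) match anything without spending the mismatch budget.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError
from .panel import Panel

MAX_PRIMER_MISMATCHES = 1


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read pair {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class TrimmedReadPair:
    id: str
    amplicon_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    mismatches1: int
    mismatches2: int


@dataclass
class TrimStats:
    total_pairs: int = 0
    assigned_pairs: int = 0
    discarded_pairs: int = 0
    per_amplicon: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("total_pairs", self.total_pairs), ("assigned_pairs", self.assigned_pairs),
                ("discarded_pairs", self.discarded_pairs)]
        rows += [(f"assigned:{k}", v) for k, v in sorted(self.per_amplicon.items())]
        return pd.DataFrame(rows, columns=["metric", "count"])


def match_primer_prefix(read_seq: str, primer: str) -> tuple[bool, int]:
    """Test the primer against the read's first ``len(primer)`` bases.

    Returns ``(matched, mismatches)``: matched iff the read is long enough and
    the Hamming distance is at most one, with N free on either side.  Gapped
    alignment is never attempted.
    """
    n = len(primer)
    if len(read_seq) < n:
        return False, 0
    mm = 0
    for p, b in zip(primer, read_seq):
        if p != b and p != "N" and b != "N":
            mm += 1
            if mm > MAX_PRIMER_MISMATCHES:
                return False, mm
    return True, mm


def assign_and_trim(pair: ReadPair, panel: Panel) -> TrimmedReadPair | None:
    """Assign a pair to an amplicon and trim its primers, or return None.

    Read 1 is tested against each amplicon's ULSO; on a hit, read 2 is tested
    against the same amplicon's DLSO.  Both must match.  Among amplicons where
    both primers match, the one with the smallest total mismatch count wins,
    ties broken by manifest order.
    """
    best: tuple[int, int, int] | None = None  # (total_mm, manifest_idx, ...)
    best_amp = None
    best_mm = (0, 0)
    for idx, amp in enumerate(panel.amplicons):
        ok1, mm1 = match_primer_prefix(pair.seq1, amp.ulso)
        if not ok1:
            continue
        ok2, mm2 = match_primer_prefix(pair.seq2, amp.dlso)
        if not ok2:
            continue
        key = (mm1 + mm2, idx)
        if best is None or key < best:
            best = key
            best_amp = amp
            best_mm = (mm1, mm2)
    if best_amp is None:
        return None
    n1, n2 = len(best_amp.ulso), len(best_amp.dlso)
    return TrimmedReadPair(
        id=pair.id,
        amplicon_id=best_amp.id,
        seq1=pair.seq1[n1:],
        seq2=pair.seq2[n2:],
        qual1=pair.qual1[n1:],
        qual2=pair.qual2[n2:],
        mismatches1=best_mm[0],
        mismatches2=best_mm[1],
    )


def trim_pairs(
    pairs: Iterable[ReadPair],
    panel: Panel,
    rejects: list[ReadPair] | None = None,
) -> tuple[list[TrimmedReadPair], TrimStats]:
    """Assign-and-trim a stream of pairs; input order is preserved."""
    stats = TrimStats()
    out: list[TrimmedReadPair] = []
    for pair in pairs:
        stats.total_pairs += 1
        trimmed = assign_and_trim(pair, panel)
        if trimmed is None:
            stats.discarded_pairs += 1
            if rejects is not None:
                rejects.append(pair)
        else:
            stats.assigned_pairs += 1
            stats.per_amplicon[trimmed.amplicon_id] = (
                stats.per_amplicon.get(trimmed.amplicon_id, 0) + 1
            )
            out.append(trimmed)
    return out, stats


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime keeps gzip output byte-reproducible
            return io.TextIOWrapper(
                gzip.GzipFile(path, mode="wb", mtime=0), encoding="ascii"
            )
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (plain or gzip)."""
    with _open_text(fastq1) as fh1, _open_text(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        idx = 0
        while True:
            try:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record {idx}: {exc}", idx) from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FastqParseError(
                    f"FASTQ files end at different record counts (record {idx})", idx
                )
            id1 = rec1[0].split()[0]
            id2 = rec2[0].split()[0]
            for suffix in ("/1", "/2"):
                id1 = id1.removesuffix(suffix)
                id2 = id2.removesuffix(suffix)
            if id1 != id2:
                raise FastqParseError(
                    f"mate ids disagree at record {idx}: {id1!r} vs {id2!r}", idx
                )
            try:
                yield ReadPair(id1, rec1[1].upper(), rec2[1].upper(), rec1[2], rec2[2])
            except ValueError as exc:
                raise FastqParseError(str(exc), idx) from exc
            idx += 1


def write_fastq_pair(
    pairs: Iterable[ReadPair | TrimmedReadPair], fastq1: str | Path, fastq2: str | Path
) -> None:
    with _open_text(fastq1, "wt") as fh1, _open_text(fastq2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def trim_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    panel: Panel,
    out1: str | Path | None = None,
    out2: str | Path | None = None,
    rejects1: str | Path | None = None,
    rejects2: str | Path | None = None,
) -> tuple[list[TrimmedReadPair], TrimStats]:
    """Trim a FASTQ pair against a panel, optionally writing outputs.

    Returns the retained trimmed pairs and conservation statistics
    (assigned + discarded == total).
    """
    rejects: list[ReadPair] | None = [] if rejects1 else None
    trimmed, stats = trim_pairs(read_fastq_pairs(fastq1, fastq2), panel, rejects)
    if out1 and out2:
        write_fastq_pair(trimmed, out1, out2)
    if rejects1 and rejects2 and rejects is not None:
        write_fastq_pair(rejects, rejects1, rejects2)
    return trimmed, stats
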