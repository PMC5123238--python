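"""Amplicon panel model: manifest parsing, reference store, primer geometry.

An amplicon panel is described by a tab-separated manifest naming, for each
amplicon, its genomic insert interval and the two locus-specific oligos:
the ULSO (upstream primer, as it begins read 1) and the DLSO (downstream
primer, as it begins read 2, i.e. the reverse complement of the plus strand
at the downstream footprint).  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import (
    DuplicateAmpliconError,
    ManifestError,
    MissingColumnError,
    ReferenceMismatchError,
    UnknownChromError,
)

MANIFEST_COLUMNS = ["amplicon_id", "chrom", "insert_start", "insert_end", "ulso", "dlso"]

NUCLEOTIDES = set("ACGTN")


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ManifestError(f"{what} contains non-nucleotide characters: {sorted(bad)}")


def seq_matches(primer: str, ref_seq: str) -> bool:
    """True if `primer` equals `ref_seq`, treating N (either side) as wildcard."""
    if len(primer) != len(ref_seq):
        return False
    return all(p == r or p == "N" or r == "N" for p, r in zip(primer, ref_seq))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon: primer pair, insert interval and expected insert sequence.

    `ulso` is stored exactly as read 1 begins with it; `dlso` exactly as
    read 2 begins with it (reverse complement of the plus strand at the
    downstream footprint).
    """

    id: str
    chrom: str
    insert_start: int
    insert_end: int
    ulso: str
    dlso: str
    insert_seq: str

    def __post_init__(self):
        if not self.ulso or not self.dlso:
            raise ManifestError(f"amplicon {self.id}: empty primer sequence")
        _check_alphabet(self.ulso, f"amplicon {self.id} ulso")
        _check_alphabet(self.dlso, f"amplicon {self.id} dlso")
        _check_alphabet(self.insert_seq, f"amplicon {self.id} insert_seq")
        if self.insert_end - self.insert_start != len(self.insert_seq):
            raise ManifestError(
                f"amplicon {self.id}: insert interval length "
                f"{self.insert_end - self.insert_start} != insert_seq length "
                f"{len(self.insert_seq)}"
            )
        if self.insert_start - len(self.ulso) < 0:
            raise ManifestError(f"amplicon {self.id}: ULSO footprint below position 0")

    @property
    def ulso_footprint(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.insert_start - len(self.ulso), self.insert_start)

    @property
    def dlso_footprint(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.insert_end, self.insert_end + len(self.dlso))

    @property
    def span(self) -> GenomicInterval:
        """Full amplicon span, primers included."""
        return GenomicInterval(self.chrom, self.ulso_footprint.start, self.dlso_footprint.end)

    @property
    def insert_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.insert_start, self.insert_end)


@dataclass
class Panel:
    name: str
    amplicons: list[AmpliconDef] = field(default_factory=list)
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.id in seen:
                raise DuplicateAmpliconError(f"duplicate amplicon id {amp.id!r}")
            seen.add(amp.id)
            if amp.chrom not in self.reference:
                raise UnknownChromError(
                    f"amplicon {amp.id}: chromosome {amp.chrom!r} not in reference"
                )
            ref = self.reference[amp.chrom]
            if amp.dlso_footprint.end > len(ref):
                raise ManifestError(
                    f"amplicon {amp.id}: DLSO footprint beyond end of {amp.chrom}"
                )
            if amp.insert_seq != ref[amp.insert_start : amp.insert_end]:
                raise ReferenceMismatchError(
                    f"amplicon {amp.id}: insert_seq disagrees with reference "
                    f"at {amp.chrom}:{amp.insert_start}-{amp.insert_end}"
                )
            fp = amp.ulso_footprint
            if not seq_matches(amp.ulso, ref[fp.start : fp.end]):
                raise ReferenceMismatchError(
                    f"amplicon {amp.id}: ULSO does not match reference footprint"
                )
            fp = amp.dlso_footprint
            if not seq_matches(amp.dlso, reverse_complement(ref[fp.start : fp.end])):
                raise ReferenceMismatchError(
                    f"amplicon {amp.id}: DLSO does not match reverse complement "
                    "of reference footprint"
                )

    def __getitem__(self, amplicon_id: str) -> AmpliconDef:
        for amp in self.amplicons:
            if amp.id == amplicon_id:
                return amp
        raise KeyError(amplicon_id)

    def target_intervals(self, include_primers: bool = False) -> list[GenomicInterval]:
        """Merged target intervals (union of inserts, optionally with footprints)."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for amp in self.amplicons:
            iv = amp.span if include_primers else amp.insert_interval
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return merged


def load_reference(reference_path: str | Path) -> dict[str, str]:
    """Read a FASTA reference store into a chrom → sequence mapping."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(reference_path), "fasta")
    }


def parse_manifest(manifest_path: str | Path, reference_path: str | Path) -> Panel:
    """Load and validate a panel from a manifest TSV and a FASTA reference.

    Raises a named :class:`~adotrim.errors.ManifestError` subclass on any
    violation: missing column, unknown chromosome, sequence/reference
    disagreement, or duplicate amplicon id.
    """
    table = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise MissingColumnError(f"manifest is missing columns {missing}")
    reference = load_reference(reference_path)
    amplicons = []
    for row in table.itertuples(index=False):
        start, end = int(row.insert_start), int(row.insert_end)
        chrom = row.chrom
        if chrom not in reference:
            raise UnknownChromError(f"amplicon {row.amplicon_id}: unknown chrom {chrom!r}")
        amplicons.append(
            AmpliconDef(
                id=row.amplicon_id,
                chrom=chrom,
                insert_start=start,
                insert_end=end,
                ulso=row.ulso.upper(),
                dlso=row.dlso.upper(),
                insert_seq=reference[chrom][start:end],
            )
        )
    return Panel(name=str(Path(manifest_path).stem), amplicons=amplicons, reference=reference)


def write_manifest(panel: Panel, path: str | Path) -> None:
    """Write the manifest TSV (inverse of :func:`parse_manifest` modulo name)."""
    rows = [
        {
            "amplicon_id": a.id,
            "chrom": a.chrom,
            "insert_start": a.insert_start,
            "insert_end": a.insert_end,
            "ulso": a.ulso,
            "dlso": a.dlso,
        }
        for a in panel.amplicons
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_reference(panel: Panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(panel.reference):
            fh.write(f">{chrom}\n")
            seq = panel.reference[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def primer_footprints(panel: Panel) -> dict[str, tuple[GenomicInterval, GenomicInterval]]:
    """Map amplicon id → (ULSO footprint, DLSO footprint) genomic intervals."""
    return {a.id: (a.ulso_footprint, a.dlso_footprint) for a in panel.amplicons}


def generate_primer_list(panel: Panel) -> pd.DataFrame:
    """One row per amplicon with its primer pair, manifest order preserved."""
    return pd.DataFrame(
        [(a.id, a.ulso, a.dlso) for a in panel.amplicons],
        columns=["amplicon_id", "ulso", "dlso"],
    )
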