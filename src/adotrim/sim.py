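"""Synthetic allele-drop-out datasets with ground truth.

The generator reproduces a two-amplicon worst case: a region covered by two
overlapping amplicons A and B, a heterozygous mutation (m1) sitting inside
B's upstream-primer footprint, and a second linked SNV (m2) five bases
downstream on the same haplotype.  Because m1 disrupts B's primer, amplicon
B amplifies the mutated allele at a 100-fold lower yield (allele drop-out):
B read pairs draw the mutated haplotype with odds wild:mutated = 1:0.01.
Amplicon A primers bind outside the mutated region, so A pairs are an
ordinary heterozygous draw (50% mutated).  m2 rides along on mutated pairs
with probability 0.9.

Two dataset flavours exist: SD1 plants m1 as a substitution, SD2 as a
single-base insertion (which breaks gap-free primer matching outright).
Mixtures with a chosen fraction of A pairs at constant total depth emulate
varying relative amplicon efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .panel import AmpliconDef, Panel, write_manifest, write_reference
from .trim import ReadPair, write_fastq_pair

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    n_a: int = 3186
    n_b: int = 5484
    fraction_a: float | None = None     # mixing target; None = native composition
    het_fraction: float = 0.5           # mutated-haplotype probability, amplicon A
    second_mut_prob: float = 0.9
    ado_yield_ratio: float = 0.01       # mutated:wild amplification yield, amplicon B
    read_len: int = 150
    base_error_rate: float = 0.0
    mode: str = "SD1"                   # SD1 = substitution, SD2 = insertion
    seed: int = 0

    def __post_init__(self):
        for name in ("het_fraction", "second_mut_prob", "ado_yield_ratio",
                     "base_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("read counts must be non-negative")
        if self.mode not in ("SD1", "SD2"):
            raise ValueError(f"mode must be SD1 or SD2, got {self.mode!r}")


@dataclass(frozen=True)
class PlantedVariants:
    """Positions and alleles of the two planted mutations (0-based)."""

    chrom: str
    m1_pos: int
    m1_ref: str
    m1_alt: str          # SD1 substitution allele
    m1_ins: str          # SD2 inserted base (anchored after m1_pos)
    m2_pos: int
    m2_ref: str
    m2_alt: str

    def keys(self, mode: str) -> list[tuple[str, int, str, str]]:
        """Variant keys (chrom, pos, ref, alt) expected from a perfect caller."""
        if mode == "SD1":
            m1 = (self.chrom, self.m1_pos, self.m1_ref, self.m1_alt)
        else:
            m1 = (self.chrom, self.m1_pos, self.m1_ref, self.m1_ref + self.m1_ins)
        return [m1, (self.chrom, self.m2_pos, self.m2_ref, self.m2_alt)]


@dataclass
class TruthRow:
    read_id: str
    amplicon: str
    haplotype: str       # wild | mut
    carries_m1: bool
    carries_m2: bool


@dataclass
class TruthTable:
    planted: PlantedVariants
    mode: str
    rows: list[TruthRow] = field(default_factory=list)
    with_replacement: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.read_id, r.amplicon, r.haplotype, r.carries_m1, r.carries_m2)
             for r in self.rows],
            columns=["read_id", "amplicon", "haplotype", "carries_m1", "carries_m2"],
        )


@dataclass
class SimulatedDataset:
    pairs: list[ReadPair]
    truth: TruthTable
    panel: Panel
    config: SimConfig


_CHROM = "sim1"
_REF_LEN = 600
_PRIMER_LEN = 20
_A_INSERT = (100, 310)
_B_INSERT = (300, 510)
_M1_POS = 297
_M2_POS = 302


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def build_fixture_panel(seed: int = 0) -> tuple[Panel, PlantedVariants]:
    """Construct the two-amplicon fixture panel and its planted variants.

    Amplicons are 250 bp (20 bp primers, 210 bp inserts) over a random
    600 bp reference; A covers [100,310), B covers [300,510), so B's
    upstream-primer footprint [280,300) lies inside A's insert.  m1 sits at
    297 (inside that footprint), m2 at 302 (inside both inserts, outside
    every footprint).  The reference is patched so that the SD2 insertion
    shifts B's primer prefix by >= 2 mismatches and left-aligns uniquely.
    """
    rng = np.random.default_rng(seed)
    ref = [_BASES[i] for i in rng.integers(4, size=_REF_LEN)]
    # distinct neighbourhood around the insertion anchor (m1_pos):
    # shifted primer suffix must differ from the original at >= 2 positions
    if ref[_M1_POS + 1] == ref[_M1_POS + 2]:
        ref[_M1_POS + 2] = _other_base(rng, ref[_M1_POS + 1])
    ref_str = "".join(ref)

    def amp(aid: str, ins: tuple[int, int]) -> AmpliconDef:
        s, e = ins
        return AmpliconDef(
            id=aid,
            chrom=_CHROM,
            insert_start=s,
            insert_end=e,
            ulso=ref_str[s - _PRIMER_LEN : s],
            dlso=reverse_complement(ref_str[e : e + _PRIMER_LEN]),
            insert_seq=ref_str[s:e],
        )

    panel = Panel(
        name="ado-fixture",
        amplicons=[amp("A", _A_INSERT), amp("B", _B_INSERT)],
        reference={_CHROM: ref_str},
    )
    m1_ref = ref_str[_M1_POS]
    m2_ref = ref_str[_M2_POS]
    planted = PlantedVariants(
        chrom=_CHROM,
        m1_pos=_M1_POS,
        m1_ref=m1_ref,
        m1_alt=_other_base(rng, m1_ref),
        m1_ins=_other_base(rng, m1_ref, ref_str[_M1_POS + 1]),
        m2_pos=_M2_POS,
        m2_ref=m2_ref,
        m2_alt=_other_base(rng, m2_ref),
    )
    return panel, planted


def _haplotype_reads(
    panel: Panel, planted: PlantedVariants, cfg: SimConfig,
    amplicon_id: str, mutated: bool, with_m2: bool,
) -> tuple[str, str]:
    """Template (read1, read2) for one amplicon/haplotype combination."""
    amp = panel[amplicon_id]
    hap = list(panel.reference[amp.chrom])
    if mutated:
        if cfg.mode == "SD1":
            hap[planted.m1_pos] = planted.m1_alt
        else:
            hap.insert(planted.m1_pos + 1, planted.m1_ins)
    if mutated and with_m2:
        m2 = planted.m2_pos
        if cfg.mode == "SD2" and m2 > planted.m1_pos:
            m2 += 1
        hap[m2] = planted.m2_alt
    span = amp.span
    end = span.end + (1 if mutated and cfg.mode == "SD2" else 0)
    amp_seq = "".join(hap[span.start : end])
    read1 = amp_seq[: cfg.read_len]
    read2 = reverse_complement(amp_seq)[: cfg.read_len]
    return read1, read2


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = _other_base(rng, arr[i])
    return "".join(arr)


def simulate_dataset(
    cfg: SimConfig,
    panel: Panel | None = None,
    planted: PlantedVariants | None = None,
) -> SimulatedDataset:
    """Draw the full A + B read-pair population with per-pair ground truth.

    Amplicon-A pairs take the mutated haplotype with probability
    ``het_fraction``; amplicon-B pairs with probability
    ``ado_yield_ratio / (1 + ado_yield_ratio)`` (yield odds 1:ratio).
    Mutated pairs additionally carry m2 with probability ``second_mut_prob``.
    Byte-identical output for identical configs.
    """
    if panel is None or planted is None:
        panel, planted = build_fixture_panel(cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    templates = {
        (aid, mut, m2): _haplotype_reads(panel, planted, cfg, aid, mut, m2)
        for aid in ("A", "B")
        for mut in (False, True)
        for m2 in (False, True)
    }
    pairs: list[ReadPair] = []
    rows: list[TruthRow] = []
    p_mut_b = cfg.ado_yield_ratio / (1.0 + cfg.ado_yield_ratio)
    for aid, n, p_mut in (("A", cfg.n_a, cfg.het_fraction), ("B", cfg.n_b, p_mut_b)):
        mut_draw = rng.random(n) < p_mut
        m2_draw = rng.random(n) < cfg.second_mut_prob
        for i in range(n):
            mut = bool(mut_draw[i])
            with_m2 = mut and bool(m2_draw[i])
            r1, r2 = templates[(aid, mut, with_m2)]
            if cfg.base_error_rate > 0:
                r1 = _apply_errors(r1, cfg.base_error_rate, rng)
                r2 = _apply_errors(r2, cfg.base_error_rate, rng)
            rid = f"{cfg.mode}:{aid}:{i:05d}"
            pairs.append(ReadPair(rid, r1, r2, "I" * len(r1), "I" * len(r2)))
            rows.append(TruthRow(rid, aid, "mut" if mut else "wild", mut, with_m2))
    truth = TruthTable(planted=planted, mode=cfg.mode, rows=rows)
    return SimulatedDataset(pairs=pairs, truth=truth, panel=panel, config=cfg)


def mix_reads(
    dataset: SimulatedDataset,
    fraction_a: float,
    total: int | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Subsample a mixture with a target fraction of amplicon-A pairs.

    Draws ``round(fraction_a * total)`` A pairs and the complement from B,
    uniformly without replacement where the pools allow it, with replacement
    otherwise (flagged on the truth table).  The default total preserves the
    native depth n_a + n_b.
    """
    if not 0 <= fraction_a <= 1:
        raise ValueError("fraction_a must be in [0,1]")
    cfg = dataset.config
    if total is None:
        total = cfg.n_a + cfg.n_b
    n_a = round(fraction_a * total)
    n_b = total - n_a
    rng = np.random.default_rng(seed)
    idx_by_amp = {"A": [], "B": []}
    for i, row in enumerate(dataset.truth.rows):
        idx_by_amp[row.amplicon].append(i)
    picked: list[int] = []
    with_replacement = False
    for aid, n in (("A", n_a), ("B", n_b)):
        pool = np.asarray(idx_by_amp[aid], dtype=np.int64)
        if n == 0:
            continue
        if len(pool) == 0:
            raise ValueError(f"no {aid} pairs available to draw {n} from")
        replace_draw = n > len(pool)
        with_replacement = with_replacement or replace_draw
        picked.extend(rng.choice(pool, size=n, replace=replace_draw).tolist())
    order = rng.permutation(len(picked))
    pairs: list[ReadPair] = []
    rows: list[TruthRow] = []
    seen: dict[str, int] = {}
    for k in order:
        i = picked[int(k)]
        pair = dataset.pairs[i]
        row = dataset.truth.rows[i]
        count = seen.get(pair.id, 0)
        seen[pair.id] = count + 1
        rid = pair.id if count == 0 else f"{pair.id}:r{count}"
        pairs.append(replace(pair, id=rid))
        rows.append(replace(row, read_id=rid))
    truth = TruthTable(
        planted=dataset.truth.planted,
        mode=dataset.truth.mode,
        rows=rows,
        with_replacement=with_replacement,
    )
    new_cfg = replace(cfg, fraction_a=fraction_a)
    return SimulatedDataset(pairs=pairs, truth=truth, panel=dataset.panel, config=new_cfg)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path, prefix: str = "sim") -> dict[str, Path]:
    """Write FASTQ pair (gzip), truth TSV, manifest TSV and reference FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq1": out_dir / f"{prefix}_R1.fastq.gz",
        "fastq2": out_dir / f"{prefix}_R2.fastq.gz",
        "truth": out_dir / f"{prefix}_truth.tsv",
        "manifest": out_dir / f"{prefix}_manifest.tsv",
        "reference": out_dir / f"{prefix}_reference.fa",
    }
    write_fastq_pair(dataset.pairs, paths["fastq1"], paths["fastq2"])
    dataset.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    write_manifest(dataset.panel, paths["manifest"])
    write_reference(dataset.panel, paths["reference"])
    return paths
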