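import numpy as np
import pytest
from _oracles import brute_force_assign

from adotrim.errors import FastqParseError
from adotrim.panel import AmpliconDef, Panel
from adotrim.sim import SimConfig, simulate_dataset
from adotrim.trim import (
    ReadPair,
    assign_and_trim,
    match_primer_prefix,
    read_fastq_pairs,
    trim_fastq,
    trim_pairs,
    write_fastq_pair,
)


@pytest.mark.parametrize(
    "read,primer,matched,mismatches",
    [
        ("ACGTTTTT", "ACGT", True, 0),
        ("ACCTTTTT", "ACGT", True, 1),      # one mismatch tolerated
        ("ATCATTTT", "ACGT", False, 2),
        ("ACG", "ACGT", False, 0),          # read shorter than primer
        ("ANGTTTTT", "ACGT", True, 0),      # N in read is free
        ("ACGTTTTT", "ANGT", True, 0),      # N in primer is free
        ("TCGTTCGT", "ACGA", False, 2),
    ],
)
def test_match_primer_prefix(read, primer, matched, mismatches):
    got_matched, got_mm = match_primer_prefix(read, primer)
    assert got_matched == matched
    if matched:
        assert got_mm == mismatches


def _perfect_pair(panel, amp_id, read_len=150):
    amp = panel[amp_id]
    ref = panel.reference[amp.chrom]
    span = amp.span
    amp_seq = ref[span.start : span.end]
    from Bio.Seq import reverse_complement

    r1 = amp_seq[:read_len]
    r2 = reverse_complement(amp_seq)[:read_len]
    return ReadPair("p0", r1, r2, "I" * len(r1), "I" * len(r2))


def test_assign_and_trim_error_free(panel):
    pair = _perfect_pair(panel, "A")
    trimmed = assign_and_trim(pair, panel)
    assert trimmed is not None
    assert trimmed.amplicon_id == "A"
    assert (trimmed.mismatches1, trimmed.mismatches2) == (0, 0)
    assert len(trimmed.seq1) == 150 - 20
    assert len(trimmed.qual2) == 150 - 20


def test_pair_discarded_when_mate2_fails(panel):
    pair = _perfect_pair(panel, "B")
    # break read 2's primer prefix at two positions
    s2 = list(pair.seq2)
    for i in (3, 7):
        s2[i] = "A" if s2[i] != "A" else "C"
    broken = ReadPair(pair.id, pair.seq1, "".join(s2), pair.qual1, pair.qual2)
    assert assign_and_trim(broken, panel) is None


def test_sd2_insertion_breaks_primer_match(panel, planted, sd2_native):
    """A one-base insertion inside the primer prefix shifts >= 2 positions,
    so the gap-free rule discards every mutated amplicon-B pair."""
    ulso = panel["B"].ulso
    fp_start = panel["B"].ulso_footprint.start
    ref = panel.reference["sim1"]
    off = planted.m1_pos + 1 - fp_start
    shifted = ref[fp_start : planted.m1_pos + 1] + planted.m1_ins + ref[planted.m1_pos + 1 :]
    mm = sum(1 for a, b in zip(ulso, shifted[: len(ulso)]) if a != b)
    assert mm >= 2  # brute-force check of the geometry guarantee

    mut_b = {r.read_id for r in sd2_native.truth.rows
             if r.amplicon == "B" and r.haplotype == "mut"}
    assert mut_b
    trimmed, stats = trim_pairs(sd2_native.pairs, panel)
    kept = {p.id for p in trimmed}
    assert not (mut_b & kept)
    assert stats.discarded_pairs == len(mut_b)


def test_trim_conservation_and_fraction(panel, sd1_native):
    trimmed, stats = trim_pairs(sd1_native.pairs, panel)
    assert stats.assigned_pairs + stats.discarded_pairs == stats.total_pairs
    assert sum(stats.per_amplicon.values()) == stats.assigned_pairs
    # SD1 primer SNV costs only the one-mismatch budget: nothing is lost
    assert stats.assigned_pairs / stats.total_pairs >= 0.99
    assert [p.id for p in trimmed] == [
        p.id for p in sd1_native.pairs if p.id in {t.id for t in trimmed}
    ]  # output order follows input order


def test_trimming_is_idempotent(panel, sd1_small):
    trimmed, _ = trim_pairs(sd1_small.pairs, panel)
    retrimmed, stats = trim_pairs(
        (ReadPair(t.id, t.seq1, t.seq2, t.qual1, t.qual2) for t in trimmed), panel
    )
    assert retrimmed == []
    assert stats.discarded_pairs == stats.total_pairs


def test_matches_brute_force_on_random_pairs(panel, sd1_small):
    rng = np.random.default_rng(42)
    pairs = list(sd1_small.pairs)
    # add fully random pairs that should almost surely be discarded
    for i in range(100):
        s1 = "".join(rng.choice(list("ACGT"), 150))
        s2 = "".join(rng.choice(list("ACGT"), 150))
        pairs.append(ReadPair(f"rnd{i}", s1, s2, "I" * 150, "I" * 150))
    for pair in pairs:
        expected = brute_force_assign(pair, panel)
        got = assign_and_trim(pair, panel)
        assert (got.amplicon_id if got else None) == expected


def test_tie_breaking_prefers_manifest_order_on_identical_primers():
    from Bio.Seq import reverse_complement

    rng = np.random.default_rng(3)
    ref = "".join(rng.choice(list("ACGT"), 120))

    def amp(aid):
        return AmpliconDef(
            id=aid, chrom="c", insert_start=30, insert_end=70,
            ulso=ref[10:30], dlso=reverse_complement(ref[70:90]),
            insert_seq=ref[30:70],
        )

    panel = Panel("tie", [amp("X"), amp("Y")], {"c": ref})
    r2 = reverse_complement(ref[30:90])
    pair = ReadPair("t", ref[10:90], r2, "I" * 80, "I" * len(r2))
    trimmed = assign_and_trim(pair, panel)
    assert trimmed is not None and trimmed.amplicon_id == "X"


def test_all_n_reads_are_assigned_by_the_wildcard_rule(panel):
    # N matches everything for free, so an all-N pair matches the first amplicon
    pair = ReadPair("n", "N" * 150, "N" * 150, "I" * 150, "I" * 150)
    trimmed = assign_and_trim(pair, panel)
    assert trimmed is not None and trimmed.amplicon_id == "A"


def test_trim_fastq_files_and_empty_input(panel, sd1_small, tmp_path):
    f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    write_fastq_pair(sd1_small.pairs, f1, f2)
    trimmed, stats = trim_fastq(
        f1, f2, panel,
        out1=tmp_path / "t1.fastq.gz", out2=tmp_path / "t2.fastq.gz",
    )
    assert stats.total_pairs == len(sd1_small.pairs)
    back = list(read_fastq_pairs(tmp_path / "t1.fastq.gz", tmp_path / "t2.fastq.gz"))
    assert len(back) == len(trimmed)
    assert back[0].seq1 == trimmed[0].seq1

    e1, e2 = tmp_path / "e1.fastq", tmp_path / "e2.fastq"
    e1.write_text("")
    e2.write_text("")
    out, stats = trim_fastq(e1, e2, panel)
    assert out == [] and stats.total_pairs == 0


def test_malformed_fastq_raises_with_index(tmp_path, panel):
    f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    f1.write_text("@a\nACGT\n+\nIIII\n@b\nACGT\n+\nII\n")
    f2.write_text("@a\nACGT\n+\nIIII\n@b\nACGT\n+\nIIII\n")
    with pytest.raises(FastqParseError):
        list(read_fastq_pairs(f1, f2))
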