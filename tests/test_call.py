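import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adotrim.align import AlignedRead
from adotrim.call import (
    CallParams,
    PileupColumn,
    VariantCall,
    VariantSet,
    build_pileup,
    call_variants,
    compare_variant_sets,
    merge_variant_sets,
    read_vcf,
    write_vcf,
)
from adotrim.errors import VcfParseError


def _read(panel, pos, seq, ops=None, rid="r", mate=1):
    return AlignedRead(
        read_id=rid, amplicon_id="A", chrom="sim1", ref_start=pos,
        ops=ops or [("M", len(seq))], seq=seq, qual="I" * len(seq), mate=mate,
    )


def test_identical_reads_stack_in_pileup(panel):
    amp = panel["A"]
    seq = amp.insert_seq[:50]
    reads = [_read(panel, amp.insert_start, seq, rid=f"r{i}") for i in range(10)]
    cols = build_pileup(reads, panel)
    assert len(cols) == 50
    for col in cols:
        assert col.depth == 10
        assert col.base_counts == {col.ref_base: 10}


def test_deleted_bases_count_toward_depth(panel):
    amp = panel["A"]
    s = amp.insert_start
    seq = amp.insert_seq[:20] + amp.insert_seq[21:41]   # skips one ref base
    read = _read(panel, s, seq, ops=[("M", 20), ("D", 1), ("M", 20)])
    cols = {c.pos: c for c in build_pileup([read], panel)}
    del_col = cols[s + 20]
    assert del_col.del_counts == {1: 1}
    assert del_col.del_starts == {1: 1}
    assert del_col.depth == 1
    assert cols[s + 19].base_counts == {cols[s + 19].ref_base: 1}


def test_insertions_anchor_after_previous_base(panel):
    amp = panel["A"]
    s = amp.insert_start
    seq = amp.insert_seq[:20] + "A" + amp.insert_seq[20:40]
    read = _read(panel, s, seq, ops=[("M", 20), ("I", 1), ("M", 20)])
    cols = {c.pos: c for c in build_pileup([read], panel)}
    assert cols[s + 19].ins_counts == {"A": 1}
    assert cols[s + 19].depth == 1  # inserted bases add no depth


def _col(depth, alt_count, ref="C", alt="T", pos=100):
    return PileupColumn(
        chrom="sim1", pos=pos, ref_base=ref,
        base_counts={ref: depth - alt_count, alt: alt_count},
    )


@pytest.mark.parametrize(
    "depth,alt,expect_call,expect_gt",
    [
        (100, 50, True, "het"),     # balanced heterozygote
        (5484, 54, False, None),    # ADO residual ~1%: below threshold
        (8670, 1561, False, None),  # untrimmed dilution ~18% < 25%
        (100, 99, True, "hom"),
        (29, 20, False, None),      # below depth floor
        (100, 4, False, None),      # below alt-count floor (fraction irrelevant)
    ],
)
def test_threshold_caller(depth, alt, expect_call, expect_gt):
    vs = call_variants([_col(depth, alt)], CallParams())
    if expect_call:
        assert len(vs) == 1
        call = next(iter(vs))
        assert call.genotype == expect_gt
        assert call.alt_fraction == pytest.approx(alt / depth)
    else:
        assert len(vs) == 0


def test_single_best_alt_per_site():
    col = PileupColumn("sim1", 100, "C", base_counts={"C": 40, "T": 35, "A": 25})
    vs = call_variants([col], CallParams())
    assert [c.alt for c in vs] == ["T"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    depth=st.integers(30, 500),
    alt_frac=st.floats(0.0, 1.0),
    thresholds=st.lists(st.floats(0.05, 0.95), min_size=2, max_size=2, unique=True),
)
def test_caller_monotonic_in_min_alt_fraction(depth, alt_frac, thresholds):
    """Raising min_alt_fraction never adds calls."""
    lo, hi = sorted(thresholds)
    alt = int(alt_frac * depth)
    col = _col(depth, alt)
    calls_lo = call_variants([col], CallParams(min_alt_fraction=lo, hom_fraction=1.0))
    calls_hi = call_variants([col], CallParams(min_alt_fraction=hi, hom_fraction=1.0))
    assert calls_hi.keys() <= calls_lo.keys()


def _vc(pos, ref="C", alt="T", step=1, kind="SNV"):
    return VariantCall("sim1", pos, ref, alt, kind, "het", 0.5, 100, step)


def test_merge_keeps_step1_on_collision():
    step1 = VariantSet([_vc(297)])
    step2 = VariantSet([_vc(297, step=2), _vc(302, ref="G", alt="A", step=2)])
    merged = merge_variant_sets(step1, step2)
    assert len(merged) == 2
    m1 = merged.get(("sim1", 297, "C", "T"))
    assert m1.step == 1 and m1.in_both
    m2 = merged.get(("sim1", 302, "G", "A"))
    assert m2.step == 2 and not m2.in_both


def test_merge_identities():
    empty = VariantSet()
    assert len(merge_variant_sets(empty, empty)) == 0
    a = VariantSet([_vc(1), _vc(2)])
    b = VariantSet([_vc(3)])
    ab = merge_variant_sets(a, b)
    assert [c.pos for c in ab] == [1, 2, 3]  # sorted concatenation
    # idempotent and associative on disjoint keys
    assert merge_variant_sets(a, a).keys() == a.keys()
    left = merge_variant_sets(merge_variant_sets(a, b), empty)
    right = merge_variant_sets(a, merge_variant_sets(b, empty))
    assert left.keys() == right.keys()
    assert len(ab) <= len(a) + len(b)


def test_new_discovery_rate():
    a, b, c = _vc(1), _vc(2), _vc(3)
    same = compare_variant_sets(VariantSet([a, b]), VariantSet([a, b]))
    assert same["new_discovery_rate"]["all"] == 0.0
    res = compare_variant_sets(VariantSet([a, b, c]), VariantSet([a, b]))
    assert res["new_discovery_rate"]["all"] == pytest.approx(100 / 3)
    assert res["new_discovery_rate"]["SNV"] == pytest.approx(100 / 3)
    rev = compare_variant_sets(VariantSet([a]), VariantSet([a, b]))
    assert [v.pos for v in rev["baseline_only"]] == [2]


def test_vcf_round_trip(panel, tmp_path):
    vs = VariantSet([
        VariantCall("sim1", 297, "C", "T", "SNV", "het", 0.5, 867, 1),
        VariantCall("sim1", 302, "A", "AG", "INS", "het", 0.45, 800, 2, in_both=False),
        VariantCall("sim1", 150, "TA", "T", "DEL", "hom", 0.9, 120, 1),
    ])
    path = tmp_path / "calls.vcf"
    write_vcf(vs, path, panel)
    text = path.read_text()
    assert "sim1\t298\t" in text    # 0-based 297 -> VCF POS 298
    back = read_vcf(path)
    assert back.keys() == vs.keys()
    for call in back:
        orig = vs.get(call.key)
        assert call.kind == orig.kind
        assert call.genotype == orig.genotype
        assert call.step == orig.step
        assert call.alt_fraction == pytest.approx(orig.alt_fraction, abs=1e-5)


def test_empty_vcf_round_trip(panel, tmp_path):
    path = tmp_path / "empty.vcf"
    write_vcf(VariantSet(), path, panel)
    assert all(l.startswith("#") for l in path.read_text().splitlines())
    assert len(read_vcf(path)) == 0


def test_malformed_vcf_raises(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text("not a vcf\n")
    with pytest.raises(VcfParseError):
        read_vcf(path)


def test_pileup_conservation_against_naive_recount(panel, sd1_small):
    """Per-column contributions equal a naive per-read recount."""
    from adotrim.align import align_pairs
    from adotrim.trim import trim_pairs

    trimmed, _ = trim_pairs(sd1_small.pairs, panel)
    aligned, _ = align_pairs(trimmed, panel)
    cols = {(c.chrom, c.pos): c for c in build_pileup(aligned, panel)}
    naive: dict[tuple, int] = {}
    for read in aligned:
        t = read.ref_start
        for op, n in read.ops:
            if op == "M":
                for p in range(t, t + n):
                    naive[(read.chrom, p)] = naive.get((read.chrom, p), 0) + 1
                t += n
            elif op == "D":
                for p in range(t, t + n):
                    naive[(read.chrom, p)] = naive.get((read.chrom, p), 0) + 1
                t += n
    targets = panel.target_intervals(include_primers=True)
    for (chrom, pos), depth in naive.items():
        if any(iv.contains(chrom, pos) for iv in targets):
            assert cols[(chrom, pos)].depth == depth
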