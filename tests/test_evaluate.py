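from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cobin import _kmers
from cobin.decontam import align_contigs
from cobin.evaluate import (
    LARGE_INDEL,
    SMALL_INDEL,
    SNV,
    VariantRecord,
    assign_contig_truth,
    call_variants,
    classify_quality,
    count_valid_fragments,
    genome_fraction,
    nx_ngx,
    shared_variants,
    snv_density,
    truth_quality,
    write_vcf,
)
from cobin.io import AlignmentRecord, parse_paf


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _alignment(ts, te, ani=99.0, cigar=None, query="q", qlen=None, qs=0, qe=None):
    block = te - ts
    qe = qe if qe is not None else block
    qlen = qlen or qe
    return AlignmentRecord(
        query_id=query, query_length=qlen, query_start=qs, query_end=qe, strand="+",
        target_id="ref", target_length=1_000_000, target_start=ts, target_end=te,
        matches=round(block * ani / 100), block_length=block, cigar=cigar,
    )


def test_genome_fraction_arithmetic():
    assert genome_fraction(10_000, [_alignment(500, 9_500)]) == pytest.approx(90.0)
    assert genome_fraction(10_000, []) == 0.0
    # identity threshold is strict: ANI exactly 95 does not qualify
    assert genome_fraction(10_000, [_alignment(0, 10_000, ani=95.0)]) == 0.0


@given(
    st.lists(st.tuples(st.integers(0, 9_000), st.integers(1, 2_000)), max_size=40),
    st.integers(5_000, 20_000),
)
def test_genome_fraction_equals_bitmap(intervals, ref_len):
    alignments = [_alignment(s, min(s + l, ref_len)) for s, l in intervals if s < ref_len]
    bitmap = np.zeros(ref_len, dtype=bool)
    for a in alignments:
        bitmap[a.target_start : a.target_end] = True
    assert genome_fraction(ref_len, alignments) == pytest.approx(100 * bitmap.mean())


def test_nx_ngx_worked_example():
    # assembly 15 kb (half 7.5): cumulative 5,9 -> N50 = 4 kb
    # reference 10 kb (half 5): cumulative 5 -> NG50 = 5 kb
    assert nx_ngx([5_000, 4_000, 3_000, 2_000, 1_000], 10_000) == (4_000, 5_000)


def test_nx_ngx_edge_cases():
    assert nx_ngx([7_000], 10_000) == (7_000, 7_000)
    assert nx_ngx([7_000], 20_000) == (7_000, 0)  # assembly below half the reference
    assert nx_ngx([2_000, 2_000, 2_000], 6_000) == (2_000, 2_000)
    assert nx_ngx([], 10_000) == (0, 0)
    with pytest.raises(ValueError):
        nx_ngx([0, 5], 10)


@given(
    st.lists(st.integers(1, 1_000), min_size=1, max_size=100),
    st.integers(1, 50_000),
)
def test_nx_ngx_matches_brute_force(lengths, ref_len):
    n50, ng50 = nx_ngx(lengths, ref_len)
    desc = sorted(lengths, reverse=True)

    def brute(half):
        cum = 0
        for l in desc:
            cum += l
            if cum >= half:
                return l
        return 0

    assert n50 == brute(sum(lengths) / 2)
    assert ng50 == brute(ref_len / 2)


def _placements(pairs):
    return {"b1": {"ref": pairs}}


def test_valid_fragment_definition():
    six_pairs_12kb = [(i * 2_400, i * 2_400 + 300) for i in range(6)]  # span 12300
    (cluster,) = count_valid_fragments(_placements(six_pairs_12kb))
    assert cluster.valid and cluster.read_pair_count == 6

    five_pairs = six_pairs_12kb[:5]  # exactly 5 pairs: invalid (strict > 5)
    (cluster,) = count_valid_fragments(_placements(five_pairs))
    assert not cluster.valid

    six_pairs_8kb = [(i * 1_540, i * 1_540 + 300) for i in range(6)]  # span 8000
    (cluster,) = count_valid_fragments(_placements(six_pairs_8kb))
    assert cluster.span == 8_000 and not cluster.valid


def test_valid_fragment_span_boundary_exact():
    # span exactly 10,000: invalid under the strict rule
    pairs = [(i * 1_940, i * 1_940 + 300) for i in range(6)]
    assert pairs[-1][1] - pairs[0][0] == 10_000
    (cluster,) = count_valid_fragments(_placements(pairs))
    assert cluster.span == 10_000 and not cluster.valid
    # one base more is valid
    pairs[-1] = (pairs[-1][0], pairs[-1][1] + 1)
    (cluster,) = count_valid_fragments(_placements(pairs))
    assert cluster.valid


def test_clusters_split_on_large_gaps():
    near = [(i * 2_500, i * 2_500 + 300) for i in range(6)]
    far = [(200_000 + i * 2_500, 200_000 + i * 2_500 + 300) for i in range(6)]
    clusters = count_valid_fragments(_placements(near + far))
    assert len(clusters) == 2 and all(c.valid for c in clusters)


def test_valid_fragments_match_brute_force():
    rng = np.random.default_rng(41)
    placements = defaultdict(lambda: defaultdict(list))
    records = []
    for _ in range(1_000):
        barcode = f"b{rng.integers(0, 60)}"
        ref = f"ref{rng.integers(0, 3)}"
        start = int(rng.integers(0, 500_000))
        placements[barcode][ref].append((start, start + 300))
        records.append((barcode, ref, start))
    clusters = count_valid_fragments(placements)

    expected_valid = 0
    for barcode in placements:
        for ref in placements[barcode]:
            ivs = sorted(placements[barcode][ref])
            groups = [[ivs[0]]]
            for iv in ivs[1:]:
                if iv[0] - groups[-1][-1][0] > 50_000:
                    groups.append([iv])
                else:
                    groups[-1].append(iv)
            for g in groups:
                span = max(e for _, e in g) - min(s for s, _ in g)
                if len(g) > 5 and span > 10_000:
                    expected_valid += 1
    assert sum(1 for c in clusters if c.valid) == expected_valid
    assert sum(c.read_pair_count for c in clusters) == 1_000


@pytest.mark.parametrize(
    "completeness, contamination, tier",
    [
        (92, 3, "high"),
        (92, 6, "medium"),  # misses the contamination cut for high
        (49, 2, "low"),
        (90, 3, "medium"),  # completeness boundary is strict
        (92, 5, "medium"),  # contamination boundary is strict
        (50, 2, "low"),
        (100, 0, "high"),
    ],
)
def test_quality_tiers(completeness, contamination, tier):
    assert classify_quality(completeness, contamination) == tier


def test_quality_tier_range_check():
    with pytest.raises(ValueError):
        classify_quality(120, 0)
    with pytest.raises(ValueError):
        classify_quality(50, -1)


def test_truth_quality_perfect_and_mixed():
    rng = np.random.default_rng(42)
    genome = _random_seq(rng, 6_000)
    comp, cont = truth_quality([("c1", genome, "target")], ("target", genome))
    assert comp == pytest.approx(100.0) and cont == 0.0

    foreign = _random_seq(rng, 3_000)
    half = genome[:3_000]
    comp, cont = truth_quality(
        [("c1", half, "target"), ("c2", foreign, "other")], ("target", genome)
    )
    assert cont == pytest.approx(50.0)
    assert comp == pytest.approx(50.0, abs=1)


def test_truth_quality_requires_labels():
    with pytest.raises(ValueError, match="missing truth"):
        truth_quality([("c1", "ACGT", None)], ("t", "ACGT"))


def test_assign_contig_truth_by_kmer_voting():
    rng = np.random.default_rng(43)
    g1, g2 = _random_seq(rng, 3_000), _random_seq(rng, 3_000)
    truth = assign_contig_truth(
        [("a", g1[100:900]), ("b", g2[0:700]), ("junk", _random_seq(rng, 500))],
        {"g1": g1, "g2": g2},
    )
    assert truth == {"a": "g1", "b": "g2", "junk": None}


def _planted_alignment(rng, scale):
    """Reference + query with 1 SNV, one 30 bp deletion, one 60 bp insertion."""
    ref = _random_seq(rng, scale + 1_000)
    p_snv, p_del, p_ins = scale // 2, scale * 3 // 4, scale * 7 // 8
    alt = "ACGT"[("ACGT".index(ref[p_snv]) + 1) % 4]
    ins = _random_seq(rng, 60)
    query = (
        ref[:p_snv] + alt + ref[p_snv + 1 : p_del]
        + ref[p_del + 30 : p_ins] + ins + ref[p_ins:scale]
    )
    cigar = (
        f"{p_snv}=1X{p_del - p_snv - 1}={30}D{p_ins - p_del - 30}={60}I{scale - p_ins}="
    )
    rec = AlignmentRecord(
        query_id="q", query_length=len(query), query_start=0, query_end=len(query),
        strand="+", target_id="ref", target_length=len(ref), target_start=0,
        target_end=scale, matches=scale - 31, block_length=scale + 60, cigar=cigar,
    )
    return ref, query, rec, (p_snv, p_del, p_ins)


def test_variant_classes_from_cigar():
    rng = np.random.default_rng(44)
    ref, query, rec, (p_snv, p_del, p_ins) = _planted_alignment(rng, 12_000)
    variants = call_variants([rec], {"q": query}, {"ref": ref})
    by_class = {c: [v for v in variants if v.var_class == c]
                for c in (SNV, SMALL_INDEL, LARGE_INDEL)}
    assert [len(by_class[c]) for c in (SNV, SMALL_INDEL, LARGE_INDEL)] == [1, 1, 1]
    assert by_class[SNV][0].position == p_snv
    assert by_class[SNV][0].ref == ref[p_snv]
    assert by_class[SMALL_INDEL][0].position == p_del - 1
    assert len(by_class[SMALL_INDEL][0].ref) - len(by_class[SMALL_INDEL][0].alt) == 30
    assert by_class[LARGE_INDEL][0].position == p_ins - 1
    assert len(by_class[LARGE_INDEL][0].alt) - len(by_class[LARGE_INDEL][0].ref) == 60


def test_short_alignments_are_discarded_wholesale():
    rng = np.random.default_rng(45)
    ref, query, rec, _ = _planted_alignment(rng, 8_000)
    assert call_variants([rec], {"q": query}, {"ref": ref}) == []


def test_single_base_indels_ignored():
    rng = np.random.default_rng(46)
    ref = _random_seq(rng, 12_000)
    query = ref[:5_000] + ref[5_001:9_000] + "A" + ref[9_000:11_000]
    cigar = "5000=1D3999=1I2000="
    rec = AlignmentRecord(
        query_id="q", query_length=len(query), query_start=0, query_end=len(query),
        strand="+", target_id="ref", target_length=len(ref), target_start=0,
        target_end=11_000, matches=10_999, block_length=11_001, cigar=cigar,
    )
    assert call_variants([rec], {"q": query}, {"ref": ref}) == []


def test_missing_cigar_errors():
    rec = _alignment(0, 15_000)
    with pytest.raises(ValueError, match="lacks a CIGAR"):
        call_variants([rec], {"q": ""}, {"ref": ""})


def test_plant_and_recover_through_the_aligner():
    """Variants planted in a sample sequence are recovered via the toy
    aligner's CIGARs with exact class counts and near-exact positions."""
    rng = np.random.default_rng(47)
    ref = _random_seq(rng, 15_000)
    snv_pos = [2_000, 5_000, 12_000]
    del_spec = (7_000, 25)  # small
    ins_spec = (10_000, 70)  # large
    query = list(ref)
    for p in snv_pos:
        query[p] = "ACGT"[("ACGT".index(ref[p]) + 2) % 4]
    query = "".join(query)
    query = query[: ins_spec[0]] + _random_seq(rng, ins_spec[1]) + query[ins_spec[0] :]
    d0 = del_spec[0]
    query = query[:d0] + query[d0 + del_spec[1] :]
    alignments = align_contigs([("q", query)], ("ref", ref))
    variants = call_variants(
        alignments, {"q": query}, {"ref": ref}, min_alignment_len=10_000
    )
    snvs = sorted(v.position for v in variants if v.var_class == SNV)
    assert snvs == snv_pos
    smalls = [v for v in variants if v.var_class == SMALL_INDEL]
    larges = [v for v in variants if v.var_class == LARGE_INDEL]
    assert len(smalls) == 1 and len(larges) == 1
    assert abs(smalls[0].position - del_spec[0]) <= 30
    assert abs(larges[0].position - ins_spec[0]) <= 75


def test_shared_variants_keying():
    v = VariantRecord(101, "ref", 500, "A", "C", SNV)
    w = VariantRecord(101, "ref", 500, "A", "G", SNV)  # same position, other alt
    table = shared_variants({"s1": [v], "s2": [v], "s3": [v, w]})
    shared3 = table[table.n_samples == 3]
    assert len(shared3) == 1 and shared3.iloc[0].n_variants == 1
    unique = table[table.n_samples == 1]
    assert unique.iloc[0].n_variants == 1  # w is private to s3
    with pytest.raises(ValueError, match="at least two"):
        shared_variants({"s1": [v]})


def test_shared_variants_match_brute_force():
    rng = np.random.default_rng(48)
    samples = ["s1", "s2", "s3"]
    pool = [
        VariantRecord(101, "ref", int(p), "A", "ACGT"[int(a)], SNV)
        for p, a in zip(rng.integers(0, 500, 60), rng.integers(0, 4, 60))
    ]
    sets = {s: [v for v in pool if rng.random() < 0.5] for s in samples}
    table = shared_variants(sets)
    membership = defaultdict(set)
    for s, vs in sets.items():
        for v in vs:
            membership[v.key].add(s)
    for n in (1, 2, 3):
        expected = sum(1 for m in membership.values() if len(m) == n)
        got = int(table[table.n_samples == n].n_variants.sum())
        assert got == expected


def test_snv_density_convention():
    variants = [VariantRecord(1, "r", i, "A", "C", SNV) for i in range(90)]
    assert snv_density(variants, 1_000_000) == pytest.approx(9.0)
    assert snv_density([], 1_000) == 0.0
    with pytest.raises(ValueError):
        snv_density(variants, 0)


def test_vcf_output_is_one_based(tmp_path):
    variants = [VariantRecord(101, "chr", 0, "A", "C", SNV, "s1")]
    path = tmp_path / "out.vcf"
    assert write_vcf(variants, path) == 1
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert lines[0].split("\t")[:5] == ["chr", "1", ".", "A", "C"]
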