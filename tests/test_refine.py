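from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cobin.io import UNBARCODED, ClassificationRecord, ReadPairRecord
from cobin.refine import (
    BarcodeStat,
    RefinementConfig,
    collect_refined_reads,
    compute_barcode_stats,
    estimate_abundance,
    extract_taxonomy_reads,
    lift_classifications,
    rank_barcodes,
    refine_all_species,
)
from cobin.taxonomy import RANK_GENUS, RANK_ROOT, RANK_SPECIES, TaxonNode, TaxonomyTree


def _tree():
    return TaxonomyTree(
        [
            TaxonNode(1, 1, RANK_ROOT, "root"),
            TaxonNode(10, 1, RANK_GENUS, "g"),
            TaxonNode(101, 10, RANK_SPECIES, "s1"),
            TaxonNode(102, 10, RANK_SPECIES, "s2"),
            TaxonNode(1011, 101, "strain", "s1-strain"),
        ]
    )


def _pair(read_id, barcode, n_bases=200):
    half = n_bases // 2
    return ReadPairRecord(read_id, barcode, "A" * half, "C" * half, "I" * half, "I" * half)


def test_extract_taxonomy_reads_definition():
    tree = _tree()
    cls = [
        ClassificationRecord("r1", True, 101),
        ClassificationRecord("r2", True, 10),  # genus, not a TR
        ClassificationRecord("r3", False, 0),
    ]
    assert extract_taxonomy_reads(cls, 101, tree) == {"r1"}
    assert extract_taxonomy_reads([], 101, tree) == set()
    with pytest.raises(ValueError, match="not species rank"):
        extract_taxonomy_reads(cls, 10, tree)


def test_strain_assignments_lift_to_species():
    tree = _tree()
    lifted = lift_classifications([ClassificationRecord("r1", True, 1011)], tree)
    assert lifted[0].taxid == 101


def test_abundance_arithmetic():
    pairs = [_pair(f"r{i}", "1_1_1") for i in range(5000)]
    assert estimate_abundance(pairs, 100_000) == pytest.approx(10.0)
    assert estimate_abundance([], 100_000) == 0.0
    with pytest.raises(ValueError):
        estimate_abundance([], 0)


def test_barcode_stats_example():
    reads = [_pair(f"t{i}", "b1") for i in range(6)] + [_pair(f"n{i}", "b1") for i in range(2)]
    reads += [_pair(f"x{i}", "b2") for i in range(3)]  # no TRs: not a candidate
    reads += [_pair("u0", UNBARCODED)]  # unbarcoded: never a candidate
    trs = {f"t{i}" for i in range(6)} | {"u0"}
    stats = compute_barcode_stats(reads, trs)
    assert len(stats) == 1
    (stat,) = stats
    assert (stat.barcode, stat.num_t, stat.total_reads) == ("b1", 6, 8)
    assert stat.ratio_t == pytest.approx(0.75)
    assert stat.total_bases == 8 * 200


def test_barcode_stats_match_brute_force():
    rng = np.random.default_rng(12)
    reads = [_pair(f"r{i}", f"b{rng.integers(0, 40)}") for i in range(800)]
    trs = {r.read_id for r in reads if rng.random() < 0.3}
    stats = {s.barcode: s for s in compute_barcode_stats(reads, trs)}
    for barcode in {r.barcode for r in reads}:
        members = [r for r in reads if r.barcode == barcode]
        n_tr = sum(1 for r in members if r.read_id in trs)
        if n_tr == 0:
            assert barcode not in stats
        else:
            s = stats[barcode]
            assert (s.num_t, s.total_reads) == (n_tr, len(members))
            assert s.total_bases == sum(r.total_bases for r in members)


def test_rank_barcodes_stated_order():
    stats = [
        BarcodeStat("b1", 5, 10, 2000),  # ratio 0.5
        BarcodeStat("b2", 7, 23, 4600),  # highest num_t wins outright
        BarcodeStat("b3", 5, 5, 1111),  # ties b1 on num_t, higher ratio
    ]
    assert [s.barcode for s in rank_barcodes(stats)] == ["b2", "b3", "b1"]
    tied = [BarcodeStat("bB", 3, 6, 1), BarcodeStat("bA", 3, 6, 1)]
    assert [s.barcode for s in rank_barcodes(tied)] == ["bA", "bB"]


def test_rank_barcodes_matches_brute_force_sort():
    rng = np.random.default_rng(13)
    stats = []
    for i in range(1000):
        total = int(rng.integers(1, 30))
        stats.append(
            BarcodeStat(f"b{i:04d}", int(rng.integers(0, total + 1)), total, total * 200)
        )
    expected = sorted(
        stats, key=lambda s: (-s.num_t, -Fraction(s.num_t, s.total_reads), s.barcode)
    )
    assert rank_barcodes(stats) == expected


def _barcode_reads(n_barcodes, pairs_per_barcode, bases_per_pair=200):
    reads_by_barcode = {}
    ranked = []
    for i in range(n_barcodes):
        barcode = f"c{i:03d}"
        reads = [_pair(f"{barcode}_r{j}", barcode, bases_per_pair)
                 for j in range(pairs_per_barcode)]
        reads_by_barcode[barcode] = reads
        ranked.append(
            BarcodeStat(barcode, pairs_per_barcode, pairs_per_barcode,
                        pairs_per_barcode * bases_per_pair)
        )
    return ranked, reads_by_barcode


def test_cap_includes_crossing_barcode_then_stops():
    """300x cap on a 1 kb reference = 300,000 bases; 150,000-base barcodes
    mean exactly two are collected (the second crosses the cap)."""
    ranked, reads_by_barcode = _barcode_reads(4, 750)  # 150,000 bases each
    refined, collected, capped = collect_refined_reads(
        ranked, reads_by_barcode, reference_length=1_000
    )
    assert collected == ["c000", "c001"]
    assert capped
    assert len(refined) == 2 * 750


def test_below_cap_collects_everything():
    ranked, reads_by_barcode = _barcode_reads(5, 10)
    refined, collected, capped = collect_refined_reads(
        ranked, reads_by_barcode, reference_length=1_000
    )
    assert len(collected) == 5 and not capped
    assert len(refined) == 50


def test_cap_monotonicity_prefix_consistency():
    ranked, reads_by_barcode = _barcode_reads(20, 100)
    collected_prev = None
    for cap in (11, 50, 150, 300):
        cfg = RefinementConfig(cap_coverage=cap)
        _, collected, _ = collect_refined_reads(ranked, reads_by_barcode, 1_000, cfg)
        if collected_prev is not None:
            assert collected[: len(collected_prev)] == collected_prev
            assert len(collected) >= len(collected_prev)
        collected_prev = collected


@given(st.integers(1, 40), st.integers(1, 20), st.integers(500, 5_000))
def test_collect_matches_brute_force_walk(n_barcodes, pairs_per_barcode, ref_len):
    ranked, reads_by_barcode = _barcode_reads(n_barcodes, pairs_per_barcode)
    cfg = RefinementConfig()
    refined, collected, capped = collect_refined_reads(
        ranked, reads_by_barcode, ref_len, cfg
    )
    # brute-force re-walk
    cum, expected = 0, []
    for stat in ranked:
        expected.append(stat.barcode)
        cum += stat.total_bases
        if cum >= cfg.cap_coverage * ref_len:
            break
    assert collected == expected
    assert refined == {r.read_id for b in expected for r in reads_by_barcode[b]}
    assert capped == (cum >= cfg.cap_coverage * ref_len)


def _gate_inputs(n_tr_pairs):
    tree = _tree()
    reads = [_pair(f"r{i}", f"b{i % 7}") for i in range(n_tr_pairs)]
    cls = [ClassificationRecord(r.read_id, True, 101) for r in reads]
    return tree, reads, cls


def test_abundance_gate_is_strict():
    # 200-base pairs on a 1 kb reference: 50 pairs -> exactly 10.0x
    tree, reads, cls = _gate_inputs(50)
    result = refine_all_species(cls, reads, {101: 1_000}, tree)
    assert result.read_sets == {} and result.skipped[101] == pytest.approx(10.0)
    tree, reads, cls = _gate_inputs(51)  # 10.2x clears the strict gate
    result = refine_all_species(cls, reads, {101: 1_000}, tree)
    assert 101 in result.read_sets
    assert result.read_sets[101].abundance == pytest.approx(10.2)


def test_refine_all_rejects_non_species_reference():
    tree, reads, cls = _gate_inputs(20)
    with pytest.raises(ValueError, match="not a species"):
        refine_all_species(cls, reads, {10: 1_000}, tree)


def test_unbarcoded_trs_excluded_by_default_included_on_flag():
    tree = _tree()
    reads = [_pair(f"r{i}", "b1") for i in range(60)] + [_pair("u1", UNBARCODED)]
    cls = [ClassificationRecord(r.read_id, True, 101) for r in reads]
    result = refine_all_species(cls, reads, {101: 1_000}, tree)
    assert "u1" not in result.read_sets[101].refined_read_ids
    cfg = RefinementConfig(include_unbarcoded=True)
    result = refine_all_species(cls, reads, {101: 1_000}, tree, cfg)
    assert "u1" in result.read_sets[101].refined_read_ids


def test_refinement_precision_with_pure_barcodes(clean_dataset, clean_classifications):
    """collision 0 + error-free reads: every refined read originates from
    its target species."""
    ds = clean_dataset
    tree = ds.community.taxonomy
    ref_lengths = {ds.community.taxids[n]: len(s) for n, s in ds.community.references.items()}
    result = refine_all_species(clean_classifications, ds.reads, ref_lengths, tree)
    truth = {r.read_id: r.truth_genome for r in ds.reads}
    name_by_taxid = {t: n for n, t in ds.community.taxids.items()}
    assert result.read_sets  # at least one species above the gate
    for taxid, rs in result.read_sets.items():
        assert all(truth[i] == name_by_taxid[taxid] for i in rs.refined_read_ids)


def test_refined_set_recruits_beyond_trs(clean_dataset, clean_classifications):
    """Barcode recruitment recovers unclassified unique-region reads: the
    refined set strictly contains reads that are not TRs."""
    ds = clean_dataset
    tree = ds.community.taxonomy
    ref_lengths = {ds.community.taxids[n]: len(s) for n, s in ds.community.references.items()}
    result = refine_all_species(clean_classifications, ds.reads, ref_lengths, tree)
    name_by_taxid = {t: n for n, t in ds.community.taxids.items()}
    for taxid, rs in result.read_sets.items():
        assert rs.tr_read_ids <= rs.refined_read_ids
        if name_by_taxid[taxid] in ("alpha", "beta"):  # species with insertions
            assert rs.tr_read_ids < rs.refined_read_ids


def test_refinement_is_order_invariant(clean_dataset, clean_classifications):
    ds = clean_dataset
    tree = ds.community.taxonomy
    ref_lengths = {ds.community.taxids[n]: len(s) for n, s in ds.community.references.items()}
    fwd = refine_all_species(clean_classifications, ds.reads, ref_lengths, tree)
    rev = refine_all_species(
        list(clean_classifications)[::-1], list(ds.reads)[::-1], ref_lengths, tree
    )
    for taxid in fwd.read_sets:
        assert fwd.read_sets[taxid].refined_read_ids == rev.read_sets[taxid].refined_read_ids
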