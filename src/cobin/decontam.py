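"""Contamination removal by per-alignment ANI and per-contig alignment fraction.

Barcode collisions recruit a few reads from foreign species into a refined
read set; those assemble into contigs that do not resemble the target
species' reference.  Each contig is aligned to the reference; alignments
with ANI strictly above 90% contribute to the contig's alignment fraction
(AF, merged aligned bases / contig length), and only contigs with AF
strictly above 50% survive.

ANI of one alignment is ``100 * matches / block_length`` where the block
length counts match, mismatch, inserted and deleted columns (gap columns
included in the denominator).

The built-in aligner is exact-seed (19-mers) + greedy collinear chaining +
global gap-aware extension over the chained span (edlib); it emits extended
CIGARs, so the same alignments also drive variant calling.  External
aligner output is ingested as PAF with ``cg:Z`` tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from . import _kmers
from .assemble import ContigSet
from .io import AlignmentRecord, parse_cigar

TOY = "toy"
EXTERNAL_PAF = "external_paf"


def alignment_ani(record: AlignmentRecord) -> float:
    """Percent identity of one alignment: 100 x matches / block columns."""
    return record.ani


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass
class AFResult:
    contig_id: str
    contig_length: int
    qualifying_bases: int
    af: float
    kept: bool


def compute_alignment_fraction(
    contig_id: str,
    contig_length: int,
    alignments: Sequence[AlignmentRecord],
    ani_min: float = 90.0,
    af_min: float = 0.5,
) -> AFResult:
    """AF of one contig: merged query coverage by alignments with ANI > ani_min.

    Both thresholds are strict; a contig at AF exactly ``af_min`` is dropped.
    """
    qualifying = [
        (r.query_start, r.query_end)
        for r in alignments
        if r.query_id == contig_id and r.block_length > 0 and r.ani > ani_min
    ]
    covered = sum(b - a for a, b in merge_intervals(qualifying))
    af = covered / contig_length if contig_length else 0.0
    return AFResult(contig_id, contig_length, covered, af, af > af_min)


def filter_contigs(
    contig_set: ContigSet, af_results: Mapping[str, AFResult], af_min: float = 0.5
) -> tuple[ContigSet, list[AFResult]]:
    """Retain contigs with AF strictly above ``af_min``; report the dropped."""
    kept = []
    dropped = []
    for cid, seq in contig_set.contigs:
        res = af_results[cid]
        if res.af > af_min:
            kept.append((cid, seq))
        else:
            dropped.append(res)
    return ContigSet(contig_set.species, kept, contig_set.provenance), dropped


# ---------------------------------------------------------------------------
# Toy aligner: exact k-mer seeds -> greedy collinear chains -> edlib extension


@dataclass
class _Chain:
    qstart: int
    qend: int  # query position of last seed (start)
    tstart: int
    tend: int
    n_seeds: int


def _seed_index(ref_codes: np.ndarray, k: int, max_occ: int = 20) -> dict[int, list[int]]:
    index: dict[int, list[int]] = {}
    fwd = _kmers.forward_kmer_codes(ref_codes, k)
    for pos, code in enumerate(fwd.tolist()):
        slot = index.setdefault(code, [])
        if len(slot) < max_occ:
            slot.append(pos)
    return index


def _chain_anchors(
    anchors: list[tuple[int, int]], k: int, max_gap: int, max_diag_drift: int
) -> list[_Chain]:
    chains: list[_Chain] = []
    for qpos, tpos in anchors:  # anchors sorted by (qpos, tpos)
        best = None
        for chain in chains:
            if chain.qend < qpos and chain.tend < tpos:
                qgap = qpos - chain.qend
                tgap = tpos - chain.tend
                if qgap <= max_gap and tgap <= max_gap and abs(qgap - tgap) <= max_diag_drift:
                    if best is None or chain.n_seeds > best.n_seeds:
                        best = chain
        if best is None:
            chains.append(_Chain(qpos, qpos, tpos, tpos, 1))
        else:
            best.qend = qpos
            best.tend = tpos
            best.n_seeds += 1
    return [c for c in chains if c.n_seeds >= 2 or c.qend - c.qstart + k >= 200]


def _extend_chain(
    query: str, ref: str, chain: _Chain, k: int, q_lo: int, q_hi: int, pad: int = 400
) -> tuple[int, int, int, int, str] | None:
    """Globally align query[q_lo:q_hi] inside a padded reference window."""
    t_lo = max(0, chain.tstart - (chain.qstart - q_lo) - pad)
    t_hi = min(len(ref), chain.tend + k + (q_hi - chain.qend - k) + pad)
    segment = query[q_lo:q_hi]
    window = ref[t_lo:t_hi]
    if not segment or not window:
        return None
    res = edlib.align(segment, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_start, loc_end = res["locations"][0]
    cigar = _consolidate_gaps(
        res["cigar"], segment, window[loc_start : loc_end + 1]
    )
    return q_lo, q_hi, t_lo + loc_start, t_lo + loc_end + 1, cigar


def _cigar_stats(cigar: str) -> tuple[int, int]:
    matches = 0
    block = 0
    for op, length in parse_cigar(cigar):
        if op == "=":
            matches += length
        if op in "=XID":
            block += length
    return matches, block


_AFFINE = Align.PairwiseAligner()
_AFFINE.mode = "global"
_AFFINE.match_score = 1
_AFFINE.mismatch_score = -4
_AFFINE.open_gap_score = -8
_AFFINE.extend_gap_score = -0.2

_ANCHOR_RUN = 15  # '=' runs at least this long bound a messy region
_MAX_REALIGN = 2_000  # never realign regions larger than this


def _blocks_to_ops(target_seg: str, query_seg: str, aln) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    t_blocks, q_blocks = aln.aligned
    t_prev = q_prev = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > t_prev:
            ops.append(("D", ts - t_prev))
        if qs > q_prev:
            ops.append(("I", qs - q_prev))
        run_op, run_len = "", 0
        for a, b in zip(target_seg[ts:te], query_seg[qs:qe]):
            op = "=" if a == b else "X"
            if op == run_op:
                run_len += 1
            else:
                if run_len:
                    ops.append((run_op, run_len))
                run_op, run_len = op, 1
        if run_len:
            ops.append((run_op, run_len))
        t_prev, q_prev = te, qe
    if len(target_seg) > t_prev:
        ops.append(("D", len(target_seg) - t_prev))
    if len(query_seg) > q_prev:
        ops.append(("I", len(query_seg) - q_prev))
    return ops


def _consolidate_gaps(cigar: str, query_seg: str, target_seg: str) -> str:
    """Re-align messy CIGAR regions with affine gap scoring.

    Unit-cost edit-distance alignment often shreds one long indel into
    several short gaps interleaved with coincidental matches (the total
    cost is identical).  Regions between long match runs that contain more
    than one indel op are re-aligned with affine gap penalties, restoring
    contiguous gap runs the way affine-gap aligners report them.
    """
    ops = parse_cigar(cigar)
    # partition into alternating [anchor | messy] stretches
    out: list[tuple[str, int]] = []
    region: list[tuple[str, int]] = []
    qpos = tpos = 0

    def flush_region() -> None:
        nonlocal out, region
        if not region:
            return
        n_indel = sum(1 for op, _ in region if op in "ID")
        if n_indel <= 1:
            out.extend(region)
            region = []
            return
        q0 = sum(l for op, l in out if op in "=XMI")
        t0 = sum(l for op, l in out if op in "=XMD")
        ql = sum(l for op, l in region if op in "=XMI")
        tl = sum(l for op, l in region if op in "=XMD")
        if max(ql, tl) > _MAX_REALIGN or min(ql, tl) == 0:
            out.extend(region)
            region = []
            return
        q_sub = query_seg[q0 : q0 + ql]
        t_sub = target_seg[t0 : t0 + tl]
        aln = _AFFINE.align(t_sub, q_sub)[0]
        out.extend(_blocks_to_ops(t_sub, q_sub, aln))
        region = []

    for op, length in ops:
        if op == "=" and length >= _ANCHOR_RUN:
            flush_region()
            out.append((op, length))
        else:
            region.append((op, length))
    flush_region()
    # merge adjacent identical ops
    merged: list[tuple[str, int]] = []
    for op, length in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return "".join(f"{l}{o}" for o, l in merged)


def _trim_cigar_ends(
    cigar: str, anchor: int = _ANCHOR_RUN
) -> tuple[str, int, int, int, int] | None:
    """Trim alignment ends back to the outermost '=' runs of ``anchor`` bp.

    Flank extension past the truly homologous region leaves low-identity
    tails of coincidental matches; clipping to solid anchors restores the
    local-alignment ends.  Returns (cigar, leading query/target trim,
    trailing query/target trim) or None when no anchor run exists.
    """
    ops = parse_cigar(cigar)

    def consumed(sub) -> tuple[int, int]:
        q = sum(l for op, l in sub if op in "=XMI")
        t = sum(l for op, l in sub if op in "=XMD")
        return q, t

    first = next((i for i, (op, l) in enumerate(ops) if op == "=" and l >= anchor), None)
    if first is None:
        return None
    last = max(i for i, (op, l) in enumerate(ops) if op == "=" and l >= anchor)
    dq0, dt0 = consumed(ops[:first])
    dq1, dt1 = consumed(ops[last + 1 :])
    kept = ops[first : last + 1]
    return "".join(f"{l}{o}" for o, l in kept), dq0, dt0, dq1, dt1


def _split_cigar_at_gaps(
    cigar: str, q0: int, t0: int, split_gap: int
) -> list[tuple[int, int, int, int, str]]:
    """Split an extended CIGAR into local segments at indel runs >= split_gap.

    Per-alignment identity is a local notion: a contig spanning a large
    novel insertion should yield two high-identity alignments flanking the
    gap, not one alignment whose ANI is poisoned by the gap columns.
    Returns (qstart, qend, tstart, tend, cigar) per segment in the same
    (oriented-query, target) frame as the input.
    """
    segments: list[tuple[int, int, int, int, str]] = []
    qpos, tpos = q0, t0
    seg_q, seg_t = q0, t0
    seg_ops: list[str] = []
    for op, length in parse_cigar(cigar):
        if op in ("I", "D") and length >= split_gap:
            if seg_ops:
                segments.append((seg_q, qpos, seg_t, tpos, "".join(seg_ops)))
            if op == "I":
                qpos += length
            else:
                tpos += length
            seg_q, seg_t = qpos, tpos
            seg_ops = []
            continue
        seg_ops.append(f"{length}{op}")
        if op in ("=", "X", "M"):
            qpos += length
            tpos += length
        elif op == "I":
            qpos += length
        elif op == "D":
            tpos += length
    if seg_ops:
        segments.append((seg_q, qpos, seg_t, tpos, "".join(seg_ops)))
    return segments


def align_query(
    query_id: str,
    query: str,
    target_id: str,
    ref: str,
    seed_index: dict[int, list[int]],
    k: int = 19,
    max_gap: int = 20_000,
    min_chain_seeds: int = 3,
    split_gap: int = 1_000,
) -> list[AlignmentRecord]:
    """Align one sequence to the reference on both strands.

    Alignments are split into local segments at indel runs of
    ``split_gap`` bp or more, so large novel insertions separate flanking
    high-identity alignments instead of depressing one global ANI.
    """
    records: list[AlignmentRecord] = []
    qlen = len(query)
    if qlen < k:
        return records
    for strand in "+-":
        oriented = query if strand == "+" else _kmers.revcomp(query)
        codes = _kmers.seq_to_codes(oriented)
        fwd = _kmers.forward_kmer_codes(codes, k)
        stride = max(1, qlen // 800)
        anchors: list[tuple[int, int]] = []
        for qpos in range(0, fwd.size, stride):
            positions = seed_index.get(int(fwd[qpos]))
            if positions:
                for tpos in positions:
                    anchors.append((qpos, tpos))
        anchors.sort()
        # diagonal jumps >= split_gap break chains, so a large novel
        # insertion separates two local alignments instead of poisoning one
        chains = _chain_anchors(anchors, k, max_gap, max_diag_drift=split_gap // 2)
        chains = [c for c in chains if c.n_seeds >= min_chain_seeds or qlen < 3 * k]
        chains.sort(key=lambda c: c.qstart)
        end_flank = 100
        for chain in chains:
            q_lo = max(0, chain.qstart - end_flank)
            q_hi = min(qlen, chain.qend + k + end_flank)
            ext = _extend_chain(oriented, ref, chain, k, q_lo, q_hi)
            if ext is None:
                continue
            q_lo, q_hi, t_lo, t_hi, cigar = ext
            for sq0, sq1, st0, st1, sub_cigar in _split_cigar_at_gaps(
                cigar, q_lo, t_lo, split_gap
            ):
                trimmed = _trim_cigar_ends(sub_cigar)
                if trimmed is None:
                    continue
                sub_cigar, dq0, dt0, dq1, dt1 = trimmed
                sq0, st0 = sq0 + dq0, st0 + dt0
                sq1, st1 = sq1 - dq1, st1 - dt1
                matches, block = _cigar_stats(sub_cigar)
                if block == 0:
                    continue
                if strand == "+":
                    qs, qe = sq0, sq1
                else:
                    qs, qe = qlen - sq1, qlen - sq0
                records.append(
                    AlignmentRecord(
                        query_id=query_id,
                        query_length=qlen,
                        query_start=qs,
                        query_end=qe,
                        strand=strand,
                        target_id=target_id,
                        target_length=len(ref),
                        target_start=st0,
                        target_end=st1,
                        matches=matches,
                        block_length=block,
                        cigar=sub_cigar,
                    )
                )
    # keep the better strand when both produced overlapping alignments
    if len(records) > 1:
        best_by_strand: dict[str, int] = {}
        for r in records:
            best_by_strand[r.strand] = best_by_strand.get(r.strand, 0) + r.matches
        best_strand = max(sorted(best_by_strand), key=lambda s: best_by_strand[s])
        records = [r for r in records if r.strand == best_strand]
    return records


def align_contigs(
    contigs: ContigSet | Sequence[tuple[str, str]],
    reference: tuple[str, str],
    mode: str = TOY,
    paf_records: Sequence[AlignmentRecord] | None = None,
    k: int = 19,
) -> list[AlignmentRecord]:
    """Alignments of every contig against the species reference.

    ``mode='toy'`` runs the built-in aligner; ``mode='external_paf'`` simply
    returns the supplied pre-parsed PAF records.
    """
    if mode == EXTERNAL_PAF:
        if paf_records is None:
            raise ValueError("external_paf mode requires paf_records")
        return list(paf_records)
    if mode != TOY:
        raise ValueError(f"unknown alignment mode {mode!r}")
    pairs = contigs.contigs if isinstance(contigs, ContigSet) else list(contigs)
    ref_id, ref_seq = reference
    if not pairs:
        return []
    index = _seed_index(_kmers.seq_to_codes(ref_seq), k)
    records: list[AlignmentRecord] = []
    for cid, seq in pairs:
        records.extend(align_query(cid, seq, ref_id, ref_seq, index, k=k))
    return records


def decontaminate(
    contig_set: ContigSet,
    reference: tuple[str, str],
    ani_min: float = 90.0,
    af_min: float = 0.5,
    mode: str = TOY,
    paf_records: Sequence[AlignmentRecord] | None = None,
) -> tuple[ContigSet, pd.DataFrame, list[AlignmentRecord]]:
    """Full decontamination of one species' contigs.

    Returns the cleaned contig set, a per-contig report (contig, length,
    af, ani_best, kept) and the raw alignments (reusable for evaluation).
    """
    alignments = align_contigs(contig_set, reference, mode=mode, paf_records=paf_records)
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_contig.setdefault(rec.query_id, []).append(rec)
    results: dict[str, AFResult] = {}
    rows = []
    for cid, seq in contig_set.contigs:
        recs = by_contig.get(cid, [])
        res = compute_alignment_fraction(cid, len(seq), recs, ani_min=ani_min, af_min=af_min)
        results[cid] = res
        rows.append(
            {
                "contig": cid,
                "length": len(seq),
                "af": res.af,
                "ani_best": max((r.ani for r in recs), default=0.0),
                "kept": res.kept,
            }
        )
    cleaned, _ = filter_contigs(contig_set, results, af_min=af_min)
    return cleaned, pd.DataFrame(rows), alignments
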