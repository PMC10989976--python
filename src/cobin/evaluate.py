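"""Assembly assessment: completeness, contiguity, cobarcode yield, variants.

* ``genome_fraction`` — percent of the reference covered by alignments with
  identity strictly above 95% (merged on reference coordinates).
* ``nx_ngx`` — N50 against the assembly size and NG50 against the reference
  size (0 when the assembly reaches less than half the reference).
* ``count_valid_fragments`` — per-barcode read clusters on a reference; a
  cluster is a *valid fragment* when it has strictly more than five read
  pairs spanning strictly more than 10 kb (a proxy for usable long-range
  information).
* ``truth_quality`` — completeness/contamination from simulator truth
  labels: completeness is the fraction of the target genome covered by
  contigs that originate from it, contamination the fraction of contig
  bases whose origin is a different genome.  This replaces marker-gene
  completeness estimation, which only makes sense on real genomes.
* ``classify_quality`` — the standard MAG tiers: high means completeness
  > 90% and contamination < 5%; medium means completeness > 50% and
  contamination < 10% without meeting both high cuts.
* ``call_variants`` — walks extended CIGARs of alignments spanning at least
  10 kb of reference; mismatches are SNVs, single-base indels are ignored,
  2-49 bp indels are small and >= 50 bp are large.  Indel records are
  anchored VCF-style (ref/alt share a leading base).
* ``shared_variants`` — variants keyed by (species, reference, position,
  ref, alt) across samples; identical keys in several samples are shared.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from .assemble import ContigSet
from .decontam import align_contigs, merge_intervals
from .io import AlignmentRecord, parse_cigar

SNV = "snv"
SMALL_INDEL = "small_indel"
LARGE_INDEL = "large_indel"
SMALL_INDEL_MAX = 49  # indels of 50 bp and above are large; 1 bp ignored


@dataclass(frozen=True)
class VariantRecord:
    species: int
    reference_id: str
    position: int  # 0-based on the reference
    ref: str
    alt: str
    var_class: str
    sample: str = ""

    @property
    def key(self) -> tuple:
        return (self.species, self.reference_id, self.position, self.ref, self.alt)


@dataclass
class FragmentCluster:
    barcode: str
    reference_id: str
    positions: list[tuple[int, int]]  # read-pair intervals on the reference
    read_pair_count: int
    span: int
    valid: bool


@dataclass
class QualityReport:
    species: int
    completeness: float
    contamination: float
    n50: int
    ng50: int
    genome_fraction: float
    tier: str


def genome_fraction(
    reference_length: int, alignments: Sequence[AlignmentRecord], identity_min: float = 95.0
) -> float:
    """Percent of the reference covered by alignments with ANI > identity_min."""
    qualifying = [
        (r.target_start, r.target_end)
        for r in alignments
        if r.block_length > 0 and r.ani > identity_min
    ]
    covered = sum(b - a for a, b in merge_intervals(qualifying))
    return 100.0 * covered / reference_length if reference_length else 0.0


def nx_ngx(contig_lengths: Sequence[int], reference_length: int) -> tuple[int, int]:
    """(N50, NG50); NG50 is 0 when the assembly is below half the reference."""
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    if not contig_lengths:
        return 0, 0
    lengths = sorted(contig_lengths, reverse=True)
    cum = np.cumsum(lengths)
    n50 = next(l for l, c in zip(lengths, cum) if c >= sum(lengths) / 2)
    ng50 = 0
    half_ref = reference_length / 2
    for l, c in zip(lengths, cum):
        if c >= half_ref:
            ng50 = l
            break
    return int(n50), int(ng50)


def count_valid_fragments(
    read_alignments_by_barcode: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    gap_max: int = 50_000,
    min_pairs: int = 5,
    min_span: int = 10_000,
) -> list[FragmentCluster]:
    """Cluster read-pair placements per (barcode, reference) and flag valid ones.

    Input maps barcode -> reference id -> read-pair intervals (start, end) on
    that reference.  Positions are sorted and split into clusters wherever
    the gap between adjacent pair starts exceeds ``gap_max``; a cluster is
    valid iff it has strictly more than ``min_pairs`` pairs and its span
    (max end - min start) strictly exceeds ``min_span``.
    """
    clusters: list[FragmentCluster] = []
    for barcode in sorted(read_alignments_by_barcode):
        for ref_id in sorted(read_alignments_by_barcode[barcode]):
            placements = sorted(read_alignments_by_barcode[barcode][ref_id])
            if not placements:
                continue
            current: list[tuple[int, int]] = [placements[0]]
            for iv in placements[1:]:
                if iv[0] - current[-1][0] > gap_max:
                    clusters.append(_make_cluster(barcode, ref_id, current, min_pairs, min_span))
                    current = [iv]
                else:
                    current.append(iv)
            clusters.append(_make_cluster(barcode, ref_id, current, min_pairs, min_span))
    return clusters


def _make_cluster(
    barcode: str, ref_id: str, placements: list[tuple[int, int]], min_pairs: int, min_span: int
) -> FragmentCluster:
    span = max(e for _, e in placements) - min(s for s, _ in placements)
    n = len(placements)
    return FragmentCluster(
        barcode, ref_id, placements, n, span, n > min_pairs and span > min_span
    )


def assign_contig_truth(
    contigs: ContigSet | Sequence[tuple[str, str]],
    sample_genomes: Mapping[str, str],
    k: int = 31,
) -> dict[str, str | None]:
    """Truth genome of each contig by canonical k-mer voting.

    Deterministic: ties (including zero votes everywhere) yield None.
    """
    pairs = contigs.contigs if isinstance(contigs, ContigSet) else list(contigs)
    genome_kmers = {
        name: set(np.unique(_kmers.canonical_kmer_codes(seq, k)).tolist())
        for name, seq in sample_genomes.items()
    }
    out: dict[str, str | None] = {}
    for cid, seq in pairs:
        codes = set(np.unique(_kmers.canonical_kmer_codes(seq, k)).tolist())
        votes = {name: len(codes & kmers) for name, kmers in genome_kmers.items()}
        best = max(votes.values(), default=0)
        winners = sorted(name for name, v in votes.items() if v == best and v > 0)
        out[cid] = winners[0] if len(winners) == 1 else None
    return out


def truth_quality(
    contigs_with_truth: Sequence[tuple[str, str, str | None]],
    target_genome: tuple[str, str],
    ani_min: float = 90.0,
) -> tuple[float, float]:
    """(completeness %, contamination %) from truth-labelled contigs.

    ``contigs_with_truth`` holds (contig id, sequence, truth genome name).
    Completeness: target-genome bases covered by target-origin contigs
    (toy alignments with ANI > ani_min, merged), as a percent of the genome.
    Contamination: percent of total contig bases whose truth label differs
    from the target genome.
    """
    if any(truth is None for _, _, truth in contigs_with_truth):
        raise ValueError("missing truth label on a contig")
    target_name, target_seq = target_genome
    own = [(cid, seq) for cid, seq, truth in contigs_with_truth if truth == target_name]
    total_bases = sum(len(seq) for _, seq, _ in contigs_with_truth)
    foreign_bases = sum(
        len(seq) for _, seq, truth in contigs_with_truth if truth != target_name
    )
    if own:
        alignments = align_contigs(own, (target_name, target_seq))
        covered = sum(
            b - a
            for a, b in merge_intervals(
                (r.target_start, r.target_end)
                for r in alignments
                if r.block_length > 0 and r.ani > ani_min
            )
        )
    else:
        covered = 0
    completeness = 100.0 * covered / len(target_seq)
    contamination = 100.0 * foreign_bases / total_bases if total_bases else 0.0
    return completeness, contamination


def classify_quality(completeness: float, contamination: float) -> str:
    """MAG quality tier: 'high', 'medium' or 'low'."""
    for value in (completeness, contamination):
        if not 0 <= value <= 100:
            raise ValueError(f"percentage out of range: {value}")
    if completeness > 90 and contamination < 5:
        return "high"
    if completeness > 50 and contamination < 10:
        return "medium"
    return "low"


def call_variants(
    alignments: Sequence[AlignmentRecord],
    query_seqs: Mapping[str, str],
    ref_seqs: Mapping[str, str],
    species: int = 0,
    sample: str = "",
    min_alignment_len: int = 10_000,
) -> list[VariantRecord]:
    """Call SNVs and indels from extended CIGARs.

    Alignments whose reference span is shorter than ``min_alignment_len``
    are discarded wholesale.  Single-base indels are ignored entirely;
    2-49 bp indels are small, >= 50 bp large.  Positions are 0-based on the
    reference; indel alleles are anchored on the preceding reference base.
    """
    variants: list[VariantRecord] = []
    for rec in alignments:
        if rec.target_end - rec.target_start < min_alignment_len:
            continue
        if rec.cigar is None:
            raise ValueError(f"alignment of {rec.query_id} lacks a CIGAR")
        ref = ref_seqs[rec.target_id]
        query = query_seqs[rec.query_id]
        oriented = query if rec.strand == "+" else _kmers.revcomp(query)
        if rec.strand == "+":
            qpos = rec.query_start
        else:
            qpos = rec.query_length - rec.query_end
        tpos = rec.target_start
        for op, length in parse_cigar(rec.cigar):
            if op in ("=", "M"):
                if op == "M":
                    for i in range(length):
                        if ref[tpos + i] != oriented[qpos + i]:
                            variants.append(
                                VariantRecord(
                                    species, rec.target_id, tpos + i,
                                    ref[tpos + i], oriented[qpos + i], SNV, sample,
                                )
                            )
                qpos += length
                tpos += length
            elif op == "X":
                for i in range(length):
                    variants.append(
                        VariantRecord(
                            species, rec.target_id, tpos + i,
                            ref[tpos + i], oriented[qpos + i], SNV, sample,
                        )
                    )
                qpos += length
                tpos += length
            elif op == "I":  # present in query, absent from reference
                if length >= 2 and tpos > 0:
                    anchor = tpos - 1
                    variants.append(
                        VariantRecord(
                            species, rec.target_id, anchor,
                            ref[anchor], ref[anchor] + oriented[qpos : qpos + length],
                            SMALL_INDEL if length <= SMALL_INDEL_MAX else LARGE_INDEL,
                            sample,
                        )
                    )
                qpos += length
            elif op == "D":  # absent from query
                if length >= 2 and tpos > 0:
                    anchor = tpos - 1
                    variants.append(
                        VariantRecord(
                            species, rec.target_id, anchor,
                            ref[anchor : tpos + length], ref[anchor],
                            SMALL_INDEL if length <= SMALL_INDEL_MAX else LARGE_INDEL,
                            sample,
                        )
                    )
                tpos += length
            elif op in ("S", "H"):
                if op == "S":
                    qpos += length
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
    return variants


def shared_variants(
    variant_sets_by_sample: Mapping[str, Sequence[VariantRecord]],
) -> pd.DataFrame:
    """Sharing table: one row per (species, variant class, sample subset).

    A variant is shared among exactly the samples in which its
    (species, reference, position, ref, alt) key occurs.
    """
    if len(variant_sets_by_sample) < 2:
        raise ValueError("sharing requires at least two samples")
    occurrences: dict[tuple, set[str]] = defaultdict(set)
    classes: dict[tuple, str] = {}
    for sample in sorted(variant_sets_by_sample):
        for var in variant_sets_by_sample[sample]:
            occurrences[var.key].add(sample)
            classes[var.key] = var.var_class
    counts: dict[tuple, int] = defaultdict(int)
    for key, samples in occurrences.items():
        species = key[0]
        subset = ",".join(sorted(samples))
        counts[(species, classes[key], len(samples), subset)] += 1
    rows = [
        {
            "species": species,
            "var_class": var_class,
            "n_samples": n_samples,
            "samples": subset,
            "n_variants": n,
        }
        for (species, var_class, n_samples, subset), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def snv_density(variants: Sequence[VariantRecord], aligned_reference_bases: int) -> float:
    """SNVs per 100 kb of aligned reference sequence."""
    if aligned_reference_bases <= 0:
        raise ValueError("aligned_reference_bases must be > 0")
    n_snv = sum(1 for v in variants if v.var_class == SNV)
    return n_snv * 100_000 / aligned_reference_bases


def write_vcf(variants: Sequence[VariantRecord], path: str | Path) -> int:
    """Minimal 8-column VCF (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        n = 0
        for v in sorted(variants, key=lambda v: (v.reference_id, v.position, v.alt)):
            info = f"CLASS={v.var_class};SPECIES={v.species}"
            if v.sample:
                info += f";SAMPLE={v.sample}"
            fh.write(
                f"{v.reference_id}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )
            n += 1
    return n


def evaluate_assembly(
    contig_set: ContigSet,
    reference: tuple[str, str],
    alignments: Sequence[AlignmentRecord] | None = None,
    identity_min: float = 95.0,
) -> dict:
    """Contiguity and reference-coverage summary for one species' assembly."""
    ref_id, ref_seq = reference
    if alignments is None:
        alignments = align_contigs(contig_set, reference)
    lengths = contig_set.lengths
    n50, ng50 = nx_ngx(lengths, len(ref_seq)) if lengths else (0, 0)
    return {
        "n_contigs": len(lengths),
        "total_bases": sum(lengths),
        "n50": n50,
        "ng50": ng50,
        "genome_fraction": genome_fraction(len(ref_seq), alignments, identity_min),
    }
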