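"""Cobarcode-correlation read refinement — the pipeline's core algorithm.

Reads confidently classified at species rank are the *taxonomy reads* (TRs)
of that species.  Every barcode attached to at least one TR is a candidate;
candidates are ranked by the number of TRs they carry (``Num_T``,
descending) and then by the TR fraction of the barcode's reads (``Ratio_T``,
descending).  Walking the ranked barcodes, *all* reads of each barcode are
collected — this is how reads from inter-species repeats and unique
genome-specific regions, which the classifier could not place at species
rank, are recruited through their shared barcodes — until the cumulative
collected bases reach a data-size cap (300 fold-coverage of the reference by
default).  Only species whose estimated abundance (TR bases / reference
bases) exceeds 10 fold-coverage are refined at all, since lower coverage
cannot support a complete assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import UNBARCODED, ClassificationRecord, ReadPairRecord
from .taxonomy import RANK_SPECIES, TaxonomyTree


@dataclass(frozen=True)
class BarcodeStat:
    """Per-barcode refinement ranking key.

    ``total_reads``/``total_bases`` count the barcode's reads over the whole
    dataset, so ``ratio_t`` measures barcode purity with respect to the
    target species.
    """

    barcode: str
    num_t: int
    total_reads: int
    total_bases: int

    def __post_init__(self) -> None:
        if not 0 <= self.num_t <= self.total_reads:
            raise ValueError("num_t out of range")

    @property
    def ratio_t(self) -> float:
        return self.num_t / self.total_reads

    @property
    def _ratio_exact(self) -> Fraction:
        return Fraction(self.num_t, self.total_reads)


@dataclass
class RefinementConfig:
    cap_coverage: float = 300.0  # stop collecting barcodes beyond this depth
    min_abundance: float = 10.0  # skip species at or below this depth
    include_unbarcoded: bool = False  # add TRs with barcode 0_0_0 directly
    min_num_t: int | None = None  # optional per-barcode hard floors (off)
    min_ratio_t: float | None = None

    def __post_init__(self) -> None:
        if not self.cap_coverage > self.min_abundance > 0:
            raise ValueError("require cap_coverage > min_abundance > 0")


@dataclass
class SpeciesReadSet:
    """Refined read set for one target species."""

    species: int
    tr_read_ids: set[str]
    candidate_barcodes: list[BarcodeStat]
    refined_read_ids: set[str]
    collected_barcodes: list[str]
    abundance: float
    capped: bool
    cap: float = 300.0
    abundance_gate: float = 10.0


def lift_classifications(
    classifications: Iterable[ClassificationRecord], tree: TaxonomyTree
) -> list[ClassificationRecord]:
    """Lift strain-level assignments to their species ancestor.

    Assignments above species rank (or with no species ancestor) pass
    through unchanged; this makes adapter output from species-representative
    databases and the fixture classifier interchangeable.
    """
    out = []
    for rec in classifications:
        taxid = rec.taxid
        if taxid != 0 and taxid in tree.nodes and tree.rank(taxid) not in (RANK_SPECIES,):
            species = tree.species_ancestor(taxid)
            if species is not None:
                taxid = species
        out.append(ClassificationRecord(rec.read_id, taxid != 0, taxid))
    return out


def extract_taxonomy_reads(
    classifications: Iterable[ClassificationRecord], species: int, tree: TaxonomyTree
) -> set[str]:
    """Read ids whose assignment equals the species taxid exactly."""
    if tree.rank(species) != RANK_SPECIES:
        raise ValueError(f"taxid {species} is not species rank")
    return {rec.read_id for rec in classifications if rec.taxid == species}


def estimate_abundance(
    tr_reads: Iterable[ReadPairRecord] | Iterable[int], reference_length: int
) -> float:
    """Fold-coverage estimate: total TR bases (both mates) / reference bases."""
    if reference_length <= 0:
        raise ValueError("reference_length must be > 0")
    total = 0
    for item in tr_reads:
        total += item.total_bases if isinstance(item, ReadPairRecord) else int(item)
    return total / reference_length


def compute_barcode_stats(
    reads: Sequence[ReadPairRecord], tr_read_ids: set[str]
) -> list[BarcodeStat]:
    """One BarcodeStat per barcode carrying at least one TR.

    Totals are counted over the whole dataset for that barcode; the
    unbarcoded sentinel carries no cobarcoding signal and is never a
    candidate.
    """
    totals: dict[str, tuple[int, int]] = {}
    num_t: dict[str, int] = {}
    for rec in reads:
        n, b = totals.get(rec.barcode, (0, 0))
        totals[rec.barcode] = (n + 1, b + rec.total_bases)
        if rec.read_id in tr_read_ids:
            num_t[rec.barcode] = num_t.get(rec.barcode, 0) + 1
    return [
        BarcodeStat(bc, num_t[bc], *totals[bc])
        for bc in sorted(num_t)
        if bc != UNBARCODED
    ]


def rank_barcodes(stats: Iterable[BarcodeStat]) -> list[BarcodeStat]:
    """Sort by Num_T descending, Ratio_T descending, barcode ascending."""
    return sorted(stats, key=lambda s: (-s.num_t, -s._ratio_exact, s.barcode))


def collect_refined_reads(
    ranked: Sequence[BarcodeStat],
    reads_by_barcode: Mapping[str, Sequence[ReadPairRecord]],
    reference_length: int,
    config: RefinementConfig | None = None,
) -> tuple[set[str], list[str], bool]:
    """Walk ranked barcodes collecting all their reads up to the coverage cap.

    Barcodes are atomic: the barcode whose inclusion first makes the
    cumulative bases reach ``cap_coverage x reference_length`` is included
    whole, then collection stops.  Returns (refined read ids, collected
    barcodes in rank order, whether the cap fired).
    """
    config = config or RefinementConfig()
    cap_bases = config.cap_coverage * reference_length
    refined: set[str] = set()
    collected: list[str] = []
    cum = 0
    capped = False
    for stat in ranked:
        if config.min_num_t is not None and stat.num_t < config.min_num_t:
            continue
        if config.min_ratio_t is not None and stat.ratio_t < config.min_ratio_t:
            continue
        for rec in reads_by_barcode.get(stat.barcode, ()):
            refined.add(rec.read_id)
        collected.append(stat.barcode)
        cum += stat.total_bases
        if cum >= cap_bases:
            capped = True
            break
    return refined, collected, capped


@dataclass
class RefinementResult:
    read_sets: dict[int, SpeciesReadSet]
    skipped: dict[int, float]  # species taxid -> estimated abundance

    def report(self) -> pd.DataFrame:
        rows = []
        for taxid in sorted(set(self.read_sets) | set(self.skipped)):
            if taxid in self.read_sets:
                rs = self.read_sets[taxid]
                rows.append(
                    {
                        "species": taxid,
                        "abundance": rs.abundance,
                        "n_TRs": len(rs.tr_read_ids),
                        "n_candidate_barcodes": len(rs.candidate_barcodes),
                        "n_collected_barcodes": len(rs.collected_barcodes),
                        "n_refined_reads": len(rs.refined_read_ids),
                        "capped": rs.capped,
                        "status": "refined",
                    }
                )
            else:
                rows.append(
                    {
                        "species": taxid,
                        "abundance": self.skipped[taxid],
                        "n_TRs": 0,
                        "n_candidate_barcodes": 0,
                        "n_collected_barcodes": 0,
                        "n_refined_reads": 0,
                        "capped": False,
                        "status": "skipped: abundance",
                    }
                )
        return pd.DataFrame(rows)


def refine_species(
    classifications: Sequence[ClassificationRecord],
    reads: Sequence[ReadPairRecord],
    species: int,
    reference_length: int,
    tree: TaxonomyTree,
    config: RefinementConfig | None = None,
    reads_by_barcode: Mapping[str, Sequence[ReadPairRecord]] | None = None,
) -> SpeciesReadSet:
    """Full refinement for one species (no abundance gate applied here)."""
    config = config or RefinementConfig()
    tr_ids = extract_taxonomy_reads(classifications, species, tree)
    by_id = {r.read_id: r for r in reads}
    abundance = estimate_abundance((by_id[i].total_bases for i in tr_ids), reference_length)
    stats = compute_barcode_stats(reads, tr_ids)
    ranked = rank_barcodes(stats)
    if reads_by_barcode is None:
        reads_by_barcode = _group_by_barcode(reads)
    refined, collected, capped = collect_refined_reads(
        ranked, reads_by_barcode, reference_length, config
    )
    if config.include_unbarcoded:
        refined |= {i for i in tr_ids if by_id[i].barcode == UNBARCODED}
    return SpeciesReadSet(
        species=species,
        tr_read_ids=tr_ids,
        candidate_barcodes=ranked,
        refined_read_ids=refined,
        collected_barcodes=collected,
        abundance=abundance,
        capped=capped,
        cap=config.cap_coverage,
        abundance_gate=config.min_abundance,
    )


def _group_by_barcode(
    reads: Sequence[ReadPairRecord],
) -> dict[str, list[ReadPairRecord]]:
    grouped: dict[str, list[ReadPairRecord]] = {}
    for rec in reads:
        grouped.setdefault(rec.barcode, []).append(rec)
    return grouped


def refine_all_species(
    classifications: Sequence[ClassificationRecord],
    reads: Sequence[ReadPairRecord],
    reference_lengths: Mapping[int, int],
    tree: TaxonomyTree,
    config: RefinementConfig | None = None,
) -> RefinementResult:
    """Refine every species above the abundance gate (strict ``>``).

    ``reference_lengths`` maps species taxid to reference length; a key that
    is not a species-rank node in the taxonomy is an error.  Species at or
    below the gate are reported as skipped with their estimated abundance.
    """
    config = config or RefinementConfig()
    for taxid in reference_lengths:
        if taxid not in tree.nodes or tree.rank(taxid) != RANK_SPECIES:
            raise ValueError(f"reference taxid {taxid} is not a species in the taxonomy")
    classifications = lift_classifications(classifications, tree)
    by_id = {r.read_id: r for r in reads}
    reads_by_barcode = _group_by_barcode(reads)
    read_sets: dict[int, SpeciesReadSet] = {}
    skipped: dict[int, float] = {}
    for taxid in sorted(reference_lengths):
        ref_len = reference_lengths[taxid]
        tr_ids = extract_taxonomy_reads(classifications, taxid, tree)
        abundance = estimate_abundance(
            (by_id[i].total_bases for i in tr_ids if i in by_id), ref_len
        )
        if abundance <= config.min_abundance:
            skipped[taxid] = abundance
            continue
        read_sets[taxid] = refine_species(
            classifications, reads, taxid, ref_len, tree, config, reads_by_barcode
        )
    return RefinementResult(read_sets, skipped)
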