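"""Synthetic cobarcoded communities with per-read truth labels.

The generator emulates an stLFR-style library over a small multi-species
community: long DNA fragments are drawn from each sample genome, partitioned
into barcodes (with a small collision probability that two fragments share a
barcode), and short paired-end reads are sampled along each fragment.

Three read regimes are planted deliberately, because they are the premise of
the downstream refinement stage:

* ``species_specific`` — reads from sequence unique to one species' reference;
  an LCA classifier assigns them at species rank.
* ``inter_species_repeat`` — reads from blocks copied verbatim between two
  references; all their k-mers are shared, so they classify at the LCA rank
  above species.
* ``unique_genome_specific`` — reads from novel insertions present in the
  sample genome but absent from every reference; they stay unclassified.

Sample genomes diverge from their references by point substitutions at a
configurable rate plus the unique insertions; sequencing errors are
substitutions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from . import _kmers
from .io import (
    INTER_SPECIES_REPEAT,
    SPECIES_SPECIFIC,
    UNIQUE_GENOME_SPECIFIC,
    FastaRecord,
    ReadPairRecord,
    write_fasta,
    write_stlfr_fastq,
)
from .taxonomy import (
    RANK_GENUS,
    RANK_ROOT,
    RANK_SPECIES,
    TaxonNode,
    TaxonomyTree,
)


@dataclass
class SpeciesSpec:
    """One community member: reference size, coverage and divergence model."""

    name: str
    genome_length: int = 50_000
    abundance: float = 20.0  # fold-coverage of the sample genome
    divergence: float = 0.0  # substitutions per bp, sample vs reference
    unique_insertion_fraction: float = 0.0  # novel sequence, fraction of ref length
    insertion_length: int = 1_500  # size of each planted insertion
    taxid: int | None = None


@dataclass
class SharedRepeat:
    """A block copied verbatim between two species' references."""

    species_a: str
    species_b: str
    length: int


@dataclass
class LibrarySpec:
    """Cobarcoded library model.

    Fragment lengths are log-normal with the given median (stLFR-like long
    fragments); each fragment is read to ``fragment_coverage`` depth with
    100 bp paired-end reads at the given insert size.  ``collision_rate`` is
    the probability that a fragment joins an already-used barcode instead of
    receiving a fresh one.
    """

    fragment_length_median: float = 30_000.0
    fragment_length_sigma: float = 0.35
    min_fragment_length: int = 1_000
    read_length: int = 100
    insert_size_mean: float = 300.0
    insert_size_sd: float = 30.0
    fragment_coverage: float = 0.2
    collision_rate: float = 0.0
    error_rate: float = 0.0
    region_kmer: int = 31  # k used when deciding truth-region labels


@dataclass
class CommunitySpec:
    species: list[SpeciesSpec]
    shared_repeats: list[SharedRepeat] = field(default_factory=list)
    library: LibrarySpec = field(default_factory=LibrarySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for i, sp in enumerate(self.species):
            if sp.abundance <= 0:
                raise ValueError(f"abundance must be > 0 for {sp.name}")
            if not 0 <= sp.unique_insertion_fraction < 1:
                raise ValueError("unique_insertion_fraction must be in [0, 1)")
            if not 0 <= sp.divergence < 1:
                raise ValueError("divergence must be in [0, 1)")
            if sp.taxid is None:
                self.species[i] = replace(sp, taxid=1001 + i)
        if self.library.read_length > self.library.min_fragment_length:
            raise ValueError("read length exceeds minimum fragment length")

    @property
    def relative_abundances(self) -> dict[str, float]:
        total = sum(sp.abundance for sp in self.species)
        return {sp.name: sp.abundance / total for sp in self.species}


@dataclass
class Segment:
    """Piece of a sample genome: either reference-derived or an insertion."""

    sample_start: int
    sample_end: int
    kind: str  # "ref" | "ins"
    ref_start: int  # ref coordinate of sample_start when kind == "ref"


@dataclass
class SampleGenome:
    name: str
    seq: str
    segments: list[Segment]
    repeat_intervals: list[tuple[int, int]]  # reference coordinates

    def _mate_region(self, start: int, end: int, kmer: int) -> str:
        """Region class of one mate interval [start, end) in sample coords."""
        overlapping = [
            s for s in self.segments if s.sample_start < end and start < s.sample_end
        ]
        if len(overlapping) == 1:
            seg = overlapping[0]
            if seg.kind == "ins":
                return UNIQUE_GENOME_SPECIFIC
            r0 = seg.ref_start + (start - seg.sample_start)
            r1 = r0 + (end - start)
            for a, b in self.repeat_intervals:
                if a <= r0 and r1 <= b:
                    return INTER_SPECIES_REPEAT
            # specific only if the mate holds a full k-window of
            # species-specific reference sequence
            for a, b in sorted(self.repeat_intervals) + [(r1, r1)]:
                lo, hi = max(r0, 0), min(r1, a)
                if hi - lo >= kmer:
                    return SPECIES_SPECIFIC
                r0 = max(r0, b)
            return "junction"
        # straddles a segment boundary: check for a species-specific k-window
        for seg in overlapping:
            if seg.kind != "ref":
                continue
            lo = max(start, seg.sample_start)
            hi = min(end, seg.sample_end)
            if hi - lo >= kmer:
                sub = self._mate_region(lo, hi, kmer)
                if sub == SPECIES_SPECIFIC:
                    return SPECIES_SPECIFIC
        return "junction"

    def pair_region(self, fwd: tuple[int, int], rev: tuple[int, int], kmer: int) -> str:
        """Truth-region label of a read pair from its two mate intervals."""
        r1 = self._mate_region(*fwd, kmer)
        r2 = self._mate_region(*rev, kmer)
        regions = {r1, r2}
        if SPECIES_SPECIFIC in regions or "junction" in regions:
            return SPECIES_SPECIFIC
        if regions == {UNIQUE_GENOME_SPECIFIC}:
            return UNIQUE_GENOME_SPECIFIC
        return INTER_SPECIES_REPEAT


@dataclass
class Community:
    references: dict[str, str]
    sample_genomes: dict[str, SampleGenome]
    taxonomy: TaxonomyTree
    taxids: dict[str, int]


@dataclass
class FragmentRecord:
    fragment_id: str
    barcode: str
    genome: str
    start: int
    end: int


@dataclass
class SimulatedDataset:
    spec: CommunitySpec
    community: Community
    reads: list[ReadPairRecord]
    fragments: list[FragmentRecord]

    def reference_records(self) -> list[FastaRecord]:
        return [FastaRecord(n, s) for n, s in sorted(self.community.references.items())]

    def sample_genome_records(self) -> list[FastaRecord]:
        return [
            FastaRecord(n, g.seq) for n, g in sorted(self.community.sample_genomes.items())
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/FASTQ/TSV artifacts; returns a name -> path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "references": outdir / "references.fasta",
            "sample_genomes": outdir / "sample_genomes.fasta",
            "reads_fwd": outdir / "reads_1.fq",
            "reads_rev": outdir / "reads_2.fq",
            "taxonomy": outdir / "taxonomy.tsv",
            "truth_reads": outdir / "truth_reads.tsv",
            "truth_fragments": outdir / "truth_fragments.tsv",
        }
        write_fasta(self.reference_records(), paths["references"])
        write_fasta(self.sample_genome_records(), paths["sample_genomes"])
        write_stlfr_fastq(self.reads, paths["reads_fwd"], paths["reads_rev"])
        self.community.taxonomy.to_tsv(paths["taxonomy"])
        with open(paths["truth_reads"], "w") as fh:
            fh.write("read_id\tgenome\tfragment\tregion\n")
            for r in self.reads:
                fh.write(f"{r.read_id}\t{r.truth_genome}\t{r.truth_fragment}\t{r.truth_region}\n")
        with open(paths["truth_fragments"], "w") as fh:
            fh.write("fragment_id\tbarcode\tgenome\tstart\tend\n")
            for f in self.fragments:
                fh.write(f"{f.fragment_id}\t{f.barcode}\t{f.genome}\t{f.start}\t{f.end}\n")
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _build_taxonomy(spec: CommunitySpec) -> tuple[TaxonomyTree, dict[str, int]]:
    """Star-of-genera tree; species sharing a repeat block share a genus."""
    names = [sp.name for sp in spec.species]
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rep in spec.shared_repeats:
        ra, rb = find(rep.species_a), find(rep.species_b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    nodes = [TaxonNode(1, 1, RANK_ROOT, "root")]
    taxids = {sp.name: sp.taxid for sp in spec.species}
    for gi, root_name in enumerate(sorted(groups)):
        genus_taxid = 101 + gi
        nodes.append(TaxonNode(genus_taxid, 1, RANK_GENUS, f"genus_{gi + 1}"))
        for name in groups[root_name]:
            nodes.append(TaxonNode(taxids[name], genus_taxid, RANK_SPECIES, name))
    return TaxonomyTree(nodes), taxids


def generate_community(
    spec: CommunitySpec, rng: np.random.Generator | None = None
) -> Community:
    """Generate references, diverged sample genomes and the taxonomy.

    References are i.i.d. uniform DNA with the shared repeat blocks copied
    verbatim across the named pairs.  Each sample genome is its reference
    with point substitutions at the species' divergence plus novel random
    insertions totalling ``unique_insertion_fraction`` of its length.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    taxonomy, taxids = _build_taxonomy(spec)
    by_name = {sp.name: sp for sp in spec.species}

    ref_codes = {sp.name: _random_seq(rng, sp.genome_length) for sp in spec.species}
    repeat_intervals: dict[str, list[tuple[int, int]]] = {sp.name: [] for sp in spec.species}
    for rep in spec.shared_repeats:
        for name in (rep.species_a, rep.species_b):
            if rep.length > by_name[name].genome_length:
                raise ValueError(
                    f"shared repeat of {rep.length} bp exceeds genome of {name}"
                )
        block = _random_seq(rng, rep.length)
        for name in (rep.species_a, rep.species_b):
            length = by_name[name].genome_length
            placed = repeat_intervals[name]
            for _ in range(100):
                pos = int(rng.integers(0, length - rep.length + 1))
                if all(pos + rep.length <= a or b <= pos for a, b in placed):
                    break
            else:
                raise ValueError(f"cannot place repeat block in {name}")
            ref_codes[name][pos : pos + rep.length] = block
            placed.append((pos, pos + rep.length))

    references = {n: _kmers.codes_to_seq(c) for n, c in ref_codes.items()}
    sample_genomes: dict[str, SampleGenome] = {}
    for sp in spec.species:
        codes = ref_codes[sp.name].copy()
        if sp.divergence > 0:
            mask = rng.random(codes.size) < sp.divergence
            n_sub = int(mask.sum())
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_sub, dtype=np.uint8)) % 4
        total_ins = int(round(sp.unique_insertion_fraction * sp.genome_length))
        segments: list[Segment] = []
        if total_ins > 0:
            n_ins = max(1, int(round(total_ins / sp.insertion_length)))
            sizes = [total_ins // n_ins] * n_ins
            sizes[-1] += total_ins - sum(sizes)
            positions = sorted(
                int(p) for p in rng.choice(sp.genome_length - 1, size=n_ins, replace=False) + 1
            )
            pieces: list[np.ndarray] = []
            cursor = 0  # ref coordinate
            sample_pos = 0
            for pos, size in zip(positions, sizes):
                pieces.append(codes[cursor:pos])
                segments.append(Segment(sample_pos, sample_pos + (pos - cursor), "ref", cursor))
                sample_pos += pos - cursor
                ins = _random_seq(rng, size)
                pieces.append(ins)
                segments.append(Segment(sample_pos, sample_pos + size, "ins", -1))
                sample_pos += size
                cursor = pos
            pieces.append(codes[cursor:])
            segments.append(
                Segment(sample_pos, sample_pos + (codes.size - cursor), "ref", cursor)
            )
            codes = np.concatenate(pieces)
        else:
            segments.append(Segment(0, codes.size, "ref", 0))
        sample_genomes[sp.name] = SampleGenome(
            sp.name, _kmers.codes_to_seq(codes), segments, sorted(repeat_intervals[sp.name])
        )
    return Community(references, sample_genomes, taxonomy, taxids)


def _barcode_name(index: int) -> str:
    a, rem = divmod(index, 1536 * 1536)
    b, c = divmod(rem, 1536)
    return f"{a + 1}_{b + 1}_{c + 1}"


def simulate_cobarcoded_reads(
    spec: CommunitySpec,
    community: Community,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw barcoded fragments and paired reads until each species reaches
    its target fold-coverage; every read carries truth labels."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lib = spec.library
    rl = lib.read_length
    if lib.fragment_coverage * lib.min_fragment_length < 2 * rl:
        raise ValueError("fragment coverage too low to yield any read pair")
    reads: list[ReadPairRecord] = []
    fragments: list[FragmentRecord] = []
    used_barcodes: list[str] = []
    n_barcodes = 0
    read_counter = 0
    frag_counter = 0
    mu = math.log(lib.fragment_length_median)
    for sp in spec.species:
        genome = community.sample_genomes[sp.name]
        gseq = genome.seq
        glen = len(gseq)
        target = sp.abundance * glen
        acc = 0.0
        while acc < target:
            frag_len = int(rng.lognormal(mu, lib.fragment_length_sigma))
            frag_len = min(max(frag_len, lib.min_fragment_length), glen)
            start = int(rng.integers(0, glen - frag_len + 1))
            if used_barcodes and rng.random() < lib.collision_rate:
                barcode = used_barcodes[int(rng.integers(0, len(used_barcodes)))]
            else:
                barcode = _barcode_name(n_barcodes)
                n_barcodes += 1
                used_barcodes.append(barcode)
            frag_id = f"f{frag_counter}"
            frag_counter += 1
            fragments.append(FragmentRecord(frag_id, barcode, sp.name, start, start + frag_len))
            n_pairs = max(1, int(round(lib.fragment_coverage * frag_len / (2 * rl))))
            for _ in range(n_pairs):
                insert = int(round(rng.normal(lib.insert_size_mean, lib.insert_size_sd)))
                insert = min(max(insert, 2 * rl), frag_len)
                pos = start + int(rng.integers(0, frag_len - insert + 1))
                fwd_iv = (pos, pos + rl)
                rev_iv = (pos + insert - rl, pos + insert)
                seq_fwd = gseq[fwd_iv[0] : fwd_iv[1]]
                seq_rev = _kmers.revcomp(gseq[rev_iv[0] : rev_iv[1]])
                if lib.error_rate > 0:
                    seq_fwd = _apply_errors(seq_fwd, lib.error_rate, rng)
                    seq_rev = _apply_errors(seq_rev, lib.error_rate, rng)
                region = genome.pair_region(fwd_iv, rev_iv, lib.region_kmer)
                reads.append(
                    ReadPairRecord(
                        read_id=f"r{read_counter}",
                        barcode=barcode,
                        seq_fwd=seq_fwd,
                        seq_rev=seq_rev,
                        qual_fwd="I" * rl,
                        qual_rev="I" * rl,
                        truth_genome=sp.name,
                        truth_fragment=frag_id,
                        truth_region=region,
                    )
                )
                read_counter += 1
                acc += 2 * rl
    return SimulatedDataset(spec, community, reads, fragments)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _kmers.seq_to_codes(seq).copy()
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
        return _kmers.codes_to_seq(codes)
    return seq


def simulate_dataset(spec: CommunitySpec) -> SimulatedDataset:
    """Canonical entry point: community + reads from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    community = generate_community(spec, rng)
    return simulate_cobarcoded_reads(spec, community, rng)


def mock_default_spec(
    total_coverage: float = 250.0, genome_length: int = 50_000, seed: int = 0
) -> CommunitySpec:
    """Miniature analogue of the standard mock community: eight bacteria at
    12% relative abundance and two fungi at 2%, scaled to ``total_coverage``.

    Genomes are 50 kb so the whole community runs at desk scale; one shared
    repeat block and small divergence/insertion fractions keep all three
    read regimes present.
    """
    species = []
    for i in range(8):
        species.append(
            SpeciesSpec(
                name=f"bacterium_{i + 1:02d}",
                genome_length=genome_length,
                abundance=0.12 * total_coverage,
                divergence=0.001,
                unique_insertion_fraction=0.02,
                insertion_length=1_000,
            )
        )
    for i in range(2):
        species.append(
            SpeciesSpec(
                name=f"fungus_{i + 1:02d}",
                genome_length=genome_length,
                abundance=0.02 * total_coverage,
                divergence=0.001,
                unique_insertion_fraction=0.02,
                insertion_length=1_000,
            )
        )
    shared = [SharedRepeat("bacterium_01", "bacterium_02", 800)]
    return CommunitySpec(
        species=species,
        shared_repeats=shared,
        library=LibrarySpec(collision_rate=0.001, error_rate=0.0002),
        seed=seed,
    )
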