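"""Taxonomy tree queries and a built-in k-mer LCA read classifier.

The classifier is a deliberately small Kraken-style fixture: it indexes every
canonical k-mer of the reference genomes, mapping each to the lowest common
ancestor (LCA) of all genomes that contain it, and scores a read by summing
hits along root-to-node paths.  It exists so the pipeline is testable without
an external Kraken2 installation; the adapter path
(:func:`cobin.io.parse_kraken_classifications`) is interchangeable with it.

Reads whose k-mers all fall in inter-species repeat sequence collect hits
only at the repeat's LCA node and are therefore classified above species
rank; reads from sequence absent from every reference collect no hits and
stay unclassified.  These two leakage modes are exactly what the barcode
refinement stage recovers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kmers
from .io import ClassificationRecord, ReadPairRecord

RANK_ROOT = "root"
RANK_GENUS = "genus"
RANK_SPECIES = "species"
RANK_STRAIN = "strain"


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """Rooted taxonomy with parent pointers; the root is its own parent."""

    def __init__(self, nodes: Iterable[TaxonNode]) -> None:
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._validate()
        self._path_cache: dict[int, tuple[int, ...]] = {}

    def _validate(self) -> None:
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in taxonomy at taxid {taxid}")
                seen.add(cur)
                parent = self.nodes[cur].parent
                if parent not in self.nodes:
                    raise ValueError(f"orphan taxid {cur}: parent {parent} unknown")
                cur = parent

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"malformed taxonomy line {lineno}: {line!r}")
                nodes.append(TaxonNode(int(fields[0]), int(fields[1]), fields[2], fields[3]))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#taxid\tparent_taxid\trank\tname\n")
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")

    def path_to_root(self, taxid: int) -> tuple[int, ...]:
        """Taxids from root down to ``taxid`` inclusive."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        cached = self._path_cache.get(taxid)
        if cached is None:
            path = []
            cur = taxid
            while True:
                path.append(cur)
                if cur == self.root:
                    break
                cur = self.nodes[cur].parent
            cached = tuple(reversed(path))
            self._path_cache[taxid] = cached
        return cached

    def depth(self, taxid: int) -> int:
        return len(self.path_to_root(taxid)) - 1

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node ancestral to (or equal to) every input taxid."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of empty set")
        paths = [self.path_to_root(t) for t in taxids]
        lca = self.root
        for level in range(min(len(p) for p in paths)):
            node = paths[0][level]
            if all(p[level] == node for p in paths):
                lca = node
            else:
                break
        return lca

    def species_ancestor(self, taxid: int) -> int | None:
        """The species-rank node on the path to root, or None (lifts strains)."""
        for node in reversed(self.path_to_root(taxid)):
            if self.nodes[node].rank == RANK_SPECIES:
                return node
        return None

    def species_taxids(self) -> list[int]:
        return sorted(t for t, n in self.nodes.items() if n.rank == RANK_SPECIES)

    def name_to_taxid(self) -> dict[str, int]:
        return {n.name: t for t, n in self.nodes.items()}


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    return tree.lca(taxids)


@dataclass
class KmerIndex:
    """Map canonical k-mer code -> LCA taxid over all genomes containing it."""

    k: int
    table: dict[int, int]

    def __len__(self) -> int:
        return len(self.table)


def build_kmer_index(
    references: Sequence[tuple[str, int, str]], tree: TaxonomyTree, k: int = 31
) -> KmerIndex:
    """Index every canonical k-mer of ``(genome_id, taxid, sequence)`` records.

    A k-mer present in several genomes maps to the LCA of their taxids.
    """
    if not 15 <= k <= 63 or k % 2 == 0:
        raise ValueError("k must be odd and within [15, 63]")
    if not references:
        raise ValueError("no reference genomes")
    seen_ids = set()
    table: dict[int, int] = {}
    for genome_id, taxid, seq in references:
        if genome_id in seen_ids:
            raise ValueError(f"duplicate genome id {genome_id!r}")
        seen_ids.add(genome_id)
        if taxid not in tree.nodes:
            raise KeyError(f"taxid {taxid} not in taxonomy")
        codes = np.unique(_kmers.canonical_kmer_codes(seq, k))
        for code in codes.tolist():
            prev = table.get(code)
            if prev is None:
                table[code] = taxid
            elif prev != taxid:
                table[code] = tree.lca((prev, taxid))
    return KmerIndex(k=k, table=table)


def _classify_hits(hits: Counter, tree: TaxonomyTree) -> int:
    """Resolve a taxid-hit profile to one taxid by root-to-node path score.

    Candidates are the hit taxa themselves; each scores the sum of hits on
    its root-to-self path.  Highest score wins; ties go to the smallest
    taxid.  A read whose hits sit entirely on one ancestral node therefore
    classifies at that node (above species), mirroring how inter-species
    repeat reads behave under an LCA classifier.
    """
    best_taxid = 0
    best_score = -1
    for taxid in sorted(hits):
        score = sum(hits.get(a, 0) for a in tree.path_to_root(taxid))
        if score > best_score:
            best_score = score
            best_taxid = taxid
    return best_taxid


def classify_read_pair(
    seq_fwd: str, seq_rev: str, index: KmerIndex, tree: TaxonomyTree
) -> int:
    """Classify one read pair jointly (hit counts summed over both mates)."""
    hits: Counter = Counter()
    table = index.table
    for seq in (seq_fwd, seq_rev):
        if len(seq) < index.k:
            continue
        for code in _kmers.canonical_kmer_codes(seq, index.k).tolist():
            taxid = table.get(code)
            if taxid is not None:
                hits[taxid] += 1
    if not hits:
        return 0
    return _classify_hits(hits, tree)


def classify_reads_fixture(
    reads: Iterable[ReadPairRecord], index: KmerIndex, tree: TaxonomyTree
) -> list[ClassificationRecord]:
    """Classify read pairs against the fixture k-mer index.

    Deterministic and permutation-invariant over read order; reads shorter
    than k (both mates) are unclassified.
    """
    out = []
    for rec in reads:
        taxid = classify_read_pair(rec.seq_fwd, rec.seq_rev, index, tree)
        out.append(ClassificationRecord(rec.read_id, taxid != 0, taxid))
    return out
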