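"""Readers and writers for the external formats the pipeline touches.

Dialect rules implemented here:

* stLFR FASTQ — the barcode is the last ``#``-delimited token of the read
  name, written as numeric symbols (e.g. ``12_34_56``); ``0_0_0`` marks an
  unbarcoded read.  Mate suffixes ``/1``/``/2`` are stripped before the
  barcode is parsed.
* Kraken2 standard output — 5 tab-separated columns (status, read id, taxid,
  length, k-mer map); the 5th column is ignored.
* PAF — standard 12 columns plus tags; 0-based half-open coordinates; the
  ``cg:Z`` tag carries an extended CIGAR (=/X/I/D).

All internal coordinates are 0-based half-open; conversions happen only at
format boundaries (VCF output is 1-based, see :mod:`cobin.evaluate`).
Quality strings are carried verbatim and never interpreted.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

UNBARCODED = "0_0_0"

#: truth-region labels attached by the simulator
SPECIES_SPECIFIC = "species_specific"
INTER_SPECIES_REPEAT = "inter_species_repeat"
UNIQUE_GENOME_SPECIFIC = "unique_genome_specific"
READ_REGIONS = (SPECIES_SPECIFIC, INTER_SPECIES_REPEAT, UNIQUE_GENOME_SPECIFIC)


@dataclass
class ReadPairRecord:
    """One barcoded read pair, with optional simulator truth labels."""

    read_id: str
    barcode: str
    seq_fwd: str
    seq_rev: str
    qual_fwd: str
    qual_rev: str
    truth_genome: str | None = None
    truth_fragment: str | None = None
    truth_region: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq_fwd) != len(self.qual_fwd) or len(self.seq_rev) != len(self.qual_rev):
            raise ValueError(f"sequence/quality length mismatch for read {self.read_id!r}")
        if not self.barcode:
            raise ValueError(f"empty barcode for read {self.read_id!r}")

    @property
    def total_bases(self) -> int:
        return len(self.seq_fwd) + len(self.seq_rev)


@dataclass(frozen=True)
class ClassificationRecord:
    """Taxonomic assignment of one read (pair); taxid 0 means unclassified."""

    read_id: str
    classified: bool
    taxid: int

    def __post_init__(self) -> None:
        if self.classified != (self.taxid != 0):
            raise ValueError("classified flag inconsistent with taxid")


@dataclass
class AlignmentRecord:
    """One query-to-target alignment interval (PAF conventions).

    Query coordinates are always on the forward query strand; for ``strand
    == '-'`` the CIGAR describes the reverse-complemented query walked along
    the forward target, as in PAF.  ``matches`` counts identical columns and
    ``block_length`` counts match+mismatch+inserted+deleted columns.
    """

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    block_length: int
    cigar: str | None = None

    @property
    def ani(self) -> float:
        """Per-alignment average nucleotide identity, percent."""
        if self.block_length == 0:
            raise ValueError("block_length is 0; ANI undefined")
        return 100.0 * self.matches / self.block_length


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


_MATE_SUFFIX = re.compile(r"/[12]$")


def split_stlfr_name(title: str) -> tuple[str, str]:
    """Split a FASTQ title into (read id, barcode) under the stLFR dialect.

    The name is the first whitespace token; a trailing ``/1`` or ``/2`` is
    stripped; the barcode is everything after the last ``#``.  Names without
    ``#`` get the unbarcoded sentinel ``0_0_0``.
    """
    name = title.split()[0]
    name = _MATE_SUFFIX.sub("", name)
    if "#" in name:
        read_id, _, barcode = name.rpartition("#")
        return read_id, barcode
    return name, UNBARCODED


class StlfrFastqReader:
    """Iterate synchronized stLFR FASTQ mates as :class:`ReadPairRecord`.

    ``n_unbarcoded`` counts reads whose name carried no ``#`` token (they are
    kept, with barcode ``0_0_0``).  A mate-count mismatch raises.
    """

    def __init__(self, path_fwd: str | Path, path_rev: str | Path) -> None:
        self.path_fwd = Path(path_fwd)
        self.path_rev = Path(path_rev)
        self.n_unbarcoded = 0
        self.n_records = 0

    def __iter__(self) -> Iterator[ReadPairRecord]:
        with _open_text(self.path_fwd) as fh1, _open_text(self.path_rev) as fh2:
            it1 = FastqGeneralIterator(fh1)
            it2 = FastqGeneralIterator(fh2)
            while True:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
                if rec1 is None and rec2 is None:
                    return
                if rec1 is None or rec2 is None:
                    raise ValueError(
                        f"mate-count mismatch between {self.path_fwd} and {self.path_rev}"
                    )
                (t1, s1, q1), (t2, s2, q2) = rec1, rec2
                read_id, barcode = split_stlfr_name(t1)
                if "#" not in t1.split()[0]:
                    self.n_unbarcoded += 1
                self.n_records += 1
                yield ReadPairRecord(read_id, barcode, s1, s2, q1, q2)


def read_stlfr_fastq(path_fwd: str | Path, path_rev: str | Path) -> StlfrFastqReader:
    """Open a pair of synchronized stLFR FASTQ files (gzip-transparent)."""
    return StlfrFastqReader(path_fwd, path_rev)


def write_stlfr_fastq(
    records: Iterable[ReadPairRecord], path_fwd: str | Path, path_rev: str | Path
) -> int:
    """Write read pairs as two synchronized FASTQ files; returns pair count."""
    n = 0
    with _open_text(path_fwd, "wt") as fh1, _open_text(path_rev, "wt") as fh2:
        for rec in records:
            name = f"{rec.read_id}#{rec.barcode}"
            fh1.write(f"@{name}/1\n{rec.seq_fwd}\n+\n{rec.qual_fwd}\n")
            fh2.write(f"@{name}/2\n{rec.seq_rev}\n+\n{rec.qual_rev}\n")
            n += 1
    return n


def parse_kraken_classifications(path: str | Path) -> Iterator[ClassificationRecord]:
    """Parse Kraken2 5-column standard output; 'U' lines force taxid 0."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4 or fields[0] not in ("C", "U"):
                raise ValueError(f"malformed Kraken2 line {lineno}: {line!r}")
            status, read_id, taxid_s = fields[0], fields[1], fields[2]
            try:
                taxid = int(taxid_s)
            except ValueError as exc:
                raise ValueError(f"malformed Kraken2 line {lineno}: {line!r}") from exc
            if status == "U":
                taxid = 0
            yield ClassificationRecord(read_id, taxid != 0, taxid)


def write_kraken_classifications(
    records: Iterable[ClassificationRecord], path: str | Path, read_length: int = 100
) -> int:
    """Write classifications in Kraken2 5-column format (paired length column)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            status = "C" if rec.classified else "U"
            fh.write(f"{status}\t{rec.read_id}\t{rec.taxid}\t{read_length}|{read_length}\t-\n")
            n += 1
    return n


@dataclass
class FastaRecord:
    id: str
    seq: str
    description: str = ""


def parse_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA records; IDs are the first whitespace token; empty file errors."""
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(FastaRecord(rec.id, str(rec.seq).upper(), rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[FastaRecord | tuple[str, str]], path: str | Path) -> int:
    """Write FASTA, wrapping sequence lines at 80 columns."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rec = FastaRecord(*rec)
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")
            n += 1
    return n


_CIGAR_RE = re.compile(r"(\d+)([=XIDMSH])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse an extended CIGAR string into (op, length) pairs."""
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{l}{o}" for o, l in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file; the ``cg:Z`` tag, when present, becomes the CIGAR."""
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed PAF line {lineno}: expected >=12 columns")
            cigar = None
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            records.append(
                AlignmentRecord(
                    query_id=f[0],
                    query_length=int(f[1]),
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    strand=f[4],
                    target_id=f[5],
                    target_length=int(f[6]),
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    matches=int(f[9]),
                    block_length=int(f[10]),
                    cigar=cigar,
                )
            )
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in records:
            cols = [
                r.query_id, r.query_length, r.query_start, r.query_end, r.strand,
                r.target_id, r.target_length, r.target_start, r.target_end,
                r.matches, r.block_length, 60,
            ]
            line = "\t".join(str(c) for c in cols)
            if r.cigar is not None:
                line += f"\tcg:Z:{r.cigar}"
            fh.write(line + "\n")
            n += 1
    return n


def parse_taxonomy_table(path: str | Path):
    """Parse a (taxid, parent taxid, rank, name) TSV into a TaxonomyTree."""
    from .taxonomy import TaxonomyTree

    return TaxonomyTree.from_tsv(path)
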