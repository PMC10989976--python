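"""Per-species assembly: external assembler adapter or toy de Bruijn assembler.

The real pipeline delegates assembly to a production cobarcoding assembler
through a command template.  The built-in assembler is a minimal canonical
de Bruijn unitig builder: k-mers with count >= ``min_kmer_count`` form the
graph and maximal non-branching paths of at least 2k bp become contigs.  On
error-free reads its contigs are exact substrings of the source genome (up
to reverse complement), which downstream oracles rely on.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import _kmers
from .io import FastaRecord, ReadPairRecord, parse_fasta

EXTERNAL = "external"
TOY = "toy"


@dataclass
class ContigSet:
    species: int | None
    contigs: list[tuple[str, str]]  # (contig id, sequence)
    provenance: str  # "external" | "toy"

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")
        if any(not seq for _, seq in self.contigs):
            raise ValueError("empty contig sequence")

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.contigs]

    def records(self) -> list[FastaRecord]:
        return [FastaRecord(cid, seq) for cid, seq in self.contigs]


class AssemblyError(RuntimeError):
    def __init__(self, message: str, log_path: Path | None = None) -> None:
        super().__init__(message + (f" (log: {log_path})" if log_path else ""))
        self.log_path = log_path


def run_external_assembler(
    fastq_fwd: str | Path,
    fastq_rev: str | Path,
    command_template: str,
    workdir: str | Path,
    species: int | None = None,
) -> ContigSet:
    """Invoke an external assembler via a ``{fwd} {rev} {out}`` template.

    The command runs through the shell with stdout/stderr captured to a log
    file; a nonzero exit or an empty/missing output FASTA raises
    :class:`AssemblyError` carrying the log path.
    """
    for placeholder in ("{fwd}", "{rev}", "{out}"):
        if placeholder not in command_template:
            raise ValueError(f"command template lacks {placeholder}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_fasta = workdir / "contigs.fasta"
    log_path = workdir / "assembler.log"
    cmd = command_template.format(
        fwd=shlex.quote(str(fastq_fwd)), rev=shlex.quote(str(fastq_rev)),
        out=shlex.quote(str(out_fasta)),
    )
    with open(log_path, "w") as log:
        proc = subprocess.run(cmd, shell=True, stdout=log, stderr=subprocess.STDOUT)
    if proc.returncode != 0:
        raise AssemblyError(f"assembler exited with code {proc.returncode}", log_path)
    if not out_fasta.exists() or out_fasta.stat().st_size == 0:
        raise AssemblyError("assembler produced no output FASTA", log_path)
    records = parse_fasta(out_fasta)
    return ContigSet(species, [(r.id, r.seq) for r in records], EXTERNAL)


def _read_sequences(reads: Iterable[ReadPairRecord | str]) -> list[str]:
    seqs: list[str] = []
    for rec in reads:
        if isinstance(rec, str):
            seqs.append(rec)
        else:
            seqs.append(rec.seq_fwd)
            seqs.append(rec.seq_rev)
    return seqs


def _rescue_weak_kmers(
    counts: dict[int, int], solid: set[int], k: int, mask: int, shift: int
) -> set[int]:
    """Below-threshold k-mers kept when they patch solid-backbone gaps.

    A sequencing-error k-mer always competes with the solid true k-mer that
    shares its (k-1)-prefix or (k-1)-suffix, whereas a genome k-mer lost to
    a coverage dip has no such solid alternative.  Candidates without a
    solid sibling are rescued, but only if reachable from the solid graph —
    isolated weak islands (stray foreign reads, clustered errors) stay out.
    """

    def canon(code: int) -> int:
        return min(code, _kmers.revcomp_code(code, k))

    def has_solid_sibling(code: int) -> bool:
        prefix = code & ~3
        suffix = code >> 2
        for b in range(4):
            for sib in ((prefix | b), ((b << shift) | suffix)):
                if sib != code and canon(sib) in solid:
                    return True
        return False

    candidates = set()
    for code, n in counts.items():
        if code in solid:
            continue
        fwd = code
        rev = _kmers.revcomp_code(code, k)
        if not has_solid_sibling(fwd) and not has_solid_sibling(rev):
            candidates.add(code)
    if not candidates:
        return set()

    def neighbors(code: int) -> list[int]:
        out = []
        for oriented in (code, _kmers.revcomp_code(code, k)):
            base_succ = (oriented << 2) & mask
            base_pred = oriented >> 2
            for b in range(4):
                out.append(canon(base_succ | b))
                out.append(canon((b << shift) | base_pred))
        return out

    # BFS from the solid backbone through candidate k-mers
    rescued: set[int] = set()
    frontier = [c for code in solid for c in neighbors(code) if c in candidates]
    while frontier:
        nxt = []
        for code in frontier:
            if code in rescued:
                continue
            rescued.add(code)
            nxt.extend(c for c in neighbors(code) if c in candidates and c not in rescued)
        frontier = nxt
    return rescued


def toy_debruijn_assemble(
    reads: Iterable[ReadPairRecord | str],
    k: int = 31,
    min_kmer_count: int = 2,
    species: int | None = None,
) -> ContigSet:
    """Assemble reads into unitigs of the canonical de Bruijn graph.

    Deterministic given the input multiset: unitig walks start from the
    lexicographically smallest k-mers, and contigs are emitted in canonical
    orientation sorted by (length descending, sequence).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts: dict[int, int] = {}
    for seq in _read_sequences(reads):
        if len(seq) < k:
            continue
        for code in _kmers.canonical_kmer_codes(seq, k).tolist():
            counts[code] = counts.get(code, 0) + 1
    kmers = {code for code, n in counts.items() if n >= min_kmer_count}
    if not kmers:
        return ContigSet(species, [], TOY)

    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)

    def canon(code: int) -> int:
        return min(code, _kmers.revcomp_code(code, k))

    if min_kmer_count > 1:
        kmers |= _rescue_weak_kmers(counts, kmers, k, mask, shift)

    def successors(code: int) -> list[int]:
        out = []
        base = (code << 2) & mask
        for b in range(4):
            nxt = base | b
            if canon(nxt) in kmers:
                out.append(nxt)
        return out

    def predecessors(code: int) -> list[int]:
        out = []
        base = code >> 2
        for b in range(4):
            prv = (b << shift) | base
            if canon(prv) in kmers:
                out.append(prv)
        return out

    def decode(code: int) -> str:
        return _kmers.codes_to_seq([(code >> (2 * (k - 1 - i))) & 3 for i in range(k)])

    def walk(start: int, visited: set[int]) -> str:
        path = [start]
        visited.add(canon(start))
        cur = start
        while True:
            succ = successors(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(predecessors(nxt)) != 1 or canon(nxt) in visited:
                break
            visited.add(canon(nxt))
            path.append(nxt)
            cur = nxt
        seq = decode(path[0]) + "".join(decode(c)[-1] for c in path[1:])
        return seq

    visited: set[int] = set()
    contig_seqs: set[str] = set()
    # linear unitigs, started at branch points / tips, smallest k-mer first
    for code in sorted(kmers):
        for oriented in sorted({code, _kmers.revcomp_code(code, k)}):
            preds = predecessors(oriented)
            is_start = len(preds) != 1 or len(successors(preds[0])) != 1
            if is_start and canon(oriented) not in visited:
                seq = walk(oriented, visited)
                contig_seqs.add(min(seq, _kmers.revcomp(seq)))
    # remaining k-mers lie on perfect cycles
    for code in sorted(kmers):
        if code not in visited:
            seq = walk(code, visited)
            contig_seqs.add(min(seq, _kmers.revcomp(seq)))

    kept = sorted((s for s in contig_seqs if len(s) >= 2 * k), key=lambda s: (-len(s), s))
    contigs = [(f"contig_{i + 1}", seq) for i, seq in enumerate(kept)]
    return ContigSet(species, contigs, TOY)
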