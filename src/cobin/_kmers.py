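"""Integer k-mer encoding shared by the classifier, toy assembler and toy aligner.

Bases are 2-bit encoded (A=0, C=1, G=2, T=3) so that integer order on k-mer
codes coincides with lexicographic order on k-mer strings for fixed k. Only
upper-case A/C/G/T are accepted; the simulator never emits anything else.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMP)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """2-bit codes of a sequence as a uint8 array; rejects non-ACGT symbols."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.size and codes.max() > 3:
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return codes


def codes_to_seq(codes) -> str:
    return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def forward_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of all forward-strand k-mers, one per start position."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        out = (out << two) | codes[j : j + n].astype(np.uint64)
    return out


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-min) k-mer codes at every position of ``seq``."""
    codes = seq_to_codes(seq)
    fwd = forward_kmer_codes(codes, k)
    rc_codes = (3 - codes)[::-1]
    rev = forward_kmer_codes(rc_codes, k)[::-1]
    return np.minimum(fwd, rev)


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement of a single 2-bit-encoded k-mer code."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out
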