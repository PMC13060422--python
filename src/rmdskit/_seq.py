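"""Integer k-mer encodings of DNA sequence.

Motifs are encoded base-4 with A=0, C=1, G=2, T=3 and the leftmost base most
significant, so that code order equals lexicographic order over A<C<G<T.
Non-ACGT characters encode to -1 and poison any k-mer window they fall in.
"""

from __future__ import annotations

import itertools

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_bases(seq: str) -> np.ndarray:
    """Encode a sequence string to int8 codes (A/C/G/T -> 0..3, other -> -1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Forward k-mer code at every start position.

    Returns an int64 array of length ``len(base_codes) - k + 1``; positions
    whose window contains a non-ACGT base are -1.
    """
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = base_codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        w = c[j : j + n]
        out = out * 4 + np.where(w < 0, 0, w)
        valid &= w >= 0
    out[~valid] = -1
    return out


def revcomp_codes(codes: np.ndarray | int, k: int) -> np.ndarray:
    """Reverse-complement k-mer codes; -1 passes through."""
    x = np.asarray(codes, dtype=np.int64)
    rc = np.zeros_like(x)
    y = np.where(x < 0, 0, x)
    for _ in range(k):
        rc = rc * 4 + (3 - (y % 4))
        y //= 4
    return np.where(x < 0, -1, rc)


def motif_lexicon(k: int) -> list[str]:
    """All 4**k k-mers over ACGT in lexicographic (= code) order."""
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def motif_to_code(motif: str) -> int:
    code = 0
    for ch in motif:
        b = _BASE_CODE[ord(ch)]
        if b < 0:
            raise ValueError(f"non-ACGT base in motif {motif!r}")
        code = code * 4 + int(b)
    return code


def code_to_motif(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def revcomp_str(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
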