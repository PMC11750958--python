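"""Low-level DNA sequence utilities shared across the package.

Sequences are plain Python strings at the API surface and ``numpy.uint8``
arrays internally (A=0, C=1, G=2, T=3; any other character, e.g. ``N``,
encodes to 4 and never matches anything).
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N kept)."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s) if seq else 0.0


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer codes of an encoded sequence.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes ``arr[i:i+k]`` and
    ``valid[i]`` is False when the window contains a non-ACGT base (its code
    is then meaningless).  Requires ``k <= 31``.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    ambig = (arr >= 4).astype(np.int32)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (arr[j : j + n] & np.uint8(3))
    cum = np.concatenate([[0], np.cumsum(ambig)])
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Sorted-array index of all valid k-mers of a set of sequences.

    Positions are global offsets into the concatenation of the sequences,
    separated by ``k`` sentinel (ambiguous) bases so no window spans two
    records.  ``find(code)`` returns the global start positions of a k-mer.
    """

    def __init__(self, chrom_arrays: dict[str, np.ndarray], k: int):
        self.k = k
        self.chrom_names = list(chrom_arrays)
        sep = np.full(k, 4, dtype=np.uint8)
        parts, offsets, pos = [], {}, 0
        for name, a in chrom_arrays.items():
            offsets[name] = pos
            parts.append(a)
            parts.append(sep)
            pos += a.size + k
        self.concat = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.offsets = offsets
        self._bounds = np.array(
            [offsets[n] for n in self.chrom_names]
            + [self.concat.size], dtype=np.int64
        )
        self._lengths = {n: a.size for n, a in chrom_arrays.items()}
        codes, valid = kmer_codes(self.concat, k)
        idx = np.nonzero(valid)[0]
        codes = codes[idx]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = idx[order].astype(np.int64)

    def find_many(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Left/right bounds into ``sorted_pos`` for each query code."""
        lo = np.searchsorted(self.sorted_codes, query_codes, side="left")
        hi = np.searchsorted(self.sorted_codes, query_codes, side="right")
        return lo, hi

    def locate(self, gpos: int) -> tuple[str, int]:
        """Map a global offset back to (chromosome, local position)."""
        i = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        name = self.chrom_names[i]
        return name, gpos - self.offsets[name]

    def chrom_length(self, name: str) -> int:
        return self._lengths[name]
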