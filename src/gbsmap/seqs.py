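"""Low-level DNA sequence helpers shared across the pipeline.

GBS tags are short, fixed-start sequences, so almost everything in this
package reduces to end-anchored, ungapped comparison of byte arrays.  The
helpers here keep that idiom in one place: sequences travel as Python
strings at the API surface and as ``uint8`` numpy arrays (ASCII codes)
wherever mismatch counting has to be fast.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_array(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_seq(arr: np.ndarray) -> str:
    """Decode a uint8 ASCII array back into a string."""
    return arr.tobytes().decode("ascii")


def find_all(seq: str, motif: str) -> list[int]:
    """All (overlapping) occurrence positions of ``motif`` in ``seq``."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def find_site_positions(seq: str, site: str) -> list[int]:
    """Occurrences of a double-stranded recognition site.

    A restriction enzyme recognises the duplex, so both the printed site and
    its reverse complement mark a cut.  For palindromic sites (PstI CTGCAG,
    MluI ACGCGT, and the printed MseI AATT) the two searches coincide.
    """
    pos = set(find_all(seq, site))
    rc = revcomp(site)
    if rc != site:
        pos.update(find_all(seq, rc))
    return sorted(pos)


def count_mismatches(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance over the shorter of two encoded sequences.

    Comparison is end-anchored at position 0; length difference does not
    count as mismatch (quality trimming shortens reads from the ends).
    """
    n = min(a.size, b.size)
    return int(np.count_nonzero(a[:n] != b[:n]))


def mismatch_positions(a: np.ndarray, b: np.ndarray) -> list[int]:
    n = min(a.size, b.size)
    return np.flatnonzero(a[:n] != b[:n]).tolist()


class PaddedSeqMatrix:
    """A growable matrix of encoded sequences padded to a common width.

    Supports vectorised prefix-mismatch counting of one query against every
    stored sequence, which is the inner loop of both greedy clustering and
    unique alignment.  Rows keep their true lengths; padding bytes are zero
    and never take part in a comparison because mismatches are always
    counted over ``min(len(query), len(row))`` leading bases.
    """

    def __init__(self, width_hint: int = 128):
        self._data = np.zeros((0, width_hint), dtype=np.uint8)
        self._lengths = np.zeros(0, dtype=np.int64)
        self.n = 0

    @classmethod
    def from_sequences(cls, seqs: list[str]) -> "PaddedSeqMatrix":
        m = cls(width_hint=max((len(s) for s in seqs), default=128))
        for s in seqs:
            m.append(seq_array(s))
        return m

    @property
    def lengths(self) -> np.ndarray:
        return self._lengths[: self.n]

    def row(self, i: int) -> np.ndarray:
        return self._data[i, : self._lengths[i]]

    def append(self, arr: np.ndarray) -> None:
        if self.n == len(self._data) or arr.size > self._data.shape[1]:
            self._grow(arr.size)
        self._data[self.n, : arr.size] = arr
        self._lengths[self.n] = arr.size
        self.n += 1

    def _grow(self, min_width: int) -> None:
        rows = max(16, 2 * len(self._data), self.n + 1)
        width = max(self._data.shape[1], min_width)
        data = np.zeros((rows, width), dtype=np.uint8)
        data[: self.n, : self._data.shape[1]] = self._data[: self.n]
        lengths = np.zeros(rows, dtype=np.int64)
        lengths[: self.n] = self._lengths[: self.n]
        self._data, self._lengths = data, lengths

    def prefix_mismatches(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mismatch count of ``query`` vs every row over the shared prefix.

        Returns ``(mismatches, overlap_lengths)`` arrays of shape (n,).
        """
        if self.n == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        m = min(query.size, self._data.shape[1])
        neq = self._data[: self.n, :m] != query[:m]
        cum = np.cumsum(neq, axis=1)
        ov = np.minimum(self.lengths, query.size)
        mm = cum[np.arange(self.n), np.maximum(ov, 1) - 1]
        mm = np.where(ov > 0, mm, 0)
        return mm.astype(np.int64), ov
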