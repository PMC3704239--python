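"""Unique end-anchored alignment of sample reads to the tag reference.

Because every GBS read and every reference entry starts at the primary cut
site, alignment needs no offset search: a read is compared to each
reference end-anchored at position 0, ungapped, over the shorter of the
two lengths.  A read aligns to the reference with strictly the fewest
mismatches, provided that count is within the configured maximum; a tie at
the best count is unresolvable in a deduplicated reference and the read is
discarded as ambiguous ("aligned uniquely" taken literally).  Coordinates
are 0-based, half-open throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readproc import Read
from .refbuild import ReferenceEntry
from .seqs import PaddedSeqMatrix, mismatch_positions, seq_array


@dataclass
class TagAlignment:
    read_id: str
    sample: str | None
    ref_id: str
    mismatches: int
    aligned_length: int
    mismatch_offsets: list[int]


class ReferenceIndex:
    """Reference entries packed for vectorised mismatch counting."""

    def __init__(self, entries: list[ReferenceEntry]):
        self.entries = entries
        self.ids = [e.ref_id for e in entries]
        self.matrix = PaddedSeqMatrix.from_sequences([e.sequence for e in entries])
        self.by_id = {e.ref_id: e for e in entries}
        self.id_pos = {rid: i for i, rid in enumerate(self.ids)}

    def __len__(self):
        return len(self.entries)


def align_unique(
    read: "Read | str",
    index: ReferenceIndex,
    max_mismatches: int = 3,
    min_overlap: int = 30,
) -> TagAlignment | str:
    """Align one read; returns a TagAlignment, 'unaligned' or 'ambiguous'."""
    seq = read.seq if isinstance(read, Read) else read
    rid = read.id if isinstance(read, Read) else ""
    sample = read.sample if isinstance(read, Read) else None
    if len(seq) < min_overlap or len(index) == 0:
        return "unaligned"
    arr = seq_array(seq)
    mm, ov = index.matrix.prefix_mismatches(arr)
    mm = np.where(ov >= min_overlap, mm, np.iinfo(np.int64).max)
    best = int(mm.min())
    if best > max_mismatches:
        return "unaligned"
    hits = np.flatnonzero(mm == best)
    if hits.size > 1:
        return "ambiguous"
    i = int(hits[0])
    ref_arr = index.matrix.row(i)
    return TagAlignment(
        read_id=rid,
        sample=sample,
        ref_id=index.ids[i],
        mismatches=best,
        aligned_length=int(ov[i]),
        mismatch_offsets=mismatch_positions(arr, ref_arr),
    )


@dataclass
class AlignmentSet:
    """Alignments of all samples, grouped for pileup-style access.

    Reads are deduplicated by (sample, sequence) before alignment, so each
    distinct sequence is aligned once and carries a multiplicity.  The
    conservation counts (aligned / unaligned / ambiguous) refer to reads,
    not distinct sequences.
    """

    index: ReferenceIndex
    placements: dict[str, list[tuple[str, np.ndarray, int, int]]]
    # ref_id -> [(sample, encoded read seq, read count, mismatches)]
    n_aligned: int
    n_unaligned: int
    n_ambiguous: int
    samples: list[str]

    @property
    def n_input(self) -> int:
        return self.n_aligned + self.n_unaligned + self.n_ambiguous


def align_samples(
    reads_by_sample: dict[str, list[Read]],
    index: ReferenceIndex,
    max_mismatches: int = 3,
    min_overlap: int = 30,
) -> AlignmentSet:
    """Align every sample's reads to the reference index."""
    placements: dict[str, list[tuple[str, np.ndarray, int, int]]] = {}
    n_aligned = n_unaligned = n_ambiguous = 0
    decision_cache: dict[str, tuple[int, int] | str] = {}
    for sample in sorted(reads_by_sample):
        counts = Counter(r.seq for r in reads_by_sample[sample])
        for seq, n in sorted(counts.items()):
            got = decision_cache.get(seq)
            if got is None:
                res = align_unique(seq, index, max_mismatches, min_overlap)
                if isinstance(res, str):
                    got = res
                else:
                    got = (index.id_pos[res.ref_id], res.mismatches)
                decision_cache[seq] = got
            if got == "unaligned":
                n_unaligned += n
            elif got == "ambiguous":
                n_ambiguous += n
            else:
                i, mm = got
                ref_id = index.ids[i]
                placements.setdefault(ref_id, []).append((sample, seq_array(seq), n, mm))
                n_aligned += n
    return AlignmentSet(
        index=index,
        placements=placements,
        n_aligned=n_aligned,
        n_unaligned=n_unaligned,
        n_ambiguous=n_ambiguous,
        samples=sorted(reads_by_sample),
    )


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class CoverageTable:
    """Per-(reference, sample) read depth and per-offset base counts."""

    def __init__(self, alignments: AlignmentSet):
        self.alignments = alignments
        self.samples = alignments.samples
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        ids = alignments.index.ids
        depth = np.zeros((len(ids), len(self.samples)), dtype=np.int64)
        for ref_id, placed in alignments.placements.items():
            r = alignments.index.id_pos[ref_id]
            for sample, _, n, _ in placed:
                depth[r, self._sample_idx[sample]] += n
        self.depth = pd.DataFrame(depth, index=ids, columns=self.samples)

    def ref_length(self, ref_id: str) -> int:
        return len(self.alignments.index.by_id[ref_id].sequence)

    def base_counts(self, ref_id: str) -> np.ndarray:
        """Total base counts over all samples: array (ref length, 4) for ACGT."""
        L = self.ref_length(ref_id)
        out = np.zeros((L, 4), dtype=np.int64)
        for _, arr, n, _ in self.alignments.placements.get(ref_id, []):
            m = min(arr.size, L)
            code = np.searchsorted(_BASE_ARR, arr[:m])
            np.add.at(out, (np.arange(m), code), n)
        return out

    def sample_base_counts(self, ref_id: str, offsets: list[int]) -> np.ndarray:
        """Per-sample base counts at chosen offsets: (n_samples, n_offsets, 4)."""
        off = np.asarray(offsets, dtype=int)
        out = np.zeros((len(self.samples), off.size, 4), dtype=np.int64)
        for sample, arr, n, _ in self.alignments.placements.get(ref_id, []):
            s = self._sample_idx[sample]
            ok = off < arr.size
            codes = np.searchsorted(_BASE_ARR, arr[off[ok]])
            np.add.at(out, (s, np.flatnonzero(ok), codes), n)
        return out


def coverage_table(alignments: AlignmentSet) -> CoverageTable:
    return CoverageTable(alignments)


def write_alignment_tsv(alignments: AlignmentSet, path) -> None:
    """Native compact alignment table: one row per distinct placed sequence."""
    rows = []
    for ref_id in sorted(alignments.placements):
        for sample, arr, n, mm in alignments.placements[ref_id]:
            rows.append({"ref": ref_id, "sample": sample, "reads": n,
                         "mismatches": mm, "seq": arr.tobytes().decode()})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sam(alignments: AlignmentSet, path) -> None:
    """Minimal SAM export (mandatory fields only) for interoperability."""
    index = alignments.index
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for e in index.entries:
            fh.write(f"@SQ\tSN:{e.ref_id}\tLN:{len(e.sequence)}\n")
        k = 0
        for ref_id in sorted(alignments.placements):
            for sample, arr, n, mm in alignments.placements[ref_id]:
                seq = arr.tobytes().decode()
                for i in range(n):
                    k += 1
                    fh.write(
                        f"{sample}.{k}\t0\t{ref_id}\t1\t255\t{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{mm}\n"
                    )
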