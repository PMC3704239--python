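"""Build a nonredundant tag reference from parental reads.

Each parent's reads are grouped into tag clusters by greedy,
abundance-ordered clustering with end-anchored ungapped identity: GBS tags
all start at a primary cut site, so global end-anchored comparison is the
natural metric and, unlike word-based clustering heuristics, is exactly
reproducible.  Identity is computed over the shorter of the two lengths
(quality trimming shortens reads; a length difference is not a mismatch).

Clusters of the two parents are then merged one-to-one: a pair of
parental clusters within ``max_merge_mismatches`` becomes a single merged
reference entry whose differing offsets are the candidate SNP positions,
while unpaired clusters become parent-specific entries — the candidate
presence/absence loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import PaddedSeqMatrix, mismatch_positions, seq_array


@dataclass
class TagCluster:
    """A tag locus supported by one parent's reads."""

    parent: str
    representative: str  # the founding, most abundant sequence
    depth: int

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("cluster depth must be >= 1")


@dataclass
class ReferenceEntry:
    """One reference sequence, merged across parents when possible."""

    ref_id: str
    sequence: str
    source: str  # 'merged' | 'Syn-only' | 'Op-only'
    syn_rep: str | None = None
    op_rep: str | None = None
    variant_offsets: list[int] = field(default_factory=list)
    syn_depth: int = 0
    op_depth: int = 0

    @property
    def is_pa_candidate(self) -> bool:
        return self.source != "merged"

    @property
    def donor(self) -> str | None:
        return {"Syn-only": "Syn", "Op-only": "Op"}.get(self.source)


def cluster_reads(
    seqs: "list[str] | Counter[str]",
    identity_threshold: float = 0.96,
    parent: str = "",
) -> list[TagCluster]:
    """Greedy abundance-ordered clustering of one parent's trimmed reads.

    Unique sequences are processed in order of decreasing abundance (ties
    broken lexicographically).  A sequence joins the first existing cluster
    whose representative it matches at ``identity_threshold`` or better
    over the shorter length; otherwise it founds a new cluster and becomes
    its representative.
    """
    counts = seqs if isinstance(seqs, Counter) else Counter(seqs)
    if not counts:
        return []
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    reps = PaddedSeqMatrix(width_hint=max(len(s) for s in counts))
    clusters: list[TagCluster] = []
    for seq, n in ordered:
        arr = seq_array(seq)
        mm, ov = reps.prefix_mismatches(arr)
        if mm.size:
            allowed = np.floor((1.0 - identity_threshold) * ov + 1e-9)
            hits = np.flatnonzero(mm <= allowed)
            if hits.size:
                clusters[hits[0]].depth += n
                continue
        reps.append(arr)
        clusters.append(TagCluster(parent=parent, representative=seq, depth=n))
    return clusters


def merge_parental_clusters(
    syn_clusters: list[TagCluster],
    op_clusters: list[TagCluster],
    max_merge_mismatches: int = 3,
) -> list[ReferenceEntry]:
    """Pair parental clusters into a nonredundant reference.

    Syn clusters are processed in decreasing-abundance order; each is
    paired greedily and one-to-one with the not-yet-paired Op cluster at
    the fewest end-anchored mismatches, provided that count does not
    exceed ``max_merge_mismatches``.  Merged entries use the Op
    representative as the reference base sequence (an arbitrary but fixed
    convention recorded in the entry) and record the differing offsets as
    candidate variant positions.  Unpaired clusters become parent-specific
    entries.
    """
    syn_sorted = sorted(syn_clusters, key=lambda c: (-c.depth, c.representative))
    op_sorted = sorted(op_clusters, key=lambda c: (-c.depth, c.representative))
    op_mat = PaddedSeqMatrix.from_sequences([c.representative for c in op_sorted])
    taken = np.zeros(len(op_sorted), dtype=bool)

    entries: list[ReferenceEntry] = []
    for syn in syn_sorted:
        arr = seq_array(syn.representative)
        mm, _ = op_mat.prefix_mismatches(arr)
        if mm.size:
            mm = np.where(taken[: mm.size], np.iinfo(np.int64).max, mm)
            best = int(np.argmin(mm))
            if mm[best] <= max_merge_mismatches:
                taken[best] = True
                op = op_sorted[best]
                offsets = mismatch_positions(arr, seq_array(op.representative))
                entries.append(
                    ReferenceEntry(
                        ref_id="",
                        sequence=op.representative,
                        source="merged",
                        syn_rep=syn.representative,
                        op_rep=op.representative,
                        variant_offsets=offsets,
                        syn_depth=syn.depth,
                        op_depth=op.depth,
                    )
                )
                continue
        entries.append(
            ReferenceEntry(
                ref_id="",
                sequence=syn.representative,
                source="Syn-only",
                syn_rep=syn.representative,
                syn_depth=syn.depth,
            )
        )
    for i, op in enumerate(op_sorted):
        if not taken[i]:
            entries.append(
                ReferenceEntry(
                    ref_id="",
                    sequence=op.representative,
                    source="Op-only",
                    op_rep=op.representative,
                    op_depth=op.depth,
                )
            )
    for k, e in enumerate(entries):
        e.ref_id = f"ref{k:06d}"
    return entries


def cluster_report(clusters: list[TagCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parent": [c.parent for c in clusters],
            "depth": [c.depth for c in clusters],
            "length": [len(c.representative) for c in clusters],
            "representative": [c.representative for c in clusters],
        }
    )


def write_reference_fasta(entries: list[ReferenceEntry], path) -> None:
    """Reference FASTA with structured headers: ``id|source|offsets=...``."""
    from .io import write_fasta

    records = []
    for e in entries:
        off = ",".join(map(str, e.variant_offsets))
        records.append((f"{e.ref_id}|{e.source}|offsets={off}", e.sequence))
    write_fasta(records, path)


def read_reference_fasta(path) -> list[ReferenceEntry]:
    from .io import read_fasta

    entries = []
    for header, seq in read_fasta(path).items():
        ref_id, source, off = header.split("|")
        offsets = [int(x) for x in off.removeprefix("offsets=").split(",") if x]
        entries.append(ReferenceEntry(ref_id=ref_id, sequence=seq, source=source,
                                      variant_offsets=offsets))
    return entries
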