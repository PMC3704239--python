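"""In silico restriction digestion.

Given a DNA sequence and an :class:`~gbsmap.enzymes.EnzymePair`, enumerate
the sequenceable fragments: those bounded by a primary cut at one end and a
secondary cut at the other, within the size-selection window.  Each such
fragment yields one expected tag, read from the primary cut site inwards.
Fragments bounded by two primary or two secondary cuts are not ligatable to
both adapters and emit nothing, nor do the unbounded chromosome ends.

The same routine drives both the read simulator (digesting simulated
parental genomes) and contig anchoring (predicting tags on assembly
contigs), so the two stay consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .enzymes import EnzymePair
from .seqs import find_site_positions, revcomp


@dataclass(frozen=True)
class ExpectedTag:
    """One predicted sequenceable tag from an in silico digest.

    ``cut_pos`` is the 0-based coordinate of the first retained base for
    forward tags, and one past the last retained base for reverse tags, so
    ``(strand, cut_pos)`` identifies the tag locus on the source sequence.
    """

    contig: str
    strand: str  # '+' reads rightwards from the primary cut, '-' leftwards
    cut_pos: int
    fragment_length: int
    seq: str


def in_silico_digest(
    seq: str,
    enzymes: EnzymePair,
    read_len: int = 100,
    contig_id: str = "",
    masked_primary: Iterable[int] = (),
    masked_secondary: Iterable[int] = (),
) -> list[ExpectedTag]:
    """Digest ``seq`` and return the expected tags.

    ``masked_primary``/``masked_secondary`` are recognition-site start
    positions to skip (e.g. methylated sites for a methylation-sensitive
    enzyme).  Sites containing N never match and therefore never cut.
    """
    masked_p = set(masked_primary)
    masked_s = set(masked_secondary)
    plen, slen = len(enzymes.primary_site), len(enzymes.secondary_site)
    poff, soff = enzymes.primary_cut_offset, enzymes.secondary_cut_offset

    events: list[tuple[int, str]] = []  # (site start, kind)
    for p in find_site_positions(seq, enzymes.primary_site):
        if p not in masked_p:
            events.append((p, "P"))
    for p in find_site_positions(seq, enzymes.secondary_site):
        if p not in masked_s:
            events.append((p, "S"))
    events.sort()

    tags: list[ExpectedTag] = []
    for (p1, k1), (p2, k2) in zip(events, events[1:]):
        if {k1, k2} != {"P", "S"}:
            continue
        if k1 == "P":
            start = p1 + poff  # downstream of the primary cut
            end = p2 + slen - soff  # upstream boundary of the secondary cut
            if not enzymes.min_fragment_bp <= end - start <= enzymes.max_fragment_bp:
                continue
            tag = seq[start : min(start + read_len, end)]
            tags.append(ExpectedTag(contig_id, "+", start, end - start, tag))
        else:
            start = p1 + soff
            end = p2 + plen - poff  # the primary cut, read leftwards
            if not enzymes.min_fragment_bp <= end - start <= enzymes.max_fragment_bp:
                continue
            tag = revcomp(seq[max(start, end - read_len) : end])
            tags.append(ExpectedTag(contig_id, "-", end, end - start, tag))
    return tags
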