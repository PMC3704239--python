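"""Read processing: quality trimming, filtering and demultiplexing.

Raw reads begin with a sample barcode followed by the primary cut-site
remnant.  A read is assigned to a sample only when a known barcode is
immediately followed by the expected remnant — the remnant doubles as a
check that the read really starts at a primary cut site.  The barcode is
removed; the remnant stays, as the first bases of the tag sequence.

Quality control follows the published recipe: bases with phred quality
below 15 are trimmed from both ends, and a read is discarded when more
than 20% of its (remaining) bases fall below that threshold.  The >20%
rule is evaluated after trimming; the sequential wording supports either
order and evaluating it after trimming keeps more data.  Reads shorter
than ``min_read_len`` (default 30 bp) after trimming are discarded as
unclusterable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .config import PipelineConfig


@dataclass
class Read:
    """One sequencing read with per-base phred33 qualities."""

    id: str
    seq: str
    qual: str  # phred33-encoded, same length as seq
    sample: str | None = None

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence and quality lengths differ")

    @property
    def scores(self) -> np.ndarray:
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8).astype(int) - 33


class BarcodeTable:
    """Barcode -> sample mapping with remnant verification.

    Barcodes must be unique.  When one barcode is a strict prefix of
    another, assignment resolves by longest match; an exact tie (two
    distinct barcodes of the same length both matching, which cannot occur
    with unique barcodes but is guarded anyway) leaves the read unassigned.
    """

    def __init__(self, entries: Iterable[tuple[str, str]], remnant: str = "TGCAG"):
        entries = list(entries)
        barcodes = [bc for bc, _ in entries]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        self.remnant = remnant
        self.sample_of = dict(entries)
        # longest-first so the first hit is the longest match
        self.lengths = sorted({len(b) for b in barcodes}, reverse=True)
        self._by_len = {
            n: {bc: s for bc, s in entries if len(bc) == n} for n in self.lengths
        }

    def __len__(self):
        return len(self.sample_of)

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.sample_of.values()))


def trim_and_filter(read: Read, config: PipelineConfig | None = None) -> Read | None:
    """Quality-trim a read from both ends; return None when it is discarded.

    Leading and trailing runs of bases below ``q_min`` are removed; the
    read is then discarded if more than ``max_lowq_frac`` of the remaining
    bases are below ``q_min`` or fewer than ``min_read_len`` bases remain.
    """
    cfg = config or PipelineConfig()
    lo, hi = _trim_bounds(read.qual, cfg.q_min, cfg.max_lowq_frac, cfg.min_read_len)
    if lo < 0:
        return None
    if lo == 0 and hi == len(read.seq):
        return read
    return replace(read, seq=read.seq[lo:hi], qual=read.qual[lo:hi])


def _trim_bounds(qual: str, q_min: int, max_lowq_frac: float, min_len: int) -> tuple[int, int]:
    """(start, end) of the retained window, or (-1, -1) for a discard."""
    scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
    ok = scores >= q_min
    if not ok.any():
        return -1, -1
    lo = int(np.argmax(ok))
    hi = len(ok) - int(np.argmax(ok[::-1]))
    kept = ok[lo:hi]
    if hi - lo < min_len:
        return -1, -1
    if np.count_nonzero(~kept) > max_lowq_frac * kept.size:
        return -1, -1
    return lo, hi


def demultiplex(read: Read, table: BarcodeTable) -> tuple[str, Read] | None:
    """Assign a read to a sample and strip its barcode.

    Returns ``(sample, read-without-barcode)`` or None for unassigned.
    Assignment requires barcode + remnant at the very start of the read;
    the remnant is retained as part of the tag sequence.
    """
    if len(table) == 0:
        raise ValueError("empty barcode table")
    remnant = table.remnant
    hits = []
    for n in table.lengths:
        prefix = read.seq[:n]
        sample = table._by_len[n].get(prefix)
        if sample is not None and read.seq[n : n + len(remnant)] == remnant:
            hits.append((n, sample))
    if not hits:
        return None
    if len(hits) > 1 and hits[0][0] == hits[1][0]:  # exact tie
        return None
    n, sample = hits[0]  # longest match
    trimmed = replace(read, seq=read.seq[n:], qual=read.qual[n:], sample=sample)
    return sample, trimmed


@dataclass
class DemuxResult:
    """Per-sample reads plus the bookkeeping needed for reports.

    ``report`` contains one row per sample and the two assignment rates
    from the library totals: ``assigned_of_total`` counts quality-discarded
    reads in the denominator, ``assigned_of_passing`` does not.
    """

    by_sample: dict[str, list[Read]]
    n_input: int
    n_discarded: int
    n_unassigned: int
    report: pd.DataFrame = field(repr=False)


def process_reads(
    records: Iterable[tuple[str, str, str]],
    table: BarcodeTable,
    config: PipelineConfig | None = None,
) -> DemuxResult:
    """Quality-trim, filter and demultiplex a stream of raw records.

    Conservation: every input read ends up assigned, unassigned or
    discarded.  Trimming runs first, so a read whose low-quality tail
    merely shortens it can still be assigned by its intact barcode.
    """
    cfg = config or PipelineConfig()
    by_sample: dict[str, list[Read]] = {s: [] for s in table.samples}
    n_input = n_discarded = n_unassigned = 0
    bound_cache: dict[str, tuple[int, int]] = {}
    for rid, seq, qual in records:
        n_input += 1
        bounds = bound_cache.get(qual)
        if bounds is None:
            bounds = _trim_bounds(qual, cfg.q_min, cfg.max_lowq_frac, cfg.min_read_len)
            bound_cache[qual] = bounds
        lo, hi = bounds
        if lo < 0:
            n_discarded += 1
            continue
        read = Read(rid, seq[lo:hi], qual[lo:hi])
        hit = demultiplex(read, table)
        if hit is None:
            n_unassigned += 1
            continue
        sample, read = hit
        by_sample[sample].append(read)

    n_passing = n_input - n_discarded
    n_assigned = n_passing - n_unassigned
    report = pd.DataFrame(
        {
            "sample": list(by_sample),
            "assigned": [len(v) for v in by_sample.values()],
        }
    )
    report.attrs["totals"] = {
        "input": n_input,
        "discarded": n_discarded,
        "unassigned": n_unassigned,
        "assigned": n_assigned,
        "assigned_of_total": n_assigned / n_input if n_input else 0.0,
        "assigned_of_passing": n_assigned / n_passing if n_passing else 0.0,
    }
    return DemuxResult(by_sample, n_input, n_discarded, n_unassigned, report)
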