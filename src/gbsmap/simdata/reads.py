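"""Barcoded GBS read simulation.

Reads are emitted per (sample, tag locus): a barcode, the primary cut-site
remnant, and genomic sequence from the cut site, truncated to the read
length.  Per-locus amplification factors are log-normal — GBS libraries
are strongly overdispersed, with a minority of tags soaking up a large
share of reads — and per-sample per-locus read counts are Poisson around
``mean_depth_per_tag`` times that factor.  Substitution errors are applied
uniformly at ``error_rate`` per base (no indels, no position-dependent
error profile).

One deliberate simplification: recombination breakpoints are treated as
falling between restriction fragments, so every read is a faithful copy of
one parental tag sequence (chimeric reads from a crossover inside a
fragment are not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..seqs import BASES, array_seq, seq_array
from .genome import ParentGenomes
from .population import DHPopulation
from .truth import SimTruth, TagTruth, build_truth

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class QualityModel:
    """Base-quality generation: constant q40 with an optional low-q tail."""

    base_q: int = 40
    tail_len: int = 0
    tail_q: int = 2
    tail_frac: float = 0.0


def generate_barcodes(n: int, length: int = 6, seed: int = 77) -> list[str]:
    """``n`` distinct fixed-length barcodes, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        bc = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


@dataclass
class SimLibrary:
    """A simulated sequencing library with its ground truth attached."""

    records: list[tuple[str, str, str]]  # (read id, sequence, quality string)
    truth: SimTruth
    barcode_of: dict[str, str]  # sample -> barcode
    samples: list[str]  # progeny line ids + parental replicate samples
    parent_samples: dict[str, list[str]]  # 'Syn'/'Op' -> replicate sample ids
    counts: pd.DataFrame = field(repr=False)  # per-(sample, locus) Poisson draws

    @property
    def progeny_samples(self) -> list[str]:
        reps = set(self.parent_samples["Syn"]) | set(self.parent_samples["Op"])
        return [s for s in self.samples if s not in reps]

    def write_fastq(self, path) -> None:
        from ..io import write_fastq

        write_fastq(self.records, path)

    def barcode_table(self):
        from ..readproc import BarcodeTable

        return BarcodeTable([(bc, sample) for sample, bc in self.barcode_of.items()])


def simulate_reads(
    parents: ParentGenomes,
    population: DHPopulation,
    barcodes: list[str] | None = None,
    read_len: int = 100,
    mean_depth_per_tag: float = 1.0,
    error_rate: float = 0.002,
    seed: int = 0,
    parent_replicates: int = 3,
    depth_sigma: float = 1.0,
    quality: QualityModel = QualityModel(),
    truth: SimTruth | None = None,
) -> SimLibrary:
    """Simulate one barcoded single-end library for a DH population.

    The parental lines are included as ``parent_replicates`` independent
    samples each (replication increases parental depth, which downstream
    variant calling relies on to call the parents reliably).  Fails if the
    barcode set is smaller than the number of samples.  Deterministic given
    the seed: identical arguments give byte-identical records.
    """
    rng = np.random.default_rng(seed)
    truth = truth or build_truth(parents, read_len=read_len,
                                 genetic_length_cM=population.genetic_length_cM)

    samples: list[tuple[str, object]] = [(ln.line_id, ln) for ln in population]
    parent_samples = {"Syn": [], "Op": []}
    for parent, idx in (("Syn", 0), ("Op", 1)):
        for r in range(1, parent_replicates + 1):
            sid = f"{parent}_rep{r}"
            samples.append((sid, idx))
            parent_samples[parent].append(sid)
    sample_ids = [sid for sid, _ in samples]

    if barcodes is None:
        barcodes = generate_barcodes(len(samples))
    if len(barcodes) < len(samples):
        raise ValueError(f"{len(samples)} samples but only {len(barcodes)} barcodes")
    barcode_of = dict(zip(sample_ids, barcodes))

    loci: list[TagTruth] = [truth.tags[k] for k in sorted(truth.tags)]
    n_loci = len(loci)

    # per-locus amplification factor, mean-normalised log-normal
    abundance = rng.lognormal(mean=-0.5 * depth_sigma**2, sigma=depth_sigma, size=n_loci)

    # parental origin of every (sample, locus)
    origin = np.zeros((len(samples), n_loci), dtype=np.int8)
    by_chrom: dict[tuple[int, int], list[int]] = {}
    for j, t in enumerate(loci):
        by_chrom.setdefault((t.chrom, t.subgenome), []).append(j)
    for i, (_, who) in enumerate(samples):
        if isinstance(who, int):  # parental replicate
            origin[i, :] = who
        else:
            for (c, s), idxs in by_chrom.items():
                pos = np.array([min(loci[j].cut_pos, truth.chrom_len_bp - 1) for j in idxs])
                origin[i, np.array(idxs)] = who.origins_at(c, s, pos)

    # a locus yields reads only when the inherited parent carries the tag
    has_tag = np.zeros((2, n_loci), dtype=bool)
    for j, t in enumerate(loci):
        has_tag[0, j] = t.syn_seq is not None
        has_tag[1, j] = t.op_seq is not None

    lam = mean_depth_per_tag * abundance[None, :] * has_tag[origin, np.arange(n_loci)]
    counts = rng.poisson(lam)

    records: list[tuple[str, str, str]] = []
    seq_cache: dict[tuple[int, int, int], np.ndarray] = {}
    tail = quality.tail_len > 0 and quality.tail_frac > 0
    for i, sid in enumerate(sample_ids):
        bc_arr = seq_array(barcode_of[sid])
        nz = np.flatnonzero(counts[i])
        for j in nz:
            key = (i, j, int(origin[i, j]))
            base = seq_cache.get(key[1:])
            if base is None:
                t = loci[j]
                tag = t.syn_seq if origin[i, j] == 0 else t.op_seq
                base = seq_array(tag)
                seq_cache[key[1:]] = base
            read_core = base[: max(0, read_len - bc_arr.size)]
            template = np.concatenate([bc_arr, read_core])
            for k in range(counts[i, j]):
                seq = template
                if error_rate > 0:
                    n_err = rng.binomial(template.size, error_rate)
                    if n_err:
                        seq = template.copy()
                        pos = rng.choice(template.size, size=n_err, replace=False)
                        shift = rng.integers(1, 4, size=n_err)
                        idx = np.searchsorted(_BASE_ARR, seq[pos])
                        seq[pos] = _BASE_ARR[(idx + shift) % 4]
                qual = chr(quality.base_q + 33) * seq.size
                if tail and rng.random() < quality.tail_frac:
                    nt = min(quality.tail_len, seq.size)
                    qual = qual[: seq.size - nt] + chr(quality.tail_q + 33) * nt
                records.append((f"{sid}|{loci[j].tag_id}|{k}", array_seq(seq), qual))

    counts_df = pd.DataFrame(counts, index=sample_ids, columns=[t.tag_id for t in loci])
    return SimLibrary(
        records=records,
        truth=truth,
        barcode_of=barcode_of,
        samples=sample_ids,
        parent_samples=parent_samples,
        counts=counts_df,
    )
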