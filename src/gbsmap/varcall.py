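"""SNP and presence/absence calling with segregation-aware post-filters.

Genotype calling itself is deliberately simple — at ~1x coverage per tag a
sample's genotype is whatever alleles its reads show — and reliability
comes from the post-processing filters, applied in sequence to every
candidate site:

1. sites showing more than two allelic states are dropped;
2. sites where the pooled parents are not called with distinct homozygous
   alleles are dropped (variants seen only in the progeny are artifacts);
3. progeny whose basecalls differ from both parental alleles are tolerated
   in fewer than 2% of individuals and recorded as missing, otherwise the
   site is dropped;
4. sites with 80% or more missing progeny calls are dropped;
5. sites failing the allele-coverage-ratio test are dropped.

The ratio test formalises the polyploid coverage argument: when divergent
homeologous copies collapse onto one reference tag, a read showing the
genome-specific variant can only come from the one subgenome that carries
it, so the expected variant fraction of pooled carrier depth is
``1/n_subgenomes`` (1/3 in a hexaploid: the probability of recovering the
variant allele is twice less than that of the base shared by the other
homeologues).  Single-copy tags instead show only the variant in carriers.
Persistent ~1/2 fractions indicate paralog artifacts and fail both nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import CoverageTable
from .config import PipelineConfig
from .refbuild import ReferenceEntry
from .seqs import PaddedSeqMatrix, seq_array

_BASES = "ACGT"
_DROP_REASONS = ["multi_state", "monomorphic", "parents_not_polymorphic",
                 "nonparental", "missing", "allele_ratio"]


def call_sample_genotype(depth_syn: int, depth_op: int, min_depth: int = 1) -> str:
    """Codominant call from one sample's two allele depths.

    'B' is the Syn allele, 'A' the Op allele, 'H' both observed at
    ``min_depth`` or more, '-' missing.
    """
    syn_ok = depth_syn >= min_depth
    op_ok = depth_op >= min_depth
    if syn_ok and op_ok:
        return "H"
    if syn_ok:
        return "B"
    if op_ok:
        return "A"
    return "-"


def allele_ratio_test(
    variant_depth: int,
    shared_depth: int,
    alpha: float = 0.01,
    expected_variant_fraction: float = 1 / 3,
) -> bool:
    """Allele-coverage-ratio check on pooled carrier depths.

    Depths are pooled over the samples in which the variant allele was
    observed.  The site passes when either single-copy coverage is
    consistent (no shared-base reads at all in carriers) or an exact
    two-sided binomial test does not reject, at level ``alpha``, the
    collapsed-homeolog null that a carrier read shows the variant with
    probability ``expected_variant_fraction``.
    """
    total = variant_depth + shared_depth
    if total == 0:
        return False
    if shared_depth == 0:
        return True
    p = stats.binomtest(variant_depth, total, expected_variant_fraction).pvalue
    return p >= alpha


@dataclass
class SnpSite:
    """A retained biallelic SNP site with per-progeny genotype calls."""

    ref_id: str
    offset: int
    allele_syn: str
    allele_op: str
    genotypes: dict[str, str]  # progeny sample -> call in {A, B, H, -}
    allele_depths: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    @property
    def marker_id(self) -> str:
        return f"{self.ref_id}_{self.offset}_SNP"

    @property
    def missing_fraction(self) -> float:
        n = len(self.genotypes)
        return sum(g == "-" for g in self.genotypes.values()) / n if n else 1.0

    @property
    def het_fraction(self) -> float:
        n = len(self.genotypes)
        return sum(g == "H" for g in self.genotypes.values()) / n if n else 0.0


def filter_snp_sites(
    coverage: CoverageTable,
    entries: list[ReferenceEntry],
    syn_samples: list[str],
    op_samples: list[str],
    progeny: list[str],
    config: PipelineConfig | None = None,
    min_state_support: int = 2,
) -> tuple[list[SnpSite], pd.DataFrame]:
    """Apply the post-processing filter chain to every candidate site.

    Candidate sites are the recorded representative-difference offsets of
    merged reference entries plus any offset at which two or more allelic
    states are observed.  A base counts as an allelic state when it is seen
    in at least ``min_state_support`` distinct samples; singleton
    observations are sequencing errors at these depths and are handled by
    the non-parental rule (filter 3) instead of inflating filter 1.

    Returns the retained sites and an audit table of drop counts per filter.
    """
    cfg = config or PipelineConfig()
    sample_pos = {s: i for i, s in enumerate(coverage.samples)}
    syn_idx = np.array([sample_pos[s] for s in syn_samples])
    op_idx = np.array([sample_pos[s] for s in op_samples])
    prog_idx = np.array([sample_pos[s] for s in progeny])

    audit = {r: 0 for r in _DROP_REASONS}
    audit["retained"] = 0
    sites: list[SnpSite] = []

    for entry in entries:
        if entry.source != "merged":
            continue
        L = coverage.ref_length(entry.ref_id)
        tensor = coverage.sample_base_counts(entry.ref_id, list(range(L)))
        if tensor.sum() == 0:
            continue
        support = (tensor > 0).sum(axis=0)  # (L, 4): samples observing each base
        variable = np.flatnonzero((support >= min_state_support).sum(axis=1) >= 2)
        offsets = sorted(set(entry.variant_offsets) | set(variable.tolist()))
        for o in offsets:
            site = _filter_one_site(
                entry, o, tensor[:, o, :], support[o], syn_idx, op_idx, prog_idx,
                progeny, cfg, min_state_support,
            )
            if isinstance(site, str):
                audit[site] += 1
            else:
                audit["retained"] += 1
                sites.append(site)

    audit_df = pd.DataFrame(
        {"stage": list(audit), "sites": list(audit.values())}
    )
    return sites, audit_df


def _filter_one_site(entry, offset, counts, support, syn_idx, op_idx, prog_idx,
                     progeny, cfg, min_state_support):
    """Run filters 1-5 on one (reference, offset); returns SnpSite or reason."""
    states = np.flatnonzero(support >= min_state_support)
    if states.size > 2:
        return "multi_state"  # filter 1
    if states.size < 2:
        return "monomorphic"

    b1, b2 = int(states[0]), int(states[1])

    # filter 2: pooled parents must be distinct homozygotes at the two states
    syn_dep = counts[syn_idx][:, [b1, b2]].sum(axis=0)
    op_dep = counts[op_idx][:, [b1, b2]].sum(axis=0)
    syn_call = call_sample_genotype(syn_dep[0], syn_dep[1], cfg.min_depth)
    op_call = call_sample_genotype(op_dep[0], op_dep[1], cfg.min_depth)
    if {syn_call, op_call} != {"B", "A"}:  # includes H, missing, same-allele
        return "parents_not_polymorphic"
    allele_syn = _BASES[b1 if syn_call == "B" else b2]
    allele_op = _BASES[b2 if syn_call == "B" else b1]
    i_syn, i_op = _BASES.index(allele_syn), _BASES.index(allele_op)

    # filter 3: progeny with basecalls outside the parental alleles
    prog_counts = counts[prog_idx]
    other = np.ones(4, dtype=bool)
    other[[i_syn, i_op]] = False
    nonparental = prog_counts[:, other].sum(axis=1) > 0
    if nonparental.sum() >= cfg.max_nonparental_frac * len(prog_idx):
        return "nonparental"

    # filter 4: genotype the progeny, recording non-parental calls as missing
    genotypes: dict[str, str] = {}
    depths: dict[str, tuple[int, int]] = {}
    for k, s in enumerate(progeny):
        d_syn, d_op = int(prog_counts[k, i_syn]), int(prog_counts[k, i_op])
        depths[s] = (d_syn, d_op)
        genotypes[s] = "-" if nonparental[k] else call_sample_genotype(d_syn, d_op, cfg.min_depth)
    n_missing = sum(g == "-" for g in genotypes.values())
    if n_missing >= cfg.max_missing_frac * len(progeny):
        return "missing"

    # filter 5: allele coverage ratio, trying either allele as the
    # genome-specific variant
    all_counts = counts  # all samples, parents included: carriers are carriers
    for variant, shared in ((i_syn, i_op), (i_op, i_syn)):
        carriers = all_counts[:, variant] > 0
        v = int(all_counts[carriers, variant].sum())
        s_ = int(all_counts[carriers, shared].sum())
        if allele_ratio_test(v, s_, cfg.ratio_alpha, cfg.expected_variant_fraction):
            break
    else:
        return "allele_ratio"

    return SnpSite(
        ref_id=entry.ref_id,
        offset=int(offset),
        allele_syn=allele_syn,
        allele_op=allele_op,
        genotypes=genotypes,
        allele_depths=depths,
    )


@dataclass
class PaMarker:
    """A dominant presence/absence marker from a parent-specific tag."""

    ref_id: str
    donor: str  # parent whose genome carries the tag
    states: dict[str, str]  # progeny sample -> 'P' | 'A' | '-'
    depths: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def marker_id(self) -> str:
        return f"{self.ref_id}_PA"

    @property
    def n_present(self) -> int:
        return sum(v == "P" for v in self.states.values())


def call_pa_markers(
    coverage: CoverageTable,
    entries: list[ReferenceEntry],
    progeny: list[str],
    config: PipelineConfig | None = None,
) -> list[PaMarker]:
    """Score presence/absence for every parent-specific reference entry.

    'Present' needs ``min_depth`` reads.  'Absent' is only trusted when the
    sample's library did not collapse: its total assigned depth must reach
    a floor (a quarter of the median progeny library) — calling absence in
    a low-coverage GBS sample is unreliable, so shallow samples get missing
    instead.  Markers are kept only with donor-parent cluster support of at
    least ``pa_min_parent_depth`` reads and presence calls in at least
    ``min_presence`` progeny.
    """
    cfg = config or PipelineConfig()
    totals = coverage.depth.sum(axis=0)
    floor = np.median([totals[s] for s in progeny]) / 4.0
    markers: list[PaMarker] = []
    for entry in entries:
        if not entry.is_pa_candidate:
            continue
        donor_depth = entry.syn_depth if entry.donor == "Syn" else entry.op_depth
        if donor_depth < cfg.pa_min_parent_depth:
            continue
        row = coverage.depth.loc[entry.ref_id]
        states: dict[str, str] = {}
        depths: dict[str, int] = {}
        for s in progeny:
            d = int(row[s])
            depths[s] = d
            if d >= cfg.min_depth:
                states[s] = "P"
            elif totals[s] >= floor:
                states[s] = "A"
            else:
                states[s] = "-"
        marker = PaMarker(entry.ref_id, entry.donor, states, depths)
        if marker.n_present >= cfg.min_presence:
            markers.append(marker)
    return markers


def dedupe_pa_against_snp(
    pa_markers: list[PaMarker],
    pa_sequences: dict[str, str],
    snp_sites: list[SnpSite],
    snp_entries: list[ReferenceEntry],
    max_mismatches: int = 3,
) -> list[PaMarker]:
    """Remove PA markers that restate a SNP-bearing tag.

    Highly divergent parental alleles of one locus can surface once as a
    codominant SNP tag and again as a pair of dominant PA tags; a PA marker
    whose sequence matches any SNP-bearing merged reference representative
    within ``max_mismatches`` is redundant and dropped.
    """
    snp_refs = {s.ref_id for s in snp_sites}
    reps: list[str] = []
    for e in snp_entries:
        if e.ref_id in snp_refs:
            for rep in (e.syn_rep, e.op_rep, e.sequence):
                if rep:
                    reps.append(rep)
    if not reps or not pa_markers:
        return list(pa_markers)
    mat = PaddedSeqMatrix.from_sequences(sorted(set(reps)))
    kept = []
    for m in pa_markers:
        mm, _ = mat.prefix_mismatches(seq_array(pa_sequences[m.ref_id]))
        if mm.size and mm.min() <= max_mismatches:
            continue
        kept.append(m)
    return kept


def genotype_matrix(
    snp_sites: list[SnpSite],
    pa_markers: list[PaMarker],
    progeny: list[str],
) -> pd.DataFrame:
    """Markers x individuals matrix; codominant {A,B,H,-}, dominant {P,A,-}."""
    rows = []
    for s in snp_sites:
        rows.append({"marker": s.marker_id, "type": "SNP",
                     "alleles": f"{s.allele_syn}/{s.allele_op}",
                     **{p: s.genotypes.get(p, "-") for p in progeny}})
    for m in pa_markers:
        rows.append({"marker": m.marker_id, "type": "PA", "alleles": m.donor,
                     **{p: m.states.get(p, "-") for p in progeny}})
    return pd.DataFrame(rows, columns=["marker", "type", "alleles", *progeny])


def write_vcf(snp_sites: list[SnpSite], progeny: list[str], path) -> None:
    """Minimal VCF export of retained SNP sites (GT only; Syn is REF)."""
    code = {"B": "0/0", "A": "1/1", "H": "0/1", "-": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(progeny) + "\n")
        for s in snp_sites:
            calls = "\t".join(code[s.genotypes.get(p, "-")] for p in progeny)
            fh.write(f"{s.ref_id}\t{s.offset + 1}\t{s.marker_id}\t{s.allele_syn}\t"
                     f"{s.allele_op}\t.\tPASS\t.\tGT\t{calls}\n")
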