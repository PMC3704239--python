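"""From raw barcoded reads to a filtered genotype matrix.

Runs the variant-calling half of the pipeline in memory: demultiplex and
quality-trim, cluster parental reads at 96% identity, merge the parental
clusters into a reference, align every sample uniquely with up to three
mismatches, and apply the five post-filters to candidate SNP sites.
"""

import warnings
from collections import Counter

from gbsmap.align import ReferenceIndex, align_samples, coverage_table
from gbsmap.config import PipelineConfig
from gbsmap.readproc import process_reads
from gbsmap.refbuild import cluster_reads, merge_parental_clusters
from gbsmap.simdata import (
    GenomeModel, simulate_dh_population, simulate_parents, simulate_reads,
)
from gbsmap.varcall import filter_snp_sites, genotype_matrix

warnings.simplefilter("ignore")
cfg = PipelineConfig()

model = GenomeModel(n_chromosomes=1, chrom_len_bp=300_000, seed=4)
parents = simulate_parents(model)
population = simulate_dh_population(parents, 48, seed=5)
library = simulate_reads(parents, population, mean_depth_per_tag=2.0, seed=6)

demux = process_reads(library.records, library.barcode_table(), cfg)
totals = demux.report.attrs["totals"]
print(f"reads: {totals['input']}, assigned: {totals['assigned']} "
      f"({100 * totals['assigned_of_total']:.1f}%)")

syn_samples = library.parent_samples["Syn"]
op_samples = library.parent_samples["Op"]
syn_reads = Counter(r.seq for s in syn_samples for r in demux.by_sample[s])
op_reads = Counter(r.seq for s in op_samples for r in demux.by_sample[s])
entries = merge_parental_clusters(
    cluster_reads(syn_reads, cfg.snp_identity, "Syn"),
    cluster_reads(op_reads, cfg.snp_identity, "Op"),
    cfg.merge_max_mismatch,
)
print(f"reference entries: {len(entries)} "
      f"({sum(e.source == 'merged' for e in entries)} merged)")

aln = align_samples(demux.by_sample, ReferenceIndex(entries),
                    cfg.snp_max_mismatch, cfg.min_overlap)
print(f"aligned {aln.n_aligned}, ambiguous {aln.n_ambiguous}, unaligned {aln.n_unaligned}")

cov = coverage_table(aln)
progeny = [ln.line_id for ln in population]
sites, audit = filter_snp_sites(cov, entries, syn_samples, op_samples, progeny, cfg)
print(audit.to_string(index=False))
matrix = genotype_matrix(sites, [], progeny)
print(matrix.iloc[:5, :10].to_string(index=False))
# Rows are markers (reference id + offset), calls are B (Syn allele),
# A (Op allele), H, or '-' for missing; the audit table shows how many
# candidate sites each post-filter removed.
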