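"""Simulate a small allopolyploid GBS library and look at its truth.

Builds two parental genomes (two chromosomes x two subgenomes, 3%
homeolog divergence), a doubled-haploid population of 24 lines, and a
barcoded PstI-MseI read library at ~2x tag depth, then prints what the
ground-truth catalogue knows about it.
"""

import warnings

from gbsmap.simdata import (
    GenomeModel,
    build_truth,
    simulate_dh_population,
    simulate_parents,
    simulate_reads,
)

warnings.simplefilter("ignore")  # the 3% divergence collapse warning is expected

model = GenomeModel(n_chromosomes=2, chrom_len_bp=200_000, n_subgenomes=2,
                    homeolog_divergence=0.03, parent_snp_rate=0.005,
                    site_gainloss_rate=0.05, seed=1)
parents = simulate_parents(model)
population = simulate_dh_population(parents, n_lines=24, crossover_rate=0.5, seed=2)
library = simulate_reads(parents, population, mean_depth_per_tag=2.0,
                         error_rate=0.002, seed=3)

truth = library.truth
print(f"tag loci:        {len(truth.tags)}")
print(f"  SNP-bearing:   {len(truth.snp_tags())}")
print(f"  presence/absence: {len(truth.pav_tags())}")
collapsible = sum(t.collapsible for t in truth.tags.values())
print(f"  collapsible with a homeolog at 96% identity: {collapsible}")
print(f"reads emitted:   {len(library.records)} across {len(library.samples)} samples")
print(f"first read:      {library.records[0][1][:40]}...")
# Each read starts with a 6 bp sample barcode followed by the PstI remnant
# TGCAG; SNP counts above are what the pipeline should rediscover.
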