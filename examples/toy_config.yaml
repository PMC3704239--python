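# A desk-scale run configuration for the gbsmap CLI:
#   gbsmap run -c examples/toy_config.yaml -o runs/toy
seed: 1

sim:
  n_chromosomes: 2
  chrom_len_bp: 120000
  n_subgenomes: 2
  homeolog_divergence: 0.03   # homeologs collapse at the 96% clustering identity
  parent_snp_rate: 0.005
  site_gainloss_rate: 0.05
  n_lines: 24
  crossover_rate: 0.5         # 50 cM per toy chromosome
  mean_depth_per_tag: 2.0
  error_rate: 0.002
  framework_spacing_cM: 10.0
  framework_missing_rate: 0.05

# enzymes: defaults are PstI (CTGCAG) + MseI (printed site AATT); override
# e.g. secondary_site: ACGCGT for a PstI-MluI library.

pipeline:
  # all thresholds default to the published pipeline settings; override here
  max_r: 0.10
  min_presence: 10
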