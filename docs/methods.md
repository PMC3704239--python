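# Methods

This note documents the models and procedures implemented in `gbsmap`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The problem

Genotyping-by-sequencing (GBS) reduces a genome to short tags adjacent to
the cut sites of a rare-cutting restriction enzyme (PstI here, paired with
a more frequent second cutter), sequences them shallowly across a mapping
population, and scores the tags as genetic markers.  In an allopolyploid
such as bread wheat two complications dominate: homeologous copies of a
locus on different subgenomes are only a few percent diverged and readily
collapse onto a single reference tag, mimicking SNPs; and ~1x per-tag
coverage makes both heterozygote detection and "absent" calls unreliable.
`gbsmap` implements a variant-calling and mapping pipeline designed around
those two facts, together with a simulator that reproduces them with known
ground truth.

## Pipeline model

**Read processing.** Reads begin with a sample barcode followed by the
primary cut-site remnant (`TGCAG` for PstI).  Bases below phred 15 are
trimmed from both ends; reads with more than 20% sub-threshold bases after
trimming, or shorter than 30 bp, are discarded.  The >20% rule is applied
after trimming (the order is a choice; applying it after keeps more data).
Assignment requires barcode + remnant at position 0, resolved by longest
barcode match; the remnant stays on the read as the first tag bases.

**Reference construction.** Each parent's reads are clustered greedily in
decreasing-abundance order (ties lexicographic) using end-anchored,
ungapped identity over the shorter sequence — GBS tags share a fixed cut
site start, so no offset search or gapping is needed, and unlike word-based
clustering heuristics the procedure is exactly reproducible.  SNP discovery
clusters at 96% identity (which deliberately lets diverged homeologs and
alleles co-cluster); presence/absence (PA) discovery clusters at 100%.
Parental clusters within 3 mismatches are merged one-to-one (greedy, best
match first) into reference entries whose differing offsets are the
candidate SNP positions; the Op representative is the reference base
sequence by convention.  In PA mode only identical (0-mismatch) parental
clusters merge, so divergent alleles of one locus stay separate — that is
what lets them be detected as dominant markers — and PA reference entries
additionally require 2 or more supporting parental reads, so that singleton
error reads do not become loci.

**Alignment.** Reads align end-anchored and ungapped to every reference
entry; a read is placed only on a strictly unique best hit within the
mismatch bound (3 for SNP mode, 1 for PA mode; minimum 30 bp overlap).
Ties are discarded as ambiguous: in a deduplicated reference an equally
good second hit means the locus cannot be identified.  Coordinates are
0-based, half-open.

**SNP calling.** A sample's genotype at a site is whatever alleles its
reads show (`min_depth` 1 by default — at ~1x coverage demanding more
would discard most of the data; the damage a permissive caller does is
swept up by the filters).  Candidate sites (recorded merge offsets plus
any offset with two observed states) then pass five sequential filters:

1. more than two allelic states → dropped.  A base counts as a *state*
   when observed in at least `min_state_support` (default 2) distinct
   samples; singleton observations are almost always sequencing errors at
   these depths and are handled by filter 3 instead.
2. pooled parental replicates must be called as distinct homozygotes.
3. progeny with basecalls outside the two parental alleles are tolerated
   below 2% of individuals and recorded as missing; at or above 2% the
   site is dropped.
4. sites with 80% or more missing progeny calls are dropped.
5. the allele-coverage-ratio test (below).

**The allele-coverage-ratio test.** When divergent homeologous copies
collapse onto one reference tag, a carrier's reads show the genome-specific
variant only from the one subgenome carrying it: with `n` subgenomes at
roughly equal coverage the expected variant fraction of pooled carrier
depth is `1/n` — 1/3 in a hexaploid, where the variant is recovered with
twice smaller probability than the base shared by the other two
homeologues.  The check is formalised as a composite exact binomial test on
depths pooled over carrier samples: the site passes if carriers show no
shared-base reads at all (single-copy coverage), or if a two-sided binomial
test does not reject `p = expected_variant_fraction` (default 1/3) at
`alpha = 0.01`.  Both allele orientations are tried, since either parent's
allele may be the genome-specific one.  Persistent ~1/2 fractions — the
signature of paralogs sampled at equal depth — fail both nulls.  The
statistical form of this rule is this package's own formalisation of the
published coverage-ratio argument.

**PA calling.** Presence needs one read; absence is only called when the
sample's library is large enough to have seen the tag (total assigned
depth at least a quarter of the median progeny library, else missing) —
absence calls in shallow GBS libraries are otherwise dominated by dropout.
Markers need presence in at least 10 progeny.  PA markers whose sequence
matches a SNP-bearing merged reference within 3 mismatches are removed as
redundant restatements of the codominant marker.

**Bin-mapping.** For each marker, recombination fractions against every
framework-map marker are computed from parental (AA/BB) and recombinant
(AB/BA) gamete counts, excluding heterozygous and missing calls pairwise.
Candidates are framework markers with `r <= 0.10`; candidates on more than
one chromosome exclude the marker; the anchor is the candidate sharing the
fewest recombination events, ties resolved to the smallest-cM ("top") tied
marker.  For dominant PA markers only presence calls are informative;
candidacy additionally requires a one-sided exact binomial association
test `P(X >= k | Bin(n, 1/2)) < 0.001`, with the direction fixed by the
marker's known donor parent, and no multiple-testing correction (the raw
threshold is the published rule).

*Emitted interval.*  The recombination interval reported for a marker is
delimited by the framework markers immediately flanking the tied anchor
set.  Two-point counts against the anchor carry no information about which
side of it the marker lies — an anchor is precisely the marker with which
recombination was (nearly) unobserved — and empirically, one-interval
conventions that guess a side misplace a large fraction of cosegregating
markers at n≈92.  With framework markers every 10 cM the emitted bins are
about two framework intervals (~20 cM) wide; this is the honest resolution
of a 92-line population, comparable to the published ~10 cM average bins
for dominant markers.

**De novo mapping.** Input markers need at most 20% missing and 5%
heterozygous calls.  Markers are grouped by single linkage over the
relation {two-point LOD >= 8 and Haldane distance <= 20 cM}, with the DH
LOD `R log10(r) + P log10(1-r) + N log10 2` (limit `N log10 2` at R=0).
Ordering within a group is a stated heuristic, not a clone of any mapping
program: greedy nearest-neighbour chain construction from the most distal
marker, followed by 2-opt segment reversals to convergence on total
adjacent map distance, orientation normalised lexicographically.  For the
group sizes this package targets (tens of markers) 2-opt reliably recovers
the simulated order or its reversal.

**Mapping function.** Haldane throughout (`d = -50 ln(1-2r)`), consistent
with the simulator's no-interference crossover model; Kosambi is available
by configuration.

**Anchoring.** In silico digestion enumerates fragments bounded by a
primary and a secondary cut within the 30-1000 bp size selection window;
each yields one expected tag read from the primary cut inward (primary-
primary fragments are discarded: they would carry the wrong adapter pair).
Mapped tags are located on contigs by exhaustive two-strand scanning at 0
or up to 3 mismatches; a tag hitting more than 5 distinct contigs is
flagged repetitive.  Gene-to-marker distances are measured from the CDS 5'
end to the nearest anchored non-repetitive tag (0 inside the gene).

## The simulator

The generator emulates: an allopolyploid genome (default 2 subgenomes at
3% homeolog divergence — deliberately inside the 96% collapse regime);
parental haplotypes differing at 0.5% of sites within a subgenome; loss of
5% of primary cut sites in one parent (the source of PA variation);
methylation masking of cut sites for methylation-sensitive enzymes;
doubled-haploid progeny as single doubled gametes with Poisson crossovers,
uniform breakpoints and no interference (hence Haldane cM by
construction); and 100 bp single-end barcoded reads starting at the cut
site, only from fragments with a primary and a secondary end inside the
size window.  Read counts per (sample, tag) are Poisson around
`mean_depth_per_tag` times a per-locus log-normal amplification factor
(sigma 1.0, mean-normalised): GBS libraries are strongly overdispersed,
and that overdispersion is what gives a subset of tags the coverage needed
to pass the de novo missing-data filter, as in real data.  Parents are
included as three replicate samples, tripling parental depth.

Defaults chosen where no published value exists, fixed once:

- `crossover_rate = 0.5` crossovers per chromosome per gamete (one chiasma
  per bivalent shared between two of four chromatids), i.e. 50 cM toy
  chromosomes.  A physically scaled wheat megabase would be <1 cM and
  unresolvable at n=92; 50 cM keeps recombination structure resolvable
  while marker density per cM stays realistic.
- framework maps with 10 cM spacing and 5% missing calls: at 92 lines each
  10 cM bin contains ~9 observable recombination events, the minimum for
  bins to be distinguishable.
- base qualities constant q40, with an optional low-quality tail to
  exercise trimming.

Not emulated: PCR duplicates, indels, paired-end reads, instrument error
profiles, position-dependent quality, chimeric reads from crossovers
inside a restriction fragment (breakpoints are treated as falling between
fragments), and methylation differences between individuals.  Passing
tests therefore demonstrate correctness of the algorithms under the
stated statistical structure, not robustness to every artifact of real
instruments.

## Scoring against truth

Tests score pipeline output by attributing each called marker to a truth
locus.  Attribution follows the variant, not just the cluster
representative: when near-identical homeologs collapse, the called SNP
belongs to whichever subgenome copy actually carries the polymorphism, and
the marker segregates accordingly.  Loci whose homeologous counterpart is
*sequence-identical* (`homeolog_mismatches == 0`) are excluded from
chromosome-identity scoring: their read pools are inseparable in
principle, their calls are two-locus composites (e.g. a SNP whose
identical homeolog is itself a presence/absence locus), and no
sequence-based method could assign them uniquely.  Such loci are rare
(~0.5% of mapped markers at the default divergence) and are the same class
the original analysis acknowledges as unavoidably mis-mappable.

## Numerical and degenerate-input choices

- Identity and mismatch counts are always end-anchored over the shorter
  sequence; length differences (from trimming) are not mismatches.
- Clustering ties break by abundance then lexicographic order; merge ties
  by abundance of the Syn cluster; everything is deterministic.
- `recombination_fraction` with no informative pairs returns NaN and the
  pair is skipped; `two_point_lod` needs at least one informative gamete;
  `haldane_cM` is undefined at r >= 0.5 (capped at 0.4999999 only inside
  ordering, where "very far" suffices).
- Empty inputs (no reads, no clusters, no groups) yield empty outputs, not
  errors; requesting a pipeline stage before its upstream artifacts exist
  raises an error naming the stage to run first.
- Runs are deterministic given the seed; stage seeds are derived as
  seed+1, seed+2, ... for population, reads and framework map.

## Problem sizes

The self-test suite runs the full pipeline on a 2 chromosome x 1 Mb x 2
subgenome genome with 92 DH lines at ~1x tag depth (about 170,000 reads,
~900 reference loci, ~500 mapped markers), which exercises every stage at
a scale where the statistical assertions (>=95% bin recovery, group
purity) are meaningful; smaller fixtures cover unit behaviour.  De novo
linkage-group counts at this scale sit near the density limit: with only
~10 high-coverage markers per 50 cM chromosome, an unlucky draw can open a
gap wider than the 20 cM / LOD 8 linkage radius and split a group, which
is a property of the study design, not of the grouping algorithm.

## Known limitations

- Genotype calling is depth-threshold based, not likelihood based, and
  there is no imputation; both are deliberate non-goals.
- One-to-one greedy cluster merging can mispair when a parent's cluster
  has several equally close counterparts; candidates beyond 3 mismatches
  become spurious PA candidates exactly as in the published caveat about
  divergent alleles.
- The ordering heuristic optimises adjacent distance only; it is not a
  multipoint likelihood and can transpose very tightly linked markers
  (cosegregating markers have no defined order at finite n).
- Bin intervals are reported at the framework resolution; positions inside
  a bin are not estimated.
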