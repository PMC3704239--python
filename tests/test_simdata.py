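"""Simulator behaviour: genome statistics, meiosis, read emission."""

import numpy as np
import pytest

from gbsmap.digest import in_silico_digest
from gbsmap.enzymes import EnzymePair
from gbsmap.seqs import seq_array
from gbsmap.simdata import (
    GenomeModel,
    assign_seed_color,
    build_truth,
    simulate_dh_population,
    simulate_parents,
    simulate_reads,
)

from conftest import make_parents


def test_degenerate_rates_give_identical_parents():
    """With all divergence rates zero the parents are the same genome and
    the truth catalogue contains no SNP or PAV records."""
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=50_000, n_subgenomes=2,
                        homeolog_divergence=0.0, parent_snp_rate=0.0,
                        site_gainloss_rate=0.0, seed=3)
    parents = simulate_parents(model)
    for seqs in parents.sequences.values():
        assert seqs["Syn"] == seqs["Op"]
    truth = build_truth(parents)
    assert truth.snp_tags() == [] and truth.pav_tags() == []
    assert all(t.kind == "mono" for t in truth.tags.values())


def test_parent_mismatch_fraction_matches_rate():
    """Observed parent-parent divergence is binomial around the requested
    SNP rate (within three standard errors)."""
    rate, L = 0.01, 1_000_000
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=L, n_subgenomes=1,
                        parent_snp_rate=rate, site_gainloss_rate=0.0, seed=5)
    parents = simulate_parents(model)
    syn = seq_array(parents.sequences[(0, 0)]["Syn"])
    op = seq_array(parents.sequences[(0, 0)]["Op"])
    frac = np.count_nonzero(syn != op) / L
    se = np.sqrt(rate * (1 - rate) / L)
    assert abs(frac - rate) < 3 * se


def test_site_gainloss_produces_pav_truth_records():
    """A site_gainloss_rate fraction of primary cut sites becomes
    parent-specific, and every such locus is a PAV truth record with a
    donor parent."""
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=400_000, n_subgenomes=1,
                        parent_snp_rate=0.0, site_gainloss_rate=0.1, seed=7)
    parents = simulate_parents(model)
    truth = build_truth(parents)
    n_sites = len(truth.tags)  # loci observed in at least one parent
    pav = truth.pav_tags()
    assert all(t.donor in ("Syn", "Op") for t in pav)
    # knocked-out sites remove both flanking tags of the victim parent;
    # the PAV fraction of tag loci should be near the site-level rate
    frac = len(pav) / n_sites
    assert 0.04 < frac < 0.18


def test_dh_lines_without_crossovers_are_whole_parent_copies():
    pop = simulate_dh_population(
        GenomeModel(n_chromosomes=2, chrom_len_bp=10_000, n_subgenomes=1),
        n_lines=20, crossover_rate=0.0, seed=9)
    for line in pop:
        for segs in line.segments.values():
            assert len(segs) == 1  # one segment: a whole-chromosome copy


def test_dh_segments_tile_chromosome_and_are_homozygous():
    pop = simulate_dh_population(
        GenomeModel(n_chromosomes=1, chrom_len_bp=100_000, n_subgenomes=2),
        n_lines=30, crossover_rate=2.0, seed=10)
    for line in pop:
        for segs in line.segments.values():
            assert segs[0][0] == 0 and segs[-1][1] == 100_000
            for (s1, e1, p1), (s2, e2, p2) in zip(segs, segs[1:]):
                assert e1 == s2 and p1 != p2  # contiguous, alternating


def test_recombinant_fraction_follows_haldane():
    """Two loci 10 cM apart recombine in (1 - e^-0.2)/2 of gametes."""
    n = 10_000
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=1_000_000, n_subgenomes=1)
    pop = simulate_dh_population(model, n, crossover_rate=1.0, seed=13)
    # genetic length 100 cM: 10 cM apart = 100 kb
    pos = np.array([450_000, 550_000])
    rec = 0
    for line in pop:
        o = line.origins_at(0, 0, pos)
        rec += int(o[0] != o[1])
    expected = (1 - np.exp(-0.2)) / 2
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rec / n - expected) < 3 * se


def test_seed_color_white_frequency_near_one_quarter():
    model = GenomeModel(n_chromosomes=2, chrom_len_bp=100_000, n_subgenomes=1)
    pop = simulate_dh_population(model, 4000, crossover_rate=0.5, seed=15)
    assign_seed_color(pop, locus1=(0, 0, 50_000), locus2=(1, 0, 50_000))
    white = sum(ln.phenotype["seed_color"] == "white" for ln in pop)
    se = np.sqrt(0.25 * 0.75 / len(pop))
    assert abs(white / len(pop) - 0.25) < 3 * se


def _flat_parents(fragment_gap: int, n_sub: int = 1):
    """One forward tag locus with a secondary site ``fragment_gap`` away."""
    enz = EnzymePair()
    filler = ("ACGG" * fragment_gap)[: fragment_gap - 9]  # no AATT/CTGCAG inside
    seq = "T" * 50 + "CTGCAG" + filler + "AATT" + "T" * 60
    return make_parents({(0, s): seq for s in range(n_sub)}, enzymes=enz, seed=1)


def test_fragments_outside_size_selection_are_never_sequenced():
    """A 25 bp fragment falls below the size-selection window and emits no
    reads; a fragment within the window does."""
    short = _flat_parents(25)
    ok = _flat_parents(80)
    for parents, expect in ((short, 0), (ok, 1)):
        pop = simulate_dh_population(parents, 2, seed=2)
        lib = simulate_reads(parents, pop, mean_depth_per_tag=5.0,
                             error_rate=0.0, seed=3)
        n_tags = len(lib.truth.tags)
        assert (n_tags > 0) == bool(expect)
        assert (len(lib.records) > 0) == bool(expect)


def test_full_methylation_of_sensitive_primary_silences_library():
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=100_000, n_subgenomes=1,
                        methylation_fraction=1.0, seed=21)
    parents = simulate_parents(model)  # PstI is methylation sensitive
    pop = simulate_dh_population(parents, 4, seed=22)
    lib = simulate_reads(parents, pop, seed=23)
    assert lib.records == []


def test_identical_seeds_reproduce_reads_byte_for_byte(tiny_parents, tiny_population):
    a = simulate_reads(tiny_parents, tiny_population, seed=31)
    b = simulate_reads(tiny_parents, tiny_population, seed=31)
    c = simulate_reads(tiny_parents, tiny_population, seed=32)
    assert a.records == b.records
    assert a.records != c.records


def test_read_count_equals_poisson_draw_total(tiny_parents, tiny_population):
    lib = simulate_reads(tiny_parents, tiny_population, seed=33)
    assert len(lib.records) == int(lib.counts.to_numpy().sum())


def test_emitted_tags_come_from_source_genome_digest(tiny_parents, tiny_population):
    """Every error-free read, stripped of its barcode, is a prefix of an
    in silico digest tag of the source parental genome."""
    lib = simulate_reads(tiny_parents, tiny_population, error_rate=0.0, seed=35)
    expected = set()
    for (c, s), seqs in tiny_parents.sequences.items():
        for seq in seqs.values():
            for tag in in_silico_digest(seq, tiny_parents.enzymes, read_len=100):
                expected.add(tag.seq)
    for rid, seq, _ in lib.records[:500]:
        sample = rid.split("|")[0]
        bc = lib.barcode_of[sample]
        core = seq[len(bc):]
        assert any(t.startswith(core) for t in expected)


def test_low_divergence_warns_about_homeolog_collapse():
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=20_000,
                        homeolog_divergence=0.02, seed=41)
    with pytest.warns(UserWarning, match="co-cluster"):
        simulate_parents(model)


def test_barcode_shortage_is_an_error(tiny_parents, tiny_population):
    with pytest.raises(ValueError, match="barcodes"):
        simulate_reads(tiny_parents, tiny_population, barcodes=["ACGTAA"], seed=1)
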