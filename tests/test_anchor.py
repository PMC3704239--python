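"""In silico digestion, tag-to-contig anchoring, gene distances."""

import numpy as np
import pandas as pd
from hypothesis import given, settings
from hypothesis import strategies as st

from gbsmap.anchor import anchor_tags, gene_marker_distances, in_silico_digest
from gbsmap.enzymes import EnzymePair
from gbsmap.seqs import revcomp
from gbsmap.simdata import simulate_reads

from conftest import random_dna

ENZ = EnzymePair()


def test_contig_without_primary_sites_yields_nothing():
    assert in_silico_digest("ACGG" * 100, ENZ) == []


def test_single_primary_secondary_fragment():
    seq = "A" * 50 + "CTGCAG" + "C" * 100 + "AATT" + "G" * 50
    tags = in_silico_digest(seq, ENZ, read_len=100)
    assert len(tags) == 1
    t = tags[0]
    assert t.strand == "+" and t.cut_pos == 51
    assert t.seq.startswith("TGCAG")
    assert t.fragment_length == (156 + 3) - 51  # cut to cut, 108 bp
    assert t.seq == seq[51 : 151]


def test_fragment_below_size_selection_emits_no_tag():
    filler = ("ACGG" * 10)[:16]  # 25 bp fragment
    seq = "T" * 30 + "CTGCAG" + filler + "AATT" + "T" * 30
    assert in_silico_digest(seq, ENZ) == []
    filler = ("ACGG" * 20)[:40]
    seq = "T" * 30 + "CTGCAG" + filler + "AATT" + "T" * 30
    assert len(in_silico_digest(seq, ENZ)) == 1


def test_primary_primary_fragments_emit_no_tag():
    seq = "T" * 30 + "CTGCAG" + "C" * 100 + "CTGCAG" + "T" * 30
    assert in_silico_digest(seq, ENZ) == []


def test_reverse_strand_tag_reads_leftwards():
    seq = "G" * 50 + "AATT" + "C" * 100 + "CTGCAG" + "A" * 50
    tags = in_silico_digest(seq, ENZ, read_len=100)
    assert len(tags) == 1
    t = tags[0]
    assert t.strand == "-"
    assert t.seq.startswith("TGCAG")
    assert t.seq == revcomp(seq[t.cut_pos - 100 : t.cut_pos])


def test_n_in_recognition_site_kills_the_cut():
    seq = "A" * 50 + "CTGNAG" + "C" * 100 + "AATT" + "G" * 50
    assert in_silico_digest(seq, ENZ) == []


def test_masked_primary_site_is_skipped():
    seq = "A" * 50 + "CTGCAG" + "C" * 100 + "AATT" + "G" * 50
    assert in_silico_digest(seq, ENZ, masked_primary=[50]) == []


@settings(max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_digest_is_strand_symmetric(seed):
    """Digesting the reverse complement yields the mirror-image tag set."""
    rng = np.random.default_rng(seed)
    seq = random_dna(3000, rng)
    fwd = in_silico_digest(seq, ENZ, read_len=64)
    rev = in_silico_digest(revcomp(seq), ENZ, read_len=64)
    assert sorted(t.seq for t in fwd) == sorted(t.seq for t in rev)
    assert sorted(t.fragment_length for t in fwd) == sorted(t.fragment_length for t in rev)


def test_simulated_reads_match_their_genome_digest(tiny_parents, tiny_population):
    """Anchoring error-free simulated tags back onto the source genome
    recovers the recorded cut position for single-copy tags."""
    lib = simulate_reads(tiny_parents, tiny_population, error_rate=0.0, seed=61)
    contigs = {f"{p}_{c}_{s}": tiny_parents.sequences[(c, s)][p]
               for (c, s) in tiny_parents.sequences for p in ("Syn", "Op")}
    # pick a few single-copy SNP-free Syn tags
    picked = {}
    for t in lib.truth.tags.values():
        if t.syn_seq and t.strand == "+" and (t.homeolog_mismatches or 99) > 10:
            picked[t.tag_id] = t.syn_seq
        if len(picked) == 5:
            break
    anchors = anchor_tags(picked, contigs, max_mismatches=0)
    by_tag = {}
    for a in anchors:
        by_tag.setdefault(a.tag_id, []).append(a)
    for tag_id, seq in picked.items():
        t = lib.truth.tags[tag_id]
        hits = [a for a in by_tag[tag_id] if a.contig == f"Syn_{t.chrom}_{t.subgenome}"]
        assert any(a.position == t.cut_pos and a.strand == "+" for a in hits)


def test_spliced_tag_is_found_on_both_strands():
    rng = np.random.default_rng(63)
    tag = random_dna(60, rng)
    contig_f = random_dna(200, rng) + tag + random_dna(150, rng)
    contig_r = random_dna(100, rng) + revcomp(tag) + random_dna(80, rng)
    anchors = anchor_tags({"t": tag}, {"cf": contig_f, "cr": contig_r}, 0)
    spots = {(a.contig, a.position, a.strand) for a in anchors}
    assert ("cf", 200, "+") in spots
    assert ("cr", 100, "-") in spots
    assert all(not a.repetitive for a in anchors)


def test_tag_planted_in_many_contigs_is_flagged_repetitive():
    rng = np.random.default_rng(65)
    tag = random_dna(60, rng)
    contigs = {f"c{i}": random_dna(50, rng) + tag + random_dna(40, rng)
               for i in range(10)}
    anchors = anchor_tags({"t": tag}, contigs, 0, max_hits=5)
    assert anchors and all(a.repetitive for a in anchors)


def test_empty_tag_set_gives_empty_anchors():
    assert anchor_tags({}, {"c": "ACGT" * 100}, 0) == []


def test_gene_distances():
    rng = np.random.default_rng(67)
    tag = random_dna(60, rng)
    contig = random_dna(10_000, rng) + tag + random_dna(5_000, rng)
    anchors = anchor_tags({"t": tag}, {"c1": contig, "empty": random_dna(500, rng)}, 0)
    genes = pd.DataFrame([
        {"contig": "c1", "start": 9_990, "end": 10_100, "strand": "+", "name": "inside"},
        {"contig": "c1", "start": 7_000, "end": 7_500, "strand": "+", "name": "upstream"},
        {"contig": "empty", "start": 10, "end": 60, "strand": "+", "name": "orphan"},
    ])
    table, hist = gene_marker_distances(genes, anchors, bin_width_bp=1_000)
    d = dict(zip(table["name"], table["distance_bp"]))
    assert d["inside"] == 0
    assert d["upstream"] == 3_000  # anchor at 10,000, 5' end at 7,000
    assert np.isnan(d["orphan"])
    assert int(hist["genes"].sum()) == 2
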