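"""Genotype calling, the SNP post-filter chain and PA marker calling."""

from fractions import Fraction
from math import comb

import pytest

from gbsmap.align import AlignmentSet, ReferenceIndex, coverage_table
from gbsmap.config import PipelineConfig
from gbsmap.refbuild import ReferenceEntry
from gbsmap.seqs import seq_array
from gbsmap.varcall import (
    PaMarker,
    allele_ratio_test,
    call_pa_markers,
    call_sample_genotype,
    dedupe_pa_against_snp,
    filter_snp_sites,
    genotype_matrix,
)


@pytest.mark.parametrize(
    "syn, op, expected",
    [(0, 0, "-"), (0, 4, "A"), (4, 0, "B"), (2, 3, "H"), (1, 0, "B"), (0, 1, "A")],
)
def test_call_sample_genotype_rules(syn, op, expected):
    assert call_sample_genotype(syn, op) == expected


def test_call_sample_genotype_min_depth():
    assert call_sample_genotype(1, 1, min_depth=2) == "-"
    assert call_sample_genotype(2, 1, min_depth=2) == "B"


class TestAlleleRatio:
    def test_exact_one_third_passes(self):
        assert allele_ratio_test(10, 20)

    def test_single_copy_pattern_passes(self):
        assert allele_ratio_test(40, 0)

    def test_half_half_fails_at_depth(self):
        assert not allele_ratio_test(30, 30)

    def test_zero_depth_fails(self):
        assert not allele_ratio_test(0, 0)

    def test_binomial_decision_matches_exact_tail_oracle(self):
        """The pass/fail decision agrees with an exact binomial two-sided
        p-value computed from scratch with rational arithmetic (the
        minimum-likelihood definition of two-sidedness)."""

        def exact_two_sided(k, n, p=Fraction(1, 3)):
            probs = [comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(n + 1)]
            return float(sum(q for q in probs if q <= probs[k] * (1 + Fraction(1, 10**9))))

        for v, s in [(5, 10), (10, 20), (12, 18), (20, 20), (2, 28), (15, 15), (30, 30)]:
            n = v + s
            expected = exact_two_sided(v, n) >= 0.01
            assert allele_ratio_test(v, s) == expected, (v, s)


def test_filter_chain_matches_hand_computation(hand_built_calls):
    """On the hand-built seven-site matrix, each of the five filters drops
    exactly its intended site and the two clean sites survive with the
    expected genotype calls."""
    h = hand_built_calls
    cov = coverage_table(h.alignments)
    sites, audit = filter_snp_sites(cov, h.entries, h.SYN, h.OP, h.PROGENY,
                                    h.config, min_state_support=h.MIN_STATE_SUPPORT)
    counts = dict(zip(audit["stage"], audit["sites"]))
    for reason in set(h.expected_drop.values()):
        assert counts[reason] == 1, reason
    assert counts["retained"] == len(h.expected_retained) == len(sites)
    assert {s.ref_id for s in sites} == {f"site_{n}" for n in h.expected_retained}
    clean = next(s for s in sites if s.ref_id == "site_clean")
    assert clean.genotypes == h.expected_clean_calls
    assert clean.allele_syn == "A" and clean.allele_op == "C"
    tol = next(s for s in sites if s.ref_id == "site_tolerated")
    assert tol.genotypes["p01"] == "-"  # non-parental call recorded as missing


def test_retained_sites_satisfy_contract(hand_built_calls):
    h = hand_built_calls
    cov = coverage_table(h.alignments)
    sites, _ = filter_snp_sites(cov, h.entries, h.SYN, h.OP, h.PROGENY, h.config,
                                min_state_support=h.MIN_STATE_SUPPORT)
    for s in sites:
        assert s.allele_syn != s.allele_op
        assert s.missing_fraction < h.config.max_missing_frac


# ---------------------------------------------------------------------------
# presence/absence calling


def _pa_setup(progeny_depths, donor_depth=5, totals_scale=1.0):
    """One Syn-only entry plus a dummy shared entry carrying library depth."""
    L = 40
    seq = ("ACGT" * 10)[:L]
    other = "T" * L
    entries = [
        ReferenceEntry(ref_id="pa0", sequence=seq, source="Syn-only",
                       syn_rep=seq, syn_depth=donor_depth),
        ReferenceEntry(ref_id="shared", sequence=other, source="merged"),
    ]
    index = ReferenceIndex(entries)
    progeny = sorted(progeny_depths)
    placements = {"pa0": [], "shared": []}
    for s, d in progeny_depths.items():
        if d:
            placements["pa0"].append((s, seq_array(seq), d, 0))
        # library-size ballast so 'absent' calls are trusted
        ballast = int(20 * totals_scale) if not s.endswith("low") else 1
        placements["shared"].append((s, seq_array(other), ballast, 0))
    aln = AlignmentSet(index=index, placements=placements, n_aligned=1,
                       n_unaligned=0, n_ambiguous=0, samples=progeny)
    return coverage_table(aln), entries, progeny


def test_pa_marker_needs_min_presence_calls():
    cfg = PipelineConfig()
    depths9 = {f"p{i:02d}": (3 if i <= 9 else 0) for i in range(1, 25)}
    cov, entries, progeny = _pa_setup(depths9)
    assert call_pa_markers(cov, entries, progeny, cfg) == []
    depths10 = dict(depths9, p10=3)
    cov, entries, progeny = _pa_setup(depths10)
    markers = call_pa_markers(cov, entries, progeny, cfg)
    assert len(markers) == 1 and markers[0].n_present == 10


def test_pa_absence_requires_adequate_library():
    """Zero depth in a collapsed library is missing, not absent."""
    depths = {f"p{i:02d}": (3 if i <= 10 else 0) for i in range(1, 21)}
    depths["p21low"] = 0  # shallow library: one ballast read only
    cov, entries, progeny = _pa_setup(depths)
    markers = call_pa_markers(cov, entries, progeny, PipelineConfig())
    m = markers[0]
    assert m.states["p21low"] == "-"
    assert m.states["p11"] == "A"  # deep library, no reads: genuinely absent
    assert m.states["p03"] == "P"


def test_pa_marker_requires_parental_support():
    depths = {f"p{i:02d}": 3 for i in range(1, 15)}
    cov, entries, progeny = _pa_setup(depths, donor_depth=1)
    assert call_pa_markers(cov, entries, progeny, PipelineConfig()) == []


def test_dedupe_removes_pa_markers_restating_snp_tags():
    snp_seq = ("ACGT" * 25)[:100]

    def mut(seq, pos):
        return seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] + seq[pos + 1:]

    snp_entry = ReferenceEntry(ref_id="s0", sequence=snp_seq, source="merged",
                               syn_rep=mut(snp_seq, 10), op_rep=snp_seq,
                               variant_offsets=[10])
    site = type("S", (), {"ref_id": "s0"})()
    markers = [PaMarker("paA", "Syn", {"p1": "P"}), PaMarker("paB", "Op", {"p1": "P"})]
    pa_seqs = {"paA": mut(snp_seq, 10), "paB": "T" * 100}
    kept = dedupe_pa_against_snp(markers, pa_seqs, [site], [snp_entry])
    assert [m.ref_id for m in kept] == ["paB"]
    # with no SNP sites nothing is removed
    assert dedupe_pa_against_snp(markers, pa_seqs, [], [snp_entry]) == markers


def test_genotype_matrix_layout(hand_built_calls):
    h = hand_built_calls
    cov = coverage_table(h.alignments)
    sites, _ = filter_snp_sites(cov, h.entries, h.SYN, h.OP, h.PROGENY, h.config,
                                min_state_support=h.MIN_STATE_SUPPORT)
    pa = [PaMarker("pa0", "Syn", {p: "P" for p in h.PROGENY})]
    m = genotype_matrix(sites, pa, h.PROGENY)
    assert list(m.columns[:3]) == ["marker", "type", "alleles"]
    assert set(m["type"]) == {"SNP", "PA"}
    assert m.shape == (len(sites) + 1, 3 + len(h.PROGENY))
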