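"""Two-point statistics, bin-mapping and de novo map construction."""

import math

import numpy as np
import pandas as pd
import pytest

from gbsmap.config import PipelineConfig
from gbsmap.genmap import (
    BinAssignment,
    ReferenceMap,
    bin_map_pa,
    bin_map_snp,
    build_linkage_groups,
    denovo_input_filter,
    haldane_cM,
    haldane_r,
    order_group,
    pa_binomial_pvalue,
    pairwise_r_matrix,
    recombination_fraction,
    two_point_lod,
)
from gbsmap.simdata import GenomeModel, simulate_dh_population


def test_recombination_fraction_counts():
    a = ["A"] * 10 + ["B"] * 10
    assert recombination_fraction(a, a) == (20, 0, 0.0)
    b = list(a)
    b[0], b[19] = "B", "A"
    assert recombination_fraction(a, b) == (18, 2, 0.10)


def test_recombination_fraction_excludes_het_and_missing_pairwise():
    x = ["A", "B", "H", "A", "-"]
    y = ["A", "A", "B", "-", "B"]
    p, r, frac = recombination_fraction(x, y)
    assert (p, r) == (1, 1) and frac == 0.5


def test_disjoint_informative_sets_are_undefined():
    x = ["A", "A", "-", "-"]
    y = ["-", "-", "B", "B"]
    assert math.isnan(recombination_fraction(x, y)[2])


def test_length_mismatch_is_an_error():
    with pytest.raises(ValueError):
        recombination_fraction(["A"], ["A", "B"])


def test_two_point_lod_closed_forms():
    assert two_point_lod(20, 0) == pytest.approx(20 * math.log10(2))
    assert two_point_lod(5, 5) == pytest.approx(0.0)
    expected = 2 * math.log10(0.1) + 18 * math.log10(0.9) + 20 * math.log10(2)
    assert two_point_lod(18, 2) == pytest.approx(expected)


def test_haldane_mapping_function():
    assert haldane_cM(0.0) == 0.0
    assert haldane_cM(0.1) == pytest.approx(11.157, abs=1e-3)
    assert haldane_cM(0.2) == pytest.approx(25.541, abs=1e-3)
    assert haldane_r(haldane_cM(0.23)) == pytest.approx(0.23)
    with pytest.raises(ValueError):
        haldane_cM(0.5)


def test_pa_binomial_closed_forms():
    assert pa_binomial_pvalue(15, 15) == pytest.approx(0.5**15)
    assert pa_binomial_pvalue(10, 7) == pytest.approx(176 / 1024)
    assert pa_binomial_pvalue(12, 6) > 0.5  # at the null centre
    assert pa_binomial_pvalue(0, 0) == 1.0


# ---------------------------------------------------------------------------
# bin-mapping on a hand-built framework map


def _toy_refmap(n=40, seed=17):
    """Two chromosomes, markers every 10 cM, genotypes from simulated meiosis."""
    model = GenomeModel(n_chromosomes=2, chrom_len_bp=500_000, n_subgenomes=1)
    pop = simulate_dh_population(model, n, crossover_rate=0.5, seed=seed)
    rows = []
    ids = [ln.line_id for ln in pop]
    for c in range(2):
        for cm in range(0, 51, 10):
            pos = min(int(cm / 50 * 500_000), 499_999)
            calls = ["B" if ln.origin_at(c, 0, pos) == 0 else "A" for ln in pop]
            rows.append({"marker": f"F{c+1}A_{cm}", "chromosome": f"{c+1}A",
                         "cM": float(cm), **dict(zip(ids, calls))})
    return ReferenceMap(pd.DataFrame(rows)), pop


def test_framework_markers_bin_to_themselves():
    """Self-consistency: every framework marker mapped against its own map
    anchors at itself with zero recombination events, and the emitted
    interval contains its own position."""
    refmap, _ = _toy_refmap()
    for i, marker in enumerate(refmap.markers):
        calls = refmap.table.iloc[i][refmap.individuals].tolist()
        res = bin_map_snp(marker, calls, refmap)
        assert isinstance(res, BinAssignment)
        assert res.R == 0
        assert res.anchor_marker == marker or res.r == 0.0
        assert res.contains_cM(refmap.cM[i])
        assert res.chromosome == refmap.chromosomes[i]


def test_gbs_marker_between_framework_markers_lands_in_true_interval():
    refmap, pop = _toy_refmap()
    pos = int(26 / 50 * 500_000)  # truly at 26 cM on chromosome 1A
    calls = ["B" if ln.origin_at(0, 0, pos) == 0 else "A" for ln in pop]
    res = bin_map_snp("gbs1", calls, refmap)
    assert isinstance(res, BinAssignment)
    assert res.chromosome == "1A" and res.contains_cM(26.0)


def test_marker_linked_to_two_chromosomes_is_excluded():
    refmap, pop = _toy_refmap()
    # calls copied from chromosome 1 markers but grafted onto a vector that
    # also cosegregates with a chromosome 2 marker: build a hybrid by using
    # chromosome 1 origins for half the lines and chromosome 2 for the rest
    rows = refmap.table
    m1 = rows.iloc[0][refmap.individuals].tolist()
    m2 = rows.iloc[6][refmap.individuals].tolist()
    hybrid = list(m1)
    # a marker identical to framework markers on both chromosomes
    refmap2 = ReferenceMap(pd.concat([
        rows, pd.DataFrame([{**dict(zip(refmap.individuals, m1)),
                             "marker": "dup", "chromosome": "2A", "cM": 0.0}]),
    ], ignore_index=True).sort_values(["chromosome", "cM"]).reset_index(drop=True))
    res = bin_map_snp("gbs2", hybrid, refmap2)
    assert res == "excluded"


def test_marker_beyond_max_r_is_unmapped():
    refmap, pop = _toy_refmap()
    rng = np.random.default_rng(3)
    # independent segregation: unlinked to every framework marker
    calls = ["B" if rng.random() < 0.5 else "A" for _ in refmap.individuals]
    res = bin_map_snp("gbs3", calls, refmap)
    assert res == "unmapped"


def test_pa_marker_maps_through_presence_calls():
    refmap, pop = _toy_refmap()
    pos = int(23 / 50 * 500_000)
    donors = ["P" if ln.origin_at(0, 0, pos) == 0 else "A" for ln in pop]
    res = bin_map_pa("pa1", donors, "Syn", refmap)
    assert isinstance(res, BinAssignment)
    assert res.chromosome == "1A" and res.contains_cM(23.0)
    assert res.p_value is not None and res.p_value < PipelineConfig().pa_pvalue


def test_pa_p_value_threshold_is_strict():
    """n=20, k=17 gives p ~ 0.0013 >= 0.001: not significant, unmapped."""
    rows = []
    ids = [f"i{k}" for k in range(20)]
    calls = ["B"] * 17 + ["A"] * 3
    rows.append({"marker": "F1", "chromosome": "1A", "cM": 0.0,
                 **dict(zip(ids, calls))})
    rows.append({"marker": "F2", "chromosome": "1A", "cM": 10.0,
                 **dict(zip(ids, calls))})
    refmap = ReferenceMap(pd.DataFrame(rows))
    states = ["P"] * 20
    assert pa_binomial_pvalue(20, 17) >= 0.001
    assert bin_map_pa("pa2", states, "Syn", refmap) == "unmapped"
    # all 20 presence calls on the donor allele: p = 0.5^20, mapped
    rows2 = [dict(r, **dict(zip(ids, ["B"] * 20))) for r in rows]
    refmap2 = ReferenceMap(pd.DataFrame(rows2))
    res = bin_map_pa("pa3", states, "Syn", refmap2)
    assert isinstance(res, BinAssignment)
    assert res.p_value == pytest.approx(0.5**20)
    assert res.R == 0


# ---------------------------------------------------------------------------
# linkage grouping and ordering


def _matrix_from_vectors(vectors: dict[str, list[str]]) -> pd.DataFrame:
    return pd.DataFrame(vectors).T


def test_identical_markers_group_together():
    v = ["A"] * 20 + ["B"] * 20
    groups, singles = build_linkage_groups(_matrix_from_vectors({"a": v, "b": v}),
                                           lod_min=8, max_dist_cM=20)
    assert groups == [["a", "b"]] and singles == []


def test_independent_chromosomes_never_group():
    model = GenomeModel(n_chromosomes=2, chrom_len_bp=100_000, n_subgenomes=1)
    pop = simulate_dh_population(model, 100, crossover_rate=0.5, seed=19)
    va = ["B" if ln.origin_at(0, 0, 50_000) == 0 else "A" for ln in pop]
    vb = ["B" if ln.origin_at(1, 0, 50_000) == 0 else "A" for ln in pop]
    groups, singles = build_linkage_groups(_matrix_from_vectors({"a": va, "b": vb}),
                                           lod_min=8, max_dist_cM=20)
    assert groups == [] and set(singles) == {"a", "b"}


def test_transitive_chaining_links_unlinked_extremes():
    """a-b and b-c are linked but a-c is beyond the distance threshold;
    single linkage still puts all three in one group."""
    n = 100
    b = ["A"] * 50 + ["B"] * 50
    a = list(b)
    c = list(b)
    for i in range(10):
        a[i] = "B" if a[i] == "A" else "A"
    for i in range(50, 60):
        c[i] = "B" if c[i] == "A" else "A"
    # a-b and b-c: r=0.10 (11.2 cM); a-c: r=0.20 (25.5 cM > 20)
    assert haldane_cM(0.2) > 20
    groups, _ = build_linkage_groups(_matrix_from_vectors({"a": a, "b": b, "c": c}),
                                     lod_min=8, max_dist_cM=20)
    assert groups == [["a", "b", "c"]]


def test_order_group_of_three_recovers_the_middle_marker():
    n = 200
    b = ["A"] * 100 + ["B"] * 100
    a, c = list(b), list(b)
    for i in range(10):
        a[i] = "B" if a[i] == "A" else "A"
    for i in range(100, 110):
        c[i] = "B" if c[i] == "A" else "A"
    mat = _matrix_from_vectors({"a": a, "b": b, "c": c})
    r = pairwise_r_matrix(mat)
    dm = order_group(["a", "b", "c"], r)
    assert dm.markers[1] == "b"  # b between a and c, either orientation
    assert dm.length_cM == pytest.approx(haldane_cM(0.05) * 2, rel=1e-6)


def test_order_group_recovers_simulated_marker_order():
    """Ten markers on one simulated chromosome, 200 DH lines: the greedy +
    2-opt order equals the true physical order or its reversal."""
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=1_000_000, n_subgenomes=1)
    pop = simulate_dh_population(model, 200, crossover_rate=1.0, seed=23)
    positions = np.linspace(50_000, 950_000, 10).astype(int)
    vectors = {}
    for k, pos in enumerate(positions):
        vectors[f"m{k}"] = ["B" if ln.origin_at(0, 0, int(pos)) == 0 else "A"
                            for ln in pop]
    mat = _matrix_from_vectors(vectors)
    r = pairwise_r_matrix(mat)
    dm = order_group(list(mat.index), r)
    want = [f"m{k}" for k in range(10)]
    assert dm.markers in (want, want[::-1])


def test_denovo_filter_thresholds():
    rows = {
        "ok": ["A"] * 16 + ["-"] * 3 + ["H"],          # 15% missing, 5% het
        "toomissing": ["A"] * 15 + ["-"] * 5,           # 25% missing
        "toohet": ["A"] * 18 + ["H"] * 2,               # 10% het
    }
    kept = denovo_input_filter(_matrix_from_vectors(rows))
    assert list(kept.index) == ["ok"]


def test_map_length_grows_with_genotyping_error():
    """Injected call errors inflate apparent recombination, so the total
    de novo map length increases monotonically with the error rate."""
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=1_000_000, n_subgenomes=1)
    pop = simulate_dh_population(model, 150, crossover_rate=0.5, seed=29)
    positions = np.linspace(20_000, 980_000, 12).astype(int)
    clean = {f"m{k}": ["B" if ln.origin_at(0, 0, int(p)) == 0 else "A" for ln in pop]
             for k, p in enumerate(positions)}

    def with_error(rate, seed):
        rng = np.random.default_rng(seed)
        out = {}
        for m, calls in clean.items():
            out[m] = [("B" if c == "A" else "A") if rng.random() < rate else c
                      for c in calls]
        return out

    lengths = []
    for rate in (0.0, 0.02, 0.05):
        mat = _matrix_from_vectors(with_error(rate, 31))
        r = pairwise_r_matrix(mat)
        dm = order_group(list(mat.index), r)
        lengths.append(dm.length_cM)
    assert lengths[0] < lengths[1] < lengths[2]
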