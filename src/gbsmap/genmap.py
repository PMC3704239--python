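"""Genetic mapping: bin-mapping onto a reference map and de novo maps.

Bin-mapping places each GBS marker into a recombination interval of a
framework map instead of re-estimating the whole map: recombination
fractions to every framework marker are computed from parental and
recombinant gamete counts, markers within ``max_r`` of at least one
framework marker are kept, markers linked to framework markers on more
than one chromosome are excluded, and the anchor is the framework marker
sharing the fewest recombination events.  De novo maps are built directly
from high-quality SNP markers by single-linkage grouping on a two-point
LOD / distance rule and ordered with a travelling-salesman-style
heuristic (greedy nearest neighbour + 2-opt) rather than a clone of any
particular mapping program.

All call vectors are parent-coded: 'A' (Op allele), 'B' (Syn allele), 'H',
'-'.  In a DH population heterozygous calls are errors and are excluded
pairwise, like missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

_CODE = {"A": 0, "B": 1, "H": 2, "-": 3}


def _encode(calls) -> np.ndarray:
    return np.array([_CODE.get(c, 3) for c in calls], dtype=np.int8)


# ---------------------------------------------------------------------------
# reference map container


class ReferenceMap:
    """An ordered framework map with genotypes over the population.

    Built from a table with columns ``marker``, ``chromosome``, ``cM`` and
    one parent-coded genotype column per individual; positions must be
    non-decreasing within each chromosome.
    """

    def __init__(self, table: pd.DataFrame):
        meta_cols = ["marker", "chromosome", "cM"]
        missing = [c for c in meta_cols if c not in table.columns]
        if missing:
            raise ValueError(f"reference map lacks columns: {missing}")
        table = table.reset_index(drop=True)
        for _, grp in table.groupby("chromosome", sort=False):
            if not grp["cM"].is_monotonic_increasing:
                raise ValueError("cM positions must be non-decreasing within a chromosome")
        self.table = table
        self.individuals = [c for c in table.columns if c not in meta_cols]
        self.markers = table["marker"].tolist()
        self.chromosomes = table["chromosome"].to_numpy()
        self.cM = table["cM"].to_numpy(dtype=float)
        self.calls = np.stack([_encode(table[c]) for c in self.individuals], axis=1)
        self._pos = {m: i for i, m in enumerate(self.markers)}

    def __len__(self):
        return len(self.markers)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# two-point statistics


def recombination_fraction(calls_x, calls_y) -> tuple[int, int, float]:
    """Parental/recombinant gamete counts and recombination fraction.

    ``P`` counts AA and BB pairs, ``R`` counts AB and BA; heterozygous and
    missing calls are excluded pairwise.  ``r`` is ``R/(P+R)``, or NaN when
    no informative pair exists (the marker pair is then uninformative and
    skipped by callers).
    """
    x, y = _encode(calls_x), _encode(calls_y)
    if x.size != y.size:
        raise ValueError("call vectors must cover the same individuals")
    inf = (x < 2) & (y < 2)
    n = int(inf.sum())
    if n == 0:
        return 0, 0, float("nan")
    r_count = int((x[inf] != y[inf]).sum())
    return n - r_count, r_count, r_count / n


def two_point_lod(P: int, R: int) -> float:
    """Two-point LOD for DH data at the MLE recombination fraction.

    ``LOD = R log10 r + P log10(1-r) + (P+R) log10 2`` with ``r = R/(P+R)``;
    at R = 0 the limit is ``N log10 2``.
    """
    n = P + R
    if n < 1:
        raise ValueError("need at least one informative gamete")
    if R == 0:
        return n * math.log10(2.0)
    if P == 0:
        return 0.0 if R == n else n * math.log10(2.0)
    r = R / n
    return R * math.log10(r) + P * math.log10(1 - r) + n * math.log10(2.0)


def haldane_cM(r: float) -> float:
    """Haldane map distance in cM; defined for 0 <= r < 0.5."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return -50.0 * math.log(1.0 - 2.0 * r)

def haldane_r(d_cM: float) -> float:
    """Inverse of :func:`haldane_cM`."""
    return 0.5 * (1.0 - math.exp(-d_cM / 50.0))


def kosambi_cM(r: float) -> float:
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def map_distance(r: float, config: PipelineConfig | None = None) -> float:
    cfg = config or PipelineConfig()
    fn = haldane_cM if cfg.mapping_function == "haldane" else kosambi_cM
    return fn(min(r, 0.4999999))


def pa_binomial_pvalue(n: int, k: int) -> float:
    """One-sided exact binomial tail for presence/framework association.

    ``p = P(X >= k | X ~ Bin(n, 1/2))``: of ``n`` informative presence
    calls, ``k`` carry the donor-parent allele at the framework marker.
    The direction is fixed because the donor parent of a PA tag is known
    from the parental libraries.  ``n = 0`` gives ``p = 1``.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, 0.5))


# ---------------------------------------------------------------------------
# bin-mapping


@dataclass
class BinAssignment:
    """Placement of a GBS marker into a framework recombination interval."""

    marker_id: str
    chromosome: str
    anchor_marker: str
    left_marker: str
    left_cM: float
    right_marker: str
    right_cM: float
    R: int  # recombination events shared with the anchor
    N: int  # informative gametes against the anchor
    p_value: float | None = None  # PA markers only

    @property
    def r(self) -> float:
        return self.R / self.N if self.N else float("nan")

    def contains_cM(self, cm: float, tol: float = 1e-9) -> bool:
        return self.left_cM - tol <= cm <= self.right_cM + tol


def _interval_for_anchor(
    refmap: ReferenceMap,
    chrom_rows: np.ndarray,
    tied_rows: np.ndarray,
    events: np.ndarray,
) -> tuple[int, int, int]:
    """Resolve the emitted interval; returns (anchor_row, left_row, right_row).

    With several framework markers tied at the minimal recombination-event
    count, the marker is placed at the top (smallest cM) tied marker, which
    becomes the anchor.  The emitted recombination interval is delimited by
    the framework markers immediately flanking the tied set: two-point
    counts against a single anchor carry no information about which side of
    it the marker lies on (that would need recombination events between the
    marker and the anchor to be observed, and an anchor is precisely the
    marker sharing fewest such events), so the honest interval runs from
    the anchor's lower neighbour to the upper neighbour of the last tied
    marker.  At a chromosome end the boundary stops at the terminal marker.
    """
    lo, hi = int(tied_rows[0]), int(tied_rows[-1])
    a = lo
    i_lo = int(np.flatnonzero(chrom_rows == lo)[0])
    i_hi = int(np.flatnonzero(chrom_rows == hi)[0])
    left = int(chrom_rows[i_lo - 1]) if i_lo > 0 else lo
    right = int(chrom_rows[i_hi + 1]) if i_hi + 1 < chrom_rows.size else hi
    return a, left, right


def _bin_from_candidates(
    marker_id: str,
    refmap: ReferenceMap,
    cand_rows: np.ndarray,
    events: np.ndarray,
    informative: np.ndarray,
    p_values: np.ndarray | None = None,
) -> BinAssignment | str:
    chroms = set(refmap.chromosomes[cand_rows])
    if len(chroms) > 1:
        return "excluded"
    chrom = chroms.pop()
    chrom_rows = np.flatnonzero(refmap.chromosomes == chrom)
    best = events[cand_rows].min()
    tied = cand_rows[events[cand_rows] == best]
    tied = tied[np.argsort(refmap.cM[tied], kind="stable")]
    anchor, left, right = _interval_for_anchor(refmap, chrom_rows, tied, events)
    return BinAssignment(
        marker_id=marker_id,
        chromosome=str(chrom),
        anchor_marker=refmap.markers[anchor],
        left_marker=refmap.markers[left],
        left_cM=float(refmap.cM[left]),
        right_marker=refmap.markers[right],
        right_cM=float(refmap.cM[right]),
        R=int(events[anchor]),
        N=int(informative[anchor]),
        p_value=None if p_values is None else float(p_values[anchor]),
    )


def bin_map_snp(
    marker_id: str,
    calls,
    refmap: ReferenceMap,
    config: PipelineConfig | None = None,
) -> BinAssignment | str:
    """Bin-map one codominant GBS marker; 'unmapped' or 'excluded' on failure.

    Candidates are framework markers within ``max_r`` recombination
    fraction; candidates on more than one chromosome exclude the marker;
    the anchor minimises shared recombination events.
    """
    cfg = config or PipelineConfig()
    x = _encode(calls)
    if x.size != len(refmap.individuals):
        raise ValueError("marker calls and reference map cover different individuals")
    inf = (refmap.calls < 2) & (x[None, :] < 2)
    n = inf.sum(axis=1)
    mism = ((refmap.calls != x[None, :]) & inf).sum(axis=1)
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, mism / np.maximum(n, 1), np.nan)
    cand = np.flatnonzero((n > 0) & (r <= cfg.max_r))
    if cand.size == 0:
        return "unmapped"
    return _bin_from_candidates(marker_id, refmap, cand, mism, n)


def bin_map_pa(
    marker_id: str,
    states,
    donor: str,
    refmap: ReferenceMap,
    config: PipelineConfig | None = None,
) -> BinAssignment | str:
    """Bin-map one dominant PA marker; 'removed' or 'unmapped' on failure.

    Only presence calls are informative (absence is unreliable at low
    coverage): against each framework marker, ``n`` presence calls overlap
    an A/B framework call and ``k`` of them carry the donor-parent allele.
    Candidates need binomial ``p < pa_pvalue`` and dominant recombination
    fraction ``(n-k)/n <= max_r``; significant association with more than
    one chromosome removes the marker as repetitive.
    """
    cfg = config or PipelineConfig()
    donor_code = 1 if donor == "Syn" else 0
    s = np.array([1 if v == "P" else 0 for v in states], dtype=np.int8)
    if s.size != len(refmap.individuals):
        raise ValueError("marker states and reference map cover different individuals")
    inf = (refmap.calls < 2) & (s[None, :] == 1)
    n = inf.sum(axis=1)
    k = ((refmap.calls == donor_code) & inf).sum(axis=1)
    pvals = np.array([pa_binomial_pvalue(int(nn), int(kk)) for nn, kk in zip(n, k)])
    events = n - k  # presence calls recombinant with the framework marker
    with np.errstate(invalid="ignore"):
        r_d = np.where(n > 0, events / np.maximum(n, 1), np.nan)
    cand = np.flatnonzero((n > 0) & (pvals < cfg.pa_pvalue) & (r_d <= cfg.max_r))
    if cand.size == 0:
        return "unmapped"
    chroms = set(refmap.chromosomes[cand])
    if len(chroms) > 1:
        return "removed"
    return _bin_from_candidates(marker_id, refmap, cand, events, n, pvals)


def bin_assignments_frame(assignments: list[BinAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append({
            "marker": a.marker_id, "chromosome": a.chromosome,
            "anchor": a.anchor_marker,
            "left_marker": a.left_marker, "left_cM": a.left_cM,
            "right_marker": a.right_marker, "right_cM": a.right_cM,
            "R": a.R, "N": a.N,
            "p_value": "" if a.p_value is None else a.p_value,
        })
    cols = ["marker", "chromosome", "anchor", "left_marker", "left_cM",
            "right_marker", "right_cM", "R", "N", "p_value"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# de novo mapping


def denovo_input_filter(
    matrix: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Select high-quality markers for de novo mapping.

    Keeps markers with at most ``denovo_max_missing`` missing and
    ``denovo_max_het`` heterozygous calls (markers x individuals frame of
    parent-coded calls).
    """
    cfg = config or PipelineConfig()
    vals = matrix.to_numpy()
    n = vals.shape[1]
    miss = (vals == "-").sum(axis=1) / n
    het = (vals == "H").sum(axis=1) / n
    keep = (miss <= cfg.denovo_max_missing) & (het <= cfg.denovo_max_het)
    return matrix.loc[keep]


def _pairwise_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Informative-pair and recombinant counts for all marker pairs."""
    informative = codes < 2
    m = codes.shape[0]
    N = np.zeros((m, m), dtype=np.int64)
    R = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        inf = informative[i] & informative
        N[i] = inf.sum(axis=1)
        R[i] = ((codes[i] != codes) & inf).sum(axis=1)
    return N, R


def pairwise_r_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise recombination fractions (NaN where uninformative)."""
    if matrix.empty:
        return pd.DataFrame(index=matrix.index, columns=matrix.index, dtype=float)
    codes = np.stack([_encode(row) for _, row in matrix.iterrows()])
    N, R = _pairwise_counts(codes)
    with np.errstate(invalid="ignore"):
        r = np.where(N > 0, R / np.maximum(N, 1), np.nan)
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


def build_linkage_groups(
    matrix: pd.DataFrame,
    lod_min: float = 8.0,
    max_dist_cM: float = 20.0,
    config: PipelineConfig | None = None,
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage grouping of markers by two-point LOD and distance.

    Two markers are linked when their LOD reaches ``lod_min`` and their map
    distance is at most ``max_dist_cM``; groups are the transitive closure
    of that relation.  Returns (groups of two or more markers, singletons),
    groups ordered by size then name.
    """
    cfg = config or PipelineConfig()
    ids = list(matrix.index)
    if not ids:
        return [], []
    codes = np.stack([_encode(row) for _, row in matrix.iterrows()])
    m = len(ids)
    N, R = _pairwise_counts(codes)
    linked = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            if N[i, j] == 0:
                continue
            r = R[i, j] / N[i, j]
            if r >= 0.5:
                continue
            lod = two_point_lod(int(N[i, j] - R[i, j]), int(R[i, j]))
            if lod >= lod_min and map_distance(r, cfg) <= max_dist_cM:
                linked[i, j] = linked[j, i] = True

    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(linked, directed=False)
    groups: list[list[str]] = []
    singles: list[str] = []
    for comp in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(labels == comp)]
        if len(members) > 1:
            groups.append(sorted(members))
        else:
            singles.extend(members)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, sorted(singles)


@dataclass
class DeNovoMap:
    """An ordered linkage group with cumulative Haldane distances."""

    markers: list[str]
    distances_cM: list[float]  # adjacent distances, len(markers) - 1

    @property
    def length_cM(self) -> float:
        return float(sum(self.distances_cM))

    @property
    def positions_cM(self) -> list[float]:
        return np.concatenate([[0.0], np.cumsum(self.distances_cM)]).tolist()


def order_group(
    group: list[str],
    r_matrix: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> DeNovoMap:
    """Order one linkage group by greedy nearest neighbour plus 2-opt.

    The objective is the total adjacent map distance.  Construction starts
    from the marker whose summed distance to all others is largest (an end
    of the group, heuristically) and repeatedly appends the nearest
    unplaced marker; 2-opt segment reversals then run to convergence.
    Deterministic given the input order; orientation is normalised so the
    lexicographically smaller endpoint comes first.
    """
    cfg = config or PipelineConfig()
    if len(group) < 2:
        raise ValueError("ordering needs at least two markers")
    ids = list(group)
    r = r_matrix.loc[ids, ids].to_numpy(dtype=float)
    d = np.where(np.isnan(r), np.inf, r)
    d = np.vectorize(lambda x: map_distance(x, cfg) if np.isfinite(x) else 1e6)(d)
    np.fill_diagonal(d, 0.0)

    start = int(np.argmax(np.where(np.isfinite(d), d, 0).sum(axis=1)))
    order = [start]
    left = set(range(len(ids))) - {start}
    while left:
        last = order[-1]
        nxt = min(sorted(left), key=lambda j: (d[last, j], j))
        order.append(nxt)
        left.remove(nxt)

    def total(o):
        return sum(d[o[i], o[i + 1]] for i in range(len(o) - 1))

    improved = True
    while improved:
        improved = False
        for i in range(len(order) - 1):
            for j in range(i + 2, len(order) + (0 if i > 0 else -1)):
                cand = order[:i + 1] + order[i + 1 : j + 1][::-1] + order[j + 1 :]
                if total(cand) < total(order) - 1e-12:
                    order = cand
                    improved = True

    if ids[order[-1]] < ids[order[0]]:
        order = order[::-1]
    markers = [ids[i] for i in order]
    dists = [float(d[order[i], order[i + 1]]) for i in range(len(order) - 1)]
    return DeNovoMap(markers=markers, distances_cM=dists)


def denovo_map_frame(maps: list[DeNovoMap]) -> pd.DataFrame:
    rows = []
    for g, m in enumerate(maps, start=1):
        pos = m.positions_cM
        for i, marker in enumerate(m.markers):
            rows.append({"group": g, "order": i, "marker": marker,
                         "cM": round(pos[i], 4)})
    return pd.DataFrame(rows, columns=["group", "order", "marker", "cM"])
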