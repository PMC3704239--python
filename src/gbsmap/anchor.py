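"""Anchoring genetically mapped tags onto sequence contigs.

The same in silico digestion used by the simulator predicts which tags a
contig should produce; mapped tag sequences are then located on contigs by
exhaustive scanning of both strands at 0 or up to 3 mismatches (matching
the two alignment stringencies used for tag discovery).  Tags hitting many
distinct contigs are flagged repetitive — in a large repeat-rich genome a
sizeable fraction of tags originates from dispersed repeats and such hits
carry no positional information.  Finally, per-gene distances from the
5' end of each CDS to the nearest anchored mapped tag summarise how close
the map gets to genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest import ExpectedTag, in_silico_digest  # noqa: F401  (re-exported)
from .seqs import revcomp, seq_array


@dataclass
class ContigAnchor:
    """One placement of a mapped tag on a contig."""

    tag_id: str
    contig: str
    position: int  # 0-based start of the match on the forward strand
    strand: str
    mismatches: int
    repetitive: bool = False
    chromosome: str | None = None  # carried over from the tag's bin assignment
    bin_interval: tuple[float, float] | None = None


def _scan(contig_arr: np.ndarray, tag: np.ndarray, max_mm: int) -> np.ndarray:
    """Start positions where ``tag`` matches within ``max_mm`` mismatches."""
    n = contig_arr.size - tag.size + 1
    if n <= 0:
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(contig_arr, tag.size)
    mm = (windows != tag).sum(axis=1)
    return np.flatnonzero(mm <= max_mm)


def anchor_tags(
    tags: dict[str, str],
    contigs: dict[str, str],
    max_mismatches: int = 0,
    max_hits: int = 5,
    bins: dict[str, tuple[str, float, float]] | None = None,
) -> list[ContigAnchor]:
    """Locate each mapped tag on every contig, both strands.

    All matches within ``max_mismatches`` are reported; a tag matching more
    than ``max_hits`` distinct contigs has all its anchors flagged
    repetitive.  ``bins`` optionally maps tag id to its genetic placement
    ``(chromosome, left_cM, right_cM)``, copied onto the anchors.
    """
    encoded = {cid: (seq_array(seq), seq_array(revcomp(seq))) for cid, seq in contigs.items()}
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    anchors: list[ContigAnchor] = []
    for tag_id in sorted(tags):
        tag_arr = seq_array(tags[tag_id])
        found: list[ContigAnchor] = []
        for cid in sorted(contigs):
            fwd, rev = encoded[cid]
            for pos in _scan(fwd, tag_arr, max_mismatches):
                mm = int((fwd[pos : pos + tag_arr.size] != tag_arr).sum())
                found.append(ContigAnchor(tag_id, cid, int(pos), "+", mm))
            for pos in _scan(rev, tag_arr, max_mismatches):
                mm = int((rev[pos : pos + tag_arr.size] != tag_arr).sum())
                fwd_pos = lengths[cid] - int(pos) - tag_arr.size
                found.append(ContigAnchor(tag_id, cid, fwd_pos, "-", mm))
        repetitive = len({a.contig for a in found}) > max_hits
        for a in found:
            a.repetitive = repetitive
            if bins and tag_id in bins:
                chrom, lo, hi = bins[tag_id]
                a.chromosome = chrom
                a.bin_interval = (lo, hi)
        anchors.extend(found)
    return anchors


def gene_marker_distances(
    genes: pd.DataFrame,
    anchors: list[ContigAnchor],
    bin_width_bp: int = 10_000,
    include_repetitive: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance from each gene's CDS 5' end to the nearest anchored tag.

    ``genes`` needs columns ``contig``, ``start``, ``end`` (0-based,
    half-open) and ``strand``; an optional ``name`` column labels the
    output.  An anchor inside the gene interval gives distance 0; genes on
    contigs without anchors get NaN.  Returns (per-gene table, histogram
    of finite distances with ``bin_width_bp`` bins).
    """
    by_contig: dict[str, list[int]] = {}
    for a in anchors:
        if a.repetitive and not include_repetitive:
            continue
        by_contig.setdefault(a.contig, []).append(a.position)

    rows = []
    for i, g in genes.iterrows():
        name = g.get("name", f"gene{i}")
        five_prime = int(g["start"]) if g.get("strand", "+") != "-" else int(g["end"]) - 1
        positions = by_contig.get(g["contig"])
        if not positions:
            rows.append({"name": name, "contig": g["contig"], "distance_bp": np.nan})
            continue
        pos = np.array(sorted(positions))
        inside = (pos >= int(g["start"])) & (pos < int(g["end"]))
        dist = 0 if inside.any() else int(np.abs(pos - five_prime).min())
        rows.append({"name": name, "contig": g["contig"], "distance_bp": dist})
    table = pd.DataFrame(rows)

    finite = table["distance_bp"].dropna().to_numpy(dtype=float)
    if finite.size:
        top = (int(finite.max() // bin_width_bp) + 1) * bin_width_bp
        counts, edges = np.histogram(finite, bins=np.arange(0, top + bin_width_bp, bin_width_bp))
        hist = pd.DataFrame({"bin_start_bp": edges[:-1].astype(int),
                             "bin_end_bp": edges[1:].astype(int), "genes": counts})
    else:
        hist = pd.DataFrame(columns=["bin_start_bp", "bin_end_bp", "genes"])
    return table, hist


def read_genes_bed(path) -> pd.DataFrame:
    """Genes from BED (0-based half-open): contig, start, end[, name, score, strand]."""
    cols = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    if "strand" not in df:
        df["strand"] = "+"
    if "name" not in df:
        df["name"] = [f"gene{i}" for i in range(len(df))]
    return df[["contig", "start", "end", "name", "strand"]]


def read_genes_gff3(path, feature: str = "CDS") -> pd.DataFrame:
    """Genes from GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != feature:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv) if len(f) > 8 else {}
            rows.append({"contig": f[0], "start": int(f[3]) - 1, "end": int(f[4]),
                         "name": attrs.get("ID", f"{f[0]}:{f[3]}"), "strand": f[6]})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "strand"])


def anchors_frame(anchors: list[ContigAnchor]) -> pd.DataFrame:
    rows = []
    for a in anchors:
        rows.append({
            "tag": a.tag_id, "contig": a.contig, "position": a.position,
            "strand": a.strand, "mismatches": a.mismatches,
            "repetitive": a.repetitive,
            "chromosome": a.chromosome or "",
            "bin_left_cM": "" if a.bin_interval is None else a.bin_interval[0],
            "bin_right_cM": "" if a.bin_interval is None else a.bin_interval[1],
        })
    return pd.DataFrame(rows, columns=["tag", "contig", "position", "strand",
                                       "mismatches", "repetitive", "chromosome",
                                       "bin_left_cM", "bin_right_cM"])
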