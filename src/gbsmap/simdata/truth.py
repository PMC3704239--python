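"""Ground truth for simulated libraries: the test oracle.

Every sequenceable tag locus of the simulated parents is catalogued with
its true genomic and genetic position, its parental sequences, the SNPs it
carries, whether it is a presence/absence locus and which parent donated
it, and how far its nearest homeologous counterpart is — everything a test
needs to score the pipeline's output without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..digest import in_silico_digest
from ..seqs import seq_array
from .genome import ParentGenomes, chromosome_name
from .population import DHLine


@dataclass
class TagTruth:
    """Ground truth for one tag locus (one primary cut-site direction)."""

    tag_id: str
    chrom: int
    subgenome: int
    chrom_name: str
    strand: str
    cut_pos: int
    cM: float
    syn_seq: str | None
    op_seq: str | None
    snps: list[tuple[int, str, str]]  # (offset in tag, Syn base, Op base)
    kind: str  # 'snp' | 'pav' | 'mono'
    donor: str | None = None  # for PAV loci: the parent carrying the tag
    homeolog_mismatches: int | None = None  # None when no homeologous tag exists

    @property
    def collapsible(self) -> bool:
        """Would this tag co-cluster with its homeolog at 96% identity?"""
        if self.homeolog_mismatches is None:
            return False
        n = len(self.syn_seq or self.op_seq)
        return self.homeolog_mismatches <= (1 - 0.96) * n


@dataclass
class SimTruth:
    """Complete ground truth of a simulated library."""

    tags: dict[str, TagTruth]
    genetic_length_cM: float
    chrom_len_bp: int

    def match_sequence(self, seq: str, max_mismatches: int = 3) -> TagTruth | None:
        """Find the truth tag whose parental sequence best matches ``seq``.

        End-anchored comparison over the shorter length, like the pipeline
        itself; returns None when nothing matches within the bound or the
        best match is ambiguous between distinct loci.  Used to score
        pipeline output (reference entries, markers) against the truth.
        """
        from ..seqs import PaddedSeqMatrix, seq_array

        if not hasattr(self, "_seq_index"):
            owners: list[str] = []
            seqs: list[str] = []
            for tid in sorted(self.tags):
                t = self.tags[tid]
                for s in (t.syn_seq, t.op_seq):
                    if s is not None:
                        owners.append(tid)
                        seqs.append(s)
            self._seq_index = (PaddedSeqMatrix.from_sequences(seqs), owners)
        mat, owners = self._seq_index
        mm, _ = mat.prefix_mismatches(seq_array(seq))
        if mm.size == 0 or mm.min() > max_mismatches:
            return None
        import numpy as _np

        hits = {owners[i] for i in _np.flatnonzero(mm == mm.min())}
        if len(hits) > 1:
            return None
        return self.tags[hits.pop()]

    def match_snp_marker(
        self,
        syn_rep: str | None,
        op_rep: str | None,
        offset: int,
        allele_syn: str,
        allele_op: str,
        max_mismatches: int = 3,
    ) -> TagTruth | None:
        """Attribute a called SNP marker to the truth locus carrying it.

        When homeologous tags are nearly identical they collapse onto one
        reference entry and the called variant may belong to either copy;
        the marker then segregates with the subgenome that actually carries
        the polymorphism, regardless of which copy supplied the cluster
        representative.  Attribution therefore prefers, among truth tags
        close to either parental representative, one with a true SNP at the
        called offset and alleles; it falls back to the best sequence match.
        """
        from ..seqs import PaddedSeqMatrix, seq_array

        candidates: dict[str, TagTruth] = {}
        for rep in (syn_rep, op_rep):
            if rep is None:
                continue
            if not hasattr(self, "_seq_index"):
                self.match_sequence(rep)  # builds the index
            mat, owners = self._seq_index
            mm, _ = mat.prefix_mismatches(seq_array(rep))
            import numpy as _np

            for i in _np.flatnonzero(mm <= max_mismatches):
                candidates[owners[i]] = self.tags[owners[i]]
        exact = [
            t for t in candidates.values()
            if any(o == offset and a == allele_syn and b == allele_op for o, a, b in t.snps)
        ]
        if len(exact) == 1:
            return exact[0]
        if exact:
            return None  # genuinely ambiguous between loci
        return self.match_sequence(syn_rep or op_rep, max_mismatches)

    def snp_tags(self) -> list[TagTruth]:
        return [t for t in self.tags.values() if t.kind == "snp"]

    def pav_tags(self) -> list[TagTruth]:
        return [t for t in self.tags.values() if t.kind == "pav"]

    def true_call(self, line: DHLine, tag_id: str) -> str:
        """True codominant call of a line at a SNP tag: 'B' (Syn) or 'A' (Op)."""
        t = self.tags[tag_id]
        return "B" if line.origin_at(t.chrom, t.subgenome, min(t.cut_pos, self.chrom_len_bp - 1)) == 0 else "A"

    def true_presence(self, line: DHLine, tag_id: str) -> bool:
        """Whether a line truly carries a PAV tag (inherited the donor allele)."""
        t = self.tags[tag_id]
        donor_idx = 0 if t.donor == "Syn" else 1
        return line.origin_at(t.chrom, t.subgenome, min(t.cut_pos, self.chrom_len_bp - 1)) == donor_idx

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tags.values():
            rows.append(
                {
                    "tag_id": t.tag_id,
                    "chromosome": t.chrom_name,
                    "strand": t.strand,
                    "cut_pos": t.cut_pos,
                    "cM": round(t.cM, 4),
                    "kind": t.kind,
                    "donor": t.donor or "",
                    "n_snps": len(t.snps),
                    "snp_offsets": ",".join(str(o) for o, _, _ in t.snps),
                    "homeolog_mismatches": "" if t.homeolog_mismatches is None else t.homeolog_mismatches,
                }
            )
        return pd.DataFrame(rows).sort_values("tag_id").reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_truth(
    parents: ParentGenomes,
    read_len: int = 100,
    genetic_length_cM: float = 50.0,
) -> SimTruth:
    """Digest both parental genomes and assemble the truth catalogue.

    A locus is identified by ``(chromosome, subgenome, strand, cut
    position)``; because the simulator introduces substitutions only,
    coordinates are directly comparable between parents.  True genetic
    positions assume a uniform recombination landscape: ``cM =
    genetic_length_cM * pos / chrom_len``.
    """
    model, enz = parents.model, parents.enzymes
    per_parent: dict[str, dict[tuple[int, int, str, int], str]] = {"Syn": {}, "Op": {}}
    for (c, s), seqs in sorted(parents.sequences.items()):
        for parent, seq in seqs.items():
            for tag in in_silico_digest(
                seq,
                enz,
                read_len=read_len,
                contig_id=chromosome_name(c, s),
                masked_primary=parents.masked_primary.get((c, s), ()),
                masked_secondary=parents.masked_secondary.get((c, s), ()),
            ):
                per_parent[parent][(c, s, tag.strand, tag.cut_pos)] = tag.seq

    tags: dict[str, TagTruth] = {}
    all_keys = sorted(set(per_parent["Syn"]) | set(per_parent["Op"]))
    for c, s, strand, pos in all_keys:
        syn = per_parent["Syn"].get((c, s, strand, pos))
        op = per_parent["Op"].get((c, s, strand, pos))
        name = chromosome_name(c, s)
        tag_id = f"{name}{strand}{pos}"
        if syn is not None and op is not None:
            n = min(len(syn), len(op))
            a, b = seq_array(syn[:n]), seq_array(op[:n])
            offsets = np.flatnonzero(a != b)
            snps = [(int(o), syn[o], op[o]) for o in offsets]
            kind = "snp" if snps else "mono"
            donor = None
        else:
            snps = []
            kind = "pav"
            donor = "Syn" if syn is not None else "Op"
        tags[tag_id] = TagTruth(
            tag_id=tag_id,
            chrom=c,
            subgenome=s,
            chrom_name=name,
            strand=strand,
            cut_pos=pos,
            cM=genetic_length_cM * pos / model.chrom_len_bp,
            syn_seq=syn,
            op_seq=op,
            snps=snps,
            kind=kind,
            donor=donor,
        )

    # nearest homeologous counterpart (same chromosome & locus, other subgenome)
    for t in tags.values():
        own = t.syn_seq or t.op_seq
        own_arr = seq_array(own)
        best = None
        for s2 in range(model.n_subgenomes):
            if s2 == t.subgenome:
                continue
            other = tags.get(f"{chromosome_name(t.chrom, s2)}{t.strand}{t.cut_pos}")
            if other is None:
                continue
            o = other.syn_seq or other.op_seq
            o_arr = seq_array(o)
            n = min(own_arr.size, o_arr.size)
            mm = int(np.count_nonzero(own_arr[:n] != o_arr[:n]))
            best = mm if best is None else min(best, mm)
        t.homeolog_mismatches = best

    return SimTruth(tags=tags, genetic_length_cM=genetic_length_cM, chrom_len_bp=model.chrom_len_bp)
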