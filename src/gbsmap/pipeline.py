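"""End-to-end pipeline orchestration with resumable on-disk artifacts.

Stages run in a fixed order — simulate, demux, build-ref, align, call,
map, anchor, report — each reading only the artifacts of its upstream
stages and writing its own under the run directory.  A manifest records
the config snapshot, seed, completed stages and output checksums, so a
run is resumable and a rerun with the same config and seed reproduces the
same artifacts byte for byte.  Everything is single-threaded and
deterministic; a ``threads`` setting is accepted for interface
compatibility and never affects results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import anchor as an
from . import genmap as gm
from . import readproc as rp
from . import refbuild as rb
from . import varcall as vc
from .config import PipelineConfig
from .enzymes import EnzymePair
from .io import read_fasta, read_fastq, write_fastq
from .simdata import (
    GenomeModel,
    QualityModel,
    framework_map,
    simulate_dh_population,
    simulate_parents,
    simulate_reads,
)

STAGES = ["simulate", "demux", "build-ref", "align", "call", "map", "anchor", "report"]
_DEPS = {s: ([] if i == 0 else [STAGES[i - 1]]) for i, s in enumerate(STAGES)}

_SIM_DEFAULTS = dict(
    n_chromosomes=2, chrom_len_bp=1_000_000, n_subgenomes=2,
    homeolog_divergence=0.03, parent_snp_rate=0.005, site_gainloss_rate=0.05,
    methylation_fraction=0.0, n_lines=92, crossover_rate=0.5, read_len=100,
    mean_depth_per_tag=1.0, error_rate=0.002, depth_sigma=1.0,
    parent_replicates=3, framework_spacing_cM=10.0, framework_missing_rate=0.05,
)


class PipelineError(RuntimeError):
    pass


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = dict(raw)
    sim = dict(_SIM_DEFAULTS)
    sim.update(cfg.get("sim") or {})
    cfg["sim"] = sim
    cfg["pipeline"] = PipelineConfig.from_dict(cfg.get("pipeline") or {})
    cfg["enzymes"] = EnzymePair(**(cfg.get("enzymes") or {}))
    cfg.setdefault("seed", 0)
    cfg.setdefault("anchor", {})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """One pipeline run rooted at an output directory."""

    def __init__(self, config: dict, outdir: str | Path, seed: int | None = None):
        self.cfg = config
        self.seed = int(config["seed"] if seed is None else seed)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()

    # -- manifest -----------------------------------------------------------

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        pcfg = self.cfg["pipeline"]
        return {
            "seed": self.seed,
            "config": {
                "sim": self.cfg["sim"],
                "pipeline": pcfg.to_dict(),
                "enzymes": dataclasses.asdict(self.cfg["enzymes"]),
            },
            "stages": {},
        }

    def _record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "completed": True,
            "seconds": round(time.time() - t0, 2),
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def completed(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        if not info or not info.get("completed"):
            return False
        return all((self.outdir / rel).exists() for rel in info["outputs"])

    def _require(self, stage: str) -> None:
        for dep in _DEPS[stage]:
            if not self.completed(dep):
                raise PipelineError(
                    f"stage '{stage}' requires completed stage '{dep}'; run '{dep}' first"
                )

    # -- stage execution ----------------------------------------------------

    def run(self, stages: list[str] | None = None, resume: bool = False) -> None:
        for stage in stages or STAGES:
            if stage not in STAGES:
                raise PipelineError(f"unknown stage '{stage}' (choose from {STAGES})")
            if resume and self.completed(stage):
                continue
            self._require(stage)
            t0 = time.time()
            outputs = getattr(self, "stage_" + stage.replace("-", "_"))()
            self._record(stage, outputs, t0)

    # -- individual stages --------------------------------------------------

    def stage_simulate(self) -> list[Path]:
        d = self.outdir / "sim"
        d.mkdir(exist_ok=True)
        sim = self.cfg["sim"]
        model = GenomeModel(
            n_chromosomes=sim["n_chromosomes"], chrom_len_bp=sim["chrom_len_bp"],
            n_subgenomes=sim["n_subgenomes"],
            homeolog_divergence=sim["homeolog_divergence"],
            parent_snp_rate=sim["parent_snp_rate"],
            site_gainloss_rate=sim["site_gainloss_rate"],
            methylation_fraction=sim["methylation_fraction"],
            seed=self.seed,
        )
        parents = simulate_parents(model, self.cfg["enzymes"])
        pop = simulate_dh_population(parents, sim["n_lines"], sim["crossover_rate"],
                                     seed=self.seed + 1)
        lib = simulate_reads(
            parents, pop, read_len=sim["read_len"],
            mean_depth_per_tag=sim["mean_depth_per_tag"],
            error_rate=sim["error_rate"], seed=self.seed + 2,
            parent_replicates=sim["parent_replicates"],
            depth_sigma=sim["depth_sigma"], quality=QualityModel(),
        )
        refmap = framework_map(pop, model, spacing_cM=sim["framework_spacing_cM"],
                               missing_rate=sim["framework_missing_rate"],
                               seed=self.seed + 3)
        lib.write_fastq(d / "reads.fastq")
        pd.DataFrame(
            [(bc, s) for s, bc in lib.barcode_of.items()], columns=["barcode", "sample"]
        ).to_csv(d / "barcodes.tsv", sep="\t", index=False)
        lib.truth.write_tsv(d / "truth.tsv")
        refmap.to_tsv(d / "refmap.tsv")
        parents.write_fasta(d / "genomes.fasta")
        roles = [
            {"sample": s, "role": "syn_parent" if s in lib.parent_samples["Syn"]
             else "op_parent" if s in lib.parent_samples["Op"] else "progeny"}
            for s in lib.samples
        ]
        pd.DataFrame(roles).to_csv(d / "samples.tsv", sep="\t", index=False)
        return [d / f for f in ("reads.fastq", "barcodes.tsv", "truth.tsv",
                                "refmap.tsv", "genomes.fasta", "samples.tsv")]

    def stage_demux(self) -> list[Path]:
        d = self.outdir / "demux"
        d.mkdir(exist_ok=True)
        bc = pd.read_csv(self.outdir / "sim/barcodes.tsv", sep="\t")
        table = rp.BarcodeTable(list(zip(bc["barcode"], bc["sample"])),
                                remnant=self.cfg["enzymes"].primary_remnant)
        result = rp.process_reads(read_fastq(self.outdir / "sim/reads.fastq"),
                                  table, self.cfg["pipeline"])
        records = []
        for sample in sorted(result.by_sample):
            for r in result.by_sample[sample]:
                records.append((f"{sample}|{r.id}", r.seq, r.qual))
        write_fastq(records, d / "assigned.fastq")
        rep = result.report.copy()
        rep.to_csv(d / "report.tsv", sep="\t", index=False)
        (d / "totals.json").write_text(json.dumps(result.report.attrs["totals"], indent=1))
        return [d / "assigned.fastq", d / "report.tsv", d / "totals.json"]

    def _load_assigned(self) -> dict[str, list[rp.Read]]:
        by_sample: dict[str, list[rp.Read]] = {}
        for rid, seq, qual in read_fastq(self.outdir / "demux/assigned.fastq"):
            sample, orig = rid.split("|", 1)
            by_sample.setdefault(sample, []).append(rp.Read(orig, seq, qual, sample))
        return by_sample

    def _roles(self) -> tuple[list[str], list[str], list[str]]:
        roles = pd.read_csv(self.outdir / "sim/samples.tsv", sep="\t")
        syn = roles.loc[roles["role"] == "syn_parent", "sample"].tolist()
        op = roles.loc[roles["role"] == "op_parent", "sample"].tolist()
        prog = roles.loc[roles["role"] == "progeny", "sample"].tolist()
        return syn, op, prog

    def stage_build_ref(self) -> list[Path]:
        d = self.outdir / "ref"
        d.mkdir(exist_ok=True)
        cfg = self.cfg["pipeline"]
        by_sample = self._load_assigned()
        syn, op, _ = self._roles()
        syn_seqs = Counter(r.seq for s in syn for r in by_sample.get(s, []))
        op_seqs = Counter(r.seq for s in op for r in by_sample.get(s, []))
        outputs = []
        for mode, identity, merge_mm in (
            ("snp", cfg.snp_identity, cfg.merge_max_mismatch),
            ("pa", cfg.pa_identity, cfg.pa_merge_max_mismatch),
        ):
            syn_clusters = rb.cluster_reads(syn_seqs, identity, parent="Syn")
            op_clusters = rb.cluster_reads(op_seqs, identity, parent="Op")
            entries = rb.merge_parental_clusters(syn_clusters, op_clusters, merge_mm)
            _write_entries(entries, d / f"{mode}_entries.tsv")
            rb.write_reference_fasta(entries, d / f"{mode}_reference.fasta")
            outputs += [d / f"{mode}_entries.tsv", d / f"{mode}_reference.fasta"]
        return outputs

    def stage_align(self) -> list[Path]:
        d = self.outdir / "align"
        d.mkdir(exist_ok=True)
        cfg = self.cfg["pipeline"]
        by_sample = self._load_assigned()
        outputs = []
        for mode, max_mm in (("snp", cfg.snp_max_mismatch), ("pa", cfg.pa_max_mismatch)):
            entries = _read_entries(self.outdir / f"ref/{mode}_entries.tsv")
            if mode == "pa":
                entries = [e for e in entries
                           if not e.is_pa_candidate
                           or max(e.syn_depth, e.op_depth) >= cfg.pa_min_parent_depth]
            index = al.ReferenceIndex(entries)
            aln = al.align_samples(by_sample, index, max_mm, cfg.min_overlap)
            al.write_alignment_tsv(aln, d / f"{mode}_alignments.tsv")
            (d / f"{mode}_stats.json").write_text(json.dumps({
                "aligned": aln.n_aligned, "unaligned": aln.n_unaligned,
                "ambiguous": aln.n_ambiguous}, indent=1))
            outputs += [d / f"{mode}_alignments.tsv", d / f"{mode}_stats.json"]
        return outputs

    def _load_alignments(self, mode: str) -> al.AlignmentSet:
        entries = _read_entries(self.outdir / f"ref/{mode}_entries.tsv")
        cfg = self.cfg["pipeline"]
        if mode == "pa":
            entries = [e for e in entries
                       if not e.is_pa_candidate
                       or max(e.syn_depth, e.op_depth) >= cfg.pa_min_parent_depth]
        index = al.ReferenceIndex(entries)
        stats = json.loads((self.outdir / f"align/{mode}_stats.json").read_text())
        df = pd.read_csv(self.outdir / f"align/{mode}_alignments.tsv", sep="\t")
        placements: dict[str, list] = {}
        samples = set()
        from .seqs import seq_array
        for row in df.itertuples():
            samples.add(row.sample)
            placements.setdefault(row.ref, []).append(
                (row.sample, seq_array(row.seq), int(row.reads), int(row.mismatches)))
        syn, op, prog = self._roles()
        samples.update(syn + op + prog)
        return al.AlignmentSet(index=index, placements=placements,
                               n_aligned=stats["aligned"], n_unaligned=stats["unaligned"],
                               n_ambiguous=stats["ambiguous"], samples=sorted(samples))

    def stage_call(self) -> list[Path]:
        d = self.outdir / "calls"
        d.mkdir(exist_ok=True)
        cfg = self.cfg["pipeline"]
        syn, op, prog = self._roles()

        snp_aln = self._load_alignments("snp")
        snp_cov = al.coverage_table(snp_aln)
        sites, audit = vc.filter_snp_sites(snp_cov, snp_aln.index.entries, syn, op,
                                           prog, cfg)

        pa_aln = self._load_alignments("pa")
        pa_cov = al.coverage_table(pa_aln)
        pa_markers = vc.call_pa_markers(pa_cov, pa_aln.index.entries, prog, cfg)
        pa_seqs = {e.ref_id: e.sequence for e in pa_aln.index.entries}
        pa_markers = vc.dedupe_pa_against_snp(pa_markers, pa_seqs, sites,
                                              snp_aln.index.entries,
                                              cfg.merge_max_mismatch)

        matrix = vc.genotype_matrix(sites, pa_markers, prog)
        matrix.to_csv(d / "genotypes.tsv", sep="\t", index=False)
        audit.to_csv(d / "snp_filter_audit.tsv", sep="\t", index=False)
        vc.write_vcf(sites, prog, d / "snps.vcf")
        # donor map for PA bin-mapping
        pd.DataFrame({"marker": [m.marker_id for m in pa_markers],
                      "donor": [m.donor for m in pa_markers]}).to_csv(
            d / "pa_donors.tsv", sep="\t", index=False)
        return [d / "genotypes.tsv", d / "snp_filter_audit.tsv", d / "snps.vcf",
                d / "pa_donors.tsv"]

    def stage_map(self) -> list[Path]:
        d = self.outdir / "map"
        d.mkdir(exist_ok=True)
        cfg = self.cfg["pipeline"]
        refmap = gm.ReferenceMap.from_tsv(self.outdir / "sim/refmap.tsv")
        matrix = pd.read_csv(self.outdir / "calls/genotypes.tsv", sep="\t")
        donors = pd.read_csv(self.outdir / "calls/pa_donors.tsv", sep="\t")
        donor_of = dict(zip(donors["marker"], donors["donor"])) if len(donors) else {}
        individuals = refmap.individuals

        assignments, statuses = [], []
        for row in matrix.itertuples():
            calls = [getattr(row, s) for s in individuals]
            if row.type == "SNP":
                res = gm.bin_map_snp(row.marker, calls, refmap, cfg)
            else:
                res = gm.bin_map_pa(row.marker, calls, donor_of.get(row.marker, "Syn"),
                                    refmap, cfg)
            if isinstance(res, str):
                statuses.append({"marker": row.marker, "type": row.type, "status": res})
            else:
                statuses.append({"marker": row.marker, "type": row.type, "status": "mapped"})
                assignments.append(res)
        frame = gm.bin_assignments_frame(assignments)
        types = {s["marker"]: s["type"] for s in statuses}
        if len(frame):
            frame.insert(1, "type", [types[m] for m in frame["marker"]])
        frame.to_csv(d / "binmap.tsv", sep="\t", index=False)
        pd.DataFrame(statuses).to_csv(d / "binmap_status.tsv", sep="\t", index=False)

        snp = matrix[matrix["type"] == "SNP"].set_index("marker")[individuals]
        denovo_input = gm.denovo_input_filter(snp, cfg)
        groups, singles = gm.build_linkage_groups(denovo_input, cfg.lod_denovo,
                                                  cfg.max_dist_cM, cfg)
        r_mat = gm.pairwise_r_matrix(denovo_input) if len(denovo_input) else None
        maps = [gm.order_group(g, r_mat, cfg) for g in groups]
        gm.denovo_map_frame(maps).to_csv(d / "denovo.tsv", sep="\t", index=False)
        pd.DataFrame({"marker": singles}).to_csv(d / "denovo_singletons.tsv",
                                                 sep="\t", index=False)
        return [d / "binmap.tsv", d / "binmap_status.tsv", d / "denovo.tsv",
                d / "denovo_singletons.tsv"]

    def stage_anchor(self) -> list[Path]:
        d = self.outdir / "anchor"
        d.mkdir(exist_ok=True)
        acfg = self.cfg.get("anchor") or {}
        contigs_path = acfg.get("contigs") or (self.outdir / "sim/genomes.fasta")
        contigs = read_fasta(contigs_path)
        binmap = pd.read_csv(self.outdir / "map/binmap.tsv", sep="\t")
        snp_entries = {e.ref_id: e for e in _read_entries(self.outdir / "ref/snp_entries.tsv")}
        pa_entries = {e.ref_id: e for e in _read_entries(self.outdir / "ref/pa_entries.tsv")}
        tags, bins = {}, {}
        for row in binmap.itertuples():
            ref_id = row.marker.rsplit("_", 2)[0] if row.type == "SNP" else row.marker.rsplit("_", 1)[0]
            entry = (snp_entries if row.type == "SNP" else pa_entries).get(ref_id)
            if entry is None:
                continue
            tags[row.marker] = entry.sequence
            bins[row.marker] = (row.chromosome, float(row.left_cM), float(row.right_cM))
        anchors = an.anchor_tags(tags, contigs,
                                 max_mismatches=int(acfg.get("max_mismatches", 0)),
                                 max_hits=int(acfg.get("max_hits", 5)), bins=bins)
        an.anchors_frame(anchors).to_csv(d / "anchors.tsv", sep="\t", index=False)
        outputs = [d / "anchors.tsv"]
        genes_path = acfg.get("genes")
        if genes_path:
            genes = an.read_genes_bed(genes_path)
            table, hist = an.gene_marker_distances(genes, anchors)
            table.to_csv(d / "gene_distances.tsv", sep="\t", index=False)
            hist.to_csv(d / "gene_distance_hist.tsv", sep="\t", index=False)
            outputs += [d / "gene_distances.tsv", d / "gene_distance_hist.tsv"]
        return outputs

    def stage_report(self) -> list[Path]:
        d = self.outdir / "report"
        d.mkdir(exist_ok=True)
        binmap = pd.read_csv(self.outdir / "map/binmap.tsv", sep="\t")
        matrix = pd.read_csv(self.outdir / "calls/genotypes.tsv", sep="\t")
        meta_cols = ["marker", "type", "alleles"]
        individuals = [c for c in matrix.columns if c not in meta_cols]

        per_chrom = (binmap.groupby(["chromosome", "type"]).size()
                     .rename("markers").reset_index()) if len(binmap) else \
            pd.DataFrame(columns=["chromosome", "type", "markers"])
        per_chrom.to_csv(d / "markers_per_chromosome.tsv", sep="\t", index=False)

        vals = matrix[individuals].to_numpy()
        miss = (vals == "-").sum(axis=1) / max(len(individuals), 1)
        missing = pd.DataFrame({"marker": matrix["marker"], "type": matrix["type"],
                                "missing_frac": miss.round(4)})
        missing.to_csv(d / "missing_distribution.tsv", sep="\t", index=False)

        denovo = pd.read_csv(self.outdir / "map/denovo.tsv", sep="\t")
        if len(denovo):
            lengths = denovo.groupby("group")["cM"].max().rename("length_cM").reset_index()
            sizes = denovo.groupby("group").size().rename("markers").reset_index()
            lengths = lengths.merge(sizes, on="group")
        else:
            lengths = pd.DataFrame(columns=["group", "length_cM", "markers"])
        lengths.to_csv(d / "map_lengths.tsv", sep="\t", index=False)

        summary = {
            "markers_total": int(len(matrix)),
            "markers_snp": int((matrix["type"] == "SNP").sum()),
            "markers_pa": int((matrix["type"] == "PA").sum()),
            "markers_mapped": int(len(binmap)),
            "denovo_groups": int(denovo["group"].nunique()) if len(denovo) else 0,
            "mean_missing_frac": float(np.round(miss.mean(), 4)) if len(matrix) else 0.0,
        }
        (d / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return [d / "markers_per_chromosome.tsv", d / "missing_distribution.tsv",
                d / "map_lengths.tsv", d / "summary.json"]


def _write_entries(entries: list[rb.ReferenceEntry], path: Path) -> None:
    rows = []
    for e in entries:
        rows.append({"ref_id": e.ref_id, "source": e.source, "sequence": e.sequence,
                     "syn_rep": e.syn_rep or "", "op_rep": e.op_rep or "",
                     "variant_offsets": ",".join(map(str, e.variant_offsets)),
                     "syn_depth": e.syn_depth, "op_depth": e.op_depth})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_entries(path: Path) -> list[rb.ReferenceEntry]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = []
    for row in df.itertuples():
        offsets = [int(x) for x in str(row.variant_offsets).split(",") if x not in ("", "nan")]
        entries.append(rb.ReferenceEntry(
            ref_id=row.ref_id, sequence=row.sequence, source=row.source,
            syn_rep=row.syn_rep or None, op_rep=row.op_rep or None,
            variant_offsets=offsets, syn_depth=int(row.syn_depth),
            op_depth=int(row.op_depth)))
    return entries


def library_overlap(seqs_a: list[str], seqs_b: list[str], identity: float = 0.96) -> float:
    """Fraction of library-A tag sequences highly similar to any in library B.

    Used to report marker redundancy between libraries built with different
    enzyme pairs; comparison is end-anchored identity over the shorter
    sequence, as elsewhere in the pipeline.
    """
    if not seqs_a or not seqs_b:
        return 0.0
    from .seqs import PaddedSeqMatrix, seq_array

    mat = PaddedSeqMatrix.from_sequences(seqs_b)
    hits = 0
    for s in seqs_a:
        mm, ov = mat.prefix_mismatches(seq_array(s))
        allowed = np.floor((1.0 - identity) * ov + 1e-9)
        if np.any(mm <= allowed):
            hits += 1
    return hits / len(seqs_a)
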