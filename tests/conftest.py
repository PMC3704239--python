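"""Shared fixtures: tiny simulated libraries and hand-built call matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gbsmap.config import PipelineConfig
from gbsmap.enzymes import EnzymePair
from gbsmap.simdata import (
    GenomeModel,
    ParentGenomes,
    simulate_dh_population,
    simulate_parents,
)


def make_parents(
    syn: dict[tuple[int, int], str],
    op: dict[tuple[int, int], str] | None = None,
    enzymes: EnzymePair | None = None,
    **model_kwargs,
) -> ParentGenomes:
    """Hand-built parental genomes from explicit sequences.

    ``syn``/``op`` map (chromosome, subgenome) to sequence; ``op`` defaults
    to a copy of ``syn``.  Lets tests plant cut sites and variants exactly
    where they need them.
    """
    op = op or dict(syn)
    lengths = {len(s) for s in syn.values()} | {len(s) for s in op.values()}
    assert len(lengths) == 1, "all chromosomes must share one length"
    chroms = sorted({c for c, _ in syn})
    subs = sorted({s for _, s in syn})
    model = GenomeModel(
        n_chromosomes=len(chroms),
        chrom_len_bp=lengths.pop(),
        n_subgenomes=len(subs),
        **model_kwargs,
    )
    enzymes = enzymes or EnzymePair()
    sequences = {key: {"Syn": syn[key], "Op": op[key]} for key in syn}
    return ParentGenomes(model, enzymes, sequences,
                         {k: set() for k in syn}, {k: set() for k in syn})


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def tiny_parents() -> ParentGenomes:
    """A 1-chromosome, 2-subgenome genome small enough for per-test runs."""
    model = GenomeModel(n_chromosomes=1, chrom_len_bp=60_000, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_parents(model)


@pytest.fixture(scope="session")
def tiny_population(tiny_parents):
    return simulate_dh_population(tiny_parents, 16, crossover_rate=0.5, seed=12)


@pytest.fixture()
def default_config() -> PipelineConfig:
    return PipelineConfig()


# ---------------------------------------------------------------------------
# hand-built coverage fixture exercising every SNP post-filter


class HandBuiltCalls:
    """A small coverage table built read-by-read, with hand-computed truth.

    Ten progeny (p01..p10) plus two replicate samples per parent.  Seven
    single-offset sites are laid out so that exactly one site trips each of
    the five filters and two sites survive.  Sites are evaluated with a
    state-support threshold of 3 samples, so a base must be seen in three
    samples to count as an allelic state.  Expected outcomes are written
    down next to the construction, not derived from the code under test.
    """

    PROGENY = [f"p{i:02d}" for i in range(1, 11)]
    SYN = ["Syn1", "Syn2"]
    OP = ["Op1", "Op2"]
    MIN_STATE_SUPPORT = 3

    def __init__(self):
        from gbsmap.align import AlignmentSet, ReferenceIndex
        from gbsmap.refbuild import ReferenceEntry
        from gbsmap.seqs import seq_array

        L = 40
        base = ("ACGT" * 10)[:L]

        def variant(b, off=10):
            return base[:off] + b + base[off + 1 :]

        syn_A = {"Syn1": [("A", 2)], "Syn2": [("A", 2)]}
        op_C = {"Op1": [("C", 2)], "Op2": [("C", 2)]}

        self.sites = {
            # filter 1: three states, each seen in >=3 samples
            "multi": {**syn_A, **op_C, "p01": [("A", 2)], "p02": [("C", 2)],
                      "p03": [("G", 2)], "p04": [("G", 1)], "p05": [("G", 1)]},
            # filter 2: both parents homozygous for the same base
            "sameparent": {"Syn1": [("A", 2)], "Syn2": [("A", 2)],
                           "Op1": [("A", 2)], "Op2": [("A", 2)],
                           **{p: [("A", 1)] for p in self.PROGENY[:5]},
                           **{p: [("C", 1)] for p in self.PROGENY[5:]}},
            # filter 3: three progeny carry non-parental singleton bases
            # (3/10 >= 25%); G is seen in only two samples, T in one, so
            # neither becomes a state
            "nonparental": {**syn_A, **op_C,
                            "p01": [("G", 1)], "p02": [("G", 1)], "p03": [("T", 1)],
                            **{p: [("A", 1)] for p in ("p04", "p05", "p06")},
                            **{p: [("C", 1)] for p in ("p07", "p08", "p09", "p10")}},
            # filter 4: only two progeny have reads (8/10 missing >= 80%)
            "missing": {**syn_A, **op_C, "p01": [("A", 2)], "p02": [("C", 2)]},
            # filter 5: clean homozygous parents, but every progeny carrier
            # sees a persistent ~1/2 depth split (paralog artifact pattern)
            "ratio": {"Syn1": [("A", 15)], "Syn2": [("A", 15)],
                      "Op1": [("C", 15)], "Op2": [("C", 15)],
                      **{p: [("A", 6), ("C", 6)] for p in self.PROGENY}},
            # retained: clean single-copy site, 5 B lines / 4 A lines / 1 missing
            "clean": {**syn_A, **op_C,
                      **{p: [("A", 1)] for p in self.PROGENY[:5]},
                      **{p: [("C", 1)] for p in ("p06", "p07", "p08", "p09")}},
            # retained with one non-parental progeny (1/10 < 25% -> missing)
            "tolerated": {**syn_A, **op_C, "p01": [("G", 1)],
                          **{p: [("A", 1)] for p in ("p02", "p03", "p04", "p05")},
                          **{p: [("C", 1)] for p in ("p06", "p07", "p08", "p09")}},
        }
        # hand-computed expectations (site name -> audit stage)
        self.expected_drop = {
            "multi": "multi_state",
            "sameparent": "parents_not_polymorphic",
            "nonparental": "nonparental",
            "missing": "missing",
            "ratio": "allele_ratio",
        }
        self.expected_retained = {"clean", "tolerated"}
        # "clean": Syn allele is A, so A-readers are B; p10 has no reads
        self.expected_clean_calls = dict(
            **{p: "B" for p in self.PROGENY[:5]},
            **{p: "A" for p in ("p06", "p07", "p08", "p09")},
            p10="-",
        )

        entries = []
        placements = {}
        for k, name in enumerate(sorted(self.sites)):
            e = ReferenceEntry(ref_id=f"site_{name}", sequence=base, source="merged",
                               syn_rep=variant("A"), op_rep=base,
                               variant_offsets=[10])
            entries.append(e)
            placed = []
            for sample, obs in sorted(self.sites[name].items()):
                for b, n in obs:
                    placed.append((sample, seq_array(variant(b)), n, 1))
            placements[e.ref_id] = placed
        index = ReferenceIndex(entries)
        n_reads = sum(n for placed in placements.values() for _, _, n, _ in placed)
        self.alignments = AlignmentSet(
            index=index, placements=placements, n_aligned=n_reads,
            n_unaligned=0, n_ambiguous=0,
            samples=self.SYN + self.OP + self.PROGENY,
        )
        self.entries = entries
        self.config = PipelineConfig(max_nonparental_frac=0.25)


@pytest.fixture(scope="session")
def hand_built_calls() -> HandBuiltCalls:
    return HandBuiltCalls()


# ---------------------------------------------------------------------------
# the full parameter-recovery run (simulate -> map at study conditions)


class RecoveryRun:
    """Pipeline run on the toy allopolyploid study design, with truth."""

    SIM = dict(n_chromosomes=2, chrom_len_bp=1_000_000, n_subgenomes=2,
               homeolog_divergence=0.03, parent_snp_rate=0.005,
               site_gainloss_rate=0.05, n_lines=92, mean_depth_per_tag=1.0,
               error_rate=0.002)
    SEED = 1

    def __init__(self, outdir):
        import pandas as pd

        from gbsmap.pipeline import Run, _read_entries
        from gbsmap.simdata import build_truth

        cfg = {"seed": self.SEED, "sim": dict(self.SIM),
               "pipeline": PipelineConfig(), "enzymes": EnzymePair(), "anchor": {}}
        from gbsmap.pipeline import _SIM_DEFAULTS

        sim = dict(_SIM_DEFAULTS)
        sim.update(cfg["sim"])
        cfg["sim"] = sim
        self.run = Run(cfg, outdir)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.run.run(["simulate", "demux", "build-ref", "align", "call", "map"])
            model = GenomeModel(seed=self.SEED, **{k: sim[k] for k in (
                "n_chromosomes", "chrom_len_bp", "n_subgenomes",
                "homeolog_divergence", "parent_snp_rate", "site_gainloss_rate")})
            parents = simulate_parents(model, cfg["enzymes"])
            pop = simulate_dh_population(parents, sim["n_lines"],
                                         sim["crossover_rate"], seed=self.SEED + 1)
            self.truth = build_truth(parents, genetic_length_cM=pop.genetic_length_cM)
        self.population = pop
        out = self.run.outdir
        self.snp_entries = {e.ref_id: e for e in _read_entries(out / "ref/snp_entries.tsv")}
        self.pa_entries = {e.ref_id: e for e in _read_entries(out / "ref/pa_entries.tsv")}
        self.binmap = pd.read_csv(out / "map/binmap.tsv", sep="\t")
        self.matrix = pd.read_csv(out / "calls/genotypes.tsv", sep="\t").set_index("marker")
        self.denovo = pd.read_csv(out / "map/denovo.tsv", sep="\t")
        self.denovo_singletons = pd.read_csv(out / "map/denovo_singletons.tsv", sep="\t")

    def attribute(self, marker: str, mtype: str):
        """Truth tag for a mapped marker (None when not attributable)."""
        if mtype == "SNP":
            ref, off, _ = marker.rsplit("_", 2)
            e = self.snp_entries[ref]
            a_syn, a_op = self.matrix.loc[marker, "alleles"].split("/")
            return self.truth.match_snp_marker(e.syn_rep, e.op_rep, int(off), a_syn, a_op)
        ref = marker.rsplit("_", 1)[0]
        return self.truth.match_sequence(self.pa_entries[ref].sequence)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory) -> RecoveryRun:
    return RecoveryRun(tmp_path_factory.mktemp("recovery"))
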