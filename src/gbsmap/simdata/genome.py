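"""Synthetic allopolyploid parental genomes.

The simulator emulates the genome structure a polyploid GBS pipeline has to
cope with: two (or more) homeologous subgenomes a few percent diverged from
each other, two parental haplotypes differing by SNPs within each
subgenome, and restriction-site gain/loss between the parents which drives
presence/absence variation.  Each ``(chromosome, subgenome)`` pair behaves
as an independent genetic chromosome and is named in the wheat style
("1A", "1B", "2A", ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..enzymes import EnzymePair
from ..seqs import array_seq, find_site_positions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeModel:
    """Parameters of the simulated allopolyploid genome.

    Rates are per-site probabilities.  ``homeolog_divergence`` is the
    divergence of every additional subgenome from the first; with the
    default 96% clustering identity, divergence below ~4% makes homeologous
    tags collapse onto a single reference cluster, which is the mechanism
    the collapsed-homeolog allele-ratio filter exists for.
    """

    n_chromosomes: int = 2
    chrom_len_bp: int = 1_000_000
    n_subgenomes: int = 2
    homeolog_divergence: float = 0.03
    parent_snp_rate: float = 0.005
    site_gainloss_rate: float = 0.05
    methylation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("homeolog_divergence", "parent_snp_rate",
                     "site_gainloss_rate", "methylation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_subgenomes < 1:
            raise ValueError("n_subgenomes must be >= 1")
        if self.chrom_len_bp <= 0 or self.n_chromosomes <= 0:
            raise ValueError("chromosome count and length must be positive")


def chromosome_name(chrom: int, subgenome: int) -> str:
    """Wheat-style genetic chromosome label, e.g. (0, 1) -> '1B'."""
    return f"{chrom + 1}{chr(ord('A') + subgenome)}"


@dataclass
class ParentGenomes:
    """The two simulated parental genomes plus masking metadata.

    ``sequences[(c, s)]`` maps parent name ('Syn' or 'Op') to the sequence
    of chromosome ``c`` in subgenome ``s``.  Methylation masks are assigned
    to site positions once per locus and shared by both parents and all
    progeny (methylation state is treated as heritable and stable).
    """

    model: GenomeModel
    enzymes: EnzymePair
    sequences: dict[tuple[int, int], dict[str, str]]
    masked_primary: dict[tuple[int, int], set[int]] = field(default_factory=dict)
    masked_secondary: dict[tuple[int, int], set[int]] = field(default_factory=dict)

    @property
    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.sequences)

    def write_fasta(self, path) -> None:
        from ..io import write_fasta

        records = []
        for (c, s), seqs in sorted(self.sequences.items()):
            for parent, seq in sorted(seqs.items()):
                records.append((f"{parent}_{chromosome_name(c, s)}", seq))
        write_fasta(records, path)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a ``rate`` fraction of sites with a different base."""
    out = seq.copy()
    if rate <= 0:
        return out
    pos = np.flatnonzero(rng.random(seq.size) < rate)
    if pos.size:
        # shift each hit by 1-3 positions in base space: always a change
        idx = np.searchsorted(_BASES, out[pos])
        out[pos] = _BASES[(idx + rng.integers(1, 4, size=pos.size)) % 4]
    return out


def simulate_parents(model: GenomeModel, enzymes: EnzymePair | None = None) -> ParentGenomes:
    """Generate the two parental genomes ('Syn' and 'Op').

    For each chromosome an ancestral sequence is drawn; subgenome copies
    beyond the first diverge from it at ``homeolog_divergence``; within each
    subgenome the Op parent diverges from Syn at ``parent_snp_rate``; and a
    ``site_gainloss_rate`` fraction of primary recognition sites are then
    knocked out in one randomly chosen parent (one substitution inside the
    site), creating presence/absence loci.  Deterministic given
    ``model.seed``.
    """
    enzymes = enzymes or EnzymePair()
    if 0.0 < model.homeolog_divergence < 0.04 and model.n_subgenomes > 1:
        warnings.warn(
            "homeolog divergence below ~4%: homeologous tags will co-cluster "
            "at the default 96% identity threshold (collapsed-homeolog regime)",
            stacklevel=2,
        )
    rng = np.random.default_rng(model.seed)
    sequences: dict[tuple[int, int], dict[str, str]] = {}
    masked_p: dict[tuple[int, int], set[int]] = {}
    masked_s: dict[tuple[int, int], set[int]] = {}

    for c in range(model.n_chromosomes):
        ancestral = _BASES[rng.integers(0, 4, size=model.chrom_len_bp)]
        for s in range(model.n_subgenomes):
            sub = ancestral if s == 0 else _mutate(ancestral, model.homeolog_divergence, rng)
            syn = sub.copy()
            op = _mutate(syn, model.parent_snp_rate, rng)

            # restriction-site gain/loss: knock out a fraction of primary
            # sites in exactly one parent each
            both = {"Syn": syn, "Op": op}
            site_positions = sorted(
                set(find_site_positions(array_seq(syn), enzymes.primary_site))
                | set(find_site_positions(array_seq(op), enzymes.primary_site))
            )
            for p in site_positions:
                if rng.random() < model.site_gainloss_rate:
                    victim = both["Syn" if rng.random() < 0.5 else "Op"]
                    off = int(rng.integers(0, len(enzymes.primary_site)))
                    idx = np.searchsorted(_BASES, victim[p + off])
                    victim[p + off] = _BASES[(idx + int(rng.integers(1, 4))) % 4]

            sequences[(c, s)] = {"Syn": array_seq(syn), "Op": array_seq(op)}

            # methylation masks over the union of parental site positions
            mp: set[int] = set()
            ms: set[int] = set()
            if model.methylation_fraction > 0:
                union_p = sorted(
                    set(find_site_positions(sequences[(c, s)]["Syn"], enzymes.primary_site))
                    | set(find_site_positions(sequences[(c, s)]["Op"], enzymes.primary_site))
                )
                mp = {p for p in union_p if rng.random() < model.methylation_fraction}
                union_s = sorted(
                    set(find_site_positions(sequences[(c, s)]["Syn"], enzymes.secondary_site))
                    | set(find_site_positions(sequences[(c, s)]["Op"], enzymes.secondary_site))
                )
                ms = {p for p in union_s if rng.random() < model.methylation_fraction}
            masked_p[(c, s)] = mp if enzymes.methylation_sensitive_primary else set()
            masked_s[(c, s)] = ms if enzymes.methylation_sensitive_secondary else set()

    return ParentGenomes(model, enzymes, sequences, masked_p, masked_s)
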