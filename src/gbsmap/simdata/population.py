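"""Doubled-haploid progeny simulation.

A DH line is a single recombinant gamete with its chromosomes doubled, so
every line is fully homozygous and one meiosis separates it from the F1.
Crossovers per chromosome are Poisson distributed with uniform breakpoints
and no interference, which makes map distance Haldane by construction:
loci ``d`` Morgans apart recombine with probability ``(1 - exp(-2d)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel, ParentGenomes, chromosome_name

PARENTS = ("Syn", "Op")


@dataclass
class DHLine:
    """One doubled-haploid line: parental-origin segments per chromosome.

    ``segments[(c, s)]`` is a list of ``(start_bp, end_bp, parent_index)``
    half-open segments tiling the chromosome; parent 0 is Syn, 1 is Op.
    Homozygosity is structural: there is only one haplotype to carry.
    """

    line_id: str
    segments: dict[tuple[int, int], list[tuple[int, int, int]]]
    phenotype: dict[str, str] = field(default_factory=dict)

    def origin_at(self, chrom: int, subgenome: int, pos: int) -> int:
        """Parent index (0=Syn, 1=Op) at a physical position."""
        for start, end, parent in self.segments[(chrom, subgenome)]:
            if start <= pos < end:
                return parent
        raise ValueError(f"position {pos} outside chromosome {chromosome_name(chrom, subgenome)}")

    def origins_at(self, chrom: int, subgenome: int, positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`origin_at` for sorted or unsorted positions."""
        segs = self.segments[(chrom, subgenome)]
        starts = np.array([s for s, _, _ in segs])
        parents = np.array([p for _, _, p in segs])
        idx = np.searchsorted(starts, positions, side="right") - 1
        return parents[idx]


@dataclass
class DHPopulation:
    """A list of DH lines plus the meiosis parameters that produced them."""

    lines: list[DHLine]
    crossover_rate: float
    chrom_len_bp: int

    def __iter__(self):
        return iter(self.lines)

    def __len__(self):
        return len(self.lines)

    def __getitem__(self, i):
        return self.lines[i]

    @property
    def genetic_length_cM(self) -> float:
        """Expected map length of each chromosome: 100 cM per crossover."""
        return 100.0 * self.crossover_rate


def simulate_dh_population(
    parents: ParentGenomes | GenomeModel,
    n_lines: int,
    crossover_rate: float = 0.5,
    seed: int = 0,
) -> DHPopulation:
    """Simulate ``n_lines`` doubled-haploid progeny of the Syn x Op cross.

    ``crossover_rate`` is the expected number of crossovers per chromosome
    per transmitted gamete.  The default of 0.5 corresponds to one chiasma
    per bivalent shared between two of the four chromatids — the textbook
    minimum for regular segregation — giving 50 cM toy chromosomes.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    model = parents.model if isinstance(parents, ParentGenomes) else parents
    rng = np.random.default_rng(seed)
    length = model.chrom_len_bp
    lines = []
    for i in range(n_lines):
        segments: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
        for c in range(model.n_chromosomes):
            for s in range(model.n_subgenomes):
                n_co = rng.poisson(crossover_rate)
                breaks = np.sort(rng.integers(1, length, size=n_co))
                parent = int(rng.integers(0, 2))
                segs = []
                prev = 0
                for b in breaks.tolist() + [length]:
                    if b > prev:
                        segs.append((prev, b, parent))
                        prev = b
                    parent = 1 - parent
                # merge zero-length crossover artefacts (coincident breaks)
                merged = [segs[0]]
                for seg in segs[1:]:
                    if seg[2] == merged[-1][2]:
                        merged[-1] = (merged[-1][0], seg[1], seg[2])
                    else:
                        merged.append(seg)
                segments[(c, s)] = merged
        lines.append(DHLine(line_id=f"DH{i + 1:03d}", segments=segments))
    return DHPopulation(lines, crossover_rate, length)


def assign_seed_color(
    population: DHPopulation,
    locus1: tuple[int, int, int],
    locus2: tuple[int, int, int],
) -> None:
    """Score the two-locus complementary seed-color phenotype in place.

    Both parents carry a dominant red allele at one of two unlinked loci, so
    a line is white only with the fixed two-locus combination: the Syn
    allele at ``locus1`` and the Op allele at ``locus2`` (each locus given
    as ``(chrom, subgenome, pos)``).  Expected segregation is 3 red : 1
    white.
    """
    for line in population:
        white = (
            line.origin_at(*locus1) == 0  # Syn allele at the first locus
            and line.origin_at(*locus2) == 1  # Op allele at the second
        )
        line.phenotype["seed_color"] = "white" if white else "red"
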