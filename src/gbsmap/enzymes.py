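"""Restriction enzyme pair configuration for complexity-reduced libraries.

A GBS library is built with a rare-cutting primary enzyme (PstI by default)
paired with a second, more frequent cutter.  Sequenced fragments carry the
primary cut-site remnant at the read start, which is what anchors every
downstream comparison in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

_DNA = set("ACGT")


@dataclass(frozen=True)
class EnzymePair:
    """A primary/secondary restriction enzyme combination.

    Attributes
    ----------
    primary_site:
        Recognition sequence of the primary (tag-defining) enzyme.
    primary_remnant:
        Sequence left at the start of a read after the primary cut and
        adapter ligation (PstI leaves ``TGCAG``).
    secondary_site:
        Recognition sequence of the second enzyme.  The default follows the
        printed MseI string ``AATT``; the enzyme's canonical site is TTAA,
        and the field is plain configuration, so either can be used.
    methylation_sensitive_primary / methylation_sensitive_secondary:
        Whether cut sites of each enzyme are blocked by methylation.
    min_fragment_bp / max_fragment_bp:
        Size-selection window; only fragments inside it are sequenced.
    primary_cut_offset / secondary_cut_offset:
        Offset of the cut within the recognition site (bases retained on the
        upstream side).  Strand-symmetric cutting is assumed; no further
        overhang chemistry is modelled beyond the remnant string.
    """

    primary_site: str = "CTGCAG"
    primary_remnant: str = "TGCAG"
    secondary_site: str = "AATT"
    methylation_sensitive_primary: bool = True
    methylation_sensitive_secondary: bool = False
    min_fragment_bp: int = 30
    max_fragment_bp: int = 1000
    primary_cut_offset: int = 1
    secondary_cut_offset: int = 1

    def __post_init__(self):
        for name in ("primary_site", "secondary_site"):
            site = getattr(self, name)
            if not site or not set(site) <= _DNA:
                raise ValueError(f"{name} must be a nonempty string over ACGT, got {site!r}")
        if not self.min_fragment_bp < self.max_fragment_bp:
            raise ValueError("min_fragment_bp must be smaller than max_fragment_bp")
        if not 0 <= self.primary_cut_offset <= len(self.primary_site):
            raise ValueError("primary_cut_offset outside recognition site")
        if not 0 <= self.secondary_cut_offset <= len(self.secondary_site):
            raise ValueError("secondary_cut_offset outside recognition site")


#: PstI + MseI (printed site), the main library design.
PSTI_MSEI = EnzymePair()

#: PstI + MluI, both methylation sensitive.
PSTI_MLUI = EnzymePair(secondary_site="ACGCGT", methylation_sensitive_secondary=True)

#: PstI + MspI, used for externally generated libraries.
PSTI_MSPI = EnzymePair(secondary_site="CCGG")
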