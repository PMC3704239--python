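"""Framework reference maps derived from simulator ground truth.

Bin-mapping needs a trusted, ordered framework map (in real data it comes
from an independent marker platform).  For simulations the equivalent is a
set of evenly spaced framework loci whose genotypes are read directly off
each line's true parental-origin segments, optionally thinned with missing
data to mimic a real genotyping assay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genmap import ReferenceMap
from .genome import GenomeModel, chromosome_name
from .population import DHPopulation


def framework_map(
    population: DHPopulation,
    model: GenomeModel,
    spacing_cM: float = 10.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> ReferenceMap:
    """Build a framework map with markers every ``spacing_cM``.

    Framework genotypes are true parental origins ('B' for Syn, 'A' for
    Op); a ``missing_rate`` fraction of calls is masked at random to mimic
    platform dropout.  Spacing is a resolution choice: with ~100 lines each
    framework bin should contain several observable recombination events,
    so bins much narrower than a few cM cannot be told apart.
    """
    rng = np.random.default_rng(seed)
    length_cM = population.genetic_length_cM
    L = population.chrom_len_bp
    rows = []
    line_ids = [ln.line_id for ln in population]
    n_marks = max(2, int(round(length_cM / spacing_cM)) + 1)
    cms = np.linspace(0.0, length_cM, n_marks)
    for c in range(model.n_chromosomes):
        for s in range(model.n_subgenomes):
            name = chromosome_name(c, s)
            positions = np.minimum((cms / length_cM * L).astype(int), L - 1)
            for cm, pos in zip(cms, positions):
                calls = []
                for ln in population:
                    if missing_rate > 0 and rng.random() < missing_rate:
                        calls.append("-")
                    else:
                        calls.append("B" if ln.origin_at(c, s, int(pos)) == 0 else "A")
                rows.append({"marker": f"F{name}_{cm:g}", "chromosome": name,
                             "cM": float(cm), **dict(zip(line_ids, calls))})
    return ReferenceMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cM", *line_ids]))
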